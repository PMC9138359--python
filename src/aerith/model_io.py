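"""Model input/output and deletion-candidate classification.

Two dialects are supported, BiGG JSON and SBML Level 3 + FBC, both read and
written through cobrapy (libsbml underneath).  On load every reaction is
assigned a structural :class:`~aerith.model.ReactionCategory`:

* exchange — single-metabolite boundary reaction;
* transport — the same chemical species (compartment suffix stripped)
  appears on both sides in different compartments;
* abc_transport / pts — transport systems that remain knockout-accessible
  (ABC transporters with a gene association, phosphotransferase reactions),
  recognised by subsystem/name/id annotation with user-overridable id lists;
* biomass / atp_maintenance — the growth and maintenance pseudo-reactions;
* internal — everything else.

Deletion candidates are all internal reactions plus gene-associated ABC
transporters plus PTS reactions; exchanges, plain transporters, biomass and
ATP maintenance are never candidates.
"""

from __future__ import annotations

import json
import re
from pathlib import Path

from .errors import ModelFormatError
from .model import MetabolicModel, Metabolite, Reaction, ReactionCategory

#: trailing BiGG-style compartment tag, e.g. glc__D_e -> glc__D
DEFAULT_COMPARTMENT_SUFFIX = re.compile(r"_([a-z][a-z0-9]?)$")

_ABC_PATTERN = re.compile(r"\babc\b|abc transporter|atp-binding cassette", re.IGNORECASE)
_PTS_PATTERN = re.compile(r"phosphotransferase|\bpts\b", re.IGNORECASE)


def _base_species(met_id: str, suffix_re: re.Pattern = DEFAULT_COMPARTMENT_SUFFIX) -> str:
    return suffix_re.sub("", met_id)


def assign_categories(
    model: MetabolicModel,
    *,
    abc_ids: set[str] | None = None,
    pts_ids: set[str] | None = None,
    compartment_suffix: re.Pattern = DEFAULT_COMPARTMENT_SUFFIX,
) -> None:
    """Assign a ReactionCategory to every reaction in place.

    ``abc_ids`` / ``pts_ids`` force the respective category for listed ids,
    overriding the annotation heuristics (model annotations vary by dialect).
    """
    abc_ids = abc_ids or set()
    pts_ids = pts_ids or set()
    met_comp = {m.id: m.compartment for m in model.metabolites}
    for rxn in model.reactions:
        if rxn.id == model.biomass_reaction_id:
            rxn.category = ReactionCategory.BIOMASS
            continue
        if rxn.id == model.atp_maintenance_id:
            rxn.category = ReactionCategory.ATP_MAINTENANCE
            continue
        annot = f"{rxn.id} {rxn.name} {rxn.subsystem}"
        if rxn.id in pts_ids or _PTS_PATTERN.search(annot):
            rxn.category = ReactionCategory.PTS
            continue
        if len(rxn.stoichiometry) == 1:
            rxn.category = ReactionCategory.EXCHANGE
            continue
        # transport: same base species present in two different compartments
        is_transport = False
        by_species: dict[str, set[str]] = {}
        for mid in rxn.stoichiometry:
            comp = met_comp.get(mid, "")
            by_species.setdefault(_base_species(mid, compartment_suffix), set()).add(comp)
        if any(len(comps) > 1 for comps in by_species.values()):
            is_transport = True
        if rxn.id in abc_ids or (is_transport and _ABC_PATTERN.search(annot)):
            rxn.category = ReactionCategory.ABC_TRANSPORT
        elif is_transport:
            rxn.category = ReactionCategory.TRANSPORT
        else:
            rxn.category = ReactionCategory.INTERNAL


# ---------------------------------------------------------------------------
# cobra conversion layer
# ---------------------------------------------------------------------------


def _detect_biomass(cobra_model) -> str | None:
    objective = [r.id for r in cobra_model.reactions if r.objective_coefficient]
    if len(objective) == 1:
        return objective[0]
    biomass_like = [r.id for r in cobra_model.reactions if "biomass" in r.id.lower()]
    if len(biomass_like) >= 1:
        # prefer the model's flagged core biomass if several are present
        core = [rid for rid in biomass_like if "core" in rid.lower()]
        return sorted(core or biomass_like)[0]
    return None


def _detect_anchor(cobra_model, preferred: list[str], substring: str) -> str | None:
    ids = {r.id for r in cobra_model.reactions}
    for rid in preferred:
        if rid in ids:
            return rid
    hits = sorted(rid for rid in ids if rid.startswith("EX_") and substring in rid.lower())
    return hits[0] if hits else None


def model_from_cobra(
    cobra_model,
    *,
    biomass_reaction_id: str | None = None,
    glucose_exchange_id: str | None = None,
    oxygen_exchange_id: str | None = None,
    atp_maintenance_id: str | None = None,
    abc_ids: set[str] | None = None,
    pts_ids: set[str] | None = None,
) -> MetabolicModel:
    """Convert a cobra.Model into a MetabolicModel and classify its reactions."""
    used = {m.id for r in cobra_model.reactions for m in r.metabolites}
    metabolites = [
        Metabolite(id=m.id, compartment=str(m.compartment or ""), name=m.name or "")
        for m in cobra_model.metabolites
        if m.id in used  # drop orphan rows so S has no all-zero metabolite rows
    ]
    reactions = [
        Reaction(
            id=r.id,
            stoichiometry={m.id: float(c) for m, c in r.metabolites.items()},
            lower_bound=float(r.lower_bound),
            upper_bound=float(r.upper_bound),
            has_gpr=bool(r.gene_reaction_rule.strip()),
            name=r.name or "",
            subsystem=r.subsystem or "",
        )
        for r in cobra_model.reactions
    ]
    biomass = biomass_reaction_id or _detect_biomass(cobra_model)
    if biomass is None:
        raise ModelFormatError(
            "could not detect an objective (biomass) reaction; "
            "pass biomass_reaction_id explicitly"
        )
    model = MetabolicModel(
        metabolites=metabolites,
        reactions=reactions,
        biomass_reaction_id=biomass,
        glucose_exchange_id=glucose_exchange_id
        or _detect_anchor(cobra_model, ["EX_glc__D_e", "EX_glc_e"], "glc"),
        oxygen_exchange_id=oxygen_exchange_id
        or _detect_anchor(cobra_model, ["EX_o2_e"], "o2"),
        atp_maintenance_id=atp_maintenance_id
        or next((r.id for r in cobra_model.reactions if r.id in ("ATPM", "ATPM_NGAM")), None),
        id=cobra_model.id or "model",
    )
    assign_categories(model, abc_ids=abc_ids, pts_ids=pts_ids)
    model.validate()
    return model


def model_to_cobra(model: MetabolicModel):
    """Convert back to a cobra.Model (objective = biomass)."""
    import cobra

    cm = cobra.Model(model.id)
    comps = {m.id: m.compartment for m in model.metabolites}
    cmets = {}
    for m in model.metabolites:
        cmet = cobra.Metabolite(m.id, name=m.name, compartment=m.compartment)
        cmets[m.id] = cmet
    cm.add_metabolites(list(cmets.values()))
    crxns = []
    for r in model.reactions:
        cr = cobra.Reaction(r.id, name=r.name, lower_bound=r.lower_bound, upper_bound=r.upper_bound)
        cr.subsystem = r.subsystem
        crxns.append(cr)
    cm.add_reactions(crxns)
    for r in model.reactions:
        cm.reactions.get_by_id(r.id).add_metabolites(
            {cmets[mid]: coeff for mid, coeff in r.stoichiometry.items()}
        )
        if r.has_gpr:
            cm.reactions.get_by_id(r.id).gene_reaction_rule = f"g_{r.id}"
    cm.objective = model.biomass_reaction_id
    del comps
    return cm


def load_model_from_dict(d: dict, **kwargs) -> MetabolicModel:
    """Build a MetabolicModel from a BiGG-JSON-schema dict (cobra underneath)."""
    from cobra.io.dict import model_from_dict as cobra_from_dict

    for rxn in d.get("reactions", []):
        lb, ub = rxn.get("lower_bound", 0.0), rxn.get("upper_bound", 0.0)
        if lb > ub:
            raise ModelFormatError(
                f"reaction {rxn.get('id')!r}: lower_bound {lb} > upper_bound {ub}"
            )
    try:
        cm = cobra_from_dict(d)
    except Exception as exc:  # noqa: BLE001 - surface the offending element
        raise ModelFormatError(f"BiGG JSON dict does not parse: {exc}") from exc
    return model_from_cobra(cm, **kwargs)


def _sniff_format(path: Path, format: str) -> str:
    if format != "auto":
        return format
    if path.suffix.lower() == ".json":
        return "bigg_json"
    if path.suffix.lower() in (".xml", ".sbml"):
        return "sbml_fbc"
    raise ModelFormatError(f"cannot infer model format from suffix of {path}")


def load_model(path, format: str = "auto", **kwargs) -> MetabolicModel:
    """Load a model from BiGG JSON or SBML L3+FBC.

    Keyword arguments (``biomass_reaction_id``, ``glucose_exchange_id``,
    ``oxygen_exchange_id``, ``atp_maintenance_id``, ``abc_ids``, ``pts_ids``)
    override the automatic anchor detection and category heuristics.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _sniff_format(path, format)
    if fmt == "bigg_json":
        try:
            with open(path) as fh:
                d = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ModelFormatError(f"{path} is not valid JSON: {exc}") from exc
        return load_model_from_dict(d, **kwargs)
    if fmt == "sbml_fbc":
        from cobra.io import read_sbml_model

        try:
            cm = read_sbml_model(str(path))
        except Exception as exc:  # noqa: BLE001
            raise ModelFormatError(f"{path} does not parse as SBML-FBC: {exc}") from exc
        return model_from_cobra(cm, **kwargs)
    raise ModelFormatError(f"unknown model format {fmt!r}")


def save_model(model: MetabolicModel, path, format: str = "auto") -> None:
    """Write a model so that ``load_model(save_model(m)) == m`` on all fields."""
    model.validate()
    path = Path(path)
    fmt = _sniff_format(path, format)
    cm = model_to_cobra(model)
    if fmt == "bigg_json":
        from cobra.io.dict import model_to_dict as cobra_to_dict

        d = cobra_to_dict(cm)
        with open(path, "w") as fh:
            json.dump(d, fh, indent=1, default=str)
    elif fmt == "sbml_fbc":
        from cobra.io import write_sbml_model

        write_sbml_model(cm, str(path))
    else:
        raise ModelFormatError(f"unknown model format {fmt!r}")


# ---------------------------------------------------------------------------
# candidate classification
# ---------------------------------------------------------------------------

CANDIDATE_CATEGORIES = frozenset(
    {ReactionCategory.INTERNAL, ReactionCategory.ABC_TRANSPORT, ReactionCategory.PTS}
)


def classify_deletion_candidates(
    model: MetabolicModel,
    *,
    exclude: set[str] | None = None,
    exclusion_file=None,
) -> set[str]:
    """Reaction ids that are legal deletion candidates.

    Exchange and plain transport reactions are excluded; gene-associated ABC
    transporters and PTS reactions are included; biomass and ATP maintenance
    are always excluded.  An explicit exclusion list (set or one-id-per-line
    file) can pin the candidate set exactly when annotations are ambiguous.
    """
    excluded = set(exclude or ())
    if exclusion_file is not None:
        with open(exclusion_file) as fh:
            excluded |= {line.strip() for line in fh if line.strip()}
    candidates = set()
    for rxn in model.reactions:
        if rxn.id in excluded:
            continue
        if rxn.category is ReactionCategory.ABC_TRANSPORT:
            if rxn.has_gpr:
                candidates.add(rxn.id)
        elif rxn.category in CANDIDATE_CATEGORIES:
            candidates.add(rxn.id)
    candidates.discard(model.biomass_reaction_id)
    if model.atp_maintenance_id:
        candidates.discard(model.atp_maintenance_id)
    return candidates


def write_candidate_list(candidates: set[str], path) -> None:
    """Export one reaction id per line, sorted."""
    with open(path, "w") as fh:
        for rid in sorted(candidates):
            fh.write(rid + "\n")
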