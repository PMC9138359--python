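"""Synthetic test networks with a known knockout optimum.

:func:`make_toy_network` builds a small, stoichiometrically consistent
network that reproduces, at desk scale, the structure the deletion search
exploits in genome-scale models: a substrate hub feeding (i) a target
synthesis branch, (ii) a growth (biomass-precursor) route of limited
capacity, and (iii) ``n`` capacity-limited byproduct branches that also
yield the growth precursor while secreting a byproduct.  At growth maximum
all routes saturate, so the byproduct branches carry flux and the target
receives only the leftover substrate; deleting a branch provably raises the
target flux at maximal growth by freeing its substrate share.  Capacities
are small distinct integers (drawn deterministically from the seed) so LP
vertices are exactly representable and the greedy step-by-step optimum
coincides with the exhaustive one.

Networks are emitted through the BiGG-JSON dict path so they exercise the
same loader as real models.  :func:`brute_force_knockout_oracle` provides
the independent exhaustive-enumeration reference.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from .errors import EnumerationBudgetError, ModelFormatError
from .fba_core import FBAConfig, compute_growth_max
from .model import MetabolicModel
from .model_io import classify_deletion_candidates, load_model_from_dict

#: biomass precursor demand per unit growth; the ATP share models
#: growth-associated maintenance and makes ATP generation essential
DEFAULT_BIOMASS = {"p_c": 1.0, "atp_c": 0.5}


@dataclass(frozen=True)
class ToySpec:
    """Parameters of a generated toy network.

    branch_yields : growth-precursor yield of each byproduct branch per unit
        substrate (default 1.0 each, making every route equally substrate-
        efficient so route choice is decided purely by capacity).
    uptake_limit : substrate exchange bound, mmol/gDCW/h.
    """

    n_byproduct_branches: int = 1
    branch_yields: tuple[float, ...] | None = None
    biomass_stoichiometry: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BIOMASS)
    )
    uptake_limit: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_byproduct_branches < 0:
            raise ValueError("n_byproduct_branches must be >= 0")
        if self.branch_yields is not None and len(self.branch_yields) != self.n_byproduct_branches:
            raise ValueError("branch_yields length must equal n_byproduct_branches")
        if self.uptake_limit <= 0:
            raise ValueError("uptake_limit must be positive")


def branch_capacities(spec: ToySpec) -> list[int]:
    """Deterministic distinct integer capacities for the byproduct branches."""
    n = spec.n_byproduct_branches
    pool = np.arange(2, 2 + max(3, n))
    rng = np.random.default_rng(spec.seed)
    return [int(c) for c in rng.permutation(pool)[:n]]


def toy_network_dict(spec: ToySpec) -> dict:
    """BiGG-JSON-schema dict for the toy network (see module docstring)."""
    yields = spec.branch_yields or (1.0,) * spec.n_byproduct_branches
    caps = branch_capacities(spec)
    known = {"glc__D_c", "p_c", "atp_c", "tgt_c"}
    for mid in spec.biomass_stoichiometry:
        if mid not in known:
            raise ModelFormatError(
                f"biomass precursor {mid!r} is not producible in the toy network"
            )

    mets = [
        ("glc__D_e", "e", "D-glucose"),
        ("glc__D_c", "c", "D-glucose"),
        ("p_c", "c", "biomass precursor"),
        ("atp_c", "c", "ATP"),
        ("tgt_c", "c", "target compound"),
        ("tgt_e", "e", "target compound"),
    ]
    reactions = [
        {
            "id": "EX_glc__D_e",
            "name": "D-glucose exchange",
            "metabolites": {"glc__D_e": -1.0},
            "lower_bound": -spec.uptake_limit,
            "upper_bound": 1000.0,
        },
        {
            "id": "GLCt",
            "name": "glucose transport",
            "metabolites": {"glc__D_e": -1.0, "glc__D_c": 1.0},
            "lower_bound": 0.0,
            "upper_bound": 1000.0,
        },
        {
            "id": "R_PBASE",
            "name": "base precursor route",
            "metabolites": {"glc__D_c": -1.0, "p_c": 1.0},
            "lower_bound": 0.0,
            "upper_bound": 1.0,  # smallest capacity: kept as the growth lifeline
            "gene_reaction_rule": "g_base",
        },
        {
            "id": "ATPGEN",
            "name": "ATP generation",
            "metabolites": {"glc__D_c": -1.0, "atp_c": 1.0},
            "lower_bound": 0.0,
            "upper_bound": 1000.0,
            "gene_reaction_rule": "g_atp",
        },
        {
            "id": "ATPM",
            "name": "ATP maintenance requirement",
            "metabolites": {"atp_c": -1.0},
            "lower_bound": 0.0,
            "upper_bound": 1000.0,
        },
        {
            "id": "TGT_SYN",
            "name": "target synthesis",
            "metabolites": {"glc__D_c": -1.0, "tgt_c": 1.0},
            "lower_bound": 0.0,
            "upper_bound": 1000.0,
            "gene_reaction_rule": "g_tgt",
        },
        {
            "id": "TGTt",
            "name": "target transport",
            "metabolites": {"tgt_c": -1.0, "tgt_e": 1.0},
            "lower_bound": 0.0,
            "upper_bound": 1000.0,
        },
        {
            "id": "EX_tgt_e",
            "name": "target exchange",
            "metabolites": {"tgt_e": -1.0},
            "lower_bound": 0.0,
            "upper_bound": 1000.0,
        },
        {
            "id": "BIOMASS_toy",
            "name": "biomass synthesis",
            "metabolites": {mid: -coeff for mid, coeff in spec.biomass_stoichiometry.items()},
            "lower_bound": 0.0,
            "upper_bound": 1000.0,
            "objective_coefficient": 1.0,
        },
    ]
    for i, (cap, y) in enumerate(zip(caps, yields), start=1):
        mets += [(f"byp{i}_c", "c", f"byproduct {i}"), (f"byp{i}_e", "e", f"byproduct {i}")]
        reactions += [
            {
                "id": f"R_BRANCH{i}",
                "name": f"byproduct branch {i}",
                "metabolites": {"glc__D_c": -1.0, "p_c": float(y), f"byp{i}_c": 1.0},
                "lower_bound": 0.0,
                "upper_bound": float(cap),
                "gene_reaction_rule": f"g_branch{i}",
            },
            {
                "id": f"BYPt{i}",
                "name": f"byproduct {i} transport",
                "metabolites": {f"byp{i}_c": -1.0, f"byp{i}_e": 1.0},
                "lower_bound": 0.0,
                "upper_bound": 1000.0,
            },
            {
                "id": f"EX_byp{i}_e",
                "name": f"byproduct {i} exchange",
                "metabolites": {f"byp{i}_e": -1.0},
                "lower_bound": 0.0,
                "upper_bound": 1000.0,
            },
        ]
    genes = sorted({g for r in reactions for g in [r.get("gene_reaction_rule", "")] if g})
    return {
        "id": f"toy_{spec.n_byproduct_branches}branch_seed{spec.seed}",
        "compartments": {"c": "cytosol", "e": "extracellular space"},
        "metabolites": [
            {"id": mid, "name": name, "compartment": comp} for mid, comp, name in mets
        ],
        "reactions": reactions,
        "genes": [{"id": g, "name": g} for g in genes],
        "version": "1",
    }


def make_toy_network(spec: ToySpec) -> MetabolicModel:
    """Generate the toy network; deterministic for a fixed seed."""
    model = load_model_from_dict(
        toy_network_dict(spec), atp_maintenance_id="ATPM", oxygen_exchange_id=None
    )
    return model


def toy_byproduct_whitelist(model: MetabolicModel) -> frozenset[str]:
    """Exchange ids of the toy byproducts (native products of the toy cell)."""
    return frozenset(r.id for r in model.reactions if r.id.startswith("EX_byp"))


def toy_fba_config(model: MetabolicModel, **overrides) -> FBAConfig:
    """FBAConfig matched to the toy scale (uptake 20, modest maintenance)."""
    defaults = dict(
        gur_max=20.0,
        our_min=None,
        ngam=1.0,
        mu_min=0.05,
        native_byproduct_whitelist=toy_byproduct_whitelist(model),
        co2_exchange_id=None,
    )
    defaults.update(overrides)
    return FBAConfig(**defaults)


def brute_force_knockout_oracle(
    model: MetabolicModel,
    target_exchange: str,
    fba_config: FBAConfig,
    k_max: int,
    candidates: set[str] | None = None,
    budget: int = 100_000,
) -> dict[int, tuple[tuple[str, ...], float]]:
    """Best target flux at growth maximum per deletion-set size 0..k_max.

    Exhaustively enumerates deletion subsets of the candidate set and
    evaluates each with the growth-maximizing solve.  Returns
    ``{size: (sorted deletion ids, target flux)}``; infeasible sets are
    skipped.  Ties are broken toward the lexicographically smallest set so
    the oracle itself is deterministic.
    """
    if candidates is None:
        candidates = classify_deletion_candidates(model)
    pool = sorted(candidates)
    total = sum(math.comb(len(pool), k) for k in range(k_max + 1))
    if total > budget:
        raise EnumerationBudgetError(
            f"{total} deletion sets exceed the enumeration budget {budget}; lower k_max"
        )
    best: dict[int, tuple[tuple[str, ...], float]] = {}
    top: tuple[tuple[str, ...], float] | None = None
    for k in range(k_max + 1):
        # best over sets of size <= k: carry the smaller-size optimum forward
        for combo in combinations(pool, k):
            state = compute_growth_max(model, target_exchange, fba_config, combo)
            if not state.optimal:
                continue
            flux = state.flux(target_exchange)
            if top is None or flux > top[1] + 1e-9:
                top = (combo, flux)
        if top is not None:
            best[k] = top
    return best
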