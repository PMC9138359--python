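"""The iterative single-level LP deletion search (AERITH).

Each iteration solves two FBAs under the accumulated deletion constraints —
one maximizing the target exchange flux (v^Tmax) and one maximizing growth
with a small target tie-break (v^Gmax) — scores every candidate reaction by
the relative flux change

    chg_j = (v_j^Tmax - v_j^Gmax) / v_j^Gmax,

selects one reaction inside the relaxed window
[chg_min, ko_r = r * chg_min], adds the constraint v_j = 0, and repeats.
Reactions with chg near -1 carry flux when the cell grows maximally but not
when the target is made maximally — exactly the byproduct routes whose
removal couples growth to production.  The window (rather than the literal
minimum) permits deleting reactions that are preferentially used for cell
synthesis but are not essential; within the window the reaction with the
largest v^Gmax is taken, residual ties broken by lexicographic id so runs
are deterministic.

Fluxes enter chg as absolute magnitudes, so chg >= -1 always holds and a
direction flip of a reversible reaction registers as a flux change.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import pandas as pd

from .errors import InfeasibleModelError
from .fba_core import (
    FBAConfig,
    FluxState,
    compute_growth_max,
    compute_theoretical_max,
)
from .model import MetabolicModel
from .model_io import classify_deletion_candidates

# terminal statuses of a deletion trace
NO_CANDIDATE = "no_candidate"
MAX_DELETIONS = "max_deletions"
INFEASIBLE_NEXT = "infeasible_next"
TARGET_REACHED = "target_reached"
NOT_PRODUCIBLE = "not_producible"
EVALUATED = "evaluated"


@dataclass(frozen=True)
class RunConfig:
    """Tunable parameters of the deletion search.

    r : window relaxation factor in (0, 1]; the eligibility window is
        [chg_min, r * chg_min].
    max_deletions : hard cap on accumulated deletions (guarantees
        termination; designs with >20 deletions are routinely reachable).
    y_obj : minimum target production flux (mmol/gDCW/h) for a step to be
        flagged as a productive design; stops the run early only when
        stop_at_yobj is set.
    flux_zero_tolerance : |flux| below this counts as zero.
    gmax_zero_guard : value substituted for v^Gmax = 0 in chg to avoid
        division by zero.
    selection : "window" treats the whole ko_r window as tied (largest
        v^Gmax wins); "minimum" is the literal minimum-chg rule.
    refresh_tmax : recompute the target-max flux vector under the current
        deletions each iteration (default); False freezes the wild-type
        vector as the chg reference.
    """

    r: float = 0.95
    max_deletions: int = 30
    y_obj: float = 1e-3
    flux_zero_tolerance: float = 1e-9
    gmax_zero_guard: float = 1e-6
    selection: str = "window"
    refresh_tmax: bool = True
    stop_at_yobj: bool = False
    eligibility_tolerance: float = 1e-9

    def __post_init__(self) -> None:
        if not (0 < self.r <= 1):
            raise ValueError("r must lie in (0, 1]")
        if self.max_deletions < 1:
            raise ValueError("max_deletions must be >= 1")
        if self.y_obj < 0:
            raise ValueError("y_obj must be non-negative")
        if self.selection not in ("window", "minimum"):
            raise ValueError(f"unknown selection policy {self.selection!r}")


def compute_chg(vT: float, vG: float, config: RunConfig = RunConfig()) -> float:
    """Relative flux change between the target-max and growth-max optima.

    Inputs are absolute flux magnitudes; a v^Gmax below the zero tolerance
    is replaced by ``gmax_zero_guard`` to prevent division by zero.
    """
    if vT < 0 or vG < 0:
        raise ValueError("chg expects absolute flux magnitudes (>= 0)")
    if vG < config.flux_zero_tolerance:
        vG = config.gmax_zero_guard
    return (vT - vG) / vG


@dataclass(frozen=True)
class ChgRecord:
    reaction_id: str
    v_tmax: float
    v_gmax: float
    chg: float
    both_zero: bool


@dataclass
class ChgTable:
    """Per-candidate chg scores for one iteration.

    ``chg_min`` is the minimum over candidates with at least one nonzero
    flux (both-zero reactions would trivially score -1 but their deletion is
    a no-op at the current optimum, so they are ineligible), ``ko_r`` is
    r * chg_min, ``eligible`` the candidates falling inside the window.
    """

    records: dict[str, ChgRecord]
    chg_min: float
    ko_r: float
    eligible: set[str] = field(default_factory=set)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "reaction_id": rec.reaction_id,
                "v_tmax": rec.v_tmax,
                "v_gmax": rec.v_gmax,
                "chg": rec.chg,
                "eligible": rec.reaction_id in self.eligible,
            }
            for rec in sorted(self.records.values(), key=lambda r: r.chg)
        ]
        return pd.DataFrame(rows)


def build_chg_table(
    tmax_state: FluxState,
    gmax_state: FluxState,
    candidates: Iterable[str],
    config: RunConfig,
) -> ChgTable:
    records: dict[str, ChgRecord] = {}
    tol = config.flux_zero_tolerance
    for rid in candidates:
        vT = abs(tmax_state.flux(rid))
        vG = abs(gmax_state.flux(rid))
        both_zero = vT < tol and vG < tol
        records[rid] = ChgRecord(rid, vT, vG, compute_chg(vT, vG, config), both_zero)
    scored = [rec.chg for rec in records.values() if not rec.both_zero]
    chg_min = min(scored) if scored else math.nan
    ko_r = config.r * chg_min
    table = ChgTable(records=records, chg_min=chg_min, ko_r=ko_r)
    if not math.isnan(chg_min):
        eps = config.eligibility_tolerance
        table.eligible = {
            rid
            for rid, rec in records.items()
            if not rec.both_zero and chg_min - eps <= rec.chg <= ko_r + eps
        }
    return table


def score_all(
    model: MetabolicModel,
    target_exchange: str,
    fba_config: FBAConfig,
    run_config: RunConfig = RunConfig(),
    deletions: Iterable[str] = (),
    candidates: Iterable[str] | None = None,
    tmax_reference: FluxState | None = None,
) -> ChgTable:
    """Score all deletion candidates under the current deletion set.

    ``tmax_reference`` supplies a frozen target-max flux vector when
    ``refresh_tmax`` is off; otherwise the target-max LP is re-solved under
    the deletions.  Infeasibility of either LP propagates as
    InfeasibleModelError (the run loop never calls this on an infeasible
    deletion set).
    """
    deletions = set(deletions)
    if candidates is None:
        candidates = classify_deletion_candidates(model)
    candidates = set(candidates) - deletions
    if run_config.refresh_tmax or tmax_reference is None:
        tmax_state, _ = compute_theoretical_max(model, target_exchange, fba_config, deletions)
    else:
        tmax_state = tmax_reference
    if not tmax_state.optimal:
        raise InfeasibleModelError("target-max LP infeasible under current deletions")
    gmax_state = compute_growth_max(model, target_exchange, fba_config, deletions)
    if not gmax_state.optimal:
        raise InfeasibleModelError("growth-max LP infeasible under current deletions")
    return build_chg_table(tmax_state, gmax_state, candidates, run_config)


def select_next_deletion(
    table: ChgTable, run_config: RunConfig = RunConfig(), exclude: Iterable[str] = ()
) -> str | None:
    """Pick the next deletion from a chg table, or None if nothing qualifies.

    Nothing qualifies when the eligible window is empty or when chg_min >= 0
    (no reaction carries more growth-max than target-max flux, so no
    deletion can redirect flux toward the target).
    """
    if math.isnan(table.chg_min) or table.chg_min >= 0:
        return None
    pool = table.eligible - set(exclude)
    if not pool:
        return None
    if run_config.selection == "minimum":
        eps = run_config.eligibility_tolerance
        pool = {rid for rid in pool if table.records[rid].chg <= table.chg_min + eps}
        if not pool:
            return None
    # window-as-tie: the highest v^Gmax wins, residual ties lexicographic
    return min(pool, key=lambda rid: (-table.records[rid].v_gmax, rid))


@dataclass(frozen=True)
class TraceStep:
    k: int
    reaction_id: str | None
    biomass_flux: float
    target_flux: float
    yield_fraction: float
    status: str = "optimal"
    productive: bool = False


@dataclass
class DeletionTrace:
    """Ordered record of a deletion search (step 0 is the undeleted state)."""

    target_exchange: str
    theoretical_max: float
    our_min: float | None
    steps: list[TraceStep]
    terminal_status: str

    @property
    def deletions(self) -> list[str]:
        return [s.reaction_id for s in self.steps if s.k > 0 and s.reaction_id is not None]

    @property
    def final_target_flux(self) -> float:
        feasible = [s for s in self.steps if s.status == "optimal"]
        return feasible[-1].target_flux if feasible else math.nan

    @property
    def final_yield_fraction(self) -> float:
        feasible = [s for s in self.steps if s.status == "optimal"]
        return feasible[-1].yield_fraction if feasible else math.nan

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "step": s.k,
                    "reaction_id": s.reaction_id or "",
                    "biomass_flux": s.biomass_flux,
                    "target_flux": s.target_flux,
                    "yield_fraction": s.yield_fraction,
                    "status": s.status,
                    "productive": s.productive,
                }
                for s in self.steps
            ]
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _make_step(
    k: int,
    rid: str | None,
    state: FluxState,
    model: MetabolicModel,
    target_exchange: str,
    tmax_objective: float,
    y_obj: float,
) -> TraceStep:
    mu = state.flux(model.biomass_reaction_id)
    vt = state.flux(target_exchange)
    yld = vt / tmax_objective if tmax_objective > 0 else math.nan
    return TraceStep(k, rid, mu, vt, yld, productive=vt >= y_obj)


def run_aerith(
    model: MetabolicModel,
    target_exchange: str,
    fba_config: FBAConfig,
    run_config: RunConfig = RunConfig(),
    candidates: Iterable[str] | None = None,
) -> DeletionTrace:
    """Run the iterative deletion search on a policy-applied model.

    The wild-type target-max solve fixes the theoretical maximum (the yield
    denominator) and OUR_min for the whole run.  Candidates whose deletion
    makes the growth LP infeasible are discarded permanently and selection
    retries within the same iteration; the search stops when no eligible
    candidate remains, when the deletion cap is hit, or (with
    ``stop_at_yobj``) when the production floor y_obj is reached.
    """
    model.reaction(target_exchange)
    tmax_state, our = compute_theoretical_max(model, target_exchange, fba_config)
    if not tmax_state.optimal or tmax_state.objective_value <= run_config.flux_zero_tolerance:
        return DeletionTrace(
            target_exchange=target_exchange,
            theoretical_max=0.0 if not tmax_state.optimal else tmax_state.objective_value,
            our_min=our,
            steps=[],
            terminal_status=NOT_PRODUCIBLE,
        )
    tstar = tmax_state.objective_value
    fixed = replace(fba_config, our_min=our if our is not None else None)
    if candidates is None:
        candidates = classify_deletion_candidates(model)
    candidates = set(candidates)

    baseline = compute_growth_max(model, target_exchange, fixed)
    if not baseline.optimal:
        raise InfeasibleModelError(
            "model infeasible under the growth floor mu_min before any deletion"
        )
    steps = [_make_step(0, None, baseline, model, target_exchange, tstar, run_config.y_obj)]
    deletions: list[str] = []
    blacklist: set[str] = set()
    terminal = MAX_DELETIONS

    if run_config.stop_at_yobj and steps[0].target_flux >= run_config.y_obj:
        return DeletionTrace(target_exchange, tstar, our, steps, TARGET_REACHED)

    while len(deletions) < run_config.max_deletions:
        table = score_all(
            model,
            target_exchange,
            fixed,
            run_config,
            deletions,
            candidates=candidates - blacklist,
            tmax_reference=tmax_state,
        )
        tried_infeasible = False
        accepted: tuple[str, FluxState] | None = None
        rejected: set[str] = set()
        while True:
            pick = select_next_deletion(table, run_config, exclude=rejected)
            if pick is None:
                break
            trial = compute_growth_max(model, target_exchange, fixed, [*deletions, pick])
            if trial.optimal:
                accepted = (pick, trial)
                break
            # this deletion kills growth: drop it for good, retry next-best
            tried_infeasible = True
            blacklist.add(pick)
            rejected.add(pick)
        if accepted is None:
            terminal = INFEASIBLE_NEXT if tried_infeasible else NO_CANDIDATE
            break
        rid, state = accepted
        deletions.append(rid)
        steps.append(
            _make_step(len(deletions), rid, state, model, target_exchange, tstar, run_config.y_obj)
        )
        if run_config.stop_at_yobj and steps[-1].target_flux >= run_config.y_obj:
            terminal = TARGET_REACHED
            break
    return DeletionTrace(target_exchange, tstar, our, steps, terminal)


def evaluate_design(
    model: MetabolicModel,
    target_exchange: str,
    deletions: Sequence[str],
    fba_config: FBAConfig,
) -> DeletionTrace:
    """Score a fixed, ordered deletion set by cumulative prefixes.

    Each prefix is evaluated with the growth-maximizing solve; an infeasible
    prefix is recorded as such and evaluation continues, so published designs
    containing a lethal reaction are still reported in full.
    """
    for rid in deletions:
        model.reaction(rid)
    tmax_state, our = compute_theoretical_max(model, target_exchange, fba_config)
    tstar = tmax_state.objective_value if tmax_state.optimal else 0.0
    fixed = replace(fba_config, our_min=our if our is not None else None)
    steps = []
    for k in range(len(deletions) + 1):
        state = compute_growth_max(model, target_exchange, fixed, deletions[:k])
        rid = deletions[k - 1] if k else None
        if state.optimal:
            steps.append(_make_step(k, rid, state, model, target_exchange, tstar, 1e-3))
        else:
            steps.append(TraceStep(k, rid, math.nan, math.nan, math.nan, status="infeasible"))
    return DeletionTrace(target_exchange, tstar, our, steps, EVALUATED)
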