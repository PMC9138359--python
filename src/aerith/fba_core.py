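"""Flux balance analysis: LP assembly, solving, and the exchange-bound policy.

The steady-state LP is

    max  c'v
    s.t. S v = 0
         v_glc_uptake <= GUR_max        (glucose exchange lb >= -GUR_max)
         v_o2_uptake  >= OUR_min        (oxygen exchange ub <= -OUR_min)
         v_atpm       >= NGAM
         v_growth     >= mu_min
         lb_j <= v_j <= ub_j            (lb_j = 0 for irreversible j)
         v_j = 0 for every deleted j

with BiGG sign convention: exchange uptake is negative flux, so the
uptake-positive magnitudes GUR/OUR of the configuration are converted at the
LP boundary.  All four physiological floors are expressed as bound
tightenings, applied *after* deletion bounds so that deleting e.g. a
biomass-essential reaction correctly renders the LP infeasible.

Default solver is GLPK simplex via swiglpk (deterministic for a fixed
build); ``solver="scipy"`` substitutes scipy.optimize.linprog/HiGHS.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Mapping

import numpy as np
from scipy import sparse

from .errors import NotExchangeReactionError
from .model import MetabolicModel, ReactionCategory

OPTIMAL = "optimal"
INFEASIBLE = "infeasible"
UNBOUNDED = "unbounded"

#: exchanges that must stay open for secretion under the close-all policy,
#: or nearly every genome-scale model becomes infeasible (water, protons)
DEFAULT_ALWAYS_OPEN = frozenset({"EX_h2o_e", "EX_h_e"})


@dataclass(frozen=True)
class FBAConfig:
    """Physiological parameters of the steady-state LP.

    gur_max : maximal glucose uptake rate, mmol/gDCW/h.
    our_min : minimal oxygen uptake rate (uptake-positive); "auto" means
        "fix it from the wild-type target-maximizing solve", None disables it.
    ngam : non-growth-associated ATP maintenance floor, mmol/gDCW/h.
    mu_min : minimal specific growth rate, 1/h.
    global_flux_bound : magnitude used when (re)opening a secretion bound.
    tiebreak_coefficient : weight of the target flux in the composite
        growth-maximization objective, used to pick a unique vertex among
        growth-degenerate alternate optima.
    """

    gur_max: float = 10.0
    our_min: float | str | None = "auto"
    ngam: float = 3.15
    mu_min: float = 0.05
    global_flux_bound: float = 1000.0
    native_byproduct_whitelist: frozenset[str] = frozenset()
    co2_exchange_id: str | None = "EX_co2_e"
    always_open_exchanges: frozenset[str] = DEFAULT_ALWAYS_OPEN
    tiebreak_coefficient: float = 1e-5
    solver: str = "glpk"

    def __post_init__(self) -> None:
        if self.gur_max <= 0:
            raise ValueError("gur_max must be positive")
        if self.ngam < 0 or self.mu_min < 0:
            raise ValueError("ngam and mu_min must be non-negative")
        if not (0 < self.tiebreak_coefficient < 1):
            raise ValueError("tiebreak_coefficient must lie in (0, 1)")
        if self.solver not in ("glpk", "scipy"):
            raise ValueError(f"unknown solver {self.solver!r}")


@dataclass(frozen=True)
class ObjectiveSpec:
    coefficients: Mapping[str, float]
    sense: str = "maximize"

    def __post_init__(self) -> None:
        if not any(self.coefficients.values()):
            raise ValueError("objective needs at least one nonzero coefficient")
        if self.sense != "maximize":
            raise ValueError("only maximization objectives are supported")


@dataclass
class FluxState:
    """One LP solution; ``fluxes`` is empty unless status is optimal."""

    fluxes: dict[str, float]
    objective_value: float
    status: str

    @property
    def optimal(self) -> bool:
        return self.status == OPTIMAL

    def flux(self, rid: str) -> float:
        return self.fluxes.get(rid, 0.0)


# ---------------------------------------------------------------------------
# exchange-bound policy
# ---------------------------------------------------------------------------


def apply_exchange_policy(
    model: MetabolicModel, target_exchange: str, config: FBAConfig
) -> MetabolicModel:
    """Close all secretion routes except the target and known native products.

    Returns a bound-modified copy: every exchange upper bound is set to 0
    except the target exchange, whitelisted native byproducts, CO2, and the
    obligatory outputs (water/protons), which are opened to
    ``global_flux_bound``.  Uptake (lower) bounds are untouched except the
    glucose exchange, clamped to ``-gur_max``.
    """
    target = model.reaction(target_exchange)
    if target.category is not ReactionCategory.EXCHANGE:
        raise NotExchangeReactionError(
            f"{target_exchange!r} is not an exchange reaction (category {target.category.value})"
        )
    keep_open = (
        {target_exchange}
        | set(config.native_byproduct_whitelist)
        | set(config.always_open_exchanges)
    )
    if config.co2_exchange_id:
        keep_open.add(config.co2_exchange_id)
    out = model.copy()
    for rxn in out.reactions:
        if rxn.category is not ReactionCategory.EXCHANGE:
            continue
        rxn.upper_bound = config.global_flux_bound if rxn.id in keep_open else 0.0
        if rxn.id == out.glucose_exchange_id:
            rxn.lower_bound = max(rxn.lower_bound, -config.gur_max)
    return out


# ---------------------------------------------------------------------------
# LP assembly and backends
# ---------------------------------------------------------------------------


def _tightened_bounds(
    model: MetabolicModel, config: FBAConfig, deletions: Iterable[str]
) -> tuple[np.ndarray, np.ndarray]:
    lb, ub = model.bounds_arrays()
    idx = model.reaction_index
    for rid in deletions:
        if rid not in idx:
            raise KeyError(f"deletion target {rid!r} not in model")
        j = idx[rid]
        lb[j] = 0.0
        ub[j] = 0.0
    # physiological floors come after deletions on purpose: deleting an
    # essential reaction must make the LP infeasible, not relax the floor
    if model.glucose_exchange_id is not None:
        j = idx[model.glucose_exchange_id]
        lb[j] = max(lb[j], -config.gur_max)
    if model.oxygen_exchange_id is not None and isinstance(config.our_min, (int, float)):
        j = idx[model.oxygen_exchange_id]
        ub[j] = min(ub[j], -float(config.our_min))
    if model.atp_maintenance_id is not None and config.ngam > 0:
        j = idx[model.atp_maintenance_id]
        lb[j] = max(lb[j], config.ngam)
    j = idx[model.biomass_reaction_id]
    lb[j] = max(lb[j], config.mu_min)
    return lb, ub


def _solve_glpk(S: sparse.spmatrix, lb, ub, c) -> tuple[str, np.ndarray | None, float]:
    import swiglpk as glp

    coo = sparse.coo_matrix(S)
    m, n = coo.shape
    lp = glp.glp_create_prob()
    try:
        glp.glp_set_obj_dir(lp, glp.GLP_MAX)
        glp.glp_add_rows(lp, m)
        for i in range(1, m + 1):
            glp.glp_set_row_bnds(lp, i, glp.GLP_FX, 0.0, 0.0)
        glp.glp_add_cols(lp, n)
        for j in range(n):
            l, u = float(lb[j]), float(ub[j])
            if l == u:
                glp.glp_set_col_bnds(lp, j + 1, glp.GLP_FX, l, u)
            elif np.isinf(l) and np.isinf(u):
                glp.glp_set_col_bnds(lp, j + 1, glp.GLP_FR, 0.0, 0.0)
            elif np.isinf(l):
                glp.glp_set_col_bnds(lp, j + 1, glp.GLP_UP, 0.0, u)
            elif np.isinf(u):
                glp.glp_set_col_bnds(lp, j + 1, glp.GLP_LO, l, 0.0)
            else:
                glp.glp_set_col_bnds(lp, j + 1, glp.GLP_DB, l, u)
            if c[j] != 0.0:
                glp.glp_set_obj_coef(lp, j + 1, float(c[j]))
        nnz = coo.nnz
        ia = glp.intArray(nnz + 1)
        ja = glp.intArray(nnz + 1)
        ar = glp.doubleArray(nnz + 1)
        for k in range(nnz):
            ia[k + 1] = int(coo.row[k]) + 1
            ja[k + 1] = int(coo.col[k]) + 1
            ar[k + 1] = float(coo.data[k])
        glp.glp_load_matrix(lp, nnz, ia, ja, ar)
        parm = glp.glp_smcp()
        glp.glp_init_smcp(parm)
        parm.msg_lev = glp.GLP_MSG_ERR
        ret = glp.glp_simplex(lp, parm)
        status = glp.glp_get_status(lp)
        if ret == 0 and status == glp.GLP_OPT:
            x = np.fromiter(
                (glp.glp_get_col_prim(lp, j + 1) for j in range(n)), dtype=float, count=n
            )
            return OPTIMAL, x, glp.glp_get_obj_val(lp)
        if status == glp.GLP_UNBND:
            return UNBOUNDED, None, np.inf
        return INFEASIBLE, None, np.nan
    finally:
        glp.glp_delete_prob(lp)


def _solve_scipy(S: sparse.spmatrix, lb, ub, c) -> tuple[str, np.ndarray | None, float]:
    from scipy.optimize import linprog

    res = linprog(
        -np.asarray(c, dtype=float),
        A_eq=S,
        b_eq=np.zeros(S.shape[0]),
        bounds=np.column_stack([lb, ub]),
        method="highs",
    )
    if res.status == 0:
        return OPTIMAL, res.x, -res.fun
    if res.status == 3:
        return UNBOUNDED, None, np.inf
    return INFEASIBLE, None, np.nan


_BACKENDS = {"glpk": _solve_glpk, "scipy": _solve_scipy}


def _solve(
    model: MetabolicModel,
    coefficients: Mapping[str, float],
    config: FBAConfig,
    deletions: Iterable[str] = (),
    extra_lower: Mapping[str, float] | None = None,
) -> FluxState:
    lb, ub = _tightened_bounds(model, config, deletions)
    idx = model.reaction_index
    if extra_lower:
        for rid, floor in extra_lower.items():
            lb[idx[rid]] = max(lb[idx[rid]], floor)
    if np.any(lb > ub):
        return FluxState(fluxes={}, objective_value=np.nan, status=INFEASIBLE)
    c = np.zeros(len(model.reactions))
    for rid, coeff in coefficients.items():
        c[idx[rid]] = coeff
    status, x, obj = _BACKENDS[config.solver](model.stoichiometric_matrix(), lb, ub, c)
    if status != OPTIMAL:
        return FluxState(fluxes={}, objective_value=obj, status=status)
    fluxes = {r.id: float(x[j]) for j, r in enumerate(model.reactions)}
    return FluxState(fluxes=fluxes, objective_value=float(obj), status=OPTIMAL)


# ---------------------------------------------------------------------------
# public solves
# ---------------------------------------------------------------------------


def solve_fba(
    model: MetabolicModel,
    objective: ObjectiveSpec | Mapping[str, float] | str,
    config: FBAConfig,
    deletions: Iterable[str] = (),
) -> FluxState:
    """Solve one steady-state LP; infeasibility is returned, never raised."""
    if isinstance(objective, str):
        coefficients: Mapping[str, float] = {objective: 1.0}
    elif isinstance(objective, ObjectiveSpec):
        coefficients = objective.coefficients
    else:
        coefficients = ObjectiveSpec(objective).coefficients
    for rid in coefficients:
        model.reaction(rid)  # raises KeyError on unknown ids
    return _solve(model, coefficients, config, deletions)


def compute_theoretical_max(
    model: MetabolicModel,
    target_exchange: str,
    config: FBAConfig,
    deletions: Iterable[str] = (),
) -> tuple[FluxState, float | None]:
    """Maximize the target exchange flux (growth floor mu_min active).

    The oxygen floor is *not* applied during this solve; instead the oxygen
    uptake magnitude realised at the optimum is returned, to be fixed as
    OUR_min in every subsequent LP of a run.  Returns ``(state, our_min)``;
    ``our_min`` is None for models without an oxygen exchange.
    """
    relaxed = replace(config, our_min=None)
    state = _solve(model, {target_exchange: 1.0}, relaxed, deletions)
    our = None
    if state.optimal and model.oxygen_exchange_id is not None:
        our = max(0.0, -state.flux(model.oxygen_exchange_id))
    return state, our


def compute_growth_max(
    model: MetabolicModel,
    target_exchange: str,
    config: FBAConfig,
    deletions: Iterable[str] = (),
    mode: str = "composite",
) -> FluxState:
    """Growth-maximizing flux state with a well-defined target flux.

    ``composite`` (default): one LP maximizing
    ``biomass + tiebreak_coefficient * target``, the small target term
    selecting a unique vertex among growth-degenerate alternate optima.
    ``lexicographic``: exact two-stage solve (max biomass; fix it; max
    target), provided as an independent cross-check.
    """
    biomass = model.biomass_reaction_id
    if mode == "composite":
        coeff = {biomass: 1.0, target_exchange: config.tiebreak_coefficient}
        if target_exchange == biomass:
            coeff = {biomass: 1.0}
        return _solve(model, coeff, config, deletions)
    if mode == "lexicographic":
        stage1 = _solve(model, {biomass: 1.0}, config, deletions)
        if not stage1.optimal:
            return stage1
        mu_star = stage1.flux(biomass)
        return _solve(
            model,
            {target_exchange: 1.0},
            config,
            deletions,
            extra_lower={biomass: mu_star - 1e-9},
        )
    raise ValueError(f"unknown growth-max mode {mode!r}")


def steady_state_residual(model: MetabolicModel, state: FluxState) -> float:
    """max_i |S v|_i for an optimal state (0.0 for non-optimal states)."""
    if not state.optimal:
        return 0.0
    v = np.array([state.fluxes[r.id] for r in model.reactions])
    return float(np.max(np.abs(model.stoichiometric_matrix() @ v), initial=0.0))
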