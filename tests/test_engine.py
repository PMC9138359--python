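"""The chg score, the selection window, and the iterative deletion loop."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aerith import (
    RunConfig,
    brute_force_knockout_oracle,
    compute_chg,
    evaluate_design,
    run_aerith,
    score_all,
    select_next_deletion,
)
from aerith.engine import ChgRecord, ChgTable
from conftest import TARGET, build_bounded_toy


# -- chg ---------------------------------------------------------------------


@pytest.mark.parametrize(
    "vT,vG,expected",
    [
        (0.0, 5.0, -1.0),  # growth-only reaction: the minimum value
        (4.0, 4.0, 0.0),
        (2.0, 8.0, -0.75),
        (1.0, 0.0, 999999.0),  # zero v^Gmax guarded by the 1e-6 substitution
    ],
)
def test_chg_cases(vT, vG, expected):
    assert compute_chg(vT, vG) == pytest.approx(expected, rel=1e-9)


def test_chg_rejects_signed_fluxes():
    with pytest.raises(ValueError):
        compute_chg(-1.0, 2.0)
    with pytest.raises(ValueError):
        compute_chg(1.0, -2.0)


@settings(max_examples=200, derandomize=True, database=None)
@given(
    vT=st.floats(min_value=0.0, max_value=1e4, allow_nan=False),
    vG=st.floats(min_value=0.0, max_value=1e4, allow_nan=False),
)
def test_chg_floor_and_monotonicity(vT, vG):
    """chg >= -1 for any absolute-flux pair, and chg grows with v^Tmax."""
    value = compute_chg(vT, vG)
    assert value >= -1.0
    assert compute_chg(vT + 1.0, vG) > value


# -- selection ---------------------------------------------------------------


def _table(chg_map, vg_map, r=0.95):
    records = {
        rid: ChgRecord(rid, v_tmax=0.0, v_gmax=vg_map[rid], chg=chg, both_zero=False)
        for rid, chg in chg_map.items()
    }
    chg_min = min(chg_map.values())
    table = ChgTable(records=records, chg_min=chg_min, ko_r=r * chg_min)
    table.eligible = {
        rid for rid, chg in chg_map.items() if chg_min - 1e-9 <= chg <= r * chg_min + 1e-9
    }
    return table


def test_window_selection_prefers_highest_growth_flux():
    """r=0.95 window [-1, -0.95] holds R1 and R2; R2 wins on v^Gmax."""
    table = _table({"R1": -1.0, "R2": -0.97, "R3": -0.5}, {"R1": 2.0, "R2": 7.0, "R3": 9.0})
    assert table.eligible == {"R1", "R2"}
    assert select_next_deletion(table) == "R2"


def test_no_selection_when_nothing_gains():
    table = _table({"R1": 0.0, "R2": 0.4}, {"R1": 1.0, "R2": 1.0})
    assert select_next_deletion(table) is None


def test_singleton_window_ignores_growth_flux():
    table = _table({"R1": -0.8, "R2": -0.1}, {"R1": 0.001, "R2": 50.0})
    assert table.eligible == {"R1"}
    assert select_next_deletion(table) == "R1"


def test_equal_growth_flux_breaks_ties_lexicographically():
    table = _table({"Rb": -1.0, "Ra": -1.0}, {"Rb": 2.0, "Ra": 2.0})
    assert select_next_deletion(table) == "Ra"


def test_literal_minimum_selection_mode():
    table = _table({"R1": -1.0, "R2": -0.97}, {"R1": 2.0, "R2": 7.0})
    assert select_next_deletion(table, RunConfig(selection="minimum")) == "R1"


def test_excluded_candidates_are_skipped():
    table = _table({"R1": -1.0, "R2": -0.97}, {"R1": 2.0, "R2": 7.0})
    assert select_next_deletion(table, exclude={"R2"}) == "R1"
    assert select_next_deletion(table, exclude={"R1", "R2"}) is None


# -- scoring on the two-route network (hand-solved LPs) ----------------------


def test_score_table_matches_hand_computed_fluxes(two_route_model, two_route_config):
    """Wild type: growth max routes all 10 glc through A (v_Gmax=10); target
    max keeps only the mu_min=0.05 growth floor on A and sends 9.95 to the
    target.  chg(A) = (0.05-10)/10, B carries no flux either way, TGT_SYN is
    target-only so its guarded chg is hugely positive."""
    table = score_all(two_route_model, "EX_tgt_e", two_route_config)
    assert set(table.records) == {"R_A", "R_B", "TGT_SYN"}
    rec_a = table.records["R_A"]
    assert rec_a.v_gmax == pytest.approx(10.0, abs=1e-9)
    assert rec_a.v_tmax == pytest.approx(0.05, abs=1e-9)
    assert rec_a.chg == pytest.approx(-0.995, abs=1e-9)
    assert table.records["R_B"].both_zero
    assert table.records["TGT_SYN"].chg > 0
    assert table.chg_min == pytest.approx(-0.995, abs=1e-9)
    assert table.ko_r == pytest.approx(0.95 * -0.995, abs=1e-9)
    assert table.eligible == {"R_A"}


def test_growth_only_branch_scores_minus_one(bounded_toy):
    """A byproduct branch carrying growth-max flux but no target-max flux is
    the canonical chg = -1 deletion candidate."""
    model, config = bounded_toy
    table = score_all(model, TARGET, config)
    branch = table.records["R_BRANCH2"]
    assert branch.v_gmax > 0
    assert branch.chg == pytest.approx(-1.0, abs=0.06)  # near the floor
    assert "R_BRANCH2" in table.eligible
    assert table.chg_min >= -1.0


def test_all_fluxes_equal_gives_zero_chg_min():
    table = _table({"R1": 0.0, "R2": 0.0}, {"R1": 1.0, "R2": 2.0})
    assert table.chg_min == 0.0
    assert select_next_deletion(table) is None


# -- the iterative loop ------------------------------------------------------


def test_two_route_trace_matches_hand_solution(two_route_model, two_route_config):
    """One deletion (route A) is found; the final state matches the
    exhaustively enumerated single-deletion optimum (mu=3, target=4)."""
    trace = run_aerith(two_route_model, "EX_tgt_e", two_route_config)
    assert trace.theoretical_max == pytest.approx(9.95, abs=1e-9)
    assert trace.deletions == ["R_A"]
    step0, step1 = trace.steps
    assert step0.biomass_flux == pytest.approx(10.0, abs=1e-9)
    assert step0.target_flux == pytest.approx(0.0, abs=1e-9)
    assert step1.biomass_flux == pytest.approx(3.0, abs=1e-9)
    assert step1.target_flux == pytest.approx(4.0, abs=1e-9)
    assert step1.yield_fraction == pytest.approx(4.0 / 9.95, abs=1e-9)
    assert trace.terminal_status == "infeasible_next"  # deleting B would kill growth
    oracle = brute_force_knockout_oracle(
        two_route_model, "EX_tgt_e", two_route_config, k_max=1
    )
    assert oracle[1][1] == pytest.approx(trace.final_target_flux, abs=1e-9)


def test_trace_biomass_monotone_and_target_bounded():
    for seed in range(5):
        model, config = build_bounded_toy(3, seed)
        trace = run_aerith(model, TARGET, config)
        mus = [s.biomass_flux for s in trace.steps]
        assert all(a >= b - 1e-6 for a, b in zip(mus, mus[1:]))
        assert all(s.target_flux <= trace.theoretical_max + 1e-6 for s in trace.steps)
        assert len(set(trace.deletions)) == len(trace.deletions)


def test_traces_are_deterministic(bounded_toy):
    model, config = bounded_toy
    first = run_aerith(model, TARGET, config)
    second = run_aerith(model, TARGET, config)
    assert first.deletions == second.deletions
    assert first.terminal_status == second.terminal_status
    assert [(s.biomass_flux, s.target_flux) for s in first.steps] == [
        (s.biomass_flux, s.target_flux) for s in second.steps
    ]


def test_nothing_to_delete_terminates_at_step_zero():
    """With no byproduct branch the only growth route is essential, so the
    search ends immediately with the baseline (nonzero) target flux."""
    model, config = build_bounded_toy(0, seed=0)
    trace = run_aerith(model, TARGET, config)
    assert trace.deletions == []
    assert trace.steps[0].target_flux > 0
    assert trace.terminal_status in ("no_candidate", "infeasible_next")


def test_unproducible_target_reported_not_raised(two_route_model, two_route_config):
    # glucose can only be taken up, never resecreted: its maximal exchange
    # flux is zero, so the search reports the target as not producible
    trace = run_aerith(two_route_model, "EX_glc__D_e", two_route_config)
    assert trace.terminal_status == "not_producible"
    assert trace.steps == []


def test_max_deletions_cap_respected(bounded_toy):
    model, config = bounded_toy
    trace = run_aerith(model, TARGET, config, RunConfig(max_deletions=1))
    assert len(trace.deletions) == 1
    assert trace.terminal_status == "max_deletions"


def test_stop_at_yobj_halts_early(bounded_toy):
    model, config = bounded_toy
    trace = run_aerith(
        model, TARGET, config, RunConfig(y_obj=0.5, stop_at_yobj=True)
    )
    assert trace.terminal_status == "target_reached"
    assert trace.steps[-1].target_flux >= 0.5


def test_essential_candidate_in_window_is_discarded_and_search_continues():
    """With no maintenance floor the ATP-generation reaction scores deep in
    the window yet its deletion kills growth; it must be discarded and the
    byproduct branches still found."""
    model, config = build_bounded_toy(2, seed=1, ngam=0.0)
    trace = run_aerith(model, TARGET, config)
    assert "ATPGEN" not in trace.deletions
    assert {"R_BRANCH1", "R_BRANCH2"} <= set(trace.deletions)


# -- evaluating fixed designs ------------------------------------------------


def test_evaluate_empty_design_is_wild_type(bounded_toy):
    model, config = bounded_toy
    trace = evaluate_design(model, TARGET, [], config)
    assert len(trace.steps) == 1
    baseline = run_aerith(model, TARGET, config, RunConfig(max_deletions=1))
    assert trace.steps[0].biomass_flux == pytest.approx(
        baseline.steps[0].biomass_flux, abs=1e-9
    )


def test_evaluate_reproduces_search_endpoint(bounded_toy):
    model, config = bounded_toy
    found = run_aerith(model, TARGET, config)
    replay = evaluate_design(model, TARGET, found.deletions, config)
    assert replay.steps[-1].target_flux == pytest.approx(
        found.final_target_flux, abs=1e-9
    )
    assert replay.steps[-1].biomass_flux == pytest.approx(
        found.steps[-1].biomass_flux, abs=1e-9
    )


def test_evaluate_flags_infeasible_prefix_and_continues(bounded_toy):
    model, config = bounded_toy
    trace = evaluate_design(
        model, TARGET, ["R_BRANCH1", "ATPGEN", "R_BRANCH2"], config
    )
    statuses = [s.status for s in trace.steps]
    assert statuses[0] == "optimal" and statuses[1] == "optimal"
    assert statuses[2] == "infeasible"  # ATP generation is essential (ngam=1)
    assert len(trace.steps) == 4  # evaluation continues past the lethal prefix
    assert math.isnan(trace.steps[2].biomass_flux)
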