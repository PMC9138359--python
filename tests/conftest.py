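import pytest

from aerith import (
    FBAConfig,
    ToySpec,
    apply_exchange_policy,
    load_model_from_dict,
    make_toy_network,
    toy_fba_config,
)

TARGET = "EX_tgt_e"

# Minimal two-route network with hand-computable optima: route A converts
# glucose to the growth precursor 1:1 while secreting a byproduct; route B is
# half as substrate-efficient but byproduct-free and capacity-capped at 3.
# Wild-type growth max routes everything through A (mu = 10, target 0);
# deleting A forces B (mu = 3) and frees 4 units of glucose for the target.
TWO_ROUTE_DICT = {
    "id": "two_route",
    "compartments": {"c": "cytosol", "e": "extracellular space"},
    "metabolites": [
        {"id": "glc__D_e", "name": "glucose", "compartment": "e"},
        {"id": "glc__D_c", "name": "glucose", "compartment": "c"},
        {"id": "p_c", "name": "precursor", "compartment": "c"},
        {"id": "byp_c", "name": "byproduct", "compartment": "c"},
        {"id": "byp_e", "name": "byproduct", "compartment": "e"},
        {"id": "tgt_c", "name": "target", "compartment": "c"},
        {"id": "tgt_e", "name": "target", "compartment": "e"},
    ],
    "reactions": [
        {"id": "EX_glc__D_e", "metabolites": {"glc__D_e": -1.0},
         "lower_bound": -10.0, "upper_bound": 1000.0},
        {"id": "GLCt", "metabolites": {"glc__D_e": -1.0, "glc__D_c": 1.0},
         "lower_bound": 0.0, "upper_bound": 1000.0},
        {"id": "R_A", "metabolites": {"glc__D_c": -1.0, "p_c": 1.0, "byp_c": 1.0},
         "lower_bound": 0.0, "upper_bound": 1000.0},
        {"id": "R_B", "metabolites": {"glc__D_c": -2.0, "p_c": 1.0},
         "lower_bound": 0.0, "upper_bound": 3.0},
        {"id": "TGT_SYN", "metabolites": {"glc__D_c": -1.0, "tgt_c": 1.0},
         "lower_bound": 0.0, "upper_bound": 1000.0},
        {"id": "TGTt", "metabolites": {"tgt_c": -1.0, "tgt_e": 1.0},
         "lower_bound": 0.0, "upper_bound": 1000.0},
        {"id": "BYPt", "metabolites": {"byp_c": -1.0, "byp_e": 1.0},
         "lower_bound": 0.0, "upper_bound": 1000.0},
        {"id": "EX_byp_e", "metabolites": {"byp_e": -1.0},
         "lower_bound": 0.0, "upper_bound": 1000.0},
        {"id": "EX_tgt_e", "metabolites": {"tgt_e": -1.0},
         "lower_bound": 0.0, "upper_bound": 1000.0},
        {"id": "BIOMASS_two", "metabolites": {"p_c": -1.0},
         "lower_bound": 0.0, "upper_bound": 1000.0, "objective_coefficient": 1.0},
    ],
    "genes": [],
    "version": "1",
}


@pytest.fixture()
def two_route_model():
    return load_model_from_dict(TWO_ROUTE_DICT, oxygen_exchange_id=None)


@pytest.fixture()
def two_route_config():
    return FBAConfig(
        gur_max=10.0,
        our_min=None,
        ngam=0.0,
        mu_min=0.05,
        native_byproduct_whitelist=frozenset({"EX_byp_e"}),
        co2_exchange_id=None,
    )


def build_bounded_toy(n_branches: int, seed: int, **config_overrides):
    """Seeded toy network with the exchange-bound policy already applied."""
    model = make_toy_network(ToySpec(n_byproduct_branches=n_branches, seed=seed))
    config = toy_fba_config(model, **config_overrides)
    return apply_exchange_policy(model, TARGET, config), config


@pytest.fixture()
def bounded_toy():
    return build_bounded_toy(2, seed=1)
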