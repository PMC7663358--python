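import math

import pytest

from toxsig.model_io import MetabolicNetwork, Metabolite, Reaction
from toxsig.synthetic import SyntheticScenario, make_toy_network, simulate_omics


@pytest.fixture
def chain_network():
    """SRC (ub 10) -> A_c -> B_e: the minimal production chain."""
    return MetabolicNetwork(
        [
            Metabolite(id="A_c", compartment="c"),
            Metabolite(id="B_e", compartment="e", extracellular=True),
        ],
        [
            Reaction(id="SRC", stoichiometry={"A_c": 1.0}, lower_bound=0.0,
                     upper_bound=10.0),
            Reaction(id="R2", stoichiometry={"A_c": -1.0, "B_e": 1.0},
                     lower_bound=0.0, upper_bound=math.inf, gpr="g1"),
        ],
    )


@pytest.fixture
def parallel_network(chain_network):
    """Chain plus a parallel isozyme route (R2b) for the middle step."""
    return MetabolicNetwork(
        list(chain_network.metabolites),
        list(chain_network.reactions)
        + [Reaction(id="R2b", stoichiometry={"A_c": -1.0, "B_e": 1.0},
                    lower_bound=0.0, upper_bound=math.inf, gpr="g2")],
    )


@pytest.fixture
def small_scenario():
    """A reduced scenario for fast unit tests."""
    return SyntheticScenario(
        n_pathways=3,
        reactions_per_pathway=3,
        n_background_genes=40,
        n_background_metabolites=8,
        perturbations=(("pathway_1", "up", 2.0), ("pathway_2", "down", 1.0)),
        n_per_group=4,
        missing_rate=0.05,
        seed=7,
    )


@pytest.fixture(scope="session")
def strong_signal_data():
    """Default strong-signal scenario dataset, shared across tests."""
    scenario = SyntheticScenario()
    network, truth = make_toy_network(scenario)
    gene_table, met_table, truth = simulate_omics(network, scenario, truth)
    return scenario, network, truth, gene_table, met_table
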