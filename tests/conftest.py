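import networkx as nx
import pytest
from hypothesis import settings

settings.register_profile("netstate", derandomize=True, deadline=None, database=None)
settings.load_profile("netstate")

from netstate import io, networks, outcomes
from netstate.features import assemble_feature_matrix
from netstate.simulate import SimConfig, simulate_cohort


def star(n_leaves: int = 4) -> nx.Graph:
    g = nx.Graph()
    for i in range(1, n_leaves + 1):
        g.add_edge("hub", f"leaf{i}", weight=1)
    return g


def triangle(w: int = 1) -> nx.Graph:
    g = nx.Graph()
    g.add_edge("a", "b", weight=w)
    g.add_edge("b", "c", weight=w)
    g.add_edge("a", "c", weight=w)
    return g


def path3(weights=(1, 1)) -> nx.Graph:
    g = nx.Graph()
    g.add_edge("a", "b", weight=weights[0])
    g.add_edge("b", "c", weight=weights[1])
    return g


@pytest.fixture(scope="session")
def tiny_config() -> SimConfig:
    """A 12-person, 3-week cohort small enough for repeated model fits."""
    return SimConfig(n_participants=12, n_weeks=3, block_sizes=(6, 6), seed=7)


@pytest.fixture(scope="session")
def tiny_cohort(tiny_config):
    return simulate_cohort(tiny_config)


@pytest.fixture(scope="session")
def tiny_tables(tiny_config, tiny_cohort):
    """(feature matrix, outcome table) of the tiny simulated cohort."""
    weeks = io.work_weeks(tiny_config.start_monday, tiny_config.n_weeks)
    nets = networks.build_all_networks(io.split_work_weeks(tiny_cohort.interactions, weeks))
    matrix = assemble_feature_matrix(nets)
    table = outcomes.build_outcome_table(io.split_work_weeks(tiny_cohort.ema, weeks))
    return matrix, table
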