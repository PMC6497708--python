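import networkx as nx
import numpy as np
import pytest

from netcoord import (
    EXPERIMENT,
    PreferenceAssignment,
    RunConfig,
    Trace,
)
from netcoord.networks import Network
from netcoord.subjects import generate_experiment
from netcoord.workflow import analyze


def build_network(n_nodes, edges, class_label="custom"):
    g = nx.Graph()
    g.add_nodes_from(range(n_nodes))
    g.add_edges_from(edges)
    return Network(g, class_label)


def make_trace(actions, prefs, network=None, scheme=EXPERIMENT, seed=0, learning_rate=0.5):
    """Trace from an explicit node x round matrix of 'A'/'B' actions."""
    actions = np.asarray(actions, dtype="<U1")
    n = actions.shape[0]
    if network is None:
        network = build_network(n, [(i, i + 1) for i in range(n - 1)])
    return Trace(actions, PreferenceAssignment(prefs), network, seed, learning_rate, scheme)


@pytest.fixture
def dyad():
    """Two connected players with opposite preferences."""
    network = build_network(2, [(0, 1)])
    prefs = PreferenceAssignment({0: "A", 1: "B"})
    return network, prefs


@pytest.fixture
def star6():
    """Hub (prefers A) with five leaves; balanced 3 A / 3 B overall."""
    network = build_network(6, [(0, i) for i in range(1, 6)])
    prefs = PreferenceAssignment({0: "A", 1: "A", 2: "A", 3: "B", 4: "B", 5: "B"})
    return network, prefs


@pytest.fixture
def bridged_cliques():
    """Two 5-cliques joined by one edge, opposite within-clique majorities."""
    edges = [(i, j) for i in range(5) for j in range(i + 1, 5)]
    edges += [(i, j) for i in range(5, 10) for j in range(i + 1, 10)]
    edges += [(4, 5)]
    network = build_network(10, edges)
    prefs = PreferenceAssignment(
        {0: "A", 1: "A", 2: "A", 3: "A", 4: "B", 5: "B", 6: "B", 7: "B", 8: "B", 9: "A"}
    )
    partition = [list(range(5)), list(range(5, 10))]
    return network, prefs, partition


@pytest.fixture(scope="session")
def default_study():
    """The full default synthetic study (12 sessions x 3 networks, seed 1)."""
    config = RunConfig(seed=1)
    sessions = generate_experiment(config)
    return config, sessions


@pytest.fixture(scope="session")
def default_summary(default_study):
    config, sessions = default_study
    return analyze(config, sessions)
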