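import itertools

import pytest

from triplefocus import Graph, PlantedConfig, generate_study


def make_graph(edges, extra_nodes=()):
    g = Graph()
    for v in extra_nodes:
        g.add_node(v)
    for u, v in edges:
        g.add_edge(u, v)
    return g


def clique_edges(nodes):
    return list(itertools.combinations(nodes, 2))


@pytest.fixture
def path3():
    return make_graph([("A", "B"), ("B", "C")])


@pytest.fixture
def star5():
    """Star: center C plus 4 leaves (n=5)."""
    return make_graph([("C", f"L{i}") for i in range(4)])


@pytest.fixture
def cycle5():
    nodes = ["A", "B", "C", "D", "E"]
    return make_graph(
        [(nodes[i], nodes[(i + 1) % 5]) for i in range(5)]
    )


@pytest.fixture
def two_k3_bridged():
    """Two triangles joined by one edge C-D; m = 7."""
    return make_graph(
        clique_edges(["A", "B", "C"]) + clique_edges(["D", "E", "F"]) + [("C", "D")]
    )


@pytest.fixture
def two_k4_bridged():
    """Two K4 cliques joined by one edge D-E."""
    return make_graph(
        clique_edges(["A", "B", "C", "D"])
        + clique_edges(["E", "F", "G", "H"])
        + [("D", "E")]
    )


@pytest.fixture(scope="session")
def benchmark_config():
    """The benchmark study conditions: 4 blocks x 25, 4 bridges."""
    return PlantedConfig(seed=7)


@pytest.fixture(scope="session")
def planted_study(benchmark_config):
    """One full synthetic instance at the benchmark conditions."""
    return generate_study(benchmark_config)
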