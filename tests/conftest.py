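import networkx as nx
import numpy as np
import pytest

from netprox import fixtures
from netprox.graphio import Interactome, load_interactome


def build_interactome(edges, evidence="literature"):
    inter = Interactome()
    for e in edges:
        inter.add_edge(e[0], e[1], e[2] if len(e) > 2 else evidence)
    return inter


@pytest.fixture
def path5():
    """Path graph N1-N2-N3-N4-N5."""
    return build_interactome([("N1", "N2"), ("N2", "N3"), ("N3", "N4"), ("N4", "N5")])


@pytest.fixture(scope="session")
def ba500(tmp_path_factory):
    """500-node Barabasi-Albert fixture interactome (heavy-tailed degrees)."""
    out = tmp_path_factory.mktemp("ba500")
    edge_path, _ = fixtures.make_graph(
        {"model": "barabasi_albert", "n_nodes": 500, "m": 3, "seed": 7}, out
    )
    return load_interactome(edge_path)


@pytest.fixture(scope="session")
def screen_fixture(tmp_path_factory):
    """Planted screen fixture: 5 drugs x 4 modules, one proximal pair."""
    out = tmp_path_factory.mktemp("screen_fx")
    return fixtures.make_screen_fixture(out, seed=1)


def random_interactome(rng: np.random.Generator, n_nodes: int, p: float) -> Interactome:
    """Connected-ish random graph for oracle sweeps (may be disconnected)."""
    g = nx.gnp_random_graph(n_nodes, p, seed=int(rng.integers(2**31)))
    inter = Interactome()
    for node in g.nodes:
        inter.g.add_node(f"N{node}")
    for a, b in g.edges:
        inter.add_edge(f"N{a}", f"N{b}")
    return inter


def brute_force_closest(inter: Interactome, a_set, b_set):
    """Independent oracle: all-pairs shortest paths via Floyd-Warshall, then
    the closest-proximity definition applied literally, excluding genes with
    no finite distance to the other set from sum and normalizer."""
    dist = dict(nx.floyd_warshall(inter.g))
    total, count = 0.0, 0
    for a in a_set:
        best = min(dist[a][b] for b in b_set)
        if np.isfinite(best):
            total += best
            count += 1
    for b in b_set:
        best = min(dist[a][b] for a in a_set)
        if np.isfinite(best):
            total += best
            count += 1
    if count == 0:
        return None
    return total / count
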