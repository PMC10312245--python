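"""Shared fixtures: a miniature synthetic world and small reference graphs."""

import itertools

import networkx as nx
import numpy as np
import pytest

import coopnet as cn


@pytest.fixture(scope="session")
def mini_cfg():
    """Tiny but non-degenerate simulation: 40 practices, 800 patients, 8 years."""
    return cn.test_scale_config(
        n_practices_initial=40, n_patients_initial=800, n_years=8,
        ip_cooperation_drift=0.06, seed=11)


@pytest.fixture(scope="session")
def mini_world(mini_cfg):
    practices = cn.generate_practices(mini_cfg)
    patients = cn.generate_patients(mini_cfg)
    claims = cn.generate_claims(mini_cfg, practices, patients)
    return mini_cfg, practices, patients, claims


@pytest.fixture(scope="session")
def mini_networks(mini_world):
    cfg, practices, patients, claims = mini_world
    return cn.build_networks(claims, practices, patients, cn.FilterConfig())


@pytest.fixture(scope="session")
def mini_node_metrics(mini_networks):
    return cn.node_metrics(mini_networks)


def _random_graphs(max_nodes=8, per_size=4, seed=5):
    rng = np.random.default_rng(seed)
    graphs = []
    for n in range(2, max_nodes + 1):
        for _ in range(per_size):
            p = rng.uniform(0.2, 0.8)
            g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2 ** 31)))
            graphs.append(g)
    return graphs


@pytest.fixture(scope="session")
def small_graphs():
    """Exhaustive oracle fixture suite: named + random graphs, <= 8 nodes."""
    named = [
        nx.path_graph(3),
        nx.path_graph(5),
        nx.cycle_graph(4),
        nx.cycle_graph(6),
        nx.star_graph(5),          # 6 nodes
        nx.complete_graph(5),
        nx.complete_graph(8),
        nx.barbell_graph(3, 1),    # 7 nodes
        nx.Graph([(0, 1), (2, 3)]),            # two disconnected edges
        nx.Graph([(0, 1), (1, 2), (3, 4), (4, 5), (5, 3)]),  # path + triangle
    ]
    return named + _random_graphs()


# ---------------------------------------------------------------------------
# brute-force oracles (kept deliberately naive and independent of the package)

def brute_density(g):
    n = g.number_of_nodes()
    pairs = list(itertools.combinations(g.nodes, 2))
    return sum(g.has_edge(a, b) for a, b in pairs) / len(pairs)


def brute_all_shortest_distances(g):
    """Floyd–Warshall on the node list; inf for disconnected pairs."""
    nodes = list(g.nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    n = len(nodes)
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0.0)
    for a, b in g.edges:
        d[idx[a], idx[b]] = d[idx[b], idx[a]] = 1.0
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    return nodes, d


def brute_mean_distance(g):
    _, d = brute_all_shortest_distances(g)
    iu = np.triu_indices(len(d), k=1)
    vals = d[iu]
    finite = vals[np.isfinite(vals)]
    return finite.mean() if finite.size else np.nan


def _all_shortest_paths(g, s, t):
    """Enumerate all shortest s-t paths by breadth-first layering."""
    try:
        dist = nx.shortest_path_length(g, s)
    except nx.NetworkXNoPath:  # pragma: no cover
        return []
    if t not in dist:
        return []

    def extend(path):
        last = path[-1]
        if last == t:
            yield path
            return
        for nb in g.neighbors(last):
            if nb in dist and dist[nb] == dist[last] + 1:
                yield from extend(path + [nb])

    return list(extend([s]))


def brute_betweenness(g):
    """Normalized betweenness by explicit shortest-path enumeration."""
    nodes = list(g.nodes)
    n = len(nodes)
    score = dict.fromkeys(nodes, 0.0)
    for s, t in itertools.combinations(nodes, 2):
        paths = _all_shortest_paths(g, s, t)
        if not paths:
            continue
        for path in paths:
            for v in path[1:-1]:
                score[v] += 1.0 / len(paths)
    norm = (n - 1) * (n - 2) / 2.0
    return {v: score[v] / norm for v in nodes}


def brute_eigenvector(g):
    """Dominant eigenvector of the dense adjacency via numpy eigh, unit max."""
    nodes = list(g.nodes)
    a = nx.to_numpy_array(g, nodelist=nodes)
    w, v = np.linalg.eigh(a)
    vec = np.abs(v[:, np.argmax(w)])
    return dict(zip(nodes, vec / vec.max()))
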