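"""Cooperation indicators on yearly patient-sharing networks.

Network level: density, mean distance (average shortest-path length over
connected pairs), and a transformed mean distance that expresses the observed
mean distance in standard deviations from the mean of uniform random graphs
with the same node and edge counts (a G(n, m) null), so the indicator tracks
network efficiency independently of density.  Node level: degree, eigenvector
and betweenness centrality, each with a within-year percentage ranking that
makes arbitrary-scale scores comparable across years.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import networkx as nx
import numpy as np
import pandas as pd
from scipy import sparse
from scipy.sparse.csgraph import shortest_path
from scipy.sparse.linalg import ArpackNoConvergence, eigsh
from scipy.stats import rankdata

from .errors import (ConfigurationError, DegenerateNullError,
                     NonConvergenceError, UndefinedMetricError)

__all__ = [
    "NullDistribution",
    "density",
    "mean_distance",
    "transformed_mean_distance",
    "degree_centrality",
    "eigenvector_centrality",
    "betweenness_centrality",
    "percentile_rank",
    "average_percentage_change",
    "node_metrics",
    "summarize_networks",
    "average_change_row",
    "heatmap_order",
    "export_heatmap_data",
]


@dataclass(frozen=True)
class NullDistribution:
    """Mean-distance distribution over G(n, m) random-graph replicates."""

    n_replicates: int
    null_mean: float
    null_sd: float
    seed: int


def density(net: nx.Graph) -> float:
    """Edges divided by possible edges, n(n-1)/2."""
    n = net.number_of_nodes()
    if n < 2:
        raise UndefinedMetricError("density undefined for fewer than 2 nodes")
    return net.number_of_edges() / (n * (n - 1) / 2)


def _mean_distance_from_adjacency(adj: sparse.spmatrix) -> float:
    """Average shortest-path length over connected unordered pairs."""
    d = shortest_path(adj, method="auto", directed=False, unweighted=True)
    iu = np.triu_indices_from(d, k=1)
    vals = d[iu]
    finite = vals[np.isfinite(vals)]
    if finite.size == 0:
        raise UndefinedMetricError("mean distance undefined: no connected "
                                   "pair of nodes")
    return float(finite.mean())


def mean_distance(net: nx.Graph) -> float:
    """Average number of edges on shortest paths between connected pairs.

    Disconnected pairs are excluded from the average (the usual convention
    for claims networks, which routinely contain isolated practices).
    """
    if net.number_of_edges() == 0:
        raise UndefinedMetricError("mean distance undefined: graph has no "
                                   "edges")
    adj = nx.to_scipy_sparse_array(net, format="csr", dtype=np.int8)
    return _mean_distance_from_adjacency(adj)


def _decode_pairs(codes: np.ndarray, n: int) -> tuple[np.ndarray, np.ndarray]:
    """Map linear indices in [0, C(n,2)) to upper-triangle (i, j) pairs."""
    # row i starts at offset i*n - i*(i+1)/2 - i ... solve quadratic instead
    b = 2 * n - 1
    i = np.floor((b - np.sqrt(b * b - 8.0 * codes)) / 2.0).astype(np.int64)
    start = i * (b - i) // 2
    j = codes - start + i + 1
    return i, j


def _gnm_mean_distances(n: int, m: int, n_replicates: int,
                        rng: np.random.Generator) -> np.ndarray:
    total = n * (n - 1) // 2
    out = np.empty(n_replicates)
    for r in range(n_replicates):
        codes = rng.choice(total, size=m, replace=False)
        i, j = _decode_pairs(codes.astype(np.int64), n)
        adj = sparse.coo_matrix(
            (np.ones(m, dtype=np.int8), (i, j)), shape=(n, n)).tocsr()
        out[r] = _mean_distance_from_adjacency(adj + adj.T)
    return out


def transformed_mean_distance(net: nx.Graph, n_replicates: int = 5000,
                              seed: int = 0) -> tuple[float, NullDistribution]:
    """Observed mean distance as a z-score against the G(n, m) null.

    Draws ``n_replicates`` uniform random graphs with the observed node and
    edge counts (holding density exactly fixed), computes their mean
    distances, and returns ``(observed - null_mean) / null_sd`` along with
    the null distribution summary.  Deterministic given ``seed``.
    """
    if n_replicates < 2:
        raise ConfigurationError("n_replicates must be >= 2")
    n, m = net.number_of_nodes(), net.number_of_edges()
    if m == 0:
        raise UndefinedMetricError("transformed mean distance needs >= 1 edge")
    observed = mean_distance(net)
    rng = np.random.default_rng(seed)
    dists = _gnm_mean_distances(n, m, n_replicates, rng)
    null_mean, null_sd = float(dists.mean()), float(dists.std(ddof=1))
    null = NullDistribution(n_replicates, null_mean, null_sd, seed)
    if null_sd == 0.0:
        raise DegenerateNullError(
            f"null distribution degenerate (all {n_replicates} replicates "
            f"have mean distance {null_mean}); z-score undefined")
    return (observed - null_mean) / null_sd, null


def degree_centrality(net: nx.Graph) -> pd.DataFrame:
    """Raw and normalized degree per node (normalized by n-1)."""
    n = net.number_of_nodes()
    if n < 2:
        raise UndefinedMetricError("degree centrality needs >= 2 nodes")
    deg = dict(net.degree())
    nodes = list(net.nodes)
    d = np.array([deg[v] for v in nodes], dtype=float)
    return pd.DataFrame({"practice_id": nodes, "degree": d.astype(int),
                         "degree_normalized": d / (n - 1)})


def eigenvector_centrality(net: nx.Graph, tol: float = 0.0,
                           max_iter: int = 10_000,
                           mode: str = "global") -> pd.Series:
    """Dominant-eigenvector scores of the binary adjacency, unit maximum.

    ``mode="global"`` runs power iteration on the whole adjacency, so nodes
    outside the dominant component get (near-)zero scores and rank low —
    appropriate when the giant component carries the cooperation structure.
    ``mode="per_component"`` computes scores within each connected component
    separately (each scaled to unit maximum).
    """
    if net.number_of_edges() == 0:
        raise UndefinedMetricError("eigenvector centrality needs >= 1 edge")
    if mode == "per_component":
        out = pd.Series(0.0, index=list(net.nodes))
        for comp in nx.connected_components(net):
            sub = net.subgraph(comp)
            if sub.number_of_edges() == 0:
                continue
            out.update(eigenvector_centrality(sub, tol, max_iter, "global"))
        return out
    if mode != "global":
        raise ConfigurationError(f"unknown mode {mode!r}")

    nodes = list(net.nodes)
    n = len(nodes)
    a = nx.to_scipy_sparse_array(net, nodelist=nodes, format="csr",
                                 dtype=float)
    if n == 2:  # ARPACK needs k < n-?; trivial case solved directly
        return pd.Series([1.0, 1.0], index=nodes)
    try:
        # Lanczos iteration on the largest algebraic eigenvalue; a fixed
        # positive start vector keeps the result deterministic, and Krylov
        # acceleration copes with near-degenerate dominant eigenvalues that
        # stall plain power iteration (e.g. two similar communities)
        _, vecs = eigsh(a, k=1, which="LA", v0=np.ones(n),
                        maxiter=max_iter, tol=tol)
    except ArpackNoConvergence as exc:
        raise NonConvergenceError(
            f"eigenvector iteration did not converge in {max_iter} "
            "iterations") from exc
    x = np.abs(vecs[:, 0])
    if x.max() == 0.0:
        raise UndefinedMetricError("degenerate zero eigenvector")
    return pd.Series(x / x.max(), index=nodes)


def betweenness_centrality(net: nx.Graph) -> pd.Series:
    """Shortest-path betweenness, normalized by (n-1)(n-2)/2.

    Equal-length shortest paths split the pair's weight evenly.
    """
    if net.number_of_nodes() < 3:
        raise UndefinedMetricError("betweenness needs >= 3 nodes")
    return pd.Series(nx.betweenness_centrality(net, normalized=True))


def percentile_rank(values) -> np.ndarray:
    """Ascending average ranks divided by n; the untied maximum maps to 1."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise UndefinedMetricError("percentile rank of an empty vector")
    return rankdata(values, method="average") / values.size


def average_percentage_change(series) -> float:
    """Mean of consecutive year-over-year percentage changes, in percent."""
    x = np.asarray(series, dtype=float)
    if x.size < 2:
        raise UndefinedMetricError("need >= 2 values for percentage changes")
    if (x[:-1] == 0).any():
        raise UndefinedMetricError("zero value makes a percentage change "
                                   "undefined")
    return float(100.0 * np.mean(x[1:] / x[:-1] - 1.0))


def node_metrics(nets: dict[int, nx.Graph], *,
                 ev_tol: float = 1e-10, ev_max_iter: int = 10_000,
                 ev_mode: str = "global") -> pd.DataFrame:
    """Per practice-year centralities and within-year percentage rankings.

    Years whose network has no edges (or too few nodes for a metric) yield
    zero centralities, with ranks still defined by the tie convention.
    """
    frames = []
    for year in sorted(nets):
        g = nets[year]
        nodes = list(g.nodes)
        if not nodes:
            continue
        n = len(nodes)
        deg = np.array([g.degree(v) for v in nodes], dtype=float)
        if g.number_of_edges() > 0:
            ev = eigenvector_centrality(g, ev_tol, ev_max_iter,
                                        ev_mode).reindex(nodes).to_numpy()
        else:
            ev = np.zeros(n)
        if n >= 3:
            be = betweenness_centrality(g).reindex(nodes).to_numpy()
        else:
            be = np.zeros(n)
        frames.append(pd.DataFrame({
            "practice_id": nodes,
            "year": year,
            "degree": deg.astype(int),
            "degree_normalized": deg / (n - 1) if n > 1 else 0.0,
            "ev_centrality": ev,
            "ev_rank": percentile_rank(ev),
            "be_centrality": be,
            "be_rank": percentile_rank(be),
        }))
    if not frames:
        return pd.DataFrame(columns=[
            "practice_id", "year", "degree", "degree_normalized",
            "ev_centrality", "ev_rank", "be_centrality", "be_rank"])
    return pd.concat(frames, ignore_index=True)


SUMMARY_COLUMNS = ["density", "mean_distance", "transformed_mean_distance",
                   "n_nodes", "n_ip_nodes", "n_patients"]


class SummaryResult(NamedTuple):
    per_year: pd.DataFrame
    average_change: pd.Series


def summarize_networks(nets: dict[int, nx.Graph], n_replicates: int = 5000,
                       seed: int = 0) -> SummaryResult:
    """Yearly network-level indicator table plus its average-change row.

    One row per year with density, mean distance, transformed mean distance,
    node count, IP node count and patient count, and a final series holding
    the mean year-over-year percentage change of each column.
    """
    if len(nets) < 2:
        raise UndefinedMetricError("need >= 2 years to summarize evolution")
    rows = []
    for k, year in enumerate(sorted(nets)):
        g = nets[year]
        z, _ = transformed_mean_distance(g, n_replicates, seed + k)
        rows.append({
            "year": year,
            "density": density(g),
            "mean_distance": mean_distance(g),
            "transformed_mean_distance": z,
            "n_nodes": g.number_of_nodes(),
            "n_ip_nodes": sum(1 for v in g.nodes
                              if g.nodes[v].get("is_ip", False)),
            "n_patients": g.graph.get("n_patients", np.nan),
        })
    per_year = pd.DataFrame(rows).set_index("year")
    return SummaryResult(per_year, average_change_row(per_year))


def average_change_row(per_year: pd.DataFrame) -> pd.Series:
    """Average year-over-year percentage change of each summary column."""
    out = {}
    for col in per_year.columns:
        try:
            out[col] = average_percentage_change(per_year[col].to_numpy())
        except UndefinedMetricError:
            out[col] = np.nan
    return pd.Series(out, name="average_pct_change")


_GROUP_ORDER = ["IP-GP", "IP-specialist", "non-IP-GP", "non-IP-specialist"]


def heatmap_order(net: nx.Graph) -> tuple[list, list[str]]:
    """Node ordering and group labels for the cooperation heat-map export.

    Groups practices into IP GPs, IP specialists, non-IP GPs and non-IP
    specialists (in that block order, alphabetical within a block).
    """
    def group(v):
        ip = net.nodes[v].get("is_ip", False)
        gp = net.nodes[v].get("specialty", "") == "GP"
        return f"{'IP' if ip else 'non-IP'}-{'GP' if gp else 'specialist'}"

    labelled = sorted(net.nodes, key=lambda v: (_GROUP_ORDER.index(group(v)),
                                                str(v)))
    return labelled, [group(v) for v in labelled]


def export_heatmap_data(net: nx.Graph, matrix_path, labels_path) -> None:
    """Write the group-ordered adjacency matrix and its label sidecar."""
    order, groups = heatmap_order(net)
    a = nx.to_numpy_array(net, nodelist=order, dtype=int)
    pd.DataFrame(a, index=order, columns=order).to_csv(matrix_path)
    pd.DataFrame({"practice_id": order, "group": groups}).to_csv(
        labels_path, index=False)
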