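"""Yearly patient-sharing networks from visit-level claims.

The construction follows the shared-patient approach to identifying
cooperation between physician practices: emergency visits and visits to
specialties with little involvement in care coordination (anaesthesiology,
radiology, neuropathology) are dropped, practices seeing fewer than 30
distinct patients in a year are excluded as inactive, the number of distinct
patients shared by each surviving pair of practices within the calendar year
is counted (a unipartite projection of the patient-practice bipartite graph),
and an undirected edge is kept where the count reaches a threshold (default
9 shared patients, at which a shared-patient tie is a reliable proxy for a
meaningful information-sharing relationship).  Isolated practices that pass
the activity filter remain as nodes.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import sparse

from .errors import ConfigurationError, ConsistencyError

__all__ = [
    "FilterConfig",
    "SharedPatientMatrix",
    "filter_claims",
    "active_practices",
    "count_shared_patients",
    "apply_threshold",
    "build_networks",
    "write_edge_list",
    "write_adjacency",
]

DEFAULT_EXCLUDED_SPECIALTIES = frozenset(
    {"Anaesthesiology", "Radiology", "Neuropathology"})


@dataclass(frozen=True)
class FilterConfig:
    """Claim filters and the edge threshold for network construction."""

    excluded_specialties: frozenset = DEFAULT_EXCLUDED_SPECIALTIES
    exclude_emergency: bool = True
    min_patients_per_year: int = 30
    shared_patient_threshold: int = 9

    def __post_init__(self):
        object.__setattr__(self, "excluded_specialties",
                           frozenset(self.excluded_specialties))
        if self.shared_patient_threshold < 1:
            raise ConfigurationError("shared_patient_threshold must be >= 1")
        if self.min_patients_per_year < 0:
            raise ConfigurationError("min_patients_per_year must be >= 0")


@dataclass
class SharedPatientMatrix:
    """Symmetric distinct-shared-patient counts between active practices."""

    year: int
    node_ids: list
    counts: np.ndarray  # (n, n) int, symmetric, zero diagonal

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        n = len(self.node_ids)
        if self.counts.shape != (n, n):
            raise ConsistencyError("counts shape does not match node_ids")
        if (self.counts != self.counts.T).any():
            raise ConsistencyError("shared-patient matrix must be symmetric")
        if np.diag(self.counts).any():
            raise ConsistencyError("shared-patient matrix diagonal must be 0")


def filter_claims(claims: pd.DataFrame, cfg: FilterConfig) -> pd.DataFrame:
    """Drop emergency visits and visits to excluded specialties.

    Row order of survivors is preserved and the input is left untouched.
    Specialty labels not on the exclusion list pass through unchanged.
    """
    keep = ~claims["specialty"].isin(cfg.excluded_specialties)
    if cfg.exclude_emergency:
        keep &= claims["visit_type"] != "emergency"
    return claims.loc[keep].copy()


def active_practices(claims: pd.DataFrame, year: int,
                     cfg: FilterConfig) -> set:
    """Practices with at least ``min_patients_per_year`` distinct patients.

    Expects claims already passed through :func:`filter_claims`.  A year
    absent from the claims yields the empty set.
    """
    sub = claims[claims["year"] == year]
    if sub.empty:
        return set()
    counts = sub.groupby("practice_id")["patient_id"].nunique()
    return set(counts.index[counts >= cfg.min_patients_per_year])


def count_shared_patients(claims: pd.DataFrame, year: int,
                          node_ids) -> SharedPatientMatrix:
    """Distinct patients shared by each pair of practices in one year.

    Computed as B^T B on the binary patient-by-practice incidence matrix of
    retained visits, diagonal zeroed: entry (i, j) is the number of distinct
    patients with at least one retained visit to both i and j.  Practices in
    ``node_ids`` without claims that year get zero rows/columns.
    """
    node_ids = list(node_ids)
    n = len(node_ids)
    pos = {p: k for k, p in enumerate(node_ids)}
    sub = claims[(claims["year"] == year)
                 & claims["practice_id"].isin(set(node_ids))]
    if sub.empty:
        return SharedPatientMatrix(year, node_ids,
                                   np.zeros((n, n), dtype=np.int64))
    pairs = sub[["patient_id", "practice_id"]].drop_duplicates()
    pat_codes, _ = pd.factorize(pairs["patient_id"])
    pr_codes = pairs["practice_id"].map(pos).to_numpy()
    b = sparse.csr_matrix(
        (np.ones(len(pairs), dtype=np.int64), (pat_codes, pr_codes)),
        shape=(pat_codes.max() + 1, n))
    counts = (b.T @ b).toarray()
    np.fill_diagonal(counts, 0)
    return SharedPatientMatrix(year, node_ids, counts)


def apply_threshold(m: SharedPatientMatrix, threshold: int) -> nx.Graph:
    """Binary undirected network: edge iff shared-patient count >= threshold.

    Isolated nodes are retained.  The retained shared count is stored as the
    ``shared_patients`` edge attribute for sensitivity reruns.
    """
    if threshold < 1:
        raise ConfigurationError("threshold must be >= 1")
    g = nx.Graph(year=m.year, threshold_used=threshold)
    g.add_nodes_from(m.node_ids)
    ii, jj = np.nonzero(np.triu(m.counts >= threshold, k=1))
    for i, j in zip(ii, jj):
        g.add_edge(m.node_ids[i], m.node_ids[j],
                   shared_patients=int(m.counts[i, j]))
    return g


def build_networks(claims: pd.DataFrame, practices: pd.DataFrame,
                   patient_years: pd.DataFrame,
                   cfg: FilterConfig) -> dict[int, nx.Graph]:
    """Compose the full construction for every year present in the claims.

    Pipeline per year: filter claims -> activity filter -> shared-patient
    counts -> threshold.  Node attributes ``is_ip``, ``specialty``,
    ``n_patients`` (distinct retained patients) and ``mean_charlson`` (mean
    score of those patients that year) are attached from the rosters.
    """
    known = set(practices["practice_id"])
    unknown = set(claims["practice_id"].unique()) - known
    if unknown:
        raise ConsistencyError(
            f"claims reference unknown practices: {sorted(unknown)[:5]}")
    attrs = practices.set_index("practice_id")
    charlson = patient_years.set_index(["patient_id", "year"])[
        "charlson_score"] if "charlson_score" in patient_years else None

    retained = filter_claims(claims, cfg)
    networks: dict[int, nx.Graph] = {}
    for year in sorted(claims["year"].unique()):
        nodes = sorted(active_practices(retained, year, cfg))
        m = count_shared_patients(retained, year, nodes)
        g = apply_threshold(m, cfg.shared_patient_threshold)
        sub = retained[(retained["year"] == year)
                       & retained["practice_id"].isin(set(nodes))]
        g.graph["n_patients"] = int(sub["patient_id"].nunique())
        by_pr = sub.groupby("practice_id")["patient_id"].agg(set)
        for node in g.nodes:
            pats = by_pr.get(node, set())
            g.nodes[node]["is_ip"] = bool(attrs.at[node, "is_ip"])
            g.nodes[node]["specialty"] = attrs.at[node, "specialty"]
            g.nodes[node]["n_patients"] = len(pats)
            if charlson is not None and pats:
                scores = charlson.reindex(
                    [(p, year) for p in pats]).dropna()
                g.nodes[node]["mean_charlson"] = (
                    float(scores.mean()) if len(scores) else float("nan"))
            else:
                g.nodes[node]["mean_charlson"] = float("nan")
        networks[year] = g
    return networks


def write_edge_list(g: nx.Graph, path) -> None:
    """Tab-separated edges: node_a, node_b, shared_count."""
    with open(path, "w") as fh:
        fh.write("node_a\tnode_b\tshared_patients\n")
        for a, b, d in g.edges(data=True):
            fh.write(f"{a}\t{b}\t{d.get('shared_patients', '')}\n")


def write_adjacency(g: nx.Graph, path, node_order=None) -> None:
    """Dense binary adjacency as CSV, rows/columns labelled by practice id."""
    order = list(node_order) if node_order is not None else sorted(g.nodes)
    a = nx.to_numpy_array(g, nodelist=order, dtype=int)
    pd.DataFrame(a, index=order, columns=order).to_csv(path)
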