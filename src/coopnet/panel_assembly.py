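"""Assembly of the unbalanced practice-year panel for the dynamic model.

One row per practice-year in which the practice was an active network node,
holding the chosen cooperation outcome (normalized degree or a centrality
percentage ranking), the integrated-practice indicator, the year index, the
practice-size and case-mix controls, and gap-aware lags of the outcome.
Practice fixed effects are not a column: they are eliminated inside the GMM
transformations downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .errors import ConfigurationError, ConsistencyError

__all__ = ["PanelSpec", "assemble_panel", "add_lags", "PANEL_COLUMNS"]

_OUTCOMES = {"degree": "degree_normalized", "ev_rank": "ev_rank",
             "be_rank": "be_rank"}

#: Lag order of the outcome per model, as used in the three headline models.
DEFAULT_N_LAGS = {"degree": 2, "ev_rank": 1, "be_rank": 1}

PANEL_COLUMNS = ["practice_id", "year", "year_index", "y", "ip", "ip_year",
                 "n_patients", "mean_charlson"]


@dataclass(frozen=True)
class PanelSpec:
    """Which outcome the panel carries and how many of its lags."""

    outcome: str = "degree"
    n_lags: int | None = None  # None -> per-outcome default
    use_normalized_degree: bool = True

    def __post_init__(self):
        if self.outcome not in _OUTCOMES:
            raise ConfigurationError(
                f"outcome must be one of {sorted(_OUTCOMES)}")
        if self.n_lags is not None and self.n_lags < 1:
            raise ConfigurationError("n_lags must be >= 1")

    @property
    def lags(self) -> int:
        return self.n_lags if self.n_lags is not None \
            else DEFAULT_N_LAGS[self.outcome]

    @property
    def outcome_column(self) -> str:
        if self.outcome == "degree" and not self.use_normalized_degree:
            return "degree"
        return _OUTCOMES[self.outcome]


def assemble_panel(nets: dict[int, nx.Graph], node_metrics: pd.DataFrame,
                   spec: PanelSpec) -> pd.DataFrame:
    """Build the practice-year panel from networks and node metrics.

    ``n_patients`` (distinct retained patients) and ``mean_charlson`` are
    read off the network node attributes, which the construction stage
    computed from retained claims; ``ip_year = ip * year_index`` is the
    interaction the model's coefficient of interest multiplies.  Lags per
    ``spec`` are appended via :func:`add_lags`.
    """
    if node_metrics.empty:
        raise ConsistencyError("node metrics table is empty")
    first_year = min(nets)
    col = spec.outcome_column
    rows = []
    for year in sorted(nets):
        g = nets[year]
        sub = node_metrics[node_metrics["year"] == year]
        for _, r in sub.iterrows():
            pid = r["practice_id"]
            if pid not in g.nodes:
                raise ConsistencyError(
                    f"practice {pid!r} in metrics but not in {year} network")
            attrs = g.nodes[pid]
            if "is_ip" not in attrs or "n_patients" not in attrs:
                raise ConsistencyError(
                    f"practice {pid!r} lacks node attributes in {year}")
            t = year - first_year
            ip = bool(attrs["is_ip"])
            rows.append({
                "practice_id": pid, "year": year, "year_index": t,
                "y": float(r[col]), "ip": ip,
                "ip_year": float(ip) * t,
                "n_patients": int(attrs["n_patients"]),
                "mean_charlson": float(attrs.get("mean_charlson", np.nan)),
            })
    panel = pd.DataFrame(rows, columns=PANEL_COLUMNS)
    if panel.duplicated(["practice_id", "year"]).any():
        raise ConsistencyError("duplicate (practice, year) rows")
    panel = panel.sort_values(["practice_id", "year"]).reset_index(drop=True)
    return add_lags(panel, spec.lags)


def add_lags(panel: pd.DataFrame, n_lags: int) -> pd.DataFrame:
    """Append gap-aware lag columns ``y_lag1..y_lagK``.

    ``y_lagk`` at (i, t) is y(i, t-k) when that exact row exists; gaps are
    never bridged — a practice unobserved in t-1 has a missing first lag in
    year t even if t-2 is observed.
    """
    out = panel.copy()
    base = panel[["practice_id", "year", "y"]]
    for k in range(1, n_lags + 1):
        shifted = base.rename(columns={"y": f"y_lag{k}"}).copy()
        shifted["year"] = shifted["year"] + k
        out = out.merge(shifted, on=["practice_id", "year"], how="left")
    return out
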