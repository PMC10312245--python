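"""End-to-end orchestration: simulate/ingest -> networks -> metrics ->
panel -> system GMM -> reports, plus the edge-threshold sensitivity rerun.

Every artifact written carries the configuration hash and global seed, so a
run is fully reproducible from its config file.  The pipeline accepts either
a simulation configuration or paths to claims/practice/patient CSV tables in
the same schema, so real claims extracts can be swapped in for the synthetic
generator unchanged.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd
import yaml

from . import dynamic_panel_gmm as gmm
from . import network_construction as nc
from . import network_metrics as nm
from . import panel_assembly as pa
from . import synthetic_claims as sc
from .errors import ConfigurationError, ConsistencyError, CoopnetError

__all__ = [
    "PipelineConfig",
    "PipelineResult",
    "SensitivityReport",
    "run_pipeline",
    "sensitivity_analysis",
    "render_table1",
    "load_tables",
]

log = logging.getLogger("coopnet")

SENSITIVITY_THRESHOLDS = (3, 6, 9, 12, 15)


@dataclass(frozen=True)
class PipelineConfig:
    """Full configuration of one pipeline run."""

    simulation: sc.SimulationConfig | None = None
    claims_path: str | None = None
    practices_path: str | None = None
    patients_path: str | None = None
    filters: nc.FilterConfig = field(default_factory=nc.FilterConfig)
    null_replicates: int = 5000
    outcomes: tuple = ("degree", "ev_rank", "be_rank")
    gmm_specs: dict = field(default_factory=dict)  # outcome -> GMMSpec
    output_dir: str | None = None
    global_seed: int = 1

    def __post_init__(self):
        if self.simulation is None and self.claims_path is None:
            raise ConfigurationError(
                "provide either a simulation config or claims/practice/"
                "patient table paths")
        for out in self.outcomes:
            if out not in pa.DEFAULT_N_LAGS:
                raise ConfigurationError(f"unknown outcome {out!r}")

    def gmm_spec_for(self, outcome: str) -> gmm.GMMSpec:
        if outcome in self.gmm_specs:
            return self.gmm_specs[outcome]
        lo, hi = gmm.DEFAULT_INSTRUMENT_LAGS[outcome]
        return gmm.GMMSpec(instrument_lag_min=lo, instrument_lag_max=hi,
                           n_y_lags=pa.DEFAULT_N_LAGS[outcome])

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.simulation is not None:
            d["simulation"] = self.simulation.to_dict()
        d["filters"] = {
            "excluded_specialties": sorted(self.filters.excluded_specialties),
            "exclude_emergency": self.filters.exclude_emergency,
            "min_patients_per_year": self.filters.min_patients_per_year,
            "shared_patient_threshold": self.filters.shared_patient_threshold,
        }
        d["gmm_specs"] = {k: dataclasses.asdict(v)
                          for k, v in self.gmm_specs.items()}
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        sim = raw.pop("simulation", None)
        filters = raw.pop("filters", None)
        specs = raw.pop("gmm_specs", {})
        kwargs = dict(raw)
        if sim is not None:
            kwargs["simulation"] = sc.SimulationConfig(**sim)
        if filters is not None:
            filters = dict(filters)
            if "excluded_specialties" in filters:
                filters["excluded_specialties"] = frozenset(
                    filters["excluded_specialties"])
            kwargs["filters"] = nc.FilterConfig(**filters)
        kwargs["gmm_specs"] = {k: gmm.GMMSpec(**v) for k, v in specs.items()}
        if "outcomes" in kwargs:
            kwargs["outcomes"] = tuple(kwargs["outcomes"])
        return cls(**kwargs)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


class PipelineResult(NamedTuple):
    claims: pd.DataFrame
    practices: pd.DataFrame
    patients: pd.DataFrame
    networks: dict
    summary: nm.SummaryResult
    node_metrics: pd.DataFrame
    panels: dict
    gmm_results: dict


class SensitivityReport(NamedTuple):
    """Per-threshold network summaries and the IP-by-year coefficient."""

    summaries: dict            # threshold -> per-year summary DataFrame
    theta3: pd.DataFrame       # threshold x outcome: coef, se, p
    degenerate: list           # thresholds where the network lost all edges


def load_tables(config: PipelineConfig):
    """Simulate or read the claims, practice and patient tables."""
    if config.simulation is not None:
        simcfg = config.simulation.replace(seed=config.global_seed)
        log.info("simulating claims: %d practices, %d patients, %d years",
                 simcfg.n_practices_initial, simcfg.n_patients_initial,
                 simcfg.n_years)
        practices = sc.generate_practices(simcfg)
        patients = sc.generate_patients(simcfg)
        claims = sc.generate_claims(simcfg, practices, patients)
        return claims, practices, patients
    for name in ("claims_path", "practices_path", "patients_path"):
        p = getattr(config, name)
        if p is None or not Path(p).exists():
            raise ConsistencyError(
                f"ingestion stage: {name}={p!r} does not exist")
    claims = pd.read_csv(config.claims_path)
    practices = pd.read_csv(config.practices_path)
    patients = pd.read_csv(config.patients_path)
    return claims, practices, patients


def _fit_models(networks, node_metrics, config: PipelineConfig):
    panels, results = {}, {}
    for outcome in config.outcomes:
        spec = pa.PanelSpec(outcome=outcome)
        panel = pa.assemble_panel(networks, node_metrics, spec)
        panels[outcome] = panel
        log.info("panel[%s]: %d rows, %d practices", outcome, len(panel),
                 panel["practice_id"].nunique())
        results[outcome] = gmm.fit_system_gmm(panel,
                                              config.gmm_spec_for(outcome))
    return panels, results


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute every stage and (optionally) write the report bundle."""
    claims, practices, patients = load_tables(config)
    log.info("claims: %d rows over years %s..%s", len(claims),
             claims["year"].min() if len(claims) else "-",
             claims["year"].max() if len(claims) else "-")

    networks = nc.build_networks(claims, practices, patients, config.filters)
    for year, g in networks.items():
        if g.number_of_nodes() == 0:
            log.warning("year %s network has zero nodes", year)
    summary = nm.summarize_networks(networks, config.null_replicates,
                                    seed=config.global_seed)
    metrics = nm.node_metrics(networks)
    panels, results = _fit_models(networks, metrics, config)

    result = PipelineResult(claims, practices, patients, networks, summary,
                            metrics, panels, results)
    if config.output_dir is not None:
        _write_bundle(result, config)
    return result


def _write_bundle(result: PipelineResult, config: PipelineConfig) -> None:
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = {"config_hash": config.config_hash(),
            "global_seed": config.global_seed,
            "config": config.to_dict()}
    (out / "metadata.json").write_text(json.dumps(meta, indent=2,
                                                  default=str))
    result.claims.to_csv(out / "claims.csv", index=False)
    result.practices.to_csv(out / "practices.csv", index=False)
    result.patients.to_csv(out / "patient_years.csv", index=False)
    summary = result.summary.per_year.copy()
    summary.loc["average_pct_change"] = result.summary.average_change
    summary.to_csv(out / "network_summary.csv")
    result.node_metrics.to_csv(out / "node_metrics.csv", index=False)
    (out / "table1.txt").write_text(render_table1(result.summary.per_year))
    years = sorted(result.networks)
    for year in (years[0], years[-1]):
        g = result.networks[year]
        nc.write_edge_list(g, out / f"edges_{year}.tsv")
        nm.export_heatmap_data(g, out / f"heatmap_{year}.csv",
                               out / f"heatmap_{year}_labels.csv")
    for outcome, res in result.gmm_results.items():
        result.panels[outcome].to_csv(out / f"panel_{outcome}.csv",
                                      index=False)
        payload = res.to_dict()
        payload["config_hash"] = meta["config_hash"]
        payload["global_seed"] = config.global_seed
        (out / f"gmm_{outcome}.json").write_text(
            json.dumps(payload, indent=2))
        (out / f"gmm_{outcome}.txt").write_text(
            gmm.format_report(res, f"System GMM: {outcome}"))


def sensitivity_analysis(claims: pd.DataFrame, practices: pd.DataFrame,
                         patients: pd.DataFrame, config: PipelineConfig,
                         thresholds=SENSITIVITY_THRESHOLDS,
                         outcomes: tuple | None = None) -> SensitivityReport:
    """Re-run construction through GMM across the edge-threshold ladder.

    Reports, per threshold, the yearly network summary and the coefficient
    of the IP-by-year interaction (sign and significance) for each outcome.
    A threshold that empties the network is reported as degenerate rather
    than failing the whole analysis.
    """
    outcomes = config.outcomes if outcomes is None else outcomes
    summaries, degenerate, rows = {}, [], []
    for thr in sorted(thresholds):
        filters = dataclasses.replace(config.filters,
                                      shared_patient_threshold=thr)
        nets = nc.build_networks(claims, practices, patients, filters)
        if all(g.number_of_edges() == 0 for g in nets.values()):
            degenerate.append(thr)
            continue
        try:
            summ = nm.summarize_networks(nets, config.null_replicates,
                                         seed=config.global_seed)
            summaries[thr] = summ.per_year
        except CoopnetError as exc:
            log.warning("threshold %d: summary degenerate (%s)", thr, exc)
            degenerate.append(thr)
            continue
        metrics = nm.node_metrics(nets)
        for outcome in outcomes:
            spec = pa.PanelSpec(outcome=outcome)
            panel = pa.assemble_panel(nets, metrics, spec)
            try:
                res = gmm.fit_system_gmm(panel, config.gmm_spec_for(outcome))
            except CoopnetError as exc:
                log.warning("threshold %d, outcome %s: estimation failed "
                            "(%s)", thr, outcome, exc)
                continue
            rows.append({
                "threshold": thr, "outcome": outcome,
                "theta3": res.coefficients["ip_year"],
                "se": res.se["ip_year"],
                "p": res.pvalues["ip_year"],
                "significant_5pct": res.pvalues["ip_year"] < 0.05,
            })
    theta3 = pd.DataFrame(rows, columns=["threshold", "outcome", "theta3",
                                         "se", "p", "significant_5pct"])
    return SensitivityReport(summaries, theta3, degenerate)


_TABLE1_HEADER = ["YEAR", "DENSITY", "MEAN DISTANCE",
                  "TRANSFORMED MEAN DISTANCE", "N PRACTICES",
                  "N INTEGRATED PRACTICES", "TOTAL PATIENTS"]


def render_table1(per_year: pd.DataFrame) -> str:
    """Format the yearly summary plus its average-percentage-change row."""
    if len(per_year) < 2:
        raise ConfigurationError("need >= 2 yearly summaries")
    lines = ["\t".join(_TABLE1_HEADER)]
    for year, r in per_year.iterrows():
        lines.append("\t".join([
            str(year), f"{r['density']:.3f}", f"{r['mean_distance']:.3f}",
            f"{r['transformed_mean_distance']:.2f}",
            str(int(r['n_nodes'])), str(int(r['n_ip_nodes'])),
            f"{int(r['n_patients']):,}" if np.isfinite(r['n_patients'])
            else "-",
        ]))
    avg = nm.average_change_row(per_year)
    lines.append("\t".join(
        ["Average percentage change"]
        + [f"{avg[c]:.2f}%" if np.isfinite(avg[c]) else "-"
           for c in ["density", "mean_distance", "transformed_mean_distance",
                     "n_nodes", "n_ip_nodes", "n_patients"]]))
    return "\n".join(lines)
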