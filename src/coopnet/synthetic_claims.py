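"""Seeded synthetic outpatient-claims generator.

Real claims data linking pseudonymous patients to physician practices are
almost never publicly available, so this module emulates the statistical
structure a regional patient-sharing analysis assumes: a roster of practices
(a minority participating in an integrated healthcare system, "IPs"), a
growing patient population with right-skewed Charlson comorbidity scores, and
visit records in which patients spread their care across practices according
to a community-block attachment model.  A latent cooperation process gives IP
practices an attachment bonus that grows linearly in time, so that under the
generator's defaults integrated practices drift toward network centrality —
the signal the downstream panel model is designed to detect.

The module also provides a direct simulator of the node-level dynamic panel
model (an AR(1) outcome with year trend, IP-by-year interaction, practice
size and case-mix covariates, fixed effects and white noise), used to test
the system-GMM estimator against known coefficients.

All generators are deterministic given their seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ConsistencyError

__all__ = [
    "SimulationConfig",
    "full_scale_config",
    "test_scale_config",
    "generate_practices",
    "generate_patients",
    "generate_claims",
    "generate_panel_from_model",
    "SPECIALTIES",
    "EXCLUDED_SPECIALTIES",
]

#: Excluded from network construction downstream; generated here on purpose so
#: the filters have something to remove.
EXCLUDED_SPECIALTIES = ("Anaesthesiology", "Radiology", "Neuropathology")

#: Controlled specialty vocabulary.  Roughly half the practices are GPs, in
#: line with a rural outpatient sector.
SPECIALTIES = (
    "GP",
    "Internal Medicine",
    "Orthopaedics",
    "Gynaecology",
    "Dermatology",
    "Paediatrics",
    "Surgery",
    "Ophthalmology",
    "ENT",
) + EXCLUDED_SPECIALTIES

_GP_SHARE = 0.5


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic claims world.

    Defaults (see :func:`full_scale_config`) are calibrated to the magnitudes
    of a 14-wave regional outpatient network: ~200 practices of which ~14%
    participate in the integrated system, ~26,000 patients growing ~1%/year.
    """

    n_practices_initial: int = 197
    ip_fraction: float = 28 / 197
    n_patients_initial: int = 25_979
    n_years: int = 14
    first_year: int = 2004
    patient_growth_rate: float = 0.0097
    practice_growth_rate: float = 0.0115
    visits_per_patient_year: float = 3.5
    community_count: int = 8
    community_attachment: float = 14.0
    practice_size_sigma: float = 0.5
    ip_cooperation_drift: float = 0.03
    emergency_fraction: float = 0.08
    excluded_specialty_fraction: float = 0.08
    charlson_mean: float = 2.0
    charlson_dispersion: float = 1.6
    practice_turnover_rate: float = 0.08
    seed: int = 1

    def validate(self) -> None:
        for name in ("ip_fraction", "emergency_fraction",
                     "excluded_specialty_fraction", "patient_growth_rate",
                     "practice_growth_rate", "practice_turnover_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name}={v!r} must lie in [0, 1]")
        for name in ("n_practices_initial", "n_patients_initial",
                     "community_count"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be >= 1")
        if self.n_years < 3:
            raise ConfigurationError(
                "n_years must be >= 3 (a lagged panel model needs it)")
        if self.visits_per_patient_year < 0:
            raise ConfigurationError("visits_per_patient_year must be >= 0")
        if self.ip_cooperation_drift < 0:
            raise ConfigurationError("ip_cooperation_drift must be >= 0")
        if self.charlson_mean < 0 or self.charlson_dispersion < 0:
            raise ConfigurationError("Charlson mean/dispersion must be >= 0")
        if self.community_attachment < 0:
            raise ConfigurationError("community_attachment must be >= 0")
        if self.practice_size_sigma < 0:
            raise ConfigurationError("practice_size_sigma must be >= 0")

    @property
    def years(self) -> range:
        return range(self.first_year, self.first_year + self.n_years)

    def replace(self, **kwargs) -> "SimulationConfig":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def full_scale_config(**overrides) -> SimulationConfig:
    """Full-scale configuration (~200 practices, ~26k patients, 14 years)."""
    return SimulationConfig(**overrides)


def test_scale_config(**overrides) -> SimulationConfig:
    """Small configuration for fast tests: 60 practices, 2,000 patients."""
    base = dict(
        n_practices_initial=60,
        ip_fraction=0.15,
        n_patients_initial=2_000,
        n_years=14,
        visits_per_patient_year=3.5,
        community_count=5,
        community_attachment=14.0,
        ip_cooperation_drift=0.04,
    )
    base.update(overrides)
    return SimulationConfig(**base)


def _yearly_targets(n0: int, rate: float, n_years: int) -> np.ndarray:
    """Deterministic yearly roster sizes n0*(1+rate)^t, rounded."""
    t = np.arange(n_years)
    return np.rint(n0 * (1.0 + rate) ** t).astype(int)


def _draw_specialties(rng: np.random.Generator, n: int,
                      excluded_fraction: float) -> np.ndarray:
    """Sample specialty labels: GPs, regular specialists, excluded specialties."""
    n_excl = len(EXCLUDED_SPECIALTIES)
    others = [s for s in SPECIALTIES
              if s != "GP" and s not in EXCLUDED_SPECIALTIES]
    p = np.empty(len(SPECIALTIES))
    labels = list(SPECIALTIES)
    rest = 1.0 - _GP_SHARE - excluded_fraction
    if rest < 0:
        raise ConfigurationError("excluded_specialty_fraction too large")
    for i, s in enumerate(labels):
        if s == "GP":
            p[i] = _GP_SHARE
        elif s in EXCLUDED_SPECIALTIES:
            p[i] = excluded_fraction / n_excl
        else:
            p[i] = rest / len(others)
    return rng.choice(labels, size=n, p=p)


def generate_practices(config: SimulationConfig,
                       rng_seed: int | None = None) -> pd.DataFrame:
    """Generate the practice roster with entry/exit over the study years.

    Returns a DataFrame with one row per practice:
    ``practice_id, is_ip, specialty, community, entry_year, exit_year``
    (both years inclusive).  The first-year roster has exactly
    ``n_practices_initial`` practices with ``round(ip_fraction * n)`` IPs;
    afterwards practices exit with probability ``practice_turnover_rate`` per
    year and new entrants keep the active count on the configured net growth
    path.  The panel is therefore unbalanced by construction.
    """
    config.validate()
    rng = np.random.default_rng(config.seed if rng_seed is None else rng_seed)
    years = list(config.years)
    targets = _yearly_targets(config.n_practices_initial,
                              config.practice_growth_rate, config.n_years)

    n0 = config.n_practices_initial
    n_ip0 = int(round(config.ip_fraction * n0))
    is_ip = np.zeros(n0, dtype=bool)
    is_ip[rng.choice(n0, size=n_ip0, replace=False)] = True

    records: list[dict] = []
    next_id = 0

    def _new_practice(entry_year: int, ip: bool, specialty: str) -> dict:
        nonlocal next_id
        rec = {
            "practice_id": f"PR{next_id:05d}",
            "is_ip": bool(ip),
            "specialty": specialty,
            "community": int(rng.integers(config.community_count)),
            "size_weight": float(rng.lognormal(0.0, config.practice_size_sigma))
            if config.practice_size_sigma > 0 else 1.0,
            "entry_year": entry_year,
            "exit_year": years[-1],
        }
        next_id += 1
        return rec

    specs0 = _draw_specialties(rng, n0, config.excluded_specialty_fraction)
    for i in range(n0):
        records.append(_new_practice(years[0], is_ip[i], specs0[i]))
    active = list(range(n0))

    for t in range(1, config.n_years):
        year = years[t]
        # random exits, then deterministic top-up to the growth target
        exits = rng.random(len(active)) < config.practice_turnover_rate
        surviving = []
        for idx, gone in zip(active, exits):
            if gone and len(active) > 1:
                records[idx]["exit_year"] = year - 1
            else:
                surviving.append(idx)
        n_new = max(int(targets[t]) - len(surviving), 0)
        if n_new:
            specs = _draw_specialties(rng, n_new,
                                      config.excluded_specialty_fraction)
            ips = rng.random(n_new) < config.ip_fraction
            for j in range(n_new):
                records.append(_new_practice(year, ips[j], specs[j]))
                surviving.append(len(records) - 1)
        active = surviving

    return pd.DataFrame.from_records(records)


def _charlson_draw(rng: np.random.Generator, n: int, mean: float,
                   sd: float) -> np.ndarray:
    """Right-skewed nonnegative scores: gamma with given mean and SD."""
    if mean == 0 or sd == 0:
        return np.full(n, float(mean))
    shape = (mean / sd) ** 2
    scale = sd ** 2 / mean
    return rng.gamma(shape, scale, size=n)


def generate_patients(config: SimulationConfig,
                      rng_seed: int | None = None) -> pd.DataFrame:
    """Generate patient-year records ``(patient_id, year, charlson_score)``.

    The enrolled population follows the configured growth path (patients stay
    enrolled once they appear); Charlson comorbidity scores are drawn fresh
    each year from a gamma distribution with mean ``charlson_mean`` and
    standard deviation ``charlson_dispersion``.
    """
    config.validate()
    rng = np.random.default_rng(
        (config.seed + 1) if rng_seed is None else rng_seed)
    targets = _yearly_targets(config.n_patients_initial,
                              config.patient_growth_rate, config.n_years)
    n_total = int(targets.max())
    ids = np.array([f"PT{i:06d}" for i in range(n_total)])

    frames = []
    for t, year in enumerate(config.years):
        n_t = int(targets[t])
        frames.append(pd.DataFrame({
            "patient_id": ids[:n_t],
            "year": year,
            "charlson_score": _charlson_draw(
                rng, n_t, config.charlson_mean, config.charlson_dispersion),
        }))
    return pd.concat(frames, ignore_index=True)


CLAIMS_COLUMNS = ["patient_id", "practice_id", "year", "visit_type",
                  "specialty"]


def generate_claims(config: SimulationConfig, practices: pd.DataFrame,
                    patients: pd.DataFrame,
                    rng_seed: int | None = None) -> pd.DataFrame:
    """Generate visit-level claims from the practice and patient rosters.

    Each patient-year draws ``Poisson(visits_per_patient_year)`` visits.  A
    visit lands on an active practice with probability proportional to

    ``(1 + community_attachment * same_community)
      * (1 + ip_cooperation_drift * year_index * is_ip)``

    so patients favour practices in their own community block, and — when the
    cooperation drift is positive — increasingly favour integrated practices
    as years pass.  With zero drift, IP and non-IP practices are exchangeable
    conditional on community.  ``emergency_fraction`` of visits are flagged
    as emergencies; excluded-specialty practices receive visits like any
    other so downstream filters have work to do.
    """
    config.validate()
    required = {"practice_id", "is_ip", "community", "entry_year",
                "exit_year", "specialty"}
    if not required.issubset(practices.columns):
        raise ConsistencyError("practice roster missing columns "
                               f"{sorted(required - set(practices.columns))}")
    if not {"patient_id", "year"}.issubset(patients.columns):
        raise ConsistencyError("patient table missing patient_id/year")
    bad_years = set(patients["year"].unique()) - set(config.years)
    if bad_years:
        raise ConsistencyError(f"patient years {sorted(bad_years)} outside "
                               "the configured simulation range")

    rng = np.random.default_rng(
        (config.seed + 2) if rng_seed is None else rng_seed)

    all_patients = pd.Index(patients["patient_id"].unique())
    patient_comm = pd.Series(
        rng.integers(config.community_count, size=len(all_patients)),
        index=all_patients)

    out_frames = []
    for t, year in enumerate(config.years):
        act = practices[(practices["entry_year"] <= year)
                        & (practices["exit_year"] >= year)]
        if act.empty:
            continue
        pr_ids = act["practice_id"].to_numpy()
        pr_spec = act["specialty"].to_numpy()
        pr_comm = act["community"].to_numpy()
        size_w = act["size_weight"].to_numpy(dtype=float) \
            if "size_weight" in act.columns else np.ones(len(act))
        ip_bonus = size_w * (1.0 + config.ip_cooperation_drift * t
                             * act["is_ip"].to_numpy(dtype=float))

        pats = patients.loc[patients["year"] == year, "patient_id"].to_numpy()
        if len(pats) == 0:
            continue
        n_visits = rng.poisson(config.visits_per_patient_year, size=len(pats))
        comm = patient_comm.loc[pats].to_numpy()

        pat_col, pr_col = [], []
        for c in range(config.community_count):
            in_c = comm == c
            total = int(n_visits[in_c].sum())
            if total == 0:
                continue
            w = (1.0 + config.community_attachment * (pr_comm == c)) * ip_bonus
            w = w / w.sum()
            chosen = rng.choice(len(pr_ids), size=total, p=w)
            pat_col.append(np.repeat(pats[in_c], n_visits[in_c]))
            pr_col.append(chosen)
        if not pat_col:
            continue
        pat_col = np.concatenate(pat_col)
        pr_col = np.concatenate(pr_col)
        emergency = rng.random(len(pat_col)) < config.emergency_fraction
        out_frames.append(pd.DataFrame({
            "patient_id": pat_col,
            "practice_id": pr_ids[pr_col],
            "year": year,
            "visit_type": np.where(emergency, "emergency", "routine"),
            "specialty": pr_spec[pr_col],
        }))

    if not out_frames:
        return pd.DataFrame(columns=CLAIMS_COLUMNS)
    claims = pd.concat(out_frames, ignore_index=True)
    return claims.sort_values(["year", "patient_id"],
                              kind="stable").reset_index(drop=True)


def generate_panel_from_model(theta, fe_sd: float, noise_sd: float,
                              n_nodes: int, n_years: int,
                              rng_seed: int = 0, *,
                              ip_fraction: float = 0.15,
                              first_year: int = 2004,
                              burn_in: int = 25) -> pd.DataFrame:
    """Simulate the node-level dynamic panel model directly.

    The outcome follows

    ``y_it = th1*y_{i,t-1} + th2*year_t + th3*ip_i*year_t
             + th4*npat_it + th5*charlson_it + fe_i + eps_it``

    with ``fe_i ~ N(0, fe_sd^2)`` and ``eps_it ~ N(0, noise_sd^2)``; ``year``
    enters as the 0-based year index.  Practice size ``npat`` is drawn
    N(100, 20^2) truncated at 1 and the Charlson covariate from a gamma with
    mean 2 and SD 0.7.  A burn-in (year index frozen at 0) puts each series
    near its stationary path before the first recorded wave, which keeps the
    initial-conditions (mean stationarity) assumption of the level moment
    conditions satisfied.

    Returns a balanced panel DataFrame with columns ``practice_id, year,
    year_index, y, ip, n_patients, mean_charlson`` plus the latent truth
    ``fe`` and ``eps`` so tests can reconstruct the identity exactly.
    """
    theta = np.asarray(theta, dtype=float)
    if theta.shape != (5,):
        raise ConfigurationError("theta must have 5 entries (th1..th5)")
    th1, th2, th3, th4, th5 = theta
    if abs(th1) >= 1:
        raise ConfigurationError(f"|theta1|={abs(th1)} >= 1: "
                                 "nonstationary dynamics rejected")
    if n_years < 4:
        raise ConfigurationError("n_years must be >= 4")
    if fe_sd < 0 or noise_sd < 0:
        raise ConfigurationError("fe_sd and noise_sd must be >= 0")

    rng = np.random.default_rng(rng_seed)
    ip = (rng.random(n_nodes) < ip_fraction).astype(float)
    fe = rng.normal(0.0, fe_sd, size=n_nodes) if fe_sd > 0 else \
        np.zeros(n_nodes)

    def _covariates(size):
        npat = np.maximum(rng.normal(100.0, 20.0, size=size), 1.0)
        charl = rng.gamma((2.0 / 0.7) ** 2, 0.7 ** 2 / 2.0, size=size)
        return npat, charl

    npat = np.empty((n_years, n_nodes))
    charl = np.empty((n_years, n_nodes))
    for t in range(n_years):
        npat[t], charl[t] = _covariates(n_nodes)

    # burn-in at year_index 0 covariate levels
    npat0, charl0 = _covariates(n_nodes)
    mu0 = th2 * 0.0 + th3 * ip * 0.0 + th4 * npat0 + th5 * charl0 + fe
    y = mu0 / (1.0 - th1) if th1 != 0 else mu0.copy()
    for _ in range(burn_in):
        eps = rng.normal(0.0, noise_sd, n_nodes) if noise_sd > 0 else 0.0
        y = th1 * y + mu0 + eps

    rows_y = np.empty((n_years, n_nodes))
    rows_eps = np.empty((n_years, n_nodes))
    for t in range(n_years):
        eps = rng.normal(0.0, noise_sd, n_nodes) if noise_sd > 0 else \
            np.zeros(n_nodes)
        y = (th1 * y + th2 * t + th3 * ip * t + th4 * npat[t]
             + th5 * charl[t] + fe + eps)
        rows_y[t] = y
        rows_eps[t] = eps

    idx_node = np.repeat(np.arange(n_nodes), n_years)
    idx_t = np.tile(np.arange(n_years), n_nodes)
    return pd.DataFrame({
        "practice_id": np.array([f"N{i:05d}" for i in range(n_nodes)]
                                )[idx_node],
        "year": first_year + idx_t,
        "year_index": idx_t,
        "y": rows_y[idx_t, idx_node],
        "ip": ip[idx_node].astype(bool),
        "ip_year": ip[idx_node] * idx_t,
        "n_patients": npat[idx_t, idx_node],
        "mean_charlson": charl[idx_t, idx_node],
        "fe": fe[idx_node],
        "eps": rows_eps[idx_t, idx_node],
    })
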