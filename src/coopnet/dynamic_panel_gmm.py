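"""Two-step system GMM for the dynamic cooperation panel.

Estimates the dynamic panel model

``y_it = th1*y_{i,t-1} (+ further lags) + th2*year + th3*ip*year
         + th4*n_patients + th5*charlson + fe_i + eps_it``

by the Blundell–Bond system estimator: first-differenced equations, which
eliminate the practice fixed effect, instrumented by lagged levels of the
outcome (a configurable lag window, one instrument per period-lag pair, or
collapsed); and level equations instrumented by the lagged first difference
of the outcome, which is valid under mean stationarity of the initial
conditions.  Exogenous regressors instrument themselves (differenced in the
difference block, in levels in the level block).  Unavailable instrument
entries are encoded as zeros, the standard convention for unbalanced panels;
observations lacking a required lag drop from the affected equation block
only.

The one-step weighting uses the tridiagonal matrix implied by i.i.d. errors
for the difference block and the identity for the level block (cross-block
zero); the second step re-weights with the first-step residual moments.
Reported standard errors apply the Windmeijer finite-sample correction by
default, since uncorrected two-step standard errors are known to be severely
downward biased.  The diagnostic battery comprises the Sargan–Hansen
overidentification J test, Arellano–Bond AR(1)/AR(2) tests on the
differenced residuals, a joint Wald test on the slope coefficients, and a
pseudo-R² defined as the squared correlation between observed and fitted
level outcomes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, EstimationError

__all__ = [
    "GMMSpec",
    "DEFAULT_INSTRUMENT_LAGS",
    "GMMResult",
    "build_instruments",
    "fit_system_gmm",
    "sargan_test",
    "ar_test",
    "wald_test",
    "pseudo_r2",
    "format_report",
]

EXOG_COLUMNS = ("year_index", "ip_year", "n_patients", "mean_charlson")

#: Outcome-specific instrument lag windows used by the three headline models.
DEFAULT_INSTRUMENT_LAGS = {"degree": (4, 11), "ev_rank": (6, 11),
                           "be_rank": (3, 14)}


@dataclass(frozen=True)
class GMMSpec:
    """Instrumentation and weighting choices for the system estimator."""

    instrument_lag_min: int = 2
    instrument_lag_max: int = 11
    two_step: bool = True
    windmeijer_correction: bool = True
    collapse_instruments: bool = False
    n_y_lags: int = 1
    exog_columns: tuple = EXOG_COLUMNS

    def __post_init__(self):
        if self.instrument_lag_min < 2:
            raise ConfigurationError(
                "instrument_lag_min must be >= 2: shallower lags of the "
                "outcome are correlated with the differenced error")
        if self.instrument_lag_max < self.instrument_lag_min:
            raise ConfigurationError("instrument_lag_max < instrument_lag_min")
        if self.n_y_lags < 1:
            raise ConfigurationError("n_y_lags must be >= 1")

    @property
    def param_names(self) -> list[str]:
        return [f"y_lag{k}" for k in range(1, self.n_y_lags + 1)] + \
            list(self.exog_columns)


class TestResult(NamedTuple):
    statistic: float
    df: int
    p: float


class ARResult(NamedTuple):
    z: float
    p: float


@dataclass
class _Individual:
    pid: object
    diff_periods: np.ndarray   # periods t of difference equations
    level_periods: np.ndarray  # periods t of level equations
    Xd: np.ndarray
    yd: np.ndarray
    Xl: np.ndarray
    yl: np.ndarray
    Z: np.ndarray              # (n_diff + n_level, n_instruments)
    H: np.ndarray              # one-step weighting block

    @property
    def X(self) -> np.ndarray:
        return np.vstack([self.Xd, self.Xl])

    @property
    def yvec(self) -> np.ndarray:
        return np.concatenate([self.yd, self.yl])

    def residuals(self, theta: np.ndarray) -> np.ndarray:
        return self.yvec - self.X @ theta


@dataclass
class InstrumentSet:
    """Per-individual design and instrument blocks for the stacked system."""

    individuals: list[_Individual]
    column_labels: list[tuple]
    param_names: list[str]
    spec: GMMSpec

    @property
    def n_instruments(self) -> int:
        return len(self.column_labels)

    @property
    def n_obs_level(self) -> int:
        return sum(len(ind.level_periods) for ind in self.individuals)

    @property
    def n_obs_diff(self) -> int:
        return sum(len(ind.diff_periods) for ind in self.individuals)


def _prepare_individuals(panel: pd.DataFrame, spec: GMMSpec):
    """Split the panel by practice; a period is usable only if the outcome
    and every exogenous regressor are present (non-missing)."""
    cols = ["y", *spec.exog_columns]
    missing = [c for c in cols + ["practice_id", "year_index"]
               if c not in panel.columns]
    if missing:
        raise ConfigurationError(f"panel lacks columns {missing}")
    per = {}
    for pid, g in panel.groupby("practice_id", sort=True):
        g = g.sort_values("year_index")
        ok = g[cols].notna().all(axis=1)
        g = g.loc[ok]
        if len(g) == 0:
            continue
        per[pid] = {
            "t": g["year_index"].to_numpy(dtype=int),
            "y": g["y"].to_numpy(dtype=float),
            "x": g[list(spec.exog_columns)].to_numpy(dtype=float),
        }
    return per


def build_instruments(panel: pd.DataFrame, spec: GMMSpec) -> InstrumentSet:
    """Construct design matrices and the stacked instrument blocks.

    Difference equations at period t (needing contiguous observations
    t-1-L..t, L the number of outcome lags) are instrumented by the levels
    ``y_{t-lag_min}..y_{t-lag_max}`` — one column per (period, lag) pair, or
    one per lag when collapsed — with zeros where a lag is unavailable.
    Level equations at period t are instrumented by ``dy_{t-1}``; exogenous
    regressors enter as their own instruments in both blocks.  Instrument
    columns that are identically zero across the panel are dropped.
    """
    per = _prepare_individuals(panel, spec)
    if not per:
        raise EstimationError("no usable observations in the panel")
    L = spec.n_y_lags
    nx = len(spec.exog_columns)

    t_min = min(int(d["t"].min()) for d in per.values())
    level_valid_all, diff_valid_all = {}, {}
    for pid, d in per.items():
        have = {int(t): k for k, t in enumerate(d["t"])}
        lv = [t for t in have
              if all((t - k) in have for k in range(1, L + 1))]
        dv = [t for t in lv if (t - 1) in lv]
        level_valid_all[pid] = sorted(lv)
        diff_valid_all[pid] = sorted(dv)

    all_diff_t = sorted({t for v in diff_valid_all.values() for t in v})
    all_level_t = sorted({t for v in level_valid_all.values() for t in v})
    if not all_level_t:
        raise EstimationError(
            "no observation satisfies the lag requirements "
            f"(n_y_lags={L}); the panel is too short or too gappy")

    labels: list[tuple] = []
    if spec.collapse_instruments:
        labels += [("gmm_diff", None, lag) for lag in
                   range(spec.instrument_lag_min, spec.instrument_lag_max + 1)]
    else:
        for t in all_diff_t:
            for lag in range(spec.instrument_lag_min,
                             spec.instrument_lag_max + 1):
                if t - lag >= t_min:
                    labels.append(("gmm_diff", t, lag))
    labels += [("iv_diff", c) for c in spec.exog_columns]
    if spec.collapse_instruments:
        labels.append(("gmm_lev", None))
    else:
        labels += [("gmm_lev", t) for t in all_level_t]
    labels += [("iv_lev", c) for c in spec.exog_columns]
    col_of = {lab: k for k, lab in enumerate(labels)}
    n_inst = len(labels)

    individuals = []
    for pid, d in per.items():
        have = {int(t): k for k, t in enumerate(d["t"])}
        y, x = d["y"], d["x"]
        lv, dv = level_valid_all[pid], diff_valid_all[pid]
        if not lv:
            continue

        Xl = np.empty((len(lv), L + nx))
        yl = np.empty(len(lv))
        for r, t in enumerate(lv):
            Xl[r, :L] = [y[have[t - k]] for k in range(1, L + 1)]
            Xl[r, L:] = x[have[t]]
            yl[r] = y[have[t]]
        Xd = np.empty((len(dv), L + nx))
        yd = np.empty(len(dv))
        for r, t in enumerate(dv):
            Xd[r, :L] = [y[have[t - k]] - y[have[t - 1 - k]]
                         for k in range(1, L + 1)]
            Xd[r, L:] = x[have[t]] - x[have[t - 1]]
            yd[r] = y[have[t]] - y[have[t - 1]]

        n_rows = len(dv) + len(lv)
        Z = np.zeros((n_rows, n_inst))
        for r, t in enumerate(dv):
            for lag in range(spec.instrument_lag_min,
                             spec.instrument_lag_max + 1):
                if (t - lag) in have:
                    lab = ("gmm_diff", None, lag) if \
                        spec.collapse_instruments else ("gmm_diff", t, lag)
                    if lab in col_of:
                        Z[r, col_of[lab]] += y[have[t - lag]]
            for c_idx, c in enumerate(spec.exog_columns):
                Z[r, col_of[("iv_diff", c)]] = Xd[r, L + c_idx]
        for r, t in enumerate(lv):
            row = len(dv) + r
            if (t - 1) in have and (t - 2) in have:
                lab = ("gmm_lev", None) if spec.collapse_instruments \
                    else ("gmm_lev", t)
                Z[row, col_of[lab]] += y[have[t - 1]] - y[have[t - 2]]
            for c_idx, c in enumerate(spec.exog_columns):
                Z[row, col_of[("iv_lev", c)]] = Xl[r, L + c_idx]

        H = np.zeros((n_rows, n_rows))
        for a, ta in enumerate(dv):
            H[a, a] = 2.0
            for b, tb in enumerate(dv):
                if abs(ta - tb) == 1:
                    H[a, b] = -1.0
        for r in range(len(lv)):
            H[len(dv) + r, len(dv) + r] = 1.0

        individuals.append(_Individual(pid, np.array(dv), np.array(lv),
                                       Xd, yd, Xl, yl, Z, H))

    # drop instrument columns that never fire
    stacked_usage = np.zeros(n_inst, dtype=bool)
    for ind in individuals:
        stacked_usage |= (ind.Z != 0).any(axis=0)
    keep = np.flatnonzero(stacked_usage)
    for ind in individuals:
        ind.Z = ind.Z[:, keep]
    labels = [labels[k] for k in keep]

    return InstrumentSet(individuals, labels, spec.param_names, spec)


@dataclass
class GMMResult:
    """Coefficients, covariance and the full diagnostic battery."""

    coefficients: pd.Series
    se: pd.Series
    vcov: np.ndarray
    n_obs: int
    n_obs_diff: int
    n_nodes: int
    n_instruments: int
    residual_vector_length: int
    sargan: TestResult
    ar1: ARResult | None
    ar2: ARResult | None
    wald: TestResult
    pseudo_r2: float
    spec: GMMSpec
    instruments: InstrumentSet = field(repr=False)
    _internals: dict = field(default_factory=dict, repr=False)

    @property
    def pvalues(self) -> pd.Series:
        z = self.coefficients / self.se
        return pd.Series(2 * stats.norm.sf(np.abs(z)),
                         index=self.coefficients.index)

    def to_dict(self) -> dict:
        return {
            "coefficients": self.coefficients.to_dict(),
            "se": self.se.to_dict(),
            "pvalues": self.pvalues.to_dict(),
            "n_obs": self.n_obs,
            "n_nodes": self.n_nodes,
            "n_instruments": self.n_instruments,
            "residual_vector_length": self.residual_vector_length,
            "sargan": self.sargan._asdict(),
            "ar1": self.ar1._asdict() if self.ar1 else None,
            "ar2": self.ar2._asdict() if self.ar2 else None,
            "wald": self.wald._asdict(),
            "pseudo_r2": self.pseudo_r2,
            "windmeijer_correction": self.spec.windmeijer_correction,
            "instrument_lags": [self.spec.instrument_lag_min,
                                self.spec.instrument_lag_max],
        }


def _pinv_sym(a: np.ndarray) -> np.ndarray:
    return np.linalg.pinv((a + a.T) / 2.0, hermitian=True)


def fit_system_gmm(panel: pd.DataFrame, spec: GMMSpec,
                   _second_step_weighting: np.ndarray | None = None
                   ) -> GMMResult:
    """Estimate the model by (one- or two-step) system GMM.

    Deterministic for a fixed panel: there is no randomness in estimation.
    Raises :class:`EstimationError` when instruments cannot identify the
    parameters, and warns when the autoregressive root estimate reaches the
    unit circle.
    """
    iset = build_instruments(panel, spec)
    inds = iset.individuals
    k = len(iset.param_names)
    if iset.n_instruments < k:
        raise EstimationError(
            f"underidentified: {iset.n_instruments} instruments for {k} "
            "parameters; widen the instrument lag window")
    if iset.n_obs_level < k:
        raise EstimationError("fewer usable observations than parameters")

    S_zx = sum(ind.Z.T @ ind.X for ind in inds)
    S_zy = sum(ind.Z.T @ ind.yvec for ind in inds)
    S_zhz = sum(ind.Z.T @ ind.H @ ind.Z for ind in inds)
    A1 = _pinv_sym(S_zhz)

    def _solve(A):
        G = S_zx.T @ A @ S_zx
        if np.linalg.matrix_rank(G) < k:
            raise EstimationError(
                "singular weighted moment matrix; reduce the instrument "
                "count (collapse or narrow the lag window) or check for "
                "collinear regressors")
        M = np.linalg.inv(G)
        return M @ (S_zx.T @ A @ S_zy), M

    theta1, M1 = _solve(A1)
    u1 = [ind.residuals(theta1) for ind in inds]
    perfect_fit = max(float(np.abs(u).max(initial=0.0)) for u in u1) < 1e-12
    S2 = sum(ind.Z.T @ np.outer(u, u) @ ind.Z for ind, u in zip(inds, u1))
    A2 = _pinv_sym(S2) if _second_step_weighting is None \
        else _second_step_weighting

    if spec.two_step and not perfect_fit:
        theta, M2 = _solve(A2)
    else:
        # with exactly-zero first-step residuals the optimal weighting is
        # undefined; the one-step estimate already fits perfectly
        theta, M2 = theta1, M1
    u = [ind.residuals(theta) for ind in inds]
    S_zu = sum(ind.Z.T @ uu for ind, uu in zip(inds, u))

    # covariance of the estimate
    V1r = M1 @ (S_zx.T @ A1 @ S2 @ A1 @ S_zx) @ M1  # robust one-step
    if not spec.two_step:
        vcov = V1r
    else:
        V2 = M2
        if spec.windmeijer_correction:
            D = np.empty((k, k))
            for j in range(k):
                Gj = sum(
                    ind.Z.T @ (np.outer(ind.X[:, j], uu)
                               + np.outer(uu, ind.X[:, j])) @ ind.Z
                    for ind, uu in zip(inds, u1))
                D[:, j] = M2 @ (S_zx.T @ A2 @ Gj @ A2 @ S_zu)
            vcov = V2 + D @ V2 + V2 @ D.T + D @ V1r @ D.T
        else:
            vcov = V2

    se = np.sqrt(np.maximum(np.diag(vcov), 0.0))
    names = iset.param_names
    coef = pd.Series(theta, index=names)
    if abs(coef.iloc[0]) >= 1.0:
        warnings.warn(
            f"estimated first autoregressive coefficient {coef.iloc[0]:.3f} "
            "lies outside the unit circle: nonstationary dynamics",
            stacklevel=2)

    internals = {
        "A2": A2, "S_zx": S_zx, "S_zu": S_zu, "M": M2, "u": u,
        "theta": theta, "vcov": vcov,
    }
    iset_ref = iset
    result = GMMResult(
        coefficients=coef,
        se=pd.Series(se, index=names),
        vcov=vcov,
        n_obs=iset.n_obs_level,
        n_obs_diff=iset.n_obs_diff,
        n_nodes=len(inds),
        n_instruments=iset.n_instruments,
        residual_vector_length=iset.n_obs_level + iset.n_obs_diff,
        sargan=TestResult(np.nan, 0, np.nan),
        ar1=None, ar2=None,
        wald=TestResult(np.nan, 0, np.nan),
        pseudo_r2=np.nan,
        spec=spec,
        instruments=iset_ref,
        _internals=internals,
    )
    if iset.n_instruments > k:
        try:
            result.sargan = sargan_test(result)
        except EstimationError:
            pass
    try:
        result.wald = wald_test(result)
    except EstimationError:
        pass
    for order, attr in ((1, "ar1"), (2, "ar2")):
        try:
            setattr(result, attr, ar_test(result, order))
        except EstimationError:
            setattr(result, attr, None)
    try:
        result.pseudo_r2 = pseudo_r2(result)
    except EstimationError:
        result.pseudo_r2 = np.nan
    return result


def sargan_test(result: GMMResult) -> TestResult:
    """Sargan–Hansen J test of the overidentifying restrictions.

    ``J = (Z'u)' W (Z'u)`` with the two-step weighting; chi-square with
    ``n_instruments - n_parameters`` degrees of freedom under instrument
    exogeneity.
    """
    k = len(result.coefficients)
    df = result.n_instruments - k
    if df < 1:
        raise EstimationError("model is just identified; the Sargan test "
                              "is undefined")
    s_zu = result._internals["S_zu"]
    j = float(s_zu @ result._internals["A2"] @ s_zu)
    return TestResult(j, df, float(stats.chi2.sf(j, df)))


def ar_test(result: GMMResult, order: int) -> ARResult:
    """Arellano–Bond test for order-``order`` serial correlation.

    Computed on the first-differenced residuals; under a serially
    uncorrelated level error the AR(1) statistic is negative by construction
    and AR(2) is centred at zero.  The variance accounts for estimation
    noise in the coefficients.
    """
    if order < 1:
        raise ConfigurationError("order must be >= 1")
    inds = result.instruments.individuals
    u = result._internals["u"]
    if max(float(np.abs(uu).max(initial=0.0)) for uu in u) < 1e-12:
        raise EstimationError("residuals are numerically zero; the AR "
                              "statistic is undefined")
    d0 = 0.0
    t1 = 0.0
    w_dot_X = np.zeros(len(result.coefficients))
    zu_uw = np.zeros(result.n_instruments)
    any_pair = False
    for ind, uu in zip(inds, u):
        nd = len(ind.diff_periods)
        if nd == 0:
            continue
        e = uu[:nd]
        pos = {t: r for r, t in enumerate(ind.diff_periods)}
        w = np.zeros(len(uu))
        for r, t in enumerate(ind.diff_periods):
            if (t - order) in pos:
                w[r] = e[pos[t - order]]
        if not w.any():
            continue
        any_pair = True
        s = float(w @ uu)
        d0 += s
        t1 += s * s
        w_dot_X += w @ ind.X
        zu_uw += ind.Z.T @ uu * s
    if not any_pair:
        raise EstimationError(
            f"no residual pairs {order} periods apart; AR({order}) test "
            "unavailable")
    if t1 == 0.0:
        raise EstimationError("all residuals are zero; the AR statistic is "
                              "undefined")
    M = result._internals["M"]
    A2 = result._internals["A2"]
    S_zx = result._internals["S_zx"]
    t2 = -2.0 * w_dot_X @ M @ (S_zx.T @ A2 @ zu_uw)
    t3 = float(w_dot_X @ result.vcov @ w_dot_X)
    var = t1 + t2 + t3
    if var <= 0:
        var = t1  # fall back to the leading term if the correction overshoots
    z = d0 / np.sqrt(var)
    return ARResult(float(z), float(2 * stats.norm.sf(abs(z))))


def wald_test(result: GMMResult) -> TestResult:
    """Joint chi-square test that all slope coefficients are zero."""
    theta = result.coefficients.to_numpy()
    k = len(theta)
    vc = result.vcov
    if np.linalg.matrix_rank(vc) < k:
        raise EstimationError("coefficient covariance is singular")
    stat = float(theta @ np.linalg.solve(vc, theta))
    return TestResult(stat, k, float(stats.chi2.sf(stat, k)))


def pseudo_r2(result: GMMResult) -> float:
    """Squared correlation between observed and fitted level outcomes."""
    theta = result._internals["theta"]
    obs, fit = [], []
    for ind in result.instruments.individuals:
        obs.append(ind.yl)
        fit.append(ind.Xl @ theta)
    obs = np.concatenate(obs)
    fit = np.concatenate(fit)
    resid = obs - fit
    if float(np.max(np.abs(resid), initial=0.0)) < 1e-12:
        return 1.0  # perfect-fit limit
    if np.std(obs) == 0 or np.std(fit) == 0:
        raise EstimationError("zero variance in observed or fitted values; "
                              "the squared correlation is undefined")
    return float(np.corrcoef(obs, fit)[0, 1] ** 2)


_STARS = ((0.001, "***"), (0.01, "**"), (0.05, "*"), (0.1, "·"))


def _stars(p: float) -> str:
    for cut, mark in _STARS:
        if p < cut:
            return mark
    return ""


def format_report(result: GMMResult, title: str = "System GMM model") -> str:
    """Plain-text regression table with the diagnostic battery."""
    lines = [title, "=" * len(title)]
    for name in result.coefficients.index:
        c, s, p = (result.coefficients[name], result.se[name],
                   result.pvalues[name])
        lines.append(f"{name:<16}{c: .4e}{_stars(p):<4}({s:.4e})")
    lines.append(f"#Obs            {result.n_obs}")
    lines.append(f"nodes           {result.n_nodes}")
    lines.append(f"Length of res. vector  {result.residual_vector_length}")
    sg = result.sargan
    if np.isfinite(sg.statistic):
        lines.append(f"Sargan test:    chisq({sg.df}) {sg.statistic:.2f} "
                     f"(p-value: {sg.p:.2f})")
    for label, ar in (("(1)", result.ar1), ("(2)", result.ar2)):
        if ar is not None:
            lines.append(f"Autocorrelation test {label}  normal {ar.z:.2f} "
                         f"(p-value: {ar.p:.2g})")
    w = result.wald
    lines.append(f"Wald test for coefficients  chisq({w.df}) "
                 f"{w.statistic:.2f} (p-value: {w.p:.2g})")
    lines.append(f"R2 corr(y, yhat)^2  {result.pseudo_r2:.2f}")
    lines.append(f"Instruments     Lags {result.spec.instrument_lag_min}:"
                 f"{result.spec.instrument_lag_max} "
                 f"({result.n_instruments} columns)")
    lines.append("Significance: *** p<0.001; ** p<0.01; * p<0.05; · p<0.1")
    return "\n".join(lines)
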