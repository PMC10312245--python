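"""System GMM estimator: instrument construction against hand-built
matrices, parameter recovery on simulated dynamics, diagnostics, and
algebraic invariances."""

import numpy as np
import pandas as pd
import pytest

from coopnet.dynamic_panel_gmm import (GMMSpec, ar_test, build_instruments,
                                       fit_system_gmm, format_report,
                                       pseudo_r2, sargan_test, wald_test)
from coopnet.errors import ConfigurationError, EstimationError
from coopnet.synthetic_claims import generate_panel_from_model

EXOG = ("year_index", "ip_year", "n_patients", "mean_charlson")


def balanced_panel(n_nodes=3, n_years=5, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_nodes):
        for t in range(n_years):
            rows.append({
                "practice_id": f"p{i}", "year": 2004 + t, "year_index": t,
                "y": rng.normal(), "ip": i % 2 == 0,
                "ip_year": float(i % 2 == 0) * t,
                "n_patients": float(rng.integers(30, 60)),
                "mean_charlson": rng.gamma(4.0, 0.5),
            })
    return pd.DataFrame(rows)


class TestSpecValidation:
    def test_shallow_instrument_lags_rejected(self):
        with pytest.raises(ConfigurationError):
            GMMSpec(instrument_lag_min=1)

    def test_inverted_window_rejected(self):
        with pytest.raises(ConfigurationError):
            GMMSpec(instrument_lag_min=4, instrument_lag_max=3)


class TestInstrumentConstruction:
    def test_matches_hand_built_matrix(self):
        """Balanced toy panel (N=3, T=5), one y-lag, instrument lags 2:3."""
        panel = balanced_panel(3, 5, seed=1)
        spec = GMMSpec(instrument_lag_min=2, instrument_lag_max=3)
        iset = build_instruments(panel, spec)
        by_label = dict(zip(iset.column_labels,
                            range(iset.n_instruments)))

        # diff-equation GMM columns: periods t=2,3,4, lags back to period 0
        assert set(lab for lab in by_label if lab[0] == "gmm_diff") == {
            ("gmm_diff", 2, 2), ("gmm_diff", 3, 2), ("gmm_diff", 3, 3),
            ("gmm_diff", 4, 2), ("gmm_diff", 4, 3)}
        # level-equation columns: dy_{t-1} defined from t=2 on (t=1 dropped)
        assert set(lab for lab in by_label if lab[0] == "gmm_lev") == {
            ("gmm_lev", 2), ("gmm_lev", 3), ("gmm_lev", 4)}
        assert iset.n_instruments == 5 + 4 + 3 + 4

        for ind in iset.individuals:
            pid = ind.pid
            y = panel.set_index(["practice_id", "year_index"])["y"]
            yv = {t: y[(pid, t)] for t in range(5)}
            # hand-built rows: diff t=2,3,4 then levels t=1,2,3,4
            assert list(ind.diff_periods) == [2, 3, 4]
            assert list(ind.level_periods) == [1, 2, 3, 4]
            Z = np.zeros((7, iset.n_instruments))
            Z[0, by_label[("gmm_diff", 2, 2)]] = yv[0]
            Z[1, by_label[("gmm_diff", 3, 2)]] = yv[1]
            Z[1, by_label[("gmm_diff", 3, 3)]] = yv[0]
            Z[2, by_label[("gmm_diff", 4, 2)]] = yv[2]
            Z[2, by_label[("gmm_diff", 4, 3)]] = yv[1]
            for r, t in enumerate((2, 3, 4)):
                Z[3 + r + 1, by_label[("gmm_lev", t)]] = \
                    yv[t - 1] - yv[t - 2]
            x = panel.set_index(["practice_id", "year_index"], drop=False)
            for c_idx, c in enumerate(EXOG):
                for r, t in enumerate((2, 3, 4)):
                    Z[r, by_label[("iv_diff", c)]] = \
                        x.at[(pid, t), c] - x.at[(pid, t - 1), c]
                for r, t in enumerate((1, 2, 3, 4)):
                    Z[3 + r, by_label[("iv_lev", c)]] = x.at[(pid, t), c]
            assert np.allclose(ind.Z, Z)

    def test_count_matches_explicit_enumeration(self):
        """Closed-form per-period instrument count vs explicit enumeration."""
        T, lo, hi = 14, 4, 11
        panel = balanced_panel(4, T, seed=2)
        iset = build_instruments(panel, GMMSpec(lo, hi))
        expected_diff = sum(
            sum(1 for lag in range(lo, hi + 1) if t - lag >= 0)
            for t in range(2, T))
        expected_lev = sum(1 for t in range(1, T) if t >= 2)
        assert iset.n_instruments == expected_diff + expected_lev + 8

    def test_collapse_one_column_per_lag_depth(self):
        panel = balanced_panel(4, 8, seed=3)
        iset = build_instruments(panel, GMMSpec(2, 5,
                                                collapse_instruments=True))
        gmm_diff = [lab for lab in iset.column_labels
                    if lab[0] == "gmm_diff"]
        assert len(gmm_diff) == 4  # lags 2, 3, 4, 5
        gmm_lev = [lab for lab in iset.column_labels if lab[0] == "gmm_lev"]
        assert len(gmm_lev) == 1

    def test_gap_drops_only_affected_equations(self):
        panel = balanced_panel(1, 7, seed=4)
        panel = panel[panel["year_index"] != 3]  # hole at t=3
        iset = build_instruments(panel, GMMSpec(2, 2))
        ind = iset.individuals[0]
        # level eqs need t-1: t in {1,2,5,6}; diff eqs need t-1,t-2: {2,6}
        assert list(ind.level_periods) == [1, 2, 5, 6]
        assert list(ind.diff_periods) == [2, 6]

    def test_too_short_panel_signalled(self):
        panel = balanced_panel(3, 3, seed=5)
        with pytest.raises(EstimationError):
            build_instruments(panel, GMMSpec(2, 4, n_y_lags=3))


class TestEstimation:
    def test_recovers_known_coefficients(self):
        theta = np.array([0.5, 0.002, 0.002, 1e-4, 0.01])
        spec = GMMSpec(2, 5)
        errs = []
        for seed in range(3):
            panel = generate_panel_from_model(theta, fe_sd=0.05,
                                              noise_sd=0.05, n_nodes=200,
                                              n_years=10, rng_seed=seed)
            r = fit_system_gmm(panel, spec)
            errs.append(r.coefficients.to_numpy() - theta)
        mean_err = np.abs(np.mean(errs, axis=0))
        assert mean_err[0] < 0.1          # autoregressive coefficient
        assert mean_err[2] < 0.001        # ip x year interaction

    def test_perfect_fit_limit(self):
        theta = np.array([0.3, 0.01, 0.0, 1e-3, 0.02])
        panel = generate_panel_from_model(theta, fe_sd=0.0, noise_sd=0.0,
                                          n_nodes=40, n_years=8, rng_seed=6)
        r = fit_system_gmm(panel, GMMSpec(2, 4))
        assert r.pseudo_r2 == 1.0
        assert np.allclose(r.coefficients.to_numpy(), theta, atol=1e-6)
        for u in r._internals["u"]:
            assert np.abs(u).max() < 1e-8
        with pytest.raises(EstimationError):
            ar_test(r, 1)

    def test_permutation_invariance(self):
        theta = np.array([0.4, 0.01, 0.002, 1e-4, 0.01])
        panel = generate_panel_from_model(theta, 0.05, 0.05, 80, 8,
                                          rng_seed=7)
        r0 = fit_system_gmm(panel, GMMSpec(2, 4))
        relabel = {pid: f"zz{hash(pid) % 10_000:05d}{pid}"
                   for pid in panel["practice_id"].unique()}
        shuffled = panel.assign(
            practice_id=panel["practice_id"].map(relabel)
        ).sample(frac=1.0, random_state=1)
        r1 = fit_system_gmm(shuffled, GMMSpec(2, 4))
        assert np.allclose(r0.coefficients.to_numpy(),
                           r1.coefficients.to_numpy(), atol=1e-9)
        assert np.allclose(r0.se.to_numpy(), r1.se.to_numpy(), atol=1e-9)

    def test_deterministic_across_runs(self):
        panel = generate_panel_from_model([0.4, 0, 0.002, 0, 0.01],
                                          0.05, 0.05, 60, 8, rng_seed=8)
        a = fit_system_gmm(panel, GMMSpec(2, 4))
        b = fit_system_gmm(panel, GMMSpec(2, 4))
        assert (a.coefficients == b.coefficients).all()
        assert a.sargan == b.sargan and a.wald == b.wald
        assert a.ar1 == b.ar1 and a.ar2 == b.ar2

    def test_two_step_equals_one_step_under_proportional_weighting(self):
        """If the second-step weighting is proportional to the first-step
        one, re-weighting must not move the estimate."""
        panel = generate_panel_from_model([0.4, 0, 0.002, 0, 0.01],
                                          0.05, 0.05, 60, 8, rng_seed=9)
        spec = GMMSpec(2, 4)
        one = fit_system_gmm(panel, GMMSpec(2, 4, two_step=False))
        iset = build_instruments(panel, spec)
        s_zhz = sum(ind.Z.T @ ind.H @ ind.Z for ind in iset.individuals)
        a1 = np.linalg.pinv((s_zhz + s_zhz.T) / 2)
        two = fit_system_gmm(panel, spec, _second_step_weighting=3.0 * a1)
        assert np.allclose(one.coefficients.to_numpy(),
                           two.coefficients.to_numpy(), atol=1e-10)

    def test_windmeijer_correction_widens_se(self):
        panel = generate_panel_from_model([0.5, 0.002, 0.002, 1e-4, 0.01],
                                          0.05, 0.05, 150, 10, rng_seed=10)
        on = fit_system_gmm(panel, GMMSpec(2, 5))
        off = fit_system_gmm(panel, GMMSpec(2, 5,
                                            windmeijer_correction=False))
        assert (on.coefficients == off.coefficients).all()
        assert (on.se.to_numpy() >= off.se.to_numpy() * 0.999).all()
        assert (on.se.to_numpy() > off.se.to_numpy()).any()


@pytest.fixture(scope="module")
def fitted():
    panel = generate_panel_from_model([0.5, 0.002, 0.002, 1e-4, 0.01],
                                      0.05, 0.05, 150, 10, rng_seed=11)
    return fit_system_gmm(panel, GMMSpec(2, 5))


class TestDiagnostics:
    def test_sargan_df_is_instruments_minus_parameters(self, fitted):
        s = sargan_test(fitted)
        assert s.df == fitted.n_instruments - len(fitted.coefficients)
        assert s.statistic >= 0

    def test_sargan_p_matches_chi2_sf(self, fitted):
        from scipy.stats import chi2
        s = fitted.sargan
        assert s.p == pytest.approx(chi2.sf(s.statistic, s.df))

    def test_wald_df_equals_parameter_count(self, fitted):
        w = wald_test(fitted)
        assert w.df == len(fitted.coefficients) == 5

    def test_wald_df_six_with_two_outcome_lags(self):
        panel = generate_panel_from_model([0.5, 0.002, 0.002, 1e-4, 0.01],
                                          0.05, 0.05, 150, 12, rng_seed=12)
        lag2 = panel.sort_values(["practice_id", "year_index"]).copy()
        r = fit_system_gmm(panel, GMMSpec(3, 6, n_y_lags=2))
        assert r.wald.df == 6
        assert r.sargan.df == r.n_instruments - 6

    def test_wald_invariant_to_outcome_scaling(self, fitted):
        panel = generate_panel_from_model([0.5, 0.002, 0.002, 1e-4, 0.01],
                                          0.05, 0.05, 150, 10, rng_seed=11)
        scaled = panel.assign(y=panel["y"] * 2.0)
        r2 = fit_system_gmm(scaled, GMMSpec(2, 5))
        assert r2.wald.statistic == pytest.approx(fitted.wald.statistic,
                                                  rel=1e-6)

    def test_ar1_negative_ar2_null(self, fitted):
        assert fitted.ar1.z < -2
        assert abs(fitted.ar2.z) < 3

    def test_pseudo_r2_equals_direct_correlation(self, fitted):
        obs = np.concatenate([ind.yl for ind in
                              fitted.instruments.individuals])
        fit = np.concatenate([
            ind.Xl @ fitted._internals["theta"]
            for ind in fitted.instruments.individuals])
        assert fitted.pseudo_r2 == pytest.approx(
            np.corrcoef(obs, fit)[0, 1] ** 2)
        assert 0 <= fitted.pseudo_r2 <= 1

    def test_constant_fitted_values_signalled(self, fitted):
        broken = fitted
        saved = broken._internals["theta"]
        try:
            broken._internals["theta"] = np.zeros_like(saved)
            with pytest.raises(EstimationError):
                pseudo_r2(broken)
        finally:
            broken._internals["theta"] = saved

    def test_report_mentions_battery(self, fitted):
        text = format_report(fitted)
        for token in ("Sargan", "Autocorrelation test (1)",
                      "Autocorrelation test (2)", "Wald", "Instruments"):
            assert token in text
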