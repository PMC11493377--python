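"""Logistic fit, bootstrap covariance, delta-method band, TIS/TIF rule."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.special import expit

from promthresh.cohort_io import PROMDefinition, Orientation
from promthresh.threshold_engine import (
    AnalysisSettings,
    CovSource,
    EstimationError,
    ProbabilityCurve,
    SeparationError,
    bootstrap_covariance,
    find_thresholds,
    fit_logistic_mle,
    inv_logit,
    probability_curve,
    run_prom_analysis,
)
from conftest import build_cohort
from oracles import grid_search_logistic, loglik


class TestInvLogit:
    def test_symmetry_point(self):
        assert inv_logit(0.0) == pytest.approx(0.5)

    def test_saturation(self):
        assert inv_logit(-50.0) < 1e-20
        assert inv_logit(50.0) == pytest.approx(1.0, abs=1e-15)

    @given(st.floats(min_value=-500, max_value=500, allow_nan=False))
    def test_complement_identity(self, eta):
        assert inv_logit(eta) + inv_logit(-eta) == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("bad", [np.nan, np.inf, -np.inf])
    def test_nonfinite_rejected(self, bad):
        with pytest.raises(ValueError):
            inv_logit(bad)


class TestFitLogisticMLE:
    def test_balanced_symmetry_gives_zero_coefficients(self):
        fit = fit_logistic_mle([-1, -1, 1, 1], [1, 0, 1, 0])
        assert fit.beta0 == pytest.approx(0.0, abs=1e-8)
        assert fit.beta1 == pytest.approx(0.0, abs=1e-8)
        assert fit.converged

    def test_matches_grid_search_oracle(self, overlap_fixture):
        x, y = overlap_fixture
        fit = fit_logistic_mle(x, y)
        b0, b1 = grid_search_logistic(x, y)
        assert fit.beta0 == pytest.approx(b0, abs=2e-3)
        assert fit.beta1 == pytest.approx(b1, abs=2e-3)
        # the MLE's likelihood is at least the oracle grid's best
        assert fit.loglik >= loglik(b0, b1, x, y) - 1e-9

    def test_matches_statsmodels(self, overlap_fixture):
        sm = pytest.importorskip("statsmodels.api")
        x, y = overlap_fixture
        fit = fit_logistic_mle(x, y)
        X = np.column_stack([np.ones_like(x), x])
        ref = sm.Logit(y, X).fit(disp=0)
        np.testing.assert_allclose(fit.beta, ref.params, atol=1e-6)
        np.testing.assert_allclose(fit.cov, ref.cov_params(), rtol=1e-4, atol=1e-8)

    def test_perfect_separation_detected(self):
        x = np.arange(10, dtype=float)
        y = (x >= 5).astype(float)
        with pytest.raises(SeparationError):
            fit_logistic_mle(x, y)

    @pytest.mark.parametrize(
        "x,y",
        [([1, 2, 3], [1, 1, 1]), ([2, 2, 2], [0, 1, 0]), ([1, 2], [0, 1, 0])],
    )
    def test_degenerate_inputs_rejected(self, x, y):
        with pytest.raises(EstimationError):
            fit_logistic_mle(x, y)

    def test_shift_equivariance(self, overlap_fixture):
        """Fitting on x and on x - c yields identical fitted probabilities."""
        x, y = overlap_fixture
        c = 5.0
        f1 = fit_logistic_mle(x, y)
        f2 = fit_logistic_mle(x - c, y)
        np.testing.assert_allclose(f1.predict(x), f2.predict(x - c), atol=1e-8)

    def test_information_covariance_is_spd(self, overlap_fixture):
        fit = fit_logistic_mle(*overlap_fixture)
        np.testing.assert_allclose(fit.cov, fit.cov.T)
        assert np.all(np.linalg.eigvalsh(fit.cov) > 0)


class TestBootstrapCovariance:
    def test_deterministic_under_seed(self, overlap_fixture):
        x, y = overlap_fixture
        a = bootstrap_covariance(x, y, B=50, seed=11)
        b = bootstrap_covariance(x, y, B=50, seed=11)
        np.testing.assert_array_equal(a.cov, b.cov)
        assert a.n_converged == b.n_converged

    def test_b_below_two_rejected(self, overlap_fixture):
        with pytest.raises(EstimationError):
            bootstrap_covariance(*overlap_fixture, B=1, seed=0)

    @staticmethod
    def _entrywise_close(cov_hat, cov_ref, B, n_se=3):
        for i in (0, 1):
            for j in (0, 1):
                # sampling error of an empirical covariance entry (normal approx)
                se = np.sqrt(
                    (cov_ref[i, i] * cov_ref[j, j] + cov_ref[i, j] ** 2) / (B - 1)
                )
                assert abs(cov_hat[i, j] - cov_ref[i, j]) < n_se * se

    def test_duplicated_data_limit_is_the_sandwich_covariance(self, overlap_fixture):
        """On a dataset duplicated 1000x the resampling distribution is
        near-deterministic and the case bootstrap converges to the robust
        (sandwich) covariance of the fixed empirical distribution."""
        x, y = overlap_fixture
        xx, yy = np.tile(x, 1000), np.tile(y, 1000)
        fit = fit_logistic_mle(xx, yy)
        X = np.column_stack([np.ones_like(xx), xx])
        p = expit(X @ fit.beta)
        A_inv = np.linalg.inv((X * (p * (1 - p))[:, None]).T @ X)
        meat = (X * ((yy - p) ** 2)[:, None]).T @ X
        sandwich = A_inv @ meat @ A_inv
        boot = bootstrap_covariance(xx, yy, B=200, seed=3)
        assert boot.n_converged >= 100
        self._entrywise_close(boot.cov, sandwich, boot.n_converged)

    def test_large_n_agreement_with_information_under_true_model(self, pain):
        """When outcomes really follow the logistic link, bootstrap and
        information covariances agree at large n (sandwich = information)."""
        from promthresh.synthetic_cohort import simulate_prom

        x, y = simulate_prom(pain, 10_000, 8.0, 4.0, -4.0, 0.3, seed=99)
        fit = fit_logistic_mle(x, y)
        boot = bootstrap_covariance(x, y, B=200, seed=4)
        self._entrywise_close(boot.cov, fit.cov, boot.n_converged)

    def test_failed_resamples_are_skipped_not_fatal(self, rng):
        # tiny rare-event data: many resamples lose the failure class entirely
        x = np.array([0, 1, 2, 3, 4, 5, 6, 7.0])
        y = np.array([0, 0, 0, 1, 0, 0, 1, 0.0])
        try:
            boot = bootstrap_covariance(x, y, B=40, seed=5)
            assert boot.n_converged < boot.n_requested
        except EstimationError as exc:
            assert "resamples converged" in str(exc)


class TestProbabilityCurve:
    def test_zero_covariance_collapses_band(self, pain):
        fit = fit_logistic_mle(*_pain_data())
        fit.cov = np.zeros((2, 2))
        curve = probability_curve(fit, pain)
        np.testing.assert_array_equal(curve.lower95, curve.p)
        np.testing.assert_array_equal(curve.upper95, curve.p)

    def test_closed_form_at_origin(self):
        """beta=(0,0), Sigma=I, x=0: p=0.5, Var=0.25^2, CI=(0.010, 0.990)."""
        prom = PROMDefinition("toy", 0, 10, Orientation.LOWER_IS_BETTER)
        fit = _manual_fit(0.0, 0.0, np.eye(2))
        curve = probability_curve(fit, prom)
        assert curve.p[0] == pytest.approx(0.5)
        assert curve.lower95[0] == pytest.approx(0.010, abs=5e-4)
        assert curve.upper95[0] == pytest.approx(0.990, abs=5e-4)
        assert curve.z == pytest.approx(1.959964, abs=1e-6)

    def test_band_ordering_and_range(self, pain):
        fit = fit_logistic_mle(*_pain_data())
        curve = probability_curve(fit, pain)
        assert np.all(curve.lower95 <= curve.p + 1e-12)
        assert np.all(curve.p <= curve.upper95 + 1e-12)
        assert np.all((curve.lower95 >= 0) & (curve.upper95 <= 1))

    def test_p_monotone_with_positive_slope(self, pain):
        fit = fit_logistic_mle(*_pain_data())
        assert fit.beta1 > 0
        curve = probability_curve(fit, pain)
        assert np.all(np.diff(curve.p) >= 0)

    def test_logit_scale_variant_needs_no_truncation(self, pain):
        fit = fit_logistic_mle(*_pain_data())
        curve = probability_curve(fit, pain, scale="logit")
        assert np.all((curve.lower95 > 0) & (curve.upper95 < 1))
        assert np.all(curve.lower95 <= curve.p) and np.all(curve.p <= curve.upper95)

    def test_asymmetric_covariance_rejected(self, pain):
        fit = _manual_fit(0.0, 0.1, np.array([[1.0, 0.5], [0.1, 1.0]]))
        with pytest.raises(ValueError, match="symmetric"):
            probability_curve(fit, pain)

    def test_indefinite_covariance_rejected(self, pain):
        fit = _manual_fit(0.0, 0.1, np.array([[1.0, 2.0], [2.0, 1.0]]))
        with pytest.raises(ValueError, match="positive semi-definite"):
            probability_curve(fit, pain)

    def test_ci_width_halves_when_n_quadruples(self, pain):
        """Delta-method band width scales like 1/sqrt(n)."""
        from promthresh.synthetic_cohort import simulate_prom

        widths = {}
        for n in (1000, 4000):
            w = []
            for s in range(10):
                x, y = simulate_prom(pain, n, 8.0, 4.0, -4.0, 0.3, seed=1000 + s)
                curve = probability_curve(fit_logistic_mle(x, y), pain)
                w.append(np.mean(curve.upper95 - curve.lower95))
            widths[n] = np.mean(w)
        assert 0.4 <= widths[4000] / widths[1000] <= 0.6


def _pain_data():
    """Overlapping two-class data spanning the pain range."""
    x = np.array([0, 1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 12, 14, 16, 18, 20], float)
    y = np.array([0, 0, 0, 0, 0, 1, 0, 0, 1, 0, 1, 1, 0, 1, 1, 1], float)
    return x, y


def _manual_fit(b0, b1, cov):
    from promthresh.threshold_engine import LogisticFit

    return LogisticFit(
        beta0=b0, beta1=b1, cov=np.asarray(cov, float),
        cov_source=CovSource.MODEL_INFORMATION, n_used=0,
        converged=True, n_iter=0, loglik=0.0,
    )


def _curve_from_bands(prom, p, lo, up):
    return ProbabilityCurve(
        prom=prom.name,
        grid=prom.grid,
        p=np.asarray(p, float),
        lower95=np.asarray(lo, float),
        upper95=np.asarray(up, float),
        z=1.959964,
    )


class TestFindThresholds:
    def setup_method(self):
        self.low = PROMDefinition("toy_low", 0, 10, Orientation.LOWER_IS_BETTER)
        self.high = PROMDefinition("toy_high", 0, 10, Orientation.HIGHER_IS_BETTER)

    def test_band_containing_baseline_everywhere_gives_no_thresholds(self):
        p = np.full(11, 0.13)
        curve = _curve_from_bands(self.low, p, p - 0.1, p + 0.1)
        thr = find_thresholds(curve, 0.13, self.low)
        assert thr.tis is None and thr.tif is None

    def test_constructed_crossings_lower_is_better(self):
        """Band below p0 at 0-3 and above at 8-10 -> TIS '<4', TIF '>7'."""
        p0 = 0.13
        up = np.where(np.arange(11) <= 3, p0 - 0.01, p0 + 0.01)
        lo = np.where(np.arange(11) >= 8, p0 + 0.01, p0 - 0.01)
        p = (lo + up) / 2
        curve = _curve_from_bands(self.low, p, lo, up)
        thr = find_thresholds(curve, p0, self.low)
        assert (thr.tis, thr.tis_relation) == (4, "<")
        assert (thr.tif, thr.tif_relation) == (7, ">")
        assert thr.format_bound("tis") == "<4" and thr.format_bound("tif") == ">7"
        # probabilities reported at the bound-adjacent qualifying scores
        assert thr.p_tis == pytest.approx(p[3]) and thr.p_tif == pytest.approx(p[8])

    def test_orientation_flip_mirrors_bounds(self):
        """The mirrored higher-is-better curve gives TIS '>6', TIF '<3'."""
        p0 = 0.13
        idx = np.arange(11)
        up = np.where(idx <= 3, p0 - 0.01, p0 + 0.01)
        lo = np.where(idx >= 8, p0 + 0.01, p0 - 0.01)
        p = (lo + up) / 2
        curve = _curve_from_bands(self.high, p[::-1], lo[::-1], up[::-1])
        thr = find_thresholds(curve, p0, self.high)
        assert (thr.tis, thr.tis_relation) == (6, ">")
        assert (thr.tif, thr.tif_relation) == (3, "<")

    def test_interior_excursions_do_not_create_thresholds(self):
        """Qualifying runs must be contiguous from the extremes."""
        p0 = 0.13
        p = np.full(11, p0)
        up = np.full(11, p0 + 0.05)
        up[5] = p0 - 0.01  # isolated interior dip of the upper bound
        lo = np.full(11, p0 - 0.05)
        curve = _curve_from_bands(self.low, p, lo, up)
        thr = find_thresholds(curve, p0, self.low)
        assert thr.tis is None and thr.tif is None

    def test_fitted_band_agrees_with_direct_scan(self, pain):
        """On a real fitted band the rule equals an independent linear scan."""
        fit = fit_logistic_mle(*_pain_data())
        curve = probability_curve(fit, pain)
        p0 = 0.3
        thr = find_thresholds(curve, p0, pain)
        # direct scan from the good end (low scores)
        k = 0
        while k < len(curve.grid) and curve.upper95[k] < p0:
            k += 1
        expected_tis = int(curve.grid[k]) if 0 < k < len(curve.grid) else None
        m = len(curve.grid) - 1
        while m >= 0 and curve.lower95[m] > p0:
            m -= 1
        expected_tif = int(curve.grid[m]) if -1 < m < len(curve.grid) - 1 else None
        assert thr.tis == expected_tis
        assert thr.tif == expected_tif

    def test_disjoint_regions_and_probability_ordering(self, pain):
        fit = fit_logistic_mle(*_pain_data())
        curve = probability_curve(fit, pain)
        thr = find_thresholds(curve, 0.3, pain)
        if thr.tis is not None and thr.tif is not None:
            assert thr.tis <= thr.tif
            assert thr.p_tis < 0.3 < thr.p_tif

    def test_invalid_baseline_rejected(self, pain):
        fit = fit_logistic_mle(*_pain_data())
        curve = probability_curve(fit, pain)
        with pytest.raises(ValueError):
            find_thresholds(curve, 0.0, pain)


class TestRunPromAnalysis:
    def test_strong_effect_brackets_true_crossing(self, pain):
        """With a known link, TIS and TIF bracket x* where p(x*) = p0."""
        from scipy.special import logit as _logit
        from promthresh.synthetic_cohort import simulate_prom

        beta = (-4.0, 0.3)
        x, y = simulate_prom(pain, 5000, 8.0, 4.0, *beta, seed=42)
        anchors = np.where(y == 1.0, 2, 5)
        cohort = build_cohort(anchors.tolist(), {"womac_pain": x.tolist()})
        res = run_prom_analysis(
            cohort, pain, AnalysisSettings(cov_source=CovSource.MODEL_INFORMATION)
        )
        thr = res.thresholds
        x_star = (float(_logit(cohort.p0)) - beta[0]) / beta[1]
        assert thr.tis is not None and thr.tif is not None
        assert thr.tis <= np.ceil(x_star)
        assert thr.tif >= np.floor(x_star)

    def test_single_class_is_an_error_naming_the_prom(self, pain):
        cohort = build_cohort([5] * 20, {"womac_pain": list(range(20))})
        with pytest.raises(EstimationError, match="womac_pain"):
            run_prom_analysis(cohort, pain)

    def test_bootstrap_and_information_thresholds_agree_at_large_n(self, pain):
        from promthresh.synthetic_cohort import simulate_prom

        x, y = simulate_prom(pain, 4000, 8.0, 4.0, -4.0, 0.3, seed=9)
        anchors = np.where(y == 1.0, 1, 6)
        cohort = build_cohort(anchors.tolist(), {"womac_pain": x.tolist()})
        boot = run_prom_analysis(
            cohort, pain, AnalysisSettings(n_boot=200, seed=2, cov_source=CovSource.BOOTSTRAP)
        ).thresholds
        info = run_prom_analysis(
            cohort, pain, AnalysisSettings(cov_source=CovSource.MODEL_INFORMATION)
        ).thresholds
        assert boot.tis is not None and info.tis is not None
        assert abs(boot.tis - info.tis) <= 1
        assert abs(boot.tif - info.tif) <= 1
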