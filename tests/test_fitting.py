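"""Curve fitters, the F-test for line comparisons, and normalization."""

import numpy as np
import pytest

import monokin as mk
from monokin.fitting import compare_lines_ftest


class TestHyperbola:
    def test_noiseless_exact(self):
        x = np.array([1, 3, 10, 30, 100, 300]) * 1e-6
        y = x / (x + 10e-6)
        fit = mk.fit_hyperbola(x, y)
        assert fit.K_M == pytest.approx(10e-6, rel=1e-8)
        assert fit.Ymax == pytest.approx(1.0, rel=1e-8)

    def test_scale_equivariance(self):
        x = np.array([1, 3, 10, 30, 100, 300]) * 1e-6
        y = 0.8 * x / (x + 25e-6)
        f1 = mk.fit_hyperbola(x, y)
        f2 = mk.fit_hyperbola(x, 2 * y)
        assert f2.Ymax == pytest.approx(2 * f1.Ymax, rel=1e-9)
        assert f2.K_M == pytest.approx(f1.K_M, rel=1e-9)

    def test_noisy_recovery_within_15_percent(self):
        rng = np.random.default_rng(42)
        x = np.array([1, 3, 10, 25, 50, 100, 300, 600]) * 1e-6
        y = x / (x + 25e-6) + rng.normal(0, 0.02, x.size)
        fit = mk.fit_hyperbola(x, y)
        assert fit.K_M == pytest.approx(25e-6, rel=0.15)

    def test_degenerate_data_rejected(self):
        x = np.array([1e-6, 1e-5, 1e-4])
        with pytest.raises(ValueError):
            mk.fit_hyperbola(x, np.ones(3))

    def test_steady_state_occupancy_is_exact_hyperbola(self, binding_scheme):
        """Oracle equivalence on the minimal instance: the stationary bound
        fraction of a single reversible binding step follows x/(x+Kd)."""
        concs = np.array([1, 3, 10, 30, 100, 300, 600]) * 1e-6
        occ = []
        for c in concs:
            p = mk.steady_state(binding_scheme, mk.IonConditions({("S", "out"): c}), 0.0)
            occ.append(p[1])
        fit = mk.fit_hyperbola(concs, np.array(occ))
        assert fit.K_M == pytest.approx(10.0 / 1.0e6, rel=1e-6)


class TestBoltzmann:
    def test_noiseless_exact(self):
        v = np.linspace(-0.09, 0.03, 7)
        y = 0.2 + 0.8 / (1 + np.exp((-0.03 - v) / 0.025))
        fit = mk.fit_boltzmann(v, y)
        assert fit.Top == pytest.approx(1.0, rel=1e-6)
        assert fit.Bottom == pytest.approx(0.2, rel=1e-6)
        assert fit.V50 == pytest.approx(-0.03, rel=1e-5)
        assert fit.Slope == pytest.approx(0.025, rel=1e-5)

    def test_flat_data_flagged_not_raised(self):
        v = np.linspace(-0.09, 0.03, 7)
        fit = mk.fit_boltzmann(v, np.full(7, 0.5))
        assert fit.Top == pytest.approx(fit.Bottom)
        assert fit.warnings

    def test_noisy_v50_within_10mV(self):
        rng = np.random.default_rng(7)
        v = np.linspace(-0.1, 0.05, 16)
        y = 0.1 + 0.9 / (1 + np.exp((-0.02 - v) / 0.02)) + rng.normal(0, 0.03, 16)
        fit = mk.fit_boltzmann(v, y)
        assert abs(fit.V50 - (-0.02)) < 0.010


class TestLineAndMonoExp:
    def test_collinear_points(self):
        fit = mk.fit_line([0.0, 1.0], [1.0, 3.0])
        assert fit.slope == pytest.approx(2.0)
        assert fit.intercept == pytest.approx(1.0)

    def test_line_matches_normal_equations(self):
        rng = np.random.default_rng(3)
        x = np.linspace(0, 1, 20)
        y = 2.5 * x - 0.3 + rng.normal(0, 0.1, 20)
        fit = mk.fit_line(x, y)
        beta = np.polyfit(x, y, 1)
        assert fit.slope == pytest.approx(beta[0], rel=1e-12)
        assert fit.intercept == pytest.approx(beta[1], rel=1e-12)

    def test_singular_design_rejected(self):
        with pytest.raises(ValueError):
            mk.fit_line([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])

    def test_monoexp_noiseless_exact(self):
        t = np.linspace(0, 3, 40)
        y = 1 - np.exp(-2.0 * t)
        fit = mk.fit_monoexp(t, y)
        assert fit.rate == pytest.approx(2.0, rel=1e-8)
        assert fit.amplitude == pytest.approx(1.0, rel=1e-8)
        assert fit.offset == pytest.approx(0.0, abs=1e-7)

    def test_monoexp_with_offset(self):
        t = np.linspace(0, 2, 30)
        y = 0.25 + 0.75 * (1 - np.exp(-1.6 * t))
        fit = mk.fit_monoexp(t, y)
        assert fit.rate == pytest.approx(1.6, rel=1e-8)
        assert fit.offset == pytest.approx(0.25, rel=1e-6)
        assert fit.tau == pytest.approx(1 / 1.6, rel=1e-8)


class TestFTest:
    def test_identical_datasets(self):
        x = np.linspace(0, 1, 10)
        y = 1.5 * x + 0.2
        res = compare_lines_ftest((x, y), (x, y))
        assert res.F == pytest.approx(0.0, abs=1e-20)
        assert res.p_value == pytest.approx(1.0)

    def test_equal_slopes_different_intercepts(self):
        rng = np.random.default_rng(11)
        x = np.linspace(0, 1, 30)
        sigma = 0.05
        ya = 2.0 * x + 0.0 + rng.normal(0, sigma, 30)
        yb = 2.0 * x + 10 * sigma + rng.normal(0, sigma, 30)
        slope_test = compare_lines_ftest((x, ya), (x, yb), "slope")
        icept_test = compare_lines_ftest((x, ya), (x, yb), "intercept")
        assert slope_test.p_value > 0.05
        assert icept_test.p_value < 1e-4

    def test_type_I_error_calibrated(self):
        """Under the null (same true line, Gaussian noise) the slope test
        rejects at alpha=0.05 about 5% of the time."""
        rng = np.random.default_rng(2024)
        x = np.linspace(-1, 1, 12)
        rejections = 0
        n_sim = 1000
        for _ in range(n_sim):
            ya = 0.7 * x + 0.1 + rng.normal(0, 0.2, x.size)
            yb = 0.7 * x + 0.1 + rng.normal(0, 0.2, x.size)
            if compare_lines_ftest((x, ya), (x, yb)).p_value < 0.05:
                rejections += 1
        assert 0.03 <= rejections / n_sim <= 0.07

    def test_insufficient_dof_rejected(self):
        with pytest.raises(ValueError):
            compare_lines_ftest(([0.0, 1.0], [0.0, 1.0]), ([0.0, 1.0], [0.0, 1.0]))


class TestNormalization:
    def test_reference_maps_to_one(self):
        series = {-0.06: -40e-12, -0.09: -60e-12}
        normed = mk.normalize_to_reference(series, -0.06)
        assert normed[-0.06] == 1.0
        assert normed[-0.09] == pytest.approx(1.5)

    def test_all_equal_series(self):
        series = {k: 3.3 for k in range(5)}
        assert all(v == 1.0 for v in mk.normalize_to_reference(series, 2).values())

    def test_round_trip(self):
        series = {"a": 2.0, "b": -4.0, "c": 0.5}
        normed = mk.normalize_to_reference(series, "a")
        back = {k: v * series["a"] for k, v in normed.items()}
        assert back == pytest.approx(series)

    def test_zero_reference_rejected(self):
        with pytest.raises(ZeroDivisionError):
            mk.normalize_to_reference({"a": 0.0, "b": 1.0}, "a")

    def test_missing_reference_rejected(self):
        with pytest.raises(KeyError):
            mk.normalize_to_reference({"a": 1.0}, "z")
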