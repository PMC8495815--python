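import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from senesim import empirics as emp


class TestBackCalculate:
    def test_full_scale_radius_returns_catch_length(self):
        out = emp.back_calculate(146.0, 2.0, [0.5, 1.0, 1.999999], b_exp=0.641)
        assert out[-1] == pytest.approx(146.0, rel=1e-5)

    def test_linear_exponent_halves_length_at_half_radius(self):
        out = emp.back_calculate(146.0, 1.0, [0.5], b_exp=1.0)
        assert out[0] == pytest.approx(73.0)

    def test_monastyrsky_exponent_at_half_radius(self):
        # 146 * 0.5**0.641
        out = emp.back_calculate(146.0, 1.0, [0.5], b_exp=0.641)
        assert out[0] == pytest.approx(146.0 * 0.5**0.641, abs=1e-9)
        assert out[0] == pytest.approx(93.6, abs=0.1)

    @given(scale=st.floats(0.1, 100.0))
    @settings(derandomize=True, max_examples=50)
    def test_scale_invariance(self, scale):
        radii = np.array([0.3, 0.55, 0.8])
        a = emp.back_calculate(150.0, 1.0, radii)
        b = emp.back_calculate(150.0, scale, radii * scale)
        assert np.allclose(a, b, rtol=1e-9)

    def test_output_strictly_increasing(self):
        out = emp.back_calculate(150.0, 1.0, [0.2, 0.4, 0.6, 0.9])
        assert np.all(np.diff(out) > 0)

    @pytest.mark.parametrize(
        "radii", [[0.5, 0.4], [0.5, 0.5], [1.2], [-0.1, 0.5]]
    )
    def test_bad_radii_rejected(self, radii):
        with pytest.raises(emp.EmpiricsError):
            emp.back_calculate(150.0, 1.0, radii)


class TestFitVB:
    def test_exact_recovery_on_noise_free_curve(self):
        ages = np.arange(1, 7, dtype=float)
        lengths = emp.vb_length(ages, 16.0, 0.5, 0.0)
        fit = emp.fit_vb(ages, lengths)
        assert fit.l_inf == pytest.approx(16.0, abs=1e-6)
        assert fit.k == pytest.approx(0.5, abs=1e-6)
        assert fit.l0 == pytest.approx(0.0, abs=1e-6)

    def test_exact_recovery_with_nonzero_l0(self):
        ages = np.arange(1, 8, dtype=float)
        lengths = emp.vb_length(ages, 14.0, 0.7, 2.0)
        fit = emp.fit_vb(ages, lengths)
        assert fit.l_inf == pytest.approx(14.0, abs=1e-5)
        assert fit.l0 == pytest.approx(2.0, abs=1e-4)

    def test_underdetermined_data_raises(self):
        with pytest.raises(emp.VBFitError):
            emp.fit_vb([3.0], [10.0])
        # 3 points cannot support a free-L0 (3-parameter) fit
        with pytest.raises(emp.VBFitError):
            emp.fit_vb([1.0, 2.0, 3.0], [5.0, 8.0, 10.0])

    def test_fit_error_carries_fish_id(self):
        with pytest.raises(emp.VBFitError) as exc:
            emp.fit_vb([1.0], [5.0], fish_id="F007")
        assert exc.value.fish_id == "F007"

    def test_fixed_l0_fit_on_three_points(self):
        ages = np.array([1.0, 2.0, 3.0])
        lengths = emp.vb_length(ages, 12.0, 0.8, 0.0)
        fit = emp.fit_vb(ages, lengths, l0=0.0)
        assert fit.l_inf == pytest.approx(12.0, abs=1e-6)
        assert fit.k == pytest.approx(0.8, abs=1e-6)


class TestRegressions:
    def test_collinear_points_recover_exact_slope(self):
        linf = np.array([10.0, 12.0, 14.0, 16.0])
        fits = [
            emp.VBParams(l_inf=l, k=float(np.exp(1.0 - 0.2 * l)), l0=0.0)
            for l in linf
        ]
        reg = emp.fit_k_on_linf(fits)
        assert reg.slope == pytest.approx(-0.2, abs=1e-12)
        assert reg.intercept == pytest.approx(1.0, abs=1e-10)
        assert reg.resid_sd == pytest.approx(0.0, abs=1e-7)

    def test_two_points_insufficient(self):
        fits = [emp.VBParams(10.0, 0.5), emp.VBParams(12.0, 0.4)]
        with pytest.raises(emp.EmpiricsError):
            emp.fit_k_on_linf(fits)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(5)
        linf = rng.uniform(10, 18, 8)
        lnk = 1.27 - 0.13 * linf + rng.normal(0, 0.3, 8)
        fits = [
            emp.VBParams(l_inf=float(l), k=float(np.exp(y)))
            for l, y in zip(linf, lnk)
        ]
        reg = emp.fit_k_on_linf(fits)
        # brute-force normal equations
        X = np.column_stack([np.ones(8), linf])
        beta = np.linalg.solve(X.T @ X, X.T @ lnk)
        resid = lnk - X @ beta
        sd = np.sqrt(resid @ resid / 6)
        assert reg.intercept == pytest.approx(beta[0], abs=1e-10)
        assert reg.slope == pytest.approx(beta[1], abs=1e-10)
        assert reg.resid_sd == pytest.approx(sd, abs=1e-10)

    def test_length_weight_exact_on_noiseless_power_law(self):
        lengths = np.linspace(120, 170, 12)
        weights = 7e-6 * lengths**2.943
        fit = emp.fit_length_weight(list(zip(lengths, weights)))
        assert fit.a == pytest.approx(7e-6, rel=1e-6)
        assert fit.b == pytest.approx(2.943, rel=1e-6)
        assert emp.predict_weight_g(146.0, fit) == pytest.approx(16.4, abs=0.2)

    def test_length_weight_doubling_scaling_identity(self):
        fit = emp.LengthWeightFit(a=7e-6, b=2.943)
        ratio = emp.predict_weight_g(292.0, fit) / emp.predict_weight_g(146.0, fit)
        assert ratio == pytest.approx(2**2.943, rel=1e-12)

    def test_length_weight_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(9)
        L = rng.uniform(100, 180, 7)
        W = 6e-6 * L**3.0 * np.exp(rng.normal(0, 0.05, 7))
        fit = emp.fit_length_weight(list(zip(L, W)))
        X = np.column_stack([np.ones(7), np.log(L)])
        beta = np.linalg.solve(X.T @ X, X.T @ np.log(W))
        assert fit.a == pytest.approx(np.exp(beta[0]), rel=1e-10)
        assert fit.b == pytest.approx(beta[1], abs=1e-10)

    def test_length_weight_rejects_nonpositive(self):
        with pytest.raises(emp.EmpiricsError):
            emp.fit_length_weight([(120.0, 12.0), (-1.0, 15.0), (150.0, 18.0)])


class TestFecundity:
    @pytest.mark.parametrize(
        "weight,expected",
        [(0.0, 39.06), (1.0, 157.53), (18.7, 39.06 + 118.47 * 18.7)],
    )
    def test_linear_model_values(self, weight, expected):
        model = emp.FecundityModel(intercept=39.06, slope=118.47)
        assert emp.fecundity(weight, model) == pytest.approx(expected, abs=1e-9)
        assert emp.fecundity(18.7, model) == pytest.approx(2254.4, abs=0.1)

    def test_negative_weight_rejected(self):
        with pytest.raises(emp.EmpiricsError):
            emp.fecundity(-1.0, emp.FecundityModel(intercept=39.06, slope=118.47))


class TestGsiFactors:
    GSI = {1: 25_000.0, 2: 24_747.0, 3: 23_184.0, 4: 18_841.0}

    def test_published_ratios(self):
        f = emp.gsi_to_factors(self.GSI, mode="senescent")
        assert round(f.factor(2), 3) == 0.990
        assert round(f.factor(3), 3) == 0.927
        assert round(f.factor(4), 3) == 0.754
        assert f.factor(5) == 0.612
        assert f.factor(6) == 0.498
        assert f.factor(7) == 0.498
        assert f.factor(1) == 0.0

    def test_non_senescent_mode_is_flat(self):
        f = emp.gsi_to_factors({}, mode="non-senescent")
        assert f.factor(1) == 0.0
        assert all(f.factor(a) == 1.0 for a in range(2, 8))

    def test_senescent_factors_non_increasing(self):
        f = emp.gsi_to_factors(self.GSI, mode="senescent")
        vals = [f.factor(a) for a in range(2, 8)]
        assert all(b <= a for a, b in zip(vals, vals[1:]))

    def test_missing_age_rejected(self):
        with pytest.raises(emp.EmpiricsError):
            emp.gsi_to_factors({1: 25000.0, 2: 24747.0}, mode="senescent")

    def test_extrapolated_tail_from_linear_fit(self):
        f = emp.gsi_to_factors(self.GSI, mode="senescent", extrapolate=True)
        ages = np.array([1.0, 2.0, 3.0, 4.0])
        gsi = np.array([self.GSI[a] for a in (1, 2, 3, 4)])
        slope, intercept = np.polyfit(ages, gsi, 1)
        assert f.factor(5) == pytest.approx((intercept + 5 * slope) / 25000.0)


class TestParameterFile:
    def test_json_round_trip(self, tmp_path):
        params = emp.EmpiricalParameters(
            k_regression=emp.LinfKRegression(1.27, -0.13, 0.30),
            length_weight=emp.LengthWeightFit(7e-6, 2.943),
            fecundity_model=emp.FecundityModel(39.06, 118.47),
            factors_senescent=emp.gsi_to_factors(TestGsiFactors.GSI),
        )
        path = tmp_path / "params.json"
        params.to_json(path)
        back = emp.EmpiricalParameters.from_json(path)
        assert back.k_regression == params.k_regression
        assert back.length_weight == params.length_weight
        assert back.factors_senescent.factor_by_age == params.factors_senescent.factor_by_age
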