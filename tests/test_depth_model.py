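import numpy as np
import pytest

from soc3d.depth_model import (
    DepthFunctionParams, IdentifiabilityError, discretize_profile,
    evaluate_soc, fit_depth_function, integrate_stock,
)
from tests.conftest import profile_from_params, random_params


class TestEvaluate:
    def test_plateau_holds_mattic_value(self):
        # the 18-cm mattic example profile: content constant within the mat
        p = DepthFunctionParams(has_mattic=True, d_mat=0.18, c_a=41.56, k=2.0)
        assert evaluate_soc(p, 0.10) == pytest.approx(41.56)

    def test_surface_value_without_mattic(self):
        p = DepthFunctionParams(has_mattic=False, d_mat=0.0, c_a=22.15, k=1.5)
        assert evaluate_soc(p, 0.0) == pytest.approx(22.15)

    def test_decay_reaches_deep_value(self):
        # k inverted so that the 90-100 cm midpoint carries 7.03 kg/m3
        k = np.log(41.56 / 7.03) / 0.77
        p = DepthFunctionParams(has_mattic=True, d_mat=0.18, c_a=41.56, k=k)
        assert evaluate_soc(p, 0.95) == pytest.approx(7.03, rel=1e-9)

    def test_negative_depth_rejected(self):
        p = DepthFunctionParams(has_mattic=False, d_mat=0.0, c_a=10.0, k=1.0)
        with pytest.raises(ValueError):
            evaluate_soc(p, -0.1)

    def test_continuous_and_non_increasing(self):
        rng = np.random.default_rng(11)
        z = np.linspace(0, 1.5, 2001)
        for _ in range(200):
            p = random_params(rng)
            v = evaluate_soc(p, z)
            assert np.all(np.diff(v) <= 1e-12)
            eps = 1e-9
            if p.has_mattic:
                assert evaluate_soc(p, p.d_mat + eps) == pytest.approx(
                    evaluate_soc(p, p.d_mat), rel=1e-6
                )

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            DepthFunctionParams(has_mattic=True, d_mat=0.0, c_a=10.0, k=1.0)
        with pytest.raises(ValueError):
            DepthFunctionParams(has_mattic=False, d_mat=0.0, c_a=-1.0, k=1.0)

    def test_json_round_trip(self):
        p = DepthFunctionParams(has_mattic=True, d_mat=0.15, c_a=40.0, k=2.0)
        assert DepthFunctionParams.from_json(p.to_json()) == p


class TestIntegrate:
    def test_within_plateau_is_rectangle(self):
        p = DepthFunctionParams(has_mattic=True, d_mat=0.15, c_a=40.0, k=2.0)
        assert integrate_stock(p, 0.0, 0.10) == pytest.approx(4.0)

    def test_mixed_interval_closed_form(self):
        p = DepthFunctionParams(has_mattic=True, d_mat=0.15, c_a=40.0, k=2.0)
        expected = 6.0 + 20.0 * (1 - np.exp(-1.7))
        assert integrate_stock(p, 0.0, 1.0) == pytest.approx(expected, rel=1e-12)

    def test_large_k_leaves_plateau_only(self):
        p = DepthFunctionParams(has_mattic=True, d_mat=0.15, c_a=40.0, k=1e6)
        assert integrate_stock(p, 0.0, 1.0) == pytest.approx(
            40.0 * 0.15, rel=1e-3
        )

    def test_empty_interval_rejected(self):
        p = DepthFunctionParams(has_mattic=False, d_mat=0.0, c_a=10.0, k=1.0)
        with pytest.raises(ValueError):
            integrate_stock(p, 0.5, 0.5)

    def test_additive_over_adjacent_intervals(self):
        rng = np.random.default_rng(5)
        for _ in range(300):
            p = random_params(rng)
            a = rng.uniform(0.05, 0.9)
            b = rng.uniform(a + 0.01, 1.5)
            s = integrate_stock(p, 0.0, a) + integrate_stock(p, a, b)
            assert s == pytest.approx(integrate_stock(p, 0.0, b), rel=1e-12)

    def test_matches_quadrature(self):
        # brute-force trapezoid oracle over random realistic draws
        rng = np.random.default_rng(7)
        h = 1e-4
        base = np.arange(0, 1.0 + h / 2, h)
        for _ in range(300):
            p = random_params(rng, k_max=3.0)
            z = np.unique(np.concatenate([base, [p.d_mat]]))
            quad = np.trapezoid(evaluate_soc(p, z), z)
            assert integrate_stock(p, 0.0, 1.0) == pytest.approx(quad, rel=1e-8)


class TestDiscretize:
    def test_slice_count(self):
        p = DepthFunctionParams(has_mattic=False, d_mat=0.0, c_a=10.0, k=1.0)
        assert discretize_profile(p, dz=0.01, z_max=1.0).shape == (100,)

    def test_constant_within_plateau(self):
        p = DepthFunctionParams(has_mattic=True, d_mat=0.30, c_a=33.0, k=1.0)
        v = discretize_profile(p, dz=0.01, z_max=0.30)
        assert np.allclose(v, 33.0)

    def test_midpoint_sum_close_to_integral(self):
        rng = np.random.default_rng(9)
        for _ in range(100):
            p = random_params(rng, k_max=5.0)
            approx = discretize_profile(p, dz=0.01, z_max=1.0).sum() * 0.01
            exact = integrate_stock(p, 0.0, 1.0)
            assert approx == pytest.approx(exact, rel=5e-3)

    def test_non_multiple_zmax_rejected(self):
        p = DepthFunctionParams(has_mattic=False, d_mat=0.0, c_a=10.0, k=1.0)
        with pytest.raises(ValueError):
            discretize_profile(p, dz=0.03, z_max=1.0)


class TestFit:
    def test_exact_recovery_no_noise(self):
        rng = np.random.default_rng(21)
        mids = [0.05, 0.2, 0.4, 0.7, 0.95]
        for _ in range(50):
            true = random_params(rng, k_max=4.0)
            pedon = profile_from_params(true, mids)
            fit = fit_depth_function(pedon)
            assert fit.params.c_a == pytest.approx(true.c_a, rel=1e-6)
            assert fit.params.k == pytest.approx(true.k, rel=1e-6)
            assert fit.r_squared == pytest.approx(1.0, abs=1e-9)

    def test_two_point_closed_form(self):
        # two observations invert exactly: k = ln(v1/v2)/(z2-z1)
        p = DepthFunctionParams(has_mattic=False, d_mat=0.0, c_a=39.46, k=1.0)
        pedon = profile_from_params(p, [0.1, 0.5])
        pedon.horizons[0].soc_volume = 30.0
        pedon.horizons[1].soc_volume = 10.0
        fit = fit_depth_function(pedon)
        k_expected = np.log(3.0) / 0.4
        assert fit.params.k == pytest.approx(k_expected, rel=1e-6)
        assert fit.params.c_a == pytest.approx(30.0 * np.exp(k_expected * 0.1),
                                               rel=1e-6)

    def test_all_horizons_in_plateau_unidentifiable(self):
        p = DepthFunctionParams(has_mattic=True, d_mat=0.30, c_a=40.0, k=2.0)
        pedon = profile_from_params(p, [0.05, 0.15, 0.25])
        with pytest.raises(IdentifiabilityError):
            fit_depth_function(pedon)

    def test_single_horizon_unidentifiable(self):
        p = DepthFunctionParams(has_mattic=False, d_mat=0.0, c_a=40.0, k=2.0)
        with pytest.raises(IdentifiabilityError):
            fit_depth_function(profile_from_params(p, [0.3]))

    def test_noisy_fit_quality(self):
        # 10% multiplicative noise on profiles with clear depth decline
        # (k >= 1, as observed in these soils): mean R2 stays high
        rng = np.random.default_rng(33)
        mids = [0.06, 0.2, 0.4, 0.65, 0.9]
        r2 = []
        for _ in range(100):
            true = random_params(rng, k_max=4.0, k_min=1.0)
            pedon = profile_from_params(true, mids)
            for hz in pedon.horizons:
                hz.soc_volume *= float(rng.lognormal(0.0, 0.10))
            r2.append(fit_depth_function(pedon).r_squared)
        assert np.mean(r2) >= 0.85
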