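"""Symmetry functions: defining formulas, normalizations, invariances."""

import numpy as np
import pytest

import tpslearn as t
from tpslearn.featurize import (SymmetryFunctionParams, g2_probe_volume_quadrature,
                                g5_probe_volume)


def params_g2(**kw):
    base = dict(kind="G2", r_s=0.5, eta=25.0, alpha_c=100.0, r_cut=2.0, rho_N=1.0)
    base.update(kw)
    return SymmetryFunctionParams(**base)


def params_g5(**kw):
    base = dict(kind="G5", r_s=0.5, eta=25.0, alpha_c=100.0, r_cut=2.0,
                rho_N=1.0, zeta=2, lam=-1)
    base.update(kw)
    return SymmetryFunctionParams(**base)


class TestFermiCutoff:
    def test_vanishes_beyond_cutoff(self):
        assert t.fermi_cutoff(1.001, 100.0, 1.0) == 0.0

    def test_deep_inside_near_one(self):
        assert t.fermi_cutoff(0.0, 100.0, 1.0) > 0.999

    def test_value_at_cutoff_from_defining_formula(self):
        # at r = r_cut the argument is -sqrt(alpha_c) = -10
        assert t.fermi_cutoff(1.0, 100.0, 1.0) == pytest.approx(1 / (1 + np.exp(-10)), rel=1e-12)

    def test_nonincreasing_with_compact_support(self):
        r = np.linspace(0, 3, 400)
        f = t.fermi_cutoff(r, 50.0, 1.5)
        assert np.all(np.diff(f) <= 1e-15)
        assert np.all(f[r > 1.5] == 0.0)
        assert np.all((f >= 0) & (f <= 1))


class TestG2:
    def test_empty_cloud_is_zero(self):
        assert t.g2(np.zeros(3), np.empty((0, 3)), params_g2()) == 0.0

    def test_single_point_at_shell_peak(self):
        p = params_g2()
        cloud = np.array([[p.r_s, 0.0, 0.0]])
        val = t.g2(np.zeros(3), cloud, p, normalized=False)
        assert val == pytest.approx(float(t.fermi_cutoff(p.r_s, p.alpha_c, p.r_cut)), rel=1e-12)
        assert val == pytest.approx(1.0, abs=1e-3)

    def test_ideal_gas_mean_is_one(self):
        # normalized G2 over uniform clouds at density rho_N has mean ~ 1;
        # the quadrature/closed-form volume ratio corrects the small-eta bias
        rng = np.random.default_rng(0)
        p = params_g2(eta=25.0, r_s=0.5, r_cut=1.5, rho_N=2.0)
        box = 4.0
        vals = []
        for _ in range(600):
            n = rng.poisson(p.rho_N * box**3)
            cloud = rng.uniform(-box / 2, box / 2, size=(n, 3))
            vals.append(t.g2(np.zeros(3), cloud, p))
        ratio = g2_probe_volume_quadrature(p) / (8 * np.pi * p.r_s**2 * np.sqrt(2 / p.eta))
        mean = np.mean(vals) / ratio
        se = np.std(vals, ddof=1) / np.sqrt(len(vals)) / ratio
        assert abs(mean - 1.0) < 3 * se

    def test_rigid_motion_and_permutation_invariance(self):
        rng = np.random.default_rng(1)
        cloud = rng.uniform(-1, 1, size=(12, 3))
        center = np.array([0.1, -0.2, 0.05])
        p2, p5 = params_g2(), params_g5()
        ref2 = t.g2(center, cloud, p2)
        ref5 = t.g5(center, cloud, p5)
        # random rotation via QR, translation, and shuffle
        Q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
        shift = rng.standard_normal(3)
        moved = cloud @ Q.T + shift
        perm = rng.permutation(12)
        assert t.g2(center @ Q.T + shift, moved[perm], p2) == pytest.approx(ref2, abs=1e-12)
        assert t.g5(center @ Q.T + shift, moved[perm], p5) == pytest.approx(ref5, abs=1e-12)


class TestG5:
    def test_single_point_is_zero(self):
        assert t.g5(np.zeros(3), np.array([[0.5, 0, 0]]), params_g5()) == 0.0

    def test_collinear_pair_maximal_angular_factor(self):
        p = params_g5(zeta=4, lam=-1)
        cloud = np.array([[p.r_s, 0, 0], [-p.r_s, 0, 0]])  # theta = pi
        val = t.g5(np.zeros(3), cloud, p, normalized=False)
        fc = float(t.fermi_cutoff(p.r_s, p.alpha_c, p.r_cut))
        assert val == pytest.approx(2**p.zeta * fc**2, rel=1e-9)

    def test_right_angle_pair_unit_angular_factor(self):
        p = params_g5(zeta=2, lam=-1)
        cloud = np.array([[p.r_s, 0, 0], [0, p.r_s, 0]])  # theta = pi/2
        val = t.g5(np.zeros(3), cloud, p, normalized=False)
        fc = float(t.fermi_cutoff(p.r_s, p.alpha_c, p.r_cut))
        assert val == pytest.approx(1.0 * fc**2, rel=1e-9)  # (1 - cos(pi/2))^2 = 1


class TestNormalizers:
    def test_g2_scales_with_shell_radius_squared(self):
        p1, p2 = params_g2(r_s=0.5), params_g2(r_s=1.0)
        assert t.g2_normalizer(p2) == pytest.approx(4 * t.g2_normalizer(p1), rel=1e-12)

    def test_g2_zero_density_flagged(self):
        with pytest.warns(UserWarning):
            assert t.g2_normalizer(params_g2(rho_N=0.0)) == 0.0

    def test_g5_volume_zeta2_is_three_quarters_of_g2(self):
        p = params_g5(zeta=2)
        v2 = 8 * np.pi * p.r_s**2 * np.sqrt(2 / p.eta)
        assert g5_probe_volume(p) == pytest.approx(0.75 * v2, rel=1e-12)

    def test_pair_count_nonnegative_below_one_atom(self):
        # <N_atoms> = 0.5 -> <N_pairs> = 0.125 under the squared approximation
        p = params_g5(zeta=2)
        v5 = g5_probe_volume(p)
        rho = 0.5 / v5
        assert t.g5_normalizer(params_g5(zeta=2, rho_N=rho)) == pytest.approx(0.125, rel=1e-9)

    def test_g5_volume_decreases_with_zeta(self):
        vols = [g5_probe_volume(params_g5(zeta=z)) for z in (2, 4, 6, 8, 10)]
        assert np.all(np.diff(vols) < 0)

    def test_quadrature_oracle_is_finite_and_positive(self):
        ratio = g2_probe_volume_quadrature(params_g2()) / \
            (8 * np.pi * 0.5**2 * np.sqrt(2 / 25.0))
        assert 0 < ratio < 10  # mismatch quantified, not asserted away


class TestSwitchAndScaling:
    def test_rational_switch_reference_values(self):
        assert t.rational_switch(0.0, 2.0) == 1.0
        assert t.rational_switch(2.0, 2.0) == pytest.approx(0.5, rel=1e-12)
        assert t.rational_switch(4.0, 2.0) == pytest.approx(63 / 4095, rel=1e-9)

    def test_switch_equals_unsimplified_form_away_from_pole(self):
        r = np.array([0.3, 1.1, 1.9, 2.5, 3.7])
        u = (r / 2.0)
        naive = (1 - u**6) / (1 - u**12)
        np.testing.assert_allclose(t.rational_switch(r, 2.0), naive, rtol=1e-12)

    def test_minmax_and_roundtrip(self):
        X = np.array([[2.0, 1.0], [4.0, 1.0], [6.0, 3.0]])
        scaled, rec = t.scale_features(X[:, :1], "minmax")
        np.testing.assert_allclose(scaled[:, 0], [0, 0.5, 1])
        back = t.unscale_features(scaled, rec)
        np.testing.assert_allclose(back, X[:, :1], atol=1e-12)

    def test_constant_column_warns_and_maps_to_zero(self):
        X = np.array([[1.0, 5.0], [2.0, 5.0]])
        with pytest.warns(UserWarning):
            scaled, rec = t.scale_features(X, "minmax")
        assert np.all(scaled[:, 1] == 0.0)
        np.testing.assert_allclose(t.unscale_features(scaled, rec)[:, 1], 5.0)

    def test_isotropic_matches_normalized_g2(self):
        rng = np.random.default_rng(2)
        p = params_g2()
        cloud = rng.uniform(-2, 2, size=(40, 3))
        raw = t.g2(np.zeros(3), cloud, p, normalized=False)
        scaled, _ = t.scale_features(np.array([[raw]]), "isotropic",
                                     normalizers=np.array([t.g2_normalizer(p)]))
        assert scaled[0, 0] == pytest.approx(t.g2(np.zeros(3), cloud, p), rel=1e-12)

    def test_augment_appends_and_rejects_collision(self):
        fv = t.FeatureVector(np.array([0.2]), ("g2_0",))
        out = t.augment_with_parameters(fv, {"kT": 0.25, "sigma": 0.315})
        assert out.names == ("g2_0", "kT", "sigma") and out.values[1] == 0.25
        with pytest.raises(ValueError):
            t.augment_with_parameters(out, {"kT": 1.0})

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            SymmetryFunctionParams(kind="G5", r_s=0.5, eta=25.0, alpha_c=100.0,
                                   r_cut=2.0, rho_N=1.0, zeta=3, lam=-1)
        with pytest.raises(ValueError):
            SymmetryFunctionParams(kind="G2", r_s=0.5, eta=-1.0, alpha_c=100.0,
                                   r_cut=2.0, rho_N=1.0)
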