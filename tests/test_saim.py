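"""Optics forward model and per-pixel height inversion."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ajmech.saim import (
    AngleSweep,
    FitConfig,
    LayerStack,
    excitation_profile,
    fit_pixel,
    fit_stack,
    mirror_reflectance,
    roi_zcenter,
    topographic_map,
    _varpro_ss,
)
from ajmech.synth import gen_saim_stack


def characteristic_matrix_r(theta_deg, stack, polarization):
    """Independent transfer-matrix oracle (Born & Wolf 2x2 characteristic
    matrix of the oxide film), coded separately from the Airy-sum path."""
    n1 = complex(stack.n_medium)
    n2 = complex(stack.n_oxide)
    n3 = complex(stack.n_silicon).conjugate() \
        if complex(stack.n_silicon).imag < 0 else complex(stack.n_silicon)
    th1 = np.deg2rad(theta_deg)
    s1 = n1 * np.sin(th1)
    c1 = np.cos(th1)
    c2 = np.sqrt(1 + 0j - (s1 / n2) ** 2)
    c3 = np.sqrt(1 + 0j - (s1 / n3) ** 2)
    if polarization == "TE":
        e1, e2, e3 = n1 * c1, n2 * c2, n3 * c3
    else:
        e1, e2, e3 = n1 / c1, n2 / c2, n3 / c3
    beta = 2 * np.pi * n2 * stack.oxide_thickness_nm * c2 / stack.wavelength_nm
    m11 = np.cos(beta)
    m12 = -1j * np.sin(beta) / e2
    m21 = -1j * e2 * np.sin(beta)
    m22 = np.cos(beta)
    num = e1 * m11 + e1 * e3 * m12 - m21 - e3 * m22
    den = e1 * m11 + e1 * e3 * m12 + m21 + e3 * m22
    r = num / den
    if polarization == "TM":
        # the admittance form returns the H-field reflection coefficient;
        # the package reports the E-field (Verdet) convention, which flips
        # the sign for p-polarization
        r = -r
    return r


class TestMirrorReflectance:
    def test_degenerate_spacer_is_single_interface_fresnel(self):
        bare = LayerStack(oxide_thickness_nm=0.0)
        r = mirror_reflectance(0.0, bare, "TE")
        n1 = bare.n_medium
        n3 = complex(bare.n_silicon).conjugate()
        expected = (n1 - n3) / (n1 + n3)
        assert r == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("pol", ["TE", "TM"])
    @pytest.mark.parametrize("theta", [0.0, 17.3, 36.0, 52.0, 75.0])
    def test_matches_characteristic_matrix_oracle(self, layers, theta, pol):
        r = mirror_reflectance(theta, layers, pol)
        r_oracle = characteristic_matrix_r(theta, layers, pol)
        assert r == pytest.approx(r_oracle, abs=1e-10)

    def test_absorbing_silicon_is_passive(self, layers):
        theta = np.linspace(0, 89.0, 200)
        for pol in ("TE", "TM"):
            r = mirror_reflectance(theta, layers, pol)
            assert np.all(np.abs(r) < 1.0)

    def test_positive_imag_silicon_accepted_identically(self):
        a = LayerStack(n_silicon=4.37 - 0.08j)
        b = LayerStack(n_silicon=4.37 + 0.08j)
        assert mirror_reflectance(30.0, a) == pytest.approx(
            mirror_reflectance(30.0, b), abs=1e-14)

    def test_angle_out_of_range_rejected(self, layers):
        with pytest.raises(ValueError):
            mirror_reflectance(90.0, layers)

    def test_tir_regime_rejected_for_lossless_dense_medium(self):
        # medium denser than a lossless "mirror" layer: evanescent regime
        dense = LayerStack(n_medium=1.6, n_oxide=1.1, n_silicon=4.37 - 0.08j)
        with pytest.raises(ValueError, match="total-internal-reflection"):
            mirror_reflectance(80.0, dense)


class TestExcitationProfile:
    def test_zero_height_at_normal_incidence(self, layers):
        sweep = AngleSweep((0.0, 4.0, 8.0))
        F = excitation_profile(0.0, sweep, layers)
        r0 = mirror_reflectance(0.0, layers)
        assert F[0] == pytest.approx(abs(1 + r0) ** 2, abs=1e-12)

    def test_matches_direct_formula(self, sweep, layers):
        h = 100.0
        F = excitation_profile(h, sweep, layers)
        theta = sweep.as_array()
        r = np.array([mirror_reflectance(t, layers) for t in theta])
        phi = 4 * np.pi * layers.n_medium * h * np.cos(np.deg2rad(theta)) \
            / layers.wavelength_nm
        assert F == pytest.approx(np.abs(1 + r * np.exp(1j * phi)) ** 2,
                                  abs=1e-12)

    @given(h=st.floats(0.0, 400.0), theta=st.floats(0.0, 80.0))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_bounded_between_0_and_4(self, h, theta):
        layers = LayerStack()
        sweep = AngleSweep((theta, theta + 1.0, theta + 2.0))
        F = excitation_profile(h, sweep, layers)
        assert np.all((F >= 0.0) & (F <= 4.0))

    def test_periodic_in_height(self, layers):
        theta = 20.0
        sweep = AngleSweep((theta, theta + 4, theta + 8))
        period = layers.wavelength_nm / (2 * layers.n_medium
                                         * np.cos(np.deg2rad(theta)))
        F1 = excitation_profile(30.0, sweep, layers)[0]
        F2 = excitation_profile(30.0 + period, sweep, layers)[0]
        assert F1 == pytest.approx(F2, rel=1e-9)

    def test_empty_sweep_rejected(self, layers):
        with pytest.raises(ValueError):
            AngleSweep(())


class TestFitPixel:
    def test_noiseless_self_consistency(self, sweep, layers):
        F = excitation_profile(100.0, sweep, layers)
        fit = fit_pixel(500.0 * F + 50.0, sweep, layers)
        assert fit.converged
        assert fit.height_nm == pytest.approx(100.0, abs=0.1)
        assert fit.amplitude == pytest.approx(500.0, rel=1e-3)
        assert fit.offset == pytest.approx(50.0, rel=1e-3)

    def test_matches_exhaustive_grid_search(self, sweep, layers, rng):
        """The multi-start fit lands on the global minimum located by an
        exhaustive 0.01-nm grid search with the (A, B) subproblem solved
        linearly at every height."""
        h_grid = np.arange(0.0, 200.0 + 1e-9, 0.01)
        for _ in range(20):
            h_true = rng.uniform(10.0, 150.0)
            A, B = rng.uniform(100, 1000), rng.uniform(0, 200)
            I = A * excitation_profile(h_true, sweep, layers) + B
            ss = _varpro_ss(h_grid, I, sweep, layers, "TE")
            h_oracle = h_grid[np.argmin(ss)]
            fit = fit_pixel(I, sweep, layers)
            assert fit.height_nm == pytest.approx(h_oracle, abs=0.011)

    def test_forward_inverse_consistency_over_height_grid(self, sweep, layers):
        for h in np.linspace(10.0, 150.0, 15):
            I = 300.0 * excitation_profile(h, sweep, layers) + 20.0
            fit = fit_pixel(I, sweep, layers)
            assert fit.height_nm == pytest.approx(h, abs=0.1)

    def test_constant_intensities_flagged_unconverged(self, sweep, layers):
        fit = fit_pixel(np.full(len(sweep), 7.0), sweep, layers)
        assert not fit.converged

    def test_length_mismatch_rejected(self, sweep, layers):
        with pytest.raises(ValueError):
            fit_pixel(np.ones(5), sweep, layers)


class TestFitStack:
    def test_uniform_field_recovered(self, sweep, layers):
        stack, _ = gen_saim_stack(80.0, shape=(8, 8), noise_frac=0.0)
        hm, fits = fit_stack(stack, sweep, layers)
        assert np.allclose(hm, 80.0, atol=0.05)
        assert fits["converged"].all()

    def test_two_region_phantom(self, sweep, layers):
        hmap = np.full((10, 10), 50.0)
        hmap[:, 5:] = 90.0
        stack, _ = gen_saim_stack(hmap, shape=(10, 10), noise_frac=0.0)
        hm, _ = fit_stack(stack, sweep, layers)
        assert np.median(hm[:, :5]) == pytest.approx(50.0, abs=0.05)
        assert np.median(hm[:, 5:]) == pytest.approx(90.0, abs=0.05)

    def test_masking_contract(self, sweep, layers):
        stack, _ = gen_saim_stack(60.0, shape=(6, 6), noise_frac=0.0)
        mask = np.zeros((6, 6), bool)
        mask[:, :3] = True
        hm, _ = fit_stack(stack, sweep, layers, mask=mask)
        assert np.all(np.isfinite(hm[:, :3]))
        assert np.all(np.isnan(hm[:, 3:]))

    def test_empty_mask_rejected(self, sweep, layers):
        stack, _ = gen_saim_stack(60.0, shape=(4, 4), noise_frac=0.0)
        with pytest.raises(ValueError, match="mask"):
            fit_stack(stack, sweep, layers, mask=np.zeros((4, 4), bool))

    def test_noise_robustness_median_error(self, sweep, layers):
        """At 2% multiplicative noise the per-pixel error distribution over
        a 64x64 phantom stays centred: |median error| < 2 nm."""
        stack, truth = gen_saim_stack(55.93, noise_frac=0.02, seed=11)
        hm, _ = fit_stack(stack, sweep, layers)
        err = hm - truth["height_nm"]
        assert abs(np.median(err)) < 2.0


class TestRoiZcenter:
    def test_constant_field(self):
        hm = np.full((4, 4), 46.56)
        res = roi_zcenter(hm, np.ones((4, 4), bool))
        assert res.z_center_nm == pytest.approx(46.56)
        assert res.n_pixels == 16

    def test_even_count_median_convention(self):
        hm = np.array([[50.0, 60.0]])
        res = roi_zcenter(hm, np.ones((1, 2), bool))
        assert res.z_center_nm == pytest.approx(55.0)

    def test_nonfinite_pixels_excluded(self):
        hm = np.array([[50.0, np.nan, 70.0]])
        res = roi_zcenter(hm, np.ones((1, 3), bool))
        assert res.n_pixels == 2
        assert res.z_center_nm == pytest.approx(60.0)

    def test_all_nan_rejected(self):
        with pytest.raises(ValueError):
            roi_zcenter(np.full((2, 2), np.nan), np.ones((2, 2), bool))

    @given(st.permutations(list(range(9))))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_median_permutation_invariant(self, perm):
        base = np.linspace(40.0, 90.0, 9)
        hm = base[np.array(perm)].reshape(3, 3)
        res = roi_zcenter(hm, np.ones((3, 3), bool))
        assert res.z_center_nm == pytest.approx(np.median(base))

    def test_median_robust_to_minority_outliers(self, rng):
        vals = np.full(21, 55.0)
        vals[:10] = rng.uniform(0.0, 200.0, 10)  # <50% outliers in bounds
        res = roi_zcenter(vals.reshape(3, 7), np.ones((3, 7), bool))
        assert 40.0 <= res.z_center_nm <= 70.0


class TestTopographicMap:
    def test_constant_map_uniform_color(self):
        img = topographic_map(np.full((3, 3), 90.0))
        assert (img == img[0, 0]).all()

    def test_out_of_range_clamped_to_end_colors(self):
        img = topographic_map(np.array([[0.0, 40.0], [140.0, 500.0]]))
        assert (img[0, 0] == img[0, 1]).all()
        assert (img[1, 0] == img[1, 1]).all()

    def test_invalid_range_rejected(self):
        with pytest.raises(ValueError):
            topographic_map(np.ones((2, 2)), color_range=(100.0, 100.0))
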