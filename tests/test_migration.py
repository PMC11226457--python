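"""Angular statistics of migration velocity fields."""

import numpy as np
import pytest

from ajmech.migration import (
    VelocityField,
    angular_distribution,
    block_velocimetry,
    compare_major_angles,
    gaussian_major_angle,
    segment_tissue,
    speed_filter,
)
from ajmech.synth import gen_velocity_fields


def field_from_vectors(u, v):
    u = np.asarray(u, float)
    v = np.asarray(v, float)
    return VelocityField(x_um=np.arange(u.size, dtype=float),
                         y_um=np.zeros(u.size), u_um_h=u, v_um_h=v)


class TestSpeedFilter:
    def test_all_slow_vectors_removed(self):
        f = field_from_vectors([5.0, 3.0], [0.0, 0.0])
        assert speed_filter(f).valid.sum() == 0

    def test_boundary_value_retained(self):
        f = field_from_vectors([5.0, 10.0, 15.0], [0.0, 0.0, 0.0])
        kept = speed_filter(f)
        assert list(kept.valid) == [False, True, True]

    def test_matches_brute_force_count(self, rng):
        u = rng.uniform(-30, 30, 500)
        v = rng.uniform(-30, 30, 500)
        kept = speed_filter(field_from_vectors(u, v))
        brute = sum(1 for a, b in zip(u, v) if np.hypot(a, b) >= 10.0)
        assert kept.valid.sum() == brute


class TestAngularDistribution:
    def test_delta_distribution_along_zero(self):
        f = field_from_vectors([20.0] * 5, [0.0] * 5)
        d = angular_distribution(f)
        i = np.argmax(d.frequency)
        assert d.bin_edges_deg[i] <= 0 < d.bin_edges_deg[i + 1]
        assert d.frequency[i] == 1.0
        assert d.relative_angular_speed_um_h[i] == pytest.approx(20.0)
        assert np.nansum(np.delete(d.relative_angular_speed_um_h, i)) == 0.0

    def test_two_vector_hand_computation(self):
        f = field_from_vectors([10.0, 0.0], [0.0, 30.0])
        d = angular_distribution(f)
        i0 = np.argmax(d.relative_angular_speed_um_h == 5.0)
        i90 = np.argmax(d.relative_angular_speed_um_h == 15.0)
        assert d.frequency[i0] == 0.5 and d.frequency[i90] == 0.5
        assert d.mean_speed_um_h[i0] == pytest.approx(10.0)
        assert d.mean_speed_um_h[i90] == pytest.approx(30.0)

    def test_frequency_sums_to_one_and_weighted_mean_identity(self, rng):
        u = rng.uniform(-40, 40, 800)
        v = rng.uniform(-40, 40, 800)
        f = field_from_vectors(u, v)
        d = angular_distribution(f)
        assert d.frequency.sum() == pytest.approx(1.0, abs=1e-12)
        speeds = np.hypot(u, v)
        retained = speeds[speeds >= 10.0]
        assert np.nansum(d.relative_angular_speed_um_h) == pytest.approx(
            retained.mean(), rel=1e-12)

    def test_rotation_by_one_bin_shifts_histogram(self, rng):
        u = rng.uniform(-40, 40, 600)
        v = rng.uniform(-40, 40, 600)
        d0 = angular_distribution(field_from_vectors(u, v))
        ang = np.deg2rad(30.0)
        u2 = u * np.cos(ang) - v * np.sin(ang)
        v2 = u * np.sin(ang) + v * np.cos(ang)
        d1 = angular_distribution(field_from_vectors(u2, v2))
        assert d1.frequency == pytest.approx(np.roll(d0.frequency, 1),
                                             abs=1e-12)

    def test_empty_retained_set_rejected(self):
        with pytest.raises(ValueError):
            angular_distribution(field_from_vectors([1.0], [1.0]))


class TestGaussianMajorAngle:
    def test_symmetric_histogram_centred_on_zero(self):
        rng = np.random.default_rng(2)
        ang = rng.vonmises(0.0, 4.0, 4000)
        u = 20 * np.cos(ang)
        v = 20 * np.sin(ang)
        fit = gaussian_major_angle(
            angular_distribution(field_from_vectors(u, v)))
        assert fit.converged and fit.amplitude > 0
        assert abs(fit.mean_deg) < 5.0

    @pytest.mark.parametrize("true_deg", [-120.0, -45.0, 20.0, 170.0])
    def test_recovers_wrapped_gaussian_direction(self, true_deg):
        rng = np.random.default_rng(int(abs(true_deg)))
        ang = rng.vonmises(np.deg2rad(true_deg), 4.0, 4000)
        u = 20 * np.cos(ang)
        v = 20 * np.sin(ang)
        fit = gaussian_major_angle(
            angular_distribution(field_from_vectors(u, v)))
        delta = (fit.mean_deg - true_deg + 180) % 360 - 180
        assert abs(delta) < 5.0

    def test_too_few_bins_rejected(self):
        d = angular_distribution(field_from_vectors([20.0], [0.0]))
        with pytest.raises(ValueError):
            gaussian_major_angle(d)


class TestCompareMajorAngles:
    def _fits(self, mean_deg, n, seed):
        fields, _ = gen_velocity_fields(mean_angle_deg=mean_deg,
                                        angular_concentration=4.0,
                                        n_frames=2, seed=seed)
        out = []
        for i in range(n):
            f, _ = gen_velocity_fields(mean_angle_deg=mean_deg,
                                       angular_concentration=4.0,
                                       n_frames=2, seed=seed + i)
            out.append(gaussian_major_angle(angular_distribution(f)))
        return out

    def test_identical_conditions_not_significant(self):
        fits = self._fits(0.0, 5, 10)
        _, anova, pairwise = compare_major_angles({"a": fits,
                                                   "b": list(fits)})
        assert anova["p_value"] > 0.99

    def test_zero_vs_45_degrees_significant(self):
        _, anova, pairwise = compare_major_angles({
            "wt": self._fits(0.0, 5, 20),
            "kd": self._fits(45.0, 5, 40)})
        assert anova["p_value"] < 0.01

    def test_single_condition_rejected(self):
        with pytest.raises(ValueError):
            compare_major_angles({"a": self._fits(0.0, 3, 5)})


class TestSegmentTissue:
    def test_textured_half_detected(self, rng):
        img = np.zeros((60, 60))
        img[:, 30:] = rng.uniform(0, 1, (60, 30))
        mask = segment_tissue(img)
        assert mask[:, 35:].mean() > 0.9
        assert mask[:, :25].mean() < 0.1

    def test_uniform_image_rejected(self):
        with pytest.raises(ValueError):
            segment_tissue(np.full((40, 40), 3.0))

    def test_idempotent_on_masked_region(self, rng):
        img = np.zeros((60, 60))
        img[:, 30:] = rng.uniform(0, 1, (60, 30))
        m1 = segment_tissue(img)
        m2 = segment_tissue(np.where(m1, img, 0.0))
        assert (m1 & m2).sum() / m1.sum() > 0.9


class TestBlockVelocimetry:
    def test_rigid_shift_recovered(self, rng):
        a = rng.uniform(0, 1, (96, 96))
        b = np.roll(a, 3, axis=1)  # shift +3 px along x
        field = block_velocimetry(a, b, window=32, dt_h=1.0, px_um=1.0)
        assert np.median(field.u_um_h[field.valid]) == pytest.approx(3.0)
        assert np.median(np.abs(field.v_um_h[field.valid])) == 0.0

    def test_zero_shift_zero_field(self, rng):
        a = rng.uniform(0, 1, (64, 64))
        field = block_velocimetry(a, a.copy(), window=32)
        assert np.all(field.u_um_h[field.valid] == 0.0)
        assert np.all(field.v_um_h[field.valid] == 0.0)

    def test_featureless_window_flagged(self, rng):
        a = np.zeros((64, 64))
        a[:32, :32] = rng.uniform(0, 1, (32, 32))
        field = block_velocimetry(a, a.copy(), window=32, overlap=0.0)
        assert not field.valid.all()
        assert field.valid.any()

    def test_synthetic_flow_median_angle_error(self, rng):
        a = rng.uniform(0, 1, (96, 96))
        b = np.roll(np.roll(a, 2, axis=1), 1, axis=0)  # flow at atan2(1,2)
        field = block_velocimetry(a, b, window=32)
        ang = np.degrees(np.arctan2(field.v_um_h[field.valid],
                                    field.u_um_h[field.valid]))
        true = np.degrees(np.arctan2(1, 2))
        assert np.median(np.abs(ang - true)) < 10.0
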