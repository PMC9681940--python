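"""Mutual information, point-based registration, resampling and TRE."""

import numpy as np
import pytest
from scipy import optimize

from slnfusion.registration import (
    MIOptions,
    mutual_information,
    register_points,
    register_rigid_mi,
    resample,
    target_registration_error,
)
from slnfusion.transforms import RigidTransform
from slnfusion.volume import Volume


def vol(values, spacing=1.0, origin=(0, 0, 0)):
    return Volume(values=np.asarray(values), spacing=np.full(3, float(spacing)), origin=origin)


class TestMutualInformation:
    def test_balanced_binary_self_information_is_one_bit(self, rng):
        values = np.zeros(40 * 50 * 50)
        values[rng.permutation(values.size)[: values.size // 2]] = 1.0  # exactly half set
        a = vol(values.reshape(40, 50, 50))
        assert mutual_information(a, a) == pytest.approx(1.0, abs=1e-9)

    def test_independent_images_near_zero(self, rng):
        a = vol(rng.random((50, 50, 50)))
        b = vol(rng.random((50, 50, 50)))
        assert a.values.size >= 1e5
        assert mutual_information(a, b) < 0.05

    def test_self_beats_permutation(self, rng):
        values = rng.normal(size=(20, 20, 20))
        a = vol(values)
        perm = values.ravel().copy()
        rng.shuffle(perm)
        b = vol(perm.reshape(values.shape))
        assert mutual_information(a, a) >= mutual_information(a, b)

    def test_constant_image_warns_and_returns_zero(self):
        a = vol(np.zeros((8, 8, 8)))
        b = vol(np.arange(512, dtype=float).reshape(8, 8, 8))
        with pytest.warns(UserWarning):
            assert mutual_information(a, b) == 0.0

    def test_mask_restricts_sample(self, rng):
        a = vol(rng.random((12, 12, 12)))
        mask = np.zeros((12, 12, 12), dtype=bool)
        mask[:6] = True
        sub = vol(a.values[:6])
        assert mutual_information(a, a, mask=mask) == pytest.approx(mutual_information(sub, sub), abs=1e-12)

    def test_bad_bins_rejected(self, rng):
        a = vol(rng.random((5, 5, 5)))
        with pytest.raises(ValueError):
            mutual_information(a, a, n_bins=1)


def fre_of(transform, moving, fixed):
    return float(np.sqrt(np.mean(np.sum((transform.apply(moving) - fixed) ** 2, axis=1))))


class TestRegisterPoints:
    def test_exact_recovery_from_noiseless_points(self, rng):
        moving = rng.uniform(0, 100, size=(4, 3))
        truth = RigidTransform.from_params((4, -9, 15), (10, -3, 7))
        res = register_points(moving, truth.apply(moving))
        assert res.fre_mm < 1e-9
        assert res.transform.almost_equal(truth, atol=1e-9)

    def test_collinear_points_rejected(self):
        pts = np.array([[0, 0, 0], [1, 1, 1], [2, 2, 2], [3, 3, 3]], dtype=float)
        with pytest.raises(ValueError):
            register_points(pts, pts + 5.0)

    def test_fre_matches_bruteforce_oracle_under_noise(self, rng):
        """Closed-form FRE equals the minimum found by an independent 6-DOF search."""
        moving = rng.uniform(0, 80, size=(8, 3))
        truth = RigidTransform.from_params((6, 3, -10), (5, 8, -4))
        fixed = truth.apply(moving) + rng.normal(0, 0.5, size=(8, 3))
        res = register_points(moving, fixed)

        def cost(p):
            return fre_of(RigidTransform.from_params(p[:3], p[3:]), moving, fixed)

        best = np.inf
        for _ in range(60):  # random multistart + simplex polish, no SVD involved
            x0 = np.r_[rng.uniform(-15, 15, 3), rng.uniform(-15, 15, 3)]
            r = optimize.minimize(cost, x0, method="Nelder-Mead",
                                  options={"xatol": 1e-10, "fatol": 1e-14, "maxiter": 4000})
            best = min(best, r.fun)
        assert res.fre_mm == pytest.approx(best, abs=1e-6)
        assert res.fre_mm <= best + 1e-9  # closed form is the global optimum


class TestResample:
    def test_identity_same_grid_is_exact(self, rng):
        a = vol(rng.normal(size=(15, 12, 10)).astype(np.float32), spacing=1.3, origin=(4, -2, 7))
        out = resample(a, RigidTransform.identity(), a)
        assert np.array_equal(out.values, a.values)

    def test_one_voxel_translation_shifts_exactly(self, rng):
        a = vol(rng.normal(size=(12, 12, 12)).astype(np.float32), spacing=2.0)
        t = RigidTransform.from_params((0, 0, 0), (2.0, 0, 0))
        out = resample(a, t, a)
        assert np.array_equal(out.values[1:], a.values[:-1])

    def test_half_voxel_shift_of_ramp_averages_neighbors(self):
        ramp = np.tile(np.arange(16, dtype=np.float64)[:, None, None], (1, 4, 4))
        a = vol(ramp)
        t = RigidTransform.from_params((0, 0, 0), (0.5, 0, 0))
        out = resample(a, t, a)
        expected = 0.5 * (ramp[4:8] + ramp[3:7])
        assert out.values[4:8] == pytest.approx(expected, abs=1e-12)

    def test_nearest_mode_preserves_labels(self, rng):
        lab = vol(rng.integers(0, 5, size=(10, 10, 10)).astype(np.int16))
        t = RigidTransform.from_params((0, 0, 3.0), (0.2, -0.3, 0.1))
        out = resample(lab, t, lab, interpolation="nearest")
        assert out.values.dtype == lab.values.dtype
        assert set(np.unique(out.values)) <= set(np.unique(lab.values))

    def test_group_property_round_trip(self, rng):
        from scipy import ndimage

        smooth = ndimage.gaussian_filter(rng.normal(size=(24, 24, 24)), 2.0)
        a = vol(np.float32(smooth * 100.0))
        t = RigidTransform.from_params((3, -2, 4), (1.5, -2.5, 0.75))
        back = resample(resample(a, t, a), t.inverse(), a)
        interior = (slice(4, -4),) * 3
        mae = np.abs(back.values[interior] - a.values[interior]).mean()
        assert mae < 0.01 * np.ptp(a.values)


class TestTargetRegistrationError:
    def test_identical_transforms_zero(self):
        t = RigidTransform.from_params((3, 4, 5), (1, 2, 3))
        assert target_registration_error(t, t, [(0, 0, 0), (10, 20, 30)]) == pytest.approx([0, 0], abs=1e-12)

    def test_pure_translation_gives_norm(self):
        t = RigidTransform.identity()
        s = RigidTransform.from_params((0, 0, 0), (3, 4, 0))
        assert target_registration_error(s, t, [(5, 5, 5), (-7, 2, 9)]) == pytest.approx([5.0, 5.0], abs=1e-12)

    def test_matches_naive_per_point_arithmetic(self, rng):
        a = RigidTransform.from_params(rng.uniform(-20, 20, 3), rng.uniform(-10, 10, 3))
        b = RigidTransform.from_params(rng.uniform(-20, 20, 3), rng.uniform(-10, 10, 3))
        targets = rng.uniform(0, 100, size=(5, 3))
        expected = [float(np.linalg.norm(a.apply(p) - b.apply(p))) for p in targets]
        assert target_registration_error(a, b, targets) == pytest.approx(expected, abs=1e-12)

    def test_empty_targets_rejected(self):
        with pytest.raises(ValueError):
            target_registration_error(RigidTransform.identity(), RigidTransform.identity(), [])


class TestRegisterRigidMI:
    def test_aligned_pair_stays_near_identity(self, small_ct_identity):
        opts = MIOptions(shrink_factors=(2, 1), max_evaluations=(120, 60), initial_steps=(0.5, 0.1),
                         xtol=(0.02, 0.005))
        res = register_rigid_mi(small_ct_identity, small_ct_identity, options=opts)
        assert res.transform.rotation_angle_deg <= 0.2
        assert np.linalg.norm(res.transform.apply((55.0, 45.0, 40.0)) - (55.0, 45.0, 40.0)) <= 0.2

    def test_constant_volume_rejected(self, small_ct_identity):
        flat = small_ct_identity.with_values(np.zeros_like(small_ct_identity.values))
        with pytest.raises(ValueError):
            register_rigid_mi(small_ct_identity, flat)

    def test_recovers_known_misalignment(self, small_labelmap, noiseless_ct_model, small_ct_identity, small_spec):
        """A 5 deg / 10 mm misalignment is recovered within 1 deg and one SPECT voxel."""
        from slnfusion.phantom import render_ct

        mis = RigidTransform.from_params((0, 3.0, -4.0), (6.0, -8.0, 0.0), center=small_spec.fov_center)
        moving = render_ct(small_labelmap, noiseless_ct_model, mis, seed=0)
        res = register_rigid_mi(small_ct_identity, moving)
        t_true = mis.inverse()
        err = (res.transform @ t_true.inverse())
        assert err.rotation_angle_deg <= 1.0
        targets = mis.apply(np.asarray(small_spec.sln_centers, float))
        tre = target_registration_error(res.transform, t_true, targets)
        assert np.all(tre <= 4.4)


class TestCenteredInit:
    def test_pure_shift_recovered_by_foreground_centroids(self, small_labelmap, noiseless_ct_model, small_ct_identity):
        from slnfusion.phantom import render_ct
        from slnfusion.registration import centered_init

        shift = RigidTransform.from_params((0, 0, 0), (9.0, -5.0, 4.0))
        moving = render_ct(small_labelmap, noiseless_ct_model, shift, seed=0)
        init = centered_init(small_ct_identity, moving)
        # init maps moving world -> fixed world, i.e. approximately shift^-1
        assert np.linalg.norm(init.translation - shift.inverse().translation) < 1.0

    def test_empty_foreground_rejected(self):
        from slnfusion.registration import centered_init

        flat = vol(np.zeros((8, 8, 8)))
        with pytest.raises(ValueError):
            centered_init(flat, flat)
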