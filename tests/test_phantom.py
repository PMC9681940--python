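"""Phantom voxelization fidelity and modality simulation contracts."""

import numpy as np
import pytest
from pydantic import ValidationError

from slnfusion import (
    PhantomSpec,
    RigidTransform,
    build_phantom_labelmap,
    render_ct,
    render_spect,
    sample_rigid_misalignment,
)
from slnfusion.phantom import default_spect_model


class TestSpecValidation:
    def test_zero_diameter_rejected(self):
        with pytest.raises(ValidationError):
            PhantomSpec(sln_left_diameter=0.0)

    def test_left_must_be_left(self):
        with pytest.raises(ValidationError):
            PhantomSpec(sln_centers=((135.0, 90.0, 70.0), (65.0, 90.0, 70.0)))

    def test_coplanar_fiducials_rejected(self):
        with pytest.raises(ValidationError):
            PhantomSpec(fiducials=[(20, 30, 40), (60, 30, 40), (20, 70, 40), (60, 70, 40)])

    def test_too_few_fiducials_rejected(self):
        with pytest.raises(ValidationError):
            PhantomSpec(fiducials=[(20, 30, 40), (60, 30, 50), (20, 70, 60)])

    def test_structure_outside_fov_rejected(self):
        with pytest.raises(ValidationError):
            PhantomSpec(sln_centers=((65.0, 90.0, 70.0), (199.0, 90.0, 70.0)))


class TestLabelmap:
    def test_expected_structures_present(self, default_labelmap_1mm):
        lm = default_labelmap_1mm
        assert lm.voxel_count("sln_left") > 0 and lm.voxel_count("sln_right") > 0
        assert lm.structure_volume_mm3("sln_right") > lm.structure_volume_mm3("sln_left")
        assert lm.voxel_count("bone") > 0 and lm.voxel_count("vessel") > 0
        assert sum(1 for n in lm.names if n.startswith("fiducial")) >= 4

    def test_sphere_volume_matches_analytic(self, default_labelmap_1mm):
        # 15 mm sphere at 1 mm voxels: (4/3) pi 7.5^3 ~ 1767 voxels
        count = default_labelmap_1mm.voxel_count("sln_right")
        assert count == pytest.approx(4.0 / 3.0 * np.pi * 7.5**3, rel=0.02)

    def test_voxelization_error_shrinks_under_refinement(self, small_spec):
        """Estimated 15 mm sphere volume converges to the analytic value as the grid refines."""
        analytic = 4.0 / 3.0 * np.pi * 7.5**3
        errors = [
            abs(build_phantom_labelmap(small_spec, h).structure_volume_mm3("sln_right") - analytic) / analytic
            for h in (1.0, 0.5, 0.25)
        ]
        assert errors[0] < 0.02
        assert errors[1] < errors[0] and errors[2] < errors[1]
        assert errors[2] < 0.005

    def test_labels_disjoint_by_construction(self, small_labelmap):
        # each voxel carries exactly one label; the vocabulary covers all values
        values = small_labelmap.volume.values
        assert set(np.unique(values)) <= set(small_labelmap.labels.values())

    def test_centroid_matches_spec_centers(self, small_spec, small_labelmap):
        for name, center in zip(("sln_left", "sln_right"), small_spec.sln_centers):
            assert small_labelmap.centroid_mm(name) == pytest.approx(np.asarray(center), abs=0.2)

    def test_bad_voxel_size_rejected(self, small_spec):
        with pytest.raises(ValueError):
            build_phantom_labelmap(small_spec, 0.0)


class TestRenderCT:
    def test_zero_noise_identity_gives_exact_intensities(self, small_labelmap, noiseless_ct_model, small_ct_identity):
        lut = dict(noiseless_ct_model.tissue_intensities)
        v = small_ct_identity.values
        assert np.all(v[small_labelmap.mask("bone")] == lut["bone"])
        assert np.all(v[small_labelmap.mask("sln_left")] == lut["sln"])
        assert np.all(v[small_labelmap.mask("fiducial_0")] == lut["fiducial"])
        assert np.all(v[small_labelmap.mask("background")] == lut["background"])

    def test_same_seed_is_bit_identical(self, small_labelmap, ct_model):
        pose = sample_rigid_misalignment(5, 10, seed=7, center=(55, 45, 40))
        a = render_ct(small_labelmap, ct_model, pose, seed=11)
        b = render_ct(small_labelmap, ct_model, pose, seed=11)
        assert np.array_equal(a.values, b.values)
        c = render_ct(small_labelmap, ct_model, pose, seed=12)
        assert not np.array_equal(a.values, c.values)

    def test_integer_voxel_shift_preserves_histogram(self, small_labelmap, noiseless_ct_model):
        identity = render_ct(small_labelmap, noiseless_ct_model, RigidTransform.identity(), seed=0)
        shift = RigidTransform.from_params((0, 0, 0), (3.0, -2.0, 1.0))  # integer multiples of 1 mm voxels
        shifted = render_ct(small_labelmap, noiseless_ct_model, shift, seed=0)
        vals, counts = np.unique(identity.values, return_counts=True)
        vals2, counts2 = np.unique(shifted.values, return_counts=True)
        assert np.array_equal(vals, vals2) and np.array_equal(counts, counts2)

    def test_pose_moving_all_slns_out_errors(self, small_labelmap, ct_model):
        far = RigidTransform.from_params((0, 0, 0), (500.0, 0.0, 0.0))
        with pytest.raises(ValueError):
            render_ct(small_labelmap, ct_model, far, seed=0)

    def test_wrong_modality_kind_rejected(self, small_labelmap, spect_model):
        with pytest.raises(ValueError):
            render_ct(small_labelmap, spect_model, RigidTransform.identity(), seed=0)


class TestRenderSPECT:
    def test_zero_activity_gives_all_zero(self, small_labelmap):
        model = default_spect_model(sln_activity=0.0)
        vol = render_spect(small_labelmap, model, RigidTransform.identity(), seed=0)
        assert not np.any(vol.values)

    def test_psf_conserves_total_activity(self, small_labelmap):
        blurred = render_spect(small_labelmap, default_spect_model(poisson_scale=0.0),
                               RigidTransform.identity(), seed=0)
        sharp = render_spect(small_labelmap, default_spect_model(poisson_scale=0.0, psf_fwhm_mm=0.0),
                             RigidTransform.identity(), seed=0)
        assert blurred.values.sum() == pytest.approx(sharp.values.sum(), rel=0.01)

    def test_two_hotspots_right_larger(self, small_spect_identity, small_spec):
        from scipy import ndimage

        v = small_spect_identity.values
        lab, n = ndimage.label(v >= 0.15 * v.max(), structure=np.ones((3, 3, 3)))
        assert n >= 2
        sizes = np.sort(np.bincount(lab.ravel())[1:])[::-1]
        assert sizes[0] > sizes[1]  # 15 mm node yields the larger hot region

    def test_determinism(self, small_labelmap, spect_model):
        a = render_spect(small_labelmap, spect_model, RigidTransform.identity(), seed=5)
        b = render_spect(small_labelmap, spect_model, RigidTransform.identity(), seed=5)
        assert np.array_equal(a.values, b.values)


class TestModalityColocation:
    def test_identity_pose_centroids_agree_across_modalities(self, small_labelmap, noiseless_ct_model, spect_model):
        """SLN centers seen by CT and SPECT agree within one SPECT voxel."""
        ct = render_ct(small_labelmap, noiseless_ct_model, RigidTransform.identity(), seed=0)
        sp = render_spect(small_labelmap, spect_model, RigidTransform.identity(), seed=0)
        for name in ("sln_left", "sln_right"):
            m = ct.values == noiseless_ct_model.tissue_intensities["sln"]
            # restrict to this node via the labelmap
            m = m & small_labelmap.mask(name)
            ct_centroid = ct.voxel_to_world(np.argwhere(m).mean(axis=0))
            # SPECT: intensity-weighted centroid in a window around the node
            idx = np.round(sp.world_to_voxel(ct_centroid)).astype(int)
            sl = tuple(slice(max(i - 4, 0), i + 5) for i in idx)
            w = sp.values[sl]
            local = np.argwhere(w >= 0) + [s.start for s in sl]
            cent = sp.voxel_to_world((local * w.ravel()[:, None]).sum(axis=0) / w.sum())
            assert np.linalg.norm(cent - ct_centroid) <= 4.4
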