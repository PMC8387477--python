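from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from radstab.imaging import read_volume
from radstab.stability import lin_ccc
from radstab.synthetic import (
    AcquisitionProfile,
    CohortConfig,
    LesionSpec,
    build_demo_cohort,
    degrade_acquisition,
    demo_profiles,
    identity_profile,
    make_phantom,
    simulate_feature_pairs,
)

SHAPE = (32, 32, 4)
SPACING = (2.0, 2.0, 5.0)


def _spec(**kw):
    base = dict(center=(16.0, 16.0, 2.0), radius_mm=10.0, contrast=50.0, texture_amplitude=10.0)
    base.update(kw)
    return LesionSpec(**base)


class TestMakePhantom:
    def test_deterministic(self):
        a = make_phantom(_spec(), SHAPE, SPACING, seed=3)
        b = make_phantom(_spec(), SHAPE, SPACING, seed=3)
        np.testing.assert_array_equal(a.intensities, b.intensities)
        np.testing.assert_array_equal(a.mask, b.mask)

    def test_mask_equals_brute_force_sphere(self):
        vol = make_phantom(_spec(radius_mm=10.0), SHAPE, (1.0, 1.0, 5.0), seed=0)
        count = 0
        for x in range(SHAPE[0]):
            for y in range(SHAPE[1]):
                for z in range(SHAPE[2]):
                    d2 = (x - 16.0) ** 2 + (y - 16.0) ** 2 + ((z - 2.0) * 5.0) ** 2
                    count += d2 <= 100.0
        assert vol.roi_voxels == count

    def test_constant_lesion_when_amplitude_zero(self):
        vol = make_phantom(
            _spec(texture_amplitude=0.0, background_amplitude=0.0), SHAPE, SPACING, seed=1
        )
        inside = vol.intensities[vol.mask != 0]
        assert np.unique(inside).size == 1

    def test_lesion_must_fit(self):
        with pytest.raises(ValueError, match="fit"):
            make_phantom(_spec(center=(2.0, 16.0, 2.0)), SHAPE, SPACING, seed=0)

    def test_hyperintense(self):
        vol = make_phantom(_spec(), SHAPE, SPACING, seed=5)
        assert vol.intensities[vol.mask != 0].mean() > vol.intensities[vol.mask == 0].mean()


class TestDegradeAcquisition:
    def test_identity_profile_is_identity(self):
        truth = make_phantom(_spec(), SHAPE, SPACING, seed=2)
        out = degrade_acquisition(truth, identity_profile("conventional", SHAPE), seed=9)
        np.testing.assert_array_equal(out.intensities, truth.intensities)
        np.testing.assert_array_equal(out.mask, truth.mask)
        assert out.spacing == truth.spacing

    def test_halved_matrix_matches_hand_interpolation(self):
        # in-plane ramp: each coarse voxel centre falls midway between two
        # fine centres, so linear interpolation averages the neighbours
        ramp = np.tile(np.arange(32.0)[:, None, None], (1, 32, 2))
        truth_mask = np.ones((32, 32, 2), dtype=np.uint8)
        from radstab.imaging import VolumeWithMask

        truth = VolumeWithMask(ramp, (1.0, 1.0, 1.0), truth_mask, meta={"contrast": 1.0})
        prof = AcquisitionProfile("half", (16, 16))
        out = degrade_acquisition(truth, prof, seed=0)
        # coarse centre j sits at (2j+1) mm -> fine index 2j + 0.5
        np.testing.assert_allclose(out.intensities[:, 0, 0], 2 * np.arange(16.0) + 0.5)
        assert out.spacing == (2.0, 2.0, 1.0)

    def test_seed_contract(self):
        truth = make_phantom(_spec(), SHAPE, SPACING, seed=2)
        prof = AcquisitionProfile("noisy", (16, 16), noise_sigma=0.1)
        a = degrade_acquisition(truth, prof, seed=4)
        b = degrade_acquisition(truth, prof, seed=4)
        c = degrade_acquisition(truth, prof, seed=5)
        np.testing.assert_array_equal(a.intensities, b.intensities)
        assert not np.array_equal(a.intensities, c.intensities)

    def test_matrix_larger_than_truth_rejected(self):
        truth = make_phantom(_spec(), SHAPE, SPACING, seed=2)
        with pytest.raises(ValueError, match="exceeds"):
            degrade_acquisition(truth, AcquisitionProfile("big", (64, 64)), seed=0)

    def test_mask_jitter_changes_boundary_only(self):
        truth = make_phantom(_spec(), SHAPE, SPACING, seed=2)
        prof = AcquisitionProfile("jit", (32, 32), mask_flip_prob=0.5)
        out = degrade_acquisition(truth, prof, seed=1)
        assert not np.array_equal(out.mask, truth.mask)
        from scipy import ndimage

        st = np.zeros((3, 3, 3), dtype=bool)
        st[:, :, 1] = True
        grown = ndimage.binary_dilation(truth.mask != 0, structure=st)
        assert not np.any((out.mask != 0) & ~grown)  # additions stay on the boundary


class TestProfiles:
    def test_matrix_minimum(self):
        with pytest.raises(ValueError, match=">= 16"):
            AcquisitionProfile("tiny", (8, 8))

    def test_demo_profiles_follow_protocol_ratios(self):
        profs = demo_profiles(scale=4)
        assert profs["conventional"].matrix == (64, 54)
        assert profs["EPI"].matrix == (32, 32)
        assert profs["ETL"].matrix == (48, 48)
        assert profs["TR"].matrix == (64, 64)


class TestSimulateFeaturePairs:
    def test_perfect_concordance(self):
        df = simulate_feature_pairs(10, 3, 1.0, seed=0)
        for _, grp in df.groupby("feature_name"):
            np.testing.assert_array_equal(grp["x"].to_numpy(), grp["y"].to_numpy())
            assert lin_ccc(grp["x"], grp["y"])[0] == 1.0

    def test_large_n_recovery(self):
        df = simulate_feature_pairs(5000, 1, 0.9, seed=1)
        ccc, n = lin_ccc(df["x"], df["y"])
        assert n == 5000
        assert abs(ccc - 0.9) < 0.02

    def test_too_few_subjects(self):
        with pytest.raises(ValueError, match="at least 3"):
            simulate_feature_pairs(2, 1, 0.5, seed=0)

    def test_target_outside_unit_interval(self):
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            simulate_feature_pairs(5, 1, 1.2, seed=0)

    def test_deterministic(self):
        a = simulate_feature_pairs(20, 4, 0.7, seed=3)
        b = simulate_feature_pairs(20, 4, 0.7, seed=3)
        pd.testing.assert_frame_equal(a, b)


class TestBuildDemoCohort:
    def test_counts_by_construction(self, tmp_path):
        manifest = build_demo_cohort(4, seed=0, outdir=tmp_path)
        assert manifest["subject_id"].nunique() == 8
        assert len(manifest) == 24
        assert len(list(tmp_path.glob("*_vol.nii"))) == 24
        assert len(list(tmp_path.glob("*_mask.nii"))) == 24

    def test_seed_reproducibility(self, tmp_path):
        m1 = build_demo_cohort(2, seed=7, outdir=tmp_path / "a")
        m2 = build_demo_cohort(2, seed=7, outdir=tmp_path / "b")
        pd.testing.assert_frame_equal(m1, m2)
        v1 = read_volume(tmp_path / "a" / m1.iloc[0]["volume_path"])
        v2 = read_volume(tmp_path / "b" / m2.iloc[0]["volume_path"])
        np.testing.assert_array_equal(v1.intensities, v2.intensities)

    def test_empty_cohort(self, tmp_path):
        manifest = build_demo_cohort(0, seed=0, outdir=tmp_path)
        assert manifest.empty
        assert not list(tmp_path.glob("*.nii"))

    def test_group_sequence_assignment(self, tmp_path):
        manifest = build_demo_cohort(1, seed=0, outdir=tmp_path)
        first = set(manifest[manifest["group"] == "first"]["sequence"])
        second = set(manifest[manifest["group"] == "second"]["sequence"])
        assert first == {"conventional", "EPI", "ETL"}
        assert second == {"conventional", "ETL", "TR"}
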