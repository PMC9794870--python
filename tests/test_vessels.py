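"""Vessel segmentation, centerline, thickness and feature aggregation,
validated against analytic cylinder oracles."""

import numpy as np
import pytest
from scipy import ndimage, stats

from brainage_bag.types import Volume3D
from brainage_bag.vessels import (
    Centerline, VESSEL_FEATURE_NAMES, VesselMask, aggregate_features,
    compute_thickness, extract_centerline, extract_vessel_features,
    segment_vessels,
)

from conftest import make_cylinder


class TestSegmentation:
    def test_noiseless_tubes_segment_exactly(self):
        vol, _ = make_cylinder(radius=3)
        mask = segment_vessels(vol, k=2.0)
        np.testing.assert_array_equal(mask.data, vol.data > 0)

    def test_all_background_raises(self):
        flat = Volume3D(np.zeros((32, 32, 32)), modality="tof-like")
        with pytest.raises(ValueError, match="threshold"):
            segment_vessels(flat)

    def test_cylinder_volume_oracle(self):
        """Mask voxel count within 10 % of pi r^2 L for a radius-3 tube."""
        length = 30
        vol, _ = make_cylinder(radius=3, length=length)
        mask = segment_vessels(vol, k=2.0)
        analytic = np.pi * 9 * length
        assert abs(int(mask.data.sum()) - analytic) / analytic < 0.10

    def test_small_components_removed(self):
        vol, _ = make_cylinder(radius=3)
        vol.data[2, 2, 2] = 10.0  # an isolated speck
        mask = segment_vessels(vol, k=2.0, min_component_voxels=10)
        assert not mask.data[2, 2, 2]

    def test_modality_check(self):
        vol, _ = make_cylinder(radius=3)
        vol.modality = "t1-like"
        with pytest.raises(ValueError, match="tof-like"):
            segment_vessels(vol)


class TestCenterline:
    def test_cylinder_skeleton_follows_axis(self):
        """A straight axis-aligned cylinder thins to a single 26-connected
        path within one voxel of the true axis."""
        vol, axis_coords = make_cylinder(radius=3, length=30)
        mask = segment_vessels(vol)
        cl = extract_centerline(mask)
        assert len(cl) > 10
        # single connected component
        skel = np.zeros(mask.data.shape, dtype=bool)
        skel[tuple(cl.coords.T)] = True
        _, n_comp = ndimage.label(skel, structure=np.ones((3, 3, 3)))
        assert n_comp == 1
        # every skeleton voxel within 1 voxel of the axis (in-plane distance)
        c = vol.shape[0] // 2
        inplane = np.linalg.norm(cl.coords[:, :2] - c, axis=1)
        assert inplane.max() <= 1.0 + 1e-9

    def test_single_voxel_is_its_own_skeleton(self):
        data = np.zeros((32, 32, 32), dtype=bool)
        data[10, 11, 12] = True
        cl = extract_centerline(VesselMask(data))
        np.testing.assert_array_equal(cl.coords, [[10, 11, 12]])

    def test_topology_preserved_for_disjoint_tubes(self):
        data = np.zeros((48, 48, 48))
        ii = np.arange(48)
        for cx, cy in ((12, 12), (34, 34)):  # two parallel z-tubes, apart
            plane = (np.add.outer((ii - cx) ** 2, (ii - cy) ** 2)) <= 4
            data[plane, 10:38] = 10.0
        mask = VesselMask(data > 0)
        cl = extract_centerline(mask)
        skel = np.zeros(data.shape, dtype=bool)
        skel[tuple(cl.coords.T)] = True
        _, n_mask = ndimage.label(mask.data, structure=np.ones((3, 3, 3)))
        _, n_skel = ndimage.label(skel, structure=np.ones((3, 3, 3)))
        assert n_mask == n_skel == 2

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            extract_centerline(VesselMask(np.zeros((20, 20, 20), dtype=bool)))


class TestThickness:
    @pytest.mark.parametrize("radius", [2, 3, 5])
    def test_cylinder_radius_recovered(self, radius):
        """EDT thickness at interior centerline voxels within one voxel of
        the true radius; diameters within one voxel of 2 r."""
        vol, _ = make_cylinder(radius=radius, length=34)
        mask = segment_vessels(vol)
        cl = compute_thickness(mask, extract_centerline(mask))
        c = vol.shape[0] // 2
        interior = np.abs(cl.coords[:, 2] - c) < 9  # away from the end caps
        assert interior.sum() > 5
        assert np.all(np.abs(cl.thickness[interior] - radius) <= 1.0)
        assert np.all(np.abs(cl.diameters[interior] - 2 * radius) <= 1.0)

    def test_anisotropic_spacing(self):
        """With 2 mm slices along the tube axis, in-plane thickness is still
        measured in mm."""
        vol, _ = make_cylinder(radius=3, length=30, spacing=(1.0, 1.0, 2.0))
        mask = segment_vessels(vol)
        cl = compute_thickness(mask, extract_centerline(mask))
        c = vol.shape[0] // 2
        interior = np.abs(cl.coords[:, 2] - c) < 6
        assert np.all(np.abs(cl.thickness[interior] - 3.0) <= 1.0)

    def test_single_voxel_thickness_is_one_spacing(self):
        data = np.zeros((32, 32, 32), dtype=bool)
        data[5, 6, 7] = True
        mask = VesselMask(data, spacing=(1.0, 1.0, 1.0))
        cl = compute_thickness(mask, Centerline(np.array([[5, 6, 7]])))
        assert cl.thickness[0] == pytest.approx(1.0)

    def test_centerline_outside_mask_rejected(self):
        data = np.zeros((32, 32, 32), dtype=bool)
        data[5, 6, 7] = True
        with pytest.raises(ValueError, match="inside the mask"):
            compute_thickness(VesselMask(data), Centerline(np.array([[1, 1, 1]])))


class TestAggregation:
    def test_full_schema_on_phantom(self, atlas48, cohort_and_gt):
        from brainage_bag.synthetic import generate_vessel_volume
        cohort, gt = cohort_and_gt
        vol, _ = generate_vessel_volume(cohort.iloc[0], atlas48, gt, seed=1)
        feats = extract_vessel_features(vol, atlas48)
        assert len(feats) == 24
        assert list(feats.index) == list(VESSEL_FEATURE_NAMES)
        dens = feats[[f"density_{t}" for t in
                      ("ACA_L", "ACA_R", "MCA_L", "MCA_R", "PCA_L", "PCA_R")]]
        assert ((dens >= 0) & (dens <= 1)).all()

    def test_segment_diameters_track_true_radii(self, atlas48, cohort_and_gt):
        """Mean per-segment diameters within one voxel spacing of 2 x the
        true phantom radii (noiseless)."""
        from brainage_bag.synthetic import GroundTruth, generate_vessel_volume
        import pandas as pd
        _, gt = cohort_and_gt
        gt2 = GroundTruth.from_dict(gt.to_dict())
        gt2.tof_noise_sd = 0.0
        gt2.radius_subject_sd = 0.0
        gt2.radius_jitter_sd = 0.0
        vol, radii = generate_vessel_volume(pd.Series({"age": 40.0}), atlas48, gt2, 1)
        feats = extract_vessel_features(vol, atlas48)
        for name, r in radii.items():
            est = feats[f"diam_seg_{name}"]
            assert abs(est - 2 * r) <= 1.0 + 1e-9, (name, est, 2 * r)

    def test_empty_territory_yields_zero_with_warning(self, atlas48, caplog):
        data = np.zeros((48, 48, 48), dtype=bool)
        data[24, 10:14, 8:20] = True  # a blob in one posterior territory only
        mask = VesselMask(data)
        cl = compute_thickness(mask, extract_centerline(mask))
        with caplog.at_level("WARNING"):
            feats = aggregate_features(cl, mask, atlas48)
        assert "no centerline voxels" in caplog.text
        assert feats["diam_territory_ACA_L"] == 0.0
        assert feats["density_ACA_L"] == 0.0

    def test_grid_mismatch_rejected(self, atlas48):
        data = np.zeros((32, 32, 32), dtype=bool)
        data[16, 16, 10:20] = True
        mask = VesselMask(data)
        cl = compute_thickness(mask, extract_centerline(mask))
        with pytest.raises(ValueError, match="grid"):
            aggregate_features(cl, mask, atlas48)


class TestProperties:
    def test_diameter_monotone_in_radius(self):
        """Estimated diameter strictly increases with true radius
        (Spearman rho = 1 over radii 2..6, noiseless)."""
        estimates = []
        for r in (2, 3, 4, 5, 6):
            vol, _ = make_cylinder(radius=r, length=34)
            mask = segment_vessels(vol)
            cl = compute_thickness(mask, extract_centerline(mask))
            c = vol.shape[0] // 2
            interior = np.abs(cl.coords[:, 2] - c) < 8
            estimates.append(float(np.mean(cl.diameters[interior])))
        assert np.all(np.diff(estimates) > 0)
        rho = stats.spearmanr(estimates, [2, 3, 4, 5, 6]).statistic
        assert rho == pytest.approx(1.0, abs=1e-9)

    def test_density_increases_with_second_tube(self, atlas48):
        one = np.zeros((48, 48, 48), dtype=bool)
        one[20, 20:28, 26:40] = True
        two = one.copy()
        two[30, 20:28, 26:40] = True
        def density(data):
            mask = VesselMask(data)
            cl = compute_thickness(mask, extract_centerline(mask))
            return aggregate_features(cl, mask, atlas48)
        d1 = density(one)
        d2 = density(two)
        terr = [n for n in VESSEL_FEATURE_NAMES if n.startswith("density")]
        assert sum(d2[terr]) > sum(d1[terr])

    def test_pipeline_deterministic(self, atlas48, cohort_and_gt):
        from brainage_bag.synthetic import generate_vessel_volume
        cohort, gt = cohort_and_gt
        vol, _ = generate_vessel_volume(cohort.iloc[2], atlas48, gt, seed=3)
        a = extract_vessel_features(vol, atlas48)
        b = extract_vessel_features(vol, atlas48)
        assert (a == b).all()
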