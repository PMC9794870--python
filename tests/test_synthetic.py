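"""Cohort, morphometry and phantom generators: moments, determinism,
parameter recovery and geometric oracles."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from brainage_bag.synthetic import (
    DemographicsConfig, GroundTruth, RISK_FACTORS, age_distribution,
    generate_brain_volume, generate_cohort, generate_morphometry,
    generate_vessel_volume, make_roi_atlas, t1_feature_names,
)
from brainage_bag.types import SEGMENT_NAMES, TERRITORY_NAMES


class TestCohort:
    def test_reported_moments_at_study_size(self):
        cohort, _ = generate_cohort(1658, seed=11)
        assert abs(cohort["age"].mean() - 49.9) < 1.0
        assert abs(cohort["age"].std() - 13.7) < 1.0
        assert cohort["age"].between(21, 81).all()
        assert abs((cohort["sex"] == 0).mean() - 909 / 1658) < 0.05
        assert abs(cohort["bp"].mean() - 126.0) < 2.0
        assert abs(cohort["bmi"].mean() - 27.3) < 0.5
        assert not cohort.isna().any().any()
        assert cohort["smoking"].isin(range(5)).all()
        assert cohort["alcohol"].isin(range(4)).all()

    def test_seed_determinism(self):
        a, _ = generate_cohort(10, seed=3)
        b, _ = generate_cohort(10, seed=3)
        pd.testing.assert_frame_equal(a, b)

    def test_degenerate_smoking_distribution(self):
        cfg = DemographicsConfig(smoking_weights=(1, 0, 0, 0, 0))
        cohort, _ = generate_cohort(50_000, seed=1, config=cfg)
        assert (cohort["smoking"] == 0).all()

    def test_invalid_probability_vector_rejected(self):
        with pytest.raises(ValueError, match="not normalizable"):
            DemographicsConfig(alcohol_weights=(0, 0, 0, 0))
        with pytest.raises(ValueError, match="not normalizable"):
            DemographicsConfig(smoking_weights=(-1, 2, 0, 0, 0))

    def test_minimum_cohort_size(self):
        with pytest.raises(ValueError):
            generate_cohort(5, seed=0)

    def test_moment_convergence_large_n(self):
        """Sample moments of the continuous factors approach the configured
        population moments at n = 50,000 (within 2 %)."""
        cfg = DemographicsConfig()
        cohort, gt = generate_cohort(50_000, seed=2, config=cfg)
        moments = cfg.factor_moments()
        for col in ("bp", "bmi", "whr"):
            m, s = moments[col]
            assert abs(cohort[col].mean() - m) / m < 0.02
            assert abs(cohort[col].std() - s) / s < 0.02
        assert abs(cohort["age"].mean() - 49.9) / 49.9 < 0.02
        assert abs(cohort["age"].std() - 13.7) / 13.7 < 0.02

    def test_copula_induces_age_correlation_preserving_marginals(self):
        cfg = DemographicsConfig(age_correlations={"bp": 0.5})
        cohort, _ = generate_cohort(50_000, seed=4, config=cfg)
        r = np.corrcoef(cohort["age"], cohort["bp"])[0, 1]
        assert abs(r - 0.5) < 0.05
        assert abs(cohort["bp"].mean() - 126.0) < 0.5
        assert abs(cohort["bp"].std() - 16.4) < 0.5

    def test_hidden_offset_loads_on_risk_factors(self):
        cohort, gt = generate_cohort(50_000, seed=5)
        z = (cohort["bmi"] - cohort["bmi"].mean()) / cohort["bmi"].std()
        fit = np.polyfit(z, cohort["brain_age_offset"], 1)
        assert abs(fit[0] - gt.delta_risk_slopes["bmi"]) < 0.1


class TestMorphometry:
    def test_column_count_is_223(self, cohort_and_gt):
        cohort, gt = cohort_and_gt
        table = generate_morphometry(cohort, gt, seed=1)
        assert table.shape[1] == 223 + 1  # + subject_id
        assert len(t1_feature_names()) == 223
        assert np.isfinite(table.drop(columns="subject_id").to_numpy()).all()

    def test_noiseless_column_exactly_linear_in_age(self, cohort_and_gt):
        cohort, gt = cohort_and_gt
        cohort = cohort.copy()
        cohort["brain_age_offset"] = 0.0
        gt2 = GroundTruth.from_dict(gt.to_dict())
        gt2.noise_sd[:] = 0.0
        gt2.risk_slopes[:] = 0.0
        gt2.sex_offset[:] = 0.0
        table = generate_morphometry(cohort, gt2, seed=1)
        j = 5
        col = table[gt2.feature_names[j]].to_numpy()
        expected = gt2.intercept[j] + gt2.age_slope[j] * cohort["age"].to_numpy()
        np.testing.assert_allclose(col, expected, rtol=1e-10)

    def test_ols_recovers_injected_slopes(self):
        """At n = 5,000 a feature regressed on (age, sex) recovers its
        ground-truth coefficients within 3 standard errors when age and sex
        are the only active channels."""
        cohort, gt = generate_cohort(5000, seed=9)
        cohort = cohort.copy()
        cohort["brain_age_offset"] = 0.0
        gt2 = GroundTruth.from_dict(gt.to_dict())
        gt2.risk_slopes[:] = 0.0
        table = generate_morphometry(cohort, gt2, seed=10)
        rng = np.random.default_rng(0)
        for j in rng.choice(223, size=5, replace=False):
            name = gt2.feature_names[j]
            X = sm.add_constant(cohort[["age", "sex"]].to_numpy(float))
            fit = sm.OLS(table[name].to_numpy(), X).fit()
            assert abs(fit.params[1] - gt2.age_slope[j]) < 3 * fit.bse[1], name
            assert abs(fit.params[2] - gt2.sex_offset[j]) < 3 * fit.bse[2], name

    def test_missing_factor_rejected(self, cohort_and_gt):
        cohort, gt = cohort_and_gt
        with pytest.raises(ValueError, match="missing"):
            generate_morphometry(cohort.drop(columns=["bmi"]), gt, seed=0)


class TestBrainVolume:
    def test_ventricle_grows_with_age(self, cohort_and_gt):
        _, gt = cohort_and_gt
        gt2 = GroundTruth.from_dict(gt.to_dict())
        gt2.t1_noise_sd = 0.0
        gt2.ventricle_jitter_frac = 0.0
        counts = []
        for age in (30.0, 70.0):
            subject = pd.Series({"age": age, "brain_age_offset": 0.0})
            _, masks = generate_brain_volume(subject, 48, gt2, seed=1,
                                             return_masks=True)
            counts.append(int(masks["ventricle"].sum()))
        assert counts[1] > counts[0]

    def test_center_scaling(self, cohort_and_gt):
        cohort, gt = cohort_and_gt
        vol = generate_brain_volume(cohort.iloc[0], 48, gt, seed=2)
        assert abs(vol.data.mean()) < 1e-6
        assert abs(vol.data.std() - 1.0) < 1e-6

    def test_determinism_and_grid_check(self, cohort_and_gt):
        cohort, gt = cohort_and_gt
        a = generate_brain_volume(cohort.iloc[3], 48, gt, seed=5)
        b = generate_brain_volume(cohort.iloc[3], 48, gt, seed=5)
        np.testing.assert_array_equal(a.data, b.data)
        with pytest.raises(ValueError):
            generate_brain_volume(cohort.iloc[0], 16, gt, seed=0)


class TestVesselVolume:
    def test_zero_decay_gives_age_independent_radii(self, atlas48, cohort_and_gt):
        _, gt = cohort_and_gt
        gt2 = GroundTruth.from_dict(gt.to_dict())
        gt2.radius_decay = 0.0
        gt2.radius_subject_sd = 0.0
        gt2.radius_jitter_sd = 0.0
        r30 = generate_vessel_volume(pd.Series({"age": 30.0}), atlas48, gt2, 1)[1]
        r75 = generate_vessel_volume(pd.Series({"age": 75.0}), atlas48, gt2, 1)[1]
        assert r30 == r75

    def test_tube_volume_matches_analytic_cylinder(self, atlas48, cohort_and_gt):
        """A straight noiseless tube of radius 3 voxels has a drawn voxel
        count within 10 % of pi r^2 L."""
        _, gt = cohort_and_gt
        gt2 = GroundTruth.from_dict(gt.to_dict())
        gt2.tof_noise_sd = 0.0
        gt2.radius_decay = 0.0
        gt2.radius_subject_sd = 0.0
        gt2.radius_jitter_sd = 0.0
        for name in gt2.vessel_base_radius:
            gt2.vessel_base_radius[name] = 1.0
        gt2.vessel_base_radius["BA"] = 3.0  # straight vertical segment
        vol, radii = generate_vessel_volume(pd.Series({"age": 21.0}), atlas48, gt2, 1)
        g = 48
        # count bright voxels in a window around the BA path, away from
        # the junction with the PCA tubes
        c = (g - 1) / 2.0
        y0 = int(round(c - 0.26 * g))
        zlo, zhi = int(c - 0.30 * g), int(c - 0.14 * g)
        window = vol.data[:, y0 - 6: y0 + 7, zlo:zhi]
        count = int((window == gt2.tube_intensity).sum())
        analytic = np.pi * 3.0 ** 2 * (zhi - zlo)
        assert abs(count - analytic) / analytic < 0.10

    def test_determinism(self, atlas48, cohort_and_gt):
        cohort, gt = cohort_and_gt
        a, ra = generate_vessel_volume(cohort.iloc[1], atlas48, gt, seed=9)
        b, rb = generate_vessel_volume(cohort.iloc[1], atlas48, gt, seed=9)
        np.testing.assert_array_equal(a.data, b.data)
        assert ra == rb

    def test_radius_clamp_warns(self, atlas48, cohort_and_gt, caplog):
        _, gt = cohort_and_gt
        gt2 = GroundTruth.from_dict(gt.to_dict())
        gt2.radius_decay = 0.1  # extreme thinning
        gt2.radius_subject_sd = 0.0
        gt2.radius_jitter_sd = 0.0
        with caplog.at_level("WARNING"):
            _, radii = generate_vessel_volume(pd.Series({"age": 81.0}), atlas48, gt2, 1)
        assert "clamped" in caplog.text
        assert min(radii.values()) == atlas48.spacing[0]


class TestAtlas:
    def test_label_families_disjoint_and_complete(self, atlas48):
        assert set(atlas48.territory_labels.values()) == set(TERRITORY_NAMES)
        assert set(atlas48.segment_labels.values()) == set(SEGMENT_NAMES)
        assert len(atlas48.segment_labels) == 11
        assert len(atlas48.territory_labels) == 6
        # labels within a family are disjoint by construction of a single
        # integer volume; territories must tile the brain mask disjointly
        for fam in (atlas48.territories, atlas48.segments):
            assert fam.min() >= 0

    def test_segments_lie_in_one_territory_or_midline(self, atlas48):
        g = atlas48.shape[0]
        c = (g - 1) / 2.0
        for lab, name in atlas48.segment_labels.items():
            region = atlas48.segments == lab
            terr = set(np.unique(atlas48.territories[region])) - {0}
            sides = {atlas48.territory_labels[t][-1] for t in terr}
            if len(sides) > 1:
                # only segments straddling the midline may touch both sides
                xs = np.argwhere(region)[:, 0]
                assert xs.min() < c < xs.max(), name
                assert name in ("BA", "ACA_A1", "ACA_A2"), name

    def test_determinism(self):
        a = make_roi_atlas(48)
        b = make_roi_atlas(48)
        np.testing.assert_array_equal(a.territories, b.territories)
        np.testing.assert_array_equal(a.segments, b.segments)
        with pytest.raises(ValueError):
            make_roi_atlas(16)


class TestGroundTruthSerialization:
    def test_yaml_roundtrip(self, cohort_and_gt, tmp_path):
        _, gt = cohort_and_gt
        path = tmp_path / "gt.yaml"
        gt.to_yaml(str(path))
        back = GroundTruth.from_yaml(str(path))
        np.testing.assert_allclose(back.age_slope, gt.age_slope)
        np.testing.assert_allclose(back.risk_slopes, gt.risk_slopes)
        assert back.vessel_base_radius == gt.vessel_base_radius
        assert back.delta_risk_slopes == gt.delta_risk_slopes
        assert back.demographics == gt.demographics

    def test_null_model_reference_distribution(self):
        """The age distribution helper integrates to the configured moments."""
        d = age_distribution()
        m, v = d.stats(moments="mv")
        assert abs(float(m) - 49.9) < 1e-6
        assert abs(float(np.sqrt(v)) - 13.7) < 1e-6
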