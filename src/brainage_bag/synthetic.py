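"""Synthetic cohorts, morphometry tables and imaging phantoms.

Every downstream stage of the pipeline (feature extraction, age predictors,
fusion, bias correction, risk-factor association) is exercised on data from
this module, which emulates a population study of adults aged 21-81 with
cardiovascular risk factors, a FastSurfer-style 223-column T1 morphometry
table, and 3-D T1-like / TOF-MRA-like phantom volumes whose geometry carries
a known age signal (ventricle growth, cortical-shell atrophy, artery
thinning).  All generators are deterministic given a seed, and every synthetic
output is accompanied by the :class:`GroundTruth` that produced it so
parameter-recovery tests can close the loop.
"""

from __future__ import annotations

import dataclasses
import logging
from functools import lru_cache
import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .types import ROIAtlas, SEGMENT_NAMES, TERRITORY_NAMES, Volume3D

logger = logging.getLogger(__name__)

__all__ = [
    "DemographicsConfig",
    "GroundTruth",
    "RISK_FACTORS",
    "age_distribution",
    "t1_feature_names",
    "generate_cohort",
    "generate_morphometry",
    "generate_brain_volume",
    "generate_vessel_volume",
    "make_roi_atlas",
]

#: Cardiovascular risk factors carried by the cohort, in canonical order:
#: systolic blood pressure (mmHg), body-mass index (kg/m^2), waist-to-hip
#: ratio, smoking status (ordinal 0-4) and alcohol consumption (ordinal 0-3).
RISK_FACTORS = ("bp", "bmi", "whr", "smoking", "alcohol")


def t1_feature_names() -> list[str]:
    """The 223-name T1 morphometry schema (31 subcortical/global volumes plus
    64 cortical structures x {surface area, gray volume, average thickness})."""
    text = resources.files("brainage_bag.data").joinpath("t1_feature_names.txt").read_text()
    names = [ln for ln in text.splitlines() if ln]
    assert len(names) == 223
    return names


# ---------------------------------------------------------------------------
# Demographics
# ---------------------------------------------------------------------------

@dataclass
class DemographicsConfig:
    """Marginal distributions of the cohort variables.

    Defaults reproduce the summary statistics of the emulated study
    population: age truncated-normal(49.9, 13.7) on [21, 81]; 909 of 1,658
    participants female; blood pressure N(126.0, 16.4) mmHg; BMI N(27.3, 4.2)
    kg/m^2; waist-to-hip ratio sex-conditional N(0.82, 0.06) for women and
    N(0.94, 0.07) for men; smoking counts (668, 56, 347, 266, 321) over codes
    0-4 and alcohol counts (112, 458, 963, 125) over codes 0-3.

    ``age_correlations`` optionally couples each factor to age through a
    Gaussian copula on the latent normals (default: all zero -- the emulated
    study reports marginals only).
    """

    age_mean: float = 49.9
    age_sd: float = 13.7
    age_range: tuple[float, float] = (21.0, 81.0)
    p_female: float = 909 / 1658
    bp_mean: float = 126.0
    bp_sd: float = 16.4
    bmi_mean: float = 27.3
    bmi_sd: float = 4.2
    whr_female: tuple[float, float] = (0.82, 0.06)
    whr_male: tuple[float, float] = (0.94, 0.07)
    smoking_weights: tuple[float, ...] = (668, 56, 347, 266, 321)
    alcohol_weights: tuple[float, ...] = (112, 458, 963, 125)
    age_correlations: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, w in (("smoking", self.smoking_weights), ("alcohol", self.alcohol_weights)):
            w = np.asarray(w, dtype=float)
            if np.any(w < 0) or w.sum() <= 0 or not np.all(np.isfinite(w)):
                raise ValueError(f"{name} probability weights are not normalizable: {tuple(w)}")
        for k, rho in self.age_correlations.items():
            if k not in RISK_FACTORS:
                raise ValueError(f"unknown risk factor in age_correlations: {k!r}")
            if not -1.0 < rho < 1.0:
                raise ValueError(f"age correlation for {k!r} must be in (-1, 1)")

    def factor_moments(self) -> dict[str, tuple[float, float]]:
        """Population mean/sd per risk factor implied by the configuration
        (used to standardize factors when injecting effects)."""
        def cat(w):
            w = np.asarray(w, float)
            p = w / w.sum()
            codes = np.arange(len(p))
            m = float(p @ codes)
            return m, float(np.sqrt(p @ (codes - m) ** 2))

        pf = self.p_female
        whr_m = pf * self.whr_female[0] + (1 - pf) * self.whr_male[0]
        whr_v = (pf * (self.whr_female[1] ** 2 + self.whr_female[0] ** 2)
                 + (1 - pf) * (self.whr_male[1] ** 2 + self.whr_male[0] ** 2) - whr_m ** 2)
        return {
            "bp": (self.bp_mean, self.bp_sd),
            "bmi": (self.bmi_mean, self.bmi_sd),
            "whr": (whr_m, float(np.sqrt(whr_v))),
            "smoking": cat(self.smoking_weights),
            "alcohol": cat(self.alcohol_weights),
        }


# ---------------------------------------------------------------------------
# Ground truth
# ---------------------------------------------------------------------------

@dataclass
class GroundTruth:
    """Everything the generators injected, for parameter-recovery tests.

    Feature-table effects: per feature an intercept, an age slope (units/year),
    a sex offset (male minus female), one slope per standardized risk factor,
    and a Gaussian noise sd.  Phantom effects: ventricle growth and cortical
    shell atrophy rates (fraction of grid per year) for the T1-like phantom,
    and per-segment baseline artery radii (mm) with a common age decay rate
    (mm/year) for the TOF-like phantom.
    """

    demographics: DemographicsConfig
    feature_names: list[str]
    intercept: np.ndarray
    age_slope: np.ndarray
    sex_offset: np.ndarray
    risk_slopes: np.ndarray  # (n_features, len(RISK_FACTORS))
    noise_sd: np.ndarray
    # hidden per-subject biological brain-age offset delta (years): every
    # age-dependent generator responds to (age + delta), so delta is the
    # ground-truth brain age gap.  It loads on the standardized risk factors
    # (years per sd) plus independent noise, capping achievable prediction
    # accuracy the way true biological variability does.
    delta_risk_slopes: dict[str, float] = field(default_factory=dict)
    delta_sd: float = 5.0
    # T1-like phantom (fractions of grid size; rates per year of age over 21)
    ventricle_base_frac: float = 0.10
    ventricle_growth_frac: float = 0.0012
    brain_base_frac: float = 0.42
    atrophy_frac: float = 0.0006
    t1_noise_sd: float = 0.05
    ventricle_jitter_frac: float = 0.01
    # TOF-like phantom
    vessel_base_radius: dict[str, float] = field(default_factory=dict)
    radius_decay: float = 0.010  # mm per year of age over 21
    radius_subject_sd: float = 0.12  # per-subject common caliber, mm
    radius_jitter_sd: float = 0.08  # per-subject, per-segment, mm
    tube_intensity: float = 10.0
    tof_noise_sd: float = 0.5

    # -- serialization (round-trips through YAML) ---------------------------

    def to_dict(self) -> dict:
        d = {
            "demographics": dataclasses.asdict(self.demographics),
            "feature_names": list(self.feature_names),
            "intercept": self.intercept.tolist(),
            "age_slope": self.age_slope.tolist(),
            "sex_offset": self.sex_offset.tolist(),
            "risk_slopes": self.risk_slopes.tolist(),
            "noise_sd": self.noise_sd.tolist(),
            "vessel_base_radius": dict(self.vessel_base_radius),
            "delta_risk_slopes": {k: float(v) for k, v in self.delta_risk_slopes.items()},
        }
        for k in ("ventricle_base_frac", "ventricle_growth_frac", "brain_base_frac",
                  "atrophy_frac", "t1_noise_sd", "ventricle_jitter_frac",
                  "radius_decay", "radius_subject_sd", "radius_jitter_sd",
                  "tube_intensity", "tof_noise_sd", "delta_sd"):
            d[k] = float(getattr(self, k))
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        demo = d["demographics"]
        demo["age_range"] = tuple(demo["age_range"])
        demo["whr_female"] = tuple(demo["whr_female"])
        demo["whr_male"] = tuple(demo["whr_male"])
        demo["smoking_weights"] = tuple(demo["smoking_weights"])
        demo["alcohol_weights"] = tuple(demo["alcohol_weights"])
        kwargs = {k: float(d[k]) for k in (
            "ventricle_base_frac", "ventricle_growth_frac", "brain_base_frac",
            "atrophy_frac", "t1_noise_sd", "ventricle_jitter_frac",
            "radius_decay", "radius_subject_sd", "radius_jitter_sd",
            "tube_intensity", "tof_noise_sd", "delta_sd")}
        kwargs["delta_risk_slopes"] = {
            k: float(v) for k, v in d["delta_risk_slopes"].items()}
        return cls(
            demographics=DemographicsConfig(**demo),
            feature_names=list(d["feature_names"]),
            intercept=np.asarray(d["intercept"], float),
            age_slope=np.asarray(d["age_slope"], float),
            sex_offset=np.asarray(d["sex_offset"], float),
            risk_slopes=np.asarray(d["risk_slopes"], float),
            noise_sd=np.asarray(d["noise_sd"], float),
            vessel_base_radius={k: float(v) for k, v in d["vessel_base_radius"].items()},
            **kwargs,
        )

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh)

    @classmethod
    def from_yaml(cls, path: str) -> "GroundTruth":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _default_ground_truth(config: DemographicsConfig, rng: np.random.Generator) -> GroundTruth:
    """Draw plausible per-feature effect sizes for the 223-feature schema.

    Magnitudes follow the broad strokes of structural brain aging: cortical
    thickness shrinks by ~0.005 mm/year, areas and gray volumes decline,
    ventricular volumes expand, total brain volume declines by ~0.15 %/year,
    and men have systematically larger areas/volumes.  Risk-factor slopes are
    small relative to the age effect and drawn once per seed.
    """
    names = t1_feature_names()
    n = len(names)
    intercept = np.empty(n)
    age_slope = np.empty(n)
    sex_offset = np.empty(n)
    noise_sd = np.empty(n)
    for i, name in enumerate(names):
        if name.endswith("thicknessavg"):
            intercept[i] = rng.uniform(2.0, 3.2)
            age_slope[i] = -rng.uniform(0.003, 0.008)
            sex_offset[i] = rng.normal(0.0, 0.02)
            noise_sd[i] = 0.12
        elif name.endswith("surfacearea"):
            intercept[i] = rng.uniform(1500, 4000)
            age_slope[i] = -rng.uniform(1.0, 5.0)
            sex_offset[i] = rng.uniform(50, 300)
            noise_sd[i] = 180.0
        elif name.endswith("grayvol"):
            intercept[i] = rng.uniform(3000, 9000)
            age_slope[i] = -rng.uniform(5.0, 15.0)
            sex_offset[i] = rng.uniform(100, 600)
            noise_sd[i] = 450.0
        elif name == "TotalBrainVolume":
            intercept[i] = 1.15e6
            age_slope[i] = -1800.0
            sex_offset[i] = 1.2e5
            noise_sd[i] = 4.5e4
        elif "Ventricle" in name or "Vent" in name or name == "CSF":
            intercept[i] = rng.uniform(1000, 8000)
            age_slope[i] = rng.uniform(20, 120)  # ventricles expand with age
            sex_offset[i] = rng.uniform(0, 400)
            noise_sd[i] = 900.0
        elif name == "WM-hypointensities":
            intercept[i] = 800.0
            age_slope[i] = rng.uniform(20, 60)
            sex_offset[i] = rng.normal(0, 50)
            noise_sd[i] = 600.0
        else:  # subcortical gray volumes, brainstem, corpus callosum
            intercept[i] = rng.uniform(1500, 16000)
            age_slope[i] = -rng.uniform(3.0, 20.0)
            sex_offset[i] = rng.uniform(50, 800)
            noise_sd[i] = 500.0
    # Risk-factor slopes per standardized factor, a modest fraction of the
    # feature noise so associations are present but not dominant.
    risk = rng.normal(0.0, 0.15, size=(n, len(RISK_FACTORS))) * noise_sd[:, None]
    # baseline radii (mm, at age 21) sit so the 0.6 mm lifetime thinning
    # sweep stays inside radius bands the unit voxel grid resolves well --
    # the distance transform's attainable values form a discrete spectrum
    # with gaps after 1.41 and 2.24 voxels
    base_radius = {
        "PCA_L": 2.1, "PCA_R": 2.1, "MCA_M1_L": 2.15, "MCA_M1_R": 2.15,
        "MCA_M2_L": 2.05, "MCA_M2_R": 2.05, "BA": 2.95, "ICA_L": 3.0,
        "ICA_R": 3.0, "ACA_A1": 2.05, "ACA_A2": 2.1,
    }
    # years of extra biological brain age per sd of each risk factor: obesity
    # markers load strongest, blood pressure next, smoking modestly, alcohol
    # not at all -- the direction of association the emulated study reports
    delta_slopes = {"bp": 0.5, "bmi": 0.7, "whr": 0.6, "smoking": 0.3,
                    "alcohol": 0.0}
    return GroundTruth(
        demographics=config,
        feature_names=names,
        intercept=intercept,
        age_slope=age_slope,
        sex_offset=sex_offset,
        risk_slopes=risk,
        noise_sd=noise_sd,
        vessel_base_radius=base_radius,
        delta_risk_slopes=delta_slopes,
    )


# ---------------------------------------------------------------------------
# Cohort
# ---------------------------------------------------------------------------

@lru_cache(maxsize=16)
def _matched_truncnorm_params(mean: float, sd: float, lo: float, hi: float) -> tuple[float, float]:
    """Parent normal (mu, sigma) whose truncation to [lo, hi] has the given
    mean and sd.  A cohort reported with mean 49.9 / sd 13.7 on [21, 81]
    exhibits those moments *after* truncation, so the parent is wider."""
    from scipy import optimize

    def residual(p):
        mu, s = p
        a, b = (lo - mu) / s, (hi - mu) / s
        m, v = stats.truncnorm.stats(a, b, loc=mu, scale=s, moments="mv")
        return [float(m) - mean, float(np.sqrt(v)) - sd]

    sol = optimize.fsolve(residual, [mean, sd * 1.3], full_output=False)
    return float(sol[0]), float(sol[1])


def age_distribution(config: DemographicsConfig | None = None):
    """The frozen truncated-normal age distribution implied by the config."""
    config = config or DemographicsConfig()
    lo, hi = config.age_range
    mu, s = _matched_truncnorm_params(config.age_mean, config.age_sd, lo, hi)
    return stats.truncnorm((lo - mu) / s, (hi - mu) / s, loc=mu, scale=s)


def _categorical_from_latent(z: np.ndarray, weights) -> np.ndarray:
    """Map standard-normal latents to ordinal codes with the given marginal."""
    w = np.asarray(weights, float)
    p = w / w.sum()
    edges = stats.norm.ppf(np.cumsum(p)[:-1])
    return np.searchsorted(edges, z, side="right").astype(int)


def generate_cohort(
    n: int,
    seed: int,
    config: DemographicsConfig | None = None,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate a cohort of ``n`` adults with demographics and risk factors.

    Ages follow a truncated normal on the configured range, parameterized so
    the *truncated* distribution exhibits the configured mean and sd; all
    other marginals follow :class:`DemographicsConfig`.  Optional factor-age
    correlations are induced through a Gaussian copula on the latent normals,
    leaving each marginal intact.

    Returns the cohort table (columns ``subject_id, age, sex, bp, bmi, whr,
    smoking, alcohol`` plus the hidden ground-truth ``brain_age_offset``)
    and the :class:`GroundTruth` for all downstream generators.  The offset
    column is the subject's true biological brain-age deviation in years --
    it drives every imaging generator but is never a model input.
    """
    if n < 10:
        raise ValueError("cohort size must be at least 10")
    config = config or DemographicsConfig()
    gt = _default_ground_truth(config, np.random.default_rng(seed + 1))
    rng = np.random.default_rng(seed)

    z_age = rng.standard_normal(n)
    age = age_distribution(config).ppf(stats.norm.cdf(z_age))

    def latent(name: str) -> np.ndarray:
        eps = rng.standard_normal(n)
        rho = config.age_correlations.get(name, 0.0)
        return rho * z_age + np.sqrt(1.0 - rho ** 2) * eps

    sex = (rng.random(n) >= config.p_female).astype(int)  # 0 female, 1 male
    bp = config.bp_mean + config.bp_sd * latent("bp")
    bmi = config.bmi_mean + config.bmi_sd * latent("bmi")
    z_whr = latent("whr")
    whr = np.where(
        sex == 0,
        config.whr_female[0] + config.whr_female[1] * z_whr,
        config.whr_male[0] + config.whr_male[1] * z_whr,
    )
    smoking = _categorical_from_latent(latent("smoking"), config.smoking_weights)
    alcohol = _categorical_from_latent(latent("alcohol"), config.alcohol_weights)

    cohort = pd.DataFrame({
        "subject_id": [f"sub-{i:05d}" for i in range(n)],
        "age": age,
        "sex": sex,
        "bp": bp,
        "bmi": bmi,
        "whr": whr,
        "smoking": smoking,
        "alcohol": alcohol,
    })
    # hidden biological brain-age offset: risk-factor loadings plus noise
    moments = config.factor_moments()
    delta = rng.normal(0.0, gt.delta_sd, size=n)
    for f in RISK_FACTORS:
        m, sd_f = moments[f]
        if sd_f == 0:  # degenerate marginal carries no signal
            continue
        z = (cohort[f].to_numpy(float) - m) / sd_f
        delta = delta + gt.delta_risk_slopes.get(f, 0.0) * z
    cohort["brain_age_offset"] = delta
    return cohort, gt


def standardized_factors(cohort: pd.DataFrame, gt: GroundTruth) -> np.ndarray:
    """Risk factors z-scored with the *population* moments implied by the
    demographics configuration (deterministic in the cohort size)."""
    moments = gt.demographics.factor_moments()
    cols = []
    for f in RISK_FACTORS:
        m, s = moments[f]
        if s == 0:  # degenerate marginal: standardized value is zero
            cols.append(np.zeros(len(cohort)))
        else:
            cols.append((cohort[f].to_numpy(float) - m) / s)
    return np.column_stack(cols)


def generate_morphometry(cohort: pd.DataFrame, gt: GroundTruth, seed: int) -> pd.DataFrame:
    """T1 morphometry table: 223 columns, linear in effective age (chronological
    age plus the hidden brain-age offset), sex and standardized risk factors,
    with independent Gaussian noise per feature; indexed by ``subject_id``."""
    missing = [c for c in ("age", "sex", *RISK_FACTORS) if c not in cohort.columns]
    if missing:
        raise ValueError(f"cohort is missing required columns: {missing}")
    rng = np.random.default_rng(seed)
    age = cohort["age"].to_numpy(float)[:, None]
    if "brain_age_offset" in cohort.columns:
        age = age + cohort["brain_age_offset"].to_numpy(float)[:, None]
    sex = cohort["sex"].to_numpy(float)[:, None]
    z = standardized_factors(cohort, gt)
    values = (
        gt.intercept[None, :]
        + age * gt.age_slope[None, :]
        + sex * gt.sex_offset[None, :]
        + z @ gt.risk_slopes.T
        + rng.standard_normal((len(cohort), len(gt.feature_names))) * gt.noise_sd[None, :]
    )
    table = pd.DataFrame(values, columns=gt.feature_names)
    table.insert(0, "subject_id", cohort["subject_id"].to_numpy())
    return table


# ---------------------------------------------------------------------------
# T1-like phantom
# ---------------------------------------------------------------------------

def generate_brain_volume(
    subject: pd.Series,
    grid_size: int,
    gt: GroundTruth,
    seed: int,
    return_masks: bool = False,
):
    """T1-like head phantom with age-dependent geometry.

    A bright "tissue" ellipsoid whose outer extent shrinks with age (cortical
    atrophy) encloses a dark central "ventricle" ellipsoid whose radius grows
    with age.  Gaussian noise is added and the volume is center-scaled to zero
    mean / unit sd over all voxels, mirroring intensity normalization of real
    scans.  With ``return_masks=True`` the pre-noise ventricle and brain masks
    are returned alongside for oracle tests.
    """
    g = int(grid_size)
    if g < 32:
        raise ValueError("grid_size must be >= 32")
    rng = np.random.default_rng(seed)
    age_off = float(subject["age"]) + float(subject.get("brain_age_offset", 0.0)) - 21.0

    c = (g - 1) / 2.0
    x, y, z = np.meshgrid(*(np.arange(g, dtype=float) - c,) * 3, indexing="ij")
    brain_frac = gt.brain_base_frac - gt.atrophy_frac * age_off
    semi = np.array([0.95, 1.05, 0.88]) * brain_frac * g
    brain = (x / semi[0]) ** 2 + (y / semi[1]) ** 2 + (z / semi[2]) ** 2 <= 1.0
    vent_frac = (gt.ventricle_base_frac + gt.ventricle_growth_frac * age_off
                 + rng.normal(0.0, gt.ventricle_jitter_frac))
    vent_r = max(vent_frac, 0.02) * g
    vent_semi = np.array([0.8, 1.2, 0.7]) * vent_r
    vent = (x / vent_semi[0]) ** 2 + (y / vent_semi[1]) ** 2 + (z / vent_semi[2]) ** 2 <= 1.0

    vol = np.zeros((g, g, g))
    vol[brain] = 1.0
    vol[vent & brain] = 0.1  # CSF: dark on T1
    vol += rng.standard_normal(vol.shape) * gt.t1_noise_sd
    vol = (vol - vol.mean()) / vol.std()

    out = Volume3D(vol, (1.0, 1.0, 1.0), "t1-like")
    if return_masks:
        return out, {"brain": brain, "ventricle": vent & brain}
    return out


# ---------------------------------------------------------------------------
# ROI atlas and TOF-like phantom
# ---------------------------------------------------------------------------

def _segment_paths(g: int) -> dict[str, np.ndarray]:
    """Canonical piecewise-linear centerline paths per artery segment, in
    voxel coordinates on a ``g``-sized grid.  Deterministic in ``g``."""
    c = (g - 1) / 2.0

    def P(*pts):
        # control points snap to voxel centers: a tube axis running between
        # voxel centers has a blocky cross-section whose distance transform
        # saturates well below the nominal radius
        return np.round(np.asarray(
            [[c + fx * g, c + fy * g, c + fz * g] for fx, fy, fz in pts]))

    paths = {
        # straight segments carry a one-voxel lateral drift so the axis
        # samples a range of sub-voxel alignments (a perfectly lattice-
        # aligned axis sits at a worst-case of the distance-transform's
        # discrete radius spectrum)
        "ICA_L":    P((-0.10, -0.05, -0.40), (-0.12, -0.05, -0.10)),
        "ICA_R":    P((+0.10, -0.05, -0.40), (+0.12, -0.05, -0.10)),
        "BA":       P((0.0, -0.26, -0.34), (0.02, -0.26, -0.08)),
        "MCA_M1_L": P((-0.10, 0.0, -0.08), (-0.30, 0.0, -0.06)),
        "MCA_M1_R": P((+0.10, 0.0, -0.08), (+0.30, 0.0, -0.06)),
        "MCA_M2_L": P((-0.30, 0.0, -0.08), (-0.40, 0.06, 0.10)),
        "MCA_M2_R": P((+0.30, 0.0, -0.08), (+0.40, 0.06, 0.10)),
        "PCA_L":    P((-0.02, -0.26, -0.10), (-0.24, -0.35, -0.01)),
        "PCA_R":    P((+0.02, -0.26, -0.10), (+0.24, -0.35, -0.01)),
        "ACA_A1":   P((0.0, 0.03, -0.06), (0.0, 0.21, -0.04)),
        # the paired pericallosal arteries run close to the midline; the
        # single A2 label weaves across it so both ACA territories see
        # centerline voxels
        "ACA_A2":   P((0.0, 0.21, -0.06), (-0.04, 0.25, 0.01),
                      (+0.04, 0.29, 0.08), (0.0, 0.32, 0.15)),
    }
    assert set(paths) == set(SEGMENT_NAMES)
    return paths


@lru_cache(maxsize=4)
def _path_distances(g: int) -> dict[str, np.ndarray]:
    """Distance field (voxels) to each segment's canonical path, cached per
    grid size -- the geometry is subject-independent, only radii vary."""
    paths = _segment_paths(g)
    return {n: _distance_to_path((g, g, g), p).astype(np.float32)
            for n, p in paths.items()}


def _distance_to_path(shape: tuple[int, int, int], path: np.ndarray) -> np.ndarray:
    """Per-voxel Euclidean distance (voxels) to a piecewise-linear path."""
    g = shape
    x, y, z = np.meshgrid(*(np.arange(s, dtype=float) for s in g), indexing="ij")
    pts = np.stack([x, y, z], axis=-1)
    dmin = np.full(g, np.inf)
    for a, b in zip(path[:-1], path[1:]):
        ab = b - a
        denom = float(ab @ ab)
        if denom == 0:
            d = np.linalg.norm(pts - a, axis=-1)
        else:
            t = np.clip(((pts - a) @ ab) / denom, 0.0, 1.0)
            proj = a + t[..., None] * ab
            d = np.linalg.norm(pts - proj, axis=-1)
        np.minimum(dmin, d, out=dmin)
    return dmin


def make_roi_atlas(grid_size: int) -> ROIAtlas:
    """Deterministic geometric atlas: 6 flow territories tiling the brain
    mask (ACA/MCA/PCA x left/right, split by a sagittal midplane and two
    coronal planes) and 11 artery-segment labels as tubular regions around
    the canonical centerline paths."""
    g = int(grid_size)
    if g < 32:
        raise ValueError("grid_size must be >= 32")
    c = (g - 1) / 2.0
    x, y, z = np.meshgrid(*(np.arange(g, dtype=float) - c,) * 3, indexing="ij")
    semi = np.array([0.95, 1.05, 0.88]) * 0.44 * g
    brain = (x / semi[0]) ** 2 + (y / semi[1]) ** 2 + (z / semi[2]) ** 2 <= 1.0

    territories = np.zeros((g, g, g), dtype=np.int16)
    ant = y > 0.13 * g
    post = y < -0.16 * g
    mid = ~ant & ~post
    left = x < 0
    for lab, (name, region) in enumerate(
        [("ACA_L", ant & left), ("ACA_R", ant & ~left),
         ("MCA_L", mid & left), ("MCA_R", mid & ~left),
         ("PCA_L", post & left), ("PCA_R", post & ~left)], start=1):
        territories[brain & region] = lab
    territory_labels = {i + 1: n for i, n in enumerate(TERRITORY_NAMES)}

    # nearest-path (Voronoi) labelling within a fixed capture radius, so
    # voxels near a junction attribute to the closest segment's path
    region_radius = max(3.0, 0.085 * g)
    dists = _path_distances(g)
    D = np.stack([dists[name] for name in SEGMENT_NAMES])
    segments = np.where(D.min(axis=0) <= region_radius,
                        D.argmin(axis=0) + 1, 0).astype(np.int16)
    segment_labels = {i + 1: n for i, n in enumerate(SEGMENT_NAMES)}

    return ROIAtlas(territories, segments, (1.0, 1.0, 1.0),
                    territory_labels, segment_labels)


def generate_vessel_volume(
    subject: pd.Series,
    atlas: ROIAtlas,
    gt: GroundTruth,
    seed: int,
) -> tuple[Volume3D, dict[str, float]]:
    """TOF-MRA-like phantom: bright tubes along the canonical artery paths.

    Each segment's tube radius (mm) is ``baseline - decay * (effective age -
    21)`` plus a per-subject common caliber offset and a per-segment jitter
    (anatomical variability), clamped at one voxel (a warning is logged when
    the clamp engages).  Returns the volume plus the true per-segment radii
    for oracle tests.
    """
    g = atlas.shape[0]
    if atlas.shape != (g, g, g):
        raise ValueError("atlas grid must be cubic")
    rng = np.random.default_rng(seed)
    age_off = float(subject["age"]) + float(subject.get("brain_age_offset", 0.0)) - 21.0
    spacing = atlas.spacing[0]

    vol = rng.standard_normal(atlas.shape) * gt.tof_noise_sd
    dists = _path_distances(g)
    caliber = rng.normal(0.0, gt.radius_subject_sd)
    radii: dict[str, float] = {}
    for name in SEGMENT_NAMES:
        r = (gt.vessel_base_radius[name] - gt.radius_decay * age_off
             + caliber + rng.normal(0.0, gt.radius_jitter_sd))
        if r < spacing:
            logger.warning("segment %s radius clamped to 1 voxel (was %.2f mm)", name, r)
            r = spacing
        radii[name] = r
        vol[dists[name] * spacing <= r] = gt.tube_intensity
    return Volume3D(vol, atlas.spacing, "tof-like"), radii
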