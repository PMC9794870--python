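"""End-to-end experiment: simulate -> extract -> train -> fuse -> BAG.

One :class:`ExperimentConfig` drives the whole pipeline: cohort and phantom
simulation, vessel feature extraction, training of the four individual age
predictors (MLP_T1, MLP_TOF, CNN_T1, CNN_TOF) under age-stratified k-fold
cross-validation, stacked fusion of five model combinations, Wilcoxon
comparisons, age-bias correction, BAG computation and risk-factor
associations.  Two training profiles ship with the package:

* ``desk``  -- a single-CPU profile: narrower CNN filters, volumes
  down-sampled 2x before the CNN, and substantially fewer epochs.  This is
  the profile used by the test-suite and the reproduction script.
* ``full`` -- the complete protocol (filters 32/64/128/256, native grids,
  1000/200 epochs), appropriate for long runs.

All randomness fans out from one root seed through ``SeedSequence`` children,
so a run is fully reproducible from its config.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import bag as bag_mod
from . import cv, fusion, synthetic
from .predictors import (
    CNNSpec, MLPSpec, TabularPredictor, TrainConfig, VolumePredictor,
    build_cnn, build_mlp, cnn_train_config, mlp_train_config, train,
)
from .saliency import mlp_importance, smoothgrad
from .synthetic import RISK_FACTORS
from .vessels import VESSEL_FEATURE_NAMES, extract_vessel_features

logger = logging.getLogger(__name__)

__all__ = ["ExperimentConfig", "ExperimentResult", "run_experiment",
           "INDIVIDUAL_MODELS", "COMBINED_MODELS"]

INDIVIDUAL_MODELS = ("MLP_T1", "MLP_TOF", "CNN_T1", "CNN_TOF")

#: Stacked combinations reported alongside the individual models.
COMBINED_MODELS = {
    "Combined_T1": ("CNN_T1", "MLP_T1"),
    "Combined_TOF": ("CNN_TOF", "MLP_TOF"),
    "Combined_MLP": ("MLP_T1", "MLP_TOF"),
    "Combined_CNN": ("CNN_T1", "CNN_TOF"),
    "All_combined": ("CNN_T1", "CNN_TOF", "MLP_T1", "MLP_TOF"),
}

#: Paired comparisons of pooled test absolute errors.
WILCOXON_PAIRS = (
    ("CNN_T1", "Combined_T1"),
    ("CNN_TOF", "Combined_TOF"),
    ("Combined_CNN", "All_combined"),
)


@dataclass
class ExperimentConfig:
    """Everything needed to reproduce one experiment run."""

    n_subjects: int = 400
    seed: int = 1
    grid_size: int = 48
    k_folds: int = 5
    val_frac: float = 0.15
    n_bins: int = 10
    profile: str = "desk"  # "desk" | "full"
    mlp_t1_hidden: tuple[int, ...] = (256, 128)
    mlp_tof_hidden: tuple[int, ...] = (8, 16, 32)
    include_saliency: bool = True
    fdr_alpha: float = 0.05
    out_dir: str | None = None
    #: optional epoch overrides (None = the profile's default)
    mlp_epochs: int | None = None
    cnn_epochs: int | None = None

    def mlp_config(self, seed: int) -> TrainConfig:
        if self.profile == "full":
            return mlp_train_config(seed=seed, epochs=self.mlp_epochs or 1000)
        return mlp_train_config(epochs=self.mlp_epochs or 300, seed=seed)

    def cnn_config(self, seed: int) -> TrainConfig:
        if self.profile == "full":
            return cnn_train_config(seed=seed, epochs=self.cnn_epochs or 200)
        # coarser grid -> fewer epochs, translations scaled to the 2x grid
        return cnn_train_config(epochs=self.cnn_epochs or 8, translate_vox=3,
                                seed=seed)

    def cnn_spec(self) -> CNNSpec:
        if self.profile == "full":
            return CNNSpec()
        return CNNSpec(filters=(8, 16, 32, 64))

    @property
    def cnn_downsample(self) -> int:
        return 1 if self.profile == "full" else 2

    def to_yaml(self, path: str) -> None:
        d = dataclasses.asdict(self)
        d["mlp_t1_hidden"] = list(self.mlp_t1_hidden)
        d["mlp_tof_hidden"] = list(self.mlp_tof_hidden)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh)

    @classmethod
    def from_yaml(cls, path: str) -> "ExperimentConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        d["mlp_t1_hidden"] = tuple(d.get("mlp_t1_hidden", (256, 128)))
        d["mlp_tof_hidden"] = tuple(d.get("mlp_tof_hidden", (8, 16, 32)))
        return cls(**d)


@dataclass
class ExperimentResult:
    """Outputs of one run; tables are pandas DataFrames."""

    config: ExperimentConfig
    cohort: pd.DataFrame
    predictions: pd.DataFrame        # subject_id, fold, split, model, age, predicted
    metrics: pd.DataFrame            # 10 rows: null + 4 individual + 5 combined
    corrected_metrics: pd.DataFrame  # individual models after bias correction
    stack_weights: list[dict]
    wilcoxon: dict[str, float]
    bag_table: pd.DataFrame          # subject_id, model, fold, age, bag
    associations: pd.DataFrame
    saliency: dict[str, object] = field(default_factory=dict)

    def save(self, out_dir: str) -> None:
        import os

        os.makedirs(out_dir, exist_ok=True)
        self.config.to_yaml(os.path.join(out_dir, "config.yaml"))
        self.cohort.to_csv(os.path.join(out_dir, "cohort.csv"), index=False)
        self.predictions.to_csv(os.path.join(out_dir, "predictions.csv"), index=False)
        self.metrics.to_csv(os.path.join(out_dir, "metrics.tsv"), sep="\t")
        self.corrected_metrics.to_csv(
            os.path.join(out_dir, "metrics_corrected.tsv"), sep="\t")
        self.bag_table.to_csv(os.path.join(out_dir, "bag.csv"), index=False)
        self.associations.to_csv(
            os.path.join(out_dir, "associations.tsv"), sep="\t", index=False)
        with open(os.path.join(out_dir, "stack_weights.yaml"), "w") as fh:
            yaml.safe_dump(self.stack_weights, fh)
        with open(os.path.join(out_dir, "wilcoxon.yaml"), "w") as fh:
            yaml.safe_dump({k: float(v) for k, v in self.wilcoxon.items()}, fh)


def _child_seeds(seed: int, n: int) -> list[int]:
    """Deterministic fan-out of the root seed into n independent 31-bit seeds."""
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2 ** 31) for s in ss.generate_state(n, dtype=np.uint64)]


def run_experiment(config: ExperimentConfig) -> ExperimentResult:
    """Run the full pipeline; deterministic given ``config.seed``."""
    (seed_cohort, seed_feat, seed_vol, seed_plan, seed_train,
     seed_sal) = _child_seeds(config.seed, 6)

    # ----- simulate -------------------------------------------------------
    logger.info("simulating cohort of %d subjects", config.n_subjects)
    cohort, gt = synthetic.generate_cohort(config.n_subjects, seed_cohort)
    t1_table = synthetic.generate_morphometry(cohort, gt, seed_feat)
    atlas = synthetic.make_roi_atlas(config.grid_size)

    g = config.grid_size
    n = len(cohort)
    brain_vols = np.empty((n, g, g, g), dtype=np.float32)
    vessel_vols = np.empty((n, g, g, g), dtype=np.float32)
    vol_seeds = _child_seeds(seed_vol, 2 * n)
    for i, (_, subject) in enumerate(cohort.iterrows()):
        brain_vols[i] = synthetic.generate_brain_volume(
            subject, g, gt, vol_seeds[2 * i]).data
        vessel_vols[i] = synthetic.generate_vessel_volume(
            subject, atlas, gt, vol_seeds[2 * i + 1])[0].data

    # ----- extract vessel features ---------------------------------------
    logger.info("extracting vessel features")
    from .types import Volume3D

    rows = []
    for i in range(n):
        vol = Volume3D(vessel_vols[i], atlas.spacing, "tof-like")
        rows.append(extract_vessel_features(vol, atlas))
    tof_table = pd.DataFrame(rows).reset_index(drop=True)
    tof_table.insert(0, "subject_id", cohort["subject_id"].to_numpy())
    # the MLP_TOF input: 24 artery features + total brain volume
    tof_table["TotalBrainVolume"] = t1_table["TotalBrainVolume"].to_numpy()
    tof_features = [*VESSEL_FEATURE_NAMES, "TotalBrainVolume"]

    # ----- folds ----------------------------------------------------------
    plan = cv.plan_folds(cohort, config.k_folds, config.val_frac,
                         config.n_bins, seed_plan)
    ages = cohort.set_index("subject_id")["age"]
    idx_of = {sid: i for i, sid in enumerate(cohort["subject_id"])}

    train_seeds = _child_seeds(seed_train, config.k_folds * 4)
    pred_rows: list[pd.DataFrame] = []
    last_models: dict[str, object] = {}  # the final fold's trained predictors

    def record(model: str, fold: int, split: str, sids: list[str], pred: np.ndarray):
        pred_rows.append(pd.DataFrame({
            "subject_id": sids, "fold": fold, "split": split, "model": model,
            "age": ages.loc[sids].to_numpy(), "predicted": pred,
        }))

    for fold in range(config.k_folds):
        tr_ids, va_ids, te_ids = (plan.train_ids(fold), plan.val_ids(fold),
                                  plan.test_ids(fold))
        logger.info("fold %d: train %d / val %d / test %d",
                    fold, len(tr_ids), len(va_ids), len(te_ids))
        y_tr = ages.loc[tr_ids].to_numpy()
        y_va = ages.loc[va_ids].to_numpy()

        # null model: training-mean age (train + validation portion)
        non_test = tr_ids + va_ids
        record("Null", fold, "test", te_ids,
               cv.null_model(ages.loc[non_test].to_numpy(),
                             ages.loc[te_ids].to_numpy()))

        # --- MLPs on feature tables
        for model_id, table, feats, hidden in (
            ("MLP_T1", t1_table, gt.feature_names, config.mlp_t1_hidden),
            ("MLP_TOF", tof_table, tof_features, config.mlp_tof_hidden),
        ):
            s = train_seeds[fold * 4 + (0 if model_id == "MLP_T1" else 1)]
            tab = table.set_index("subject_id")
            net = build_mlp(len(feats), MLPSpec(tuple(hidden)), seed=s)
            pred_model = TabularPredictor.fit_scaler(net, tab.loc[tr_ids], list(feats))
            X_tr = pred_model.transform(tab.loc[tr_ids])
            X_va = pred_model.transform(tab.loc[va_ids])
            train(net, X_tr, y_tr, X_va, y_va, config.mlp_config(seed=s))
            record(model_id, fold, "val", va_ids, pred_model.predict(tab.loc[va_ids]))
            record(model_id, fold, "test", te_ids, pred_model.predict(tab.loc[te_ids]))
            last_models[model_id] = pred_model

        # --- CNNs on volumes
        for model_id, vols in (("CNN_T1", brain_vols), ("CNN_TOF", vessel_vols)):
            s = train_seeds[fold * 4 + (2 if model_id == "CNN_T1" else 3)]
            vp = VolumePredictor(net=None, downsample=config.cnn_downsample)
            Xtr = vp.transform(vols[[idx_of[i] for i in tr_ids]])
            Xva = vp.transform(vols[[idx_of[i] for i in va_ids]])
            vp.net = build_cnn(Xtr.shape[1:4], config.cnn_spec(), seed=s)
            train(vp.net, Xtr, y_tr, Xva, y_va, config.cnn_config(seed=s),
                  volumetric=True)
            record(model_id, fold, "val", va_ids,
                   vp.predict(vols[[idx_of[i] for i in va_ids]]))
            record(model_id, fold, "test", te_ids,
                   vp.predict(vols[[idx_of[i] for i in te_ids]]))
            last_models[model_id] = vp

    predictions = pd.concat(pred_rows, ignore_index=True)

    # ----- stacking -------------------------------------------------------
    def preds(model: str, fold: int, split: str) -> np.ndarray:
        sel = predictions[(predictions["model"] == model)
                          & (predictions["fold"] == fold)
                          & (predictions["split"] == split)]
        return sel.sort_values("subject_id")["predicted"].to_numpy()

    def split_ids(fold: int, split: str) -> list[str]:
        ids = {"val": plan.val_ids(fold), "test": plan.test_ids(fold)}[split]
        return sorted(ids)

    stack_weights: list[dict] = []
    for combo, members in COMBINED_MODELS.items():
        for fold in range(config.k_folds):
            va_ids = split_ids(fold, "val")
            w = fusion.fit_stack({m: preds(m, fold, "val") for m in members},
                                 ages.loc[va_ids].to_numpy(), fold=fold)
            te_ids = split_ids(fold, "test")
            combined = fusion.apply_stack(
                w, {m: preds(m, fold, "test") for m in members})
            record(combo, fold, "test", te_ids, combined)
            val_combined = fusion.apply_stack(
                w, {m: preds(m, fold, "val") for m in members})
            record(combo, fold, "val", va_ids, val_combined)
            d = w.to_dict()
            d["combo"] = combo
            stack_weights.append(d)
    predictions = pd.concat(pred_rows, ignore_index=True)

    # ----- metrics table (Null + 4 individual + 5 combined) ---------------
    def summary_row(model: str) -> dict:
        sel = predictions[(predictions["model"] == model)
                          & (predictions["split"] == "test")]
        table = cv.evaluate(sel)
        return {
            "model": model,
            "mae": table.loc["mean", "mae"], "mae_sd": table.loc["sd", "mae"],
            "pearson_r": table.loc["mean", "pearson_r"],
            "pearson_r_sd": table.loc["sd", "pearson_r"],
            "bias_r": table.loc["mean", "bias_r"],
            "bias_r_sd": table.loc["sd", "bias_r"],
        }

    model_rows = ["Null", *INDIVIDUAL_MODELS, *COMBINED_MODELS]
    metrics = pd.DataFrame([summary_row(m) for m in model_rows]).set_index("model")

    # ----- Wilcoxon comparisons on pooled test absolute errors ------------
    wilcoxon: dict[str, float] = {}
    pooled = predictions[predictions["split"] == "test"]

    def pooled_errors(model: str) -> np.ndarray:
        sel = pooled[pooled["model"] == model].sort_values(["subject_id"])
        return (sel["predicted"] - sel["age"]).to_numpy()

    for a, b in WILCOXON_PAIRS:
        wilcoxon[f"{a}_vs_{b}"] = fusion.compare_abs_errors(
            pooled_errors(a), pooled_errors(b))

    # ----- bias correction and BAG (individual models) --------------------
    bag_rows = []
    corr_rows = []
    for model in INDIVIDUAL_MODELS:
        for fold in range(config.k_folds):
            va_ids = split_ids(fold, "val")
            params = bag_mod.fit_bias(preds(model, fold, "val"),
                                      ages.loc[va_ids].to_numpy(),
                                      fold=fold, model=model)
            te_ids = split_ids(fold, "test")
            y_te = ages.loc[te_ids].to_numpy()
            corrected = bag_mod.correct(preds(model, fold, "test"), y_te, params)
            gap = bag_mod.compute_bag(corrected, y_te)
            bag_rows.append(pd.DataFrame({
                "subject_id": te_ids, "model": model, "fold": fold,
                "age": y_te, "bag": gap, "corrected": corrected,
            }))
            corr_rows.append(pd.DataFrame({
                "subject_id": te_ids, "fold": fold, "split": "test",
                "model": model, "age": y_te, "predicted": corrected,
            }))
    bag_table = pd.concat(bag_rows, ignore_index=True)
    corrected_pred = pd.concat(corr_rows, ignore_index=True)
    corrected_metrics = pd.DataFrame([
        {**{"model": m},
         **{k: cv.evaluate(corrected_pred[corrected_pred["model"] == m])
            .loc["mean", k] for k in ("mae", "pearson_r", "bias_r")}}
        for m in INDIVIDUAL_MODELS
    ]).set_index("model")

    # ----- associations ---------------------------------------------------
    cohort_idx = cohort.set_index("subject_id")
    bags = {}
    for model in INDIVIDUAL_MODELS:
        sel = bag_table[bag_table["model"] == model].sort_values("subject_id")
        bags[model] = sel["bag"].to_numpy()
    sub = cohort_idx.loc[sorted(bag_table["subject_id"].unique())].reset_index()
    associations = bag_mod.associate_all(bags, sub, RISK_FACTORS,
                                         alpha=config.fdr_alpha)

    # ----- saliency on the last fold's trained models ---------------------
    sal: dict[str, object] = {}
    if config.include_saliency:
        demo_sid = cohort["subject_id"].iloc[0]
        mlp: TabularPredictor = last_models["MLP_T1"]
        tab = t1_table.set_index("subject_id")
        sal["mlp_t1_ranking"] = mlp_importance(
            mlp.net, mlp.transform(tab.loc[[demo_sid]])[0],
            mlp.feature_names, seed=seed_sal)
        cnn: VolumePredictor = last_models["CNN_T1"]
        x = cnn.transform(brain_vols[idx_of[demo_sid]][None])[0]
        sal["cnn_t1_map"] = smoothgrad(cnn.net, x, seed=seed_sal)

    result = ExperimentResult(
        config=config, cohort=cohort, predictions=predictions, metrics=metrics,
        corrected_metrics=corrected_metrics, stack_weights=stack_weights,
        wilcoxon=wilcoxon, bag_table=bag_table, associations=associations,
        saliency=sal,
    )
    if config.out_dir:
        result.save(config.out_dir)
    return result
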