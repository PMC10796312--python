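"""End-to-end experiment orchestration with a re-runnable run directory.

The full experiment is: simulate a phantom cohort -> preprocess (resample
+ crop) -> stratified split -> (optional offline augmentation inside each
training fold) -> 4-fold cross-validation -> size-weighted ensemble ->
single test-set evaluation (AUC with DeLong CI, both threshold rules,
confusion metrics) -> paired SUVmax comparison with crossing-based test
dispatch -> Grad-CAM galleries.  The held-out test partition is touched
exactly once, at the end.

Every stage reads and writes a fixed run-directory layout, so stages can
be re-run independently (this is what the CLI subcommands do):

    run_dir/
      config.yaml             experiment configuration
      cohort/                 NRRD volumes + manifest.csv
      preprocessed/           40^3 crops (NRRD), suvmax.csv
      split.json              subject -> partition assignment
      models/                 per-fold checkpoints + histories
      metrics.csv             per-fold validation AUCs
      summary.json            machine-readable results
      gradcam/                PNG fusion galleries

All randomness flows from the single global seed through documented
sub-seeds (cohort = seed, split = seed + 1, training = seed + 2,
permutation test = seed + 3), which the summary records.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .augment import AugmentationPlan
from .models import BUILDERS, load_model, save_model
from .phantom import PhantomSpec, generate_cohort, suvmax_score
from .preprocess import crop_cube, resample_isotropic
from .roc_stats import (average_thresholds, classify, compare_scores,
                        confusion_metrics, constrained_threshold, delong_ci,
                        empirical_roc, youden_threshold)
from .training import (TrainConfig, build_ensemble, cross_validate,
                       stratified_split)
from .volume import read_manifest, read_nrrd, write_nrrd

logger = logging.getLogger("petnodule")

SUMMARY_SCHEMA_VERSION = 1


@dataclass
class ExperimentConfig:
    """Aggregated configuration of one experiment run."""

    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    arch: str = "stacked3d"
    train: TrainConfig = field(default_factory=TrainConfig)
    augment: bool = False
    plan: AugmentationPlan = field(default_factory=AugmentationPlan)
    n_permutations: int = 2000
    ci_level: float = 0.95
    min_sens: float = 0.95
    n_gradcam: int = 2
    seed: int = 0

    def __post_init__(self):
        if self.arch not in BUILDERS:
            raise ValueError(f"arch must be one of {sorted(BUILDERS)}")
        # propagate the global seed through documented sub-seeds
        self.phantom.seed = self.seed
        self.train.seed = self.seed + 2
        self.plan.seed = self.seed + 4

    @property
    def split_seed(self):
        return self.seed + 1

    @property
    def vb_seed(self):
        return self.seed + 3

    def to_yaml(self) -> str:
        d = {"phantom": asdict(self.phantom), "arch": self.arch,
             "train": asdict(self.train), "augment": self.augment,
             "plan": yaml.safe_load(self.plan.to_yaml()),
             "n_permutations": self.n_permutations,
             "ci_level": self.ci_level, "min_sens": self.min_sens,
             "n_gradcam": self.n_gradcam, "seed": self.seed}
        return yaml.safe_dump(d, sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "ExperimentConfig":
        d = yaml.safe_load(text)
        ph = d.get("phantom", {})
        for key in ("field_mm", "native_spacing_mm", "diameter_range_mm"):
            if key in ph and ph[key] is not None:
                ph[key] = tuple(ph[key])
        plan = d.get("plan")
        return cls(phantom=PhantomSpec(**ph), arch=d.get("arch", "stacked3d"),
                   train=TrainConfig(**d.get("train", {})),
                   augment=d.get("augment", False),
                   plan=(AugmentationPlan.from_yaml(yaml.safe_dump(plan))
                         if plan else AugmentationPlan()),
                   n_permutations=d.get("n_permutations", 2000),
                   ci_level=d.get("ci_level", 0.95),
                   min_sens=d.get("min_sens", 0.95),
                   n_gradcam=d.get("n_gradcam", 2),
                   seed=d.get("seed", 0))


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            t0 = time.time()
            try:
                out = fn(*args, **kwargs)
            except Exception as e:
                raise StageError(f"stage '{name}' failed: {e}") from e
            logger.info("stage %s done in %.1fs", name, time.time() - t0)
            return out
        wrapper.__name__ = fn.__name__
        wrapper.__doc__ = fn.__doc__
        return wrapper
    return deco


# ---------------------------------------------------------------------------
# stages


@_stage("simulate")
def stage_simulate(config: ExperimentConfig, run_dir):
    """Generate the phantom cohort (NRRD volumes + manifest)."""
    run_dir = Path(run_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    (run_dir / "config.yaml").write_text(config.to_yaml())
    manifest = generate_cohort(config.phantom, run_dir / "cohort")
    logger.info("simulated %d subjects (%d malignant)", len(manifest),
                int(manifest.labels.sum()))
    return manifest


@_stage("preprocess")
def stage_preprocess(config: ExperimentConfig, run_dir):
    """Resample to isotropic voxels, crop 40^3 tensors, score SUVmax."""
    run_dir = Path(run_dir)
    manifest = read_manifest(run_dir / "cohort" / "manifest.csv")
    out = run_dir / "preprocessed"
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for i in range(len(manifest)):
        rec = manifest.records.iloc[i]
        ann = manifest.annotation(i)
        vol = read_nrrd(rec.path, subject_id=rec.subject_id)
        iso = resample_isotropic(vol, config.phantom.voxel_mm)
        tensor = crop_cube(iso, ann.center_mm)
        rel = f"{rec.subject_id}.nrrd"
        write_nrrd(
            _tensor_volume(tensor.values, config.phantom.voxel_mm,
                           rec.subject_id), out / rel)
        rows.append({"subject_id": rec.subject_id, "path": rel,
                     "label": rec.label,
                     "suvmax": suvmax_score(iso, ann)})
    pd.DataFrame(rows).to_csv(out / "tensors.csv", index=False)
    return out


def _tensor_volume(values, spacing, subject_id):
    from .volume import PetVolume
    return PetVolume(values=np.maximum(values, 0.0),
                     spacing_mm=np.full(3, spacing), subject_id=subject_id)


def _load_tensors(run_dir):
    base = Path(run_dir) / "preprocessed"
    df = pd.read_csv(base / "tensors.csv")
    tensors = [read_nrrd(p if Path(p).is_absolute() else base / p).values
               for p in df.path]
    labels = (df.label == "malignant").to_numpy(dtype=int)
    return df.subject_id.tolist(), tensors, labels, df.suvmax.to_numpy()


@_stage("split")
def stage_split(config: ExperimentConfig, run_dir):
    """Stratified 5-way split; partition 4 is the held-out test set."""
    run_dir = Path(run_dir)
    manifest = read_manifest(run_dir / "cohort" / "manifest.csv")
    split = stratified_split(manifest.records.subject_id.tolist(),
                             manifest.records.label.tolist(),
                             seed=config.split_seed)
    (run_dir / "split.json").write_text(json.dumps(
        {"assignment": split.assignment, "seed": split.seed,
         "test_partition": split.test_partition}))
    return split


def load_split(run_dir):
    from .training import FoldSplit
    d = json.loads((Path(run_dir) / "split.json").read_text())
    return FoldSplit(assignment=d["assignment"], seed=d["seed"],
                     test_partition=d["test_partition"])


@_stage("train")
def stage_train(config: ExperimentConfig, run_dir):
    """4-fold cross-validation of the chosen architecture."""
    run_dir = Path(run_dir)
    ids, tensors, labels, _ = _load_tensors(run_dir)
    split = load_split(run_dir)
    spec = BUILDERS[config.arch](config.train.l2_lambda)
    cv = cross_validate(spec, tensors, labels, ids, split, config.train,
                        augment_plan=config.plan if config.augment else None)
    mdir = run_dir / "models"
    mdir.mkdir(exist_ok=True)
    for i, model in enumerate(cv.models):
        save_model(model, mdir / f"fold{i}")
    pd.DataFrame({"fold": range(4), "val_auc": cv.fold_aucs}).to_csv(
        run_dir / "metrics.csv", index=False)
    (mdir / "cv.json").write_text(json.dumps(
        {"fold_aucs": cv.fold_aucs, "mean_auc": cv.mean_auc,
         "sd_auc": cv.sd_auc, "fold_val_ids": cv.fold_val_ids}))
    return cv


def _load_cv(run_dir):
    mdir = Path(run_dir) / "models"
    meta = json.loads((mdir / "cv.json").read_text())
    models = [load_model(mdir / f"fold{i}") for i in range(4)]
    return models, meta


@_stage("evaluate")
def stage_evaluate(config: ExperimentConfig, run_dir):
    """Ensemble the fold models and evaluate once on the test partition."""
    run_dir = Path(run_dir)
    ids, tensors, labels, suvmax = _load_tensors(run_dir)
    split = load_split(run_dir)
    models, meta = _load_cv(run_dir)
    ensemble = build_ensemble(models, split)
    by_id = {s: i for i, s in enumerate(ids)}

    # per-fold decision thresholds from the fold validation partitions
    thresholds = {"youden": [], "min_sensitivity": []}
    for model, val_ids in zip(models, meta["fold_val_ids"]):
        xi = [tensors[by_id[s]] for s in val_ids]
        yi = np.array([labels[by_id[s]] for s in val_ids])
        from .preprocess import apply_minmax
        xn = np.stack([apply_minmax(t, model.norm_stats) for t in xi])
        pi = model.predict_proba(xn)
        thresholds["youden"].append(youden_threshold(pi, yi).threshold)
        thresholds["min_sensitivity"].append(
            constrained_threshold(pi, yi, config.min_sens).threshold)
    thr_youden = average_thresholds(thresholds["youden"])
    thr_minsens = average_thresholds(thresholds["min_sensitivity"])

    test_ids = split.test_ids
    x_test = [tensors[by_id[s]] for s in test_ids]
    y_test = np.array([labels[by_id[s]] for s in test_ids])
    p_test = ensemble.predict_proba(x_test)
    dl = delong_ci(p_test, y_test, level=config.ci_level)
    result = {
        "fold_aucs": meta["fold_aucs"], "cv_mean_auc": meta["mean_auc"],
        "cv_sd_auc": meta["sd_auc"],
        "ensemble_weights": ensemble.weights.tolist(),
        "test_ids": test_ids,
        "test_probabilities": p_test.tolist(),
        "test_labels": y_test.tolist(),
        "test_auc": dl.auc, "test_ci": [dl.ci_low, dl.ci_high],
        "thresholds": {
            "youden": {"per_fold": thresholds["youden"],
                       "averaged": thr_youden,
                       "test": confusion_metrics(
                           classify(p_test, thr_youden), y_test)},
            "min_sensitivity": {"per_fold": thresholds["min_sensitivity"],
                                "averaged": thr_minsens,
                                "test": confusion_metrics(
                                    classify(p_test, thr_minsens), y_test)},
        },
    }
    (run_dir / "evaluation.json").write_text(json.dumps(result))
    return result


@_stage("compare_suvmax")
def stage_compare_suvmax(config: ExperimentConfig, run_dir):
    """Paired CNN-vs-SUVmax ROC comparison with crossing dispatch."""
    run_dir = Path(run_dir)
    ids, _tensors, _labels, suvmax = _load_tensors(run_dir)
    split = load_split(run_dir)
    ev = json.loads((run_dir / "evaluation.json").read_text())
    by_id = {s: i for i, s in enumerate(ids)}
    test_ids = ev["test_ids"]
    p_test = np.asarray(ev["test_probabilities"])
    y_test = np.asarray(ev["test_labels"])
    suv_test = np.array([suvmax[by_id[s]] for s in test_ids])
    comp = compare_scores(p_test, suv_test, y_test,
                          n_permutations=config.n_permutations,
                          seed=config.vb_seed)
    (run_dir / "comparison.json").write_text(json.dumps(comp))
    return comp


@_stage("explain")
def stage_explain(config: ExperimentConfig, run_dir):
    """Grad-CAM fusion galleries for the first test subjects."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from .explain import gradcam3d, gradcam_gallery
    from .preprocess import apply_minmax
    run_dir = Path(run_dir)
    ids, tensors, labels, _ = _load_tensors(run_dir)
    split = load_split(run_dir)
    models, _meta = _load_cv(run_dir)
    by_id = {s: i for i, s in enumerate(ids)}
    gdir = run_dir / "gradcam"
    gdir.mkdir(exist_ok=True)
    outputs = []
    for sid in split.test_ids[:config.n_gradcam]:
        raw = tensors[by_id[sid]]
        maps = []
        for model in models:
            xn = apply_minmax(raw, model.norm_stats)
            maps.append(gradcam3d(model, xn))
        rows = gradcam_gallery(raw, maps)
        fig, axes = plt.subplots(len(rows), len(rows[0]),
                                 figsize=(len(rows[0]) * 1.2, len(rows) * 1.3))
        for r, row in enumerate(rows):
            for c, img in enumerate(row):
                ax = axes[r][c]
                ax.imshow(np.rot90(img))
                ax.set_axis_off()
        fig.suptitle(f"{sid} ({'malignant' if labels[by_id[sid]] else 'benign'})")
        path = gdir / f"{sid}.png"
        fig.savefig(path, dpi=80)
        plt.close(fig)
        outputs.append(str(path.relative_to(run_dir)))
    return outputs


def run_experiment(config: ExperimentConfig, run_dir) -> dict:
    """Execute every stage and write the machine-readable summary."""
    run_dir = Path(run_dir)
    t0 = time.time()
    stage_simulate(config, run_dir)
    stage_preprocess(config, run_dir)
    stage_split(config, run_dir)
    stage_train(config, run_dir)
    evaluation = stage_evaluate(config, run_dir)
    comparison = stage_compare_suvmax(config, run_dir)
    gallery = stage_explain(config, run_dir)
    summary = {
        "schema_version": SUMMARY_SCHEMA_VERSION,
        "config": yaml.safe_load(config.to_yaml()),
        "seeds": {"global": config.seed, "cohort": config.phantom.seed,
                  "split": config.split_seed, "train": config.train.seed,
                  "permutation_test": config.vb_seed},
        "evaluation": evaluation,
        "suvmax_comparison": comparison,
        "gradcam_galleries": gallery,
        "wall_time_s": time.time() - t0,
    }
    (run_dir / "summary.json").write_text(json.dumps(summary, indent=1))
    return summary
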