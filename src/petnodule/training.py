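"""Stratified splitting, fold training with early stopping, ensembling.

The experiment protocol: subjects are split into five class-stratified
partitions of near-equal size; the fifth is held out for testing and the
first four drive 4-fold cross-validation (train on three, validate on
one).  Models train with Adam on binary cross-entropy plus L2, shuffling
every epoch, and stop at the minimum validation loss with a patience of
ten epochs (or a 100-epoch cap), restoring the best-epoch parameters.
The four fold models form an ensemble whose output is the average of
their probabilities weighted by fold training-set size.

Training is single-threaded NumPy and fully deterministic given the
config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import logging

import numpy as np

from .augment import AugmentationPlan, build_augmented_dataset
from .models import ArchitectureSpec, TrainedModel, build_network
from .nn import Adam, bce_with_logits, sigmoid
from .nn.layers import DTYPE
from .preprocess import NormStats, apply_minmax, fit_minmax
from .roc_stats import empirical_roc

N_PARTITIONS = 5
TEST_PARTITION = 4


# ---------------------------------------------------------------------------
# stratified splitting


@dataclass
class FoldSplit:
    """Subject-to-partition assignment; partition 4 is the test set."""

    assignment: dict  # subject_id -> partition index 0..4
    seed: int = 0
    test_partition: int = TEST_PARTITION

    def partition_ids(self, k: int) -> list:
        return [s for s, p in self.assignment.items() if p == k]

    @property
    def test_ids(self) -> list:
        return self.partition_ids(self.test_partition)

    @property
    def cv_partitions(self) -> list:
        return [k for k in range(N_PARTITIONS) if k != self.test_partition]

    def cv_folds(self):
        """Yield (fold_index, train_ids, val_ids) over the four CV folds."""
        for i, k in enumerate(self.cv_partitions):
            val = self.partition_ids(k)
            train = [s for j in self.cv_partitions if j != k
                     for s in self.partition_ids(j)]
            yield i, train, val

    def sizes(self) -> list:
        return [len(self.partition_ids(k)) for k in range(N_PARTITIONS)]


def stratified_split(subject_ids, labels, seed: int = 0) -> FoldSplit:
    """Five stratified partitions by largest-remainder allocation.

    Within each class, floor(n_c/5) subjects go to every partition and the
    remainder is assigned one-per-partition to the currently smallest
    partitions (classes processed from largest to smallest), which keeps
    per-partition class counts within 1 of proportional and partition
    totals balanced.
    """
    subject_ids = list(subject_ids)
    labels = list(labels)
    if len(subject_ids) != len(labels):
        raise ValueError("subject_ids and labels must align")
    rng = np.random.default_rng(seed)
    by_class = {}
    for s, y in zip(subject_ids, labels):
        by_class.setdefault(y, []).append(s)
    for y, members in by_class.items():
        if len(members) < N_PARTITIONS:
            raise ValueError(
                f"class {y!r} has {len(members)} subjects; at least "
                f"{N_PARTITIONS} per class are required")
    assignment = {}
    totals = np.zeros(N_PARTITIONS, dtype=int)
    for y in sorted(by_class, key=lambda c: -len(by_class[c])):
        members = list(by_class[y])
        rng.shuffle(members)
        base, rem = divmod(len(members), N_PARTITIONS)
        pos = 0
        for k in range(N_PARTITIONS):
            for s in members[pos:pos + base]:
                assignment[s] = k
            pos += base
            totals[k] += base
        # remainders: one each to the smallest partitions (stable ties)
        order = np.argsort(totals, kind="stable")[:rem]
        for k in order:
            assignment[members[pos]] = int(k)
            pos += 1
            totals[k] += 1
    return FoldSplit(assignment=assignment, seed=seed)


# ---------------------------------------------------------------------------
# single-model training


@dataclass
class TrainConfig:
    """Optimisation hyperparameters (loss is BCE, optimiser is Adam)."""

    learning_rate: float = 0.001
    batch_size: object = "full"  # int, or "full" for the whole training set
    l2_lambda: float = 0.00098
    max_epochs: int = 100
    patience: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if not self.patience < self.max_epochs:
            raise ValueError("patience must be smaller than max_epochs")

    def resolve_batch(self, n: int) -> int:
        if self.batch_size == "full":
            return n
        b = int(self.batch_size)
        if b < 1:
            raise ValueError("batch_size must be >= 1 or 'full'")
        return min(b, n)


def _as_xy(tensors, labels):
    x = np.stack([np.asarray(t, dtype=DTYPE) for t in tensors])[:, None]
    y = np.asarray(labels, dtype=np.float64)
    return x, y


def _eval_loss(network, x, y, lam, batch=32):
    logits = []
    for i in range(0, len(x), batch):
        logits.append(network.forward_logits(x[i:i + batch]))
    z = np.concatenate(logits)
    return bce_with_logits(z, y) + network.l2_penalty(lam)


def train_model(spec: ArchitectureSpec, train_tensors, train_labels,
                val_tensors, val_labels, config: TrainConfig,
                norm_stats: Optional[NormStats] = None) -> TrainedModel:
    """Fit one network with epoch shuffling and patience-based stopping.

    Returns the model with the parameters of the epoch that achieved the
    lowest validation loss.
    """
    if len(train_tensors) == 0 or len(val_tensors) == 0:
        raise ValueError("training and validation sets must be non-empty")
    x_tr, y_tr = _as_xy(train_tensors, train_labels)
    x_va, y_va = _as_xy(val_tensors, val_labels)
    rng = np.random.default_rng(config.seed)
    network = build_network(spec, rng=rng)
    lam = config.l2_lambda if config.l2_lambda is not None else spec.l2_lambda
    opt = Adam(network, lr=config.learning_rate)
    batch = config.resolve_batch(len(x_tr))

    history = {"train_loss": [], "val_loss": []}
    best_loss = np.inf
    best_weights = network.get_weights()
    best_epoch = 0
    since_best = 0
    for epoch in range(config.max_epochs):
        perm = rng.permutation(len(x_tr))
        losses = []
        for i in range(0, len(perm), batch):
            idx = perm[i:i + batch]
            xb, yb = x_tr[idx], y_tr[idx]
            z = network.forward_logits(xb, train=True)
            p = sigmoid(z)
            losses.append(bce_with_logits(z, yb) + network.l2_penalty(lam))
            network.backward((p - yb) / len(yb))
            network.add_l2_gradients(lam)
            opt.step()
        history["train_loss"].append(float(np.mean(losses)))
        val_loss = _eval_loss(network, x_va, y_va, lam)
        history["val_loss"].append(val_loss)
        logger.debug("epoch %d: train_loss %.4f val_loss %.4f", epoch,
                     history["train_loss"][-1], val_loss)
        if val_loss < best_loss:
            best_loss = val_loss
            best_weights = network.get_weights()
            best_epoch = epoch
            since_best = 0
        else:
            since_best += 1
            if since_best >= config.patience:
                break
    network.set_weights(best_weights)
    return TrainedModel(spec=spec, network=network, history=history,
                        best_epoch=best_epoch, norm_stats=norm_stats)


# ---------------------------------------------------------------------------
# cross-validation


logger = logging.getLogger("petnodule")


@dataclass
class CVResult:
    fold_aucs: list
    models: list  # TrainedModel per fold
    fold_val_ids: list
    fold_train_sizes: list = field(default_factory=list)
    mean_auc: float = field(init=False)
    sd_auc: float = field(init=False)

    def __post_init__(self):
        a = np.asarray(self.fold_aucs, dtype=float)
        self.mean_auc = float(a.mean())
        self.sd_auc = float(a.std(ddof=1)) if len(a) > 1 else 0.0


def _leakage_check(split: FoldSplit, used_ids):
    inter = set(split.test_ids) & set(used_ids)
    if inter:
        raise RuntimeError(f"test subjects leaked into training: {sorted(inter)}")


def cross_validate(spec: ArchitectureSpec, tensors, labels, subject_ids,
                   split: FoldSplit, config: TrainConfig,
                   augment_plan: Optional[AugmentationPlan] = None,
                   clip: bool = False) -> CVResult:
    """4-fold CV with fold-specific normalisation and optional augmentation.

    ``tensors`` are raw (un-normalised) 40^3 crops aligned with ``labels``
    and ``subject_ids``.  Normalisation statistics are fitted on each
    fold's original training tensors; augmentation (if any) is applied to
    the normalised training tensors only — every fold model is evaluated
    on its original, never augmented, validation partition.
    """
    by_id = {s: (t, y) for s, t, y in zip(subject_ids, tensors, labels)}
    fold_aucs, models, fold_val_ids, fold_train_sizes = [], [], [], []
    for fold, train_ids, val_ids in split.cv_folds():
        _leakage_check(split, train_ids + val_ids)
        x_tr = [by_id[s][0] for s in train_ids]
        y_tr = [by_id[s][1] for s in train_ids]
        x_va = [by_id[s][0] for s in val_ids]
        y_va = [by_id[s][1] for s in val_ids]
        stats = fit_minmax(x_tr, fold_id=f"fold{fold}")
        x_tr_n = [apply_minmax(t, stats, clip=clip) for t in x_tr]
        x_va_n = [apply_minmax(t, stats, clip=clip) for t in x_va]
        if augment_plan is not None:
            x_tr_n, y_tr = build_augmented_dataset(
                x_tr_n, y_tr, augment_plan, subject_ids=train_ids)
        fold_train_sizes.append(len(x_tr_n))
        logger.info("fold %d: training on %d tensors, validating on %d",
                    fold, len(x_tr_n), len(x_va_n))
        fold_cfg = TrainConfig(learning_rate=config.learning_rate,
                               batch_size=config.batch_size,
                               l2_lambda=config.l2_lambda,
                               max_epochs=config.max_epochs,
                               patience=config.patience,
                               seed=config.seed + 1000 * fold)
        model = train_model(spec, x_tr_n, y_tr, x_va_n, y_va, fold_cfg,
                            norm_stats=stats)
        probs = model.predict_proba(np.stack(x_va_n))
        fold_aucs.append(empirical_roc(probs, y_va).auc)
        models.append(model)
        fold_val_ids.append(list(val_ids))
    return CVResult(fold_aucs=fold_aucs, models=models,
                    fold_val_ids=fold_val_ids,
                    fold_train_sizes=fold_train_sizes)


def repeat_cv(spec: ArchitectureSpec, tensors, labels, subject_ids,
              split: FoldSplit, config: TrainConfig, iterations: int = 10,
              augment_plan: Optional[AugmentationPlan] = None) -> dict:
    """Re-run cross-validation with varied seeds; average the fold means."""
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    results = []
    for it in range(iterations):
        cfg = TrainConfig(learning_rate=config.learning_rate,
                          batch_size=config.batch_size,
                          l2_lambda=config.l2_lambda,
                          max_epochs=config.max_epochs,
                          patience=config.patience,
                          seed=config.seed + 100_003 * it)
        results.append(cross_validate(spec, tensors, labels, subject_ids,
                                      split, cfg, augment_plan=augment_plan))
    means = [r.mean_auc for r in results]
    return {"iterations": iterations,
            "mean_auc": float(np.mean(means)),
            "sd_auc": float(np.std(means, ddof=1)) if iterations > 1 else 0.0,
            "per_iteration": results}


# ---------------------------------------------------------------------------
# ensembling


@dataclass
class EnsembleModel:
    """Four fold models averaged with training-set-size weights."""

    fold_models: list
    weights: np.ndarray

    def __post_init__(self):
        if len(self.fold_models) != 4:
            raise ValueError("the ensemble requires exactly four fold models")
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape != (4,) or np.any(self.weights <= 0):
            raise ValueError("need four positive weights")
        s = self.weights.sum()
        if not np.isclose(s, 1.0, atol=1e-9):
            raise ValueError("ensemble weights must sum to 1")

    def predict_proba(self, raw_tensors, clip: bool = False) -> np.ndarray:
        """Weighted-average probability for raw (un-normalised) tensors.

        Each fold model normalises the inputs with its own fold statistics
        before scoring, as the test set is normalised "with values of the
        training set of the respective fold".
        """
        raw = [np.asarray(t) for t in raw_tensors]
        total = None
        for w, model in zip(self.weights, self.fold_models):
            if model.norm_stats is None:
                x = np.stack(raw)
            else:
                x = np.stack([apply_minmax(t, model.norm_stats, clip=clip)
                              for t in raw])
            p = model.predict_proba(x)
            total = w * p if total is None else total + w * p
        return total


def build_ensemble(fold_models, split: FoldSplit) -> EnsembleModel:
    """Weights proportional to each fold's training-partition size."""
    if len(fold_models) != 4:
        raise ValueError("exactly four fold models are required")
    sizes = []
    for _fold, train_ids, _val_ids in split.cv_folds():
        sizes.append(len(train_ids))
    sizes = np.asarray(sizes, dtype=float)
    if sizes.sum() <= 0:
        raise ValueError("cannot normalise ensemble weights")
    return EnsembleModel(fold_models=list(fold_models),
                         weights=sizes / sizes.sum())
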