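"""Nonparametric ROC machinery: AUC, DeLong, Venkatraman-Begg, thresholds.

All operating points use the "score >= threshold -> positive" convention,
consistently in ROC construction and in final classification.  The AUC is
the trapezoidal integral of the empirical curve, which equals the
Mann-Whitney pair-counting statistic with ties counted 1/2.

Two paired-comparison procedures are provided, dispatched on whether the
two ROC curves cross: the DeLong test compares areas when one curve
uniformly dominates; the Venkatraman-Begg permutation test compares the
whole curve shapes and remains valid when the curves cross.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps


# ---------------------------------------------------------------------------
# empirical ROC


@dataclass
class RocCurve:
    """Operating points (FPR, TPR) at every distinct score cutpoint."""

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float


def _check_binary(labels):
    labels = np.asarray(labels).astype(int)
    if set(np.unique(labels)) - {0, 1}:
        raise ValueError("labels must be 0/1")
    if labels.min() == labels.max():
        raise ValueError("both classes must be present")
    return labels


def empirical_roc(scores, labels) -> RocCurve:
    """Nonparametric ROC with cutpoints at the observed scores.

    For each distinct score t (descending), positives are predictions with
    score >= t.  The curve starts at (0,0) (t = +inf) and ends at (1,1).
    """
    scores = np.asarray(scores, dtype=float)
    labels = _check_binary(labels)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    order = np.argsort(-scores, kind="mergesort")
    s, y = scores[order], labels[order]
    distinct = np.r_[np.diff(s) != 0, True]
    tps = np.cumsum(y)[distinct]
    fps = np.cumsum(1 - y)[distinct]
    tpr = np.r_[0.0, tps / n_pos]
    fpr = np.r_[0.0, fps / n_neg]
    thresholds = np.r_[np.inf, s[distinct]]
    auc = float(np.trapezoid(tpr, fpr))
    return RocCurve(fpr=fpr, tpr=tpr, thresholds=thresholds, auc=auc)


def mann_whitney_auc(scores, labels) -> float:
    """Pair-counting AUC (ties counted 1/2); oracle-equivalent to trapezoid."""
    scores = np.asarray(scores, dtype=float)
    labels = _check_binary(labels)
    pos = scores[labels == 1][:, None]
    neg = scores[labels == 0][None, :]
    return float((pos > neg).mean() + 0.5 * (pos == neg).mean())


# ---------------------------------------------------------------------------
# DeLong variance machinery


@dataclass
class DelongResult:
    auc: float
    variance: float
    ci_low: float = np.nan
    ci_high: float = np.nan
    z: float = np.nan
    p_value: float = np.nan
    auc_b: float = np.nan
    truncated: bool = False


def _midrank(x):
    """Midranks as used by the DeLong structural components."""
    return sps.rankdata(x, method="average")


def _delong_components(scores, labels):
    """Placement values V10 (per positive) and V01 (per negative)."""
    scores = np.asarray(scores, dtype=float)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = len(pos), len(neg)
    tx = _midrank(pos)
    ty = _midrank(neg)
    tz = _midrank(np.r_[pos, neg])
    auc = (tz[:m].sum() / (m * n)) - (m + 1.0) / (2.0 * n)
    v10 = (tz[:m] - tx) / n
    v01 = 1.0 - (tz[m:] - ty) / m
    return float(auc), v10, v01


def delong_ci(scores, labels, level: float = 0.95) -> DelongResult:
    """AUC with DeLong variance and a normal CI truncated to [0, 1]."""
    labels = _check_binary(labels)
    auc, v10, v01 = _delong_components(scores, labels)
    m, n = len(v10), len(v01)
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    var = s10 / m + s01 / n
    zq = sps.norm.ppf(0.5 + level / 2.0)
    half = zq * np.sqrt(var)
    lo, hi = auc - half, auc + half
    truncated = lo < 0.0 or hi > 1.0
    if var == 0.0 and auc in (0.0, 1.0):
        warnings.warn("degenerate DeLong variance at perfect separation; "
                      "CI truncated", RuntimeWarning, stacklevel=2)
        truncated = True
    return DelongResult(auc=auc, variance=var,
                        ci_low=max(lo, 0.0), ci_high=min(hi, 1.0),
                        truncated=truncated)


def delong_paired_test(scores_a, scores_b, labels) -> DelongResult:
    """Paired z-test of AUC_a - AUC_b using the DeLong covariance."""
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    if scores_a.shape != scores_b.shape:
        raise ValueError("paired score vectors must have equal length")
    labels = _check_binary(labels)
    auc_a, v10a, v01a = _delong_components(scores_a, labels)
    auc_b, v10b, v01b = _delong_components(scores_b, labels)
    m, n = len(v10a), len(v01a)
    s10 = np.cov(np.stack([v10a, v10b]), ddof=1) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(np.stack([v01a, v01b]), ddof=1) if n > 1 else np.zeros((2, 2))
    cov = s10 / m + s01 / n
    var_diff = cov[0, 0] + cov[1, 1] - 2.0 * cov[0, 1]
    diff = auc_a - auc_b
    if var_diff <= 0:
        if diff != 0:
            warnings.warn("zero DeLong variance with unequal AUCs",
                          RuntimeWarning, stacklevel=2)
        z = 0.0 if diff == 0 else np.sign(diff) * np.inf
        p = 1.0 if diff == 0 else 0.0
    else:
        z = diff / np.sqrt(var_diff)
        p = float(2.0 * sps.norm.sf(abs(z)))
    return DelongResult(auc=auc_a, auc_b=auc_b,
                        variance=var_diff, z=float(z), p_value=p)


# ---------------------------------------------------------------------------
# curve crossing and the Venkatraman-Begg shape test


def _tpr_at(curve: RocCurve, fpr_grid):
    """Upper envelope of the ROC step function at the given FPR values."""
    out = np.empty(len(fpr_grid))
    for i, f in enumerate(fpr_grid):
        out[i] = curve.tpr[curve.fpr <= f + 1e-12].max()
    return out


def curves_cross(curve_a: RocCurve, curve_b: RocCurve,
                 tol: float = 1e-9) -> bool:
    """True iff TPR_a - TPR_b changes sign on the union grid of FPR values."""
    grid = np.unique(np.r_[curve_a.fpr, curve_b.fpr])
    diff = _tpr_at(curve_a, grid) - _tpr_at(curve_b, grid)
    return bool((diff > tol).any() and (diff < -tol).any())


@dataclass
class VenkatramanResult:
    e_stat: float
    p_value: float
    n_permutations: int
    seed: int
    e_null: np.ndarray = field(default=None, repr=False)


def _vb_errors(ranks, labels, n):
    """Classification-error count at each rank cutpoint k = 1..n-1.

    At cutpoint k the subjects with rank > k are called positive; the error
    is (positives with rank <= k) + (negatives with rank > k).
    """
    # cumulative positives/negatives ordered by rank
    order = np.argsort(ranks)
    y = labels[order]
    cum_pos = np.cumsum(y)
    cum_neg = np.cumsum(1 - y)
    total_neg = cum_neg[-1]
    k = np.arange(1, n)
    return cum_pos[:-1] + (total_neg - cum_neg[:-1])


def _vb_estat(x, y, labels, rng, jitter_scale):
    n = len(labels)
    # tie-breaking jitter smaller than the minimal score gap, then ranks
    xj = x + rng.uniform(-jitter_scale, jitter_scale, n)
    yj = y + rng.uniform(-jitter_scale, jitter_scale, n)
    rx = sps.rankdata(xj, method="ordinal")
    ry = sps.rankdata(yj, method="ordinal")
    ex = _vb_errors(rx, labels, n)
    ey = _vb_errors(ry, labels, n)
    return float(np.abs(ex - ey).sum())


def _min_gap(v):
    u = np.unique(v)
    return float(np.diff(u).min()) if len(u) > 1 else 1.0


def venkatraman_begg_test(scores_a, scores_b, labels,
                          n_permutations: int = 2000,
                          seed: int = 0) -> VenkatramanResult:
    """Permutation test comparing the shapes of two paired ROC curves.

    The statistic E sums, over all rank cutpoints, the absolute difference
    in classification errors between the two modalities.  The null
    distribution exchanges the two modalities' values within each subject
    with probability 1/2 per subject; tie-breaking jitter is redrawn and
    ranks recomputed on every permutation.  The p-value is the fraction of
    permuted E at or above the observed E.
    """
    x = np.asarray(scores_a, dtype=float)
    y = np.asarray(scores_b, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired score vectors must have equal length")
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    labels = _check_binary(labels)
    n = len(labels)
    rng = np.random.default_rng(seed)
    jitter = 0.49 * min(_min_gap(x), _min_gap(y))
    e_obs = _vb_estat(x, y, labels, rng, jitter)
    e_null = np.empty(n_permutations)
    for b in range(n_permutations):
        swap = rng.random(n) < 0.5
        xp = np.where(swap, y, x)
        yp = np.where(swap, x, y)
        e_null[b] = _vb_estat(xp, yp, labels, rng, jitter)
    p = float((e_null >= e_obs - 1e-12).mean())
    return VenkatramanResult(e_stat=e_obs, p_value=p,
                             n_permutations=n_permutations, seed=seed,
                             e_null=e_null)


def compare_scores(scores_a, scores_b, labels, n_permutations: int = 2000,
                   seed: int = 0) -> dict:
    """Crossing-dispatched paired comparison of two scoring rules.

    Uses the DeLong area test when one empirical ROC curve uniformly
    dominates the other, and the Venkatraman-Begg shape test when the
    curves cross.
    """
    curve_a = empirical_roc(scores_a, labels)
    curve_b = empirical_roc(scores_b, labels)
    crossed = curves_cross(curve_a, curve_b)
    out = {"auc_a": curve_a.auc, "auc_b": curve_b.auc,
           "curves_cross": crossed}
    if crossed:
        vb = venkatraman_begg_test(scores_a, scores_b, labels,
                                   n_permutations=n_permutations, seed=seed)
        out.update({"test": "venkatraman_begg", "e_stat": vb.e_stat,
                    "p_value": vb.p_value,
                    "n_permutations": vb.n_permutations, "seed": seed})
    else:
        dl = delong_paired_test(scores_a, scores_b, labels)
        out.update({"test": "delong", "z": dl.z, "p_value": dl.p_value})
    return out


# ---------------------------------------------------------------------------
# decision thresholds


@dataclass
class ThresholdResult:
    threshold: float
    rule: str
    sensitivity: float
    specificity: float
    youden_j: float


def _operating_points(scores, labels):
    """Sens/spec for thresholding at every distinct observed score."""
    scores = np.asarray(scores, dtype=float)
    labels = _check_binary(labels)
    cand = np.unique(scores)
    sens = np.array([(scores[labels == 1] >= t).mean() for t in cand])
    spec = np.array([(scores[labels == 0] < t).mean() for t in cand])
    return cand, sens, spec


def youden_threshold(scores, labels) -> ThresholdResult:
    """Observed-score threshold maximising J = sens + spec - 1.

    Ties break toward the lower threshold, i.e. higher sensitivity — the
    appropriate direction when false negatives carry the greater cost.
    """
    cand, sens, spec = _operating_points(scores, labels)
    j = sens + spec - 1.0
    # ties (within float noise) break toward the lowest threshold
    best = int(np.flatnonzero(j >= j.max() - 1e-12)[0])
    return ThresholdResult(threshold=float(cand[best]), rule="youden",
                           sensitivity=float(sens[best]),
                           specificity=float(spec[best]),
                           youden_j=float(j[best]))


def constrained_threshold(scores, labels,
                          min_sens: float = 0.95) -> ThresholdResult:
    """Max-specificity threshold among those with sensitivity >= min_sens."""
    cand, sens, spec = _operating_points(scores, labels)
    ok = sens >= min_sens
    if not ok.any():
        warnings.warn("no threshold reaches the sensitivity floor; "
                      "falling back to the minimal observed score",
                      RuntimeWarning, stacklevel=2)
        best = 0
    else:
        idx = np.flatnonzero(ok)
        smax = spec[idx].max()
        best = int(idx[np.flatnonzero(spec[idx] >= smax - 1e-12)[0]])
    j = sens[best] + spec[best] - 1.0
    return ThresholdResult(threshold=float(cand[best]), rule="min_sensitivity",
                           sensitivity=float(sens[best]),
                           specificity=float(spec[best]), youden_j=float(j))


def average_thresholds(thresholds) -> float:
    """Arithmetic mean of the four fold thresholds."""
    t = np.asarray(thresholds, dtype=float)
    if len(t) != 4:
        raise ValueError("expected exactly four fold thresholds")
    return float(t.mean())


def classify(prob, threshold: float) -> np.ndarray:
    """1 (malignant) where probability >= threshold, else 0."""
    return (np.asarray(prob, dtype=float) >= threshold).astype(int)


def read_scores_csv(path, score_column: str = "score",
                    label_column: str = "label"):
    """Read a score/label table (CSV) into arrays for the tests above."""
    import pandas as pd
    df = pd.read_csv(path)
    for col in (score_column, label_column):
        if col not in df.columns:
            raise ValueError(f"score table missing column {col!r}")
    return df[score_column].to_numpy(float), df[label_column].to_numpy(int)


def write_roc_csv(curve: RocCurve, path) -> None:
    """Write ROC operating points (threshold, FPR, TPR) as CSV."""
    import pandas as pd
    pd.DataFrame({"threshold": curve.thresholds, "fpr": curve.fpr,
                  "tpr": curve.tpr}).to_csv(path, index=False)


def confusion_metrics(preds, labels) -> dict:
    """Sensitivity, specificity, accuracy from aligned 0/1 arrays."""
    preds = np.asarray(preds).astype(int)
    labels = np.asarray(labels).astype(int)
    if preds.shape != labels.shape:
        raise ValueError("preds and labels must align")
    tp = int(((preds == 1) & (labels == 1)).sum())
    tn = int(((preds == 0) & (labels == 0)).sum())
    fp = int(((preds == 1) & (labels == 0)).sum())
    fn = int(((preds == 0) & (labels == 1)).sum())
    sens = tp / (tp + fn) if tp + fn else np.nan
    spec = tn / (tn + fp) if tn + fp else np.nan
    acc = (tp + tn) / len(labels)
    return {"sensitivity": sens, "specificity": spec, "accuracy": acc,
            "tp": tp, "fp": fp, "tn": tn, "fn": fn}
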