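"""Evaluation metrics and statistical tests.

Covers the confusion-matrix metrics (MCC with a documented
zero-denominator convention, accuracy, precision), the dual-threshold
selective-prediction analysis, Welch's two-sample t-test, a permutation
energy-distance two-sample test, and Pearson correlation.

Undefined metric values (empty denominator, zero retention, zero
variance) are flagged as ``nan`` rather than raising.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist
from scipy.stats import pearsonr, ttest_ind

from .exceptions import ParameterError

__all__ = [
    "ConfusionCounts",
    "DualThresholdRow",
    "ComparisonReport",
    "confusion",
    "mcc",
    "accuracy",
    "precision",
    "dual_threshold",
    "default_threshold_pairs",
    "two_sample_ttest",
    "energy_distance_test",
    "pearson_r",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ParameterError("confusion counts must be nonnegative")
        if self.total < 1:
            raise ParameterError("confusion counts must sum to >= 1")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def confusion(pred_labels, true_labels) -> ConfusionCounts:
    pred = np.asarray(pred_labels)
    true = np.asarray(true_labels)
    if pred.shape != true.shape or pred.ndim != 1:
        raise ParameterError("prediction and truth vectors must be equal-length 1D")
    if pred.size < 1:
        raise ParameterError("need at least one sample")
    for v in (pred, true):
        if not np.isin(v, (0, 1)).all():
            raise ParameterError("labels must be binary (0/1)")
    return ConfusionCounts(
        tp=int(np.sum((pred == 1) & (true == 1))),
        fp=int(np.sum((pred == 1) & (true == 0))),
        tn=int(np.sum((pred == 0) & (true == 0))),
        fn=int(np.sum((pred == 0) & (true == 1))),
    )


def mcc(c: ConfusionCounts) -> float:
    """Matthews correlation coefficient.

    Convention: if any marginal factor of the denominator is zero the
    expression is 0/0 and we return 0.0.
    """
    tp, fp, tn, fn = float(c.tp), float(c.fp), float(c.tn), float(c.fn)
    denom2 = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom2 == 0.0:
        return 0.0
    return (tp * tn - fp * fn) / math.sqrt(denom2)


def accuracy(c: ConfusionCounts) -> float:
    return (c.tp + c.tn) / c.total


def precision(c: ConfusionCounts) -> float:
    """TP / (TP + FP); ``nan`` when no positive predictions were made."""
    if c.tp + c.fp == 0:
        return float("nan")
    return c.tp / (c.tp + c.fp)


@dataclass(frozen=True)
class DualThresholdRow:
    lower: float
    upper: float
    retained_fraction: float
    mcc: float  # nan when no samples retained
    n_retained: int


def default_threshold_pairs() -> list[tuple[float, float]]:
    """Symmetric pairs (t, 1-t), t = 0.50, 0.45, ..., 0.05."""
    return [(round(t, 2), round(1 - t, 2)) for t in np.arange(0.50, 0.049, -0.05)]


def dual_threshold(probabilities, true_labels=None,
                   threshold_pairs=None) -> list[DualThresholdRow]:
    """Selective prediction: classify p >= upper as 1, p <= lower as 0.

    Intermediate-confidence samples are dropped; MCC is computed on the
    retained samples only and the retained fraction recorded. The first
    argument may be a PredictionSet-like object (with ``probabilities``
    and ``labels`` attributes) instead of a probability vector.
    """
    if true_labels is None and hasattr(probabilities, "probabilities"):
        true_labels = probabilities.labels
        probabilities = probabilities.probabilities
    probs = np.asarray(probabilities, dtype=float)
    labels = np.asarray(true_labels)
    if probs.shape != labels.shape or probs.ndim != 1:
        raise ParameterError("probabilities and labels must be equal-length 1D")
    if probs.size < 1:
        raise ParameterError("need at least one sample")
    if threshold_pairs is None:
        threshold_pairs = default_threshold_pairs()
    rows = []
    for lower, upper in threshold_pairs:
        if lower > upper:
            raise ParameterError(f"lower threshold {lower} exceeds upper {upper}")
        keep_lo = probs <= lower
        keep_hi = probs >= upper
        keep = keep_lo | keep_hi
        n_kept = int(keep.sum())
        if n_kept == 0:
            rows.append(DualThresholdRow(lower, upper, 0.0, float("nan"), 0))
            continue
        pred = keep_hi[keep].astype(int)
        rows.append(DualThresholdRow(
            lower, upper, n_kept / probs.size,
            mcc(confusion(pred, labels[keep])), n_kept))
    return rows


@dataclass
class ComparisonReport:
    """Two-condition metric comparison via Welch's t-test."""

    samples_a: list[float]
    samples_b: list[float]
    mean_a: float = field(init=False)
    sd_a: float = field(init=False)
    mean_b: float = field(init=False)
    sd_b: float = field(init=False)
    t_statistic: float = field(init=False)
    p_value: float = field(init=False)

    def __post_init__(self):
        a = np.asarray(self.samples_a, dtype=float)
        b = np.asarray(self.samples_b, dtype=float)
        if a.size < 2 or b.size < 2:
            raise ParameterError("need >= 2 samples per group")
        self.mean_a = float(a.mean())
        self.sd_a = float(a.std(ddof=1))
        self.mean_b = float(b.mean())
        self.sd_b = float(b.std(ddof=1))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            t, p = ttest_ind(a, b, equal_var=False)
        if np.isnan(t):  # both groups constant with equal means: no evidence
            t, p = 0.0, 1.0
        elif np.isinf(t):  # zero variance, different means: maximal evidence
            p = 0.0
        self.t_statistic = float(t)
        self.p_value = float(p)


def two_sample_ttest(samples_a, samples_b) -> ComparisonReport:
    """Welch two-sample t-test (two-sided)."""
    return ComparisonReport(list(map(float, samples_a)), list(map(float, samples_b)))


def _energy_statistic(d_xy: np.ndarray, d_xx: np.ndarray, d_yy: np.ndarray) -> float:
    return float(2.0 * d_xy.mean() - d_xx.mean() - d_yy.mean())


def energy_distance_test(x_samples, y_samples, n_permutations: int = 999,
                         seed: int = 0) -> tuple[float, float]:
    """Permutation energy-distance two-sample test.

    E = 2 E||X-Y|| - E||X-X'|| - E||Y-Y'|| (V-statistic form); the
    p-value uses the add-one permutation estimator
    p = (1 + #{E_perm >= E_obs}) / (1 + n_permutations).
    """
    x = np.atleast_2d(np.asarray(x_samples, dtype=float))
    y = np.atleast_2d(np.asarray(y_samples, dtype=float))
    if x.ndim == 2 and np.asarray(x_samples).ndim == 1:
        x = x.T
        y = y.T
    if x.shape[1] != y.shape[1]:
        raise ParameterError("sample vectors must have matching length")
    nx, ny = x.shape[0], y.shape[0]
    if nx < 2 or ny < 2:
        raise ParameterError("need >= 2 samples per group")
    pooled = np.vstack([x, y])
    dmat = cdist(pooled, pooled)
    idx_x = np.arange(nx)
    idx_y = np.arange(nx, nx + ny)
    observed = _energy_statistic(dmat[np.ix_(idx_x, idx_y)],
                                 dmat[np.ix_(idx_x, idx_x)],
                                 dmat[np.ix_(idx_y, idx_y)])
    rng = np.random.default_rng(seed)
    n_extreme = 0
    all_idx = np.arange(nx + ny)
    for _ in range(n_permutations):
        perm = rng.permutation(all_idx)
        px, py = perm[:nx], perm[nx:]
        stat = _energy_statistic(dmat[np.ix_(px, py)],
                                 dmat[np.ix_(px, px)],
                                 dmat[np.ix_(py, py)])
        if stat >= observed:
            n_extreme += 1
    p = (1 + n_extreme) / (1 + n_permutations)
    return observed, p


def pearson_r(x, y) -> tuple[float, float]:
    """Product-moment correlation with two-sided p; nan on zero variance."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ParameterError("need >= 3 paired values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan"), float("nan")
    r, p = pearsonr(x, y)
    return float(r), float(p)
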