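"""Occlusion-based attribution.

For each subject slice, a square window slides over the image on a
stride grid (with a final flush-to-border position per axis so every
pixel is covered); window content is replaced by the corresponding
pixels of a neutral reference image (the candidate whose logit is
closest to zero), and the drop in the fixed model's logit is recorded.
The per-pixel raw score is the mean drop over all windows covering that
pixel. Scores are sign-adjusted by class so positive values mark
regions supporting correct classification, thresholded per subject at
the top ``top_fraction`` quantile, and aggregated into a group
frequency map that is Gaussian-smoothed for visualization.

Models are passed as batch predictors ``f(images) -> logits`` so any
callable (trained classifier or analytic toy) can be attributed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, NamedTuple, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

from .exceptions import ParameterError

__all__ = [
    "OcclusionConfig",
    "AttributionMap",
    "FrequencyMap",
    "NeutralReference",
    "patch_starts",
    "neutral_reference",
    "occlusion_scores",
    "sign_adjust",
    "subject_threshold",
    "frequency_map",
    "slice_occlusion_summary",
    "attribute_dataset",
]

Predictor = Callable[[np.ndarray], np.ndarray]


@dataclass(frozen=True)
class OcclusionConfig:
    window: int = 15
    stride: int = 5
    top_fraction: float = 0.05

    def __post_init__(self):
        if not self.window >= self.stride >= 1:
            raise ParameterError("require window >= stride >= 1")
        if not 0.0 < self.top_fraction < 1.0:
            raise ParameterError("top_fraction must be in (0, 1)")


@dataclass
class AttributionMap:
    raw: np.ndarray
    adjusted: np.ndarray
    tau: float
    indicator: np.ndarray
    subject_id: str
    label: int


@dataclass
class FrequencyMap:
    values: np.ndarray
    n_subjects: int
    smoothed: np.ndarray
    smoothing_sigma: float


class NeutralReference(NamedTuple):
    index: int
    image: np.ndarray
    logit: float


def patch_starts(extent: int, window: int, stride: int) -> list[int]:
    """Window start offsets along one axis, plus a flush-to-border final one."""
    if extent < window:
        raise ParameterError(f"extent {extent} smaller than window {window}")
    starts = list(range(0, extent - window + 1, stride))
    if starts[-1] != extent - window:
        starts.append(extent - window)
    return starts


def neutral_reference(predict_fn: Predictor, candidates: np.ndarray) -> NeutralReference:
    """Candidate whose predicted logit is closest to zero (ties: lowest index)."""
    candidates = np.asarray(candidates)
    if len(candidates) == 0:
        raise ParameterError("candidate pool is empty")
    logits = np.asarray(predict_fn(candidates), dtype=float)
    idx = int(np.argmin(np.abs(logits)))
    return NeutralReference(index=idx, image=candidates[idx], logit=float(logits[idx]))


def occlusion_scores(predict_fn: Predictor, image: np.ndarray, neutral: np.ndarray,
                     cfg: OcclusionConfig | None = None,
                     batch_size: int = 128) -> np.ndarray:
    """Raw per-pixel occlusion score grid for one image.

    score(i, j) = mean over covering windows p of f(x) - f(x with window p
    replaced by the neutral image content).
    """
    cfg = cfg or OcclusionConfig()
    image = np.asarray(image, dtype=np.float32)
    neutral = np.asarray(neutral, dtype=np.float32)
    if image.shape != neutral.shape or image.ndim != 2:
        raise ParameterError("image and neutral must be equal-shape 2D arrays")
    h, w = image.shape
    rows = patch_starts(h, cfg.window, cfg.stride)
    cols = patch_starts(w, cfg.window, cfg.stride)
    positions = [(r, c) for r in rows for c in cols]

    occluded = np.repeat(image[None], len(positions), axis=0)
    for k, (r, c) in enumerate(positions):
        occluded[k, r:r + cfg.window, c:c + cfg.window] = \
            neutral[r:r + cfg.window, c:c + cfg.window]

    f_orig = float(np.asarray(predict_fn(image[None]), dtype=float)[0])
    logits = np.empty(len(positions), dtype=float)
    for start in range(0, len(positions), batch_size):
        logits[start:start + batch_size] = np.asarray(
            predict_fn(occluded[start:start + batch_size]), dtype=float)

    drop_sum = np.zeros((h, w), dtype=np.float64)
    cover = np.zeros((h, w), dtype=np.int64)
    for (r, c), logit in zip(positions, logits):
        drop_sum[r:r + cfg.window, c:c + cfg.window] += f_orig - logit
        cover[r:r + cfg.window, c:c + cfg.window] += 1
    return drop_sum / cover


def sign_adjust(raw: np.ndarray, label: int) -> np.ndarray:
    """Identity for the positive class, negation for the negative class."""
    if label not in (0, 1):
        raise ParameterError("label must be binary")
    raw = np.asarray(raw)
    return raw.copy() if label == 1 else -raw


def subject_threshold(adjusted: np.ndarray,
                      top_fraction: float = 0.05) -> tuple[float, np.ndarray]:
    """Quantile threshold tau and the indicator grid ``adjusted >= tau``.

    Ties at tau are all retained, so at least ceil(top_fraction * P)
    pixels are always set.
    """
    adjusted = np.asarray(adjusted)
    if adjusted.size == 0:
        raise ParameterError("empty attribution grid")
    tau = float(np.percentile(adjusted, 100.0 * (1.0 - top_fraction)))
    return tau, (adjusted >= tau)


def frequency_map(indicators: Sequence[np.ndarray], sigma: float = 1.0) -> FrequencyMap:
    """Mean of subject indicator grids, plus a Gaussian-smoothed copy.

    Thresholding happens before smoothing; smoothing uses reflective
    boundaries and is for visualization/peak-finding only.
    """
    indicators = [np.asarray(g) for g in indicators]
    if not indicators:
        raise ParameterError("need at least one indicator grid")
    shape = indicators[0].shape
    if any(g.shape != shape for g in indicators):
        raise ParameterError("indicator grids must share one shape")
    values = np.mean([g.astype(float) for g in indicators], axis=0)
    smoothed = gaussian_filter(values, sigma=sigma, mode="reflect")
    return FrequencyMap(values=values, n_subjects=len(indicators),
                        smoothed=smoothed, smoothing_sigma=sigma)


def slice_occlusion_summary(adjusted_grids: Sequence[np.ndarray]) -> float:
    """Mean over subjects of the per-subject maximum sign-adjusted score."""
    grids = [np.asarray(g) for g in adjusted_grids]
    if not grids:
        raise ParameterError("need at least one grid")
    return float(np.mean([g.max() for g in grids]))


def attribute_dataset(predict_fn: Predictor, images: np.ndarray, labels, subject_ids,
                      cfg: OcclusionConfig | None = None,
                      sigma: float = 1.0) -> tuple[list[AttributionMap], FrequencyMap]:
    """Full attribution pass over a test split.

    The neutral reference is chosen from the same image pool; one map per
    scan is produced, then summarized into a frequency map.
    """
    cfg = cfg or OcclusionConfig()
    images = np.asarray(images, dtype=np.float32)
    labels = np.asarray(labels)
    neutral = neutral_reference(predict_fn, images)
    maps = []
    for img, label, sid in zip(images, labels, subject_ids):
        raw = occlusion_scores(predict_fn, img, neutral.image, cfg)
        adjusted = sign_adjust(raw, int(label))
        tau, indicator = subject_threshold(adjusted, cfg.top_fraction)
        maps.append(AttributionMap(raw=raw, adjusted=adjusted, tau=tau,
                                   indicator=indicator, subject_id=sid, label=int(label)))
    fmap = frequency_map([m.indicator for m in maps], sigma=sigma)
    return maps, fmap
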