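"""Volume I/O, plane-wise slicing, slice sampling, and subject-level splits.

Volumes are plain 3D numpy arrays wrapped in :class:`LabeledVolume`.
Anatomical planes map onto array axes as:

========  ====  =========================
plane     axis  orientation
========  ====  =========================
sagittal  0     left-right
coronal   1     front-back
axial     2     superior-inferior
========  ====  =========================

A slice index names the fixed coordinate along the plane's axis
(0-based); the returned 2D image preserves the order of the remaining
two axes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .exceptions import ParameterError

PLANES = ("sagittal", "coronal", "axial")
PLANE_AXES = {"sagittal": 0, "coronal": 1, "axial": 2}


@dataclass
class LabeledVolume:
    """One subject-scan: 3D intensity grid + identifiers + binary label."""

    voxels: np.ndarray
    subject_id: str
    label: int
    scan_id: str = ""

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ParameterError("voxels must be a 3D array")
        if not np.all(np.isfinite(self.voxels)):
            raise ParameterError("voxel intensities must be finite")
        if self.label not in (0, 1):
            raise ParameterError("label must be 0 or 1")
        if not self.scan_id:
            self.scan_id = self.subject_id


@dataclass(frozen=True)
class SliceSpec:
    plane: str
    index: int

    def __post_init__(self):
        if self.plane not in PLANE_AXES:
            raise ParameterError(f"unknown plane {self.plane!r}")
        if self.index < 0:
            raise ParameterError("slice index must be nonnegative")

    @property
    def axis(self) -> int:
        return PLANE_AXES[self.plane]

    def image_axes(self) -> tuple[int, int]:
        """The two volume axes spanning the slice image, in order."""
        return tuple(a for a in range(3) if a != self.axis)  # type: ignore[return-value]


@dataclass(frozen=True)
class SubjectSplit:
    train_ids: frozenset[str]
    val_ids: frozenset[str]
    test_ids: frozenset[str]
    seed: int = 0

    def __post_init__(self):
        if (self.train_ids & self.val_ids or self.train_ids & self.test_ids
                or self.val_ids & self.test_ids):
            raise ParameterError("split sets must be pairwise disjoint")

    def tag_of(self, subject_id: str) -> str:
        if subject_id in self.train_ids:
            return "train"
        if subject_id in self.val_ids:
            return "val"
        if subject_id in self.test_ids:
            return "test"
        raise KeyError(subject_id)


@dataclass
class SliceDataset:
    """2D images for one (plane, slice-index), with labels and subject IDs."""

    images: np.ndarray
    labels: np.ndarray
    subject_ids: list[str]
    slice_spec: SliceSpec
    split: str = ""

    def __post_init__(self):
        self.images = np.asarray(self.images)
        self.labels = np.asarray(self.labels)
        if not (len(self.images) == len(self.labels) == len(self.subject_ids)):
            raise ParameterError("images, labels and subject_ids must have equal length")

    def __len__(self) -> int:
        return len(self.labels)


def extract_slice(volume: LabeledVolume | np.ndarray, spec: SliceSpec) -> np.ndarray:
    """Extract the 2D image at ``spec`` from a volume."""
    arr = volume.voxels if isinstance(volume, LabeledVolume) else np.asarray(volume)
    if spec.index >= arr.shape[spec.axis]:
        raise ParameterError(
            f"slice index {spec.index} out of range for axis extent {arr.shape[spec.axis]}")
    return np.take(arr, spec.index, axis=spec.axis)


def stack_slices(images: list[np.ndarray], plane: str) -> np.ndarray:
    """Inverse of slicing a whole volume along ``plane``."""
    return np.stack(images, axis=PLANE_AXES[plane])


def sample_slice_indices(axis_extent: int, target_count: int = 40,
                         dense_band: float = 0.5, density_ratio: int = 2,
                         margin: int | None = None) -> list[int]:
    """Deterministic slice-index sampling with denser coverage mid-axis.

    Indices span ``[margin, axis_extent - 1 - margin]``; within the central
    ``dense_band`` fraction of the axis the stride is ``1/density_ratio``
    of the peripheral stride. The returned count is within +-20% of
    ``target_count``.
    """
    if target_count < 3:
        raise ParameterError("target_count must be >= 3")
    if axis_extent < target_count:
        raise ParameterError("axis extent smaller than target count")
    if margin is None:
        margin = max(2, axis_extent // 20)
    usable = axis_extent - 2 * margin
    if usable < target_count:
        raise ParameterError(
            f"axis extent {axis_extent} with margin {margin} cannot host {target_count} indices")
    lo_band = axis_extent * (1 - dense_band) / 2
    hi_band = axis_extent * (1 + dense_band) / 2
    last = axis_extent - 1 - margin

    def walk(stride_c: int) -> list[int]:
        indices = []
        i = margin
        while i <= last:
            indices.append(i)
            i += stride_c if lo_band <= i < hi_band else density_ratio * stride_c
        return indices

    # pick the central stride whose resulting count lands closest to target
    best = min((walk(sc) for sc in range(1, usable + 1)),
               key=lambda idx: (abs(len(idx) - target_count), idx[0]))
    return best


def _largest_remainder(n: int, ratios: tuple[float, ...]) -> list[int]:
    raw = [n * r for r in ratios]
    base = [math.floor(v) for v in raw]
    remainder = n - sum(base)
    order = sorted(range(len(ratios)), key=lambda i: (-(raw[i] - base[i]), i))
    for i in order[:remainder]:
        base[i] += 1
    return base


def split_subjects(subject_ids, ratios: tuple[float, float, float] = (0.64, 0.16, 0.20),
                   seed: int = 0) -> SubjectSplit:
    """Leakage-safe subject-level split with largest-remainder rounding."""
    ids = sorted(set(subject_ids))
    if len(ids) < 3:
        raise ParameterError("need at least 3 subjects to split")
    if len(ratios) != 3 or any(r < 0 for r in ratios) or abs(sum(ratios) - 1.0) > 1e-9:
        raise ParameterError("ratios must be three nonnegative values summing to 1")
    sizes = _largest_remainder(len(ids), tuple(ratios))
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ids))
    shuffled = [ids[i] for i in perm]
    n_tr, n_va, _ = sizes
    return SubjectSplit(
        train_ids=frozenset(shuffled[:n_tr]),
        val_ids=frozenset(shuffled[n_tr:n_tr + n_va]),
        test_ids=frozenset(shuffled[n_tr + n_va:]),
        seed=seed,
    )


def make_slice_datasets(volumes: list[LabeledVolume], split: SubjectSplit,
                        spec: SliceSpec) -> dict[str, SliceDataset]:
    """Slice every volume at ``spec`` and partition by the subject split."""
    buckets: dict[str, list] = {"train": [], "val": [], "test": []}
    for v in volumes:
        tag = split.tag_of(v.subject_id)
        buckets[tag].append(v)
    out = {}
    for tag, vols in buckets.items():
        images = np.stack([extract_slice(v, spec) for v in vols]) if vols else \
            np.empty((0,) + _slice_shape(volumes[0].voxels.shape, spec))
        out[tag] = SliceDataset(
            images=images,
            labels=np.array([v.label for v in vols], dtype=np.int64),
            subject_ids=[v.subject_id for v in vols],
            slice_spec=spec,
            split=tag,
        )
    return out


def _slice_shape(shape: tuple[int, int, int], spec: SliceSpec) -> tuple[int, int]:
    a, b = spec.image_axes()
    return (shape[a], shape[b])


def save_cohort(volumes: list[LabeledVolume], out_dir: str | Path,
                split: SubjectSplit | None = None) -> Path:
    """Write NIfTI files plus a ``manifest.csv`` and return the manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for v in volumes:
        fname = f"{v.scan_id}.nii.gz"
        img = nib.Nifti1Image(np.asarray(v.voxels, dtype=np.float32), affine=np.eye(4))
        nib.save(img, str(out_dir / fname))
        rows.append({
            "subject_id": v.subject_id,
            "scan_id": v.scan_id,
            "label": v.label,
            "path": fname,
            "split": split.tag_of(v.subject_id) if split is not None else "",
        })
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def load_cohort(manifest_path: str | Path) -> tuple[list[LabeledVolume], SubjectSplit | None]:
    """Read a cohort back from a manifest written by :func:`save_cohort`."""
    manifest_path = Path(manifest_path)
    df = pd.read_csv(manifest_path, keep_default_na=False)
    base = manifest_path.parent
    volumes = []
    tags: dict[str, set[str]] = {"train": set(), "val": set(), "test": set()}
    for row in df.itertuples():
        data = np.asanyarray(nib.load(str(base / row.path)).dataobj, dtype=np.float32)
        volumes.append(LabeledVolume(voxels=data, subject_id=str(row.subject_id),
                                     label=int(row.label), scan_id=str(row.scan_id)))
        if getattr(row, "split", "") in tags:
            tags[row.split].add(str(row.subject_id))
    split = None
    if any(tags.values()):
        split = SubjectSplit(frozenset(tags["train"]), frozenset(tags["val"]),
                             frozenset(tags["test"]))
    return volumes, split
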