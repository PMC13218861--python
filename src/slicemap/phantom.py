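"""Synthetic class-labeled 3D cohorts and the signal-injection rule.

The phantom is a deliberately simple stand-in for a registered,
skull-stripped structural scan: a smooth ellipsoidal foreground on a
zero background, carrying per-subject low-frequency texture, optional
diffuse class-correlated structure, and white noise. Signal injection
replaces every voxel ``v`` inside a fixed box, for one class only, by an
independent Gaussian draw with mean ``mean_multiplier * v`` (default 2v)
and a fixed standard deviation (default 1); everything outside the box —
and every volume of the other class — is left bit-identical.

Injection uses its own seed stream, so injecting never perturbs cohort
generation randomness.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.ndimage import gaussian_filter

from .exceptions import DegenerateInputError, ParameterError
from .localization import RegionBox
from .volumes_io import LabeledVolume

__all__ = [
    "PhantomSpec",
    "InjectionSpec",
    "generate_cohort",
    "inject_signal",
    "normalize_intensity",
    "brain_mask",
]


@dataclass(frozen=True)
class PhantomSpec:
    volume_shape: tuple[int, int, int] = (64, 64, 64)
    n_subjects: int = 200
    class_balance: float = 0.5
    diffuse_effect_size: float = 0.0
    noise_sd: float = 0.2
    seed: int = 0

    def __post_init__(self):
        if len(self.volume_shape) != 3 or any(s < 1 for s in self.volume_shape):
            raise ParameterError("volume_shape must be three positive integers")
        if self.n_subjects < 2:
            raise ParameterError("need at least 2 subjects (one per class)")
        if not 0.0 < self.class_balance < 1.0:
            raise ParameterError("class_balance must lie in (0, 1)")
        if self.diffuse_effect_size < 0:
            raise ParameterError("diffuse_effect_size must be nonnegative")
        if self.noise_sd <= 0:
            raise ParameterError("noise_sd must be positive")
        n_pos = round(self.n_subjects * self.class_balance)
        if n_pos < 1 or n_pos > self.n_subjects - 1:
            raise ParameterError("class balance leaves a class empty")


@dataclass(frozen=True)
class InjectionSpec:
    region: RegionBox = RegionBox.cube(25, 34)
    target_class: int = 0
    mean_multiplier: float = 2.0
    sd: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.target_class not in (0, 1):
            raise ParameterError("target_class must be binary")
        if not np.isfinite(self.mean_multiplier) or not np.isfinite(self.sd):
            raise ParameterError("mean_multiplier and sd must be finite")
        if self.sd <= 0:
            raise ParameterError("sd must be positive")


def brain_mask(volume_shape: tuple[int, int, int],
               radius_fraction: float = 0.42) -> np.ndarray:
    """Ellipsoidal foreground mask shared by every phantom subject."""
    grids = np.ogrid[tuple(slice(0, s) for s in volume_shape)]
    centers = [(s - 1) / 2 for s in volume_shape]
    radii = [radius_fraction * s for s in volume_shape]
    dist2 = sum(((g - c) / r) ** 2 for g, c, r in zip(grids, centers, radii))
    return dist2 <= 1.0


def generate_cohort(spec: PhantomSpec) -> list[LabeledVolume]:
    """Generate ``n_subjects`` labeled phantom volumes, deterministically.

    Class 1 foreground intensity is shifted by a fixed smooth spatial
    pattern scaled so the shift equals ``diffuse_effect_size`` noise
    standard deviations (RMS over the foreground). With effect size 0 the
    two classes are drawn from one distribution.
    """
    rng = np.random.default_rng(spec.seed)
    shape = spec.volume_shape
    mask = brain_mask(shape)
    sigma_lo = max(1.0, min(shape) / 8)

    # fixed class-contrast pattern, unit RMS over the foreground
    pattern = gaussian_filter(rng.standard_normal(shape), sigma=sigma_lo)
    pattern /= np.sqrt(np.mean(pattern[mask] ** 2))

    n_pos = round(spec.n_subjects * spec.class_balance)
    labels = np.array([1] * n_pos + [0] * (spec.n_subjects - n_pos))
    rng.shuffle(labels)

    volumes = []
    for i, label in enumerate(labels):
        texture = gaussian_filter(rng.standard_normal(shape), sigma=sigma_lo / 2)
        texture /= np.sqrt(np.mean(texture[mask] ** 2))
        vox = (1.0
               + 0.1 * texture
               + label * spec.diffuse_effect_size * spec.noise_sd * pattern
               + rng.normal(0.0, spec.noise_sd, size=shape))
        vox = np.where(mask, vox, 0.0).astype(np.float32)
        volumes.append(LabeledVolume(voxels=vox, subject_id=f"sub-{i:04d}",
                                     label=int(label), scan_id=f"scan-{i:04d}"))
    return volumes


def inject_signal(volumes: list[LabeledVolume],
                  injection: InjectionSpec) -> list[LabeledVolume]:
    """Apply the cube-replacement rule to target-class volumes.

    Draws are independent per voxel and per subject. Non-target volumes
    are passed through untouched; target volumes are copied, with voxels
    outside the region bit-identical to the input.
    """
    if not volumes:
        return []
    shape = volumes[0].voxels.shape
    if not injection.region.within(shape):
        raise ParameterError(
            f"injection region {injection.region} outside volume shape {shape}")
    rng = np.random.default_rng(injection.seed)
    out = []
    for v in volumes:
        if v.label != injection.target_class:
            out.append(v)
            continue
        vox = v.voxels.copy()
        sl = injection.region.slices
        original = vox[sl]
        vox[sl] = rng.normal(injection.mean_multiplier * original,
                             injection.sd).astype(vox.dtype)
        out.append(replace(v, voxels=vox))
    return out


def normalize_intensity(volume: LabeledVolume | np.ndarray):
    """Z-score nonzero voxels (foreground) to mean 0, sd 1; keep zeros.

    Idempotent up to floating error. Raises for all-zero or
    constant-foreground input.
    """
    arr = volume.voxels if isinstance(volume, LabeledVolume) else np.asarray(volume)
    fg = arr != 0
    if not fg.any():
        raise DegenerateInputError("volume has no nonzero voxels")
    vals = arr[fg].astype(np.float64)
    sd = vals.std()
    if sd == 0:
        raise DegenerateInputError("constant nonzero foreground (sd = 0)")
    out = arr.astype(np.float64, copy=True)
    out[fg] = (vals - vals.mean()) / sd
    out = out.astype(np.float32)
    if isinstance(volume, LabeledVolume):
        return replace(volume, voxels=out)
    return out
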