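"""Shared fixtures.

The heavyweight 200-subject phantom cohorts are session-scoped so the
acceptance tests can share them; everything else is generated per test
at small scale.
"""

from __future__ import annotations

import numpy as np
import pytest

from slicemap.localization import RegionBox
from slicemap.models import TrainConfig
from slicemap.phantom import InjectionSpec, PhantomSpec, generate_cohort, \
    inject_signal, normalize_intensity
from slicemap.volumes_io import split_subjects

# desk-scale training configuration used throughout the suite: the tiny
# cohorts need a larger learning rate / far fewer epochs than the
# paper-scale defaults to converge within the CI budget
FAST_TRAIN = dict(lr=1e-3, max_epochs=12, scheduler_step=None, batch_size=32)

INJECTION_CUBE = RegionBox.cube(25, 34)


def fast_cfg(seed: int = 0, **overrides) -> TrainConfig:
    return TrainConfig(**{**FAST_TRAIN, **overrides, "seed": seed})


@pytest.fixture(scope="session")
def phantom200():
    """Original-condition cohort, intensity-normalized."""
    spec = PhantomSpec(volume_shape=(64, 64, 64), n_subjects=200,
                       class_balance=0.5, diffuse_effect_size=0.0,
                       noise_sd=0.2, seed=7)
    return [normalize_intensity(v) for v in generate_cohort(spec)]


@pytest.fixture(scope="session")
def phantom200_injected(phantom200):
    """Normalized cohort with the Gaussian cube replacement applied to
    class 0 (injection into the already-normalized data, so the signal
    stays confined to the cube)."""
    return inject_signal(phantom200, InjectionSpec(
        region=INJECTION_CUBE, target_class=0, mean_multiplier=2.0, sd=1.0, seed=8))


@pytest.fixture(scope="session")
def split200(phantom200):
    return split_subjects([v.subject_id for v in phantom200], seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_blob_dataset(n: int, side: int, effect: float, seed: int,
                      label_seed: int | None = None):
    """Linearly separable synthetic slices: one Gaussian blob per class,
    shifted apart by ``effect`` standard deviations."""
    gen = np.random.default_rng(seed)
    labels = np.array([0, 1] * (n // 2) + [0] * (n % 2))
    gen.shuffle(labels)
    yy, xx = np.mgrid[0:side, 0:side]
    images = np.empty((n, side, side), dtype=np.float32)
    for i, lab in enumerate(labels):
        cx = side / 2 + (effect if lab else -effect)
        blob = np.exp(-(((xx - cx) ** 2 + (yy - side / 2) ** 2) / (2 * (side / 6) ** 2)))
        images[i] = blob + gen.normal(0, 0.3, size=(side, side))
    ids = [f"s{i:03d}" for i in range(n)]
    return images, labels, ids


def split_arrays(images, labels, ids, n_train, n_val):
    tr = (images[:n_train], labels[:n_train], ids[:n_train])
    va = (images[n_train:n_train + n_val], labels[n_train:n_train + n_val],
          ids[n_train:n_train + n_val])
    te = (images[n_train + n_val:], labels[n_train + n_val:], ids[n_train + n_val:])
    return tr, va, te
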