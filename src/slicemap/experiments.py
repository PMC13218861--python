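"""End-to-end studies: slice sweep, signal-injection simulation,
permutation null, dual-threshold comparison, fusion, and the
MCC-vs-attribution correlation.

All functions operate on an in-memory cohort (``list[LabeledVolume]``)
plus a :class:`~slicemap.volumes_io.SubjectSplit`; the CLI layer handles
file I/O. Defaults are desk-scale (small repeat counts); paper-scale
settings are plain arguments.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .attribution import OcclusionConfig, attribute_dataset, slice_occlusion_summary
from .exceptions import ParameterError
from .localization import SliceSweepResult
from .metrics import ComparisonReport, dual_threshold, energy_distance_test, \
    pearson_r, two_sample_ttest
from .models import PredictionSet, TrainConfig, build_cnn2d, build_fusion, train_model
from .phantom import InjectionSpec, inject_signal
from .volumes_io import PLANES, PLANE_AXES, LabeledVolume, SliceSpec, SubjectSplit, \
    make_slice_datasets, sample_slice_indices

__all__ = [
    "SimulationReport",
    "PermutationStudyResult",
    "FusionStudyResult",
    "train_slice_model",
    "run_slice_sweep",
    "run_simulation_study",
    "run_permutation_study",
    "run_fusion_study",
    "run_occlusion_for_slice",
    "run_mcc_attribution_correlation",
    "permute_labels",
    "config_fingerprint",
]


def _repeat_seed(base: int, repeat: int) -> int:
    return base + 1000 * repeat


def train_slice_model(volumes: list[LabeledVolume], split: SubjectSplit,
                      spec: SliceSpec, cfg: TrainConfig, model_spec=None):
    """Train one slice-specific 2D CNN; returns (model, TrainResult)."""
    data = make_slice_datasets(volumes, split, spec)
    model = build_cnn2d(spec=model_spec, input_shape=data["train"].images.shape[1:],
                        seed=cfg.seed)
    result = train_model(model, data["train"], data["val"], data["test"], cfg)
    return model, result


def run_slice_sweep(volumes: list[LabeledVolume], split: SubjectSplit,
                    cfg: TrainConfig, planes=PLANES,
                    slice_indices: dict[str, list[int]] | None = None,
                    target_count: int = 20, n_repeats: int = 3,
                    model_spec=None) -> SliceSweepResult:
    """Train (plane, slice, repeat) models and tabulate mean/sd metrics."""
    shape = volumes[0].voxels.shape
    rows = []
    for plane in planes:
        if slice_indices is not None and plane in slice_indices:
            indices = slice_indices[plane]
        else:
            indices = sample_slice_indices(shape[PLANE_AXES[plane]], target_count)
        for idx in indices:
            per_metric: dict[str, list[float]] = {"mcc": [], "accuracy": [], "precision": []}
            for r in range(n_repeats):
                rcfg = replace(cfg, seed=_repeat_seed(cfg.seed, r))
                _, result = train_slice_model(volumes, split, SliceSpec(plane, idx),
                                              rcfg, model_spec)
                for k, v in result.test_predictions.metrics().items():
                    per_metric[k].append(v)
            row = {"plane": plane, "slice_index": idx, "n_repeats": n_repeats}
            for k, vals in per_metric.items():
                row[f"{k}_mean"] = float(np.mean(vals))
                row[f"{k}_sd"] = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
            rows.append(row)
    return SliceSweepResult(pd.DataFrame(rows))


@dataclass
class SimulationReport:
    original: SliceSweepResult
    injected: SliceSweepResult
    energy_before: tuple[float, float]  # (statistic, p)
    energy_after: tuple[float, float]

    def __post_init__(self):
        a = self.original.table[["plane", "slice_index"]]
        b = self.injected.table[["plane", "slice_index"]]
        if not a.reset_index(drop=True).equals(b.reset_index(drop=True)):
            raise ParameterError("original and injected curves must cover identical slices")


def _region_class_vectors(volumes, region) -> tuple[np.ndarray, np.ndarray]:
    vecs = {0: [], 1: []}
    for v in volumes:
        vecs[v.label].append(v.voxels[region.slices].ravel())
    return np.array(vecs[0]), np.array(vecs[1])


def run_simulation_study(volumes: list[LabeledVolume], injection: InjectionSpec,
                         split: SubjectSplit, cfg: TrainConfig,
                         slice_indices: dict[str, list[int]] | None = None,
                         planes=PLANES, n_repeats: int = 3,
                         n_energy_permutations: int = 499,
                         model_spec=None) -> SimulationReport:
    """Identical slice sweeps on the original and injected cohorts, plus
    energy-distance tests on region voxels before/after injection."""
    shape = volumes[0].voxels.shape
    if slice_indices is None:
        # span the injected region plus flanks on each plane
        slice_indices = {}
        for plane in planes:
            axis = PLANE_AXES[plane]
            lo, hi = injection.region.ranges[axis]
            flank = (hi - lo + 1)
            indices = range(max(0, lo - flank), min(shape[axis], hi + flank + 1), 3)
            slice_indices[plane] = list(indices)
    injected = inject_signal(volumes, injection)
    x0_before, x1_before = _region_class_vectors(volumes, injection.region)
    x0_after, x1_after = _region_class_vectors(injected, injection.region)
    energy_before = energy_distance_test(x0_before, x1_before,
                                         n_permutations=n_energy_permutations,
                                         seed=cfg.seed)
    energy_after = energy_distance_test(x0_after, x1_after,
                                        n_permutations=n_energy_permutations,
                                        seed=cfg.seed)
    sweep_orig = run_slice_sweep(volumes, split, cfg, planes=planes,
                                 slice_indices=slice_indices, n_repeats=n_repeats,
                                 model_spec=model_spec)
    sweep_inj = run_slice_sweep(injected, split, cfg, planes=planes,
                                slice_indices=slice_indices, n_repeats=n_repeats,
                                model_spec=model_spec)
    return SimulationReport(original=sweep_orig, injected=sweep_inj,
                            energy_before=energy_before, energy_after=energy_after)


def permute_labels(volumes: list[LabeledVolume], seed: int) -> list[LabeledVolume]:
    """Shuffle labels at the subject level; scans of a subject stay consistent."""
    subject_labels: dict[str, int] = {}
    for v in volumes:
        subject_labels.setdefault(v.subject_id, v.label)
    subjects = sorted(subject_labels)
    labels = np.array([subject_labels[s] for s in subjects])
    rng = np.random.default_rng(seed)
    permuted = dict(zip(subjects, labels[rng.permutation(len(labels))]))
    return [replace(v, label=int(permuted[v.subject_id])) for v in volumes]


@dataclass
class PermutationStudyResult:
    true_mccs: list[float]
    permuted_mccs: list[float]
    report: ComparisonReport
    true_predictions: list[PredictionSet] = field(default_factory=list)
    permuted_predictions: list[PredictionSet] = field(default_factory=list)
    threshold_reports: pd.DataFrame | None = None


def run_permutation_study(volumes: list[LabeledVolume], split: SubjectSplit,
                          slice_specs: dict[str, SliceSpec], cfg: TrainConfig,
                          n_repeats: int = 10, permutation_seed: int = 0,
                          include_dual_threshold: bool = False,
                          model_spec=None) -> dict[str, PermutationStudyResult]:
    """Retrain per plane with subject-level permuted labels and compare MCCs.

    With ``include_dual_threshold``, the true-vs-permuted comparison is
    additionally run within each dual-threshold bin.
    """
    out = {}
    for plane, spec in slice_specs.items():
        shuffled = permute_labels(volumes, seed=permutation_seed)
        true_preds, perm_preds = [], []
        for r in range(n_repeats):
            rcfg = replace(cfg, seed=_repeat_seed(cfg.seed, r))
            _, res_t = train_slice_model(volumes, split, spec, rcfg, model_spec)
            _, res_p = train_slice_model(shuffled, split, spec, rcfg, model_spec)
            true_preds.append(res_t.test_predictions)
            perm_preds.append(res_p.test_predictions)
        true_mccs = [p.metrics()["mcc"] for p in true_preds]
        perm_mccs = [p.metrics()["mcc"] for p in perm_preds]
        threshold_table = None
        if include_dual_threshold:
            rows = []
            pairs = [(round(t, 2), round(1 - t, 2)) for t in (0.5, 0.35, 0.2)]
            for lower, upper in pairs:
                mt = [dual_threshold(p.probabilities, p.labels, [(lower, upper)])[0].mcc
                      for p in true_preds]
                mp = [dual_threshold(p.probabilities, p.labels, [(lower, upper)])[0].mcc
                      for p in perm_preds]
                mt = [v for v in mt if np.isfinite(v)]
                mp = [v for v in mp if np.isfinite(v)]
                if len(mt) >= 2 and len(mp) >= 2:
                    rep = two_sample_ttest(mt, mp)
                    rows.append({"lower": lower, "upper": upper,
                                 "t": rep.t_statistic, "p": rep.p_value,
                                 "true_mean": rep.mean_a, "perm_mean": rep.mean_b})
            threshold_table = pd.DataFrame(rows)
        out[plane] = PermutationStudyResult(
            true_mccs=true_mccs, permuted_mccs=perm_mccs,
            report=two_sample_ttest(true_mccs, perm_mccs),
            true_predictions=true_preds, permuted_predictions=perm_preds,
            threshold_reports=threshold_table)
    return out


@dataclass
class FusionStudyResult:
    mccs: list[float]
    accuracies: list[float]
    precisions: list[float]

    def summary(self) -> dict[str, float]:
        return {
            "mcc_mean": float(np.mean(self.mccs)),
            "mcc_sd": float(np.std(self.mccs, ddof=1)) if len(self.mccs) > 1 else 0.0,
            "accuracy_mean": float(np.mean(self.accuracies)),
            "precision_mean": float(np.nanmean(self.precisions)),
        }


def run_fusion_study(volumes: list[LabeledVolume], split: SubjectSplit,
                     best_slices: dict[str, int], cfg: TrainConfig,
                     n_repeats: int = 3, model_spec=None) -> FusionStudyResult:
    """Train the three-slice fusion model on each plane's best slice."""
    if set(best_slices) != set(PLANES):
        raise ParameterError("best_slices must name all three planes")
    datasets = {plane: make_slice_datasets(volumes, split,
                                           SliceSpec(plane, best_slices[plane]))
                for plane in PLANES}
    shapes = [datasets[p]["train"].images.shape[1:] for p in PLANES]

    def bundle(tag):
        xs = [datasets[p][tag].images for p in PLANES]
        ref = datasets[PLANES[0]][tag]
        return xs, ref.labels, ref.subject_ids

    mccs, accs, precs = [], [], []
    for r in range(n_repeats):
        seed = _repeat_seed(cfg.seed, r)
        model = build_fusion(shapes, spec=model_spec, seed=seed)
        res = train_model(model, bundle("train"), bundle("val"), bundle("test"),
                          replace(cfg, seed=seed))
        m = res.test_predictions.metrics()
        mccs.append(m["mcc"])
        accs.append(m["accuracy"])
        precs.append(m["precision"])
    return FusionStudyResult(mccs=mccs, accuracies=accs, precisions=precs)


def run_occlusion_for_slice(volumes: list[LabeledVolume], split: SubjectSplit,
                            spec: SliceSpec, cfg: TrainConfig,
                            occlusion: OcclusionConfig | None = None,
                            sigma: float = 1.0, model_spec=None):
    """Train a slice model, then attribute the test split.

    Returns (maps, frequency_map, summary, train_result).
    """
    model, result = train_slice_model(volumes, split, spec, cfg, model_spec)
    data = make_slice_datasets(volumes, split, spec)["test"]
    maps, fmap = attribute_dataset(model.predict_logits, data.images, data.labels,
                                   data.subject_ids, cfg=occlusion, sigma=sigma)
    summary = slice_occlusion_summary([m.adjusted for m in maps])
    return maps, fmap, summary, result


def run_mcc_attribution_correlation(sweep: SliceSweepResult,
                                    summaries: pd.DataFrame) -> dict[str, tuple[float, float]]:
    """Pearson r between slice-wise mean MCC and occlusion summaries per plane.

    ``summaries`` columns: plane, slice_index, occlusion_summary.
    """
    merged = sweep.table.merge(summaries, on=["plane", "slice_index"])
    out = {}
    for plane, grp in merged.groupby("plane"):
        if len(grp) < 3:
            raise ParameterError(f"need >= 3 slices with both quantities for {plane}")
        out[plane] = pearson_r(grp["mcc_mean"].to_numpy(),
                               grp["occlusion_summary"].to_numpy())
    return out


def config_fingerprint(obj) -> str:
    """Stable hash of a (nested) config for run manifests."""
    def default(o):
        if hasattr(o, "__dataclass_fields__"):
            return {k: getattr(o, k) for k in o.__dataclass_fields__}
        if isinstance(o, (np.integer, np.floating)):
            return o.item()
        if isinstance(o, (set, frozenset)):
            return sorted(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        return str(o)

    text = json.dumps(obj, default=default, sort_keys=True)
    return hashlib.sha256(text.encode()).hexdigest()[:16]
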