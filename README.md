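# slicemap

A slice-based 2D pipeline for localizing discriminative 3D regions in
structural brain MRI. Plane-specific 2D CNN binary classifiers are
trained on sagittal/coronal/axial slices; the best slice per plane
(by Matthews correlation coefficient) is subjected to occlusion-based
attribution; the cross-plane consensus of high-attribution peaks defines
a candidate cubic ROI, which is validated with a lightweight 3D patch
classifier against a size-matched low-attribution negative control.
A validity harness — signal-injection simulation, subject-level label
permutation, dual-threshold selective prediction, and an
energy-distance two-sample test — accompanies the pipeline, along with
a synthetic phantom cohort generator so everything runs without
restricted imaging data.

The neural networks are implemented on a small NumPy engine
(`slicemap.nn`: convolution, pooling, batch/layer norm, dropout, AdamW,
StepLR, BCE-with-logits, hand-derived backprop, finite-difference
tested), so the package has no deep-learning framework dependency.

## Layout

| module | contents |
| --- | --- |
| `slicemap.phantom` | synthetic labeled 3D cohorts, Gaussian cube signal injection, foreground z-scoring |
| `slicemap.volumes_io` | NIfTI/manifest I/O, plane-wise slicing, slice-index sampling, leakage-safe subject splits |
| `slicemap.nn` | NumPy layers/optimizer/loss used by all classifiers |
| `slicemap.models` | 2D slice CNN, 3D patch CNN, three-slice fusion model, training loop, hyperparameter search |
| `slicemap.metrics` | confusion metrics (MCC, accuracy, precision), dual-threshold analysis, Welch t-test, permutation energy-distance test, Pearson r |
| `slicemap.attribution` | occlusion scores, sign adjustment, subject thresholds, group frequency maps |
| `slicemap.localization` | best-slice selection, cross-plane ROI definition, negative control search, 3D validation |
| `slicemap.experiments` | end-to-end studies: slice sweep, simulation, permutation, fusion, MCC-attribution correlation |
| `slicemap.cli` | `slicemap` command-line entry point |

## CLI

```bash
# synthetic cohort with an injected cube, normalized, split 64:16:20
slicemap phantom --n 200 --shape 64 --normalize --inject 25:34 --seed 7 --out data/

# slice-wise performance sweep and best-slice selection
slicemap sweep --manifest data/manifest.csv --repeats 3 --epochs 12 --lr 1e-3 --out run/

# occlusion attribution for one slice (trains the slice model first)
slicemap occlude --manifest data/manifest.csv --plane axial --slice 29 --out run/

# full localization with 3D validation
slicemap localize --manifest data/manifest.csv --sweep-table run/tables/sweep.csv --out run/
```

Other subcommands: `slice`, `train`, `simulate`, `permute`, `fuse`,
`report`. Every command records its seed in the outputs; tables are CSV
and reports JSON under the chosen output directory.

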