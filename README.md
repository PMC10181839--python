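# peakcloud

Point-cloud instance segmentation for untargeted feature detection and
quantification in profile LC-HRMS data.

## The problem

In full-scan and DDA acquisitions an LC-MS run is a sparse 3D signal: every
profile sample is a point (RT, *m/z*, *I*), and each eluting analyte leaves
a Gaussian-like 3D peak — a **feature** — that overlaps its neighbors and
sits on chemical noise.  Mainstream software finds features by reducing the
data to 2D slices (EICs) or by gridding it, losing the native 3D
distribution and with it detection and quantification accuracy.  peakcloud
instead treats feature extraction as **instance segmentation on the raw
point cloud**: every profile point is classified (feature vs. noise),
assigned to its feature, and features are quantified by integrating raw
intensities inside an explicitly predicted boundary.  It is aimed at
metabolomics / proteomics tool builders and anyone who needs lossless 3D
feature extraction from mzML profile data.

## The model

A run is tiled into overlapping RT × *m/z* windows.  Each windowed cloud is
normalized — RT by a typical chromatographic FWHM, *m/z* by the analyzer's
theoretical peak FWHM (constant resolving power *R* for TOF so
FWHM = *m/z*/R; *R* ∝ *m/z*^(−1/2) for Orbitrap so FWHM ∝ *m/z*^1.5), and
intensity by log₂ — all reversibly, so quantification happens on raw
values.

A hierarchical point network (local spatial encoding → intensity-weighted
subsampling levels with interpolated convolutions → decoding by inverse-
distance interpolation with skip connections) produces three per-point
outputs:

* **semantic** — P(point belongs to a feature), trained with focal loss;
* **center** — P(point is its feature's center), trained with quality focal
  loss against a Gaussian centerness target;
* **polar mask** — a star-convex feature contour encoded as 36 equiangular
  ray lengths in the normalized RT–*m/z* plane, trained with
  −log IoU, IoU = Σₖ min(aₖ,bₖ) / Σₖ max(aₖ,bₖ).

Assembly selects candidate centers by thresholding both probabilities,
suppresses duplicates greedily by mask containment, assigns every in-mask
point to its nearest accepted center (no point is quantified twice), and
reports each feature's location (denormalized center) and volume (sum of
raw member intensities).  Only features centered in a window's un-expanded
rectangle survive the merge, so the tiling is exhaustive and
duplicate-free.

The network and its training loop (Adam, decoupled weight decay, per-epoch
scale/offset augmentation, batch padding with simulated noise) run on a
compact NumPy reverse-mode autodiff core — no GPU or deep-learning
framework required.

## Worked example

Everything below runs offline on synthetic data; the generator writes
annotated clouds in the same CSV format used for training corpora
(`rt,mz,intensity,label`).

```bash
peakcloud simulate --n-clouds 50 --seed 7 --out demo_data
peakcloud train --data demo_data --epochs 10 --seed 0 --out demo_model.npz
peakcloud predict --input demo_data/cloud_0000.csv \
                  --weights demo_model.npz --output demo_features.csv
peakcloud evaluate --detected demo_features.csv \
                   --truth demo_data/truth_0000.csv --tol-mz 0.017 --tol-rt 0.18
```

The `evaluate` step prints, for the first cloud of this short demo run:

```
matched: 3
truth: 3
detected: 3
recall: 1.0
precision: 1.0
median_abs_dmz: 0.0008903680207481557
median_abs_drt: 0.01009110782416156
```

`matched` is the number of detected features paired one-to-one with truth
features inside the *m/z*/RT tolerances; `recall` and `precision` are the
matched fractions of truth and detections; the medians are the location
deviations of matched pairs in Da and minutes (here ≈5% of an *m/z* peak
FWHM and ≈10% of a typical chromatographic FWHM).  One easy cloud is not a
benchmark: over 50 held-out clouds the full desk-scale configuration
(200 training clouds, 30 epochs, ensemble inference and validation-
calibrated thresholds; `peakcloud.benchmark`) measures recall ≈ 0.83 at
precision ≈ 0.93 with median volume error below 1%.

The same workflow is available as a scikit-learn style estimator:

```python
from peakcloud import PeakCloudDetector, SimConfig
from peakcloud.simdata import generate_dataset

clouds = [c for c, _ in generate_dataset(SimConfig(), 50, seed=7)]
det = PeakCloudDetector(window_rt=10.0, window_mz=1.0, epochs=10).fit(clouds)
table = det.predict(clouds[0])          # DataFrame: feature_id, mz, rt, volume
```

## Layout

| module | contents |
| --- | --- |
| `peakcloud.io` | mzML reading (pyteomics), annotated-cloud CSV, feature tables |
| `peakcloud.preprocess` | window planning, noise filtering, reversible normalization, resolution models |
| `peakcloud.polarmask` | polar-mask geometry: construction, membership, IoU, area |
| `peakcloud.network` | the point network and its autodiff-backed blocks |
| `peakcloud.trainer` | targets, augmentation, batching, losses, training loop |
| `peakcloud.extractor` | candidate selection, suppression, quantification, window merge |
| `peakcloud.simdata` | synthetic annotated clouds + mzML writer |
| `peakcloud.evalstats` | matching, fold change, CV, marker statistics |
| `peakcloud.estimator` | `PeakCloudDetector`, the sklearn-style front door |
| `peakcloud.benchmark` | the desk-scale self-benchmark used by tests and `scripts/acceptance.py` |

See `docs/methods.md` for the scientific details and design choices.
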