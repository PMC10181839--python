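# Methods

## Data model

A profile LC-HRMS run is treated as a global point set: one point per
(scan, *m/z* sample) with positive intensity, coordinates
(RT in minutes, *m/z* in Da, intensity in detector counts).  A **feature**
is the 3D peak one analyte leaves in this set — approximately a separable
Gaussian in RT and *m/z* whose apex is the analyte's elution maximum.
Feature extraction is posed as instance segmentation: classify every point
(feature vs. noise), group the feature points by analyte, and integrate
each group.

## Windowing and normalization

The run is tiled into half-open initial windows (defaults 6 min × 0.8 Da,
the scale used for manually annotated training corpora), each expanded by a
margin that must exceed the largest feature width (defaults 0.3 min,
0.05 Da).  A feature centered inside an initial window is then always seen
whole by the network; at merge time a feature is kept only by the window
whose initial rectangle contains its center, which makes the merged list
exhaustive and duplicate-free (boundary centers belong to the upper window
by the half-open convention).

Each windowed cloud is normalized by an affine, exactly invertible map:

* RT: `(rt − rt_mid) / rt_fwhm_typical`, with `rt_fwhm_typical` a
  user-set chromatographic width (default 0.1 min);
* *m/z*: `(mz − mz_mid) / FWHM_theo(mz_mid)`, with the theoretical FWHM
  from the analyzer's resolving power *R*: constant for TOF
  (`FWHM = mz / R`), `R ∝ mz^(−1/2)` for Orbitrap
  (`FWHM = mz^1.5 / (R_ref √mz_ref)`) — the standard physical models of the
  two analyzer families;
* intensity: `log2(max(I, 1))`.

One *m/z* scale per window (evaluated at the window center) keeps the map
affine; over a sub-Da window the FWHM varies by < 0.2%, far below peak
width variability.  Midpoints of the expanded window define the centers.
After detection all coordinates and intensities are mapped back through
the stored parameters, so quantification always happens on raw values;
the round trip is exact to floating-point precision (< 1e−9, tested on
1000 random clouds).

## Polar masks

A feature boundary is a star-convex contour in the normalized RT–*m/z*
plane: a center plus 36 equiangular ray lengths (ray k at angle 2πk/36
counterclockwise from the +RT axis; the count is configurable, 36 is the
default because boundary accuracy saturates there).  Between rays the
radius is linearly interpolated.  Ground-truth rays for a point set are
built by sector max: each member point raises the two rays adjacent to its
angle to at least its radial distance — this two-sided update makes the
containment guarantee (every member lies inside the resulting mask) a
theorem rather than an accident, which a nearest-ray binning does not give
under interpolated membership.  Sectors without support are filled by
circular interpolation between occupied rays, so compact features never get
zero-length wedges.  Mask IoU is Σ min / Σ max over paired rays (defined as
1 for two empty masks so the loss stays finite on degenerate targets).

## Network

Input is the normalized (rt', mz', I') cloud.  The backbone:

1. **Local spatial encoding** — for each point, its k = 16 nearest
   neighbors; per neighbor the relative 3D offset and its norm are encoded
   by a shared two-layer MLP (width 32) and max-aggregated.  The descriptor
   is translation invariant by construction.
2. **Encoding levels** (3) — the cloud is subsampled to ½, ¼, ⅛ of its
   points by intensity-probability sampling (inclusion probability
   proportional to normalized intensity, exponential-key weighted sampling
   without replacement; random keys are assigned in a canonical
   lexicographic point order so the whole forward pass is permutation
   equivariant).  Each sampled point gathers k neighbor features from the
   previous level, weighted by inverse distance, concatenated with relative
   coordinates, shared MLP (widths 64/128/256), max over neighbors.
3. **Decoding levels** (3) — features are propagated back level by level:
   inverse-distance interpolation over the 3 nearest coarse points,
   concatenation with the finer level's skip features, shared MLP.

Neighbor queries use the full 3D metric by default (`knn_dims = 2`
restricts them to the RT'–*m/z*' plane; in our experiments the two were
equivalent at desk scale).

Heads: three fully connected branches (128 → 64) on the concatenation of
the decoded features, the local-encoding skip, the point's own normalized
intensity and its local-max margin (own log-intensity minus the
neighborhood maximum — non-negative exactly at local intensity maxima, the
natural apex cue).  Semantic and center probabilities use a sigmoid;
ray lengths use an exponential activation so they are strictly positive
and gradients never die at zero.

## Targets and losses

* **Semantic**: 1 iff the point's instance label ≥ 0; focal loss
  (α = 0.25, γ = 2, the standard values).
* **Centerness**: `exp(−d²/2σ²)` of the distance to the feature's apex
  (maximum-intensity member, ties to smaller RT then *m/z*), σ = 0.5
  normalized units by default; 0 on noise.  Trained with quality focal
  loss — binary cross-entropy against the soft target modulated by
  |y − p|^γ.  The α-weighted binary focal form, applied to this continuous
  target, lets the overwhelming majority of near-zero-target points
  dominate and in our experiments stalls the branch entirely (validation
  center loss flat over a full run); the |y − p|^γ modulation concentrates
  gradient on badly predicted points regardless of their target value and
  fixed it.
* **Rays**: ground-truth rays are recomputed about *each* member point as
  center, because inference reads the ray head at whichever point is
  selected as center; loss is −log IoU over member points, optionally with
  an auxiliary per-sector log-ray mean-square term (`ray_log_weight`): the
  IoU couples all 36 sectors through its sums, and the auxiliary term
  measurably sharpens individual sectors.  A centerness-weighted variant of
  the IoU term is also available but gave no gain and is off by default.

Total loss is the weighted sum of the three (weights (1, 1, 1) by
default; the desk preset doubles the center branch, whose target carries
the least supervision per cloud).  Optimization: Adam, decoupled weight decay 0.01 on weight
matrices, batch size 8 clouds, reference learning rate 5e-4.  Augmentation
is redrawn every epoch: each dimension scaled by an independent log-uniform
factor in [0.5, 2] plus RT/*m/z* offsets.  `pad_batch` can equalize point
counts inside a batch with simulated low-intensity noise (flagged so
metrics exclude it); the per-cloud training loop does not need equal
counts, and since uniformly scattered padding points teach the semantic
branch to reject faint feature edges, padding is off in the desk-scale
preset.

The engine underneath is a compact vectorized reverse-mode automatic
differentiation core (`peakcloud.autodiff`) — float32 tensors, the exact
operator set the network needs, gradient-checked against central finite
differences.

## Assembly

Candidates = points with semantic ≥ `sem_threshold` AND center ≥
`center_threshold`, ordered by center probability (ties to higher
intensity).  Greedy suppression: accept a candidate iff it is not inside
any already-accepted center's mask (containment only; no IoU criterion).
Every point inside at least one accepted mask is assigned to the nearest
accepted center among those containing it, so no point is quantified
twice.  Volume = sum of raw member intensities — a Riemann sum on the
acquisition grid; all features of a run share the grid, so grid-spacing
normalization cancels in any within-run comparison.  Feature location is
the denormalized coordinate of the selected center point.

Both thresholds default to 0.5.  Two inference refinements are available
and used by the desk preset:

* **Stochastic-forward ensembling** (`n_ensemble = 5`): the forward pass is
  stochastic through intensity-probability sampling; semantic probabilities
  and rays are averaged over seeds while the center probability takes the
  per-point maximum, because sampling noise predominantly *suppresses* weak
  true centers (faint features, shoulders of brighter neighbors).
* **Validation-calibrated operating point**: after training, the center
  threshold is chosen on the training run's own validation clouds — network
  predictions are cached once, a small threshold grid is scored by
  matching assembled features against the validation truth, and the highest
  recall with precision ≥ 0.9 wins (best F1 as fallback).  This mirrors how
  an operating point would be chosen on annotated data in practice, and
  uses no held-out evaluation data.

## Synthetic data

The generator emulates an annotated training corpus: per window
(1.2 min × 0.15 Da by default), 2–5 features with separable-Gaussian
shape; RT FWHM uniform in 0.08–0.18 min; *m/z* σ from the TOF resolution
model (R = 30 000 at 500 Da) through FWHM = 2√(2 ln 2)·σ; amplitudes
log-uniform in 500–20 000 counts; 25% of features seeded 1–2.8σ from a
host feature to force overlap; 5% multiplicative detector noise; sparse
chemical noise (≈ 600 points per min·Da, 5–150 counts, log-uniform) on the
scan grid; grid nodes below 1% of the minimum amplitude dropped; each
surviving node labeled with its dominant feature (argmax of
contributions), matching single-instance-per-point annotation.  The truth
table records each feature's analytic grid-sum volume (its own
contribution over the full lattice, ≈ A·2πσ_rt σ_mz/(Δrt Δmz)).

What this emulates: peak shape and width statistics, profile sampling
density, dynamic range, overlap geometry, floor truncation.  What it does
not: isotope envelopes and charge states, chromatographic tailing (an EMG
option is deliberately out of scope), RT drift between runs, structured
chemical streaks, detector saturation.  Passing the end-to-end checks
therefore demonstrates that the architecture, losses, assembly and
bookkeeping work as specified on Gaussian-like features over noise — not
that the shipped defaults transfer to any particular instrument without
retraining on annotated real data.

## Desk-scale benchmark

The self-contained benchmark (`peakcloud.benchmark`, driven by
`scripts/acceptance.py` and the acceptance tests) trains on 200 synthetic
clouds (7:3 train/validation split — at the annotated-corpus scale of 306
clouds the same split gives 214/92), 30 epochs with k = 32 neighbors,
calibrates the screening threshold on the validation clouds, and
evaluates on 50
held-out clouds: recall/precision at one-FWHM matching tolerances, median
relative volume error over isolated features, and the fraction of
2σ-separated overlapping pairs with both members recovered.  These sizes
are the package's chosen desk scale: one full cycle runs in minutes on a
single CPU core.  With only ~540 optimizer steps (two orders of magnitude
fewer than a production run), the preset scales the Adam step to 2e-3; the
reference configuration keeps 5e-4.

## Numerical choices and degenerate inputs

* Half-open `[lo, hi)` intervals everywhere; boundary points belong to the
  lower window, boundary-centered features to the upper window at merge.
* Clouds smaller than k: neighbor lists padded by self-duplication rather
  than erroring.
* Focal-loss probabilities clamped to [1e−7, 1−1e−7]; IoU clamped before
  the log; ray-head pre-activations clipped at ±30 before exp.
* Empty member sets: `mask_from_points` raises; a candidate whose mask
  captures no points is dropped with a log entry.
* All randomness flows through explicit integer seeds
  (`numpy.random.default_rng`); identical seeds give identical datasets,
  training runs and feature tables.

## Known limitations

* The supplementary-level internals of the original architecture family
  (exact block widths, kernel details) are not public; the blocks here
  implement the documented operator properties (point-wise, interpolated,
  growing receptive field) with their own internals.
* Centroided spectra are accepted with a warning but the model assumes
  profile peak shapes.
* No cross-run alignment, gap-filling, or isotope/adduct grouping —
  downstream tools own those steps.
* Volume estimates are grid Riemann sums; absolute (grid-independent)
  volumes require multiplying by Δrt·Δmz.
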