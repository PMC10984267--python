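# Methods

## Plot locating

A frame covers the central plot plus parts of its neighbours, separated by
bare-soil lanes. The locator assumes (i) vegetation is markedly greener than
soil, (ii) exactly one plot of known pixel extent is near the frame center,
and (iii) the lanes run parallel to the image axes. Under these assumptions
the row/column white-pixel profiles of the binarised vegetation map dip in
the lanes, and the window whose two boundary lines have the smallest summed
smoothed profile is the plot.

Choices the procedure leaves open, and how they are fixed here:

* **Otsu on a continuous index.** Otsu thresholding is histogram-based, so
  the CIVE map is affinely rescaled (min → 0, max → 255), rounded into 256
  integer bins, thresholded with `skimage.filters.threshold_otsu`, and the
  threshold mapped back to CIVE units. Vegetation is the *low* side
  (CIVE ≤ threshold), because the −0.811 G term makes green pixels minimise
  the index. A constant map has no separable classes; it yields an all-False
  mask with an explicit `degenerate` flag.
* **Moving average.** Centered, window 100 px, truncated at the array edges
  (mean over the valid entries). A trailing window would shift every
  boundary systematically by half a window; centering avoids that. For the
  even default window, index *i* averages samples *i*−49 … *i*+50.
* **Boundary indices.** For a window of height *h* the placement cost is
  `smoothed[i] + smoothed[i + h − 1]`, so both boundary rows lie inside the
  window and the window is exactly *h* rows.
* **Tie handling.** When the window height equals the plot pitch the cost
  valley floor is flat (up to pixel noise) over as much as
  2·gap − smoothing-window placements, so the minimiser alone is not well
  defined. Placements within 1% of the cost range above the minimum are
  treated as tied and the lower-median tied index is returned. The 1% band
  is far above the noise of a profile averaged over 100 lines and far below
  the lane slopes, so in practice it selects the center of the valley —
  appropriate for frames centered on their plot. The same rule is the
  published contract, and the exhaustive-search test oracle implements it
  independently.
* **Coordinates.** 0-based (row, col); windows half-open
  [row0, row0+h) × [col0, col0+w). The default window, 3800 × 2000 px,
  corresponds to the planting geometry (30 cm between plants, 50 cm between
  plots) at the campaign's flight altitude; the cm→px factor depends on
  altitude and zoom, so the window extent is a user parameter, not derived.

## Tiled detection and merging

Tiles are square (default 1000 px) with stride
`round(tile · (1 − overlap))`; the final offset per axis is clamped to
`extent − tile` so the last tile aligns with the image edge rather than
padding with synthetic border pixels. With the default 25% overlap an
interior pixel lies in at most 4 tiles, and coverage is complete for any
plot at least one tile wide.

Two suppression stages exist, mirroring the separation of model inference
and cross-tile merging: the backend's *internal* NMS (IoU 0.5; part of the
detector contract — its output must arrive deduplicated) and the *merge*
NMS across lifted tiles (IoU 0.25, after dropping scores < 0.3; prediction
thresholds; validation-style evaluation uses 0.05/0.5). Filtering before
merge NMS is order-safe and cheaper. Greedy NMS visits boxes by descending
score, breaking ties by larger area then input order, so merged output is
deterministic and invariant to tile order. Counting a plot is the
cardinality of the merged set.

The reference blob detector (colour threshold → 8-connected components →
bounding boxes, fixed score) drops components whose box touches the tile
border. This is the standard sliced-inference edge rule: any blob narrower
than the tile overlap lies strictly inside at least one tile, so it is
still detected — as the *identical* plot-frame box in every tile that
contains it whole — and merge NMS removes the duplicates exactly. A partial
sliver of a boundary-straddling blob, by contrast, can overlap the whole
detection by less than the 0.25 merge IoU and would double-count. The rule
is configurable (`BlobDetectorConfig.ignore_border`).

## Evaluation metrics

RMSE and R² = 1 − SS_res/SS_tot are computed over per-image
(manual, predicted) count pairs; R² may be negative for a predictor worse
than the mean, and is undefined (an error) when all manual counts are
equal. Matching is greedy by descending prediction score: each prediction
claims the unmatched ground-truth box of highest IoU if that IoU reaches
the threshold; equal-IoU ties take the lower ground-truth index. AP@k uses
101-point interpolation (precision at recall level r = maximum precision at
recall ≥ r), the convention of the COCO benchmark family that the
mAP@50:5:95 name refers to. mAP@50:5:95 averages AP over the ten thresholds
0.50, 0.55, …, 0.95; a `divisor` parameter exposes the 9-divisor variant
for comparison with sources that normalise that way. A recall level counts
as attained at equal recall up to 1e-10 so that one-ulp float differences
between level grids and count ratios do not drop exact crossings.

## Trait extraction

The heading date at fraction f is evaluated over *observed* flight dates
only — the literal argmin — so resolution is bounded by flight cadence;
interpolating between dates is deliberately not done by default.
The maximum M is the per-curve maximum of raw counts. Raw counts are used
without monotonic regularisation; a running-maximum preprocessing
(`monotonize=True`) is available for visibly fluctuating curves but off by
default, since regularisation changes which date first attains a stage.
Ties break to the earliest date. Dates are handled internally as integer
day ordinals; ISO-8601 dates are accepted at I/O and reported back as ISO
dates. The traits are date-shift equivariant and count-scale invariant by
construction.

## Synthetic fixtures

**Field scenes** emulate a drilled trial: vegetation-toned ground with two
horizontal and two vertical soil lanes bordering a plot at a seeded random
offset — so vegetated neighbour-plot strips lie beyond the lanes, which is
what makes the boundary cost locally convex and the locator's optimum
well-defined. Panicles are axis-aligned ellipses in a straw tone
(235, 210, 120) well separated from foliage (65, 125, 55) and soil
(125, 95, 65) under the additive Gaussian pixel noise (σ = 5), placed with
≥ 20 px edge clearance between blobs and ≥ 30 px clearance from the plot
boundary. Default geometry is a scaled-down frame (1000 × 1500 px image,
600 × 1000 px plot, 50 px lanes, 25 panicles of 4–8 px semi-axes) keeping
the real proportions; generation and the full per-frame pipeline then run
in ~0.2 s, so hundreds of scenes fit comfortably in a test run. Ground
truth (plot window, exact rendered blob boxes) is recorded at generation.

What scenes do **not** model: perspective and lens distortion, lighting
gradients and shadows, occlusion and overlap of panicles with each other or
foliage, colour ambiguity between panicles and senescing leaves, and lane
curvature. Passing end-to-end tests therefore certify the *pipeline
machinery* — locating, tiling, lifting, merging, counting — not detector
robustness on real imagery; a trained network is expected to replace the
reference detector there, through the same contract.

**Count series** are logistic: counts(t) = round(max(0, K/(1+e^{−r(t−t₀)})
+ ε_t)), ε_t ~ N(0, σ), sampled at 42 daily flights (t = 0…41). Analytic
heading dates are the noiseless crossings t₀ + ln(f/(1−f))/r clipped to the
sampled range, giving a 10%→80% stage of ln(36)/r. Defaults: K ~ U(150,
350) in recovery studies (plot-scale plateau counts), r ~ U(0.4, 0.9)
(heading spread of ~4–9 days), t₀ ~ U(14, 26) (mid-campaign), and
σ = 0.015·K — the scale of the few-panicle counting error a tuned detector
achieves on plots with plateau counts in the low hundreds. Under these
conditions the literal argmin recovers hd10/hd50/hd80 within ±1 day in
≥ 95% of replicates; at substantially higher noise (σ ≈ 0.03·K) the flat
pre-heading tail begins to compete with the 10% crossing and the argmin
estimator degrades — an inherent property of the estimator worth knowing
before applying it to very noisy curves (monotonizing mitigates it).

## Problem sizes and determinism

Acceptance-style computations use 1000 NMS instances (≤ 50 boxes), 100
scenes for locating and for end-to-end counting, 100 random tilings, and
500 series replicates — sizes at which every stochastic rate estimate is
stable to a few parts in a thousand across seeds. All randomness flows
through `numpy.random.default_rng` seeded per generator call; the pipeline
itself is deterministic given inputs and config, and reruns produce
byte-identical trait CSVs.

## Known limitations

* One plot per frame; no orthomosaic stitching, geo-referencing, or
  multi-plot layouts.
* No alternative vegetation indices (ExG, NDVI); CIVE only.
* The detector contract ships with the reference blob detector only;
  training or running neural detectors is out of scope (their outputs are
  consumed via COCO-JSON/YOLO-txt).
* No tracking of individual panicles across dates; counts are per-date
  snapshots.
* Heading-date resolution is bounded by flight cadence (1 day in the
  fixtures); no sub-day interpolation.
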