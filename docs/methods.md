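# Methods

This note documents the models, parameter choices and numerical decisions
behind `nucfate`, in the package's own terms. Nothing here states a result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Per-frame nuclear measurement

Each two-channel frame is processed as: z-projection (maximum by default —
granules are bright, and a max projection preserves their contrast; mean
projection is available) → integer upsampling by the "pixel factor"
(bicubic, default 2) → Otsu segmentation of the chromatin channel → Sobel
edge counting inside the mask. The chromatin compaction parameter is
`CCP = edge_count / area`, with `area` the pixel count of the hole-filled
mask; the reporter channel is summarized as its mean inside the same mask.

Numerical choices that required a decision:

* **Segmentation guard.** Otsu's threshold always exists, even for an
  all-background ROI where it merely splits the noise. A threshold is
  accepted only if its between-class variance fraction (Otsu's separability
  η) reaches 0.75; pure Gaussian noise gives η ≈ 0.64, a stained nucleus on
  dark background ≈ 0.95+. Below the guard the frame carries the empty-mask
  flag.
* **Debris floor.** Connected components under 120 upsampled pixels are
  dropped. The floor is far below any nuclear cross-section (≈2000 px even
  for terminally shrunken nuclei at default geometry) and above the
  footprint of a single bright chromatin granule, so a rim-adjacent granule
  cannot register as a second nucleus. ROIs with more than one surviving
  component are flagged invalid and excluded from classification.
* **Edge threshold.** The Sobel magnitude threshold is 2.5× the *median*
  within-mask magnitude — the bulk-anchored convention of classic Sobel
  auto-thresholding. It is invariant to global intensity scaling, and it is
  monotone in granule content because the median tracks the smooth-texture
  bulk. We also implement the alternative of Otsu's threshold on the
  gradient magnitudes, but found it unsuitable as a default: for a unimodal
  gradient distribution Otsu fixes the edge *fraction* near a constant
  quantile regardless of texture, and when strong granules form a separate
  gradient class the threshold jumps between classes, which can invert the
  dose–response of CCP to granulation. A fixed numeric threshold is also
  available.
* **Gradient floor.** The median rule additionally never classifies as edge
  a pixel whose gradient is below 1% of the mean within-mask intensity.
  Gradients that small are interpolation or sensor residue; the floor makes
  an exactly uniform disk give CCP = 0 even through the upsampling step.
* **Rim exclusion.** Before edge counting the mask is eroded with a
  disk-shaped footprint of radius 10 px (post-upsampling): 2 px of Sobel
  kernel support plus the intensity-transition band of the nuclear rim and
  the support of bicubic ringing. A disk footprint matters — iterated
  erosion with the default cross-shaped structuring element erodes only
  ~0.7× as deep diagonally and leaks rim gradients into the count.
* **Baseline normalization** divides each series (area, edge count, CCP,
  reporter mean) by the mean of its first three frames; a non-positive
  baseline raises an error rather than propagating infinities.

## Fate classification

The five-step rules and all thresholds (0.035, 0.8, 1.1, 0.75, 0.5,
14-fold) follow the published protocol; open details were resolved as:

* the "end of recording" window for the dying-cell gradient is the last 3
  inter-frame gradients (30 min), configurable;
* gradients are signed by default (absolute-value mode available);
* "decreased to least 75%" is read as final area ≤ 0.75× the first frame;
* the 14-fold event rule is a strict inequality (a peak of exactly 14.0 is
  not an event);
* steps 2 and 4 compare the first and last *frames'* normalized values, not
  extrema.

Alignment anchors each cell at the first frame where |normalized area − 1|
exceeds 0.1 for at least 2 consecutive frames; apoptotic shrinkage (to 0.26
within 30 min) and necrotic swelling (to 1.17) cross this robustly while
control jitter does not. Cells without a crossing are excluded from aligned
averages.

## Synthetic time-lapse generator

The generator renders one nucleus per ROI as a soft-edged disk (logistic
edge, width 1 px) of baseline radius 24 px in a 96×96 frame (111 nm/px,
10-min frames, 49 frames ≈ 8 h), with three intensity components in the
chromatin channel:

1. a static low-frequency texture (Gaussian-filtered noise, σ = 6 px,
   ±25%), fixed per cell — chromatin structure persists across frames;
2. **speckles/granules**: Gaussian spots (σ = 1 px, amplitude 0.9× the
   nuclear intensity) drawn from a per-cell position pool confined to 0.92
   of the radius. Eight spots per reference nucleus are present from the
   first frame (chromocenter-like baseline granularity); granulation adds
   spots from the same pool. This matters for measurement stability: the
   within-mask gradient distribution is then bimodal (smooth bulk vs spot
   rims) at every time point, and the edge count responds monotonically to
   spot density;
3. multiplicative Gaussian sensor noise (default 1%).

The reporter channel is a constant level inside the disk following the
programmed fold-change course plus a small floor.

**Programmed courses.** Piecewise-linear area, CCP-ratio and reporter
courses per fate:

* *apoptosis*: area 1.0 until the event, falling to 0.26 within 30 min;
  granulation ramps from 210 min before the event, anchored so the
  programmed CCP ratio is 1.55 two hours before the first detectable
  size-change frame (event + 10 min), and keeps rising to the event; it
  holds ~2 h, then clears by event + 3 h — the terminal pyknotic nucleus is
  uniformly dense, so even the baseline speckle contrast dissolves
  (programmed ratio 0.2), and the final-frame CCP satisfies the
  classifier's step-2 "no granules at the end" signature. The reporter
  rises steeply through the 14-fold threshold at the event and keeps
  rising ~1 fold/frame (caspase substrate accumulates), which is what makes
  the cell "dying" under step 1.
* *necrosis*: area 1.0 → 1.12 at event+10 → 1.17 at event+20 → 0.51 by
  event+130. The intermediate 1.12 point makes the first
  alignment-detectable frame precede the peak by exactly one frame, so the
  aligned peak lands at relative +10 min, as reported for swelling. The
  reporter drifts 1.0 → 1.3 during the hour after the event (per-frame
  gradient 0.05 > 0.035: not "surviving", never "dying"); granulation ramps
  to ratio 1.9 by the event and persists.
* *granulating-only*: texture ramp to 1.9 with flat area and reporter.
* *control*: everything flat.

Onset jitter of granulation is not separately modeled; per-cell variability
comes from the event-time draw (uniform 240–300 min in cultures), texture
and noise seeds.

**Calibration (frozen).** Two mappings tie programmed truth to what the
default measurement chain reports; both are produced once by
`scripts/calibrate_synthetic.py` and frozen in `_calibration.py`:

* spot count → mean measured CCP ratio (48 textures; monotone over counts
  8–40, reaching ratio ≈ 3.1). The generator inverts this to realize a
  programmed CCP course; fractional counts are realized by a per-cell
  dither so population means are unbiased.
* per-spot segmentation-area drift (−0.0006 relative area per excess
  spot): bright spots raise the Otsu intensity threshold and shrink the
  measured mask slightly; the renderer compensates the disk radius so the
  *measured* normalized area follows the programmed course. Without this
  the ~4% pre-event drift under full granulation swallows the 1.12
  swelling-detection crossing.

**What the generator does not emulate**: cell migration and ROI drift
(registration is out of scope), anisotropic or lobed nuclear shapes,
photobleaching, background cells entering the ROI, and z-structure (the
optional 7-plane stack is an attenuated replica whose max projection equals
the rendered plane). Passing tests therefore demonstrate correct recovery
of the programmed dynamics under these idealized conditions, not robustness
to those real-data complications.

## Synthetic SMLM generator

Molecule positions follow a Thomas-type cluster process in a disk: uniform
parent points (density `clusters_per_um2`), a `clustered_fraction` of
molecules Gaussian-scattered (σ = `cluster_sd_nm`) around parents, the rest
uniform. Each molecule emits geometric runs of consecutive-frame events
(p = 0.5), re-blinking with probability 0.3 after a single off frame;
events carry 4-nm localization jitter, lognormal spot widths (median FWHM
150 nm, ln-σ 0.3 — deliberately spilling below 65 nm and above 225 nm so
the width gates are exercised) and lognormal photon counts. 20 000 frames,
reference 20 000 molecules.

Stage profiles 1–5 sweep clustering upward (clustered fraction 0 → 0.85,
cluster σ 150 → 50 nm, cluster density 2 → 10 µm⁻²) with nuclear shrinkage
factors 0.9 and 0.6 at stages 4–5. One per-stage effective-radius factor is
calibrated (quadratic fit of mean log-density against log radius factor;
frozen) so the full merge → filter → Voronoi → count-normalize pipeline
reproduces the published per-stage mean log10 normalized densities at the
reference molecule count; for clustered patterns the normalized mean is
only weakly N-dependent, so moderate deviations from the reference count
are benign.

## SMLM post-processing and Voronoi analysis

* **Order**: blinking merge first, then the FWHM filter. Filtering first
  punches >1-frame gaps into emission runs and splits chains — on a
  complete-spatial-randomness stage-1 pattern this measurably biases the
  Clark–Evans index below 1 (≈0.95) via spurious near-duplicate molecules;
  with merge-first the index is ≈1.00.
* **Merge**: greedy frame-ordered linking — each localization joins the
  nearest open chain within 20 nm whose last frame is at most 2 behind
  (one off frame), ties broken by input order, one joiner per chain per
  frame; a chain reports the intensity-weighted mean position, first frame,
  summed intensity and event count, with no limit on chain length. The
  greedy rule is deterministic; it is idempotent whenever chains are
  unambiguous (inter-molecule spacing beyond the merge radius), which is
  how the idempotence property is tested — for arbitrarily noisy input a
  second pass may legitimately link chains the first pass split.
* **FWHM gates**: FWHM = 2√(2 ln 2)·σ; rows with 65 ≤ FWHM ≤ 225 nm are
  kept (boundary values retained).
* **Voronoi densities**: scipy's Voronoi diagram; each *bounded* cell's
  area via the shoelace formula on its angularly ordered vertices (cells
  are convex, so the angular sort about the vertex centroid is valid);
  generators on the convex hull have unbounded cells and are flagged
  `boundary_excluded`, carrying no density — their count is reported.
  Duplicate coordinates are de-degenerated by a deterministic ≤1e-6 nm
  jitter with a warning; collinear input raises an error.
* **Normalization and log**: densities are divided by the localization
  count of the nucleus and log10-transformed. Base 10 is self-consistent
  with the published scale: ~3×10⁵ localizations in a ≈4–5 µm nucleus give
  a count-normalized density near 10⁻⁷·⁸ nm⁻², whereas a natural-log
  convention would sit near −18.
* **Histograms**: 1D PDFs over log10 density on [−10, −5] (counts divided
  by total×bin-width, area 1 ± 1e-6); 2D radius×density histograms on
  [0, 8000] nm × [−10, −5], volume-normalized, with the 10⁻⁵–10⁻³
  color-scale clip recorded as rendering metadata only. Out-of-limit
  values are clipped into the edge bins (count-conserving).
* A known property of the log-mean: for a uniform (Poisson) pattern the
  mean log10 normalized density is log10(1/(πR²)) *plus* the Jensen term
  −E[log10(Aλ)] ≈ +0.06 (Poisson–Voronoi area distribution), which the
  uniform-disk tests assert explicitly.

## Problem sizes

Defaults were chosen so every stage runs comfortably on a single desktop
core: synthetic recovery runs use 20–30 cells of 49 frames at 96×96 px
(≈1 s/cell through the full measurement chain), the classifier-recovery
suite uses a 100-cell culture, and Voronoi checks use 4–100 k
localizations (scipy's qhull handles 10⁵ points in seconds).

## Known limitations

* The granule-count → CCP-ratio response saturates near ratio ≈ 3; courses
  programmed above that are rendered at the saturation density.
* CCP measured on strongly shrunken nuclei is noisier than at baseline
  (fewer spots and a proportionally larger eroded-rim share); the
  classifier thresholds tolerate this, but single terminal-frame CCP values
  should not be over-interpreted.
* The merge step is O(events × active chains) with a per-frame index; it is
  intended for per-nucleus tables (≲10⁶ events), not whole-field datasets.
* Stage labels for the per-stage summaries are taken as input; no
  morphological stage classifier is included.
* Descriptive statistics only (mean, SD, SEM); no inferential testing.
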