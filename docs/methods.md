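# Methods

This note documents the analysis model, its tunable parameters, the phantom
generator used for validation, and the numerical and design choices made
where the procedure left room for judgement.

## Image model and segmentation

An anterior-segment B-scan is modelled as three stacked regions per column:
dark air at the top, a bright corneal band, and the dark aqueous of the
anterior chamber below.  Bright pixels belong to the cornea, iris, lens or
artifacts — with the single exception of small hyperreflective specks inside
the chamber, which are cells.  All coordinates are row-major, origin
top-left, `x` = column, `y` = row, 0-based.

**Corneal cutoff.**  The intensity histogram of the median-blurred image
(kernel `histogram_smooth_kernel`, default 5 — strong enough to merge
speckle spikes, irrelevant to cell detection because cells are detected on
the original image) is smoothed with a centred moving average of
`histogram_window` = 11 bins, truncated at the histogram ends so no phantom
zero bins enter the average.  The dark-lobe peak is the argmax over bins
[0, `left_peak_max_bin` = 127], the bright-lobe peak the argmax over the
rest.  The cutoff is the leftmost minimum of the moving average strictly
between the two peaks and strictly below both.  This equals the classical
"first zero-gradient point right of the dark peak" on clean histograms but
is immune to comb ripple: rescaling 8-bit intensities by a non-integer
exposure factor leaves periodic sparse/dense bins whose moving average
oscillates by a few percent, and a first-local-dip rule locks onto those
dips far inside the dark lobe.  If no interior minimum lies below both
peaks (unimodal or flat histograms), Otsu's threshold on the smoothed
histogram is used and the scan is downgraded to `qc_status=warning`.

**Region masks.**  The original image is thresholded at the cutoff.  The
largest 8-connected above-cutoff component is the corneal band; if it spans
less than `min_cornea_width_fraction` = 50% of the image width the scan is
declared `unanalyzable` (air, cornea and chamber cannot be distinguished —
the same exclusion an operator would make).  Per column, the top envelope is
the first band pixel and the bottom envelope the end of the *contiguous*
band run starting there.  Using the bottommost component pixel instead is
wrong in an instructive way: a full-height reflection line crossing the iris
fuses band + line + iris into one component and would misplace the band's
lower edge by hundreds of rows across every iris column.  Columns the band
misses are bridged by linear interpolation of both envelopes.  Air is
everything above the top envelope; the cornea class additionally absorbs
(i) the 21×21 large-structure mask and (ii) every other above-cutoff
component of at least `large_component_min_px` = 64 pixels.  Item (ii) is
needed because a median mask under-covers right-angle corners: at the corner
of an iris band only ~a quarter of the 21×21 window is bright, so the
corner survives the filter and would otherwise leak into the chamber as a
~35-px false "cell" (64 px is comfortably above the ~50 px upper end of
plausible cell sizes and far below any anatomical structure).  The chamber
is the remainder below the bottom envelope.  The three masks are asserted
disjoint and exhaustive on every scan.

## Artifact mask and candidate rule

The 21×21 median filter (replicate borders) preserves structures wider than
roughly half its kernel and erases isolated specks; pixels whose filtered
value exceeds the corneal cutoff form the large-structure mask.  The 3×3
median separates compact multi-pixel specks from single-pixel shot noise.  A
chamber pixel is a cell candidate iff

* its intensity exceeds the noise threshold, **and**
* its 3×3-median intensity exceeds the noise threshold, **and**
* it is outside the large-structure mask.

Requiring both intensity conditions makes the rule independent of whether
the median filter runs before or after thresholding.  A consequence worth
knowing: the 3×3-median condition needs a majority (≥ 5) of bright pixels in
some window, so no 4-pixel cell and no plus-shaped 5-pixel cell can ever be
detected — the corners of a 3×3 square cell are likewise trimmed, leaving
its 5-px plus.  This is intrinsic to the method, not an implementation
limit.  Finally, any column with ≥ `column_threshold` = 16 candidate pixels
is declared a vertical reflection artifact and cleared (no plausible cell
stacks 16 bright pixels in one column); cleared columns are recorded
per scan.

## Noise floor and cell extraction

Air-pixel intensities are pure instrument noise, strongly right-skewed (a
Shapiro test rejects normality, and mean + 2·SD sits far below the true
tail).  The detection threshold is the nearest-rank 99.5th percentile
(`noise_percentile`) of the air multiset — an observed integer value, no
interpolation — recomputed per image, which also absorbs global
brightness/exposure differences.  Candidates are grouped into 8-connected
components (8-connectivity keeps diagonal 2-px cells whole); components
below `min_pixels` = 2 are dropped (the 2-px floor follows the established
convention for this modality; a 1-px floor would admit residual shot
noise).  Components are ordered by bounding-box (y0, x0), so results are
independent of processing order.

## Cell geometry

The outer boundary of each component is traced through its outermost pixel
centres (Moore-neighbourhood tracing, clockwise, Jacob's stopping
criterion).  Perimeter `L` is the polygon arc length (axis steps 1, diagonal
steps √2); area `S` is the shoelace area.  A single pixel yields S = L = 0
by construction — degenerate cells are real observations, and their area is
reported as 0 rather than invented.  The eccentricity comes from the
closed form in the README; implementation details:

* if |L⁴ − 16π²S²| ≤ 1e-9·L⁴ the pair lies on the circle manifold up to
  rounding and e = 0 exactly;
* if L⁴ − 16π²S² < 0 beyond that tolerance, or S ≤ 0, or L ≤ 0, e is
  undefined and stored as missing — never coerced to 0 or 1, because both
  are meaningful shape values;
* the result is clamped to [0, 1].

Pixelation inflates the perimeter of small components, so e is biased high
for small cells (a 3×3 square measures e = 0.8744…) and the bias decays
only partially with size: rasterised ellipses at growing scales approach
√(1 − a²/b²) down to a residual of a few hundredths, because a staircase
boundary retains a perimeter excess at any scale.  No correction is applied;
cells with fewer than `eccentricity_min_pixels` = 3 pixels are excluded from
eccentricity statistics, and the bias is documented here instead of hidden.
Cell density is `cell_count / chamber_area × 10⁶` (cells per million
chamber pixels); it is undefined (and the scan `unanalyzable`) when the
chamber is empty.

Scans with mean intensity below `dark_image_floor` = 10 are flagged
`warning`: very dark images are where noise is most easily misrecognised as
cells.

## Phantom generator

`PhantomSpec` renders, deterministically per seed: a parabolic corneal band
(496×512 default, vertex row 190, thickness 42, Gaussian intensity 180±18);
an optional iris band with a central pupil gap (row 430, thickness 30,
150±18); speckle noise in air and chamber drawn from a two-component
mixture — a gamma body (shape 2, scale 8: mass essentially inside 0–60,
right-skewed, non-normal) plus a 0.7% "hot pixel" component uniform over
[60, 255]; planted cells as filled rasterised ellipses (pixel counts
lognormal with median 10, clipped to 4–20 by default; aspect ratio uniform
in [1.1, 2.2]; intensity 2× the theoretical noise threshold ±8), placed
non-overlapping with a 2-px moat, away from borders and ≥ 2 columns from
any line artifact; then full-height reflection lines and elliptical ghost
blobs; finally a global brightness offset, clipped to [0, 255].

Choices that matter:

* **Hot-pixel tail.**  With 8-bit data, a body-only noise distribution steps
  through its upper tail in increments of ~5·10⁻⁴ probability per grey
  level, so "0.5% of pixels above the 99.5th percentile" could never hold to
  statistical accuracy.  The sparse uniform tail (~3.6·10⁻⁵ mass per level)
  makes the percentile well-resolved; it emulates the occasional
  hyperreflective shot-noise specks real scans show, and it is what lets the
  calibration study close to within binomial error.  Its side effect: the
  phantom noise floor (~116) lies above the corneal cutoff (~56–90), so a
  solidly bright reflection line is absorbed by the corneal component and
  structure mask before the column rule ever sees it; the column rule is
  therefore validated directly on candidate rasters as well.
* **Cell sizes.**  The lognormal-around-10-px default represents a mid-grade
  image; given that sub-5-px cells are invisible to the 3×3-median rule by
  construction, a size floor of 4 px keeps a small (~1–2%) intrinsically
  undetectable fraction in the ground truth, which recovery metrics then
  honestly reflect.
* **Cohorts.**  `generate_cohort` draws per-scan cell counts Poisson around
  `density × chamber_area`, with one independent, reproducible random stream
  per scan (seed-sequence spawned from the cohort seed), so cohort results
  do not depend on generation order.  The default grade→density map
  (5/25/60/120/250/500 cells per 10⁶ px for 0+ … 4+) is strictly increasing
  with roughly geometric spacing, mirroring how clinical grades compress at
  the low end.

What the phantom does **not** emulate: physically realistic OCT speckle
correlation, frame averaging, corneal-thickness anatomy, cells touching
structures, and densities so high that cells merge (the paper-world analogue
of total hyphema).  Passing recovery tests on phantoms therefore shows the
pipeline implements its specification correctly, not that it meets any
clinical performance bar on patient data.

## Validation problem sizes

The acceptance suite and `scripts/acceptance.py` use: a 136-pair semi-axis
grid (a, b ∈ {0.5, …, 8}) for the closed form; 50 cell-free phantoms
(≈ 5.8M pooled chamber pixels) for noise calibration; 20 phantoms × 30 cells
for recovery (recall/precision thresholds 0.9, density ±10%); 12
line-artifact pairs (widths 1–3); a 6-grade × 20-scan cohort for
monotonicity (median density strictly increasing, rank correlation ≥ 0.95);
and 21 slices × 8 scans at constant density for the location null (every
slice median within 20% of the grand median).  These sizes put all binomial
and median sampling errors well inside the stated tolerances while keeping
the full run around a minute.

## Known limitations

* Cells adjacent to the cornea or iris are occluded by the structure masks
  and missed — a faithful reproduction of the method's acknowledged
  behaviour.
* Eccentricity is biased high for small cells (see above); comparisons are
  meaningful between groups measured the same way, not against analytic
  ellipse values.
* The histogram valley requires genuinely bimodal content; images that are
  almost entirely cornea or entirely dark fall back to Otsu or are excluded.
* The 16-px column rule assumes vertical reflection lines; oblique artifacts
  are only handled insofar as the 21×21 mask catches them.
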