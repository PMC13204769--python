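# Methods

`neglectscore` automates the scoring of six paper-and-pencil subtests used
to assess unilateral spatial neglect — three cancellation tasks (line
crossing, letter cancellation, star cancellation), line bisection, and two
figure copies (a four-pointed star and a diamond with a vertical midline) —
together with the battery-level arithmetic (standard values, subset
weighting, diagnostic cut-offs), inter-rater agreement statistics, and a
synthetic sheet generator that stands in for the copyrighted printed
materials and for clinical scans, which cannot be redistributed.

Everything is deterministic: no learned components, no stochastic steps at
scoring time. Re-scoring the same file always reproduces the same output,
so test–retest agreement of the automated scores is 100% by construction.

## Canonical coordinates

All geometry is expressed in *canonical pixels*: every page is rescaled so
its width equals 1400 px (A4 portrait, ≈0.15 mm/px), making the figure-copy
drawing region 1000 px wide. The copy-scoring thresholds quoted in pixels
(e.g. 100 px radial consistency, 200 px span difference) are meaningful
only at a fixed working resolution; this package pins that resolution and
exposes it, like every other threshold, in `PipelineConfig`.

## Image pipeline

1. **Orientation.** A solid arrow printed near the bottom edge marks the
   bottom of the page. Orientation is chosen among the four cardinal
   rotations by maximizing arrow-region ink density plus a
   printed-template registration score; templates without a fiducial fall
   back to registration alone.
2. **Rescaling** to canonical width (aspect preserved, page padded or
   cropped to the canonical height).
3. **Deskew.** Scanner-style affine skew within ±6° is estimated
   coarse-to-fine (1° → 0.2° → 0.05° grids) on a 5× downsampled page. With
   a template available the objective is registration against the rendered
   printed layer — the periodic target grids make this sharply unimodal —
   otherwise the variance of row/column projection profiles. Corrections
   below 0.1° are not applied, which makes normalization idempotent: an
   already-normalized page passes through bit-identically.
4. **Ink isolation.** The page is binarized with a global Otsu threshold
   (capped at 180, manually overridable); a registered render of the
   printed template, dilated by 3 px, is subtracted; connected components
   below 12 px are removed as noise. Intensities between the threshold and
   near-white (245) count as *faint* ink: when faint ink dominates
   (ratio > 0.6), the sheet is flagged `low_contrast` — the signature of
   thin pencils or red pens that also defeat manual scoring.
5. **Quality control** is a deterministic flag set: `low_contrast`,
   `excessive_noise` (isolated-speck density > 1e-4/px²),
   `distorted_print` (template registration < 0.55),
   `out_of_region_drawing`, `multiple_bisection_marks`, `no_fiducial`.
   Flagged sheets are scored where possible but marked for manual review.

Template subtraction is possible because the layout template carries
enough information to re-render the printed layer exactly; for scanned
commercial sheets the same role would be played by a registered blank
scan. Keystone (perspective) correction is out of scope: inputs are
assumed to come from flatbed or sheet-fed scanners.

## Cancellation scoring

A target counts as crossed when the patient-ink fraction of a 51×51 px
window centred on the target reaches 0.003. On clean renders the
separation is wide — uncrossed targets score exactly 0 after template
subtraction, crossed targets ≥ 0.005 even when the stroke largely overlaps
the printed glyph — and windowed coverage makes detection monotone in ink
(zigzag or repeated crossings count once). Known, deliberately tolerated
failure mode: a marking that traces the printed contour adds almost no ink
outside the subtracted template and is not detected. Left/right counts
come from the template's side labels; middle-column targets and the
examiner's demonstration targets (flagged `excluded`) never contribute.
The laterality index (R−L)/(R+L) summarizes the spatial gradient; the full
center-of-cancellation statistic is out of scope.

## Line bisection

The mark on each of the three lines (top/middle/bottom) is the
ink-weighted centroid of the crossing cluster inside a ±15 px band;
clusters separated by more than 40 px mean multiple marks → the sheet is
unscorable (matching the scan-exclusion rules). The signed deviation from
the true midpoint maps through nested bands to 3/2/1/0 points. The
commercial scoring-template widths are not public, so the bands are
fractions of the half-line length — 3 points within 10%, 2 within 25%,
1 within 50% — configurable and documented as a dialect. Inner boundaries
are closed (a deviation exactly on a boundary earns the higher score);
zero deviation serializes with no direction letter.

## Figure-copy scoring

Corners are detected on a radial outline profile: the maximum ink radius
per 1° angular bin around the drawing's centroid. Profile maxima are outer
tips (star) or corners (diamond). Empty bins (stroke gaps) are bridged by
circular interpolation so stroke ends do not masquerade as corners. A
star's inner vertices are *not* taken at profile minima — for blunt stars
the radius minimum of a straight edge lies mid-edge, not at the vertex —
but as intersections of principal-axis line fits to the two edges of each
wedge, which recovers vertex positions to ~1 px and angles to ~0.1° on
clean strokes. Measured angles are quantized to 0.1° before threshold
comparison so drawings exactly on a printed boundary are not tipped over
by sub-resolution fit noise.

The archetype anchors an idealized polygon to the detected corners (outer
tips exact, star inner vertices snapped to their class-mean radius), so it
translates and scales with the drawing. Overshooting corrected strokes
inflate it — a documented failure mode that then fails the shape
criterion. Edge presence = ink coverage ≥ 0.75 inside a ±7 px corridor
along each archetype edge *and* no uncovered run longer than 14 px (the
closure tolerance); tremor-induced waviness within the corridor is
tolerated, larger gaps are not.

Star criteria (thresholds as printed, in canonical px/degrees): shape
requires all edges present and per-class corner radii within 100 px of
their class mean; detail requires shape and exactly 8 corners; arrangement
requires axis-aligned span difference ≤ 200 px, opposing-tip misalignment
≤ 200 px (the more-horizontal opposing pair is checked for Δy, the other
for Δx), inner-corner spacing deviation ≤ 100 px, and all tip angles
within 40° of the expected 110° with at least two within 30°. The
span/alignment checks are axis-aligned, so arrangement is deliberately not
rotation invariant: a perfect star rotated 45° fails via opposing-tip
misalignment (its axis-aligned spans are actually unchanged — the
misalignment term is what carries the axis-alignment dialect). Note that a
four-pointed star with alternating vertices cannot open wider than 135° at
the tips, so the strict-angle rule is exercised from the sharp side (70°
tips: deviation 40° passes the outer rule, no angle within 30° fails the
strict rule).

Diamond criteria: shape requires all four outer edges closed; detail
requires the vertical midline, detected in a ±9 px corridor between the
top and bottom corners with endpoint capture windows of 25 px — a midline
detached from the corners by more than that counts as absent (reproducing
the documented misclassification when the midline floats free);
arrangement allows at most one of the four midline-to-edge angles to
deviate from 45° by more than 7°. Besides the plain NET sum, a
hierarchical variant gates detail on shape and arrangement on both. The
BIT-style binary completeness score is shape ∧ detail for both figures.

## Battery arithmetic

Raw scores convert to NET standard values (0–10 in 0.5 steps). Only the
letter-cancellation table is public (0–1 → 0, 2–3 → 0.5, … , 40 → 10);
the other subtests ship proportional stand-in tables (raw/raw_max × 10,
floored to 0.5 steps) as editable config — owners of the test manuals
should substitute the official tables. Subset weighting preserves the full
battery's incidental weighting: weight_s = max_s / Σ max; for the
published subset {40, 9, 1, 1, 1, 1} this yields 75.47 / 16.98 / 1.89 (%),
a maximum weighted total of 31.79, and a neglect cut-off of 28.09
(≤ 129/146 = 88.36% of the subset maximum). NET severity bands rescale the
full-battery cut-offs 72/135/166 of 170 proportionally (25.41 / 47.65 /
58.59 for an SV maximum of 60). Boundary arithmetic uses raw fractions and
rounds half-up at 2 decimals; the battery total sums exact SVs before any
rounding.

## Synthetic sheets

The generator emulates the *geometric and statistical* structure the
scorer consumes, not visually realistic handwriting. Layouts are an
original dialect of the same geometry class as the commercial sheets
(printed target grids with 36–48 scoreable targets and a 40-target letter
grid matching the published maximum; three staggered 800 px bisection
lines; 1000×1000 px drawing regions; a bottom-of-page arrow on every
sheet). The response model:

- **Cancellation.** P(cross) = 1 − s·σ(k(m − u)) with steepness k = 8 and
  midpoint m = 0.35 over the normalized horizontal position u; s = 0
  crosses everything, s = 1 leaves the leftmost targets crossed with
  probability ≈ 0.057 — a closed form the Monte-Carlo tests check against.
- **Bisection.** Offset ~ N(s · 0.35 · half-length, 10 px), rightward bias
  as in left-neglect; explicit per-line offsets for controlled tests.
- **Copying.** Parametric star/diamond polylines with optional vertex
  jitter, sinusoidal tremor, per-edge gaps (left-biased with severity),
  deleted tips, and exact angle prescriptions for sweep tests.

Scan corruption (small rotation, salt-and-pepper specks, faint-pen
contrast fading applied to the ink layer only) is drawn from a named RNG
substream, so toggling corruption never changes the simulated responses.
Ground truth records every stochastic choice; rendering is a pure function
of (spec, seed).

What passing tests show — and what they do not: clean synthetic sheets
have perfectly registered prints, single-stroke responses and no touching
marks, so exact recovery demonstrates the correctness of the geometry and
the scoring rules, not robustness to degraded clinical scans (overlapping
corrections, contour-hugging marks, print defects), which is exactly the
regime where the quality-control flags route sheets to manual review.

## Agreement statistics

Implemented from their defining formulas (no wrapper around an existing
implementation, which instead serves as an independent oracle in the
tests): Krippendorff's alpha in the coincidence-matrix form with
nominal/ordinal/interval metrics and missing data; weighted Cohen's kappa
(linear weights by default — the weighting scheme used in the original
ratings is not stated, so the default is documented, not asserted);
ICC(A,1) from the two-way mean-square decomposition with the McGraw–Wong
F-based confidence interval; tie-corrected Kendall tau-b (scores are
heavily tied); exact/within-±1 agreement, mean absolute difference; and
2×2 diagnostic concordance (sensitivity = N+ recall) with a rank-based AUC
when continuous scores are supplied. Degenerate inputs follow the stated
conventions: zero expected disagreement → alpha/kappa 1 with a warning;
zero total variance → ICC undefined (missing).

## Problem sizes used in the test suite

The acceptance-style suites run 200 clean sheets per cancellation subtest
(counts must match ground truth on every sheet), 500 sampled bisection
offsets away from band boundaries plus 25 fully rendered sheets, a 15-step
diamond angle sweep and star corner/angle sweeps, a re-scored 2-patient
fixture batch for byte-level determinism, brute-force oracle equivalence
at 1e-10 on 12-unit matrices, and 1000-seed Monte-Carlo checks of the
severity model — sizes chosen so the whole suite completes in a few
minutes on one CPU while leaving the statistical checks well-powered.

## Known limitations

- Flower, Necker-cube and clock-drawing subtests are not automated (high
  idiosyncratic variability; rule-based vision is a poor fit).
- No perspective correction; photographed pages are out of scope.
- Corrections, clinician-added marks and multiple midpoints are not
  disambiguated — they are flagged for manual review instead.
- Bisection endpoint-weighted bias indices and the center-of-cancellation
  statistic are not computed.
- The per-subtest SV tables other than letter cancellation are
  proportional stand-ins, clearly marked as such in the config.
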