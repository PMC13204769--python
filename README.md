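# neglectscore

Deterministic computer-vision scoring of the paper-and-pencil subtests
used to assess **unilateral spatial neglect** after stroke — the three
cancellation tasks (line crossing, letter cancellation, star
cancellation), line bisection, and figure copying (four-pointed star,
diamond with vertical midline) — plus the battery-level arithmetic
(standard values, subset weighting, diagnostic cut-offs), agreement
statistics for validating automated against human scores, and a seeded
synthetic sheet generator with exact ground truth.

It is written for neuropsychologists and researchers who score these
batteries from flatbed scans and want reproducible, rule-transparent
results: the pipeline operationalizes the printed scoring criteria
explicitly (no learned components), so identical inputs always produce
identical scores and every decision can be inspected on an overlay image.

## The scoring model in brief

- **Cancellation:** a printed target is *crossed* when the patient-ink
  fraction of a window around it reaches a threshold; scores are the
  left/right/total counts `(LS, RS, total)` plus the NET standard value
  SV ∈ {0, 0.5, …, 10}. A laterality index (R−L)/(R+L) summarizes the
  spatial gradient of omissions.
- **Line bisection:** the mark's signed deviation d from the true midpoint
  maps through nested bands (fractions of the half-line length) to
  3/2/1/0 points with an L/R direction flag; the subtest score is the sum
  over the three lines (0–9).
- **Figure copying:** corners are detected on the radial outline profile
  of the drawing, an idealized archetype is anchored to them, and three
  binary attributes are scored — shape (all edges present within a
  closure tolerance, consistent radial structure), detail (all corners /
  the midline), arrangement (spans, tip alignment, angles: 110° ± 40°/30°
  for the star, 45° ± 7° for the diamond, at most one violation) — plus
  the BIT-style binary completeness score = shape ∧ detail.
- **Battery:** subset weight_s = max_s / Σ max (for the published subset
  {40, 9, 1, 1, 1, 1}: 75.47/16.98/1.89 %); weighted total ≤ 31.79 with
  neglect cut-off ≤ 28.09 (the 129/146 = 88.36% criterion rescaled); NET
  severity bands 72/135/166 of 170 rescaled to the administered subset
  (25.41/47.65/58.59 for an SV maximum of 60).

See `docs/methods.md` for the full account, including every numeric
default and the known failure modes.

## Worked example

Generate a three-patient synthetic batch (severities 0, 0.45, 0.9) and
score it:

```bash
neglectscore make-synthetic --out demo --patients 3 --seed 42
neglectscore score-batch demo --out demo/report.csv
```

The report contains one row per patient (selected columns):

```
patient_id,LetC_LS,LetC_RS,LetC,LetC_SV,LineB_T,LineB_M,LineB_B,LineB,LineB_SV,BIT_weighted_total,BIT_diagnosis,NET_SV_total,NET_severity
P000,20,20,40,10.0,3R,3L,3L,9,10.0,39.13,N-,60.0,none
P001,9,20,29,7.0,2R,2R,2R,6,6.5,31.93,N+,43.0,strong
P002,5,19,24,6.0,1R,1R,1R,3,3.0,24.21,N+,34.0,strong
```

P000 (severity 0) crosses all 40 letters (SV 10), bisects all three lines
in the innermost zone (9/9) and reaches the battery maximum: no neglect.
With rising severity the left-side letter count collapses (20 → 9 → 5
while the right side stays near 20), bisection marks drift rightward
(`3R` → `1R`), the weighted total falls through the 28.09 cut-off
(`N+`), and the NET SV total drops into the *strong neglect* band
(25.42–47.65 of 60).

A single sheet prints its per-subtest tuple:

```bash
$ neglectscore score-single line_bisection demo/P002_line_bisection.png \
      --template demo/templates/line_bisection.yaml
(1R, 1R, 1R, 3, 3.0)
```

— one point per line, every mark right of centre, subtest score 3, SV 3.0.

`compare-scores ref.csv pred.csv` computes the agreement panel (exact
agreement, within ±1, mean absolute difference, ICC(A,1) with CI,
weighted kappa, Kendall tau-b) per shared column.

## Scope

Clock drawing, Necker-cube and flower copying are not automated; no
perspective correction of photographed pages; corrections and multiple
midpoint marks are flagged for manual review rather than adjudicated. Use
with the commercial batteries requires lawful access to the official test
materials; the bundled layouts are an original dialect for development
and testing.
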