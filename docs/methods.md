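# Methods

## The measurement being modelled

The niacin skin flush test applies nicotinic-acid solutions (0.1, 0.01,
0.001 M) to forearm skin on 2×2-cm papers and records the erythema with a
fixed camera in a closed, constantly lit chamber: one frame every 60 s
for 15 min, i.e. 15 frames per concentration. The analysis quantifies the
reaction as *differential* colour features — a descriptor computed inside
a reaction patch minus the same descriptor in unexposed control skin of
the *same* frame — which removes the subject's baseline skin tone and
residual illumination. Feature keys are
`<channel><statistic>_<index>_<code>`; frame *k* (1-based) carries
timestamp (*k* − 0.5) minutes, the only assignment consistent with index
3 ↔ 2.5 min and index 6 ↔ 5.5 min, and codes A/B/C are 0.1/0.01/0.001 M
by descending molarity (only A is named in the source material; B/C
follow by order).

## Colour model

The hue/saturation/value construction is implemented exactly as the
acquisition method defines it:

    θ = arccos[((R−G) + (R−B)) / (2·√((R−G)² + (R−B)(G−B)))]   (degrees)
    H = θ if B ≤ G else 360 − θ
    S = 1 − 3·min(R,G,B)/(R+G+B)
    V = max(R,G,B)

This is the HSI-style hue/saturation, not the standard hexcone HSV; it is
kept verbatim deliberately rather than substituted with a library
conversion. The radicand equals (a − b/2)² + 3b²/4 for a = R−G, b = R−B,
so it is non-negative and vanishes exactly for achromatic pixels; there
H := 0, and S := 0 when R+G+B = 0. H is differenced as plain degrees (no
circular statistics) — adequate for skin hues far from the 0/360 wrap,
and flagged here as a simplification.

Descriptors per channel and ROI: mean, median, mode, min, max, range.
The mode is taken on an integer-binned histogram (whole intensity levels
for R/G/B/V, whole degrees for H, 1/255 steps for S), ties resolved to
the smallest bin. For a constant ROI the mean/median are returned as the
value itself, exactly, so the zero-response null case propagates to
exactly-zero differential features.

## Synthetic cohort generator

No imaging data were deposited with the source study, so the generator is
the test bed for every downstream stage. It emulates:

- **Cohort structure** — default group sizes 33 FEP / 22 BD / 13 SA /
  13 CS / 39 HC (the study's design), with metadata sampled around the
  published cohort descriptives (patient median BMI ≈ 24.6 vs 21.3 kg/m²,
  physical activity 0 vs 45 min/week, PANSS ≈ 74, olanzapine equivalents
  ≈ 25 mg, etc.). Disease-related fields are NaN for HC.
- **Flush response** — each frame shows all three patches (vertical
  column, descending molarity); a patch's colour shift is
  `amplitude(group, concentration) × subject_factor × kernel(t)`.
  The three per-concentration sequences of a subject share the same
  rendered frames, which is how a single 15-frame recording yields 15
  frames for *each* concentration.
- **Temporal kernel** — a log-normal bump
  `exp(−ln²(t/t_peak)/(2σ²))`, 0 at t = 0, exactly 1 at the peak
  (default 4 min, inside the diagnostically informative 2.5–5.5-min
  window), width σ = 0.6. The source material describes formation and
  disappearance but no functional form; this shape (fast rise, slow
  decay, continuous) is a design choice of this package.
- **Amplitudes** — default peak shift for HC at 0.1 M is
  (ΔR, ΔG, ΔB) = (45, 30, 22) intensity units, scaled per group
  (HC 1.0 > BD 0.6 > FEP 0.45 > SA 0.3 > CS 0.15 — controls flush fully,
  chronic schizophrenia is most blunted) and per concentration
  (1.0 / 0.35 / 0.1 — only 0.1 M reacts strongly). These orderings encode
  the qualitative blunted-response findings; the absolute values are
  generator choices with no published counterpart.
- **Baseline skin** — per-subject RGB baseline ~ N((150, 115, 95), 10²)
  per channel, clipped to [0, 255], exercising the control-normalisation.
- **Noise** — i.i.d. Gaussian per pixel per channel (default SD 2), then
  rounding and clipping to 8-bit. Subject-level variability is a
  log-normal amplitude factor (σ = 0.15).
- **Confounding (optional)** — `confound_spec` adds β × standardised
  covariate to all channel amplitudes, giving the exclusion stage true
  positives to find.
- **Geometry** — square patches (default 40 px on 480×640 frames; the
  physical 2-cm paper has no fixed pixel scale) and a square control
  region offset to the side. Ground-truth masks, baselines and amplitude
  trajectories are returned for oracle tests.

Not emulated: photorealistic skin texture, illumination drift, camera
sensor effects, inter-subject variability in flush *timing* (all subjects
share the kernel). Passing tests therefore demonstrate the correctness of
the computational pipeline under the stated statistical structure, not
performance on real skin images.

## Feature selection

Fixed order, each stage consuming the previous stage's survivors:

1. **Screening** — per feature, Shapiro–Wilk in each class; both normal →
   Student's t, else Mann–Whitney U; keep if p < α = 0.05. Constant
   features are flagged degenerate and dropped. No multiple-testing
   correction, matching the raw-threshold screening of the original
   procedure (an FDR switch would be a natural extension but is not the
   default, as a faithfulness choice).
2. **Confounder exclusion** — factors: age, gender, chronic disease,
   family history, BMI, physical activity, smoking; assessed separately
   in the pooled patient group and in HC. Continuous factor: Pearson if
   feature and factor both pass Shapiro–Wilk in that group, else
   Spearman; binary factor: Mann–Whitney across levels. One significant
   association in either group removes the feature regardless of effect
   size (p-only criterion). Factors constant within a group are skipped
   and logged.
3. **Disease-related exclusion** — same logic, patients only, factors:
   illness duration, hospitalizations, olanzapine equivalents, PANSS
   total. Supplying HC rows is a hard error.

α = 0.05 everywhere. Results are invariant to row/column order; factor
ordering affects only which trigger is listed first in the ledger, since
any single hit removes a feature.

## C&RT and ROC

Greedy binary partitioning maximising Gini impurity decrease. Split
candidates are midpoints of consecutive sorted unique values; a split
must leave ≥ `min_leaf` (default 5) on each side; growth stops at
`max_depth` (default 3) or when the best decrease is below 1e-4. Ties in
impurity decrease are broken toward the lexicographically smallest
feature, then the smallest threshold, so fits are deterministic. Values
equal to a threshold go to the "≤" branch, matching the cut-off phrasing
"less than or equal to". No surrogate splits: missing features at
prediction time are hard errors (synthetic data is complete). The Gini
criterion itself is a documented assumption — the original analysis names
only the C&RT algorithm, and Gini is that family's default.

ROC curves sweep the unique scores high→low with tied scores moving as a
block; the trapezoidal area then equals the pairwise concordance
probability with ½ credit for ties (verified against a brute-force
pairwise oracle and against scikit-learn in tests).

## Published rule encoding

The seven pairwise comparisons are shipped as ordered "≤ cut-off"
cascades with their published AUCs (FEP/HC 0.80, CS/HC 0.90, SA/HC 0.79,
BD/HC 0.64, FEP/CS 0.86, SA/CS 0.89, BD/SA 0.80); all splits use 0.1 M.
Two places in the source material disagree between the summary table and
the narrative on a time point or statistic (SA vs CS; BD vs SA); the
table's coordinates are kept and each affected rule carries a note. The
FEP-vs-CS second split names no statistic in the narrative; mean is
assumed and noted. The full branch topology of the published trees is not
available in the text, so rule application uses the conjunctive reading
consistent with the published leaf descriptions: the "≤" side of every
split is the blunted-response branch, a record exits to the
stronger-flush group at its first "> cut-off", and for patient-vs-patient
comparisons the blunted side is the more chronic group (CS, then SA).
The pooled patients-vs-HC tree is deliberately not encoded: its
thresholds were never printed.

## Integration

Variables appearing in ≥ 2 comparisons' rule sets are "shared" and
removed from every characteristic list; the remainder characterise their
comparison. The alternative reading ("repeated within two diagnostic
groups") is not implemented; the report output states the interpretation
used. Integration runs after ROC evaluation — reported AUCs always
reflect full trees — and never alters thresholds.

## Problem sizes and numerical choices

The analysis drivers and tests run the imaging pipeline at reduced
resolution (160×200-px frames, 16–20-px patches) and the statistical
test beds at n = 40–400 subjects and 100 replicates — sizes chosen so the
complete study re-runs in minutes on one core while keeping every
Monte-Carlo check well-powered. Segmentation uses Otsu thresholding of
the colour deviation from the frame's median skin tone with
morphological opening/closing; when any expected patch has no matching
component (weak or absent reaction — by design true for the 0.01 and
0.001 M patches under default amplitudes), the layout-prior rectangles
are used and a warning is logged, the automated analogue of manual ROI
correction. The acceptance script reduces its `--seed` modulo 2²⁰ before
deriving per-replicate seeds so all generator seeds stay far below 2³¹.

## Known limitations

- The published variable counts (1184 screened → 469 → 137 → 84) are
  cohort-dependent and cannot be reproduced without the original images;
  the package reproduces the *procedure* and reports its own counts. The
  implemented full feature grid has 3 × 15 × 6 × 6 = 1620 keys; which
  subset produced the published 1184 is not stated in the source.
- Published AUCs (0.64–0.90) describe the original 120-subject clinical
  cohort; synthetic-cohort AUCs reflect generator settings and validate
  the pipeline, not the clinical claim.
- Hue differencing is linear, not circular.
- Whether H/S/V differentials should be computed from differenced RGB or
  differenced independently is ambiguous in the source; this package
  differences each channel's descriptors independently.
- Video container decoding is out of scope; frame directories are the
  canonical input.
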