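# Methods

## The problem

Pneumothorax (PTX) — air in the pleural space — abolishes the sonographic
signs of apposed, aerated lung at the probe site. On B-mode, normal lung
shows the pleural line shimmering "to and fro" with respiration (pleural
sliding) and may show vertical B-line/comet-tail reverberations that arise
at the visceral pleura; both exclude PTX at that interspace. On M-mode,
normal sliding scatters granular speckle below the pleural line (seashore
sign), while PTX freezes the sub-pleural field into horizontal lines
(stratosphere/barcode sign). `pleurascan` implements a rule-based detector
for these signs, a seeded phantom generator that renders them with known
ground truth, and the reader-study statistics used to evaluate such a
detector against an expert reference.

## B-mode pipeline

Stages run on normalized [0, 1] intensities, row 0 at the skin surface.
Static-structure stages use the temporal median frame, which is robust to
sliding motion.

1. **Rib shadows.** A shadow is a maximal run of columns (width ≥ 8 px)
   whose mean intensity over the deep half of the median frame falls below
   0.5× the deep-half global mean. The rib cap is the brightest row above
   the deep half within the run. A uniform image yields no shadows because
   no column can fall below half the common mean.
2. **Intercostal space.** The widest gap between two consecutive shadow
   intervals, shrunk by a 4-px margin per side; fewer than two shadows, or
   a shrunk gap under 20 px, means no space and an indeterminate exam.
3. **Pleural line.** Among rows strictly below the deepest rib cap, a row
   qualifies when ≥ 60 % of space columns reach 1.5× the mean intensity of
   the search region; the brightest qualifying row wins. The reference
   mean is floored at 0.02 so an all-black clip reports "no line" rather
   than fitting a degenerate one. The threshold is deliberately relative
   to the *region* mean, not the row's own mean — a uniformly bright line
   can never exceed a multiple of its own mean, so a row-relative test
   would reject exactly the lines it is meant to find.
4. **Sliding.** A strip of 6 rows starting 2 rows below the fitted line,
   restricted to the space columns, is matched between consecutive frames
   by integer-shift normalized cross-correlation over ±10 px (ties break
   toward zero shift; variance-free strips report zero). Sliding is called
   when the half peak-to-peak excursion of the cumulative displacement is
   ≥ 1.5 px **and** the displacement sequence reverses sign at least once.
   The sign-change requirement operationalizes "to and fro": a monotone
   drift (e.g. probe slip) of any amplitude is not sliding.
5. **Reverberation.** Per space column, the penetration score is the
   fraction of rows from 4 rows below the line to the bottom edge whose
   intensity reaches 0.5× the fitted line brightness. An artifact band is
   ≥ 3 consecutive columns with scores above 0.6. Because detected
   reverberation counts as evidence *against* PTX in the decision rule,
   reverberation is modeled as vertical B-line-like bands; horizontal
   A-lines (which classically accompany PTX) are not rendered by default
   and not scored. This rule-level ambiguity is inherent to the method
   being implemented and is flagged here rather than resolved.
6. **Decision.** No pleural line → indeterminate (dominates everything);
   sliding or reverberation → negative; neither → positive. Too few frames
   (< 3) for motion analysis becomes indeterminate with a recorded reason,
   never a crash.

## M-mode pipeline

The pleural line is the brightest contiguous row (same contiguity test as
B-mode) outside the top 5 rows, a guard against near-field skin
reverberation; the guard excludes those rows from candidacy, so a bright
superficial band simply cedes to the next-best row. Texture below
`depth_row + 3` is scored by the per-row temporal coefficient of variation
(cv = std/mean along the sweep). Rows constant in time have cv ≈ 0; fully
developed Rayleigh speckle has cv ≈ √((4−π)/π) ≈ 0.52, so a cv threshold
of 0.1 separates the regimes with a wide margin. Rows with mean below 0.02
are scored cv = 0 (an echo-free region cannot show granular motion). The
`barcode_fraction` — the share of sub-pleural rows with cv < 0.1 — drives
the call: ≥ 0.6 → positive (stratosphere), otherwise negative (seashore);
no line → indeterminate, extending the B-mode rule. cv is scale-free, so
the scores are invariant under global intensity rescaling as long as no
row crosses the mean floor. Only the sub-pleural region is used; the
static supra-pleural layers are not needed as a reference because cv is
already normalized per row.

## Phantom generator

The generator renders exactly the features the detector keys on, in
rectangular (linear-probe) geometry; phased-array exams are the same
rectangle flagged `transducer="phased"`, since the detection logic is
geometry-agnostic. Background tissue is multiplicative Rayleigh speckle
(scale 0.15 by default, clipped to [0, 1]) — the standard first-order
model of fully developed ultrasound speckle. Rib caps are 0.9-intensity
blocks at 30 px depth; columns below a cap are attenuated ×0.15
(posterior shadowing). The pleural band (brightness 0.95, 2 px thick,
default depth 60 px) spans the non-rib columns. Sliding is rigid lateral
translation of the sub-pleural speckle by `round(A·sin(2πt/P))` px per
frame — supra-pleural tissue static — with the shift table exposed as
ground truth (`PhantomConfig.shift_sequence`). B-lines are bright
(0.85) vertical bands baked into the moving sub-pleural field, spanning
pleura to bottom edge. No frame-wise noise is added, so a zero-sliding
exam is pixel-identical below the pleura across frames.

M-mode phantoms place static horizontal bands above the pleura; below it,
seashore draws independent speckle per (row, column) and stratosphere
draws one value per row held across the sweep.

Label semantics follow the clinical signs: a negative (no-PTX) exam must
carry at least one sign of aerated lung (sliding and/or B-lines); a
positive exam carries neither. Every output is a pure function of
`(config, seed)`.

**Cohorts.** `make_cohort(n_positive, negative_ratio, ...)` renders
`n_positive` positives plus `round(ratio · n_positive)` negatives — the
2:1 negative:positive plan of the original reader study corresponds to
`(49, 2.0)` → 147 exams — with per-exam nuisance jitter: rib centers
±6 px, cap depth ±4 px, pleural depth 50–72 px, speckle scale 0.10–0.22,
sliding amplitude 2.5–6 px over an 8–12-frame period, 1–2 B-lines, and a
negative-sign profile of sliding-only/B-lines-only/both at 0.4/0.3/0.3.
Metadata nuisance (20 % M-mode, 60 % linear transducer, quality scores
3/4/5 at 0.34/0.51/0.15) echoes the marginal composition of the original
study's image set. Output order is randomized by the same seeded stream.

**What the phantoms do not emulate:** sector-geometry scan conversion,
depth-dependent attenuation and focusing, cardiac "lung pulse" motion,
A-line reverberations (generatable in principle but off by default, per
the decision rule above), probe motion, and compression artifacts of
clinical video export. Passing the recovery tests therefore shows that
the pipeline implements its stated rules faithfully on clean realizations
of the signs, not that it would reach the same accuracy on archived
clinical images — on the real reader study the original algorithm reached
79 % sensitivity and 87 % specificity, well below its phantom ceiling.

## Evaluation statistics

* **Adjudication.** An exam enters analysis only when all raters (≥ 2)
  agree; under the quality rule the median ACEP quality score must be ≥ 3
  (scores 1–2 are non-diagnostic by convention). Non-unanimous exams are
  flagged for plenary review, which is a human step outside this package.
  Disagreement takes precedence over low quality when both apply, since a
  disagreeing panel would meet regardless of image quality.
* **Confusion matrices.** Positive = pneumothorax. Reference-indeterminate
  exams are always excluded; algorithm-indeterminate calls follow an
  explicit policy (`exclude`, or `as_error` counting them against the
  algorithm), because published 2×2 tables rarely state which convention
  produced them.
* **Proportion CIs** are exact Clopper–Pearson, computed from beta
  quantiles: lower = B(α/2; k, n−k+1), upper = B(1−α/2; k+1, n−k), with
  the k = 0 lower bound and k = n upper bound exactly 0 and 1. The test
  suite checks every (k, n) with n ≤ 50 against an independent bisection
  of the exact binomial tail sums. Percentages round half away from zero.
  Zero-denominator statistics are reported as explicitly undefined,
  never 0.
* **Cohen's kappa** κ = (p_o − p_e)/(1 − p_e) is computed in integer
  arithmetic (so the worked 45/5/5/45 table gives exactly 0.8), with the
  large-sample CI κ ± z·√(p_o(1−p_o)/n)/(1−p_e) clipped to [−1, 1], and
  the conventional bands: > 0.75 excellent, 0.40–0.75 fair to good. κ is
  undefined (raises) when expected agreement is 1.
* **Stratified reports** partition by ACEP quality, imaging mode, or
  transducer; stratum matrices sum cell-wise to the overall matrix, and
  empty strata are reported as undefined rather than dropped.

## Numerical and design choices

* Intensities normalized by dtype maximum; out-of-range floats raise
  rather than clamp, so no reader silently alters data.
* All detector thresholds live in two frozen dataclasses (`BModeParams`,
  `MModeParams`) with the defaults above; every classification records a
  parameter snapshot in its result.
* Cross-correlation uses integer shifts only; sub-pixel refinement is
  unnecessary at the 1.5-px decision threshold.
* The maximum search shift adapts downward for narrow spaces
  (`min(max_shift, (width−2)//4)`) so the correlation window never
  degenerates.
* Problem sizes: the recovery experiments use 128×192-px, 16-frame clips
  in cohorts of 200 (B-mode) and 40 single images (M-mode) — large enough
  that every detector stage operates in its intended regime while a full
  run completes in seconds.
* DICOM is not parsed; the package standardizes on TIFF/PNG plus JSON
  sidecars. Video codecs, scan conversion, and multi-interspace scanning
  are out of scope.

## Known limitations

Thresholds were chosen for normalized linear-geometry images and may need
retuning for curvilinear or heavily post-processed exports. The sliding
test assumes the probe is still; gross probe translation produces a
monotone drift that is correctly rejected, but periodic probe motion
could masquerade as sliding. The M-mode classifier assumes the sweep is
long enough (≥ 8 columns) to estimate per-row temporal variation. The
phantom's idealizations (listed above) mean recovery rates near 1.0 on
synthetic cohorts are an upper bound, not a clinical accuracy estimate.
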