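# Methods

## Scoring model

The unit of observation is the quartet: four neighbouring spots of one
bait–TF transformant on a 1536-position selection plate (16 × 24 quartet
grid). All statistics operate on the natural log of colony pixel areas.
Under the null (no interaction), quartet mean ln-areas on a plate are
treated as approximately normal; an interaction shows up as a positive
shift of one quartet against the plate's own background. Because the signal
of interest is growth *above* background, p-values are one-sided upper-tail
normal probabilities of the quartet Z-score.

### Quartet QC

Filters are applied in a fixed order; the first failing rule sets the
exclusion status:

1. fewer than two present, circular colonies (a single colony cannot be
   distinguished from a stray; zero colonies are even less informative, so
   the "one detectable colony" rule is read as "fewer than two");
2. mean ln-area < 2 (≈ 7 pixels — background-level growth);
3. index of dispersion > 0.2, computed as sample variance (n−1 denominator)
   divided by the mean of the ln-areas.

Both the mean and the dispersion operate on the ln-areas of detected,
circular colonies only; absent spots are not zero-filled. Exclusion uses
strict inequalities, so a quartet at mean exactly 2 or dispersion exactly
0.2 survives. A pixel area of 0 means "no colony detected", never ln(0).

### Per-plate background

Pipeline order: **edge correction → Grubbs screening → background
estimation → Z-scores**. Edge correction precedes outlier screening because
Z-scores are defined on edge-corrected values and the background
distribution is both outlier-screened and edge-corrected; applying the
systematic (spatial) correction before the distributional screen avoids
flagging edge quartets as outliers when the plate has a real edge gradient.

* **Edge correction.** Edge stratum = quartets with row ∈ {1,2,15,16} or
  column ∈ {1,2,23,24} (144 positions); interior = the other 240. The test
  is Welch's t (strata sizes differ and variances need not match; a pooled
  variant is available) at α = 0.05. When significant, edge values are
  shifted by −(mean_edge − mean_interior). The shift is signed: an edge
  *deficit* is corrected upward by the same rule, rather than leaving that
  branch undefined.
* **Grubbs screening.** Two-sided, iterative: remove the most extreme value
  while G = max|xᵢ − x̄|/s exceeds
  ((n−1)/√n)·√(t²/(n−2+t²)), t the upper α/(2n) Student-t quantile on n−2
  df; α = 0.05. One removal per iteration, statistics recomputed after each.
  Zero-spread input yields no outliers; screening stops if fewer than three
  values remain.
* **Z-scores** use the survivors' mean and sample (n−1) sd. Every
  QC-passing quartet is scored, including the Grubbs-removed ones (that is
  the point of the screen: outliers are candidate interactions, removed
  only from the background estimate). Control quartets (untransformed and
  AD-only positions) contribute to the background but are never eligible to
  be called. Plates with fewer than three usable quartets or degenerate
  spread are unscorable; their pairs are reported as untested.

### Calling

An interaction is called when the same (bait, TF) pair is significant
(p < 0.005, strict) at ≥ 2 distinct 3AT levels on day 7. Levels are counted
as distinct concentrations, not plates: the same level significant on both
source-array plates counts once. Day-10 data are retained for sensitivity
analysis only. Pairs on excluded plates or with QC-excluded quartets are
*missing*, never negative, and drop out of denominators. Multiple-testing
correction is deliberately absent: the fixed threshold plus the multi-level
consensus is the error-control mechanism.

## Synthetic screens

The generator emulates the screen design: 26 baits (8 *mel*, 9 *pse*,
9 *will*; three further fragments that could never be integrated are not
generated), 670 TFs on two 384-position source arrays with 8 AD-only and
the remaining free positions as untransformed controls, three 3AT levels
per bait, imaging days 7 and 10.

Colony ln-areas are x = μ₀ + δ·1[planted at this level] + Δ_edge·1[edge
quartet] + q + ε, with q ~ N(0, (f·σ₀)²) a quartet-level offset shared by
the four spots (replicates are clones of one transformant and therefore
correlated; shared across the two imaging days of a plate) and ε per-spot
noise filling the remaining variance. Pixel areas are round(exp(x)).
Defaults: μ₀ = 5.5 (≈ 245-pixel colonies), σ₀ = 0.3, f = 0.5, day-10 shift
+0.4, noncircular and missing-colony rates 1% each, Δ_edge = 0. These are
the generator's study conditions, not tuning knobs. Identical seeds give
byte-identical plate files.

What the generator does **not** emulate: growth kinetics, colony-size
saturation and neighbour competition, spatial gradients other than the
two-row edge step, image-segmentation failure modes beyond a flat
noncircular rate, and plate-to-plate batch structure. Passing tests
therefore demonstrate the pipeline's correctness and calibration under the
stated model, not performance on any particular laboratory's plates.

### Null false-positive calibration

The pipeline's per-pair false-call rate under the null is not exactly the
nominal multi-level binomial rate (3·0.005² ≈ 7.5×10⁻⁵): Grubbs trimming
biases the background sd slightly downward while finite-sample estimation
adds noise, and quartet correlation spans levels. The empirical rate was
therefore fixed once by brute-force simulation — 100 reduced null screens
(2 baits × 360 TFs × 3 levels, seeds 10000–10099) gave 4 false pairs in
72 000, i.e. 5.6×10⁻⁵ — and is frozen as
`y1hscreen.CALIBRATED_NULL_FP_RATE`. Monitoring tests compare fresh null
screens against this value within 3 binomial SDs instead of re-deriving it.

### Reduced problem sizes

Simulation studies (recall, null rate, edge detection) use a reduced screen
— one 360-TF source array, 1–3 baits, day 7 — because the per-plate
statistics are identical at any screen width and the reduced design already
gives thousands of null pairs per run; the full 312-plate design is
exercised once in the sensitivity-curve test. These sizes are the package's
own choice of experiment scale.

## Input conventions and design choices

* **Gitter dialect.** Column names and the noncircularity convention are
  configurable (`GitterDialect`); the default is columns
  `row, col, size, circularity, flags` with flag code `NC`, optionally
  augmented by a circularity cutoff. Published table dumps vary across
  quantifier versions, so the dialect is data, not code.
* **Quartet geometry.** Quartet (qr, qc) owns wells (2qr−1..2qr,
  2qc−1..2qc) — the standard 384→1536 quadruplication; 1-based indices.
* **Manual contaminant masking** is reproduced as data: an optional
  per-plate well mask forces listed wells to "absent".
* **RNAi phenotypes and nuclear-receptor status** are wet-lab inputs,
  shipped as versioned TSVs (`y1hscreen/data/`), never computed. The RNAi
  table lists the 32 TFs with knockdown phenotypes; the full 125-TF tested
  list is not public, so TFs absent from the table are reported as "not
  tested by RNAi" even though some were tested and negative. The overlap
  statistic is unaffected (it only needs the affected set).
* The published summary table's "more than one 3AT levels" legend and the
  "at least two concentrations" rule in the results text are treated as the
  same ≥ 2-level rule.

## Numerical notes

* Grubbs ties (two equally extreme values) resolve to the first index;
  ties have probability zero under the continuous model.
* The edge t-test is skipped (no correction, warning semantics) when either
  stratum has fewer than two usable values.
* `index_of_dispersion` raises on fewer than two values or a zero mean; the
  QC path never reaches the zero-mean case because the mean-area rule fires
  first at default cutoffs.
* Survivor Z-scores are exactly standardised (mean 0, sd 1 to 1e−9) by
  construction; tests assert this on every scored plate.

## Known limitations

* The Grubbs variant (iterative, two-sided, α = 0.05) and the edge-test
  granularity (quartet-level) are conventional defaults; original analyses
  of this screen type do not always state theirs, so small call-set
  differences against other implementations are possible. Both are
  configurable.
* Repressor-type interactions detectable only at the lowest 3AT level are
  outside the consensus rule by design and will be missed.
* No cross-plate normalisation beyond the per-plate background; strong
  plate-wide growth differences are absorbed by the per-plate Z-scores but
  batch structure in artifact rates is not modelled.
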