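# Methods

## The problem

Induced gynogenesis in rainbow trout (activating eggs with UV-inactivated
spermatozoa, then blocking the first mitotic cleavage with a hydrostatic
pressure shock) produces fully homozygous doubled haploids, but survival of
those embryos varies enormously between egg clutches — in the motivating
experiment, three of four females yielded eyed-stage survival of 3–6% while
one reached 57%.  Because the early embryo runs entirely on maternal mRNA
deposited during oogenesis, the maternal transcriptome of the egg is a
natural place to look for correlates of that competence.  `gynoscreen`
implements the corresponding screen: given per-sample transcript counts
from each female's eggs in two states (non-activated control eggs and
gynogenetically activated eggs) and replicate-level survival records, it
ranks transcripts by how tightly their expression tracks the per-female
gynogenesis efficiency in *both* conditions.

## The screen

Let `K[i, j]` be the read count of transcript `i` in sample `j`, one sample
per (female, condition), with four females and conditions
{control, gynogenetic}.

1. **Normalization (median-of-ratios).**  For each sample `j`,

       s_j = median_i  K[i, j] / ( prod_j' K[i, j'] )^(1/S)

   with the median taken over the reference set of transcripts with
   strictly positive counts in all `S` samples (geometric means computed in
   log space; even-sized medians take the midpoint of the central pair, on
   the ratio scale).  Normalized expression is `x[i, j] = K[i, j] / s_j`,
   and the *base mean* `b_i` is the mean of `x[i, ·]` over all samples,
   both conditions pooled.  Size factors are identified only up to a global
   scale; all downstream quantities (correlations, base-mean ranking) are
   invariant to that scale.

2. **Efficiency vector.**  Per-replicate survival is
   `100 · n_stage / n_initial`; each group reports the arithmetic mean and
   sample (n−1) SD over replicates.  The per-female mean survival of the
   gynogenetic groups at a chosen checkpoint is the efficiency vector
   `e = (e_1, …, e_4)`.  The default checkpoint is the eyed stage (27 days
   post-fertilization) — the earlier, larger-count measure; the swim-up
   stage (57 dpf) is a configuration switch, and both vectors are always
   computable, because the source experiment does not pin down which stage
   defined "efficiency".

3. **Dual-condition correlation.**  For each transcript, Pearson's r
   between `x[i, ·]` and `e` is computed twice: over the four control
   samples and over the four gynogenetic samples (each ordered by female).
   The candidate score is `|r_ctrl| + |r_gyno|`, and a transcript is
   selected iff

       b_i > 1   and   |r_ctrl| + |r_gyno| > 1.99,

   both inequalities strict, exactly as printed in the source protocol.  A
   zero-variance (constant) expression vector makes r undefined; such
   transcripts are flagged (NaN, direction "na") and excluded rather than
   silently scored 0.  Pearson on raw normalized counts is the default
   reading of "correlation coefficients": with n = 4 points a rank
   correlation takes only a handful of values, which cannot discriminate at
   a 1.99 threshold; Spearman and a `log2(x+1)` expression transform are
   offered as options.  Passing transcripts are aggregated to distinct
   genes through the transcript→gene map; unmapped transcripts count as
   their own gene.

4. **Structure.**  The passing transcripts' expression (rows unit-variance
   scaled by default, configurable to `center`/`none`) feeds (a)
   agglomerative clustering of samples and of transcripts under Euclidean
   distance with average linkage (complete/single available), and (b) PCA
   computed as an SVD of the column-centered sample × transcript matrix.
   Missing entries — absent in simulated data but accepted on ingest — are
   imputed by iterating column-mean initialization → rank-k SVD
   reconstruction until the largest imputed-cell change falls below `tol =
   1e-6` (max 100 iterations).  Component signs are fixed by making each
   component's largest-magnitude loading positive; variance-explained
   percentages are reported over all components and sum to 100.

5. **Survival comparison.**  Group differences in replicate survival rates
   use the Kruskal–Wallis rank test with midranks and the tie correction
   `1 − Σ(t³−t)/(N³−N)`; p-values come from the χ² approximation with k−1
   degrees of freedom (the conventional software behaviour even at these
   tiny group sizes), with an exhaustive-permutation p available for pooled
   N ≤ 12.  When every observation is identical, H is defined as 0 and p as
   1 rather than dividing by a zero tie correction.

## Why 1.99 is a severe threshold

With four females, the null distribution of Pearson's r is uniform on
[−1, 1], so a single condition exceeds |r| > 0.995 with probability 0.005
and the dual-condition score exceeds 1.99 with probability ≈ 5 × 10⁻⁵.
Among ~5000 background transcripts that is ≈ 0.25 false positives per
dataset — the filter is effectively a demand for near-perfect tracking in
both conditions, which is what makes a four-point correlation screen
usable at all.  The flip side is severity against true effects: any
within-female noise visible at the scale of the between-female signal
pushes scores below 1.99 (see "Simulator defaults" below).

## The synthetic-data generator

The generator reproduces the study design: 4 females × {control,
gynogenetic}, one library per (female, condition), 5000 transcripts by
default (a scaled-down transcriptome; the full ~45k is a parameter),
gynogenetic survival means (3.5, 57.2, 3.1, 6.2)% eyed / (0.8, 41.5, 1.0,
5.0)% swim-up, controls near 94.5%/90.1%, three gynogenetic and two
control incubation replicates of 327 and 120 eggs.

* **Counts.**  Background transcripts draw a baseline mean log-uniform on
  [0.5, 500] (so a realistic share sits below the base-mean filter),
  identical across females.  Counts are negative binomial via a
  gamma–Poisson mixture with `var = μ + φμ²` (φ = 0 is exactly Poisson),
  scaled by per-sample library factors drawn log-uniform on [0.5, 2].
* **Planted signal.**  `n_planted = 60` transcripts get their log2 mean
  shifted by `effect_slope × (e_f − mean(e))` per female, identically in
  both conditions — mirroring the observation that the high-survival
  female's eggs diverged in the control as well as the activated state.
  Planting uses the *configured* survival means; the screen then runs
  against the *realized* simulated survival, preserving honest phenotype
  noise in recovery experiments.
* **Survival.**  Per replicate, `n_eyed ~ Binomial(n_eggs, p_eyed)` and
  `n_swimup ~ Binomial(n_eyed, p_swim/p_eyed)`, so expected stage rates
  match the configured means exactly.
* **Determinism.**  All randomness flows from one seed through named
  substreams (planting / counts / survival); identical configurations give
  byte-identical outputs.

### Simulator defaults (effect size, dispersion, planted baselines)

The defaults are `effect_slope = 0.1` log2 units per survival percentage
point, `φ = 0.1`, planted baselines log-uniform on [10, 500].  These were
fixed by a power analysis of the threshold geometry before any recovery
experiment was run.  The survival vector is dominated by one female
(+39.7 points above the mean); a planted slope of 0.1 therefore separates
her expression ~40-fold, and the score threshold demands the within-female
coefficient of variation (`≈ sqrt(1/μ + φ)`) be small relative to that
separation.  At slope 0.05 the separation (~6×) is comparable to NB noise
at φ = 0.1–0.2 and per-transcript recall collapses to 0.1–0.6; at slope
0.1 with φ ≤ 0.2 recall is ≥ 0.9.  φ = 0.1 itself is an ordinary bulk
RNA-seq biological-replicate dispersion; planted baselines start at 10
because a correlation screen cannot, by construction, recover transcripts
hovering at its own expression filter.

All planted effects are **up-regulated by default** (`up_fraction = 1`).
This is deliberate: with log2-linear planting, a down-regulated
transcript's response saturates at zero for the high-survival female, and
the resulting curvature caps the noise-free candidate score at ≈ 1.984 —
below the 1.99 threshold on the count scale.  A Pearson screen on raw
normalized counts is therefore structurally blind to proportional
down-regulation at this effect size (consistent with screened candidate
sets being predominantly up-regulated); `up_fraction` can be lowered to
study exactly that blind spot, and the `log2` expression option removes
the curvature.

### What the generator does not emulate

No read-level noise (mapping/quantification error), no transcript-level
dispersion trends or mean–dispersion relationships, no correlation between
transcripts (co-regulation), no isoform structure in the gene map, and no
genetic component linking survival to expression — the planted association
is phenomenological.  Recovery results therefore demonstrate that the
pipeline's inference machinery is correct and calibrated under its own
assumptions, not that the thresholds would achieve the same sensitivity on
real libraries.

## Numerical and design choices

* Strict inequalities for both filters, as printed.
* Non-integer counts at ingest are rounded half-up (a logged repair;
  upstream quantifiers emit "rounded effective counts").
* Base mean is computed over all 8 samples, both conditions pooled (the
  single-dataset convention); per-condition base means are not used.
* Output ordering: descending score, ties broken lexicographically by
  transcript ID, so result files are reproducible.
* Degenerate inputs: empty reference set for size factors raises with a
  diagnostic count; an all-tied Kruskal–Wallis sample returns (0, 1); a
  single-replicate group reports SD 0 with a warning; zero-variance rows
  are dropped (with a warning) before unit-variance scaling.
* The problem sizes used in tests and in `scripts/acceptance.py`
  (5000-transcript simulations, 20 recovery runs, 200 survival-calibration
  seeds) are the package's default experiment sizes; they complete in
  seconds and estimate the reported rates to well under a percentage
  point.

## Known limitations

* n = 4 females: no multiple-testing correction is applied (the composite
  score threshold plays that role, as in the source protocol), and no
  p-values are attached to candidate correlations.
* The down-regulation blind spot described above.
* The screen assumes exactly one expression library per (female,
  condition); pooled or replicated libraries must be collapsed upstream.
* Hierarchical clustering delegates to SciPy's linkage; exact tie-breaking
  among equidistant merges follows SciPy's convention (ties have measure
  zero for continuous expression data).
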