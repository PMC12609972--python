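# Methods

This note documents the statistical procedures, the synthetic-data model,
the numerical choices, and the limitations of the package. It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Preprocessing model

A two-color hybridization measures, per printed spot, foreground and local
background intensities in two channels: channel 1 (Cy3/Alexa555, control)
and channel 2 (Cy5/Alexa647, treated). The chain is:

1. **Background correction**: s_c = fg_c − bg_c per channel. Spots where
   either corrected signal is ≤ 0 are flagged BAD (reason `nonpositive`)
   rather than dropped, so the filtering step can report them; the default
   filter then removes them. Flag-then-filter keeps the audit trail.
2. **Quality filtering**: BAD-flagged spots and spots with
   min(fg1/max(bg1,1), fg2/max(bg2,1)) below `min_snr` (default 1.5) are
   removed, with per-reason counts. The SNR default is a configurable
   convention, not a measured constant.
3. **M/A transform**: M = log2 s2 − log2 s1 (treated minus control),
   A = (log2 s1 + log2 s2)/2. For dye-swapped arrays M is negated so its
   sign convention is uniform.
4. **LOWESS normalization**: M′ = M − f̂(A), where f̂ is a locally weighted
   linear fit of M on A with tri-cube weights, a span of 0.3 (the fraction
   of points entering each local fit — the standard reading of a LOWESS
   "smoothing parameter"), and 3 robustness iterations (the classic
   default). The fit is delegated to
   `statsmodels.nonparametric.lowess`; fitted values are interpolated
   between anchor points spaced 0.5% of the A-range apart (`delta`), which
   changes results by far less than the fit's own bias and makes the cost
   linear. Below 50 records a local fit is unreliable and the routine
   falls back to median-centering with a warning. Constant A is a
   degenerate-fit error.
5. **Replicate averaging**: unweighted mean of normalized M over duplicate
   spots within each array, then unweighted mean of those array means
   across biological replicate arrays, in that order. Genes present in
   fewer than `min_arrays` arrays are dropped and reported.

QC metrics: per-array spot-pass fraction (threshold 0.95), minimum pairwise
Pearson correlation of per-array gene-level M on shared genes
("array reproducibility", threshold 0.90), and the same minimum restricted
to pairs of opposite dye orientation when dye swaps are present
("replicate consistency", threshold 0.85). Pearson r is used throughout;
with a single array the correlations are reported as not applicable rather
than failing.

## The intensity-dependent Z-score

Ratio noise on two-color arrays grows toward low intensity, so gene-level
significance is judged against a *local* null. Genes are ranked by A (ties
broken by symbol, stably); gene i's window is the `window_size` (default
500) genes nearest in rank, clamped at the extremes so every window holds
exactly min(window_size, n) genes. Then

    Z_i = (R_i − μ_i) / σ_i,

with μ_i the window mean and σ_i the window sample SD (n−1 denominator).
The focal gene is included in its own window — with 500 members
self-inclusion shifts Z negligibly, and `include_self=False` is available.
Thresholds are inclusive: UP at Z ≥ 2, DOWN at Z ≤ −2, STABLE at
|Z| ≤ 1.5; a zero window SD leaves Z undefined and the gene uncalled. The
window statistics are deliberately non-robust (plain mean/SD): strong
planted signal inflates σ locally and makes calling conservative, which
the simulator-based tests quantify.

`null_calibration` verifies the "|Z| ≥ 2 ≈ p < 0.05" reading empirically:
on signal-free simulations the called fraction should sit near the
two-sided Gaussian tail at 2 (≈ 0.0455). The acceptance suite runs 20
replicates of 2000 genes, a size chosen to keep Monte-Carlo error near
one part in a thousand while the whole run stays in the order of seconds.

No gene-level FDR is computed for the array calls; the Z thresholds are
the calling rule, and FDR control enters only at the pathway level.

## Over-representation analysis

One-sided hypergeometric upper tail per term (`scipy.stats.hypergeom.sf`,
an exact-fraction enumeration serves as test oracle for all N ≤ 25), with
every term intersected with the background before testing. The default
background is the full set of genes on the array — the natural universe
when the query is derived from that same array — and is configurable.
Benjamini–Hochberg adjustment is applied within one collection at a time
(run KEGG and each GO branch separately) so FDR statements are
per-analysis. Tiers use inclusive boundaries: significant at FDR ≤ 0.05,
suggestive at 0.05 < FDR ≤ 0.10; terms with fold enrichment below 5 are
demoted to no tier (but retained in the output) when the FE filter is on.
Term networks connect tiered terms whose query-restricted member sets have
Jaccard similarity ≥ 0.2 (both the measure and the cutoff are
configurable; edge weight is the shared-gene count).

## Interaction graphs and hubs

Edge scores live in [0, 1]; the confidence filter keeps scores ≥ 0.700
("minimum required score" read as inclusive). Hub genes are nodes with
degree ≥ 10 *on the filtered graph*; isolated nodes survive filtering with
degree 0 so reports cover every input gene. Connected-component sizes are
reported in place of any proprietary embedding-based clustering, which is
not re-implemented.

## Survival and correlation

Signature score = mean over signature genes of per-gene z-standardized
expression (population SD); zero-variance genes are dropped with a
warning. Subjects are split at the median score with ties assigned to the
low group (documented, configurable by re-labeling). The two-group
log-rank test is computed from explicit risk-set tables; the hazard ratio
is the O/E ratio estimator

    HR = (O_h/E_h) / (O_l/E_l),  SE(log HR) ≈ sqrt(1/E_h + 1/E_l),

chosen over a fitted proportional-hazards model because it is fully
determined by the tables the test already computes and is adequate for a
two-group median split (lifelines' log-rank serves as an independent
cross-check in the tests; Kaplan–Meier step functions come from
lifelines). Spearman correlation uses mid-ranks; its p-value is the exact
permutation tail (all n! orderings, two-sided on |ρ|) for n ≤ 9 and the
large-sample t approximation otherwise.

## Synthetic-data model

The generator emulates the quantified output of a ~5000-probe two-color
platform printed in duplicate, with defaults set to the emulated study
design: 5000 genes × 2 duplicate spots, 2 biological replicate arrays
(hybridizations are paired control vs treated, so one array per replicate
pair; the replicate count is configurable and deliberately does not
resolve the ambiguity between the four biological replicates collected
and the two arrays averaged in the emulated workflow), 3% truly DE genes
at |log2FC| = 1.5, log2 intensities N(10, 1.5²).

* **Dye bias**: a polynomial c(u) in the standardized intensity
  u = (A − mean)/(2·SD), added to M — the classic "banana" MA distortion;
  a low-order polynomial is smooth, recoverable by LOWESS, and the default
  cubic (0.25, −0.3, 0, 0.2) keeps the bias within a few tenths of a log2
  unit over the bulk of the intensity range.
* **Noise**: ratio-noise SD is log-linear in A between anchors at
  mean ± 2 SD, from 0.45 at low A to 0.15 at high A — the variance
  heterogeneity that motivates the windowed Z. Setting either anchor to 0
  disables ratio noise entirely (the noise-free limit used by exactness
  tests).
* **Background**: the stored per-spot background equals the additive
  background injected, so background correction is exact in simulation.
  Real arrays estimate local background with error; that error mode is not
  emulated, so passing tests say nothing about background-estimation
  artifacts.
* **Streams**: one RNG stream per array derived from (seed, array index),
  so increasing `n_arrays` never perturbs earlier arrays; gene-level truth
  has its own stream. Identical configs give bit-identical output.
* **Cohorts**: event times are exponential; the planted effect
  `planted_log_hr` applies to the indicator of the upper median-split half
  of the standardized signature score, so exp(planted_log_hr) is *exactly*
  the high-vs-low hazard ratio the downstream analysis estimates — the
  planted parameter is identifiable by the pipeline's own estimator, which
  is what the recovery tests check. Censoring marks a Bernoulli
  (`censor_rate`) subset of subjects, independent of covariates, and
  truncates their follow-up uniformly within (0, T). Infiltration scores
  are coupled to one gene through a Gaussian copula with Pearson parameter
  2·sin(πρ/6), targeting Spearman ρ and exact at ρ = ±1.

What the simulator does **not** emulate: spot morphology and image-level
artifacts, print-tip or block effects, carry-over between duplicates,
background-estimation error, non-exponential hazards, and covariate-
dependent censoring. Passing recovery tests therefore demonstrate
correctness of the estimators under the stated model, not robustness to
these real-data failure modes.

## Numerical choices and degenerate inputs

* Window statistics use cumulative sums with the variance clamped at 0
  before the square root; windows with σ = 0 yield uncalled genes.
* Hypergeometric p-values are clamped to (tiny, 1]; BH output is capped
  at 1 with ties preserved.
* Thresholds on Z, FDR, fold enrichment, edge score, and hub degree are
  all inclusive.
* Duplicate interaction pairs keep the maximum score; self-loops are
  dropped with a warning at parse time and rejected at graph-build time.
* The log-rank variance term skips risk sets of size 1; with zero
  variance the statistic is 0 and p = 1.
* Literature tables allow exactly one label per symbol; conflicting
  duplicates are an error naming the symbol.

## Packaged fixtures

`data/published_zscores.tsv` carries the 56 published per-gene Z-scores of
the top up/downregulated genes (25 at Z ≥ 2, 31 at Z ≤ −2).
`data/literature_db_synthetic.tsv` is a *partly synthetic* reconstruction
of the curated literature label table: rows marked `reported` carry
published labels; rows marked `synthetic-fill` pad the stably-expressed
category to its reported size of 12 with housekeeping symbols and are not
literature claims. One gene with context-dependent published direction is
omitted because the table format allows a single label per symbol.

## Known limitations

* A single global LOWESS; no print-tip, composite, or quantile
  normalization variants.
* The STABLE band is applied to the same treated-vs-control Z as the DE
  calls; a separate control-condition statistic would require
  control-vs-control hybridizations, which the data model does not
  include. `classify_overlap` accepts a second call set for exactly that
  use.
* The O/E hazard-ratio estimator is slightly conservative for strong
  effects (it attenuates toward the null relative to a Cox fit); the
  recovery tests bound this at the effect sizes used.
* Symbol standardization is table-driven and offline; the shipped alias
  table is minimal and meant to be replaced by a user-supplied one.
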