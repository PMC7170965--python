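# Methods

## The statistical model

Counts for peak *i* in library *j* are modelled as negative binomial with
mean μ_ij and dispersion φ_i, using the RNA-seq convention
Var = μ + φμ². The full model for the log mean is

    log μ_ij = β_i0 + β_i^IP X_j^IP + β_i^STIM X_j^STIM
               + β_i^STIM:IP X_j^IP X_j^STIM + log s_j

with indicator covariates for the IP fraction and the treated condition and
the log size factor as an offset. β^IP is baseline antibody enrichment,
β^STIM the gene-expression response to the condition (it appears in IP and
input libraries alike), and the interaction β^STIM:IP is the quantity of
interest: condition-dependent enrichment, i.e. differential methylation net
of expression change. The reduced model drops the interaction. Both are fit
by iteratively reweighted least squares (IRLS) at a fixed per-peak
dispersion, and the deviance difference is referred to χ² with 1 degree of
freedom. The design requires at least one sample in each of the four
fraction × condition cells (and ≥2 replicates per condition for dispersion
estimation); single-replicate designs are refused rather than tested.

Numerical choices: convergence is declared when the relative deviance change
falls below 1e-8, with a 100-iteration cap and step-halving on deviance
increases; linear predictors are clipped at ±30; dispersions at or below
1e-9 are routed to the exact Poisson limit (the `gammaln(y + 1/φ)` terms
lose precision there, and the NB pmf is analytically Poisson in that limit);
an all-zero count row is flagged degenerate and excluded from testing; a
numerically negative LRT statistic within 1e-6 of zero is clipped to zero,
and anything more negative is reported as a convergence failure with a
missing p-value. Non-converged peaks are never counted significant.
Missing p-values are excluded from Benjamini–Hochberg adjustment and stay
missing.

## Normalization

Size factors are median-of-ratios (or total-count), computed **within** the
IP group and within the input group separately, each rescaled to geometric
mean 1. Global antibody enrichment therefore never distorts the input size
factors; the mean IP/input depth ratio is absorbed by β^IP. This choice is
echoed in every output's provenance block.

## Dispersion estimation

Per-peak estimates maximize the Cox–Reid adjusted profile likelihood
(APL) — the NB log-likelihood at the IRLS-fitted coefficients minus
½ log det(XᵀWX) — over φ on a log grid in [1e-4, 10] refined by golden
section, with a boundary estimate of 0 when the data show no
overdispersion. Dispersions are estimated once under the full model and
shared by the full and reduced fits, standard LRT practice.

Raw per-peak estimates are too noisy to plug into a χ² test at typical
replicate numbers, so both pipeline variants regularize them:

* **trend_shrink** fits the trend φ(μ) = a0 + a1/μ to the per-peak
  estimates by non-negative least squares against mean normalized count,
  then shrinks log-dispersions toward the trend with an empirical-Bayes
  weight: the prior variance is the robust (MAD-based) spread of
  log-residuals around the trend minus the known sampling variance of a
  log-dispersion estimate, trigamma(resid_df/2), floored at 0.01. When
  peaks scatter no more than sampling noise predicts, nearly all weight
  goes to the trend; genuinely heterogeneous data keep more of the
  per-peak signal. Estimates more than 4× above the trend are left
  unshrunk — shrinking a true dispersion outlier down would
  anticonservatively inflate its test. Shrinking in both directions (rather
  than leaving below-trend estimates at their MLEs) is deliberate:
  one-sided shrinkage systematically underestimates dispersion and breaks
  type-I-error calibration, which the test suite checks directly.
* **common_tagwise** shrinks toward a single common dispersion (the
  maximizer of the summed per-peak APL on the shared grid) with a prior
  weight equivalent to 10 observations against the residual degrees of
  freedom — a weighted log-average of common and per-peak estimates.

The two variants stand in for the common practice of running two
independent NB implementations that differ chiefly in dispersion handling;
`combine_calls` takes the union (sensitive) or intersect (conservative) of
their FDR < 0.05 sets. Reimplementing external packages' exact estimators
is out of scope by design.

## Fold changes and filters

Peak-IP and gene-input log2 fold changes are ratios of mean
size-factor-normalized counts (treated vs control) with a pseudocount of
0.5; `delta_log2fc` is the absolute difference between them, which cancels
for proportional (expression-driven) changes. `min_peak_count` is the
minimum raw peak count over all samples. Default filters: significance by
the chosen combine rule at α = 0.05, delta ≥ 1, minimum count ≥ 10, and
optionally exon location against a user-supplied exon BED. Filters are
pure row predicates, so their application is order-independent. Genes with
zero input counts throughout a condition are flagged low-expression rather
than dropped.

## Goodness of fit (Poisson vs NB)

Per peak and per fraction × condition cell (pooling only replicates, so
condition effects never inflate the variance estimate), both models are fit
by maximum likelihood: the Poisson rate and NB mean are the sample mean (the
exact MLE in both cases); the NB dispersion is profiled on a log grid
refined by golden section, with φ̂ = 0 returned at the boundary when the
sample variance does not exceed the mean. The parametric bootstrap then
redraws every unit from its fitted model `n_sim` times (default 500),
recomputes the mean over peaks of the per-peak log-likelihood at the same
fitted parameters, and places the observed statistic as a percentile of the
simulated reference distribution. Overdispersed data assessed under Poisson
fall below every simulation (percentile 0); under NB the observed value is
unexceptional. Each unit's bootstrap draws come from a generator keyed by
(seed, peak, fraction, condition), so the report is invariant to peak order.
Fewer than 20 simulations are refused as meaningless.

## Reproducibility metrics

Peak identity across replicates and experiments is positional — ≥1 shared
base — not by id string. Merging produces maximal covered runs (per-base
union semantics, so bookended intervals join, matching a bedtools-style
merge and the brute-force oracle used in tests). Cross-experiment overlap
is the percent of experiment-1 peaks hitting an experiment-2 peak, counting
only peaks on genes with mean input coverage ≥ 10× in **both** experiments
(the gate applies symmetrically to numerator and denominator; an empty
considered set reports a missing percentage, not 0). Saturation curves
draw random k-replicate subsets (configurable subsamples per k; a single
draw at k = n) and count merged-union peaks captured; recurrence curves
report the percent of union peaks present in ≥ r replicates. Coverage
saturation bins genes by mean input coverage into 20 log-spaced bins and
reports the percent with ≥ k merged peaks per bin; as a scalar operating
point, the smallest bin reaching 90% of a curve's plateau is reported —
an explicit operationalization of reading the "shoulder" of the sigmoid.

DRAC-motif enrichment ([AGT][AG]AC on DNA, U mapped to T) compares the
fraction of peaks containing the motif against same-length intervals placed
uniformly within the same gene's sequence (length and gene of origin
preserved to control composition; genome-wide shuffling would confound).
The empirical p-value is (1 + #shuffles ≥ observed)/(n_shuffles + 1). A
zero background with a nonzero observed fraction caps the ratio with a
flag; zero everywhere reports a missing ratio. Coverage summaries are the
per-position mean and sample SD (n−1; zero for a single replicate) across
replicates per fraction × condition, with optional per-condition y-scaling
in plots, which makes expression-proportional "methylation changes"
visually obvious.

## Power analysis

For each candidate replicate number k, replicates are drawn without
replacement independently per condition — IP/input pairs always travel
together, respecting the paired design — and the full pipeline re-runs on
the reduced experiment, re-estimating size factors and dispersions as a
real k-replicate study would. The fraction of subsamples (default 10) in
which each peak is significant is recorded; at k equal to the full design
the single deterministic run yields a fraction of exactly 0 or 1. The
smallest k with fraction ≥ 0.5 ("consistent detection") is summarized with
quartiles across peaks.

## The synthetic-data generator

The generator emulates exactly the structure the model assumes: paired
IP/input NB counts with a mean-dependent dispersion trend, condition
effects on gene expression (input and IP alike) and on IP enrichment
(methylation, treated condition only), unequal library sizes, and a shared
lognormal replicate-pair scale for biological pairing. Defaults define the
calibration conditions used throughout the tests: 2000 peaks (one per
gene), six paired replicates per condition, peak input means log-uniform on
50–500 reads, dispersion trend a0 = 0.05, a1 = 5 (typical bulk RNA-seq
magnitudes), four-fold IP enrichment, library-size lognormal σ = 0.2,
pair σ = 0.1, gene input means 3× peak means (a gene body collects more
reads than one peak). Effect sizes are exposed as free parameters
(magnitude plus the fraction of peaks/genes affected, random signs) rather
than a canonical distribution, which no consensus defines. All draws come
from one seeded generator; identical configs reproduce byte-identical
fixture files (provenance headers carry the seed, never a timestamp).

Sequence/coverage emission plants a GGACT motif at the center of changed
peaks at a configurable rate on a configurable background alphabet, and
builds piecewise-constant IP coverage whose integral over a peak equals
count × read length, with flat gene-background input coverage — sufficient
for testing motif enrichment and coverage summaries, with no pretence of
modelling fragment-length or antibody-bias structure.

What passing tests on these simulations do **not** show: robustness to
peak-calling errors, isoform structure, positional coverage biases within
peaks, batch effects between studies, or antibody lot variability — none of
which the generator emulates. Calibration results here mean the inference
machinery is correct under its own assumptions, not that real MeRIP-seq
data meet them.

## Problem sizes and known limitations

Test and acceptance runs use desk-scale sizes chosen to exercise every code
path at meaningful statistical resolution: the null calibration uses the
full 2000-peak default; goodness-of-fit direction uses 20 independent
60-peak experiments with 500 bootstrap generations; power analysis uses 50
peaks over k ∈ {2,3,4,6,8} with 10 subsamples per k.

Known limitations: the LRT relies on plug-in dispersions, which is slightly
liberal at very small replicate numbers (the test suite pins the 6+6
design inside the 99% binomial band around 5%); per-peak interaction
estimates carry irreducible sampling noise of roughly
√(Σ_cells (1/μ + φ)/n) nats regardless of estimator, so individual-peak
effect sizes at moderate depth are only coarsely recoverable even when the
test is well calibrated; multi-gene peaks take the longest-overlap gene
(ties lexicographic, logged); counting ignores strand by default (a flag
enables stranded counting) and never de-duplicates reads.
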