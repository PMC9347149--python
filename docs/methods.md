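# Methods

## Model and rationale

A sequenced tumour region carries S somatic mutations. Each mutation has a
true cell-level mutant-allele frequency; clonal mutations sit at a fixed
frequency (default 0.5, the heterozygous-diploid value) and subclonal
frequencies follow a Beta(α, β) spectrum. Tumour purity ρ scales every
frequency multiplicatively (normal-cell reads dilute the mutant
proportion). At a site with depth d, the mutant-read count is
Binomial(d, ρf); marginally over a beta spectrum it is beta-binomial.

Threshold TMB counts detected sites whose observed proportion reaches τ and
divides by the region size in megabases. Two distortions follow:

1. **Truncation.** Only sites with at least c mutant reads are seen
   (c = 1 for bare detection; the τ-threshold itself imposes
   c = ⌈d·τ⌉). The retained counts are left-truncated binomials, so the
   retained proportion is biased upward: E[X/N | X ≥ 1] = f/(1 − (1−f)^N),
   and more severely for larger c. `trunc_binom` provides the truncated
   pmf/mean, exact seeded sampling, and the one-parameter ML estimator
   (bounded scalar search on [1e−8, 1 − 1e−8], tolerance 1e−8; the
   truncated likelihood is a one-parameter exponential-family conditioning
   and unimodal).
2. **Crossing asymmetry.** The expected observed above-threshold count is
   E = Σ_i P(X_i ≥ ⌈d_i·τ⌉) with X_i beta-binomial, versus the true
   T = (1 − F_B(τ))·S. When the spectrum density falls steeply at τ, many
   more sites sit just below the threshold than just above it, so E > T at
   finite depth; (E − T)/T → 0 as depth grows. `spectrum_model` evaluates
   both counts and the relative-error curve.

### Pass rule

"Observed proportion ≥ τ" is implemented everywhere as the integer cut
X ≥ ⌈d·τ⌉, with a 1e−9 epsilon inside the ceiling so that binary
floating-point excess (e.g. 100 × 0.05 evaluating fractionally above 5)
never shifts the cut. The theoretical E uses the identical rule, keeping
theory and simulation exactly comparable. Strictness at the boundary is
immaterial for the continuous beta component (measure zero).

### Spectrum-model TMB

The detected mutant-read counts (including sub-threshold ones — the point
is to use all of the data) are modelled by a truncated beta-binomial
likelihood: a site detected at cut c_i contributes
pmf_BB(x_i; d_i, α, β) / P(X ≥ c_i; d_i, α, β). Sites with observed VAF ≥
0.35 (configurable) are excluded as clonal and counted separately, since
the beta component models subclonal mass only. Optimization is Nelder-Mead
on (log α, log β) from four fixed starts (0.1, 10), (0.1, 100), (1, 10),
(0.5, 50), tolerance 1e−6, ties broken by log-likelihood then smaller α.
Abundance is recovered by inverse-probability weighting,
Ŝ = Σ_i 1/P(X ≥ c_i; d_i, α̂, β̂) — a capture–recapture-style estimator
that separates the well-conditioned two-parameter shape fit from abundance
recovery, rather than a joint ML over (α, β, S). Model TMB is
[n_clonal_observed + Ŝ·(1 − F_B(τ; α̂, β̂))]/Mb. The likelihood, clonal
handling and abundance recovery are this package's own concrete design; the
general "estimate the whole spectrum" idea does not prescribe them.

### Numerical choices

- Beta-binomial log-pmfs are log-gamma differences; upper tails are
  log-sum-exp over the support. Computing a small tail as 1 − CDF loses all
  precision to cancellation — during development this created spurious
  optima in the truncated likelihood (parameter corners whose tail
  probability underflowed looked spuriously likely). The same applies to the
  truncated-binomial mean, computed in log space over the retained support.
- Truncated-binomial sampling is rejection sampling against the untruncated
  binomial, exact and fast while the acceptance probability
  P(X ≥ c) ≥ 0.01; below that it falls back to inverse-CDF sampling of the
  conditional distribution (uniform draws on the retained CDF mass through
  the binomial quantile function), which is exact for any truncation.
- Degenerate ML inputs (all counts at the support edge) pin the estimate at
  the clamped boundary with a warning flag instead of failing.
- Every stochastic operation takes an explicit seed; cohort generators
  derive per-sample seeds from a master generator. No global RNG state.

## The simulator and what it does (not) capture

`synthetic_data` emulates: per-site depth (fixed, Poisson, or
negative-binomial with var = m + m²/k), clonal + beta-subclonal true VAFs,
purity scaling, binomial read sampling, and read-level down-sampling as
independent binomial thinning of mutant and reference reads (the exact
read-count analog of randomly subsampling a BAM; thinning by g then h is
distributionally thinning by g·h). Samples serialize to a commented TSV
(bit-exact float round trip via `repr`) and a minimal VCF v4.2 with AD/DP
and an INFO `TRUE_VAF` field at synthetic positions.

Deliberately absent: sequencing and mapping errors, mutation-caller
behaviour beyond a minimum-alt-read cut, copy-number variation, local
depth correlation along the genome, multi-subclone structure beyond a
single beta component, and tumour-normal contamination asymmetries. Tests
passing here therefore demonstrate the statistical mechanisms on clean
binomial data, not the end-to-end accuracy of any real variant-calling
pipeline. The two-component clonal/subclonal generative split is an
explicit stand-in for the clonal-fraction annotations real cohorts derive
from subclonal deconvolution.

## Experiment defaults and why

- **Truncation-bias experiment**: depth 100, τ = 0.05, 1,000 draws per
  frequency on a 0.01–0.50 grid — the classic demonstration conditions.
  The naive estimator averages per-draw proportions (the per-sample
  interpretation); a pooled-count variant is available.
- **Threshold crossing**: Beta(0.1, 100), S = 200, depth 100 — a spectrum
  steep enough that up-crossers outnumber down-crossers ~50-fold.
- **Detection stand-in**: `min_alt_reads` defaults to 3 in the pipeline
  API. The cohort experiments (down-sampling, depth-correlation) default
  to 5 supporting reads: real somatic callers at moderate depth are far
  less sensitive than an ideal "any 3 mutant reads" detector, and an
  unrealistically sensitive detector suppresses exactly the
  depth-dependent power loss these experiments probe. With the cut at 5,
  halving reads from ~100× pushes the effective VAF floor from 0.05 to
  0.10 and TMB falls in essentially every subclonal-heavy sample; with an
  ideal cut of 3 the truncation asymmetry dominates instead and thinning
  *raises* threshold TMB — a regime no real pipeline inhabits, because
  callers lose far more sub-threshold sites than binomial sampling alone
  suggests.
- **Down-sampling cohort**: 1,000 clonal + 20,000 subclonal Beta(0.1, 100)
  mutations per sample over 35 Mb (WES-scale region; a heavily mutated,
  heterogeneous tumour), Poisson depth 100, thinned to 50%.
- **Depth-correlation cohort**: 400 mutations per sample over 35 Mb, mean
  depths uniform on 50–400×, strata at clonal fraction 0–0.2 vs 0.8–1.0
  (split at 50% as in the stratified real-cohort analysis). The subclonal
  spectrum is Beta(2, 20) (mean VAF ≈ 0.09): subclonal clusters with
  appreciable mass on both sides of τ = 0.05, the regime where detection
  power and crossing bias both pull TMB with depth. Under the extreme
  Beta(0.1, 100) spectrum virtually no subclonal mutation approaches τ and
  the depth–TMB correlation inverts; real heterogeneous tumours carry
  near-threshold subclones. The correlation statistic is Spearman's ρ with
  a seeded 10,000-permutation two-sided p-value — robust to the skewed TMB
  distribution; the test is not prescribed by the counting definition, so
  a distribution-free choice is safest. Per-sample mean site depth stands
  in for total mapped reads as the depth proxy.

## Problem sizes

Analyses and tests run at desk scale: cohorts of 20–200 samples,
400–21,000 sites per sample, 50–2,000 Monte-Carlo replicates, 10,000
permutations. These sizes give Monte-Carlo standard errors comfortably
inside every asserted tolerance while keeping each analysis in seconds.

## Known limitations

- The abundance estimator Ŝ is only as good as the detected-count
  information. For extremely steep spectra (e.g. Beta(0.1, 100) at depth
  100 with a 3-read cut) the detected window sees only f ≳ 0.02 while the
  spectrum's mass lies near 10⁻³: (α, β) are then nearly unidentifiable
  from realistic numbers of detected sites, Ŝ is unstable over the
  likelihood ridge, and only above-threshold functionals such as
  Ŝ·(1 − F_B(τ)) remain stable (which is why the model-based TMB is
  reliable there even though the parameters are not). Binomial counting
  noise alone bounds the precision of Ŝ: with detection probability p and
  S·p detected sites, the coefficient of variation of Ŝ cannot fall below
  √((1−p)/(S·p)) even if (α, β) were known exactly.
- The spectrum fit conditions on detection but not on the clonal-exclusion
  cut (observed VAF < 0.35); for spectra with non-negligible mass near
  0.35 this right-truncation is slightly misspecified.
- Purity adjustment divides observed VAF by a *known* purity; purity
  estimation is out of scope.
- The model-based estimator assumes a single beta subclonal component; a
  multi-component spectrum must be handled by the simulator, not the
  closed-form theory.
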