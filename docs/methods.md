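# Methods

## Data model and preprocessing

Input matrices are features × samples TSVs ("NA" for missing). Features with
more than 20% missing values are dropped; the rest are median-imputed, a
choice that is rank-neutral under the subsequent CDF transform. Paired
tumor/adjacent-normal measurements are contrasted per role: element-wise
ratios for expression and copy-number probes, beta *differences* for
methylation — the difference keeps the bounded [−1, 1] scale, and all
downstream screening is correlation-based, hence invariant to this affine
choice.

Each feature's values over a cohort are replaced by mid-rank CDF values
`y = midrank / (n + 1)`. The mid-rank convention keeps every value strictly
inside (0, 1), so the logarithms of the trinary formulas are always defined;
ties share values and a constant row maps to 0.5. The transform is exactly
invariant under strictly monotone maps of a row, which also makes the
pipeline insensitive to whether ratios are logged.

The trinary state probabilities use the closed forms

    P(x=+1|y) = y/(1 − ln y),   P(x=−1|y) = (1−y)/(1 − ln(1−y)),

with P(x=0|y) the complement. These are valid probabilities (each term lies
in [0, 1] and the complement is non-negative on (0, 1)), mirror-symmetric
under y → 1−y, and strictly monotone; the test suite asserts these
properties on a 10⁴-point grid at 1e−12.

Copy-number probes are aggregated to chromosome arms by the median over the
arm's probes, with arm membership taken from the annotation table; arm-scale
coherence is the dominant structure of tumor CNV profiles and finer
segmentation is deliberately out of scope. Probes or genes without arm
annotation are dropped.

**Scale convention for screening.** Arm-level CNV ratio distributions are
heavily right-skewed (roughly lognormal under the generator), which
attenuates Pearson correlations against rank-CDF expression and makes
screening outcomes depend on a few extreme samples. All association
screening therefore correlates rank-CDF expression with *rank-CDF* arm CNV
(methylation contrasts are bounded and are screened on their continuous
values). Effector states entering the logistic model are likewise the
trinary expectations of the effectors' rank-CDF values.

## Module discovery

Per gene, candidates with |r| ≥ 0.5 are retained under sign constraints: the
gene's own arm only with r > 0 (cis), other arms with either sign (trans),
methylation effectors only with r < 0. The same threshold applies to every
aberration type by default and is configurable per type. Methylation rows
must show a minimum standard deviation (default 0.05 on the beta-difference
scale) to enter the effector pool — effectors need variation to explain
anything.

The per-gene model is P(y|x) = exp(Σ λᵢ fᵢ(x,y))/Z(x) with λᵢ ≥ 0 and
feature functions fᵢ(x,y) = directionᵢ·E[xᵢ]·y evaluated under the soft
trinary assignments; the fit maximizes the expected log-likelihood
Σₛ (E[yₛ]·aₛ − log(e^aₛ + e^−aₛ + 1)), aₛ = Σ λᵢ zᵢₛ, which is concave in λ.
This feature form is the simplest one consistent with signed associations
under the non-negativity constraint; alternatives (e.g. products of full
probability triples) would change little because only E[x] and E[y] enter
the sufficient statistics. Optimization is projected gradient ascent with
adaptive step size, tolerance 1e−8 on the projected gradient, 500 iteration
cap; the objective is smooth and one-to-few dimensional, so this converges
in tens of iterations.

Covariates are tried greedily in the layer order cis → trans → methylation
(the order of decreasing mechanistic certainty), within a layer by
decreasing |screening r| with ties broken by effector id, and kept only when
BIC = −2·loglik + k·ln(n) strictly improves. BIC was chosen as the
fit/complexity balance; with n ≈ 60 its penalty (ln 60 ≈ 4.1) keeps the
false-inclusion rate of an independent candidate near 2% per trial, which
the permutation test in the suite verifies (≥ 95/100 rejections).

Genes are grouped per selected effector; a gene can appear in several
modules. Trans-module regulators are the genes on the effector arm that are
themselves cis targets of it. Modules below the minimum size (default 5)
are dropped — large enough to suppress singleton noise, small enough to keep
compact methylation modules discoverable. All orderings are lexicographic,
so discovery is byte-deterministic.

## Validation battery

Validation cohorts provide expression and right-censored survival; the
expression matrix is rank-CDF normalized per cohort and all three tests run
on that scale.

* **Coherence** — all pairwise Pearson correlations among the module's
  mappable targets versus the pairwise correlations of 1000 randomly chosen
  genes (both pools capped at 50 000 pairs), compared by a one-sided
  (positive-shift) KS test. The one-sided p feeds the size adjustment; the
  two-sided p is reported alongside.
* **Cox shift** — univariate proportional-hazards coefficients per gene
  (Breslow ties, Newton iterations at tolerance 1e−9, vectorized across
  genes; non-converged or non-identified genes are recorded as missing),
  module coefficients versus the all-gene background, one-sided KS for a
  positive shift (high expression ↦ shorter survival).
* **Aggregate-biomarker log-rank** — per patient the median expression over
  module targets; the high group exceeds the mean expression over all genes
  in the matrix (on the CDF scale that mean is ≈ 0.5, so the split is close
  to the biomarker median). A variant splitting at the mean of the
  aggregate itself is available via `split_reference="biomarker_mean"`.
  A zero log-rank statistic is reported as p = 1 exactly.

KS p-values are asymptotic (Kolmogorov survival function two-sided,
exp(−2·n_eff·D²) one-sided) and computed directly from sorted arrays so the
permutation batteries stay cheap; the implementation is cross-checked
against a brute-force pooled-ECDF scan and scipy in the tests. Because the
raw KS p depends strongly on set size, both KS tests report a size-adjusted
p: the add-one rank of the observed raw p among raw p-values of random
size-matched gene sets, (1 + #{p_rand ≤ p_obs})/(n_adjust + 1), which cannot
be zero and is uniform under the null by exchangeability. Thresholds:
adjusted p < 0.05 for coherence and Cox shift, p < 0.1 for log-rank.

Any non-evaluable test (fewer than two mappable targets or coefficients, an
empty patient group) **fails closed**: degenerate modules can never
validate. A module's overall pass requires all three tests in every
required cohort.

## False-discovery rates

*Pairwise*: sample labels of each effector matrix are shuffled against
expression (preserving within-matrix structure, breaking every cross-omics
link — the null the FDR ratio requires; for correlation screening shuffling
expression instead would be symmetric), significant pairs are recounted at
the unchanged discovery thresholds over 100 permutations, and
FDR = mean null count / observed count, per aberration type and pooled. A
zero observed count yields a NaN sentinel, never 0.

*Module level*: genes are randomly reassigned to modules matching the
discovered size multiset and pushed through the full battery; expected pass
counts per test and for the conjunction are reported over the runs. Two
cost controls, both statistically neutral: n_adjust is reduced to 200
(adjusted-p granularity 1/201, ample at α = 0.05), and the size-matched null
raw-p pool is computed once per (cohort, size) and shared by all random
modules of that size — the pool *is* the size-matched null distribution, so
sharing changes nothing.

## Two-block PLS

NIPALS with tolerance 1e−10 on the score change and a 5000-iteration cap
(convergence is linear at the squared ratio of the top two singular values
of X_cᵀY_c; random blocks occasionally need a few thousand iterations, and a
non-convergence is a hard error, never a silent truncation). Regression-mode
deflation (X by t·pᵀ, Y by t·cᵀ) is the default because one block is treated
as the response; a canonical mode is available since two target sets are
symmetric in principle. Scores are mutually orthogonal and X = T·Pᵀ + E
holds to 1e−8 (asserted). Cumulative R²(m) = 1 − ‖Y_c − Σ t_k c_kᵀ‖²/‖Y_c‖²
is non-decreasing in m and equals the least-squares fit of Y_c on the
scores. When two modules are compared both orientations can be reported;
note the statistic is in-sample and sizeable even for independent blocks
when variables are numerous relative to samples — the acceptance report
prints the within-module versus independent-modules contrast for exactly
this reason. The correlation circle gives each variable's correlations with
the first two scores; constant variables are flagged at the origin.

The effector–target shift analysis correlates a focal arm's CNV with each
target's expression and compares against the pooled correlations of the
remaining arms with the same targets (one-sided KS), localizing which arm
plausibly drives an externally defined target set.

## Enrichment (offline)

Literature ranking intersects module targets with the top 5% of an offline
citation-count table (ties at the cutoff included). Gene-set
over-representation uses the right-tailed hypergeometric test against the
measured-gene background (not the genome — unmeasured genes could never
appear in a module), Benjamini–Hochberg adjustment across sets, and reports
only sets with adjusted p < 0.01 *and* overlap > 4. Both the tail
probability and the BH step are oracle-checked (direct enumeration; a
hand-computed 10-value table).

## Synthetic study conditions

The default layout is 20 chromosomes × 2 arms × 50 genes (2000 genes), 60
tumor/normal training pairs, 10 CNV probes per arm, 100 methylation-measured
genes. Latent arm signals are N(0, σ_arm = 1) shared by the arm's probes
plus probe noise (sd 0.3); tumor/normal log-ratios of planted targets are
β·(standardized driver) + N(0, noise_sd), so β = 1 with noise 1 gives a
target–driver correlation of 1/√2 ≈ 0.707, the middle of the screening
regime (the suite asserts the realized mean |r| lies in (0.6, 0.8) at
n = 60). Trans modules route through regulators (cis targets with smaller
noise, 0.5); methylation modules share a uniform latent beta-difference with
negative loading on their targets.

Validation cohorts (150 patients each, between the smaller and larger cohort
sizes such studies report) regenerate each planted module's targets from a
common latent factor and draw exponential survival times with hazard
λ₀·exp(γ·standardized median target expression), λ₀ = 0.1 per time unit,
independent exponential censoring calibrated by bisection to a 30% censored
fraction (a Weibull option applies a common power transform, preserving
order and censoring status). The default study plants γ = 1.2 in the
"EastAsian-female" cohort and γ = 0 in the "EastAsian-male" cohort — one
effect cohort and one null cohort. A single null cohort is a deliberate
design point: the specificity check requires the log-rank test to stay
non-significant (p ≥ 0.1, probability 0.9 under the null) in *every*
zero-effect cohort, so the all-fail probability decays as 0.9^k with k null
cohorts and the seed-consistency count would measure the multiplicity of
nulls rather than the specificity of the effect.

The null-FDR condition uses a fully null training cohort with 30 samples:
at n = 30 the |r| ≥ 0.5 threshold is crossed by chance often enough
(hundreds of pooled pairwise calls) that the observed/expected ratio
concentrates near 1, making the ≥ 0.9 bound on the null FDR a sharp test
rather than a small-count lottery.

What the generator does *not* emulate: microarray probe-level artifacts,
batch effects, realistic CNV breakpoint or LD structure, correlated
background genes, or confounding between subpopulation labels and unrelated
expression differences. Passing tests therefore demonstrate the statistical
machinery — recovery at the stated effect sizes, calibration of the
permutation p-values, specificity of the survival linkage — not robustness
to platform noise on real cohorts.

## Numerical choices and degenerate inputs

Cox coefficients with monotone partial likelihood (e.g. perfect separation
of events by the covariate) or flat likelihood (no covariate variation in
any risk set) are reported as missing/zero respectively; Newton steps are
clipped to |Δβ| ≤ 2 and estimates escaping |β| > 10 are treated as
non-identified. Covariates are centered per gene before exponentiation
(the partial likelihood is invariant to shifts). The problem sizes used in
the test suite (2000-gene cohorts, 10-seed recovery runs, 200-draw
calibrations, 2200 random modules for the conjunction bound) were chosen so
each statistical bound is measured with enough replicates for its stated
tolerance while the whole suite stays in the minutes range on one CPU.

## Known limitations

* Per-type screening thresholds beyond the single default are configurable
  but untuned; real studies would calibrate them per platform.
* The feature functions of the logistic model use only first moments of the
  trinary states; interactions between effectors are not modeled.
* Multivariate Cox models with clinical covariates, proportional-hazards
  diagnostics, and sub-arm CNV segmentation are out of scope.
* The PLS R² is descriptive and in-sample; no significance test is
  attached to it.
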