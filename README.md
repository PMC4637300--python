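# assocmod

Discovery and validation of **association modules** in multi-omic cancer
cohorts: statistical couplings between an effector DNA aberration — the copy
number of a chromosome arm, or the methylation state of specific genes — and
the set of target genes whose mRNA expression it explains. The package is
aimed at researchers integrating paired tumor/normal expression, copy-number
and methylation data who want to ask whether a DNA-level lesion drives a
transcriptional program, whether that program replicates in independent
cohorts, and whether it carries prognostic weight only in particular patient
subpopulations (e.g. one gender or ethnicity).

## The model

Expression, CNV and methylation measurements of each feature are reduced to
rank-CDF values `y ∈ (0,1)` over the cohort, then softened into a trinary
regulation state `x ∈ {down = −1, no-change = 0, up = +1}`:

    P(x = +1 | y) = y / (1 − ln y)
    P(x = −1 | y) = (1 − y) / (1 − ln(1 − y))
    P(x =  0 | y) = 1 − P(x = +1 | y) − P(x = −1 | y)

Per gene, candidate effectors are screened by Pearson correlation
(|r| ≥ 0.5, sign-constrained: cis-CNV positive, methylation negative) and a
logistic model of the expression state is grown greedily in the layer order
cis-CNV → trans-CNV → methylation:

    P(y | x) = exp(Σᵢ λᵢ fᵢ(x, y)) / Z(x),   λᵢ ≥ 0,
    fᵢ(x, y) = directionᵢ · E[xᵢ] · y

keeping a covariate only when the BIC strictly improves. Genes sharing a
selected effector form an association module (cis, trans with mediating
regulators, or methylation).

Modules are validated per cohort with three tests — expression coherence
(one-sided KS of pairwise target correlations against a 1000-gene random
background), Cox-coefficient shift (one-sided KS of per-gene univariate
proportional-hazards coefficients against the all-gene background), and an
aggregate-biomarker Kaplan–Meier log-rank test (patients split by whether
the median target expression exceeds the cohort's mean expression). The KS
tests use size-adjusted permutation p-values (rank among size-matched random
gene sets). False-discovery rates come from label permutations (pairwise)
and random size-matched modules (module level); dependency between two
modules' target sets is quantified with two-block NIPALS PLS (correlation
circle and cumulative R²).

A synthetic cohort generator plants all three module types, with
arm-coherent CNV probes, paired tumor/normal matrices, and right-censored
survival whose hazard depends on a module's median expression only in
designated subpopulations — so every statistical property above can be
verified end to end.

## Worked example

```python
from assocmod import (default_spec, simulate_training_cohort, simulate_validation_cohorts,
                      discover_modules, score_recovery, validate_module, ValidationConfig)
from assocmod.pipeline import preprocess_training

spec = default_spec(seed=1)                      # 2000 genes, 60 tumor/normal pairs,
training, truth = simulate_training_cohort(spec) # one planted 40-target cis module on chr1p
expr_cdf, arm_cnv, meth = preprocess_training(training)
modules, models = discover_modules(expr_cdf, arm_cnv, meth, training.annotation)
for m in modules:
    print(f"{m.module_id}  type={m.kind}  effector={m.effectors[0]}  targets={m.size}")
print(score_recovery(modules, truth)[["effector", "precision", "recall"]].to_string(index=False))

cohorts, _ = simulate_validation_cohorts(spec)   # survival effect only in EastAsian-female
result = validate_module(modules[0], cohorts, ValidationConfig(n_adjust=200, seed=1))
for name, prog in result.prognostic.items():
    coh = result.coherence[name]
    print(f"{name}: coherence adj p={coh.adjusted_p:.4f}  cox adj p={prog.cox_adjusted_p:.4f}  "
          f"log-rank p={prog.logrank_p:.3g}  groups {prog.n_high}/{prog.n_low}")
```

prints

```
M01  type=cis_cnv  effector=chr1p  targets=40
effector  precision  recall
   chr1p        1.0     1.0
EastAsian-female: coherence adj p=0.0050  cox adj p=0.0050  log-rank p=9.96e-11  groups 72/78
EastAsian-male: coherence adj p=0.0050  cox adj p=0.3980  log-rank p=0.74  groups 78/72
```

The planted chr1p module is recovered exactly (precision = recall = 1). Its
target expressions cohere in both validation cohorts (adjusted p = 0.005,
the smallest value 200 permutations can resolve), but the prognostic tests
separate the subpopulations: in the female East-Asian cohort — where the
generator ties the hazard to module expression — the Cox-coefficient
distribution is significantly shifted and the high/low biomarker groups'
survival curves differ at log-rank p ≈ 1e−10, while the male cohort (no
planted effect) shows neither.

The same flow is available from the shell:

```sh
assocmod all --outdir results_pipeline --seed 1
```

which writes per-stage TSV reports (modules, validation, FDR, PLS,
enrichment) and manifests with config hashes and seeds.

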