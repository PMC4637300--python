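"""Validation of association modules on independent expression cohorts.

Three tests are applied per module and cohort:

* **Expression coherence** -- the module's pairwise target correlations are
  compared with the pairwise correlations of a large random gene background
  by a one-sided (positive-shift) KS test.
* **Cox-coefficient shift** -- per-gene univariate Cox coefficients of the
  targets are compared with the all-gene coefficient background by a
  one-sided KS test; a positive shift means high expression associates with
  shorter survival.
* **Aggregate-biomarker log-rank** -- patients are split by whether the
  median expression over the module targets exceeds the mean expression of
  all genes in the cohort, and the two Kaplan-Meier curves are compared with
  a log-rank test.

KS p-values depend strongly on module size, so the first two tests report a
size-adjusted p: the rank of the module's raw p among raw p-values of random
size-matched gene sets, with the add-one convention
(1 + #{random p <= observed p}) / (n_adjust + 1).

Any non-evaluable test (too few mappable targets, an empty patient group)
fails closed: it can never contribute to an overall pass.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from lifelines.statistics import logrank_test

from .cox import cox_per_gene
from .discovery import AssociationModule
from .io import CohortBundle
from .preprocess import ecdf_normalize
from .stats import ks_compare, ks_p_against_background

logger = logging.getLogger(__name__)

#: cap on the number of pairwise correlations kept per distribution
MAX_PAIRS = 50_000


@dataclass
class ValidationConfig:
    """Thresholds and replicate counts of the validation battery."""

    n_background: int = 1000
    n_adjust: int = 1000
    coherence_alpha: float = 0.05
    cox_alpha: float = 0.05
    logrank_alpha: float = 0.1
    #: "global_mean" splits patients at the mean over all genes; the
    #: "biomarker_mean" variant splits at the mean of the aggregate itself
    split_reference: str = "global_mean"
    required_cohorts: list[str] | None = None
    seed: int = 0


@dataclass
class CoherenceResult:
    module_id: str
    cohort: str
    n_targets: int
    ks_stat: float = np.nan
    raw_p_one_sided: float = np.nan
    raw_p_two_sided: float = np.nan
    adjusted_p: float = np.nan
    evaluable: bool = False
    passed: bool = False


@dataclass
class PrognosticResult:
    module_id: str
    cohort: str
    cox_ks_stat: float = np.nan
    cox_raw_p: float = np.nan
    cox_adjusted_p: float = np.nan
    cox_evaluable: bool = False
    pass_cox: bool = False
    logrank_stat: float = np.nan
    logrank_p: float = np.nan
    n_high: int = 0
    n_low: int = 0
    logrank_evaluable: bool = False
    pass_logrank: bool = False


@dataclass
class ModuleValidationResult:
    module_id: str
    coherence: dict[str, CoherenceResult] = field(default_factory=dict)
    prognostic: dict[str, PrognosticResult] = field(default_factory=dict)
    overall_pass: bool = False

    def to_rows(self) -> list[dict]:
        rows = []
        for cohort in self.coherence:
            c = self.coherence[cohort]
            p = self.prognostic.get(cohort)
            row = {
                "module_id": self.module_id,
                "cohort": cohort,
                "n_targets": c.n_targets,
                "coherence_ks": c.ks_stat,
                "coherence_raw_p": c.raw_p_one_sided,
                "coherence_raw_p_two_sided": c.raw_p_two_sided,
                "coherence_adjusted_p": c.adjusted_p,
                "pass_coherence": c.passed,
            }
            if p is not None:
                row.update(
                    {
                        "cox_ks": p.cox_ks_stat,
                        "cox_raw_p": p.cox_raw_p,
                        "cox_adjusted_p": p.cox_adjusted_p,
                        "pass_cox": p.pass_cox,
                        "logrank_stat": p.logrank_stat,
                        "logrank_p": p.logrank_p,
                        "n_high": p.n_high,
                        "n_low": p.n_low,
                        "pass_logrank": p.pass_logrank,
                    }
                )
            row["overall_pass"] = self.overall_pass
            rows.append(row)
        return rows


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _standardize_rows(values: np.ndarray) -> np.ndarray:
    z = values - values.mean(axis=1, keepdims=True)
    sd = np.sqrt((z**2).sum(axis=1))
    sd[sd == 0] = np.nan
    return z / sd[:, None]


def _pairwise_correlations(z: np.ndarray, rows: np.ndarray, rng: np.random.Generator,
                           max_pairs: int = MAX_PAIRS) -> np.ndarray:
    """Upper-triangle correlations among ``rows`` of a standardized matrix."""
    m = rows.size
    n_pairs = m * (m - 1) // 2
    if n_pairs <= max_pairs:
        sub = z[rows]
        corr = sub @ sub.T
        iu = np.triu_indices(m, k=1)
        vals = corr[iu]
    else:
        ii = rng.integers(0, m, size=2 * max_pairs)
        jj = rng.integers(0, m, size=2 * max_pairs)
        keep = ii < jj
        ii, jj = ii[keep][:max_pairs], jj[keep][:max_pairs]
        vals = np.einsum("ij,ij->i", z[rows[ii]], z[rows[jj]])
    return vals[np.isfinite(vals)]


def background_correlations(
    expr_cdf: pd.DataFrame,
    n_background: int,
    rng: np.random.Generator,
    z: np.ndarray | None = None,
) -> np.ndarray:
    """Pairwise correlations among ``n_background`` randomly selected genes."""
    g = expr_cdf.shape[0]
    n_background = min(n_background, g)
    if z is None:
        z = _standardize_rows(expr_cdf.to_numpy(dtype=float))
    rows = rng.choice(g, size=n_background, replace=False)
    return _pairwise_correlations(z, rows, rng)


def _sized_null_raw_ps(
    z: np.ndarray,
    size: int,
    n_sets: int,
    background_sorted: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Raw one-sided KS p-values of random size-matched gene sets."""
    g = z.shape[0]
    out = np.empty(n_sets)
    for k in range(n_sets):
        rows = rng.choice(g, size=size, replace=False)
        vals = _pairwise_correlations(z, rows, rng)
        out[k] = ks_p_against_background(vals, background_sorted, side="greater")
    return out


def adjusted_p_from_null(raw_p: float, null_ps: np.ndarray) -> float:
    """Add-one permutation p: rank of the observed raw p among null raw ps."""
    return float((1 + np.sum(null_ps <= raw_p)) / (null_ps.size + 1))


# ---------------------------------------------------------------------------
# coherence
# ---------------------------------------------------------------------------

def coherence_test(
    module: AssociationModule,
    expr_cdf: pd.DataFrame,
    n_background: int = 1000,
    n_adjust: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
    cohort: str = "",
    _z: np.ndarray | None = None,
    _background: np.ndarray | None = None,
    _null_ps: np.ndarray | None = None,
) -> CoherenceResult:
    """Size-adjusted expression-coherence test of one module in one cohort.

    Private ``_z`` / ``_background`` / ``_null_ps`` arguments let batch
    callers (the module-level FDR) reuse the standardized matrix, the
    background correlation distribution and per-size null p-value pools.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 101]))
    present = [g for g in module.targets if g in expr_cdf.index]
    result = CoherenceResult(module_id=module.module_id, cohort=cohort, n_targets=len(present))
    if len(present) < 2:
        logger.warning("module %s: <2 targets mappable in cohort %s", module.module_id, cohort)
        return result

    z = _z if _z is not None else _standardize_rows(expr_cdf.to_numpy(dtype=float))
    rows = expr_cdf.index.get_indexer(present)
    module_corrs = _pairwise_correlations(z, rows, rng)
    if module_corrs.size < 1:
        return result

    bg = _background
    if bg is None:
        if expr_cdf.shape[0] <= len(present) + 2:
            raise ValueError("cohort has too few genes for a background distribution")
        bg = background_correlations(expr_cdf, n_background, rng, z=z)
    bg_sorted = np.sort(bg)

    # direct background comparison keeps two-target modules (one pairwise
    # correlation) evaluable
    from .stats import _ks_distances

    d_two, d_one = _ks_distances(np.sort(module_corrs), bg_sorted)
    p_two = ks_p_against_background(module_corrs, bg_sorted, side="two_sided")
    p_one = ks_p_against_background(module_corrs, bg_sorted, side="greater")
    null_ps = _null_ps
    if null_ps is None:
        null_ps = _sized_null_raw_ps(z, len(present), n_adjust, bg_sorted, rng)
    adj = adjusted_p_from_null(p_one, null_ps)
    return replace(
        result,
        ks_stat=d_one,
        raw_p_one_sided=p_one,
        raw_p_two_sided=p_two,
        adjusted_p=adj,
        evaluable=True,
        passed=bool(adj < alpha),
    )


# ---------------------------------------------------------------------------
# Cox-coefficient shift
# ---------------------------------------------------------------------------

def cox_shift_test(
    module: AssociationModule,
    cox_all: pd.Series,
    n_adjust: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
    _null_ps: np.ndarray | None = None,
) -> tuple[float, float, float, bool, bool]:
    """One-sided KS of module Cox coefficients vs the all-gene background.

    Returns ``(D, raw_p, adjusted_p, evaluable, passed)``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 202]))
    background = cox_all.dropna()
    coefs = background.reindex([g for g in module.targets if g in background.index]).dropna()
    if coefs.size < 2 or background.size < 4:
        logger.warning("module %s: too few Cox coefficients; test not evaluable", module.module_id)
        return np.nan, np.nan, np.nan, False, False

    bg_sorted = np.sort(background.to_numpy())
    d, raw_p = ks_compare(coefs.to_numpy(), bg_sorted, side="greater")
    null_ps = _null_ps
    if null_ps is None:
        null_ps = np.empty(n_adjust)
        for k in range(n_adjust):
            sub = rng.choice(bg_sorted, size=coefs.size, replace=False)
            null_ps[k] = ks_p_against_background(sub, bg_sorted, side="greater")
    adj = adjusted_p_from_null(raw_p, null_ps)
    return d, raw_p, adj, True, bool(adj < alpha)


# ---------------------------------------------------------------------------
# aggregate-biomarker Kaplan-Meier / log-rank
# ---------------------------------------------------------------------------

def km_logrank_on_aggregate(
    module: AssociationModule,
    expr_cdf: pd.DataFrame,
    clinical: pd.DataFrame,
    alpha: float = 0.1,
    split_reference: str = "global_mean",
) -> dict:
    """Split patients by the module's aggregate biomarker and log-rank them.

    The aggregate biomarker of a patient is the median expression over the
    module's targets; the high group holds patients whose aggregate exceeds
    the mean expression over all genes in the matrix (``global_mean``) or
    the mean aggregate (``biomarker_mean``).
    """
    present = [g for g in module.targets if g in expr_cdf.index]
    out = {
        "logrank_stat": np.nan, "logrank_p": np.nan,
        "n_high": 0, "n_low": 0, "evaluable": False, "passed": False,
    }
    if not present:
        return out
    samples = [s for s in expr_cdf.columns if s in clinical.index]
    aggregate = expr_cdf.loc[present, samples].median(axis=0)
    if split_reference == "global_mean":
        threshold = float(expr_cdf.to_numpy().mean())
    elif split_reference == "biomarker_mean":
        threshold = float(aggregate.mean())
    else:
        raise ValueError(f"unknown split_reference {split_reference!r}")
    high = aggregate > threshold
    clin = clinical.loc[samples]
    n_high, n_low = int(high.sum()), int((~high).sum())
    out["n_high"], out["n_low"] = n_high, n_low
    if n_high == 0 or n_low == 0:
        logger.warning("module %s: one-sided biomarker split; log-rank not evaluable", module.module_id)
        return out
    res = logrank_test(
        clin.loc[high.values, "time"], clin.loc[~high.values, "time"],
        event_observed_A=clin.loc[high.values, "event"].astype(int),
        event_observed_B=clin.loc[~high.values, "event"].astype(int),
    )
    stat = float(res.test_statistic)
    p = 1.0 if stat == 0.0 else float(res.p_value)
    out.update({"logrank_stat": stat, "logrank_p": p, "evaluable": True, "passed": bool(p < alpha)})
    return out


def km_curve_coordinates(times, events) -> pd.DataFrame:
    """Kaplan-Meier coordinates (time, survival) for export/plotting."""
    from lifelines import KaplanMeierFitter

    km = KaplanMeierFitter()
    km.fit(times, event_observed=np.asarray(events, dtype=int))
    sf = km.survival_function_
    return pd.DataFrame({"time": sf.index.to_numpy(), "survival": sf.iloc[:, 0].to_numpy()})


# ---------------------------------------------------------------------------
# full battery
# ---------------------------------------------------------------------------

def prepare_validation_cohort(bundle: CohortBundle) -> tuple[str, pd.DataFrame, pd.DataFrame]:
    """CDF-normalize a cohort's expression matrix for validation."""
    label = next(
        (k for k, m in bundle.matrices.items() if m.role == "expression"), None
    )
    if label is None:
        raise ValueError(f"cohort {bundle.name!r} has no expression matrix")
    expr_cdf = ecdf_normalize(bundle.matrices[label])
    if bundle.clinical is None:
        raise ValueError(f"cohort {bundle.name!r} has no clinical table")
    return bundle.name, expr_cdf, bundle.clinical


def validate_module(
    module: AssociationModule,
    cohorts: list[CohortBundle],
    config: ValidationConfig | None = None,
    _prepared: list[tuple[str, pd.DataFrame, pd.DataFrame]] | None = None,
    _cox_all: dict[str, pd.Series] | None = None,
) -> ModuleValidationResult:
    """Run the three-test battery for one module over validation cohorts.

    ``overall_pass`` requires coherence, Cox-shift and log-rank to pass in
    every required cohort (all cohorts unless ``config.required_cohorts``
    narrows the list); any non-evaluable test fails closed.
    """
    config = config or ValidationConfig()
    prepared = _prepared or [prepare_validation_cohort(b) for b in cohorts]
    result = ModuleValidationResult(module_id=module.module_id)
    required = config.required_cohorts or [name for name, _, _ in prepared]

    for name, expr_cdf, clinical in prepared:
        coh = coherence_test(
            module, expr_cdf,
            n_background=config.n_background, n_adjust=config.n_adjust,
            seed=config.seed, alpha=config.coherence_alpha, cohort=name,
        )
        cox_all = (_cox_all or {}).get(name)
        if cox_all is None:
            cox_all = cox_per_gene(expr_cdf, clinical)
        d, raw, adj, ok, passed = cox_shift_test(
            module, cox_all, n_adjust=config.n_adjust, seed=config.seed,
            alpha=config.cox_alpha,
        )
        km = km_logrank_on_aggregate(
            module, expr_cdf, clinical,
            alpha=config.logrank_alpha, split_reference=config.split_reference,
        )
        result.coherence[name] = coh
        result.prognostic[name] = PrognosticResult(
            module_id=module.module_id, cohort=name,
            cox_ks_stat=d, cox_raw_p=raw, cox_adjusted_p=adj,
            cox_evaluable=ok, pass_cox=passed,
            logrank_stat=km["logrank_stat"], logrank_p=km["logrank_p"],
            n_high=km["n_high"], n_low=km["n_low"],
            logrank_evaluable=km["evaluable"], pass_logrank=km["passed"],
        )

    result.overall_pass = all(
        result.coherence[c].passed
        and result.prognostic[c].pass_cox
        and result.prognostic[c].pass_logrank
        for c in required
        if c in result.coherence
    ) and all(c in result.coherence for c in required)
    return result


def validate_modules(
    modules: list[AssociationModule],
    cohorts: list[CohortBundle],
    config: ValidationConfig | None = None,
) -> list[ModuleValidationResult]:
    """Validate many modules, sharing per-cohort preparations."""
    config = config or ValidationConfig()
    prepared = [prepare_validation_cohort(b) for b in cohorts]
    cox_all = {name: cox_per_gene(expr, clin) for name, expr, clin in prepared}
    return [
        validate_module(m, cohorts, config, _prepared=prepared, _cox_all=cox_all)
        for m in modules
    ]
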