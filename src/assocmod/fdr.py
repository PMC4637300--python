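"""Permutation false-discovery rates.

Two levels are estimated:

* **Pairwise** -- the sample labels of each effector matrix (arm CNV,
  methylation) are shuffled against the expression matrix, significant
  effector-gene correlations are recounted at the discovery thresholds, and
  FDR = (mean null count over permutations) / (observed count).
* **Module level** -- genes are randomly reassigned to modules matching the
  discovered size multiset, the full validation battery is applied, and the
  expected number of random modules passing each test (and all tests
  jointly) is recorded.

Shuffling effector labels (rather than expression) preserves the internal
structure of each data type while breaking every cross-omics link, which is
the null the FDR ratio requires; for correlation screening the two choices
are symmetric.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .discovery import AssociationModule, DiscoveryConfig
from .io import arm_labels
from .stats import ks_p_against_background
from .validation import (
    ValidationConfig,
    _pairwise_correlations,
    _sized_null_raw_ps,
    _standardize_rows,
    adjusted_p_from_null,
    background_correlations,
    km_logrank_on_aggregate,
    ks_compare,
)
from .cox import cox_per_gene

logger = logging.getLogger(__name__)


@dataclass
class FDRReport:
    level: str  # "pairwise" | "module"
    name: str  # aberration type or test name
    observed_positives: float
    expected_null_positives: float
    fdr: float  # NaN sentinel when no observed positives

    def to_row(self) -> dict:
        return {
            "level": self.level,
            "name": self.name,
            "observed_positives": self.observed_positives,
            "expected_null_positives": self.expected_null_positives,
            "fdr": self.fdr,
        }


def _fdr_value(null_mean: float, observed: float) -> float:
    if observed <= 0:
        return np.nan
    return float(null_mean / observed)


# ---------------------------------------------------------------------------
# pairwise FDR
# ---------------------------------------------------------------------------

def _count_pairwise(
    ez: np.ndarray,
    arm_z: np.ndarray,
    own_arm_col: np.ndarray,
    meth_z: np.ndarray | None,
    thresholds: DiscoveryConfig,
) -> dict[str, int]:
    """Count significant effector-gene correlations per aberration type.

    ``ez``/``arm_z``/``meth_z`` are row-standardized matrices; ``own_arm_col``
    gives, per gene, the column index of its own arm in ``arm_z`` (-1 when
    unannotated).
    """
    r = ez @ arm_z.T  # genes x arms
    gi = np.arange(r.shape[0])
    cis_mask = own_arm_col >= 0
    r_cis = r[gi[cis_mask], own_arm_col[cis_mask]]
    counts = {"cis_cnv": int(np.sum(r_cis >= thresholds.threshold("cis_cnv")))}
    trans = np.abs(r) >= thresholds.threshold("trans_cnv")
    if cis_mask.any():
        trans[gi[cis_mask], own_arm_col[cis_mask]] = False
    counts["trans_cnv"] = int(trans.sum())
    if meth_z is not None:
        rm = ez @ meth_z.T
        counts["methylation"] = int(np.sum(rm <= -thresholds.threshold("methylation")))
    else:
        counts["methylation"] = 0
    return counts


def pairwise_fdr(
    expr_cdf: pd.DataFrame,
    arm_cnv: pd.DataFrame,
    methylation: pd.DataFrame | None,
    annotation: pd.DataFrame,
    config: DiscoveryConfig | None = None,
    n_perm: int = 100,
    seed: int = 0,
) -> list[FDRReport]:
    """Permutation FDR of pairwise effector-gene associations, per type.

    Returns one report per aberration type plus a pooled ``overall`` row.
    An observed count of zero yields a NaN FDR sentinel, never 0.
    """
    if n_perm <= 0:
        raise ValueError("pairwise_fdr requires n_perm >= 1")
    config = config or DiscoveryConfig()
    rng = np.random.default_rng(np.random.SeedSequence([seed, 303]))

    ez = np.nan_to_num(_standardize_rows(expr_cdf.to_numpy(dtype=float)))
    # same scale convention as discovery screening: CNV on rank-CDF values
    from .preprocess import ecdf_normalize

    arm_z = np.nan_to_num(_standardize_rows(ecdf_normalize(arm_cnv).to_numpy(dtype=float)))
    meth_z = None
    if methylation is not None and len(methylation):
        sd = methylation.std(axis=1, ddof=1)
        pool = methylation.loc[sd >= config.meth_min_sd]
        if len(pool):
            meth_z = np.nan_to_num(_standardize_rows(pool.to_numpy(dtype=float)))

    gene_arm = arm_labels(annotation).reindex(expr_cdf.index)
    arm_index = {a: i for i, a in enumerate(arm_cnv.index)}
    own_arm_col = np.array([arm_index.get(a, -1) for a in gene_arm.fillna("")], dtype=int)

    observed = _count_pairwise(ez, arm_z, own_arm_col, meth_z, config)
    null_totals = {k: 0.0 for k in observed}
    n = ez.shape[1]
    for _ in range(n_perm):
        perm_a = rng.permutation(n)
        counts = _count_pairwise(
            ez,
            arm_z[:, perm_a],
            own_arm_col,
            meth_z[:, rng.permutation(n)] if meth_z is not None else None,
            config,
        )
        for k, v in counts.items():
            null_totals[k] += v
    reports = []
    for kind in ("cis_cnv", "trans_cnv", "methylation"):
        null_mean = null_totals[kind] / n_perm
        reports.append(
            FDRReport("pairwise", kind, observed[kind], null_mean, _fdr_value(null_mean, observed[kind]))
        )
    obs_all = sum(observed.values())
    null_all = sum(null_totals.values()) / n_perm
    reports.append(FDRReport("pairwise", "overall", obs_all, null_all, _fdr_value(null_all, obs_all)))
    return reports


# ---------------------------------------------------------------------------
# module-level FDR
# ---------------------------------------------------------------------------

def module_level_fdr(
    module_sizes: list[int],
    cohorts: list[tuple[str, pd.DataFrame, pd.DataFrame]],
    n_runs: int = 200,
    n_adjust: int = 200,
    seed: int = 0,
    config: ValidationConfig | None = None,
    n_real_passing: int | None = None,
) -> tuple[list[FDRReport], pd.DataFrame]:
    """Validation-battery FDR from randomly assembled size-matched modules.

    ``cohorts`` are prepared triples (name, expr_cdf, clinical); see
    ``validation.prepare_validation_cohort``.  Per run, genes are randomly
    assigned to modules matching ``module_sizes``; each random module is
    pushed through coherence, Cox-shift and log-rank in every cohort.  The
    adjusted p-values reuse, per cohort and module size, one pool of
    ``n_adjust`` size-matched null raw p-values (the pool is exactly the
    size-matched null distribution, so sharing it across modules of equal
    size changes nothing statistically and avoids quadratic cost).

    Returns FDR reports (per test and the all-test conjunction) and a
    per-run count table.
    """
    if n_runs <= 0:
        raise ValueError("module_level_fdr requires n_runs >= 1")
    config = config or ValidationConfig()
    rng = np.random.default_rng(np.random.SeedSequence([seed, 404]))

    # per-cohort shared machinery
    prep = []
    for name, expr_cdf, clinical in cohorts:
        z = _standardize_rows(expr_cdf.to_numpy(dtype=float))
        bg = background_correlations(expr_cdf, config.n_background, rng, z=z)
        bg_sorted = np.sort(bg)
        cox_all = cox_per_gene(expr_cdf, clinical)
        cox_bg_sorted = np.sort(cox_all.dropna().to_numpy())
        coh_null: dict[int, np.ndarray] = {}
        cox_null: dict[int, np.ndarray] = {}
        for size in sorted(set(module_sizes)):
            coh_null[size] = _sized_null_raw_ps(z, size, n_adjust, bg_sorted, rng)
            draws = np.empty(n_adjust)
            for k in range(n_adjust):
                sub = rng.choice(cox_bg_sorted, size=size, replace=False)
                draws[k] = ks_p_against_background(sub, cox_bg_sorted, side="greater")
            cox_null[size] = draws
        prep.append((name, expr_cdf, clinical, z, bg_sorted, cox_all, cox_bg_sorted, coh_null, cox_null))

    genes = cohorts[0][1].index.to_numpy()
    rows = []
    for run in range(n_runs):
        perm = rng.permutation(genes.size)
        offset = 0
        for mi, size in enumerate(module_sizes):
            members = genes[perm[offset:offset + size]]
            offset += size
            module = AssociationModule(
                module_id=f"R{run}_{mi}", kind="cis_cnv", effectors=["random"], targets=list(members)
            )
            pass_coh = pass_cox = pass_lr = True
            for name, expr_cdf, clinical, z, bg_sorted, cox_all, cox_bg_sorted, coh_null, cox_null in prep:
                idx = expr_cdf.index.get_indexer(members)
                vals = _pairwise_correlations(z, idx, rng)
                raw = ks_p_against_background(vals, bg_sorted, side="greater")
                adj = adjusted_p_from_null(raw, coh_null[size])
                pass_coh &= adj < config.coherence_alpha

                coefs = cox_all.reindex(members).dropna().to_numpy()
                if coefs.size < 2:
                    pass_cox = False
                else:
                    raw_c = ks_p_against_background(coefs, cox_bg_sorted, side="greater")
                    adj_c = adjusted_p_from_null(raw_c, cox_null[size])
                    pass_cox &= adj_c < config.cox_alpha

                km = km_logrank_on_aggregate(
                    module, expr_cdf, clinical,
                    alpha=config.logrank_alpha, split_reference=config.split_reference,
                )
                pass_lr &= km["passed"]
            rows.append(
                {
                    "run": run, "module": mi, "size": size,
                    "pass_coherence": pass_coh, "pass_cox": pass_cox,
                    "pass_logrank": pass_lr,
                    "pass_all": pass_coh and pass_cox and pass_lr,
                }
            )
    table = pd.DataFrame(rows)
    n_modules = len(module_sizes)
    reports = []
    for test in ("pass_coherence", "pass_cox", "pass_logrank", "pass_all"):
        expected = float(table[test].sum()) / n_runs
        name = test.removeprefix("pass_")
        if test == "pass_all":
            fdr = _fdr_value(expected, n_real_passing) if n_real_passing is not None else np.nan
            reports.append(FDRReport("module", "all_tests", float(n_real_passing or 0), expected, fdr))
        else:
            reports.append(FDRReport("module", name, np.nan, expected, np.nan))
    logger.info(
        "module-level FDR: %.4f of %d random modules passed all tests",
        table["pass_all"].mean(), n_runs * n_modules,
    )
    return reports, table


def write_fdr_report(reports: list[FDRReport], path, seed: int | None = None) -> None:
    frame = pd.DataFrame([r.to_row() for r in reports])
    with open(path, "w", encoding="utf-8") as fh:
        if seed is not None:
            fh.write(f"# seed={seed}\n")
        frame.to_csv(fh, sep="\t", index=False, float_format="%.6g")
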