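"""Association-module discovery.

For every gene the algorithm (i) screens candidate effectors -- the gene's
own chromosome arm CNV (cis), the CNVs of other arms (trans), and
methylation states of variable genes -- by Pearson correlation with the
gene's CDF-normalized expression; (ii) fits a logistic model of the trinary
expression state on the retained candidates,

    P(y | x) = exp(sum_i lambda_i f_i(x, y)) / Z(x),   lambda_i >= 0,

with signed feature functions f_i(x, y) = direction_i * E[x_i] * y evaluated
under the soft trinary assignments, adding covariates greedily in the layer
order cis -> trans -> methylation and keeping one only when it strictly
improves the BIC; and (iii) groups genes sharing a selected effector into
association modules.

Sign conventions follow the module-type definitions: cis associations are
positive by construction, methylation effects are repressive (negative), and
trans associations may carry either sign.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import DataError, arm_labels
from .preprocess import ecdf_normalize, trinary_expectation, trinary_probabilities

logger = logging.getLogger(__name__)

#: candidate layers in inclusion priority order
KIND_ORDER = ("cis_cnv", "trans_cnv", "methylation")


@dataclass(frozen=True)
class EffectorCandidate:
    """A screened effector: its kind, reference id, sign and screening score."""

    kind: str  # cis_cnv | trans_cnv | methylation
    reference: str  # arm id (chr7p) or methylation gene id
    direction: int  # +1 or -1
    screen_score: float  # Pearson r at screening


@dataclass
class GeneModel:
    """Fitted per-gene logistic model over selected effectors."""

    gene_id: str
    selected: list[tuple[EffectorCandidate, float]] = field(default_factory=list)
    loglik: float = 0.0
    bic: float = np.inf

    @property
    def effector_keys(self) -> list[tuple[str, str]]:
        return [(c.kind, c.reference) for c, _ in self.selected]


@dataclass
class AssociationModule:
    """An effector aberration with the genes whose expression it explains."""

    module_id: str
    kind: str  # cis_cnv | trans_cnv | methylation
    effectors: list[str]
    targets: list[str]
    regulators: list[str] = field(default_factory=list)

    @property
    def size(self) -> int:
        return len(self.targets)


@dataclass
class DiscoveryConfig:
    """Knobs of the module-finding algorithm.

    ``screen_threshold`` may be a float applied to every aberration type or
    a dict keyed by kind.  ``meth_min_sd`` filters methylation rows to those
    with enough variation to act as effectors.
    """

    screen_threshold: float | dict = 0.5
    min_module_size: int = 5
    meth_min_sd: float = 0.05
    min_shared_samples: int = 10
    optimizer_tol: float = 1e-8
    optimizer_max_iter: int = 500

    def threshold(self, kind: str) -> float:
        if isinstance(self.screen_threshold, dict):
            return float(self.screen_threshold[kind])
        return float(self.screen_threshold)


# ---------------------------------------------------------------------------
# candidate screening
# ---------------------------------------------------------------------------

def _pearson_rows(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Row-by-row Pearson correlation matrix between a (p x n) and b (q x n)."""
    az = a - a.mean(axis=1, keepdims=True)
    bz = b - b.mean(axis=1, keepdims=True)
    asd = np.sqrt((az**2).sum(axis=1))
    bsd = np.sqrt((bz**2).sum(axis=1))
    asd[asd == 0] = np.nan
    bsd[bsd == 0] = np.nan
    return (az @ bz.T) / np.outer(asd, bsd)


def screen_candidates(
    gene_id: str,
    expr_row,
    arm_cnv: pd.DataFrame,
    methylation: pd.DataFrame | None,
    annotation: pd.DataFrame,
    config: DiscoveryConfig | None = None,
) -> list[EffectorCandidate]:
    """Screen effector candidates for one gene.

    ``expr_row`` is the gene's CDF-normalized expression over samples;
    ``arm_cnv`` is arms x samples; ``methylation`` (optional) holds the
    tumor-normal methylation contrasts of candidate effector genes.
    Candidates are retained when |r| meets the kind's threshold and the sign
    satisfies the kind constraint (cis: positive; methylation: negative).
    """
    config = config or DiscoveryConfig()
    expr = np.asarray(expr_row, dtype=float)[None, :]
    if expr.shape[1] < config.min_shared_samples:
        raise DataError(
            f"screening needs >= {config.min_shared_samples} shared samples, got {expr.shape[1]}"
        )
    own_arm = None
    if gene_id in annotation.index:
        own_arm = arm_labels(annotation).loc[gene_id]

    out: list[EffectorCandidate] = []
    # CNV is brought onto the same rank-CDF scale as expression before
    # correlating, so heavy-tailed ratio distributions cannot mask
    # monotone associations
    r_arm = _pearson_rows(expr, ecdf_normalize(arm_cnv).to_numpy(dtype=float))[0]
    for arm, r in zip(arm_cnv.index, r_arm):
        if not np.isfinite(r):
            continue
        if arm == own_arm:
            if r >= config.threshold("cis_cnv"):
                out.append(EffectorCandidate("cis_cnv", arm, +1, float(r)))
        elif abs(r) >= config.threshold("trans_cnv"):
            out.append(EffectorCandidate("trans_cnv", arm, int(np.sign(r)), float(r)))
    if methylation is not None and len(methylation):
        r_meth = _pearson_rows(expr, methylation.to_numpy(dtype=float))[0]
        for ref, r in zip(methylation.index, r_meth):
            if ref == gene_id:
                continue
            if np.isfinite(r) and r <= -config.threshold("methylation"):
                out.append(EffectorCandidate("methylation", str(ref), -1, float(r)))
    return out


# ---------------------------------------------------------------------------
# logistic model with non-negative weights
# ---------------------------------------------------------------------------

def _expected_loglik(lam: np.ndarray, Z: np.ndarray, ey: np.ndarray) -> float:
    """Expected log-likelihood of P(y|x) under soft trinary labels.

    ``Z`` is candidates x samples with rows direction_i * E[x_i]; ``ey`` is
    the per-sample expected expression state E[y].  With a = sum_i lam_i Z_i,
    log P(y|x) = a*y - log(e^a + e^-a + 1).
    """
    a = lam @ Z if lam.size else np.zeros_like(ey)
    return float(np.sum(ey * a - np.logaddexp(np.logaddexp(a, -a), 0.0)))


def _loglik_grad(lam: np.ndarray, Z: np.ndarray, ey: np.ndarray) -> np.ndarray:
    a = lam @ Z
    ea, ema = np.exp(np.clip(a, -500, 500)), np.exp(np.clip(-a, -500, 500))
    mu = (ea - ema) / (ea + ema + 1.0)
    return Z @ (ey - mu)


def _maximize_nonneg(Z: np.ndarray, ey: np.ndarray, tol: float, max_iter: int) -> tuple[np.ndarray, float, bool]:
    """Projected gradient ascent of the expected log-likelihood over lam >= 0."""
    lam = np.zeros(Z.shape[0])
    ll = _expected_loglik(lam, Z, ey)
    step = 1.0 / max(1.0, np.sum(Z**2))
    for _ in range(max_iter):
        g = _loglik_grad(lam, Z, ey)
        # projected gradient: at an active bound only an inward push counts
        gp = np.where(lam > 0, g, np.maximum(g, 0.0))
        if np.max(np.abs(gp)) < tol:
            return lam, ll, True
        improved = False
        for _ in range(40):
            cand = np.maximum(lam + step * g, 0.0)
            ll_new = _expected_loglik(cand, Z, ey)
            if ll_new > ll:
                lam, ll = cand, ll_new
                step *= 1.5
                improved = True
                break
            step *= 0.5
        if not improved:
            # no ascent direction at machine precision
            return lam, ll, True
    return lam, ll, False


def fit_gene_model(
    gene_id: str,
    y_cdf,
    candidates: list[EffectorCandidate],
    effector_states: dict[tuple[str, str], np.ndarray],
    config: DiscoveryConfig | None = None,
) -> GeneModel:
    """Greedy forward fit of the trinary logistic model for one gene.

    Parameters
    ----------
    y_cdf : array over samples
        The gene's CDF-normalized expression (converted internally to the
        expected trinary state E[y]).
    candidates : screened effector candidates.
    effector_states : maps (kind, reference) -> E[x] per sample, the soft
        trinary state of each effector.
    Candidates are tried strictly in layer order (cis, then trans, then
    methylation; within a layer by |screening score| descending, ties broken
    by reference id) and kept only when the BIC strictly improves.
    """
    config = config or DiscoveryConfig()
    ey = trinary_expectation(np.asarray(y_cdf, dtype=float))
    n = ey.size

    ordered = sorted(
        candidates,
        key=lambda c: (KIND_ORDER.index(c.kind), -abs(c.screen_score), c.reference),
    )

    null_ll = -n * np.log(3.0)
    best = GeneModel(gene_id=gene_id, selected=[], loglik=null_ll, bic=-2.0 * null_ll)
    current: list[EffectorCandidate] = []
    for cand in ordered:
        trial = current + [cand]
        Z = np.vstack([c.direction * effector_states[(c.kind, c.reference)] for c in trial])
        lam, ll, converged = _maximize_nonneg(Z, ey, config.optimizer_tol, config.optimizer_max_iter)
        if not converged:
            logger.warning("optimizer did not converge for %s + %s; candidate skipped", gene_id, cand.reference)
            continue
        bic = -2.0 * ll + len(trial) * np.log(n)
        if bic < best.bic:
            current = trial
            best = GeneModel(
                gene_id=gene_id,
                selected=list(zip(trial, lam.tolist())),
                loglik=ll,
                bic=bic,
            )
    return best


# ---------------------------------------------------------------------------
# module assembly
# ---------------------------------------------------------------------------

def assemble_modules(
    models: list[GeneModel],
    annotation: pd.DataFrame,
    min_size: int = 5,
) -> list[AssociationModule]:
    """Group genes sharing a selected effector into association modules.

    A gene may belong to several modules.  For a trans module the regulators
    are the genes located on the effector arm that are themselves cis
    targets of that arm.  Modules smaller than ``min_size`` are dropped.
    Output ordering (and target ordering) is deterministic: by kind, then
    effector id, with gene ids sorted lexicographically.
    """
    by_effector: dict[tuple[str, str], set[str]] = {}
    for model in models:
        for kind, ref in model.effector_keys:
            by_effector.setdefault((kind, ref), set()).add(model.gene_id)

    cis_targets = {
        ref: members for (kind, ref), members in by_effector.items() if kind == "cis_cnv"
    }

    modules: list[AssociationModule] = []
    keys = sorted(by_effector, key=lambda k: (KIND_ORDER.index(k[0]), k[1]))
    for kind, ref in keys:
        targets = sorted(by_effector[(kind, ref)])
        if len(targets) < min_size:
            continue
        regulators: list[str] = []
        if kind == "trans_cnv":
            regulators = sorted(cis_targets.get(ref, set()))
        modules.append(
            AssociationModule(
                module_id="",
                kind=kind,
                effectors=[ref],
                targets=targets,
                regulators=regulators,
            )
        )
    for i, m in enumerate(modules, start=1):
        m.module_id = f"M{i:02d}"
    return modules


# ---------------------------------------------------------------------------
# end-to-end discovery
# ---------------------------------------------------------------------------

def discover_modules(
    expr_cdf: pd.DataFrame,
    arm_cnv: pd.DataFrame,
    methylation: pd.DataFrame | None,
    annotation: pd.DataFrame,
    config: DiscoveryConfig | None = None,
) -> tuple[list[AssociationModule], list[GeneModel]]:
    """Run screening, model fitting and grouping over all genes.

    ``expr_cdf``: genes x samples CDF-normalized expression contrasts;
    ``arm_cnv``: arms x samples median CNV ratios; ``methylation``:
    methylation contrasts of measured genes (rows failing the variation
    filter are excluded from the effector pool).  Returns the module list
    and the per-gene models of genes with at least one selected effector.
    """
    config = config or DiscoveryConfig()
    n = expr_cdf.shape[1]
    if n < config.min_shared_samples:
        raise DataError(f"need >= {config.min_shared_samples} shared samples, got {n}")

    meth_eff = None
    if methylation is not None and len(methylation):
        sd = methylation.std(axis=1, ddof=1)
        meth_eff = methylation.loc[sd >= config.meth_min_sd]
        if meth_eff.empty:
            meth_eff = None

    # soft trinary states of all effectors (rank-CDF within each effector row)
    effector_states: dict[tuple[str, str], np.ndarray] = {}
    arm_cdf = ecdf_normalize(arm_cnv)
    for arm in arm_cnv.index:
        state = trinary_expectation(arm_cdf.loc[arm].to_numpy())
        effector_states[("cis_cnv", arm)] = state
        effector_states[("trans_cnv", arm)] = state
    if meth_eff is not None:
        meth_cdf = ecdf_normalize(meth_eff)
        for ref in meth_eff.index:
            effector_states[("methylation", str(ref))] = trinary_expectation(
                meth_cdf.loc[ref].to_numpy()
            )

    # bulk screening correlations (CNV on the rank-CDF scale, like expression)
    expr_values = expr_cdf.to_numpy(dtype=float)
    r_arm = _pearson_rows(expr_values, arm_cdf.to_numpy(dtype=float))
    r_meth = (
        _pearson_rows(expr_values, meth_eff.to_numpy(dtype=float)) if meth_eff is not None else None
    )
    arms = list(arm_cnv.index)
    gene_arm = arm_labels(annotation)

    models: list[GeneModel] = []
    for gi, gene in enumerate(expr_cdf.index):
        own = gene_arm.get(gene)
        cands: list[EffectorCandidate] = []
        for ai, arm in enumerate(arms):
            r = r_arm[gi, ai]
            if not np.isfinite(r):
                continue
            if arm == own:
                if r >= config.threshold("cis_cnv"):
                    cands.append(EffectorCandidate("cis_cnv", arm, +1, float(r)))
            elif abs(r) >= config.threshold("trans_cnv"):
                cands.append(EffectorCandidate("trans_cnv", arm, int(np.sign(r)), float(r)))
        if r_meth is not None:
            for mi, ref in enumerate(meth_eff.index):
                if ref == gene:
                    continue
                r = r_meth[gi, mi]
                if np.isfinite(r) and r <= -config.threshold("methylation"):
                    cands.append(EffectorCandidate("methylation", str(ref), -1, float(r)))
        if not cands:
            continue
        model = fit_gene_model(gene, expr_cdf.iloc[gi].to_numpy(), cands, effector_states, config)
        if model.selected:
            models.append(model)

    modules = assemble_modules(models, annotation, min_size=config.min_module_size)
    logger.info("discovered %d modules from %d gene models", len(modules), len(models))
    return modules, models
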