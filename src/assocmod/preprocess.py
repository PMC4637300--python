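"""Tumor/normal ratios, rank-CDF normalization, trinary states, aggregation.

The normalization pipeline mirrors how heterogeneous platforms are brought
onto one scale: each feature's values across a cohort are replaced by their
empirical cumulative-distribution (mid-rank) values in the open interval
(0, 1).  The CDF value y of a gene in a sample is then softened into a
probability triple over the hidden trinary regulation state
x in {up = +1, no-change = 0, down = -1}:

    P(x = +1 | y) = y / (1 - ln y)
    P(x = -1 | y) = (1 - y) / (1 - ln(1 - y))
    P(x =  0 | y) = 1 - P(x = +1 | y) - P(x = -1 | y)

These closed forms are valid probabilities, symmetric under y -> 1 - y, and
strictly monotone in y.  Copy-number probes are summarized at chromosome-arm
resolution (the median over the arm's probes) because arm-scale coherence is
the dominant structure of tumor CNV profiles.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .io import DataError, OmicsMatrix, arm_labels

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# tumor / adjacent-normal contrast
# ---------------------------------------------------------------------------

def tumor_normal_ratio(tumor: OmicsMatrix, normal: OmicsMatrix) -> OmicsMatrix:
    """Per-feature tumor-vs-normal contrast for paired samples.

    Expression and copy-number probes use the element-wise ratio
    tumor / normal; methylation betas use the difference tumor - normal,
    which keeps the bounded [-1, 1] scale (downstream screening is
    correlation-based, hence invariant to this affine choice).

    Features with a non-positive normal value in any sample (for ratio
    roles) are dropped with a warning.
    """
    if tumor.role != normal.role:
        raise DataError(f"role mismatch: {tumor.role} vs {normal.role}")
    if not tumor.feature_ids.equals(normal.feature_ids):
        raise DataError("tumor and normal matrices must share identical feature ids")
    if not tumor.sample_ids.equals(normal.sample_ids):
        raise DataError("tumor and normal matrices must be paired on the same samples")

    if tumor.role == "methylation":
        out = tumor.data - normal.data
        return OmicsMatrix(role=tumor.role, data=out)

    bad = (normal.data <= 0).any(axis=1)
    t, n = tumor.data, normal.data
    if bad.any():
        logger.warning(
            "tumor_normal_ratio: dropping %d features with non-positive normal values",
            int(bad.sum()),
        )
        t, n = t.loc[~bad], n.loc[~bad]
    return OmicsMatrix(role=tumor.role, data=t / n)


# ---------------------------------------------------------------------------
# empirical-CDF normalization
# ---------------------------------------------------------------------------

def ecdf_normalize(matrix: OmicsMatrix | pd.DataFrame) -> pd.DataFrame:
    """Per-row mid-rank CDF transform: y_j = midrank(v_j) / (n + 1).

    Output values lie strictly inside (0, 1) (ties share values; a constant
    row maps to 0.5 everywhere), so downstream logarithms are always
    defined.  Strictly monotone transforms of a row leave its output
    unchanged.
    """
    data = matrix.data if isinstance(matrix, OmicsMatrix) else matrix
    values = data.to_numpy(dtype=float)
    if not np.isfinite(values).all():
        raise DataError("ecdf_normalize requires finite values; impute first")
    n = values.shape[1]
    ranks = rankdata(values, axis=1, method="average")
    return pd.DataFrame(ranks / (n + 1), index=data.index, columns=data.columns)


# ---------------------------------------------------------------------------
# trinary state probabilities
# ---------------------------------------------------------------------------

def trinary_probabilities(y):
    """Probability triple (P(x=+1|y), P(x=-1|y), P(x=0|y)) for CDF values y.

    Accepts scalars or arrays; every y must lie strictly in (0, 1).
    """
    arr = np.asarray(y, dtype=float)
    if np.any(arr <= 0.0) or np.any(arr >= 1.0):
        raise DataError("trinary_probabilities requires CDF values strictly inside (0, 1)")
    p_up = arr / (1.0 - np.log(arr))
    p_down = (1.0 - arr) / (1.0 - np.log1p(-arr))
    p_zero = 1.0 - p_up - p_down
    return p_up, p_down, p_zero


def trinary_expectation(y):
    """E[x | y] = P(x=+1|y) - P(x=-1|y), the soft trinary state."""
    p_up, p_down, _ = trinary_probabilities(y)
    return p_up - p_down


# ---------------------------------------------------------------------------
# grouped aggregation (probes -> genes, CNV probes -> arms)
# ---------------------------------------------------------------------------

def aggregate_by_group(matrix: OmicsMatrix | pd.DataFrame, grouping) -> pd.DataFrame:
    """Median over member features, per (group, sample).

    ``grouping`` maps feature id -> group id (dict or Series); features
    without a group are dropped, empty groups are omitted with a warning.
    """
    data = matrix.data if isinstance(matrix, OmicsMatrix) else matrix
    mapping = pd.Series(grouping) if not isinstance(grouping, pd.Series) else grouping
    mapping = mapping.reindex(data.index).dropna()
    dropped = len(data.index) - len(mapping)
    if dropped:
        logger.warning("aggregate_by_group: %d features lack a group and were dropped", dropped)
    if mapping.empty:
        raise DataError("aggregate_by_group: no feature maps to any group")
    grouped = data.loc[mapping.index].groupby(mapping, sort=True).median()
    grouped.index.name = data.index.name
    return grouped


def arm_cnv_matrix(cnv_ratio: OmicsMatrix | pd.DataFrame, probe_annotation: pd.DataFrame) -> pd.DataFrame:
    """Arm-level CNV: median probe tumor/normal ratio per chromosome arm.

    ``probe_annotation`` follows the gene-annotation schema (probe id,
    chromosome, arm, position); probes lacking arm annotation are dropped.
    Row ids of the result are segment ids like ``chr7p``.
    """
    labels = arm_labels(probe_annotation)
    return aggregate_by_group(cnv_ratio, labels)
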