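"""Offline effector-candidate ranking and gene-set over-representation.

Candidate effectors are prioritized by intersecting module targets with the
top fraction of an offline literature co-citation count table.  Functional
characterization uses generic gene-set over-representation: a right-tailed
hypergeometric (Fisher) p-value per set against the cohort's measured-gene
background, Benjamini-Hochberg adjustment across sets, and a reporting
filter of adjusted p < 0.01 with an overlap of more than 4 genes.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .io import DataError


def top_cited_intersection(
    citation_counts: pd.Series,
    targets: list[str],
    fraction: float = 0.05,
) -> list[str]:
    """Module targets among the top-cited fraction of genes.

    The cut sits at the count of the ceil(fraction * N)-th ranked gene;
    ties at the cutoff are included.  Output is ordered by (count
    descending, gene id).
    """
    if citation_counts.empty:
        raise DataError("citation count table is empty")
    if len(citation_counts) < 20:
        raise DataError("citation count table must cover at least 20 genes")
    n = len(citation_counts)
    k = max(1, math.ceil(fraction * n))
    ordered = citation_counts.sort_values(ascending=False, kind="stable")
    threshold = float(ordered.iloc[k - 1])
    top = set(ordered[ordered >= threshold].index)
    hits = [g for g in top if g in set(targets)]
    return sorted(hits, key=lambda g: (-float(citation_counts[g]), g))


def geneset_enrichment(
    module_targets: list[str],
    gene_sets: dict[str, list[str]],
    background: list[str],
    alpha: float = 0.01,
    min_overlap: int = 4,
) -> pd.DataFrame:
    """Right-tailed hypergeometric over-representation of module targets.

    ``background`` is the gene universe (all measured genes) and must
    contain every module target.  Sets with no background overlap are
    skipped.  The ``reported`` flag requires BH-adjusted p < ``alpha`` AND
    overlap strictly greater than ``min_overlap``.
    """
    bg = set(background)
    targets = set(module_targets)
    if not targets <= bg:
        raise DataError("background must contain every module target")
    n_bg = len(bg)
    n_mod = len(targets)

    rows = []
    for name, members in gene_sets.items():
        in_bg = bg.intersection(members)
        if not in_bg:
            continue
        overlap = len(targets & in_bg)
        # P(K >= overlap) drawing n_mod genes from n_bg with len(in_bg) marked
        raw_p = float(hypergeom.sf(overlap - 1, n_bg, len(in_bg), n_mod))
        rows.append(
            {
                "set_name": name,
                "overlap_count": overlap,
                "set_size": len(in_bg),
                "module_size": n_mod,
                "background_size": n_bg,
                "raw_p": raw_p,
            }
        )
    if not rows:
        return pd.DataFrame(
            columns=[
                "set_name", "overlap_count", "set_size", "module_size",
                "background_size", "raw_p", "bh_adjusted_p", "reported",
            ]
        )
    frame = pd.DataFrame(rows)
    frame["bh_adjusted_p"] = multipletests(frame["raw_p"].to_numpy(), method="fdr_bh")[1]
    frame["reported"] = (frame["bh_adjusted_p"] < alpha) & (frame["overlap_count"] > min_overlap)
    return frame.sort_values(["bh_adjusted_p", "set_name"], kind="stable").reset_index(drop=True)
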