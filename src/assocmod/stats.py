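"""Two-sample Kolmogorov-Smirnov comparisons against (large) backgrounds.

The validation battery evaluates tens of thousands of KS statistics of small
gene-set samples against one fixed background distribution, so the statistic
is computed directly from sorted arrays (O((n+m) log m)) and the p-value from
the asymptotic KS distribution: the Kolmogorov survival function for the
two-sided statistic and exp(-2 n_eff D^2) for the one-sided statistic, with
n_eff = n m / (n + m).
"""

from __future__ import annotations

import numpy as np
from scipy.special import kolmogorov


def _ks_distances(a_sorted: np.ndarray, b_sorted: np.ndarray) -> tuple[float, float]:
    """(D_two, D_greater) between two sorted samples.

    ``D_greater`` is the signed one-sided statistic sup_x (F_b - F_a),
    large when sample ``a`` is shifted toward larger values than ``b``.
    """
    n = a_sorted.size
    m = b_sorted.size
    i = np.arange(1, n + 1)
    # F_b just below each a-point (left limits) and at each a-point
    fb_left = np.searchsorted(b_sorted, a_sorted, side="left") / m
    fb_right = np.searchsorted(b_sorted, a_sorted, side="right") / m
    # sup(F_b - F_a): F_b - F_a only increases at b-jumps, so its supremum is
    # attained just before an a-point (or at +inf where it is 0)
    d_plus = max(0.0, float(np.max(fb_left - (i - 1) / n)))
    # sup(F_a - F_b): attained at a-points
    d_minus = max(0.0, float(np.max(i / n - fb_right)))
    return max(d_plus, d_minus), d_plus


def ks_compare(sample_a, sample_b, side: str = "two_sided") -> tuple[float, float]:
    """Two-sample KS test with asymptotic p-value.

    Parameters
    ----------
    sample_a, sample_b : array-like
        Samples of size >= 2 each.
    side : {"two_sided", "greater"}
        ``greater`` tests for a positive shift of ``sample_a`` relative to
        ``sample_b`` (sample_a stochastically larger).

    Returns
    -------
    (D, p) : statistic and asymptotic p-value.
    """
    a = np.sort(np.asarray(sample_a, dtype=float))
    b = np.sort(np.asarray(sample_b, dtype=float))
    if a.size < 2 or b.size < 2:
        raise ValueError("ks_compare requires both samples to have size >= 2")
    d_two, d_plus = _ks_distances(a, b)
    n_eff = a.size * b.size / (a.size + b.size)
    if side == "two_sided":
        d = d_two
        p = float(kolmogorov(np.sqrt(n_eff) * d))
    elif side == "greater":
        d = d_plus
        p = float(np.exp(-2.0 * n_eff * d * d))
    else:
        raise ValueError(f"unknown side {side!r}")
    return d, min(max(p, 0.0), 1.0)


def ks_p_against_background(sample, background_sorted: np.ndarray, side: str = "greater") -> float:
    """Fast KS p of a small sample against a pre-sorted background."""
    a = np.sort(np.asarray(sample, dtype=float))
    d_two, d_plus = _ks_distances(a, background_sorted)
    n_eff = a.size * background_sorted.size / (a.size + background_sorted.size)
    if side == "greater":
        return float(np.exp(-2.0 * n_eff * d_plus * d_plus))
    return float(kolmogorov(np.sqrt(n_eff) * d_two))
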