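"""Univariate Cox proportional-hazards coefficients, vectorized over genes.

The validation battery needs one partial-likelihood maximizer per gene over
thousands of genes and permutation replicates, so Newton iterations on the
Breslow partial likelihood are carried out for all genes simultaneously with
array operations.  A positive coefficient means high covariate values
associate with a higher hazard, i.e. shorter survival.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

#: coefficients escaping this magnitude are treated as non-identified
BETA_BOUND = 10.0


def cox_univariate(
    X: pd.DataFrame | np.ndarray,
    time,
    event,
    tol: float = 1e-9,
    max_iter: int = 60,
) -> pd.Series:
    """Fit one univariate Cox model per row of ``X``.

    Parameters
    ----------
    X : DataFrame or array, genes x samples
        Covariate values (one gene per row).
    time, event : array-like over samples
        Right-censored survival times and event indicators.
    tol : float
        Convergence tolerance on the Newton step.

    Returns
    -------
    pandas.Series of coefficients indexed like ``X``; genes whose Newton
    iteration does not converge (or diverges beyond ``BETA_BOUND``) are NaN.

    Ties are handled with the Breslow approximation: tied event times share
    the full common risk set.
    """
    if isinstance(X, pd.DataFrame):
        index = X.index
        values = X.to_numpy(dtype=float)
    else:
        values = np.asarray(X, dtype=float)
        index = pd.RangeIndex(values.shape[0])
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=bool)
    if values.shape[1] != t.size or t.size != e.size:
        raise ValueError("covariates, times and events must agree on sample count")
    if not e.any():
        raise ValueError("no events observed; Cox coefficients undefined")

    order = np.argsort(t, kind="stable")
    t_s = t[order]
    e_s = e[order]
    # centered covariates, samples x genes, in time order (centering leaves
    # the partial likelihood invariant but conditions the exponentials)
    xs = values.T[order]
    xs = xs - xs.mean(axis=0, keepdims=True)
    n, g = xs.shape

    # risk set of an event at position i = all positions >= first index with
    # the same time (Breslow tie handling)
    first = np.searchsorted(t_s, t_s, side="left")
    ev_rows = np.flatnonzero(e_s)
    ev_first = first[ev_rows]
    x_ev = xs[ev_rows]

    beta = np.zeros(g)
    active = np.ones(g, dtype=bool)
    failed = np.zeros(g, dtype=bool)
    for _ in range(max_iter):
        if not active.any():
            break
        xa = xs[:, active]
        ba = beta[active]
        eta = np.clip(ba[None, :] * xa, -500, 500)
        w = np.exp(eta)
        s0 = np.cumsum(w[::-1], axis=0)[::-1]
        s1 = np.cumsum((w * xa)[::-1], axis=0)[::-1]
        s2 = np.cumsum((w * xa * xa)[::-1], axis=0)[::-1]
        s0e = s0[ev_first]
        mean_x = s1[ev_first] / s0e
        grad = (x_ev[:, active] - mean_x).sum(axis=0)
        info = (s2[ev_first] / s0e - mean_x**2).sum(axis=0)

        step = np.zeros_like(grad)
        ok = info > 1e-12
        step[ok] = grad[ok] / info[ok]
        # flat information with a non-zero gradient: monotone likelihood
        failed_now = (~ok) & (np.abs(grad) > 1e-8)
        np.clip(step, -2.0, 2.0, out=step)
        ba = ba + step

        diverged = np.abs(ba) > BETA_BOUND
        converged = np.abs(step) < tol

        idx = np.flatnonzero(active)
        beta[idx] = ba
        failed[idx[failed_now | diverged]] = True
        still = ~(converged | failed_now | diverged)
        active[idx] = still
    # whatever is still active after max_iter did not converge
    failed |= active
    beta = beta.astype(float)
    beta[failed] = np.nan
    return pd.Series(beta, index=index, name="cox_coefficient")


def cox_per_gene(expr: pd.DataFrame, clinical: pd.DataFrame, min_events: int = 10) -> pd.Series:
    """Univariate Cox coefficient for every gene of an expression matrix.

    ``expr`` is genes x samples (CDF-normalized by convention); ``clinical``
    must cover every expression sample with ``time`` and ``event`` columns.
    """
    samples = [s for s in expr.columns if s in clinical.index]
    if len(samples) < expr.shape[1]:
        expr = expr.loc[:, samples]
    clin = clinical.loc[samples]
    n_events = int(clin["event"].astype(bool).sum())
    if n_events == 0:
        raise ValueError("cohort has zero events; cannot estimate Cox coefficients")
    if n_events < min_events:
        raise ValueError(f"cohort has only {n_events} events (< {min_events} required)")
    return cox_univariate(expr, clin["time"].to_numpy(), clin["event"].to_numpy())


def cox_partial_loglik(beta: float, x, time, event) -> float:
    """Breslow partial log-likelihood of a single covariate at ``beta``.

    Reference implementation used for diagnostics; the solver above
    maximizes exactly this function.
    """
    x = np.asarray(x, dtype=float)
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=bool)
    ll = 0.0
    for i in np.flatnonzero(e):
        risk = t >= t[i]
        ll += beta * x[i] - np.log(np.sum(np.exp(beta * x[risk])))
    return float(ll)
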