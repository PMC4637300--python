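"""Two-block partial least squares between the target sets of two modules.

X and Y are samples x genes blocks (each the expression of one module's
targets).  NIPALS iterations extract latent components maximizing the X-Y
covariance; in regression mode both blocks are deflated by the X-scores
(X <- X - t p', Y <- Y - t c'), so the score vectors are mutually orthogonal
and X admits the bilinear reconstruction X = T P' + E.  The cumulative R^2
of the Y block after m components and the correlation-circle coordinates
(per-variable correlations with the first two scores) are the two summaries
used to quantify inter-module dependency.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .stats import ks_compare

logger = logging.getLogger(__name__)


@dataclass
class PLSModel:
    """Fitted two-block PLS decomposition."""

    n_components: int
    x_scores: np.ndarray  # n x M (T)
    x_weights: np.ndarray  # p x M (w)
    x_loadings: np.ndarray  # p x M (P)
    y_weights: np.ndarray  # q x M (c)
    x_mean: np.ndarray
    y_mean: np.ndarray
    x_residual: np.ndarray  # E_M
    y_residual: np.ndarray
    component_covariances: np.ndarray = field(default_factory=lambda: np.empty(0))
    mode: str = "regression"


def fit_pls(
    X,
    Y,
    n_components: int,
    mode: str = "regression",
    tol: float = 1e-10,
    max_iter: int = 5000,
) -> PLSModel:
    """Fit a two-block PLS model by NIPALS.

    Parameters
    ----------
    X, Y : arrays or DataFrames, samples x variables
        Columns are centered internally; zero-variance columns are dropped
        with a warning (their weights/loadings are reported as 0).
    n_components : int
        Number of latent components (0 allowed: the model is just the
        centered data).
    mode : {"regression", "canonical"}
        Regression mode deflates Y by the X-scores (Y treated as response);
        canonical mode deflates each block by its own scores.
    """
    Xa = np.asarray(X, dtype=float)
    Ya = np.asarray(Y, dtype=float)
    if Xa.shape[0] != Ya.shape[0]:
        raise ValueError("X and Y must share samples")
    n = Xa.shape[0]
    if n < 3:
        raise ValueError("PLS requires at least 3 shared samples")
    if mode not in ("regression", "canonical"):
        raise ValueError(f"unknown PLS mode {mode!r}")

    x_mean = Xa.mean(axis=0)
    y_mean = Ya.mean(axis=0)
    Xc = Xa - x_mean
    Yc = Ya - y_mean

    x_keep = Xc.std(axis=0) > 0
    y_keep = Yc.std(axis=0) > 0
    if not x_keep.all() or not y_keep.all():
        logger.warning(
            "fit_pls: dropping %d X and %d Y zero-variance columns",
            int((~x_keep).sum()), int((~y_keep).sum()),
        )
    Xw = Xc[:, x_keep]
    Yw = Yc[:, y_keep]
    max_rank = min(np.linalg.matrix_rank(Xw), np.linalg.matrix_rank(Yw)) if n_components else 0
    if n_components > max_rank:
        raise ValueError(f"n_components={n_components} exceeds min rank {max_rank}")

    p_all, q_all = Xa.shape[1], Ya.shape[1]
    T = np.zeros((n, n_components))
    W = np.zeros((p_all, n_components))
    P = np.zeros((p_all, n_components))
    C = np.zeros((q_all, n_components))
    covs = np.zeros(n_components)

    Ex, Ey = Xw.copy(), Yw.copy()
    for m in range(n_components):
        # start u from the Y column with the largest variance
        u = Ey[:, int(np.argmax(Ey.var(axis=0)))].copy()
        t_old = np.zeros(n)
        for it in range(max_iter):
            w = Ex.T @ u
            nw = np.linalg.norm(w)
            if nw == 0:
                raise RuntimeError(f"PLS component {m + 1}: degenerate weight vector")
            w /= nw
            t = Ex @ w
            c = Ey.T @ t / (t @ t)
            nc = np.linalg.norm(c)
            u = Ey @ c / (nc * nc) if nc > 0 else t
            if np.linalg.norm(t - t_old) < tol * max(1.0, np.linalg.norm(t)):
                break
            t_old = t
        else:
            raise RuntimeError(
                f"NIPALS did not converge for component {m + 1} after {max_iter} iterations"
            )
        p_load = Ex.T @ t / (t @ t)
        Ex = Ex - np.outer(t, p_load)
        if mode == "regression":
            Ey = Ey - np.outer(t, c)
        else:
            y_score = Ey @ c
            denom = y_score @ y_score
            if denom > 0:
                Ey = Ey - np.outer(y_score, Ey.T @ y_score / denom)
        T[:, m] = t
        W[x_keep, m] = w
        P[x_keep, m] = p_load
        C[y_keep, m] = c
        covs[m] = abs(t @ (Yw @ c)) / n

    x_res = np.zeros((n, p_all))
    y_res = np.zeros((n, q_all))
    x_res[:, x_keep] = Ex
    y_res[:, y_keep] = Ey
    return PLSModel(
        n_components=n_components,
        x_scores=T, x_weights=W, x_loadings=P, y_weights=C,
        x_mean=x_mean, y_mean=y_mean,
        x_residual=x_res, y_residual=y_res,
        component_covariances=covs, mode=mode,
    )


def cumulative_r2(model: PLSModel, Y, m: int) -> float:
    """Fraction of centered-Y variance explained by the first m X-scores.

    R^2(m) = 1 - ||Y_c - sum_{k<=m} t_k c_k'||_F^2 / ||Y_c||_F^2, which is
    non-decreasing in m for regression-mode deflation.
    """
    if not 1 <= m <= model.n_components:
        raise ValueError(f"m must be in [1, {model.n_components}]")
    Yc = np.asarray(Y, dtype=float) - model.y_mean
    approx = model.x_scores[:, :m] @ model.y_weights[:, :m].T
    denom = float(np.sum(Yc**2))
    if denom == 0:
        return np.nan
    return float(1.0 - np.sum((Yc - approx) ** 2) / denom)


def correlation_circle(model: PLSModel, X, Y) -> pd.DataFrame:
    """Per-variable correlations with the first two PLS components.

    Returns a frame with columns (variable, block, c1, c2); constant
    variables get coordinates (0, 0) and ``flagged=True``.
    """
    if model.n_components < 2:
        raise ValueError("correlation_circle requires at least 2 components")
    t1, t2 = model.x_scores[:, 0], model.x_scores[:, 1]

    rows = []
    for block, data in (("X", X), ("Y", Y)):
        arr = np.asarray(data, dtype=float)
        names = list(data.columns) if isinstance(data, pd.DataFrame) else [
            f"{block}{j}" for j in range(arr.shape[1])
        ]
        for j, name in enumerate(names):
            v = arr[:, j]
            if np.std(v) == 0:
                rows.append({"variable": name, "block": block, "c1": 0.0, "c2": 0.0, "flagged": True})
                continue
            rows.append(
                {
                    "variable": name, "block": block,
                    "c1": float(np.corrcoef(v, t1)[0, 1]),
                    "c2": float(np.corrcoef(v, t2)[0, 1]),
                    "flagged": False,
                }
            )
    return pd.DataFrame(rows)


def effector_target_shift(
    focal_arm,
    other_arms: pd.DataFrame,
    targets: pd.DataFrame,
) -> tuple[np.ndarray, np.ndarray, float, float]:
    """Correlation shift of a focal arm CNV against target expressions.

    Pearson correlations of the focal arm with each target are compared by
    one-sided KS against the pooled correlations of background arms with
    the same targets.  Returns (focal r's, background r's, D, p).
    """
    if targets.shape[0] < 5:
        raise ValueError("effector_target_shift requires >= 5 targets")
    if other_arms.shape[0] < 1:
        raise ValueError("effector_target_shift requires >= 1 background arm")
    focal = np.asarray(focal_arm, dtype=float)
    tz = targets.to_numpy(dtype=float)

    def _corr_with(v: np.ndarray) -> np.ndarray:
        vz = v - v.mean()
        tzc = tz - tz.mean(axis=1, keepdims=True)
        denom = np.linalg.norm(vz) * np.linalg.norm(tzc, axis=1)
        denom[denom == 0] = np.nan
        out = tzc @ vz / denom
        return out[np.isfinite(out)]

    focal_r = _corr_with(focal)
    background_r = np.concatenate(
        [_corr_with(other_arms.loc[a].to_numpy(dtype=float)) for a in other_arms.index]
    )
    d, p = ks_compare(focal_r, background_r, side="greater")
    return focal_r, background_r, d, p
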