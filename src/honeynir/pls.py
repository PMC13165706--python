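"""Single-response partial least squares (PLS1) with selection diagnostics.

The core is a transparent NIPALS implementation with X-block deflation
only; y-loadings are recomputed against the centred response per component
(equivalent to y-deflation because successive scores are orthogonal). With
as many components as the predictor rank the regression coefficients
coincide with ordinary least squares.

Diagnostics follow the standard literature definitions:

* VIP (variable importance in projection) for variable j:

      VIP_j = sqrt( p * sum_a SS_a * (w_ja / ||w_a||)^2 / sum_a SS_a )

  with SS_a the response variance explained by component a. The mean of
  the squared VIPs is identically 1, so VIP >= 1 marks above-average
  influence.

* Selectivity ratio via target projection: X is projected onto the
  normalised regression vector; SR_j is the ratio of explained to residual
  variance of column j under that rank-one approximation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

__all__ = ["PLSModel", "fit_pls", "vip", "selectivity_ratio", "rmsecv", "rmsecv_curve"]

log = logging.getLogger(__name__)


@dataclass
class PLSModel:
    """Fitted PLS1 model with per-component blocks.

    Attributes
    ----------
    n_lv : int
        Number of latent variables actually extracted (may be smaller than
        requested if the residual X-block ran out of rank).
    weights, loadings : (p, A) arrays
        NIPALS weights W and X-loadings P.
    y_loadings : (A,) array
        y-loadings q, computed against the centred response.
    scores : (n, A) array
        X-scores T (mutually orthogonal).
    rotations : (p, A) array
        R = W (P'W)^-1 so that T = Xc R and b_A = R[:, :A] q[:A].
    coefficients : (p,) array
        Regression vector for the full model: yhat = (x - x_mean) b + y_mean.
    explained_y_variance : (A,) array
        Response sum of squares captured per component (SS_a = q_a^2 t_a't_a).
    """

    n_lv: int
    weights: np.ndarray
    loadings: np.ndarray
    y_loadings: np.ndarray
    scores: np.ndarray
    rotations: np.ndarray
    coefficients: np.ndarray
    x_mean: np.ndarray
    y_mean: float
    explained_y_variance: np.ndarray

    def coefficients_for(self, n_lv: int) -> np.ndarray:
        """Regression vector of the truncated model with ``n_lv`` components."""
        if not 1 <= n_lv <= self.n_lv:
            raise ValueError(f"n_lv must be within 1..{self.n_lv}")
        return self.rotations[:, :n_lv] @ self.y_loadings[:n_lv]

    def predict(self, X: np.ndarray, n_lv: int | None = None) -> np.ndarray:
        b = self.coefficients if n_lv is None else self.coefficients_for(n_lv)
        return (np.asarray(X, dtype=float) - self.x_mean) @ b + self.y_mean


def fit_pls(
    X: np.ndarray,
    y: np.ndarray,
    n_lv: int,
    tol: float = 1e-10,
    max_iter: int = 500,
) -> PLSModel:
    """Fit PLS1 by NIPALS with X-deflation.

    Components whose residual covariance with y vanishes (below ``tol``)
    terminate extraction early; the model then carries fewer components
    than requested. Requesting the full rank of a tall full-column-rank X
    reproduces the OLS solution.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if n < 2:
        raise ValueError("need at least 2 samples")
    if y.size != n:
        raise ValueError("y length must match X rows")
    if not (np.isfinite(X).all() and np.isfinite(y).all()):
        raise ValueError("X and y must be finite")
    max_lv = min(n - 1, p)
    if not 1 <= n_lv <= max_lv:
        raise ValueError(f"n_lv must be within 1..{max_lv} (= min(n-1, p)), got {n_lv}")
    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    yc = y - y_mean
    if np.allclose(yc, 0):
        raise ValueError("y has zero variance")

    Xd = X - x_mean
    W = np.zeros((p, n_lv))
    P = np.zeros((p, n_lv))
    T = np.zeros((n, n_lv))
    q = np.zeros(n_lv)
    A = 0
    for a in range(n_lv):
        cov = Xd.T @ yc
        if np.linalg.norm(cov) < tol:
            break
        # NIPALS inner iteration on the weight vector. With a single
        # response the y-block score is the (centred) response itself, so
        # the fixed point is reached after one pass; the loop is kept so
        # the tolerance contract is explicit.
        w = cov / np.linalg.norm(cov)
        for _ in range(max_iter):
            w_new = Xd.T @ yc
            w_new = w_new / np.linalg.norm(w_new)
            if np.linalg.norm(w_new - w) < tol:
                w = w_new
                break
            w = w_new
        t = Xd @ w
        tt = t @ t
        if tt < tol:
            break
        p_a = Xd.T @ t / tt
        q[a] = (yc @ t) / tt
        W[:, a], P[:, a], T[:, a] = w, p_a, t
        Xd = Xd - np.outer(t, p_a)
        A += 1
    if A == 0:
        raise ValueError("no PLS component could be extracted (X'y ~ 0)")
    W, P, T, q = W[:, :A], P[:, :A], T[:, :A], q[:A]
    R = W @ np.linalg.inv(P.T @ W)
    coef = R @ q
    ss = q**2 * np.einsum("ij,ij->j", T, T)
    return PLSModel(
        n_lv=A, weights=W, loadings=P, y_loadings=q, scores=T, rotations=R,
        coefficients=coef, x_mean=x_mean, y_mean=y_mean, explained_y_variance=ss,
    )


def vip(model: PLSModel) -> np.ndarray:
    """Variable importance in projection; mean of squared VIPs is 1."""
    ss = model.explained_y_variance
    total = ss.sum()
    if total <= 0:
        raise ValueError("model explains no response variance; VIP undefined")
    p = model.weights.shape[0]
    wnorm2 = model.weights**2  # columns already unit length
    return np.sqrt(p * (wnorm2 @ ss) / total)


def selectivity_ratio(model: PLSModel, X: np.ndarray) -> np.ndarray:
    """Selectivity ratio of each predictor under target projection.

    SR_j = explained / residual variance of column j after projecting the
    centred X onto the normalised regression vector. Columns with zero
    residual variance (perfectly explained) are set to the largest finite
    SR observed, with a log record.
    """
    X = np.asarray(X, dtype=float)
    Xc = X - model.x_mean
    b = model.coefficients
    nb = np.linalg.norm(b)
    if nb == 0:
        raise ValueError("zero regression vector; SR undefined")
    t_tp = Xc @ (b / nb)
    tt = t_tp @ t_tp
    if tt == 0:
        raise ValueError("degenerate target projection (zero scores)")
    p_tp = Xc.T @ t_tp / tt
    explained = tt * p_tp**2  # ||t p_j||^2 per column
    residual = np.einsum("ij,ij->j", Xc, Xc) - explained
    residual = np.maximum(residual, 0.0)
    sr = np.empty_like(explained)
    zero = residual <= 1e-12 * np.maximum(explained, 1.0)
    sr[~zero] = explained[~zero] / residual[~zero]
    if zero.any():
        finite_max = sr[~zero].max() if (~zero).any() else 1.0
        sr[zero] = finite_max
        log.info("selectivity_ratio: %d column(s) with zero residual variance "
                 "set to max finite SR", int(zero.sum()))
    return sr


def rmsecv_curve(X, y, folds, max_n_lv: int) -> np.ndarray:
    """RMSECV for every component count 1..max_n_lv (pooled residuals).

    ``folds`` is a FoldAssignment-like object with ``fold_of_row`` and ``k``
    attributes, or an integer vector of fold labels.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    fold_of_row = np.asarray(getattr(folds, "fold_of_row", folds))
    labels = np.unique(fold_of_row)
    n = y.size
    cap = min(max_n_lv, X.shape[1])
    preds = np.full((cap, n), np.nan)
    for lab in labels:
        test = fold_of_row == lab
        train = ~test
        if test.sum() < 1 or train.sum() < 2:
            raise ValueError("each fold must leave >= 1 test and >= 2 train rows")
        a_max = min(cap, train.sum() - 1)
        model = fit_pls(X[train], y[train], a_max)
        for a in range(1, a_max + 1):
            preds[a - 1, test] = model.predict(X[test], n_lv=min(a, model.n_lv))
        for a in range(a_max + 1, cap + 1):
            preds[a - 1, test] = model.predict(X[test])
    resid = preds - y[None, :]
    return np.sqrt(np.nanmean(resid**2, axis=1))


def rmsecv(X, y, n_lv: int, folds) -> float:
    """Root mean square error of cross-validation, pooling all held-out
    residuals before averaging."""
    return float(rmsecv_curve(X, y, folds, n_lv)[-1])
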