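"""Partial least squares regression (NIPALS PLS2) and VIP marker screening.

The fingerprint-toxicity relationship is modelled by regressing serum enzyme
responses (Y, e.g. per-sample mean ALT and AST) on common-peak areas (X).
Both blocks are autoscaled (mean-centred, unit variance).  Variable
importance for the projection,

    VIP_j = sqrt( p * sum_a SSY_a w_aj^2 / sum_a SSY_a ),

with unit-norm weight vectors w_a and SSY_a the Y sum of squares explained
by component a, satisfies sum_j VIP_j^2 = p; variables with VIP above 1.0
are conventionally retained.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "PLSModel",
    "VIPResult",
    "fit_pls",
    "predict",
    "vip",
    "screen_by_vip",
    "adjusted_r_squared",
]


@dataclass
class PLSModel:
    n_components: int
    weights: np.ndarray  # W, p x A, unit-norm columns
    x_loadings: np.ndarray  # P, p x A
    y_loadings: np.ndarray  # C, m x A
    x_scores: np.ndarray  # T, n x A
    x_mean: np.ndarray
    x_scale: np.ndarray
    y_mean: np.ndarray
    y_scale: np.ndarray
    ssy: np.ndarray  # per-component explained Y sum of squares (scaled block)
    r_squared: float
    n_samples: int

    @property
    def coef(self) -> np.ndarray:
        """Regression coefficients B (p x m) on the autoscaled blocks."""
        W, P, C = self.weights, self.x_loadings, self.y_loadings
        return W @ np.linalg.solve(P.T @ W, C.T)


def _autoscale(M: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mean = M.mean(axis=0)
    scale = M.std(axis=0, ddof=1)
    if np.any(scale == 0):
        bad = [int(i) for i in np.flatnonzero(scale == 0)]
        raise ValueError(f"constant column(s) {bad}: cannot autoscale")
    return (M - mean) / scale, mean, scale


def _nipals(
    Xs: np.ndarray, Ys: np.ndarray, A: int, tol: float = 1e-10, max_iter: int = 500
):
    n, p = Xs.shape
    m = Ys.shape[1]
    X, Y = Xs.copy(), Ys.copy()
    W = np.zeros((p, A))
    P = np.zeros((p, A))
    C = np.zeros((m, A))
    T = np.zeros((n, A))
    ssy = np.zeros(A)
    for a in range(A):
        u = Y[:, 0].copy()
        w = np.zeros(p)
        for _ in range(max_iter):
            w_new = X.T @ u
            nrm = np.linalg.norm(w_new)
            if nrm == 0:
                raise ValueError("degenerate component: X'u vanished")
            w_new /= nrm
            t = X @ w_new
            c = Y.T @ t / (t @ t)
            u = Y @ c / (c @ c)
            if np.linalg.norm(w_new - w) < tol:
                w = w_new
                break
            w = w_new
        t = X @ w
        tt = t @ t
        c = Y.T @ t / tt
        p_load = X.T @ t / tt
        X = X - np.outer(t, p_load)
        Y = Y - np.outer(t, c)
        W[:, a], P[:, a], C[:, a], T[:, a] = w, p_load, c, t
        ssy[a] = tt * (c @ c)
    return W, P, C, T, ssy


def fit_pls(
    X: np.ndarray,
    Y: np.ndarray,
    n_components: "int | None" = None,
    max_components: int = 5,
) -> PLSModel:
    """Fit a PLS2 model on autoscaled X (n x p) and Y (n x m).

    When ``n_components`` is None the number of components is chosen by
    leave-one-out cross-validation (maximum Q^2), capped at
    ``min(n - 1, p, max_components)``.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(Y))):
        raise ValueError("X and Y must be finite")
    n, p = X.shape
    if n < 3:
        raise ValueError("need at least 3 samples")
    cap = min(n - 1, p)
    if n_components is None:
        A = _choose_components(X, Y, min(cap, max_components))
    else:
        A = int(n_components)
        if A < 1 or A > cap:
            raise ValueError(f"n_components must be in [1, {cap}]")

    Xs, x_mean, x_scale = _autoscale(X)
    Ys, y_mean, y_scale = _autoscale(Y)
    W, P, C, T, ssy = _nipals(Xs, Ys, A)
    B = W @ np.linalg.solve(P.T @ W, C.T)
    resid = Ys - Xs @ B
    r2 = 1.0 - float((resid**2).sum() / (Ys**2).sum())
    return PLSModel(
        n_components=A,
        weights=W,
        x_loadings=P,
        y_loadings=C,
        x_scores=T,
        x_mean=x_mean,
        x_scale=x_scale,
        y_mean=y_mean,
        y_scale=y_scale,
        ssy=ssy,
        r_squared=r2,
        n_samples=n,
    )


def _choose_components(X: np.ndarray, Y: np.ndarray, a_max: int) -> int:
    """Leave-one-out Q^2 model-order selection."""
    n = X.shape[0]
    press = np.zeros(a_max)
    ss_tot = 0.0
    for i in range(n):
        mask = np.arange(n) != i
        Xtr, Ytr = X[mask], Y[mask]
        try:
            Xs, xm, xs = _autoscale(Xtr)
            Ys, ym, ys = _autoscale(Ytr)
        except ValueError:
            continue
        W, P, C, T, _ = _nipals(Xs, Ys, min(a_max, Xtr.shape[0] - 1))
        xi = (X[i] - xm) / xs
        yi = (Y[i] - ym) / ys
        ss_tot += float(yi @ yi)
        for a in range(1, min(a_max, W.shape[1]) + 1):
            Ba = W[:, :a] @ np.linalg.solve(P[:, :a].T @ W[:, :a], C[:, :a].T)
            press[a - 1] += float(((yi - xi @ Ba) ** 2).sum())
    q2 = 1.0 - press / ss_tot
    return int(np.argmax(q2)) + 1


def predict(model: PLSModel, X: np.ndarray) -> np.ndarray:
    """Predict responses in original Y units."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Xs = (X - model.x_mean) / model.x_scale
    return Xs @ model.coef * model.y_scale + model.y_mean


@dataclass
class VIPResult:
    vip: np.ndarray
    peak_ids: list[int]
    threshold: float
    selected: list[int]
    r_squared: float
    adjusted_r_squared: "float | None"


def vip(
    model: PLSModel,
    peak_ids: "Sequence[int] | None" = None,
    threshold: float = 1.0,
) -> VIPResult:
    """VIP scores of a fitted PLS model and the VIP > threshold selection."""
    W, ssy = model.weights, model.ssy
    p = W.shape[0]
    if ssy.sum() <= 0:
        raise ValueError("model explains no Y variance; VIP undefined")
    v = np.sqrt(p * (W**2 @ ssy) / ssy.sum())
    ids = list(peak_ids) if peak_ids is not None else list(range(1, p + 1))
    selected = screen_by_vip_values(v, ids, threshold)
    n, preds = model.n_samples, p
    adj = (
        adjusted_r_squared(model.r_squared, n, preds) if n > preds + 1 else None
    )
    return VIPResult(
        vip=v,
        peak_ids=ids,
        threshold=threshold,
        selected=selected,
        r_squared=model.r_squared,
        adjusted_r_squared=adj,
    )


def screen_by_vip_values(
    vip_values: np.ndarray, peak_ids: Sequence[int], threshold: float = 1.0
) -> list[int]:
    """Peak ids with VIP strictly above threshold, sorted by VIP descending."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    vip_values = np.asarray(vip_values, dtype=float)
    order = np.argsort(-vip_values, kind="stable")
    return [peak_ids[i] for i in order if vip_values[i] > threshold]


def screen_by_vip(v: VIPResult, threshold: "float | None" = None) -> list[int]:
    """Apply the VIP > threshold rule to a VIPResult."""
    thr = v.threshold if threshold is None else threshold
    return screen_by_vip_values(v.vip, v.peak_ids, thr)


def adjusted_r_squared(r2: float, n: int, p: int) -> float:
    """Adjusted R^2 = 1 - (1 - R^2)(n - 1)/(n - p - 1)."""
    if n <= p + 1:
        raise ValueError("adjusted R^2 requires n > p + 1")
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)
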