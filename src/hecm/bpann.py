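"""Back-propagation neural network and mean-impact-value (MIV) screening.

A classic three-layer feed-forward network (p inputs, a small sigmoid hidden
layer — three units by default — and a linear output layer) is trained by
full-batch gradient descent on squared error; inputs and outputs are min-max
scaled to [0, 1] internally.  Variable influence is measured by the mean
impact value: each input column is perturbed to (1 +/- delta) times its
value, and

    IV_j = sum over samples and outputs of (prediction+ - prediction-),
    MIV_j = IV_j / n,

with n the number of observations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = ["ANNModel", "MIVResult", "train_bpann", "predict", "miv", "rank_variables"]


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-z))


_ACTIVATIONS = {
    "sigmoid": (_sigmoid, lambda h: h * (1.0 - h)),
    "tanh": (np.tanh, lambda h: 1.0 - h**2),
    "linear": (lambda z: z, lambda h: np.ones_like(h)),
}


@dataclass
class ANNModel:
    """Weights, scaling parameters and training diagnostics of a BP-ANN."""

    w1: np.ndarray  # p x h
    b1: np.ndarray  # h
    w2: np.ndarray  # h x m
    b2: np.ndarray  # m
    activation: str
    x_min: np.ndarray
    x_range: np.ndarray
    y_min: np.ndarray
    y_range: np.ndarray
    mse_trace: np.ndarray = field(repr=False, default=None)
    grad_trace: np.ndarray = field(repr=False, default=None)

    @property
    def n_inputs(self) -> int:
        return self.w1.shape[0]


def _minmax_fit(M: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    lo = M.min(axis=0)
    rng = M.max(axis=0) - lo
    rng[rng == 0] = 1.0  # constant column maps to 0
    return lo, rng


def _forward(w1, b1, w2, b2, act, Xs):
    H = act(Xs @ w1 + b1)
    return H, H @ w2 + b2


def _loss_and_grads(w1, b1, w2, b2, activation: str, Xs, Ys):
    """MSE over samples and outputs, with analytic gradients (full batch)."""
    act, dact = _ACTIVATIONS[activation]
    n = Xs.shape[0]
    H, out = _forward(w1, b1, w2, b2, act, Xs)
    err = out - Ys
    mse = float((err**2).mean())
    scale = 2.0 / err.size
    g_out = err * scale
    gw2 = H.T @ g_out
    gb2 = g_out.sum(axis=0)
    g_h = (g_out @ w2.T) * dact(H)
    gw1 = Xs.T @ g_h
    gb1 = g_h.sum(axis=0)
    return mse, (gw1, gb1, gw2, gb2)


def train_bpann(
    X: np.ndarray,
    Y: np.ndarray,
    hidden: int = 3,
    epochs: int = 5000,
    lr: float = 0.05,
    momentum: float = 0.0,
    activation: str = "sigmoid",
    seed: int = 0,
) -> ANNModel:
    """Train a p-hidden-m network by full-batch gradient descent.

    Deterministic for a fixed ``seed`` (weights start uniform in
    [-0.5, 0.5]).  Per-epoch MSE and gradient norm are recorded as training
    diagnostics.  A non-finite loss aborts with the offending epoch.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(Y))):
        raise ValueError("X and Y must be finite")
    n, p = X.shape
    m = Y.shape[1]
    if n < 4:
        raise ValueError("need at least 4 samples")
    if epochs < 1:
        raise ValueError("epochs must be >= 1")
    if activation not in _ACTIVATIONS:
        raise ValueError(f"unknown activation {activation!r}")

    x_min, x_range = _minmax_fit(X)
    y_min, y_range = _minmax_fit(Y)
    Xs = (X - x_min) / x_range
    Ys = (Y - y_min) / y_range

    rng = np.random.default_rng(seed)
    w1 = rng.uniform(-0.5, 0.5, size=(p, hidden))
    b1 = rng.uniform(-0.5, 0.5, size=hidden)
    w2 = rng.uniform(-0.5, 0.5, size=(hidden, m))
    b2 = rng.uniform(-0.5, 0.5, size=m)
    v = [np.zeros_like(w1), np.zeros_like(b1), np.zeros_like(w2), np.zeros_like(b2)]

    mse_trace = np.empty(epochs)
    grad_trace = np.empty(epochs)
    params = [w1, b1, w2, b2]
    for epoch in range(epochs):
        mse, grads = _loss_and_grads(*params, activation, Xs, Ys)
        if not np.isfinite(mse):
            raise RuntimeError(f"training diverged: non-finite loss at epoch {epoch}")
        mse_trace[epoch] = mse
        grad_trace[epoch] = float(
            np.sqrt(sum(float((g**2).sum()) for g in grads))
        )
        for k in range(4):
            v[k] = momentum * v[k] - lr * grads[k]
            params[k] = params[k] + v[k]
    w1, b1, w2, b2 = params

    return ANNModel(
        w1=w1,
        b1=b1,
        w2=w2,
        b2=b2,
        activation=activation,
        x_min=x_min,
        x_range=x_range,
        y_min=y_min,
        y_range=y_range,
        mse_trace=mse_trace,
        grad_trace=grad_trace,
    )


def predict(model: ANNModel, X: np.ndarray, scaled: bool = False) -> np.ndarray:
    """Network output for raw-unit inputs; original Y units unless ``scaled``."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Xs = (X - model.x_min) / model.x_range
    act = _ACTIVATIONS[model.activation][0]
    _, out = _forward(model.w1, model.b1, model.w2, model.b2, act, Xs)
    if scaled:
        return out
    return out * model.y_range + model.y_min


@dataclass
class MIVResult:
    iv: np.ndarray
    miv: np.ndarray
    n: int
    peak_ids: list[int]
    ranking_signed: list[int]  # by signed MIV, descending
    ranking_abs: list[int]  # by |MIV|, descending


def miv(
    model: ANNModel,
    X: np.ndarray,
    delta: float = 0.10,
    peak_ids: "Sequence[int] | None" = None,
    scaled_space: bool = True,
) -> MIVResult:
    """Mean impact value of each input variable at a +/- ``delta`` perturbation.

    By default the perturbation is applied to the network's min-max-scaled
    training inputs and predictions are compared in the scaled output space,
    so variables and endpoints with different units contribute comparably
    (the classical MIV construction).  ``scaled_space=False`` perturbs and
    compares in raw units instead.
    """
    if not 0 < delta < 1:
        raise ValueError("delta must be in (0, 1)")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, p = X.shape
    ids = list(peak_ids) if peak_ids is not None else list(range(1, p + 1))
    act = _ACTIVATIONS[model.activation][0]
    Xs = (X - model.x_min) / model.x_range if scaled_space else X
    iv = np.zeros(p)
    for j in range(p):
        x_up, x_dn = Xs.copy(), Xs.copy()
        x_up[:, j] *= 1.0 + delta
        x_dn[:, j] *= 1.0 - delta
        if scaled_space:
            _, o_up = _forward(model.w1, model.b1, model.w2, model.b2, act, x_up)
            _, o_dn = _forward(model.w1, model.b1, model.w2, model.b2, act, x_dn)
            diff = o_up - o_dn
        else:
            diff = predict(model, x_up) - predict(model, x_dn)
        iv[j] = float(diff.sum())
    mv = iv / n
    order_signed = sorted(range(p), key=lambda j: (-mv[j], ids[j]))
    order_abs = sorted(range(p), key=lambda j: (-abs(mv[j]), ids[j]))
    return MIVResult(
        iv=iv,
        miv=mv,
        n=n,
        peak_ids=ids,
        ranking_signed=[ids[j] for j in order_signed],
        ranking_abs=[ids[j] for j in order_abs],
    )


def rank_variables(r: MIVResult, top_k: int, by: str = "signed") -> list[int]:
    """Top-k peak ids by MIV, descending; ties break toward the lower peak id.

    ``by="signed"`` ranks on the signed MIV (largest positive impacts first,
    matching how positive toxicity drivers are screened); ``by="abs"`` ranks
    on |MIV|.
    """
    if top_k > len(r.peak_ids):
        raise ValueError("top_k exceeds the number of variables")
    if by == "signed":
        return r.ranking_signed[:top_k]
    if by == "abs":
        return r.ranking_abs[:top_k]
    raise ValueError("by must be 'signed' or 'abs'")
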