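"""Univariate partial least squares regression (PLS1) via NIPALS.

The model regresses a single response y (here: dose) on a wide predictor
matrix X (here: difference-spectrum intensities) through k latent
variables. With a univariate response each NIPALS component is closed
form — no inner iteration is needed — and the algorithm is fully
deterministic:

    center X and y; then per component
        w  = X'y / ||X'y||          (weight, unit norm)
        t  = X w                    (score — the latent variable)
        p  = X't / (t't)            (X loading)
        q  = y't / (t't)            (y loading / regression coefficient)
        X <- X - t p' ;  y <- y - q t   (deflation)

    b  = W (P'W)^{-1} q             (regression vector on centred X)

P'W is unit upper triangular in exact arithmetic, so b is obtained by a
triangular back-substitution; a conditioning guard rejects systems whose
condition number exceeds 1e10. Predictions are (X_new - x_mean) b +
y_mean, identical to the reconstruction through T q on training data.

X columns are centred but not variance-scaled by default: the predictors
are 0–1-normalized absorbances on a common scale, and autoscaling would
distort band-height information. Pass ``scale=True`` for the autoscaled
variant.

At k = rank(X) the training predictions coincide with ordinary least
squares; with fewer components PLS shrinks along directions of low
covariance with y, which is what makes it usable at p >> n.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import solve_triangular

from .errors import ConditioningError, DegeneracyError, ParameterError, ShapeError

_COND_LIMIT = 1e10


@dataclass
class PLSModel:
    """A fitted PLS1 model.

    W (p × k) weights with unit-norm columns; T (n × k) training scores
    (the latent variables, mutually orthogonal); P (p × k) X-loadings;
    q (k,) y-loadings — the regression coefficients for T; b (p,) the
    collapsed regression vector on centred predictors.
    """

    x_mean: np.ndarray
    y_mean: float
    W: np.ndarray
    T: np.ndarray
    P: np.ndarray
    q: np.ndarray
    b: np.ndarray
    n_lv: int
    ss_x: float  # total centred X sum of squares (diagnostics)
    ss_y: float  # total centred y sum of squares


def _regression_vector(W: np.ndarray, P: np.ndarray, q: np.ndarray) -> np.ndarray:
    k = q.size
    PtW = P.T @ W
    if np.linalg.cond(PtW) > _COND_LIMIT:
        raise ConditioningError("P'W is too ill-conditioned; reduce n_lv")
    # unit upper triangular in exact arithmetic
    gamma = solve_triangular(PtW, q, lower=False)
    return W[:, :k] @ gamma


def fit_pls(X: np.ndarray, y: np.ndarray, n_lv: int, scale: bool = False) -> PLSModel:
    """Fit a PLS1 model with ``n_lv`` latent variables.

    Requires 1 <= n_lv <= min(n - 1, p), n >= 2, and non-constant y.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.ndim != 2:
        raise ShapeError("X must be a 2-D matrix")
    n, p = X.shape
    if y.size != n:
        raise ShapeError(f"y length {y.size} != X rows {n}")
    if n < 2:
        raise ParameterError("need at least two samples")
    if not 1 <= n_lv <= min(n - 1, p):
        raise ParameterError(
            f"n_lv must lie in [1, {min(n - 1, p)}] for X of shape {X.shape}, got {n_lv}"
        )
    y_mean = float(y.mean())
    yc = y - y_mean
    if np.allclose(yc, 0.0):
        raise DegeneracyError("y has zero variance")
    x_mean = X.mean(axis=0)
    Xc = X - x_mean
    if scale:
        x_sd = Xc.std(axis=0, ddof=1)
        x_sd[x_sd == 0] = 1.0
        Xc = Xc / x_sd
    ss_x = float(np.sum(Xc * Xc))
    ss_y = float(yc @ yc)

    W = np.empty((p, n_lv))
    T = np.empty((n, n_lv))
    P = np.empty((p, n_lv))
    q = np.empty(n_lv)
    Xd, yd = Xc.copy(), yc.copy()
    for k in range(n_lv):
        w = Xd.T @ yd
        norm = np.linalg.norm(w)
        if norm == 0 or not np.isfinite(norm):
            raise DegeneracyError(
                f"X'y vanished at component {k + 1}; X carries no further covariance with y"
            )
        w /= norm
        t = Xd @ w
        tt = float(t @ t)
        if tt == 0:
            raise DegeneracyError(f"zero-variance score at component {k + 1}")
        pk = Xd.T @ t / tt
        qk = float(yd @ t) / tt
        Xd -= np.outer(t, pk)
        yd -= qk * t
        W[:, k], T[:, k], P[:, k], q[k] = w, t, pk, qk

    b = _regression_vector(W, P, q)
    if scale:
        b = b / x_sd
        # fold scaling into the regression vector so predict() stays (X - mean) b
    return PLSModel(x_mean=x_mean, y_mean=y_mean, W=W, T=T, P=P, q=q, b=b,
                    n_lv=n_lv, ss_x=ss_x, ss_y=ss_y)


def predict(model: PLSModel, X_new: np.ndarray) -> np.ndarray:
    """Predicted response: (X_new - x_mean) b + y_mean."""
    X_new = np.asarray(X_new, dtype=float)
    if X_new.ndim == 1:
        X_new = X_new[None, :]
    if X_new.shape[1] != model.x_mean.size:
        raise ShapeError(
            f"X_new has {X_new.shape[1]} columns, model expects {model.x_mean.size}"
        )
    return (X_new - model.x_mean) @ model.b + model.y_mean


def predict_components(model: PLSModel, X_new: np.ndarray) -> np.ndarray:
    """Predictions using 1..k leading components; shape (m, n_lv).

    Column j-1 is the prediction of the model truncated to j latent
    variables — the quantity cross-validated when choosing k.
    """
    X_new = np.asarray(X_new, dtype=float)
    if X_new.ndim == 1:
        X_new = X_new[None, :]
    if X_new.shape[1] != model.x_mean.size:
        raise ShapeError("X_new column count does not match the model")
    Xc = X_new - model.x_mean
    out = np.empty((X_new.shape[0], model.n_lv))
    for j in range(1, model.n_lv + 1):
        bj = _regression_vector(model.W[:, :j], model.P[:, :j], model.q[:j])
        out[:, j - 1] = Xc @ bj + model.y_mean
    return out


def explained_variance(model: PLSModel) -> dict:
    """Per-component fractions of X and y variance captured.

    Returns arrays ``x_frac`` and ``y_frac`` (each in [0, 1], summing to
    at most 1) plus their cumulative sums; cumulative y fractions are
    non-decreasing by construction of the deflation.
    """
    tt = np.sum(model.T * model.T, axis=0)
    x_frac = tt * np.sum(model.P * model.P, axis=0) / model.ss_x
    y_frac = model.q ** 2 * tt / model.ss_y
    return {
        "x_frac": x_frac,
        "y_frac": y_frac,
        "x_cumulative": np.cumsum(x_frac),
        "y_cumulative": np.cumsum(y_frac),
    }


# ---------------------------------------------------------------------------
# Plain-text model serialization (train/predict CLI round trips)


def save_model(model: PLSModel, path) -> None:
    import json

    payload = {
        "x_mean": model.x_mean.tolist(),
        "y_mean": model.y_mean,
        "W": model.W.tolist(),
        "T": model.T.tolist(),
        "P": model.P.tolist(),
        "q": model.q.tolist(),
        "b": model.b.tolist(),
        "n_lv": model.n_lv,
        "ss_x": model.ss_x,
        "ss_y": model.ss_y,
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh)


def load_model(path) -> PLSModel:
    import json

    with open(path, encoding="utf-8") as fh:
        payload = json.load(fh)
    return PLSModel(
        x_mean=np.array(payload["x_mean"]),
        y_mean=float(payload["y_mean"]),
        W=np.array(payload["W"]),
        T=np.array(payload["T"]),
        P=np.array(payload["P"]),
        q=np.array(payload["q"]),
        b=np.array(payload["b"]),
        n_lv=int(payload["n_lv"]),
        ss_x=float(payload["ss_x"]),
        ss_y=float(payload["ss_y"]),
    )
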