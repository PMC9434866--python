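"""Partial least squares regression (PLS1) with leave-one-out CV.

The engine is orthogonal-scores NIPALS for a single response. With one
response the algorithm is non-iterative: each component's weight vector is
the (normalized) covariance direction ``w = Xᵀy`` of the current deflated
data, scores are ``t = Xw``, loadings ``p = Xᵀt/tᵀt``, ``q = yᵀt/tᵀt``, and
both X and y are deflated before the next component. The regression vector
in centered predictor space is the standard identity ``b = W(PᵀW)⁻¹q``.

Predictors are centered but not autoscaled (SNV preprocessing already puts
spectra on a common scale); autoscaling is available via ``scale=True``.

:func:`loocv_curve` computes the full RMSECV-vs-components curve with one
NIPALS decomposition per left-out sample — the per-component regression
vectors of a single fit give the predictions for every candidate component
count at once, so the curve is exactly what a brute-force loop of
independent refits would produce.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

from nircarb.errors import (
    DegenerateResponseError,
    DomainError,
    ZeroVarianceError,
)

_EPS = np.finfo(float).eps


@dataclass
class PLSModel:
    """Fitted PLS1 decomposition plus everything needed to predict."""

    x_mean: np.ndarray
    y_mean: float
    x_scale: np.ndarray  # all-ones unless scale=True at fit time
    weights: np.ndarray  # W, (p, A)
    x_loadings: np.ndarray  # P, (p, A)
    y_loadings: np.ndarray  # q, (A,)
    scores: np.ndarray  # T, (n, A)
    b: np.ndarray  # regression vector in centered (scaled) space
    intercept: float
    ncomp: int
    variable_indices: np.ndarray | None = None

    def to_dict(self) -> dict:
        d = {
            "x_mean": self.x_mean.tolist(),
            "y_mean": self.y_mean,
            "x_scale": self.x_scale.tolist(),
            "weights": self.weights.tolist(),
            "x_loadings": self.x_loadings.tolist(),
            "y_loadings": self.y_loadings.tolist(),
            "scores": self.scores.tolist(),
            "b": self.b.tolist(),
            "intercept": self.intercept,
            "ncomp": self.ncomp,
            "variable_indices": None
            if self.variable_indices is None
            else np.asarray(self.variable_indices).tolist(),
        }
        return d

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def from_dict(cls, d: dict) -> "PLSModel":
        return cls(
            x_mean=np.asarray(d["x_mean"], dtype=float),
            y_mean=float(d["y_mean"]),
            x_scale=np.asarray(d["x_scale"], dtype=float),
            weights=np.asarray(d["weights"], dtype=float),
            x_loadings=np.asarray(d["x_loadings"], dtype=float),
            y_loadings=np.asarray(d["y_loadings"], dtype=float),
            scores=np.asarray(d["scores"], dtype=float),
            b=np.asarray(d["b"], dtype=float),
            intercept=float(d["intercept"]),
            ncomp=int(d["ncomp"]),
            variable_indices=None
            if d.get("variable_indices") is None
            else np.asarray(d["variable_indices"], dtype=int),
        )

    @classmethod
    def from_json(cls, path) -> "PLSModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass
class CVCurve:
    """Leave-one-out CV statistics per candidate component count."""

    press: np.ndarray
    rmsecv: np.ndarray
    r2_cv: np.ndarray
    n_samples: int
    max_components: int

    def __post_init__(self) -> None:
        if not (len(self.press) == len(self.rmsecv) == len(self.r2_cv)):
            raise DomainError("CVCurve arrays must have equal lengths")


def _nipals_pls1(
    Xc: np.ndarray, yc: np.ndarray, ncomp: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """NIPALS decomposition of centered data; may stop early on rank loss.

    Returns (W, P, q, T) trimmed to the number of components extracted.
    """
    n, p = Xc.shape
    Xr = Xc.copy()
    yr = yc.astype(float).copy()
    W = np.zeros((p, ncomp))
    P = np.zeros((p, ncomp))
    q = np.zeros(ncomp)
    T = np.zeros((n, ncomp))
    x_norm = np.linalg.norm(Xc) + _EPS
    y_norm = np.linalg.norm(yc) + _EPS
    a_eff = 0
    for a in range(ncomp):
        w = Xr.T @ yr
        nw = np.linalg.norm(w)
        if nw <= 1e-12 * x_norm * y_norm:
            break
        w /= nw
        t = Xr @ w
        tt = t @ t
        if tt <= (1e-12 * x_norm) ** 2:
            break
        p_a = Xr.T @ t / tt
        q_a = (yr @ t) / tt
        Xr -= np.outer(t, p_a)
        yr -= q_a * t
        W[:, a] = w
        P[:, a] = p_a
        q[a] = q_a
        T[:, a] = t
        a_eff += 1
    return W[:, :a_eff], P[:, :a_eff], q[:a_eff], T[:, :a_eff]


def _regression_vectors(W: np.ndarray, P: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Regression vectors for every truncation a=1..A, shape (p, A).

    ``b_a = W_a (P_aᵀ W_a)⁻¹ q_a``; for PLS1 the matrix ``PᵀW`` is upper
    triangular with unit diagonal, so the per-a solves are cheap.
    """
    A = W.shape[1]
    if A == 0:
        return np.zeros((W.shape[0], 0))
    PtW = P.T @ W
    B = np.empty((W.shape[0], A))
    for a in range(1, A + 1):
        coef = np.linalg.solve(PtW[:a, :a], q[:a])
        B[:, a - 1] = W[:, :a] @ coef
    return B


def _center(
    X: np.ndarray, y: np.ndarray, scale: bool
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float, np.ndarray]:
    x_mean = X.mean(axis=0)
    y_mean = float(np.mean(y))
    if scale:
        x_scale = X.std(axis=0, ddof=1)
        x_scale[x_scale == 0] = 1.0
    else:
        x_scale = np.ones(X.shape[1])
    Xc = (X - x_mean) / x_scale
    yc = np.asarray(y, dtype=float) - y_mean
    return Xc, yc, x_mean, y_mean, x_scale


def _cap_ncomp(ncomp: int, n: int, p: int) -> int:
    bound = min(n - 1, p)
    if ncomp > bound:
        warnings.warn(
            f"ncomp={ncomp} exceeds the rank bound min(n-1, p)={bound}; capped",
            stacklevel=3,
        )
        return bound
    return ncomp


def fit_pls(
    X: np.ndarray,
    y: np.ndarray,
    ncomp: int,
    scale: bool = False,
    variable_indices: np.ndarray | None = None,
) -> PLSModel:
    """Fit a PLS1 model with ``ncomp`` latent components.

    ``variable_indices`` is bookkeeping only (which original channels the
    columns of X correspond to); pass the already-subset matrix.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.ndim != 2 or X.shape[0] != y.size or y.size < 2:
        raise DomainError("X must be (n, p) with n == len(y) >= 2")
    if ncomp < 1:
        raise DomainError("ncomp must be >= 1")
    if np.std(y) == 0:
        raise DegenerateResponseError("response has zero variance")
    n, p = X.shape
    ncomp = _cap_ncomp(ncomp, n, p)
    Xc, yc, x_mean, y_mean, x_scale = _center(X, y, scale)
    W, P, q, T = _nipals_pls1(Xc, yc, ncomp)
    if W.shape[1] == 0:
        raise DegenerateResponseError("no covariance between X and y")
    B = _regression_vectors(W, P, q)
    b = B[:, -1]
    intercept = y_mean - float((x_mean / x_scale) @ b)
    return PLSModel(
        x_mean=x_mean,
        y_mean=y_mean,
        x_scale=x_scale,
        weights=W,
        x_loadings=P,
        y_loadings=q,
        scores=T,
        b=b,
        intercept=intercept,
        ncomp=W.shape[1],
        variable_indices=None
        if variable_indices is None
        else np.asarray(variable_indices, dtype=int),
    )


def predict_pls(model: PLSModel, X_new: np.ndarray) -> np.ndarray:
    """Predict responses: ``ŷ = (X_new − x̄)/s · b + ȳ``."""
    X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    if X_new.shape[1] != model.b.size:
        raise DomainError(
            f"X_new has {X_new.shape[1]} channels, model expects {model.b.size}"
        )
    return ((X_new - model.x_mean) / model.x_scale) @ model.b + model.y_mean


def loocv_curve(
    X: np.ndarray, y: np.ndarray, max_comp: int, scale: bool = False
) -> CVCurve:
    """Leave-one-out CV curve for component counts 1..max_comp.

    PRESS(a) is the sum of squared LOO residuals at a components; RMSECV =
    sqrt(PRESS/n); R²_CV = 1 − PRESS/SST with SST about the full-sample
    mean of y. When a left-out fit runs out of rank before ``a``
    components, its prediction at the largest attainable count is used for
    the remaining entries.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if max_comp < 1:
        raise DomainError("max_comp must be >= 1")
    n, p = X.shape
    if n < 3:
        raise DomainError("leave-one-out CV needs n >= 3")
    if np.std(y) == 0:
        raise DegenerateResponseError("response has zero variance")
    bound = max(1, min(n - 2, p))  # each LOO fit sees n-1 samples
    if max_comp > bound:
        warnings.warn(
            f"max_comp={max_comp} exceeds the LOO rank bound {bound}; capped",
            stacklevel=2,
        )
        max_comp = bound
    press = np.zeros(max_comp)
    idx = np.arange(n)
    for i in range(n):
        train = idx != i
        Xc, yc, x_mean, y_mean, x_scale = _center(X[train], y[train], scale)
        W, P, q, _ = _nipals_pls1(Xc, yc, max_comp)
        B = _regression_vectors(W, P, q)
        a_eff = B.shape[1]
        if a_eff == 0:
            preds = np.full(max_comp, y_mean)
        else:
            xi = (X[i] - x_mean) / x_scale
            preds_eff = xi @ B + y_mean
            preds = np.concatenate(
                [preds_eff, np.full(max_comp - a_eff, preds_eff[-1])]
            )
        press += (y[i] - preds) ** 2
    sst = float(np.sum((y - y.mean()) ** 2))
    rmsecv = np.sqrt(press / n)
    r2_cv = 1.0 - press / sst
    return CVCurve(
        press=press,
        rmsecv=rmsecv,
        r2_cv=r2_cv,
        n_samples=n,
        max_components=max_comp,
    )


def select_ncomp(curve: CVCurve) -> int:
    """Component count minimizing RMSECV; ties go to fewer components."""
    if len(curve.rmsecv) == 0:
        raise DomainError("empty CV curve")
    return int(np.argmin(curve.rmsecv)) + 1


def regression_metrics(y: np.ndarray, yhat: np.ndarray) -> tuple[float, float]:
    """(R², RMSE) of predictions against observations.

    R² = 1 − SSE/SST with SST about mean(y); RMSE = sqrt(mean squared
    error). R² is undefined (error) for a constant y.
    """
    y = np.asarray(y, dtype=float).ravel()
    yhat = np.asarray(yhat, dtype=float).ravel()
    if y.size != yhat.size or y.size < 2:
        raise DomainError("y and yhat must have equal lengths >= 2")
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst == 0:
        raise ZeroVarianceError("R² undefined for zero-variance y")
    sse = float(np.sum((y - yhat) ** 2))
    rmse = float(np.sqrt(np.mean((y - yhat) ** 2)))
    return 1.0 - sse / sst, rmse
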