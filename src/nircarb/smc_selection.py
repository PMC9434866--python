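"""Significance multivariate correlation (sMC) variable selection.

sMC tests, per wavelength, how much of a channel's variance is explained
by the direction of the PLS regression vector b. The predictor matrix is
projected onto b, ``X̂ = X b bᵀ / (bᵀ b)``, the remainder ``E = X − X̂``
is treated as residual, and each channel j gets the variance ratio

    F_j = (Σ_i X̂²_ij / 1) / (Σ_i E²_ij / (n − 2)),

referred to an F(1, n−2) distribution. Channels with F above the
upper-alpha quantile are retained and the PLS model is refit on them,
keeping the component count of the full-spectrum model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from nircarb.errors import (
    DegenerateDirectionError,
    DomainError,
    InsufficientSamplesError,
)
from nircarb.plsr_core import PLSModel, fit_pls

#: Sentinel replacing an infinite F (zero residual, e.g. the single-channel
#: case where the projection reproduces X exactly).
F_SENTINEL = 1e15


@dataclass
class SMCResult:
    """Per-channel F statistics with the selection they imply."""

    F: np.ndarray
    f_critical: float
    alpha: float
    selected: np.ndarray  # indices with F > f_critical (or argmax fallback)
    n_samples: int
    fallback_used: bool = False


def smc_statistics(
    X: np.ndarray, b: np.ndarray, center: bool = True
) -> np.ndarray:
    """Per-channel sMC F statistics for regression vector ``b``.

    ``X`` is column-centered first unless ``center=False`` (pass False only
    if X is already centered). Invariant to rescaling of b.
    """
    X = np.asarray(X, dtype=float)
    b = np.asarray(b, dtype=float).ravel()
    if X.ndim != 2 or X.shape[1] != b.size:
        raise DomainError("columns of X must match the length of b")
    n = X.shape[0]
    if n <= 2:
        raise InsufficientSamplesError("sMC needs n > 2 for its F denominator")
    bb = float(b @ b)
    if bb == 0:
        raise DegenerateDirectionError("regression vector is zero")
    Xc = X - X.mean(axis=0) if center else X
    scores = Xc @ b / bb  # (n,)
    Xhat = np.outer(scores, b)
    E = Xc - Xhat
    ssr = (Xhat**2).sum(axis=0)
    sse = (E**2).sum(axis=0)
    scale = np.maximum(ssr, (Xc**2).sum(axis=0))
    F = np.zeros_like(ssr)
    exact = sse <= 1e-12 * np.maximum(scale, _tiny(scale))
    with np.errstate(divide="ignore", invalid="ignore"):
        F = np.where(sse > 0, ssr / (sse / (n - 2)), 0.0)
    F[exact & (ssr > 0)] = F_SENTINEL
    F[ssr == 0] = 0.0
    return F


def _tiny(x: np.ndarray) -> float:
    return np.finfo(float).tiny


def select_variables(F: np.ndarray, n: int, alpha: float = 0.05) -> SMCResult:
    """Threshold F statistics at the upper-alpha F(1, n−2) quantile.

    If nothing clears the threshold the single largest-F channel is
    returned with a warning, so downstream refits always have a predictor.
    """
    F = np.asarray(F, dtype=float)
    if n < 3:
        raise InsufficientSamplesError("need n >= 3 for F(1, n-2)")
    if not 0 < alpha < 1:
        raise DomainError(f"alpha must be in (0, 1), got {alpha}")
    f_critical = float(stats.f.isf(alpha, 1, n - 2))
    selected = np.flatnonzero(F > f_critical)
    fallback = False
    if selected.size == 0:
        warnings.warn(
            "no channel exceeded the sMC critical value; "
            "falling back to the single largest-F channel",
            stacklevel=2,
        )
        selected = np.array([int(np.argmax(F))])
        fallback = True
    return SMCResult(
        F=F,
        f_critical=f_critical,
        alpha=alpha,
        selected=selected,
        n_samples=n,
        fallback_used=fallback,
    )


def smc_pls_refit(
    X: np.ndarray,
    y: np.ndarray,
    result: SMCResult,
    ncomp: int,
    scale: bool = False,
) -> PLSModel:
    """Refit PLS on the sMC-selected channels.

    ``ncomp`` is normally carried over from the full-spectrum model (the
    optimal component count is observed to be stable under sMC reduction);
    it is capped, with a warning, if the reduced matrix cannot support it.
    """
    if result.selected.size == 0:
        raise DomainError("empty selection; run select_variables first")
    X = np.asarray(X, dtype=float)
    X_sel = X[:, result.selected]
    return fit_pls(
        X_sel, y, ncomp, scale=scale, variable_indices=result.selected
    )


def run_smc(
    X: np.ndarray,
    y: np.ndarray,
    full_model: PLSModel,
    alpha: float = 0.05,
    scale: bool = False,
) -> tuple[SMCResult, PLSModel]:
    """Convenience: statistics from the full model's b, select, refit."""
    F = smc_statistics(X, full_model.b)
    result = select_variables(F, X.shape[0], alpha=alpha)
    reduced = smc_pls_refit(X, y, result, full_model.ncomp, scale=scale)
    return result, reduced
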