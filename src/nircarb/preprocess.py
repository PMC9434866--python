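"""Spectral preprocessing: replicates -> model-ready predictor matrix.

The pipeline applied by :func:`preprocess_matrix` is, in order:

1. average the replicate reflectance spectra of each sample,
2. convert reflectance to absorbance, ``A = log10(1/R)``,
3. standard normal variate (SNV) per spectrum,
4. Savitzky–Golay first derivative (13-point window, polynomial order 2 by
   default), dropping the half-window of channels at each edge.

SNV removes per-spectrum affine distortions (multiplicative scatter plus a
baseline offset); the derivative suppresses the remaining slowly varying
baseline and sharpens overlapping absorption bands. On the standard
acquisition grid (1100–2500 nm at 8 nm, 175 channels) the 13-point
derivative leaves 163 effective channels.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.signal import savgol_filter

from nircarb.containers import PredictorMatrix, SpectraSet, check_grid
from nircarb.errors import (
    DomainError,
    InvalidGridError,
    MissingReplicateError,
    ZeroVarianceError,
)

DEFAULT_WINDOW = 13
DEFAULT_POLYORDER = 2


def wavelength_grid(start_nm: float, stop_nm: float, step_nm: float) -> np.ndarray:
    """Arithmetic wavelength grid covering the half-open range [start, stop).

    The half-open convention reproduces instrument channel counts: a
    1100–2500 nm range at 8 nm resolution yields exactly 175 channels
    (1100 + 174 * 8 = 2492 nm is the last one).
    """
    if step_nm <= 0:
        raise InvalidGridError(f"step must be positive, got {step_nm}")
    if stop_nm <= start_nm:
        raise InvalidGridError("stop must exceed start")
    n = int(np.ceil((stop_nm - start_nm) / step_nm - 1e-9))
    return check_grid(start_nm + step_nm * np.arange(n))


def average_replicates(spectra: SpectraSet) -> SpectraSet:
    """Mean reflectance spectrum per sample (computed before any log).

    Returns a new :class:`SpectraSet` with a single replicate (numbered 0)
    per sample; metadata is carried over unchanged.
    """
    samples = spectra.samples
    means = np.empty((len(samples), spectra.n_channels))
    for i, sid in enumerate(samples):
        rows = spectra.rows_for(sid)
        if rows.size == 0:  # unreachable through the public constructor
            raise MissingReplicateError(f"sample {sid!r} has no replicates")
        means[i] = spectra.reflectance[rows].mean(axis=0)
    return SpectraSet(
        grid=spectra.grid,
        reflectance=means,
        sample_id=np.array(samples, dtype=object),
        replicate=np.zeros(len(samples), dtype=int),
        metadata=spectra.metadata,
    )


def reflectance_to_absorbance(reflectance: np.ndarray) -> np.ndarray:
    """Absorbance ``A = log10(1/R)`` elementwise.

    R must be positive; values above 1 (possible with noisy bright
    references) are clipped to 1 with a warning, giving A = 0 there.
    """
    r = np.asarray(reflectance, dtype=float)
    if np.any(r <= 0):
        raise DomainError("reflectance must be positive to take log10(1/R)")
    if np.any(r > 1):
        warnings.warn("reflectance > 1 encountered; clipping to 1", stacklevel=2)
        r = np.minimum(r, 1.0)
    return -np.log10(r)


def snv(spectrum: np.ndarray, ddof: int = 1) -> np.ndarray:
    """Standard normal variate: centre and scale one spectrum to sd 1.

    Uses the n−1 denominator by default (``ddof=1``). Invariant under any
    per-spectrum affine distortion ``a*x + b`` with a > 0.
    """
    x = np.asarray(spectrum, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise DomainError("snv needs a 1-D spectrum of length >= 2")
    sd = x.std(ddof=ddof)
    if sd == 0 or not np.isfinite(sd):
        raise ZeroVarianceError("constant spectrum: SNV undefined")
    return (x - x.mean()) / sd


def savitzky_golay_first_derivative(
    spectrum: np.ndarray,
    grid: np.ndarray,
    window: int = DEFAULT_WINDOW,
    polyorder: int = DEFAULT_POLYORDER,
) -> tuple[np.ndarray, np.ndarray]:
    """First derivative by Savitzky–Golay local polynomial fit.

    Returns ``(derivative, trimmed_grid)`` where the (window−1)/2 channels
    at each edge are dropped rather than extrapolated, and the derivative is
    scaled by the grid step so units are absorbance per nm. Requires a
    uniform grid.
    """
    x = np.asarray(spectrum, dtype=float)
    grid = check_grid(grid)
    if window % 2 == 0:
        raise DomainError(f"window must be odd, got {window}")
    if polyorder >= window:
        raise DomainError("polyorder must be smaller than window")
    if x.size != grid.size:
        raise InvalidGridError("spectrum and grid lengths differ")
    if x.size < window:
        raise DomainError(
            f"spectrum of length {x.size} shorter than window {window}"
        )
    steps = np.diff(grid)
    if not np.allclose(steps, steps[0], rtol=1e-8, atol=0):
        raise InvalidGridError("Savitzky–Golay derivative requires a uniform grid")
    deriv = savgol_filter(x, window, polyorder, deriv=1, delta=steps[0])
    half = (window - 1) // 2
    return deriv[half : x.size - half], grid[half : grid.size - half]


def preprocess_matrix(
    spectra: SpectraSet,
    window: int = DEFAULT_WINDOW,
    polyorder: int = DEFAULT_POLYORDER,
    snv_ddof: int = 1,
) -> PredictorMatrix:
    """Full preprocessing chain producing the PLSR predictor matrix.

    Order: average replicates -> absorbance -> SNV -> SG first derivative.
    The returned provenance lists each step with its parameters, in the
    order applied.
    """
    averaged = average_replicates(spectra)
    rows = []
    effective_grid = None
    for i in range(averaged.reflectance.shape[0]):
        absorbance = reflectance_to_absorbance(averaged.reflectance[i])
        standardized = snv(absorbance, ddof=snv_ddof)
        deriv, effective_grid = savitzky_golay_first_derivative(
            standardized, averaged.grid, window=window, polyorder=polyorder
        )
        rows.append(deriv)
    provenance = [
        {"step": "average_replicates"},
        {"step": "reflectance_to_absorbance", "log_base": 10},
        {"step": "snv", "ddof": snv_ddof},
        {
            "step": "savitzky_golay_first_derivative",
            "window": window,
            "polyorder": polyorder,
        },
    ]
    return PredictorMatrix(
        X=np.vstack(rows),
        effective_grid=effective_grid,
        sample_ids=averaged.samples,
        provenance=provenance,
    )
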