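"""In-memory containers shared across the pipeline.

A :class:`SpectraSet` holds replicate reflectance spectra on a common
wavelength grid together with per-sample metadata; a
:class:`PredictorMatrix` is the model-ready matrix that preprocessing
produces from it. Chemistry reference values travel as a plain
:class:`pandas.DataFrame` with the columns listed in
:data:`CHEMISTRY_COLUMNS` (see :func:`validate_chemistry_table`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from nircarb.errors import InvalidGridError, MissingReplicateError, ParseError

METADATA_COLUMNS = ("tissue", "season", "treatment", "side")
CONSTITUENTS = ("glucose", "fructose", "sucrose", "starch")
CHEMISTRY_COLUMNS = (
    "sample_id",
    *METADATA_COLUMNS,
    *CONSTITUENTS,
    "nsc",
)


def check_grid(grid: np.ndarray) -> np.ndarray:
    """Validate a wavelength grid: 1-D, >= 1 channel, strictly increasing."""
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or grid.size < 1:
        raise InvalidGridError("wavelength grid must be a non-empty 1-D vector")
    if grid.size > 1 and not np.all(np.diff(grid) > 0):
        raise InvalidGridError("wavelength grid must be strictly increasing")
    return grid


@dataclass
class SpectraSet:
    """Replicate reflectance spectra on a shared wavelength grid.

    Parameters
    ----------
    grid
        Wavelength vector in nm, strictly increasing, shape ``(p,)``.
    reflectance
        One row per (sample, replicate), shape ``(n_spectra, p)``; values
        must lie in ``(0, 1]``.
    sample_id, replicate
        Per-row sample identifier and replicate number, shape ``(n_spectra,)``.
    metadata
        DataFrame indexed by sample_id carrying the tissue / season /
        treatment / side labels for every sample present.
    """

    grid: np.ndarray
    reflectance: np.ndarray
    sample_id: np.ndarray
    replicate: np.ndarray
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        self.grid = check_grid(self.grid)
        self.reflectance = np.asarray(self.reflectance, dtype=float)
        self.sample_id = np.asarray(self.sample_id, dtype=object)
        self.replicate = np.asarray(self.replicate, dtype=int)
        n, p = self.reflectance.shape
        if p != self.grid.size:
            raise InvalidGridError(
                f"reflectance has {p} channels but grid has {self.grid.size}"
            )
        if self.sample_id.shape != (n,) or self.replicate.shape != (n,):
            raise ParseError("sample_id/replicate length must match spectra count")
        if n == 0:
            raise MissingReplicateError("spectra set contains no spectra")
        if np.any(self.reflectance <= 0) or np.any(self.reflectance > 1):
            raise ParseError("reflectance values must lie in (0, 1]")
        missing = set(self.samples) - set(self.metadata.index)
        if missing:
            raise ParseError(f"metadata missing for samples: {sorted(missing)[:5]}")
        for col in METADATA_COLUMNS:
            if col not in self.metadata.columns:
                raise ParseError(f"metadata lacks required column {col!r}")

    @property
    def samples(self) -> list[str]:
        """Unique sample ids, in order of first appearance."""
        return list(pd.unique(self.sample_id))

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_channels(self) -> int:
        return int(self.grid.size)

    def replicate_counts(self) -> pd.Series:
        return pd.Series(self.sample_id).value_counts().reindex(self.samples)

    def rows_for(self, sample: str) -> np.ndarray:
        """Row indices (into ``reflectance``) belonging to one sample."""
        return np.flatnonzero(self.sample_id == sample)


@dataclass
class PredictorMatrix:
    """Preprocessed predictor matrix with its provenance trail.

    ``X`` has one row per sample (in ``sample_ids`` order) and one column per
    retained wavelength in ``effective_grid``. ``provenance`` is the ordered
    list of applied transforms with their parameters.
    """

    X: np.ndarray
    effective_grid: np.ndarray
    sample_ids: list[str]
    provenance: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.effective_grid = check_grid(self.effective_grid)
        if self.X.shape != (len(self.sample_ids), self.effective_grid.size):
            raise ParseError(
                "PredictorMatrix shape inconsistent with sample_ids/effective_grid"
            )


def validate_chemistry_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check a chemistry reference table for the documented columns.

    Requires all of :data:`CHEMISTRY_COLUMNS`, non-negative concentrations,
    and an ``nsc`` column equal to the sum of the four constituents.
    """
    missing = [c for c in CHEMISTRY_COLUMNS if c not in table.columns]
    if missing:
        raise ParseError(f"chemistry table missing columns: {missing}")
    values = table[list(CONSTITUENTS)].to_numpy(dtype=float)
    if np.any(values < 0):
        raise ParseError("chemistry table contains negative concentrations")
    nsc = table["nsc"].to_numpy(dtype=float)
    if not np.allclose(nsc, values.sum(axis=1), rtol=0, atol=1e-9):
        raise ParseError("nsc column is not the sum of the four constituents")
    return table
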