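"""Wet-chemistry bookkeeping for the reference values.

The enzymatic assay measures free glucose, fructose and sucrose directly,
then digests starch with amylase and re-measures total glucose. Starch is
the excess of the post-digestion total over the free-sugar sum; total
non-structural carbohydrate (NSC) is starch plus the three free sugars.
All quantities are percentages of tissue dry mass, subtracted directly
with no molar (hexose-per-sucrose) correction — the mass-percent
bookkeeping the reference values are reported in.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from nircarb.containers import CONSTITUENTS
from nircarb.errors import AssayInconsistencyError, DomainError


@dataclass(frozen=True)
class AssayRecord:
    """One sample's assay readings, all in % dry mass.

    ``total_glucose_after_digestion`` is the glucose-equivalent measured
    after the invertase/isomerase conversion of fructose and sucrose and
    the amylase digestion of starch; it must cover the free-sugar sum.
    """

    sample_id: str
    glucose_free: float
    fructose_free: float
    sucrose_free: float
    total_glucose_after_digestion: float

    def __post_init__(self) -> None:
        for name in (
            "glucose_free",
            "fructose_free",
            "sucrose_free",
            "total_glucose_after_digestion",
        ):
            if getattr(self, name) < 0:
                raise DomainError(f"{name} must be >= 0 for {self.sample_id!r}")


def starch_from_digestion(record: AssayRecord) -> float:
    """Starch (% dry mass) from the digestion assay.

    starch = total glucose after digestion − (glucose + fructose + sucrose).
    A negative difference means the assay readings are inconsistent and
    raises :class:`AssayInconsistencyError` naming the sample.
    """
    free = record.glucose_free + record.fructose_free + record.sucrose_free
    starch = record.total_glucose_after_digestion - free
    if starch < 0:
        raise AssayInconsistencyError(
            f"sample {record.sample_id!r}: digestion total "
            f"{record.total_glucose_after_digestion} below free-sugar sum {free}"
        )
    return starch


def nsc_total(
    starch: float, glucose: float, fructose: float, sucrose: float
) -> float:
    """NSC = starch + glucose + fructose + sucrose (% dry mass)."""
    for name, value in (
        ("starch", starch),
        ("glucose", glucose),
        ("fructose", fructose),
        ("sucrose", sucrose),
    ):
        if value < 0:
            raise DomainError(f"{name} must be >= 0, got {value}")
    return starch + glucose + fructose + sucrose


def assay_from_concentrations(
    sample_id: str, glucose: float, fructose: float, sucrose: float, starch: float
) -> AssayRecord:
    """Build the assay record a given true composition would produce.

    Round-trip companion of :func:`starch_from_digestion`:
    ``starch_from_digestion(assay_from_concentrations(...))`` recovers the
    starch value exactly.
    """
    return AssayRecord(
        sample_id=sample_id,
        glucose_free=glucose,
        fructose_free=fructose,
        sucrose_free=sucrose,
        total_glucose_after_digestion=glucose + fructose + sucrose + starch,
    )


def add_nsc_column(table: pd.DataFrame) -> pd.DataFrame:
    """Return a copy of ``table`` with ``nsc`` recomputed from constituents."""
    out = table.copy()
    out["nsc"] = out[list(CONSTITUENTS)].to_numpy(dtype=float).sum(axis=1)
    return out


def starch_column_from_assays(records: list[AssayRecord]) -> pd.DataFrame:
    """Vectorized convenience: one row per assay with derived starch and NSC."""
    rows = []
    for rec in records:
        starch = starch_from_digestion(rec)
        rows.append(
            {
                "sample_id": rec.sample_id,
                "glucose": rec.glucose_free,
                "fructose": rec.fructose_free,
                "sucrose": rec.sucrose_free,
                "starch": starch,
                "nsc": nsc_total(
                    starch, rec.glucose_free, rec.fructose_free, rec.sucrose_free
                ),
            }
        )
    return pd.DataFrame(rows)
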