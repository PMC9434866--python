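"""CSV/YAML/JSON formats and run manifests.

Spectra travel as long-format CSV (sample_id, replicate, wavelength_nm,
reflectance, plus the four metadata labels) so the grid stays explicit and
diffs stay readable; a wide export is offered for interoperability.
Chemistry tables and reports are plain CSV; scenario configuration is
strict YAML (unknown keys rejected); every CLI run writes a JSON manifest
(config hash, seed, package version) sufficient to reproduce its outputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from nircarb.containers import (
    CHEMISTRY_COLUMNS,
    METADATA_COLUMNS,
    PredictorMatrix,
    SpectraSet,
    validate_chemistry_table,
)
from nircarb.errors import ConfigError, ParseError
from nircarb.evaluation import SimulationReport, SplitSpec
from nircarb.synthetic_data import (
    NoiseConfig,
    TissueDesign,
    default_tissue_designs,
)

SPECTRA_COLUMNS = ("sample_id", "replicate", "wavelength_nm", "reflectance")


def write_spectra_csv(spectra: SpectraSet, path) -> None:
    """Write a SpectraSet in the long-format dialect."""
    n_rows, p = spectra.reflectance.shape
    meta = spectra.metadata.loc[list(spectra.sample_id)]
    frame = pd.DataFrame(
        {
            "sample_id": np.repeat(spectra.sample_id, p),
            "replicate": np.repeat(spectra.replicate, p),
            "wavelength_nm": np.tile(spectra.grid, n_rows),
            "reflectance": spectra.reflectance.ravel(),
        }
    )
    for col in METADATA_COLUMNS:
        frame[col] = np.repeat(meta[col].to_numpy(), p)
    frame.to_csv(path, index=False, float_format="%.12g")


def read_spectra_csv(path) -> SpectraSet:
    """Read the long-format spectra dialect back into a SpectraSet.

    Raises :class:`ParseError` naming the offending location for empty
    files, missing columns, non-numeric cells, duplicate
    (sample, replicate, wavelength) keys, or ragged grids.
    """
    path = Path(path)
    try:
        frame = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise ParseError(f"{path}: empty input file") from exc
    if frame.empty:
        raise ParseError(f"{path}: no spectra rows")
    missing = [c for c in SPECTRA_COLUMNS if c not in frame.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    for col in ("wavelength_nm", "reflectance"):
        coerced = pd.to_numeric(frame[col], errors="coerce")
        bad = frame.index[coerced.isna() & frame[col].notna()]
        if len(bad):
            raise ParseError(
                f"{path}: non-numeric {col} at csv row {int(bad[0]) + 2}"
            )
        if coerced.isna().any():
            raise ParseError(f"{path}: missing {col} value")
        frame[col] = coerced
    dup = frame.duplicated(["sample_id", "replicate", "wavelength_nm"])
    if dup.any():
        row = frame[dup].iloc[0]
        raise ParseError(
            f"{path}: duplicate key (sample_id={row['sample_id']!r}, "
            f"replicate={row['replicate']}, wavelength={row['wavelength_nm']})"
        )
    has_meta = all(c in frame.columns for c in METADATA_COLUMNS)
    grid = np.sort(frame["wavelength_nm"].unique())
    wide = frame.pivot_table(
        index=["sample_id", "replicate"],
        columns="wavelength_nm",
        values="reflectance",
    )
    if wide.isna().any().any():
        bad_key = wide.index[wide.isna().any(axis=1)][0]
        raise ParseError(
            f"{path}: ragged grid — spectrum {bad_key} lacks some wavelengths"
        )
    wide = wide[grid]
    sample_id = np.array([k[0] for k in wide.index], dtype=object)
    replicate = np.array([int(k[1]) for k in wide.index])
    if has_meta:
        metadata = (
            frame[["sample_id", *METADATA_COLUMNS]]
            .drop_duplicates("sample_id")
            .set_index("sample_id")
        )
    else:
        metadata = pd.DataFrame(
            {c: "unknown" for c in METADATA_COLUMNS},
            index=pd.Index(pd.unique(sample_id), name="sample_id"),
        )
    return SpectraSet(
        grid=grid,
        reflectance=wide.to_numpy(),
        sample_id=sample_id,
        replicate=replicate,
        metadata=metadata,
    )


def write_spectra_wide_csv(spectra: SpectraSet, path) -> None:
    """Interoperability export: one row per spectrum, wavelengths as columns."""
    frame = pd.DataFrame(
        spectra.reflectance, columns=[f"{w:g}" for w in spectra.grid]
    )
    frame.insert(0, "replicate", spectra.replicate)
    frame.insert(0, "sample_id", spectra.sample_id)
    frame.to_csv(path, index=False, float_format="%.12g")


def write_chemistry_csv(table: pd.DataFrame, path) -> None:
    validate_chemistry_table(table)
    table[list(CHEMISTRY_COLUMNS)].to_csv(path, index=False, float_format="%.12g")


def read_chemistry_csv(path) -> pd.DataFrame:
    path = Path(path)
    try:
        table = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise ParseError(f"{path}: empty input file") from exc
    return validate_chemistry_table(table)


def write_predictor_matrix(matrix: PredictorMatrix, path) -> None:
    """Matrix CSV (wavelength column headers) + provenance JSON sidecar."""
    path = Path(path)
    frame = pd.DataFrame(
        matrix.X, columns=[f"{w:g}" for w in matrix.effective_grid]
    )
    frame.insert(0, "sample_id", matrix.sample_ids)
    frame.to_csv(path, index=False, float_format="%.12g")
    with open(path.with_suffix(path.suffix + ".provenance.json"), "w") as fh:
        json.dump(matrix.provenance, fh, indent=2)


def read_predictor_matrix(path) -> PredictorMatrix:
    path = Path(path)
    frame = pd.read_csv(path)
    grid = np.array([float(c) for c in frame.columns[1:]])
    sidecar = path.with_suffix(path.suffix + ".provenance.json")
    provenance = []
    if sidecar.exists():
        with open(sidecar) as fh:
            provenance = json.load(fh)
    return PredictorMatrix(
        X=frame.iloc[:, 1:].to_numpy(dtype=float),
        effective_grid=grid,
        sample_ids=frame["sample_id"].tolist(),
        provenance=provenance,
    )


def write_report(report: SimulationReport, base_path) -> None:
    """Write a SimulationReport as CSVs plus a JSON summary.

    ``base_path`` is a stem: produces ``<stem>_simulations.csv``,
    ``<stem>_sample_predictions.csv`` and ``<stem>_summary.json``.
    """
    base = Path(base_path)
    base.parent.mkdir(parents=True, exist_ok=True)
    report.table.to_csv(f"{base}_simulations.csv", index=False)
    report.sample_predictions.to_csv(
        f"{base}_sample_predictions.csv", index=False
    )
    summary = {
        "n_skipped": report.n_skipped,
        "statistics": report.summary.to_dict(orient="records"),
    }
    with open(f"{base}_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)


def write_smc_csv(grid: np.ndarray, result, path) -> None:
    """sMC result as (wavelength, F, selected) for plotting against spectra."""
    selected = np.zeros(len(grid), dtype=bool)
    selected[result.selected] = True
    pd.DataFrame(
        {"wavelength_nm": grid, "F": result.F, "selected": selected}
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Scenario configuration


_GRID_KEYS = {"start_nm", "stop_nm", "step_nm"}
_DESIGN_KEYS = {
    "tissue", "season", "treatment", "side", "n_samples",
    "starch", "glucose", "fructose", "sucrose", "rel_sd",
    "glucose_fructose_rho", "water_mean", "water_sd",
}
_NOISE_KEYS = {
    "replicate_noise_sd", "baseline_offset_sd", "baseline_slope_sd",
    "multiplicative_scatter_sd", "seed",
}
_SPLIT_KEYS = {"calibration_fraction", "n_simulations", "base_seed", "stratify_by"}
_PREPROC_KEYS = {"window", "polyorder", "snv_ddof"}
_TOP_KEYS = {"grid", "designs", "noise", "split", "preprocessing", "smc_alpha"}


def _check_keys(mapping: dict, allowed: set, where: str) -> None:
    unknown = set(mapping) - allowed
    if unknown:
        raise ConfigError(f"unknown keys in {where}: {sorted(unknown)}")


@dataclass
class ScenarioConfig:
    """Validated scenario: grid, designs, noise, split and model settings."""

    grid: dict = field(
        default_factory=lambda: {"start_nm": 1100.0, "stop_nm": 2500.0, "step_nm": 8.0}
    )
    designs: list[dict] = field(default_factory=list)
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    split: SplitSpec = field(default_factory=SplitSpec)
    preprocessing: dict = field(
        default_factory=lambda: {"window": 13, "polyorder": 2, "snv_ddof": 1}
    )
    smc_alpha: float = 0.05

    @classmethod
    def from_dict(cls, raw: dict) -> "ScenarioConfig":
        _check_keys(raw, _TOP_KEYS, "scenario")
        cfg = cls()
        if "grid" in raw:
            _check_keys(raw["grid"], _GRID_KEYS, "grid")
            cfg.grid.update(raw["grid"])
        for dsg in raw.get("designs", []):
            _check_keys(dsg, _DESIGN_KEYS, f"design {dsg.get('tissue', '?')!r}")
            cfg.designs.append(dict(dsg))
        if "noise" in raw:
            _check_keys(raw["noise"], _NOISE_KEYS, "noise")
            cfg.noise = NoiseConfig(**raw["noise"])
        if "split" in raw:
            _check_keys(raw["split"], _SPLIT_KEYS, "split")
            cfg.split = SplitSpec(**raw["split"])
        if "preprocessing" in raw:
            _check_keys(raw["preprocessing"], _PREPROC_KEYS, "preprocessing")
            cfg.preprocessing.update(raw["preprocessing"])
        if "smc_alpha" in raw:
            alpha = float(raw["smc_alpha"])
            if not 0 < alpha < 1:
                raise ConfigError("smc_alpha must be in (0, 1)")
            cfg.smc_alpha = alpha
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "ScenarioConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if raw is None:
            raw = {}
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: scenario config must be a mapping")
        return cls.from_dict(raw)

    def tissue_designs(self) -> list[TissueDesign]:
        """Materialize designs; defaults to the six standard tissues."""
        from nircarb.synthetic_data import design as make_design

        if not self.designs:
            return list(default_tissue_designs().values())
        out = []
        for d in self.designs:
            d = dict(d)
            tissue = d.pop("tissue")
            out.append(
                make_design(
                    tissue,
                    d.pop("starch"),
                    d.pop("glucose"),
                    d.pop("fructose"),
                    d.pop("sucrose"),
                    **d,
                )
            )
        return out

    def to_dict(self) -> dict:
        return {
            "grid": dict(self.grid),
            "designs": [dict(d) for d in self.designs],
            "noise": asdict(self.noise),
            "split": asdict(self.split),
            "preprocessing": dict(self.preprocessing),
            "smc_alpha": self.smc_alpha,
        }

    def config_hash(self) -> str:
        canonical = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()


def write_manifest(path, config: ScenarioConfig | None, seed: int | None,
                   command: str, extra: dict | None = None) -> None:
    """Machine-readable record of a run: enough to reproduce it bit-for-bit."""
    from nircarb import __version__

    manifest = {
        "command": command,
        "package_version": __version__,
        "seed": seed,
        "config_hash": None if config is None else config.config_hash(),
        "config": None if config is None else config.to_dict(),
    }
    if extra:
        manifest.update(extra)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
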