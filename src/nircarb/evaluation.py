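"""Repeated random-split model evaluation.

The study design this reproduces: split the samples 80/20 into calibration
and validation by random sampling, calibrate a PLSR model on the
calibration set (component count chosen by leave-one-out CV), evaluate on
the validation set, run sMC variable selection and refit, and repeat the
whole procedure 100 times to obtain distributions — mean and 95%
percentile intervals — of R²_CV, RMSE_CV, R²_V and RMSE_V for both the
full-spectrum and the sMC-reduced model, plus per-sample prediction
uncertainty across the splits.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from nircarb.errors import DomainError, SplitSizeError
from nircarb.plsr_core import (
    fit_pls,
    loocv_curve,
    predict_pls,
    regression_metrics,
    select_ncomp,
)
from nircarb.smc_selection import run_smc

logger = logging.getLogger("nircarb.evaluation")

STATISTICS = ("r2_cv", "rmse_cv", "r2_v", "rmse_v")
DEFAULT_MAX_COMP = 20


@dataclass(frozen=True)
class SplitSpec:
    """Repeated-split design: fraction, repetitions, seeding, stratification."""

    calibration_fraction: float = 0.8
    n_simulations: int = 100
    base_seed: int = 0
    stratify_by: str | None = None

    def __post_init__(self) -> None:
        if not 0 < self.calibration_fraction < 1:
            raise DomainError("calibration_fraction must be in (0, 1)")
        if self.n_simulations < 1:
            raise DomainError("n_simulations must be >= 1")


@dataclass
class SimulationResult:
    """One split's statistics for both model variants."""

    index: int
    rows: list[dict]
    val_indices: np.ndarray
    val_pred: dict[str, np.ndarray]


@dataclass
class SimulationReport:
    """Aggregated repeated-split results.

    ``table`` has one row per (simulation, variant); ``summary`` carries the
    mean and 2.5/97.5 percentile bounds per (variant, statistic);
    ``sample_predictions`` gives, per sample, the mean and sd of its
    validation-set predictions across the simulations in which it was held
    out, per variant.
    """

    table: pd.DataFrame
    summary: pd.DataFrame
    sample_predictions: pd.DataFrame
    n_skipped: int = 0


def random_split(
    n: int,
    spec: SplitSpec,
    simulation_index: int,
    labels: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Disjoint, exhaustive calibration/validation index sets.

    |calibration| = floor(fraction * n). Reproducible from
    ``(base_seed, simulation_index)``. If ``labels`` is given and the spec
    requests stratification, the calibration fraction is applied within
    each label level.
    """
    if n < 5:
        raise SplitSizeError(f"need n >= 5 to populate both sets, got {n}")
    rng = np.random.default_rng((spec.base_seed + simulation_index) % (2**31))
    n_cal = math.floor(spec.calibration_fraction * n)
    if n_cal < 1 or n_cal >= n:
        raise SplitSizeError("calibration fraction leaves an empty set")
    if spec.stratify_by is not None and labels is not None:
        labels = np.asarray(labels)
        cal_parts = []
        for level in pd.unique(labels):
            level_idx = np.flatnonzero(labels == level)
            perm = rng.permutation(level_idx)
            k = math.floor(spec.calibration_fraction * level_idx.size)
            cal_parts.append(perm[:k])
        cal = np.sort(np.concatenate(cal_parts))
        val = np.setdiff1d(np.arange(n), cal)
        return cal, val
    perm = rng.permutation(n)
    return np.sort(perm[:n_cal]), np.sort(perm[n_cal:])


def run_single_simulation(
    X: np.ndarray,
    y: np.ndarray,
    spec: SplitSpec,
    simulation_index: int,
    smc_alpha: float = 0.05,
    max_comp: int | None = None,
    labels: np.ndarray | None = None,
) -> SimulationResult | None:
    """One split: calibrate, validate, select variables, refit, re-validate.

    Returns ``None`` (with a log entry) on a degenerate split whose
    calibration response has zero variance.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.shape[0] != y.size:
        raise DomainError("X and y disagree on sample count")
    cal, val = random_split(y.size, spec, simulation_index, labels=labels)
    if np.std(y[cal]) == 0 or np.std(y[val]) == 0:
        logger.warning(
            "simulation %d skipped: zero-variance response in split",
            simulation_index,
        )
        return None
    n_cal, p = cal.size, X.shape[1]
    if max_comp is None:
        max_comp = min(DEFAULT_MAX_COMP, n_cal - 1, p)
    X_cal, y_cal = X[cal], y[cal]
    X_val, y_val = X[val], y[val]

    curve = loocv_curve(X_cal, y_cal, max_comp)
    ncomp = select_ncomp(curve)
    full_model = fit_pls(X_cal, y_cal, ncomp)
    r2_v, rmse_v = regression_metrics(y_val, predict_pls(full_model, X_val))
    rows = [
        {
            "simulation": simulation_index,
            "variant": "full",
            "ncomp": ncomp,
            "n_channels": p,
            "r2_cv": float(curve.r2_cv[ncomp - 1]),
            "rmse_cv": float(curve.rmsecv[ncomp - 1]),
            "r2_v": float(r2_v),
            "rmse_v": float(rmse_v),
        }
    ]
    val_pred = {"full": predict_pls(full_model, X_val)}

    smc_result, smc_model = run_smc(X_cal, y_cal, full_model, alpha=smc_alpha)
    sel = smc_result.selected
    smc_curve = loocv_curve(X_cal[:, sel], y_cal, smc_model.ncomp)
    a = min(smc_model.ncomp, smc_curve.max_components)
    r2_v_s, rmse_v_s = regression_metrics(
        y_val, predict_pls(smc_model, X_val[:, sel])
    )
    rows.append(
        {
            "simulation": simulation_index,
            "variant": "smc",
            "ncomp": a,
            "n_channels": int(sel.size),
            "r2_cv": float(smc_curve.r2_cv[a - 1]),
            "rmse_cv": float(smc_curve.rmsecv[a - 1]),
            "r2_v": float(r2_v_s),
            "rmse_v": float(rmse_v_s),
        }
    )
    val_pred["smc"] = predict_pls(smc_model, X_val[:, sel])
    return SimulationResult(
        index=simulation_index, rows=rows, val_indices=val, val_pred=val_pred
    )


def summarize_simulations(
    results: list[SimulationResult],
    n_samples: int | None = None,
    sample_ids: list[str] | None = None,
) -> SimulationReport:
    """Aggregate repeated-split results into a :class:`SimulationReport`."""
    results = [r for r in results if r is not None]
    rows = [row for r in results for row in r.rows]
    table = pd.DataFrame(rows)
    if table.empty or table.groupby("variant").size().min() < 2:
        raise DomainError("need >= 2 simulations per variant to summarize")

    records = []
    for variant, sub in table.groupby("variant"):
        for stat in STATISTICS:
            vals = sub[stat].to_numpy()
            lo, hi = np.percentile(vals, [2.5, 97.5])
            records.append(
                {
                    "variant": variant,
                    "statistic": stat,
                    "mean": float(vals.mean()),
                    "ci_low": float(lo),
                    "ci_high": float(hi),
                }
            )
        records.append(
            {
                "variant": variant,
                "statistic": "n_channels",
                "mean": float(sub["n_channels"].mean()),
                "ci_low": float(sub["n_channels"].min()),
                "ci_high": float(sub["n_channels"].max()),
            }
        )
    summary = pd.DataFrame(records)

    if n_samples is None:
        n_samples = int(max(r.val_indices.max() for r in results)) + 1
    pred_rows = []
    for variant in ("full", "smc"):
        sums = np.zeros(n_samples)
        sq = np.zeros(n_samples)
        counts = np.zeros(n_samples, dtype=int)
        for r in results:
            pred = r.val_pred[variant]
            np.add.at(sums, r.val_indices, pred)
            np.add.at(sq, r.val_indices, pred**2)
            np.add.at(counts, r.val_indices, 1)
        with np.errstate(invalid="ignore", divide="ignore"):
            mean = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
            var = sq / np.maximum(counts, 1) - mean**2
            sd = np.sqrt(np.maximum(var, 0.0))
            sd[counts < 2] = np.nan
        for i in range(n_samples):
            pred_rows.append(
                {
                    "sample": sample_ids[i] if sample_ids else i,
                    "variant": variant,
                    "n_validations": int(counts[i]),
                    "pred_mean": float(mean[i]),
                    "pred_sd": float(sd[i]),
                }
            )
    sample_predictions = pd.DataFrame(pred_rows)
    uncovered = sample_predictions.groupby("sample")["n_validations"].max()
    if (uncovered == 0).any():
        logger.warning(
            "%d samples never appeared in a validation set",
            int((uncovered == 0).sum()),
        )
    return SimulationReport(
        table=table, summary=summary, sample_predictions=sample_predictions
    )


def run_repeated_evaluation(
    X: np.ndarray,
    y: np.ndarray,
    spec: SplitSpec,
    smc_alpha: float = 0.05,
    max_comp: int | None = None,
    labels: np.ndarray | None = None,
    sample_ids: list[str] | None = None,
) -> SimulationReport:
    """Run the full repeated-split evaluation and summarize it."""
    results = []
    skipped = 0
    for i in range(spec.n_simulations):
        res = run_single_simulation(
            X, y, spec, i, smc_alpha=smc_alpha, max_comp=max_comp, labels=labels
        )
        if res is None:
            skipped += 1
        else:
            results.append(res)
    report = summarize_simulations(
        results, n_samples=np.asarray(y).size, sample_ids=sample_ids
    )
    report.n_skipped = skipped
    return report
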