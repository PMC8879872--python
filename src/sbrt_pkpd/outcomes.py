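"""Cohort outcome statistics.

Treatment efficacy is the percent change in gross tumour volume between
the planning CT and the follow-up CT::

    efficacy(%) = 100 - 100 * v_post / v_pre

100% means the lesion was no longer measurable; negative values mean
progression.  Per-regimen effectiveness is the unweighted mean of
per-lesion efficacies within each (total dose, fraction count) group,
restricted to lesions flagged ``in_regimen_stats`` (the reference cohort
excludes two lesions from that accounting).

The module also provides the measured-vs-simulated regression used to
validate calibration, and the baseline-volume uncertainty analysis:
re-simulate each lesion with its fitted gamma after perturbing the
initial volume by 5 / 10 / 20% and report the percent change in the
simulated final volume.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .calibrate import CalibrationResult
from .cohort import LesionRecord
from .model import PKPDParams, final_reported_volume

__all__ = [
    "RegressionSummary",
    "efficacy",
    "efficacy_table",
    "regimen_efficacy",
    "classify_responses",
    "measured_vs_simulated_regression",
    "sensitivity_analysis",
    "sensitivity_cohort",
    "sensitivity_quartiles",
    "outcomes_summary",
]

DEFAULT_SENSITIVITY_LEVELS = (0.05, 0.10, 0.20)


def efficacy(v_pre: float, v_post: float) -> float:
    """Percent volume reduction; negative for progression."""
    if not (v_pre > 0):
        raise ValueError(f"v_pre must be > 0, got {v_pre}")
    if v_post < 0:
        raise ValueError(f"v_post must be >= 0, got {v_post}")
    return 100.0 - 100.0 * v_post / v_pre


def efficacy_table(records: Sequence[LesionRecord]) -> pd.DataFrame:
    """One row per lesion: regimen label, efficacy, response class."""
    rows = []
    for rec in records:
        eff = efficacy(rec.v_pre_cm3, rec.v_post_cm3)
        rows.append(
            {
                "patient_id": rec.patient_id,
                "lesion_index": rec.lesion_index,
                "regimen": rec.regimen,
                "efficacy": eff,
                "response_class": "decreased" if eff > 0 else "stable_or_increased",
                "in_regimen_stats": rec.in_regimen_stats,
            }
        )
    return pd.DataFrame(rows)


def regimen_efficacy(records: Sequence[LesionRecord]) -> dict[str, float]:
    """Unweighted mean efficacy per fractionation regimen.

    Only lesions with ``in_regimen_stats=True`` contribute.  Regimens
    whose lesions are all excluded are omitted with a warning.
    """
    table = efficacy_table(records)
    out: dict[str, float] = {}
    for regimen, group in table.groupby("regimen", sort=True):
        included = group[group["in_regimen_stats"]]
        if included.empty:
            warnings.warn(
                f"regimen {regimen}: no lesions counted toward regimen "
                f"statistics; group omitted",
                stacklevel=2,
            )
            continue
        out[str(regimen)] = float(included["efficacy"].mean())
    return out


def classify_responses(records: Sequence[LesionRecord]) -> dict[str, int]:
    """Count lesions that decreased (efficacy > 0) vs stayed stable or
    increased, over all lesions."""
    table = efficacy_table(records)
    decreased = int((table["response_class"] == "decreased").sum())
    return {
        "decreased": decreased,
        "stable_or_increased": len(table) - decreased,
    }


@dataclass(frozen=True)
class RegressionSummary:
    """OLS of simulated final volume on measured post-RT volume."""

    slope: float
    intercept: float
    r: float  # Pearson correlation coefficient
    rmse: float  # cm^3, simulated vs measured
    n: int


def measured_vs_simulated_regression(
    records: Sequence[LesionRecord],
    calibrations: Sequence[CalibrationResult],
) -> RegressionSummary:
    """Regression of the calibrated model's final volumes on the measured
    post-RT volumes, across all lesions with a calibration."""
    by_key = {c.key: c for c in calibrations}
    measured, simulated = [], []
    for rec in records:
        cal = by_key.get(rec.key)
        if cal is None:
            raise ValueError(f"no calibration for lesion {rec.label}")
        measured.append(rec.v_post_cm3)
        simulated.append(cal.v_sim_final)
    if len(measured) < 2:
        raise ValueError(f"regression needs >= 2 lesions, got {len(measured)}")
    x = np.asarray(measured)
    y = np.asarray(simulated)
    fit = stats.linregress(x, y)
    rmse = float(np.sqrt(np.mean((y - x) ** 2)))
    return RegressionSummary(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r=float(fit.rvalue),
        rmse=rmse,
        n=len(x),
    )


def sensitivity_analysis(
    record: LesionRecord,
    params: PKPDParams,
    gamma: float,
    levels: Sequence[float] = DEFAULT_SENSITIVITY_LEVELS,
    sign: int = -1,
) -> pd.DataFrame:
    """Baseline-volume uncertainty analysis for one lesion.

    Re-simulates with the initial volume scaled by ``(1 + sign*level)``
    (decreases by default), gamma held at its fitted value, and reports
    ``pct_change_final = 100 |V_pert - V| / V``.  If the unperturbed
    final volume is not positive the absolute change in mm^3 is reported
    instead (``abs_change_mm3`` column, ``pct_change_final`` NaN).
    """
    base = final_reported_volume(record, params, gamma=gamma)
    rows = []
    for level in levels:
        if not (0 <= level < 1):
            raise ValueError(f"perturbation level must be in [0, 1), got {level}")
        scaled = record.with_(v_pre_cm3=record.v_pre_cm3 * (1.0 + sign * level))
        pert = final_reported_volume(scaled, params, gamma=gamma) if level else base
        rows.append(
            {
                "patient_id": record.patient_id,
                "lesion_index": record.lesion_index,
                "perturbation": level,
                "pct_change_final": 100.0 * abs(pert - base) / base
                if base > 0
                else np.nan,
                "abs_change_mm3": abs(pert - base),
            }
        )
    return pd.DataFrame(rows)


def sensitivity_cohort(
    records: Sequence[LesionRecord],
    calibrations: Sequence[CalibrationResult],
    params: PKPDParams,
    levels: Sequence[float] = DEFAULT_SENSITIVITY_LEVELS,
    sign: int = -1,
) -> pd.DataFrame:
    """One sensitivity row per (lesion, level), gamma from calibration."""
    by_key = {c.key: c for c in calibrations}
    frames = []
    for rec in records:
        cal = by_key.get(rec.key)
        if cal is None or not np.isfinite(cal.gamma_hat):
            raise ValueError(f"no usable calibration for lesion {rec.label}")
        frames.append(sensitivity_analysis(rec, params, cal.gamma_hat, levels, sign))
    return pd.concat(frames, ignore_index=True)


def sensitivity_quartiles(sens: pd.DataFrame) -> dict[str, dict[str, float]]:
    """Per-level 25th/50th/75th percentiles of the percent change (the
    numbers behind a box-plot summary)."""
    out: dict[str, dict[str, float]] = {}
    for level, group in sens.groupby("perturbation"):
        vals = group["pct_change_final"].dropna().to_numpy()
        q25, q50, q75 = np.percentile(vals, [25, 50, 75])
        out[f"{level:g}"] = {"q25": float(q25), "median": float(q50), "q75": float(q75)}
    return out


def outcomes_summary(
    records: Sequence[LesionRecord],
    calibrations: Sequence[CalibrationResult],
    params: PKPDParams,
    levels: Sequence[float] = DEFAULT_SENSITIVITY_LEVELS,
) -> dict:
    """JSON-ready summary: regimen means, response counts, regression,
    and sensitivity quartiles."""
    regression = measured_vs_simulated_regression(records, calibrations)
    sens = sensitivity_cohort(records, calibrations, params, levels)
    return {
        "regimen_means": regimen_efficacy(records),
        "response_counts": classify_responses(records),
        "regression": {
            "slope": regression.slope,
            "intercept": regression.intercept,
            "r": regression.r,
            "rmse": regression.rmse,
            "n": regression.n,
        },
        "sensitivity_quartiles": sensitivity_quartiles(sens),
    }
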