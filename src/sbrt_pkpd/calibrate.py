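"""Per-lesion calibration of the patient-response parameter gamma.

Each lesion contributes exactly one residual — the difference between the
simulated reported volume at the follow-up time and the measured post-RT
volume — because the clinical protocol provides exactly two CT
measurements per lesion.  The synergy sigma stays fixed at 8 throughout
(single-modality treatment), and all other coefficients keep their
defaults; gamma alone absorbs the patient-to-patient variability.

The fit is a deterministic bounded scalar minimisation: the squared
error is first scanned on a 32-point geometric grid over the gamma
bounds (guarding against flat or multimodal stretches), then refined by
bounded Brent iteration inside the bracketing interval to an absolute
gamma tolerance of 1e-5.  Lesions measured as no longer present
(v_post = 0) fit against a target of 0 mm^3; the optimizer pushes gamma
to the upper bound and ``bound_hit`` flags them for reporting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .cohort import LesionRecord
from .model import CM3_TO_MM3, PKPDParams, final_reported_volume

__all__ = [
    "CalibrationResult",
    "CalibrationError",
    "DEFAULT_GAMMA_BOUNDS",
    "GAMMA_TOL",
    "objective",
    "calibrate_lesion",
    "calibrate_cohort",
    "results_to_frame",
    "write_calibration_report",
    "load_gamma_file",
]

DEFAULT_GAMMA_BOUNDS = (1e-3, 1.0)
GAMMA_TOL = 1e-5
_GRID_SIZE = 32


class CalibrationError(RuntimeError):
    """Raised when a lesion's objective cannot be evaluated or bracketed."""


@dataclass(frozen=True)
class CalibrationResult:
    patient_id: str
    lesion_index: int
    gamma_hat: float
    objective_value: float  # (mm^3)^2
    v_sim_final: float  # cm^3
    converged: bool
    n_evaluations: int
    bound_hit: str  # "none" | "lower" | "upper"
    error: str | None = None

    @property
    def key(self) -> tuple[str, int]:
        return (self.patient_id, self.lesion_index)


def objective(
    gamma: float, record: LesionRecord, params: PKPDParams
) -> float:
    """Squared mismatch (mm^3)^2 between simulated and measured volume.

    Deterministic in its inputs; propagates simulation failures.
    """
    if not (gamma > 0):
        raise ValueError(f"gamma must be > 0, got {gamma}")
    v_sim = final_reported_volume(record, params, gamma=gamma)
    return (v_sim - record.v_post_cm3 * CM3_TO_MM3) ** 2


def calibrate_lesion(
    record: LesionRecord,
    params: PKPDParams,
    bounds: tuple[float, float] = DEFAULT_GAMMA_BOUNDS,
) -> CalibrationResult:
    """Fit gamma for one lesion by grid scan + bounded Brent refinement.

    Ties within the gamma tolerance resolve to the smallest gamma.
    Raises :class:`CalibrationError` if the objective is non-finite
    anywhere on the initial grid.
    """
    lo, hi = bounds
    if not (0 < lo < hi):
        raise ValueError(f"invalid gamma bounds {bounds}")
    n_eval = 0

    def f(g: float) -> float:
        nonlocal n_eval
        n_eval += 1
        return objective(g, record, params)

    grid = np.geomspace(lo, hi, _GRID_SIZE)
    grid_obj = np.array([f(g) for g in grid])
    if not np.all(np.isfinite(grid_obj)):
        bad = grid[~np.isfinite(grid_obj)]
        raise CalibrationError(
            f"{record.label}: non-finite objective at gamma={bad[0]:g}"
        )

    # refine inside the bracketing interval around the best grid point;
    # on a tie (flat stretch) start from the smallest tying gamma
    tol_tie = 1e-9 * (1.0 + grid_obj.min())
    best = int(np.flatnonzero(grid_obj <= grid_obj.min() + tol_tie)[0])
    b_lo = grid[max(best - 1, 0)]
    b_hi = grid[min(best + 1, _GRID_SIZE - 1)]
    res = minimize_scalar(
        f, bounds=(b_lo, b_hi), method="bounded", options={"xatol": GAMMA_TOL}
    )
    gamma_hat, obj_hat = float(res.x), float(res.fun)
    if grid_obj[best] < obj_hat:  # keep the grid point if refinement lost it
        gamma_hat, obj_hat = float(grid[best]), float(grid_obj[best])

    if gamma_hat - lo <= 10 * GAMMA_TOL:
        gamma_hat, bound_hit = lo, "lower"
    elif hi - gamma_hat <= 10 * GAMMA_TOL:
        gamma_hat, bound_hit = hi, "upper"
    else:
        bound_hit = "none"

    v_sim = final_reported_volume(record, params, gamma=gamma_hat)
    return CalibrationResult(
        patient_id=record.patient_id,
        lesion_index=record.lesion_index,
        gamma_hat=gamma_hat,
        objective_value=(v_sim - record.v_post_cm3 * CM3_TO_MM3) ** 2,
        v_sim_final=v_sim / CM3_TO_MM3,
        converged=bool(res.success),
        n_evaluations=n_eval,
        bound_hit=bound_hit,
    )


def calibrate_cohort(
    records: Sequence[LesionRecord],
    params: PKPDParams,
    bounds: tuple[float, float] = DEFAULT_GAMMA_BOUNDS,
) -> list[CalibrationResult]:
    """Independent per-lesion fits (multi-lesion patients are treated as
    separate single sites).  Per-record failures are collected into the
    result list (``converged=False``) rather than aborting the batch."""
    results = []
    for record in records:
        try:
            results.append(calibrate_lesion(record, params, bounds))
        except Exception as exc:  # noqa: BLE001 - collected per record
            results.append(
                CalibrationResult(
                    patient_id=record.patient_id,
                    lesion_index=record.lesion_index,
                    gamma_hat=math.nan,
                    objective_value=math.nan,
                    v_sim_final=math.nan,
                    converged=False,
                    n_evaluations=0,
                    bound_hit="none",
                    error=f"{type(exc).__name__}: {exc}",
                )
            )
    return results


def results_to_frame(
    results: Sequence[CalibrationResult],
    records: Sequence[LesionRecord] | None = None,
) -> pd.DataFrame:
    """Calibration report table (one row per lesion)."""
    by_key = {r.key: r for r in records} if records else {}
    rows = []
    for res in results:
        rec = by_key.get(res.key)
        rows.append(
            {
                "patient_id": res.patient_id,
                "lesion_index": res.lesion_index,
                "gamma_hat": res.gamma_hat,
                "v_pre_cm3": rec.v_pre_cm3 if rec else math.nan,
                "v_post_cm3": rec.v_post_cm3 if rec else math.nan,
                "v_sim_final_cm3": res.v_sim_final,
                "objective": res.objective_value,
                "converged": res.converged,
                "bound_hit": res.bound_hit,
            }
        )
    return pd.DataFrame(rows)


def write_calibration_report(
    results: Sequence[CalibrationResult],
    path: str | Path,
    records: Sequence[LesionRecord] | None = None,
) -> None:
    results_to_frame(results, records).to_csv(path, index=False)


def load_gamma_file(path: str | Path) -> dict[tuple[str, int], float]:
    """Read per-lesion gamma values from a calibration report (or any CSV
    with patient_id, lesion_index and a gamma/gamma_hat column)."""
    frame = pd.read_csv(path, dtype={"patient_id": str})
    col = "gamma_hat" if "gamma_hat" in frame.columns else "gamma"
    if col not in frame.columns:
        raise ValueError(f"{path}: no gamma_hat/gamma column")
    return {
        (str(row["patient_id"]), int(row["lesion_index"])): float(row[col])
        for _, row in frame.iterrows()
    }
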