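"""Tumour-growth PKPD model under fractionated radiotherapy.

State variables (volumes in mm^3, drug levels in dose units):

==========  =====================================================
``x1``      proliferating tumour volume
``x2``      necrotic tumour volume
``x3, xe3`` antiangiogenic level and its effect-site level (inert)
``x4, xe4`` immunotherapy level and its effect-site level (inert)
``x5, xe5`` radiotherapy level and its effect-site level
==========  =====================================================

Dynamics::

    x1' = (a - n) x1 - E x1
    x2' = n x1 + E x1 - lambda_w x2
    x5' = -c_r x5 + u_r(t) * gy_to_conc
    xe5' = -c_r xe5 + E_tr x5

with the antiangiogenic and immunotherapy branches structurally present
but driven by zero inputs (radiotherapy-only cohort).  The kill rate E
(1/day) couples tumour burden and the radiotherapy effect-site level
through a sigmoid interaction::

    U_nt = normalised tumour burden      (tumour / half-effect volume)
    U_nr = xe5 / C50r                    (effect-site dose rate / half-effect)
    I    = U_nt + U_nr + sigma * U_nr * U_nt
    E    = emax_rate * I^gamma / (1 + I^gamma)

``gamma`` is the per-patient response steepness (the calibrated
parameter); ``sigma`` the tumour-radiation synergy.  The reported volume
is by default the active volume ``delta_v = total - necrotic = x1``.

See ``docs/methods.md`` for the reasoning behind the ``emax_rate``
closure and the tumour-burden normalisation modes.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml
from scipy.integrate import solve_ivp

from .cohort import LesionRecord
from .dosing import DEFAULT_PULSE_WIDTH, DoseSchedule, build_schedule

__all__ = [
    "PKPDParams",
    "Trajectory",
    "IntegrationError",
    "STATE_NAMES",
    "normalized_dose",
    "normalized_tumor",
    "interaction_index",
    "hill_effect",
    "combined_effect",
    "rhs",
    "simulate",
    "final_reported_volume",
    "load_params",
    "save_params",
]

STATE_NAMES = ("x1", "x2", "x3", "xe3", "x4", "xe4", "x5", "xe5")

CM3_TO_MM3 = 1000.0


class IntegrationError(RuntimeError):
    """Raised when the ODE integrator fails to meet its tolerances."""


@dataclass(frozen=True)
class PKPDParams:
    """Model coefficients.

    Rates are per day.  ``cr=None`` selects the per-lesion rule
    c_r = 3 / treatment_duration; ``etr=None`` ties the effect-site
    transfer rate to c_r (unit steady-state gain of the effect
    compartment).  ``c50t`` is the half-effect tumour burden: an absolute
    volume in mm^3 in ``absolute`` mode, or a percentage of the lesion's
    own baseline in ``relative`` mode.  ``emax_rate`` is the maximal kill
    rate constant; its default is calibrated once so that, at the lowest
    reported patient response (gamma = 0.043), the therapy-free balance
    point of growth against the burden-driven kill sits at the reference
    cohort's median baseline volume (~1.2 cm^3), reproducing the observed
    stable-disease behaviour at low gamma.
    """

    a: float = 0.693  # tumour growth rate, 1/day
    n: float = 0.10  # necrosis rate, 1/day
    cr: float | None = None  # RT clearance, 1/day; None -> 3/treatment_duration
    ca: float = 0.0  # antiangiogenic clearance (branch inert)
    ci: float = 0.0  # immunotherapy clearance (branch inert)
    etr: float | None = None  # RT effect-site transfer; None -> cr
    eta: float | None = None  # None -> ca
    eti: float | None = None  # None -> ci
    c50r: float = 20.0  # half-effect RT level, Gy/day
    c50t: float = 50.0  # half-effect tumour burden (mm^3 or %, by mode)
    emax_rate: float = 1.10  # maximal kill rate, 1/day
    gamma: float = 0.1  # patient response (per lesion, calibrated)
    sigma: float = 8.0  # tumour-radiation synergy
    washout: float = 1.0  # necrotic clearance lambda_w, 1/day
    normalization_mode: str = "absolute"  # or "relative"
    reported_volume: str = "delta_v"  # or "total"
    gy_to_conc: float = 1.0  # Gy -> model concentration units
    pulse_width: float = DEFAULT_PULSE_WIDTH  # days
    rtol: float = 1e-8
    atol: float = 1e-8

    def __post_init__(self) -> None:
        for name in ("a", "n", "ca", "ci", "washout"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        for name in ("gamma", "c50r", "c50t", "emax_rate", "gy_to_conc", "pulse_width"):
            if not (getattr(self, name) > 0):
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")
        if self.cr is not None and self.cr < 0:
            raise ValueError(f"cr must be >= 0, got {self.cr}")
        if self.normalization_mode not in ("absolute", "relative"):
            raise ValueError(f"unknown normalization_mode {self.normalization_mode!r}")
        if self.reported_volume not in ("delta_v", "total"):
            raise ValueError(f"unknown reported_volume {self.reported_volume!r}")

    def with_(self, **changes) -> "PKPDParams":
        return replace(self, **changes)

    def resolve_cr(self, schedule: DoseSchedule | None) -> float:
        """Effective c_r for a lesion (per-lesion rule when ``cr`` unset)."""
        if self.cr is not None:
            return self.cr
        if schedule is None:
            raise ValueError("cr=None requires a dose schedule to derive 3/duration")
        return 3.0 / schedule.treatment_duration

    def resolve_etr(self, cr: float) -> float:
        return self.etr if self.etr is not None else cr


def normalized_dose(ur_level: float, c50r: float) -> float:
    """Radiotherapy effect-site level normalised to its half-effect value."""
    if not (c50r > 0):
        raise ValueError(f"c50r must be > 0, got {c50r}")
    if ur_level < 0:
        raise ValueError(f"dose level must be >= 0, got {ur_level}")
    return ur_level / c50r


def normalized_tumor(x1: float, x2: float, v0: float, params: PKPDParams) -> float:
    """Tumour burden normalised to its half-effect value.

    ``absolute`` mode (default): ``(x1 + x2) / c50t`` with ``c50t`` an
    absolute volume in mm^3.  ``relative`` mode: the burden as a
    percentage of the lesion's own baseline ``v0``, divided by ``c50t``
    in percent.  Relative mode makes the whole system scale-invariant in
    volume (final volume exactly proportional to the initial volume),
    which is why absolute mode is the default: measured outcomes respond
    sub-proportionally to baseline-volume perturbations.
    """
    if x1 < 0 or x2 < 0:
        raise ValueError("tumour volumes must be >= 0")
    total = x1 + x2
    if params.normalization_mode == "relative":
        if not (v0 > 0):
            raise ValueError(f"relative mode requires v0 > 0, got {v0}")
        return (100.0 * total / v0) / params.c50t
    return total / params.c50t


def interaction_index(unt: float, unr: float, sigma: float) -> float:
    """Combined tumour-dose interaction I = U_nt + U_nr + sigma U_nr U_nt."""
    return unt + unr + sigma * unr * unt


def hill_effect(i: float, gamma: float) -> float:
    """Sigmoid effect ``I^gamma / (1 + I^gamma)`` in [0, 1).

    Zero at I = 0, one half at I = 1 for any gamma, strictly increasing.
    """
    if i < 0:
        raise ValueError(f"interaction index must be >= 0, got {i}")
    if not (gamma > 0):
        raise ValueError(f"gamma must be > 0, got {gamma}")
    if i == 0.0:
        return 0.0
    # log-space guard against overflow for extreme I^gamma
    z = gamma * math.log(i)
    if z > 700:
        return 1.0
    p = math.exp(z)
    return p / (1.0 + p)


def combined_effect(unt: float, unr: float, params: PKPDParams) -> float:
    """Kill rate E (1/day), bounded by ``emax_rate``."""
    i = interaction_index(unt, unr, params.sigma)
    return params.emax_rate * hill_effect(i, params.gamma)


def rhs(
    t: float,
    state: Sequence[float],
    params: PKPDParams,
    schedule: DoseSchedule | None,
    v0: float,
    cr: float | None = None,
) -> np.ndarray:
    """Time derivative of the full 8-dimensional state.

    ``v0`` is the lesion's baseline volume in mm^3 (used only by the
    relative normalisation mode).  ``cr`` may be passed to pin the
    clearance rate; otherwise it is resolved from ``params``/``schedule``.
    """
    x1, x2, x3, xe3, x4, xe4, x5, xe5 = (max(float(s), 0.0) for s in state)
    cr_eff = cr if cr is not None else params.resolve_cr(schedule)
    etr = params.resolve_etr(cr_eff)
    eta = params.eta if params.eta is not None else params.ca
    eti = params.eti if params.eti is not None else params.ci
    ur = schedule.forcing(t) if schedule is not None else 0.0

    unr = normalized_dose(xe5, params.c50r)
    unt = normalized_tumor(x1, x2, v0, params)
    e = combined_effect(unt, unr, params)

    return np.array(
        [
            (params.a - params.n) * x1 - e * x1,
            params.n * x1 + e * x1 - params.washout * x2,
            -params.ca * x3,  # u_a(t) = 0 (branch inert)
            -params.ca * xe3 + eta * x3,
            -params.ci * x4,  # u_i(t) = 0 (branch inert)
            -params.ci * xe4 + eti * x4,
            -cr_eff * x5 + ur * params.gy_to_conc,
            -cr_eff * xe5 + etr * x5,
        ]
    )


@dataclass(frozen=True)
class Trajectory:
    """Time-indexed model states with derived volume series.

    ``states`` has one row per time point, columns ordered as
    :data:`STATE_NAMES`.  ``effect`` is the kill rate E(t) in 1/day.
    """

    times: np.ndarray
    states: np.ndarray
    effect: np.ndarray
    reported_volume: str = "delta_v"

    def __post_init__(self) -> None:
        if self.states.shape != (len(self.times), len(STATE_NAMES)):
            raise ValueError("states must be (n_times, 8)")

    @property
    def x1(self) -> np.ndarray:
        return self.states[:, 0]

    @property
    def x2(self) -> np.ndarray:
        return self.states[:, 1]

    @property
    def x5(self) -> np.ndarray:
        return self.states[:, 6]

    @property
    def xe5(self) -> np.ndarray:
        return self.states[:, 7]

    @property
    def total_volume(self) -> np.ndarray:
        """Total tumour volume x1 + x2 (mm^3)."""
        return self.x1 + self.x2

    @property
    def delta_v(self) -> np.ndarray:
        """Active volume: total minus necrotic (mm^3)."""
        return self.total_volume - self.x2

    @property
    def reported(self) -> np.ndarray:
        """The volume series selected for comparison with measurements."""
        return self.total_volume if self.reported_volume == "total" else self.delta_v

    @property
    def final_reported(self) -> float:
        return float(self.reported[-1])

    def to_frame(self):
        """Trajectory as a DataFrame in the export-CSV column layout."""
        import pandas as pd

        return pd.DataFrame(
            {
                "t_days": self.times,
                "x1_mm3": self.x1,
                "x2_mm3": self.x2,
                "x5": self.x5,
                "xe5": self.xe5,
                "total_mm3": self.total_volume,
                "delta_v_mm3": self.delta_v,
                "effect_per_day": self.effect,
            }
        )


def _integrate(
    v0_mm3: float,
    schedule: DoseSchedule | None,
    params: PKPDParams,
    t_final: float,
    t_eval: np.ndarray,
    context: str = "",
) -> Trajectory:
    """Integrate the radiotherapy subsystem piecewise between forcing
    breakpoints (the forcing is constant inside each segment, so the
    adaptive Runge-Kutta scheme sees a smooth problem throughout)."""
    cr = params.resolve_cr(schedule) if schedule is not None else (params.cr or 0.0)
    etr = params.resolve_etr(cr)
    a, n, lam_w = params.a, params.n, params.washout
    c50r, c50t, sigma, gamma = params.c50r, params.c50t, params.sigma, params.gamma
    emax, g2c = params.emax_rate, params.gy_to_conc
    relative = params.normalization_mode == "relative"
    unt_scale = (100.0 / (v0_mm3 * c50t)) if relative else (1.0 / c50t)

    def make_rhs(ur: float):
        def f(t, y):
            x1 = y[0] if y[0] > 0 else 0.0
            x2 = y[1] if y[1] > 0 else 0.0
            x5 = y[2] if y[2] > 0 else 0.0
            xe5 = y[3] if y[3] > 0 else 0.0
            unr = xe5 / c50r
            unt = (x1 + x2) * unt_scale
            i = unt + unr + sigma * unr * unt
            if i <= 0.0:
                e = 0.0
            else:
                z = gamma * math.log(i)
                p = math.exp(z) if z < 700 else math.inf
                e = emax * (1.0 if p == math.inf else p / (1.0 + p))
            kill = e * x1
            return (
                (a - n) * x1 - kill,
                n * x1 + kill - lam_w * x2,
                -cr * x5 + ur * g2c,
                -cr * xe5 + etr * x5,
            )

        return f

    breaks = (
        schedule.breakpoints(t_final)
        if schedule is not None
        else np.array([0.0, float(t_final)])
    )
    t_eval = np.asarray(t_eval, dtype=float)
    if t_eval[0] < 0 or t_eval[-1] > t_final + 1e-12:
        raise ValueError("output grid must lie within [0, followup]")

    y = np.array([v0_mm3, 0.0, 0.0, 0.0])
    out_t: list[float] = []
    out_y: list[np.ndarray] = []
    if t_eval[0] == 0.0:
        out_t.append(0.0)
        out_y.append(y.copy())

    for t0, t1 in zip(breaks[:-1], breaks[1:]):
        ur = schedule.forcing((t0 + t1) / 2.0) if schedule is not None else 0.0
        seg_eval = t_eval[(t_eval > t0) & (t_eval <= t1)]
        # always land exactly on the segment end to hand off the state
        eval_pts = np.unique(np.append(seg_eval, t1))
        sol = solve_ivp(
            make_rhs(ur),
            (t0, t1),
            y,
            method="RK45",
            rtol=params.rtol,
            atol=params.atol,
            max_step=params.pulse_width / 5.0 if ur > 0 else np.inf,
            t_eval=eval_pts,
        )
        if not sol.success:
            raise IntegrationError(
                f"integration failed{' for ' + context if context else ''} "
                f"on [{t0:g}, {t1:g}] d: {sol.message}"
            )
        y = sol.y[:, -1].copy()
        requested = np.isin(sol.t, seg_eval)
        for tk, yk in zip(sol.t[requested], sol.y[:, requested].T):
            out_t.append(float(tk))
            out_y.append(yk.copy())

    times = np.array(out_t)
    ys = np.array(out_y)  # (n, 4): x1, x2, x5, xe5
    # tolerate and clip the integrator's tiny negative excursions
    scale = max(v0_mm3, 1.0)
    if ys.min() < -1e-6 * scale:
        raise IntegrationError(
            f"state went negative beyond tolerance ({ys.min():.3g} mm^3)"
            f"{' for ' + context if context else ''}"
        )
    ys = np.clip(ys, 0.0, None)

    states = np.zeros((len(times), len(STATE_NAMES)))
    states[:, 0] = ys[:, 0]
    states[:, 1] = ys[:, 1]
    states[:, 6] = ys[:, 2]
    states[:, 7] = ys[:, 3]

    unr = ys[:, 3] / c50r
    unt = (ys[:, 0] + ys[:, 1]) * unt_scale
    i_idx = unt + unr + sigma * unr * unt
    p = np.zeros_like(i_idx)
    mask = i_idx > 0
    p[mask] = np.power(i_idx[mask], gamma)
    effect = emax * p / (1.0 + p)

    return Trajectory(
        times=times,
        states=states,
        effect=effect,
        reported_volume=params.reported_volume,
    )


def simulate(
    record: LesionRecord,
    params: PKPDParams,
    output_grid: np.ndarray | None = None,
) -> Trajectory:
    """Simulate one lesion from treatment start to its follow-up CT.

    Initial condition: ``x1(0) = v_pre * 1000`` mm^3, all other states
    zero.  ``output_grid`` (days) defaults to a daily grid over
    ``[0, followup_days]`` refined during the treatment window.
    """
    schedule = build_schedule(record, params.pulse_width)
    t_final = float(record.followup_days)
    if output_grid is None:
        daily = np.linspace(0.0, t_final, int(round(t_final)) + 1)
        fine = np.arange(0.0, min(schedule.pulse_starts[-1] + 2.0, t_final), 0.05)
        output_grid = np.unique(np.concatenate([daily, fine, [t_final]]))
    else:
        output_grid = np.unique(np.asarray(output_grid, dtype=float))
    return _integrate(
        record.v_pre_cm3 * CM3_TO_MM3,
        schedule,
        params,
        t_final,
        output_grid,
        context=record.label,
    )


def final_reported_volume(
    record: LesionRecord, params: PKPDParams, gamma: float | None = None
) -> float:
    """Reported volume (mm^3) at the follow-up time, optionally overriding
    gamma.  Fast path used by the calibration objective."""
    if gamma is not None:
        params = params.with_(gamma=gamma)
    traj = simulate(record, params, output_grid=np.array([record.followup_days], dtype=float))
    return traj.final_reported


def save_params(params: PKPDParams, path: str | Path) -> None:
    """Write parameters as a flat YAML mapping keyed by field name."""
    data = asdict(params)
    Path(path).write_text(yaml.safe_dump(data, sort_keys=True))


def load_params(path: str | Path, base: PKPDParams | None = None) -> PKPDParams:
    """Read a flat YAML parameter file; unspecified keys keep defaults."""
    data = yaml.safe_load(Path(path).read_text()) or {}
    known = set(PKPDParams.__dataclass_fields__)
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown parameter key(s): {', '.join(sorted(unknown))}")
    base = base if base is not None else PKPDParams()
    return base.with_(**data)
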