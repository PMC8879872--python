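"""Radiotherapy forcing schedules.

Each fraction is delivered as a rectangular dose-rate pulse: a pulse of
width ``pulse_width`` days (default 0.1) starting at the beginning of its
treatment day, with height ``dose_per_pulse / pulse_width`` Gy/day.  The
finite dose rate keeps the ODE system non-stiff while making the
delivered-dose integral exact: the forcing integrates to the prescribed
total dose by construction.

Elapsed simulation time starts at the first treatment day (t = 0), so a
lesion treated on calendar days 1-3-6 has pulses starting at t = 0, 2, 5.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cohort import LesionRecord

__all__ = ["DoseSchedule", "ScheduleError", "build_schedule"]

DEFAULT_PULSE_WIDTH = 0.1  # days


class ScheduleError(ValueError):
    """Raised for an unrealisable dosing schedule."""


@dataclass(frozen=True)
class DoseSchedule:
    """Piecewise-constant radiotherapy dose-rate u_r(t).

    ``pulse_starts`` are elapsed days (first pulse at 0); all pulses share
    the same width and dose.  ``treatment_duration`` is the span from the
    first to the last fraction day, inclusive, in days — the denominator
    of the per-lesion clearance rate c_r = 3 / treatment_duration.
    """

    pulse_starts: tuple[float, ...]
    pulse_width: float
    fraction_dose: float  # Gy per pulse
    treatment_duration: float  # days

    @property
    def n_pulses(self) -> int:
        return len(self.pulse_starts)

    @property
    def total_dose(self) -> float:
        """Total delivered dose in Gy (sum of per-pulse doses)."""
        return self.fraction_dose * self.n_pulses

    @property
    def dose_rate_during_pulse(self) -> float:
        """Gy/day while a pulse is on."""
        return self.fraction_dose / self.pulse_width

    def forcing(self, t: float) -> float:
        """Dose rate u_r(t) in Gy/day at elapsed time ``t``."""
        rate = self.dose_rate_during_pulse
        for start in self.pulse_starts:
            if start <= t < start + self.pulse_width:
                return rate
        return 0.0

    def breakpoints(self, t_final: float) -> np.ndarray:
        """Sorted switching times of the forcing within ``[0, t_final]``."""
        pts = {0.0, float(t_final)}
        for start in self.pulse_starts:
            if start < t_final:
                pts.add(float(start))
            end = start + self.pulse_width
            if end < t_final:
                pts.add(float(end))
        return np.array(sorted(pts))

    def delivered_dose(self, t: float) -> float:
        """Cumulative dose integral of the forcing over ``[0, t]`` (Gy)."""
        rate = self.dose_rate_during_pulse
        total = 0.0
        for start in self.pulse_starts:
            overlap = min(t, start + self.pulse_width) - max(0.0, start)
            if overlap > 0:
                total += rate * overlap
        return total


def build_schedule(
    record: LesionRecord, pulse_width: float = DEFAULT_PULSE_WIDTH
) -> DoseSchedule:
    """Derive the dose-rate forcing for one lesion from its day list.

    One pulse per listed treatment day; the per-pulse dose is
    ``total_dose / n_pulses`` so the delivered dose always equals the
    prescribed total dose, even for records whose printed day list and
    fraction count disagree (the schedule follows the day list).

    Raises
    ------
    ScheduleError
        If ``pulse_width`` is non-positive, a full day or longer, or not
        smaller than the minimal inter-fraction gap (overlapping pulses).
    """
    if not (pulse_width > 0):
        raise ScheduleError(f"pulse_width must be > 0, got {pulse_width}")
    if pulse_width >= 1.0:
        raise ScheduleError(f"pulse_width must be < 1 day, got {pulse_width}")

    days = record.treatment_days
    starts = tuple(float(d - days[0]) for d in days)
    gaps = [b - a for a, b in zip(starts, starts[1:])]
    if gaps and pulse_width >= min(gaps):
        raise ScheduleError(
            f"{record.label}: pulse_width {pulse_width} d >= minimal "
            f"inter-fraction gap {min(gaps)} d; pulses would overlap"
        )
    return DoseSchedule(
        pulse_starts=starts,
        pulse_width=float(pulse_width),
        fraction_dose=record.total_dose_gy / len(starts),
        treatment_duration=float(days[-1] - days[0] + 1),
    )
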