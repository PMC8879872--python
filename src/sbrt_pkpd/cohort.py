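"""Lesion-level cohort tables: reading, validation, and writing.

A cohort is a flat CSV with one row per treated lesion.  Volumes are in
cm^3 (as a radiation oncologist would report them from CT); the model core
works in mm^3 and the conversion happens at the cohort -> simulation
boundary (see :mod:`sbrt_pkpd.model`).

The package ships a reference cohort of 23 lesions from 19 patients with
NSCLC treated with four hypofractionated SBRT regimens (1x34 Gy, 3x18 Gy,
4x12 Gy, 8x7.5 Gy).  Load it with ``load_cohort("bundled")``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "LesionRecord",
    "CohortValidationError",
    "load_cohort",
    "write_cohort",
    "bundled_cohort_path",
    "COHORT_COLUMNS",
]

#: Column order of the cohort CSV dialect.
COHORT_COLUMNS = [
    "patient_id",
    "lesion_index",
    "total_dose_gy",
    "n_fractions",
    "treatment_days",
    "followup_days",
    "v_pre_cm3",
    "v_post_cm3",
    "not_measurable",
    "in_regimen_stats",
    "mld_gy",
    "tlv_cm3",
    "v5_pct",
    "v20_pct",
]


class CohortValidationError(ValueError):
    """Raised when a cohort file or record violates the cohort contract.

    The message always names the offending row (patient id / lesion index
    or file row number) and field so batch ingestion failures are
    actionable.
    """


@dataclass(frozen=True)
class LesionRecord:
    """One treated lesion with its dosing scheme and the two CT volumes.

    ``treatment_days`` are 1-based calendar-day indices as prescribed
    (e.g. ``(1, 3, 6)`` for three fractions over six days);
    ``followup_days`` is the interval between the planning CT and the
    follow-up CT.  ``v_post_cm3 == 0`` encodes a lesion that was no longer
    measurable at follow-up; ``not_measurable`` marks the subset where the
    clinicians explicitly attributed this to a radiation-pneumonitis field
    with no detectable nodule.

    ``in_regimen_stats`` controls whether the lesion counts toward
    per-regimen efficacy averages (two reference-cohort lesions are
    excluded from that accounting; see :mod:`sbrt_pkpd.outcomes`).

    The dose-volume-histogram fields (``mld_gy``, ``tlv_cm3``, ``v5_pct``,
    ``v20_pct``) are carried through for reporting only and never enter
    any computation.
    """

    patient_id: str
    lesion_index: int
    total_dose_gy: float
    n_fractions: int
    treatment_days: tuple[int, ...]
    followup_days: float
    v_pre_cm3: float
    v_post_cm3: float
    not_measurable: bool = False
    in_regimen_stats: bool = True
    mld_gy: float = math.nan
    tlv_cm3: float = math.nan
    v5_pct: float = math.nan
    v20_pct: float = math.nan

    def __eq__(self, other) -> bool:
        # NaN-tolerant equality so records with unrecorded DVH fields
        # still satisfy the write -> load round-trip identity.
        if not isinstance(other, LesionRecord):
            return NotImplemented
        for name in self.__dataclass_fields__:
            a, b = getattr(self, name), getattr(other, name)
            if isinstance(a, float) and isinstance(b, float):
                if not (a == b or (math.isnan(a) and math.isnan(b))):
                    return False
            elif a != b:
                return False
        return True

    def __hash__(self) -> int:
        return hash((self.patient_id, self.lesion_index))

    @property
    def key(self) -> tuple[str, int]:
        return (self.patient_id, self.lesion_index)

    @property
    def label(self) -> str:
        return f"{self.patient_id}-les.{self.lesion_index}"

    @property
    def regimen(self) -> str:
        """Regimen label, e.g. ``"54 Gy/3"`` for 3 x 18 Gy."""
        return f"{self.total_dose_gy:g} Gy/{self.n_fractions}"

    @property
    def treatment_duration_days(self) -> int:
        """Span from first to last fraction, inclusive (>= 1)."""
        return self.treatment_days[-1] - self.treatment_days[0] + 1

    def validate(self, strict: bool = True) -> None:
        """Check record invariants; raise :class:`CohortValidationError`.

        With ``strict=False`` the fraction-count / day-list consistency
        check is skipped.  The reference cohort prints two rows (patient
        020) whose day list and fraction count disagree as published;
        they are bundled verbatim rather than silently corrected, so the
        bundled loader uses the relaxed mode.
        """
        ctx = self.label

        def fail(field_name: str, msg: str) -> None:
            raise CohortValidationError(f"{ctx}: field '{field_name}': {msg}")

        if not self.patient_id:
            fail("patient_id", "must be non-empty")
        if self.lesion_index < 1:
            fail("lesion_index", "must be a positive 1-based index")
        if not (self.total_dose_gy > 0):
            fail("total_dose_gy", f"must be > 0, got {self.total_dose_gy}")
        if self.n_fractions < 1:
            fail("n_fractions", f"must be >= 1, got {self.n_fractions}")
        if len(self.treatment_days) == 0:
            fail("treatment_days", "must list at least one treatment day")
        if any(d < 1 for d in self.treatment_days):
            fail("treatment_days", "day indices are 1-based, got a value < 1")
        if any(b <= a for a, b in zip(self.treatment_days, self.treatment_days[1:])):
            fail("treatment_days", f"must be strictly increasing, got {self.treatment_days}")
        if strict and len(self.treatment_days) != self.n_fractions:
            fail(
                "treatment_days",
                f"{len(self.treatment_days)} treatment days listed for "
                f"{self.n_fractions} fractions",
            )
        if not (self.followup_days > 0):
            fail("followup_days", f"must be > 0, got {self.followup_days}")
        if self.treatment_days[-1] > self.followup_days:
            fail(
                "treatment_days",
                f"last treatment day {self.treatment_days[-1]} exceeds "
                f"follow-up interval {self.followup_days}",
            )
        if not (self.v_pre_cm3 > 0):
            fail("v_pre_cm3", f"must be > 0, got {self.v_pre_cm3}")
        if self.v_post_cm3 < 0:
            fail("v_post_cm3", f"must be >= 0, got {self.v_post_cm3}")

    def with_(self, **changes) -> "LesionRecord":
        """Return a copy with the given fields replaced (no validation)."""
        return replace(self, **changes)


def bundled_cohort_path() -> Path:
    """Filesystem path of the bundled reference cohort CSV."""
    return Path(resources.files("sbrt_pkpd").joinpath("data/cohort_table2.csv"))


def _parse_bool(value, row: str, col: str) -> bool:
    if isinstance(value, bool):
        return value
    text = str(value).strip().lower()
    if text in {"true", "1", "yes"}:
        return True
    if text in {"false", "0", "no"}:
        return False
    raise CohortValidationError(f"{row}: field '{col}': not a boolean: {value!r}")


def _parse_days(value, row: str) -> tuple[int, ...]:
    try:
        return tuple(int(tok) for tok in str(value).strip().split("-"))
    except ValueError:
        raise CohortValidationError(
            f"{row}: field 'treatment_days': expected hyphen-separated "
            f"integers like '1-3-6', got {value!r}"
        ) from None


def _parse_float(value, row: str, col: str, *, optional: bool = False) -> float:
    if optional and (value is None or (isinstance(value, float) and math.isnan(value)) or str(value).strip() == ""):
        return math.nan
    try:
        return float(value)
    except (TypeError, ValueError):
        raise CohortValidationError(f"{row}: field '{col}': not numeric: {value!r}") from None


def load_cohort(path: str | Path, strict: bool | None = None) -> list[LesionRecord]:
    """Read a cohort CSV into validated :class:`LesionRecord` objects.

    Parameters
    ----------
    path
        A filesystem path, or the token ``"bundled"`` for the packaged
        reference cohort.
    strict
        Enforce the fraction-count / day-list consistency invariant.
        Defaults to ``True`` for user files and ``False`` for the bundled
        cohort (which reproduces its source table verbatim, including two
        rows printed with swapped day lists).

    Raises
    ------
    CohortValidationError
        On a missing column, an unparseable value, or an invariant
        violation; no partial cohort is returned.
    """
    if str(path) == "bundled":
        path = bundled_cohort_path()
        if strict is None:
            strict = False
    if strict is None:
        strict = True

    try:
        frame = pd.read_csv(path, dtype={"patient_id": str}, float_precision="round_trip")
    except pd.errors.EmptyDataError:
        raise CohortValidationError(f"{path}: empty file, not a cohort CSV") from None

    missing = [c for c in COHORT_COLUMNS if c not in frame.columns]
    if missing:
        raise CohortValidationError(f"{path}: missing column(s): {', '.join(missing)}")

    records: list[LesionRecord] = []
    for i, raw in frame.iterrows():
        row = f"row {i + 2} ({raw['patient_id']}-les.{raw['lesion_index']})"
        record = LesionRecord(
            patient_id=str(raw["patient_id"]).strip(),
            lesion_index=int(_parse_float(raw["lesion_index"], row, "lesion_index")),
            total_dose_gy=_parse_float(raw["total_dose_gy"], row, "total_dose_gy"),
            n_fractions=int(_parse_float(raw["n_fractions"], row, "n_fractions")),
            treatment_days=_parse_days(raw["treatment_days"], row),
            followup_days=_parse_float(raw["followup_days"], row, "followup_days"),
            v_pre_cm3=_parse_float(raw["v_pre_cm3"], row, "v_pre_cm3"),
            v_post_cm3=_parse_float(raw["v_post_cm3"], row, "v_post_cm3"),
            not_measurable=_parse_bool(raw["not_measurable"], row, "not_measurable"),
            in_regimen_stats=_parse_bool(raw["in_regimen_stats"], row, "in_regimen_stats"),
            mld_gy=_parse_float(raw["mld_gy"], row, "mld_gy", optional=True),
            tlv_cm3=_parse_float(raw["tlv_cm3"], row, "tlv_cm3", optional=True),
            v5_pct=_parse_float(raw["v5_pct"], row, "v5_pct", optional=True),
            v20_pct=_parse_float(raw["v20_pct"], row, "v20_pct", optional=True),
        )
        record.validate(strict=strict)
        records.append(record)
    return records


def _fmt(x: float) -> str:
    if isinstance(x, float) and math.isnan(x):
        return ""
    return f"{x:g}"


def write_cohort(records: Iterable[LesionRecord], path: str | Path) -> None:
    """Write records as a cohort CSV that round-trips through
    :func:`load_cohort`.  An empty record list yields a header-only file."""
    rows = []
    for rec in records:
        rows.append(
            {
                "patient_id": rec.patient_id,
                "lesion_index": rec.lesion_index,
                "total_dose_gy": _fmt(rec.total_dose_gy),
                "n_fractions": rec.n_fractions,
                "treatment_days": "-".join(str(d) for d in rec.treatment_days),
                "followup_days": _fmt(rec.followup_days),
                "v_pre_cm3": repr(rec.v_pre_cm3),
                "v_post_cm3": repr(rec.v_post_cm3),
                "not_measurable": "true" if rec.not_measurable else "false",
                "in_regimen_stats": "true" if rec.in_regimen_stats else "false",
                "mld_gy": _fmt(rec.mld_gy),
                "tlv_cm3": _fmt(rec.tlv_cm3),
                "v5_pct": _fmt(rec.v5_pct),
                "v20_pct": _fmt(rec.v20_pct),
            }
        )
    frame = pd.DataFrame(rows, columns=COHORT_COLUMNS)
    frame.to_csv(path, index=False)
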