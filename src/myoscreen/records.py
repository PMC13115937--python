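"""Per-subject ocular record container and tabular conversions.

A :class:`SubjectRecord` holds one child's demographics, visual acuity and
ocular biometry in the units the screening rules expect (age in completed
years, refraction in diopters, AL/CR in millimetres).  Cohorts move through
the package as pandas DataFrames in the :data:`COHORT_COLUMNS` schema; the
record class is the validated single-subject view.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = ["SubjectRecord", "COHORT_COLUMNS", "records_to_frame", "frame_to_records"]

#: Canonical CSV / DataFrame column order for cohorts.
COHORT_COLUMNS = [
    "id",
    "age",
    "sex",
    "acuity_logmar",
    "sphere_d",
    "cylinder_d",
    "se_d",
    "al_mm",
    "cr_mm",
    "dilated",
]

_SE_TOL = 1e-9


class RecordValidationError(ValueError):
    """A subject record violates a structural invariant; names the field."""


def _finite(x) -> bool:
    return x is not None and not (isinstance(x, float) and not math.isfinite(x))


@dataclass(frozen=True)
class SubjectRecord:
    """One child's screening measurements.

    Parameters
    ----------
    subject_id : opaque identifier (any string).
    age : completed years; the rules support 6–12.
    sex : 0 = male, 1 = female.
    acuity : logMAR visual acuity (lower is better).
    sphere, cylinder : diopters; optional when ``se`` is supplied directly.
    se : spherical equivalent, D (sphere + cylinder / 2).
    al : axial length, mm.
    cr : corneal radius of curvature, mm.
    al_cr : AL/CR ratio; derived from ``al`` and ``cr`` when omitted.
    dilated : True if the refraction was cycloplegic.
    """

    subject_id: str
    age: float
    sex: int
    acuity: float
    se: float
    al: float
    cr: float
    sphere: float | None = None
    cylinder: float | None = None
    al_cr: float | None = None
    dilated: bool = False

    def __post_init__(self) -> None:
        if not _finite(self.age):
            raise RecordValidationError("age: missing or non-finite")
        if self.sex not in (0, 1):
            raise RecordValidationError(f"sex: expected 0 (male) or 1 (female), got {self.sex!r}")
        if not _finite(self.se):
            raise RecordValidationError("se: missing or non-finite")
        for name in ("al", "cr"):
            value = getattr(self, name)
            if not _finite(value):
                raise RecordValidationError(f"{name}: missing or non-finite")
            if value <= 0:
                raise RecordValidationError(f"{name}: must be positive, got {value!r}")
        if self.sphere is not None and self.cylinder is not None:
            implied = self.sphere + self.cylinder / 2.0
            if abs(implied - self.se) > _SE_TOL:
                raise RecordValidationError(
                    f"se: {self.se} inconsistent with sphere + cylinder/2 = {implied}"
                )
        if self.al_cr is None:
            object.__setattr__(self, "al_cr", self.al / self.cr)
        elif abs(self.al_cr - self.al / self.cr) > 1e-9:
            raise RecordValidationError(
                f"al_cr: {self.al_cr} inconsistent with al/cr = {self.al / self.cr}"
            )

    def with_se(self, se: float) -> "SubjectRecord":
        """Copy of this record with a different spherical equivalent."""
        return replace(self, se=se, sphere=None, cylinder=None)


def records_to_frame(records: Iterable[SubjectRecord]) -> pd.DataFrame:
    """Stack records into the canonical cohort DataFrame."""
    rows = [
        (
            r.subject_id,
            r.age,
            r.sex,
            r.acuity,
            np.nan if r.sphere is None else r.sphere,
            np.nan if r.cylinder is None else r.cylinder,
            r.se,
            r.al,
            r.cr,
            r.dilated,
        )
        for r in records
    ]
    return pd.DataFrame(rows, columns=COHORT_COLUMNS)


def frame_to_records(frame: pd.DataFrame) -> list[SubjectRecord]:
    """Validate each cohort row into a :class:`SubjectRecord`."""
    records = []
    for row in frame.itertuples(index=False):
        sphere = getattr(row, "sphere_d", np.nan)
        cylinder = getattr(row, "cylinder_d", np.nan)
        records.append(
            SubjectRecord(
                subject_id=str(row.id),
                age=row.age,
                sex=int(row.sex),
                acuity=row.acuity_logmar,
                sphere=None if pd.isna(sphere) else float(sphere),
                cylinder=None if pd.isna(cylinder) else float(cylinder),
                se=row.se_d,
                al=row.al_mm,
                cr=row.cr_mm,
                dilated=bool(row.dilated),
            )
        )
    return records
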