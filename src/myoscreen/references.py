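"""Age-specific clinical reference values for pediatric ocular biometry.

Guideline consensus documents for Chinese school-aged children publish
age-indexed reference intervals for three quantities that anchor the
screening rules:

* the *hyperopia reserve* — the residual physiological farsightedness a
  child of a given age is expected to retain (diopters); its upper bound
  separates hyperopia from the pre-myopic band;
* the *axial length* (AL) of the globe (mm); its age maximum flags
  structurally elongated eyes;
* the *corneal radius of curvature* (CR, mm), used both for plausibility
  checks and for the AL/CR ratio.

The tables are shipped as versioned CSV files inside the package so that a
guideline revision is a one-file edit, and cover completed ages 6–12
(the source consensus prints rows for these ages only; requests outside
that range are refused rather than extrapolated).  The AL/CR structural
risk threshold is 3.00, the consensus diagnostic cut.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping

import pandas as pd

__all__ = [
    "AGE_MIN",
    "AGE_MAX",
    "AL_CR_THRESHOLD",
    "ReserveInterval",
    "AxialReference",
    "CornealReference",
    "ReferenceTables",
    "build_reference_tables",
]

AGE_MIN = 6
AGE_MAX = 12

#: Diagnostic cut on the axial-length / corneal-radius ratio (dimensionless).
AL_CR_THRESHOLD = 3.00


class AgeOutOfRangeError(ValueError):
    """Raised when a reference lookup is requested outside ages 6–12."""


@dataclass(frozen=True)
class ReserveInterval:
    """Hyperopia-reserve reference row for one completed year of age."""

    age: int
    mean: float   # D
    lower: float  # D
    upper: float  # D

    def __post_init__(self) -> None:
        if not (self.lower <= self.mean <= self.upper):
            raise ValueError(
                f"reserve interval for age {self.age} violates "
                f"lower <= mean <= upper: ({self.lower}, {self.mean}, {self.upper})"
            )


@dataclass(frozen=True)
class AxialReference:
    """Axial-length reference row (mm) for one completed year of age."""

    age: int
    al_min: float
    al_max: float
    al_mean: float

    def __post_init__(self) -> None:
        if not (self.al_min < self.al_mean < self.al_max):
            raise ValueError(
                f"axial reference for age {self.age} violates min < mean < max"
            )


@dataclass(frozen=True)
class CornealReference:
    """Corneal-curvature-radius reference row (mm) for one completed year of age."""

    age: int
    cr_min: float
    cr_max: float
    cr_mean: float

    def __post_init__(self) -> None:
        if not (self.cr_min < self.cr_mean < self.cr_max):
            raise ValueError(
                f"corneal reference for age {self.age} violates min < mean < max"
            )


def _coerce_age(age: float, *, rounding: str) -> int:
    """Map a possibly fractional age to a table row age.

    ``rounding='floor'`` (the default everywhere) truncates to the completed
    year, matching how ages written as ``"6/0"`` (years/months) are parsed;
    ``'nearest'`` rounds half away from zero.
    """
    import math

    if rounding == "floor":
        key = math.floor(age)
    elif rounding == "nearest":
        key = math.floor(age + 0.5)
    else:
        raise ValueError(f"unknown age rounding {rounding!r}")
    return int(key)


@dataclass(frozen=True)
class ReferenceTables:
    """Bundle of the three age-indexed guideline tables plus the AL/CR cut.

    Instances are built by :func:`build_reference_tables`; lookups floor
    fractional ages to the completed year by default and raise
    :class:`AgeOutOfRangeError` outside ages 6–12.
    """

    reserves: Mapping[int, ReserveInterval]
    axial: Mapping[int, AxialReference]
    corneal: Mapping[int, CornealReference]
    al_cr_threshold: float = AL_CR_THRESHOLD
    age_rounding: str = field(default="floor")

    def __post_init__(self) -> None:
        expected = set(range(AGE_MIN, AGE_MAX + 1))
        for name, table in (
            ("reserves", self.reserves),
            ("axial", self.axial),
            ("corneal", self.corneal),
        ):
            if set(table) != expected:
                raise ValueError(
                    f"{name} table must cover ages {AGE_MIN}..{AGE_MAX} exactly; "
                    f"got {sorted(table)}"
                )

    def _row(self, table: Mapping[int, object], age: float):
        key = _coerce_age(age, rounding=self.age_rounding)
        if key not in table:
            raise AgeOutOfRangeError(
                f"age {age!r} outside supported reference range "
                f"{AGE_MIN}-{AGE_MAX} years"
            )
        return table[key]

    def hyperopia_reserve(self, age: float) -> ReserveInterval:
        """Hyperopia-reserve interval (D) for ``age`` completed years."""
        return self._row(self.reserves, age)

    def al_reference(self, age: float) -> AxialReference:
        """Axial-length reference (mm) for ``age`` completed years."""
        return self._row(self.axial, age)

    def cr_reference(self, age: float) -> CornealReference:
        """Corneal-radius reference (mm) for ``age`` completed years."""
        return self._row(self.corneal, age)

    # --- serialization -------------------------------------------------

    def to_frames(self) -> dict[str, pd.DataFrame]:
        """Return the three tables as DataFrames in the packaged CSV schema."""
        reserves = pd.DataFrame(
            [(r.age, r.mean, r.lower, r.upper) for r in self.reserves.values()],
            columns=["age", "mean_d", "lower_d", "upper_d"],
        )
        axial = pd.DataFrame(
            [(r.age, r.al_min, r.al_max, r.al_mean) for r in self.axial.values()],
            columns=["age", "al_min_mm", "al_max_mm", "al_mean_mm"],
        )
        corneal = pd.DataFrame(
            [(r.age, r.cr_min, r.cr_max, r.cr_mean) for r in self.corneal.values()],
            columns=["age", "cr_min_mm", "cr_max_mm", "cr_mean_mm"],
        )
        return {
            "hyperopia_reserve": reserves.sort_values("age", ignore_index=True),
            "axial_length": axial.sort_values("age", ignore_index=True),
            "corneal_radius": corneal.sort_values("age", ignore_index=True),
        }

    def to_csv_dir(self, directory: str | Path) -> None:
        """Write the three tables as CSVs (same schema as the packaged files)."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for name, frame in self.to_frames().items():
            frame.to_csv(directory / f"{name}.csv", index=False)


def _read_packaged_csv(name: str) -> pd.DataFrame:
    with resources.files("myoscreen.data").joinpath(name).open("r") as fh:
        return pd.read_csv(fh)


def build_reference_tables(
    data_dir: str | Path | None = None, *, age_rounding: str = "floor"
) -> ReferenceTables:
    """Load the guideline reference tables.

    Parameters
    ----------
    data_dir
        Optional directory containing ``hyperopia_reserve.csv``,
        ``axial_length.csv`` and ``corneal_radius.csv`` in the packaged
        schema; by default the CSVs shipped inside the package are used.
    age_rounding
        ``'floor'`` (default) or ``'nearest'``; how fractional ages map to
        integer table rows at lookup time.
    """
    if data_dir is None:
        reserve_df = _read_packaged_csv("hyperopia_reserve.csv")
        axial_df = _read_packaged_csv("axial_length.csv")
        corneal_df = _read_packaged_csv("corneal_radius.csv")
    else:
        data_dir = Path(data_dir)
        reserve_df = pd.read_csv(data_dir / "hyperopia_reserve.csv")
        axial_df = pd.read_csv(data_dir / "axial_length.csv")
        corneal_df = pd.read_csv(data_dir / "corneal_radius.csv")

    reserves = {
        int(row.age): ReserveInterval(int(row.age), row.mean_d, row.lower_d, row.upper_d)
        for row in reserve_df.itertuples()
    }
    axial = {
        int(row.age): AxialReference(int(row.age), row.al_min_mm, row.al_max_mm, row.al_mean_mm)
        for row in axial_df.itertuples()
    }
    corneal = {
        int(row.age): CornealReference(int(row.age), row.cr_min_mm, row.cr_max_mm, row.cr_mean_mm)
        for row in corneal_df.itertuples()
    }
    return ReferenceTables(
        reserves=reserves, axial=axial, corneal=corneal, age_rounding=age_rounding
    )
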