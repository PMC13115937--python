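"""Data-quality pipeline: parsing, encoding, pseudonymization, plausibility
screening, stratified median imputation, and train-fitted standardization.

The pipeline is leakage-safe by construction: imputation medians and
z-score parameters are fitted on the training partition only and then
applied unchanged to validation/test data.  Implausible records are never
dropped automatically — they are quarantined with named flags and re-enter
the pipeline only through an explicit reviewer decision, mirroring the
two-ophthalmologist review such records receive in practice.
"""

from __future__ import annotations

import hashlib
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .records import RecordValidationError, SubjectRecord

__all__ = [
    "PlausibilityBounds",
    "PlausibilityFlag",
    "ScalerState",
    "StratifiedMedianImputer",
    "parse_age",
    "encode_sex",
    "generate_subject_id",
    "flag_implausible",
    "quarantine_cohort",
    "apply_review",
    "fit_scaler",
    "apply_scaler",
]

_MALE = {"m", "male", "boy", "b", "0"}
_FEMALE = {"f", "female", "girl", "g", "1"}


def parse_age(raw) -> int:
    """Parse an age cell to completed years.

    Ages recorded as ``"A/B"`` (years/months) yield the numerator ``A``;
    plain numbers and numeric strings are floored to the completed year.
    """
    if raw is None or (isinstance(raw, str) and not raw.strip()):
        raise RecordValidationError("age: empty value")
    if isinstance(raw, str):
        text = raw.strip()
        if "/" in text:
            text = text.split("/", 1)[0].strip()
        try:
            value = float(text)
        except ValueError:
            raise RecordValidationError(f"age: cannot parse {raw!r}") from None
    else:
        value = float(raw)
    if not math.isfinite(value):
        raise RecordValidationError(f"age: non-finite value {raw!r}")
    return int(math.floor(value))


def encode_sex(raw) -> int:
    """Encode sex to the 0 = male / 1 = female convention."""
    if raw is None or (isinstance(raw, str) and not raw.strip()):
        raise RecordValidationError("sex: empty value")
    if isinstance(raw, str):
        key = raw.strip().lower()
        if key in _MALE:
            return 0
        if key in _FEMALE:
            return 1
        raise RecordValidationError(f"sex: unrecognized value {raw!r}")
    value = int(raw)
    if value in (0, 1):
        return value
    raise RecordValidationError(f"sex: expected 0/1, got {raw!r}")


def generate_subject_id(canonical_fields: str | Sequence[str]) -> str:
    """Deterministic pseudonymous subject identifier.

    The canonical identifying fields (e.g. name, birthdate, record number)
    are pipe-joined in input order, UTF-8 encoded and SHA256-hashed; the id
    is the first 16 hex characters of the digest, uppercased and grouped
    4-4-4-4 with hyphens (``XXXX-XXXX-XXXX-XXXX``).
    """
    if isinstance(canonical_fields, str):
        canonical = canonical_fields
    else:
        canonical = "|".join(str(f) for f in canonical_fields)
    if not canonical:
        raise RecordValidationError("canonical_fields: empty input")
    digest = hashlib.sha256(canonical.encode("utf-8")).hexdigest()[:16].upper()
    return "-".join(digest[i : i + 4] for i in range(0, 16, 4))


@dataclass(frozen=True)
class PlausibilityBounds:
    """Clinically plausible ranges; values outside are flagged for review.

    Only the axial-length ceiling of 30 mm is a published screening
    threshold; the remaining defaults are visible, configurable package
    choices covering the physiological range of school-aged eyes.
    """

    al: tuple[float, float] = (18.0, 30.0)      # mm
    cr: tuple[float, float] = (6.5, 9.5)        # mm
    se: tuple[float, float] = (-15.0, 10.0)     # D
    age: tuple[float, float] = (6.0, 12.0)      # years
    acuity: tuple[float, float] = (-0.3, 1.5)   # logMAR

    def __post_init__(self) -> None:
        for name in ("al", "cr", "se", "age", "acuity"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ValueError(f"{name} bounds: min must be < max, got ({lo}, {hi})")


@dataclass(frozen=True)
class PlausibilityFlag:
    field: str
    value: float
    bound: tuple[float, float]

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.field}={self.value} outside [{self.bound[0]}, {self.bound[1]}]"


_FIELD_COLUMNS = {
    "al": "al_mm",
    "cr": "cr_mm",
    "se": "se_d",
    "age": "age",
    "acuity": "acuity_logmar",
}


def flag_implausible(
    record: SubjectRecord, bounds: PlausibilityBounds | None = None
) -> list[PlausibilityFlag]:
    """Return one flag per bound the record violates; empty if plausible.

    Flagging never raises: a flagged record is quarantined for human
    review, not rejected.
    """
    bounds = bounds or PlausibilityBounds()
    values = {
        "al": record.al,
        "cr": record.cr,
        "se": record.se,
        "age": record.age,
        "acuity": record.acuity,
    }
    flags = []
    for name, value in values.items():
        if value is None or not math.isfinite(value):
            continue
        lo, hi = getattr(bounds, name)
        if not lo <= value <= hi:
            flags.append(PlausibilityFlag(name, float(value), (lo, hi)))
    return flags


def quarantine_cohort(
    frame: pd.DataFrame, bounds: PlausibilityBounds | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split a cohort frame into (clean, quarantined-for-review).

    The quarantine frame carries a ``flags`` column naming every violated
    bound and an empty ``reviewer_decision`` column ("keep"/"drop") that a
    human must fill before :func:`apply_review` readmits any row.
    """
    bounds = bounds or PlausibilityBounds()
    flag_strings = []
    for _, row in frame.iterrows():
        row_flags = []
        for name, col in _FIELD_COLUMNS.items():
            if col not in frame.columns:
                continue
            value = row[col]
            if pd.isna(value):
                continue
            lo, hi = getattr(bounds, name)
            if not lo <= value <= hi:
                row_flags.append(f"{name}={value} outside [{lo}, {hi}]")
        flag_strings.append("; ".join(row_flags))
    flagged = pd.Series(flag_strings, index=frame.index) != ""
    clean = frame.loc[~flagged].copy()
    quarantined = frame.loc[flagged].copy()
    quarantined["flags"] = [s for s, f in zip(flag_strings, flagged) if f]
    quarantined["reviewer_decision"] = ""
    return clean, quarantined


def apply_review(quarantined: pd.DataFrame) -> pd.DataFrame:
    """Readmit quarantined rows whose reviewer_decision is 'keep'.

    Rows with any other (or missing) decision stay out; nothing is dropped
    silently — the caller keeps the quarantine frame as the audit record.
    """
    if "reviewer_decision" not in quarantined.columns:
        raise ValueError("quarantine frame lacks a reviewer_decision column")
    kept = quarantined[quarantined["reviewer_decision"].str.lower() == "keep"]
    return kept.drop(columns=["flags", "reviewer_decision"], errors="ignore")


class StratifiedMedianImputer:
    """Median imputation stratified by (age, sex), with graceful fallback.

    Medians are computed on the partition passed to :meth:`fit` (the
    training data) and reused for every later :meth:`transform`, so no
    information flows from validation/test partitions into the statistics.
    Missing cells are filled from the (age, sex) stratum median, falling
    back to the age stratum, then to the global median.
    """

    def __init__(self, features: Sequence[str]):
        self.features = list(features)
        self._strata: dict[str, pd.Series] | None = None
        self._by_age: dict[str, pd.Series] | None = None
        self._global: dict[str, float] | None = None

    def fit(self, train: pd.DataFrame) -> "StratifiedMedianImputer":
        self._strata, self._by_age, self._global = {}, {}, {}
        for feature in self.features:
            col = train[feature]
            if col.isna().all():
                raise RecordValidationError(
                    f"{feature}: no observed values to impute from"
                )
            self._strata[feature] = train.groupby(["age", "sex"])[feature].median()
            self._by_age[feature] = train.groupby("age")[feature].median()
            self._global[feature] = float(col.median())
        return self

    def transform(self, frame: pd.DataFrame) -> pd.DataFrame:
        if self._global is None:
            raise RuntimeError("imputer not fitted; call fit() on the training partition")
        out = frame.copy()
        for feature in self.features:
            mask = out[feature].isna()
            if not mask.any():
                continue
            for idx in out.index[mask]:
                age, sex = out.at[idx, "age"], out.at[idx, "sex"]
                value = self._strata[feature].get((age, sex), np.nan)
                if pd.isna(value):
                    value = self._by_age[feature].get(age, np.nan)
                if pd.isna(value):
                    value = self._global[feature]
                out.at[idx, feature] = value
        return out

    def fit_transform(self, train: pd.DataFrame) -> pd.DataFrame:
        return self.fit(train).transform(train)


def impute_missing(
    cohort: pd.DataFrame,
    features: Sequence[str],
    train: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Impute missing numeric values by stratified median.

    ``train`` designates the partition the medians are computed from;
    when omitted, ``cohort`` itself is treated as the training partition.
    """
    imputer = StratifiedMedianImputer(features)
    imputer.fit(cohort if train is None else train)
    return imputer.transform(cohort)


@dataclass(frozen=True)
class ScalerState:
    """Fitted z-score parameters, tagged with the partition they came from."""

    features: tuple[str, ...]
    mean: np.ndarray
    sd: np.ndarray
    zero_variance: tuple[str, ...]
    fitted_on: str = "train"


def fit_scaler(
    train: pd.DataFrame, features: Sequence[str], fitted_on: str = "train"
) -> ScalerState:
    """Fit per-feature mean and standard deviation on the training partition.

    Zero-variance features are recorded in the state (and later transformed
    to zeros with a warning) rather than divided by zero.
    """
    if train.empty:
        raise RecordValidationError("train: empty partition")
    sub = train[list(features)]
    if sub.isna().any().any():
        missing = sub.columns[sub.isna().any()].tolist()
        raise RecordValidationError(f"missing values in features {missing}; impute first")
    mean = sub.mean(axis=0).to_numpy(dtype=float)
    sd = sub.std(axis=0, ddof=0).to_numpy(dtype=float)
    zero = tuple(f for f, s in zip(features, sd) if s == 0.0)
    return ScalerState(
        features=tuple(features), mean=mean, sd=sd, zero_variance=zero, fitted_on=fitted_on
    )


def apply_scaler(state: ScalerState, frame: pd.DataFrame) -> pd.DataFrame:
    """Z-score ``frame``'s feature columns using the fitted parameters only."""
    out = frame.copy()
    for i, feature in enumerate(state.features):
        if feature in state.zero_variance:
            warnings.warn(
                f"feature {feature!r} had zero variance on {state.fitted_on}; "
                "transformed to zeros",
                UserWarning,
                stacklevel=2,
            )
            out[feature] = 0.0
        else:
            out[feature] = (out[feature] - state.mean[i]) / state.sd[i]
    return out
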