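"""Guideline-derived screening rules: refractive classification and risk flag.

The screening logic is a fixed IF/ELSE chain over spherical equivalent (SE)
plus a structural risk test on ocular biometry:

Refractive status (five categories, evaluated in order):

1. ``SE > reserve_upper(age)``          → Hyperopia
2. ``SE > +0.75``                       → Pre-myopia (borderline high
   hyperopia still inside the age reserve; distinct trace id)
3. ``onset < SE <= +0.75``              → Pre-myopia
4. ``-3.00 <= SE <= onset``             → Low myopia
5. ``-6.00 <= SE < -3.00``              → Moderate myopia
6. ``SE < -6.00``                       → High myopia

where ``onset`` is the myopia-onset cutoff: −0.50 D under the standard
(cycloplegic) definition, tightened to −0.75 D in ``non_cycloplegic`` mode
to compensate for accommodative spasm over-minusing un-dilated children.
The two modes disagree only on the band −0.75 < SE < −0.50 (and the exact
point SE = −0.75, myopic only without cycloplegia); at SE = −0.50 both
modes call the child pre-myopic.

Structural progression risk (independent of the SE category):

``flag = 1 iff AL/CR >= 3.00 or AL > AL_max(age)``

AL and CR are invariant to accommodation, which is what makes the flag
trustworthy in a non-cycloplegic screening setting.

Visual acuity is a supplementary criterion only: acuity worse than decimal
0.7 (logMAR > ~0.155) is flagged and traced but never changes the SE-based
category.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .records import RecordValidationError, SubjectRecord
from .references import ReferenceTables

__all__ = [
    "CATEGORIES",
    "MODES",
    "RuleResult",
    "RuleEngine",
    "compute_se",
    "compute_al_cr",
    "cr_from_keratometry",
    "classify_refractive_status",
    "progression_risk_flag",
    "evaluate_rules",
    "rule_features",
    "al_deviation_pct",
    "cr_deviation_pct",
    "acuity_subnormal",
]

#: Category labels in clinical order, least to most myopic.
CATEGORIES = ("Hyperopia", "Pre-myopia", "Low myopia", "Moderate myopia", "High myopia")

MODES = ("standard", "non_cycloplegic")

#: Myopia-onset SE cutoffs (D) per mode. Standard: myopia iff SE < -0.50.
#: Non-cycloplegic: myopia iff SE <= -0.75 (stricter, to offset
#: accommodative over-minusing in un-dilated refraction).
STANDARD_ONSET = -0.50
NON_CYCLOPLEGIC_ONSET = -0.75

LOW_MODERATE_CUT = -3.00
MODERATE_HIGH_CUT = -6.00
PRE_MYOPIA_UPPER = 0.75

#: Decimal visual acuity below which acuity is supplementary-flagged (ages 6-12).
ACUITY_DECIMAL_FLOOR = 0.7
ACUITY_LOGMAR_FLOOR = -math.log10(ACUITY_DECIMAL_FLOOR)

#: Default keratometric index constant: CR(mm) = 337.5 / K(D).
KERATOMETRIC_CONSTANT = 337.5


@dataclass(frozen=True)
class RuleResult:
    """Outcome of the rule chain for one subject."""

    category: str
    risk_flag: int
    trace: tuple[str, ...]
    mode: str
    acuity_flag: bool = False

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if self.risk_flag not in (0, 1):
            raise ValueError(f"risk_flag must be 0 or 1, got {self.risk_flag!r}")
        if not self.trace:
            raise ValueError("trace must be non-empty")


def _check_mode(mode: str) -> None:
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}, got {mode!r}")


def compute_se(sphere: float, cylinder: float) -> float:
    """Spherical equivalent: sphere + cylinder / 2, in diopters."""
    for name, value in (("sphere", sphere), ("cylinder", cylinder)):
        if value is None or not math.isfinite(value):
            raise RecordValidationError(f"{name}: missing or non-finite")
    return sphere + cylinder / 2.0


def compute_al_cr(al: float, cr: float) -> float:
    """Axial-length to corneal-radius ratio (dimensionless)."""
    if al is None or not math.isfinite(al) or al <= 0:
        raise RecordValidationError(f"al: must be positive and finite, got {al!r}")
    if cr is None or not math.isfinite(cr) or cr <= 0:
        raise RecordValidationError(f"cr: must be positive and finite, got {cr!r}")
    return al / cr


def cr_from_keratometry(k: float, constant: float = KERATOMETRIC_CONSTANT) -> float:
    """Convert corneal power K (diopters) to corneal radius (mm)."""
    if k is None or not math.isfinite(k) or k <= 0:
        raise RecordValidationError(f"k: must be positive and finite, got {k!r}")
    return constant / k


def _onset(mode: str) -> float:
    return NON_CYCLOPLEGIC_ONSET if mode == "non_cycloplegic" else STANDARD_ONSET


def _classify(age: float, se: float, tables: ReferenceTables, mode: str) -> tuple[str, str]:
    """Run the classification chain; return (category, fired-rule id)."""
    upper = tables.hyperopia_reserve(age).upper
    if se > upper:
        return "Hyperopia", "hyperopia_above_reserve_upper"
    if se > PRE_MYOPIA_UPPER:
        # Above +0.75 D yet inside the age reserve: borderline high hyperopia,
        # grouped with pre-myopia but individually recoverable via the trace.
        return "Pre-myopia", "premyopia_borderline_high_hyperopia"
    onset = _onset(mode)
    myopic = se <= onset if mode == "non_cycloplegic" else se < onset
    if not myopic:
        return "Pre-myopia", "premyopia_band"
    if se >= LOW_MODERATE_CUT:
        return "Low myopia", "low_myopia"
    if se >= MODERATE_HIGH_CUT:
        return "Moderate myopia", "moderate_myopia"
    return "High myopia", "high_myopia"


def classify_refractive_status(
    age: float, se: float, tables: ReferenceTables, mode: str = "non_cycloplegic"
) -> str:
    """Classify a subject's refractive status from age and spherical equivalent.

    ``mode`` selects the myopia-onset cutoff: ``'standard'`` uses the
    cycloplegic definition SE < −0.50 D; ``'non_cycloplegic'`` (default)
    the tightened SE ≤ −0.75 D.
    """
    _check_mode(mode)
    if se is None or not math.isfinite(se):
        raise RecordValidationError(f"se: missing or non-finite, got {se!r}")
    category, _ = _classify(age, se, tables, mode)
    return category


def progression_risk_flag(
    age: float, al: float, cr: float, tables: ReferenceTables
) -> int:
    """Binary structural progression-risk flag.

    1 iff AL/CR ≥ 3.00 or AL exceeds the age-specific reference maximum.
    """
    ratio = compute_al_cr(al, cr)
    al_max = tables.al_reference(age).al_max
    return int(ratio >= tables.al_cr_threshold or al > al_max)


def evaluate_rules(
    record: SubjectRecord,
    tables: ReferenceTables,
    mode: str = "non_cycloplegic",
) -> RuleResult:
    """Apply the full rule chain to a validated record.

    Returns the refractive category, the structural risk flag, the ordered
    trace of fired rule identifiers, and the supplementary acuity flag.
    Deterministic and side-effect free.
    """
    _check_mode(mode)
    trace: list[str] = ["compute_al_cr_ratio"]
    category, rule_id = _classify(record.age, record.se, tables, mode)
    trace.append(rule_id)

    ratio = record.al_cr
    al_max = tables.al_reference(record.age).al_max
    if ratio >= tables.al_cr_threshold:
        risk, risk_id = 1, "risk_al_cr_ratio_at_or_above_3.00"
    elif record.al > al_max:
        risk, risk_id = 1, "risk_al_above_age_max"
    else:
        risk, risk_id = 0, "risk_clear"
    trace.append(risk_id)

    acuity_flag = acuity_subnormal(record.acuity)
    if acuity_flag:
        trace.append("acuity_below_0.7_decimal_supplementary")

    return RuleResult(
        category=category,
        risk_flag=risk,
        trace=tuple(trace),
        mode=mode,
        acuity_flag=acuity_flag,
    )


def acuity_subnormal(acuity_logmar: float) -> bool:
    """Supplementary acuity criterion: worse than decimal 0.7 for ages 6–12."""
    if acuity_logmar is None or not math.isfinite(acuity_logmar):
        return False
    return acuity_logmar > ACUITY_LOGMAR_FLOOR + 1e-12


def rule_features(result: RuleResult, weight: float = 1.0) -> np.ndarray:
    """Encode a rule outcome as weighted features for the ML harness.

    One-hot over the five categories followed by the risk flag, each scaled
    by ``weight`` (length 6). These are the explicit "instructions" handed
    to the classifiers so learned boundaries respect the guideline ones.
    """
    if weight is None or not math.isfinite(weight) or weight < 0:
        raise RecordValidationError(f"weight: must be a finite non-negative scalar, got {weight!r}")
    vec = np.zeros(6, dtype=float)
    vec[CATEGORIES.index(result.category)] = weight
    vec[5] = weight * result.risk_flag
    return vec


def al_deviation_pct(age: float, al: float, tables: ReferenceTables) -> float:
    """Axial-length deviation from the age-matched reference mean, in percent."""
    mean = tables.al_reference(age).al_mean
    return (al - mean) / mean * 100.0


def cr_deviation_pct(age: float, cr: float, tables: ReferenceTables) -> float:
    """Corneal-radius deviation from the age-matched reference mean, in percent."""
    mean = tables.cr_reference(age).cr_mean
    return (cr - mean) / mean * 100.0


class RuleEngine:
    """Convenience wrapper binding tables, mode and rule-feature weight.

    The default mode is ``non_cycloplegic``, the operating condition of a
    screening programme that cannot dilate every child.
    """

    def __init__(
        self,
        tables: ReferenceTables,
        mode: str = "non_cycloplegic",
        rule_weight: float = 1.0,
    ) -> None:
        _check_mode(mode)
        if rule_weight < 0:
            raise RecordValidationError("rule_weight: must be non-negative")
        self.tables = tables
        self.mode = mode
        self.rule_weight = rule_weight

    def classify(self, age: float, se: float) -> str:
        return classify_refractive_status(age, se, self.tables, self.mode)

    def risk(self, age: float, al: float, cr: float) -> int:
        return progression_risk_flag(age, al, cr, self.tables)

    def evaluate(self, record: SubjectRecord) -> RuleResult:
        return evaluate_rules(record, self.tables, self.mode)

    def features(self, record: SubjectRecord) -> np.ndarray:
        return rule_features(self.evaluate(record), self.rule_weight)
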