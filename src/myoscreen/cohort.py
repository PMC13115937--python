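"""Synthetic pediatric ocular-biometry cohorts.

The generator emulates the statistical structure of a hospital-clinic
developmental cohort of 6–12-year-old children referred for refractive
assessment: a five-class refractive mixture dominated by pre-myopia
(~52.7%), mean spherical equivalent ≈ −0.66 D, mean axial length ≈ 23.56
mm and mean AL/CR ≈ 3.05.  Generation is class-first: each subject's
refractive category is drawn from the mixture, the spherical equivalent is
then drawn inside that category's rule interval, and the biometry is
derived so the rule engine reproduces the drawn class by construction:

    CR  ~  Normal(cr_mean(age) + cr_mean_shift, cr_sd), clipped to the
           age's reference interval
    AL  =  CR · al_cr_baseline  −  SE / al_coupling  +  Normal(0, al_noise_sd)

i.e. an emmetropic eye sits at AL/CR = ``al_cr_baseline`` and every
diopter of myopia adds 1/3 mm of axial length (the ~3.00 D-per-mm axial
coupling), which makes AL/CR correlate strongly negatively with SE.

Defaults are calibrated once to the developmental-cohort summary; see
docs/methods.md for the calibration arithmetic and for the features of
real data the generator deliberately does not model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .records import COHORT_COLUMNS
from .references import ReferenceTables, build_reference_tables
from .rules import CATEGORIES, classify_refractive_status, progression_risk_flag

__all__ = ["CohortConfig", "CohortSummary", "generate_cohort", "label_cohort", "summarize_cohort"]

_EPS = 1e-6

#: Triangular (left, mode, right) SE bands per class, diopters. The
#: hyperopia band is uniform above the age-specific reserve upper bound and
#: is parameterized by ``hyperopia_band_width`` instead.
DEFAULT_SE_BANDS: Mapping[str, tuple[float, float, float]] = {
    "Pre-myopia": (-0.75 + _EPS, -0.30, 0.75),
    "Low myopia": (-3.0, -3.0, -0.75),
    "Moderate myopia": (-6.0 + _EPS, -4.0, -3.0 - _EPS),
    "High myopia": (-9.0, -6.5, -6.0 - _EPS),
}

#: Developmental-cohort class mixture: hyperopia, pre-myopia, low, moderate,
#: high myopia.
DEFAULT_MIXTURE = (0.1074, 0.5268, 0.3101, 0.0487, 0.0070)


@dataclass(frozen=True)
class CohortConfig:
    """Parameters of the synthetic cohort generator.

    The defaults reproduce the developmental training cohort: n = 1006,
    49.7% boys, the five-class mixture above, and biometry calibrated so
    the cohort means land on SE ≈ −0.66 D, AL ≈ 23.56 mm, AL/CR ≈ 3.05.
    """

    n: int = 1006
    seed: int | None = None
    age_range: tuple[int, int] = (6, 12)
    sex_balance: float = 0.497           # proportion male (code 0)
    class_mixture: tuple[float, ...] = DEFAULT_MIXTURE
    se_bands: Mapping[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_SE_BANDS)
    )
    hyperopia_band_width: float = 1.0    # D above the age reserve upper
    cr_mean_shift: float = -0.23         # mm below the population reference mean
    cr_sd: float = 0.18                  # mm, within-age spread
    al_cr_baseline: float = 3.021        # emmetropic AL/CR ratio
    al_coupling: float = 3.0             # D of myopic shift per mm of AL
    al_noise_sd: float = 0.3             # mm, residual axial noise
    acuity_base: float = 0.42            # logMAR intercept
    acuity_slope: float = 0.25           # logMAR per D of myopia
    acuity_noise: float = 0.25           # logMAR sd
    cylinder_sd: float = 0.3             # D, |cylinder| half-normal scale
    missing_rate: float = 0.0
    missing_mechanism: str = "mcar"      # or "mar_age"
    outlier_rate: float = 0.0
    allocation: str = "stratified"       # or "multinomial"
    mode: str = "non_cycloplegic"        # rule mode the classes are matched to

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ValueError(f"n must be positive, got {self.n}")
        if len(self.class_mixture) != len(CATEGORIES):
            raise ValueError("class_mixture must have five entries")
        if abs(sum(self.class_mixture) - 1.0) > 1e-6:
            raise ValueError(f"class_mixture must sum to 1, got {sum(self.class_mixture)}")
        for name, rate in (("missing_rate", self.missing_rate), ("outlier_rate", self.outlier_rate)):
            if not 0.0 <= rate < 1.0:
                raise ValueError(f"{name} must be in [0, 1), got {rate}")
        if not 0.0 <= self.sex_balance <= 1.0:
            raise ValueError("sex_balance must be a proportion")
        for cls, (left, mode_, right) in self.se_bands.items():
            if not (left <= mode_ <= right) or left >= right:
                raise ValueError(f"infeasible SE band for {cls!r}: ({left}, {mode_}, {right})")
        if self.hyperopia_band_width <= 0:
            raise ValueError("hyperopia_band_width must be positive")
        if self.allocation not in ("stratified", "multinomial"):
            raise ValueError(f"unknown allocation {self.allocation!r}")
        if self.missing_mechanism not in ("mcar", "mar_age"):
            raise ValueError(f"unknown missing_mechanism {self.missing_mechanism!r}")


def _allocate_classes(config: CohortConfig, rng: np.random.Generator) -> np.ndarray:
    """Class index per subject: exact largest-remainder counts or multinomial."""
    k = len(CATEGORIES)
    if config.allocation == "multinomial":
        return rng.choice(k, size=config.n, p=np.asarray(config.class_mixture))
    raw = np.asarray(config.class_mixture) * config.n
    counts = np.floor(raw).astype(int)
    shortfall = config.n - counts.sum()
    order = np.argsort(-(raw - counts))
    counts[order[:shortfall]] += 1
    labels = np.repeat(np.arange(k), counts)
    rng.shuffle(labels)
    return labels


def _draw_se(
    classes: np.ndarray,
    ages: np.ndarray,
    config: CohortConfig,
    tables: ReferenceTables,
    rng: np.random.Generator,
) -> np.ndarray:
    se = np.empty(len(classes), dtype=float)
    uppers = np.array([tables.hyperopia_reserve(int(a)).upper for a in ages])
    hyper = classes == 0
    se[hyper] = uppers[hyper] + _EPS + rng.uniform(
        0.0, config.hyperopia_band_width, size=int(hyper.sum())
    )
    for idx, cls in enumerate(CATEGORIES[1:], start=1):
        mask = classes == idx
        if not mask.any():
            continue
        left, mode_, right = config.se_bands[cls]
        se[mask] = rng.triangular(left, mode_, right, size=int(mask.sum()))
    return se


def generate_cohort(
    config: CohortConfig | None = None,
    tables: ReferenceTables | None = None,
) -> pd.DataFrame:
    """Generate a synthetic cohort in the canonical column schema.

    Fully reproducible under a fixed ``config.seed``; the returned frame
    has one row per subject and, at the default zero missing/outlier
    rates, validates row-by-row into :class:`~myoscreen.records.SubjectRecord`.
    """
    config = config or CohortConfig()
    tables = tables or build_reference_tables()
    rng = np.random.default_rng(config.seed)
    n = config.n

    ages = rng.integers(config.age_range[0], config.age_range[1] + 1, size=n)
    sex = (rng.random(n) >= config.sex_balance).astype(int)  # 0 = male
    classes = _allocate_classes(config, rng)
    se = _draw_se(classes, ages, config, tables, rng)

    cr_lo = np.array([tables.cr_reference(int(a)).cr_min for a in ages])
    cr_hi = np.array([tables.cr_reference(int(a)).cr_max for a in ages])
    cr_mu = np.array([tables.cr_reference(int(a)).cr_mean for a in ages])
    cr = np.clip(
        rng.normal(np.clip(cr_mu + config.cr_mean_shift, cr_lo, cr_hi), config.cr_sd),
        cr_lo,
        cr_hi,
    )

    al = (
        cr * config.al_cr_baseline
        - se / config.al_coupling
        + rng.normal(0.0, config.al_noise_sd, size=n)
    )

    acuity = np.clip(
        config.acuity_base
        + config.acuity_slope * np.maximum(-se, 0.0)
        + rng.normal(0.0, config.acuity_noise, size=n),
        -0.1,
        1.5,
    )

    cylinder = -np.abs(rng.normal(0.0, config.cylinder_sd, size=n))
    sphere = se - cylinder / 2.0

    frame = pd.DataFrame(
        {
            "id": [f"S{i:05d}" for i in range(n)],
            "age": ages.astype(int),
            "sex": sex,
            "acuity_logmar": acuity,
            "sphere_d": sphere,
            "cylinder_d": cylinder,
            "se_d": se,
            "al_mm": al,
            "cr_mm": cr,
            "dilated": False,
        },
        columns=COHORT_COLUMNS,
    )

    if config.outlier_rate > 0:
        hit = rng.random(n) < config.outlier_rate
        frame.loc[hit, "al_mm"] = rng.uniform(30.2, 33.0, size=int(hit.sum()))

    if config.missing_rate > 0:
        for col in ("acuity_logmar", "al_mm", "cr_mm"):
            if config.missing_mechanism == "mar_age":
                # older children more likely to have the field missing
                p = config.missing_rate * (ages - config.age_range[0] + 1) / (
                    config.age_range[1] - config.age_range[0] + 1
                ) * 2.0
                hit = rng.random(n) < np.clip(p, 0.0, 1.0)
            else:
                hit = rng.random(n) < config.missing_rate
            frame.loc[hit, col] = np.nan

    return frame


def label_cohort(
    frame: pd.DataFrame,
    tables: ReferenceTables | None = None,
    mode: str = "non_cycloplegic",
    noise_rate: float = 0.0,
    seed: int | None = None,
) -> pd.DataFrame:
    """Append ground-truth ``category`` and ``risk_flag`` columns.

    Labels are the rule-engine outputs for each row; rows with missing
    age/SE (or biometry, for the flag) get missing labels.  An optional
    ``noise_rate`` flips that fraction of labels to a uniformly-chosen
    different category, for harness stress tests.
    """
    tables = tables or build_reference_tables()
    rng = np.random.default_rng(seed)
    out = frame.copy()
    categories: list[object] = []
    flags: list[object] = []
    for row in out.itertuples(index=False):
        if pd.isna(row.age) or pd.isna(row.se_d):
            categories.append(np.nan)
        else:
            categories.append(
                classify_refractive_status(row.age, row.se_d, tables, mode)
            )
        if pd.isna(row.age) or pd.isna(row.al_mm) or pd.isna(row.cr_mm):
            flags.append(np.nan)
        else:
            flags.append(progression_risk_flag(row.age, row.al_mm, row.cr_mm, tables))
    out["category"] = categories
    out["risk_flag"] = flags
    if noise_rate > 0:
        flip = rng.random(len(out)) < noise_rate
        for idx in out.index[flip]:
            current = out.at[idx, "category"]
            if pd.isna(current):
                continue
            others = [c for c in CATEGORIES if c != current]
            out.at[idx, "category"] = others[rng.integers(len(others))]
    return out


@dataclass(frozen=True)
class CohortSummary:
    """Cohort-characteristics summary (mean ± sd and class counts)."""

    n: int
    pct_male: float
    age: tuple[float, float]
    acuity: tuple[float, float]
    se: tuple[float, float]
    al: tuple[float, float]
    al_cr: tuple[float, float]
    class_counts: Mapping[str, int]
    class_pcts: Mapping[str, float]
    degenerate_sd: bool = False  # single-subject cohort: sds reported as 0

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "pct_male": self.pct_male,
            "age_mean": self.age[0],
            "age_sd": self.age[1],
            "acuity_mean": self.acuity[0],
            "acuity_sd": self.acuity[1],
            "se_mean": self.se[0],
            "se_sd": self.se[1],
            "al_mean": self.al[0],
            "al_sd": self.al[1],
            "al_cr_mean": self.al_cr[0],
            "al_cr_sd": self.al_cr[1],
            "class_counts": dict(self.class_counts),
            "class_pcts": dict(self.class_pcts),
            "degenerate_sd": self.degenerate_sd,
        }


def _mean_sd(series: pd.Series) -> tuple[float, float]:
    mean = float(series.mean())
    sd = float(series.std(ddof=1)) if len(series.dropna()) > 1 else 0.0
    return mean, sd


def summarize_cohort(
    frame: pd.DataFrame,
    tables: ReferenceTables | None = None,
    mode: str = "non_cycloplegic",
) -> CohortSummary:
    """Summarize a cohort in the developmental-dataset layout.

    If the frame is unlabeled, rule-engine categories are computed on the
    fly for the class breakdown.  Deterministic.
    """
    if frame.empty:
        raise ValueError("cannot summarize an empty cohort")
    labeled = frame if "category" in frame.columns else label_cohort(frame, tables, mode)
    counts = {c: int((labeled["category"] == c).sum()) for c in CATEGORIES}
    n = len(frame)
    ratio = frame["al_mm"] / frame["cr_mm"]
    return CohortSummary(
        n=n,
        pct_male=float((frame["sex"] == 0).mean() * 100.0),
        age=_mean_sd(frame["age"]),
        acuity=_mean_sd(frame["acuity_logmar"]),
        se=_mean_sd(frame["se_d"]),
        al=_mean_sd(frame["al_mm"]),
        al_cr=_mean_sd(ratio),
        class_counts=counts,
        class_pcts={c: counts[c] / n * 100.0 for c in CATEGORIES},
        degenerate_sd=n == 1,
    )
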