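"""Rule-engine behaviour: classification chain, risk flag, traces, features."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from myoscreen import (
    CATEGORIES,
    RuleEngine,
    SubjectRecord,
    classify_refractive_status,
    compute_al_cr,
    compute_se,
    evaluate_rules,
    progression_risk_flag,
    rule_features,
)
from myoscreen.records import RecordValidationError
from myoscreen.rules import al_deviation_pct, cr_from_keratometry

# ---------------------------------------------------------------------------
# Independent oracle: a literal transcription of the published IF/ELSE chain
# with its own hard-coded reserve uppers, kept separate from the package path.

_ORACLE_UPPER = {6: 3.63, 7: 3.63, 8: 3.38, 9: 3.13, 10: 2.88, 11: 2.88, 12: 2.50}


def oracle_classify(age, se, mode="standard"):
    upper = _ORACLE_UPPER[age]
    if se > upper:
        return "Hyperopia"
    if se > 0.75:
        return "Pre-myopia"
    onset = -0.75 if mode == "non_cycloplegic" else -0.50
    if (se > onset) if mode == "non_cycloplegic" else (se >= onset):
        return "Pre-myopia"
    if se >= -3.00:
        return "Low myopia"
    if se >= -6.00:
        return "Moderate myopia"
    return "High myopia"


# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "sphere, cylinder, expected",
    [(-1.00, -0.50, -1.25), (0.0, 0.0, 0.0), (2.00, -1.00, 1.50)],
)
def test_spherical_equivalent_formula(sphere, cylinder, expected):
    assert compute_se(sphere, cylinder) == pytest.approx(expected)


def test_spherical_equivalent_rejects_non_finite():
    with pytest.raises(RecordValidationError):
        compute_se(float("nan"), -0.5)


def test_al_cr_ratio():
    assert compute_al_cr(24.00, 8.00) == pytest.approx(3.00)
    assert compute_al_cr(22.46, 8.19) == pytest.approx(22.46 / 8.19)
    with pytest.raises(RecordValidationError):
        compute_al_cr(23.0, 0.0)


def test_keratometric_conversion():
    assert cr_from_keratometry(43.0) == pytest.approx(337.5 / 43.0)


@pytest.mark.parametrize(
    "age, se, mode, expected",
    [
        (7, 4.00, "standard", "Hyperopia"),
        (10, 0.00, "standard", "Pre-myopia"),
        (9, -10.00, "standard", "High myopia"),
        (8, -0.60, "non_cycloplegic", "Pre-myopia"),
        (8, -0.60, "standard", "Low myopia"),
        # boundary assignments follow the printed comparison operators
        (9, 0.75, "standard", "Pre-myopia"),
        (9, -0.50, "standard", "Pre-myopia"),
        (9, -0.75, "non_cycloplegic", "Low myopia"),
        (9, -3.00, "standard", "Low myopia"),
        (9, -6.00, "standard", "Moderate myopia"),
        # borderline high hyperopia: above +0.75 but inside the age reserve
        (6, 2.00, "standard", "Pre-myopia"),
    ],
)
def test_classification_examples(tables, age, se, mode, expected):
    assert classify_refractive_status(age, se, tables, mode) == expected


def test_borderline_high_hyperopia_has_distinct_trace(tables):
    record = SubjectRecord("x", 6, 0, 0.1, se=2.0, al=22.0, cr=8.0)
    result = evaluate_rules(record, tables, "standard")
    assert result.category == "Pre-myopia"
    assert "premyopia_borderline_high_hyperopia" in result.trace


def test_partition_grid_agrees_with_oracle(tables):
    """Exactly one category fires on the full (age, SE) grid, the same one
    the literal transcription of the published chain produces."""
    ses = np.round(np.arange(-15.0, 10.0 + 1e-9, 0.01), 2)
    for mode in ("standard", "non_cycloplegic"):
        for age in range(6, 13):
            got = [classify_refractive_status(age, se, tables, mode) for se in ses]
            expected = [oracle_classify(age, se, mode) for se in ses]
            assert got == expected


def test_modes_differ_only_in_the_gap(tables):
    """Standard and non-cycloplegic classifications agree everywhere except
    the open band −0.75 < SE < −0.50 (at −0.75 exactly, both call it myopia)."""
    ses = np.round(np.arange(-15.0, 10.0 + 1e-9, 0.01), 2)
    for age in range(6, 13):
        for se in ses:
            std = classify_refractive_status(age, se, tables, "standard")
            ncp = classify_refractive_status(age, se, tables, "non_cycloplegic")
            if -0.75 < se < -0.50:
                assert (std, ncp) == ("Low myopia", "Pre-myopia")
            else:
                assert std == ncp


@settings(max_examples=200, derandomize=True)
@given(
    age=st.integers(6, 12),
    se_hi=st.floats(-14.9, 10.0),
    delta=st.floats(0.001, 5.0),
    mode=st.sampled_from(["standard", "non_cycloplegic"]),
)
def test_category_monotone_in_se(tables, age, se_hi, delta, mode):
    """Lowering SE never moves the category toward less myopic."""
    rank_hi = CATEGORIES.index(classify_refractive_status(age, se_hi, tables, mode))
    rank_lo = CATEGORIES.index(classify_refractive_status(age, se_hi - delta, tables, mode))
    assert rank_lo >= rank_hi


@pytest.mark.parametrize(
    "age, al, cr, expected",
    [
        (8, 24.00, 8.00, 1),   # ratio exactly at the 3.00 threshold
        (12, 25.00, 8.60, 1),  # ratio 2.907 < 3.00 but AL above the age max
        (6, 22.46, 8.19, 0),   # age-6 mean biometry
    ],
)
def test_progression_risk_flag(tables, age, al, cr, expected):
    assert progression_risk_flag(age, al, cr, tables) == expected


@settings(max_examples=100, derandomize=True)
@given(
    age=st.integers(6, 12),
    al=st.floats(19.0, 28.0),
    bump=st.floats(0.0, 3.0),
    cr=st.floats(7.0, 9.0),
)
def test_risk_flag_non_decreasing_in_al(tables, age, al, bump, cr):
    assert progression_risk_flag(age, al + bump, cr, tables) >= progression_risk_flag(
        age, al, cr, tables
    )


def test_evaluate_rules_hand_traced_subjects(tables):
    a = SubjectRecord("a", 6, 0, 0.2, se=0.50, al=22.0, cr=8.0)
    res_a = evaluate_rules(a, tables, "standard")
    assert (res_a.category, res_a.risk_flag) == ("Pre-myopia", 0)

    b = SubjectRecord("b", 9, 1, 0.6, se=-3.50, al=25.0, cr=7.8)
    res_b = evaluate_rules(b, tables, "standard")
    assert (res_b.category, res_b.risk_flag) == ("Moderate myopia", 1)
    assert "risk_al_cr_ratio_at_or_above_3.00" in res_b.trace


def test_evaluate_rules_is_deterministic(tables):
    record = SubjectRecord("r", 10, 1, 0.4, se=-1.2, al=24.1, cr=7.9)
    first = evaluate_rules(record, tables)
    assert all(evaluate_rules(record, tables) == first for _ in range(5))
    assert first.trace and first.category in CATEGORIES


def test_record_validation_errors_name_the_field():
    with pytest.raises(RecordValidationError, match="cr"):
        SubjectRecord("bad", 8, 0, 0.2, se=-1.0, al=23.0, cr=0.0)
    with pytest.raises(RecordValidationError, match="se"):
        SubjectRecord("bad", 8, 0, 0.2, se=-1.0, al=23.0, cr=7.8, sphere=-2.0, cylinder=-0.5)


def test_rule_features_encoding(tables):
    pre = evaluate_rules(SubjectRecord("p", 10, 0, 0.3, se=0.0, al=22.0, cr=8.0), tables)
    assert pre.category == "Pre-myopia" and pre.risk_flag == 0
    assert rule_features(pre, 1.0).tolist() == [0, 1, 0, 0, 0, 0]

    high = evaluate_rules(SubjectRecord("h", 9, 0, 1.0, se=-8.0, al=26.5, cr=7.7), tables)
    assert high.category == "High myopia" and high.risk_flag == 1
    assert rule_features(high, 2.0).tolist() == [0, 0, 0, 0, 2, 2]
    assert rule_features(high, 0.0).tolist() == [0] * 6
    with pytest.raises(RecordValidationError):
        rule_features(high, -1.0)


def test_acuity_is_supplementary_only(tables):
    sharp = SubjectRecord("s", 8, 0, 0.0, se=-1.0, al=23.0, cr=7.9)
    blurry = SubjectRecord("b", 8, 0, 1.0, se=-1.0, al=23.0, cr=7.9)
    res_sharp, res_blurry = evaluate_rules(sharp, tables), evaluate_rules(blurry, tables)
    assert res_sharp.category == res_blurry.category
    assert not res_sharp.acuity_flag and res_blurry.acuity_flag


def test_deviation_features_zero_at_reference_mean(tables):
    assert al_deviation_pct(9, tables.al_reference(9).al_mean, tables) == pytest.approx(0.0)


def test_rule_engine_wrapper_defaults_to_non_cycloplegic(tables):
    engine = RuleEngine(tables)
    assert engine.mode == "non_cycloplegic"
    assert engine.classify(8, -0.60) == "Pre-myopia"
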