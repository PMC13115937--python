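"""Run the leakage-safe preprocessing pipeline on a messy cohort.

Generates a cohort with missing values and implausible outliers, then:
pseudonymizes ids, quarantines implausible rows for review, imputes
missing values by (age, sex) stratum medians, and z-scores the biometric
features with train-fitted parameters.
"""

from myoscreen import (
    CohortConfig,
    StratifiedMedianImputer,
    apply_scaler,
    fit_scaler,
    generate_cohort,
    generate_subject_id,
    quarantine_cohort,
)

frame = generate_cohort(CohortConfig(n=500, seed=7, missing_rate=0.05, outlier_rate=0.02))

# pseudonymize: hash the raw id into the grouped 16-hex-character format
frame["id"] = [generate_subject_id([raw, "clinic-01"]) for raw in frame["id"]]
print("example pseudonymous id:", frame["id"].iloc[0])

clean, quarantined = quarantine_cohort(frame)
print(f"quarantined {len(quarantined)} of {len(frame)} rows, e.g.:")
print(" ", quarantined["flags"].iloc[0])
# Quarantined rows wait for an explicit reviewer keep/drop decision; they
# are never dropped silently.

features = ["acuity_logmar", "se_d", "al_mm", "cr_mm"]
train, test = clean.iloc[:350], clean.iloc[350:]

imputer = StratifiedMedianImputer(features).fit(train)
train_full, test_full = imputer.transform(train), imputer.transform(test)
print("missing cells after imputation:", int(test_full[features].isna().sum().sum()))

scaler = fit_scaler(train_full, features)
train_scaled = apply_scaler(scaler, train_full)
test_scaled = apply_scaler(scaler, test_full)
print("train AL mean/sd after scaling: "
      f"{train_scaled['al_mm'].mean():+.2e} / {train_scaled['al_mm'].std(ddof=0):.3f}")
print("test  AL mean after scaling  : "
      f"{test_scaled['al_mm'].mean():+.3f}  (train parameters applied, so not exactly 0)")
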