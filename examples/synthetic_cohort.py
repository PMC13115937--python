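"""Generate and summarize a calibrated synthetic screening cohort.

Draws the default 1006-subject cohort (the developmental-cohort
conditions: ~52.7% pre-myopia, mean SE ≈ −0.66 D, mean AL/CR ≈ 3.05),
labels it with the rule engine, and prints the summary table.
"""

from myoscreen import CohortConfig, generate_cohort, label_cohort, summarize_cohort

frame = generate_cohort(CohortConfig(n=1006, seed=42))
labeled = label_cohort(frame)
summary = summarize_cohort(labeled)

print(f"n = {summary.n}, boys = {summary.pct_male:.1f}%")
print(f"age    : {summary.age[0]:.2f} +/- {summary.age[1]:.2f} years")
print(f"acuity : {summary.acuity[0]:.2f} +/- {summary.acuity[1]:.2f} logMAR")
print(f"SE     : {summary.se[0]:+.2f} +/- {summary.se[1]:.2f} D")
print(f"AL     : {summary.al[0]:.2f} +/- {summary.al[1]:.2f} mm")
print(f"AL/CR  : {summary.al_cr[0]:.3f} +/- {summary.al_cr[1]:.3f}")
print("class mixture:")
for category, count in summary.class_counts.items():
    print(f"  {category:16s} {count:4d} ({summary.class_pcts[category]:5.2f}%)")
# The class percentages reproduce the configured mixture exactly (the
# default allocation is stratified), and the biometric means sit on the
# calibration targets to within sampling error.
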