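"""Classify a few children with the guideline rule engine.

Builds three subject records, evaluates the screening rules in
non-cycloplegic mode, and prints the category, structural risk flag and
the fired-rule trace for each.
"""

from myoscreen import RuleEngine, SubjectRecord, build_reference_tables

tables = build_reference_tables()
engine = RuleEngine(tables, mode="non_cycloplegic")

subjects = [
    # a 7-year-old with a healthy hyperopia reserve and normal biometry
    SubjectRecord("child-A", age=7, sex=0, acuity=0.1, se=1.25, al=22.5, cr=8.0),
    # an 8-year-old in the non-cycloplegic grey zone (-0.75 < SE < -0.50):
    # pre-myopic here, but myopic under the standard cycloplegic cutoff
    SubjectRecord("child-B", age=8, sex=1, acuity=0.4, se=-0.60, al=23.4, cr=7.8),
    # a 10-year-old with frank myopia and an elongated eye (AL/CR above 3.00)
    SubjectRecord("child-C", age=10, sex=0, acuity=0.9, se=-4.25, al=25.1, cr=7.7),
]

for subject in subjects:
    result = engine.evaluate(subject)
    print(f"{subject.subject_id}: SE {subject.se:+.2f} D, AL/CR {subject.al_cr:.3f}")
    print(f"  category   : {result.category}")
    print(f"  risk flag  : {result.risk_flag}  (1 = structural progression risk)")
    print(f"  trace      : {' -> '.join(result.trace)}")

# The same grey-zone child under the standard (cycloplegic) cutoff:
standard = RuleEngine(tables, mode="standard")
print("\nchild-B under the standard cutoff:", standard.classify(8, -0.60))
# Non-cycloplegic screening deliberately calls this child pre-myopic rather
# than myopic, because un-dilated refraction over-estimates myopia.
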