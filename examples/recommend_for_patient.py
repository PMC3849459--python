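"""Rank candidate tests for one patient from a tiny co-occurrence matrix.

Four training visits — {HGB, GLUF}, {HGB, GLUF}, {HGB, TSH}, {TSH} — encode
a hemoglobin / fasting-glucose pairing (the classic diabetes work-up) plus
an unrelated thyroid test.  For a new patient who has taken only HGB, the
log-odds score should put GLUF ahead of TSH.
"""

from labrec import (
    PatientCase,
    SmoothingConfig,
    TestUniverse,
    WeightConfig,
    build_training_matrix,
    rank_candidates,
)

visits = [
    {"HGB", "GLUF"},
    {"HGB", "GLUF"},
    {"HGB", "TSH"},
    {"TSH"},
]
cases = [
    PatientCase(case_id=f"v{i}", taken_tests=frozenset(v), patient_id=f"p{i}")
    for i, v in enumerate(visits)
]
universe = TestUniverse.from_codes(t for v in visits for t in v)
matrix = build_training_matrix(cases, universe)

patient = PatientCase(case_id="new", taken_tests=frozenset({"HGB"}), patient_id="new")
config = WeightConfig(smoothing=SmoothingConfig("none", 0.0, 0.0))
rec = rank_candidates(patient, matrix, config)

print("patient has taken: HGB")
for rank, (code, w) in enumerate(rec.ranked, start=1):
    print(f"  {rank}. {code:5s} weight = {w:+.6f}")
print(
    "\nA positive weight means the posterior odds favour 'taken': GLUF\n"
    "co-occurred with HGB in 2 of HGB's 3 visits, TSH in only 1, so the\n"
    "glucose test is the stronger recommendation."
)
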