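"""Generate a seeded synthetic cohort and triage it.

Synthetic records draw crisp codes uniformly from their code sets and
continuous values uniformly within each variable's axis domain, so the
cohort exercises the engine's full operating range reproducibly.
"""

from collections import Counter

from cardiotriage import (
    SyntheticConfig,
    build_index,
    canonical_variables,
    classify,
    enumerate_rules,
    generate_synthetic_records,
)

rb = enumerate_rules(canonical_variables())
idx = build_index(rb)

table = generate_synthetic_records(SyntheticConfig(n=200, seed=42))
results = [classify(rec, rb, idx) for rec in table.records]

counts = Counter(r.criticality_class for r in results)
print(f"classified {len(results)} synthetic records")
for cls, label in ((1, "very critical"), (2, "less critical"), (3, "normal")):
    print(f"  ring {cls} ({label:13s}): {counts.get(cls, 0):4d} records")
mean_fired = sum(r.fired_rule_count for r in results) / len(results)
print(f"mean rules fired per record: {mean_fired:.1f} (candidate bound 3456)")

# Every record lands in one of the three protection rings; with uniform
# sampling most mass sits mid-scale, so "less critical" dominates. The
# fired-rule count stays far below the 3,456-rule candidate block because
# most candidate rules have zero firing strength for any one record.
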