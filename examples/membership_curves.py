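"""Fuzzify a few raw measurements and show their membership degrees.

Each diagnostic attribute is covered by named fuzzy sets with
piecewise-linear membership functions; a crisp measurement maps to a degree
in [0, 1] per set. Degrees of 1.0 sit on a set's plateau, fractional degrees
on a ramp between two sets.
"""

from cardiotriage import canonical_variables, membership_value

variables = {v.name: v for v in canonical_variables()}

print("blood pressure (mmHg):")
for x in (100, 120, 147.5, 155, 180):
    bp = variables["blood_pressure"]
    degs = {s: membership_value(bp, s, x) for s in bp.set_names}
    print(f"  {x:6.1f} -> " + ", ".join(f"{s}={d:.2f}" for s, d in degs.items()))

print("\nblood sugar (mg/dL):")
for x in (90, 110, 150):
    bs = variables["blood_sugar"]
    degs = {s: membership_value(bs, s, x) for s in bs.set_names}
    print(f"  {x:6.1f} -> " + ", ".join(f"{s}={d:.2f}" for s, d in degs.items()))

print("\nage (years):")
for x in (20, 33, 50, 58, 70):
    age = variables["age"]
    degs = {s: membership_value(age, s, x) for s in age.set_names}
    print(f"  {x:6.1f} -> " + ", ".join(f"{s}={d:.2f}" for s, d in degs.items()))

# A blood pressure of 120 is half-way down the "low" ramp (degree 0.5);
# 155 sits exactly on the "high" apex (degree 1.0). Values can belong to
# two adjacent sets at once - that is the point of the fuzzy encoding.
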