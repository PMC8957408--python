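# Methods

## Model and pipeline

`cardiotriage` is a Mamdani-type fuzzy inference system. For a patient
record the pipeline is:

1. **Fuzzification.** Each of the ten diagnostic attributes is evaluated
   against its fuzzy sets' piecewise-linear membership functions, yielding
   degrees in [0, 1]. The crisp attributes (chest pain type, thallium scan,
   gender) produce one-hot degree maps because their sets never overlap.
2. **Candidate selection.** With an index built on the crisp attributes,
   only the leaf block matching the record's composite crisp key is
   scanned; otherwise the whole rule base is. The two routes are provably
   equivalent: any rule outside the leaf block names a different crisp set
   for some key attribute and therefore has firing strength 0.
3. **Rule firing.** AND is the minimum: a rule's strength is the minimum of
   its antecedent's per-variable degrees.
4. **Aggregation.** Per criticality class, the activation is the maximum
   strength among fired rules with that consequent; it clips the class's
   output set.
5. **Defuzzification.** The center of sums integrates the algebraic sum of
   the clipped output sets (overlaps counted multiply) to a crisp score z*;
   a centroid-of-max variant is selectable.
6. **Read-out.** The class whose output set has maximal membership at z*
   wins; exact ties resolve toward the more critical class (patient-safety
   bias). The protection ring equals the class: ring 1 holds the most
   critical records.

## Membership functions

All breakpoints live in the single constants table in
`membership.py::_CANONICAL_SPEC`; each entry cites its anchors, so a
correction is a one-line edit. Shapes are the standard ramp-down /
ramp-up / triangle / trapezoid primitives plus crisp singletons on integer
codes. The canonical cardinalities are chest pain 4, blood pressure 4,
cholesterol 4, blood sugar 2, max heart rate 3, ECG 3, old peak 3,
thallium 3, gender 2, age 4 — a rule space of 82,944.

Several sets are flagged `reconstructed=True`: the published anchor
material for them is incomplete or internally inconsistent, so their shapes
are implementation choices constrained by the legible anchors and by the
coverage requirement below:

- blood pressure *medium*: triangle 125/136/152 (the printed slopes around
  those anchors contradict each other);
- max heart rate *medium*: triangle 110/153/195;
- blood sugar *normal*: 1 below 100 mg/dL, ramp down 100→120, mirroring the
  *very high* ramp so the two sets sum to 1 on the crossover;
- ECG: three evenly spaced sets over the code axis [0, 2]
  (*normal*, *st_t_abnormal*, *hypertrophy*);
- old peak: three evenly spaced sets over [0, 6] mm ST depression
  (*low*, *risk*, *terrible*).

The 95–255 bpm anchor family is assigned to maximum heart rate: those
values are physiologic for peak exercise heart rate and for no other
attribute in the panel.

**Coverage** is enforced at construction: every fuzzy variable is swept at
1,001 points of its axis and must have at least one set with positive
membership everywhere. Combined with full Cartesian rule enumeration this
guarantees every valid complete record fires at least one rule, so
generator output is always classifiable.

**Out-of-domain values are rejected, not clamped** — a blood pressure of
500 mmHg is a unit mistake the reader should surface, not absorb.

## Consequent policy

No per-rule consequents are published, only the rule-space size, so the
default *severity-sum* policy is an implementation choice: each fuzzy set
carries an ordinal severity in the constants table (e.g. BP low=1 …
very high=4; thallium normal=1, fixed defect=2, reversible defect=3). For
max heart rate the ordering is inverted (low achieved max HR = severity 3)
because a low peak heart rate, not a high one, is the clinical risk
direction. A rule's severities are summed and normalized to s ∈ [0, 1]
over the attainable range (min 10, max 32); cut points s < 0.40 → class 3,
0.40 ≤ s < 0.70 → class 2, s ≥ 0.70 → class 1. The cut points are
documented constants (`rulebase.SEVERITY_CUTS`), and fully explicit
user-supplied rule files bypass the policy entirely, so every structural
result (counts, block sizes, reduction, indexed/exhaustive equivalence) is
policy-independent.

Antecedents are pure conjunctions; a disjunctive rule is expressed as
multiple rules.

## Rule order and the index

Rules are enumerated with the crisp variables first (chest pain, thallium,
gender) and the last variable varying fastest, so sorting by the composite
crisp key is a no-op on the canonical base and every key block is a
contiguous span of rule ids. The index stores a stable argsort of the rules
by composite key plus sorted key → span tables per level — the observable
contract of a B+ tree's leaf level (sorted keys, contiguous linked leaves,
O(log n) lookup) without literal tree nodes, for which no node arithmetic
is specified anywhere. Composite keys compare by declared key-variable
order, then set name, so block spans are reproducible byte-for-byte.

On the full base the leaf blocks are even: 4 × 20,736 → 12 × 6,912 →
24 × 3,456, and the reduction factor (total / mean leaf size) is exactly
24. On non-product rule bases blocks may be uneven and the factor reports
total / mean-leaf-size; per-size candidate counts of uneven bases are not
asserted anywhere because no rounding rule for them is defined.

## Output axis and defuzzification numerics

The output variable fixes only three labels and integers 1–3, so the axis
is a design choice: z ∈ [0.5, 3.5] with symmetric triangles of half-width 1
at z = 1, 2, 3, apexes on the class integers. The class-1 and class-3
triangles are truncated by the axis ends; only the class-2 triangle is
symmetric within the axis, which is the case the "apex read-out" exactness
property tests.

Integration uses a uniform grid (default 1,001 points, configurable)
**augmented with the exact kink locations** of the clipped output sets —
set breakpoints plus clip-level crossings — and a closed-form per-cell
quadrature for both moments (∫f and ∫z·f are exact for a curve linear
within each cell). A plain uniform grid leaves kinks between nodes and caps
relative accuracy near 1e-5 however fine the grid; with the augmentation
the center of sums is exact to float round-off, and agreement with an
independent 10×-resolution trapezoidal integral is limited only by that
oracle's own discretization (measured ≲ 7e-8 for activations ≥ 0.01; below
that the oracle, not the engine, dominates the difference). The
centroid-of-max variant shares the machinery; kinks where two clipped
curves cross mid-cell are resolved only to grid resolution, which is
immaterial for the single-activated-class case where the two defuzzifiers
coincide exactly.

All-zero activations raise `UnclassifiableRecord` rather than returning a
score — records that fire nothing are reported, never silently dropped.

## Data handling

The reader consumes the UCI processed-Cleveland dialect (14 columns, `?`
missing). `exang`, `slope` and `ca` are not among the ten diagnostic
inputs and are dropped with a logged notice; `num` (the dataset's original
disease label, 0–4) is carried through to results for external comparison
only and never used as input. The `fbs` column is a 0/1 flag for fasting
blood sugar > 120 mg/dL while the engine's variable is in mg/dL; flags map
to representative concentrations (0 → 90, 1 → 150 mg/dL) chosen to
fuzzify to exactly one-hot normal / very-high degrees, and a value > 1 in
that column is taken as mg/dL directly. The writer emits mg/dL with
shortest-exact float formatting, so write→read round-trips are lossless.
Rows with a missing crisp key attribute are retained but flagged: the
index cannot route them, so they fall back to exhaustive search or are
excluded, per caller choice.

## Synthetic records

The generator emulates records spanning the engine's full operating range:
crisp codes uniform over their code sets (chest pain 1–4, thallium
3/6/7, gender 0/1, ECG 0/1/2 as integer codes), continuous attributes
uniform over their axis domains, all driven by one `numpy` Generator seeded
from a single top-level seed, so identical configs reproduce identical
tables. An optional `critical_skew` knob (power-transform toward each
variable's severe end) supports stress tests; it defaults to 0 and is not
used in any shipped result. What the generator does **not** emulate:
empirical correlations between attributes (age–max-HR, cholesterol–BP),
realistic marginal distributions, or missingness patterns of clinical
data. Passing tests therefore demonstrate the engine's combinatorial and
numerical correctness over the full input space, not clinical accuracy on
real cohorts — validating the severity-sum policy against outcomes data is
out of scope.

## Problem sizes and determinism

The shipped tests and the acceptance script run the full 82,944-rule base
(enumeration ≈ 1 s, index build < 1 s) and 1,000 synthetic records for the
indexed-vs-exhaustive equivalence check (vectorized strengths over the
antecedent index matrix; ≈ 10 s). All randomness flows through explicit
seeds; enumeration, indexing and serialization are fully deterministic.

## Known limitations

- The reconstructed membership shapes (flagged above) are constrained
  choices, not published ground truth; swapping in corrected anchors is a
  one-line edit per set in the constants table.
- The severity-sum consequent policy is a stand-in for expert-authored
  rules; the engine accepts explicit rule files for production use.
- Cholesterol thresholds are applied to the CSV's cholesterol column as-is;
  whether that column is LDL or total cholesterol differs between sources.
- The index is rebuilt from the rule file on each run; it is not persisted
  and not safe under concurrent mutation.
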