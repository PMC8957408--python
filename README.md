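# cardiotriage

A Mamdani fuzzy inference engine that triages heart-disease patient records
into three criticality classes — 1 *very critical*, 2 *less critical*,
3 *normal* — and routes each to the matching protection ring, with an
indexed rule store that cuts rule search on the full rule base by 24:1.

It is aimed at clinical decision-support and health-records work: records
arrive in the UCI processed-Cleveland CSV layout (14 comma-separated
attributes, `?` for missing), and ten diagnostic attributes feed the
engine: chest pain type, blood pressure, cholesterol, blood sugar, maximum
heart rate, resting ECG, old peak (exercise-induced ST depression),
thallium scan, gender and age.

## The model

Each attribute *i* is a fuzzy variable with ordered linguistic sets and
piecewise-linear membership functions μ(x) ∈ [0, 1] (e.g. blood pressure:
*low*, *medium*, *high*, *very high*). The rule base is the full Cartesian
product of the set names,

    N = ∏ᵢ (number of fuzzy values of variable i)
      = 4·4·4·2·3·3·3·3·2·4 = 82,944 rules,

each an AND-connected IF–THEN rule whose firing strength for a fuzzified
record is the minimum of its antecedent degrees. Per class, the maximum
firing strength clips that class's output set on the score axis
z ∈ [0.5, 3.5] (triangles at z = 1, 2, 3), and the *center of sums*
defuzzifier

    z* = ∫ z Σ_c min(μ_c(z), a_c) dz / ∫ Σ_c min(μ_c(z), a_c) dz

yields the crisp criticality score; the class with maximum output
membership at z* (ties toward the more critical class) is the verdict and
protection ring.

Three attributes — chest pain type, thallium scan, gender — are *crisp*:
their sets never overlap, so a record matches exactly one set of each.
Sorting the rules by this composite key and indexing the sorted blocks
(B+-tree leaf contract: sorted keys, contiguous linked leaves) lets a query
fetch a single leaf block: 82,944 → 20,736 (chest pain) → 6,912
(+ thallium) → 3,456 (+ gender), a 4·3·2 = 24:1 reduction in rules
scanned, with bit-identical classification results.

Because no published rule→class mapping exists, consequents are assigned by
a documented *severity-sum* policy (ordinal per-set severities, normalized
sum, cuts at 0.40 / 0.70) — or supplied explicitly in the rule file, which
makes the engine policy-agnostic.

## Worked example

```sh
python examples/classify_record.py
```

```
defuzzified criticality score z* = 2.000
criticality class               = 2 (less_critical)
protection ring                 = 2
rules fired                     = 1
search scope                    = indexed
```

The record (asymptomatic angina, BP 100 mmHg, cholesterol 210 mg/dL, sugar
90 mg/dL, hypertrophy ECG, max HR 80 bpm, old peak 3.0, normal thallium,
female, age 70) sits on membership plateaus for every attribute, so exactly
one rule fires at full strength; its class-2 output set defuzzifies to
z* = 2.0, read out as *less critical* and routed to protection ring 2. The
indexed search scanned only the 3,456-rule leaf block for (asymptomatic,
normal, female) rather than all 82,944 rules.

The other examples show membership curves (`membership_curves.py`), the
index's block structure and 24:1 ratio (`rule_indexing.py`) and a seeded
200-record synthetic cohort (`synthetic_cohort.py`).

## Command line

```sh
cardiotriage simulate --n 100 --seed 1 --out records.csv
cardiotriage generate-rules --out rules.jsonl
cardiotriage classify records.csv --rules rules.jsonl --out results.csv
cardiotriage benchmark records.csv     # exhaustive vs indexed counts
cardiotriage show-variables            # fuzzy variable definitions as JSON
```

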