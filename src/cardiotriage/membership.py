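"""Fuzzy variables, membership functions and fuzzification.

The ten diagnostic attributes of a heart-disease record (chest pain type,
blood pressure, cholesterol, blood sugar, maximum heart rate, resting ECG,
old peak, thallium scan, gender, age) are modelled as fuzzy variables. Each
variable carries an ordered list of fuzzy sets with piecewise-linear
membership functions; three of the variables (chest pain type, thallium
scan, gender) are *crisp* — their sets never overlap, a record matches
exactly one set, and they can therefore serve as index keys downstream.

Every numeric breakpoint lives in the single ``_CANONICAL_SPEC`` table below
so that a correction to any membership anchor is a one-line edit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

__all__ = [
    "FuzzySet",
    "FuzzyVariable",
    "PatientRecord",
    "FuzzifiedRecord",
    "canonical_variables",
    "membership_value",
    "fuzzify",
    "variables_to_json",
    "variables_from_json",
    "CRISP_VARIABLES",
]

# Set kinds. "crisp" is a singleton on an integer code; the rest are the
# standard piecewise-linear shapes.
_KINDS = ("crisp", "ramp_down", "ramp_up", "triangle", "trapezoid")

_N_BREAKPOINTS = {
    "crisp": 2,  # [code, code]
    "ramp_down": 2,  # 1 for x<=a, linear a->b, 0 beyond
    "ramp_up": 2,  # 0 for x<=a, linear a->b, 1 beyond
    "triangle": 3,
    "trapezoid": 4,
}


@dataclass(frozen=True)
class FuzzySet:
    """One linguistic value of a fuzzy variable.

    ``severity`` is the ordinal position of this set on the variable's
    clinical risk scale (1 = least severe); it drives the default
    rule-consequent policy. ``reconstructed`` flags sets whose shape is an
    implementation reconstruction rather than a published anchor set.
    """

    name: str
    kind: str
    breakpoints: tuple[float, ...]
    severity: int = 1
    reconstructed: bool = False

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown fuzzy set kind {self.kind!r}")
        bp = tuple(float(b) for b in self.breakpoints)
        object.__setattr__(self, "breakpoints", bp)
        if len(bp) != _N_BREAKPOINTS[self.kind]:
            raise ValueError(
                f"set {self.name!r}: kind {self.kind!r} needs "
                f"{_N_BREAKPOINTS[self.kind]} breakpoints, got {len(bp)}"
            )
        if any(b2 < b1 for b1, b2 in zip(bp, bp[1:])):
            raise ValueError(f"set {self.name!r}: breakpoints must be non-decreasing: {bp}")
        if self.severity < 1:
            raise ValueError(f"set {self.name!r}: severity must be >= 1")

    def degree(self, x: float) -> float:
        """Membership degree of ``x``, always in [0, 1]."""
        bp = self.breakpoints
        if self.kind == "crisp":
            return 1.0 if x == bp[0] else 0.0
        if self.kind == "ramp_down":
            a, b = bp
            if x <= a:
                return 1.0
            if x >= b:
                return 0.0
            return (b - x) / (b - a)
        if self.kind == "ramp_up":
            a, b = bp
            if x <= a:
                return 0.0
            if x >= b:
                return 1.0
            return (x - a) / (b - a)
        if self.kind == "triangle":
            a, b, c = bp
            if x <= a or x >= c:
                # apex may sit on a degenerate shoulder
                return 1.0 if x == b else 0.0
            if x <= b:
                return 1.0 if a == b else (x - a) / (b - a)
            return 1.0 if b == c else (c - x) / (c - b)
        # trapezoid
        a, b, c, d = bp
        if x < a or x > d:
            return 0.0
        if x < b:
            return (x - a) / (b - a)
        if x <= c:
            return 1.0
        if x == d:
            return 0.0
        return (d - x) / (d - c)


@dataclass(frozen=True)
class FuzzyVariable:
    """A named input attribute with its ordered fuzzy sets.

    ``is_constant`` marks the crisp attributes whose sets never overlap
    (chest pain type, thallium scan, gender) — these are usable as composite
    index keys. Construction enforces set-name uniqueness and coverage: every
    point of ``domain`` must have positive membership in at least one set.
    """

    name: str
    domain: tuple[float, float]
    units: str
    sets: tuple[FuzzySet, ...]
    is_constant: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "domain", (float(self.domain[0]), float(self.domain[1])))
        object.__setattr__(self, "sets", tuple(self.sets))
        names = [s.name for s in self.sets]
        if len(set(names)) != len(names):
            raise ValueError(f"variable {self.name!r}: duplicate set names {names}")
        if not self.sets:
            raise ValueError(f"variable {self.name!r}: needs at least one set")
        if self.domain[0] >= self.domain[1]:
            raise ValueError(f"variable {self.name!r}: empty domain {self.domain}")
        self._check_coverage()

    def _check_coverage(self) -> None:
        if self.is_constant:
            # crisp variables cover only their codes; nothing to sweep
            return
        lo, hi = self.domain
        n = 1001
        for i in range(n):
            x = lo + (hi - lo) * i / (n - 1)
            if not any(s.degree(x) > 0.0 for s in self.sets):
                raise ValueError(
                    f"variable {self.name!r}: no set has positive membership at x={x:g}"
                )

    @property
    def set_names(self) -> tuple[str, ...]:
        return tuple(s.name for s in self.sets)

    def set(self, name: str) -> FuzzySet:
        for s in self.sets:
            if s.name == name:
                return s
        raise KeyError(f"variable {self.name!r} has no set {name!r}; have {self.set_names}")

    @property
    def cardinality(self) -> int:
        return len(self.sets)

    def codes(self) -> tuple[float, ...]:
        """Valid codes of a crisp variable."""
        if not self.is_constant:
            raise ValueError(f"variable {self.name!r} is not crisp")
        return tuple(s.breakpoints[0] for s in self.sets)


def membership_value(variable: FuzzyVariable, set_name: str, x: float) -> float:
    """Evaluate the named set's membership at ``x``.

    Raises ``KeyError`` for an unknown set name and ``ValueError`` when ``x``
    falls outside the variable's domain (rejected rather than clamped, so
    unit mistakes surface at the reader instead of being silently absorbed).
    """
    s = variable.set(set_name)
    lo, hi = variable.domain
    if not (lo <= x <= hi):
        raise ValueError(
            f"{variable.name}={x:g} outside domain [{lo:g}, {hi:g}] ({variable.units})"
        )
    d = s.degree(float(x))
    # piecewise pieces are already bounded; clip guards float round-off
    return min(1.0, max(0.0, d))


# ---------------------------------------------------------------------------
# Canonical variable definitions
#
# ONE constants table. Each entry: (set name, kind, breakpoints, severity,
# reconstructed). Comments cite the source anchors; "reconstructed" marks
# shapes chosen here because no legible anchors exist for them.
# ---------------------------------------------------------------------------

CRISP_VARIABLES = ("chest_pain", "thallium", "gender")

_CANONICAL_SPEC: tuple[dict, ...] = (
    {
        "name": "chest_pain",
        "units": "code",
        "domain": (1, 4),
        "is_constant": True,
        "sets": [
            # codes 1-4: typical / atypical / nontypical / asymptomatic angina
            ("typical", "crisp", (1, 1), 1, False),
            ("atypical", "crisp", (2, 2), 2, False),
            ("nontypical", "crisp", (3, 3), 3, False),
            ("asymptomatic", "crisp", (4, 4), 4, False),
        ],
    },
    {
        "name": "blood_pressure",
        "units": "mmHg",
        "domain": (80, 220),
        "is_constant": False,
        "sets": [
            # low: 1 below 110, (130-x)/20 on [110,130)
            ("low", "ramp_down", (110, 130), 1, False),
            # medium: legible anchors 125 / 136 / 152; printed slopes corrupt
            ("medium", "triangle", (125, 136, 152), 2, True),
            # high: (x-140)/15, 1 at 155, (170-x)/15
            ("high", "triangle", (140, 155, 170), 3, False),
            # very high: ramp 152->170, plateau above 170
            ("very_high", "ramp_up", (152, 170), 4, False),
        ],
    },
    {
        "name": "cholesterol",
        "units": "mg/dL",
        "domain": (100, 600),
        "is_constant": False,
        "sets": [
            # low: plateau below 145, (195-x)/50 on [145,195)
            ("low", "ramp_down", (145, 195), 1, False),
            # medium: (x-186)/24, 1 at 210, (245-x)/35
            ("medium", "triangle", (186, 210, 245), 2, False),
            # high: (x-215)/45, 1 at 260, (306-x)/46
            ("high", "triangle", (215, 260, 306), 3, False),
            # very high: ramp 280->345, plateau above
            ("very_high", "ramp_up", (280, 345), 4, False),
        ],
    },
    {
        "name": "blood_sugar",
        "units": "mg/dL",
        "domain": (50, 400),
        "is_constant": False,
        "sets": [
            # normal complement is never printed; mirror of the very-high ramp
            ("normal", "ramp_down", (100, 120), 1, True),
            # very high: (x-100)/20 on [100,120), 1 above 120
            ("very_high", "ramp_up", (100, 120), 2, False),
        ],
    },
    {
        "name": "max_heart_rate",
        "units": "bpm",
        "domain": (60, 260),
        "is_constant": False,
        "sets": [
            # low: 1 below 95, (140-x)/45 on [95,140); low achieved max HR is
            # the clinical risk direction, hence the inverted severities
            ("low", "ramp_down", (95, 140), 3, False),
            # medium: legible anchors 110 / 153 / 195
            ("medium", "triangle", (110, 153, 195), 2, True),
            # high: (x-155)/60 on [155,215), 1 above 215
            ("high", "ramp_up", (155, 215), 1, False),
        ],
    },
    {
        "name": "ecg",
        "units": "code",
        "domain": (0, 2),
        "is_constant": False,
        "sets": [
            # no membership functions are published for resting ECG; three
            # evenly spaced triangles over the 0/1/2 code axis
            ("normal", "ramp_down", (0, 1), 1, True),
            ("st_t_abnormal", "triangle", (0, 1, 2), 2, True),
            ("hypertrophy", "ramp_up", (1, 2), 3, True),
        ],
    },
    {
        "name": "old_peak",
        "units": "mm ST depression",
        "domain": (0, 6),
        "is_constant": False,
        "sets": [
            # shapes unpublished; "risk" is the one named linguistic value
            ("low", "ramp_down", (0, 3), 1, True),
            ("risk", "triangle", (0, 3, 6), 2, True),
            ("terrible", "ramp_up", (3, 6), 3, True),
        ],
    },
    {
        "name": "thallium",
        "units": "code",
        "domain": (3, 7),
        "is_constant": True,
        "sets": [
            # UCI codes: 3 normal, 6 fixed defect, 7 reversible defect;
            # alphabetical set order (fixed_defect, normal, reversible_defect)
            ("fixed_defect", "crisp", (6, 6), 2, False),
            ("normal", "crisp", (3, 3), 1, False),
            ("reversible_defect", "crisp", (7, 7), 3, False),
        ],
    },
    {
        "name": "gender",
        "units": "code",
        "domain": (0, 1),
        "is_constant": True,
        "sets": [
            # 0 = male, 1 = female
            ("male", "crisp", (0, 0), 2, False),
            ("female", "crisp", (1, 1), 1, False),
        ],
    },
    {
        "name": "age",
        "units": "years",
        "domain": (1, 120),
        "is_constant": False,
        "sets": [
            # young: plateau below 25, (35-x)/10 on [25,35)
            ("young", "ramp_down", (25, 35), 1, False),
            # mid: (x-30)/5, 1 at 35, (45-x)/10
            ("mid", "triangle", (30, 35, 45), 2, False),
            # old: (x-42)/8, 1 at 50, (58-x)/8
            ("old", "triangle", (42, 50, 58), 3, False),
            # very old: (x-55)/6 on [55,61), 1 above 61
            ("very_old", "ramp_up", (55, 61), 4, False),
        ],
    },
)

VARIABLE_ORDER = tuple(v["name"] for v in _CANONICAL_SPEC)


def canonical_variables() -> list[FuzzyVariable]:
    """The ten diagnostic fuzzy variables with their canonical fuzzy sets.

    Cardinalities are 4, 4, 4, 2, 3, 3, 3, 3, 2, 4 (chest pain, blood
    pressure, cholesterol, blood sugar, max heart rate, ECG, old peak,
    thallium, gender, age), giving a full rule space of 82,944 combinations.
    """
    out = []
    for spec in _CANONICAL_SPEC:
        sets = tuple(
            FuzzySet(name=n, kind=k, breakpoints=bp, severity=sev, reconstructed=rec)
            for (n, k, bp, sev, rec) in spec["sets"]
        )
        out.append(
            FuzzyVariable(
                name=spec["name"],
                domain=spec["domain"],
                units=spec["units"],
                sets=sets,
                is_constant=spec["is_constant"],
            )
        )
    return out


# ---------------------------------------------------------------------------
# Records and fuzzification
# ---------------------------------------------------------------------------


@dataclass
class PatientRecord:
    """One patient's crisp attribute values.

    Codes: chest_pain 1-4; ecg 0-2; thallium 3/6/7; gender 0 male, 1 female.
    Continuous values in the units of their variables (mmHg, mg/dL, bpm,
    years). ``None`` marks a missing value.
    """

    chest_pain: float | None = None
    blood_pressure: float | None = None
    cholesterol: float | None = None
    blood_sugar: float | None = None
    max_heart_rate: float | None = None
    ecg: float | None = None
    old_peak: float | None = None
    thallium: float | None = None
    gender: float | None = None
    age: float | None = None
    record_id: int | None = None

    def value(self, variable_name: str) -> float | None:
        return getattr(self, variable_name)

    def missing(self) -> list[str]:
        return [v for v in VARIABLE_ORDER if getattr(self, v) is None]

    def validate(self, variables: Sequence[FuzzyVariable]) -> None:
        """Check every present value against its variable's domain/codes."""
        for var in variables:
            x = self.value(var.name)
            if x is None:
                continue
            lo, hi = var.domain
            if not (lo <= x <= hi):
                raise ValueError(
                    f"record {self.record_id}: {var.name}={x:g} outside "
                    f"[{lo:g}, {hi:g}] ({var.units})"
                )
            if var.is_constant and x not in var.codes():
                raise ValueError(
                    f"record {self.record_id}: {var.name}={x:g} is not one of "
                    f"the valid codes {var.codes()}"
                )


@dataclass
class FuzzifiedRecord:
    """Per-variable map set-name -> membership degree in [0, 1]."""

    degrees: dict[str, dict[str, float]] = field(default_factory=dict)

    def degree(self, variable_name: str, set_name: str) -> float:
        try:
            return self.degrees[variable_name][set_name]
        except KeyError:
            raise KeyError(
                f"no fuzzified degree for {variable_name}.{set_name}"
            ) from None


def fuzzify(record: PatientRecord, variables: Sequence[FuzzyVariable]) -> FuzzifiedRecord:
    """Compute membership degrees of every set of every variable.

    Crisp variables yield a one-hot degree map. Missing values raise — the
    caller decides whether to skip or fall back.
    """
    record.validate(variables)
    degrees: dict[str, dict[str, float]] = {}
    for var in variables:
        x = record.value(var.name)
        if x is None:
            raise ValueError(
                f"record {record.record_id}: missing value for {var.name!r}; "
                "cannot fuzzify"
            )
        degrees[var.name] = {s.name: membership_value(var, s.name, x) for s in var.sets}
    return FuzzifiedRecord(degrees=degrees)


# ---------------------------------------------------------------------------
# JSON round-trip — the variables file is the single source of truth used by
# the rule base, the index and the CLI.
# ---------------------------------------------------------------------------


def variables_to_json(variables: Sequence[FuzzyVariable]) -> str:
    doc = [
        {
            "name": v.name,
            "units": v.units,
            "domain": list(v.domain),
            "is_constant": v.is_constant,
            "sets": [
                {
                    "name": s.name,
                    "kind": s.kind,
                    "breakpoints": list(s.breakpoints),
                    "severity": s.severity,
                    "reconstructed": s.reconstructed,
                }
                for s in v.sets
            ],
        }
        for v in variables
    ]
    return json.dumps(doc, indent=2)


def variables_from_json(text: str) -> list[FuzzyVariable]:
    doc = json.loads(text)
    out = []
    for v in doc:
        sets = tuple(
            FuzzySet(
                name=s["name"],
                kind=s["kind"],
                breakpoints=tuple(s["breakpoints"]),
                severity=s.get("severity", 1),
                reconstructed=s.get("reconstructed", False),
            )
            for s in v["sets"]
        )
        out.append(
            FuzzyVariable(
                name=v["name"],
                domain=tuple(v["domain"]),
                units=v.get("units", ""),
                sets=sets,
                is_constant=v.get("is_constant", False),
            )
        )
    return out
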