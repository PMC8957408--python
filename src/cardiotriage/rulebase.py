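"""Fuzzy rule base: enumeration, consequent policies, serialization.

A rule base over the ten canonical variables is the full Cartesian product
of their fuzzy-set names — 4*4*4*2*3*3*3*3*2*4 = 82,944 AND-connected
IF-THEN rules, each mapping an antecedent (one fuzzy set per variable) to a
criticality class: 1 very critical, 2 less critical, 3 normal.

Rules are enumerated in a canonical order: the crisp (constant) variables
first — chest pain type, thallium scan, gender — then the remaining
variables, with the last variable varying fastest. This makes every
composite-key block of the rule index a contiguous span of rule ids.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from itertools import product
from typing import Iterable, Sequence

import numpy as np

from .membership import CRISP_VARIABLES, FuzzyVariable

__all__ = [
    "FuzzyRule",
    "RuleBase",
    "rule_space_size",
    "enumerate_rules",
    "assign_consequents",
    "canonical_rule_order",
    "save_rules",
    "load_rules",
    "CONSEQUENT_POLICIES",
    "SEVERITY_CUTS",
]

VERY_CRITICAL, LESS_CRITICAL, NORMAL = 1, 2, 3

# Normalized severity-sum cut points: s < 0.40 -> normal (3),
# 0.40 <= s < 0.70 -> less critical (2), s >= 0.70 -> very critical (1).
SEVERITY_CUTS = (0.40, 0.70)

CONSEQUENT_POLICIES = ("severity-sum", "explicit")


@dataclass(frozen=True)
class FuzzyRule:
    """One IF-THEN rule: AND-connected antecedent plus a criticality class."""

    rule_id: int
    antecedent: tuple[tuple[str, str], ...]  # ((variable, set), ...) in canonical order
    consequent: int  # 1 very critical | 2 less critical | 3 normal

    def __post_init__(self) -> None:
        if self.consequent not in (1, 2, 3):
            raise ValueError(f"rule {self.rule_id}: consequent must be 1, 2 or 3")

    @property
    def antecedent_map(self) -> dict[str, str]:
        return dict(self.antecedent)


def canonical_rule_order(variables: Sequence[FuzzyVariable]) -> list[FuzzyVariable]:
    """Constant (crisp) variables first, then the rest in declared order."""
    crisp = [v for v in variables if v.name in CRISP_VARIABLES and v.is_constant]
    crisp.sort(key=lambda v: CRISP_VARIABLES.index(v.name))
    rest = [v for v in variables if v not in crisp]
    return crisp + rest


@dataclass
class RuleBase:
    """A list of rules plus the variables they were built against."""

    variables: list[FuzzyVariable]
    rules: list[FuzzyRule]
    provenance: str = "enumerated"
    policy: str = "severity-sum"
    _matrix_cache: np.ndarray | None = field(default=None, repr=False, compare=False)
    _consequent_cache: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __len__(self) -> int:
        return len(self.rules)

    @property
    def variable_order(self) -> tuple[str, ...]:
        return tuple(v.name for v in self.variables)

    def variable(self, name: str) -> FuzzyVariable:
        for v in self.variables:
            if v.name == name:
                return v
        raise KeyError(f"rule base has no variable {name!r}")

    def validate(self) -> None:
        """Antecedents reference declared sets only; antecedents are unique."""
        sets = {v.name: set(v.set_names) for v in self.variables}
        seen: set[tuple] = set()
        ids: set[int] = set()
        for r in self.rules:
            if r.rule_id in ids:
                raise ValueError(f"duplicate rule_id {r.rule_id}")
            ids.add(r.rule_id)
            if r.antecedent in seen:
                raise ValueError(f"rule {r.rule_id}: duplicate antecedent {r.antecedent}")
            seen.add(r.antecedent)
            for var, sname in r.antecedent:
                if var not in sets:
                    raise ValueError(f"rule {r.rule_id}: unknown variable {var!r}")
                if sname not in sets[var]:
                    raise ValueError(
                        f"rule {r.rule_id}: variable {var!r} has no set {sname!r}"
                    )

    def antecedent_matrix(self) -> np.ndarray:
        """(n_rules, n_variables) int matrix of set indices, for vectorized
        firing-strength evaluation. Column order = ``variable_order``."""
        if self._matrix_cache is None:
            set_index = {
                v.name: {s: i for i, s in enumerate(v.set_names)} for v in self.variables
            }
            m = np.empty((len(self.rules), len(self.variables)), dtype=np.int64)
            order = self.variable_order
            for i, r in enumerate(self.rules):
                amap = r.antecedent_map
                for j, vname in enumerate(order):
                    m[i, j] = set_index[vname][amap[vname]]
            self._matrix_cache = m
        return self._matrix_cache

    def consequents_array(self) -> np.ndarray:
        if self._consequent_cache is None:
            self._consequent_cache = np.fromiter(
                (r.consequent for r in self.rules), dtype=np.int64, count=len(self.rules)
            )
        return self._consequent_cache


def rule_space_size(cardinalities: Iterable[int]) -> int:
    """Size of the full rule space: the product of per-variable fuzzy-value
    counts. The canonical cardinalities (4,4,4,2,3,3,3,3,2,4) give 82,944."""
    cards = list(cardinalities)
    if not cards:
        raise ValueError("cardinalities must be non-empty")
    if any(c < 1 for c in cards):
        raise ValueError(f"cardinalities must all be >= 1, got {cards}")
    return math.prod(cards)


def _severity_class(antecedent: tuple[tuple[str, str], ...],
                    severity: dict[str, dict[str, int]],
                    smin: int, smax: int) -> int:
    total = sum(severity[v][s] for v, s in antecedent)
    s = 0.0 if smax == smin else (total - smin) / (smax - smin)
    lo, hi = SEVERITY_CUTS
    if s < lo:
        return NORMAL
    if s < hi:
        return LESS_CRITICAL
    return VERY_CRITICAL


def enumerate_rules(variables: Sequence[FuzzyVariable],
                    consequent_policy: str = "severity-sum") -> RuleBase:
    """Enumerate one rule per element of the Cartesian product of fuzzy-set
    names, in canonical order, with consequents assigned by the named policy.

    Deterministic: the same variables yield byte-identical rule lists.
    """
    if consequent_policy not in CONSEQUENT_POLICIES:
        raise ValueError(
            f"unknown consequent policy {consequent_policy!r}; "
            f"available: {CONSEQUENT_POLICIES}"
        )
    if consequent_policy == "explicit":
        raise ValueError(
            "policy 'explicit' requires consequents already present; "
            "load them from a rule file instead of enumerating"
        )
    ordered = canonical_rule_order(list(variables))
    severity = {v.name: {s.name: s.severity for s in v.sets} for v in ordered}
    smin = sum(min(d.values()) for d in severity.values())
    smax = sum(max(d.values()) for d in severity.values())
    names = [v.name for v in ordered]
    rules: list[FuzzyRule] = []
    for rid, combo in enumerate(product(*(v.set_names for v in ordered))):
        ant = tuple(zip(names, combo))
        rules.append(
            FuzzyRule(
                rule_id=rid,
                antecedent=ant,
                consequent=_severity_class(ant, severity, smin, smax),
            )
        )
    return RuleBase(variables=ordered, rules=rules,
                    provenance="enumerated", policy=consequent_policy)


def assign_consequents(rules: Sequence[FuzzyRule],
                       variables: Sequence[FuzzyVariable],
                       policy: str = "severity-sum") -> list[FuzzyRule]:
    """Re-assign consequents to existing rules under the named policy."""
    if policy == "explicit":
        if any(r.consequent not in (1, 2, 3) for r in rules):
            raise ValueError("policy 'explicit': every rule must carry a consequent")
        return list(rules)
    if policy != "severity-sum":
        raise ValueError(f"unknown consequent policy {policy!r}; available: {CONSEQUENT_POLICIES}")
    severity: dict[str, dict[str, int]] = {}
    for v in variables:
        severity[v.name] = {s.name: s.severity for s in v.sets}
    smin = sum(min(d.values()) for d in severity.values())
    smax = sum(max(d.values()) for d in severity.values())
    out = []
    for r in rules:
        for vname, sname in r.antecedent:
            if vname not in severity or sname not in severity[vname]:
                raise ValueError(
                    f"rule {r.rule_id}: no severity annotation for {vname}.{sname}"
                )
        out.append(
            FuzzyRule(
                rule_id=r.rule_id,
                antecedent=r.antecedent,
                consequent=_severity_class(r.antecedent, severity, smin, smax),
            )
        )
    return out


# ---------------------------------------------------------------------------
# Serialization: JSON Lines, one rule per line, with a header line recording
# the hash of the variables document the base was built against.
# ---------------------------------------------------------------------------


def _variables_hash(variables: Sequence[FuzzyVariable]) -> str:
    from .membership import variables_to_json

    return hashlib.sha256(variables_to_json(variables).encode()).hexdigest()[:16]


def save_rules(rulebase: RuleBase, destination) -> None:
    """Write a rule base as JSON Lines: a header line, then one rule per line
    ``{"id": int, "if": {var: set, ...}, "then": 1|2|3}``."""

    def _write(fh) -> None:
        header = {
            "format": "cardiotriage-rules-v1",
            "variables_hash": _variables_hash(rulebase.variables),
            "provenance": rulebase.provenance,
            "policy": rulebase.policy,
            "n_rules": len(rulebase.rules),
        }
        fh.write(json.dumps(header) + "\n")
        for r in rulebase.rules:
            fh.write(
                json.dumps(
                    {"id": r.rule_id, "if": dict(r.antecedent), "then": r.consequent},
                    separators=(",", ":"),
                )
                + "\n"
            )

    if hasattr(destination, "write"):
        _write(destination)
    else:
        with open(destination, "w") as fh:
            _write(fh)


def load_rules(source, variables: Sequence[FuzzyVariable]) -> RuleBase:
    """Read a JSON Lines rule file and validate it against ``variables``.

    Raises a parse error with line context for malformed lines and a
    validation error for rules naming undeclared variables or sets.
    """

    def _read(fh) -> RuleBase:
        lines = fh.read().splitlines()
        if not lines:
            raise ValueError("empty rule file")
        try:
            header = json.loads(lines[0])
        except json.JSONDecodeError as e:
            raise ValueError(f"rule file line 1: bad header: {e}") from e
        rules = []
        var_order = [v.name for v in variables]
        for lineno, line in enumerate(lines[1:], start=2):
            if not line.strip():
                continue
            try:
                doc = json.loads(line)
                if len(rules) == 0 and set(doc["if"]) == set(var_order):
                    # antecedent key order in the file is authoritative
                    var_order = list(doc["if"])
                ant = tuple((v, doc["if"][v]) for v in var_order)
                if set(doc["if"]) != set(var_order):
                    raise KeyError(
                        f"antecedent variables {sorted(doc['if'])} != "
                        f"declared {sorted(var_order)}"
                    )
                rules.append(
                    FuzzyRule(rule_id=int(doc["id"]), antecedent=ant,
                              consequent=int(doc["then"]))
                )
            except (json.JSONDecodeError, KeyError, TypeError, ValueError) as e:
                raise ValueError(f"rule file line {lineno}: {e}") from e
        by_name = {v.name: v for v in variables}
        ordered_vars = [by_name[n] for n in var_order if n in by_name]
        if len(ordered_vars) != len(variables):
            ordered_vars = list(variables)
        rb = RuleBase(
            variables=ordered_vars,
            rules=rules,
            provenance=header.get("provenance", "loaded"),
            policy=header.get("policy", "explicit"),
        )
        rb.validate()
        return rb

    if hasattr(source, "read"):
        return _read(source)
    with open(source) as fh:
        return _read(fh)
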