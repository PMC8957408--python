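"""Record I/O and synthetic record generation.

Reads patient records in the UCI processed-Cleveland CSV dialect: 14
comma-separated attributes per row in the order

    age, sex, cp, trestbps, chol, fbs, restecg, thalach, exang, oldpeak,
    slope, ca, thal, num

with "?" marking missing values. Ten of the fourteen feed the fuzzy engine
(exang, slope and ca are not among its diagnostic inputs and are dropped
with a logged notice; num — the original dataset's disease label — is
carried through to results for external comparison only, never used as
input).

The fbs column is a 0/1 "fasting blood sugar > 120 mg/dL" flag while the
engine's blood-sugar variable is in mg/dL; flag values are mapped to
representative concentrations (0 -> 90, 1 -> 150 mg/dL) that fuzzify to
exactly one-hot normal / very-high degrees. A numeric value > 1 in that
column is taken as mg/dL directly, which makes write/read round-trips exact.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .membership import (
    CRISP_VARIABLES,
    FuzzyVariable,
    PatientRecord,
    VARIABLE_ORDER,
    canonical_variables,
)

__all__ = [
    "RecordTable",
    "SyntheticConfig",
    "read_uci_csv",
    "write_records_csv",
    "generate_synthetic_records",
    "UCI_COLUMNS",
    "FBS_FLAG_MGDL",
]

logger = logging.getLogger("cardiotriage")

UCI_COLUMNS = (
    "age", "sex", "cp", "trestbps", "chol", "fbs", "restecg",
    "thalach", "exang", "oldpeak", "slope", "ca", "thal", "num",
)
_DROPPED = ("exang", "slope", "ca")

# representative mg/dL for the UCI 0/1 fasting-blood-sugar flag
FBS_FLAG_MGDL = {0.0: 90.0, 1.0: 150.0}

# UCI column -> engine variable
_COLUMN_MAP = {
    "age": "age",
    "sex": "gender",
    "cp": "chest_pain",
    "trestbps": "blood_pressure",
    "chol": "cholesterol",
    "fbs": "blood_sugar",
    "restecg": "ecg",
    "thalach": "max_heart_rate",
    "oldpeak": "old_peak",
    "thal": "thallium",
}


@dataclass
class RecordTable:
    """Parsed records with provenance and a missing-value mask."""

    records: list[PatientRecord]
    line_numbers: list[int]
    missing_key: list[bool]  # True: a crisp key attribute is missing
    num_labels: list[float | None]  # UCI "num" column, carried through only
    n_rejected: int = 0
    reject_reasons: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def classifiable(self) -> list[PatientRecord]:
        return [r for r, m in zip(self.records, self.missing_key) if not m
                and not r.missing()]


def _parse_field(raw: str, column: str, lineno: int) -> float | None:
    raw = raw.strip()
    if raw in ("?", ""):
        return None
    try:
        return float(raw)
    except ValueError:
        raise ValueError(
            f"line {lineno}: non-numeric value {raw!r} in column {column!r}"
        ) from None


def read_uci_csv(source,
                 variables: Sequence[FuzzyVariable] | None = None) -> RecordTable:
    """Parse a UCI processed-Cleveland style CSV into a RecordTable.

    Rows failing domain validation are rejected (counted and logged with
    reasons); rows missing a crisp key attribute (chest pain, thallium,
    gender) are retained but flagged, since the indexed search cannot route
    them. A header row matching the UCI column names is skipped.
    """
    variables = list(variables) if variables is not None else canonical_variables()
    if hasattr(source, "read"):
        text = source.read()
    else:
        with open(source) as fh:
            text = fh.read()

    records: list[PatientRecord] = []
    line_numbers: list[int] = []
    missing_key: list[bool] = []
    num_labels: list[float | None] = []
    reject_reasons: list[str] = []
    dropped_noted = False

    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            continue
        fields = [f.strip() for f in line.split(",")]
        if lineno == 1 and fields[0].lower() == "age":
            continue  # header row
        if len(fields) != len(UCI_COLUMNS):
            raise ValueError(
                f"line {lineno}: expected {len(UCI_COLUMNS)} comma-separated "
                f"fields, got {len(fields)}"
            )
        if not dropped_noted:
            logger.info("columns %s are not diagnostic inputs; dropped", _DROPPED)
            dropped_noted = True
        row = {
            col: _parse_field(raw, col, lineno)
            for col, raw in zip(UCI_COLUMNS, fields)
        }
        kwargs: dict[str, float | None] = {}
        for col, varname in _COLUMN_MAP.items():
            val = row[col]
            if col == "fbs" and val is not None and val in FBS_FLAG_MGDL:
                val = FBS_FLAG_MGDL[val]
            kwargs[varname] = val
        rec = PatientRecord(record_id=len(records), **kwargs)
        try:
            rec.validate(variables)
        except ValueError as e:
            reject_reasons.append(str(e))
            logger.warning("rejected %s", e)
            continue
        records.append(rec)
        line_numbers.append(lineno)
        missing_key.append(any(rec.value(k) is None for k in CRISP_VARIABLES))
        num_labels.append(row["num"])

    return RecordTable(
        records=records,
        line_numbers=line_numbers,
        missing_key=missing_key,
        num_labels=num_labels,
        n_rejected=len(reject_reasons),
        reject_reasons=reject_reasons,
    )


def write_records_csv(table: RecordTable, destination) -> None:
    """Write records back in the UCI 14-column layout ("?" for missing).

    The fbs column carries mg/dL (values > 1); exang/slope/ca, which the
    engine does not model, are written as "?". Re-reading the output yields
    identical records.
    """

    def _fmt(x: float | None) -> str:
        if x is None:
            return "?"
        # shortest exact float representation, so re-reading is lossless
        return repr(float(x))

    def _write(fh) -> None:
        for rec, num in zip(table.records, table.num_labels):
            row = {
                "age": rec.age, "sex": rec.gender, "cp": rec.chest_pain,
                "trestbps": rec.blood_pressure, "chol": rec.cholesterol,
                "fbs": rec.blood_sugar, "restecg": rec.ecg,
                "thalach": rec.max_heart_rate, "exang": None,
                "oldpeak": rec.old_peak, "slope": None, "ca": None,
                "thal": rec.thallium, "num": num,
            }
            fh.write(",".join(_fmt(row[c]) for c in UCI_COLUMNS) + "\n")

    if hasattr(destination, "write"):
        _write(destination)
    else:
        with open(destination, "w") as fh:
            _write(fh)


@dataclass
class SyntheticConfig:
    """Configuration of the synthetic record generator.

    Crisp codes are drawn uniformly from their code sets and continuous
    values uniformly within each variable's axis domain, emulating records
    whose attributes span the engine's full operating range; ``ranges`` can
    narrow any variable's sampling interval for stress tests, and
    ``critical_skew`` > 0 shifts continuous draws toward each variable's
    high-severity end (0 = uniform, 1 = strongly skewed).
    """

    n: int
    seed: int = 0
    ranges: dict[str, tuple[float, float]] = field(default_factory=dict)
    critical_skew: float = 0.0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if not 0.0 <= self.critical_skew <= 1.0:
            raise ValueError("critical_skew must be in [0, 1]")


def generate_synthetic_records(
    config: SyntheticConfig,
    variables: Sequence[FuzzyVariable] | None = None,
) -> RecordTable:
    """Draw ``config.n`` reproducible synthetic patient records.

    Same (n, seed, config) -> identical records. All generated records pass
    validation and carry no missing values, so they are always classifiable.
    """
    variables = list(variables) if variables is not None else canonical_variables()
    rng = np.random.default_rng(config.seed)
    records: list[PatientRecord] = []
    for i in range(config.n):
        kwargs: dict[str, float] = {}
        for var in variables:
            if var.is_constant:
                codes = var.codes()
                kwargs[var.name] = float(rng.choice(codes))
            elif var.name == "ecg":
                # resting ECG is recorded as an integer code even though the
                # engine treats it as a fuzzy variable
                lo, hi = config.ranges.get(var.name, var.domain)
                kwargs[var.name] = float(rng.integers(int(lo), int(hi) + 1))
            else:
                lo, hi = config.ranges.get(var.name, var.domain)
                u = rng.uniform()
                if config.critical_skew > 0.0:
                    # power transform pushes mass toward the severe end
                    sev_first = var.sets[0].severity
                    sev_last = var.sets[-1].severity
                    u = u ** (1.0 / (1.0 + config.critical_skew)) \
                        if sev_last >= sev_first else u ** (1.0 + config.critical_skew)
                kwargs[var.name] = lo + (hi - lo) * u
        records.append(PatientRecord(record_id=i, **kwargs))
    for rec in records:
        rec.validate(variables)
    return RecordTable(
        records=records,
        line_numbers=list(range(1, len(records) + 1)),
        missing_key=[False] * len(records),
        num_labels=[None] * len(records),
    )
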