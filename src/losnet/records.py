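"""Admission records, DRG reference tables, and design-matrix encoding.

The unit of analysis is one hospitalization in a department of internal and
emergency medicine.  Each record carries the admission covariates used as
network inputs (sex, age class, cancer flag, admission type, time slot,
weekday, principal discharge diagnosis), the DRG code that links it to the
national reference table, the observed length of stay in days and the
discharge mode.

Two encodings are supported:

* ``macro`` — the whole department pooled; inputs are the covariate dummies
  plus 10 top diagnosis-group dummies and one residual dummy (30 columns).
* ``micro`` — a single clinical unit; same blocks with unit-specific top
  diagnoses plus an internal-transfer indicator (31 columns).

All categorical blocks are fully one-hot encoded (no reference level is
dropped): a perceptron needs no identifiability constraint, and the complete
dummy matrix mirrors how the covariates are specified.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field, fields

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Clinical units of the department.
UNITS = (
    "cardiology",
    "hematology",
    "geriatrics",
    "infectious diseases",
    "internal medicine",
    "emergency medicine",
    "nephrology",
    "neurology",
    "coronary care",
    "gastroenterology",
    "oncology",
    "respiratory diseases",
    "rheumatology",
)

#: Units large enough for a per-unit (micro) model.
MICRO_UNITS = (
    "internal medicine",
    "cardiology",
    "emergency medicine",
    "geriatrics",
    "respiratory diseases",
    "neurology",
    "oncology",
)

AGE_CLASSES = ("18-40", "41-65", "66-75", ">75")
ADMISSION_TYPES = ("urgent_direct", "urgent_from_ER", "planned")
TIME_SLOTS = ("morning", "afternoon", "night")
WEEKDAYS = ("Mon", "Tue", "Wed", "Thu", "Fri", "Sat", "Sun")
DISCHARGE_MODES = ("home", "transfer", "death", "other")

RESIDUAL_DIAGNOSIS = "__other__"


class RecordValidationError(ValueError):
    """A CSV row failed domain validation; message names row and field."""


@dataclass
class HospitalizationRecord:
    """One hospital admission with its covariates and outcome ingredients.

    ``los_days`` is the observed length of stay in days (real-valued;
    administrative integer day counts are accepted).  ``transfer`` flags an
    internal transfer between units and is used only by micro models.
    """

    record_id: str
    unit: str
    sex: int                 # 1 = male
    age_class: str
    cancer: int
    admission_type: str
    time_slot: str
    weekday: str
    diagnosis_code: str
    diagnosis_group: str
    drg_code: str
    los_days: float
    discharge_mode: str
    transfer: int = 0
    year: int = 2018

    def __post_init__(self) -> None:
        _check_enum("unit", self.unit, UNITS)
        _check_enum("age_class", self.age_class, AGE_CLASSES)
        _check_enum("admission_type", self.admission_type, ADMISSION_TYPES)
        _check_enum("time_slot", self.time_slot, TIME_SLOTS)
        _check_enum("weekday", self.weekday, WEEKDAYS)
        _check_enum("discharge_mode", self.discharge_mode, DISCHARGE_MODES)
        for name in ("sex", "cancer", "transfer"):
            v = getattr(self, name)
            if v not in (0, 1):
                raise RecordValidationError(f"field {name!r}: {v!r} is not binary (0/1)")
        if not np.isfinite(self.los_days) or self.los_days < 0:
            raise RecordValidationError(f"field 'los_days': {self.los_days!r} must be >= 0")


def _check_enum(name: str, value: str, domain: tuple[str, ...]) -> None:
    if value not in domain:
        raise RecordValidationError(
            f"field {name!r}: unknown level {value!r} (expected one of {', '.join(domain)})"
        )


@dataclass(frozen=True)
class DRGReference:
    """National reference values for one DRG code.

    ``benchmark_los`` is the national mean stay for the DRG (annual ministry
    report); ``threshold_los`` is the fixed ministerial outlier cutoff, which
    is always above the benchmark; ``mean_reimbursement`` is the average
    tariff in EUR per hospitalization under the DRG.
    """

    drg_code: str
    benchmark_los: float
    threshold_los: float
    mean_reimbursement: float

    def __post_init__(self) -> None:
        if not self.benchmark_los > 0:
            raise ValueError(f"DRG {self.drg_code}: benchmark_los must be positive")
        if not self.threshold_los > self.benchmark_los:
            raise ValueError(
                f"DRG {self.drg_code}: threshold_los ({self.threshold_los}) must exceed "
                f"benchmark_los ({self.benchmark_los})"
            )
        if self.mean_reimbursement < 0:
            raise ValueError(f"DRG {self.drg_code}: mean_reimbursement must be >= 0")


@dataclass(frozen=True)
class EncodingSpec:
    """How to turn records into a binary design matrix.

    ``mode`` is ``"macro"`` (pooled department) or ``"micro"`` (one unit;
    ``unit`` required, transfer column added).  ``diagnosis_dummies`` is the
    ordered list of top diagnosis groups; a residual dummy is always appended.
    """

    mode: str
    diagnosis_dummies: tuple[str, ...]
    unit: str | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("macro", "micro"):
            raise ValueError(f"mode must be 'macro' or 'micro', got {self.mode!r}")
        if self.mode == "micro" and self.unit is None:
            raise ValueError("micro encoding requires a unit")

    @property
    def column_names(self) -> list[str]:
        cols = ["sex_male"]
        cols += [f"age_{a}" for a in AGE_CLASSES]
        cols += ["cancer"]
        cols += [f"adm_{a}" for a in ADMISSION_TYPES]
        cols += [f"slot_{t}" for t in TIME_SLOTS]
        cols += [f"day_{d}" for d in WEEKDAYS]
        cols += [f"diag_{d}" for d in self.diagnosis_dummies]
        cols += [f"diag_{RESIDUAL_DIAGNOSIS}"]
        if self.mode == "micro":
            cols += ["transfer"]
        return cols


# ---------------------------------------------------------------------------
# CSV I/O

_CSV_FIELDS = [f.name for f in fields(HospitalizationRecord)]


def read_hospitalizations(path) -> list[HospitalizationRecord]:
    """Read admission records from a CSV file (header row required).

    Raises :class:`RecordValidationError` naming the row and field on any
    domain violation; a missing LOS is an error.
    """
    records: list[HospitalizationRecord] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        missing = set(_CSV_FIELDS) - set(reader.fieldnames or [])
        if missing:
            raise RecordValidationError(f"missing columns: {sorted(missing)}")
        for i, row in enumerate(reader, start=2):  # header is line 1
            try:
                if row["los_days"] in ("", None):
                    raise RecordValidationError("field 'los_days': missing value")
                rec = HospitalizationRecord(
                    record_id=row["record_id"],
                    unit=row["unit"],
                    sex=_parse_binary(row["sex"], "sex"),
                    age_class=row["age_class"],
                    cancer=_parse_binary(row["cancer"], "cancer"),
                    admission_type=row["admission_type"],
                    time_slot=row["time_slot"],
                    weekday=row["weekday"],
                    diagnosis_code=row["diagnosis_code"],
                    diagnosis_group=row["diagnosis_group"],
                    drg_code=row["drg_code"],
                    los_days=float(row["los_days"]),
                    discharge_mode=row["discharge_mode"],
                    transfer=_parse_binary(row.get("transfer", "0") or "0", "transfer"),
                    year=int(row.get("year", 2018) or 2018),
                )
            except (RecordValidationError, ValueError, KeyError) as exc:
                raise RecordValidationError(f"row {i}: {exc}") from exc
            records.append(rec)
    return records


def _parse_binary(value: str, name: str) -> int:
    try:
        v = int(value)
    except (TypeError, ValueError):
        raise RecordValidationError(f"field {name!r}: {value!r} is not binary (0/1)")
    if v not in (0, 1):
        raise RecordValidationError(f"field {name!r}: {value!r} is not binary (0/1)")
    return v


def write_hospitalizations(records: list[HospitalizationRecord], path) -> None:
    """Write records to CSV in the same dialect ``read_hospitalizations`` reads."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.DictWriter(fh, fieldnames=_CSV_FIELDS)
        writer.writeheader()
        for rec in records:
            writer.writerow({name: getattr(rec, name) for name in _CSV_FIELDS})


def read_drg_reference(path) -> dict[str, DRGReference]:
    """Read the per-DRG national reference table.

    Every entry must satisfy ``threshold_los > benchmark_los``; duplicate DRG
    codes are an error.  An empty file yields an empty map with a warning.
    """
    table: dict[str, DRGReference] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        for i, row in enumerate(reader, start=2):
            code = row["drg_code"]
            if code in table:
                raise ValueError(f"row {i}: duplicate drg_code {code!r}")
            table[code] = DRGReference(
                drg_code=code,
                benchmark_los=float(row["benchmark_los"]),
                threshold_los=float(row["threshold_los"]),
                mean_reimbursement=float(row["mean_reimbursement"]),
            )
    if not table:
        logger.warning("DRG reference file %s contained no rows", path)
    return table


def write_drg_reference(table: dict[str, DRGReference], path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["drg_code", "benchmark_los", "threshold_los", "mean_reimbursement"])
        for ref in table.values():
            writer.writerow(
                [ref.drg_code, ref.benchmark_los, ref.threshold_los, ref.mean_reimbursement]
            )


# ---------------------------------------------------------------------------
# Design-matrix encoding

def select_top_diagnoses(records: list[HospitalizationRecord], k: int = 10) -> tuple[str, ...]:
    """The ``k`` most frequent diagnosis groups, ties broken lexicographically.

    Returns the ordered tuple of group names (most frequent first).  A
    residual class capturing everything else is appended at encoding time,
    not here.  With fewer than ``k`` distinct groups, all are returned.
    """
    if not records:
        raise ValueError("records must be non-empty")
    counts: dict[str, int] = {}
    for rec in records:
        counts[rec.diagnosis_group] = counts.get(rec.diagnosis_group, 0) + 1
    # sort by descending count, then ascending name (lexicographic tie rule)
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return tuple(name for name, _ in ranked[:k])


def encode_design_matrix(
    records: list[HospitalizationRecord], spec: EncodingSpec
) -> pd.DataFrame:
    """Encode records as a fully one-hot binary design matrix.

    Column blocks in fixed order: sex(1), age(4), cancer(1),
    admission_type(3), time_slot(3), weekday(7), diagnosis(k+1), and — for
    micro specs — transfer(1).  Rows follow record order.
    """
    if spec.mode == "micro":
        bad = [r.record_id for r in records if r.unit != spec.unit]
        if bad:
            raise ValueError(
                f"micro encoding for unit {spec.unit!r} received {len(bad)} records "
                f"from other units (first: {bad[0]})"
            )
    cols = spec.column_names
    X = np.zeros((len(records), len(cols)), dtype=np.uint8)
    idx = {c: j for j, c in enumerate(cols)}
    diag_set = set(spec.diagnosis_dummies)
    for i, rec in enumerate(records):
        X[i, idx["sex_male"]] = rec.sex
        X[i, idx[f"age_{rec.age_class}"]] = 1
        X[i, idx["cancer"]] = rec.cancer
        X[i, idx[f"adm_{rec.admission_type}"]] = 1
        X[i, idx[f"slot_{rec.time_slot}"]] = 1
        X[i, idx[f"day_{rec.weekday}"]] = 1
        group = rec.diagnosis_group if rec.diagnosis_group in diag_set else RESIDUAL_DIAGNOSIS
        X[i, idx[f"diag_{group}"]] = 1
        if spec.mode == "micro":
            X[i, idx["transfer"]] = rec.transfer
    return pd.DataFrame(X, columns=cols)
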