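"""Cohort CSV input/output and arm-level aggregation.

The cohort file is UTF-8, comma-separated, "." decimal mark, with a required
header.  Blank cells are missing questionnaire items and map to ``None`` on
the optional :class:`~telecost.types.PatientRecord` fields.
"""

from __future__ import annotations

import logging
import math
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd
from pydantic import ValidationError

from .types import (
    AGGREGATE_FIELD_FOR,
    Arm,
    ArmAggregate,
    CONTINUOUS_VARIABLES,
    PatientRecord,
    VariableStats,
)

logger = logging.getLogger(__name__)

#: canonical column order of the cohort CSV
COHORT_COLUMNS = (
    "patient_id",
    "arm",
    "indication",
    "age_band",
    "sex",
    "employed",
    "one_way_distance_km",
    "travel_time_min",
    "waiting_time_min",
    "treatment_duration_min",
    "total_time_min",
    "absent_from_work",
    "transport_mode",
)

_BOOL_TRUE = {"true", "1", "yes"}
_BOOL_FALSE = {"false", "0", "no"}


class CohortValidationError(ValueError):
    """A cohort row failed validation; the message names the offending row."""


def _parse_bool(cell: str, *, row: int, column: str) -> Optional[bool]:
    text = cell.strip().lower()
    if text == "":
        return None
    if text in _BOOL_TRUE:
        return True
    if text in _BOOL_FALSE:
        return False
    raise CohortValidationError(
        f"row {row}: column {column!r}: cannot interpret {cell!r} as a boolean"
    )


def read_cohort(path: Union[str, Path]) -> list[PatientRecord]:
    """Read and validate a cohort CSV into a list of patient records.

    Raises :class:`CohortValidationError` with a row-addressed message for
    malformed numeric cells, unknown category labels, or negative
    distances/times.  An empty data section yields an empty list with a
    warning.
    """
    path = Path(path)
    frame = pd.read_csv(path, dtype=str, keep_default_na=False, encoding="utf-8")
    missing = [c for c in COHORT_COLUMNS if c not in frame.columns]
    if missing:
        raise CohortValidationError(f"{path}: missing required columns {missing}")
    if frame.empty:
        logger.warning("%s: cohort file has a header but no data rows", path)
        return []

    records: list[PatientRecord] = []
    for idx, row in enumerate(frame.itertuples(index=False), start=1):
        raw = dict(zip(frame.columns, row))
        payload: dict = {}
        for column in COHORT_COLUMNS:
            cell = raw[column].strip()
            if column in ("employed", "absent_from_work"):
                payload[column] = _parse_bool(cell, row=idx, column=column)
            elif column in CONTINUOUS_VARIABLES:
                if cell == "":
                    payload[column] = None
                else:
                    try:
                        payload[column] = float(cell)
                    except ValueError as exc:
                        raise CohortValidationError(
                            f"row {idx}: column {column!r}: malformed numeric cell {cell!r}"
                        ) from exc
            elif column == "transport_mode" and cell == "":
                pass  # fall back to the record default (car)
            else:
                payload[column] = cell
        try:
            records.append(PatientRecord(**payload))
        except ValidationError as exc:
            raise CohortValidationError(f"row {idx}: {exc}") from exc
    return records


def _format_cell(value) -> str:
    if value is None:
        return ""
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, float):
        return repr(value)  # shortest representation that round-trips exactly
    if hasattr(value, "value"):  # enums
        return value.value
    return str(value)


def write_cohort(records: Iterable[PatientRecord], path: Union[str, Path]) -> None:
    """Write records to the cohort CSV dialect (round-trips with read_cohort)."""
    rows = [
        {col: _format_cell(getattr(rec, col)) for col in COHORT_COLUMNS}
        for rec in records
    ]
    frame = pd.DataFrame(rows, columns=list(COHORT_COLUMNS))
    frame.to_csv(path, index=False, encoding="utf-8")


def _variable_stats(values: Sequence[float]) -> VariableStats:
    # sorting makes the statistics exactly independent of record order
    arr = np.sort(np.asarray(values, dtype=float))
    n = arr.size
    # sample SD (n-1); defined as 0 for a singleton
    sd = float(np.std(arr, ddof=1)) if n > 1 else 0.0
    q1, med, q3 = np.percentile(arr, [25, 50, 75])  # linear interpolation
    return VariableStats(
        n=n, mean=float(arr.mean()), sd=sd, median=float(med), q1=float(q1), q3=float(q3)
    )


def aggregate_arm(records: Iterable[PatientRecord], arm: Arm) -> ArmAggregate:
    """Summarise one arm: per-variable n/mean/SD/median/IQR and employment counts.

    Statistics are computed over non-missing values only, so denominators may
    differ between variables.  Raises ``ValueError`` for an arm with no
    records.
    """
    arm = Arm(arm)
    arm_records = [r for r in records if r.arm == arm]
    if not arm_records:
        raise ValueError(f"no records in arm {arm.value!r}")

    stats: dict[str, VariableStats] = {}
    for field in CONTINUOUS_VARIABLES:
        values = [
            getattr(r, field)
            for r in arm_records
            if getattr(r, field) is not None and math.isfinite(getattr(r, field))
        ]
        if not values:
            raise ValueError(f"arm {arm.value!r}: no observed values for {field}")
        stats[AGGREGATE_FIELD_FOR[field]] = _variable_stats(values)

    employed_known = [r for r in arm_records if r.employed is not None]
    n_employed = sum(1 for r in employed_known if r.employed)
    n_absent = sum(1 for r in arm_records if r.absent_from_work is True)
    return ArmAggregate(
        arm=arm,
        n_records=len(arm_records),
        n_employed_known=len(employed_known),
        n_employed=n_employed,
        n_absent=n_absent,
        **stats,
    )


def pooled_mean_distance(*aggregates: ArmAggregate) -> float:
    """n-weighted mean of the arms' one-way distance means (kilometers)."""
    total_n = sum(a.one_way_distance.n for a in aggregates)
    if total_n == 0:
        raise ValueError("no distance observations in any aggregate")
    return sum(a.one_way_distance.mean * a.one_way_distance.n for a in aggregates) / total_n
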