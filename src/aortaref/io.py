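"""Cohort CSV readers/writers and scoring of whole files.

The cohort schema is a UTF-8 CSV with unit-bearing column names —
``ga_weeks, bpd_mm, fl_mm, dmax_mm, dmin_mm`` — one row per fetus.
Distensibility is always computed from the diameters, never read, and is
never persisted as a percentage.  Rows violating the measurement
invariants are collected into a rejects report rather than silently
dropped.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import AortaRefError, SchemaError, UnknownChartError
from .models import (
    BiometryRecord,
    Predictor,
    ReferenceChart,
    Response,
    score_record,
)

REQUIRED_COLUMNS = ("ga_weeks", "dmax_mm", "dmin_mm")
OPTIONAL_COLUMNS = ("bpd_mm", "fl_mm")

#: numbers are serialized with 6 significant digits
FLOAT_FORMAT = "%.6g"


@dataclass(frozen=True)
class RejectedRow:
    index: int
    reason: str


@dataclass(frozen=True)
class CohortReadResult:
    records: tuple[BiometryRecord, ...]
    rejects: tuple[RejectedRow, ...]


def read_cohort(path) -> CohortReadResult:
    """Parse a cohort CSV into records, collecting invalid rows as rejects."""
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"empty cohort file: {path}") from exc
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s) {missing} in {path}")
    records: list[BiometryRecord] = []
    rejects: list[RejectedRow] = []
    for idx, row in df.iterrows():
        try:
            values = {}
            for col in REQUIRED_COLUMNS + OPTIONAL_COLUMNS:
                if col in df.columns and not pd.isna(row[col]):
                    values[col] = float(row[col])
                elif col in REQUIRED_COLUMNS:
                    raise ValueError(f"missing value in {col}")
            records.append(
                BiometryRecord(
                    ga=values["ga_weeks"],
                    dmax=values["dmax_mm"],
                    dmin=values["dmin_mm"],
                    bpd=values.get("bpd_mm"),
                    fl=values.get("fl_mm"),
                )
            )
        except (ValueError, TypeError) as exc:
            rejects.append(RejectedRow(int(idx), f"unparseable: {exc}"))
        except AortaRefError as exc:
            rejects.append(RejectedRow(int(idx), type(exc).__name__ + ": " + str(exc)))
    return CohortReadResult(records=tuple(records), rejects=tuple(rejects))


def cohort_to_frame(records: Sequence[BiometryRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "ga_weeks": [r.ga for r in records],
            "bpd_mm": [r.bpd for r in records],
            "fl_mm": [r.fl for r in records],
            "dmax_mm": [r.dmax for r in records],
            "dmin_mm": [r.dmin for r in records],
        }
    )


def write_cohort(records: Sequence[BiometryRecord], path) -> None:
    cohort_to_frame(records).to_csv(path, index=False, float_format=FLOAT_FORMAT)


def score_file(
    path,
    selections: Sequence[tuple[Response, Predictor]],
    registry: Mapping[tuple[Response, Predictor], ReferenceChart],
    out_path=None,
) -> tuple[pd.DataFrame, dict]:
    """Score a cohort CSV against registry charts.

    Appends one ``z_<response>_<predictor>`` and one band column per
    selection and returns a summary (n, mean z, SD of z, coverage at the
    1.65 band) per selection.  Raises before writing anything if any
    requested chart is missing (atomicity: no partial output file).
    """
    for key in selections:
        if key not in registry:
            raise UnknownChartError(f"no chart registered for {key[0]}~{key[1]}")
    read = read_cohort(path)
    df = cohort_to_frame(read.records)
    summary: dict = {"n": len(read.records), "n_rejected": len(read.rejects), "charts": {}}
    for response, predictor in selections:
        zs = [
            score_record(rec, response, predictor, registry)
            for rec in read.records
        ]
        zcol = f"z_{response}_{predictor}"
        df[zcol] = [r.z for r in zs]
        df[f"band_{response}_{predictor}"] = [r.band_flag for r in zs]
        z = np.array([r.z for r in zs])
        summary["charts"][f"{response}~{predictor}"] = {
            "mean_z": float(z.mean()) if z.size else math.nan,
            "sd_z": float(z.std(ddof=1)) if z.size > 1 else math.nan,
            "coverage_165": float(np.mean(np.abs(z) > 1.65)) if z.size else math.nan,
        }
    if out_path is not None:
        df.to_csv(out_path, index=False, float_format=FLOAT_FORMAT)
    return df, summary


def write_json(obj: dict, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2) + "\n", encoding="utf-8")
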