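"""Readers and writers for the 11-column medical-record file.

The canonical dialect is tab-delimited UTF-8 with a header row naming the
11 progress-note fields (order-insensitive, case-insensitive); free-text
fields routinely contain commas, so comma-delimited input is accepted only
via an explicit flag.  Rows with an empty subjective component or an
unparseable ICD-9 code are dropped with a logged count.
"""

from __future__ import annotations

import logging
import re
from pathlib import Path
from typing import Sequence

import pandas as pd

from .hierarchy import HierarchyError, HierarchyTable, load_hierarchy, parse_code
from .synthetic import RECORD_FIELDS, MedicalRecord

logger = logging.getLogger(__name__)

__all__ = ["SchemaError", "read_records", "write_records"]

# tolerated header spellings -> canonical field names
_ALIASES = {
    "inpatient id": "inpatient_id",
    "medical record id": "record_id",
    "medical_record_id": "record_id",
    "icd-9 code": "icd9_code",
    "icd9 code": "icd9_code",
    "icd-9": "icd9_code",
    "subjective component": "subjective",
    "objective component": "objective",
}


class SchemaError(ValueError):
    """The record file is missing required columns."""


def _canon(name: str) -> str:
    key = re.sub(r"\s+", " ", str(name).strip().lower())
    return _ALIASES.get(key, key.replace(" ", "_"))


def read_records(
    path: str | Path,
    *,
    delimiter: str = "\t",
    table: HierarchyTable | None = None,
) -> list[MedicalRecord]:
    """Read a delimited medical-record file into MedicalRecord rows."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    frame = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False,
                        encoding="utf-8")
    frame.columns = [_canon(c) for c in frame.columns]
    missing = [f for f in RECORD_FIELDS if f not in frame.columns]
    if missing:
        raise SchemaError(f"missing required columns: {', '.join(missing)}")
    table = table if table is not None else load_hierarchy()
    records: list[MedicalRecord] = []
    dropped = 0
    for row in frame.itertuples(index=False):
        values = {f: getattr(row, f) for f in RECORD_FIELDS}
        if not values["subjective"].strip():
            dropped += 1
            continue
        try:
            parse_code(values["icd9_code"], table)
        except HierarchyError:
            dropped += 1
            continue
        records.append(MedicalRecord(**values))
    if dropped:
        logger.info("dropped %d record(s) with empty subjective text or "
                    "unparseable ICD-9 code", dropped)
    return records


def write_records(records: Sequence[MedicalRecord], path: str | Path,
                  *, delimiter: str = "\t") -> None:
    """Write records as the same 11-column delimited file the reader
    consumes (lossless round trip)."""
    frame = pd.DataFrame([{f: getattr(r, f) for f in RECORD_FIELDS} for r in records],
                         columns=list(RECORD_FIELDS))
    frame.to_csv(path, sep=delimiter, index=False, encoding="utf-8")
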