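"""Delimited-text readers and writers for patient data and result tables.

Patient files are CSV/TSV with a declared column mapping onto the canonical
columns used throughout the package: time (years since diagnosis), event
(all-cause death 0/1), exposure (0/1), mediator (categorical), age (years at
diagnosis), sex, year (of diagnosis) and optionally stratum (lifetable
stratum label) and id.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import SchemaError
from .relsurv import validate_patient_frame

__all__ = ["PatientSchema", "read_patients", "write_patients"]

_CANONICAL = ("time", "event", "exposure", "mediator", "age", "sex", "year")


def read_delimited(path) -> pd.DataFrame:
    """CSV/TSV reader with correctly rounded float parsing (bit-faithful
    round trips); the separator is taken from the header line."""
    with open(path) as fh:
        header = fh.readline()
    sep = "\t" if "\t" in header else ","
    return pd.read_csv(path, sep=sep, float_precision="round_trip")


@dataclass(frozen=True)
class PatientSchema:
    """Column-name mapping for patient-level files."""

    time: str = "time"
    event: str = "event"
    exposure: str = "exposure"
    mediator: str = "mediator"
    age: str = "age"
    sex: str = "sex"
    year: str = "year"
    stratum: str | None = None
    id: str | None = None

    @classmethod
    def from_mapping(cls, mapping: dict | None) -> "PatientSchema":
        return cls(**mapping) if mapping else cls()


def read_patients(path, schema: PatientSchema | None = None, mediator_levels=None) -> pd.DataFrame:
    """Read and validate a patient file; returns canonical columns."""
    schema = schema or PatientSchema()
    df = read_delimited(path)
    rename = {getattr(schema, c): c for c in _CANONICAL}
    for opt in ("stratum", "id"):
        src = getattr(schema, opt)
        if src is not None:
            rename[src] = opt
    missing = [c for c in rename if c not in df.columns]
    if missing:
        raise SchemaError(
            f"patient file {path} is missing column(s) {missing}; found {list(df.columns)}"
        )
    out = df.rename(columns=rename)[list(rename.values())]
    out["time"] = out["time"].astype(float)
    out["event"] = out["event"].astype(int)
    out["exposure"] = out["exposure"].astype(int)
    out["age"] = out["age"].astype(float)
    out["sex"] = out["sex"].astype(str)
    out["year"] = out["year"].astype(float)
    out["mediator"] = out["mediator"].astype(str)
    if "stratum" in out.columns:
        out["stratum"] = out["stratum"].astype(str)
    validate_patient_frame(out, mediator_levels=mediator_levels)
    return out


def write_patients(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, index=False, float_format="%.17g")
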