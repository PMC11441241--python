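"""Readers for the TSV dialects the pipeline consumes."""

from __future__ import annotations

import pandas as pd

from .preprocess import DataError, StandardMap

__all__ = ["read_records", "read_injections", "read_standard_map"]

_RECORD_COLUMNS = {"name", "adduct", "grade", "ppm"}


def read_records(path: str) -> pd.DataFrame:
    """Identification export: name, adduct, grade, ppm + area columns."""
    frame = pd.read_csv(path, sep="\t")
    missing = _RECORD_COLUMNS - set(frame.columns)
    if missing:
        raise DataError(f"{path}: missing columns {sorted(missing)}")
    return frame


def read_injections(path: str) -> pd.DataFrame:
    """Per-injection metadata, indexed by injection id."""
    frame = pd.read_csv(path, sep="\t", index_col=0)
    required = {"sample_id", "condition", "set_id", "replicate", "is_blank"}
    missing = required - set(frame.columns)
    if missing:
        raise DataError(f"{path}: missing columns {sorted(missing)}")
    frame["is_blank"] = frame["is_blank"].astype(bool)
    return frame


def read_standard_map(path: str) -> StandardMap:
    frame = pd.read_csv(path, sep="\t").fillna("")
    if "class_code" not in frame.columns:
        raise DataError(f"{path}: missing class_code column")
    return StandardMap.from_frame(frame)
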