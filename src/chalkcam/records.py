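"""CSV readers/writers for per-grain chalk records and manifests."""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .errors import ValidationError
from .quantify import ChalkRecord

__all__ = ["write_records", "read_records", "RECORD_COLUMNS"]

RECORD_COLUMNS = ["grain_id", "label", "chalky_score", "chalk_area_percent", "layer", "threshold"]


def write_records(records, path) -> None:
    """Write records (ChalkRecord list or DataFrame) as UTF-8 CSV with a
    deterministic column order; floats carry 6 significant digits."""
    if isinstance(records, pd.DataFrame):
        df = records.copy()
    else:
        df = pd.DataFrame([r.as_row() for r in records])
    if len(df):
        missing = [c for c in RECORD_COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"records are missing columns: {missing}")
        extras = sorted(c for c in df.columns if c not in RECORD_COLUMNS)
        df = df[RECORD_COLUMNS + extras]
    else:
        df = pd.DataFrame(columns=RECORD_COLUMNS)
    df.to_csv(path, index=False, float_format="%.6g", encoding="utf-8")


def read_records(path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, encoding="utf-8")
    missing = [c for c in RECORD_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: records are missing columns: {missing}")
    return df
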