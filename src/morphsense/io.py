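"""Trial-table CSV dialect and configuration files.

The interchange format is a plain UTF-8 CSV with a mandatory header and
"." as the decimal separator.  Required columns: ``participant_id``,
``session_id``, ``condition``, ``face_id``, ``dilution_pct``,
``test_interval``, ``response_interval``, ``correct``; optional metadata
columns: ``duration_ms``, ``image_size_deg``, ``software``.  Intervals are
coded 1/2 (first/second); ``correct`` is stored as 0/1 and must equal
``test_interval == response_interval`` on every row.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from .simulate import TrialRecord

__all__ = [
    "REQUIRED_COLUMNS",
    "OPTIONAL_COLUMNS",
    "TrialTableError",
    "read_trials",
    "write_trials",
    "records_to_frame",
    "frame_to_records",
    "load_config",
]

REQUIRED_COLUMNS = (
    "participant_id",
    "session_id",
    "condition",
    "face_id",
    "dilution_pct",
    "test_interval",
    "response_interval",
    "correct",
)
OPTIONAL_COLUMNS = ("duration_ms", "image_size_deg", "software")


class TrialTableError(ValueError):
    """A trial table violates the dialect; names the offending row/column."""

    def __init__(self, message: str, row: int | None = None, column: str | None = None):
        loc = []
        if row is not None:
            loc.append(f"row {row}")  # 1-based data row, header = row 0
        if column is not None:
            loc.append(f"column {column!r}")
        super().__init__(f"{message} ({', '.join(loc)})" if loc else message)
        self.row = row
        self.column = column


def records_to_frame(records: Iterable[TrialRecord]) -> pd.DataFrame:
    """Flatten trial records into the dialect's DataFrame representation."""
    rows = []
    for r in records:
        row = {
            "participant_id": r.participant_id,
            "session_id": r.session_id,
            "condition": r.condition,
            "face_id": r.face_id,
            "dilution_pct": float(r.dilution_pct),
            "test_interval": int(r.test_interval),
            "response_interval": int(r.response_interval),
            "correct": bool(r.correct),
        }
        for key in OPTIONAL_COLUMNS:
            if key in r.metadata:
                row[key] = r.metadata[key]
        rows.append(row)
    return pd.DataFrame(rows)


def frame_to_records(frame: pd.DataFrame) -> list[TrialRecord]:
    """Inverse of :func:`records_to_frame` (optional columns -> metadata)."""
    records = []
    opt = [c for c in OPTIONAL_COLUMNS if c in frame.columns]
    for row in frame.itertuples(index=False):
        meta = {c: getattr(row, c) for c in opt if pd.notna(getattr(row, c))}
        records.append(
            TrialRecord(
                participant_id=str(row.participant_id),
                session_id=str(row.session_id),
                condition=str(row.condition),
                face_id=str(row.face_id),
                dilution_pct=float(row.dilution_pct),
                test_interval=int(row.test_interval),
                response_interval=int(row.response_interval),
                correct=bool(row.correct),
                metadata=meta,
            )
        )
    return records


def _validate_frame(df: pd.DataFrame) -> pd.DataFrame:
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise TrialTableError("missing required column", column=col)
    df = df.copy()
    # numeric parses with row-resolved diagnostics
    for col in ("dilution_pct",):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() & df[col].notna()
        if bad.any() or df[col].isna().any():
            row = int(np.flatnonzero(bad | df[col].isna())[0]) + 1
            raise TrialTableError("unparseable or missing value", row=row, column=col)
        df[col] = vals.astype(float)
    for col in ("test_interval", "response_interval"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = ~vals.isin([1, 2])
        if bad.any():
            row = int(np.flatnonzero(bad)[0]) + 1
            raise TrialTableError("interval must be 1 or 2", row=row, column=col)
        df[col] = vals.astype(int)
    out_of_range = (df["dilution_pct"] < 0) | (df["dilution_pct"] > 100)
    if out_of_range.any():
        row = int(np.flatnonzero(out_of_range)[0]) + 1
        raise TrialTableError(
            "dilution_pct must lie in [0, 100]", row=row, column="dilution_pct"
        )
    correct = df["correct"]
    if correct.dtype == object:
        correct = correct.map(
            {"True": True, "False": False, "true": True, "false": False,
             "1": True, "0": False, 1: True, 0: False, True: True, False: False}
        )
        if correct.isna().any():
            row = int(np.flatnonzero(correct.isna())[0]) + 1
            raise TrialTableError("unparseable boolean", row=row, column="correct")
    df["correct"] = correct.astype(bool)
    contradiction = df["correct"] != (df["test_interval"] == df["response_interval"])
    if contradiction.any():
        row = int(np.flatnonzero(contradiction)[0]) + 1
        raise TrialTableError(
            "correct contradicts test_interval/response_interval",
            row=row,
            column="correct",
        )
    for col in ("participant_id", "session_id", "condition", "face_id"):
        df[col] = df[col].astype(str)
    return df


def read_trials(path: str | Path) -> pd.DataFrame:
    """Read and validate a trial-table CSV.

    Returns a validated DataFrame (the canonical in-memory container);
    use :func:`frame_to_records` for the record-object view.  Errors name
    the offending 1-based data row and column.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    return _validate_frame(df)


def write_trials(
    trials: pd.DataFrame | Sequence[TrialRecord], path: str | Path
) -> None:
    """Write trials to the CSV dialect (comma separator, LF endings)."""
    if not isinstance(trials, pd.DataFrame):
        trials = records_to_frame(trials)
    df = trials.copy()
    df["correct"] = df["correct"].astype(bool).astype(int)
    cols = [c for c in REQUIRED_COLUMNS if c in df.columns] + [
        c for c in OPTIONAL_COLUMNS if c in df.columns
    ]
    df[cols].to_csv(path, index=False, lineterminator="\n")


def load_config(path: str | Path) -> dict:
    """Load a nested key-value (YAML) study configuration file."""
    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"configuration in {path} must be a mapping")
    return cfg
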