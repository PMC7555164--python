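"""Reading and writing the pipeline's tabular formats.

Trial tables are CSV/TSV with columns ``participant_id, task_id,
rt_ms | rt_s, correct``; the RT unit is auto-detected from the header and
converted to seconds internally.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

__all__ = ["read_trials", "write_trials", "read_participants"]

_REQUIRED = {"participant_id", "task_id", "correct"}


def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in (".tsv", ".tab") else ","


def read_trials(path) -> pd.DataFrame:
    """Load a trial table; returns columns participant_id, task_id, rt
    (seconds), correct."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path))
    missing = _REQUIRED - set(df.columns)
    if missing:
        raise ValueError(f"trial table missing column(s): {sorted(missing)}")
    if "rt_s" in df.columns:
        df["rt"] = df["rt_s"].astype(float)
    elif "rt_ms" in df.columns:
        df["rt"] = df["rt_ms"].astype(float) / 1000.0
    elif "rt" in df.columns:
        df["rt"] = df["rt"].astype(float)  # assumed seconds
    else:
        raise ValueError("trial table needs an rt_ms, rt_s, or rt column")
    if not df["correct"].isin((0, 1)).all():
        raise ValueError("correct must be coded 0/1")
    return df[["participant_id", "task_id", "rt", "correct"]]


def write_trials(df: pd.DataFrame, path, unit: str = "s") -> None:
    path = Path(path)
    out = df.copy()
    if unit == "ms":
        out["rt_ms"] = out.pop("rt") * 1000.0
    else:
        out = out.rename(columns={"rt": "rt_s"})
    out.to_csv(path, sep=_sep_for(path), index=False)


def read_participants(path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path))
    if "participant_id" not in df.columns or "age" not in df.columns:
        raise ValueError("participant table needs participant_id and age columns")
    return df
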