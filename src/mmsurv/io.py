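"""CSV ingestion and emission for all pipeline stages.

All intermediate artifacts are flat CSV files with documented headers so
any stage can be re-run in isolation.  Files may begin with a single ``#``
comment line carrying provenance metadata (config hash, seed); readers
skip it.
"""

from __future__ import annotations

from pathlib import Path
from typing import List, Optional

import pandas as pd

from .simulate import OBSERVATION_COLUMNS

__all__ = ["ValidationError", "read_observations", "write_table", "read_table"]


class ValidationError(ValueError):
    """Raised when an input table violates the observation schema."""


def read_observations(path) -> pd.DataFrame:
    """Read and validate an observation table.

    The file must contain the documented columns (extra columns are kept);
    rows are sorted by (condition, replicate, lineage, frame).  Frames must
    be strictly increasing within a lineage and lengths/areas strictly
    positive; violations are reported with row numbers.
    """
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"{path}: file does not exist")
    df = pd.read_csv(path, comment="#")
    missing = [c for c in OBSERVATION_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing required column(s): {', '.join(missing)}")
    if df.empty:
        raise ValidationError(f"{path}: no observation rows")

    problems: List[str] = []
    for col in ("length_um", "area_um2"):
        bad = df.index[df[col] <= 0]
        for i in bad[:10]:
            problems.append(f"row {i + 2}: non-positive {col} ({df.at[i, col]})")
    df = df.sort_values(
        ["condition", "replicate_id", "lineage_id", "frame"], kind="stable"
    ).reset_index(drop=True)
    frame_diff = df.groupby(
        ["condition", "replicate_id", "lineage_id"], sort=False, observed=True
    )["frame"].diff()
    bad = df.index[frame_diff <= 0]
    for i in bad[:10]:
        problems.append(f"row {i + 2}: non-increasing frame index within lineage")
    if problems:
        raise ValidationError(f"{path}: " + "; ".join(problems))
    return df


def write_table(df: pd.DataFrame, path, meta: Optional[dict] = None) -> None:
    """Write any stage table as UTF-8 CSV (LF newlines, '.' decimals)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        if meta:
            fh.write("# " + " ".join(f"{k}={v}" for k, v in meta.items()) + "\n")
        df.to_csv(fh, index=False, lineterminator="\n")


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")
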