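"""Shared tabular readers/writers, run manifests, and logging setup.

TSV is the canonical tabular format; CSV is accepted on read. Matrices are
feature x sample pandas DataFrames with string identifiers on both axes.
"""

from __future__ import annotations

import json
import logging
import sys
from pathlib import Path
from typing import Any

import pandas as pd

logger = logging.getLogger("telomaint")

MISSING_MARKERS = ["", "NA", "NaN", "nan"]


def setup_logging(level: str = "INFO") -> None:
    logging.basicConfig(
        stream=sys.stderr,
        level=getattr(logging, level.upper()),
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
    )


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_matrix(
    path: str | Path, orientation: str = "features_by_samples"
) -> pd.DataFrame:
    """Read a numeric matrix with a header row and leading id column.

    Parameters
    ----------
    orientation:
        ``"features_by_samples"`` (rows are features; no transpose) or
        ``"samples_by_features"`` (file is transposed on read so the
        returned frame is always features x samples).
    """
    path = Path(path)
    df = pd.read_csv(
        path,
        sep=_sep_for(path),
        index_col=0,
        na_values=MISSING_MARKERS,
        keep_default_na=False,
    )
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ValueError(f"{path}: empty matrix")
    if orientation == "samples_by_features":
        df = df.T
    elif orientation != "features_by_samples":
        raise ValueError(f"unknown orientation {orientation!r}")
    dup_rows = df.index[df.index.duplicated()].unique().tolist()
    dup_cols = df.columns[df.columns.duplicated()].unique().tolist()
    if dup_rows or dup_cols:
        raise ValueError(
            f"{path}: duplicate identifiers rows={dup_rows} cols={dup_cols}"
        )
    non_numeric = []
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df[col].notna() & coerced.isna()
        if bad.any():
            row = df.index[bad.to_numpy().argmax()]
            non_numeric.append((row, col, df.loc[row, col]))
        df[col] = coerced
    if non_numeric:
        row, col, value = non_numeric[0]
        raise ValueError(
            f"{path}: non-numeric cell at row {row!r}, column {col!r}: {value!r}"
        )
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return df


def read_table(path: str | Path) -> pd.DataFrame:
    """Read a plain TSV/CSV table (header row, no index column)."""
    path = Path(path)
    return pd.read_csv(
        path, sep=_sep_for(path), na_values=MISSING_MARKERS, keep_default_na=False
    )


def write_table(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index, lineterminator="\n")


def write_manifest(out_dir: str | Path, entries: dict[str, Any]) -> Path:
    """Write/merge a machine-readable manifest of parameters and outputs."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / "manifest.json"
    manifest: dict[str, Any] = {}
    if path.exists():
        manifest = json.loads(path.read_text())
    manifest.update(entries)
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return path


def log_drop_report(stage: str, reason_counts: dict[str, int]) -> None:
    """Log filter decisions as aggregate counts, not per-item spam."""
    for reason, count in reason_counts.items():
        if count:
            logger.info("%s: dropped %d items (%s)", stage, count, reason)
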