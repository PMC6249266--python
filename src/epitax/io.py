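"""File-format adapters: BED, dense TSV matrices, GMT gene sets, YAML config, JSON reports.

All genomic coordinates are 0-based half-open (BED native). Matrix TSVs are
dense, feature IDs in the first column, sample IDs in the header row.
"""

from __future__ import annotations

import json
import logging
import warnings
from pathlib import Path

import pandas as pd
import yaml

logger = logging.getLogger("epitax")

BED_COLUMNS = ("chrom", "start", "end", "name", "score", "strand")


class MalformedFileError(ValueError):
    """Raised when an input file violates its dialect; carries file and line context."""


def read_bed(path: str | Path) -> pd.DataFrame:
    """Read a BED3-BED6 file into a DataFrame with 0-based half-open coordinates.

    Raises :class:`MalformedFileError` naming the file, line number and content
    for any malformed line (wrong column count, non-integer coordinates,
    start >= end).
    """
    path = Path(path)
    rows = []
    ncols = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3 or len(fields) > 6:
                raise MalformedFileError(
                    f"{path}:{lineno}: expected 3-6 tab-separated columns, "
                    f"got {len(fields)}: {line!r}"
                )
            if ncols is None:
                ncols = len(fields)
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise MalformedFileError(
                    f"{path}:{lineno}: non-integer coordinates: {line!r}"
                ) from exc
            if start < 0 or start >= end:
                raise MalformedFileError(
                    f"{path}:{lineno}: requires 0 <= start < end: {line!r}"
                )
            rows.append([fields[0], start, end] + fields[3:])
    ncols = ncols or 3
    df = pd.DataFrame(rows, columns=list(BED_COLUMNS[:ncols]))
    if not df.empty:
        df["start"] = df["start"].astype(int)
        df["end"] = df["end"].astype(int)
        if "score" in df.columns:
            df["score"] = pd.to_numeric(df["score"], errors="coerce")
    return df


def write_bed(df: pd.DataFrame, path: str | Path) -> None:
    """Write intervals (chrom/start/end plus optional name/score/strand) as BED."""
    cols = [c for c in BED_COLUMNS if c in df.columns]
    df[cols].to_csv(path, sep="\t", header=False, index=False)


def read_matrix_tsv(path: str | Path) -> pd.DataFrame:
    """Read a dense feature-by-sample TSV (feature IDs first column, sample header)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        warnings.warn(f"{path}: duplicate feature IDs present")
    return df


def write_matrix_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=True)


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Read a GMT gene-set file: set name, description, then member genes.

    Duplicate set names: last occurrence wins, with a warning (documented
    dialect rule).
    """
    path = Path(path)
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise MalformedFileError(
                    f"{path}:{lineno}: GMT line needs >=3 columns "
                    f"(name, description, genes...): {line!r}"
                )
            name = fields[0]
            genes = [g for g in fields[2:] if g]
            if name in sets:
                warnings.warn(f"{path}:{lineno}: duplicate gene set {name!r}; last wins")
            sets[name] = genes
    return sets


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise MalformedFileError(f"{path}: config must be a YAML mapping")
    return cfg


def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def _json_default(obj):
    try:
        return obj.item()  # numpy scalars
    except AttributeError:
        return str(obj)
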