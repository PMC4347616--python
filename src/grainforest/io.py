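"""Readers/writers and reproducibility plumbing.

Feature tables are comma-separated (``.tsv`` → tab) UTF-8 files with a
mandatory header, one ``label`` column (0/1), one ``grain_id`` column
(string), and any number of numeric feature columns. Results are written as
a tidy TSV (one run record per row), a JSON summary, and a run manifest
capturing everything needed to reproduce the output bit-for-bit.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .experiments import RunRecord, records_to_dataframe
from .table import GrainTable

__all__ = ["read_grain_table", "write_grain_table", "RunManifest", "write_results"]


def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in (".tsv", ".tab") else ","


def read_grain_table(path, label_col: str = "label", grain_col: str = "grain_id") -> GrainTable:
    """Parse a delimited feature table into a GrainTable.

    Row order is preserved; a non-numeric feature cell raises with its
    row/column location. Grain values duplicated across classes are legal
    (mixed-label partitions occur in real data).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(
        path,
        sep=_sep_for(path),
        dtype={grain_col: str} if grain_col else None,
        float_precision="round_trip",
    )
    if df.empty:
        raise ValueError(f"{path}: empty table")
    for col in (label_col, grain_col):
        if col not in df.columns:
            raise ValueError(f"{path}: required column {col!r} missing")
    labels = pd.to_numeric(df[label_col], errors="coerce")
    if labels.isna().any() or not labels.isin((0, 1)).all():
        bad = int(np.flatnonzero(~labels.isin((0, 1)))[0])
        raise ValueError(f"{path}: non-binary label at row {bad} (column {label_col!r})")
    feature_cols = [c for c in df.columns if c not in (label_col, grain_col)]
    if not feature_cols:
        raise ValueError(f"{path}: no feature columns")
    features = np.empty((len(df), len(feature_cols)))
    for j, col in enumerate(feature_cols):
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any() and not df[col].isna().all():
            bad = int(np.flatnonzero(vals.isna() & df[col].notna())[0])
            raise ValueError(
                f"{path}: non-numeric value {df[col].iloc[bad]!r} at row {bad}, column {col!r}"
            )
        features[:, j] = vals.to_numpy()
    return GrainTable(
        features=features,
        labels=labels.to_numpy(dtype=int),
        grain_ids=df[grain_col].to_numpy(),
        feature_names=feature_cols,
    )


def write_grain_table(table: GrainTable, path, label_col: str = "label", grain_col: str = "grain_id") -> None:
    """Write a table in the standard dialect (full float precision)."""
    path = Path(path)
    table.to_dataframe(label_col=label_col, grain_col=grain_col).to_csv(
        path, sep=_sep_for(path), index=False
    )


@dataclass
class RunManifest:
    """Snapshot sufficient to reproduce an output directory bit-for-bit."""

    config: dict
    master_seed: int
    package_version: str = __version__
    child_seeds: dict = field(default_factory=dict)
    created: str = field(default_factory=lambda: datetime.now(timezone.utc).isoformat())

    def to_dict(self) -> dict:
        return {
            "config": self.config,
            "master_seed": self.master_seed,
            "package_version": self.package_version,
            "child_seeds": self.child_seeds,
            "created": self.created,
        }

    @classmethod
    def from_json(cls, path) -> "RunManifest":
        with open(path) as fh:
            d = json.load(fh)
        return cls(**d)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def write_results(records: list[RunRecord], manifest: RunManifest, outdir) -> dict:
    """Write records.tsv + summary.json + manifest.json into ``outdir``.

    Overwrites existing files with a warning. Returns the written paths.
    """
    if not records:
        raise ValueError("no records to write")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "records": outdir / "records.tsv",
        "summary": outdir / "summary.json",
        "manifest": outdir / "manifest.json",
    }
    for p in paths.values():
        if p.exists():
            warnings.warn(f"overwriting {p}", stacklevel=2)
    df = records_to_dataframe(records)
    df.to_csv(paths["records"], sep="\t", index=False)
    metric_cols = [c for c in df.columns if c not in ("scheme", "partition_size", "noise_level", "repetition")]
    summary = {
        scheme: group[metric_cols].mean().to_dict()
        for scheme, group in df.groupby("scheme")
    }
    with open(paths["summary"], "w") as fh:
        json.dump(summary, fh, indent=2)
    manifest.save(paths["manifest"])
    return paths
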