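"""Dataset manifest: which tracks exist, for which genome, from which source.

A manifest is a TSV with columns ``dataset_id, genome_id, assay, source,
clip_threshold`` and optionally ``path`` (track file) and ``count`` (number
of identically-configured datasets the row stands for; defaults to 1).
Aggregate rows with ``count`` > 1 are how full-compendium task totals are
declared without enumerating thousands of files.
"""

from __future__ import annotations

from typing import Dict

import pandas as pd

from .prep import SOURCE_CLIP_DEFAULTS

REQUIRED_COLUMNS = ["dataset_id", "genome_id", "assay", "source"]
KNOWN_ASSAYS = {"cage", "dnase_atac", "chip", "acc"}


def load_manifest(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    return validate_manifest(df)


def validate_manifest(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"manifest missing columns: {missing}")
    df = df.copy()
    if "count" not in df.columns:
        df["count"] = 1
    if df["count"].min() < 1:
        raise ValueError("manifest count column must be >= 1")
    unknown = set(df["assay"].str.lower()) - KNOWN_ASSAYS
    if unknown:
        raise ValueError(f"unknown assay classes: {sorted(unknown)}")
    if "clip_threshold" not in df.columns:
        df["clip_threshold"] = [
            SOURCE_CLIP_DEFAULTS.get(str(s).lower(), 32.0) for s in df["source"]
        ]
    if df["dataset_id"].duplicated().any():
        raise ValueError("duplicate dataset_id in manifest")
    return df


def head_tasks(manifest: pd.DataFrame) -> Dict[str, int]:
    """Number of prediction tasks per genome head."""
    return {g: int(sub["count"].sum()) for g, sub in manifest.groupby("genome_id")}


def total_tasks(manifest: pd.DataFrame) -> int:
    return int(manifest["count"].sum())
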