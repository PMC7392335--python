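"""Signed per-dataset variant effect scores via allele-difference prediction.

A variant's score for dataset d is the summed predicted signal across the
sequence window with the alternative allele minus the same sum with the
reference allele (sign convention: alt - ref, recorded in table metadata).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd

from .io import VcfRecord, fetch_sequence
from .model import Model
from .prep import encode_sequence, reverse_complement_onehot

VALID_ALLELES = set("ACGT")


@dataclass(frozen=True)
class Variant:
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    id: str = "."

    def __post_init__(self):
        if self.ref not in VALID_ALLELES or self.alt not in VALID_ALLELES:
            raise ValueError(f"only biallelic SNVs supported: {self.ref}>{self.alt}")

    @property
    def start(self) -> int:
        return self.pos - 1

    @classmethod
    def from_vcf_record(cls, r: VcfRecord) -> "Variant":
        return cls(chrom=r.chrom, pos=r.pos, ref=r.ref, alt=r.alt, id=r.id)


def _variant_window(genome, variant: Variant, seq_len: int, shift: int = 0):
    """Encoded window of length seq_len with the variant at the center,
    shifted by ``shift`` bp; returns (onehot, center_index)."""
    contig_len = len(genome[variant.chrom])
    center = variant.start
    start = center - seq_len // 2 + shift
    end = start + seq_len
    if start < 0 or end > contig_len:
        raise ValueError(
            f"window [{start}, {end}) off contig {variant.chrom} (len {contig_len})")
    seq = fetch_sequence(genome, variant.chrom, start, end)
    offset = center - start
    if seq[offset].upper() != variant.ref:
        raise ValueError(
            f"reference mismatch at {variant.chrom}:{variant.pos}: "
            f"genome has {seq[offset].upper()!r}, variant says {variant.ref!r}")
    return encode_sequence(seq), offset


_ALLELE_ROW = {b: i for i, b in enumerate("ACGT")}


def score_variant(
    model: Model,
    genome,
    variant: Variant,
    genome_id: str,
    shift: int = 0,
    rc: bool = False,
) -> np.ndarray:
    """Per-dataset signed score: sum over bins of (pred_alt - pred_ref)."""
    onehot_ref, offset = _variant_window(genome, variant, model.config.seq_len, shift)
    onehot_alt = onehot_ref.copy()
    onehot_alt[:, offset] = 0.0
    onehot_alt[_ALLELE_ROW[variant.alt], offset] = 1.0
    if variant.alt == variant.ref:
        return np.zeros(model.config.heads[genome_id], dtype=np.float64)
    if rc:
        onehot_ref = reverse_complement_onehot(onehot_ref)
        onehot_alt = reverse_complement_onehot(onehot_alt)
    x = np.stack([onehot_ref, onehot_alt])
    pred = model.predict(x, genome_id)  # (2, n_bins, n_tasks)
    return (pred[1] - pred[0]).sum(axis=0).astype(np.float64)


def ensemble_scores(
    model: Model,
    genome,
    variant: Variant,
    genome_id: str,
    shifts: Sequence[int] = (-1, 0, 1),
    rc: bool = True,
) -> np.ndarray:
    """Arithmetic mean of score_variant over {forward, rc} x shifts."""
    if sorted(shifts) != sorted(-s for s in shifts):
        raise ValueError("shift set must be symmetric around 0")
    rcs = (False, True) if rc else (False,)
    scores = [score_variant(model, genome, variant, genome_id, shift=s, rc=r)
              for r in rcs for s in shifts]
    return np.mean(scores, axis=0)


@dataclass
class VariantScoreTable:
    scores: pd.DataFrame  # variants x datasets
    metadata: Dict[str, str]

    def __post_init__(self):
        if not np.all(np.isfinite(self.scores.values)):
            raise ValueError("scores must be finite")

    def to_tsv(self, path: str):
        self.scores.to_csv(path, sep="\t", index_label="variant_id")

    def export_sldp(self, path: str, variants: Sequence[Variant]):
        """Long-format signed annotation table (one row per variant x dataset)
        suitable for downstream signed-LD-profile style analyses."""
        by_id = {v.id: v for v in variants}
        rows = []
        for vid, row in self.scores.iterrows():
            v = by_id[vid]
            for dataset, score in row.items():
                rows.append((v.chrom, v.pos, v.ref, v.alt, vid, dataset, score))
        pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "variant_id",
                                    "dataset", "score"]).to_csv(path, sep="\t", index=False)


def score_table(
    model: Model,
    genome,
    variants: Sequence[Variant],
    genome_id: str,
    dataset_ids: Optional[Sequence[str]] = None,
    shifts: Sequence[int] = (-1, 0, 1),
    rc: bool = True,
) -> VariantScoreTable:
    n_tasks = model.config.heads[genome_id]
    if dataset_ids is None:
        dataset_ids = [f"{genome_id}_task{j}" for j in range(n_tasks)]
    rows = [ensemble_scores(model, genome, v, genome_id, shifts=shifts, rc=rc)
            for v in variants]
    df = pd.DataFrame(rows, index=[v.id for v in variants], columns=list(dataset_ids))
    return VariantScoreTable(
        scores=df,
        metadata={
            "sign_convention": "alt_minus_ref",
            "genome_id": genome_id,
            "shifts": ",".join(str(s) for s in shifts),
            "rc_averaged": str(rc),
        },
    )
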