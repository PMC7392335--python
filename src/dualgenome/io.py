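"""Readers and writers for the plain-text genomic formats used throughout.

Coordinates are 0-based half-open everywhere internally; VCF positions are
converted on ingest.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Dict, Iterable, List, Sequence, Tuple

import numpy as np
import pyfaidx


# ---------------------------------------------------------------------------
# FASTA / chrom.sizes


def write_fasta(path: str, sequences: Dict[str, str], width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path: str) -> "pyfaidx.Fasta":
    """Open a FASTA with an index, rebuilding the index if stale."""
    return pyfaidx.Fasta(path, rebuild=True, as_raw=True, sequence_always_upper=True)


def fetch_sequence(fasta: "pyfaidx.Fasta", chrom: str, start: int, end: int) -> str:
    """Fetch [start, end) from an open FASTA, 0-based half-open."""
    return str(fasta[chrom][start:end])


def read_chrom_sizes(path: str) -> Dict[str, int]:
    sizes: Dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            chrom, size = line.split()[:2]
            sizes[chrom] = int(size)
    return sizes


def write_chrom_sizes(path: str, sizes: Dict[str, int]) -> None:
    with open(path, "w") as fh:
        for chrom, size in sizes.items():
            fh.write(f"{chrom}\t{size}\n")


def chrom_sizes_from_fasta(path: str) -> Dict[str, int]:
    fa = read_fasta(path)
    return {name: len(fa[name]) for name in fa.keys()}


# ---------------------------------------------------------------------------
# Coverage tracks (bedGraph, run-length encoded)


def write_bedgraph(path: str, values: Dict[str, np.ndarray]) -> None:
    """Write per-bp arrays as a run-length-encoded bedGraph."""
    with open(path, "w") as fh:
        for chrom, arr in values.items():
            arr = np.asarray(arr)
            if arr.size == 0:
                continue
            # boundaries of constant runs
            change = np.flatnonzero(arr[1:] != arr[:-1]) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [arr.size]))
            for s, e in zip(starts, ends):
                v = float(arr[s])
                fh.write(f"{chrom}\t{s}\t{e}\t{v:.6g}\n")


def read_bedgraph(path: str, chrom_sizes: Dict[str, int], dtype=np.float32) -> Dict[str, np.ndarray]:
    """Expand a bedGraph into dense per-bp arrays (zero where uncovered)."""
    out = {c: np.zeros(n, dtype=dtype) for c, n in chrom_sizes.items()}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            chrom, start, end, value = line.split()[:4]
            if chrom not in out:
                raise ValueError(f"bedGraph chromosome {chrom!r} not in chrom sizes")
            out[chrom][int(start) : int(end)] = float(value)
    return out


# ---------------------------------------------------------------------------
# BED


def read_bed(path: str) -> List[Tuple[str, int, int, str]]:
    """Read BED3+ records as (chrom, start, end, name); name '' if absent."""
    records = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.rstrip("\n").split("\t")
            name = fields[3] if len(fields) > 3 else ""
            records.append((fields[0], int(fields[1]), int(fields[2]), name))
    return records


def write_bed(path: str, records: Iterable[Sequence]) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write("\t".join(str(x) for x in rec) + "\n")


# ---------------------------------------------------------------------------
# Alignment (net-dialect TSV and UCSC chain subset)


@dataclass(frozen=True)
class AlignmentBlock:
    """One gap-free aligned block between the two genomes.

    Coordinates are 0-based half-open on both genomes. ``aligned_len`` is the
    number of aligned base pairs the block contributes (equal to the span for
    gap-free blocks).
    """

    chrom_a: str
    start_a: int
    end_a: int
    chrom_b: str
    start_b: int
    end_b: int
    strand: str = "+"
    aligned_len: int = 0

    def __post_init__(self):
        if self.aligned_len <= 0:
            object.__setattr__(self, "aligned_len", self.end_a - self.start_a)
        if self.end_a <= self.start_a or self.end_b <= self.start_b:
            raise ValueError(f"empty alignment block: {self}")


NET_HEADER = "#chromA\tstartA\tendA\tchromB\tstartB\tendB\tstrand\taligned_len"


def write_net_tsv(path: str, blocks: Iterable[AlignmentBlock]) -> None:
    with open(path, "w") as fh:
        fh.write(NET_HEADER + "\n")
        for b in blocks:
            fh.write(
                f"{b.chrom_a}\t{b.start_a}\t{b.end_a}\t{b.chrom_b}\t"
                f"{b.start_b}\t{b.end_b}\t{b.strand}\t{b.aligned_len}\n"
            )


def read_net_tsv(path: str) -> List[AlignmentBlock]:
    blocks = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 8:
                raise ValueError(f"{path}:{lineno}: expected 8 fields, got {len(fields)}")
            blocks.append(
                AlignmentBlock(
                    chrom_a=fields[0],
                    start_a=int(fields[1]),
                    end_a=int(fields[2]),
                    chrom_b=fields[3],
                    start_b=int(fields[4]),
                    end_b=int(fields[5]),
                    strand=fields[6],
                    aligned_len=int(fields[7]),
                )
            )
    return blocks


def read_chain(path: str) -> List[AlignmentBlock]:
    """Read the gap-free blocks of a UCSC chain file as AlignmentBlocks.

    Supports the plain-text chain dialect: a ``chain`` header line followed by
    block lines ``size [dt dq]``. Negative-strand query coordinates are
    converted to positive-strand coordinates.
    """
    blocks: List[AlignmentBlock] = []
    with open(path) as fh:
        header = None
        t_pos = q_pos = 0
        for line in fh:
            line = line.strip()
            if not line:
                header = None
                continue
            if line.startswith("chain"):
                f = line.split()
                # chain score tName tSize tStrand tStart tEnd qName qSize qStrand qStart qEnd id
                header = {
                    "t_name": f[2], "t_size": int(f[3]), "t_strand": f[4],
                    "t_start": int(f[5]), "q_name": f[7], "q_size": int(f[8]),
                    "q_strand": f[9], "q_start": int(f[10]),
                }
                t_pos, q_pos = header["t_start"], header["q_start"]
                continue
            if header is None:
                raise ValueError(f"chain block line before chain header: {line!r}")
            f = line.split()
            size = int(f[0])
            q_start, q_end = q_pos, q_pos + size
            if header["q_strand"] == "-":
                q_start, q_end = header["q_size"] - q_end, header["q_size"] - q_pos
            blocks.append(
                AlignmentBlock(
                    chrom_a=header["t_name"],
                    start_a=t_pos,
                    end_a=t_pos + size,
                    chrom_b=header["q_name"],
                    start_b=q_start,
                    end_b=q_end,
                    strand=header["q_strand"],
                    aligned_len=size,
                )
            )
            if len(f) == 3:
                t_pos += size + int(f[1])
                q_pos += size + int(f[2])
            else:
                header = None
    return blocks


# ---------------------------------------------------------------------------
# VCF (minimal SNV dialect)


@dataclass(frozen=True)
class VcfRecord:
    chrom: str
    pos: int  # 1-based, as in the file
    id: str
    ref: str
    alt: str
    info: Dict[str, str]

    @property
    def start(self) -> int:
        """0-based position."""
        return self.pos - 1


def write_vcf(path: str, records: Iterable[VcfRecord], extra_headers: Sequence[str] = ()) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for h in extra_headers:
            fh.write(h.rstrip("\n") + "\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for r in records:
            info = ";".join(f"{k}={v}" for k, v in r.info.items()) or "."
            fh.write(f"{r.chrom}\t{r.pos}\t{r.id}\t{r.ref}\t{r.alt}\t.\t.\t{info}\n")


def read_vcf(path: str) -> List[VcfRecord]:
    records = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            info: Dict[str, str] = {}
            if len(f) > 7 and f[7] != ".":
                for item in f[7].split(";"):
                    if "=" in item:
                        k, v = item.split("=", 1)
                        info[k] = v
                    else:
                        info[item] = ""
            records.append(
                VcfRecord(chrom=f[0], pos=int(f[1]), id=f[2], ref=f[3], alt=f[4], info=info)
            )
    return records


def ensure_dir(path: str) -> str:
    os.makedirs(path, exist_ok=True)
    return path
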