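"""Coverage-track preprocessing and model-ready example construction.

Fixed preprocessing order, logged in ``PreprocessConfig.pipeline``:
clip negatives -> mask blacklist/unmappable to the per-dataset percentile ->
average replicates -> bin to windows -> soft-clip binned values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import h5py
import numpy as np

SOURCE_CLIP_DEFAULTS = {"cage": 384.0, "encode": 32.0, "geo": 64.0}

PIPELINE = ("clip_negatives", "mask_to_percentile", "average_replicates",
            "bin_signal", "soft_clip")


@dataclass
class PreprocessConfig:
    clip_threshold: float = 32.0
    mask_percentile: float = 25.0
    negative_policy: str = "clip-to-zero"
    pipeline: Tuple[str, ...] = PIPELINE

    def __post_init__(self):
        if not self.clip_threshold > 0:
            raise ValueError("clip_threshold must be positive")
        if not 0 <= self.mask_percentile <= 100:
            raise ValueError("mask_percentile must be in [0, 100]")

    @classmethod
    def for_source(cls, source: str, **kwargs) -> "PreprocessConfig":
        t = SOURCE_CLIP_DEFAULTS.get(source.lower())
        if t is None:
            raise ValueError(f"unknown source {source!r}; expected one of "
                             f"{sorted(SOURCE_CLIP_DEFAULTS)}")
        return cls(clip_threshold=t, **kwargs)


@dataclass
class CoverageTrack:
    dataset_id: str
    genome_id: str
    values: Dict[str, np.ndarray]
    source: str = "encode"

    def total_length(self) -> int:
        return sum(len(v) for v in self.values.values())


def clip_negatives(track: CoverageTrack) -> CoverageTrack:
    return CoverageTrack(track.dataset_id, track.genome_id,
                         {c: np.maximum(v, 0.0) for c, v in track.values.items()},
                         track.source)


def soft_clip(x, t_c: float):
    """min(x, t_c + sqrt(max(0, x - t_c))): identity below the threshold,
    square-root growth of the residual above it."""
    x = np.asarray(x, dtype=float)
    clipped = t_c + np.sqrt(np.maximum(0.0, x - t_c))
    out = np.minimum(x, clipped)
    return out if out.ndim else float(out)


def track_percentile(track: CoverageTrack, percentile: float) -> float:
    """Genome-wide percentile of negative-clipped values (pre-mask)."""
    if track.total_length() == 0:
        raise ValueError(f"empty track {track.dataset_id!r}")
    allv = np.concatenate([np.maximum(v, 0.0) for v in track.values.values()])
    return float(np.percentile(allv, percentile, method="lower"))


def mask_to_percentile(
    track: CoverageTrack,
    regions: Sequence[Tuple[str, int, int, str]],
    percentile: float = 25.0,
) -> CoverageTrack:
    """Set all bp inside ``regions`` to the dataset's genome-wide percentile."""
    fill = track_percentile(track, percentile)
    values = {c: v.copy() for c, v in track.values.items()}
    for chrom, start, end, *_ in regions:
        if chrom in values:
            values[chrom][start:end] = fill
    return CoverageTrack(track.dataset_id, track.genome_id, values, track.source)


def average_replicates(tracks: Sequence[CoverageTrack]) -> CoverageTrack:
    if not tracks:
        raise ValueError("no tracks to average")
    first = tracks[0]
    for t in tracks[1:]:
        if t.genome_id != first.genome_id:
            raise ValueError("replicates must share a genome")
        if set(t.values) != set(first.values) or any(
            len(t.values[c]) != len(first.values[c]) for c in first.values
        ):
            raise ValueError("replicate track lengths do not match")
    values = {
        c: np.mean([t.values[c] for t in tracks], axis=0) for c in first.values
    }
    return CoverageTrack(first.dataset_id, first.genome_id, values, first.source)


def bin_signal(values: np.ndarray, width: int = 128) -> np.ndarray:
    """Per-bin sum of per-bp signal; total signal is conserved."""
    values = np.asarray(values)
    if values.size % width != 0:
        raise ValueError(f"length {values.size} not divisible by bin width {width}")
    return values.reshape(-1, width).sum(axis=1)


def preprocess_track(
    replicates: Sequence[CoverageTrack],
    config: PreprocessConfig,
    mask_regions: Sequence[Tuple] = (),
) -> CoverageTrack:
    """Run the per-bp stages of the fixed pipeline (soft-clip happens on
    binned values at example-construction time)."""
    staged = [clip_negatives(t) for t in replicates]
    if mask_regions:
        staged = [mask_to_percentile(t, mask_regions, config.mask_percentile)
                  for t in staged]
    return average_replicates(staged)


# ---------------------------------------------------------------------------
# Sequence encoding


_ENCODE_LUT = np.zeros((256, 4), dtype=np.float32)
for _i, _b in enumerate("ACGT"):
    _ENCODE_LUT[ord(_b), _i] = 1.0
    _ENCODE_LUT[ord(_b.lower()), _i] = 1.0
_ENCODE_LUT[ord("N")] = _ENCODE_LUT[ord("n")] = 0.25
_VALID = np.zeros(256, dtype=bool)
for _b in "ACGTNacgtn":
    _VALID[ord(_b)] = True


def encode_sequence(dna: str) -> np.ndarray:
    """One-hot encode to a 4 x L matrix, rows A,C,G,T; N -> uniform 0.25."""
    raw = np.frombuffer(dna.encode(), dtype=np.uint8)
    bad = np.flatnonzero(~_VALID[raw])
    if bad.size:
        raise ValueError(f"invalid character {dna[bad[0]]!r} at position {bad[0]}")
    return _ENCODE_LUT[raw].T.copy()


def reverse_complement_onehot(x: np.ndarray) -> np.ndarray:
    """Reverse-complement an encoded (4 x L) matrix: flip rows (A<->T, C<->G)
    and flip positions."""
    return x[::-1, ::-1].copy()


# ---------------------------------------------------------------------------
# Interval tiling


def default_stride(seq_len: int) -> int:
    """50% overlap minus 63 bp, so window and pooling boundaries shift too."""
    return seq_len // 2 + 63


def tile_training_intervals(
    split_bed: Sequence[Tuple[str, int, int, str]],
    seq_len: int,
    stride: Optional[int] = None,
) -> List[Tuple[str, int, int, str]]:
    """Tile length-``seq_len`` intervals at ``stride`` within contiguous
    same-split territory; intervals never cross split boundaries."""
    if stride is None:
        stride = default_stride(seq_len)
    # merge adjacent records of the same chrom+split into contiguous blocks
    blocks: List[Tuple[str, int, int, str]] = []
    for chrom, start, end, name in sorted(split_bed):
        if blocks and blocks[-1][0] == chrom and blocks[-1][3] == name \
                and blocks[-1][2] == start:
            blocks[-1] = (chrom, blocks[-1][1], end, name)
        else:
            blocks.append((chrom, start, end, name))
    intervals = []
    any_short = False
    for chrom, start, end, name in blocks:
        if end - start < seq_len:
            any_short = True
            continue
        for s in range(start, end - seq_len + 1, stride):
            intervals.append((chrom, s, s + seq_len, name))
    if any_short and not intervals:
        warnings.warn("every contiguous block is shorter than the sequence length")
    return intervals


# ---------------------------------------------------------------------------
# Training examples and the on-disk container


@dataclass
class TrainingExample:
    sequence: np.ndarray  # 4 x L float32
    targets: np.ndarray  # n_bins x n_datasets float32
    genome_id: str
    split: str
    chrom: str
    start: int
    end: int


def make_examples(
    genome,  # pyfaidx.Fasta
    tracks: Sequence[CoverageTrack],
    intervals: Sequence[Tuple[str, int, int, str]],
    genome_id: str,
    bin_width: int = 128,
    configs: Optional[Sequence[PreprocessConfig]] = None,
) -> List[TrainingExample]:
    """Cut encoded sequences and binned, soft-clipped targets at intervals."""
    from .io import fetch_sequence

    if configs is None:
        configs = [PreprocessConfig() for _ in tracks]
    examples = []
    for chrom, start, end, split_name in intervals:
        seq = encode_sequence(fetch_sequence(genome, chrom, start, end))
        cols = []
        for track, cfg in zip(tracks, configs):
            binned = bin_signal(track.values[chrom][start:end], bin_width)
            cols.append(soft_clip(binned, cfg.clip_threshold))
        targets = np.stack(cols, axis=1).astype(np.float32)
        examples.append(TrainingExample(seq, targets, genome_id, split_name,
                                        chrom, start, end))
    return examples


def write_dataset(examples: Sequence[TrainingExample], path: str) -> None:
    with h5py.File(path, "w") as f:
        n = len(examples)
        f.attrs["n_examples"] = n
        if n == 0:
            return
        seq = np.stack([e.sequence for e in examples])
        tgt = np.stack([e.targets for e in examples])
        f.create_dataset("sequence", data=seq, chunks=(1,) + seq.shape[1:])
        f.create_dataset("targets", data=tgt, chunks=(1,) + tgt.shape[1:])
        str_dt = h5py.string_dtype()
        f.create_dataset("genome_id", data=[e.genome_id for e in examples], dtype=str_dt)
        f.create_dataset("split", data=[e.split for e in examples], dtype=str_dt)
        f.create_dataset("chrom", data=[e.chrom for e in examples], dtype=str_dt)
        f.create_dataset("coords", data=[(e.start, e.end) for e in examples])


def read_dataset(path: str, batch_size: Optional[int] = None
                 ) -> Iterable[List[TrainingExample]]:
    """Stream examples back in batches (one batch holding all if unset)."""
    with h5py.File(path, "r") as f:
        n = int(f.attrs["n_examples"])
        if n == 0:
            yield []
            return
        step = batch_size or n
        for lo in range(0, n, step):
            hi = min(lo + step, n)
            seq = f["sequence"][lo:hi]
            tgt = f["targets"][lo:hi]
            gid = [s.decode() for s in f["genome_id"][lo:hi]]
            spl = [s.decode() for s in f["split"][lo:hi]]
            chrom = [s.decode() for s in f["chrom"][lo:hi]]
            coords = f["coords"][lo:hi]
            yield [
                TrainingExample(seq[i], tgt[i], gid[i], spl[i], chrom[i],
                                int(coords[i][0]), int(coords[i][1]))
                for i in range(hi - lo)
            ]


def load_dataset(path: str) -> List[TrainingExample]:
    return next(iter(read_dataset(path)))
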