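"""End-to-end desk-scale benchmark pipeline on the synthetic species pair.

Wires the full stack together: generate a two-species benchmark, build the
homology-aware split, cut training examples, and train joint versus
single-genome models. Used by the acceptance suite and the CLI demo.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import io, prep, split as gsplit, synthetic
from .model import Model, ModelConfig, build_model, toy_config
from .training import TrainConfig, evaluate, train


@dataclass
class BenchmarkData:
    pair: synthetic.SyntheticPair
    grammar: synthetic.GrammarSpec
    assignment: Dict[gsplit.GenomeRegion, str]
    examples: Dict[str, List[prep.TrainingExample]]  # genome -> all splits
    track_ids: Dict[str, List[str]]  # genome -> ordered dataset ids
    genomes: Dict[str, object] = field(default_factory=dict)

    def split_examples(self, genome_id: str, split_name: str
                       ) -> List[prep.TrainingExample]:
        return [e for e in self.examples[genome_id] if e.split == split_name]


def build_benchmark(
    out_dir: str,
    seed: int,
    n_chrom: int = 2,
    chrom_len: int = 262_144,
    shared_fraction: float = 0.7,
    tissues: Sequence[str] = ("alpha", "beta", "gamma", "delta"),
    seq_len: int = 16_384,
    bin_width: int = 16,
    tile_size: int = 65_536,
    min_aligned: int = 16_384,
    noise_depth: Optional[float] = 0.5,
    stride: Optional[int] = None,
    substitution_rate: float = 0.05,
    clip_thresholds: Dict[str, float] = None,  # per assay; cage clipped harder

    n_variants: int = 60,
    tss_per_block: int = 3,
    grammar_kwargs: Optional[Dict] = None,
) -> BenchmarkData:
    """Generate the synthetic pair and produce split-labelled examples."""
    grammar = synthetic.default_grammar(
        tissues=tissues, seed=seed, substitution_rate=substitution_rate,
        **(grammar_kwargs or {}))
    pair = synthetic.generate_species_pair(
        grammar, n_chrom=n_chrom, chrom_len=chrom_len,
        shared_fraction=shared_fraction, out_dir=out_dir,
        tss_per_block=tss_per_block, distal_range=(300, 1000))
    synthetic.simulate_signal_tracks(
        pair, grammar, noise_depth=noise_depth, noise_seed=seed)
    if n_variants:
        synthetic.simulate_variant_truth(pair, grammar, n_variants, seed=seed)

    regions = {g: gsplit.tile_genome(pair.chrom_sizes[g], tile_size, g) for g in "AB"}
    blocks = io.read_net_tsv(pair.alignment)
    graph = gsplit.build_homology_graph(regions["A"], regions["B"], blocks, min_aligned)
    cfg = gsplit.SplitConfig(tile_size=tile_size, min_aligned=min_aligned, seed=seed)
    assignment = gsplit.partition_components(graph, cfg)

    examples: Dict[str, List[prep.TrainingExample]] = {}
    track_ids: Dict[str, List[str]] = {}
    genomes: Dict[str, object] = {}
    for g in "AB":
        fa = io.read_fasta(pair.genome_path(g))
        genomes[g] = fa
        ids = [t for t in pair.track_order if t.endswith(f":{g}")]
        track_ids[g] = ids
        tracks = [
            prep.CoverageTrack(tid, g,
                               io.read_bedgraph(pair.truth_tracks[tid],
                                                pair.chrom_sizes[g]))
            for tid in ids
        ]
        clips = clip_thresholds or {"cage": 64.0, "acc": 64.0}
        configs = [prep.PreprocessConfig(
            clip_threshold=clips[tid.split(":")[1]]) for tid in ids]
        bed = gsplit.assignment_to_bed(assignment, g)
        intervals = prep.tile_training_intervals(bed, seq_len, stride=stride)
        examples[g] = prep.make_examples(fa, tracks, intervals, g,
                                         bin_width=bin_width, configs=configs)
    return BenchmarkData(pair, grammar, assignment, examples, track_ids, genomes)


def benchmark_model_config(data: BenchmarkData, seq_len: int = 16_384,
                           tower_blocks: int = 4, dilated_blocks: int = 6,
                           filters: int = 12, seed: int = 0,
                           **kwargs) -> ModelConfig:
    heads = {g: len(data.track_ids[g]) for g in data.track_ids}
    # dilation growth 2.0 keeps the receptive field (~ +-1 kb) wide enough to
    # see the benchmark's distal clusters despite the short dilated stack
    kwargs.setdefault("dilation_growth", 2.0)
    kwargs.setdefault("bn_momentum", 0.9)
    return toy_config(seq_len=seq_len, tower_blocks=tower_blocks,
                      dilated_blocks=dilated_blocks, filters=filters,
                      heads=heads, seed=seed, **kwargs)


def train_model(
    data: BenchmarkData,
    genomes: Sequence[str],
    seed: int,
    train_config: Optional[TrainConfig] = None,
    model_config: Optional[ModelConfig] = None,
    **config_kwargs,
) -> Tuple[Model, Dict[str, np.ndarray]]:
    """Train on the listed genomes and evaluate per-task test Pearson r."""
    if model_config is None:
        model_config = benchmark_model_config(data, seed=seed, **config_kwargs)
        model_config.heads = {g: len(data.track_ids[g]) for g in genomes}
    model = build_model(model_config)
    cfg = train_config or TrainConfig(seed=seed, lr=0.02, momentum=0.98,
                                      joint_patience=5, max_epochs=15)
    train_set = {g: data.split_examples(g, "train") for g in genomes}
    valid_set = {g: data.split_examples(g, "valid") for g in genomes}
    train(model, train_set, valid_set, cfg, genomes=data.genomes)
    test_set = [e for g in genomes for e in data.split_examples(g, "test")]
    corr = evaluate(model, test_set)
    return model, corr


def joint_vs_single(
    data: BenchmarkData,
    seeds: Sequence[int],
    train_config: Optional[TrainConfig] = None,
    **config_kwargs,
) -> Dict[str, Dict[str, np.ndarray]]:
    """Mean per-task test r for joint and per-genome single training."""
    acc: Dict[str, List[Dict[str, np.ndarray]]] = {"joint": [], "A": [], "B": []}
    for seed in seeds:
        _, corr = train_model(data, ["A", "B"], seed, train_config, **config_kwargs)
        acc["joint"].append(corr)
        for g in "AB":
            _, corr = train_model(data, [g], seed, train_config, **config_kwargs)
            acc[g].append(corr)
    out: Dict[str, Dict[str, np.ndarray]] = {}
    for mode, runs in acc.items():
        merged: Dict[str, np.ndarray] = {}
        for g in runs[0]:
            merged[g] = np.mean([r[g] for r in runs], axis=0)
        out[mode] = merged
    return out


def cage_task_indices(data: BenchmarkData, genome_id: str) -> List[int]:
    return [i for i, t in enumerate(data.track_ids[genome_id])
            if ":cage:" in t]


def _holdout_tss(data: BenchmarkData, genome_id: str,
                 splits=("valid", "test"), margin: int = 0):
    """TSSs of ``genome_id`` lying in held-out tiles, window-safe."""
    held = [(r.chrom, r.start, r.end) for r, s in data.assignment.items()
            if r.genome_id == genome_id and s in splits]
    tss = io.read_bed(data.pair.truth_tss[genome_id])
    sizes = data.pair.chrom_sizes[genome_id]
    out = []
    for chrom, start, _end, name in tss:
        if start - margin < 0 or start + margin > sizes[chrom]:
            continue
        if any(c == chrom and s <= start < e for c, s, e in held):
            out.append((chrom, start, name))
    return out


def tss_activity_matrices(
    data: BenchmarkData,
    model: Model,
    obs_genome: str = "A",
    pred_head: str = "B",
    assay: str = "cage",
    splits=("valid", "test"),
    window_bins: int = 4,
):
    """Observed vs cross-species-predicted activity at held-out TSSs.

    Observed values come from ``obs_genome``'s simulated tracks; predictions
    run the ``pred_head`` genome head on ``obs_genome`` sequence windows
    centered at each TSS, summing the central bins. Rows are TSSs, columns
    tissues.
    """
    import pandas as pd

    L = model.config.seq_len
    bin_width = model.config.bin_width
    tss = _holdout_tss(data, obs_genome, splits=splits, margin=L // 2)
    tissues = sorted({t.split(":")[0] for t in data.track_ids[obs_genome]})
    obs_tracks = {
        t: io.read_bedgraph(
            data.pair.truth_tracks[f"{t}:{assay}:{obs_genome}"],
            data.pair.chrom_sizes[obs_genome])
        for t in tissues
    }
    fa = data.genomes[obs_genome]
    pred_tissue_idx = {
        t: data.track_ids[pred_head].index(f"{t}:{assay}:{pred_head}")
        for t in tissues
    }
    half_bp = window_bins * bin_width // 2
    obs_rows, pred_rows, names = [], [], []
    windows = []
    for chrom, start, name in tss:
        names.append(name)
        obs_rows.append([
            float(obs_tracks[t][chrom][start - half_bp : start + half_bp].sum())
            for t in tissues
        ])
        windows.append((chrom, start))
    # batch the prediction forwards
    center = model.config.n_bins // 2
    for lo in range(0, len(windows), 4):
        chunk = windows[lo : lo + 4]
        x = np.stack([
            prep.encode_sequence(io.fetch_sequence(fa, c, s - L // 2, s + L // 2))
            for c, s in chunk
        ])
        pred = model.predict(x, pred_head)
        sl = slice(center - window_bins // 2, center + window_bins // 2)
        for b in range(len(chunk)):
            pred_rows.append([
                float(pred[b, sl, pred_tissue_idx[t]].sum()) for t in tissues
            ])
    observed = pd.DataFrame(obs_rows, index=names, columns=tissues)
    predicted = pd.DataFrame(pred_rows, index=names, columns=tissues)
    return observed, predicted


def scoreable_truth_variants(
    data: BenchmarkData,
    model: Model,
    genome_id: str = "A",
    classes=("disrupt", "create"),
):
    """Planted variants of the given classes whose windows fit the contig,
    with their per-track generative effects."""
    from .variants import Variant

    L = model.config.seq_len
    sizes = data.pair.chrom_sizes[genome_id]
    out = []
    for rec in io.read_vcf(data.pair.planted_variants):
        if rec.info.get("CLASS") not in classes:
            continue
        if rec.start - L // 2 < 0 or rec.start + L // 2 > sizes[rec.chrom]:
            continue
        effects = np.array([float(x) for x in rec.info["GEN_EFFECT"].split(",")])
        out.append((Variant.from_vcf_record(rec), rec.info["CLASS"], effects))
    return out


def variant_sign_agreement(
    data: BenchmarkData,
    model: Model,
    genome_id: str = "A",
    max_variants: Optional[int] = None,
    min_effect: float = 1.0,
) -> Tuple[int, int]:
    """(agreements, evaluated) between ensemble score signs and generative
    effect signs, judged on each variant's largest-|effect| track."""
    from .variants import ensemble_scores

    fa = data.genomes[genome_id]
    track_labels = [t.rsplit(":", 1)[0] for t in data.track_ids[genome_id]]
    candidates = scoreable_truth_variants(data, model, genome_id)
    agree = total = 0
    for variant, _cls, effects in candidates:
        if max_variants is not None and total >= max_variants:
            break
        j = int(np.argmax(np.abs(effects)))
        if abs(effects[j]) < min_effect:
            continue
        track_idx = track_labels.index(
            [f"{t}:{a}" for t in data.grammar.tissues for a in ("cage", "acc")][j])
        scores = ensemble_scores(model, fa, variant, genome_id)
        total += 1
        if np.sign(scores[track_idx]) == np.sign(effects[j]):
            agree += 1
    return agree, total
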