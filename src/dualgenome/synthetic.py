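"""Synthetic two-species benchmark with a shared regulatory grammar.

Generates a pair of genomes that share homologous blocks and a common motif
lexicon, per-tissue signal tracks driven by proximal and distal motif
contributions, and planted variants with known generative effect sizes. All
outputs are deterministic, byte-exact functions of the seed.

The generative signal model is additive: every motif placement contributes a
finite-support bump to each track, so a variant's exact truth effect (alt
track sum minus ref track sum) decomposes over the placements it overlaps.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import io

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}


def softplus(x):
    return np.logaddexp(0.0, x)


@dataclass
class GrammarSpec:
    """Shared regulatory grammar of the two species.

    motif_set: list of position-weight matrices, each 4 x width with columns
        summing to 1 (rows ordered A,C,G,T).
    tissue_profiles: per-tissue signed activity weight for every motif.
    distal_decay: exponential length scale (bp) of enhancer contributions.
    substitution_rate: per-bp substitution probability between homologs.
    """

    motif_set: List[np.ndarray]
    tissue_profiles: Dict[str, np.ndarray]
    distal_decay: float
    substitution_rate: float
    seed: int
    max_distal_bp: int = 20_000

    def __post_init__(self):
        if not self.distal_decay > 0:
            raise ValueError("distal_decay must be positive")
        if not (0 <= self.substitution_rate < 0.5):
            raise ValueError("substitution_rate must be in [0, 0.5)")
        for tissue, w in self.tissue_profiles.items():
            w = np.asarray(w, dtype=float)
            if not np.all(np.isfinite(w)) or len(w) != len(self.motif_set):
                raise ValueError(f"bad tissue profile for {tissue!r}")
            self.tissue_profiles[tissue] = w
        for i, pwm in enumerate(self.motif_set):
            pwm = np.asarray(pwm, dtype=float)
            if pwm.shape[0] != 4 or not (6 <= pwm.shape[1] <= 12):
                raise ValueError(f"motif {i}: expected 4 x (6..12) PWM, got {pwm.shape}")
            self.motif_set[i] = pwm

    @property
    def tissues(self) -> List[str]:
        return list(self.tissue_profiles)


def default_grammar(
    n_motifs: Optional[int] = None,
    tissues: Sequence[str] = ("alpha", "beta", "gamma", "delta"),
    seed: int = 0,
    motif_len: Tuple[int, int] = (7, 10),
    distal_decay: float = 8000.0,
    substitution_rate: float = 0.03,
    driver_weight: float = 3.0,
    off_driver_weight: float = -0.8,
    drivers_per_tissue: int = 1,
) -> GrammarSpec:
    """Random grammar with sharp PWMs and contrastive tissue drivers.

    Motif 0 is a shared core-promoter anchor active in every tissue. Each
    tissue owns disjoint driver motifs carrying strong positive weight; other
    tissues weight those drivers mildly negative, so tracks share a common
    activating backbone but differ sharply where drivers cluster. The lexicon
    is kept small so desk-scale models can represent every motif and its
    reverse complement in their first convolution layer.
    """
    if n_motifs is None:
        n_motifs = 1 + drivers_per_tissue * len(tissues)
    if n_motifs < 1 + drivers_per_tissue * len(tissues):
        raise ValueError("need at least 1 + drivers_per_tissue * n_tissues motifs")
    rng = np.random.default_rng(seed)
    # dinucleotide-repeat consensi with distinct base composition (and no
    # reverse-complement collisions between different motifs): gross
    # composition survives pooling, keeping the lexicon separable by small
    # first-layer filter banks
    repeat_units = [None, (0, 0), (1, 1), (0, 1), (0, 2),
                    (1, 0), (2, 1), (3, 1), (1, 2)]
    if n_motifs > len(repeat_units):
        raise ValueError(f"at most {len(repeat_units)} motifs supported")
    motifs = []
    for unit in repeat_units[:n_motifs]:
        w = int(rng.integers(motif_len[0], motif_len[1] + 1))
        if unit is None:
            # promoter anchor: random sharp consensus, so TSS positions have
            # few spurious composition near-matches in background sequence
            consensus = rng.integers(0, 4, size=w)
        else:
            consensus = np.tile(unit, w // 2 + 1)[:w]
        pwm = np.full((4, w), 0.05)
        pwm[consensus, np.arange(w)] = 0.85
        motifs.append(pwm)
    profiles: Dict[str, np.ndarray] = {}
    for ti, tissue in enumerate(tissues):
        w = rng.normal(0.0, 0.3, size=n_motifs)
        w[0] = 1.0  # shared promoter anchor
        for tj in range(len(tissues)):
            for k in range(drivers_per_tissue):
                d = 1 + drivers_per_tissue * tj + k
                w[d] = driver_weight if tj == ti else off_driver_weight
        profiles[tissue] = w
    return GrammarSpec(
        motif_set=motifs,
        tissue_profiles=profiles,
        distal_decay=distal_decay,
        substitution_rate=substitution_rate,
        seed=seed,
    )


@dataclass
class SyntheticPair:
    """File bundle describing one generated two-species benchmark."""

    genome_a: str
    genome_b: str
    alignment: str
    truth_tss: Dict[str, str]  # genome_id -> BED path
    placements: Dict[str, str]  # genome_id -> TSV path
    truth_tracks: Dict[str, str] = field(default_factory=dict)  # track_id -> bedGraph
    planted_variants: Optional[str] = None
    track_order: List[str] = field(default_factory=list)
    chrom_sizes: Dict[str, Dict[str, int]] = field(default_factory=dict)

    def genome_path(self, genome_id: str) -> str:
        return {"A": self.genome_a, "B": self.genome_b}[genome_id]


# ---------------------------------------------------------------------------
# Genome pair generation


def _random_sequence(rng: np.random.Generator, n: int) -> np.ndarray:
    return rng.integers(0, 4, size=n, dtype=np.int8)


def _mutate(rng: np.random.Generator, seq: np.ndarray, rate: float) -> np.ndarray:
    out = seq.copy()
    if rate > 0:
        hit = np.flatnonzero(rng.random(seq.size) < rate)
        out[hit] = (out[hit] + rng.integers(1, 4, size=hit.size)) % 4
    return out


def _to_string(seq: np.ndarray) -> str:
    return seq.astype(np.uint8).tobytes().translate(
        bytes.maketrans(bytes(range(4)), BASES.encode())
    ).decode()


PLACEMENT_COLUMNS = ["chrom", "start", "motif_id", "tss_id", "latent", "damaged_col"]


def _consensus_instance(pwm: np.ndarray) -> np.ndarray:
    """Planted instances carry the consensus (match score 1); divergence
    comes only from between-species substitutions and latent damage."""
    return pwm.argmax(axis=0).astype(np.int8)


def generate_species_pair(
    grammar: GrammarSpec,
    n_chrom: int,
    chrom_len: int,
    shared_fraction: float,
    out_dir: str,
    block_size: Optional[int] = None,
    tss_per_block: int = 2,
    distal_clusters_per_tss: int = 2,
    latent_per_block: int = 2,
    distal_range: Tuple[int, int] = (500, 20_000),
    min_seq_len: int = 4096,
) -> SyntheticPair:
    """Generate a homologous genome pair with planted motif placements.

    Homologous blocks carry identical motif placements (same coordinates),
    diverged only by the grammar's substitution rate; non-shared blocks have
    independent backgrounds and independent placements. The alignment TSV
    covers exactly the shared blocks.
    """
    if not (0 <= shared_fraction <= 1):
        raise ValueError("shared_fraction must be in [0, 1]")
    if chrom_len < 4 * min_seq_len:
        raise ValueError(
            f"chrom_len {chrom_len} too small: need at least 4 x {min_seq_len} bp"
        )
    if block_size is None:
        block_size = max(min(1_000_000, chrom_len // 8), min_seq_len)
    rng = np.random.default_rng(grammar.seed)
    io.ensure_dir(out_dir)

    seqs = {"A": {}, "B": {}}
    placements = {"A": [], "B": []}
    tss = {"A": [], "B": []}
    align_blocks: List[io.AlignmentBlock] = []
    tss_counter = {"A": 0, "B": 0}

    def plant_block(genome_id: str, chrom: str, seq: np.ndarray, b0: int, b1: int):
        """Plant TSSs, proximal/distal motif clusters, and latent motifs."""
        margin = min(2048, (b1 - b0) // 8)
        occupied: List[Tuple[int, int]] = []

        def free(s, e):
            return all(e <= os_ or s >= oe for os_, oe in occupied)

        def plant(pos, motif_id, tss_id, latent):
            pwm = grammar.motif_set[motif_id]
            w = pwm.shape[1]
            if pos < b0 or pos + w > b1 or not free(pos, pos + w):
                return False
            inst = _consensus_instance(pwm)
            damaged_col = -1
            if latent:
                damaged_col = int(rng.integers(0, w))
                worst = int(np.argmin(pwm[:, damaged_col]))
                inst = inst.copy()
                inst[damaged_col] = worst
            seq[pos : pos + w] = inst
            occupied.append((pos, pos + w))
            placements[genome_id].append(
                dict(chrom=chrom, start=pos, motif_id=motif_id,
                     tss_id=tss_id, latent=int(latent), damaged_col=damaged_col)
            )
            return True

        for _ in range(tss_per_block):
            t = int(rng.integers(b0 + margin, b1 - margin))
            tss_id = tss_counter[genome_id]
            tss_counter[genome_id] += 1
            tss[genome_id].append((chrom, t, f"tss_{genome_id}_{tss_id}"))
            # core-promoter anchor: motif 0 centered on the TSS itself
            anchor_w = grammar.motif_set[0].shape[1]
            plant(t - anchor_w // 2, 0, tss_id, False)
            # proximal placements flanking the TSS
            for off in (-int(rng.integers(20, 120)), int(rng.integers(20, 120))):
                plant(t + off, int(rng.integers(0, len(grammar.motif_set))), tss_id, False)
            # distal clusters
            for _ in range(distal_clusters_per_tss):
                max_d = min(grammar.max_distal_bp, margin - 50, distal_range[1])
                d = int(rng.integers(distal_range[0], max(distal_range[0] + 1, max_d)))
                side = 1 if rng.random() < 0.5 else -1
                anchor = t + side * d
                for k in range(2):
                    plant(anchor + 30 * k,
                          int(rng.integers(0, len(grammar.motif_set))), tss_id, False)
        for _ in range(latent_per_block):
            for _attempt in range(10):
                pos = int(rng.integers(b0 + margin, b1 - margin))
                if plant(pos, int(rng.integers(0, len(grammar.motif_set))), -1, True):
                    break

    for ci in range(n_chrom):
        chrom = f"chr{ci + 1}"
        n_blocks = max(1, -(-chrom_len // block_size))
        bounds = [(i * block_size, min((i + 1) * block_size, chrom_len)) for i in range(n_blocks)]
        n_shared = int(round(shared_fraction * n_blocks))
        if shared_fraction == 1.0:
            n_shared = n_blocks
        shared_idx = set(rng.choice(n_blocks, size=n_shared, replace=False).tolist())

        seq_a = _random_sequence(rng, chrom_len)
        seq_b = np.empty(chrom_len, dtype=np.int8)

        for bi, (b0, b1) in enumerate(bounds):
            if bi in shared_idx:
                plant_block("A", chrom, seq_a, b0, b1)
                # copy A's block placements into B at identical coordinates
                block_pl = [p for p in placements["A"]
                            if p["chrom"] == chrom and b0 <= p["start"] < b1]
                seq_b[b0:b1] = _mutate(rng, seq_a[b0:b1], grammar.substitution_rate)
                for p in block_pl:
                    q = dict(p)
                    if p["tss_id"] >= 0:
                        q["tss_id"] = p["tss_id"]  # remapped below via offset
                    placements["B"].append(q)
                block_tss = [t for t in tss["A"] if t[0] == chrom and b0 <= t[1] < b1]
                for (tc, tp, _tn) in block_tss:
                    tid = tss_counter["B"]
                    tss_counter["B"] += 1
                    tss["B"].append((tc, tp, f"tss_B_{tid}"))
                align_blocks.append(
                    io.AlignmentBlock(chrom_a=chrom, start_a=b0, end_a=b1,
                                      chrom_b=chrom, start_b=b0, end_b=b1)
                )
            else:
                plant_block("A", chrom, seq_a, b0, b1)
                seq_b[b0:b1] = _random_sequence(rng, b1 - b0)
                plant_block("B", chrom, seq_b, b0, b1)
        seqs["A"][chrom] = seq_a
        seqs["B"][chrom] = seq_b

    # emit files
    paths = SyntheticPair(
        genome_a=os.path.join(out_dir, "genome_A.fa"),
        genome_b=os.path.join(out_dir, "genome_B.fa"),
        alignment=os.path.join(out_dir, "alignment.net.tsv"),
        truth_tss={g: os.path.join(out_dir, f"tss_{g}.bed") for g in "AB"},
        placements={g: os.path.join(out_dir, f"placements_{g}.tsv") for g in "AB"},
        chrom_sizes={g: {c: len(s) for c, s in seqs[g].items()} for g in "AB"},
    )
    io.write_fasta(paths.genome_a, {c: _to_string(s) for c, s in seqs["A"].items()})
    io.write_fasta(paths.genome_b, {c: _to_string(s) for c, s in seqs["B"].items()})
    io.write_net_tsv(paths.alignment, align_blocks)
    for g in "AB":
        io.write_bed(paths.truth_tss[g], [(c, p, p + 1, n) for c, p, n in tss[g]])
        df = pd.DataFrame(placements[g], columns=PLACEMENT_COLUMNS)
        df.to_csv(paths.placements[g], sep="\t", index=False)
    return paths


# ---------------------------------------------------------------------------
# Generative signal model


def _load_genome_arrays(fasta_path: str) -> Dict[str, np.ndarray]:
    fa = io.read_fasta(fasta_path)
    out = {}
    for name in fa.keys():
        s = str(fa[name][:]).upper()
        arr = np.frombuffer(s.encode(), dtype=np.uint8).copy()
        conv = np.full(256, -1, dtype=np.int8)
        for b, i in _BASE_INDEX.items():
            conv[ord(b)] = i
        out[name] = conv[arr]
    return out


def _match_score(seq: np.ndarray, start: int, pwm: np.ndarray) -> float:
    """PWM match in (0, 1]: probability of the window relative to consensus."""
    w = pwm.shape[1]
    window = seq[start : start + w]
    if window.size < w or np.any(window < 0):
        return 0.0
    cols = np.arange(w)
    logp = np.log(pwm[window, cols]).sum()
    logbest = np.log(pwm.max(axis=0)).sum()
    return float(np.exp(logp - logbest))


CAGE_PEAK_HALFWIDTH = 16
ACC_PAD = 100
BACKGROUND = 0.05
ACC_GAIN = 1.5


class GenerativeModel:
    """Additive truth-signal model over motif placements.

    CAGE-like: each TSS emits a sharp peak of height softplus(proximal +
    distance-decayed distal motif contributions). Accessibility-like: each
    placement emits a plateau of height softplus(gain * weight * match).
    """

    def __init__(self, grammar: GrammarSpec, seqs: Dict[str, np.ndarray],
                 placements: pd.DataFrame, tss: List[Tuple[str, int, str]]):
        self.grammar = grammar
        self.seqs = seqs
        self.placements = placements.reset_index(drop=True)
        self.tss = tss
        self._matches = np.array([
            _match_score(seqs[r.chrom], int(r.start), grammar.motif_set[int(r.motif_id)])
            for r in self.placements.itertuples()
        ])

    def tss_score(self, tissue: str, chrom: str, tpos: int,
                  matches: Optional[np.ndarray] = None) -> float:
        w = self.grammar.tissue_profiles[tissue]
        if matches is None:
            matches = self._matches
        total = 0.0
        pl = self.placements
        on_chrom = np.flatnonzero(pl["chrom"].values == chrom)
        for i in on_chrom:
            d = abs(int(pl["start"].iloc[i]) - tpos)
            if d > self.grammar.max_distal_bp:
                continue
            decay = np.exp(-d / self.grammar.distal_decay)
            total += w[int(pl["motif_id"].iloc[i])] * matches[i] * decay
        return float(total)

    def cage_track(self, tissue: str) -> Dict[str, np.ndarray]:
        out = {c: np.full(len(s), BACKGROUND, dtype=np.float32) for c, s in self.seqs.items()}
        for chrom, tpos, _name in self.tss:
            h = softplus(self.tss_score(tissue, chrom, tpos))
            lo = max(0, tpos - CAGE_PEAK_HALFWIDTH)
            hi = min(len(out[chrom]), tpos + CAGE_PEAK_HALFWIDTH + 1)
            out[chrom][lo:hi] += h
        return out

    def acc_track(self, tissue: str) -> Dict[str, np.ndarray]:
        w = self.grammar.tissue_profiles[tissue]
        out = {c: np.full(len(s), BACKGROUND, dtype=np.float32) for c, s in self.seqs.items()}
        for i, r in enumerate(self.placements.itertuples()):
            if int(r.motif_id) == 0:
                continue  # promoter anchor contributes CAGE only
            arg = ACC_GAIN * w[int(r.motif_id)] * self._matches[i]
            h = softplus(arg) - softplus(0.0)
            if h <= 0:
                continue
            width = self.grammar.motif_set[int(r.motif_id)].shape[1]
            lo = max(0, int(r.start) - ACC_PAD)
            hi = min(len(out[r.chrom]), int(r.start) + width + ACC_PAD)
            out[r.chrom][lo:hi] += h
        return out

    def variant_effect(self, chrom: str, pos0: int, ref: str, alt: str,
                       tissue: str, assay: str) -> float:
        """Exact truth-track-sum difference (alt minus ref) for one track."""
        seq = self.seqs[chrom]
        if seq[pos0] != _BASE_INDEX[ref]:
            raise ValueError(f"ref mismatch at {chrom}:{pos0}")
        pl = self.placements
        widths = np.array([self.grammar.motif_set[int(m)].shape[1]
                           for m in pl["motif_id"]])
        affected = np.flatnonzero(
            (pl["chrom"].values == chrom)
            & (pl["start"].values <= pos0)
            & (pos0 < pl["start"].values + widths)
        )
        if affected.size == 0:
            return 0.0
        alt_seq = seq.copy()
        alt_seq[pos0] = _BASE_INDEX[alt]
        alt_matches = self._matches.copy()
        for i in affected:
            alt_matches[i] = _match_score(
                alt_seq, int(pl["start"].iloc[i]),
                self.grammar.motif_set[int(pl["motif_id"].iloc[i])])
        w = self.grammar.tissue_profiles[tissue]
        delta = 0.0
        if assay == "cage":
            peak_len = 2 * CAGE_PEAK_HALFWIDTH + 1
            touched = set()
            for i in affected:
                p = int(pl["start"].iloc[i])
                for chrom_t, tpos, name in self.tss:
                    if chrom_t == chrom and abs(tpos - p) <= self.grammar.max_distal_bp:
                        touched.add((chrom_t, tpos))
            for chrom_t, tpos in touched:
                old = softplus(self.tss_score(tissue, chrom_t, tpos))
                new = softplus(self.tss_score(tissue, chrom_t, tpos, matches=alt_matches))
                delta += (new - old) * peak_len
        elif assay == "acc":
            for i in affected:
                if int(pl["motif_id"].iloc[i]) == 0:
                    continue  # anchor has no accessibility contribution
                width = int(widths[i])
                plateau = width + 2 * ACC_PAD
                old = max(softplus(ACC_GAIN * w[int(pl["motif_id"].iloc[i])] * self._matches[i])
                          - softplus(0.0), 0.0)
                new = max(softplus(ACC_GAIN * w[int(pl["motif_id"].iloc[i])] * alt_matches[i])
                          - softplus(0.0), 0.0)
                delta += (new - old) * plateau
        else:
            raise ValueError(f"unknown assay {assay!r}")
        return float(delta)


def _build_generative(pair: SyntheticPair, grammar: GrammarSpec, genome_id: str) -> GenerativeModel:
    seqs = _load_genome_arrays(pair.genome_path(genome_id))
    placements = pd.read_csv(pair.placements[genome_id], sep="\t")
    tss = [(c, s, n) for c, s, e, n in io.read_bed(pair.truth_tss[genome_id])]
    return GenerativeModel(grammar, seqs, placements, tss)


def track_id(tissue: str, assay: str, genome_id: str) -> str:
    return f"{tissue}:{assay}:{genome_id}"


def simulate_signal_tracks(
    pair: SyntheticPair,
    grammar: GrammarSpec,
    tissues: Optional[Sequence[str]] = None,
    assays: Sequence[str] = ("cage", "acc"),
    out_dir: Optional[str] = None,
    noise_depth: Optional[float] = None,
    noise_seed: int = 0,
) -> SyntheticPair:
    """Simulate per-tissue CAGE-like and accessibility-like truth tracks.

    With ``noise_depth`` set, tracks are Poisson-resampled at that sequencing
    depth (values become rng.poisson(truth * depth) / depth).
    """
    if tissues is None:
        tissues = grammar.tissues
    for t in tissues:
        if t not in grammar.tissue_profiles:
            raise ValueError(f"unknown tissue {t!r}")
    if out_dir is None:
        out_dir = os.path.dirname(pair.genome_a)
    rng = np.random.default_rng(noise_seed)
    pair.track_order = []
    for genome_id in "AB":
        gen = _build_generative(pair, grammar, genome_id)
        for tissue in tissues:
            for assay in assays:
                track = gen.cage_track(tissue) if assay == "cage" else gen.acc_track(tissue)
                if noise_depth is not None:
                    track = {c: (rng.poisson(v * noise_depth) / noise_depth).astype(np.float32)
                             for c, v in track.items()}
                tid = track_id(tissue, assay, genome_id)
                path = os.path.join(out_dir, f"track_{tissue}_{assay}_{genome_id}.bedgraph")
                io.write_bedgraph(path, track)
                pair.truth_tracks[tid] = path
                pair.track_order.append(tid)
    return pair


def simulate_variant_truth(
    pair: SyntheticPair,
    grammar: GrammarSpec,
    n_variants: int,
    seed: int,
    genome_id: str = "A",
    tissues: Optional[Sequence[str]] = None,
    assays: Sequence[str] = ("cage", "acc"),
    out_path: Optional[str] = None,
) -> str:
    """Plant variants with known generative effects and write them as VCF.

    Variants are stratified into motif-disrupting (consensus position of a
    planted instance flipped to the worst base), motif-creating (a latent
    instance's damaged base restored to consensus), and background (far from
    every placement). INFO carries CLASS and GEN_EFFECT, a comma list over
    ``tissue:assay`` tracks for the chosen genome.
    """
    import warnings

    if tissues is None:
        tissues = grammar.tissues
    rng = np.random.default_rng(seed)
    gen = _build_generative(pair, grammar, genome_id)
    pl = gen.placements
    track_labels = [f"{t}:{a}" for t in tissues for a in assays]

    real = pl.index[pl["latent"] == 0].tolist()
    latent = pl.index[pl["latent"] == 1].tolist()
    n_each = n_variants // 3
    variants: List[io.VcfRecord] = []

    def add_variant(chrom, pos0, ref_i, alt_i, vclass):
        ref, alt = BASES[ref_i], BASES[alt_i]
        effects = [gen.variant_effect(chrom, pos0, ref, alt, t, a)
                   for t in tissues for a in assays]
        variants.append(io.VcfRecord(
            chrom=chrom, pos=pos0 + 1, id=f"v{len(variants)}", ref=ref, alt=alt,
            info={"CLASS": vclass,
                  "GEN_EFFECT": ",".join(f"{e:.6g}" for e in effects)},
        ))

    # motif-disrupting: strongest-information column of a real placement
    n_disrupt = min(n_each, len(real))
    if n_disrupt < n_each:
        warnings.warn("fewer motif instances than requested disrupting variants")
    for i in rng.choice(real, size=n_disrupt, replace=False):
        r = pl.loc[i]
        pwm = grammar.motif_set[int(r["motif_id"])]
        col = int(np.argmax(pwm.max(axis=0) - pwm.min(axis=0)))
        pos0 = int(r["start"]) + col
        ref_i = int(gen.seqs[r["chrom"]][pos0])
        alt_i = int(np.argmin(pwm[:, col]))
        if alt_i == ref_i:
            alt_i = (ref_i + 1) % 4
        add_variant(r["chrom"], pos0, ref_i, alt_i, "disrupt")

    # motif-creating: restore a latent placement's damaged column
    n_create = min(n_each, len(latent))
    if n_create < n_each:
        warnings.warn("fewer latent instances than requested creating variants")
    for i in rng.choice(latent, size=n_create, replace=False):
        r = pl.loc[i]
        pwm = grammar.motif_set[int(r["motif_id"])]
        col = int(r["damaged_col"])
        pos0 = int(r["start"]) + col
        ref_i = int(gen.seqs[r["chrom"]][pos0])
        alt_i = int(np.argmax(pwm[:, col]))
        if alt_i == ref_i:
            alt_i = (ref_i + 1) % 4
        add_variant(r["chrom"], pos0, ref_i, alt_i, "create")

    # background: far from every placement and TSS
    n_bg = n_variants - n_disrupt - n_create
    chroms = list(gen.seqs)
    placed = 0
    guard = 0
    while placed < n_bg and guard < 50 * n_bg:
        guard += 1
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        pos0 = int(rng.integers(100, len(gen.seqs[chrom]) - 100))
        near_pl = np.any((pl["chrom"].values == chrom)
                         & (np.abs(pl["start"].values - pos0) < 200))
        near_tss = any(c == chrom and abs(p - pos0) < 200 for c, p, _ in gen.tss)
        if near_pl or near_tss:
            continue
        ref_i = int(gen.seqs[chrom][pos0])
        add_variant(chrom, pos0, ref_i, (ref_i + 1) % 4, "background")
        placed += 1

    if out_path is None:
        out_path = os.path.join(os.path.dirname(pair.genome_a), f"variants_{genome_id}.vcf")
    io.write_vcf(out_path, variants, extra_headers=[
        '##INFO=<ID=CLASS,Number=1,Type=String,Description="Variant class">',
        '##INFO=<ID=GEN_EFFECT,Number=.,Type=Float,Description="Generative effect per track">',
        f"##GEN_EFFECT_TRACKS={','.join(track_labels)}",
    ])
    pair.planted_variants = out_path
    return out_path
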