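"""Leakage-free train/validation/test partitions across two genomes.

Each genome is tiled into fixed-size regions; a bipartite graph connects
region pairs with substantial aligned sequence; connected components are
assigned to splits as indivisible units so homologs never cross splits.
"""

from __future__ import annotations

import warnings
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Sequence, Set, Tuple

import numpy as np

from .io import AlignmentBlock

SPLITS = ("train", "valid", "test")


@dataclass(frozen=True)
class GenomeRegion:
    genome_id: str
    chrom: str
    start: int
    end: int
    region_index: int

    @property
    def size(self) -> int:
        return self.end - self.start


@dataclass
class SplitConfig:
    tile_size: int = 1_000_000
    min_aligned: int = 100_000
    valid_frac: float = 0.12
    test_frac: float = 0.12
    seed: int = 0

    def __post_init__(self):
        if not self.valid_frac + self.test_frac < 1:
            raise ValueError("valid_frac + test_frac must be < 1")
        if not self.min_aligned < self.tile_size:
            raise ValueError("min_aligned must be < tile_size")


def tile_genome(chrom_sizes: Dict[str, int], tile_size: int, genome_id: str) -> List[GenomeRegion]:
    """Tile each chromosome into ceil(len / tile_size) contiguous regions."""
    regions: List[GenomeRegion] = []
    idx = 0
    for chrom, size in chrom_sizes.items():
        if size <= 0:
            warnings.warn(f"skipping zero-length chromosome {chrom!r}")
            continue
        for start in range(0, size, tile_size):
            regions.append(
                GenomeRegion(genome_id, chrom, start, min(start + tile_size, size), idx)
            )
            idx += 1
    return regions


def _region_lookup(regions: Sequence[GenomeRegion]) -> Dict[str, List[GenomeRegion]]:
    by_chrom: Dict[str, List[GenomeRegion]] = defaultdict(list)
    for r in regions:
        by_chrom[r.chrom].append(r)
    for lst in by_chrom.values():
        lst.sort(key=lambda r: r.start)
    return by_chrom


def _overlap_split(by_chrom, chrom: str, start: int, end: int, what: str):
    """Yield (region, overlap_bp) for regions intersecting [start, end)."""
    if chrom not in by_chrom:
        raise ValueError(f"alignment references unknown chromosome {chrom!r} ({what})")
    for r in by_chrom[chrom]:
        lo, hi = max(start, r.start), min(end, r.end)
        if hi > lo:
            yield r, hi - lo


Edge = Tuple[GenomeRegion, GenomeRegion]


def aligned_bp_by_pair(
    regions_a: Sequence[GenomeRegion],
    regions_b: Sequence[GenomeRegion],
    alignment: Iterable[AlignmentBlock],
) -> Dict[Edge, float]:
    """Total aligned bp between every region pair touched by the alignment.

    Blocks spanning tile boundaries contribute proportionally to the overlap
    on each side, preserving total aligned length. Strand is ignored.
    """
    by_a, by_b = _region_lookup(regions_a), _region_lookup(regions_b)
    pair_bp: Dict[Edge, float] = defaultdict(float)
    for blk in alignment:
        span_a = blk.end_a - blk.start_a
        span_b = blk.end_b - blk.start_b
        for ra, ov_a in _overlap_split(by_a, blk.chrom_a, blk.start_a, blk.end_a, repr(blk)):
            for rb, ov_b in _overlap_split(by_b, blk.chrom_b, blk.start_b, blk.end_b, repr(blk)):
                frac = (ov_a / span_a) * (ov_b / span_b)
                pair_bp[(ra, rb)] += blk.aligned_len * frac
    return dict(pair_bp)


def build_homology_graph(
    regions_a: Sequence[GenomeRegion],
    regions_b: Sequence[GenomeRegion],
    alignment: Iterable[AlignmentBlock],
    min_aligned: int,
) -> Dict[GenomeRegion, Set[GenomeRegion]]:
    """Undirected bipartite adjacency; edge iff aligned bp strictly exceeds
    ``min_aligned`` summed over all blocks touching the region pair."""
    adj: Dict[GenomeRegion, Set[GenomeRegion]] = {r: set() for r in regions_a}
    adj.update({r: set() for r in regions_b})
    for (ra, rb), bp in aligned_bp_by_pair(regions_a, regions_b, alignment).items():
        if bp > min_aligned:
            adj[ra].add(rb)
            adj[rb].add(ra)
    return adj


def connected_components(adj: Dict[GenomeRegion, Set[GenomeRegion]]) -> List[List[GenomeRegion]]:
    """Breadth-first-search connected components, deterministic order."""
    seen: Set[GenomeRegion] = set()
    components: List[List[GenomeRegion]] = []
    order = sorted(adj, key=lambda r: (r.genome_id, r.chrom, r.start))
    for root in order:
        if root in seen:
            continue
        comp = [root]
        seen.add(root)
        queue = [root]
        while queue:
            node = queue.pop(0)
            for nb in sorted(adj[node], key=lambda r: (r.genome_id, r.chrom, r.start)):
                if nb not in seen:
                    seen.add(nb)
                    comp.append(nb)
                    queue.append(nb)
        components.append(comp)
    return components


class MonolithicComponentError(RuntimeError):
    pass


def partition_components(
    adj: Dict[GenomeRegion, Set[GenomeRegion]],
    config: SplitConfig,
) -> Dict[GenomeRegion, str]:
    """Assign every connected component to train/valid/test.

    Greedy: components sorted by total nucleotides descending are assigned to
    the split whose current per-genome fraction is furthest below its target,
    ties broken by seeded RNG. Fractions are accounted in nucleotides per
    genome.
    """
    comps = connected_components(adj)
    genome_total: Dict[str, float] = defaultdict(float)
    for r in adj:
        genome_total[r.genome_id] += r.size
    genomes = sorted(genome_total)
    targets = {"train": 1 - config.valid_frac - config.test_frac,
               "valid": config.valid_frac, "test": config.test_frac}

    def comp_sizes(comp):
        sizes = defaultdict(float)
        for r in comp:
            sizes[r.genome_id] += r.size
        return sizes

    limit = targets["train"]
    for comp in comps:
        sizes = comp_sizes(comp)
        for g in genomes:
            if sizes.get(g, 0) > limit * genome_total[g]:
                raise MonolithicComponentError(
                    f"a single connected component holds {sizes[g] / genome_total[g]:.1%} "
                    f"of genome {g}, more than the {limit:.0%} train target; "
                    "relax tile_size or min_aligned to break it up"
                )

    rng = np.random.default_rng(config.seed)
    assigned: Dict[str, Dict[str, float]] = {s: defaultdict(float) for s in SPLITS}
    assignment: Dict[GenomeRegion, str] = {}
    order = sorted(range(len(comps)),
                   key=lambda i: (-sum(comp_sizes(comps[i]).values()), i))
    for i in order:
        comp = comps[i]
        sizes = comp_sizes(comp)
        # deficit of each split, averaged over the genomes this component touches
        deficits = {}
        for s in SPLITS:
            d = 0.0
            for g in sizes:
                current = assigned[s][g] / genome_total[g]
                d += targets[s] - current
            deficits[s] = d / max(len(sizes), 1)
        best = max(deficits.values())
        candidates = [s for s in SPLITS if deficits[s] >= best - 1e-12]
        choice = candidates[int(rng.integers(0, len(candidates)))]
        for r in comp:
            assignment[r] = choice
            assigned[choice][r.genome_id] += r.size
    return assignment


@dataclass
class LeakageReport:
    cross_split_bp: Dict[Tuple[str, str], float] = field(default_factory=dict)
    holdout_with_train_ortholog_frac: Dict[str, float] = field(default_factory=dict)

    @property
    def total_crossing_bp(self) -> float:
        return sum(v for (s1, s2), v in self.cross_split_bp.items() if s1 != s2)


def audit_leakage(
    assignment: Dict[GenomeRegion, str],
    alignment: Iterable[AlignmentBlock],
) -> LeakageReport:
    """Exact cross-split aligned bp, with edges defined at threshold zero."""
    regions_a = [r for r in assignment if r.genome_id == "A"]
    regions_b = [r for r in assignment if r.genome_id == "B"]
    pair_bp = aligned_bp_by_pair(regions_a, regions_b, alignment)
    report = LeakageReport()
    cross: Dict[Tuple[str, str], float] = defaultdict(float)
    leaky_bp: Dict[str, float] = defaultdict(float)
    holdout_bp: Dict[str, float] = defaultdict(float)
    for r in assignment:
        if assignment[r] in ("valid", "test"):
            holdout_bp[assignment[r]] += r.size
    for (ra, rb), bp in pair_bp.items():
        sa, sb = assignment[ra], assignment[rb]
        cross[tuple(sorted((sa, sb)))] += bp
        for r, s_other in ((ra, sb), (rb, sa)):
            if assignment[r] in ("valid", "test") and s_other == "train":
                leaky_bp[assignment[r]] += bp
    report.cross_split_bp = dict(cross)
    report.holdout_with_train_ortholog_frac = {
        s: (leaky_bp[s] / holdout_bp[s] if holdout_bp[s] else 0.0) for s in ("valid", "test")
    }
    return report


def split_fractions(assignment: Dict[GenomeRegion, str]) -> Dict[str, Dict[str, float]]:
    """Per-genome nucleotide fraction of each split."""
    totals: Dict[str, float] = defaultdict(float)
    by_split: Dict[str, Dict[str, float]] = defaultdict(lambda: defaultdict(float))
    for r, s in assignment.items():
        totals[r.genome_id] += r.size
        by_split[r.genome_id][s] += r.size
    return {g: {s: by_split[g][s] / totals[g] for s in SPLITS} for g in totals}


def assignment_to_bed(assignment: Dict[GenomeRegion, str], genome_id: str) -> List[Tuple]:
    recs = [(r.chrom, r.start, r.end, s) for r, s in assignment.items()
            if r.genome_id == genome_id]
    return sorted(recs)
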