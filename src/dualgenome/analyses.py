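"""Downstream statistics on variant score tables: matched-negative
construction, cross-validated classification, eQTL effect summarization, and
case/control de novo variant tests."""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold
from statsmodels.stats.multitest import multipletests

from .io import fetch_sequence
from .variants import Variant


@dataclass
class NegMatchConfig:
    target_offset: int = 1000
    splice_exclusion: int = 20
    cluster_radius: int = 10
    search_cap: int = 200  # max bp scanned around each anchor for a ref match
    seed: int = 0

    def __post_init__(self):
        for name in ("target_offset", "splice_exclusion", "cluster_radius", "search_cap"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class ClassifierConfig:
    folds: int = 8
    iterations: int = 200
    max_features: str = "log2"
    n_estimators: int = 100
    seed: int = 0

    def __post_init__(self):
        if self.folds < 2 or self.iterations < 1:
            raise ValueError("folds >= 2 and iterations >= 1 required")


@dataclass
class DeNovoConfig:
    tss_max_distance: int = 50_000
    negative_weight: float = 10.0
    fdr_level: float = 0.05
    log_pseudocount: float = 1.0

    def __post_init__(self):
        if self.negative_weight < 1:
            raise ValueError("negative_weight must be >= 1")
        if not 0 < self.fdr_level < 1:
            raise ValueError("fdr_level must be in (0, 1)")


# ---------------------------------------------------------------------------
# Pathogenic-set filtering and matched negatives


def _distance_to_intervals(pos0: int, intervals: List[Tuple[int, int]]) -> int:
    best = np.inf
    for s, e in intervals:
        if s <= pos0 < e:
            return 0
        best = min(best, s - pos0 if pos0 < s else pos0 - (e - 1))
    return int(best) if np.isfinite(best) else int(1e18)


def filter_pathogenic_set(
    variants: Sequence[Variant],
    splice_sites: Sequence[Tuple[str, int, int, str]],
    config: NegMatchConfig,
) -> List[Variant]:
    """Drop variants near splice sites, then thin genomic clusters.

    Clustering is transitive: variants chained by gaps <= cluster_radius form
    one group; a seeded-random representative is kept per group.
    """
    sites: Dict[str, List[Tuple[int, int]]] = {}
    for chrom, start, end, *_ in splice_sites:
        sites.setdefault(chrom, []).append((start, end))
    kept = [v for v in variants
            if _distance_to_intervals(v.start, sites.get(v.chrom, []))
            > config.splice_exclusion]

    rng = np.random.default_rng(config.seed)
    out: List[Variant] = []
    by_chrom: Dict[str, List[Variant]] = {}
    for v in kept:
        by_chrom.setdefault(v.chrom, []).append(v)
    for chrom in sorted(by_chrom):
        vs = sorted(by_chrom[chrom], key=lambda v: v.pos)
        group: List[Variant] = []
        for v in vs:
            if group and v.pos - group[-1].pos <= config.cluster_radius:
                group.append(v)
            else:
                if group:
                    out.append(group[int(rng.integers(0, len(group)))])
                group = [v]
        if group:
            out.append(group[int(rng.integers(0, len(group)))])
    return out


def build_matched_negatives(
    pathogenic: Sequence[Variant],
    genome,
    config: NegMatchConfig,
) -> List[Variant]:
    """One negative per pathogenic variant with identical ref and alt.

    For each anchor (position +- target_offset), the nearest reference base
    matching the variant's ref is located (within search_cap bp); the
    candidate whose distance is closest to target_offset wins, ties broken by
    seeded RNG. Variants with no match within the cap are skipped.
    """
    rng = np.random.default_rng(config.seed)
    negatives: List[Variant] = []
    for v in pathogenic:
        contig_len = len(genome[v.chrom])
        candidates = []
        for sign in (-1, 1):
            anchor = v.start + sign * config.target_offset
            lo = max(0, anchor - config.search_cap)
            hi = min(contig_len, anchor + config.search_cap + 1)
            if hi <= lo:
                continue
            window = fetch_sequence(genome, v.chrom, lo, hi).upper()
            hits = [lo + i for i, b in enumerate(window) if b == v.ref]
            if not hits:
                continue
            best = min(hits, key=lambda p: (abs(p - anchor), p))
            candidates.append(best)
        if not candidates:
            warnings.warn(f"no matching base near {v.id} within the search cap; skipped")
            continue
        errors = [abs(abs(p - v.start) - config.target_offset) for p in candidates]
        best_err = min(errors)
        best_cands = [p for p, e in zip(candidates, errors) if e == best_err]
        pos0 = best_cands[int(rng.integers(0, len(best_cands)))]
        negatives.append(Variant(chrom=v.chrom, pos=pos0 + 1, ref=v.ref,
                                 alt=v.alt, id=f"neg_{v.id}"))
    return negatives


# ---------------------------------------------------------------------------
# Cross-validated classification


@dataclass
class CvResult:
    aurocs: np.ndarray  # one AUROC per iteration
    roc_points: pd.DataFrame  # pooled out-of-fold ROC of the final iteration
    final_model: RandomForestClassifier


def classify_with_cv(
    features: np.ndarray,
    labels: np.ndarray,
    config: ClassifierConfig,
) -> CvResult:
    """Repeated stratified k-fold CV with random forests.

    Each iteration reshuffles the folds, pools out-of-fold probabilities, and
    yields one AUROC; the returned distribution supports Mann-Whitney U
    comparisons between feature sets.
    """
    features = np.asarray(features)
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("labels contain a single class")
    aurocs = []
    fpr = tpr = None
    for it in range(config.iterations):
        skf = StratifiedKFold(n_splits=config.folds, shuffle=True,
                              random_state=config.seed + it)
        oof = np.zeros(len(labels))
        seen = np.zeros(len(labels), dtype=bool)
        for fold, (tr, te) in enumerate(skf.split(features, labels)):
            assert not seen[te].any(), "variant appears in two test folds"
            seen[te] = True
            rf = RandomForestClassifier(
                n_estimators=config.n_estimators,
                max_features=config.max_features,
                random_state=config.seed * 10_000 + it * 100 + fold,
            )
            rf.fit(features[tr], labels[tr])
            oof[te] = rf.predict_proba(features[te])[:, 1]
        assert seen.all(), "some variant missing from test folds"
        aurocs.append(roc_auc_score(labels, oof))
        if it == config.iterations - 1:
            fpr, tpr, _ = roc_curve(labels, oof)
    final = RandomForestClassifier(
        n_estimators=config.n_estimators, max_features=config.max_features,
        random_state=config.seed,
    ).fit(features, labels)
    return CvResult(
        aurocs=np.array(aurocs),
        roc_points=pd.DataFrame({"fpr": fpr, "tpr": tpr}),
        final_model=final,
    )


def compare_cv_results(a: CvResult, b: CvResult) -> Tuple[float, float]:
    """Two-sided Mann-Whitney U over iteration AUROC distributions."""
    u, p = stats.mannwhitneyu(a.aurocs, b.aurocs, alternative="two-sided")
    return float(u), float(p)


# ---------------------------------------------------------------------------
# eQTL summarization


def summarize_eqtl_effects(per_gene_correlations: Sequence[float]) -> float:
    """Mean marginal correlation over the variant's cis-gene set; NaN when
    the gene set is empty (excluded downstream)."""
    vals = np.asarray(list(per_gene_correlations), dtype=float)
    if vals.size == 0:
        return float("nan")
    return float(vals.mean())


# ---------------------------------------------------------------------------
# De novo proband/sibling statistics


def weight_scores(scores: np.ndarray, w: float) -> np.ndarray:
    """Nonnegative scores pass through; negative scores become w * |s|."""
    if w < 1:
        raise ValueError("weight must be >= 1")
    scores = np.asarray(scores, dtype=float)
    return np.where(scores >= 0, scores, w * np.abs(scores))


def filter_by_tss_distance(
    variants: Sequence[Variant],
    tss: Sequence[Tuple[str, int, int, str]],
    max_distance: int,
) -> List[Variant]:
    by_chrom: Dict[str, np.ndarray] = {}
    for chrom, start, _end, *_ in tss:
        by_chrom.setdefault(chrom, []).append(start)
    by_chrom = {c: np.sort(np.asarray(p)) for c, p in by_chrom.items()}
    out = []
    for v in variants:
        pos = by_chrom.get(v.chrom)
        if pos is None or pos.size == 0:
            continue
        i = np.searchsorted(pos, v.start)
        d = min(
            abs(v.start - pos[max(i - 1, 0)]),
            abs(v.start - pos[min(i, pos.size - 1)]),
        )
        if d <= max_distance:
            out.append(v)
    return out


def _mwu(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided MWU p: exact enumeration for small tie-free samples, normal
    approximation with tie correction otherwise."""
    exact_ok = (len(x) <= 50 and len(y) <= 50
                and len(np.unique(np.concatenate([x, y]))) == len(x) + len(y))
    method = "exact" if exact_ok else "asymptotic"
    return float(stats.mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue)


def proband_sibling_tests(
    proband_scores: pd.DataFrame,
    sibling_scores: pd.DataFrame,
    config: DeNovoConfig,
) -> pd.DataFrame:
    """Per-dataset proband-vs-sibling comparison of weighted variant scores.

    Inputs are variants x datasets tables of raw signed scores (already
    filtered to within tss_max_distance of a TSS). Returns per dataset the
    effect (mean ln(score + pseudocount) difference, proband - sibling), the
    two-sided MWU p-value, and the Benjamini-Hochberg q across datasets.
    """
    datasets = [d for d in proband_scores.columns if d in sibling_scores.columns]
    rows = []
    for d in datasets:
        p = weight_scores(proband_scores[d].to_numpy(), config.negative_weight)
        s = weight_scores(sibling_scores[d].to_numpy(), config.negative_weight)
        if len(p) == 0 or len(s) == 0:
            continue
        effect = float(np.mean(np.log(p + config.log_pseudocount))
                       - np.mean(np.log(s + config.log_pseudocount)))
        rows.append({"dataset": d, "effect": effect, "p_value": _mwu(p, s)})
    table = pd.DataFrame(rows)
    if len(table):
        table["q_value"] = multipletests(table["p_value"], method="fdr_bh")[1]
        table["significant"] = table["q_value"] < config.fdr_level
    return table


@dataclass
class RiskScoreResult:
    individual_sums: pd.DataFrame  # family, proband_sum, sibling_sum
    successes: int
    informative_families: int
    proband_fraction: float
    p_value: float


def individual_risk_score(
    family_scores: pd.DataFrame,
    config: Optional[DeNovoConfig] = None,
) -> RiskScoreResult:
    """Per-individual weighted score sums and an exact binomial test.

    ``family_scores`` has columns (family, role, score) with one row per
    variant; role is 'proband' or 'sibling'. A family counts as a success
    when the proband's sum exceeds the sibling's; tied families are excluded
    from the two-sided exact binomial test (null probability 0.5).
    """
    config = config or DeNovoConfig()
    rows = []
    for fam, grp in family_scores.groupby("family"):
        roles = set(grp["role"])
        if roles != {"proband", "sibling"}:
            warnings.warn(f"family {fam!r} missing a member; excluded")
            continue
        sums = {
            role: float(weight_scores(sub["score"].to_numpy(),
                                      config.negative_weight).sum())
            for role, sub in grp.groupby("role")
        }
        rows.append({"family": fam, "proband_sum": sums["proband"],
                     "sibling_sum": sums["sibling"]})
    table = pd.DataFrame(rows)
    diffs = table["proband_sum"] - table["sibling_sum"]
    informative = int((diffs != 0).sum())
    successes = int((diffs > 0).sum())
    if informative == 0:
        p = 1.0
        frac = float("nan")
    else:
        p = float(stats.binomtest(successes, informative, 0.5,
                                  alternative="two-sided").pvalue)
        frac = successes / informative
    return RiskScoreResult(table, successes, informative, frac, p)
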