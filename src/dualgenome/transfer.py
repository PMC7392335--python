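"""Cross-species prediction evaluation.

Pipeline (order fixed and logged): quantile normalize columns -> optional
log1p transform -> top-variable row selection -> optional per-group row mean
centering -> Pearson correlation per sample pair.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd
from scipy.stats import rankdata

PIPELINE = ("quantile_normalize", "log1p", "select_top_variable",
            "mean_center_rows", "pearson")


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Force every column onto the per-rank mean distribution.

    Ties take the mean rank (fractional ranks interpolate between adjacent
    reference values), so within-column order is preserved.
    """
    if matrix.shape[1] < 2:
        raise ValueError("quantile normalization needs >= 2 columns")
    values = matrix.to_numpy(dtype=float)
    n = values.shape[0]
    reference = np.sort(values, axis=0).mean(axis=1)
    out = np.empty_like(values)
    ranks_axis = np.arange(1, n + 1)
    for j in range(values.shape[1]):
        r = rankdata(values[:, j], method="average")
        out[:, j] = np.interp(r, ranks_axis, reference)
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def mean_center_rows(matrix: pd.DataFrame) -> pd.DataFrame:
    """Subtract each row's cross-sample mean; rows then sum to zero."""
    return matrix.sub(matrix.mean(axis=1), axis=0)


def select_top_variable(matrix: pd.DataFrame, fraction: float) -> pd.DataFrame:
    """Keep the top ``fraction`` of rows by cross-sample variance.

    Deterministic: ties and ordering resolved by row label.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    variances = matrix.var(axis=1, ddof=1)
    order = sorted(matrix.index, key=lambda i: (-variances[i], str(i)))
    k = max(1, int(round(fraction * len(order))))
    keep = sorted(order[:k], key=lambda i: list(matrix.index).index(i))
    return matrix.loc[keep]


@dataclass
class TransferResult:
    correlations: pd.DataFrame  # observed samples x predicted samples
    matched: Dict[str, str]
    pipeline: Tuple[str, ...] = PIPELINE

    def matched_correlations(self) -> Dict[str, float]:
        return {o: float(self.correlations.loc[o, p]) for o, p in self.matched.items()}

    def specificity(self) -> Dict[str, bool]:
        """Per observed sample: does the matched predicted sample beat every
        mismatched one?"""
        out = {}
        for o, p in self.matched.items():
            row = self.correlations.loc[o]
            out[o] = bool(row[p] > row.drop(p).max())
        return out


def cross_species_correlation(
    observed: pd.DataFrame,
    predicted: pd.DataFrame,
    sample_pairs: Dict[str, str],
    log_transform: bool = False,
    top_fraction: float = 1.0,
    mean_center: bool = True,
) -> TransferResult:
    """Correlate observed vs predicted activity over a shared row universe.

    ``sample_pairs`` maps each observed column to its matched predicted
    column. Mean centering is applied separately within the observed and
    predicted column groups (each row normalized by its mean across that
    group's samples).
    """
    shared = observed.index.intersection(predicted.index)
    if len(shared) < 3:
        raise ValueError(f"only {len(shared)} shared rows; need >= 3")
    obs = observed.loc[shared].add_prefix("obs:")
    pred = predicted.loc[shared].add_prefix("pred:")
    combined = pd.concat([obs, pred], axis=1)
    combined = quantile_normalize(combined)
    if log_transform:
        combined = np.log1p(combined)
    combined = select_top_variable(combined, top_fraction)
    if mean_center:
        obs_cols = [c for c in combined.columns if c.startswith("obs:")]
        pred_cols = [c for c in combined.columns if c.startswith("pred:")]
        combined[obs_cols] = mean_center_rows(combined[obs_cols])
        combined[pred_cols] = mean_center_rows(combined[pred_cols])
    corr = pd.DataFrame(
        np.corrcoef(combined.to_numpy(dtype=float), rowvar=False),
        index=combined.columns, columns=combined.columns,
    )
    obs_names = list(observed.columns)
    pred_names = list(predicted.columns)
    result = corr.loc[[f"obs:{o}" for o in obs_names],
                      [f"pred:{p}" for p in pred_names]]
    result.index = obs_names
    result.columns = pred_names
    return TransferResult(correlations=result, matched=dict(sample_pairs))


def saliency_scores(model, onehot: np.ndarray, genome_id: str,
                    task: Optional[int] = None) -> np.ndarray:
    """Per-window saliency of the prediction sum (see Model.saliency)."""
    return model.saliency(onehot, genome_id, task=task)
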