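"""Joint two-genome optimization with augmentation and early stopping.

An epoch is one pass over the union of both genomes' example lists; batches
are homogeneous in genome and their order is a seeded proportional shuffle.
Validation loss for early stopping is the per-genome loss mixed by sampling
proportion. Augmentation cycles deterministically over reverse-complement x
shift combinations with a seeded per-example phase offset.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterator, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .model import Model
from .nn import SGD
from .prep import TrainingExample, reverse_complement_onehot


@dataclass
class TrainConfig:
    batch_size: int = 4
    lr: float = 0.005
    momentum: float = 0.99
    joint_patience: int = 30
    finetune_patience: int = 10
    crop_keep: Optional[int] = None  # default round(7/8 * n_bins)
    shift_max: int = 3
    rc_augment: bool = True
    clip_norm: Optional[float] = 2.0  # global gradient-norm clip; None disables
    seed: int = 0
    max_epochs: int = 10_000

    def __post_init__(self):
        if self.shift_max < 0:
            raise ValueError("shift_max must be >= 0")

    def resolve_crop(self, n_bins: int) -> int:
        keep = self.crop_keep if self.crop_keep is not None \
            else int(round(n_bins * 7 / 8))
        if not 0 < keep <= n_bins:
            raise ValueError(f"crop_keep {keep} outside (0, {n_bins}]")
        if (n_bins - keep) % 2:
            raise ValueError(f"n_bins - crop_keep = {n_bins - keep} must be even")
        return keep


def poisson_loss(pred: np.ndarray, target: np.ndarray) -> float:
    """Mean over elements of pred - target * ln(pred)."""
    pred = np.asarray(pred, dtype=np.float64)
    target = np.asarray(target, dtype=np.float64)
    if pred.shape != target.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {target.shape}")
    if np.any(pred <= 0):
        raise ValueError("predictions must be strictly positive for Poisson loss")
    return float(np.mean(pred - target * np.log(pred)))


def poisson_loss_grad(pred: np.ndarray, target: np.ndarray) -> np.ndarray:
    return ((1.0 - target / pred) / pred.size).astype(np.float32)


def crop_center(x: np.ndarray, keep: int) -> np.ndarray:
    """Symmetrically drop bins from both ends of the bin axis (axis 0 for 2-D
    (n_bins, tasks) input, axis 1 for batched 3-D input)."""
    axis = 0 if x.ndim == 2 else 1
    n = x.shape[axis]
    if keep == n:
        return x
    drop = n - keep
    if drop < 0 or drop % 2:
        raise ValueError(f"cannot crop {n} bins to {keep}: remainder must be even and >= 0")
    lo = drop // 2
    sl = [slice(None)] * x.ndim
    sl[axis] = slice(lo, lo + keep)
    return x[tuple(sl)]


def augment_example(
    example: TrainingExample,
    rc: bool,
    shift: int,
    genome=None,
) -> TrainingExample:
    """Reverse-complement and/or shift one example.

    rc reverse-complements the sequence and reverses the target bin order.
    shift moves the sequence window by ``shift`` bp (positive = rightward)
    while targets stay fixed. True flanking sequence is fetched when a genome
    is supplied; otherwise vacated edge columns are filled with the uniform
    0.25 encoding.
    """
    seq = example.sequence
    if shift:
        from .io import fetch_sequence
        from .prep import encode_sequence

        L = seq.shape[1]
        if genome is not None:
            new_start = example.start + shift
            new_end = example.end + shift
            contig_len = len(genome[example.chrom])
            if new_start < 0 or new_end > contig_len:
                raise ValueError(
                    f"shift {shift} moves window off contig {example.chrom}")
            seq = encode_sequence(
                fetch_sequence(genome, example.chrom, new_start, new_end))
        else:
            out = np.full_like(seq, 0.25)
            if shift > 0:
                out[:, : L - shift] = seq[:, shift:]
            else:
                out[:, -shift:] = seq[:, : L + shift]
            seq = out
    targets = example.targets
    if rc:
        seq = reverse_complement_onehot(seq)
        targets = targets[::-1].copy()
    return TrainingExample(seq, targets, example.genome_id, example.split,
                           example.chrom, example.start, example.end)


def augmentation_cycle(shift_max: int, rc_augment: bool) -> List[Tuple[bool, int]]:
    shifts = list(range(-shift_max, shift_max + 1))
    rcs = [False, True] if rc_augment else [False]
    return [(rc, s) for rc in rcs for s in shifts]


def sample_genome_batches(counts: Dict[str, int], seed: int) -> Iterator[str]:
    """Infinite stream of per-batch genome choices, proportional to counts."""
    genomes = sorted(g for g, c in counts.items() if c > 0)
    if not genomes:
        raise ValueError("all genome example counts are zero")
    if any(c < 0 for c in counts.values()):
        raise ValueError("negative example count")
    probs = np.array([counts[g] for g in genomes], dtype=float)
    probs /= probs.sum()
    rng = np.random.default_rng(seed)
    while True:
        yield genomes[int(rng.choice(len(genomes), p=probs))]


@dataclass
class TrainHistory:
    records: List[dict] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.records)

    def log(self, **kwargs):
        self.records.append(kwargs)


def _batches(indices: np.ndarray, batch_size: int) -> List[np.ndarray]:
    return [indices[i : i + batch_size] for i in range(0, len(indices), batch_size)]


def _stack_batch(examples: Sequence[TrainingExample], idx: np.ndarray,
                 combos, phases, epoch: int, genomes=None):
    seqs, tgts = [], []
    for i in idx:
        rc, shift = combos[(epoch + phases[i]) % len(combos)]
        ex = examples[i]
        g = genomes.get(ex.genome_id) if genomes else None
        try:
            aug = augment_example(ex, rc, shift, genome=g)
        except ValueError:  # window at contig edge: fall back to uniform fill
            aug = augment_example(ex, rc, shift, genome=None)
        seqs.append(aug.sequence)
        tgts.append(aug.targets)
    return np.stack(seqs), np.stack(tgts)


def _validation_loss(model: Model, valid: Dict[str, List[TrainingExample]],
                     weights: Dict[str, float], keep: int,
                     batch_size: int) -> Tuple[float, Dict[str, float]]:
    per_genome: Dict[str, float] = {}
    for g, examples in valid.items():
        losses = []
        sizes = []
        for lo in range(0, len(examples), batch_size):
            chunk = examples[lo : lo + batch_size]
            x = np.stack([e.sequence for e in chunk])
            t = np.stack([e.targets for e in chunk])
            pred = model.forward(x, g, train=False)
            losses.append(poisson_loss(crop_center(pred, keep), crop_center(t, keep)))
            sizes.append(len(chunk))
        per_genome[g] = float(np.average(losses, weights=sizes))
    mixed = sum(weights[g] * per_genome[g] for g in per_genome)
    return mixed, per_genome


def train(
    model: Model,
    train_examples: Dict[str, List[TrainingExample]],
    valid_examples: Dict[str, List[TrainingExample]],
    config: TrainConfig,
    genomes: Optional[Dict[str, object]] = None,
    optimizer: Optional[SGD] = None,
    patience: Optional[int] = None,
) -> TrainHistory:
    """Train until validation loss stalls for ``patience`` epochs, then
    restore the weights that achieved the minimum validation loss."""
    train_examples = {g: v for g, v in train_examples.items() if v}
    if not train_examples:
        raise ValueError("no training examples")
    patience = config.joint_patience if patience is None else patience
    optimizer = optimizer or SGD(lr=config.lr, momentum=config.momentum)
    rng = np.random.default_rng(config.seed)
    keep = config.resolve_crop(model.config.n_bins)
    combos = augmentation_cycle(config.shift_max, config.rc_augment)
    phases = {g: rng.integers(0, len(combos), size=len(exs))
              for g, exs in train_examples.items()}
    n_total = sum(len(v) for v in train_examples.values())
    mix_weights = {g: len(v) / n_total for g, v in train_examples.items()}

    history = TrainHistory()
    best_loss = np.inf
    best_weights = model.get_weights()
    best_epoch = -1

    for epoch in range(config.max_epochs):
        batch_plan = []
        for g, exs in train_examples.items():
            order = rng.permutation(len(exs))
            batch_plan += [(g, b) for b in _batches(order, config.batch_size)]
        rng.shuffle(batch_plan)

        epoch_losses: Dict[str, List[float]] = {g: [] for g in train_examples}
        for g, idx in batch_plan:
            x, t = _stack_batch(train_examples[g], idx, combos, phases[g],
                                epoch, genomes)
            pred = model.forward(x, g, train=True)
            pred_c, t_c = crop_center(pred, keep), crop_center(t, keep)
            loss = poisson_loss(pred_c, t_c)
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"divergent loss at epoch {epoch}, genome {g}: {loss}; "
                    "reduce the learning rate")
            dy = np.zeros_like(pred)
            drop = model.config.n_bins - keep
            dy[:, drop // 2 : drop // 2 + keep, :] = poisson_loss_grad(pred_c, t_c)
            model.zero_grad()
            model.backward(dy, g)
            step_params = model.step_params(g)
            if config.clip_norm is not None:
                total = np.sqrt(sum(float((gr * gr).sum()) for _n, _p, gr in step_params))
                if total > config.clip_norm:
                    scale = config.clip_norm / total
                    for _n, _p, gr in step_params:
                        gr *= scale
            optimizer.step(step_params)
            epoch_losses[g].append(loss)

        val_mixed, val_per_genome = _validation_loss(
            model, valid_examples, mix_weights, keep, config.batch_size)
        for g in train_examples:
            history.log(epoch=epoch, split="train", genome=g,
                        loss=float(np.mean(epoch_losses[g])))
        for g, vl in val_per_genome.items():
            history.log(epoch=epoch, split="valid", genome=g, loss=vl)
        history.log(epoch=epoch, split="valid", genome="mixed", loss=val_mixed)

        if val_mixed < best_loss - 1e-9:
            best_loss = val_mixed
            best_weights = model.get_weights()
            best_epoch = epoch
        elif epoch - best_epoch > patience:
            break

    model.set_weights(best_weights)
    history.log(epoch=best_epoch, split="best", genome="mixed", loss=best_loss)
    return history


def fine_tune(
    model: Model,
    genome_id: str,
    train_examples: Dict[str, List[TrainingExample]],
    valid_examples: Dict[str, List[TrainingExample]],
    config: TrainConfig,
    genomes: Optional[Dict[str, object]] = None,
) -> TrainHistory:
    """Continue training on a single genome with the fine-tune patience;
    only the shared trunk and that genome's head are updated."""
    model._check_genome(genome_id)
    return train(
        model,
        {genome_id: train_examples[genome_id]},
        {genome_id: valid_examples[genome_id]},
        config,
        genomes=genomes,
        patience=config.finetune_patience,
    )


def pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, dtype=np.float64).ravel()
    b = np.asarray(b, dtype=np.float64).ravel()
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a * a).sum() * (b * b).sum())
    if denom == 0:
        return float("nan")
    return float((a * b).sum() / denom)


def evaluate(
    model: Model,
    test_examples: Sequence[TrainingExample],
    crop_keep: Optional[int] = None,
    batch_size: int = 4,
) -> Dict[str, np.ndarray]:
    """Per-dataset Pearson r over all cropped test bins, keyed by genome.

    Zero-variance datasets yield NaN (reported missing, not zero).
    """
    if not test_examples:
        raise ValueError("empty test set")
    keep = crop_keep if crop_keep is not None \
        else int(round(model.config.n_bins * 7 / 8))
    by_genome: Dict[str, List[TrainingExample]] = {}
    for e in test_examples:
        by_genome.setdefault(e.genome_id, []).append(e)
    out = {}
    for g, examples in by_genome.items():
        preds, tgts = [], []
        for lo in range(0, len(examples), batch_size):
            chunk = examples[lo : lo + batch_size]
            x = np.stack([e.sequence for e in chunk])
            pred = model.forward(x, g, train=False)
            preds.append(crop_center(pred, keep))
            tgts.append(crop_center(np.stack([e.targets for e in chunk]), keep))
        p = np.concatenate(preds).reshape(-1, preds[0].shape[-1])
        t = np.concatenate(tgts).reshape(-1, tgts[0].shape[-1])
        out[g] = np.array([pearson(p[:, j], t[:, j]) for j in range(p.shape[1])])
    return out
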