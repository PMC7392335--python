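"""The residual dilated convolutional sequence-to-signal architecture.

Three stages operating on (batch, 4, L) one-hot input:

1. Motif tower: repeated [conv -> batch norm -> GELU -> max pool 2] blocks
   (kernel 15 in the first block, 5 afterwards) with geometrically growing
   filter counts, until each position summarizes ``pool_width^tower_blocks``
   bp.
2. Dilated residual stack: repeated [GELU -> dilated conv w3 -> BN -> GELU ->
   conv w1 back to the trunk width -> BN -> dropout -> add input] blocks with
   geometrically growing dilation.
3. A width-1 convolution block, then one width-1 head per genome with a
   softplus activation so predictions are strictly positive. All parameters
   are shared across genomes except the head weights.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional

import h5py
import numpy as np

from . import nn


def filter_schedule(init: int, growth: float, n_blocks: int) -> List[int]:
    """Filter count per tower block: round(init * growth^(i-1))."""
    if init < 1 or growth < 1:
        raise ValueError("init >= 1 and growth >= 1 required")
    return [int(round(init * growth ** i)) for i in range(n_blocks)]


def dilation_schedule(growth: float, n_blocks: int) -> List[int]:
    """Dilation of block i: round(growth^(i-1)), floored at 1."""
    return [max(1, int(round(growth ** i))) for i in range(n_blocks)]


@dataclass
class ModelConfig:
    seq_len: int = 131_072
    tower_blocks: int = 7
    init_filters: int = 288
    filter_growth: float = 1.1776
    first_kernel: int = 15
    tower_kernel: int = 5
    pool_width: int = 2
    dilated_blocks: int = 11
    dilated_filters: int = 384
    residual_filters: int = 768
    dilation_growth: float = 1.5
    residual_dropout: float = 0.3
    final_filters: int = 1536
    final_dropout: float = 0.05
    heads: Dict[str, int] = field(default_factory=dict)
    activation: str = "gelu"
    head_activation: str = "softplus"
    bn_momentum: float = 0.99
    bn_eps: float = 1e-3
    seed: int = 0

    def __post_init__(self):
        if self.seq_len % self.pool_width ** self.tower_blocks:
            raise ValueError(
                f"seq_len {self.seq_len} not divisible by "
                f"pool_width^tower_blocks = {self.pool_width ** self.tower_blocks}"
            )
        for p in (self.residual_dropout, self.final_dropout):
            if not 0 <= p < 1:
                raise ValueError("dropout must be in [0, 1)")
        sched = filter_schedule(self.init_filters, self.filter_growth, self.tower_blocks)
        if sched[-1] != self.residual_filters:
            raise ValueError(
                f"tower ends at {sched[-1]} filters but residual_filters is "
                f"{self.residual_filters}; residual addition requires equality"
            )

    @property
    def bin_width(self) -> int:
        return self.pool_width ** self.tower_blocks

    @property
    def n_bins(self) -> int:
        return self.seq_len // self.bin_width

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, s: str) -> "ModelConfig":
        return cls(**json.loads(s))


def toy_config(seq_len: int = 16_384, tower_blocks: int = 4, dilated_blocks: int = 6,
               filters: int = 24, heads: Optional[Dict[str, int]] = None,
               seed: int = 0, **kwargs) -> ModelConfig:
    """A CPU-scale configuration preserving the architecture's shape laws."""
    return ModelConfig(
        seq_len=seq_len, tower_blocks=tower_blocks, init_filters=filters,
        filter_growth=1.0, dilated_blocks=dilated_blocks,
        dilated_filters=max(filters // 2, 4), residual_filters=filters,
        final_filters=filters * 2, heads=heads or {}, seed=seed, **kwargs,
    )


class Model:
    """Assembled network with per-genome heads and explicit backprop."""

    def __init__(self, config: ModelConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        self.dropout_rng = np.random.default_rng(config.seed + 1)
        c = config

        tower_layers: List[nn.Layer] = []
        in_ch = 4
        for i, out_ch in enumerate(
            filter_schedule(c.init_filters, c.filter_growth, c.tower_blocks)
        ):
            kernel = c.first_kernel if i == 0 else c.tower_kernel
            tower_layers += [
                nn.Conv1d(in_ch, out_ch, kernel, rng=rng),
                nn.BatchNorm1d(out_ch, momentum=c.bn_momentum, eps=c.bn_eps),
                nn.GELU(),
                nn.MaxPool1d(c.pool_width),
            ]
            in_ch = out_ch
        self.tower = nn.Sequential(tower_layers)

        core_layers: List[nn.Layer] = []
        for d in dilation_schedule(c.dilation_growth, c.dilated_blocks):
            body = nn.Sequential([
                nn.GELU(),
                nn.Conv1d(c.residual_filters, c.dilated_filters, 3, dilation=d, rng=rng),
                nn.BatchNorm1d(c.dilated_filters, momentum=c.bn_momentum, eps=c.bn_eps),
                nn.GELU(),
                nn.Conv1d(c.dilated_filters, c.residual_filters, 1, rng=rng),
                nn.BatchNorm1d(c.residual_filters, momentum=c.bn_momentum, eps=c.bn_eps),
                nn.Dropout(c.residual_dropout, self.dropout_rng),
            ])
            core_layers.append(nn.Residual(body))
        core_layers += [
            nn.Conv1d(c.residual_filters, c.final_filters, 1, rng=rng),
            nn.BatchNorm1d(c.final_filters, momentum=c.bn_momentum, eps=c.bn_eps),
            nn.GELU(),
            nn.Dropout(c.final_dropout, self.dropout_rng),
        ]
        self.core = nn.Sequential(core_layers)

        self.heads: Dict[str, nn.Sequential] = {}
        for genome_id, n_tasks in c.heads.items():
            self.heads[genome_id] = nn.Sequential([
                nn.Conv1d(c.final_filters, n_tasks, 1, rng=rng),
                nn.Softplus(),
            ])
        self._last_rep: Optional[np.ndarray] = None

    # -- shapes ------------------------------------------------------------

    @property
    def representation_length(self) -> int:
        return self.config.n_bins

    # -- forward / backward ------------------------------------------------

    def _check_genome(self, genome_id: str):
        if genome_id not in self.heads:
            raise KeyError(f"genome {genome_id!r} has no registered head "
                           f"(have {sorted(self.heads)})")

    def forward(self, x: np.ndarray, genome_id: str, train: bool = False) -> np.ndarray:
        """Predict (batch, n_bins, n_tasks) from one-hot (batch, 4, L)."""
        self._check_genome(genome_id)
        x = np.ascontiguousarray(x, dtype=nn.F32)
        if x.ndim == 2:
            x = x[None]
        if x.shape[1] != 4 or x.shape[2] != self.config.seq_len:
            raise ValueError(f"expected (batch, 4, {self.config.seq_len}), got {x.shape}")
        rep = self.tower.forward(x, train=train)
        self._last_rep = rep
        out = self.core.forward(rep, train=train)
        out = self.heads[genome_id].forward(out, train=train)
        return out.transpose(0, 2, 1)  # (B, n_bins, n_tasks)

    def backward(self, dy: np.ndarray, genome_id: str,
                 through_tower: bool = True) -> Optional[np.ndarray]:
        """Backpropagate d(loss)/d(predictions); returns d(loss)/d(rep) when
        stopping at the tower output, else d(loss)/d(input)."""
        d = self.heads[genome_id].backward(dy.transpose(0, 2, 1))
        d = self.core.backward(d)
        if not through_tower:
            return d
        return self.tower.backward(d)

    def predict(self, x: np.ndarray, genome_id: str) -> np.ndarray:
        return self.forward(x, genome_id, train=False)

    # -- parameters --------------------------------------------------------

    def trunk_params(self):
        return ([(f"tower.{n}", p, g) for n, p, g in nn.collect_params(self.tower)]
                + [(f"core.{n}", p, g) for n, p, g in nn.collect_params(self.core)])

    def head_params(self, genome_id: str):
        self._check_genome(genome_id)
        return nn.collect_params(self.heads[genome_id])

    def step_params(self, genome_id: str):
        """Parameters a batch from ``genome_id`` updates: shared trunk plus
        that genome's head only."""
        return self.trunk_params() + self.head_params(genome_id)

    def all_params(self):
        out = self.trunk_params()
        for g in sorted(self.heads):
            out += self.head_params(g)
        return out

    def zero_grad(self):
        for _n, _p, g in self.all_params():
            g[...] = 0.0

    def get_weights(self) -> List[np.ndarray]:
        return [p.copy() for _n, p, _g in self.all_params()] + \
               [b.copy() for _n, b in self._all_state()]

    def set_weights(self, weights: List[np.ndarray]):
        params = self.all_params()
        state = self._all_state()
        assert len(weights) == len(params) + len(state)
        for (_n, p, _g), w in zip(params, weights[: len(params)]):
            p[...] = w
        for (_n, b), w in zip(state, weights[len(params):]):
            b[...] = w

    def _all_state(self):
        out = ([(f"tower.{n}", b) for n, b in nn.collect_state(self.tower)]
               + [(f"core.{n}", b) for n, b in nn.collect_state(self.core)])
        for g in sorted(self.heads):
            out += [(f"head_{g}.{n}", b) for n, b in nn.collect_state(self.heads[g])]
        return out

    # -- saliency ----------------------------------------------------------

    def saliency(self, x: np.ndarray, genome_id: str,
                 task: Optional[int] = None) -> np.ndarray:
        """Per-window saliency: inner product of the prediction-sum gradient
        with each window's post-tower representation vector.

        Returns (batch, n_bins). Positive values mark windows whose
        representation locally increases the summed prediction (enhancing),
        negative values repressing.
        """
        out = self.forward(x, genome_id, train=False)
        dy = np.zeros_like(out)
        if task is None:
            dy[...] = 1.0
        else:
            dy[:, :, task] = 1.0
        grad_rep = self.backward(dy, genome_id, through_tower=False)
        return (grad_rep * self._last_rep).sum(axis=1)

    # -- checkpoints -------------------------------------------------------

    def save(self, path: str):
        with h5py.File(path, "w") as f:
            f.attrs["config"] = self.config.to_json()
            grp = f.create_group("trunk")
            for name, p, _g in self.trunk_params():
                grp.create_dataset(name, data=p)
            for g in sorted(self.heads):
                hg = f.create_group(f"head_{g}")
                for name, p, _g2 in self.head_params(g):
                    hg.create_dataset(name, data=p)
            sg = f.create_group("state")
            for name, b in self._all_state():
                sg.create_dataset(name, data=b)

    @classmethod
    def load(cls, path: str) -> "Model":
        with h5py.File(path, "r") as f:
            config = ModelConfig.from_json(f.attrs["config"])
            model = cls(config)
            for name, p, _g in model.trunk_params():
                p[...] = f["trunk"][name][...]
            for g in sorted(model.heads):
                for name, p, _g2 in model.head_params(g):
                    p[...] = f[f"head_{g}"][name][...]
            for name, b in model._all_state():
                b[...] = f["state"][name][...]
        return model


def build_model(config: ModelConfig) -> Model:
    return Model(config)
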