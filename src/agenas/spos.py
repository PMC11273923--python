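"""Single-path one-shot supernet search over 16 three-candidate choice layers.

The supernet stacks 16 choice layers between a strided stem convolution
and a (pointwise conv + global pool + fully connected) classifier head.
Each choice layer holds three independently parameterized candidate
blocks sharing input/output widths, stride and expand ratio:

    0: inverted residual, depthwise 3x3
    1: inverted residual, depthwise 5x5
    2: parallel asymmetric convolution (depthwise 1x7 / 7x1 halves)

Training samples one uniformly random path per mini-batch and updates
only that path's parameters (plus the shared stem/head); the discrete
search stage is an evolutionary search over 16-way choice vectors under
a MAC budget, ranked by validation mean absolute error.

The packaged AGE-SPOS stage plan (widths, strides, expands, head) is the
package's own reconstruction, calibrated so that the analytic counter
reproduces the published complexity of the searched network at width
multipliers 0.5 / 1.0 / 1.5; the original per-layer block order is not
recoverable from the published description beyond the fact that 8 of the
16 blocks are parallel-asymmetric, which the packaged path satisfies.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field, asdict

import numpy as np

from . import nn
from .archs import round_channels
from .complexity import count_network
from .ops_zoo import BlockSpec, make_block

__all__ = [
    "PathCode",
    "SupernetPlan",
    "EvoConfig",
    "InfeasibleBudgetError",
    "AGE_SPOS_PATH",
    "age_spos_plan",
    "build_age_spos",
    "build_supernet",
    "build_path_network",
    "sample_path",
    "SupernetTrainConfig",
    "train_supernet",
    "evolutionary_search",
]

#: candidate index -> (block kind, depthwise tap count)
CANDIDATES = (("mbconv", 3), ("mbconv", 5), ("parallel_asym", 7))


@dataclass(frozen=True)
class PathCode:
    """A length-16 choice vector; entries 0 (MB3), 1 (MB5), 2 (parallel asym)."""

    choices: tuple[int, ...]

    def __post_init__(self):
        if len(self.choices) == 0:
            raise ValueError("PathCode needs at least one choice")
        if any(c not in (0, 1, 2) for c in self.choices):
            raise ValueError("PathCode entries must be in {0, 1, 2}")

    def num_parallel_asym(self) -> int:
        return sum(1 for c in self.choices if c == 2)

    def to_dict(self) -> dict:
        return {"choices": list(self.choices)}

    @staticmethod
    def from_dict(d: dict) -> "PathCode":
        return PathCode(tuple(int(c) for c in d["choices"]))


@dataclass(frozen=True)
class SupernetPlan:
    """Per-layer schedule of the supernet (widths already scaled)."""

    stem_cout: int
    couts: tuple[int, ...]
    strides: tuple[int, ...]
    expands: tuple[float, ...]
    head_cout: int
    num_classes: int = 76
    input_channels: int = 3
    width_mult: float = 1.0

    def __post_init__(self):
        n = len(self.couts)
        if not (len(self.strides) == len(self.expands) == n):
            raise ValueError("couts / strides / expands lengths differ")
        if any(s not in (1, 2) for s in self.strides):
            raise ValueError("strides must be 1 or 2")

    @property
    def num_layers(self) -> int:
        return len(self.couts)

    def block_spec(self, layer: int, choice: int, use_se: bool = False,
                   se_reduction: int = 4) -> BlockSpec:
        kind, kernel = CANDIDATES[choice]
        cin = self.stem_cout if layer == 0 else self.couts[layer - 1]
        return BlockSpec(kind=kind, cin=cin, cout=self.couts[layer],
                         stride=self.strides[layer], expand=self.expands[layer],
                         kernel=kernel if kind == "mbconv" else 3,
                         use_se=use_se, se_reduction=se_reduction)

    def to_dict(self) -> dict:
        return asdict(self)

    @staticmethod
    def from_dict(d: dict) -> "SupernetPlan":
        d = dict(d)
        for k in ("couts", "strides", "expands"):
            d[k] = tuple(d[k])
        return SupernetPlan(**d)


@dataclass(frozen=True)
class EvoConfig:
    population: int = 50
    generations: int = 20
    mutation_prob: float = 0.1
    crossover_prob: float = 0.5
    flops_budget: float = float("inf")
    topk: int = 10

    def __post_init__(self):
        if not self.population >= self.topk >= 1:
            raise ValueError("need population >= topk >= 1")


class InfeasibleBudgetError(RuntimeError):
    """No candidate path satisfies the MAC budget."""


# ---------------------------------------------------------------------------
# the packaged AGE-SPOS
# ---------------------------------------------------------------------------

#: base (width 1.0) stage plan of the packaged AGE-SPOS reconstruction
_AGE_SPOS_BASE = {
    "stem": 32,
    "couts": (16, 16, 16, 16, 32, 48, 64, 64, 64, 96, 128, 128, 144, 176, 208, 304),
    "strides": (1, 1, 1, 2, 2, 1, 1, 2, 1, 1, 2, 1, 1, 1, 1, 1),
    "expands": (1, 6, 4, 6, 3, 4, 3, 6, 3, 6, 6, 3, 4, 4, 4, 6),
    "head": 1152,
}

#: the packaged searched path: 8 of 16 blocks are parallel-asymmetric
AGE_SPOS_PATH = PathCode((0, 2, 1, 2, 0, 2, 1, 2, 0, 2, 1, 2, 0, 2, 1, 2))


def age_spos_plan(width_mult: float = 1.0, num_classes: int = 76,
                  input_channels: int = 3) -> SupernetPlan:
    """The packaged 16-layer plan at a width multiplier in {0.5, 1.0, 1.5}.

    Block widths and the stem are scaled by ``width_mult`` and rounded to
    multiples of 8; the classifier head width is fixed across widths.
    """
    return SupernetPlan(
        stem_cout=round_channels(_AGE_SPOS_BASE["stem"] * width_mult),
        couts=tuple(round_channels(c * width_mult) for c in _AGE_SPOS_BASE["couts"]),
        strides=_AGE_SPOS_BASE["strides"],
        expands=tuple(float(e) for e in _AGE_SPOS_BASE["expands"]),
        head_cout=_AGE_SPOS_BASE["head"],
        num_classes=num_classes,
        input_channels=input_channels,
        width_mult=width_mult,
    )


def path_to_arch(plan: SupernetPlan, path: PathCode | None = None,
                 use_se: bool = False, se_reduction: int = 4,
                 name: str = "age_spos") -> dict:
    """Realize a path through a plan as a declarative architecture spec."""
    path = path if path is not None else AGE_SPOS_PATH
    if len(path.choices) != plan.num_layers:
        raise ValueError("path length does not match plan")
    blocks = [plan.block_spec(i, c, use_se, se_reduction).to_dict()
              for i, c in enumerate(path.choices)]
    return {
        "name": f"{name}_{plan.width_mult:g}x",
        "input_channels": plan.input_channels,
        "num_classes": plan.num_classes,
        "stem": {"cout": plan.stem_cout, "kernel": 3, "stride": 2},
        "blocks": blocks,
        "head": {"type": "conv_gap_fc", "cout": plan.head_cout},
    }


def build_age_spos(path: PathCode | None = None, width_mult: float = 1.0,
                   num_classes: int = 76, input_channels: int = 3,
                   use_se: bool = False, se_reduction: int = 4) -> dict:
    """The standalone AGE-SPOS architecture spec for a path and width."""
    plan = age_spos_plan(width_mult, num_classes, input_channels)
    return path_to_arch(plan, path, use_se, se_reduction)


# ---------------------------------------------------------------------------
# runtime networks
# ---------------------------------------------------------------------------

class _StemConv(nn.Module):
    def __init__(self, cin, cout, rng):
        self.conv = nn.Conv2d(cin, cout, 3, 2, rng=rng)
        self.bn = nn.BatchNorm2d(cout)

    def forward(self, x):
        return self.bn(self.conv(x)).relu6()


class _Head(nn.Module):
    def __init__(self, cin, cout, num_classes, rng):
        self.conv = nn.Conv2d(cin, cout, 1, 1, rng=rng)
        self.bn = nn.BatchNorm2d(cout)
        self.fc = nn.Linear(cout, num_classes, rng=rng)

    def forward(self, x):
        x = self.bn(self.conv(x)).relu6()
        return self.fc(x.mean(axis=(2, 3)))


class PathNetwork(nn.Module):
    """A standalone single-path network (stem -> 16 blocks -> head)."""

    def __init__(self, plan: SupernetPlan, path: PathCode,
                 rng: np.random.Generator | None = None,
                 use_se: bool = False):
        rng = rng or np.random.default_rng(0)
        self.plan = plan
        self.path = path
        self.stem = _StemConv(plan.input_channels, plan.stem_cout, rng)
        self.blocks = [make_block(plan.block_spec(i, c, use_se), rng=rng)
                       for i, c in enumerate(path.choices)]
        self.head = _Head(plan.couts[-1], plan.head_cout, plan.num_classes, rng)

    def forward(self, x):
        x = self.stem(x)
        for b in self.blocks:
            x = b(x)
        return self.head(x)


class Supernet(nn.Module):
    """One-shot supernet: 3 independently parameterized blocks per layer."""

    def __init__(self, plan: SupernetPlan,
                 rng: np.random.Generator | None = None,
                 use_se: bool = False):
        rng = rng or np.random.default_rng(0)
        self.plan = plan
        self.use_se = use_se
        self.stem = _StemConv(plan.input_channels, plan.stem_cout, rng)
        self.choice_layers = [
            [make_block(plan.block_spec(i, c, use_se), rng=rng) for c in range(3)]
            for i in range(plan.num_layers)
        ]
        self.head = _Head(plan.couts[-1], plan.head_cout, plan.num_classes, rng)

    def forward(self, x, path: PathCode):
        x = self.stem(x)
        for layer, choice in zip(self.choice_layers, path.choices):
            x = layer[choice](x)
        return self.head(x)

    def path_parameters(self, path: PathCode) -> list[nn.Parameter]:
        """Parameters active under a path (shared stem/head included)."""
        params = self.stem.parameters() + self.head.parameters()
        for layer, choice in zip(self.choice_layers, path.choices):
            params += layer[choice].parameters()
        return params

    def extract_path(self, path: PathCode) -> PathNetwork:
        """Deep-copy the path's weights into a standalone network."""
        net = PathNetwork(self.plan, path)
        net.stem = copy.deepcopy(self.stem)
        net.blocks = [copy.deepcopy(layer[c])
                      for layer, c in zip(self.choice_layers, path.choices)]
        net.head = copy.deepcopy(self.head)
        return net


def build_supernet(plan: SupernetPlan, rng: np.random.Generator | None = None,
                   use_se: bool = False) -> Supernet:
    return Supernet(plan, rng=rng, use_se=use_se)


def build_path_network(plan: SupernetPlan, path: PathCode,
                       rng: np.random.Generator | None = None,
                       use_se: bool = False) -> PathNetwork:
    return PathNetwork(plan, path, rng=rng, use_se=use_se)


def sample_path(rng: np.random.Generator, num_layers: int = 16) -> PathCode:
    """I.i.d. uniform choice over the 3 candidates per layer."""
    return PathCode(tuple(int(c) for c in rng.integers(0, 3, size=num_layers)))


# ---------------------------------------------------------------------------
# supernet training
# ---------------------------------------------------------------------------

@dataclass
class SupernetTrainConfig:
    mini_batches: int = 20000
    batch_size: int = 64
    lr: float = 0.1
    momentum: float = 0.9
    weight_decay: float = 4e-5
    label_smooth_eps: float = 0.1
    seed: int = 0


def train_supernet(supernet: Supernet, data, cfg: SupernetTrainConfig) -> list[float]:
    """Uniform single-path training with momentum SGD.

    ``data`` is ``(images, ages)``: images ``(N, C, H, W)`` float array,
    ages integer years.  One path is sampled per mini-batch; only its
    parameters (plus the shared stem and head) receive updates.  Returns
    the per-step loss trajectory.
    """
    from .age_model import label_smoothing_targets

    images, ages = data
    n = len(ages)
    if n == 0:
        raise ValueError("empty training data")
    rng = np.random.default_rng(cfg.seed)
    k = supernet.plan.num_classes
    targets_all = label_smoothing_targets(np.asarray(ages), k, cfg.label_smooth_eps)
    losses: list[float] = []
    velocity: dict[int, np.ndarray] = {}
    supernet.train()
    for step in range(cfg.mini_batches):
        idx = rng.integers(0, n, size=min(cfg.batch_size, n))
        path = sample_path(rng, supernet.plan.num_layers)
        x = nn.Tensor(images[idx])
        logits = supernet(x, path)
        loss = nn.cross_entropy(logits, targets_all[idx])
        params = supernet.path_parameters(path)
        for p in params:
            p.grad = None
        loss.backward()
        lr = cfg.lr * 0.5 * (1 + np.cos(np.pi * step / max(cfg.mini_batches, 1)))
        for p in params:
            if p.grad is None:
                continue
            g = p.grad + cfg.weight_decay * p.data
            v = velocity.setdefault(id(p), np.zeros_like(p.data))
            v *= cfg.momentum
            v += g
            p.data -= lr * v
        losses.append(float(loss.data))
    return losses


# ---------------------------------------------------------------------------
# evolutionary search
# ---------------------------------------------------------------------------

def _path_flops(plan: SupernetPlan, path: PathCode, input_size: int) -> int:
    return count_network(path_to_arch(plan, path), input_size).flops


def _path_mae(supernet: Supernet, path: PathCode, images, ages,
              batch: int = 64) -> float:
    from .age_model import dex_ages_from_logits, mae

    supernet.eval()
    preds = []
    for i in range(0, len(ages), batch):
        logits = supernet(nn.Tensor(images[i:i + batch]), path)
        preds.append(dex_ages_from_logits(logits.data))
    return mae(np.concatenate(preds), np.asarray(ages))


def evolutionary_search(supernet: Supernet, val_data, evo: EvoConfig,
                        seed: int = 0, input_size: int | None = None,
                        ) -> list[tuple[PathCode, float]]:
    """FLOPs-budgeted evolutionary search; returns top-k (path, MAE) pairs.

    Candidates violating the budget are never evaluated; if no feasible
    path can be drawn the search raises :class:`InfeasibleBudgetError`.
    Deterministic for a fixed seed.
    """
    images, ages = val_data
    plan = supernet.plan
    n_layers = plan.num_layers
    input_size = input_size or images.shape[-1]
    rng = np.random.default_rng(seed)

    def feasible(p: PathCode) -> bool:
        return _path_flops(plan, p, input_size) <= evo.flops_budget

    scored: dict[tuple, float] = {}

    def score(p: PathCode) -> float:
        key = p.choices
        if key not in scored:
            scored[key] = _path_mae(supernet, p, images, ages)
        return scored[key]

    # seed population with feasible uniform samples
    population: list[PathCode] = []
    attempts = 0
    while len(population) < evo.population:
        p = sample_path(rng, n_layers)
        attempts += 1
        if feasible(p):
            population.append(p)
        if attempts > 200 * evo.population and not population:
            raise InfeasibleBudgetError(
                f"no path within flops_budget={evo.flops_budget:g} after "
                f"{attempts} samples")
        if attempts > 1000 * evo.population:
            if not population:
                raise InfeasibleBudgetError(
                    f"no path within flops_budget={evo.flops_budget:g}")
            break

    for _ in range(evo.generations):
        ranked = sorted(population, key=lambda p: (score(p), p.choices))
        elites = ranked[:evo.topk]
        children: list[PathCode] = list(elites)
        guard = 0
        while len(children) < evo.population and guard < 100 * evo.population:
            guard += 1
            a, b = rng.choice(len(elites), size=2)
            pa, pb = elites[int(a)], elites[int(b)]
            if rng.random() < evo.crossover_prob:
                cut = int(rng.integers(1, n_layers))
                genes = pa.choices[:cut] + pb.choices[cut:]
            else:
                genes = pa.choices
            genes = tuple(
                int(rng.integers(0, 3)) if rng.random() < evo.mutation_prob else g
                for g in genes)
            child = PathCode(genes)
            if feasible(child):
                children.append(child)
        population = children

    final = sorted(population, key=lambda p: (score(p), p.choices))
    out, seen = [], set()
    for p in final:
        if p.choices not in seen:
            seen.add(p.choices)
            out.append((p, score(p)))
        if len(out) == evo.topk:
            break
    return out
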