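"""Differentiable cell search with partial channel connections.

The search network stacks cells; each cell is a DAG whose nodes are
feature maps and whose edges are *mixed operations*: softmax-weighted
sums of the 11 candidate operators,

    f_ij(x_i) = sum_o softmax(alpha^ij)_o * o(x_i).

To keep memory and compute down, only a sampled fraction of each edge's
channels (the mask S_ij, one quarter by default) enters the mixture; the
remaining channels bypass it unchanged.  Because partial sampling makes
edge outputs noisier, each node aggregates its incoming edges with a
second softmax over per-edge scalars beta (edge normalization):

    x_j = sum_{i<j} softmax(beta^(.,j))_i * f_ij^PC(x_i).

The search alternates gradient steps on the network weights (training
split) with steps on (alpha, beta) (validation split).  Discretization
keeps, per intermediate node, the two strongest incoming edges ranked by
softmax(beta) times the edge's best non-zero operator weight, and on
each kept edge the best non-zero operator.

Cell conventions: 2 input nodes, ``num_nodes`` intermediate nodes whose
outputs concatenate into the cell output; reduction cells (positions 1,
3 and 6 of 8 by default, 1-indexed) stride the edges leaving the input
nodes and double the channel count.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from . import nn
from .ops_zoo import (OperatorSpec, OpKind, list_search_operators,
                      make_operator, operator_by_name)

__all__ = [
    "ArchParams",
    "CellGenotype",
    "SearchNetworkConfig",
    "SearchHyper",
    "SearchNetwork",
    "mixed_edge_forward",
    "partial_mixed_edge_forward",
    "node_aggregate",
    "bilevel_search",
    "derive_genotype",
    "build_agenet",
    "build_agenet_network",
]

EdgeKey = tuple[str, int, int]  # (cell_type, source_node, target_node)


def _edges(num_nodes: int) -> list[tuple[int, int]]:
    """All DAG edges (i, j) into intermediate nodes j = 2 .. num_nodes+1."""
    return [(i, j) for j in range(2, num_nodes + 2) for i in range(j)]


@dataclass
class ArchParams:
    """Search state: per-edge operator logits, edge logits, channel masks."""

    alpha: dict[EdgeKey, nn.Parameter]
    beta: dict[EdgeKey, nn.Parameter]
    mask: dict[EdgeKey, np.ndarray]
    sample_ratio: float

    def parameters(self) -> list[nn.Parameter]:
        return list(self.alpha.values()) + list(self.beta.values())

    def softmax_alpha(self, key: EdgeKey) -> np.ndarray:
        a = self.alpha[key].data
        e = np.exp(a - a.max())
        return e / e.sum()

    @staticmethod
    def initialize(num_nodes: int, num_ops: int, sample_ratio: float,
                   rng: np.random.Generator,
                   cell_types=("normal", "reduce")) -> "ArchParams":
        alpha, beta = {}, {}
        for ct in cell_types:
            for (i, j) in _edges(num_nodes):
                alpha[(ct, i, j)] = nn.Parameter(
                    1e-3 * rng.normal(size=num_ops))
                beta[(ct, i, j)] = nn.Parameter(
                    1e-3 * rng.normal(size=()))
        return ArchParams(alpha=alpha, beta=beta, mask={},
                          sample_ratio=sample_ratio)


@dataclass(frozen=True)
class CellGenotype:
    """Discrete cell: per intermediate node, 2 (op_name, source) pairs."""

    normal: tuple[tuple[str, int], ...]
    reduce: tuple[tuple[str, int], ...]
    nodes: int

    def __post_init__(self):
        for arm in (self.normal, self.reduce):
            if len(arm) != 2 * self.nodes:
                raise ValueError("need exactly 2 edges per intermediate node")
            for pos, (op, src) in enumerate(arm):
                if op == "zero":
                    raise ValueError("zero operator cannot appear in a genotype")
                operator_by_name(op)
                node = 2 + pos // 2
                if not 0 <= src < node:
                    raise ValueError(f"edge source {src} not below node {node}")

    def to_dict(self) -> dict:
        return {"normal": [list(p) for p in self.normal],
                "reduce": [list(p) for p in self.reduce],
                "nodes": self.nodes}

    @staticmethod
    def from_dict(d: dict) -> "CellGenotype":
        return CellGenotype(
            normal=tuple((str(o), int(s)) for o, s in d["normal"]),
            reduce=tuple((str(o), int(s)) for o, s in d["reduce"]),
            nodes=int(d["nodes"]))


_DEFAULT_OPS = tuple(s.name for s in list_search_operators())


@dataclass(frozen=True)
class SearchNetworkConfig:
    num_cells: int = 8
    reduction_positions: tuple[int, ...] = (1, 3, 6)  # 1-indexed cell slots
    init_channels: int = 36
    num_nodes: int = 4
    input_channels: int = 3
    num_classes: int = 76
    sample_ratio: float = 0.25
    operators: tuple[str, ...] = _DEFAULT_OPS

    def __post_init__(self):
        bad = [p for p in self.reduction_positions
               if not 1 <= p <= self.num_cells]
        if bad:
            raise ValueError(f"reduction positions {bad} outside 1..{self.num_cells}")


# ---------------------------------------------------------------------------
# the three edge/node primitives
# ---------------------------------------------------------------------------

def mixed_edge_forward(x: nn.Tensor, alpha_edge, ops) -> nn.Tensor:
    """Softmax(alpha)-weighted sum of the candidate operator outputs."""
    if len(ops) == 0:
        raise ValueError("mixed edge needs at least one operator")
    alpha_edge = nn.Tensor._wrap(alpha_edge)
    if alpha_edge.data.size != len(ops):
        raise ValueError("alpha length does not match operator count")
    weights = nn.softmax(alpha_edge.reshape(1, -1)).reshape(-1)
    out = None
    shape = None
    for k, op in enumerate(ops):
        y = op(x)
        if shape is None:
            shape = y.data.shape
        elif y.data.shape != shape:
            raise ValueError(
                f"operator {k} output shape {y.data.shape} != {shape}")
        term = y * weights[k]
        out = term if out is None else out + term
    return out


def partial_mixed_edge_forward(x: nn.Tensor, alpha_edge, mask: np.ndarray,
                               ops) -> nn.Tensor:
    """Masked-in channels go through the mixture; the rest bypass unchanged.

    ``mask`` is a binary vector over the channels of ``x``; operators must
    accept the selected sub-map (stride-1, channel-preserving semantics).
    Channels are recombined in their original order.
    """
    mask = np.asarray(mask)
    if mask.shape != (x.data.shape[1],):
        raise ValueError("mask length must equal the channel count")
    sel = mask.astype(bool)
    if not sel.any():
        return x
    if sel.all():
        return mixed_edge_forward(x, alpha_edge, ops)
    mixed = mixed_edge_forward(x[:, sel], alpha_edge, ops)
    rest = x[:, ~sel]
    perm = np.concatenate([np.flatnonzero(sel), np.flatnonzero(~sel)])
    return nn.concat([mixed, rest], axis=1)[:, np.argsort(perm)]


def node_aggregate(edge_outputs: dict[int, nn.Tensor],
                   beta: dict[int, nn.Tensor]) -> nn.Tensor:
    """Edge-normalized sum: softmax over the betas of the incoming edges."""
    if not edge_outputs:
        raise ValueError("node_aggregate needs at least one incoming edge")
    srcs = sorted(edge_outputs)
    bvec = nn.concat([nn.Tensor._wrap(beta[i]).reshape(1) for i in srcs], axis=0)
    weights = nn.softmax(bvec.reshape(1, -1)).reshape(-1)
    out = None
    for k, i in enumerate(srcs):
        term = edge_outputs[i] * weights[k]
        out = term if out is None else out + term
    return out


# ---------------------------------------------------------------------------
# search network
# ---------------------------------------------------------------------------

class _Preprocess(nn.Module):
    """1x1 conv (optionally strided) + norm bringing an input to C channels."""

    def __init__(self, cin, cout, stride, rng):
        self.conv = nn.Conv2d(cin, cout, 1, stride, rng=rng)
        self.bn = nn.BatchNorm2d(cout)

    def forward(self, x):
        return self.bn(self.conv(x))


class _SearchCell(nn.Module):
    def __init__(self, cfg: SearchNetworkConfig, c_pp: int, c_p: int, c: int,
                 reduction: bool, reduction_prev: bool,
                 rng: np.random.Generator):
        self.cfg = cfg
        self.reduction = reduction
        self.c = c
        self.pre0 = _Preprocess(c_pp, c, 2 if reduction_prev else 1, rng)
        self.pre1 = _Preprocess(c_p, c, 1, rng)
        self.c_sel = max(int(round(c * cfg.sample_ratio)), 1)
        self.ops: dict[tuple[int, int], list[nn.Module]] = {}
        specs = [operator_by_name(n) for n in cfg.operators]
        for (i, j) in _edges(cfg.num_nodes):
            stride = 2 if (reduction and i < 2) else 1
            self.ops[(i, j)] = [make_operator(s, self.c_sel, stride, rng=rng)
                                for s in specs]

    def forward(self, s0, s1, arch: ArchParams, cell_type: str,
                rng: np.random.Generator):
        states = [self.pre0(s0), self.pre1(s1)]
        for j in range(2, self.cfg.num_nodes + 2):
            outs, betas = {}, {}
            for i in range(j):
                key = (cell_type, i, j)
                x = states[i]
                mask = np.zeros(self.c, dtype=int)
                mask[rng.permutation(self.c)[:self.c_sel]] = 1
                arch.mask[key] = mask
                sel = mask.astype(bool)
                stride = 2 if (self.reduction and i < 2) else 1
                mixed = mixed_edge_forward(x[:, sel], arch.alpha[key],
                                           self.ops[(i, j)])
                if stride == 1:
                    rest = x[:, ~sel]
                else:
                    # bypass channels on strided edges are average-pooled
                    rest = nn.avg_pool2d(x[:, ~sel], 2, 2)
                perm = np.concatenate([np.flatnonzero(sel), np.flatnonzero(~sel)])
                outs[i] = nn.concat([mixed, rest], axis=1)[:, np.argsort(perm)]
                betas[i] = arch.beta[key]
            states.append(node_aggregate(outs, betas))
        return nn.concat(states[2:], axis=1)


class SearchNetwork(nn.Module):
    """Stem -> stacked search cells -> global pool -> classifier."""

    def __init__(self, cfg: SearchNetworkConfig,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.cfg = cfg
        c = cfg.init_channels
        self.stem = _Preprocess(cfg.input_channels, c, 1, rng)
        self.stem.conv = nn.Conv2d(cfg.input_channels, c, 3, 1, rng=rng)
        self.cells: list[_SearchCell] = []
        self.cell_types: list[str] = []
        c_pp = c_p = c
        c_curr = c
        red_prev = False
        for k in range(1, cfg.num_cells + 1):
            reduction = k in cfg.reduction_positions
            if reduction:
                c_curr *= 2
            cell = _SearchCell(cfg, c_pp, c_p, c_curr, reduction, red_prev, rng)
            self.cells.append(cell)
            self.cell_types.append("reduce" if reduction else "normal")
            c_pp, c_p = c_p, cfg.num_nodes * c_curr
            red_prev = reduction
        self.classifier = nn.Linear(c_p, cfg.num_classes, rng=rng)
        cell_types = tuple(sorted(set(self.cell_types))) or ("normal",)
        self.arch = ArchParams.initialize(
            cfg.num_nodes, len(cfg.operators), cfg.sample_ratio, rng,
            cell_types=cell_types)

    def forward(self, x, rng: np.random.Generator):
        s0 = s1 = self.stem(x)
        for cell, ct in zip(self.cells, self.cell_types):
            s0, s1 = s1, cell(s0, s1, self.arch, ct, rng)
        return self.classifier(s1.mean(axis=(2, 3)))

    def weight_parameters(self) -> list[nn.Parameter]:
        arch_ids = {id(p) for p in self.arch.parameters()}
        return [p for p in self.parameters() if id(p) not in arch_ids]


# ---------------------------------------------------------------------------
# bilevel optimization
# ---------------------------------------------------------------------------

@dataclass
class SearchHyper:
    steps: int = 50             # alternating (weight, arch) step pairs
    batch_size: int = 16
    lr_w: float = 0.1
    momentum: float = 0.9
    weight_decay_w: float = 1e-4
    lr_arch: float = 6e-4
    weight_decay_arch: float = 1e-3
    label_smooth_eps: float = 0.1
    seed: int = 0


def bilevel_search(train_data, val_data, cfg: SearchNetworkConfig,
                   hyper: SearchHyper | None = None,
                   network: SearchNetwork | None = None,
                   ) -> tuple[ArchParams, list[dict]]:
    """Alternate weight steps (train split) with alpha/beta steps (val split).

    ``train_data`` / ``val_data`` are ``(images, ages)`` pairs — the 60/40
    split is the caller's.  Returns the final ArchParams (still attached
    to the search network) and a step log.  Deterministic given the seed.
    """
    from .age_model import label_smoothing_targets

    hyper = hyper or SearchHyper()
    xt, yt = train_data
    xv, yv = val_data
    if len(yt) == 0 or len(yv) == 0:
        raise ValueError("both search splits must be non-empty")
    rng = np.random.default_rng(hyper.seed)
    net = network or SearchNetwork(cfg, rng=np.random.default_rng(hyper.seed))
    k = cfg.num_classes
    tt = label_smoothing_targets(np.asarray(yt), k, hyper.label_smooth_eps)
    tv = label_smoothing_targets(np.asarray(yv), k, hyper.label_smooth_eps)
    opt_w = nn.SGD(net.weight_parameters(), lr=hyper.lr_w,
                   momentum=hyper.momentum, weight_decay=hyper.weight_decay_w)
    opt_a = nn.Adam(net.arch.parameters(), lr=hyper.lr_arch,
                    weight_decay=hyper.weight_decay_arch)
    log: list[dict] = []
    net.train()
    for step in range(hyper.steps):
        # -- network weights on the training split
        idx = rng.integers(0, len(yt), size=min(hyper.batch_size, len(yt)))
        loss_w = nn.cross_entropy(net(nn.Tensor(xt[idx]), rng), tt[idx])
        opt_w.zero_grad()
        opt_a.zero_grad()
        loss_w.backward()
        opt_w.step()
        # -- architecture weights on the validation split
        idx = rng.integers(0, len(yv), size=min(hyper.batch_size, len(yv)))
        loss_a = nn.cross_entropy(net(nn.Tensor(xv[idx]), rng), tv[idx])
        opt_w.zero_grad()
        opt_a.zero_grad()
        loss_a.backward()
        opt_a.step()
        log.append({"step": step, "loss_w": float(loss_w.data),
                    "loss_arch": float(loss_a.data)})
    return net.arch, log


# ---------------------------------------------------------------------------
# discretization
# ---------------------------------------------------------------------------

def derive_genotype(params: ArchParams, cfg: SearchNetworkConfig) -> CellGenotype:
    """Keep the top-2 incoming edges per node and the best non-zero op."""
    names = cfg.operators
    nonzero = [k for k, n in enumerate(names) if n != "zero"]

    def arm(cell_type: str) -> tuple[tuple[str, int], ...]:
        pairs: list[tuple[str, int]] = []
        for j in range(2, cfg.num_nodes + 2):
            incoming = [i for i in range(j)
                        if (cell_type, i, j) in params.alpha]
            b = np.array([float(params.beta[(cell_type, i, j)].data)
                          for i in incoming])
            bw = np.exp(b - b.max())
            bw /= bw.sum()
            scores = []
            for pos, i in enumerate(incoming):
                sa = params.softmax_alpha((cell_type, i, j))
                best = max(nonzero, key=lambda k: (sa[k], -k))
                scores.append((-bw[pos] * sa[best], i, names[best]))
            scores.sort()
            for _, i, op in scores[:2]:
                pairs.append((op, i))
        return tuple(pairs)

    cell_types = {ct for (ct, _, _) in params.alpha}
    normal = arm("normal") if "normal" in cell_types else arm("reduce")
    reduce_ = arm("reduce") if "reduce" in cell_types else normal
    return CellGenotype(normal=normal, reduce=reduce_, nodes=cfg.num_nodes)


# ---------------------------------------------------------------------------
# evaluation network (AGENet)
# ---------------------------------------------------------------------------

def _op_layers(op_name: str, c: int, stride: int, scale: int) -> list[dict]:
    """Primitive weighted layers of one discrete cell operator."""
    spec = operator_by_name(op_name)
    k = spec.kernel[0]
    conv = lambda cin, cout, kh, kw, g=1: {
        "op": "conv", "cin": cin, "cout": cout, "kh": kh, "kw": kw,
        "groups": g, "out_scale": scale, "bn": False}
    bn = {"op": "bn", "channels": c}
    if spec.kind is OpKind.standard_conv:
        return [conv(c, c, k, k), bn]
    if spec.kind is OpKind.separable_conv:
        return [conv(c, c, k, k, c), conv(c, c, 1, 1), bn,
                conv(c, c, k, k, c), conv(c, c, 1, 1), bn]
    if spec.kind is OpKind.group_conv:
        return [conv(c, c, k, k, spec.groups), conv(c, c, 1, 1), bn]
    if spec.kind is OpKind.asym_group_conv:
        in_scale = scale // stride
        first = dict(conv(c, c, 1, k, spec.groups), out_scale=in_scale)
        return [first, conv(c, c, k, 1, spec.groups), conv(c, c, 1, 1), bn]
    if spec.kind in (OpKind.max_pool, OpKind.avg_pool):
        return [bn]
    if spec.kind is OpKind.identity:
        return [] if stride == 1 else [conv(c, c, 1, 1), bn]
    raise ValueError(f"operator {op_name} cannot appear in a genotype")


def build_agenet(genotype: CellGenotype, init_channels: int,
                 num_cells: int = 8,
                 reduction_positions: tuple[int, ...] = (1, 3, 6),
                 input_channels: int = 3, num_classes: int = 76) -> dict:
    """Declarative spec of the evaluation network built from a genotype.

    Stem: two strided 3x3 convolutions; then ``num_cells`` cells with
    reductions at the 1-indexed positions (reduction cells double the
    channel count and halve the resolution); global pooling and a
    ``num_classes``-way expectation head.  The returned dict carries both
    the metadata to rebuild the runtime network and a pre-lowered
    ``layers`` list for the complexity counter.
    """
    c = init_channels
    layers: list[dict] = [
        {"op": "conv", "cin": input_channels, "cout": c // 2, "kh": 3, "kw": 3,
         "groups": 1, "out_scale": 2, "bn": True},
        {"op": "conv", "cin": c // 2, "cout": c, "kh": 3, "kw": 3,
         "groups": 1, "out_scale": 4, "bn": True},
    ]
    scale = 4
    c_pp = c_p = c
    c_curr = c
    for k in range(1, num_cells + 1):
        reduction = k in reduction_positions
        if reduction:
            c_curr *= 2
            scale *= 2
        arm = genotype.reduce if reduction else genotype.normal
        pre_scale = scale if not reduction else scale // 2
        layers += [
            {"op": "conv", "cin": c_pp, "cout": c_curr, "kh": 1, "kw": 1,
             "groups": 1, "out_scale": pre_scale, "bn": True},
            {"op": "conv", "cin": c_p, "cout": c_curr, "kh": 1, "kw": 1,
             "groups": 1, "out_scale": pre_scale, "bn": True},
        ]
        for pos, (op, src) in enumerate(arm):
            stride = 2 if (reduction and src < 2) else 1
            layers += _op_layers(op, c_curr, stride, scale)
        c_pp, c_p = c_p, genotype.nodes * c_curr
    layers.append({"op": "fc", "cin": c_p, "cout": num_classes, "bias": True})
    return {
        "name": f"agenet_c{init_channels}",
        "type": "agenet",
        "genotype": genotype.to_dict(),
        "init_channels": init_channels,
        "num_cells": num_cells,
        "reduction_positions": list(reduction_positions),
        "input_channels": input_channels,
        "num_classes": num_classes,
        "layers": layers,
    }


class _EvalCell(nn.Module):
    def __init__(self, genotype: CellGenotype, c_pp, c_p, c, reduction,
                 reduction_prev, rng):
        self.genotype = genotype
        self.reduction = reduction
        self.pre0 = _Preprocess(c_pp, c, 2 if reduction_prev else 1, rng)
        self.pre1 = _Preprocess(c_p, c, 1, rng)
        arm = genotype.reduce if reduction else genotype.normal
        self.edges = []
        for pos, (op, src) in enumerate(arm):
            stride = 2 if (reduction and src < 2) else 1
            self.edges.append((src, make_operator(operator_by_name(op), c,
                                                  stride, rng=rng)))

    def forward(self, s0, s1):
        states = [self.pre0(s0), self.pre1(s1)]
        n = self.genotype.nodes
        for j in range(n):
            (src_a, op_a), (src_b, op_b) = self.edges[2 * j], self.edges[2 * j + 1]
            states.append(op_a(states[src_a]) + op_b(states[src_b]))
        return nn.concat(states[2:], axis=1)


class AgeNet(nn.Module):
    """Runtime evaluation network for a searched cell genotype."""

    def __init__(self, genotype: CellGenotype, init_channels: int,
                 num_cells: int = 8,
                 reduction_positions: tuple[int, ...] = (1, 3, 6),
                 input_channels: int = 3, num_classes: int = 76,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        c = init_channels
        self.stem0 = _Preprocess(input_channels, c // 2, 2, rng)
        self.stem0.conv = nn.Conv2d(input_channels, c // 2, 3, 2, rng=rng)
        self.stem1 = _Preprocess(c // 2, c, 2, rng)
        self.stem1.conv = nn.Conv2d(c // 2, c, 3, 2, rng=rng)
        self.cells = []
        c_pp = c_p = c
        c_curr = c
        red_prev = False
        for k in range(1, num_cells + 1):
            reduction = k in reduction_positions
            if reduction:
                c_curr *= 2
            self.cells.append(_EvalCell(genotype, c_pp, c_p, c_curr,
                                        reduction, red_prev, rng))
            c_pp, c_p = c_p, genotype.nodes * c_curr
            red_prev = reduction
        self.classifier = nn.Linear(c_p, num_classes, rng=rng)

    def forward(self, x):
        s0 = s1 = self.stem1(self.stem0(x))
        for cell in self.cells:
            s0, s1 = s1, cell(s0, s1)
        return self.classifier(s1.mean(axis=(2, 3)))


def build_agenet_network(spec_or_genotype, init_channels: int | None = None,
                         rng: np.random.Generator | None = None,
                         **kwargs) -> AgeNet:
    """Runtime AgeNet from a genotype or a spec dict from build_agenet."""
    if isinstance(spec_or_genotype, dict) and "genotype" in spec_or_genotype:
        spec = spec_or_genotype
        return AgeNet(CellGenotype.from_dict(spec["genotype"]),
                      spec["init_channels"], spec["num_cells"],
                      tuple(spec["reduction_positions"]),
                      spec["input_channels"], spec["num_classes"], rng=rng)
    if init_channels is None:
        raise ValueError("init_channels required when passing a genotype")
    return AgeNet(spec_or_genotype, init_channels, rng=rng, **kwargs)
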