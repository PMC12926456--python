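"""Graph neural networks for per-vertex (node) classification.

Three architectures are provided as explicit propagation rules:

* **GCN** — each layer computes ``act(S H W + b)`` with the symmetrically
  degree-normalized adjacency ``S = D̂^{-1/2} (A + I) D̂^{-1/2}``, i.e. a
  degree-weighted average over the neighborhood including the node itself.
* **GAT** — each layer learns per-neighbor attention: per head,
  ``e_ij = LeakyReLU(a_src·Wh_i + a_dst·Wh_j)`` over ``j ∈ N(i) ∪ {i}``,
  softmax-normalized over that set, then a weighted sum of transformed
  neighbor features.  Hidden layers concatenate heads, the output layer
  averages them.
* **Graph U-Net** — an encoder/decoder: top-k pooling layers score nodes by
  a learned projection, keep the ⌈ratio·V⌉ best (ties broken toward the
  lower vertex index), gate retained features by tanh of the score and
  induce the subgraph; unpooling scatters features back to their recorded
  indices (zeros elsewhere) with additive skip connections, so the output
  has one logit row per original vertex.

All models emit raw logits for a cross-entropy objective.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, asdict

import numpy as np
from scipy import sparse as sp

from .autodiff import Parameter, Tensor, concat
from .surface_mesh import VertexGraph

__all__ = [
    "ModelConfig",
    "ConfigurationError",
    "normalized_adjacency",
    "directed_edges_with_self_loops",
    "GCNLayer",
    "GATLayer",
    "TopKPool",
    "build_model",
    "count_parameters",
    "save_checkpoint",
    "load_checkpoint",
]


class ConfigurationError(ValueError):
    """Invalid model configuration."""


@dataclass
class ModelConfig:
    """Architecture family and sizes.

    ``hidden`` fixes layer widths regardless of the input feature length,
    so the trainable-parameter count grows linearly with the feature
    dimension through the first layer only.
    """

    architecture: str = "gcn"            # gcn | gat | gunet
    hidden: tuple[int, ...] = (512, 256)
    heads: int = 4                       # GAT only
    pool_ratio: float = 0.5              # Graph U-Net only
    depth: int = 3                       # Graph U-Net only
    activation: str = "elu"
    n_classes: int = 35
    seed: int = 0

    def __post_init__(self) -> None:
        self.hidden = tuple(int(w) for w in self.hidden)
        if any(w <= 0 for w in self.hidden):
            raise ConfigurationError("hidden widths must be positive")
        if not (0.0 < self.pool_ratio <= 1.0):
            raise ConfigurationError("pool_ratio must lie in (0, 1]")
        if self.heads < 1:
            raise ConfigurationError("heads must be >= 1")
        if self.n_classes < 1:
            raise ConfigurationError("n_classes must be >= 1")


def _activation(name: str):
    table = {
        "elu": lambda t: t.elu(),
        "relu": lambda t: t.relu(),
        "tanh": lambda t: t.tanh(),
        "leaky_relu": lambda t: t.leaky_relu(),
        "linear": lambda t: t,
    }
    if name not in table:
        raise ConfigurationError(f"unknown activation {name!r}")
    return table[name]


def normalized_adjacency(graph: VertexGraph) -> sp.csr_matrix:
    """S = D̂^{-1/2} (A + I) D̂^{-1/2} with self-loops added."""
    a_hat = graph.adjacency() + sp.eye(graph.node_count, format="csr")
    deg = np.asarray(a_hat.sum(axis=1)).ravel()
    d_inv_sqrt = sp.diags(1.0 / np.sqrt(deg))
    return (d_inv_sqrt @ a_hat @ d_inv_sqrt).tocsr()


def directed_edges_with_self_loops(graph: VertexGraph) -> tuple[np.ndarray, np.ndarray]:
    """(src, dst) arrays with both edge directions plus one self-loop per node."""
    i, j = graph.edges[:, 0], graph.edges[:, 1]
    loops = np.arange(graph.node_count, dtype=np.int64)
    src = np.concatenate([i, j, loops])
    dst = np.concatenate([j, i, loops])
    return src, dst


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    bound = math.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-bound, bound, size=(fan_in, fan_out))


class GCNLayer:
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator):
        self.weight = Parameter(_glorot(rng, in_dim, out_dim))
        self.bias = Parameter(np.zeros(out_dim))

    def parameters(self):
        return [self.weight, self.bias]

    def __call__(self, h: Tensor, s_norm: sp.csr_matrix) -> Tensor:
        if h.shape[1] != self.weight.shape[0]:
            raise ValueError(
                f"feature dim {h.shape[1]} != layer in_dim {self.weight.shape[0]}"
            )
        return (h @ self.weight).spmm(s_norm) + self.bias


class GATLayer:
    """Multi-head attention layer; ``concat_heads=False`` averages heads."""

    def __init__(self, in_dim: int, out_dim: int, heads: int,
                 rng: np.random.Generator, concat_heads: bool = True):
        self.heads = heads
        self.out_dim = out_dim
        self.concat_heads = concat_heads
        self.weights = [Parameter(_glorot(rng, in_dim, out_dim)) for _ in range(heads)]
        self.att_src = [Parameter(_glorot(rng, out_dim, 1)) for _ in range(heads)]
        self.att_dst = [Parameter(_glorot(rng, out_dim, 1)) for _ in range(heads)]
        self.bias = Parameter(np.zeros(out_dim * heads if concat_heads else out_dim))

    def parameters(self):
        return self.weights + self.att_src + self.att_dst + [self.bias]

    def _head(self, h: Tensor, src: np.ndarray, dst: np.ndarray, k: int,
              n: int, return_alpha: bool = False):
        wh = h @ self.weights[k]
        s_src = wh @ self.att_src[k]
        s_dst = wh @ self.att_dst[k]
        e = (s_src.gather_rows(src) + s_dst.gather_rows(dst)).leaky_relu(0.2)
        # Stable softmax per destination group; the per-group max is a
        # constant shift with zero gradient contribution.
        group_max = np.full(n, -np.inf)
        np.maximum.at(group_max, dst, e.data.ravel())
        w = (e - Tensor(group_max[dst][:, None])).exp()
        denom = w.scatter_rows(dst, n)
        alpha = w / denom.gather_rows(dst)
        if return_alpha:
            return alpha
        msg = alpha * wh.gather_rows(src)
        return msg.scatter_rows(dst, n)

    def __call__(self, h: Tensor, edges: tuple[np.ndarray, np.ndarray]) -> Tensor:
        if h.shape[1] != self.weights[0].shape[0]:
            raise ValueError(
                f"feature dim {h.shape[1]} != layer in_dim {self.weights[0].shape[0]}"
            )
        src, dst = edges
        n = h.shape[0]
        outs = [self._head(h, src, dst, k, n) for k in range(self.heads)]
        if self.concat_heads:
            out = concat(outs, axis=1) if self.heads > 1 else outs[0]
        else:
            out = outs[0]
            for o in outs[1:]:
                out = out + o
            out = out * (1.0 / self.heads)
        return out + self.bias

    def attention(self, h: Tensor, edges: tuple[np.ndarray, np.ndarray]) -> list[np.ndarray]:
        """Per-head attention coefficients aligned with the edge arrays."""
        src, dst = edges
        n = h.shape[0]
        return [
            self._head(h, src, dst, k, n, return_alpha=True).data.ravel()
            for k in range(self.heads)
        ]


class TopKPool:
    """Learned top-k node selection with score gating."""

    def __init__(self, dim: int, ratio: float, rng: np.random.Generator):
        self.proj = Parameter(_glorot(rng, dim, 1))
        self.ratio = ratio

    def parameters(self):
        return [self.proj]

    def select(self, h: Tensor) -> tuple[np.ndarray, Tensor]:
        """Return (kept indices ascending, gated pooled features)."""
        norm = np.linalg.norm(self.proj.data) + 1e-12
        score = (h @ self.proj) * (1.0 / norm)
        n = h.shape[0]
        k = math.ceil(self.ratio * n)
        if k == 0:
            raise ConfigurationError("pooling would retain zero nodes")
        order = np.argsort(-score.data.ravel(), kind="stable")  # ties -> lower index
        idx = np.sort(order[:k])
        gate = score.gather_rows(idx).tanh()
        return idx, h.gather_rows(idx) * gate


def _induce_subgraph(edges: np.ndarray, idx: np.ndarray, n_old: int) -> VertexGraph:
    keep = np.zeros(n_old, dtype=bool)
    keep[idx] = True
    remap = np.full(n_old, -1, dtype=np.int64)
    remap[idx] = np.arange(len(idx))
    if len(edges):
        mask = keep[edges[:, 0]] & keep[edges[:, 1]]
        sub = remap[edges[mask]]
    else:
        sub = np.empty((0, 2), dtype=np.int64)
    return VertexGraph(node_count=len(idx), edges=sub)


class GCNModel:
    def __init__(self, config: ModelConfig, in_dim: int):
        rng = np.random.default_rng(config.seed)
        self.config = config
        self.act = _activation(config.activation)
        dims = [in_dim, *config.hidden, config.n_classes]
        self.layers = [GCNLayer(a, b, rng) for a, b in zip(dims[:-1], dims[1:])]

    def parameters(self):
        return [p for layer in self.layers for p in layer.parameters()]

    def forward(self, x, graph: VertexGraph) -> Tensor:
        s_norm = normalized_adjacency(graph)
        h = x if isinstance(x, Tensor) else Tensor(x)
        for layer in self.layers[:-1]:
            h = self.act(layer(h, s_norm))
        return self.layers[-1](h, s_norm)


class GATModel:
    def __init__(self, config: ModelConfig, in_dim: int):
        rng = np.random.default_rng(config.seed)
        self.config = config
        self.act = _activation(config.activation)
        self.layers: list[GATLayer] = []
        d = in_dim
        for w in config.hidden:
            self.layers.append(GATLayer(d, w, config.heads, rng, concat_heads=True))
            d = w * config.heads
        # Output layer averages heads and emits raw logits.
        self.layers.append(GATLayer(d, config.n_classes, config.heads, rng,
                                    concat_heads=False))

    def parameters(self):
        return [p for layer in self.layers for p in layer.parameters()]

    def forward(self, x, graph: VertexGraph) -> Tensor:
        edges = directed_edges_with_self_loops(graph)
        h = x if isinstance(x, Tensor) else Tensor(x)
        for layer in self.layers[:-1]:
            h = self.act(layer(h, edges))
        return self.layers[-1](h, edges)


class GraphUNetModel:
    """Encoder/decoder with top-k pooling, unpooling, and additive skips."""

    def __init__(self, config: ModelConfig, in_dim: int):
        rng = np.random.default_rng(config.seed)
        self.config = config
        self.act = _activation(config.activation)
        # Uniform internal width (first entry of `hidden`): additive skip
        # connections require matching widths across encoder/decoder levels.
        w = config.hidden[0]
        self.embed = GCNLayer(in_dim, w, rng)
        self.pools = [TopKPool(w, config.pool_ratio, rng) for _ in range(config.depth)]
        self.down = [GCNLayer(w, w, rng) for _ in range(config.depth)]
        self.up = [GCNLayer(w, w, rng) for _ in range(config.depth)]
        self.head = GCNLayer(w, config.n_classes, rng)

    def parameters(self):
        out = self.embed.parameters()
        for p in self.pools:
            out += p.parameters()
        for layer in self.down + self.up:
            out += layer.parameters()
        return out + self.head.parameters()

    def forward(self, x, graph: VertexGraph) -> Tensor:
        h = x if isinstance(x, Tensor) else Tensor(x)
        s0 = normalized_adjacency(graph)
        h = self.act(self.embed(h, s0))

        skips: list[Tensor] = []
        idx_stack: list[np.ndarray] = []
        size_stack: list[int] = []
        graphs: list[VertexGraph] = [graph]
        g = graph
        for d in range(self.config.depth):
            skips.append(h)
            idx, h = self.pools[d].select(h)
            idx_stack.append(idx)
            size_stack.append(g.node_count)
            g = _induce_subgraph(g.edges, idx, g.node_count)
            graphs.append(g)
            h = self.act(self.down[d](h, normalized_adjacency(g)))

        for d in range(self.config.depth):
            idx = idx_stack.pop()
            n_up = size_stack.pop()
            graphs.pop()
            g = graphs[-1]
            h = h.scatter_rows(idx, n_up) + skips.pop()
            h = self.act(self.up[d](h, normalized_adjacency(g)))

        return self.head(h, normalized_adjacency(graph))


def build_model(config: ModelConfig, in_dim: int):
    """Instantiate the configured architecture for ``in_dim`` input features."""
    if in_dim < 1:
        raise ConfigurationError(f"in_dim must be >= 1, got {in_dim}")
    arch = config.architecture.lower()
    if arch == "gcn":
        return GCNModel(config, in_dim)
    if arch == "gat":
        return GATModel(config, in_dim)
    if arch in {"gunet", "graph-unet", "graph_unet"}:
        return GraphUNetModel(config, in_dim)
    raise ConfigurationError(f"unknown architecture {config.architecture!r}")


def count_parameters(model) -> int:
    """Total number of trainable scalars in the model."""
    return int(sum(p.data.size for p in model.parameters()))


class CheckpointError(ValueError):
    """Checkpoint payload inconsistent with its manifest."""


def save_checkpoint(model, path: str | os.PathLike) -> None:
    """NumPy ``.npz`` checkpoint: JSON config manifest + little-endian float64 arrays."""
    cfg = asdict(model.config)
    cfg["hidden"] = list(cfg["hidden"])
    params = model.parameters()
    manifest = {
        "config": cfg,
        "in_dim": int(params[0].data.shape[0]),
        "shapes": [list(p.data.shape) for p in params],
    }
    arrays = {f"param_{i}": p.data.astype("<f8") for i, p in enumerate(params)}
    np.savez(str(path), manifest=np.frombuffer(
        json.dumps(manifest).encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path: str | os.PathLike):
    with np.load(str(path)) as data:
        manifest = json.loads(bytes(data["manifest"]).decode())
        cfg = manifest["config"]
        cfg["hidden"] = tuple(cfg["hidden"])
        model = build_model(ModelConfig(**cfg), manifest["in_dim"])
        params = model.parameters()
        for i, p in enumerate(params):
            arr = data[f"param_{i}"]
            if list(arr.shape) != manifest["shapes"][i]:
                raise CheckpointError(
                    f"checkpoint param_{i} shape {arr.shape} != "
                    f"manifest {manifest['shapes'][i]}"
                )
            p.data = arr.astype(np.float64)
    return model

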