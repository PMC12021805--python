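"""Graph-transformer classifier over metabolic brain networks.

Architecture (three stacked layers by default):

* **Gated structure fusion** — a learnable structure token ``s`` in R^d is
  blended into each node feature vector through a sigmoid gate,
  ``g_i = sigmoid(W_g [x_i || s])``, ``x~_i = g_i * x_i + (1 - g_i) * s``.
* **Adjacency-Hadamard multi-head attention** — scaled dot-product
  attention per head, softmax over keys, then an element-wise product
  with the graph's edge-weight matrix so connectivity strength attenuates
  message passing (no renormalisation by default).  The first layer
  attends globally; deeper layers are restricted to a TopK-sparsified
  neighbourhood of the graph.
* **Position-wise FFN** with exact (Gaussian-CDF) GELU.
* **Single post-LayerNorm** over the sum of the fused input, the
  attention output and the FFN output.

Readout: element-wise max over nodes of each layer's output, concatenated
(3 x 36 = 108), followed by a 3-layer MLP head (LayerNorm and dropout
before each linear) and a softmax over the three diagnostic classes.
A parallel 2-layer projection head produces the unit-norm embeddings used
by the supervised contrastive loss during training.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import _autodiff as ad
from ._autodiff import Tensor
from .r2sn import CLASSES, MetabolicGraph


@dataclass
class ModelConfig:
    n_nodes: int = 96
    d_model: int = 36
    n_layers: int = 3
    n_heads: int = 4
    d_k: int = 24
    d_v: int = 32
    d_ffn: int = 144
    head_dims: tuple[int, ...] = (128, 64, 3)
    head_dropout: float = 0.3
    n_structure_tokens: int = 1
    topk_neighbors: int = 8
    attention_masking: str = "hybrid"  # "hybrid" | "global" | "topk"
    renormalize_after_hadamard: bool = False
    projection_dims: tuple[int, int] = (64, 32)
    seed: int = 0

    def __post_init__(self):
        dims = [self.n_nodes, self.d_model, self.n_layers, self.n_heads,
                self.d_k, self.d_v, self.d_ffn, *self.head_dims]
        if any(d <= 0 for d in dims):
            raise ValueError("all model dimensions must be positive")
        if self.attention_masking not in ("hybrid", "global", "topk"):
            raise ValueError(f"bad attention_masking {self.attention_masking!r}")

    @property
    def pool_concat_dim(self) -> int:
        return self.n_layers * self.d_model

    def to_dict(self) -> dict:
        d = asdict(self)
        d["head_dims"] = list(self.head_dims)
        d["projection_dims"] = list(self.projection_dims)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        d["head_dims"] = tuple(d.get("head_dims", (128, 64, 3)))
        d["projection_dims"] = tuple(d.get("projection_dims", (64, 32)))
        return cls(**d)


class ModelParams:
    """Flat name -> Tensor store of every learnable array."""

    def __init__(self, tensors: dict[str, Tensor]):
        self.tensors = tensors

    def __getitem__(self, name: str) -> Tensor:
        return self.tensors[name]

    def items(self):
        return self.tensors.items()

    def names(self):
        return list(self.tensors)

    def zero_grad(self):
        for t in self.tensors.values():
            t.grad = None

    def l2_sum(self) -> Tensor:
        total = None
        for t in self.tensors.values():
            sq = (t * t).sum()
            total = sq if total is None else total + sq
        return total

    def checksum(self) -> str:
        h = hashlib.sha256()
        for name in sorted(self.tensors):
            h.update(name.encode())
            h.update(np.ascontiguousarray(self.tensors[name].data).tobytes())
        return h.hexdigest()

    def copy(self) -> "ModelParams":
        return ModelParams({k: Tensor(v.data.copy())
                            for k, v in self.tensors.items()})


def init_params(config: ModelConfig) -> ModelParams:
    """Glorot-style initialisation, fully reproducible from ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    t: dict[str, Tensor] = {}

    def glorot(*shape):
        fan_in, fan_out = shape[-2], shape[-1]
        sd = np.sqrt(2.0 / (fan_in + fan_out))
        return Tensor(rng.normal(0.0, sd, size=shape))

    d, dk, dv, dffn = (config.d_model, config.d_k, config.d_v, config.d_ffn)
    for l in range(config.n_layers):
        p = f"layers.{l}"
        for h in range(config.n_heads):
            t[f"{p}.Wq.{h}"] = glorot(d, dk)
            t[f"{p}.Wk.{h}"] = glorot(d, dk)
            t[f"{p}.Wv.{h}"] = glorot(d, dv)
        t[f"{p}.Wo"] = glorot(config.n_heads * dv, d)
        t[f"{p}.tokens"] = Tensor(rng.normal(0.0, 0.02,
                                             size=(config.n_structure_tokens, d)))
        t[f"{p}.Wg"] = glorot(2 * d, d)
        t[f"{p}.W1"] = glorot(d, dffn)
        t[f"{p}.b1"] = Tensor(np.zeros(dffn))
        t[f"{p}.W2"] = glorot(dffn, d)
        t[f"{p}.b2"] = Tensor(np.zeros(d))
        t[f"{p}.ln_gamma"] = Tensor(np.ones(d))
        t[f"{p}.ln_beta"] = Tensor(np.zeros(d))

    dims = (config.pool_concat_dim, *config.head_dims)
    for i in range(len(config.head_dims)):
        t[f"head.{i}.ln_gamma"] = Tensor(np.ones(dims[i]))
        t[f"head.{i}.ln_beta"] = Tensor(np.zeros(dims[i]))
        t[f"head.{i}.W"] = glorot(dims[i], dims[i + 1])
        t[f"head.{i}.b"] = Tensor(np.zeros(dims[i + 1]))

    pdims = (config.pool_concat_dim, *config.projection_dims)
    for i in range(len(config.projection_dims)):
        t[f"proj.{i}.W"] = glorot(pdims[i], pdims[i + 1])
        t[f"proj.{i}.b"] = Tensor(np.zeros(pdims[i + 1]))
    return ModelParams(t)


# ---------------------------------------------------------------------------
# sparsification and masks
# ---------------------------------------------------------------------------

def topk_sparsify(weights: np.ndarray, k: int) -> np.ndarray:
    """Binary mask keeping each node's k strongest neighbours.

    Per row, the k largest off-diagonal weights are kept (ties broken in
    favour of the lower node index); the mask is symmetrised by union and
    the diagonal is always kept.
    """
    n = weights.shape[0]
    if weights.shape != (n, n):
        raise ValueError("weights must be square")
    if k >= n:
        warnings.warn(f"topk_sparsify: k={k} >= n={n}; returning full mask")
        return np.ones((n, n), dtype=bool)
    neg = -weights.copy()
    np.fill_diagonal(neg, np.inf)
    # stable sort on -weight: equal weights keep increasing-index order,
    # so ties break in favour of the lower node index
    order = np.argsort(neg, axis=1, kind="stable")
    mask = np.zeros((n, n), dtype=bool)
    np.put_along_axis(mask, order[:, :k], True, axis=1)
    mask |= mask.T
    np.fill_diagonal(mask, True)
    return mask


def layer_masks(weights: np.ndarray, config: ModelConfig) -> list[np.ndarray | None]:
    """Per-layer attention masks: layer 1 global, deeper layers TopK
    (``attention_masking="hybrid"``, the default)."""
    if config.attention_masking == "global":
        return [None] * config.n_layers
    topk = topk_sparsify(weights, config.topk_neighbors)
    if config.attention_masking == "topk":
        return [topk] * config.n_layers
    return [None] + [topk] * (config.n_layers - 1)


# ---------------------------------------------------------------------------
# forward components (batched: leading axis = graphs in the batch)
# ---------------------------------------------------------------------------

def gated_structure_fusion(X: Tensor, tokens: Tensor, Wg: Tensor,
                           active: np.ndarray | None = None) -> Tensor:
    """Blend the (mean) structure token into each node through a gate.

    ``active`` optionally restricts fusion to nodes incident to at least
    one retained edge; isolated nodes pass through unchanged.
    """
    s = tokens.mean(axis=0)  # [d]
    s_b = X * 0.0 + s  # broadcast to X's shape, grads flow to s only
    g = ad.sigmoid(ad.concat([X, s_b], axis=-1) @ Wg)
    fused = g * X + (1.0 - g) * s_b
    if active is not None and not active.all():
        a = active.astype(np.float64)[..., None]
        fused = fused * a + X * (1.0 - a)
    return fused


def graph_attention(X: Tensor, weights: np.ndarray, mask: np.ndarray | None,
                    params: ModelParams, layer: int, config: ModelConfig,
                    attn_dropout: np.ndarray | None = None
                    ) -> tuple[Tensor, list[np.ndarray]]:
    """Multi-head scaled dot-product attention with adjacency Hadamard.

    Returns the projected output and the per-head pre-Hadamard attention
    maps (rows summing to 1 over unmasked keys).
    """
    if not np.isfinite(X.data).all() or not np.isfinite(weights).all():
        raise ValueError("non-finite inputs to attention")
    p = f"layers.{layer}"
    scale = 1.0 / np.sqrt(config.d_k)
    head_outs, alphas = [], []
    W = np.asarray(weights, dtype=np.float64)
    for h in range(config.n_heads):
        # scaling applied to Q (n x d_k) rather than the n x n scores
        Q = (X @ params[f"{p}.Wq.{h}"]) * scale
        K = X @ params[f"{p}.Wk.{h}"]
        V = X @ params[f"{p}.Wv.{h}"]
        scores = Q @ K.transpose_last()
        drop = attn_dropout[h] if attn_dropout is not None else None
        if config.renormalize_after_hadamard:
            alpha_t = ad.masked_softmax(scores, mask)
            alphas.append(alpha_t.data)
            if drop is not None:
                alpha_t = alpha_t * drop
            eff = alpha_t * W
            row = eff.sum(axis=-1, keepdims=True) + 1e-12
            head_outs.append((eff * row ** -1.0) @ V)
        else:
            # Hadamard with edge weights; no renormalisation
            ctx, alpha = ad.fused_attention(scores, V, mask, W, drop)
            alphas.append(alpha)
            head_outs.append(ctx)
    return ad.concat(head_outs, axis=-1) @ params[f"layers.{layer}.Wo"], alphas


def feed_forward(X: Tensor, W1: Tensor, b1: Tensor, W2: Tensor,
                 b2: Tensor) -> Tensor:
    return ad.gelu(X @ W1 + b1) @ W2 + b2


def transformer_layer(X: Tensor, weights: np.ndarray, mask: np.ndarray | None,
                      params: ModelParams, layer: int, config: ModelConfig,
                      attn_dropout: np.ndarray | None = None
                      ) -> tuple[Tensor, list[np.ndarray]]:
    """fusion -> attention + FFN -> one post-LayerNorm over the 3-term sum."""
    p = f"layers.{layer}"
    active = None
    if mask is not None:
        off = mask.copy()
        n = off.shape[-1]
        off[..., np.arange(n), np.arange(n)] = False
        active = off.any(axis=-1)
    Xf = gated_structure_fusion(X, params[f"{p}.tokens"], params[f"{p}.Wg"],
                                active)
    att, alphas = graph_attention(Xf, weights, mask, params, layer, config,
                                  attn_dropout)
    ffn = feed_forward(Xf, params[f"{p}.W1"], params[f"{p}.b1"],
                       params[f"{p}.W2"], params[f"{p}.b2"])
    out = ad.layer_norm(Xf + att + ffn, params[f"{p}.ln_gamma"],
                        params[f"{p}.ln_beta"])
    return out, alphas


@dataclass
class ForwardTrace:
    """Cached intermediates of one forward pass (single graph)."""

    node_reprs: list[np.ndarray]  # per layer [96, d]
    attention: list[np.ndarray]  # per layer [heads, 96, 96], pre-Hadamard
    h_pool: list[np.ndarray]  # per layer [d]
    h_concat: np.ndarray  # [n_layers * d]
    probs: np.ndarray  # [3]
    embedding: np.ndarray  # unit-norm SupCon projection
    # tape handles for the explainer
    input_tensor: Tensor = field(repr=False, default=None)
    logp_tensor: Tensor = field(repr=False, default=None)

    @property
    def predicted_class(self) -> str:
        return CLASSES[int(np.argmax(self.probs))]


def _head_and_projection(hcat: Tensor, params: ModelParams, config: ModelConfig,
                         fc_dropout: list[np.ndarray] | None = None
                         ) -> tuple[Tensor, Tensor, Tensor]:
    """MLP head (LayerNorm, dropout, linear; GELU between layers) and the
    SupCon projection.  Returns (probs, logp, z)."""
    a = hcat
    n_lin = len(config.head_dims)
    for i in range(n_lin):
        a = ad.layer_norm(a, params[f"head.{i}.ln_gamma"],
                          params[f"head.{i}.ln_beta"])
        if fc_dropout is not None:
            a = a * fc_dropout[i]
        a = a @ params[f"head.{i}.W"] + params[f"head.{i}.b"]
        if i < n_lin - 1:
            a = ad.gelu(a)
    probs = ad.masked_softmax(a, None)
    logp = ad.log(ad.clip_min(probs, 1e-12))

    z = hcat
    n_proj = len(config.projection_dims)
    for i in range(n_proj):
        z = z @ params[f"proj.{i}.W"] + params[f"proj.{i}.b"]
        if i < n_proj - 1:
            z = ad.gelu(z)
    norm = ((z * z).sum(axis=-1, keepdims=True) + 1e-12) ** 0.5
    z = z * norm ** -1.0
    return probs, logp, z


def forward_batch(params: ModelParams, config: ModelConfig,
                  X0: np.ndarray, weights: np.ndarray,
                  masks: list[np.ndarray | None],
                  dropout_masks: dict | None = None) -> dict:
    """Run the network on a stacked batch ([B, n, d], [B, n, n]).

    ``dropout_masks`` (training only) holds pre-drawn multiplier arrays:
    ``attn`` per layer [heads, B, n, n] and ``fc`` per head linear [B, dim].
    Returns tape tensors keyed by name.
    """
    if X0.shape[-2:] != (config.n_nodes, config.d_model):
        raise ValueError(
            f"input shape {X0.shape} does not match model dims "
            f"({config.n_nodes}, {config.d_model})")
    Xin = Tensor(np.asarray(X0, dtype=np.float64))
    X = Xin
    pools, all_alphas = [], []
    for l in range(config.n_layers):
        attn_drop = dropout_masks["attn"][l] if dropout_masks else None
        X, alphas = transformer_layer(X, weights, masks[l], params, l, config,
                                      attn_drop)
        pools.append(ad.max_pool_nodes(X, axis=-2))
        all_alphas.append(alphas)
    hcat = ad.concat(pools, axis=-1)
    fc_drop = dropout_masks["fc"] if dropout_masks else None
    probs, logp, z = _head_and_projection(hcat, params, config, fc_drop)
    return {"input": Xin, "pools": pools, "h_concat": hcat, "probs": probs,
            "logp": logp, "z": z, "alphas": all_alphas, "last_X": X}


def forward(graph: MetabolicGraph, params: ModelParams,
            config: ModelConfig) -> ForwardTrace:
    """Inference-mode forward pass on a single graph, caching the
    per-layer node representations and attention maps for the explainer."""
    if graph.n_nodes != config.n_nodes:
        raise ValueError(f"graph has {graph.n_nodes} nodes, "
                         f"model expects {config.n_nodes}")
    if graph.node_features.shape[1] != config.d_model:
        raise ValueError(
            f"graph features have dim {graph.node_features.shape[1]}, "
            f"model expects {config.d_model}")
    masks = layer_masks(graph.weights, config)
    X0 = graph.node_features[None]
    W = graph.weights[None]
    out = forward_batch(params, config, X0, W, masks)

    attention = []
    for l in range(config.n_layers):
        attention.append(np.stack(
            [a[0] for a in out["alphas"][l]], axis=0))
    # recover per-layer node representations by replaying shapes
    # (pools were taken from each layer output; store the reprs directly)
    node_reprs = _collect_layer_reprs(out, config)
    return ForwardTrace(
        node_reprs=node_reprs,
        attention=attention,
        h_pool=[p.data[0] for p in out["pools"]],
        h_concat=out["h_concat"].data[0],
        probs=out["probs"].data[0],
        embedding=out["z"].data[0],
        input_tensor=out["input"],
        logp_tensor=out["logp"],
    )


def _collect_layer_reprs(out: dict, config: ModelConfig) -> list[np.ndarray]:
    # each pool's parent chain starts at the layer output tensor
    reprs = []
    for p in out["pools"]:
        layer_out = p._parents[0]
        reprs.append(layer_out.data[0])
    return reprs


# ---------------------------------------------------------------------------
# checkpointing
# ---------------------------------------------------------------------------

CHECKPOINT_SCHEMA = 1


def save_checkpoint(path: str | Path, params: ModelParams,
                    config: ModelConfig, meta: dict | None = None) -> None:
    arrays = {f"param::{k}": v.data for k, v in params.items()}
    header = json.dumps({
        "schema": CHECKPOINT_SCHEMA,
        "config": config.to_dict(),
        "meta": meta or {},
    })
    np.savez(path, __header__=np.frombuffer(header.encode(), dtype=np.uint8),
             **arrays)


def load_checkpoint(path: str | Path) -> tuple[ModelParams, ModelConfig, dict]:
    with np.load(path) as npz:
        header = json.loads(bytes(npz["__header__"]).decode())
        if header.get("schema") != CHECKPOINT_SCHEMA:
            raise ValueError(f"unsupported checkpoint schema: {header.get('schema')}")
        tensors = {k[len("param::"):]: Tensor(npz[k])
                   for k in npz.files if k.startswith("param::")}
    config = ModelConfig.from_dict(header["config"])
    return ModelParams(tensors), config, header["meta"]
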