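"""Training protocol: composite loss, schedule, regularisation, optimiser.

The objective is ``L = CE + 1e-4 * ||theta||^2 + 0.2 * L_SupCon`` where
``L_SupCon`` is the supervised contrastive loss at temperature 0.07 over
unit-norm projection embeddings.  Optimisation uses Adam with a linear
warmup (0 -> 5e-4 over 5 epochs) followed by cosine decay to 1e-6, global
gradient-norm clipping at 3.0, stratified batches of 32, and early
stopping on validation loss with patience 10 (best weights restored).
A two-stage mode first trains on a pre-training cohort of clinically
possible cases, then fine-tunes on the definite-diagnosis cohort with a
fresh schedule.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from . import _autodiff as ad
from ._autodiff import Tensor
from .model import (ModelConfig, ModelParams, forward_batch, init_params,
                    layer_masks)
from .r2sn import CLASSES, MetabolicGraph


@dataclass
class TrainConfig:
    lambda_l2: float = 1e-4
    lambda_supcon: float = 0.2
    temperature: float = 0.07
    lr_peak: float = 5e-4
    lr_floor: float = 1e-6
    warmup_epochs: int = 5
    max_epochs: int = 200
    batch_size: int = 32
    clip_norm: float = 3.0
    patience: int = 10
    node_feature_dropout: float = 0.15
    attention_dropout: float = 0.10
    fc_dropout: float = 0.40
    edge_noise_fraction: float = 0.10
    edge_noise_sigma: float = 0.05
    val_fraction: float = 0.15
    seed: int = 0

    def __post_init__(self):
        rates = [self.node_feature_dropout, self.attention_dropout,
                 self.fc_dropout, self.edge_noise_fraction, self.val_fraction]
        if any(not 0.0 <= r <= 1.0 for r in rates):
            raise ValueError("all rates must lie in [0, 1]")
        if self.lr_floor >= self.lr_peak:
            raise ValueError("lr_floor must be below lr_peak")
        if self.patience >= self.max_epochs:
            raise ValueError("patience must be below max_epochs")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class LossBreakdown:
    total: float
    cross_entropy: float
    l2_penalty: float
    supcon: float
    total_tensor: Tensor = field(repr=False, default=None)
    embeddings: np.ndarray = field(repr=False, default=None)


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------

def supcon_loss(z: Tensor, labels: np.ndarray, temperature: float = 0.07) -> Tensor:
    """Supervised contrastive loss over unit-norm embeddings.

    For each anchor i with positive set P(i) (same-label, not itself):
    ``-(1/|P(i)|) sum_p log[exp(z_i.z_p/t) / sum_{a != i} exp(z_i.z_a/t)]``
    averaged over anchors with a non-empty positive set.  Returns 0 (with
    a warning) when no anchor has a positive.
    """
    labels = np.asarray(labels)
    B = labels.shape[0]
    same = labels[:, None] == labels[None, :]
    notself = ~np.eye(B, dtype=bool)
    pos = same & notself
    n_pos = pos.sum(axis=1)
    valid = n_pos > 0
    if not valid.any():
        import warnings
        warnings.warn("supcon_loss: no anchor has a positive pair; loss = 0")
        return Tensor(0.0)

    sim = (z @ z.transpose_last()) * (1.0 / temperature)  # [B, B]
    m = sim.data.max(axis=-1, keepdims=True)  # constant shift for stability
    e = ad.exp(sim - m) * notself.astype(np.float64)
    log_denom = ad.log(e.sum(axis=-1, keepdims=True)) + m  # [B, 1]
    log_prob = sim - log_denom  # log_prob[i, p]
    per_anchor = (log_prob * pos.astype(np.float64)).sum(axis=-1)
    inv_np = np.where(valid, 1.0 / np.maximum(n_pos, 1), 0.0)
    loss = -(per_anchor * inv_np).sum() * (1.0 / valid.sum())
    return loss


def cross_entropy(logp: Tensor, labels: np.ndarray) -> Tensor:
    """Mean negative log-likelihood of the true classes."""
    B, C = logp.shape
    onehot = np.zeros((B, C))
    onehot[np.arange(B), labels] = 1.0
    return -(logp * onehot).sum() * (1.0 / B)


def composite_loss(logp: Tensor, labels: np.ndarray, params: ModelParams,
                   z: Tensor | None, config: TrainConfig,
                   supcon_active: bool = True) -> LossBreakdown:
    """CE + lambda_l2 * ||theta||^2 + lambda_supcon * SupCon."""
    labels = np.asarray(labels)
    ce = cross_entropy(logp, labels)
    l2 = params.l2_sum() * config.lambda_l2
    if supcon_active and z is not None and len(labels) >= 2:
        sc = supcon_loss(z, labels, config.temperature)
    else:
        sc = Tensor(0.0)
    total = ce + l2 + sc * config.lambda_supcon
    if not np.isfinite(total.data):
        raise FloatingPointError("non-finite training loss")
    return LossBreakdown(
        total=float(total.data), cross_entropy=float(ce.data),
        l2_penalty=float(l2.data), supcon=float(sc.data),
        total_tensor=total,
        embeddings=None if z is None else z.data.copy())


# ---------------------------------------------------------------------------
# schedule and regularisation
# ---------------------------------------------------------------------------

def lr_at_step(epoch: float, config: TrainConfig) -> float:
    """Linear warmup then cosine decay, continuous at the warmup boundary."""
    w, m = config.warmup_epochs, config.max_epochs
    if epoch < 0 or epoch > m:
        raise ValueError(f"epoch {epoch} outside [0, {m}]")
    if epoch < w:
        return config.lr_peak * epoch / w
    span = m - w
    frac = (epoch - w) / span
    return config.lr_floor + (config.lr_peak - config.lr_floor) * \
        (1.0 + np.cos(np.pi * frac)) / 2.0


def apply_regularization(X: np.ndarray, weights: np.ndarray, mode: str,
                         config: TrainConfig, rng: np.random.Generator
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Input-level stochastic regularisation of a stacked batch.

    Train mode: (1) whole node-feature rows are zeroed with probability
    0.15 and survivors rescaled by 1/(1-p); (2) a random 10% of
    off-diagonal edges (per undirected pair) receive Gaussian noise,
    clipped back to [0, 1] and re-symmetrised.  Attention dropout (0.1)
    and FC-head dropout (0.4) are drawn separately by the train loop and
    applied inside the forward pass.  Eval mode is the identity.
    """
    if mode == "eval":
        return X, weights
    if mode != "train":
        raise ValueError(f"mode must be 'train' or 'eval', got {mode!r}")
    B, n, _ = X.shape
    p = config.node_feature_dropout
    keep = rng.random((B, n, 1)) >= p
    Xr = X * keep / (1.0 - p)

    W = weights.copy()
    iu, ju = np.triu_indices(n, k=1)
    for b in range(B):
        hit = rng.random(iu.shape[0]) < config.edge_noise_fraction
        noise = rng.normal(0.0, config.edge_noise_sigma, size=hit.sum())
        vals = W[b, iu[hit], ju[hit]] + noise
        vals = np.clip(vals, 0.0, 1.0)
        W[b, iu[hit], ju[hit]] = vals
        W[b, ju[hit], iu[hit]] = vals
    return Xr, W


def _dropout_masks(config: ModelConfig, tcfg: TrainConfig, B: int,
                   rng: np.random.Generator) -> dict:
    n, H = config.n_nodes, config.n_heads
    pa, pf = tcfg.attention_dropout, tcfg.fc_dropout
    attn = [
        (rng.random((H, B, n, n)) >= pa) / (1.0 - pa)
        for _ in range(config.n_layers)
    ]
    dims = (config.pool_concat_dim, *config.head_dims[:-1])
    fc = [(rng.random((B, d)) >= pf) / (1.0 - pf) for d in dims]
    return {"attn": attn, "fc": fc}


# ---------------------------------------------------------------------------
# optimiser
# ---------------------------------------------------------------------------

class Adam:
    """Adam with global gradient-norm clipping."""

    def __init__(self, params: ModelParams, clip_norm: float = 3.0,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.clip_norm = clip_norm
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = {k: np.zeros_like(t.data) for k, t in params.items()}
        self.v = {k: np.zeros_like(t.data) for k, t in params.items()}
        self.t = 0
        self.last_grad_norm = 0.0

    def step(self, lr: float):
        grads = {}
        sq = 0.0
        for k, tensor in self.params.items():
            g = tensor.grad if tensor.grad is not None else np.zeros_like(tensor.data)
            grads[k] = g
            sq += float((g * g).sum())
        norm = np.sqrt(sq)
        scale = min(1.0, self.clip_norm / norm) if norm > 0 else 1.0
        self.last_grad_norm = norm * scale
        self.t += 1
        b1t = 1.0 - self.beta1 ** self.t
        b2t = 1.0 - self.beta2 ** self.t
        for k, tensor in self.params.items():
            g = grads[k] * scale
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * g * g
            mhat = self.m[k] / b1t
            vhat = self.v[k] / b2t
            tensor.data -= lr * mhat / (np.sqrt(vhat) + self.eps)


# ---------------------------------------------------------------------------
# train loop
# ---------------------------------------------------------------------------

def _stack(graphs: list[MetabolicGraph]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    X = np.stack([g.node_features for g in graphs])
    W = np.stack([g.weights for g in graphs])
    y = np.array([CLASSES.index(g.label) for g in graphs])
    return X, W, y


def _stacked_masks(W: np.ndarray, config: ModelConfig) -> list[np.ndarray | None]:
    per_graph = [layer_masks(w, config) for w in W]
    out = []
    for l in range(config.n_layers):
        if per_graph[0][l] is None:
            out.append(None)
        else:
            out.append(np.stack([m[l] for m in per_graph]))
    return out


def _stratified_val_split(labels: np.ndarray, frac: float,
                          rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    train_idx, val_idx = [], []
    for c in np.unique(labels):
        idx = np.flatnonzero(labels == c)
        idx = rng.permutation(idx)
        n_val = max(1, int(round(frac * len(idx)))) if frac > 0 else 0
        if n_val >= len(idx):
            raise ValueError(f"validation split empties class {CLASSES[c]}")
        val_idx.extend(idx[:n_val])
        train_idx.extend(idx[n_val:])
    return np.sort(train_idx), np.sort(val_idx)


def _stratified_batches(labels: np.ndarray, batch_size: int,
                        rng: np.random.Generator) -> list[np.ndarray]:
    """Class-balanced batch composition without replacement per epoch."""
    per_class = {c: list(rng.permutation(np.flatnonzero(labels == c)))
                 for c in np.unique(labels)}
    n_total = len(labels)
    n_batches = int(np.ceil(n_total / batch_size))
    props = {c: len(v) / n_total for c, v in per_class.items()}
    batches = []
    for _ in range(n_batches):
        batch = []
        for c, pool in per_class.items():
            take = int(round(props[c] * batch_size))
            batch.extend(pool[:take])
            del pool[:take]
        batches.append(batch)
    # distribute leftovers
    leftovers = [i for pool in per_class.values() for i in pool]
    for i, item in enumerate(leftovers):
        batches[i % len(batches)].append(item)
    return [np.array(sorted(b)) for b in batches if len(b) >= 2]


def evaluate_loss(params: ModelParams, config: ModelConfig,
                  tcfg: TrainConfig, X: np.ndarray, W: np.ndarray,
                  y: np.ndarray, masks) -> tuple[float, float, float]:
    """(composite loss, cross-entropy, accuracy) in eval mode."""
    out = forward_batch(params, config, X, W, masks)
    lb = composite_loss(out["logp"], y, params, out["z"], tcfg,
                        supcon_active=len(np.unique(y)) >= 2)
    acc = float((np.argmax(out["probs"].data, axis=-1) == y).mean())
    return lb.total, lb.cross_entropy, acc


def train(cohort: list[MetabolicGraph], model_config: ModelConfig,
          train_config: TrainConfig,
          init: ModelParams | None = None,
          callback=None,
          restore_best: bool = True) -> tuple[ModelParams, list[dict]]:
    """Fit the classifier on a labelled cohort of metabolic graphs.

    Deterministic given the two configs' seeds.  Returns the best-on-
    validation parameters (or the final parameters if ``restore_best`` is
    False, e.g. for capacity/overfitting checks) and a per-epoch history.
    ``callback`` receives each epoch's record; returning a truthy value
    requests an early exit.
    """
    X_all, W_all, y_all = _stack(cohort)
    if len(np.unique(y_all)) < 2:
        raise ValueError("training requires at least 2 classes")
    rng = np.random.default_rng(train_config.seed)
    tr_idx, va_idx = _stratified_val_split(y_all, train_config.val_fraction, rng)
    Xtr, Wtr, ytr = X_all[tr_idx], W_all[tr_idx], y_all[tr_idx]
    Xva, Wva, yva = X_all[va_idx], W_all[va_idx], y_all[va_idx]
    val_masks = _stacked_masks(Wva, model_config)
    # TopK masks encode each graph's structure: computed once from the
    # clean weights, not from the noise-perturbed copies seen in training
    train_masks = _stacked_masks(Wtr, model_config)

    params = init.copy() if init is not None else init_params(model_config)
    opt = Adam(params, clip_norm=train_config.clip_norm)
    best = params.copy()
    best_val = np.inf  # raw monitor: decides which weights are kept
    best_smooth = np.inf  # smoothed monitor: decides when to stop
    smooth = None
    since_improve = 0
    history: list[dict] = []

    for epoch in range(train_config.max_epochs):
        lr = lr_at_step(epoch, train_config)
        batch_losses = []
        for batch in _stratified_batches(ytr, train_config.batch_size, rng):
            Xb, Wb, yb = Xtr[batch], Wtr[batch], ytr[batch]
            Xb, Wb = apply_regularization(Xb, Wb, "train", train_config, rng)
            masks = [None if m is None else m[batch] for m in train_masks]
            drop = _dropout_masks(model_config, train_config, len(batch), rng)
            out = forward_batch(params, model_config, Xb, Wb, masks, drop)
            lb = composite_loss(out["logp"], yb, params, out["z"], train_config,
                                supcon_active=len(np.unique(yb)) >= 2)
            params.zero_grad()
            lb.total_tensor.backward()
            opt.step(lr)
            batch_losses.append(lb)

        val_loss, val_ce, val_acc = evaluate_loss(
            params, model_config, train_config, Xva, Wva, yva, val_masks)
        rec = {
            "epoch": epoch, "lr": lr,
            "train_total": float(np.mean([b.total for b in batch_losses])),
            "train_ce": float(np.mean([b.cross_entropy for b in batch_losses])),
            "train_supcon": float(np.mean([b.supcon for b in batch_losses])),
            "train_l2": float(np.mean([b.l2_penalty for b in batch_losses])),
            "grad_norm": opt.last_grad_norm,
            "val_loss": val_loss, "val_ce": val_ce, "val_acc": val_acc,
        }
        history.append(rec)
        if callback is not None and callback({**rec, "params": params}):
            break
        # early stopping monitors the validation classification loss; the
        # L2 term is data-independent and the contrastive term is a
        # training-batch construct, so neither belongs in the monitor.
        # Monitoring starts only after LR warmup: while lr ~ 0 the model
        # cannot improve and a lucky validation draw would otherwise
        # become the benchmark that patience counts against.  Patience
        # runs on an exponentially smoothed series: with small validation
        # splits the raw loss wobbles by more per epoch than the true
        # loss moves.  Best weights still track the raw minimum.
        if epoch < train_config.warmup_epochs:
            best = params.copy()  # burn-in: carry the latest state forward
            continue
        if val_ce < best_val - 1e-12:
            best_val = val_ce
            best = params.copy()
        smooth = val_ce if smooth is None else 0.7 * smooth + 0.3 * val_ce
        if smooth < best_smooth - 1e-12:
            best_smooth = smooth
            since_improve = 0
        else:
            since_improve += 1
            if since_improve >= train_config.patience:
                break
    return (best if restore_best else params), history


def pretrain_finetune(pretrain_cohort: list[MetabolicGraph],
                      finetune_cohort: list[MetabolicGraph],
                      model_config: ModelConfig,
                      pretrain_config: TrainConfig,
                      finetune_config: TrainConfig | None = None
                      ) -> tuple[ModelParams, dict]:
    """Two-stage protocol: preliminary training on the clinically possible
    cohort, then fine-tuning from those weights with a fresh schedule."""
    finetune_config = finetune_config or pretrain_config
    logs: dict = {}
    if pretrain_cohort:
        stage1, h1 = train(pretrain_cohort, model_config, pretrain_config)
        logs["pretrain"] = h1
    else:
        stage1 = None
        logs["pretrain"] = []
    best, h2 = train(finetune_cohort, model_config, finetune_config,
                     init=stage1)
    logs["finetune"] = h2
    return best, logs


def predict(params: ModelParams, config: ModelConfig,
            graphs: list[MetabolicGraph]) -> np.ndarray:
    """Predicted class labels for a list of graphs."""
    X, W, _ = np.stack([g.node_features for g in graphs]), \
        np.stack([g.weights for g in graphs]), None
    masks = _stacked_masks(W, config)
    out = forward_batch(params, config, X, W, masks)
    return np.array([CLASSES[i] for i in np.argmax(out["probs"].data, axis=-1)])
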