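"""Reproducible benchmark experiments on synthetic cohorts.

Every function is deterministic given its seed and recomputes its
quantities from scratch by running the package's own pipeline:
structural checks of the similarity network, oracle comparisons for the
model components, gradient verification, the capacity (overfitting)
check, multi-seed classification recovery, explainer ground-truth
recovery, and empirical regularisation rates.  Both the test suite and
``scripts/acceptance.py`` drive these.
"""

from __future__ import annotations

import time

import numpy as np
from scipy.special import erf
from scipy.stats import rankdata, wilcoxon

from . import _autodiff as ad
from ._autodiff import Tensor
from .evaluation import aggregate_over_seeds, evaluate_predictions, \
    stratified_split
from .explain import (explain_group, explain_subject, jaccard_similarity,
                      node_importance, retain_top_edges)
from .model import (ModelConfig, forward_batch, graph_attention, init_params,
                    topk_sparsify)
from .pipeline import prepare_graphs
from .r2sn import CLASSES, RadiomicTable, build_r2sn
from .synthetic import CohortSpec, generate_cohort
from .training import (TrainConfig, apply_regularization, composite_loss,
                       lr_at_step, predict, supcon_loss, train)


def _sub_seed(seed: int, k: int) -> int:
    return (seed * 1009 + k) % (2 ** 31 - 1)


# ---------------------------------------------------------------------------
# structural checks
# ---------------------------------------------------------------------------

def r2sn_structure_check(seed: int, n_subjects: int = 20) -> dict:
    """Build graphs from random valid tables; verify the matrix contract
    and measure per-subject build time."""
    rng = np.random.default_rng(seed)
    max_asym = 0.0
    max_diag_err = 0.0
    out_of_range = 0
    t0 = time.perf_counter()
    for i in range(n_subjects):
        vals = rng.normal(size=(96, 36))
        t = RadiomicTable(f"s{i}", vals, [f"f{k}" for k in range(36)])
        g = build_r2sn(t)
        max_asym = max(max_asym, np.abs(g.weights - g.weights.T).max())
        max_diag_err = max(max_diag_err,
                           np.abs(np.diag(g.weights) - 1.0).max())
        out_of_range += int(((g.weights < 0) | (g.weights > 1)).sum())
    elapsed = time.perf_counter() - t0
    return {
        "n_subjects": n_subjects,
        "max_asymmetry": float(max_asym),
        "max_diagonal_error": float(max_diag_err),
        "entries_out_of_range": out_of_range,
        "seconds_per_subject": elapsed / n_subjects,
    }


def edge_retention_check() -> dict:
    """Cardinality of the default top-15% retained edge set on 96 nodes."""
    rng = np.random.default_rng(0)
    m = rng.uniform(size=(96, 96))
    m = (m + m.T) / 2
    kept = retain_top_edges(m, 0.15)
    return {"n_candidate_pairs": 96 * 95 // 2, "n_retained": len(kept),
            "retain_fraction": 0.15}


# ---------------------------------------------------------------------------
# oracle battery
# ---------------------------------------------------------------------------

def oracle_battery(seed: int) -> dict:
    """Each differentiable component vs an independent brute-force or
    closed-form oracle on <=10-node toys.  Returns per-component maximum
    absolute errors."""
    rng = np.random.default_rng(seed)
    errs: dict[str, float] = {}

    # Pearson entries vs elementwise covariance/sigma-sigma
    vals = rng.normal(size=(96, 6))
    g = build_r2sn(RadiomicTable("s", vals, [f"f{k}" for k in range(6)]))
    worst = 0.0
    for i in range(8):
        for j in range(8):
            x, y = vals[i], vals[j]
            num = ((x - x.mean()) * (y - y.mean())).sum()
            den = np.sqrt(((x - x.mean()) ** 2).sum()
                          * ((y - y.mean()) ** 2).sum())
            w = 1.0 if i == j else (num / den + 1) / 2
            worst = max(worst, abs(g.weights[i, j] - w))
    errs["pearson"] = worst

    # toy model pieces
    cfg = ModelConfig(n_nodes=6, d_model=5, n_layers=2, n_heads=2, d_k=3,
                      d_v=4, d_ffn=7, head_dims=(8, 4, 3), topk_neighbors=3,
                      projection_dims=(6, 4), seed=seed % 1000)
    params = init_params(cfg)
    X = rng.normal(size=(1, 6, 5))
    r = rng.uniform(-1, 1, size=(6, 6))
    W = ((r + r.T) / 2 + 1) / 2
    np.fill_diagonal(W, 1.0)
    mask = topk_sparsify(W, 3)

    # attention vs dense loop
    out, alphas = graph_attention(Tensor(X), W[None], mask, params, 0, cfg)
    heads = []
    for h in range(cfg.n_heads):
        Q = X[0] @ params[f"layers.0.Wq.{h}"].data
        K = X[0] @ params[f"layers.0.Wk.{h}"].data
        V = X[0] @ params[f"layers.0.Wv.{h}"].data
        ctx = np.zeros((6, cfg.d_v))
        for i in range(6):
            s = np.full(6, -np.inf)
            for j in range(6):
                if mask[i, j]:
                    s[j] = Q[i] @ K[j] / np.sqrt(cfg.d_k)
            e = np.where(np.isfinite(s), np.exp(s - s[np.isfinite(s)].max()),
                         0.0)
            a = e / e.sum()
            for j in range(6):
                ctx[i] += a[j] * W[i, j] * V[j]
        heads.append(ctx)
    expect = np.concatenate(heads, axis=1) @ params["layers.0.Wo"].data
    errs["attention"] = float(np.abs(out.data[0] - expect).max())

    # gated fusion vs formula
    s_tok = params["layers.0.tokens"].data.mean(axis=0)
    Wg = params["layers.0.Wg"].data
    from .model import gated_structure_fusion
    fused = gated_structure_fusion(Tensor(X), params["layers.0.tokens"],
                                   params["layers.0.Wg"])
    worst = 0.0
    for i in range(6):
        gate = 1 / (1 + np.exp(-(np.concatenate([X[0, i], s_tok]) @ Wg)))
        ref = gate * X[0, i] + (1 - gate) * s_tok
        worst = max(worst, np.abs(fused.data[0, i] - ref).max())
    errs["gated_fusion"] = worst

    # FFN vs scalar loop
    from .model import feed_forward
    ffn = feed_forward(Tensor(X), params["layers.0.W1"], params["layers.0.b1"],
                       params["layers.0.W2"], params["layers.0.b2"])
    pre = X[0] @ params["layers.0.W1"].data + params["layers.0.b1"].data
    act = pre * 0.5 * (1 + erf(pre / np.sqrt(2)))
    ref = act @ params["layers.0.W2"].data + params["layers.0.b2"].data
    errs["ffn"] = float(np.abs(ffn.data[0] - ref).max())

    # layer update vs step-by-step composition
    from .model import transformer_layer
    lay, _ = transformer_layer(Tensor(X), W[None], mask, params, 0, cfg)
    gate = 1 / (1 + np.exp(-(np.concatenate(
        [X[0], np.tile(s_tok, (6, 1))], axis=1) @ Wg)))
    Xf = gate * X[0] + (1 - gate) * s_tok
    att_ref = np.zeros((6, cfg.d_model))
    heads = []
    for h in range(cfg.n_heads):
        Q = Xf @ params[f"layers.0.Wq.{h}"].data
        K = Xf @ params[f"layers.0.Wk.{h}"].data
        V = Xf @ params[f"layers.0.Wv.{h}"].data
        sc = Q @ K.T / np.sqrt(cfg.d_k)
        sc[~mask] = -np.inf
        e = np.exp(sc - sc.max(axis=1, keepdims=True))
        e[~mask] = 0.0
        a = e / e.sum(axis=1, keepdims=True)
        heads.append((a * W) @ V)
    att_ref = np.concatenate(heads, axis=1) @ params["layers.0.Wo"].data
    pre = Xf @ params["layers.0.W1"].data + params["layers.0.b1"].data
    ffn_ref = (pre * 0.5 * (1 + erf(pre / np.sqrt(2)))) \
        @ params["layers.0.W2"].data + params["layers.0.b2"].data
    z = Xf + att_ref + ffn_ref
    ln = (z - z.mean(axis=1, keepdims=True)) / \
        np.sqrt(z.var(axis=1, keepdims=True) + 1e-5)
    errs["layer_update"] = float(np.abs(lay.data[0] - ln).max())

    # pooling: max over nodes
    pooled = ad.max_pool_nodes(lay, axis=-2)
    errs["pooling"] = float(np.abs(pooled.data[0] - lay.data[0].max(0)).max())

    # loss decomposition identity
    X4 = rng.normal(size=(4, 6, 5))
    W4 = np.tile(W, (4, 1, 1))
    out4 = forward_batch(params, cfg, X4, W4, [None, mask])
    tcfg = TrainConfig(seed=0)
    y = np.array([0, 0, 1, 2])
    lb = composite_loss(out4["logp"], y, params, out4["z"], tcfg)
    errs["loss_decomposition"] = abs(
        lb.total - (lb.cross_entropy + lb.l2_penalty + 0.2 * lb.supcon))

    # SupCon vs double loop
    z_np = rng.normal(size=(5, 4))
    z_np /= np.linalg.norm(z_np, axis=1, keepdims=True)
    labels = np.array([0, 0, 1, 1, 2])
    sc = supcon_loss(Tensor(z_np), labels, 0.07)
    total, n_anchor = 0.0, 0
    for i in range(5):
        pos = [p for p in range(5) if p != i and labels[p] == labels[i]]
        if not pos:
            continue
        n_anchor += 1
        denom = sum(np.exp(z_np[i] @ z_np[a] / 0.07)
                    for a in range(5) if a != i)
        total += -sum(np.log(np.exp(z_np[i] @ z_np[p] / 0.07) / denom)
                      for p in pos) / len(pos)
    errs["supcon"] = abs(float(sc.data) - total / n_anchor)

    # lr schedule vs closed form
    tc = TrainConfig(seed=0)
    worst = 0.0
    for e in np.linspace(0, 200, 41):
        if e < 5:
            ref = 5e-4 * e / 5
        else:
            ref = 1e-6 + (5e-4 - 1e-6) * (1 + np.cos(np.pi * (e - 5) / 195)) / 2
        worst = max(worst, abs(lr_at_step(e, tc) - ref))
    errs["lr_schedule"] = worst

    errs = {k: float(v) for k, v in errs.items()}
    errs["max_overall"] = max(errs.values())
    return errs


def gradient_check(seed: int, n_probes_per_group: int = 3) -> dict:
    """Analytic vs central-difference gradients on a 6-node toy."""
    cfg = ModelConfig(n_nodes=6, d_model=5, n_layers=2, n_heads=2, d_k=3,
                      d_v=4, d_ffn=7, head_dims=(8, 4, 3), topk_neighbors=3,
                      projection_dims=(6, 4), seed=seed % 1000)
    params = init_params(cfg)
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(4, 6, 5))
    r = rng.uniform(-1, 1, size=(4, 6, 6))
    W = ((r + r.transpose(0, 2, 1)) / 2 + 1) / 2
    for b in range(4):
        np.fill_diagonal(W[b], 1.0)
    masks = [None, np.stack([topk_sparsify(W[b], 3) for b in range(4)])]
    y = np.array([0, 0, 2, 1])
    tcfg = TrainConfig(seed=0)

    def loss():
        out = forward_batch(params, cfg, X, W, masks)
        return composite_loss(out["logp"], y, params, out["z"], tcfg)

    lb = loss()
    params.zero_grad()
    lb.total_tensor.backward()
    # eps balances truncation against roundoff; 1e-5 keeps both ~1e-8
    # for a loss of magnitude ~1
    eps = 1e-5
    worst = 0.0
    for name, t in params.items():
        grad = t.grad if t.grad is not None else np.zeros_like(t.data)
        flat, gflat = t.data.ravel(), grad.ravel()
        for i in rng.choice(flat.size,
                            size=min(n_probes_per_group, flat.size),
                            replace=False):
            orig = flat[i]
            flat[i] = orig + eps
            lp = loss().total
            flat[i] = orig - eps
            lm = loss().total
            flat[i] = orig
            fd = (lp - lm) / (2 * eps)
            rel = abs(fd - gflat[i]) / max(abs(fd), abs(gflat[i]), 1e-6)
            worst = max(worst, rel)
    return {"max_relative_error": float(worst),
            "n_parameter_groups": len(params.names())}


def schedule_endpoints() -> dict:
    tc = TrainConfig(seed=0)
    return {
        "lr_epoch_0": lr_at_step(0, tc),
        "lr_epoch_5": lr_at_step(5, tc),
        "lr_epoch_200": lr_at_step(200, tc),
        "warmup_boundary_jump": abs(lr_at_step(5 - 1e-9, tc)
                                    - lr_at_step(5 + 1e-9, tc)),
    }


# ---------------------------------------------------------------------------
# learning experiments
# ---------------------------------------------------------------------------

def capacity_experiment(seed: int, n_seeds: int = 5,
                        n_per_class: int = 10) -> dict:
    """Overfitting sanity: a small separable cohort must be fit to 100%
    training accuracy within the epoch budget (early stopping disabled,
    final weights kept)."""
    from .training import _stratified_val_split
    results = []
    for k in range(n_seeds):
        s = _sub_seed(seed, k)
        spec = CohortSpec(n_per_class=n_per_class, seed=s)
        graphs, _ = prepare_graphs(generate_cohort(spec).tables)
        mcfg = ModelConfig(seed=s)
        tcfg = TrainConfig(seed=s, max_epochs=200, patience=199)
        # training accuracy is measured on the subjects actually fitted,
        # i.e. excluding the internal early-stopping validation split
        y = np.array([CLASSES.index(g.label) for g in graphs])
        split_rng = np.random.default_rng(tcfg.seed)
        tr_idx, _ = _stratified_val_split(y, tcfg.val_fraction, split_rng)
        fitted = [graphs[i] for i in tr_idx]
        hit = {"epoch": None}

        def cb(rec):
            if rec["epoch"] % 5 == 4 or rec["epoch"] >= 198:
                preds = predict(rec["params"], mcfg, fitted)
                acc = float(np.mean([p == g.label
                                     for p, g in zip(preds, fitted)]))
                if acc == 1.0:
                    hit["epoch"] = rec["epoch"]
                    return True
            return False

        params, history = train(graphs, mcfg, tcfg, callback=cb,
                                restore_best=False)
        preds = predict(params, mcfg, fitted)
        acc = float(np.mean([p == g.label for p, g in zip(preds, fitted)]))
        results.append({"seed": s, "train_accuracy": acc,
                        "epochs": len(history),
                        "reached_at_epoch": hit["epoch"]})
    frac = float(np.mean([r["train_accuracy"] == 1.0 for r in results]))
    return {"runs": results, "success_fraction": frac, "n_seeds": n_seeds,
            "n_subjects": 3 * n_per_class}


def classification_recovery(seed: int, n_seeds: int = 5,
                            n_train_per_class: int = 50,
                            n_test_per_class: int = 15) -> dict:
    """Train/test the full pipeline on fresh default cohorts, one per
    seed; Table-style per-class metrics aggregated over seeds."""
    runs = []
    n_total = n_train_per_class + n_test_per_class
    for k in range(n_seeds):
        s = _sub_seed(seed, 100 + k)
        spec = CohortSpec(n_per_class=n_total, seed=s)
        cohort = generate_cohort(spec)
        labels = [t.label for t in cohort.tables]
        tr, te = stratified_split(
            cohort.tables, labels,
            (n_train_per_class / n_total, n_test_per_class / n_total), s)
        gtr, sel = prepare_graphs(tr)
        gte, _ = prepare_graphs(te, selection=sel)
        mcfg = ModelConfig(seed=s)
        tcfg = TrainConfig(seed=s)
        params, history = train(gtr, mcfg, tcfg)
        preds = predict(params, mcfg, gte)
        m = evaluate_predictions([g.label for g in gte], preds, seed=s)
        runs.append(m)
    agg = aggregate_over_seeds(runs)
    return {"aggregate": agg, "runs": runs,
            "macro_f1_mean": agg["macro_f1"]["mean"],
            "macro_f1_std": agg["macro_f1"]["std"],
            "chance_macro_f1": 100.0 / 3}


def explainer_recovery(seed: int, n_runs: int = 20,
                       n_per_class: int = 30) -> dict:
    """Ground-truth recovery of the attribution module.

    One model is trained on a planted cohort; node importance is computed
    for held-out subjects and the planted (affected) nodes' ranks are
    compared with the unaffected nodes' (Wilcoxon signed-rank over runs).
    Retained edge sets are compared within class (two disjoint held-out
    halves) and between classes via Jaccard similarity.
    """
    s = _sub_seed(seed, 777)
    spec = CohortSpec(n_per_class=n_per_class, seed=s)
    cohort = generate_cohort(spec)
    labels = [t.label for t in cohort.tables]
    tr, ho = stratified_split(cohort.tables, labels, (2 / 3, 1 / 3), s)
    gtr, sel = prepare_graphs(tr)
    gho, _ = prepare_graphs(ho, selection=sel)
    mcfg = ModelConfig(seed=s)
    tcfg = TrainConfig(seed=s)
    params, _ = train(gtr, mcfg, tcfg)

    rank_gaps = []
    for r in range(n_runs):
        g = gho[r % len(gho)]
        sig = cohort.truth[g.label]
        imp = node_importance(g, params, mcfg)
        ranks = rankdata(-imp)  # 1 = most important
        planted = [ranks[i - 1] for i in sorted(sig.affected_nodes)]
        others = [ranks[i] for i in range(96)
                  if (i + 1) not in sig.affected_nodes]
        rank_gaps.append(float(np.mean(others) - np.mean(planted)))
    w = wilcoxon(rank_gaps, alternative="greater")

    sets: dict[str, list] = {}
    for c in CLASSES:
        members = [g for g in gho if g.label == c]
        halves = (members[: len(members) // 2],
                  members[len(members) // 2:])
        sets[c] = []
        for half in halves:
            expls = [explain_subject(g, params, mcfg) for g in half]
            sets[c].append(explain_group(expls, c).retained_edges)
    within = [jaccard_similarity(sets[c][0], sets[c][1]) for c in CLASSES]
    between = [jaccard_similarity(sets[a][0], sets[b][0])
               for a in CLASSES for b in CLASSES if a < b]
    return {
        "n_runs": n_runs,
        "rank_gap_mean": float(np.mean(rank_gaps)),
        "rank_gaps_positive": int(sum(g > 0 for g in rank_gaps)),
        "wilcoxon_p": float(w.pvalue),
        "jaccard_within_mean": float(np.mean(within)),
        "jaccard_between_mean": float(np.mean(between)),
        "jaccard_within": within,
        "jaccard_between": between,
    }


def regularization_rates(seed: int, n_draws: int = 10000) -> dict:
    """Monte-Carlo of the stated stochastic-regularisation rates."""
    tcfg = TrainConfig(seed=0)
    rng = np.random.default_rng(seed)
    n = 50
    rows = 0
    zeroed = 0
    touched = 0
    pairs = 0
    batch = 20
    reps = max(1, int(np.ceil(n_draws / (batch * n))))
    X = np.ones((batch, n, 3))
    W = np.full((batch, n, n), 0.5)
    for b in range(batch):
        np.fill_diagonal(W[b], 1.0)
    for _ in range(reps):
        X2, W2 = apply_regularization(X, W, "train", tcfg, rng)
        z = (X2 == 0).all(axis=2)
        zeroed += int(z.sum())
        rows += z.size
        iu, ju = np.triu_indices(n, 1)
        d = W2[:, iu, ju] != W[:, iu, ju]
        touched += int(d.sum())
        pairs += d.size
    return {
        "node_dropout_rate": zeroed / rows,
        "node_dropout_nominal": tcfg.node_feature_dropout,
        "edge_noise_rate": touched / pairs,
        "edge_noise_nominal": tcfg.edge_noise_fraction,
        "n_row_draws": rows,
        "n_pair_draws": pairs,
    }
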