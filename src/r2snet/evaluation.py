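"""Per-class recall/precision/F1 reporting and stratified splitting.

Metrics follow the three-class reporting convention of the diagnostic
task (percent scale, per-class recall, precision, F1), with multi-seed
aggregation formatted as ``mean +/- sd`` where the resampling unit is the
random seed.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.metrics import precision_recall_fscore_support

from .r2sn import CLASSES


@dataclass
class Metrics:
    recall: dict[str, float]  # percent
    precision: dict[str, float]
    f1: dict[str, float]
    confusion: np.ndarray  # [3, 3] int
    n: int
    seed: int | None = None
    zero_division_flags: list[str] = field(default_factory=list)

    @property
    def macro_f1(self) -> float:
        return float(np.mean(list(self.f1.values())))

    @property
    def accuracy(self) -> float:
        return float(np.trace(self.confusion) / self.confusion.sum() * 100)


def _encode(labels) -> np.ndarray:
    out = []
    for lab in labels:
        if lab not in CLASSES:
            raise ValueError(f"unknown class label {lab!r}")
        out.append(CLASSES.index(lab))
    return np.array(out, dtype=int)


def confusion_matrix(true_labels, predicted_labels) -> np.ndarray:
    """3x3 count matrix; entry (c, c') = class-c subjects predicted c'."""
    yt, yp = _encode(true_labels), _encode(predicted_labels)
    if yt.shape != yp.shape:
        raise ValueError("label vectors must have equal length")
    return _sk_confusion(yt, yp, labels=range(len(CLASSES)))


def per_class_prf(confusion: np.ndarray, seed: int | None = None) -> Metrics:
    """Recall/precision/F1 per class on the percent scale.

    A class with zero support or zero predictions gets 0 for the
    undefined metric, flagged in ``zero_division_flags`` (never NaN).
    """
    confusion = np.asarray(confusion)
    if confusion.shape != (len(CLASSES), len(CLASSES)):
        raise ValueError(f"confusion must be {len(CLASSES)}x{len(CLASSES)}")
    yt = np.repeat(np.arange(len(CLASSES)), confusion.sum(axis=1))
    yp = np.concatenate([np.repeat(np.arange(len(CLASSES)), row)
                         for row in confusion])
    prec, rec, f1, _ = precision_recall_fscore_support(
        yt, yp, labels=range(len(CLASSES)), zero_division=0)
    flags = []
    for c, name in enumerate(CLASSES):
        if confusion[:, c].sum() == 0:
            flags.append(f"{name}: no predictions, precision set to 0")
        if confusion[c, :].sum() == 0:
            flags.append(f"{name}: no support, recall set to 0")
    return Metrics(
        recall={c: float(r * 100) for c, r in zip(CLASSES, rec)},
        precision={c: float(p * 100) for c, p in zip(CLASSES, prec)},
        f1={c: float(v * 100) for c, v in zip(CLASSES, f1)},
        confusion=confusion, n=int(confusion.sum()), seed=seed,
        zero_division_flags=flags)


def evaluate_predictions(true_labels, predicted_labels,
                         seed: int | None = None) -> Metrics:
    return per_class_prf(confusion_matrix(true_labels, predicted_labels), seed)


# ---------------------------------------------------------------------------
# multi-seed aggregation
# ---------------------------------------------------------------------------

def format_mean_std(mean: float, std: float | None) -> str:
    if std is None:
        return f"{mean:.1f}"
    return f"{mean:.1f} ± {std:.1f}"


_CELL_RE = re.compile(r"^\s*([\d.]+)(?:\s*±\s*([\d.]+))?\s*$")


def parse_mean_std(cell: str) -> tuple[float, float | None]:
    m = _CELL_RE.match(cell)
    if not m:
        raise ValueError(f"unparseable metric cell {cell!r}")
    return float(m.group(1)), None if m.group(2) is None else float(m.group(2))


def aggregate_over_seeds(runs: list[Metrics]) -> dict:
    """Sample mean +/- sd of every per-class metric across seeded runs.

    With a single run the std is reported absent (None).  The resampling
    unit is the seed, stated explicitly in the output.
    """
    if not runs:
        raise ValueError("need at least one run")
    single = len(runs) == 1
    out = {"unit": "seeds", "n_runs": len(runs), "cells": {}}
    for metric in ("recall", "precision", "f1"):
        for c in CLASSES:
            vals = np.array([getattr(r, metric)[c] for r in runs])
            mean = float(vals.mean())
            std = None if single else float(vals.std(ddof=1))
            out["cells"][f"{c}.{metric}"] = {
                "mean": mean, "std": std,
                "formatted": format_mean_std(mean, std),
            }
    macro = np.array([r.macro_f1 for r in runs])
    out["macro_f1"] = {
        "mean": float(macro.mean()),
        "std": None if single else float(macro.std(ddof=1)),
    }
    return out


def metrics_table(agg: dict) -> str:
    """Pretty per-class table (rows: classes; columns: R / P / F1)."""
    lines = [f"{'class':<6} {'recall':>12} {'precision':>12} {'F1':>12}"
             f"   (mean ± sd over {agg['n_runs']} {agg['unit']})"]
    for c in CLASSES:
        row = [agg["cells"][f"{c}.{m}"]["formatted"]
               for m in ("recall", "precision", "f1")]
        lines.append(f"{c:<6} {row[0]:>12} {row[1]:>12} {row[2]:>12}")
    return "\n".join(lines)


# ---------------------------------------------------------------------------
# splitting and comparison
# ---------------------------------------------------------------------------

def stratified_split(items: list, labels, fractions: tuple[float, ...],
                     seed: int) -> tuple[list, ...]:
    """Deterministic stratified partition into len(fractions) parts.

    Per-class proportions are preserved within +/- 1 subject (largest-
    remainder allocation); partitions are disjoint and exhaustive.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    labels = np.asarray(labels)
    if len(items) != len(labels):
        raise ValueError("items and labels must align")
    rng = np.random.default_rng(seed)
    parts: list[list] = [[] for _ in fractions]
    for c in np.unique(labels):
        idx = rng.permutation(np.flatnonzero(labels == c))
        if len(idx) < len(fractions):
            raise ValueError(
                f"class {c!r} has {len(idx)} subjects but "
                f"{len(fractions)} partitions are requested")
        quotas = np.array(fractions) * len(idx)
        base = np.floor(quotas).astype(int)
        rem = quotas - base
        short = len(idx) - base.sum()
        for k in np.argsort(-rem)[:short]:
            base[k] += 1
        # guarantee non-empty parts for this class
        while (base == 0).any():
            donor = int(np.argmax(base))
            base[int(np.argmin(base))] += 1
            base[donor] -= 1
        start = 0
        for part, count in zip(parts, base):
            part.extend(int(i) for i in idx[start:start + count])
            start += count
    return tuple([items[i] for i in sorted(p)] for p in parts)


def paired_t_test(f1_a, f1_b) -> tuple[float, float]:
    """Plain paired t-test on per-seed F1 vectors; returns (t, p)."""
    from scipy.stats import ttest_rel
    res = ttest_rel(f1_a, f1_b)
    return float(res.statistic), float(res.pvalue)
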