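"""Convenience wiring from radiomic tables to model-ready graphs."""

from __future__ import annotations

import json
from pathlib import Path

from .r2sn import (FeatureSelection, MetabolicGraph, RadiomicTable,
                   build_r2sn, minmax_normalize, prune_collinear_features)


def prepare_graphs(tables: list[RadiomicTable],
                   selection: FeatureSelection | None = None,
                   threshold: float = 0.9,
                   transform: str = "affine"
                   ) -> tuple[list[MetabolicGraph], FeatureSelection]:
    """Prune (fit on these tables unless a selection is given), normalise
    per subject, and build each subject's similarity network."""
    if selection is None:
        selection = prune_collinear_features(tables, threshold)
    graphs = [build_r2sn(minmax_normalize(t, selection), transform)
              for t in tables]
    return graphs, selection


def save_selection(selection: FeatureSelection, path: str | Path) -> None:
    payload = {
        "retained": list(selection.retained),
        "dropped": [[d, k, None if r != r else r] for d, k, r in selection.dropped],
        "threshold": selection.threshold,
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def load_selection(path: str | Path) -> FeatureSelection:
    raw = json.loads(Path(path).read_text())
    dropped = tuple((d, k, float("nan") if r is None else r)
                    for d, k, r in raw["dropped"])
    return FeatureSelection(tuple(raw["retained"]), dropped, raw["threshold"])
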