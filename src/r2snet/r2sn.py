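"""Regional Radiomics Similarity Network (R2SN) construction.

A subject's R2SN is a 96-node brain graph in which node *i* carries the
region's (selected, min-max normalised) radiomic feature vector and the
edge between regions *i* and *j* is the Pearson correlation of their
feature profiles, affinely mapped onto [0, 1].  The pipeline is:

1. :func:`prune_collinear_features` — drop features that are collinear
   (|r| > 0.9 by default) with an earlier-catalogued feature, fit once on
   a training cohort;
2. :func:`minmax_normalize` — per subject, rescale each retained feature
   to [0, 1] across the 96 regions;
3. :func:`build_r2sn` — inter-regional Pearson correlation matrix,
   mapped to edge weights w = (r + 1) / 2 with unit diagonal.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .atlas import ROIAtlas, load_atlas

CLASSES = ("IPD", "MSA", "PSP")


class DegenerateDataWarning(UserWarning):
    """Raised when zero-variance columns/regions force a fallback value."""


class TableParseError(ValueError):
    """A feature table failed structural validation."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class RadiomicTable:
    """Per-subject region x feature matrix of radiomic values."""

    subject_id: str
    values: np.ndarray  # [96, F]
    feature_names: list[str]
    label: str | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise TableParseError("values must be a 2-D matrix")
        if self.values.shape[1] != len(self.feature_names):
            raise TableParseError(
                f"{self.values.shape[1]} columns but "
                f"{len(self.feature_names)} feature names")
        if self.values.shape[1] < 2:
            raise TableParseError("need at least 2 features")
        if not np.isfinite(self.values).all():
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise TableParseError(
                f"non-finite value at region row {bad[0]}, "
                f"feature {self.feature_names[bad[1]]!r}")
        if self.label is not None and self.label not in CLASSES:
            raise TableParseError(f"unknown class label {self.label!r}")

    @property
    def n_features(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class FeatureSelection:
    """Result of collinearity pruning; fit once, applied everywhere."""

    retained: tuple[str, ...]
    dropped: tuple[tuple[str, str, float], ...]  # (dropped, kept-culprit, r)
    threshold: float

    def __post_init__(self):
        dropped_names = {d for d, _, _ in self.dropped}
        if dropped_names & set(self.retained):
            raise ValueError("a feature cannot be both retained and dropped")


@dataclass
class MetabolicGraph:
    """The R2SN: 96 nodes with feature vectors and [0,1] edge weights."""

    subject_id: str
    node_features: np.ndarray  # [96, d]
    weights: np.ndarray  # [96, 96]
    label: str | None = None
    feature_names: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.node_features = np.asarray(self.node_features, dtype=np.float64)
        self.weights = np.asarray(self.weights, dtype=np.float64)
        n = self.node_features.shape[0]
        if self.weights.shape != (n, n):
            raise ValueError(
                f"weights shape {self.weights.shape} does not match "
                f"{n} node-feature rows")
        if not np.allclose(self.weights, self.weights.T, atol=1e-8):
            raise ValueError("edge-weight matrix must be symmetric")
        if not np.allclose(np.diag(self.weights), 1.0, atol=1e-8):
            raise ValueError("edge-weight diagonal must be 1")
        if self.weights.min() < -1e-12 or self.weights.max() > 1 + 1e-12:
            raise ValueError("edge weights must lie in [0, 1]")
        if self.label is not None and self.label not in CLASSES:
            raise ValueError(f"unknown class label {self.label!r}")

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]


# ---------------------------------------------------------------------------
# feature-table I/O
# ---------------------------------------------------------------------------

def _read_delimited(path: Path) -> pd.DataFrame:
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    return pd.read_csv(path, sep=sep, dtype=str)


def read_feature_table(path: str | Path, atlas: ROIAtlas | None = None,
                       subject_id: str | None = None,
                       label: str | None = None) -> RadiomicTable:
    """Read a delimited region x feature table and align it to atlas order.

    The first column identifies the region by atlas name or 1-based index;
    remaining columns are radiomic features (header row gives their names).
    """
    path = Path(path)
    atlas = atlas or load_atlas()
    df = _read_delimited(path)
    if df.shape[1] < 3:
        raise TableParseError(f"{path}: need a region column and >= 2 features")
    region_col = df.columns[0]
    feature_names = list(df.columns[1:])

    # resolve regions to 0-based atlas positions
    positions = []
    for row_i, raw in enumerate(df[region_col]):
        token = str(raw).strip()
        if token.isdigit():
            idx = int(token) - 1
            if not 0 <= idx < len(atlas):
                raise TableParseError(
                    f"{path} row {row_i + 2}: region index {token} outside 1..96")
        else:
            try:
                idx = atlas.index_of(token)
            except KeyError:
                raise TableParseError(
                    f"{path} row {row_i + 2}: region {token!r} not in atlas"
                ) from None
        positions.append(idx)

    seen: dict[int, int] = {}
    for row_i, p in enumerate(positions):
        if p in seen:
            raise TableParseError(
                f"{path}: duplicate region {atlas.regions[p].name!r} "
                f"(rows {seen[p] + 2} and {row_i + 2})")
        seen[p] = row_i
    missing = set(range(len(atlas))) - set(positions)
    if missing:
        name = atlas.regions[min(missing)].name
        raise TableParseError(f"{path}: missing region {name!r}")

    values = np.empty((len(atlas), len(feature_names)), dtype=np.float64)
    for row_i, p in enumerate(positions):
        for col_i, feat in enumerate(feature_names):
            cell = df.iloc[row_i, col_i + 1]
            try:
                values[p, col_i] = float(cell)
            except (TypeError, ValueError):
                raise TableParseError(
                    f"{path} row {row_i + 2}, column {feat!r}: "
                    f"non-numeric cell {cell!r}") from None
    return RadiomicTable(subject_id or path.stem, values, feature_names, label)


def write_feature_table(table: RadiomicTable, path: str | Path,
                        atlas: ROIAtlas | None = None) -> None:
    """Write a table in the delimited format ``read_feature_table`` accepts."""
    path = Path(path)
    atlas = atlas or load_atlas()
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    with open(path, "w", encoding="utf-8") as f:
        f.write(sep.join(["region"] + table.feature_names) + "\n")
        for i, region in enumerate(atlas.regions):
            cells = [f"{v:.17g}" for v in table.values[i]]
            f.write(sep.join([region.name] + cells) + "\n")


# ---------------------------------------------------------------------------
# feature selection and normalisation
# ---------------------------------------------------------------------------

def prune_collinear_features(cohort: list[RadiomicTable],
                             threshold: float = 0.9) -> FeatureSelection:
    """Drop features collinear (|r| > threshold) with an earlier feature.

    Pearson correlations are computed over the pooled (subject, region)
    observations of the cohort.  The scan is greedy in catalogue (column)
    order: a feature is dropped iff it exceeds the threshold against an
    already-retained feature, so the earlier member of each offending pair
    survives.  Zero-variance features are dropped outright (r recorded as
    NaN).  The selection must be fit on a cohort (>= 2 subjects) and is
    then applied unchanged to validation/test data.
    """
    if len(cohort) < 2:
        raise ValueError("feature selection must be fit on >= 2 subjects")
    names = cohort[0].feature_names
    for t in cohort[1:]:
        if t.feature_names != names:
            raise ValueError("all tables must share the same feature names")
    obs = np.vstack([t.values for t in cohort])  # [n_subj*96, F]
    sd = obs.std(axis=0)
    finite_var = sd > 0
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(obs, rowvar=False)

    retained: list[str] = []
    retained_idx: list[int] = []
    dropped: list[tuple[str, str, float]] = []
    for j, name in enumerate(names):
        if not finite_var[j]:
            warnings.warn(f"feature {name!r} has zero variance; dropped",
                          DegenerateDataWarning, stacklevel=2)
            dropped.append((name, "", float("nan")))
            continue
        culprit = None
        for i in retained_idx:
            r = corr[i, j]
            if abs(r) > threshold:
                culprit = (names[i], float(r))
                break
        if culprit is None:
            retained.append(name)
            retained_idx.append(j)
        else:
            dropped.append((name, culprit[0], culprit[1]))
    return FeatureSelection(tuple(retained), tuple(dropped), threshold)


def minmax_normalize(table: RadiomicTable,
                     selection: FeatureSelection | None = None) -> RadiomicTable:
    """Per-subject min-max rescaling of each feature across the 96 regions.

    Restricts the table to the selection's retained features first (if a
    selection is given).  A constant column maps to all zeros.
    """
    if selection is not None:
        missing = set(selection.retained) - set(table.feature_names)
        if missing:
            raise ValueError(f"table lacks selected features: {sorted(missing)}")
        cols = [table.feature_names.index(f) for f in selection.retained]
        values = table.values[:, cols]
        names = list(selection.retained)
    else:
        values = table.values
        names = list(table.feature_names)

    lo = values.min(axis=0)
    hi = values.max(axis=0)
    span = hi - lo
    flat = span == 0
    if flat.any():
        warnings.warn(
            f"subject {table.subject_id}: constant feature column(s) "
            f"{[names[i] for i in np.flatnonzero(flat)]} normalised to 0",
            DegenerateDataWarning, stacklevel=2)
    safe_span = np.where(flat, 1.0, span)
    out = (values - lo) / safe_span
    out[:, flat] = 0.0
    return RadiomicTable(table.subject_id, out, names, table.label)


# ---------------------------------------------------------------------------
# network construction
# ---------------------------------------------------------------------------

def build_r2sn(table: RadiomicTable, transform: str = "affine") -> MetabolicGraph:
    """Map a normalised table to its 96 x 96 metabolic network.

    r_ij is the Pearson correlation between region i's and region j's
    feature profiles.  ``transform`` maps r to the [0, 1] edge weight:
    ``"affine"`` (default) uses w = (r + 1) / 2; ``"abs"`` uses w = |r|.
    The diagonal is fixed at 1 so self-attention is never masked out.
    A region whose feature profile has zero variance gets r = 0 against
    every other region.
    """
    x = table.values
    centered = x - x.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1)
    degenerate = norms == 0
    if degenerate.any():
        warnings.warn(
            f"subject {table.subject_id}: zero-variance region rows "
            f"{list(np.flatnonzero(degenerate))}; correlations set to 0",
            DegenerateDataWarning, stacklevel=2)
    safe = np.where(degenerate, 1.0, norms)
    unit = centered / safe[:, None]
    r = unit @ unit.T
    r[degenerate, :] = 0.0
    r[:, degenerate] = 0.0
    r = np.clip(r, -1.0, 1.0)

    if transform == "affine":
        w = (r + 1.0) / 2.0
    elif transform == "abs":
        w = np.abs(r)
    else:
        raise ValueError(f"unknown edge transform {transform!r}")
    w = (w + w.T) / 2.0
    np.fill_diagonal(w, 1.0)
    return MetabolicGraph(table.subject_id, x.copy(), w, table.label,
                          list(table.feature_names))


def group_average_network(graphs: list[MetabolicGraph]) -> MetabolicGraph:
    """Element-wise mean of weights and node features over one class."""
    if not graphs:
        raise ValueError("need at least one graph")
    labels = {g.label for g in graphs}
    if len(labels) > 1:
        raise ValueError(f"mixed class labels in group average: {labels}")
    shape = graphs[0].weights.shape
    for g in graphs[1:]:
        if g.weights.shape != shape:
            raise ValueError("graphs have mismatched dimensions")
    w = np.mean([g.weights for g in graphs], axis=0)
    x = np.mean([g.node_features for g in graphs], axis=0)
    np.fill_diagonal(w, 1.0)  # guard rounding
    return MetabolicGraph(f"group_mean_n{len(graphs)}", x, (w + w.T) / 2,
                          graphs[0].label, list(graphs[0].feature_names))


# ---------------------------------------------------------------------------
# graph store
# ---------------------------------------------------------------------------

def write_graph(graph: MetabolicGraph, path: str | Path) -> None:
    """Store a graph as a directory of delimited matrices + JSON sidecar."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    np.savetxt(path / "weights.tsv", graph.weights, delimiter="\t", fmt="%.17g")
    np.savetxt(path / "node_features.tsv", graph.node_features,
               delimiter="\t", fmt="%.17g")
    meta = {
        "subject_id": graph.subject_id,
        "label": graph.label,
        "feature_names": graph.feature_names,
        "n_nodes": graph.n_nodes,
        "transform": "affine",
    }
    (path / "meta.json").write_text(json.dumps(meta, indent=1))


def read_graph(path: str | Path) -> MetabolicGraph:
    path = Path(path)
    meta = json.loads((path / "meta.json").read_text())
    w = np.loadtxt(path / "weights.tsv", delimiter="\t", ndmin=2)
    x = np.loadtxt(path / "node_features.tsv", delimiter="\t", ndmin=2)
    n = int(meta["n_nodes"])
    if w.shape != (n, n) or x.shape[0] != n:
        raise ValueError(f"{path}: stored matrices do not match n_nodes={n}")
    return MetabolicGraph(meta["subject_id"], x, w, meta["label"],
                          list(meta["feature_names"]))
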