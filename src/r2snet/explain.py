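"""Attribution of classifier decisions to brain regions and connections.

Node importance is the L2 norm of the gradient of the target-class log
probability with respect to each node's input feature vector,
``I_node(i) = || d log p(y|G) / d x_i ||_2``.  Edge importance averages
the (head-averaged, pre-Hadamard) attention maps over the transformer
layers and symmetrises; the top 15% of undirected off-diagonal pairs is
retained by default.  Disease-level edge sets are contrasted with
Jaccard similarity.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .atlas import ROIAtlas, load_atlas
from .model import ForwardTrace, ModelConfig, ModelParams, forward
from .r2sn import CLASSES, MetabolicGraph

Edge = tuple[int, int]  # unordered pair of 0-based node indices, i < j


@dataclass
class Explanation:
    subject_id: str
    predicted_class: str
    node_importance: np.ndarray  # [96], >= 0
    edge_importance: np.ndarray  # [96, 96], symmetric, >= 0
    retained_edges: frozenset[Edge]
    roi_report: list[tuple[str, float]]  # (region name, score), ranked


@dataclass
class GroupExplanation:
    label: str
    mean_node_importance: np.ndarray
    mean_edge_importance: np.ndarray
    retained_edges: frozenset[Edge]
    jaccard_vs: dict[str, float]


# ---------------------------------------------------------------------------
# attributions
# ---------------------------------------------------------------------------

def node_importance(graph: MetabolicGraph, params: ModelParams,
                    config: ModelConfig, target: str = "predicted",
                    trace: ForwardTrace | None = None) -> np.ndarray:
    """Gradient-norm attribution of the target log-probability to nodes.

    ``target`` is ``"predicted"`` (default), ``"true"`` (the graph's
    label) or an explicit class name.
    """
    if trace is None:
        trace = forward(graph, params, config)
    if target == "predicted":
        c = int(np.argmax(trace.probs))
    elif target == "true":
        if graph.label is None:
            raise ValueError("graph has no label; cannot target true class")
        c = CLASSES.index(graph.label)
    else:
        c = CLASSES.index(target)

    xin = trace.input_tensor
    logp = trace.logp_tensor
    # select log p(y=c | G) for the single graph in the trace
    sel = np.zeros_like(logp.data)
    sel[..., c] = 1.0
    scalar = (logp * sel).sum()
    xin.grad = None
    scalar.backward()
    g = xin.grad[0]  # [96, d]
    if not np.isfinite(g).all():
        raise FloatingPointError("non-finite attribution gradient")
    return np.linalg.norm(g, axis=1)


def edge_importance(trace: ForwardTrace) -> np.ndarray:
    """Mean over layers of head-averaged attention, symmetrised."""
    if not trace.attention:
        raise ValueError("trace holds no attention maps")
    maps = [a.mean(axis=0) for a in trace.attention]  # head average, [n, n]
    mean = np.mean(maps, axis=0)
    sym = (mean + mean.T) / 2.0
    return sym


def retain_top_edges(I_edge: np.ndarray, retain_fraction: float = 0.15
                     ) -> frozenset[Edge]:
    """Keep the ceil(fraction * n*(n-1)/2) highest-scoring undirected
    pairs; ties broken by lexicographic pair order."""
    n = I_edge.shape[0]
    if not np.allclose(I_edge, I_edge.T, atol=1e-9):
        raise ValueError("edge-importance matrix must be symmetric")
    iu, ju = np.triu_indices(n, k=1)
    n_keep = int(np.ceil(retain_fraction * iu.size))
    scores = I_edge[iu, ju]
    # sort by (-score, i, j): highest first, lexicographic ties
    order = np.lexsort((ju, iu, -scores))
    keep = order[:n_keep]
    return frozenset((int(iu[k]), int(ju[k])) for k in keep)


def jaccard_similarity(set_a: frozenset[Edge] | set,
                       set_b: frozenset[Edge] | set) -> float:
    """|A n B| / |A u B|; two empty sets are identical, hence 1."""
    a, b = set(set_a), set(set_b)
    union = a | b
    if not union:
        return 1.0
    return len(a & b) / len(union)


def map_to_rois(I_node: np.ndarray, atlas: ROIAtlas | None = None
                ) -> list[tuple[str, float]]:
    """Rank regions by importance (stable atlas order on ties)."""
    atlas = atlas or load_atlas()
    if I_node.shape[0] != len(atlas):
        raise ValueError(
            f"importance vector has {I_node.shape[0]} entries, "
            f"atlas has {len(atlas)}")
    order = np.lexsort((np.arange(len(atlas)), -I_node))
    return [(atlas.regions[i].name, float(I_node[i])) for i in order]


# ---------------------------------------------------------------------------
# subject- and group-level reports
# ---------------------------------------------------------------------------

def explain_subject(graph: MetabolicGraph, params: ModelParams,
                    config: ModelConfig, atlas: ROIAtlas | None = None,
                    retain_fraction: float = 0.15,
                    target: str = "predicted") -> Explanation:
    trace = forward(graph, params, config)
    inode = node_importance(graph, params, config, target, trace)
    iedge = edge_importance(trace)
    return Explanation(
        subject_id=graph.subject_id,
        predicted_class=trace.predicted_class,
        node_importance=inode,
        edge_importance=iedge,
        retained_edges=retain_top_edges(iedge, retain_fraction),
        roi_report=map_to_rois(inode, atlas),
    )


def explain_group(explanations: list[Explanation], label: str,
                  retain_fraction: float = 0.15) -> GroupExplanation:
    """Consensus explanation: mean importances, edges retained from the
    mean edge-importance matrix."""
    if not explanations:
        raise ValueError("need at least one explanation")
    mean_node = np.mean([e.node_importance for e in explanations], axis=0)
    mean_edge = np.mean([e.edge_importance for e in explanations], axis=0)
    return GroupExplanation(
        label=label,
        mean_node_importance=mean_node,
        mean_edge_importance=mean_edge,
        retained_edges=retain_top_edges(mean_edge, retain_fraction),
        jaccard_vs={},
    )


def cross_class_jaccard(groups: list[GroupExplanation]) -> dict:
    """Fill each group's jaccard_vs map; returns the symmetric matrix as
    a nested dict keyed by class label."""
    out: dict[str, dict[str, float]] = {}
    for a in groups:
        out[a.label] = {}
        for b in groups:
            if a.label == b.label:
                continue
            j = jaccard_similarity(a.retained_edges, b.retained_edges)
            out[a.label][b.label] = j
            a.jaccard_vs[b.label] = j
    return out


def write_explanation(expl: Explanation, outdir: str | Path,
                      atlas: ROIAtlas | None = None) -> None:
    """Export node report (TSV), retained edge list (TSV) and a JSON
    summary."""
    atlas = atlas or load_atlas()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "nodes.tsv", "w") as f:
        f.write("rank\tindex\tregion\tscore\n")
        for rank, (name, score) in enumerate(expl.roi_report, 1):
            f.write(f"{rank}\t{atlas.index_of(name) + 1}\t{name}\t{score:.8g}\n")
    with open(outdir / "edges.tsv", "w") as f:
        f.write("region_a\tregion_b\tscore\n")
        for i, j in sorted(expl.retained_edges):
            f.write(f"{atlas.regions[i].name}\t{atlas.regions[j].name}\t"
                    f"{expl.edge_importance[i, j]:.8g}\n")
    summary = {
        "subject_id": expl.subject_id,
        "predicted_class": expl.predicted_class,
        "n_retained_edges": len(expl.retained_edges),
        "top_regions": [name for name, _ in expl.roi_report[:10]],
    }
    (outdir / "summary.json").write_text(json.dumps(summary, indent=1))
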