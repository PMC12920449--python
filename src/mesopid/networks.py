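"""Multiplex interaction networks and shortest-path decomposition.

The z-scored synergy and redundancy of each neuron pair define two
weighted interaction layers on the same node set. Each layer is sparsified
to an unweighted k-nearest-neighbor graph (every node keeps its k
strongest edges; an edge survives if either endpoint selects it), and the
*combined network* is the union of the two edge sets.

For each node pair the hop distances d_A (synergy layer), d_B (redundancy
layer) and d_U (union) classify the pair's shortest path:

* complementary — d_U < min(d_A, d_B): mixing layers opens a shorter route
  than either layer alone;
* shared        — d_U = d_A = d_B: both layers already offer the same
  efficiency;
* unique to one layer — d_U equals that layer's distance and beats the
  other's.

Unreachability counts as infinite distance; pairs disconnected even in
the union are reported separately and excluded from proportions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Tuple

import networkx as nx
import numpy as np
import pandas as pd

from .exceptions import PathInconsistencyError

CATEGORIES = ("complementary", "shared", "unique_a", "unique_b")


@dataclass(frozen=True)
class InteractionLayer:
    """An unweighted, kNN-sparsified interaction graph."""

    layer_name: str
    nodes: tuple
    edges: frozenset  # of ordered tuples (i, j) with i < j
    k: int

    def to_graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges)
        return g

    def to_frame(self) -> pd.DataFrame:
        e = sorted(self.edges)
        return pd.DataFrame(
            {"i": [a for a, _ in e], "j": [b for _, b in e],
             "layer_name": self.layer_name}
        )


def build_knn_layer(
    pair_weights: pd.DataFrame,
    which_component: str,
    k: int = 10,
    layer_name: Optional[str] = None,
    nodes: Optional[Iterable[int]] = None,
) -> InteractionLayer:
    """Keep each node's k strongest edges by the named weight column.

    Selection per node is by descending weight with ties broken toward the
    lower neighbor id; the layer keeps an edge if *either* endpoint selects
    it. ``k >= n_nodes - 1`` degenerates to the complete graph over nodes
    with finite weights (a warning is emitted).
    """
    if k < 1:
        raise ValueError("k must be at least 1")
    if which_component not in pair_weights.columns:
        raise ValueError(f"missing weight column {which_component!r}")
    w = pair_weights[["i", "j", which_component]].dropna()
    if not np.isfinite(w[which_component]).all():
        raise ValueError("weights must be finite")
    if nodes is None:
        nodes = sorted(set(w["i"]).union(w["j"]))
    nodes = tuple(int(n) for n in nodes)
    if k >= len(nodes):
        import warnings

        warnings.warn("k >= number of nodes: layer degenerates to the complete graph",
                      stacklevel=2)

    neighbors: Dict[int, List[Tuple[float, int]]] = {n: [] for n in nodes}
    for row in w.itertuples():
        i, j, weight = int(row.i), int(row.j), float(getattr(row, which_component))
        neighbors[i].append((weight, j))
        neighbors[j].append((weight, i))
    edges = set()
    for node, cand in neighbors.items():
        cand.sort(key=lambda t: (-t[0], t[1]))
        for weight, other in cand[:k]:
            edges.add((min(node, other), max(node, other)))
    return InteractionLayer(
        layer_name=layer_name or which_component,
        nodes=nodes,
        edges=frozenset(edges),
        k=k,
    )


def combine_layers(a: InteractionLayer, b: InteractionLayer) -> InteractionLayer:
    """Union of the edge sets of two layers over a common node set."""
    if set(a.nodes) != set(b.nodes):
        raise ValueError("layers must share the same node set")
    return InteractionLayer(
        layer_name=f"{a.layer_name}+{b.layer_name}",
        nodes=a.nodes,
        edges=a.edges | b.edges,
        k=max(a.k, b.k),
    )


def shortest_path_lengths(layer: InteractionLayer) -> Dict[Tuple[int, int], float]:
    """All-pairs unweighted hop distances; unreachable pairs map to +inf."""
    g = layer.to_graph()
    dist = dict(nx.all_pairs_shortest_path_length(g))
    nodes = sorted(layer.nodes)
    out: Dict[Tuple[int, int], float] = {}
    for a_idx, i in enumerate(nodes):
        di = dist.get(i, {})
        for j in nodes[a_idx + 1:]:
            out[(i, j)] = float(di.get(j, np.inf))
    return out


def classify_paths(
    d_a: Dict[Tuple[int, int], float],
    d_b: Dict[Tuple[int, int], float],
    d_union: Dict[Tuple[int, int], float],
) -> pd.DataFrame:
    """Per-pair path category from the three distance tables."""
    if not (d_a.keys() == d_b.keys() == d_union.keys()):
        raise ValueError("distance tables must cover the same pairs")
    rows = []
    for (i, j), du in d_union.items():
        da, db = d_a[(i, j)], d_b[(i, j)]
        lo, hi = min(da, db), max(da, db)
        if du > lo:
            raise PathInconsistencyError(
                f"pair ({i},{j}): union distance {du} exceeds min layer distance {lo}"
            )
        if np.isinf(du):
            category = "disconnected"
        elif du < lo:
            category = "complementary"
        elif du == hi:  # du == lo == hi
            category = "shared"
        elif da < db:
            category = "unique_a"
        else:
            category = "unique_b"
        rows.append({"i": i, "j": j, "d_a": da, "d_b": db,
                     "d_union": du, "category": category})
    return pd.DataFrame(rows)


def path_proportions_by_length(
    paths: pd.DataFrame, long_threshold: int = 4
) -> pd.DataFrame:
    """Category proportions per union path length, plus a pooled long-path row.

    Returns one row per finite ``d_union`` value (and one ``'long'`` row
    pooling lengths >= ``long_threshold``) with the fraction of pairs in
    each category; per-row proportions sum to 1.
    """
    if paths.empty:
        raise ValueError("no classified pairs")
    finite = paths[np.isfinite(paths["d_union"])]
    if finite.empty:
        import warnings

        warnings.warn("no connected pairs in the union network", stacklevel=2)
        return pd.DataFrame(columns=["path_length", "n_pairs", *CATEGORIES])

    def _props(group: pd.DataFrame) -> dict:
        n = len(group)
        rec = {"n_pairs": n}
        for cat in CATEGORIES:
            rec[cat] = float((group["category"] == cat).sum() / n)
        return rec

    rows = []
    for length, group in finite.groupby(finite["d_union"].astype(int)):
        rows.append({"path_length": int(length), **_props(group)})
    long_group = finite[finite["d_union"] >= long_threshold]
    if len(long_group):
        rows.append({"path_length": "long", **_props(long_group)})
    return pd.DataFrame(rows)


def decompose_multiplex(
    layer_a: InteractionLayer,
    layer_b: InteractionLayer,
    long_threshold: int = 4,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Distances, categories, and per-length proportions for two layers."""
    union = combine_layers(layer_a, layer_b)
    paths = classify_paths(
        shortest_path_lengths(layer_a),
        shortest_path_lengths(layer_b),
        shortest_path_lengths(union),
    )
    return paths, path_proportions_by_length(paths, long_threshold)


def aggregate_over_datasets(
    summaries: List[pd.DataFrame],
    band: Tuple[float, float] = (2.5, 97.5),
) -> pd.DataFrame:
    """Median and percentile band of category proportions across datasets.

    Aligns the per-dataset summaries on path length; lengths absent from a
    dataset are ignored for that dataset (medians use the datasets that
    observed the length).
    """
    if not summaries:
        raise ValueError("need at least one dataset summary")
    stacked = pd.concat(
        [s.assign(dataset=idx) for idx, s in enumerate(summaries)], ignore_index=True
    )
    rows = []
    for length, group in stacked.groupby("path_length", sort=False):
        rec: dict = {"path_length": length, "n_datasets": group["dataset"].nunique()}
        for cat in CATEGORIES:
            vals = group[cat].to_numpy(float)
            rec[f"{cat}_median"] = float(np.median(vals))
            rec[f"{cat}_lo"] = float(np.percentile(vals, band[0]))
            rec[f"{cat}_hi"] = float(np.percentile(vals, band[1]))
        rows.append(rec)
    return pd.DataFrame(rows)
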