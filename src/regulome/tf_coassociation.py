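"""Base-pair Jaccard co-association between TF peak sets and module extraction.

The co-association between two TFs is the Jaccard statistic of their
merged binding footprints: intersecting bp over union bp.  All pairwise
scores form a symmetric matrix; an elbow statistic on the sorted score
curve picks the significance threshold (falling back to 0.2 on
degenerate curves), and greedy modularity maximization on the
thresholded weighted graph extracts co-binding modules.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from regulome.core_io import GenomicInterval, intersect_bp, merge_intervals, total_bp

DEFAULT_COASSOC_THRESHOLD = 0.2


def jaccard_bp(
    set_a: Sequence[GenomicInterval], set_b: Sequence[GenomicInterval]
) -> float:
    """Base-pair Jaccard: |A n B| / |A u B| over merged footprints."""
    a = merge_intervals(set_a)
    b = merge_intervals(set_b)
    if not a and not b:
        raise ValueError("Jaccard undefined: both interval sets are empty")
    if not a or not b:
        return 0.0
    inter = intersect_bp(a, b)
    union = total_bp(a) + total_bp(b) - inter
    return inter / union


def coassociation_matrix(
    tf_peaksets: Mapping[str, Sequence[GenomicInterval]]
) -> pd.DataFrame:
    """All-pairs bp Jaccard between TF footprints; symmetric, unit diagonal.

    TFs with empty peak sets are excluded with a warning.
    """
    merged: dict[str, list[GenomicInterval]] = {}
    for tf, intervals in tf_peaksets.items():
        m = merge_intervals(intervals)
        if not m:
            warnings.warn(f"TF {tf!r} has an empty peak set; excluded")
            continue
        merged[tf] = m
    labels = sorted(merged)
    if len(labels) < 2:
        raise ValueError("need >= 2 TFs with non-empty peak sets")
    sizes = {tf: total_bp(merged[tf]) for tf in labels}
    n = len(labels)
    mat = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            inter = intersect_bp(merged[labels[i]], merged[labels[j]])
            union = sizes[labels[i]] + sizes[labels[j]] - inter
            mat[i, j] = mat[j, i] = inter / union
    return pd.DataFrame(mat, index=labels, columns=labels)


def elbow_threshold(
    scores: Sequence[float],
    fallback: float = DEFAULT_COASSOC_THRESHOLD,
) -> float:
    """Knee of the descending sorted-score curve by maximum chord distance.

    Scores are sorted descending into a curve (rank, score); both axes are
    scaled to [0, 1] and the threshold is the score at the point of
    maximum perpendicular distance to the chord joining the endpoints
    (ties -> smaller rank).  With fewer than three distinct scores or an
    essentially linear curve the configured fallback is returned with a
    warning.
    """
    s = np.sort(np.asarray(list(scores), dtype=float))[::-1]
    if np.unique(s).size < 3:
        warnings.warn("fewer than 3 distinct co-association scores; using fallback threshold")
        return fallback
    n = s.size
    x = np.linspace(0.0, 1.0, n)
    span = s[0] - s[-1]
    y = (s - s[-1]) / span
    # perpendicular distance to the chord from (0, y0) to (1, yn)
    x0, y0, x1, y1 = x[0], y[0], x[-1], y[-1]
    dist = np.abs((y1 - y0) * x - (x1 - x0) * y + x1 * y0 - y1 * x0)
    dist /= np.hypot(y1 - y0, x1 - x0)
    if dist.max() < 1e-9:
        warnings.warn("co-association score curve has no knee; using fallback threshold")
        return fallback
    return float(s[int(np.argmax(dist))])


@dataclass
class CoassociationNetwork:
    graph: nx.Graph
    threshold: float
    modules: list[set[str]] = field(default_factory=list)
    singletons: list[str] = field(default_factory=list)

    def module_of(self) -> dict[str, int]:
        return {tf: i for i, mod in enumerate(self.modules) for tf in mod}


def build_network_and_modules(
    matrix: pd.DataFrame, threshold: float
) -> CoassociationNetwork:
    """Threshold the co-association matrix into a weighted graph and extract modules.

    Edges keep pairs with Jaccard >= threshold (edge weight = score);
    modules are greedy modularity-maximizing communities on the connected
    part; nodes left without any edge are reported as singletons.  Node
    degree is stored as a size attribute for plotting.
    """
    g = nx.Graph()
    g.add_nodes_from(matrix.index)
    labels = list(matrix.index)
    for i, a in enumerate(labels):
        for b in labels[i + 1:]:
            score = float(matrix.loc[a, b])
            if score >= threshold:
                g.add_edge(a, b, weight=score)
    singletons = sorted(n for n in g.nodes if g.degree(n) == 0)
    connected = g.subgraph(n for n in g.nodes if g.degree(n) > 0)
    if connected.number_of_edges() == 0:
        warnings.warn("no co-association survives the threshold; empty network")
        modules: list[set[str]] = []
    else:
        communities = nx.community.greedy_modularity_communities(connected, weight="weight")
        modules = sorted((set(c) for c in communities), key=lambda m: sorted(m)[0])
    nx.set_node_attributes(g, dict(g.degree()), "degree")
    return CoassociationNetwork(graph=g, threshold=threshold, modules=modules, singletons=singletons)


def coassociation_pipeline(
    tf_peaksets: Mapping[str, Sequence[GenomicInterval]],
    threshold: float | None = None,
    min_peaks: int | None = None,
) -> tuple[pd.DataFrame, CoassociationNetwork]:
    """Matrix -> elbow threshold -> thresholded module network in one call.

    ``min_peaks`` optionally drops TFs with fewer peaks before scoring
    (a curation-style filter, off by default).
    """
    if min_peaks is not None:
        tf_peaksets = {tf: ivs for tf, ivs in tf_peaksets.items() if len(ivs) >= min_peaks}
    matrix = coassociation_matrix(tf_peaksets)
    if threshold is None:
        off_diag = matrix.to_numpy()[~np.eye(len(matrix), dtype=bool)]
        threshold = elbow_threshold(off_diag)
    network = build_network_and_modules(matrix, threshold)
    return matrix, network
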