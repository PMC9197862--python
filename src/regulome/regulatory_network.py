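"""Tripartite TF-miRNA-target meta-network and feed-forward-loop enumeration.

The meta-network layers upstream TFs (with binding data) above miRNA
genes and common target TF genes.  TF->miRNA and TF->gene edges come
from element target assignments; miRNA->gene edges come from a
prediction table filtered at a score cutoff (default <= 4, the
lower-is-better convention of plant miRNA target predictors).  A
feed-forward loop is a triple (a, m, b) with edges a->m, a->b and m->b
and a != b.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd
from scipy.stats import chi2_contingency

DEFAULT_MIRNA_SCORE_CUTOFF = 4.0


def filter_mirna_targets(
    table: pd.DataFrame,
    cutoff: float = DEFAULT_MIRNA_SCORE_CUTOFF,
    direction: str = "le",
) -> list[tuple[str, str]]:
    """Filter a (mirna_id, target_gene_id, score) table to retained edges.

    The default keeps rows with score <= cutoff (inclusive boundary);
    ``direction='ge'`` flips the retained set for higher-is-better
    predictors.  Duplicate (miRNA, gene) pairs are collapsed.
    """
    if direction not in ("le", "ge"):
        raise ValueError(f"direction must be 'le' or 'ge', got {direction!r}")
    if table.empty:
        return []
    scores = pd.to_numeric(table["score"], errors="coerce")
    if scores.isna().any():
        bad = int(scores.reset_index(drop=True).isna().idxmax())
        raise ValueError(f"non-numeric prediction score at row {bad}")
    keep = scores <= cutoff if direction == "le" else scores >= cutoff
    pairs = table.loc[keep, ["mirna_id", "target_gene_id"]].astype(str)
    return sorted(set(map(tuple, pairs.itertuples(index=False, name=None))))


@dataclass
class MetaNetwork:
    """Typed directed graph over upstream TFs, miRNAs and target TF genes."""

    graph: nx.DiGraph = field(default_factory=nx.DiGraph)
    dropped_edges: int = 0

    @property
    def upstream_tfs(self) -> set[str]:
        return {n for n, d in self.graph.nodes(data=True) if "upstream_TF" in d["roles"]}

    @property
    def mirnas(self) -> set[str]:
        return {n for n, d in self.graph.nodes(data=True) if "miRNA" in d["roles"]}

    @property
    def target_genes(self) -> set[str]:
        return {n for n, d in self.graph.nodes(data=True) if "target_gene" in d["roles"]}

    def edges_of_type(self, edge_type: str) -> list[tuple[str, str]]:
        return [
            (u, v) for u, v, t in self.graph.edges(data="edge_type") if t == edge_type
        ]


def build_meta_network(
    tf_targets: Mapping[str, Iterable[str]],
    mirna_edges: Sequence[tuple[str, str]],
    mirna_genes: Iterable[str],
    tf_gene_catalog: Iterable[str],
    restrict_targets_to_tf_catalog: bool = True,
) -> MetaNetwork:
    """Assemble the tripartite meta-network.

    ``tf_targets`` maps each upstream TF to the gene ids its elements were
    assigned to.  A target that is a miRNA gene becomes a tf_to_mirna
    edge; a target in the TF-gene catalog becomes a tf_to_gene edge;
    other targets are dropped (counted).  miRNA->gene edges outside the
    catalog are likewise dropped unless ``restrict_targets_to_tf_catalog``
    is off.  A gene may carry both the upstream-TF and target roles.
    """
    mirna_set = set(map(str, mirna_genes))
    catalog = set(map(str, tf_gene_catalog))
    net = MetaNetwork()
    g = net.graph

    def ensure(node: str, role: str) -> None:
        if node not in g:
            g.add_node(node, roles=set())
        g.nodes[node]["roles"].add(role)

    dropped = 0
    for tf, targets in tf_targets.items():
        tf = str(tf)
        ensure(tf, "upstream_TF")
        for target in targets:
            target = str(target)
            if target in mirna_set:
                ensure(target, "miRNA")
                g.add_edge(tf, target, edge_type="tf_to_mirna")
            elif target in catalog or not restrict_targets_to_tf_catalog:
                ensure(target, "target_gene")
                g.add_edge(tf, target, edge_type="tf_to_gene")
            else:
                dropped += 1
    for mirna, target in mirna_edges:
        mirna, target = str(mirna), str(target)
        if mirna not in mirna_set:
            dropped += 1
            continue
        if target not in catalog and restrict_targets_to_tf_catalog:
            dropped += 1
            continue
        ensure(mirna, "miRNA")
        ensure(target, "target_gene")
        g.add_edge(mirna, target, edge_type="mirna_to_gene")
    if dropped:
        warnings.warn(f"dropped {dropped} edges with endpoints outside the catalogs")
    net.dropped_edges = dropped
    return net


@dataclass(frozen=True, order=True)
class FeedForwardLoop:
    tf_a: str
    mirna: str
    tf_b: str


def enumerate_ffls(network: MetaNetwork) -> list[FeedForwardLoop]:
    """All (tf_a, mirna, tf_b) triples with edges a->m, a->b and m->b, a != b.

    Output is sorted lexicographically; a TF targeting its own gene
    (a == b) is not a loop since the motif needs three distinct roles.
    """
    g = network.graph
    loops: list[FeedForwardLoop] = []
    for a in network.upstream_tfs:
        mirnas = [v for v, t in ((v, d["edge_type"]) for v, d in g[a].items()) if t == "tf_to_mirna"]
        genes = {v for v, d in g[a].items() if d["edge_type"] == "tf_to_gene"}
        for m in mirnas:
            for b, d in g[m].items():
                if d["edge_type"] == "mirna_to_gene" and b in genes and b != a:
                    loops.append(FeedForwardLoop(a, m, b))
    return sorted(loops)


def overlap_enrichment(
    ffls_a: set, ffls_b: set, universe_size: int
) -> tuple[int, float | None, float | None]:
    """Chi-square association between two loop sets over a common universe.

    Builds the 2x2 membership contingency table and applies Pearson's
    chi-square (1 df, no continuity correction).  A degenerate table
    (zero margin) has no defined statistic: (overlap, None, None).
    """
    both = len(ffls_a & ffls_b)
    only_a = len(ffls_a) - both
    only_b = len(ffls_b) - both
    neither = universe_size - both - only_a - only_b
    if neither < 0:
        raise ValueError("universe smaller than the union of the two sets")
    table = [[both, only_a], [only_b, neither]]
    rows = [both + only_a, only_b + neither]
    cols = [both + only_b, only_a + neither]
    if 0 in rows or 0 in cols:
        warnings.warn("degenerate contingency table; chi-square undefined")
        return both, None, None
    stat, p, _dof, _exp = chi2_contingency(table, correction=False)
    return both, float(stat), float(p)


def ffls_to_frame(loops: Sequence[FeedForwardLoop]) -> pd.DataFrame:
    return pd.DataFrame(
        [(l.tf_a, l.mirna, l.tf_b) for l in loops],
        columns=["tf_a", "mirna", "tf_b"],
    )
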