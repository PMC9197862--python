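"""Promoter/enhancer classification and target-gene assignment.

Open-chromatin peaks are classified by the distance from their anchor
(summit when present, else interval midpoint) to the nearest annotated
TSS: strictly more than ``promoter_cutoff_bp`` away means enhancer, the
rest are promoters.  Elements are then linked to putative target genes:
genes whose bodies the element overlaps, or otherwise the nearest gene
start within N bp on each side, where N is the median intergenic size
capped at ``n_cap``.
"""

from __future__ import annotations

from bisect import bisect_left
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from regulome.core_io import GeneModel, GenomeAssembly, Peak, merge_intervals, tss


@dataclass
class AnnotationConfig:
    promoter_cutoff_bp: int = 1000
    n_cap: int = 3000
    anchor: str = "summit"  # summit when present, midpoint fallback
    single_nearest: bool = False  # strict single-nearest target mode

    def __post_init__(self) -> None:
        if self.promoter_cutoff_bp <= 0 or self.n_cap <= 0:
            raise ValueError("cutoffs must be positive")


@dataclass
class RegulatoryElement:
    peak: Peak
    element_class: str  # promoter | enhancer
    tss_distance: int | None  # None on an unannotated chromosome
    nearest_gene: str | None = None
    targets: list[tuple[str, str]] = field(default_factory=list)  # (gene_id, reason)


class _TssIndex:
    """Per-chromosome sorted TSS positions for nearest-neighbour queries."""

    def __init__(self, genes: Sequence[GeneModel]):
        tmp: dict[str, list[tuple[int, str]]] = {}
        for g in genes:
            chrom, pos = tss(g)
            tmp.setdefault(chrom, []).append((pos, g.gene_id))
        self.by_chrom: dict[str, tuple[list[int], list[str]]] = {}
        for chrom, pairs in tmp.items():
            # sort by position, then id, so equidistant ties resolve to the
            # lexicographically smaller gene id deterministically
            pairs.sort()
            self.by_chrom[chrom] = ([p for p, _ in pairs], [g for _, g in pairs])

    def nearest(self, chrom: str, pos: int) -> tuple[int, str] | None:
        entry = self.by_chrom.get(chrom)
        if entry is None:
            return None
        positions, ids = entry
        i = bisect_left(positions, pos)
        best: tuple[int, str] | None = None
        for j in (i - 1, i, i + 1):
            if 0 <= j < len(positions):
                cand = (abs(positions[j] - pos), ids[j])
                if best is None or cand < best:
                    best = cand
        return best


def distance_to_nearest_tss(
    chrom: str, pos: int, genes: Sequence[GeneModel]
) -> tuple[int, str] | None:
    """Minimum |bp| distance from a position to any TSS on its chromosome.

    Returns ``(distance, gene_id)`` with equidistant ties broken by the
    lexicographically smaller gene id, or ``None`` when the chromosome
    carries no annotated gene.
    """
    return _TssIndex(genes).nearest(chrom, pos)


def classify_elements(
    peaks: Sequence[Peak],
    genes: Sequence[GeneModel],
    config: AnnotationConfig | None = None,
) -> list[RegulatoryElement]:
    """Partition peaks into promoters and enhancers by anchor-to-TSS distance.

    Strictly greater than the cutoff is an enhancer; a distance equal to
    the cutoff is a promoter ("the rest").  Peaks on chromosomes without
    any annotated gene are classed as enhancers with distance ``None``.
    """
    config = config or AnnotationConfig()
    index = _TssIndex(genes)
    out: list[RegulatoryElement] = []
    for peak in peaks:
        anchor = peak.anchor if config.anchor == "summit" else peak.interval.midpoint
        hit = index.nearest(peak.interval.chrom, anchor)
        if hit is None:
            out.append(RegulatoryElement(peak, "enhancer", None, None))
            continue
        dist, gene_id = hit
        cls = "enhancer" if dist > config.promoter_cutoff_bp else "promoter"
        out.append(RegulatoryElement(peak, cls, dist, gene_id))
    return out


def median_intergenic_size(
    genes: Sequence[GeneModel],
    assembly: GenomeAssembly | None = None,
    n_cap: int = 3000,
) -> int:
    """Median gap between merged gene bodies, capped at ``n_cap``.

    Gaps at chromosome ends are excluded; only internal gaps between
    consecutive merged gene blocks count.  Even-count medians use the
    mean of the two middle gaps.
    """
    merged = merge_intervals([g.interval for g in genes])
    gaps: list[int] = []
    for prev, nxt in zip(merged, merged[1:]):
        if prev.chrom == nxt.chrom:
            gap = nxt.start - prev.end
            if gap > 0:
                gaps.append(gap)
    if not gaps:
        raise ValueError(
            "no internal intergenic gaps in the annotation; pass an explicit N instead"
        )
    n = float(np.median(gaps))
    return int(min(n, n_cap))


def assign_targets(
    element: RegulatoryElement,
    genes: Sequence[GeneModel],
    n_bp: int,
    single_nearest: bool = False,
) -> list[tuple[str, str]]:
    """Assign an element to putative target genes.

    If the element interval overlaps >= 1 gene body, all overlapping genes
    are targets (reason ``overlap``).  Otherwise the nearest gene start
    within ``n_bp`` on each side of the anchor is taken (at most one
    upstream and one downstream, so at most two genes); with
    ``single_nearest`` only the closer of the two is kept.
    """
    if n_bp <= 0:
        raise ValueError("target window N must be positive")
    iv = element.peak.interval
    overlapping = sorted(g.gene_id for g in genes if g.interval.overlaps(iv))
    if overlapping:
        result = [(gid, "overlap") for gid in overlapping]
        element.targets = result
        return result
    anchor = element.peak.anchor
    best_left: tuple[int, str] | None = None
    best_right: tuple[int, str] | None = None
    for g in genes:
        chrom, pos = tss(g)
        if chrom != iv.chrom:
            continue
        dist = abs(pos - anchor)
        if dist > n_bp:
            continue
        if pos <= anchor:
            cand = (dist, g.gene_id)
            if best_left is None or cand < best_left:
                best_left = cand
        else:
            cand = (dist, g.gene_id)
            if best_right is None or cand < best_right:
                best_right = cand
    result = []
    if best_left is not None:
        result.append((best_left[1], "nearest_upstream"))
    if best_right is not None:
        result.append((best_right[1], "nearest_downstream"))
    if single_nearest and len(result) == 2:
        keep = best_left if best_left <= best_right else best_right  # type: ignore[operator]
        reason = "nearest_upstream" if keep is best_left else "nearest_downstream"
        result = [(keep[1], reason)]  # type: ignore[index]
    element.targets = result
    return result


def annotate(
    peaks: Sequence[Peak],
    genes: Sequence[GeneModel],
    config: AnnotationConfig | None = None,
    assembly: GenomeAssembly | None = None,
) -> list[RegulatoryElement]:
    """classify_elements followed by target assignment for every element."""
    config = config or AnnotationConfig()
    elements = classify_elements(peaks, genes, config)
    n_bp = median_intergenic_size(genes, assembly, n_cap=config.n_cap)
    for element in elements:
        assign_targets(element, genes, n_bp, single_nearest=config.single_nearest)
    return elements


def elements_to_frame(elements: Sequence[RegulatoryElement]) -> pd.DataFrame:
    """Tabular view of annotated elements (one row per element)."""
    rows = []
    for i, el in enumerate(elements):
        iv = el.peak.interval
        rows.append(
            {
                "element_id": el.peak.name if el.peak.name != "." else f"el{i}",
                "chrom": iv.chrom,
                "start": iv.start,
                "end": iv.end,
                "class": el.element_class,
                "tss_distance": -1 if el.tss_distance is None else el.tss_distance,
                "nearest_gene": el.nearest_gene or "",
                "targets": ";".join(f"{g}:{r}" for g, r in el.targets),
            }
        )
    return pd.DataFrame(rows)


def write_elements_tsv(elements: Sequence[RegulatoryElement], path: str | Path) -> None:
    elements_to_frame(elements).to_csv(path, sep="\t", index=False)
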