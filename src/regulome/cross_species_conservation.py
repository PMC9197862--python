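"""Chain-based projection of regulatory regions between genomes and
conservation scoring.

An element is projected through the gapless blocks of a whole-genome
alignment chain set.  When an element intersects several blocks, only
the single (chain, block) pair with the largest bp overlap is used, so
every element maps to at most one orthologous interval.  An alignable
element is conserved in the other species when its orthologous interval
is covered by a peak there by at least ``min_overlap_fraction``
(default 50%, inclusive).  Across S comparison species the element's
alignability score counts species where projection succeeds and its
conservation score counts species that additionally carry a peak —
0 <= conservation <= alignability <= S.

Chromatin-state conservation between two segmentations uses the same
chains but projects *all* state bp (blockwise, bp-resolved) and reports
a base-pair Jaccard of the projected state-s track against the state-t
track of the other species.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

from regulome.core_io import (
    AlignmentChainSet,
    ChromatinSegmentation,
    GenomicInterval,
    intersect_bp,
    merge_intervals,
    total_bp,
)


@dataclass
class ProjectionResult:
    element_id: str
    status: str  # "alignable" | "unalignable"
    chain_id: int | None = None
    orthologous: GenomicInterval | None = None
    aligned_bp: int = 0


def _project_piece(
    chain_strand: str,
    s_start: int,
    t_start: int,
    t_end: int,
    lo: int,
    hi: int,
) -> GenomicInterval | None:
    """Linear projection of source sub-interval [lo, hi) within one block."""
    if chain_strand == "+":
        return (t_start + (lo - s_start), t_start + (hi - s_start))
    # minus: source s_start + k  ->  target t_end - 1 - k (forward frame)
    return (t_end - (hi - s_start), t_end - (lo - s_start))


def project_interval(
    element: GenomicInterval,
    chains: AlignmentChainSet,
    element_id: str = ".",
    min_aligned_fraction: float = 0.0,
) -> ProjectionResult:
    """Project an element into the target genome through alignment chains.

    Among all gapless blocks intersecting the element, the single block
    with the largest bp overlap wins (ties -> higher chain score, then
    smaller chain id); the overlapping piece is mapped linearly into
    target coordinates.  ``min_aligned_fraction`` optionally demands
    a minimum fraction of the element's length to be covered by the
    winning block (default: any positive overlap counts as alignable).
    """
    best: tuple[int, float, int] | None = None  # (overlap, score, -chain_id), max wins
    best_record: tuple[int, GenomicInterval] | None = None
    for chain in chains.chains_on(element.chrom):
        if chain.source_end <= element.start or chain.source_start >= element.end:
            continue
        for s0, s1, t0, t1 in chain.block_pairs():
            lo = max(element.start, s0)
            hi = min(element.end, s1)
            if lo >= hi:
                continue
            overlap = hi - lo
            key = (overlap, chain.score, -chain.chain_id)
            if best is None or key > best:
                best = key
                p0, p1 = _project_piece(chain.target_strand, s0, t0, t1, lo, hi)
                best_record = (
                    chain.chain_id,
                    GenomicInterval(chain.target_chrom, p0, p1),
                )
    if best is None or best_record is None:
        return ProjectionResult(element_id=element_id, status="unalignable")
    overlap = best[0]
    if overlap < min_aligned_fraction * len(element):
        return ProjectionResult(element_id=element_id, status="unalignable")
    chain_id, ortho = best_record
    return ProjectionResult(
        element_id=element_id,
        status="alignable",
        chain_id=chain_id,
        orthologous=ortho,
        aligned_bp=overlap,
    )


def is_conserved(
    projection: ProjectionResult,
    target_peaks: Sequence[GenomicInterval],
    min_overlap_fraction: float = 0.5,
) -> bool:
    """Does the orthologous interval overlap a peak by >= the minimum fraction?

    The denominator is the orthologous-interval length and the boundary
    is inclusive (an exact 50% overlap is conserved).  ``target_peaks``
    should be pre-merged for efficiency; merging here is a safeguard.
    """
    if projection.status != "alignable" or projection.orthologous is None:
        raise ValueError("is_conserved requires an alignable projection")
    ortho = projection.orthologous
    merged = merge_intervals(list(target_peaks))
    covered = sum(ortho.overlap_bp(m) for m in merged if m.chrom == ortho.chrom)
    return covered / len(ortho) >= min_overlap_fraction


@dataclass
class ConservationRecord:
    element_id: str
    alignable: dict[str, bool]
    conserved: dict[str, bool]

    @property
    def alignability_score(self) -> int:
        return sum(self.alignable.values())

    @property
    def conservation_score(self) -> int:
        return sum(self.conserved.values())


def conservation_scores(
    elements: Sequence[tuple[str, GenomicInterval]],
    species_inputs: Mapping[str, tuple[AlignmentChainSet, Sequence[GenomicInterval]]],
    min_overlap_fraction: float = 0.5,
    min_aligned_fraction: float = 0.0,
) -> list[ConservationRecord]:
    """Per-element alignability and conservation counts across species.

    ``species_inputs`` maps a comparison-species name to its chain set
    (reference -> species) and its peak intervals.  For each element and
    species: alignable if the projection succeeds, conserved if the
    orthologous interval additionally carries a peak at the overlap
    threshold.
    """
    if not species_inputs:
        raise ValueError("at least one comparison species is required")
    merged_peaks = {
        sp: merge_intervals(list(peaks)) for sp, (_c, peaks) in species_inputs.items()
    }
    records: list[ConservationRecord] = []
    for element_id, iv in elements:
        alignable: dict[str, bool] = {}
        conserved: dict[str, bool] = {}
        for sp, (chains, _peaks) in species_inputs.items():
            proj = project_interval(iv, chains, element_id, min_aligned_fraction)
            ok = proj.status == "alignable"
            alignable[sp] = ok
            conserved[sp] = ok and is_conserved(proj, merged_peaks[sp], min_overlap_fraction)
        records.append(ConservationRecord(element_id, alignable, conserved))
    return records


def project_track(
    intervals: Sequence[GenomicInterval], chains: AlignmentChainSet
) -> list[GenomicInterval]:
    """Blockwise, bp-resolved projection of a whole track (all pieces kept)."""
    pieces: list[GenomicInterval] = []
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in merge_intervals(list(intervals)):
        by_chrom.setdefault(iv.chrom, []).append(iv)
    for chain in chains.chains:
        track = by_chrom.get(chain.source_chrom)
        if not track:
            continue
        for s0, s1, t0, t1 in chain.block_pairs():
            for iv in track:
                lo = max(iv.start, s0)
                hi = min(iv.end, s1)
                if lo < hi:
                    p0, p1 = _project_piece(chain.target_strand, s0, t0, t1, lo, hi)
                    pieces.append(GenomicInterval(chain.target_chrom, p0, p1))
    return merge_intervals(pieces)


def state_conservation_jaccard(
    seg_a: ChromatinSegmentation,
    state_s: str,
    seg_b: ChromatinSegmentation,
    state_t: str,
    chains: AlignmentChainSet,
) -> float:
    """Cross-species chromatin-state Jaccard: conserved bp over union bp.

    All state-s bp of species a are projected into b coordinates;
    conserved bp are those landing in state-t regions of b, and the
    denominator is the union of the projected-s track and the state-t
    track (both in b coordinates).  A state absent from its segmentation
    scores 0 with a warning.
    """
    track_s = seg_a.intervals_of(state_s)
    track_t = seg_b.intervals_of(state_t)
    if not track_s or not track_t:
        warnings.warn(f"state {state_s!r} or {state_t!r} absent from segmentation; score 0")
        return 0.0
    projected = project_track(track_s, chains)
    merged_t = merge_intervals(track_t)
    if not projected:
        return 0.0
    inter = intersect_bp(projected, merged_t)
    union = total_bp(projected) + total_bp(merged_t) - inter
    return inter / union
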