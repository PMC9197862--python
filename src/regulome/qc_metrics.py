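"""ENCODE-style library-complexity and enrichment metrics.

Library complexity is summarized by the non-redundant fraction (NRF) and
the PCR bottlenecking coefficients PBC1 and PBC2, computed over
deduplication-eligible read positions keyed by (chromosome, strand,
5' end).  Enrichment is summarized by the fraction of reads in peaks
(FRiP).  Upstream signal metrics that require external tools (SPOT,
NSC/RSC) are out of scope.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from regulome.core_io import GenomicInterval, Peak, merge_intervals


@dataclass
class ReadPositionTally:
    """Multiset of read positions keyed by (chrom, strand, 5' position)."""

    counts: Counter = field(default_factory=Counter)

    @property
    def total_reads(self) -> int:
        return sum(self.counts.values())

    @classmethod
    def from_fragments(cls, fragments: Iterable[GenomicInterval]) -> "ReadPositionTally":
        """Tally fragment 5' ends: start on +, last base on -.

        Unstranded fragments are treated as plus-strand.
        """
        counts: Counter = Counter()
        for frag in fragments:
            if frag.strand == "-":
                counts[(frag.chrom, "-", frag.end - 1)] += 1
            else:
                counts[(frag.chrom, "+", frag.start)] += 1
        return cls(counts=counts)


def library_complexity(tally: ReadPositionTally) -> tuple[float, float, float]:
    """NRF, PBC1 and PBC2 of a read-position tally.

    NRF = distinct positions / total reads; PBC1 = M1 / M_distinct;
    PBC2 = M1 / M2, where M1 and M2 are the numbers of positions observed
    exactly once and exactly twice.  With M2 = 0 the PBC2 ratio is
    reported as +inf (a maximally complex library).
    """
    total = tally.total_reads
    if total == 0:
        raise ValueError("empty read tally: library complexity is undefined")
    distinct = len(tally.counts)
    m1 = sum(1 for c in tally.counts.values() if c == 1)
    m2 = sum(1 for c in tally.counts.values() if c == 2)
    nrf = distinct / total
    pbc1 = m1 / distinct
    pbc2 = m1 / m2 if m2 > 0 else math.inf
    return nrf, pbc1, pbc2


def frip(
    fragments: Sequence[GenomicInterval],
    peaks: Sequence[Peak],
    mode: str = "overlap",
) -> float:
    """Fraction of fragments falling in the merged peak set.

    ``mode='overlap'`` counts a fragment when it shares >= 1 bp with a
    merged peak (the default, matching common practice); ``mode='5prime'``
    requires the fragment's 5' end to lie inside a peak.
    """
    if not fragments:
        raise ValueError("FRiP undefined on an empty fragment list")
    if mode not in ("overlap", "5prime"):
        raise ValueError(f"unknown FRiP mode {mode!r}")
    merged = merge_intervals([p.interval for p in peaks])
    if not merged:
        return 0.0
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in merged:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    starts = {c: [iv.start for iv in ivs] for c, ivs in by_chrom.items()}
    import bisect

    hits = 0
    for frag in fragments:
        ivs = by_chrom.get(frag.chrom)
        if not ivs:
            continue
        if mode == "5prime":
            pos = frag.end - 1 if frag.strand == "-" else frag.start
            lo, hi = pos, pos + 1
        else:
            lo, hi = frag.start, frag.end
        # rightmost merged block starting at or before hi-1 can overlap [lo,hi)
        idx = bisect.bisect_right(starts[frag.chrom], hi - 1) - 1
        if idx >= 0 and ivs[idx].end > lo:
            hits += 1
    return hits / len(fragments)


@dataclass
class QcThresholds:
    """Pass/fail boundaries per metric (ENCODE guideline defaults)."""

    nrf_pass: float = 0.8
    pbc1_pass: float = 0.8
    pbc2_pass: float = 3.0
    frip_pass: float = 0.01


@dataclass
class QcReport:
    nrf: float
    pbc1: float
    pbc2: float
    frip: float
    tiers: dict[str, str] = field(default_factory=dict)


def qc_report(
    fragments: Sequence[GenomicInterval],
    peaks: Sequence[Peak],
    thresholds: QcThresholds | None = None,
) -> QcReport:
    """Full QC summary of one experiment: complexity plus enrichment."""
    thresholds = thresholds or QcThresholds()
    tally = ReadPositionTally.from_fragments(fragments)
    nrf, pbc1, pbc2 = library_complexity(tally)
    frip_value = frip(fragments, peaks)
    tiers = {
        "nrf": "pass" if nrf >= thresholds.nrf_pass else "concern",
        "pbc1": "pass" if pbc1 >= thresholds.pbc1_pass else "concern",
        "pbc2": "pass" if pbc2 >= thresholds.pbc2_pass else "concern",
        "frip": "pass" if frip_value >= thresholds.frip_pass else "concern",
    }
    return QcReport(nrf=nrf, pbc1=pbc1, pbc2=pbc2, frip=frip_value, tiers=tiers)
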