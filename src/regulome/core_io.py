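"""Domain types and readers/writers for the standard formats the pipeline touches.

All internal coordinates are 0-based half-open.  GFF3 (1-based inclusive)
is converted at the boundary; UCSC chain target blocks on the minus strand
are flipped to forward coordinates when block arithmetic is expanded, while
the on-disk reversed-frame representation is preserved for lossless
round-tripping.  Chromosome label matching is exact: no "chr"-prefix
normalization is ever applied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import pandas as pd


class ParseError(ValueError):
    """A file did not conform to its declared dialect."""


class ValidationError(ValueError):
    """Parsed content violated a domain invariant."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GenomeAssembly:
    """A named genome build: chromosome labels and their lengths in bp."""

    name: str
    chrom_sizes: dict[str, int]

    def __post_init__(self) -> None:
        for chrom, size in self.chrom_sizes.items():
            if size <= 0:
                raise ValidationError(f"chromosome {chrom!r} has non-positive length {size}")

    @property
    def total_bp(self) -> int:
        return sum(self.chrom_sizes.values())


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """0-based half-open interval [start, end) on a chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValidationError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} (need 0 <= start < end)"
            )
        if self.strand not in ("+", "-", "."):
            raise ValidationError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return self.start + (self.end - self.start) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_bp(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass(frozen=True)
class Peak:
    """A called peak: an interval plus optional summit offset and score.

    ``summit_offset`` is measured in bp from ``interval.start``; ``None``
    encodes the narrowPeak sentinel ``-1`` (summit not determined).
    """

    interval: GenomicInterval
    summit_offset: int | None = None
    score: float = 0.0
    name: str = "."

    def __post_init__(self) -> None:
        if self.summit_offset is not None and not 0 <= self.summit_offset < len(self.interval):
            raise ValidationError(
                f"summit offset {self.summit_offset} outside peak {self.name} "
                f"of length {len(self.interval)}"
            )
        if self.score < 0:
            raise ValidationError(f"negative peak score {self.score}")

    @property
    def anchor(self) -> int:
        """Summit position if known, else the interval midpoint."""
        if self.summit_offset is not None:
            return self.interval.start + self.summit_offset
        return self.interval.midpoint


@dataclass(frozen=True)
class GeneModel:
    """A gene body with mandatory strand, a unique id, and a coarse biotype."""

    interval: GenomicInterval
    gene_id: str
    biotype: str = "protein_coding"

    def __post_init__(self) -> None:
        if self.interval.strand not in ("+", "-"):
            raise ValidationError(f"gene {self.gene_id} must be stranded, got {self.interval.strand!r}")
        if self.biotype not in ("protein_coding", "miRNA", "other"):
            raise ValidationError(f"gene {self.gene_id}: unknown biotype {self.biotype!r}")


def tss(gene: GeneModel) -> tuple[str, int]:
    """Transcription start site of a gene (0-based position).

    For plus-strand genes this is the interval start; for minus-strand
    genes the last base of the interval.  For miRNA genes the same rule
    gives the 5' end of the precursor.
    """
    iv = gene.interval
    if iv.strand == "+":
        return iv.chrom, iv.start
    return iv.chrom, iv.end - 1


@dataclass
class ChromatinSegmentation:
    """Non-overlapping labeled intervals assigning each covered bp one state."""

    segments: list[tuple[GenomicInterval, str]]

    def __post_init__(self) -> None:
        by_chrom: dict[str, list[GenomicInterval]] = {}
        for iv, _state in self.segments:
            by_chrom.setdefault(iv.chrom, []).append(iv)
        for chrom, ivs in by_chrom.items():
            ivs = sorted(ivs, key=lambda i: i.start)
            for a, b in zip(ivs, ivs[1:]):
                if b.start < a.end:
                    raise ValidationError(
                        f"overlapping segments on {chrom}: [{a.start},{a.end}) and [{b.start},{b.end})"
                    )

    @property
    def states(self) -> set[str]:
        return {state for _iv, state in self.segments}

    def intervals_of(self, state: str) -> list[GenomicInterval]:
        return [iv for iv, s in self.segments if s == state]


@dataclass
class Chain:
    """One UCSC chain record: gapless blocks linking source and target spans.

    The source span is always on the plus strand.  ``target_start``/
    ``target_end`` are stored as written in the file, i.e. in the reversed
    frame when ``target_strand == '-'``; :meth:`block_pairs` exposes
    forward-strand target coordinates.
    """

    chain_id: int
    score: float
    source_chrom: str
    source_size: int
    source_start: int
    source_end: int
    target_chrom: str
    target_size: int
    target_strand: str
    target_start: int
    target_end: int
    # (block_size, gap_after_source, gap_after_target); last block has gaps (0, 0)
    blocks: list[tuple[int, int, int]] = field(default_factory=list)

    def validate(self) -> None:
        if not self.blocks:
            raise ValidationError(f"chain {self.chain_id}: no alignment blocks")
        if any(size <= 0 for size, _dt, _dq in self.blocks):
            raise ValidationError(f"chain {self.chain_id}: non-positive block size")
        if self.blocks[-1][1] != 0 or self.blocks[-1][2] != 0:
            raise ValidationError(f"chain {self.chain_id}: last block carries gaps")
        span_s = sum(size + dt for size, dt, _dq in self.blocks)
        span_t = sum(size + dq for size, _dt, dq in self.blocks)
        if span_s != self.source_end - self.source_start:
            raise ValidationError(
                f"chain {self.chain_id}: source block arithmetic mismatch "
                f"({span_s} != {self.source_end - self.source_start})"
            )
        if span_t != self.target_end - self.target_start:
            raise ValidationError(
                f"chain {self.chain_id}: target block arithmetic mismatch "
                f"({span_t} != {self.target_end - self.target_start})"
            )

    def block_pairs(self) -> Iterator[tuple[int, int, int, int]]:
        """Yield (src_start, src_end, tgt_fwd_start, tgt_fwd_end) per gapless block.

        Target coordinates are forward-strand; for a minus-strand chain the
        source position ``src_start + k`` maps to ``tgt_fwd_end - 1 - k``.
        """
        s = self.source_start
        t = self.target_start
        for size, dt, dq in self.blocks:
            if self.target_strand == "+":
                yield s, s + size, t, t + size
            else:
                yield s, s + size, self.target_size - (t + size), self.target_size - t
            s += size + dt
            t += size + dq


@dataclass
class AlignmentChainSet:
    """A validated collection of chains, the substrate for interval projection."""

    chains: list[Chain]

    def __post_init__(self) -> None:
        for chain in self.chains:
            chain.validate()

    def chains_on(self, chrom: str) -> list[Chain]:
        return [c for c in self.chains if c.source_chrom == chrom]


# ---------------------------------------------------------------------------
# BED / narrowPeak
# ---------------------------------------------------------------------------

_NARROWPEAK_COLS = 10
_BED6_COLS = 6


def read_bed(path: str | Path, dialect: str = "bed6") -> list[Peak]:
    """Read a BED6 or ENCODE narrowPeak file into Peaks.

    narrowPeak column 10 is the summit offset from the interval start,
    with ``-1`` meaning "summit absent".  BED6 peaks never carry a summit.
    """
    if dialect not in ("bed6", "narrowPeak"):
        raise ValueError(f"unknown BED dialect {dialect!r}")
    want = _NARROWPEAK_COLS if dialect == "narrowPeak" else _BED6_COLS
    peaks: list[Peak] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < want:
                raise ParseError(f"{path}:{lineno}: expected >= {want} columns, got {len(fields)}")
            try:
                chrom, start, end = fields[0], int(fields[1]), int(fields[2])
                name = fields[3] if len(fields) > 3 else "."
                score = float(fields[4]) if len(fields) > 4 and fields[4] != "." else 0.0
                strand = fields[5] if len(fields) > 5 else "."
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            if end <= start:
                raise ValidationError(f"{path}:{lineno}: end {end} <= start {start}")
            summit: int | None = None
            if dialect == "narrowPeak":
                try:
                    raw = int(fields[9])
                except ValueError as exc:
                    raise ParseError(f"{path}:{lineno}: bad summit column: {exc}") from exc
                summit = None if raw == -1 else raw
            peaks.append(
                Peak(
                    interval=GenomicInterval(chrom, start, end, strand if strand in "+-" else "."),
                    summit_offset=summit,
                    score=score,
                    name=name,
                )
            )
    return peaks


def write_bed(peaks: Iterable[Peak], path: str | Path, dialect: str = "bed6") -> None:
    """Write peaks in BED6 or narrowPeak; inverse of :func:`read_bed`."""
    if dialect not in ("bed6", "narrowPeak"):
        raise ValueError(f"unknown BED dialect {dialect!r}")
    with open(path, "w") as fh:
        for p in peaks:
            iv = p.interval
            base = [iv.chrom, str(iv.start), str(iv.end), p.name, _fmt_score(p.score), iv.strand]
            if dialect == "narrowPeak":
                summit = -1 if p.summit_offset is None else p.summit_offset
                base += [_fmt_score(p.score), "-1", "-1", str(summit)]
            fh.write("\t".join(base) + "\n")


def _fmt_score(x: float) -> str:
    return str(int(x)) if float(x).is_integer() else repr(float(x))


def read_intervals_bed(path: str | Path) -> list[GenomicInterval]:
    """Read a minimal >=3-column BED into bare intervals (e.g. fragments)."""
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: expected >= 3 columns")
            strand = fields[5] if len(fields) > 5 and fields[5] in "+-" else "."
            out.append(GenomicInterval(fields[0], int(fields[1]), int(fields[2]), strand))
    return out


def write_intervals_bed(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t.\t0\t{iv.strand}\n")


# ---------------------------------------------------------------------------
# Segmentation BED (4 columns: chrom start end state)
# ---------------------------------------------------------------------------


def read_segmentation(path: str | Path) -> ChromatinSegmentation:
    segments: list[tuple[GenomicInterval, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ParseError(f"{path}:{lineno}: expected 4 columns (chrom start end state)")
            segments.append((GenomicInterval(fields[0], int(fields[1]), int(fields[2])), fields[3]))
    return ChromatinSegmentation(segments)


def write_segmentation(seg: ChromatinSegmentation, path: str | Path) -> None:
    ordered = sorted(seg.segments, key=lambda t: (t[0].chrom, t[0].start))
    with open(path, "w") as fh:
        for iv, state in ordered:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{state}\n")


# ---------------------------------------------------------------------------
# GFF3 genes
# ---------------------------------------------------------------------------


def read_gff3_genes(path: str | Path) -> list[GeneModel]:
    """Extract ``gene`` features from a GFF3 file.

    GFF3 1-based inclusive coordinates are converted to the internal
    0-based half-open convention.  A gene without an ``ID`` attribute or
    with strand ``.`` is a validation error: downstream TSS logic is
    undefined without them.
    """
    genes: list[GeneModel] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ParseError(f"{path}:{lineno}: expected 9 GFF3 columns, got {len(fields)}")
            if fields[2] != "gene":
                continue
            chrom, start1, end1, strand, attrs = fields[0], fields[3], fields[4], fields[6], fields[8]
            attributes = _parse_gff3_attributes(attrs)
            gene_id = attributes.get("ID")
            if gene_id is None:
                raise ValidationError(f"{path}:{lineno}: gene feature lacks an ID attribute")
            if strand not in ("+", "-"):
                raise ValidationError(f"{path}:{lineno}: gene {gene_id} has strand {strand!r}")
            if gene_id in seen:
                raise ValidationError(f"{path}:{lineno}: duplicate gene ID {gene_id!r}")
            seen.add(gene_id)
            biotype = attributes.get("biotype", "protein_coding")
            if biotype not in ("protein_coding", "miRNA", "other"):
                biotype = "other"
            genes.append(
                GeneModel(
                    interval=GenomicInterval(chrom, int(start1) - 1, int(end1), strand),
                    gene_id=gene_id,
                    biotype=biotype,
                )
            )
    return genes


def _parse_gff3_attributes(text: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for part in text.split(";"):
        part = part.strip()
        if not part or "=" not in part:
            continue
        key, value = part.split("=", 1)
        out[key] = value
    return out


def write_gff3_genes(genes: Iterable[GeneModel], path: str | Path, source: str = "regulome") -> None:
    """Write GeneModels as GFF3 gene features (1-based inclusive on disk)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            iv = g.interval
            fh.write(
                f"{iv.chrom}\t{source}\tgene\t{iv.start + 1}\t{iv.end}\t.\t{iv.strand}\t.\t"
                f"ID={g.gene_id};biotype={g.biotype}\n"
            )


# ---------------------------------------------------------------------------
# UCSC chain
# ---------------------------------------------------------------------------


def read_chain(path: str | Path) -> AlignmentChainSet:
    """Parse a UCSC chain file, validating block arithmetic per record."""
    chains: list[Chain] = []
    current: Chain | None = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith("chain"):
                fields = line.split()
                if len(fields) != 13:
                    raise ParseError(f"{path}:{lineno}: chain header needs 13 fields")
                (_kw, score, s_chrom, s_size, s_strand, s_start, s_end,
                 t_chrom, t_size, t_strand, t_start, t_end, chain_id) = fields
                if s_strand != "+":
                    raise ValidationError(f"{path}:{lineno}: source strand must be '+'")
                if t_strand not in ("+", "-"):
                    raise ValidationError(f"{path}:{lineno}: bad target strand {t_strand!r}")
                current = Chain(
                    chain_id=int(chain_id),
                    score=float(score),
                    source_chrom=s_chrom,
                    source_size=int(s_size),
                    source_start=int(s_start),
                    source_end=int(s_end),
                    target_chrom=t_chrom,
                    target_size=int(t_size),
                    target_strand=t_strand,
                    target_start=int(t_start),
                    target_end=int(t_end),
                )
                chains.append(current)
            else:
                if current is None:
                    raise ParseError(f"{path}:{lineno}: block line outside a chain record")
                parts = line.split()
                if len(parts) == 1:
                    current.blocks.append((int(parts[0]), 0, 0))
                elif len(parts) == 3:
                    current.blocks.append((int(parts[0]), int(parts[1]), int(parts[2])))
                else:
                    raise ParseError(f"{path}:{lineno}: block line needs 1 or 3 fields")
    return AlignmentChainSet(chains)


def write_chain(chain_set: AlignmentChainSet, path: str | Path) -> None:
    """Write chains in UCSC chain format; inverse of :func:`read_chain`."""
    with open(path, "w") as fh:
        for c in chain_set.chains:
            fh.write(
                f"chain {_fmt_score(c.score)} {c.source_chrom} {c.source_size} + "
                f"{c.source_start} {c.source_end} {c.target_chrom} {c.target_size} "
                f"{c.target_strand} {c.target_start} {c.target_end} {c.chain_id}\n"
            )
            for size, dt, dq in c.blocks[:-1]:
                fh.write(f"{size} {dt} {dq}\n")
            fh.write(f"{c.blocks[-1][0]}\n\n")


# ---------------------------------------------------------------------------
# chrom.sizes and accessibility matrices
# ---------------------------------------------------------------------------


def read_chrom_sizes(path: str | Path, name: str = "assembly") -> GenomeAssembly:
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ParseError(f"{path}:{lineno}: expected two tab-separated columns")
            if fields[0] in sizes:
                raise ValidationError(f"{path}:{lineno}: duplicate chromosome {fields[0]!r}")
            sizes[fields[0]] = int(fields[1])
    return GenomeAssembly(name=name, chrom_sizes=sizes)


def write_chrom_sizes(assembly: GenomeAssembly, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, size in assembly.chrom_sizes.items():
            fh.write(f"{chrom}\t{size}\n")


def read_accessibility_matrix(path: str | Path) -> pd.DataFrame:
    """Elements x tissues TSV: first column element id, header = tissue labels."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[1] < 2:
        raise ValidationError("accessibility matrix needs >= 2 tissue columns")
    if df.columns.duplicated().any():
        raise ValidationError("duplicate tissue labels in accessibility matrix")
    if (df.values < 0).any():
        raise ValidationError("accessibility matrix contains negative values")
    return df


def write_accessibility_matrix(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", float_format="%.6g", index_label="element_id")


# ---------------------------------------------------------------------------
# Interval algebra
# ---------------------------------------------------------------------------


def merge_intervals(intervals: Sequence[GenomicInterval]) -> list[GenomicInterval]:
    """Merge a set of intervals into sorted, disjoint, non-touching blocks.

    Touching intervals ([0,5) + [5,9)) are fused.  Strand is discarded:
    merged blocks are unstranded occupancy footprints.
    """
    if not intervals:
        return []
    ordered = sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
    merged: list[GenomicInterval] = []
    cur_chrom, cur_start, cur_end = ordered[0].chrom, ordered[0].start, ordered[0].end
    for iv in ordered[1:]:
        if iv.chrom == cur_chrom and iv.start <= cur_end:
            cur_end = max(cur_end, iv.end)
        else:
            merged.append(GenomicInterval(cur_chrom, cur_start, cur_end))
            cur_chrom, cur_start, cur_end = iv.chrom, iv.start, iv.end
    merged.append(GenomicInterval(cur_chrom, cur_start, cur_end))
    return merged


def total_bp(merged: Sequence[GenomicInterval]) -> int:
    """Total covered bp of a (pre-merged) interval list."""
    return sum(len(iv) for iv in merged)


def intersect_merged(a: Sequence[GenomicInterval], b: Sequence[GenomicInterval]) -> list[GenomicInterval]:
    """Intersection of two merged interval lists (linear sweep per chromosome)."""
    out: list[GenomicInterval] = []
    by_chrom_b: dict[str, list[GenomicInterval]] = {}
    for iv in b:
        by_chrom_b.setdefault(iv.chrom, []).append(iv)
    by_chrom_a: dict[str, list[GenomicInterval]] = {}
    for iv in a:
        by_chrom_a.setdefault(iv.chrom, []).append(iv)
    for chrom, ivs_a in by_chrom_a.items():
        ivs_b = by_chrom_b.get(chrom)
        if not ivs_b:
            continue
        i = j = 0
        while i < len(ivs_a) and j < len(ivs_b):
            lo = max(ivs_a[i].start, ivs_b[j].start)
            hi = min(ivs_a[i].end, ivs_b[j].end)
            if lo < hi:
                out.append(GenomicInterval(chrom, lo, hi))
            if ivs_a[i].end <= ivs_b[j].end:
                i += 1
            else:
                j += 1
    return sorted(out, key=lambda iv: (iv.chrom, iv.start))


def intersect_bp(a: Sequence[GenomicInterval], b: Sequence[GenomicInterval]) -> int:
    """Shared bp between two merged interval lists."""
    return total_bp(intersect_merged(a, b))


def covered_fraction(iv: GenomicInterval, merged: Sequence[GenomicInterval]) -> float:
    """Fraction of ``iv`` covered by a merged interval list."""
    covered = sum(iv.overlap_bp(m) for m in merged if m.chrom == iv.chrom)
    return covered / len(iv)
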