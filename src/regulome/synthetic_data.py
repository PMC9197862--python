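"""Seeded generators for every input the pipeline consumes.

Each generator emits standard files (GFF3, narrowPeak/BED, TSV matrices,
UCSC chain) together with the planted ground truth, so every downstream
stage can be validated by recovery experiments without any external
download.  All randomness flows from a single integer seed fanned out to
independent per-generator streams keyed by (seed, generator name), so
adding one generator never perturbs another.

What is emulated (and what is not): gene bodies are non-overlapping with
gamma-distributed lengths and intergenic gaps; accessibility profiles
are either tissue-specific (weight w on one tissue, the remainder spread
uniformly) or broad (symmetric Dirichlet), with multiplicative
log-normal noise; TF peak sets share per-module site pools with inside/
outside inclusion probabilities; the miRNA meta-network samples edges
independently; species pairs share one blockwise partition of the
reference genome, with per-species block survival and per-peak copy
probabilities.  There is no sequence, no read-level error model, no
indel structure within alignment blocks and no inversions by default.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import gamma as gamma_dist

from regulome.core_io import (
    AlignmentChainSet,
    Chain,
    GeneModel,
    GenomeAssembly,
    GenomicInterval,
    Peak,
    write_bed,
    write_chain,
    write_chrom_sizes,
    write_gff3_genes,
    write_accessibility_matrix,
    write_intervals_bed,
)


class ConfigurationError(ValueError):
    pass


@dataclass
class SimulationConfig:
    """The stated world: sample sizes, effect sizes and rates for all generators."""

    seed: int = 0

    # genome and gene annotation
    n_chroms: int = 2
    chrom_length_bp: int = 2_000_000
    n_genes: int = 300
    gene_length_mean: float = 2_000.0
    gene_length_shape: float = 4.0
    intergenic_gap_mean: float = 8_000.0
    intergenic_gap_shape: float = 1.5
    mirna_gene_fraction: float = 0.1

    # tissue atlas
    n_tissues: int = 10
    n_elements: int = 5_000
    fraction_specific: float = 0.2
    specific_weight: float = 0.9
    noise_sigma: float = 0.25
    promoter_fraction: float = 0.5
    element_width: int = 300
    signal_scale: float = 100.0
    broad_dirichlet_alpha: float = 8.0
    peak_call_fraction: float = 0.05
    promoter_cutoff_bp: int = 1_000

    # TF co-binding
    n_tfs: int = 24
    n_modules: int = 3
    sites_per_module: int = 300
    site_width: int = 200
    p_in: float = 0.5
    p_out: float = 0.05

    # meta-network
    n_upstream_tfs: int = 50
    n_mirnas: int = 20
    n_target_tfs: int = 80
    p_tf_mirna: float = 0.15
    p_tf_gene: float = 0.10
    p_mirna_gene: float = 0.15
    n_decoy_mirna_rows: int = 100
    mirna_score_cutoff: float = 4.0

    # cross-species conservation
    n_species: int = 4  # reference + (n_species - 1) comparison species
    q_align: float = 0.8
    q_peak: float = 0.7
    q_peak_promoter: float | None = None  # class-specific overrides of q_peak
    q_peak_enhancer: float | None = None
    block_mean_bp: float = 5_000.0
    spacer_max_bp: int = 200
    n_conservation_peaks: int = 1_000
    conservation_peak_width: int = 300

    # QC fragments
    n_fragments: int = 20_000
    fragment_length: int = 100
    frip_target: float = 0.3
    duplicate_rate: float = 0.1

    def __post_init__(self) -> None:
        probs = {
            "fraction_specific": self.fraction_specific,
            "p_in": self.p_in,
            "p_out": self.p_out,
            "p_tf_mirna": self.p_tf_mirna,
            "p_tf_gene": self.p_tf_gene,
            "p_mirna_gene": self.p_mirna_gene,
            "q_align": self.q_align,
            "q_peak": self.q_peak,
            "frip_target": self.frip_target,
            "duplicate_rate": self.duplicate_rate,
            "promoter_fraction": self.promoter_fraction,
            "mirna_gene_fraction": self.mirna_gene_fraction,
        }
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"{name}={p} is not a probability")
        if self.n_tissues < 2:
            raise ConfigurationError("need K >= 2 tissues")
        if not (1.0 / self.n_tissues) < self.specific_weight <= 1.0:
            raise ConfigurationError("specific_weight must be in (1/K, 1]")

    def rng(self, name: str) -> np.random.Generator:
        """Independent stream for one generator, derived from (seed, name)."""
        return np.random.default_rng(
            np.random.SeedSequence([self.seed % (2**31), zlib.crc32(name.encode())])
        )

    @property
    def intergenic_gap_median(self) -> float:
        """Theoretical median of the intergenic-gap gamma distribution."""
        shape = self.intergenic_gap_shape
        return float(gamma_dist(shape, scale=self.intergenic_gap_mean / shape).median())


# ---------------------------------------------------------------------------
# Genome and genes
# ---------------------------------------------------------------------------


@dataclass
class GenomeResult:
    assembly: GenomeAssembly
    genes: list[GeneModel]


def make_genome_and_genes(
    config: SimulationConfig, outdir: str | Path | None = None
) -> GenomeResult:
    """Lay out non-overlapping gene bodies with gamma gaps on each chromosome.

    Genes are split evenly across chromosomes and placed sequentially;
    running past the chromosome end is a configuration error (the genome
    is too small for the requested gene count).
    """
    rng = config.rng("genome")
    chroms = [f"chr{i + 1}" for i in range(config.n_chroms)]
    sizes = {c: config.chrom_length_bp for c in chroms}
    per_chrom = [config.n_genes // config.n_chroms] * config.n_chroms
    for i in range(config.n_genes % config.n_chroms):
        per_chrom[i] += 1

    genes: list[GeneModel] = []
    gid = 0
    for chrom, count in zip(chroms, per_chrom):
        gl_shape = config.gene_length_shape
        gap_shape = config.intergenic_gap_shape
        lengths = np.maximum(
            200, rng.gamma(gl_shape, config.gene_length_mean / gl_shape, size=count)
        ).astype(int)
        gaps = np.maximum(
            1, rng.gamma(gap_shape, config.intergenic_gap_mean / gap_shape, size=count)
        ).astype(int)
        strands = rng.choice(["+", "-"], size=count)
        is_mirna = rng.random(count) < config.mirna_gene_fraction
        pos = int(gaps[0] // 2)
        for i in range(count):
            start, end = pos, pos + int(lengths[i])
            if end > sizes[chrom]:
                raise ConfigurationError(
                    f"gene packing overflows {chrom}: increase chrom_length_bp or reduce n_genes"
                )
            gid += 1
            genes.append(
                GeneModel(
                    interval=GenomicInterval(chrom, start, end, str(strands[i])),
                    gene_id=f"g{gid:05d}",
                    biotype="miRNA" if is_mirna[i] else "protein_coding",
                )
            )
            pos = end + int(gaps[i])
    assembly = GenomeAssembly(name="sim1", chrom_sizes=sizes)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_gff3_genes(genes, outdir / "genes.gff3")
        write_chrom_sizes(assembly, outdir / "chrom.sizes")
    return GenomeResult(assembly=assembly, genes=genes)


# ---------------------------------------------------------------------------
# Tissue atlas
# ---------------------------------------------------------------------------


@dataclass
class AtlasResult:
    matrix: pd.DataFrame  # elements x tissues
    peaks: dict[str, list[Peak]]  # per-tissue called peaks
    elements: list[Peak]  # one record per element (summit = planted anchor)
    truth: pd.DataFrame  # element_id, profile, tissue, element_class


def _nearest_tss_distances(anchors: np.ndarray, tss_sorted: np.ndarray) -> np.ndarray:
    """Distance from each anchor to the nearest TSS (sorted positions)."""
    idx = np.searchsorted(tss_sorted, anchors)
    left = np.where(idx > 0, np.abs(anchors - tss_sorted[np.maximum(idx - 1, 0)]), np.iinfo(np.int64).max)
    right = np.where(
        idx < tss_sorted.size,
        np.abs(tss_sorted[np.minimum(idx, tss_sorted.size - 1)] - anchors),
        np.iinfo(np.int64).max,
    )
    return np.minimum(left, right)


def make_tissue_atlas(
    config: SimulationConfig,
    genome: GenomeResult,
    outdir: str | Path | None = None,
) -> AtlasResult:
    """Plant promoter/enhancer elements with specific or broad tissue profiles.

    Promoter-like elements have their summit within the promoter cutoff
    of a TSS; enhancer-like summits are strictly beyond it.  A fraction
    of elements is tissue-specific (weight w on one tissue, the rest
    uniform); the remainder are broad (symmetric Dirichlet).  Signal is
    multiplied by log-normal noise; a peak is called in a tissue when the
    element's signal there exceeds ``peak_call_fraction`` of its row sum.
    """
    rng = config.rng("atlas")
    from regulome.core_io import tss as tss_of

    tmp: dict[str, list[int]] = {}
    for g in genome.genes:
        chrom, pos = tss_of(g)
        tmp.setdefault(chrom, []).append(pos)
    tss_by_chrom = {c: np.sort(np.array(v)) for c, v in tmp.items()}

    chroms = list(genome.assembly.chrom_sizes)
    chrom_len = config.chrom_length_bp
    cutoff = config.promoter_cutoff_bp
    half = config.element_width // 2

    n_promoter = int(round(config.n_elements * config.promoter_fraction))
    n_enhancer = config.n_elements - n_promoter

    # promoter-like anchors: jitter around random TSSs (distance <= cutoff)
    anchors: list[tuple[str, int]] = []
    classes: list[str] = []
    while len(anchors) < n_promoter:
        chrom = chroms[int(rng.integers(len(chroms)))]
        tss_pos = tss_by_chrom[chrom]
        if tss_pos.size == 0:
            continue
        pos = int(tss_pos[int(rng.integers(tss_pos.size))]) + int(rng.integers(-cutoff, cutoff + 1))
        pos = int(np.clip(pos, half, chrom_len - half - 1))
        if _nearest_tss_distances(np.array([pos]), tss_pos)[0] <= cutoff:
            anchors.append((chrom, pos))
            classes.append("promoter")
    # enhancer-like anchors: uniform positions strictly beyond the cutoff
    while len(anchors) < config.n_elements:
        chrom = chroms[int(rng.integers(len(chroms)))]
        cand = rng.integers(half, chrom_len - half, size=256)
        dists = _nearest_tss_distances(cand, tss_by_chrom[chrom])
        for pos, dist in zip(cand, dists):
            if dist > cutoff and len(anchors) < config.n_elements:
                anchors.append((chrom, int(pos)))
                classes.append("enhancer")

    n = config.n_elements
    k = config.n_tissues
    tissues = [f"T{i + 1:02d}" for i in range(k)]
    n_specific = int(round(n * config.fraction_specific))
    is_specific = np.zeros(n, dtype=bool)
    is_specific[:n_specific] = True
    is_specific = is_specific[rng.permutation(n)]
    own_tissue = rng.integers(0, k, size=n)

    profiles = np.empty((n, k))
    broad_rows = ~is_specific
    profiles[broad_rows] = rng.dirichlet(
        np.full(k, config.broad_dirichlet_alpha), size=int(broad_rows.sum())
    )
    w = config.specific_weight
    rest = (1.0 - w) / (k - 1)
    spec_profiles = np.full((int(is_specific.sum()), k), rest)
    spec_profiles[np.arange(int(is_specific.sum())), own_tissue[is_specific]] = w
    profiles[is_specific] = spec_profiles

    if config.noise_sigma > 0:
        noise = rng.lognormal(mean=0.0, sigma=config.noise_sigma, size=(n, k))
    else:
        noise = np.ones((n, k))
    signal = profiles * config.signal_scale * noise

    element_ids = [f"e{i + 1:05d}" for i in range(n)]
    matrix = pd.DataFrame(signal, index=element_ids, columns=tissues)

    elements: list[Peak] = []
    for i, (chrom, pos) in enumerate(anchors):
        start = pos - half
        end = pos + half
        elements.append(
            Peak(
                interval=GenomicInterval(chrom, start, end),
                summit_offset=pos - start,
                score=float(signal[i].sum()),
                name=element_ids[i],
            )
        )

    row_sums = signal.sum(axis=1)
    called = signal > config.peak_call_fraction * row_sums[:, None]
    peaks: dict[str, list[Peak]] = {t: [] for t in tissues}
    for j, t in enumerate(tissues):
        for i in np.nonzero(called[:, j])[0]:
            el = elements[i]
            peaks[t].append(
                Peak(
                    interval=el.interval,
                    summit_offset=el.summit_offset,
                    score=float(signal[i, j]),
                    name=element_ids[i],
                )
            )

    truth = pd.DataFrame(
        {
            "element_id": element_ids,
            "profile": np.where(is_specific, "specific", "broad"),
            "tissue": [tissues[t] if s else "" for t, s in zip(own_tissue, is_specific)],
            "element_class": classes,
        }
    ).set_index("element_id")

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_accessibility_matrix(matrix, outdir / "accessibility.tsv")
        write_bed(elements, outdir / "elements.narrowPeak", dialect="narrowPeak")
        for t in tissues:
            write_bed(peaks[t], outdir / f"atlas_{t}.narrowPeak", dialect="narrowPeak")
        truth.to_csv(outdir / "atlas_truth.tsv", sep="\t")
    return AtlasResult(matrix=matrix, peaks=peaks, elements=elements, truth=truth)


# ---------------------------------------------------------------------------
# TF peak sets with planted co-binding modules
# ---------------------------------------------------------------------------


@dataclass
class TfPeaksResult:
    peaksets: dict[str, list[GenomicInterval]]
    module_of: dict[str, int]  # planted module per TF
    pools: list[list[GenomicInterval]]


def make_tf_peaksets(
    config: SimulationConfig,
    assembly: GenomeAssembly,
    outdir: str | Path | None = None,
) -> TfPeaksResult:
    """Plant co-binding modules: each module owns a disjoint site pool.

    A TF binds each site of its own pool with probability p_in and each
    foreign-pool site with probability p_out, so within-module bp Jaccard
    exceeds the cross-module Jaccard whenever p_in > p_out.  Pools are
    laid out on a disjoint slot grid, so p_in=1/p_out=0 gives Jaccard
    exactly 1 within and 0 across modules.
    """
    rng = config.rng("tf_peaks")
    chroms = list(assembly.chrom_sizes)
    n_sites = config.n_modules * config.sites_per_module
    slot = config.site_width * 2
    slots_per_chrom = {c: assembly.chrom_sizes[c] // slot for c in chroms}
    all_slots = [(c, i) for c in chroms for i in range(slots_per_chrom[c])]
    if n_sites > len(all_slots):
        raise ConfigurationError("genome too small for the requested site pools")
    chosen = rng.choice(len(all_slots), size=n_sites, replace=False)
    sites = [
        GenomicInterval(all_slots[i][0], all_slots[i][1] * slot, all_slots[i][1] * slot + config.site_width)
        for i in chosen
    ]
    pools = [
        sites[m * config.sites_per_module : (m + 1) * config.sites_per_module]
        for m in range(config.n_modules)
    ]

    tfs_per_module = config.n_tfs // config.n_modules
    extra = config.n_tfs % config.n_modules
    module_of: dict[str, int] = {}
    peaksets: dict[str, list[GenomicInterval]] = {}
    t = 0
    for m in range(config.n_modules):
        count = tfs_per_module + (1 if m < extra else 0)
        for _ in range(count):
            t += 1
            tf = f"TF{t:03d}"
            module_of[tf] = m
            chosen_sites: list[GenomicInterval] = []
            for mm in range(config.n_modules):
                p = config.p_in if mm == m else config.p_out
                if p <= 0:
                    continue
                mask = rng.random(len(pools[mm])) < p
                chosen_sites.extend(s for s, keep in zip(pools[mm], mask) if keep)
            peaksets[tf] = sorted(chosen_sites, key=lambda iv: (iv.chrom, iv.start))

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for tf, intervals in peaksets.items():
            write_intervals_bed(intervals, outdir / f"{tf}.bed")
        pd.Series(module_of, name="module").rename_axis("tf").to_csv(
            outdir / "tf_modules_truth.tsv", sep="\t"
        )
    return TfPeaksResult(peaksets=peaksets, module_of=module_of, pools=pools)


# ---------------------------------------------------------------------------
# Meta-network with a known FFL count
# ---------------------------------------------------------------------------


@dataclass
class MetaNetworkResult:
    tf_targets: dict[str, list[str]]  # TF -> targeted genes (miRNAs + TF genes)
    mirna_table: pd.DataFrame  # mirna_id, target_gene_id, score (with decoys)
    mirna_genes: list[str]
    tf_gene_catalog: list[str]
    true_ffls: list[tuple[str, str, str]]
    true_ffl_count: int


def make_meta_network(
    config: SimulationConfig, outdir: str | Path | None = None
) -> MetaNetworkResult:
    """Sample a tripartite TF/miRNA/target network with independent edges.

    The planted FFL count is computed at generation time by exhaustive
    enumeration of (TF, miRNA, target) triples over the sampled adjacency
    arrays.  The emitted miRNA-target table mixes true edges (score drawn
    at or below the cutoff) with decoy rows above the cutoff, so the
    score filter must be applied to recover the planted network.
    """
    rng = config.rng("meta_network")
    tfs = [f"U{i + 1:03d}" for i in range(config.n_upstream_tfs)]
    mirnas = [f"MIR{i + 1:03d}" for i in range(config.n_mirnas)]
    targets = [f"TG{i + 1:03d}" for i in range(config.n_target_tfs)]

    a_m = rng.random((len(tfs), len(mirnas))) < config.p_tf_mirna
    a_g = rng.random((len(tfs), len(targets))) < config.p_tf_gene
    m_g = rng.random((len(mirnas), len(targets))) < config.p_mirna_gene

    tf_targets: dict[str, list[str]] = {}
    for i, tf in enumerate(tfs):
        row = [mirnas[j] for j in np.nonzero(a_m[i])[0]]
        row += [targets[j] for j in np.nonzero(a_g[i])[0]]
        tf_targets[tf] = row

    cutoff = config.mirna_score_cutoff
    rows = []
    for i, m in enumerate(mirnas):
        for j in np.nonzero(m_g[i])[0]:
            rows.append((m, targets[j], round(float(rng.uniform(0.5, cutoff)), 3)))
    present = {(m, g) for m, g, _s in rows}
    free = [(m, g) for m in mirnas for g in targets if (m, g) not in present]
    n_decoys = min(config.n_decoy_mirna_rows, len(free))
    for i in rng.choice(len(free), size=n_decoys, replace=False):
        m, g = free[i]
        rows.append((m, g, round(float(rng.uniform(cutoff + 0.5, cutoff + 6.0)), 3)))
    mirna_table = pd.DataFrame(rows, columns=["mirna_id", "target_gene_id", "score"])

    true_ffls: list[tuple[str, str, str]] = []
    for i in range(len(tfs)):
        for j in np.nonzero(a_m[i])[0]:
            hits = np.nonzero(m_g[j] & a_g[i])[0]
            true_ffls.extend((tfs[i], mirnas[j], targets[b]) for b in hits)
    true_ffls.sort()

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        mirna_table.to_csv(outdir / "mirna_targets.tsv", sep="\t", index=False)
        edge_rows = [(tf, t) for tf, ts in tf_targets.items() for t in ts]
        pd.DataFrame(edge_rows, columns=["tf_id", "target_id"]).to_csv(
            outdir / "tf_edges.tsv", sep="\t", index=False
        )
        with open(outdir / "meta_network_truth.json", "w") as fh:
            json.dump({"ffl_count": len(true_ffls), "ffls": true_ffls}, fh)
    return MetaNetworkResult(
        tf_targets=tf_targets,
        mirna_table=mirna_table,
        mirna_genes=mirnas,
        tf_gene_catalog=targets,
        true_ffls=true_ffls,
        true_ffl_count=len(true_ffls),
    )


# ---------------------------------------------------------------------------
# Species pairs related by blockwise chains
# ---------------------------------------------------------------------------


@dataclass
class SpeciesPairResult:
    species: str
    chain_set: AlignmentChainSet
    target_peaks: list[Peak]
    target_assembly: GenomeAssembly
    truth: pd.DataFrame  # peak name -> alignable, conserved


def make_block_partition(
    config: SimulationConfig, assembly: GenomeAssembly
) -> dict[str, np.ndarray]:
    """Shared breakpoints per chromosome (exponential block lengths)."""
    rng = config.rng("blocks")
    partition: dict[str, np.ndarray] = {}
    for chrom, length in assembly.chrom_sizes.items():
        cuts = [0]
        while cuts[-1] < length:
            cuts.append(cuts[-1] + max(500, int(rng.exponential(config.block_mean_bp))))
        cuts[-1] = length
        partition[chrom] = np.array(cuts)
    return partition


def make_conservation_peaks(
    config: SimulationConfig,
    assembly: GenomeAssembly,
    partition: dict[str, np.ndarray],
    classes: Sequence[str] | None = None,
) -> list[Peak]:
    """Place non-overlapping source peaks strictly inside single blocks.

    Keeping each peak within one block makes the planted alignable /
    conserved flags exact (no block-straddling edge effects).  ``classes``
    optionally labels peaks promoter/enhancer in round-robin for
    class-contrast experiments.
    """
    rng = config.rng("conservation_peaks")
    width = config.conservation_peak_width
    slots: list[tuple[str, int]] = []
    for chrom, cuts in partition.items():
        for b0, b1 in zip(cuts[:-1], cuts[1:]):
            pos = int(b0)
            while pos + width <= b1:
                slots.append((chrom, pos))
                pos += width + 100
    if config.n_conservation_peaks > len(slots):
        raise ConfigurationError("not enough block space for the requested peaks")
    chosen = sorted(rng.choice(len(slots), size=config.n_conservation_peaks, replace=False))
    peaks = []
    for i, si in enumerate(chosen):
        chrom, pos = slots[si]
        cls = classes[i % len(classes)] if classes else "element"
        peaks.append(
            Peak(
                interval=GenomicInterval(chrom, pos, pos + width),
                summit_offset=width // 2,
                score=1.0,
                name=f"{cls}_{i + 1:05d}",
            )
        )
    return peaks


def make_species_pair(
    config: SimulationConfig,
    source_assembly: GenomeAssembly,
    source_peaks: Sequence[Peak],
    species: str = "sp2",
    partition: dict[str, np.ndarray] | None = None,
    q_peak_by_class: dict[str, float] | None = None,
    outdir: str | Path | None = None,
) -> SpeciesPairResult:
    """Derive one comparison species: surviving blocks concatenated into chains.

    Each block of the (shared) source partition survives with probability
    q_align; surviving blocks are concatenated in order with random
    spacer shifts, yielding one chain per chromosome (adjacent gapless
    blocks are coalesced).  A source peak whose span lies in a surviving
    block is alignable; it is copied to its projected location (hence
    conserved) with probability q_peak, optionally class-specific.
    """
    rng = config.rng(f"species:{species}")
    if partition is None:
        partition = make_block_partition(config, source_assembly)

    chains: list[Chain] = []
    target_sizes: dict[str, int] = {}
    # per-chrom list of surviving (s0, s1, t0) mappings
    mapping: dict[str, list[tuple[int, int, int]]] = {}
    chain_id = 0
    for chrom, cuts in partition.items():
        starts, ends = cuts[:-1], cuts[1:]
        survives = rng.random(len(starts)) < config.q_align
        spacers = (
            rng.integers(0, config.spacer_max_bp + 1, size=len(starts))
            if config.spacer_max_bp > 0
            else np.zeros(len(starts), dtype=int)
        )
        blocks: list[tuple[int, int, int]] = []  # (s0, s1, t0)
        t_cursor = 0
        for b0, b1, alive, spacer in zip(starts, ends, survives, spacers):
            if not alive:
                continue
            t_cursor += int(spacer)
            blocks.append((int(b0), int(b1), t_cursor))
            t_cursor += int(b1 - b0)
        if not blocks:
            target_sizes[chrom] = source_assembly.chrom_sizes[chrom]
            mapping[chrom] = []
            continue
        last_s1 = blocks[-1][1]
        target_sizes[chrom] = t_cursor + (source_assembly.chrom_sizes[chrom] - last_s1)
        mapping[chrom] = blocks
        # coalesce adjacent gapless blocks, then serialize to one chain
        coalesced: list[tuple[int, int, int]] = [blocks[0]]
        for s0, s1, t0 in blocks[1:]:
            p0, p1, pt = coalesced[-1]
            if s0 == p1 and t0 == pt + (p1 - p0):
                coalesced[-1] = (p0, s1, pt)
            else:
                coalesced.append((s0, s1, t0))
        chain_blocks: list[tuple[int, int, int]] = []
        for i, (s0, s1, t0) in enumerate(coalesced):
            if i + 1 < len(coalesced):
                n0, _n1, nt = coalesced[i + 1]
                dt = n0 - s1
                dq = nt - (t0 + (s1 - s0))
            else:
                dt = dq = 0
            chain_blocks.append((s1 - s0, dt, dq))
        chain_id += 1
        chains.append(
            Chain(
                chain_id=chain_id,
                score=float(sum(s1 - s0 for s0, s1, _t in coalesced)),
                source_chrom=chrom,
                source_size=source_assembly.chrom_sizes[chrom],
                source_start=coalesced[0][0],
                source_end=coalesced[-1][1],
                target_chrom=chrom,
                target_size=target_sizes[chrom],
                target_strand="+",
                target_start=coalesced[0][2],
                target_end=coalesced[-1][2] + (coalesced[-1][1] - coalesced[-1][0]),
                blocks=chain_blocks,
            )
        )
    chain_set = AlignmentChainSet(chains)

    target_peaks: list[Peak] = []
    names, alignable_flags, conserved_flags = [], [], []
    for peak in source_peaks:
        iv = peak.interval
        blocks = mapping.get(iv.chrom, [])
        host = next((b for b in blocks if b[0] <= iv.start and iv.end <= b[1]), None)
        partial = host is not None or any(
            b[0] < iv.end and iv.start < b[1] for b in blocks
        )
        alignable = partial
        cls = peak.name.split("_")[0]
        q = (q_peak_by_class or {}).get(cls, config.q_peak)
        conserved = False
        if host is not None and rng.random() < q:
            s0, _s1, t0 = host
            shift = t0 - s0
            target_peaks.append(
                Peak(
                    interval=GenomicInterval(iv.chrom, iv.start + shift, iv.end + shift),
                    summit_offset=peak.summit_offset,
                    score=peak.score,
                    name=peak.name,
                )
            )
            conserved = True
        names.append(peak.name)
        alignable_flags.append(bool(alignable))
        conserved_flags.append(bool(conserved))
    truth = pd.DataFrame(
        {"alignable": alignable_flags, "conserved": conserved_flags}, index=pd.Index(names, name="element_id")
    )

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_chain(chain_set, outdir / f"{species}.chain")
        write_bed(target_peaks, outdir / f"{species}_peaks.narrowPeak", dialect="narrowPeak")
        truth.to_csv(outdir / f"{species}_truth.tsv", sep="\t")
    return SpeciesPairResult(
        species=species,
        chain_set=chain_set,
        target_peaks=target_peaks,
        target_assembly=GenomeAssembly(name=species, chrom_sizes=target_sizes),
        truth=truth,
    )


@dataclass
class ConservationSuiteResult:
    source_peaks: list[Peak]
    species: list[SpeciesPairResult]
    partition: dict[str, np.ndarray]


def make_conservation_suite(
    config: SimulationConfig,
    assembly: GenomeAssembly,
    classes: Sequence[str] = ("promoter", "enhancer"),
    outdir: str | Path | None = None,
) -> ConservationSuiteResult:
    """Shared block partition + source peaks + one pair per comparison species."""
    partition = make_block_partition(config, assembly)
    source_peaks = make_conservation_peaks(config, assembly, partition, classes=classes)
    q_by_class = {}
    if config.q_peak_promoter is not None:
        q_by_class["promoter"] = config.q_peak_promoter
    if config.q_peak_enhancer is not None:
        q_by_class["enhancer"] = config.q_peak_enhancer
    pairs = [
        make_species_pair(
            config,
            assembly,
            source_peaks,
            species=f"sp{i + 2}",
            partition=partition,
            q_peak_by_class=q_by_class or None,
            outdir=outdir,
        )
        for i in range(config.n_species - 1)
    ]
    if outdir is not None:
        write_bed(source_peaks, Path(outdir) / "conservation_source.narrowPeak", dialect="narrowPeak")
    return ConservationSuiteResult(source_peaks=source_peaks, species=pairs, partition=partition)


# ---------------------------------------------------------------------------
# QC fragments
# ---------------------------------------------------------------------------


def make_fragments(
    config: SimulationConfig,
    assembly: GenomeAssembly,
    peaks: Sequence[Peak],
    outdir: str | Path | None = None,
) -> list[GenomicInterval]:
    """Sequencing-free fragment intervals for the QC stage.

    A ``frip_target`` fraction of fragments starts inside randomly chosen
    peaks, the rest are uniform background; a ``duplicate_rate`` fraction
    re-emits an earlier fragment to exercise the complexity metrics.
    """
    rng = config.rng("fragments")
    chroms = list(assembly.chrom_sizes)
    frag_len = config.fragment_length
    fragments: list[GenomicInterval] = []
    merged_peaks = [p.interval for p in peaks]
    for _ in range(config.n_fragments):
        if fragments and rng.random() < config.duplicate_rate:
            fragments.append(fragments[int(rng.integers(len(fragments)))])
            continue
        if merged_peaks and rng.random() < config.frip_target:
            iv = merged_peaks[int(rng.integers(len(merged_peaks)))]
            start = int(rng.integers(iv.start, max(iv.start + 1, iv.end - frag_len)))
        else:
            chrom_name = chroms[int(rng.integers(len(chroms)))]
            start = int(rng.integers(0, assembly.chrom_sizes[chrom_name] - frag_len))
            iv = GenomicInterval(chrom_name, start, start + 1)
        strand = "+" if rng.random() < 0.5 else "-"
        fragments.append(GenomicInterval(iv.chrom, start, start + frag_len, strand))
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_intervals_bed(fragments, outdir / "fragments.bed")
    return fragments


def write_ground_truth(path: str | Path, **tables) -> None:
    """Serialize planted-truth tables/scalars into one JSON file."""
    payload = {}
    for name, value in tables.items():
        if isinstance(value, pd.DataFrame):
            payload[name] = value.reset_index().to_dict(orient="list")
        else:
            payload[name] = value
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, default=str)
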