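"""Config-driven orchestration of all analysis stages.

One verb per analysis: ``simulate`` emits every synthetic input with its
planted truth; ``qc``, ``annotate``, ``specificity``, ``coassoc``,
``network`` and ``conserve`` each consume files produced by earlier
stages and write TSV outputs plus a manifest entry.  Outputs are written
atomically (temp-then-rename) into the configured output directory, and
two runs with the same config and seed produce byte-identical data
files.  The manifest (which records wall time) is the only
non-reproducible output and is excluded from determinism guarantees.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd
import yaml

from regulome import core_io, element_annotation, qc_metrics, regulatory_network
from regulome import cross_species_conservation as conservation
from regulome import synthetic_data, tf_coassociation, tissue_specificity

logger = logging.getLogger("regulome")


class ConfigError(ValueError):
    pass


class DependencyError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    seed: int = 0
    outdir: str = "regulome_out"
    simulation: dict = field(default_factory=dict)  # SimulationConfig overrides
    promoter_cutoff_bp: int = 1000
    n_cap: int = 3000
    jsd_cutoff: float = 0.26
    coassoc_fallback: float = 0.2
    conservation_min_overlap: float = 0.5

    def sim_config(self) -> synthetic_data.SimulationConfig:
        return synthetic_data.SimulationConfig(seed=self.seed, **self.simulation)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


_TOP_KEYS = {f.name for f in dataclasses.fields(PipelineConfig)}
_SIM_KEYS = {f.name for f in dataclasses.fields(synthetic_data.SimulationConfig)}


def validate_config(source: str | Path | dict) -> PipelineConfig:
    """Normalize a config file or dict, rejecting unknown keys, filling defaults.

    Normalization is idempotent: validating the dict form of a validated
    config returns an identical config.
    """
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            raw = yaml.safe_load(fh) or {}
    else:
        raw = dict(source)
    if not isinstance(raw, dict):
        raise ConfigError("config must be a mapping")
    problems = [f"missing required key {key!r}" for key in ("seed", "outdir") if key not in raw]
    for key in raw:
        if key not in _TOP_KEYS:
            problems.append(f"unknown key {key!r}")
    sim = raw.get("simulation", {})
    if not isinstance(sim, dict):
        problems.append("'simulation' must be a mapping of generator parameters")
        sim = {}
    for key in sim:
        if key not in _SIM_KEYS or key == "seed":
            problems.append(f"unknown simulation key {key!r}")
    if problems:
        raise ConfigError("invalid config: " + "; ".join(problems))
    cfg = PipelineConfig(**{k: v for k, v in raw.items()})
    # surface parameter type errors before any compute
    cfg.sim_config()
    return cfg


# ---------------------------------------------------------------------------
# Stage machinery
# ---------------------------------------------------------------------------


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _atomic_write_frame(df: pd.DataFrame, path: Path, **kwargs) -> None:
    tmp = path.with_suffix(path.suffix + ".tmp")
    df.to_csv(tmp, sep="\t", float_format="%.10g", **kwargs)
    os.replace(tmp, path)


@dataclass
class StageSpec:
    name: str
    deps: list[str]
    outputs: list[str]  # paths relative to outdir
    fn: Callable


def _stage_outputs_exist(spec: StageSpec, outdir: Path) -> bool:
    return all((outdir / rel).exists() for rel in spec.outputs)


# ---------------------------------------------------------------------------
# Stage implementations
# ---------------------------------------------------------------------------


def _stage_simulate(config: PipelineConfig, outdir: Path) -> None:
    sim = config.sim_config()
    sim_dir = outdir / "sim"
    genome = synthetic_data.make_genome_and_genes(sim, outdir=sim_dir)
    atlas = synthetic_data.make_tissue_atlas(sim, genome, outdir=sim_dir)
    synthetic_data.make_tf_peaksets(sim, genome.assembly, outdir=sim_dir / "tf")
    synthetic_data.make_meta_network(sim, outdir=sim_dir)
    synthetic_data.make_conservation_suite(sim, genome.assembly, outdir=sim_dir / "conservation")
    synthetic_data.make_fragments(sim, genome.assembly, atlas.elements, outdir=sim_dir)


def _stage_qc(config: PipelineConfig, outdir: Path) -> None:
    fragments = core_io.read_intervals_bed(outdir / "sim" / "fragments.bed")
    peaks = core_io.read_bed(outdir / "sim" / "elements.narrowPeak", dialect="narrowPeak")
    report = qc_metrics.qc_report(fragments, peaks)
    df = pd.DataFrame(
        [
            {"metric": "nrf", "value": report.nrf, "tier": report.tiers["nrf"]},
            {"metric": "pbc1", "value": report.pbc1, "tier": report.tiers["pbc1"]},
            {"metric": "pbc2", "value": report.pbc2, "tier": report.tiers["pbc2"]},
            {"metric": "frip", "value": report.frip, "tier": report.tiers["frip"]},
        ]
    )
    _atomic_write_frame(df, outdir / "qc_report.tsv", index=False)


def _stage_annotate(config: PipelineConfig, outdir: Path) -> None:
    peaks = core_io.read_bed(outdir / "sim" / "elements.narrowPeak", dialect="narrowPeak")
    genes = core_io.read_gff3_genes(outdir / "sim" / "genes.gff3")
    ann_config = element_annotation.AnnotationConfig(
        promoter_cutoff_bp=config.promoter_cutoff_bp, n_cap=config.n_cap
    )
    elements = element_annotation.annotate(peaks, genes, ann_config)
    frame = element_annotation.elements_to_frame(elements)
    _atomic_write_frame(frame, outdir / "elements.tsv", index=False)


def _stage_specificity(config: PipelineConfig, outdir: Path) -> None:
    matrix = core_io.read_accessibility_matrix(outdir / "sim" / "accessibility.tsv")
    result = tissue_specificity.call_highly_specific(matrix, cutoff=config.jsd_cutoff)
    table = pd.DataFrame(
        {
            "jsd_score": result.scores,
            "argmax_tissue": result.argmax_tissue,
            "is_highly_specific": result.is_highly_specific,
        }
    )
    specific = matrix.loc[result.is_highly_specific]
    table["cluster"] = -1
    if len(specific) >= matrix.shape[1]:
        clusters = tissue_specificity.cluster_specific_elements(
            specific, k=matrix.shape[1], seed=config.seed
        )
        table.loc[clusters.index, "cluster"] = clusters
    sim_matrix, order = tissue_specificity.sample_similarity(matrix)
    _atomic_write_frame(table, outdir / "specificity.tsv", index_label="element_id")
    _atomic_write_frame(sim_matrix.loc[order, order], outdir / "sample_similarity.tsv", index_label="sample")


def _stage_coassoc(config: PipelineConfig, outdir: Path) -> None:
    tf_dir = outdir / "sim" / "tf"
    peaksets = {
        p.stem: [pk.interval for pk in core_io.read_bed(p, dialect="bed6")]
        for p in sorted(tf_dir.glob("TF*.bed"))
    }
    matrix, network = tf_coassociation.coassociation_pipeline(
        peaksets, threshold=None
    )
    _atomic_write_frame(matrix, outdir / "coassoc_matrix.tsv", index_label="tf")
    edges = pd.DataFrame(
        [
            {"tf_a": a, "tf_b": b, "jaccard": d["weight"]}
            for a, b, d in sorted(network.graph.edges(data=True))
        ]
    )
    _atomic_write_frame(edges, outdir / "coassoc_edges.tsv", index=False)
    module_rows = [
        {"tf": tf, "module": i}
        for i, mod in enumerate(network.modules)
        for tf in sorted(mod)
    ] + [{"tf": tf, "module": -1} for tf in network.singletons]
    _atomic_write_frame(pd.DataFrame(module_rows), outdir / "coassoc_modules.tsv", index=False)


def _stage_network(config: PipelineConfig, outdir: Path) -> None:
    tf_edges = pd.read_csv(outdir / "sim" / "tf_edges.tsv", sep="\t")
    mirna_table = pd.read_csv(outdir / "sim" / "mirna_targets.tsv", sep="\t")
    tf_targets: dict[str, list[str]] = {}
    for tf, target in tf_edges.itertuples(index=False, name=None):
        tf_targets.setdefault(str(tf), []).append(str(target))
    mirna_genes = sorted({t for ts in tf_targets.values() for t in ts if t.startswith("MIR")})
    mirna_genes = sorted(set(mirna_genes) | set(mirna_table["mirna_id"].astype(str)))
    catalog = sorted(
        {t for ts in tf_targets.values() for t in ts if not t.startswith("MIR")}
        | set(mirna_table["target_gene_id"].astype(str))
    )
    mirna_edges = regulatory_network.filter_mirna_targets(mirna_table)
    net = regulatory_network.build_meta_network(tf_targets, mirna_edges, mirna_genes, catalog)
    loops = regulatory_network.enumerate_ffls(net)
    edge_rows = [
        {"source": u, "target": v, "edge_type": t}
        for u, v, t in sorted(net.graph.edges(data="edge_type"))
    ]
    _atomic_write_frame(pd.DataFrame(edge_rows), outdir / "meta_edges.tsv", index=False)
    _atomic_write_frame(regulatory_network.ffls_to_frame(loops), outdir / "ffls.tsv", index=False)


def _stage_conserve(config: PipelineConfig, outdir: Path) -> None:
    cons_dir = outdir / "sim" / "conservation"
    source = core_io.read_bed(cons_dir / "conservation_source.narrowPeak", dialect="narrowPeak")
    sim = config.sim_config()
    species_inputs = {}
    for i in range(sim.n_species - 1):
        sp = f"sp{i + 2}"
        chain_path = cons_dir / f"{sp}.chain"
        if not chain_path.exists():
            raise ConfigError(f"species {sp} listed without a chain file")
        chains = core_io.read_chain(chain_path)
        peaks = core_io.read_bed(cons_dir / f"{sp}_peaks.narrowPeak", dialect="narrowPeak")
        species_inputs[sp] = (chains, [p.interval for p in peaks])
    elements = [(p.name, p.interval) for p in source]
    records = conservation.conservation_scores(
        elements, species_inputs, min_overlap_fraction=config.conservation_min_overlap
    )
    rows = []
    for p, rec in zip(source, records):
        rows.append(
            {
                "element_id": rec.element_id,
                "class": p.name.split("_")[0],
                "alignability_score": rec.alignability_score,
                "conservation_score": rec.conservation_score,
            }
        )
    _atomic_write_frame(pd.DataFrame(rows), outdir / "conservation.tsv", index=False)


_SIM_OUTPUTS = [
    "sim/genes.gff3",
    "sim/chrom.sizes",
    "sim/accessibility.tsv",
    "sim/elements.narrowPeak",
    "sim/atlas_truth.tsv",
    "sim/mirna_targets.tsv",
    "sim/tf_edges.tsv",
    "sim/meta_network_truth.json",
    "sim/fragments.bed",
    "sim/conservation/conservation_source.narrowPeak",
]

STAGES: dict[str, StageSpec] = {
    "simulate": StageSpec("simulate", [], _SIM_OUTPUTS, _stage_simulate),
    "qc": StageSpec("qc", ["simulate"], ["qc_report.tsv"], _stage_qc),
    "annotate": StageSpec("annotate", ["simulate"], ["elements.tsv"], _stage_annotate),
    "specificity": StageSpec(
        "specificity", ["simulate"], ["specificity.tsv", "sample_similarity.tsv"], _stage_specificity
    ),
    "coassoc": StageSpec(
        "coassoc",
        ["simulate"],
        ["coassoc_matrix.tsv", "coassoc_edges.tsv", "coassoc_modules.tsv"],
        _stage_coassoc,
    ),
    "network": StageSpec("network", ["simulate"], ["meta_edges.tsv", "ffls.tsv"], _stage_network),
    "conserve": StageSpec("conserve", ["simulate"], ["conservation.tsv"], _stage_conserve),
}

STAGE_ORDER = ["simulate", "qc", "annotate", "specificity", "coassoc", "network", "conserve"]


def run_stage(name: str, config: PipelineConfig, manifest: dict | None = None) -> dict:
    """Execute one stage, verifying dependencies and recording a manifest entry."""
    if name not in STAGES:
        raise ConfigError(f"unknown stage {name!r}; stages: {', '.join(STAGE_ORDER)}")
    spec = STAGES[name]
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for dep in spec.deps:
        if not _stage_outputs_exist(STAGES[dep], outdir):
            raise DependencyError(
                f"stage {name!r} needs outputs of stage {dep!r}; run {dep!r} first"
            )
    logger.info("stage %s: starting", name)
    t0 = time.perf_counter()
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        spec.fn(config, outdir)
    elapsed = time.perf_counter() - t0
    entry = {
        "stage": name,
        "parameters": config.to_dict(),
        "outputs": {rel: _sha256(outdir / rel) for rel in spec.outputs if (outdir / rel).exists()},
        "wall_time_s": round(elapsed, 3),
        "warnings": [str(w.message) for w in caught],
    }
    if manifest is not None:
        manifest.setdefault("stages", []).append(entry)
    logger.info("stage %s: done in %.2fs (%d warnings)", name, elapsed, len(caught))
    return entry


def run_all(config: PipelineConfig, force: bool = False) -> dict:
    """Run every stage in dependency order, recomputing only what is missing.

    A stage re-runs when any of its outputs is absent, when an upstream
    stage re-ran, or when ``force`` is set.  The manifest is written to
    ``<outdir>/manifest.json``.
    """
    outdir = Path(config.outdir)
    manifest: dict = {"config": config.to_dict(), "stages": []}
    ran: set[str] = set()
    for name in STAGE_ORDER:
        spec = STAGES[name]
        upstream_ran = any(d in ran for d in spec.deps)
        if force or upstream_ran or not _stage_outputs_exist(spec, outdir):
            run_stage(name, config, manifest)
            ran.add(name)
        else:
            logger.info("stage %s: outputs up to date, skipped", name)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    manifest["ran"] = sorted(ran)
    return manifest
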