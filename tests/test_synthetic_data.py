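"""Generator determinism, feasibility and ground-truth consistency."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from regulome.core_io import read_bed, read_gff3_genes, read_accessibility_matrix
from regulome.synthetic_data import (
    ConfigurationError,
    SimulationConfig,
    make_block_partition,
    make_conservation_peaks,
    make_conservation_suite,
    make_fragments,
    make_genome_and_genes,
    make_meta_network,
    make_species_pair,
    make_tf_peaksets,
    make_tissue_atlas,
)
from regulome.tf_coassociation import jaccard_bp


def small(**overrides):
    base = dict(
        n_chroms=1,
        chrom_length_bp=700_000,
        n_genes=40,
        n_elements=200,
        n_tissues=5,
        n_tfs=6,
        n_modules=2,
        sites_per_module=40,
        n_conservation_peaks=80,
        n_fragments=500,
        n_upstream_tfs=10,
        n_mirnas=5,
        n_target_tfs=12,
    )
    base.update(overrides)
    return SimulationConfig(**base)


class TestConfig:
    def test_probability_bounds_enforced(self):
        with pytest.raises(ConfigurationError):
            SimulationConfig(p_in=1.5)

    def test_specific_weight_must_exceed_uniform(self):
        with pytest.raises(ConfigurationError):
            SimulationConfig(n_tissues=10, specific_weight=0.05)


class TestGenome:
    def test_seeded_runs_are_byte_identical(self, tmp_path):
        cfg = small(seed=1)
        make_genome_and_genes(cfg, outdir=tmp_path / "a")
        make_genome_and_genes(cfg, outdir=tmp_path / "b")
        assert (tmp_path / "a" / "genes.gff3").read_bytes() == (
            tmp_path / "b" / "genes.gff3"
        ).read_bytes()

    def test_gene_count_and_disjoint_bodies(self):
        cfg = small(n_genes=200, chrom_length_bp=3_000_000)
        genes = make_genome_and_genes(cfg).genes
        assert len(genes) == 200
        ordered = sorted(genes, key=lambda g: (g.interval.chrom, g.interval.start))
        for a, b in zip(ordered, ordered[1:]):
            if a.interval.chrom == b.interval.chrom:
                assert a.interval.end <= b.interval.start

    def test_infeasible_packing_raises(self):
        with pytest.raises(ConfigurationError):
            make_genome_and_genes(small(chrom_length_bp=10_000, n_genes=100))

    def test_emitted_gap_median_matches_gamma_median(self, tmp_path):
        cfg = SimulationConfig(seed=2, n_chroms=2, chrom_length_bp=4_000_000, n_genes=600)
        make_genome_and_genes(cfg, outdir=tmp_path)
        genes = read_gff3_genes(tmp_path / "genes.gff3")
        by_chrom: dict[str, list] = {}
        for g in sorted(genes, key=lambda g: (g.interval.chrom, g.interval.start)):
            by_chrom.setdefault(g.interval.chrom, []).append(g.interval)
        gaps = [
            b.start - a.end
            for ivs in by_chrom.values()
            for a, b in zip(ivs, ivs[1:])
        ]
        observed = float(np.median(gaps))
        assert observed == pytest.approx(cfg.intergenic_gap_median, rel=0.15)


class TestAtlas:
    def test_fraction_specific_zero(self, tiny_genome, tiny_config):
        cfg = dataclasses.replace(tiny_config, fraction_specific=0.0)
        atlas = make_tissue_atlas(cfg, tiny_genome)
        assert (atlas.truth["profile"] == "specific").sum() == 0

    def test_pure_specific_profile_single_column(self, tiny_genome, tiny_config):
        cfg = dataclasses.replace(tiny_config, specific_weight=1.0, noise_sigma=0.0)
        atlas = make_tissue_atlas(cfg, tiny_genome)
        spec = atlas.truth["profile"] == "specific"
        nonzero_cols = (atlas.matrix.loc[spec.index[spec]] > 0).sum(axis=1)
        assert (nonzero_cols == 1).all()

    def test_emitted_files_reparse_and_agree(self, tmp_path, tiny_genome, tiny_config):
        atlas = make_tissue_atlas(tiny_config, tiny_genome, outdir=tmp_path)
        matrix = read_accessibility_matrix(tmp_path / "accessibility.tsv")
        assert list(matrix.index) == list(atlas.matrix.index)
        peaks = read_bed(tmp_path / "atlas_T01.narrowPeak", dialect="narrowPeak")
        assert {p.name for p in peaks} == {p.name for p in atlas.peaks["T01"]}
        # every called peak's signal exceeds the calling threshold
        frac = tiny_config.peak_call_fraction
        row_sums = atlas.matrix.sum(axis=1)
        for p in atlas.peaks["T01"]:
            assert atlas.matrix.loc[p.name, "T01"] > frac * row_sums[p.name]

    def test_planted_specific_scores_higher(self, tiny_genome, tiny_config):
        from regulome.tissue_specificity import jsd_specificity_matrix

        atlas = make_tissue_atlas(tiny_config, tiny_genome)
        scores = jsd_specificity_matrix(atlas.matrix)
        spec = atlas.truth["profile"] == "specific"
        assert scores[spec].mean() > scores[~spec].mean()


class TestTfPeaks:
    def test_extreme_probabilities_give_sharp_modules(self, tiny_genome):
        cfg = small(p_in=1.0, p_out=0.0, n_tfs=6, n_modules=2)
        res = make_tf_peaksets(cfg, tiny_genome.assembly)
        tfs = sorted(res.peaksets)
        for a in tfs:
            for b in tfs:
                if a >= b:
                    continue
                j = jaccard_bp(res.peaksets[a], res.peaksets[b])
                if res.module_of[a] == res.module_of[b]:
                    assert j == 1.0
                else:
                    assert j == 0.0

    def test_null_case_no_structure(self, tiny_genome):
        cfg = small(p_in=0.3, p_out=0.3, n_tfs=8, n_modules=2, sites_per_module=100)
        res = make_tf_peaksets(cfg, tiny_genome.assembly)
        from regulome.tf_coassociation import coassociation_matrix

        m = coassociation_matrix(res.peaksets)
        within, across = [], []
        for a in m.index:
            for b in m.index:
                if a < b:
                    (within if res.module_of[a] == res.module_of[b] else across).append(m.loc[a, b])
        # no planted contrast: means differ by less than the spread
        assert abs(np.mean(within) - np.mean(across)) < 2 * np.std(within + across)


class TestMetaNetwork:
    def test_zero_density_zero_ffls(self):
        cfg = small(p_tf_mirna=0.0)
        assert make_meta_network(cfg).true_ffl_count == 0

    def test_truth_count_matches_bruteforce_recount(self):
        cfg = small(seed=9)
        res = make_meta_network(cfg)
        tf_to = {tf: set(ts) for tf, ts in res.tf_targets.items()}
        mirna_to: dict[str, set] = {}
        true_edges = res.mirna_table[res.mirna_table["score"] <= cfg.mirna_score_cutoff]
        for m, g in true_edges[["mirna_id", "target_gene_id"]].itertuples(index=False, name=None):
            mirna_to.setdefault(m, set()).add(g)
        count = 0
        for a, targets in tf_to.items():
            for m in res.mirna_genes:
                if m not in targets:
                    continue
                for b in res.tf_gene_catalog:
                    if b in targets and b in mirna_to.get(m, ()):
                        count += 1
        assert count == res.true_ffl_count

    def test_decoy_rows_exceed_cutoff(self):
        cfg = small(n_decoy_mirna_rows=20)
        res = make_meta_network(cfg)
        decoys = res.mirna_table[res.mirna_table["score"] > cfg.mirna_score_cutoff]
        assert len(decoys) == 20
        # decoys never collide with a retained edge
        kept = set(
            map(tuple, res.mirna_table.loc[res.mirna_table["score"] <= cfg.mirna_score_cutoff,
                                           ["mirna_id", "target_gene_id"]].values)
        )
        assert not kept & set(map(tuple, decoys[["mirna_id", "target_gene_id"]].values))


class TestSpeciesPair:
    def test_perfect_survival_identity_chain(self, tiny_genome):
        cfg = small(q_align=1.0, q_peak=1.0, spacer_max_bp=0)
        partition = make_block_partition(cfg, tiny_genome.assembly)
        peaks = make_conservation_peaks(cfg, tiny_genome.assembly, partition)
        pair = make_species_pair(cfg, tiny_genome.assembly, peaks, partition=partition)
        for chain in pair.chain_set.chains:
            assert chain.blocks == [(chain.source_end - chain.source_start, 0, 0)]
            assert chain.source_start == chain.target_start == 0
        assert pair.truth["alignable"].all()
        assert pair.truth["conserved"].all()

    def test_no_survival_empty_chain(self, tiny_genome):
        cfg = small(q_align=0.0)
        partition = make_block_partition(cfg, tiny_genome.assembly)
        peaks = make_conservation_peaks(cfg, tiny_genome.assembly, partition)
        pair = make_species_pair(cfg, tiny_genome.assembly, peaks, partition=partition)
        assert pair.chain_set.chains == []
        assert not pair.truth["alignable"].any()

    def test_survival_rate_within_binomial_error(self, tiny_genome):
        cfg = small(q_align=0.8, q_peak=0.7, n_conservation_peaks=80)
        suite = make_conservation_suite(cfg, tiny_genome.assembly)
        frac = np.mean([pair.truth["conserved"].mean() for pair in suite.species])
        p = 0.8 * 0.7
        n = 80 * (cfg.n_species - 1)
        se = np.sqrt(p * (1 - p) / n)
        assert abs(frac - p) < 3 * se


class TestFragments:
    def test_deterministic_and_sized(self, tiny_genome, tiny_config):
        frags = make_fragments(tiny_config, tiny_genome.assembly, [])
        frags2 = make_fragments(tiny_config, tiny_genome.assembly, [])
        assert frags == frags2
        assert len(frags) == tiny_config.n_fragments
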