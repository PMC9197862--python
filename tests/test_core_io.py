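"""Readers/writers, coordinate conventions and interval algebra."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from regulome.core_io import (
    AlignmentChainSet,
    Chain,
    GenomicInterval,
    GeneModel,
    ParseError,
    Peak,
    ValidationError,
    merge_intervals,
    read_bed,
    read_chain,
    read_gff3_genes,
    total_bp,
    tss,
    write_bed,
    write_chain,
    write_gff3_genes,
)
from regulome.synthetic_data import SimulationConfig, make_genome_and_genes
from conftest import bitmap_covered_bp


class TestBed:
    def test_narrowpeak_field_mapping(self, tmp_path):
        path = tmp_path / "p.narrowPeak"
        path.write_text("chr1\t100\t200\tp1\t5\t.\t8.1\t4.2\t3.0\t50\n")
        (peak,) = read_bed(path, dialect="narrowPeak")
        assert peak.interval == GenomicInterval("chr1", 100, 200)
        assert peak.summit_offset == 50
        assert peak.name == "p1"

    def test_summit_sentinel_absent(self, tmp_path):
        path = tmp_path / "p.narrowPeak"
        path.write_text("chr1\t0\t10\t.\t0\t.\t0\t-1\t-1\t-1\n")
        (peak,) = read_bed(path, dialect="narrowPeak")
        assert peak.summit_offset is None

    def test_end_before_start_rejected(self, tmp_path):
        path = tmp_path / "bad.bed"
        path.write_text("chr1\t200\t100\tx\t0\t+\n")
        with pytest.raises(ValidationError):
            read_bed(path, dialect="bed6")

    def test_malformed_line_names_line_number(self, tmp_path):
        path = tmp_path / "bad.bed"
        path.write_text("chr1\t0\t10\ta\t0\t+\nchr1\tnope\t20\tb\t0\t+\n")
        with pytest.raises(ParseError, match=":2"):
            read_bed(path, dialect="bed6")

    @pytest.mark.parametrize("dialect", ["bed6", "narrowPeak"])
    def test_round_trip_100_records(self, tmp_path, dialect):
        rng = np.random.default_rng(5)
        peaks = []
        for i in range(100):
            start = int(rng.integers(0, 100_000))
            length = int(rng.integers(1, 1000))
            summit = int(rng.integers(0, length)) if dialect == "narrowPeak" and i % 3 else None
            peaks.append(
                Peak(GenomicInterval("chr1", start, start + length), summit, float(i), f"p{i}")
            )
        p1, p2 = tmp_path / "a.bed", tmp_path / "b.bed"
        write_bed(peaks, p1, dialect=dialect)
        reread = read_bed(p1, dialect=dialect)
        write_bed(reread, p2, dialect=dialect)
        assert p1.read_bytes() == p2.read_bytes()
        assert [(p.interval, p.summit_offset, p.name) for p in reread] == [
            (p.interval, p.summit_offset, p.name) for p in peaks
        ]


class TestGff3:
    def _write(self, tmp_path, body):
        path = tmp_path / "g.gff3"
        path.write_text("##gff-version 3\n" + body)
        return path

    def test_one_based_to_half_open(self, tmp_path):
        path = self._write(tmp_path, "chr1\tx\tgene\t1\t1000\t.\t+\t.\tID=g1\n")
        (gene,) = read_gff3_genes(path)
        assert (gene.interval.start, gene.interval.end) == (0, 1000)

    def test_minus_strand_tss(self, tmp_path):
        path = self._write(tmp_path, "chr1\tx\tgene\t501\t600\t.\t-\t.\tID=g1\n")
        (gene,) = read_gff3_genes(path)
        assert tss(gene) == ("chr1", 599)

    def test_missing_id_rejected(self, tmp_path):
        path = self._write(tmp_path, "chr1\tx\tgene\t1\t10\t.\t+\t.\tName=foo\n")
        with pytest.raises(ValidationError, match="ID"):
            read_gff3_genes(path)

    def test_unstranded_gene_rejected(self, tmp_path):
        path = self._write(tmp_path, "chr1\tx\tgene\t1\t10\t.\t.\t.\tID=g1\n")
        with pytest.raises(ValidationError, match="strand"):
            read_gff3_genes(path)

    def test_synthetic_annotation_round_trip(self, tmp_path, tiny_genome):
        path = tmp_path / "genes.gff3"
        write_gff3_genes(tiny_genome.genes, path)
        reread = read_gff3_genes(path)
        assert len(reread) == len(tiny_genome.genes)
        assert len({g.gene_id for g in reread}) == len(reread)
        assert reread == tiny_genome.genes


class TestTss:
    def test_plus_strand(self):
        g = GeneModel(GenomicInterval("chr1", 100, 500, "+"), "g1")
        assert tss(g) == ("chr1", 100)

    def test_minus_strand(self):
        g = GeneModel(GenomicInterval("chr1", 100, 500, "-"), "g1")
        assert tss(g) == ("chr1", 499)

    def test_tss_inside_gene_body_exhaustive(self, tiny_genome):
        for g in tiny_genome.genes:
            chrom, pos = tss(g)
            assert chrom == g.interval.chrom
            assert g.interval.start <= pos < g.interval.end


class TestChain:
    def test_identity_chain(self, tmp_path):
        path = tmp_path / "id.chain"
        path.write_text("chain 10000 chr1 10000 + 0 10000 chr1 10000 + 0 10000 1\n10000\n\n")
        chains = read_chain(path)
        (chain,) = chains.chains
        assert chain.blocks == [(10000, 0, 0)]
        assert list(chain.block_pairs()) == [(0, 10000, 0, 10000)]

    def test_source_gap_makes_adjacent_target_blocks(self, tmp_path):
        # 100-bp gap in the source only: target projections touch
        path = tmp_path / "gap.chain"
        path.write_text("chain 900 chr1 1000 + 0 1000 chrA 900 + 0 900 7\n400 100 0\n500\n\n")
        (chain,) = read_chain(path).chains
        pairs = list(chain.block_pairs())
        assert pairs == [(0, 400, 0, 400), (500, 1000, 400, 900)]
        assert pairs[0][3] == pairs[1][2]  # adjacent in the target

    def test_arithmetic_mismatch_names_chain(self, tmp_path):
        path = tmp_path / "bad.chain"
        path.write_text("chain 1 chr1 1000 + 0 1000 chrA 900 + 0 900 42\n400 100 0\n400\n\n")
        with pytest.raises(ValidationError, match="42"):
            read_chain(path)

    def test_minus_strand_flip(self, tmp_path):
        # target on '-': reversed-frame [0,100) of a 1000-bp chrom is forward [900,1000)
        path = tmp_path / "minus.chain"
        path.write_text("chain 1 chr1 500 + 0 100 chrA 1000 - 0 100 1\n100\n\n")
        (chain,) = read_chain(path).chains
        assert list(chain.block_pairs()) == [(0, 100, 900, 1000)]

    def test_synthetic_chain_round_trip(self, tmp_path, tiny_config, tiny_genome):
        from regulome.synthetic_data import make_conservation_suite

        suite = make_conservation_suite(tiny_config, tiny_genome.assembly)
        chain_set = suite.species[0].chain_set
        p1, p2 = tmp_path / "a.chain", tmp_path / "b.chain"
        write_chain(chain_set, p1)
        write_chain(read_chain(p1), p2)
        assert p1.read_bytes() == p2.read_bytes()


class TestMergeIntervals:
    def test_overlap_merged(self):
        out = merge_intervals([GenomicInterval("c", 0, 100), GenomicInterval("c", 50, 150)])
        assert out == [GenomicInterval("c", 0, 150)]

    def test_touching_merged(self):
        out = merge_intervals([GenomicInterval("c", 0, 5), GenomicInterval("c", 5, 9)])
        assert out == [GenomicInterval("c", 0, 9)]

    def test_empty_identity(self):
        assert merge_intervals([]) == []

    def test_random_coverage_matches_bitmap_oracle(self, oracle):
        rng = np.random.default_rng(3)
        sizes = {"chr1": 10_000}
        intervals = oracle.random_intervals(rng, 1000, sizes)
        merged = merge_intervals(intervals)
        assert total_bp(merged) == bitmap_covered_bp(intervals, sizes)
        # disjoint and sorted
        for a, b in zip(merged, merged[1:]):
            assert a.end < b.start

    @settings(deadline=None, derandomize=True, max_examples=60)
    @given(
        st.lists(
            st.tuples(st.integers(0, 500), st.integers(1, 60)).map(
                lambda t: GenomicInterval("c", t[0], t[0] + t[1])
            ),
            min_size=1,
            max_size=30,
        ),
        st.randoms(),
    )
    def test_idempotent_and_order_independent(self, intervals, rnd):
        merged = merge_intervals(intervals)
        assert merge_intervals(merged) == merged
        shuffled = list(intervals)
        rnd.shuffle(shuffled)
        assert merge_intervals(shuffled) == merged
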