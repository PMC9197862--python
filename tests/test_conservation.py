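"""Interval projection through chains and conservation scoring."""

import numpy as np
import pytest

from regulome.core_io import (
    AlignmentChainSet,
    Chain,
    ChromatinSegmentation,
    GenomicInterval,
)
from regulome.cross_species_conservation import (
    conservation_scores,
    is_conserved,
    project_interval,
    project_track,
    state_conservation_jaccard,
)
from regulome.tf_coassociation import jaccard_bp


def identity_chain(chrom="chr1", size=10_000):
    return AlignmentChainSet(
        [
            Chain(
                chain_id=1, score=size, source_chrom=chrom, source_size=size,
                source_start=0, source_end=size, target_chrom=chrom, target_size=size,
                target_strand="+", target_start=0, target_end=size, blocks=[(size, 0, 0)],
            )
        ]
    )


def shift_chain(shift=1000, chrom="chr1", size=10_000):
    return AlignmentChainSet(
        [
            Chain(
                chain_id=1, score=size, source_chrom=chrom, source_size=size,
                source_start=0, source_end=size, target_chrom=chrom,
                target_size=size + shift, target_strand="+", target_start=shift,
                target_end=size + shift, blocks=[(size, 0, 0)],
            )
        ]
    )


def iv(start, end, chrom="chr1"):
    return GenomicInterval(chrom, start, end)


class TestProjection:
    def test_identity_chain_is_identity(self):
        proj = project_interval(iv(200, 300), identity_chain())
        assert proj.status == "alignable"
        assert proj.orthologous == iv(200, 300)
        assert proj.aligned_bp == 100

    def test_shift_chain_translates(self):
        proj = project_interval(iv(200, 300), shift_chain(1000))
        assert proj.orthologous == iv(1200, 1300)

    def test_largest_block_wins(self):
        # two blocks: element overlaps 70 bp of block 1 and 30 bp of block 2
        chain = Chain(
            chain_id=1, score=1, source_chrom="chr1", source_size=1000,
            source_start=0, source_end=300, target_chrom="chrA", target_size=2000,
            target_strand="+", target_start=0, target_end=500,
            blocks=[(100, 100, 300), (100, 0, 0)],
        )
        chains = AlignmentChainSet([chain])
        # element [30, 230): 70 bp of source block [0,100), 30 bp of block [200,300)
        proj = project_interval(iv(30, 230), chains)
        assert proj.aligned_bp == 70
        assert proj.orthologous == GenomicInterval("chrA", 30, 100)

    def test_no_overlap_unalignable(self):
        chain = shift_chain(0)
        proj = project_interval(iv(200, 300, chrom="chrX"), chain)
        assert proj.status == "unalignable"

    def test_min_aligned_fraction_gate(self):
        chain = Chain(
            chain_id=1, score=1, source_chrom="chr1", source_size=1000,
            source_start=0, source_end=100, target_chrom="chrA", target_size=1000,
            target_strand="+", target_start=0, target_end=100, blocks=[(100, 0, 0)],
        )
        chains = AlignmentChainSet([chain])
        el = iv(50, 250)  # only 50/200 bp alignable
        assert project_interval(el, chains).status == "alignable"
        assert project_interval(el, chains, min_aligned_fraction=0.5).status == "unalignable"

    def test_projected_bp_never_exceeds_element(self, tiny_config, tiny_genome):
        from regulome.synthetic_data import make_conservation_suite

        suite = make_conservation_suite(tiny_config, tiny_genome.assembly)
        chains = suite.species[0].chain_set
        for p in suite.source_peaks[:50]:
            proj = project_interval(p.interval, chains)
            if proj.status == "alignable":
                assert proj.aligned_bp <= len(p.interval)
                assert len(proj.orthologous) == proj.aligned_bp


class TestIsConserved:
    def make_proj(self, start, end):
        return project_interval(iv(start, end), identity_chain())

    def test_fully_inside_peak(self):
        assert is_conserved(self.make_proj(100, 200), [iv(0, 500)])

    def test_exactly_half_inclusive(self):
        assert is_conserved(self.make_proj(100, 200), [iv(150, 300)])

    def test_49_percent_not_conserved(self):
        assert not is_conserved(self.make_proj(100, 200), [iv(151, 300)])

    def test_unalignable_rejected(self):
        proj = project_interval(iv(1, 2, chrom="chrX"), identity_chain())
        with pytest.raises(ValueError):
            is_conserved(proj, [iv(0, 10)])


class TestConservationScores:
    def test_perfect_pair_scores_one_one(self, tiny_genome):
        import dataclasses

        from regulome.synthetic_data import SimulationConfig, make_conservation_suite

        cfg = SimulationConfig(
            seed=4, q_align=1.0, q_peak=1.0, spacer_max_bp=0,
            n_conservation_peaks=50, n_species=2,
        )
        suite = make_conservation_suite(cfg, tiny_genome.assembly)
        pair = suite.species[0]
        records = conservation_scores(
            [(p.name, p.interval) for p in suite.source_peaks],
            {"sp2": (pair.chain_set, [p.interval for p in pair.target_peaks])},
        )
        assert all(r.alignability_score == 1 and r.conservation_score == 1 for r in records)

    def test_zero_alignment_scores_zero(self, tiny_genome):
        from regulome.synthetic_data import SimulationConfig, make_conservation_suite

        cfg = SimulationConfig(seed=4, q_align=0.0, n_conservation_peaks=50, n_species=2)
        suite = make_conservation_suite(cfg, tiny_genome.assembly)
        pair = suite.species[0]
        records = conservation_scores(
            [(p.name, p.interval) for p in suite.source_peaks],
            {"sp2": (pair.chain_set, [p.interval for p in pair.target_peaks])},
        )
        assert all(r.alignability_score == 0 and r.conservation_score == 0 for r in records)

    def test_no_species_rejected(self):
        with pytest.raises(ValueError):
            conservation_scores([("e", iv(0, 10))], {})

    def test_conservation_never_exceeds_alignability(self, tiny_config, tiny_genome):
        from regulome.synthetic_data import make_conservation_suite

        suite = make_conservation_suite(tiny_config, tiny_genome.assembly)
        records = conservation_scores(
            [(p.name, p.interval) for p in suite.source_peaks],
            {
                pair.species: (pair.chain_set, [p.interval for p in pair.target_peaks])
                for pair in suite.species
            },
        )
        for r in records:
            assert 0 <= r.conservation_score <= r.alignability_score <= len(suite.species)


class TestStateJaccard:
    def seg(self, pairs):
        return ChromatinSegmentation([(iv(s, e), st) for s, e, st in pairs])

    def test_identical_segmentations_identity_chain(self):
        seg = self.seg([(0, 500, "A"), (500, 900, "B")])
        assert state_conservation_jaccard(seg, "A", seg, "A", identity_chain()) == 1.0

    def test_never_colocalized_states(self):
        a = self.seg([(0, 500, "A")])
        b = self.seg([(500, 900, "B")])
        assert state_conservation_jaccard(a, "A", b, "B", identity_chain()) == 0.0

    def test_designed_overlap_matches_bitmap_oracle(self, oracle):
        # state A covers [0,1000); state B covers [400,1400): overlap 600/1400
        a = self.seg([(0, 1000, "A")])
        b = self.seg([(400, 1400, "B")])
        got = state_conservation_jaccard(a, "A", b, "B", identity_chain())
        sizes = {"chr1": 10_000}
        expected = oracle.jaccard([iv(0, 1000)], [iv(400, 1400)], sizes)
        assert got == expected == pytest.approx(600 / 1400)

    def test_absent_state_scores_zero_with_warning(self):
        a = self.seg([(0, 100, "A")])
        with pytest.warns(UserWarning, match="absent"):
            assert state_conservation_jaccard(a, "Z", a, "A", identity_chain()) == 0.0

    def test_identity_chain_equals_bp_jaccard(self):
        rng = np.random.default_rng(13)
        segs = []
        for _ in range(2):
            pos, pairs = 0, []
            while pos < 8000:
                length = int(rng.integers(100, 500))
                pairs.append((pos, min(pos + length, 8000), rng.choice(["A", "B"])))
                pos += length
            segs.append(self.seg(pairs))
        a, b = segs
        got = state_conservation_jaccard(a, "A", b, "A", identity_chain())
        assert got == pytest.approx(jaccard_bp(a.intervals_of("A"), b.intervals_of("A")))

    def test_projection_through_shift_preserves_jaccard(self):
        a = self.seg([(0, 1000, "A")])
        b_shifted = self.seg([(1400, 2400, "B")])
        got = state_conservation_jaccard(a, "A", b_shifted, "B", shift_chain(1000))
        assert got == pytest.approx(600 / 1400)
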