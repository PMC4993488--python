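"""Distributional and conservation properties of the synthetic generators."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from metacomp import simulate
from metacomp.records import SequenceRecord


class TestSimulateGenome:
    def test_gc_content_matches_target(self):
        g = simulate.simulate_genome(10000, 0.61, seed=1)
        assert abs(g.gc_fraction - 0.61) < 0.02  # ~4 binomial sd at n=10k

    def test_deterministic_under_fixed_seed(self):
        a = simulate.simulate_genome(1000, 0.5, seed=7)
        b = simulate.simulate_genome(1000, 0.5, seed=7)
        assert a.seq == b.seq

    @pytest.mark.parametrize("length,gc", [(0, 0.5), (999, 0.5), (2000, 0.0), (2000, 1.0)])
    def test_preconditions(self, length, gc):
        with pytest.raises(ValueError):
            simulate.simulate_genome(length, gc, seed=1)


class TestMutateGenome:
    def test_zero_rate_is_identity(self, genome_20kb):
        m = simulate.mutate_genome(genome_20kb, 0.0, seed=3)
        assert m.seq == genome_20kb.seq
        assert m.metadata["n_substitutions"] == 0

    def test_substitution_count_binomial(self):
        g = simulate.simulate_genome(100000, 0.5, seed=5)
        m = simulate.mutate_genome(g, 0.01, seed=6)
        n_sub = m.metadata["n_substitutions"]
        assert abs(n_sub - 1000) <= 3 * math.sqrt(1000 * 0.99)
        # metadata count equals the realized Hamming distance
        diff = sum(a != b for a, b in zip(g.seq, m.seq))
        assert diff == n_sub

    def test_rate_out_of_range(self, genome_20kb):
        with pytest.raises(ValueError):
            simulate.mutate_genome(genome_20kb, 0.6, seed=1)


class TestPlantGenes:
    def test_non_overlapping_within_bounds(self):
        g = simulate.simulate_genome(100000, 0.5, seed=8)
        genome, cat = simulate.plant_genes(g, 50, seed=8)
        assert len(cat) == 50
        intervals = sorted((gene.start, gene.end) for gene in cat)
        for (s1, e1), (s2, _) in zip(intervals, intervals[1:]):
            assert e1 < s2
        assert intervals[0][0] >= 1 and intervals[-1][1] <= len(genome)

    def test_mean_length_follows_distribution(self):
        g = simulate.simulate_genome(700000, 0.5, seed=9)
        _, cat = simulate.plant_genes(g, 500, length_mean=922, length_sd=100, seed=9)
        mean_len = np.mean([len(gene.nt_seq) for gene in cat])
        assert abs(mean_len - 922) < 15  # CLT: 3 sd ~ 13.4 at n=500

    def test_translation_has_no_internal_stops(self, planted_genome):
        _, cat = planted_genome
        for gene in cat:
            assert "*" not in gene.aa_seq
            assert len(gene.aa_seq) * 3 == len(gene.nt_seq)

    def test_genes_written_into_genome(self, planted_genome):
        genome, cat = planted_genome
        from metacomp.records import revcomp

        for gene in list(cat)[:10]:
            sl = genome.seq[gene.start - 1 : gene.end]
            assert sl == (gene.nt_seq if gene.strand == "+" else revcomp(gene.nt_seq))

    def test_capacity_error(self):
        g = simulate.simulate_genome(10000, 0.5, seed=2)
        with pytest.raises(ValueError):
            simulate.plant_genes(g, 10**4, seed=2)


class TestFragmentGenome:
    def test_single_fragment_is_genome(self, genome_20kb):
        frags = simulate.fragment_genome(genome_20kb, 1, seed=1)
        assert len(frags) == 1 and frags[0].seq == genome_20kb.seq

    @given(n=st.integers(min_value=1, max_value=20), seed=st.integers(0, 1000))
    @settings(max_examples=25, deadline=None)
    def test_concatenation_conserved(self, n, seed):
        g = simulate.simulate_genome(30000, 0.5, seed=4, genome_id="frag")
        frags = simulate.fragment_genome(g, n, seed=seed)
        assert "".join(f.seq for f in frags) == g.seq
        assert all(len(f) >= 1000 for f in frags)
        offs = [f.metadata["offset"] for f in frags]
        assert offs == sorted(offs) and offs[0] == 0

    def test_too_many_fragments(self):
        g = simulate.simulate_genome(5000, 0.5, seed=1)
        with pytest.raises(ValueError):
            simulate.fragment_genome(g, 10, seed=1)


class TestSimulateReads:
    def _design(self, error=0.0, seed=1, depth_a=10.0, depth_b=0.0):
        return simulate.CommunityDesign(
            members=[simulate.CommunityMember("g", depth_a, depth_b)],
            per_base_error_rate=error,
            seed=seed,
        )

    def test_read_count_matches_depth(self):
        g = simulate.simulate_genome(50000, 0.5, seed=3, genome_id="g")
        reads, truth = simulate.simulate_reads(self._design(), [g])
        assert len(reads["A"]) == 5000  # depth * L / read_len
        assert len(reads["B"]) == 0
        assert len(truth) == 5000

    def test_error_free_reads_are_substrings(self):
        g = simulate.simulate_genome(20000, 0.5, seed=4, genome_id="g")
        reads, truth = simulate.simulate_reads(self._design(depth_a=2.0), [g])
        pos = dict(zip(truth["read_id"], truth["pos_1based"]))
        for r in reads["A"][:50]:
            p = pos[r.id] - 1
            assert g.seq[p : p + 100] == r.seq

    def test_same_seed_identical(self):
        g = simulate.simulate_genome(20000, 0.5, seed=4, genome_id="g")
        r1, t1 = simulate.simulate_reads(self._design(error=0.01, seed=9), [g])
        r2, t2 = simulate.simulate_reads(self._design(error=0.01, seed=9), [g])
        assert [x.seq for x in r1["A"]] == [x.seq for x in r2["A"]]
        assert t1.equals(t2)

    def test_empty_membership_rejected(self):
        with pytest.raises(ValueError):
            simulate.CommunityDesign(members=[], seed=1)


class TestSimulateAmplicons:
    def test_error_free_tags_are_windows(self):
        ref = simulate.simulate_genome(1500, 0.55, seed=5, genome_id="r")
        tags, truth = simulate.simulate_amplicons([ref], 20, 0.0, 450, seed=6)
        starts = dict(zip(truth["tag_id"], truth["start_1based"]))
        for t in tags:
            p = starts[t.id] - 1
            assert ref.seq[p : p + 450] == t.seq

    def test_mean_identity_tracks_error_rate(self):
        ref = simulate.simulate_genome(1500, 0.55, seed=5, genome_id="r")
        tags, truth = simulate.simulate_amplicons([ref], 200, 0.02, 450, seed=7)
        starts = dict(zip(truth["tag_id"], truth["start_1based"]))
        idents = []
        for t in tags:
            p = starts[t.id] - 1
            src = ref.seq[p : p + 450]
            idents.append(sum(a == b for a, b in zip(src, t.seq)) / 450)
        assert abs(np.mean(idents) - 0.98) < 0.005

    def test_tag_longer_than_reference(self):
        ref = simulate.simulate_genome(1500, 0.55, seed=5, genome_id="r")
        with pytest.raises(ValueError):
            simulate.simulate_amplicons([ref], 5, 0.0, 2000, seed=1)


def test_diverged_catalog_tracks_descent(planted_genome):
    genome, cat = planted_genome
    _, div = simulate.diverged_catalog(genome, cat, 0.02, seed=13)
    assert len(div) == len(cat)
    for ga, gb in zip(cat, div):
        assert len(ga.nt_seq) == len(gb.nt_seq)
        ident = np.mean([a == b for a, b in zip(ga.nt_seq, gb.nt_seq)])
        assert ident > 0.9
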