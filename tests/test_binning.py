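"""Coverage computation, TNF signatures, bin extraction and assembly stats."""

import math

import numpy as np
import pandas as pd
import pytest

from metacomp import binning, simulate
from metacomp.binning import BinSelection, bin_stats, compute_coverage, extract_bin, tnf
from metacomp.records import SequenceRecord, revcomp

from conftest import substitute


class TestTNF:
    def test_homopolymer(self):
        v = tnf(SequenceRecord("x", "AAAA" * 250))
        assert v.shape == (136,)
        assert v.max() == 1.0 and v.sum() == pytest.approx(1.0)

    def test_reverse_complement_invariance(self):
        for seed in range(5):
            g = simulate.simulate_genome(3000, 0.5, seed=700 + seed)
            rc = SequenceRecord("rc", revcomp(g.seq))
            assert np.allclose(tnf(g), tnf(rc))

    def test_sums_to_one(self):
        g = simulate.simulate_genome(5000, 0.61, seed=71)
        assert tnf(g).sum() == pytest.approx(1.0, abs=1e-9)

    def test_uniform_random_near_uniform(self):
        g = simulate.simulate_genome(100000, 0.5, seed=72)
        v = tnf(g)
        # multinomial: sd of a canonical-pair frequency ~ sqrt(p(1-p)/n)
        p = 1 / 136
        sd = math.sqrt(2 * p * (1 - p) / 100000)
        assert v.max() < p * 2 + 3 * sd * 10  # loose cap: no pathological spike
        assert abs(v.mean() - p) < 1e-12

    def test_ambiguous_windows_skipped(self):
        v1 = tnf(SequenceRecord("x", "ACGTACGTACGT"))
        v2 = tnf(SequenceRecord("y", "ACGTACGTACGT" + "N" + "ACGTACGTACGT"))
        # N windows are dropped, composition unchanged
        assert np.allclose(v1 / v1.sum(), v2 / v2.sum())

    def test_too_short(self):
        with pytest.raises(ValueError):
            tnf(SequenceRecord("x", "ACG"))


def _single_genome_community(error=0.0, depth=10.0, length=10000, seed=80):
    g = simulate.simulate_genome(length, 0.5, seed=seed, genome_id="g")
    design = simulate.CommunityDesign(
        members=[simulate.CommunityMember("g", depth, 0.0)],
        per_base_error_rate=error,
        seed=seed,
    )
    reads, truth = simulate.simulate_reads(design, [g])
    return g, reads, truth


class TestComputeCoverage:
    def test_depth_recovered(self):
        g, reads, _ = _single_genome_community(depth=10.0)
        prof = compute_coverage([g], reads_by_sample=reads)
        assert abs(prof.loc[0, "cov_A"] - 10.0) < 0.5
        assert prof.loc[0, "cov_B"] == 0.0

    def test_low_identity_reads_excluded(self):
        # reads carrying exactly 12 substitutions per 100 bp: 88% < 90% cutoff
        g = simulate.simulate_genome(10000, 0.5, seed=81, genome_id="g")
        rng = np.random.default_rng(81)
        reads = []
        for i in range(100):
            start = int(rng.integers(0, 9900))
            raw = g.seq[start : start + 100]
            reads.append(
                SequenceRecord(f"r{i}", substitute(raw, rng.choice(100, 12, replace=False)))
            )
        prof = compute_coverage([g], reads_by_sample={"A": reads, "B": []})
        assert prof.loc[0, "cov_A"] == 0.0

    def test_empty_read_set(self):
        g = simulate.simulate_genome(5000, 0.5, seed=82, genome_id="g")
        prof = compute_coverage([g], reads_by_sample={"A": [], "B": []})
        assert (prof[["cov_A", "cov_B"]] == 0).all().all()

    def test_placement_table_path(self):
        g = simulate.simulate_genome(2000, 0.5, seed=83, genome_id="g")
        placements = pd.DataFrame(
            {
                "read_id": ["r1", "r2", "r3"],
                "scaffold_id": ["g", "g", "g"],
                "identity": [100.0, 89.0, 95.0],
                "aligned_fraction": [1.0, 1.0, 0.90],
                "aligned_bases": [100, 100, 90],
                "sample": ["A", "A", "A"],
            }
        )
        prof = compute_coverage([g], placements=placements)
        # only r1 passes both filters: 100 bases over 2000 bp
        assert prof.loc[0, "cov_A"] == pytest.approx(0.05)

    def test_unknown_scaffold_in_placements(self):
        g = simulate.simulate_genome(2000, 0.5, seed=84, genome_id="g")
        placements = pd.DataFrame(
            {
                "read_id": ["r1"],
                "scaffold_id": ["missing"],
                "identity": [100.0],
                "aligned_fraction": [1.0],
                "aligned_bases": [100],
                "sample": ["A"],
            }
        )
        with pytest.raises(ValueError, match="unknown scaffold"):
            compute_coverage([g], placements=placements)

    def test_short_scaffold_rejected(self):
        with pytest.raises(ValueError, match="1000"):
            compute_coverage([SequenceRecord("s", "ACGT" * 100)], reads_by_sample={"A": [], "B": []})


@pytest.fixture(scope="module")
def community():
    g1 = simulate.simulate_genome(20000, 0.61, seed=90, genome_id="g1")
    g2 = simulate.simulate_genome(20000, 0.45, seed=91, genome_id="g2")
    scaffolds = simulate.fragment_genome(g1, 10, seed=92) + simulate.fragment_genome(
        g2, 10, seed=93
    )
    design = simulate.CommunityDesign(
        members=[
            simulate.CommunityMember("g1", 30.0, 5.0),
            simulate.CommunityMember("g2", 5.0, 30.0),
        ],
        per_base_error_rate=0.005,
        seed=94,
    )
    reads, _ = simulate.simulate_reads(design, [g1, g2])
    profile = compute_coverage(scaffolds, reads_by_sample=reads)
    return scaffolds, profile


class TestExtractBin:
    def test_planted_genome_recovered(self, community):
        scaffolds, profile = community
        sel = BinSelection(
            math.log10(30) - 0.3, math.log10(30) + 0.3,
            math.log10(5) - 0.3, math.log10(5) + 0.3,
        )
        gbin = extract_bin(profile, scaffolds, sel)
        got = set(gbin.scaffold_ids)
        true = {s.id for s in scaffolds if s.id.startswith("g1")}
        tp = len(got & true)
        f1 = 2 * tp / (len(got) + len(true))
        assert f1 >= 0.95

    def test_box_enclosing_everything(self, community):
        scaffolds, profile = community
        sel = BinSelection(-5, 5, -5, 5, tnf_max_distance=None)
        gbin = extract_bin(profile, scaffolds, sel)
        assert set(gbin.scaffold_ids) == {s.id for s in scaffolds}

    def test_empty_box(self, community):
        scaffolds, profile = community
        with pytest.raises(ValueError, match="no scaffolds"):
            extract_bin(profile, scaffolds, BinSelection(3.9, 4.0, 3.9, 4.0))

    def test_tnf_refinement_increases_precision(self):
        # same coverage box, GC 16 points apart: composition must rescue
        # what coverage alone cannot separate
        target = simulate.simulate_genome(24000, 0.61, seed=95, genome_id="tg")
        contam = simulate.simulate_genome(12000, 0.45, seed=96, genome_id="ct")
        scaffolds = simulate.fragment_genome(target, 12, seed=97) + simulate.fragment_genome(
            contam, 6, seed=98
        )
        design = simulate.CommunityDesign(
            members=[
                simulate.CommunityMember("tg", 20.0, 20.0),
                simulate.CommunityMember("ct", 20.0, 20.0),
            ],
            seed=99,
        )
        reads, _ = simulate.simulate_reads(design, [target, contam])
        profile = compute_coverage(scaffolds, reads_by_sample=reads)
        lo, hi = math.log10(20) - 0.3, math.log10(20) + 0.3

        def precision(sel):
            gbin = extract_bin(profile, scaffolds, sel)
            got = set(gbin.scaffold_ids)
            return sum(1 for s in got if s.startswith("tg")) / len(got)

        p_box = precision(BinSelection(lo, hi, lo, hi, tnf_max_distance=None))
        p_tnf = precision(BinSelection(lo, hi, lo, hi))
        assert p_tnf > p_box


class TestBinStats:
    def test_hand_countable(self):
        gbin = bin_stats(lengths=[5000, 3000, 2000])
        assert gbin.total_bp == 10000
        assert gbin.n50 == 5000
        assert gbin.mean_len == 3333
        assert gbin.max_len == 5000

    def test_mean_lengths_from_totals(self):
        # whole-assembly and bin-scale size spectra: mean = total / count,
        # rounded half-up
        lengths = [43617366 // 12801] * 12801
        for i in range(43617366 - sum(lengths)):
            lengths[i] += 1
        assert sum(lengths) == 43617366
        assert bin_stats(lengths=lengths).mean_len == 3407
        lengths = [4262673 // 369] * 369
        for i in range(4262673 - sum(lengths)):
            lengths[i] += 1
        assert bin_stats(lengths=lengths).mean_len == 11552

    def test_single_scaffold(self):
        gbin = bin_stats(lengths=[7777])
        assert gbin.n50 == gbin.max_len == gbin.total_bp == 7777

    def test_n50_brute_force_oracle(self, rng):
        def brute_n50(lengths):
            desc = sorted(lengths, reverse=True)
            half = sum(lengths) / 2
            acc = 0
            for ln in desc:
                acc += ln
                if acc >= half:
                    return ln

        for _ in range(50):
            lengths = rng.integers(1000, 50000, size=int(rng.integers(1, 200))).tolist()
            assert bin_stats(lengths=lengths).n50 == brute_n50(lengths)

    def test_gc_percent(self):
        recs = [SequenceRecord("a", "GGCC" * 300), SequenceRecord("b", "AATT" * 300)]
        gbin = bin_stats(recs)
        assert gbin.gc_percent == pytest.approx(50.0)

    def test_empty_bin(self):
        with pytest.raises(ValueError):
            bin_stats(lengths=[])
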