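"""RBH orthology, ANI recovery and pangenome partitioning."""

import numpy as np
import pytest

from metacomp import simulate
from metacomp.align import align_local
from metacomp.compare import (
    ani_matrix,
    ani_table,
    partition_pangenome,
    reciprocal_best_hits,
)
from metacomp.records import Gene, GeneCatalog, SequenceRecord


def _catalog(genome_id, seqs):
    genes = [
        Gene(f"{genome_id}_g{i}", genome_id, 1, len(s), "+", s, "")
        for i, s in enumerate(seqs)
    ]
    return GeneCatalog(genome_id, genes)


def _protein_catalog(genome_id, aas):
    genes = [
        Gene(f"{genome_id}_p{i}", genome_id, 1, len(a) * 3, "+", "A" * (len(a) * 3), a)
        for i, a in enumerate(aas)
    ]
    return GeneCatalog(genome_id, genes)


@pytest.fixture(scope="module")
def base():
    g = simulate.simulate_genome(40000, 0.61, seed=41, genome_id="base")
    return simulate.plant_genes(g, 30, 900, 100, seed=41)


class TestReciprocalBestHits:
    def test_identical_catalogs(self, base):
        _, cat = base
        other = GeneCatalog(
            "copy",
            [Gene(f"c_{g.gene_id}", "copy", g.start, g.end, g.strand, g.nt_seq, "") for g in cat],
        )
        res = reciprocal_best_hits(cat, other)
        assert res.n_orthologs == len(cat)
        assert res.ani == pytest.approx(100.0)

    def test_short_alignment_screened_out(self):
        rng = np.random.default_rng(42)
        full = "".join("ACGT"[i] for i in rng.integers(0, 4, 1000))
        other = "".join("ACGT"[i] for i in rng.integers(0, 4, 1000))
        cat_a = _catalog("A", [full])
        # B's only gene shares just the first 390 bp (39% of A's gene)
        cat_b = _catalog("B", [full[:390]])
        res = reciprocal_best_hits(cat_a, cat_b)
        assert res.n_orthologs == 0 and res.ani is None
        # relaxing the screen recovers the pair
        res2 = reciprocal_best_hits(cat_a, cat_b, min_aln_fraction=0.30)
        assert res2.n_orthologs == 1
        del other

    def test_ani_matches_hamming_oracle(self, base):
        genome, cat = base
        _, div = simulate.diverged_catalog(genome, cat, 0.01, seed=43)
        res = reciprocal_best_hits(cat, div)
        oracle = np.mean(
            [
                100.0 * np.mean([a == b for a, b in zip(x.nt_seq, y.nt_seq)])
                for x, y in zip(cat, div)
            ]
        )
        assert res.n_orthologs == len(cat)
        assert res.ani == pytest.approx(oracle, abs=0.3)

    def test_ani_symmetric(self, base):
        genome, cat = base
        _, div = simulate.diverged_catalog(genome, cat, 0.05, seed=44)
        fwd = reciprocal_best_hits(cat, div)
        rev = reciprocal_best_hits(div, cat)
        assert fwd.n_orthologs == rev.n_orthologs
        assert fwd.ani == pytest.approx(rev.ani, abs=1e-9)

    def test_empty_catalog_rejected(self, base):
        _, cat = base
        with pytest.raises(ValueError):
            reciprocal_best_hits(cat, GeneCatalog("empty", []))


class TestAniMatrix:
    def test_divergence_ladder_ordering(self, base):
        genome, cat = base
        catalogs = [cat]
        for p in (0.01, 0.05, 0.10):
            _, d = simulate.diverged_catalog(genome, cat, p, seed=int(p * 1000), genome_id=f"d{p:g}")
            catalogs.append(d)
        ani, orth = ani_matrix(catalogs)
        row = ani.loc["base", ["d0.01", "d0.05", "d0.1"]].to_numpy()
        assert row[0] > row[1] > row[2]
        assert (orth.loc["base", ["d0.01", "d0.05", "d0.1"]] == len(cat)).all()
        # combined layout: integer percents above diagonal, counts below
        table = ani_table(ani, orth)
        assert table.loc["base", "d0.01"] == "99%"
        assert table.loc["d0.01", "base"] == len(cat)

    def test_single_catalog_rejected(self, base):
        _, cat = base
        with pytest.raises(ValueError):
            ani_matrix([cat])


class TestPartitionPangenome:
    def _random_proteins(self, n, length, seed):
        rng = np.random.default_rng(seed)
        aa = "ACDEFGHIKLMNPQRSTVWY"
        return ["".join(aa[i] for i in rng.integers(0, 20, length)) for _ in range(n)]

    def test_identical_proteomes_have_no_unique_genes(self):
        prots = self._random_proteins(8, 250, 1)
        part = partition_pangenome([_protein_catalog("A", prots), _protein_catalog("B", prots)])
        assert part.unique == {"A": set(), "B": set()}
        assert len(part.core["A"]) == 8

    def test_planted_private_gene_is_unique(self):
        shared = self._random_proteins(5, 250, 2)
        private = self._random_proteins(1, 250, 3)  # unrelated -> <<50% identity
        part = partition_pangenome(
            [_protein_catalog("A", shared + private), _protein_catalog("B", shared)]
        )
        assert part.unique["A"] == {"A_p5"}
        assert part.unique["B"] == set()

    def test_exactly_half_coverage_is_not_enough(self):
        # strict > cutoffs: a hit covering exactly 50% of the query fails
        prot = self._random_proteins(1, 200, 4)[0]
        part = partition_pangenome(
            [_protein_catalog("A", [prot]), _protein_catalog("B", [prot[:100]])]
        )
        assert part.unique["A"] == {"A_p0"}

    def test_brute_force_presence_oracle(self):
        # independent double loop over align_local with the same cutoffs
        core = self._random_proteins(6, 200, 5)
        catalogs = []
        for gi in range(3):
            private = self._random_proteins(2, 200, 60 + gi)
            catalogs.append(_protein_catalog(f"G{gi}", core + private))
        part = partition_pangenome(catalogs)

        aa = {c.genome_id: c.aa_records() for c in catalogs}
        for gid, recs in aa.items():
            for gene in recs:
                present = {gid}
                for other, others in aa.items():
                    if other == gid:
                        continue
                    for subj in others:
                        hit = align_local(gene, subj, "aa")
                        if hit and hit.identity > 50.0 and hit.q_cov_fraction > 0.5:
                            present.add(other)
                            break
                row = part.presence.set_index("gene_id").loc[gene.id]
                assert row["pattern"] == "+".join(sorted(present))

    def test_venn_counts_partition_each_genome(self):
        core = self._random_proteins(4, 200, 7)
        catalogs = [
            _protein_catalog(f"G{gi}", core + self._random_proteins(2, 200, 80 + gi))
            for gi in range(3)
        ]
        part = partition_pangenome(catalogs)
        # every gene of every genome lands in exactly one region
        assert sum(part.venn_counts.values()) == sum(len(c) for c in catalogs)
        per_genome = part.presence.groupby("genome").size()
        for cat in catalogs:
            assert per_genome[cat.genome_id] == len(cat)
        # all genomes' core sets map to the all-genomes region
        all_region = tuple(sorted(part.genomes))
        assert part.venn_counts[all_region] == sum(len(s) for s in part.core.values())

    def test_fewer_than_two_rejected(self):
        with pytest.raises(ValueError):
            partition_pangenome([_protein_catalog("A", self._random_proteins(2, 100, 9))])
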