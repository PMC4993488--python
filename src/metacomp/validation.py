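"""Ground-truth recovery experiments on synthetic communities.

Each experiment generates inputs with :mod:`metacomp.simulate`, runs the
corresponding analysis stage, and scores the result against the planted
truth. They are the package's own calibration/validation harnesses (and
what the worked examples run); every quantity is recomputed from scratch
for the given seed.
"""

from __future__ import annotations

import math

import numpy as np

from . import binning, compare, markers, simulate
from .amplicon import UNASSIGNED, AmpliconReference, assign_tags
from .records import SequenceRecord

# depth-pair menu: every pair of members differs by >= 4x on at least one axis
DEPTH_MENU: list[tuple[float, float]] = [
    (20.0, 5.0),
    (5.0, 20.0),
    (20.0, 20.0),
    (5.0, 5.0),
    (80.0, 20.0),
]
GC_MENU = [0.61, 0.45, 0.55, 0.50, 0.62]


def ani_recovery_experiment(
    sub_rate: float,
    n_genes: int = 500,
    gene_length_mean: float = 900.0,
    gene_length_sd: float = 100.0,
    seed: int = 0,
) -> dict:
    """RBH ANI between a gene catalog and a copy diverged at ``sub_rate``.

    Expected ANI is 100*(1 - sub_rate); the returned ``oracle`` is the
    exact mean Hamming identity of the constructed gene pairs.
    """
    genome_len = int(n_genes * (gene_length_mean + 200))
    genome = simulate.simulate_genome(genome_len, 0.61, seed=seed, genome_id="anibase")
    genome, catalog = simulate.plant_genes(
        genome, n_genes, gene_length_mean, gene_length_sd, seed=seed
    )
    _, diverged = simulate.diverged_catalog(genome, catalog, sub_rate, seed=seed + 1)
    # Hamming oracle over the known descent pairs
    idents = []
    for ga, gb in zip(catalog, diverged):
        a = np.frombuffer(ga.nt_seq.encode(), dtype=np.uint8)
        b = np.frombuffer(gb.nt_seq.encode(), dtype=np.uint8)
        idents.append(100.0 * float(np.mean(a == b)))
    res = compare.reciprocal_best_hits(catalog, diverged)
    return {
        "sub_rate": sub_rate,
        "ani": res.ani,
        "expected": 100.0 * (1.0 - sub_rate),
        "oracle": float(np.mean(idents)),
        "n_orthologs": res.n_orthologs,
        "n_genes": n_genes,
    }


def _community_truth(
    seed: int,
    n_genomes: int,
    genome_length: int,
    n_scaffolds: int,
    per_base_error_rate: float,
) -> tuple[list[SequenceRecord], list[SequenceRecord], dict[str, str], simulate.CommunityDesign]:
    genomes = []
    scaffolds: list[SequenceRecord] = []
    genome_of: dict[str, str] = {}
    for i in range(n_genomes):
        g = simulate.simulate_genome(
            genome_length, GC_MENU[i], seed=seed * 10 + i, genome_id=f"g{i + 1}"
        )
        genomes.append(g)
        frags = simulate.fragment_genome(g, n_scaffolds, seed=seed * 10 + i)
        scaffolds.extend(frags)
        genome_of.update({f.id: g.id for f in frags})
    design = simulate.CommunityDesign(
        members=[
            simulate.CommunityMember(g.id, *DEPTH_MENU[i]) for i, g in enumerate(genomes)
        ],
        per_base_error_rate=per_base_error_rate,
        seed=seed,
    )
    return genomes, scaffolds, genome_of, design


def bin_recovery_experiment(
    n_communities: int = 20,
    seed: int = 0,
    genome_length: int = 12000,
    n_scaffolds: int = 8,
    per_base_error_rate: float = 0.005,
    box_margin: float = 0.3,
) -> dict:
    """Membership F1 of coverage-box + TNF bin extraction, many communities.

    Each community has 3-5 genomes at depth pairs separated by >= 4x on at
    least one axis; the bin targeted is the first member, with the
    selection box placed around its designed depths.
    """
    f1s = []
    for c in range(n_communities):
        cseed = seed * 100 + c + 1
        n_genomes = 3 + c % 3
        genomes, scaffolds, genome_of, design = _community_truth(
            cseed, n_genomes, genome_length, n_scaffolds, per_base_error_rate
        )
        reads, _ = simulate.simulate_reads(design, genomes)
        profile = binning.compute_coverage(scaffolds, reads_by_sample=reads)
        da, db = DEPTH_MENU[0]
        sel = binning.BinSelection(
            math.log10(da) - box_margin,
            math.log10(da) + box_margin,
            math.log10(db) - box_margin,
            math.log10(db) + box_margin,
        )
        gbin = binning.extract_bin(profile, scaffolds, sel)
        target = genomes[0].id
        true_set = {sid for sid, gid in genome_of.items() if gid == target}
        got = set(gbin.scaffold_ids)
        tp = len(got & true_set)
        precision = tp / len(got) if got else 0.0
        recall = tp / len(true_set)
        f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
        f1s.append(f1)
    return {"mean_f1": float(np.mean(f1s)), "f1": f1s, "n_communities": n_communities}


def tag_assignment_experiment(
    per_base_error_rate: float,
    n_tags: int = 1000,
    n_groups: int = 4,
    tag_length: int = 450,
    ref_length: int = 1500,
    seed: int = 0,
) -> dict:
    """Fraction of simulated tags assigned back to their source group."""
    refs = []
    plain = []
    for i in range(n_groups):
        rec = simulate.simulate_genome(
            ref_length, 0.55, seed=seed * 10 + i, genome_id=f"ref{i + 1}"
        )
        rec.metadata["group"] = f"group{i + 1}"
        plain.append(rec)
        refs.append(AmpliconReference(f"group{i + 1}", rec))
    tags, truth = simulate.simulate_amplicons(
        plain, n_tags, per_base_error_rate, tag_length, seed=seed + 1
    )
    assignments = assign_tags(tags, refs)
    truth_group = dict(zip(truth["tag_id"], truth["group"]))
    n_correct = sum(a.assigned_group == truth_group[a.tag_id] for a in assignments)
    n_unassigned = sum(a.assigned_group == UNASSIGNED for a in assignments)
    return {
        "per_base_error_rate": per_base_error_rate,
        "accuracy": 100.0 * n_correct / n_tags,
        "unassigned_rate": n_unassigned / n_tags,
        "n_tags": n_tags,
    }


def subsample_completeness_experiment(
    retained_fraction: float = 0.8,
    n_markers: int = 200,
    n_seeds: int = 20,
    n_scaffolds: int = 50,
    seed: int = 0,
) -> dict:
    """Mean estimated completeness after random scaffold loss.

    A genome with ``n_markers`` planted single-copy markers is fragmented
    and subsampled at ``retained_fraction`` over ``n_seeds`` replicates;
    expected completeness approximates 100 * retained_fraction.
    """
    genome = simulate.simulate_genome(
        n_markers * 1200, 0.61, seed=seed, genome_id="subsample_genome"
    )
    genome, catalog = simulate.plant_genes(genome, n_markers, 900, 100, seed=seed)
    marker_of_gene = {g.gene_id: f"m{i + 1:04d}" for i, g in enumerate(catalog)}
    panel = markers.MarkerPanel("planted", frozenset(marker_of_gene.values()))
    values = []
    for s in range(n_seeds):
        rep = markers.subsample_recovery(
            genome, catalog, panel, marker_of_gene,
            retained_fraction, seed=seed * 1000 + s, n_scaffolds=n_scaffolds,
        )
        values.append(rep.completeness)
    return {
        "retained_fraction": retained_fraction,
        "mean_completeness": float(np.mean(values)),
        "completeness": values,
        "n_seeds": n_seeds,
    }
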