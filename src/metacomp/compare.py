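"""Whole-genome comparison: reciprocal-best-hit ANI and pangenome partition.

Average nucleotide identity (ANI) between two genomes is computed over
their gene catalogs: every gene of genome A is aligned against genome B's
genes and vice versa, alignments covering less than 40% of either gene's
length are discarded, and a gene pair is an ortholog when each member is
the other's best surviving hit. ANI is the unweighted mean percent
identity over those reciprocal pairs; the ortholog count is the number of
pairs. Conventionally ANI >= ~95% indicates the same species.

The pangenome partition works on protein sequences: a gene is *unique*
to its genome when it has no hit in any other genome at > 50% identity
over > 50% of the protein length (strict inequalities); it belongs to
the conserved core when it has a qualifying hit in every other genome.
Per-gene presence patterns across genomes yield the Venn-region counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .align import AlignmentHit, SeedIndex, _better, align_local
from .records import GeneCatalog, SequenceRecord

DEFAULT_MIN_ALN_FRACTION = 0.40
DEFAULT_PANGENOME_ID_CUTOFF = 50.0
DEFAULT_PANGENOME_COV_CUTOFF = 0.50


@dataclass
class RBHResult:
    genome_a: str
    genome_b: str
    pairs: pd.DataFrame  # columns gene_a, gene_b, identity
    ani: float | None  # percent; None when no pair survives
    n_orthologs: int


def _best_hits_oneway(
    queries: list[SequenceRecord],
    index: SeedIndex,
    min_aln_fraction: float,
    max_candidates: int = 8,
) -> dict[str, AlignmentHit]:
    """Best surviving hit per query (coverage screen applied pre-selection)."""
    out: dict[str, AlignmentHit] = {}
    for q in queries:
        cand = index.candidates(q, max_candidates)
        pool = [index.subjects[i] for i in cand] if cand else index.subjects
        best: AlignmentHit | None = None
        for subj in pool:
            hit = align_local(q, subj, index.alphabet)
            if hit is None:
                continue
            # screen: alignment must cover >= min_aln_fraction of both genes
            if hit.q_cov_fraction < min_aln_fraction or hit.s_cov_fraction < min_aln_fraction:
                continue
            if _better(hit, best):
                best = hit
        if best is not None:
            out[q.id] = best
    return out


def reciprocal_best_hits(
    genes_a: GeneCatalog,
    genes_b: GeneCatalog,
    min_aln_fraction: float = DEFAULT_MIN_ALN_FRACTION,
) -> RBHResult:
    """Orthologs and ANI between two gene catalogs (nucleotide space).

    Alignments shorter than ``min_aln_fraction`` of either gene are
    removed before best-hit selection; a pair is kept iff each gene is the
    other's best hit. ANI is the unweighted mean identity over pairs, or
    None when no pair survives.
    """
    if len(genes_a) == 0 or len(genes_b) == 0:
        raise ValueError("reciprocal_best_hits: empty catalog")
    recs_a = genes_a.nt_records()
    recs_b = genes_b.nt_records()
    fwd = _best_hits_oneway(recs_a, SeedIndex(recs_b, "nt"), min_aln_fraction)
    rev = _best_hits_oneway(recs_b, SeedIndex(recs_a, "nt"), min_aln_fraction)
    rows = []
    for ga, hit in sorted(fwd.items()):
        gb = hit.subject_id
        back = rev.get(gb)
        if back is not None and back.subject_id == ga:
            rows.append({"gene_a": ga, "gene_b": gb, "identity": hit.identity})
    pairs = pd.DataFrame(rows, columns=["gene_a", "gene_b", "identity"])
    ani = float(pairs["identity"].mean()) if len(pairs) else None
    return RBHResult(genes_a.genome_id, genes_b.genome_id, pairs, ani, len(pairs))


def ani_matrix(catalogs: list[GeneCatalog]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise ANI (percent, float) and ortholog-count matrices.

    Returns ``(ani, n_orthologs)`` as symmetric DataFrames indexed by
    genome id, diagonal NaN / 0. Use :func:`ani_table` for the combined
    upper-ANI / lower-orthologs layout.
    """
    if len(catalogs) < 2:
        raise ValueError("ani_matrix needs at least 2 catalogs")
    ids = [c.genome_id for c in catalogs]
    ani = pd.DataFrame(np.nan, index=ids, columns=ids)
    orth = pd.DataFrame(0, index=ids, columns=ids)
    for i in range(len(catalogs)):
        for j in range(i + 1, len(catalogs)):
            res = reciprocal_best_hits(catalogs[i], catalogs[j])
            val = np.nan if res.ani is None else res.ani
            ani.iloc[i, j] = ani.iloc[j, i] = val
            orth.iloc[i, j] = orth.iloc[j, i] = res.n_orthologs
    return ani, orth


def ani_table(ani: pd.DataFrame, orth: pd.DataFrame) -> pd.DataFrame:
    """Combined matrix: ANI as integer percent above the diagonal,
    ortholog counts below, ``\\`` on the diagonal."""
    ids = list(ani.index)
    out = pd.DataFrame("\\", index=ids, columns=ids, dtype=object)
    for i, a in enumerate(ids):
        for j, b in enumerate(ids):
            if i < j:
                v = ani.loc[a, b]
                out.loc[a, b] = "" if np.isnan(v) else f"{int(np.floor(v + 0.5))}%"
            elif i > j:
                out.loc[a, b] = int(orth.loc[a, b])
    return out


@dataclass
class PangenomePartition:
    genomes: list[str]
    unique: dict[str, set[str]]  # genome -> its private gene ids
    core: dict[str, set[str]]  # genome -> its genes present in all others
    venn_counts: dict[tuple[str, ...], int]  # presence pattern -> gene count
    presence: pd.DataFrame  # gene_id, genome, pattern, is_unique, is_core


def partition_pangenome(
    proteomes: list[GeneCatalog],
    id_cutoff: float = DEFAULT_PANGENOME_ID_CUTOFF,
    cov_cutoff: float = DEFAULT_PANGENOME_COV_CUTOFF,
) -> PangenomePartition:
    """Partition genes into unique / shared / conserved-core sets.

    A gene counts as present in another genome when some protein there
    aligns at identity > id_cutoff over > cov_cutoff of the query protein
    (strict inequalities). The presence pattern of a gene is its own
    genome plus every other genome with a qualifying hit; Venn-region
    counts aggregate genes by pattern.
    """
    if len(proteomes) < 2:
        raise ValueError("partition_pangenome needs at least 2 proteomes")
    ids = [c.genome_id for c in proteomes]
    if len(ids) != len(set(ids)):
        raise ValueError("duplicate genome ids")
    aa = {c.genome_id: c.aa_records() for c in proteomes}
    indexes = {gid: SeedIndex(recs, "aa") for gid, recs in aa.items() if recs}

    unique: dict[str, set[str]] = {gid: set() for gid in ids}
    core: dict[str, set[str]] = {gid: set() for gid in ids}
    venn_counts: dict[tuple[str, ...], int] = {}
    rows = []
    for gid in ids:
        others = [o for o in ids if o != gid]
        for gene in aa[gid]:
            present_in = {gid}
            for other in others:
                index = indexes.get(other)
                if index is None:
                    continue
                cand = index.candidates(gene, max_candidates=8)
                pool = [index.subjects[i] for i in cand] if cand else index.subjects
                for subj in pool:
                    hit = align_local(gene, subj, "aa")
                    if (
                        hit is not None
                        and hit.identity > id_cutoff
                        and hit.q_cov_fraction > cov_cutoff
                    ):
                        present_in.add(other)
                        break
            pattern = tuple(sorted(present_in))
            venn_counts[pattern] = venn_counts.get(pattern, 0) + 1
            is_unique = len(present_in) == 1
            is_core = len(present_in) == len(ids)
            if is_unique:
                unique[gid].add(gene.id)
            if is_core:
                core[gid].add(gene.id)
            rows.append(
                {
                    "gene_id": gene.id,
                    "genome": gid,
                    "pattern": "+".join(pattern),
                    "is_unique": is_unique,
                    "is_core": is_core,
                }
            )
    presence = pd.DataFrame(rows, columns=["gene_id", "genome", "pattern", "is_unique", "is_core"])
    return PangenomePartition(ids, unique, core, venn_counts, presence)
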