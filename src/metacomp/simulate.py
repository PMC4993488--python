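"""Synthetic community generator with known ground truth.

Everything the downstream stages consume can be simulated here: genomes at
a chosen GC content, relatives diverged at a known per-site substitution
rate, gene catalogs with planted (single-copy) genes, fragmented scaffold
sets, two-sample read sets at designed depths, and error-bearing 16S-like
amplicon tags. Each generator emits a truth table alongside its sequences,
so recovery of bins, orthologs and tag assignments can be scored exactly.

The error model is substitution-only (no indels), which keeps expected
identities analytic: a per-site rate ``p`` yields an expected percent
identity of ``100 * (1 - p)``.

Randomness: every operation takes an integer ``seed`` and derives its own
stream as ``default_rng([STREAM_<OP>, seed])``, so different operations
called with the same top-level seed do not share draws, and a fixed seed
reproduces byte-identical FASTA/TSV output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .records import Gene, GeneCatalog, SequenceRecord, revcomp

# Fixed per-operation stream offsets (mixed with the user seed).
STREAM_GENOME = 1
STREAM_MUTATE = 2
STREAM_GENES = 3
STREAM_FRAGMENT = 4
STREAM_READS = 5
STREAM_AMPLICONS = 6

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i


def seq_to_codes(seq: str) -> np.ndarray:
    """Encode an ACGT string as uint8 codes 0-3 (other chars -> 255)."""
    return _CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]


def codes_to_seq(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode()


def simulate_genome(length: int, gc_fraction: float, seed: int, genome_id: str = "genome") -> SequenceRecord:
    """Simulate an i.i.d. genome with the requested GC content.

    P(G) = P(C) = gc/2 and P(A) = P(T) = (1-gc)/2 per site.
    """
    if length < 1000:
        raise ValueError(f"genome length must be >= 1000, got {length}")
    if not 0.0 < gc_fraction < 1.0:
        raise ValueError(f"gc_fraction must be in (0, 1), got {gc_fraction}")
    rng = np.random.default_rng([STREAM_GENOME, seed])
    at = (1.0 - gc_fraction) / 2.0
    gc = gc_fraction / 2.0
    codes = rng.choice(4, size=length, p=[at, gc, gc, at]).astype(np.uint8)
    return SequenceRecord(genome_id, codes_to_seq(codes), metadata={"gc_target": gc_fraction})


def mutate_genome(genome: SequenceRecord, sub_rate: float, seed: int, genome_id: str | None = None) -> SequenceRecord:
    """Substitute each site independently with probability ``sub_rate``.

    Substituted sites receive a uniformly chosen *different* base, so the
    realized divergence equals the number of flipped sites. That count is
    kept in ``metadata["n_substitutions"]`` as ground truth for identity
    and ANI recovery checks.
    """
    if not 0.0 <= sub_rate < 0.5:
        raise ValueError(f"sub_rate must be in [0, 0.5), got {sub_rate}")
    codes = seq_to_codes(genome.seq)
    rng = np.random.default_rng([STREAM_MUTATE, seed])
    mask = rng.random(len(codes)) < sub_rate
    n_sub = int(mask.sum())
    # shift by 1..3 mod 4 guarantees a different base at every hit site
    shifts = rng.integers(1, 4, size=n_sub).astype(np.uint8)
    out = codes.copy()
    out[mask] = (out[mask] + shifts) % 4
    new_id = genome_id or f"{genome.id}_mut{sub_rate:g}"
    return SequenceRecord(
        new_id,
        codes_to_seq(out),
        metadata={"source": genome.id, "sub_rate": sub_rate, "n_substitutions": n_sub},
    )


_STOPS = {"TAA", "TAG", "TGA"}
_NONSTOP_CODONS = sorted(
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in _STOPS and a + b + c != "ATG"
)


def _random_cds(length: int, rng: np.random.Generator) -> str:
    """A CDS of the given length: ATG start then non-stop codons."""
    n_codons = length // 3
    body = rng.choice(len(_NONSTOP_CODONS), size=n_codons - 1)
    return "ATG" + "".join(_NONSTOP_CODONS[i] for i in body)


def plant_genes(
    genome: SequenceRecord,
    n_genes: int,
    length_mean: float = 900.0,
    length_sd: float = 100.0,
    seed: int = 0,
    gene_prefix: str | None = None,
) -> tuple[SequenceRecord, GeneCatalog]:
    """Plant non-overlapping protein-coding genes into a genome.

    Gene lengths are drawn Normal(mean, sd), floored at 90 bp and rounded
    to a codon multiple. Coding sequences are sampled codon-wise without
    internal stop codons and written into the genome (reverse-complemented
    for ``-`` strand genes), so the returned genome sequence and catalog
    agree. Returns ``(genome_with_genes, catalog)``.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    rng = np.random.default_rng([STREAM_GENES, seed])
    lengths = np.maximum(90, np.round(rng.normal(length_mean, length_sd, size=n_genes) / 3).astype(np.int64) * 3)
    total = int(lengths.sum())
    slack = len(genome) - total
    if slack < n_genes + 1:
        raise ValueError(
            f"genome of {len(genome)} bp cannot hold {n_genes} genes totalling {total} bp"
        )
    # distribute the slack as n_genes+1 non-negative gaps
    cuts = np.sort(rng.integers(0, slack + 1, size=n_genes))
    gaps = np.diff(np.concatenate([[0], cuts, [slack]]))
    strands = rng.choice(["+", "-"], size=n_genes)
    prefix = gene_prefix or f"{genome.id}_g"

    arr = np.frombuffer(genome.seq.encode(), dtype=np.uint8).copy()
    genes: list[Gene] = []
    pos = 0
    for i in range(n_genes):
        pos += int(gaps[i])
        length = int(lengths[i])
        cds = _random_cds(length, rng)
        placed = cds if strands[i] == "+" else revcomp(cds)
        arr[pos : pos + length] = np.frombuffer(placed.encode(), dtype=np.uint8)
        aa = str(Seq(cds).translate())
        genes.append(
            Gene(
                gene_id=f"{prefix}{i + 1:04d}",
                scaffold_id=genome.id,
                start=pos + 1,
                end=pos + length,
                strand=str(strands[i]),
                nt_seq=cds,
                aa_seq=aa,
            )
        )
        pos += length
    new_genome = SequenceRecord(genome.id, arr.tobytes().decode(), metadata=dict(genome.metadata))
    return new_genome, GeneCatalog(genome.id, genes)


def diverged_catalog(
    genome: SequenceRecord,
    catalog: GeneCatalog,
    sub_rate: float,
    seed: int,
    genome_id: str | None = None,
) -> tuple[SequenceRecord, GeneCatalog]:
    """Mutate a genome and re-extract its gene catalog at the same loci.

    Ground truth for ortholog/ANI recovery: gene i of the diverged catalog
    descends from gene i of the input, with expected nucleotide identity
    100 * (1 - sub_rate). Amino-acid sequences are not re-translated
    (mutation may introduce stops); nt sequences are authoritative here.
    """
    mut = mutate_genome(genome, sub_rate, seed, genome_id=genome_id)
    genes = []
    for g in catalog:
        raw = mut.seq[g.start - 1 : g.end]
        genes.append(
            Gene(
                gene_id=f"{mut.id}_{g.gene_id}",
                scaffold_id=mut.id,
                start=g.start,
                end=g.end,
                strand=g.strand,
                nt_seq=raw if g.strand == "+" else revcomp(raw),
                aa_seq="",
            )
        )
    return mut, GeneCatalog(mut.id, genes)


def fragment_genome(
    genome: SequenceRecord, n_scaffolds: int, seed: int, min_len: int = 1000
) -> list[SequenceRecord]:
    """Cut a genome into ``n_scaffolds`` contiguous fragments, each >= 1 kb.

    The concatenation of the fragments in order reproduces the genome
    exactly; each fragment's metadata records its source and 0-based
    offset.
    """
    if n_scaffolds < 1:
        raise ValueError("n_scaffolds must be >= 1")
    if n_scaffolds * min_len > len(genome):
        raise ValueError(
            f"cannot cut {len(genome)} bp into {n_scaffolds} fragments of >= {min_len} bp"
        )
    rng = np.random.default_rng([STREAM_FRAGMENT, seed])
    slack = len(genome) - n_scaffolds * min_len
    cuts = np.sort(rng.integers(0, slack + 1, size=n_scaffolds - 1))
    sizes = np.diff(np.concatenate([[0], cuts, [slack]])) + min_len
    out: list[SequenceRecord] = []
    off = 0
    for i, size in enumerate(sizes):
        size = int(size)
        out.append(
            SequenceRecord(
                f"{genome.id}_s{i + 1:03d}",
                genome.seq[off : off + size],
                metadata={"source": genome.id, "offset": off},
            )
        )
        off += size
    return out


def genes_on_scaffolds(catalog: GeneCatalog, scaffolds: list[SequenceRecord]) -> dict[str, str]:
    """Map each gene to the fragment containing its midpoint.

    Fragments must carry the ``source``/``offset`` provenance written by
    :func:`fragment_genome`.
    """
    bounds = []
    for sc in scaffolds:
        if sc.metadata.get("source") != catalog.genome_id:
            continue
        off = sc.metadata["offset"]
        bounds.append((off, off + len(sc), sc.id))
    bounds.sort()
    mapping: dict[str, str] = {}
    for gene in catalog:
        mid = (gene.start + gene.end) // 2 - 1  # 0-based midpoint
        for lo, hi, sid in bounds:
            if lo <= mid < hi:
                mapping[gene.gene_id] = sid
                break
    return mapping


@dataclass
class CommunityMember:
    genome_id: str
    depth_a: float
    depth_b: float

    def __post_init__(self) -> None:
        if self.depth_a < 0 or self.depth_b < 0:
            raise ValueError(f"{self.genome_id}: depths must be >= 0")


@dataclass
class CommunityDesign:
    """Design of a two-sample synthetic metagenome.

    Each member genome is sequenced at ``depth_a`` x-fold in sample A and
    ``depth_b`` in sample B; the depth contrast between samples is what
    makes bi-dimensional coverage binning possible.
    """

    members: list[CommunityMember]
    read_length: int = 100
    per_base_error_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("community design needs at least one member")
        if not 0.0 <= self.per_base_error_rate < 0.25:
            raise ValueError("per_base_error_rate must be in [0, 0.25)")
        if self.read_length < 20:
            raise ValueError("read_length must be >= 20")
        ids = [m.genome_id for m in self.members]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate genome_id in community design")


def simulate_reads(
    design: CommunityDesign, genomes: list[SequenceRecord]
) -> tuple[dict[str, list[SequenceRecord]], pd.DataFrame]:
    """Draw single-end reads per the community design.

    Reads start uniformly along each genome; per-base substitution errors
    are applied at the design rate. Returns ``(reads_by_sample, truth)``
    where truth has columns read_id, genome_id, pos_1based, sample.
    """
    by_id = {g.id: g for g in genomes}
    missing = [m.genome_id for m in design.members if m.genome_id not in by_id]
    if missing:
        raise ValueError(f"design references unknown genomes: {missing}")
    rng = np.random.default_rng([STREAM_READS, design.seed])
    L = design.read_length
    reads: dict[str, list[SequenceRecord]] = {"A": [], "B": []}
    truth_rows: list[tuple[str, str, int, str]] = []
    counters = {"A": 0, "B": 0}
    for member in design.members:
        genome = by_id[member.genome_id]
        if len(genome) < L:
            raise ValueError(f"genome {genome.id} shorter than read length")
        codes = seq_to_codes(genome.seq)
        for sample, depth in (("A", member.depth_a), ("B", member.depth_b)):
            n_reads = int(round(depth * len(genome) / L))
            if n_reads == 0:
                continue
            starts = rng.integers(0, len(genome) - L + 1, size=n_reads)
            mat = codes[starts[:, None] + np.arange(L)]
            if design.per_base_error_rate > 0:
                mask = rng.random(mat.shape) < design.per_base_error_rate
                shifts = rng.integers(1, 4, size=int(mask.sum())).astype(np.uint8)
                mat[mask] = (mat[mask] + shifts) % 4
            chars = _BASES[mat]
            for row, start in zip(chars, starts):
                counters[sample] += 1
                rid = f"read_{sample}_{counters[sample]:07d}"
                reads[sample].append(SequenceRecord(rid, row.tobytes().decode()))
                truth_rows.append((rid, genome.id, int(start) + 1, sample))
    truth = pd.DataFrame(truth_rows, columns=["read_id", "genome_id", "pos_1based", "sample"])
    return reads, truth


def simulate_amplicons(
    refs: list[SequenceRecord],
    n_tags: int,
    per_base_error_rate: float,
    tag_length: int,
    seed: int,
) -> tuple[list[SequenceRecord], pd.DataFrame]:
    """Simulate amplicon tags as noisy windows of reference sequences.

    Each tag is a contiguous ``tag_length`` window of a uniformly chosen
    reference with substitutions at the stated rate. The truth table
    records the source reference and its group label (taken from the
    reference's ``metadata["group"]``, falling back to its id).
    """
    if not refs:
        raise ValueError("no reference sequences given")
    if n_tags < 1:
        raise ValueError("n_tags must be >= 1")
    if not 0.0 <= per_base_error_rate < 0.25:
        raise ValueError("per_base_error_rate must be in [0, 0.25)")
    short = [r.id for r in refs if len(r) < tag_length]
    if short:
        raise ValueError(f"tag_length {tag_length} exceeds reference length for: {short}")
    rng = np.random.default_rng([STREAM_AMPLICONS, seed])
    ref_codes = [seq_to_codes(r.seq) for r in refs]
    tags: list[SequenceRecord] = []
    rows: list[tuple[str, str, str, int]] = []
    choices = rng.integers(0, len(refs), size=n_tags)
    for i, ri in enumerate(choices):
        ref = refs[ri]
        start = int(rng.integers(0, len(ref) - tag_length + 1))
        window = ref_codes[ri][start : start + tag_length].copy()
        if per_base_error_rate > 0:
            mask = rng.random(tag_length) < per_base_error_rate
            shifts = rng.integers(1, 4, size=int(mask.sum())).astype(np.uint8)
            window[mask] = (window[mask] + shifts) % 4
        tid = f"tag_{i + 1:05d}"
        tags.append(SequenceRecord(tid, codes_to_seq(window)))
        rows.append((tid, ref.id, str(ref.metadata.get("group", ref.id)), start + 1))
    truth = pd.DataFrame(rows, columns=["tag_id", "ref_id", "group", "start_1based"])
    return tags, truth
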