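"""Sequence and gene-catalog containers plus FASTA/TSV I/O.

``SequenceRecord`` is the universal carrier for every nucleotide or protein
sequence in the toolkit (genomes, scaffolds, reads, amplicon tags, genes).
FASTA round-trips go through :mod:`Bio.SeqIO`; the thin wrapper here only
adds validation and a free-form ``metadata`` dict used for provenance
(source genome, offsets, planted substitution counts, group labels).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

NT_ALPHABET = frozenset("ACGT")
NT_ALPHABET_N = frozenset("ACGTN")
AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWY")
AA_ALPHABET_X = AA_ALPHABET | {"X", "*"}

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (N-aware)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class SequenceRecord:
    """A named sequence.

    Parameters
    ----------
    id:
        Non-empty identifier, unique within any one file.
    seq:
        Uppercase sequence; nucleotide records are over ACGT with N
        permitted only on read-in.
    metadata:
        Free-form provenance (never serialized to FASTA beyond the
        description line).
    """

    id: str
    seq: str
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("SequenceRecord id must be non-empty")
        if len(self.seq) < 1:
            raise ValueError(f"SequenceRecord {self.id!r}: empty sequence")

    def __len__(self) -> int:
        return len(self.seq)

    @property
    def gc_fraction(self) -> float:
        s = self.seq
        acgt = sum(s.count(b) for b in "ACGT")
        if acgt == 0:
            return 0.0
        return (s.count("G") + s.count("C")) / acgt


def validate_alphabet(record: SequenceRecord, alphabet: str) -> None:
    """Raise ``ValueError`` on characters outside the declared alphabet.

    ``alphabet`` is ``"nt"`` (ACGT + N) or ``"aa"`` (20 amino acids + X/*).
    """
    if alphabet == "nt":
        allowed = NT_ALPHABET_N
    elif alphabet == "aa":
        allowed = AA_ALPHABET_X
    else:
        raise ValueError(f"unknown alphabet {alphabet!r}")
    bad = set(record.seq) - allowed
    if bad:
        raise ValueError(
            f"record {record.id!r}: characters {sorted(bad)} outside {alphabet} alphabet"
        )


def read_fasta(path: str | Path, alphabet: str | None = "nt") -> list[SequenceRecord]:
    """Read a FASTA file into SequenceRecords, enforcing unique ids."""
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
        seen.add(rec.id)
        sr = SequenceRecord(rec.id, str(rec.seq).upper())
        if alphabet is not None:
            validate_alphabet(sr, alphabet)
        records.append(sr)
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    """Write SequenceRecords as wrapped FASTA via Bio.SeqIO."""
    bio = (SeqRecord(Seq(r.seq), id=r.id, description="") for r in records)
    SeqIO.write(bio, str(path), "fasta")


@dataclass
class Gene:
    """One gene on a scaffold; coordinates are 1-based inclusive.

    ``nt_seq`` is the strand-oriented coding sequence: for a ``-`` strand
    gene it is the reverse complement of the scaffold slice.
    """

    gene_id: str
    scaffold_id: str
    start: int
    end: int
    strand: str
    nt_seq: str
    aa_seq: str

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(f"gene {self.gene_id}: invalid interval {self.start}..{self.end}")
        if self.strand not in {"+", "-"}:
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")
        if len(self.nt_seq) != self.end - self.start + 1:
            raise ValueError(f"gene {self.gene_id}: nt length != end - start + 1")


@dataclass
class GeneCatalog:
    """All predicted/planted genes of one genome."""

    genome_id: str
    genes: list[Gene]

    def __post_init__(self) -> None:
        ids = [g.gene_id for g in self.genes]
        if len(ids) != len(set(ids)):
            raise ValueError(f"catalog {self.genome_id}: duplicate gene ids")

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self) -> Iterator[Gene]:
        return iter(self.genes)

    def nt_records(self) -> list[SequenceRecord]:
        return [SequenceRecord(g.gene_id, g.nt_seq) for g in self.genes]

    def aa_records(self) -> list[SequenceRecord]:
        return [SequenceRecord(g.gene_id, g.aa_seq) for g in self.genes]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "gene_id": g.gene_id,
                    "scaffold_id": g.scaffold_id,
                    "start": g.start,
                    "end": g.end,
                    "strand": g.strand,
                    "length_nt": len(g.nt_seq),
                }
                for g in self.genes
            ]
        )


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
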