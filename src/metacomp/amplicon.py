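"""16S amplicon tag profiling for PAO/GAO communities.

Tags (denoised amplicon reads covering the V3-V4 region) are assigned to
reference groups — e.g. Accumulibacter, Tetrasphaera, Competibacter
subgroups, Defluviicoccus TFO clusters — by best local alignment against
full-length reference 16S rRNA genes (>= 1200 bp). A tag is assigned to
its best hit's group only when the hit reaches >= 97% identity over an
alignment of >= 400 columns (both cutoffs inclusive); otherwise it stays
UNASSIGNED. Group abundances are tag fractions per replicate, summarized
as mean and sample standard deviation across replicates.

qPCR-side estimates live here too: 16S copy counts corrected by rrn
operon copy number (2 for the Accumulibacter reference genome, 4 for
finished bacterial genomes) give a cell-fraction estimate, and ppk1 copy
numbers per clade give within-lineage clade proportions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .align import AlignmentHit, SeedIndex
from .records import SequenceRecord

UNASSIGNED = "UNASSIGNED"
MIN_REF_LENGTH = 1200
DEFAULT_ID_CUTOFF = 97.0
DEFAULT_LEN_CUTOFF = 400


@dataclass
class AmpliconReference:
    """A full-length reference 16S gene labelled with its taxonomic group."""

    group: str
    record: SequenceRecord

    def __post_init__(self) -> None:
        if len(self.record) < MIN_REF_LENGTH:
            raise ValueError(
                f"reference {self.record.id}: length {len(self.record)} < {MIN_REF_LENGTH} bp"
            )


def references_from_records(records: list[SequenceRecord]) -> list[AmpliconReference]:
    """Build references from FASTA records with ``id|group`` headers.

    The group taxonomy is data, not code: it rides in the header suffix
    (falling back to the whole id when no ``|`` is present).
    """
    refs = []
    for rec in records:
        if "|" in rec.id:
            rid, group = rec.id.rsplit("|", 1)
        else:
            rid, group = rec.id, rec.id
        r = SequenceRecord(rid, rec.seq, metadata=dict(rec.metadata))
        r.metadata["group"] = group
        refs.append(AmpliconReference(group, r))
    return refs


@dataclass
class TagAssignment:
    tag_id: str
    assigned_group: str  # UNASSIGNED when cutoffs not met
    best_hit: AlignmentHit | None


def assign_tags(
    tags: list[SequenceRecord],
    refs: list[AmpliconReference],
    id_cutoff: float = DEFAULT_ID_CUTOFF,
    len_cutoff: int = DEFAULT_LEN_CUTOFF,
) -> list[TagAssignment]:
    """Assign each tag to the group of its best reference hit.

    Assignment requires identity >= id_cutoff AND alignment length >=
    len_cutoff (inclusive); a tag failing either is UNASSIGNED but keeps
    its best hit for margin reporting.
    """
    if not tags:
        raise ValueError("assign_tags: empty tag set")
    if not refs:
        raise ValueError("assign_tags: no references")
    group_of = {r.record.id: r.group for r in refs}
    index = SeedIndex([r.record for r in refs], alphabet="nt")
    out: list[TagAssignment] = []
    for tag in tags:
        hit = index.best_hit(tag)
        if hit is not None and hit.identity >= id_cutoff and hit.aln_len >= len_cutoff:
            group = group_of[hit.subject_id]
        else:
            group = UNASSIGNED
        out.append(TagAssignment(tag.id, group, hit))
    return out


def assignments_to_dataframe(assignments: list[TagAssignment]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "tag_id": a.tag_id,
                "assigned_group": a.assigned_group,
                "best_ref": a.best_hit.subject_id if a.best_hit else "",
                "identity": round(a.best_hit.identity, 2) if a.best_hit else np.nan,
                "aln_len": a.best_hit.aln_len if a.best_hit else 0,
            }
            for a in assignments
        ]
    )


def abundance_table(
    assignments_per_replicate: list[list[TagAssignment]],
    totals: list[int] | None = None,
) -> pd.DataFrame:
    """Per-group abundance fractions across replicates, with mean and sd.

    ``totals`` are the total tag counts per replicate (defaulting to the
    number of assignments handed in, i.e. assuming every tag of the
    replicate was scored). The sd is the sample standard deviation
    (ddof=1); with a single replicate it is reported as 0 with a warning.
    """
    if not assignments_per_replicate:
        raise ValueError("no replicates")
    if totals is None:
        totals = [len(reps) for reps in assignments_per_replicate]
    if len(totals) != len(assignments_per_replicate):
        raise ValueError("totals length mismatch")
    if any(t <= 0 for t in totals):
        raise ValueError("replicate with zero tags")

    groups = sorted(
        {a.assigned_group for reps in assignments_per_replicate for a in reps} - {UNASSIGNED}
    )
    n_rep = len(assignments_per_replicate)
    rows = []
    for group in groups:
        fracs = [
            sum(a.assigned_group == group for a in reps) / tot
            for reps, tot in zip(assignments_per_replicate, totals)
        ]
        if n_rep == 1:
            sd = 0.0
        else:
            sd = float(np.std(fracs, ddof=1))
        row = {"group": group}
        row.update({f"rep{i + 1}": f for i, f in enumerate(fracs)})
        row["mean"] = float(np.mean(fracs))
        row["sd"] = sd
        rows.append(row)
    if n_rep == 1:
        warnings.warn("single replicate: standard deviation reported as 0", stacklevel=2)
    cols = ["group"] + [f"rep{i + 1}" for i in range(n_rep)] + ["mean", "sd"]
    if not rows:
        return pd.DataFrame(columns=cols)
    return pd.DataFrame(rows, columns=cols)


@dataclass
class QpcrMeasurement:
    """qPCR copy numbers for the rrn-corrected abundance estimate.

    acc_rrn_copies defaults to 2 (rrn operons in the Accumulibacter
    reference genome) and bact_rrn_copies to 4 (typical of finished
    bacterial genomes), the denominators used to convert 16S gene copies
    to cell counts.
    """

    acc_16s_copies: float
    total_bact_16s_copies: float
    acc_rrn_copies: float = 2.0
    bact_rrn_copies: float = 4.0
    clade_ppk1_copies: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.acc_16s_copies < 0 or self.total_bact_16s_copies < 0:
            raise ValueError("copy numbers must be >= 0")
        if self.acc_rrn_copies < 1 or self.bact_rrn_copies < 1:
            raise ValueError("rrn copy numbers must be >= 1")
        if any(v < 0 for v in self.clade_ppk1_copies.values()):
            raise ValueError("ppk1 copy numbers must be >= 0")


def rrn_corrected_fraction(m: QpcrMeasurement) -> float:
    """Cell fraction of the target lineage from 16S qPCR copies.

    fraction = (acc_16S / acc_rrn) / (total_16S / bact_rrn): both copy
    counts are divided by their genomes' rrn operon copy numbers before
    taking the ratio. A fraction above 1 indicates inconsistent input and
    is flagged with a warning.
    """
    if m.total_bact_16s_copies == 0:
        raise ValueError("total bacterial 16S copies is zero")
    frac = (m.acc_16s_copies / m.acc_rrn_copies) / (m.total_bact_16s_copies / m.bact_rrn_copies)
    if frac > 1.0:
        warnings.warn(f"rrn-corrected fraction {frac:.3f} > 1: inconsistent input", stacklevel=2)
    return frac


def clade_proportions(clade_ppk1_copies: dict[str, float]) -> dict[str, float]:
    """Within-lineage clade proportions from per-clade ppk1 copy numbers."""
    if not clade_ppk1_copies:
        raise ValueError("no clade ppk1 measurements")
    total = float(sum(clade_ppk1_copies.values()))
    if total <= 0:
        raise ValueError("all ppk1 copy numbers are zero")
    return {clade: copies / total for clade, copies in clade_ppk1_copies.items()}
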