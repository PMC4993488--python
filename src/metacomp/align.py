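"""Pairwise local alignment and percent identity.

One scoring scheme is declared once and shared by every consumer (amplicon
assignment, reciprocal best hits, pangenome partitioning): nucleotide
match +1 / mismatch -2, gap open -5 / extend -2; protein BLOSUM62 with gap
open -11 / extend -1. All downstream cutoffs in this toolkit are on
percent identity and alignment length, never on raw score, so the scheme
only needs to be BLAST-like, not identical to any particular tool.

Percent identity uses the alignment-column denominator (matches /
(matches + mismatches + gap columns)), the convention of BLAST tabular
output. Alignments scoring below a minimum reportable score (30 nt, 40 aa)
are suppressed as noise.

Alignment itself is delegated to :class:`Bio.Align.PairwiseAligner`
(exact affine-gap local DP); :class:`SeedIndex` adds an exact k-mer
prefilter so large best-hit searches only align plausible candidates,
falling back to an exhaustive scan when no seed matches.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

import pandas as pd
from Bio import Align

from .records import SequenceRecord, validate_alphabet

MIN_REPORT_SCORE = {"nt": 30.0, "aa": 40.0}
SEED_K = {"nt": 15, "aa": 5}


def _make_aligner(alphabet: str) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    if alphabet == "nt":
        aligner.match_score = 1.0
        aligner.mismatch_score = -2.0
        aligner.open_gap_score = -5.0
        aligner.extend_gap_score = -2.0
    elif alphabet == "aa":
        aligner.substitution_matrix = Align.substitution_matrices.load("BLOSUM62")
        aligner.open_gap_score = -11.0
        aligner.extend_gap_score = -1.0
    else:
        raise ValueError(f"unknown alphabet {alphabet!r}")
    return aligner


_ALIGNERS: dict[str, Align.PairwiseAligner] = {}


def _aligner(alphabet: str) -> Align.PairwiseAligner:
    if alphabet not in _ALIGNERS:
        _ALIGNERS[alphabet] = _make_aligner(alphabet)
    return _ALIGNERS[alphabet]


@dataclass
class AlignmentHit:
    """Best local alignment between a query and a subject.

    identity is 100 * matches / aln_len where aln_len counts every
    alignment column including gaps; q_cov_fraction / s_cov_fraction are
    the aligned spans divided by the full sequence lengths.
    """

    query_id: str
    subject_id: str
    identity: float
    aln_len: int
    matches: int
    mismatches: int
    gaps: int
    score: float
    q_start: int  # 1-based inclusive on the query
    q_end: int
    s_start: int
    s_end: int
    q_cov_fraction: float
    s_cov_fraction: float


def align_local(
    query: SequenceRecord, subject: SequenceRecord, alphabet: str = "nt"
) -> AlignmentHit | None:
    """Best-scoring local alignment, or None below the report threshold."""
    validate_alphabet(query, alphabet)
    validate_alphabet(subject, alphabet)
    aligner = _aligner(alphabet)
    alignments = aligner.align(query.seq, subject.seq)
    try:
        best = alignments[0]
    except IndexError:
        return None
    score = float(alignments.score)
    if score < MIN_REPORT_SCORE[alphabet]:
        return None
    counts = best.counts()
    matches = int(counts.identities)
    mismatches = int(counts.mismatches)
    gaps = int(counts.gaps)
    aln_len = matches + mismatches + gaps
    if aln_len == 0:
        return None
    blocks = best.aligned  # [0]=query blocks, [1]=subject blocks
    q_start = int(blocks[0][0][0])
    q_end = int(blocks[0][-1][1])
    s_start = int(blocks[1][0][0])
    s_end = int(blocks[1][-1][1])
    return AlignmentHit(
        query_id=query.id,
        subject_id=subject.id,
        identity=100.0 * matches / aln_len,
        aln_len=aln_len,
        matches=matches,
        mismatches=mismatches,
        gaps=gaps,
        score=score,
        q_start=q_start + 1,
        q_end=q_end,
        s_start=s_start + 1,
        s_end=s_end,
        q_cov_fraction=(q_end - q_start) / len(query),
        s_cov_fraction=(s_end - s_start) / len(subject),
    )


def _better(a: AlignmentHit, b: AlignmentHit | None) -> bool:
    """Is hit ``a`` preferred over ``b``?

    Order: higher score, then higher identity, then lexicographically
    smallest subject id.
    """
    if b is None:
        return True
    if a.score != b.score:
        return a.score > b.score
    if a.identity != b.identity:
        return a.identity > b.identity
    return a.subject_id < b.subject_id


def best_hit(
    query: SequenceRecord, subjects: list[SequenceRecord], alphabet: str = "nt"
) -> AlignmentHit | None:
    """Exhaustive best hit of a query over a subject list."""
    if not subjects:
        raise ValueError("best_hit: empty subject list")
    best: AlignmentHit | None = None
    for subj in subjects:
        hit = align_local(query, subj, alphabet)
        if hit is not None and _better(hit, best):
            best = hit
    return best


class SeedIndex:
    """Exact k-mer index over a subject set for candidate prefiltering.

    Candidates are subjects sharing at least one exact k-mer with the
    query, ranked by the number of distinct shared k-mers. ``best_hit``
    aligns only the top candidates and falls back to an exhaustive scan
    when no seed matches, so the prefilter never changes which hits are
    reportable, only how many alignments are attempted.
    """

    def __init__(self, subjects: list[SequenceRecord], alphabet: str = "nt", k: int | None = None):
        if not subjects:
            raise ValueError("SeedIndex: empty subject list")
        self.subjects = subjects
        self.alphabet = alphabet
        self.k = k if k is not None else SEED_K[alphabet]
        self._index: dict[str, set[int]] = defaultdict(set)
        for idx, subj in enumerate(subjects):
            s = subj.seq
            for i in range(len(s) - self.k + 1):
                self._index[s[i : i + self.k]].add(idx)

    def candidates(self, query: SequenceRecord, max_candidates: int = 8) -> list[int]:
        hits: dict[int, int] = defaultdict(int)
        s = query.seq
        k = self.k
        index = self._index
        for i in range(len(s) - k + 1):
            for idx in index.get(s[i : i + k], ()):
                hits[idx] += 1
        ranked = sorted(hits, key=lambda idx: (-hits[idx], self.subjects[idx].id))
        return ranked[:max_candidates]

    def best_hit(
        self, query: SequenceRecord, max_candidates: int = 8, exhaustive_fallback: bool = True
    ) -> AlignmentHit | None:
        cand = self.candidates(query, max_candidates)
        if not cand:
            if exhaustive_fallback:
                return best_hit(query, self.subjects, self.alphabet)
            return None
        best: AlignmentHit | None = None
        for idx in cand:
            hit = align_local(query, self.subjects[idx], self.alphabet)
            if hit is not None and _better(hit, best):
                best = hit
        return best


def hits_to_dataframe(hits: list[AlignmentHit]) -> pd.DataFrame:
    """BLAST outfmt-6-like tabular view of a hit list."""
    return pd.DataFrame(
        [
            {
                "query": h.query_id,
                "subject": h.subject_id,
                "identity": round(h.identity, 2),
                "aln_len": h.aln_len,
                "mismatches": h.mismatches,
                "gaps": h.gaps,
                "q_start": h.q_start,
                "q_end": h.q_end,
                "s_start": h.s_start,
                "s_end": h.s_end,
                "score": h.score,
            }
            for h in hits
        ]
    )
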