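# Methods

This note documents the models, parameter choices and numerical
conventions behind each module, what the synthetic data do and do not
emulate, and the known limitations.

## Synthetic communities and the error model

All generators draw i.i.d. bases: a genome at GC fraction *g* has
P(G)=P(C)=g/2, P(A)=P(T)=(1−g)/2. Divergence, sequencing error and
amplicon error are all **substitution-only**: each site independently
flips to a uniformly chosen different base with probability *p*. This
makes every expected identity analytic — a pair diverged at rate *p* has
expected percent identity 100·(1−p), and substituted-site counts are
Binomial(L, p) — which is what allows recovery tests to use closed-form
oracles. Indels, quality-score structure, chimeras and amplification
bias are deliberately absent; passing tests therefore demonstrate that
the *decision rules* (cutoffs, best-hit logic, screens) are implemented
correctly, not that the toolkit is robust to indel-rich or biased real
libraries.

Reads are single-end, drawn uniformly along each genome at
`round(depth·L/read_length)` per sample; coverage arithmetic never needs
pairing, and single-end truth tables stay one row per read. Planted
genes are codon-sampled (ATG start, no internal stops) and written into
the genome so catalog and sequence agree; gene lengths are
Normal(mean, sd) floored at 90 bp and rounded to codon multiples, with
defaults mean 900 / sd 100 bp, the scale of typical bacterial ORF means
(~800–950 bp). Fragmentation cuts the genome into contiguous pieces of
≥ 1 kb whose concatenation reproduces it exactly.

Randomness: every operation derives its stream as
`default_rng([STREAM_CONSTANT, seed])` with a fixed per-operation
constant, so one top-level seed yields independent, reproducible streams
and byte-identical files.

## Alignment and identity

Local alignment is exact affine-gap DP (`Bio.Align.PairwiseAligner`):
nucleotide match +1, mismatch −2, gap open −5, extend −2 (the open score
applies to the first gap column, extend to subsequent ones); protein
BLOSUM62 with open −11 / extend −1. Every downstream decision is made on
percent identity and alignment length, never raw score, so the scheme
only needs to rank alignments sensibly. Identity uses the
alignment-column denominator (matches / (matches+mismatches+gaps)), the
BLAST tabular convention. Alignments scoring under 30 (nt) / 40 (aa) are
suppressed; unrelated 100-mers never reach the nucleotide threshold.
Best-hit ties break by higher identity, then lexicographically smallest
subject id, making results order-independent.

Large searches go through an exact k-mer prefilter (nt k=15, aa k=5):
only subjects sharing a k-mer are aligned, ranked by shared-seed count,
with a per-query exhaustive fallback when no seed hits — so the filter
changes cost, not outcomes, at the divergences used here (a 15-mer
survives 20% divergence with probability 0.8^15 ≈ 3.5%, leaving dozens
of expected seeds per 900 bp gene).

## Amplicon profiling

Assignment cutoffs (identity ≥ 97%, alignment ≥ 400 columns) are
**inclusive**: a tag at exactly 97.0% over exactly 400 columns is
assigned. Abundances are per-replicate fractions with sample SD (ddof=1);
a single replicate reports SD 0 with a warning. The rrn correction is
`(acc_16S/acc_rrn) / (total_16S/bact_rrn)` with defaults 2 and 4 rrn
operons; fractions above 1 are flagged as inconsistent input rather than
clamped. ppk1 clade proportions are simple normalization and are kept
separate from the 16S-based lineage total — how to compose the two into
one figure is left to the caller.

## Coverage binning

The internal mapper is 31-mer seeded with ungapped (Hamming) extension,
probing seeds every 8 bp along the read; under the substitution-only
error model the best placement is ungapped, so this is exact where it
matters and linear-time. Placement tables derived from external mappings
can be substituted. A read counts toward a scaffold only at ≥ 90%
identity over ≥ 95% of its length.

Coverage axes are log10 with pseudocount 0.01 so zero-coverage scaffolds
remain plottable; the selection box is numeric configuration, not an
interactive gesture. TNF vectors use the 136 canonical tetramers
(reverse-complement pairs merged), windows with non-ACGT skipped. The
refinement drops candidates farther than `tnf_max_distance` (Euclidean)
from the length-weighted candidate centroid. The default 0.034 is the
99th percentile of intra-genome scaffold-to-centroid distances measured
on simulated-genome fragments at the 1–2 kb minimum-scaffold scale
(GC 0.45–0.61) — TNF noise scales as 1/√windows, so calibrating at the
small-fragment end keeps the false-drop rate near 1% where the filter
actually operates; `suggest_tnf_threshold` recomputes it for any
fixture. The centroid-distance filter is a declared stand-in for
published composition-refinement practice and is validated only on
synthetic data.

N50 is the length at which the descending cumulative sum first reaches
half the total; means are rounded half-up (10000/3 → 3333;
43,617,366/12,801 → 3,407).

## Marker QC

Panels are strict intersections: a marker qualifies only if present
(copy ≥ 1) in every neighbor inventory. Completeness = 100·found/total;
redundancy = 100·(markers with copy ≥ 2)/total, counting each multi-copy
marker once, which bounds redundancy at 100 and makes "2 duplicated of
105 → 1.9%" exact. Integer reporting is half-up (89.3 → 89). Marker
detection itself is consumed as inventories; only planted synthetic
markers are counted internally. The subsample-recovery harness retains a
fraction of scaffold *count* (genes located by midpoint), so expected
completeness ≈ 100·fraction when markers are spread uniformly —
hypergeometric scatter of a few points at 50 scaffolds is expected.

## ANI and pangenome

The 40% screen is applied against **both** genes' lengths in each
direction (the directionality is otherwise ambiguous; enforcing both
keeps the pair set symmetric), before best-hit selection. ANI is the
unweighted mean over reciprocal pairs, not length-weighted; with no
surviving pair it is undefined (None) rather than 0. The combined matrix
prints ANI as integer percent above the diagonal and ortholog counts
below.

Pangenome cutoffs are **strict** (> 50% identity over > 50% of the query
protein): a hit covering exactly half the protein does not rescue it
from uniqueness. "Core" means a qualifying hit in every other genome of
the set (not merely pairwise sharing). Venn regions are per-gene
presence patterns; region counts aggregate genes from all genomes, and
each genome's genes partition exactly across the regions containing it.

## Pipeline

Stages are pure compositions of the library with no hidden state; each
rereads its declared inputs from the run directory. Config validation
(range checks on every cutoff) happens before any stage executes; the
CLI maps validation to exit 2 and data errors to exit 3. The manifest
records SHA-256 checksums of every output, and identical config + seed
reproduces identical checksums.

## Problem sizes

Defaults were chosen so the full validation battery runs in minutes on
one core while keeping the statistics meaningful: 20 communities of 3–5
genomes (12 kb each, 8 scaffolds, depth pairs separated ≥ 4× on at least
one axis) for bin recovery; 500 planted genes for ANI recovery (binomial
SE on the mean identity ≈ 0.015 points, far inside the 0.5-point check);
1000 tags for assignment accuracy; 200 markers × 20 seeds for subsample
completeness. Genome sizes are orders of magnitude below real bacterial
genomes; nothing in the algorithms depends on absolute scale, but
wall-clock behaviour on full-size assemblies has not been profiled.

## Known limitations

- Substitution-only error model; no indels anywhere, so alignment gap
  handling is exercised only lightly.
- The internal read mapper assumes forward-strand, ungapped placements —
  adequate for its synthetic inputs, not a general-purpose mapper.
- No automatic multi-bin clustering; one bin per configured selection.
- Marker annotation, OTU clustering/denoising, assembly and gene calling
  are out of scope; their outputs are consumed as inputs.
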