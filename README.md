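# metacomp

A toolkit for the computational core of an enhanced-biological-phosphorus-
removal (EBPR) community study: profiling polyphosphate- and glycogen-
accumulating organisms (PAOs/GAOs) from 16S amplicon tags, retrieving a
draft genome from a two-sample metagenome by bi-dimensional coverage
binning, scoring the bin with single-copy-marker completeness/redundancy,
and comparing genomes by reciprocal-best-hit average nucleotide identity
(ANI) and core/unique pangenome partitioning.

Real EBPR sequencing data are large and reactor-specific, so every stage
here is paired with a synthetic-community generator that plants the
ground truth (genome memberships, divergence rates, marker copies, tag
sources) and lets each method's recovery be scored exactly. The package
is used from Python (see `examples/`), with a thin `metacomp` CLI for
running the stage pipeline end to end.

## Methods at a glance

- **Tag assignment** — each amplicon tag gets its best local-alignment
  hit over group-labelled reference 16S genes (≥ 1200 bp); it is assigned
  to the group only when identity ≥ 97% over ≥ 400 alignment columns.
  Group abundance = assigned tags / total tags per replicate, summarized
  as mean ± sample SD across replicates. qPCR 16S copies are converted to
  cell fractions via rrn operon copy numbers
  (`(N_acc/2) / (N_bact/4)`), and ppk1 copy numbers per clade give
  within-lineage clade proportions.
- **Coverage binning** — per-scaffold coverage in two samples
  (`Σ aligned read bases / scaffold length`, counting placements at
  ≥ 90% identity over ≥ 95% of the read), a rectangular selection in
  `log10(cov+0.01)` space, then a compositional refinement: scaffolds
  whose 136-dimensional canonical tetranucleotide-frequency (TNF) vector
  is farther than a threshold (default 0.034, Euclidean) from the
  length-weighted bin centroid are dropped.
- **Marker QC** — panel = intersection of markers present in every
  neighbor genome; completeness = % of panel markers found at least
  once; redundancy = % found at least twice (each multi-copy marker
  counted once).
- **ANI / pangenome** — orthologs are reciprocal best hits between gene
  catalogs after discarding alignments covering < 40% of either gene;
  ANI = unweighted mean pair identity. A protein is *unique* to its
  genome when no other genome has a hit at > 50% identity over > 50% of
  its length; genes with hits in every genome form the conserved core.

## Worked example

```bash
python examples/05_comparative_genomics.py
```

prints (abridged):

```
ANI (upper triangle, integer %) / shared orthologs (lower):
        IIC_ref div0.01 div0.05 div0.1
IIC_ref       \     99%     95%    90%
div0.01      50       \     94%    89%
div0.05      50      50       \    86%
div0.1       50      50      50      \
```

A 50-gene catalog was mutated at per-site rates 1%, 5% and 10%; the
recovered ANI values (99%, 95%, 90% against the reference) equal
100·(1−p) for the planted rate p, and every gene found its ortholog
(50 shared pairs in the lower triangle). Genomes above ~95% ANI would
conventionally be called the same species. The other examples cover
community simulation, amplicon profiling (abundance tables with SDs,
rrn-corrected fractions), bin extraction scored against truth, and
marker-based QC.

The same stages run end to end from the shell:

```bash
metacomp run-all --outdir runs/demo --seed 1
```

which writes FASTA/TSV/JSON outputs plus a `manifest.json` of SHA-256
checksums; identical config + seed reproduces identical bytes.

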