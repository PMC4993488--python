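"""End-to-end orchestration of the synthetic-community analysis stages.

Stages (simulate -> profile -> bin -> qc -> compare) are pure
compositions of the library modules: each stage reads its declared inputs
from the run directory (or generates them, for the synthetic stages),
writes plain-text outputs (FASTA/TSV/JSON), and records them in a run
manifest with SHA-256 checksums. Identical config + seed reproduces
byte-identical outputs, so the manifest doubles as a reproducibility
receipt.

Configuration is one YAML file; every tunable mirrors a library default.
Validation errors (out-of-range cutoffs, malformed blocks) are raised as
:class:`ConfigError` before any stage runs; missing upstream files or
inconsistent data raise :class:`DataError`.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd
import yaml

from . import amplicon, binning, compare, markers, simulate
from .records import Gene, GeneCatalog, SequenceRecord, read_fasta, write_fasta, write_tsv

STAGES = ["simulate", "profile", "bin", "qc", "compare"]


class ConfigError(ValueError):
    """Invalid pipeline configuration (caught before execution)."""


class DataError(RuntimeError):
    """Missing or inconsistent data at stage run time."""


DEFAULT_CONFIG: dict = {
    "seed": 1,
    "outdir": "runs/demo",
    "simulate": {
        "genome_length": 20000,
        "members": [
            {"genome_id": "gA", "depth_a": 30.0, "depth_b": 5.0, "gc": 0.61},
            {"genome_id": "gB", "depth_a": 5.0, "depth_b": 30.0, "gc": 0.45},
            {"genome_id": "gC", "depth_a": 12.0, "depth_b": 12.0, "gc": 0.55},
        ],
        "n_scaffolds": 8,
        "read_length": 100,
        "per_base_error_rate": 0.005,
        "amplicons": {
            "n_tags": 300,
            "tag_length": 450,
            "per_base_error_rate": 0.01,
            "ref_length": 1500,
            "replicates": 3,
        },
    },
    "profile": {"id_cutoff": 97.0, "len_cutoff": 400},
    "bin": {
        "target": "gA",
        "box_margin": 0.35,
        "tnf_max_distance": binning.DEFAULT_TNF_MAX_DISTANCE,
        "min_identity": 90.0,
        "min_read_fraction": 0.95,
    },
    "qc": {"n_markers": 100, "retained_fraction": 0.8, "n_scaffolds": 50},
    "compare": {
        "divergences": [0.01, 0.05],
        "n_genes": 60,
        "gene_length_mean": 900,
        "gene_length_sd": 100,
        "pangenome": {"n_genomes": 3, "n_core": 30, "n_unique": 6},
    },
}


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(base.get(k), dict):
            out[k] = _merge(base[k], v)
        else:
            out[k] = v
    return out


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> dict:
    cfg = DEFAULT_CONFIG
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        if not isinstance(user, dict):
            raise ConfigError(f"config {path}: top level must be a mapping")
        cfg = _merge(cfg, user)
    if overrides:
        cfg = _merge(cfg, overrides)
    validate_config(cfg)
    return cfg


def validate_config(cfg: dict) -> None:
    """Range-check every cutoff before execution."""
    def fail(msg: str) -> None:
        raise ConfigError(msg)

    if not isinstance(cfg.get("seed"), int) or cfg["seed"] < 0:
        fail("seed must be a non-negative integer")
    sim = cfg["simulate"]
    if sim["genome_length"] < 2000:
        fail("simulate.genome_length must be >= 2000")
    if not sim["members"]:
        fail("simulate.members must be non-empty")
    for m in sim["members"]:
        if m.get("depth_a", 0) < 0 or m.get("depth_b", 0) < 0:
            fail(f"member {m.get('genome_id')}: depths must be >= 0")
        if not 0 < m.get("gc", 0.5) < 1:
            fail(f"member {m.get('genome_id')}: gc must be in (0,1)")
    if not 0 <= sim["per_base_error_rate"] < 0.25:
        fail("simulate.per_base_error_rate must be in [0, 0.25)")
    amp = sim["amplicons"]
    if not 0 <= amp["per_base_error_rate"] < 0.25:
        fail("simulate.amplicons.per_base_error_rate must be in [0, 0.25)")
    prof = cfg["profile"]
    if not 0 <= prof["id_cutoff"] <= 100:
        fail("profile.id_cutoff must be a percent in [0, 100]")
    if prof["len_cutoff"] < 1:
        fail("profile.len_cutoff must be >= 1")
    b = cfg["bin"]
    if not 0 <= b["min_identity"] <= 100:
        fail("bin.min_identity must be in [0, 100]")
    if not 0 < b["min_read_fraction"] <= 1:
        fail("bin.min_read_fraction must be in (0, 1]")
    if b["tnf_max_distance"] is not None and b["tnf_max_distance"] <= 0:
        fail("bin.tnf_max_distance must be > 0 or null")
    q = cfg["qc"]
    if not 0 < q["retained_fraction"] <= 1:
        fail("qc.retained_fraction must be in (0, 1]")
    comp = cfg["compare"]
    for d in comp["divergences"]:
        if not 0 <= d < 0.5:
            fail("compare.divergences must be in [0, 0.5)")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


# --- stages -----------------------------------------------------------------

def stage_simulate(cfg: dict, outdir: Path) -> list[Path]:
    sim = cfg["simulate"]
    seed = cfg["seed"]
    genomes = [
        simulate.simulate_genome(
            sim["genome_length"], m.get("gc", 0.5), seed=seed * 1000 + i, genome_id=m["genome_id"]
        )
        for i, m in enumerate(sim["members"])
    ]
    scaffolds: list[SequenceRecord] = []
    truth_rows = []
    for i, g in enumerate(genomes):
        frags = simulate.fragment_genome(g, sim["n_scaffolds"], seed=seed * 1000 + i)
        scaffolds.extend(frags)
        truth_rows.extend({"scaffold_id": f.id, "genome_id": g.id} for f in frags)
    design = simulate.CommunityDesign(
        members=[
            simulate.CommunityMember(m["genome_id"], m["depth_a"], m["depth_b"])
            for m in sim["members"]
        ],
        read_length=sim["read_length"],
        per_base_error_rate=sim["per_base_error_rate"],
        seed=seed,
    )
    reads, read_truth = simulate.simulate_reads(design, genomes)

    amp = sim["amplicons"]
    refs = []
    for g in genomes:
        ref = SequenceRecord(
            f"{g.id}_16S|{g.id}", g.seq[: amp["ref_length"]], metadata={"group": g.id}
        )
        refs.append(ref)
    outputs = []

    def emit(name: str, writer) -> None:
        path = outdir / name
        writer(path)
        outputs.append(path)

    emit("genomes.fasta", lambda p: write_fasta(genomes, p))
    emit("scaffolds.fasta", lambda p: write_fasta(scaffolds, p))
    emit("scaffold_truth.tsv", lambda p: write_tsv(pd.DataFrame(truth_rows), p))
    emit("reads_A.fasta", lambda p: write_fasta(reads["A"], p))
    emit("reads_B.fasta", lambda p: write_fasta(reads["B"], p))
    emit("read_truth.tsv", lambda p: write_tsv(read_truth, p))
    emit("amplicon_refs.fasta", lambda p: write_fasta(refs, p))
    plain_refs = [SequenceRecord(r.id.split("|")[0], r.seq, metadata=dict(r.metadata)) for r in refs]
    for rep in range(1, amp["replicates"] + 1):
        tags, tag_truth = simulate.simulate_amplicons(
            plain_refs,
            amp["n_tags"],
            amp["per_base_error_rate"],
            amp["tag_length"],
            seed=seed * 100 + rep,
        )
        emit(f"tags_rep{rep}.fasta", lambda p, t=tags: write_fasta(t, p))
        emit(f"tag_truth_rep{rep}.tsv", lambda p, t=tag_truth: write_tsv(t, p))
    return outputs


def stage_profile(cfg: dict, outdir: Path) -> list[Path]:
    prof = cfg["profile"]
    refs_path = outdir / "amplicon_refs.fasta"
    if not refs_path.exists():
        raise DataError("profile stage: amplicon_refs.fasta missing (run simulate first)")
    refs = amplicon.references_from_records(read_fasta(refs_path))
    replicates = sorted(outdir.glob("tags_rep*.fasta"))
    if not replicates:
        raise DataError("profile stage: no tags_rep*.fasta found")
    outputs = []
    per_rep = []
    for path in replicates:
        tags = read_fasta(path)
        assigns = amplicon.assign_tags(tags, refs, prof["id_cutoff"], prof["len_cutoff"])
        per_rep.append(assigns)
        out = outdir / path.name.replace("tags_", "assignments_").replace(".fasta", ".tsv")
        write_tsv(amplicon.assignments_to_dataframe(assigns), out)
        outputs.append(out)
    table = amplicon.abundance_table(per_rep)
    out = outdir / "abundance.tsv"
    write_tsv(table, out)
    outputs.append(out)
    return outputs


def stage_bin(cfg: dict, outdir: Path) -> list[Path]:
    b = cfg["bin"]
    sim = cfg["simulate"]
    scaff_path = outdir / "scaffolds.fasta"
    if not scaff_path.exists():
        raise DataError("bin stage: scaffolds.fasta missing (run simulate first)")
    scaffolds = read_fasta(scaff_path)
    reads = {
        "A": read_fasta(outdir / "reads_A.fasta"),
        "B": read_fasta(outdir / "reads_B.fasta"),
    }
    profile = binning.compute_coverage(
        scaffolds,
        reads_by_sample=reads,
        min_identity=b["min_identity"],
        min_read_fraction=b["min_read_fraction"],
    )
    member_cfg = {m["genome_id"]: m for m in sim["members"]}
    target = b["target"]
    if target not in member_cfg:
        raise DataError(f"bin stage: target genome {target!r} not in community design")
    if "box" in b:
        box = b["box"]
        sel = binning.BinSelection(
            box["log_cov_a_min"], box["log_cov_a_max"],
            box["log_cov_b_min"], box["log_cov_b_max"],
            tnf_max_distance=b["tnf_max_distance"],
        )
    else:
        import math

        m = member_cfg[target]
        margin = b["box_margin"]
        la = math.log10(m["depth_a"] + binning.COVERAGE_PSEUDOCOUNT)
        lb = math.log10(m["depth_b"] + binning.COVERAGE_PSEUDOCOUNT)
        sel = binning.BinSelection(
            la - margin, la + margin, lb - margin, lb + margin,
            tnf_max_distance=b["tnf_max_distance"],
        )
    gbin = binning.extract_bin(profile, scaffolds, sel)
    outputs = []
    cov_out = outdir / "coverage.tsv"
    write_tsv(profile.round(4), cov_out)
    outputs.append(cov_out)
    members_out = outdir / "bin_members.tsv"
    write_tsv(pd.DataFrame({"scaffold_id": gbin.scaffold_ids}), members_out)
    outputs.append(members_out)
    stats = {
        "target_genome": target,
        "n_scaffolds": gbin.n_scaffolds,
        "total_bp": gbin.total_bp,
        "mean_len": gbin.mean_len,
        "n50": gbin.n50,
        "max_len": gbin.max_len,
        "gc_percent": None if gbin.gc_percent is None else round(gbin.gc_percent, 2),
    }
    truth_path = outdir / "scaffold_truth.tsv"
    if truth_path.exists():
        truth = pd.read_csv(truth_path, sep="\t")
        true_set = set(truth.loc[truth["genome_id"] == target, "scaffold_id"])
        got = set(gbin.scaffold_ids)
        tp = len(got & true_set)
        precision = tp / len(got) if got else 0.0
        recall = tp / len(true_set) if true_set else 0.0
        f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
        stats.update(
            {"precision": round(precision, 4), "recall": round(recall, 4), "f1": round(f1, 4)}
        )
    stats_out = outdir / "bin_stats.json"
    _write_json(stats, stats_out)
    outputs.append(stats_out)
    return outputs


def stage_qc(cfg: dict, outdir: Path) -> list[Path]:
    q = cfg["qc"]
    seed = cfg["seed"]
    genome = simulate.simulate_genome(
        max(cfg["simulate"]["genome_length"], q["n_markers"] * 1200), 0.61,
        seed=seed + 777, genome_id="qc_genome",
    )
    genome, catalog = simulate.plant_genes(
        genome, q["n_markers"], length_mean=900, length_sd=100, seed=seed + 777
    )
    marker_of_gene = {g.gene_id: f"marker_{i + 1:04d}" for i, g in enumerate(catalog)}
    panel = markers.MarkerPanel("planted", frozenset(marker_of_gene.values()),
                               construction_rule="planted single-copy genes")
    full = markers.qc(panel, markers.inventory_from_catalog(catalog, marker_of_gene))
    sub = markers.subsample_recovery(
        genome, catalog, panel, marker_of_gene,
        q["retained_fraction"], seed=seed + 778, n_scaffolds=q["n_scaffolds"],
    )
    out = outdir / "qc_report.json"
    _write_json({"full": full.to_dict(), "subsampled": sub.to_dict(),
                 "retained_fraction": q["retained_fraction"]}, out)
    return [out]


def stage_compare(cfg: dict, outdir: Path) -> list[Path]:
    comp = cfg["compare"]
    seed = cfg["seed"]
    genome = simulate.simulate_genome(
        max(20000, comp["n_genes"] * (comp["gene_length_mean"] + 200)), 0.61,
        seed=seed + 999, genome_id="base",
    )
    genome, base_catalog = simulate.plant_genes(
        genome, comp["n_genes"], comp["gene_length_mean"], comp["gene_length_sd"], seed=seed + 999
    )
    catalogs = [base_catalog]
    for d in comp["divergences"]:
        _, cat = simulate.diverged_catalog(
            genome, base_catalog, d, seed=seed + int(d * 10000), genome_id=f"div{d:g}"
        )
        catalogs.append(cat)
    ani, orth = compare.ani_matrix(catalogs)
    outputs = []
    ani_out = outdir / "ani_matrix.tsv"
    compare.ani_table(ani, orth).to_csv(ani_out, sep="\t")
    outputs.append(ani_out)
    raw_out = outdir / "ani_raw.tsv"
    ani.round(3).to_csv(raw_out, sep="\t")
    outputs.append(raw_out)

    pg = comp["pangenome"]
    proteomes = _synthetic_proteomes(pg["n_genomes"], pg["n_core"], pg["n_unique"], seed + 555)
    part = compare.partition_pangenome(proteomes)
    venn_out = outdir / "venn_counts.json"
    _write_json(
        {
            "regions": {"+".join(k): v for k, v in sorted(part.venn_counts.items())},
            "unique": {g: len(s) for g, s in sorted(part.unique.items())},
            "core": {g: len(s) for g, s in sorted(part.core.items())},
        },
        venn_out,
    )
    outputs.append(venn_out)
    part_out = outdir / "pangenome_partition.tsv"
    write_tsv(part.presence, part_out)
    outputs.append(part_out)
    return outputs


def _synthetic_proteomes(n_genomes: int, n_core: int, n_unique: int, seed: int) -> list[GeneCatalog]:
    """Proteomes sharing n_core identical genes plus n_unique private each."""
    import numpy as np

    rng = np.random.default_rng([23, seed])
    aa_alpha = "ACDEFGHIKLMNPQRSTVWY"

    def protein(length: int) -> str:
        return "".join(aa_alpha[i] for i in rng.integers(0, 20, size=length))

    core = [protein(250) for _ in range(n_core)]
    catalogs = []
    for gi in range(n_genomes):
        gid = f"pg{gi + 1}"
        genes = []
        for ci, aa in enumerate(core):
            genes.append(
                Gene(f"{gid}_core{ci + 1:03d}", gid, 1, len(aa) * 3, "+", "A" * (len(aa) * 3), aa)
            )
        for ui in range(n_unique):
            aa = protein(250)
            genes.append(
                Gene(f"{gid}_uniq{ui + 1:03d}", gid, 1, len(aa) * 3, "+", "A" * (len(aa) * 3), aa)
            )
        catalogs.append(GeneCatalog(gid, genes))
    return catalogs


_STAGE_FN = {
    "simulate": stage_simulate,
    "profile": stage_profile,
    "bin": stage_bin,
    "qc": stage_qc,
    "compare": stage_compare,
}


def run_pipeline(cfg: dict, stages: list[str] | None = None) -> dict:
    """Run the requested stages in order; return the manifest dict.

    The manifest records the config, per-stage output paths and SHA-256
    checksums; it is also written to ``<outdir>/manifest.json``.
    """
    validate_config(cfg)
    stages = stages or STAGES
    bad = [s for s in stages if s not in STAGES]
    if bad:
        raise ConfigError(f"unknown stages: {bad}")
    stages = [s for s in STAGES if s in stages]
    outdir = Path(cfg["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": cfg["seed"], "config": cfg, "stages": {}}
    for stage in stages:
        try:
            outputs = _STAGE_FN[stage](cfg, outdir)
        except FileNotFoundError as exc:
            raise DataError(f"stage {stage}: missing input ({exc})") from exc
        manifest["stages"][stage] = {
            str(p.relative_to(outdir)): _sha256(p) for p in sorted(outputs)
        }
    _write_json(manifest, outdir / "manifest.json")
    return manifest
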