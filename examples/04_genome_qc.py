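"""Estimate bin completeness and redundancy from single-copy markers.

Builds a marker panel by intersecting neighbor-genome inventories, scores
an incomplete bin against it, and validates the estimator by randomly
dropping scaffolds of a genome with planted markers.
"""

from metacomp import simulate
from metacomp.markers import (
    MarkerInventory,
    MarkerPanel,
    build_panel,
    qc,
    subsample_recovery,
)

# panel from three neighbors: markers present in every one of them
neighbors = [
    MarkerInventory("n1", {"a": 1, "b": 1, "c": 1, "d": 1}),
    MarkerInventory("n2", {"a": 1, "b": 2, "c": 1}),
    MarkerInventory("n3", {"a": 1, "b": 1, "c": 3, "e": 1}),
]
panel = build_panel(neighbors)
print(f"panel from 3 neighbors: {sorted(panel.marker_ids)}")

report = qc(panel, MarkerInventory("bin", {"a": 1, "b": 2}))
print(f"bin QC: completeness {report.completeness:.1f}% ({report.completeness_int}%), "
      f"redundancy {report.redundancy:.1f}%  "
      f"[{report.n_found}/{report.n_total} found, {report.n_multi} multi-copy]")

# estimator validation: drop 20% of scaffolds of a 100-marker genome
genome = simulate.simulate_genome(120000, 0.61, seed=7, genome_id="val")
genome, catalog = simulate.plant_genes(genome, 100, 900, 100, seed=7)
marker_of_gene = {g.gene_id: f"m{i:03d}" for i, g in enumerate(catalog)}
planted = MarkerPanel("planted", frozenset(marker_of_gene.values()))
rep = subsample_recovery(genome, catalog, planted, marker_of_gene,
                         retained_fraction=0.8, seed=8)
print(f"\nafter retaining 80% of scaffolds: completeness {rep.completeness:.0f}%")
print(
    "Completeness counts markers found at least once; redundancy counts"
    "\nmarkers found twice or more, each once. Both are percentages of the"
    "\npanel size."
)
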