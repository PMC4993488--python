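"""Simulate a two-sample community with known ground truth.

Builds three genomes at different GC contents, fragments them into
scaffolds, and draws reads at designed per-sample depths. The truth
table maps every read to its source genome — the basis of all recovery
scoring downstream.
"""

from metacomp import simulate

genomes = [
    simulate.simulate_genome(20000, gc, seed=i, genome_id=gid)
    for i, (gid, gc) in enumerate([("acc_IIC", 0.61), ("competibacter", 0.45), ("other", 0.55)])
]
scaffolds = []
for i, g in enumerate(genomes):
    scaffolds += simulate.fragment_genome(g, 8, seed=i)

design = simulate.CommunityDesign(
    members=[
        simulate.CommunityMember("acc_IIC", depth_a=30, depth_b=5),
        simulate.CommunityMember("competibacter", depth_a=5, depth_b=30),
        simulate.CommunityMember("other", depth_a=12, depth_b=12),
    ],
    per_base_error_rate=0.005,
    seed=42,
)
reads, truth = simulate.simulate_reads(design, genomes)

print(f"{len(genomes)} genomes, {len(scaffolds)} scaffolds (>= 1 kb each)")
print(f"sample A: {len(reads['A'])} reads, sample B: {len(reads['B'])} reads")
print(truth.groupby(["genome_id", "sample"]).size().unstack())
print(
    "\nRead counts follow depth * genome_length / read_length; the depth"
    "\ncontrast between samples A and B is what separates the genomes in"
    "\ncoverage space for binning."
)
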