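"""Generate a ground-truthed synthetic 3' end sequencing experiment.

Builds a toy genome of multi-PAS genes, plants knockdown effects on distal
poly(A)-site usage, simulates tail-carrying reads for a control and a
knockdown sample, and writes the bundle (FASTA, annotation TSV, SAM files,
truth table, config) to ./example_fixture/.
"""

from apakit.simulate import SimulationConfig, simulate_bundle

config = SimulationConfig(
    seed=11,
    n_genes=40,
    samples=(("ctrl_rep1", "ctrl", 10_000), ("kd_rep1", "kd", 10_000)),
)
assets, truth, manifest = simulate_bundle(config, "example_fixture")

n_pas = len(truth.pas)
n_planted = (truth.genes["planted_direction"] != "none").sum()
print(f"genes: {len(assets.annotation)}, PASs: {n_pas}, "
      f"genes with a planted usage shift: {n_planted}")
print("files written:")
for name in sorted(manifest):
    print(f"  example_fixture/{name}")
# The truth table is the reference every downstream claim can be checked
# against: per-PAS usage per condition and the intended direction.
print(truth.pas.head(4).to_string(index=False))
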