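"""Simulate a complete synthetic study fixture with planted ground truth.

Writes a toy two-chromosome genome with genes, CpG islands, repeats,
chromatin states, 5hmC bin counts, per-CpG methylation, bulk expression,
single-cell counts and region-level read fragments, all derived from one
master seed.
"""

from epidiff import SimulationConfig, simulate_truth, write_fixture

truth = simulate_truth(SimulationConfig(), seed=1)
info = write_fixture("example_fixture", truth)

print(f"genome: {truth.layout.chrom_names} x {truth.layout.chrom_lengths}")
print(f"genes: {len(truth.genes)} ({len(truth.ieg_genes)} IEG-like)")
print(f"planted DhMRs: {len(truth.planted_dhmrs)} (fold {truth.config.fold_hmc})")
print(f"planted DMRs: {len(truth.planted_dmrs)} (delta {truth.config.meth_shift})")
print(f"files: {info}")
# Every downstream stage can now be run against example_fixture/ and its
# calls compared with truth.json.
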