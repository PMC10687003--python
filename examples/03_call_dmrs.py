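"""DMR calling: beta-binomial site test, merge (< 100 bp) and filter
(> 5 DM CpGs, mean methylation difference > 0.2)."""

from epidiff import SimulationConfig, call_dmrs, simulate_methylation, simulate_truth

truth = simulate_truth(SimulationConfig(), seed=1)
sites = simulate_methylation(truth)
print(f"{sites.n_sites} CpG sites, mean coverage "
      f"{sites.total.mean():.1f} reads/site/sample")

calls, site_results = call_dmrs(sites)
hyper = sum(c.direction == "hyper" for c in calls)
hypo = sum(c.direction == "hypo" for c in calls)
print(f"DM sites (BH < 0.05): {int(site_results['is_dm'].sum())}")
print(f"DMRs: {hyper} hyper, {hypo} hypo "
      f"(planted {truth.config.n_hyper} + {truth.config.n_hypo})")
for c in calls[:3]:
    print(f"  {c.interval.chrom}:{c.interval.start}-{c.interval.end} "
          f"{c.direction} n_dm={c.n_dm_sites} mean_diff={c.mean_meth_diff:+.2f}")
# Each DMR is a run of nearby significantly differential CpGs whose mean
# treated-mock methylation difference exceeds 0.2 in one direction.
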