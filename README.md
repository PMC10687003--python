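# epidiff

Differential 5-hydroxymethylcytosine (5hmC) and 5-methylcytosine (5mC)
analysis for two-group brain methylome studies, with downstream
integration against bulk and single-nucleus transcriptomes.

The package targets the analysis pattern of maternal-immune-activation
(MIA) offspring-brain studies: enrichment-based 5hmC sequencing and
base-resolution 5mC counts from a handful of replicates per group
(mock vs treated), bulk RNA-seq fold changes, and clustered snRNA-seq
counts. Everything is exercisable on a seeded synthetic fixture with
planted ground truth, so every stage has a known recovery target.

## What it computes

**Differential 5hmC regions (DhMRs).** Read counts in 500-bp genome bins
are compared between groups with a simplified quantile-adjusted
conditional maximum likelihood (qCML) engine: counts are
quantile-adjusted to the geometric-mean library size, a common
negative-binomial dispersion φ is estimated by maximizing the
conditional log-likelihood given per-group bin totals, and each bin gets
a two-sided exact test on the adjusted group sums conditional on their
total (at φ = 0 this is the conditional binomial test). Bins with
Benjamini–Hochberg FDR < 0.05 become gain/loss region calls, with
adjacent same-direction bins merged. Genome-wide behaviour is summarized
by OLS regression of treated on mock bin densities and by length-
normalized meta-profiles over gene bodies.

**Differential methylation regions (DMRs).** Per-CpG (methylated, total)
counts are tested with a beta-binomial likelihood-ratio test (shared
precision, profile-maximized; χ²₁ reference). BH-adjusted p < 0.05 flags
DM sites; DM sites less than 100 bp apart merge into candidates, and
candidates with more than 5 DM CpGs whose mean methylation difference
exceeds 0.2 become hyper/hypo DMR calls.

**Annotation and enrichment.** Regions get exactly one primary feature
at their midpoint (promoter > 5'UTR > exon > 3'UTR > TTS > intron >
intergenic; promoter = TSS−2000..TSS+500), orthogonal CpG-island and
repeat-class flags, Fisher-exact chromatin-state enrichment against a
background set, and per-class fractions of repeat elements gaining 5hmC.

**Methylome–transcriptome concordance.** Gain-of-5hmC activated genes
(expression log2FC > 0 with a significant gain region in the gene body,
region p < 0.05) and loss-of-5hmC repressed genes, plus the 5mC analogue
pairing hyper DMRs with downregulated DEGs (base mean > 150,
|log2FC| > 0.15) and hypo DMRs with upregulated DEGs. Overlap of any
gene set with a disease list is scored with a one-sided exact binomial
test against the list's frequency in the gene universe.

**IEG bin-matrix statistics.** Immediate-early-gene bodies
(TSS−1000..TES+1000) and promoters (TSS−3000..TSS+1000) are split into
500-bp tiles of ten 50-bp bins; pooled per-group CPM rows form a 2×10
matrix tested with an unpaired Student's t-test (pooled variance,
18 df). Neuronal and non-neuronal signals combine as

    combined level = level(NeuN+) × 0.28 + level(NeuN−) × 0.72

using the fixed cortex composition (28% neuronal).

**snRNA-seq DEG burden.** Each cluster is downsampled to 50 cells per
group 10 times; each draw is DE-tested (Wilcoxon rank-sum on
log-normalized counts, FDR < 0.01, |log2FC| ≥ 0.15) and the per-
repetition DEG counts estimate the cluster's burden, compared pairwise
with t-tests.

## Worked example

```python
from epidiff import (SimulationConfig, simulate_truth, simulate_5hmc_counts,
                     estimate_common_dispersion, bin_exact_test, call_dhmrs)

truth = simulate_truth(SimulationConfig(), seed=1)   # 2 x 5 Mb, 100 planted regions
m = simulate_5hmc_counts(truth)                      # 20000 bins x 6 samples
disp = estimate_common_dispersion(m)
calls = call_dhmrs(bin_exact_test(m, disp), fdr_threshold=0.05)
```

Running `python examples/02_call_dhmrs.py` prints:

```
common dispersion (true 0.05): 0.0500
called regions: 57 gain, 55 loss (planted 50 gain + 50 loss)
global regression: slope=0.908 r=0.877
```

The dispersion estimate recovers the generative value; the 112 calls
cover the 100 planted regions (a planted region can split into more than
one call and a handful of calls are false positives — measured
sensitivity 0.88 at empirical FDR 0.07 on this seed). The regression
slope near 1 says there is no genome-wide 5hmC shift beyond the planted
regions. The other `examples/*.py` scripts walk through DMR calling,
annotation, concordance, the IEG matrix statistic and the DEG burden in
the same style, each printing the quantity it computes next to the
planted truth.

A thin CLI mirrors the stages
(`epidiff simulate|dhmr|dmr|annotate|integrate|ieg|burden|all`):

```bash
epidiff all --out run1 --seed 1       # simulate a fixture and run all stages
```

Outputs are deterministic: identical seeds give byte-identical trees.

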