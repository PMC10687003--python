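# Methods

This note documents the statistical models, the synthetic-data
generator, numerical choices and known limitations of `epidiff`.

## Coordinate and data conventions

All coordinates are 0-based half-open internally; BED input/output is
passed through unchanged and any 1-based table would be converted at the
reader boundary. Chromosome order comes from the genome layout and fixes
the row order of every output, which is what makes runs byte-identical
under a fixed seed. The sample sheet (sample_id, group, library_size) is
the single source of group labels; groups are always `mock` and
`treated`.

Reads are assigned to bins by fragment midpoint, so each read lands in
exactly one bin and totals are conserved. Terminal bins are clipped to
the chromosome end; clipped bins shorter than half the bin width are
retained in the matrix but excluded from differential testing to avoid
density inflation on short tails.

## Differential 5hmC (binned counts)

Counts in uniform bins (default 500 bp) for n = 3 + 3 replicates are
modelled as negative binomial with a common dispersion φ
(variance μ + φμ²).

*Library equalization.* Counts are quantile-adjusted to the geometric
mean N\* of the library sizes by normal quantile matching: an
observation z standard deviations from its library-specific NB mean maps
to the same z under N\*. This is a simplification of the full
quantile-to-quantile NB transform; it preserves means exactly and is
monotone. The adjustment and dispersion estimation iterate three times
(adjust at the current φ, re-estimate).

*Common dispersion.* φ maximizes the conditional log-likelihood of the
adjusted counts given their per-group bin totals,

  ℓ(φ) = Σ_groups Σ_bins [ Σ_j lnΓ(y_j + 1/φ) − n lnΓ(1/φ)
          + lnΓ(n/φ) − lnΓ(z + n/φ) ],

optimized over δ = φ/(1+φ) ∈ [10⁻⁶, 0.95] by bounded Brent search
(xatol 10⁻⁷). A maximum on the lower boundary returns φ = 0 (no
extra-Poisson variation). Only the common dispersion is estimated — no
tagwise or trended shrinkage.

*Exact test.* Per bin, the adjusted group sums (s₁, s₂) are rounded to
integers and s₁ is referred to its conditional law given t = s₁ + s₂:
the convolution of NB(n₁μ̂, n₁/φ) and NB(n₂μ̂, n₂/φ) with μ̂ = t/(n₁+n₂),
enumerated over 0..t (vectorized over bins in batches). At φ < 10⁻¹⁰ an
exact binomial branch is used, Binomial(t, n₁/(n₁+n₂)), which keeps the
agreement with rational-arithmetic enumeration at the 10⁻¹² level. The
two-sided p doubles the smaller tail and caps at 1. A bin with t = 0
reports p = 1, log₂FC = 0. The log₂ fold change uses a 0.5 pseudo-count
on the mean adjusted counts and never feeds back into the test.

*Region calls.* BH adjustment runs over all tested bins; significant
bins (FDR < 0.05) become calls, and adjacent significant bins (gap 0,
same chromosome and direction) merge into one region whose p/FDR are the
member minima and whose fold change is the most significant member's. A
flag disables merging to report bins directly, since the source
procedure's behaviour between the two is not observable from region
counts alone.

*Global summaries.* The genome-wide comparison is an OLS regression of
treated group-mean density (CPM) on mock group-mean density across bins,
with Pearson r. Meta-profiles sample each region at n equally spaced
relative positions (minus-strand regions flipped), read the bin density
under each position, and also return per-region mean densities per group
with a two-sided unpaired Welch t-test between groups.

## Differential methylation (per-CpG counts)

Each site's per-sample counts (m_j, t_j) are beta-binomial with mean π
and precision θ (α = πθ, β = (1−π)θ). The likelihood-ratio test compares
one common π across groups (null) with group-specific π (alternative),
with θ profile-maximized in both models over the grid
{2, 5, 10, 20, 50, 100, 300, 1000, 10⁴}; π is maximized on a 101-point
grid on [10⁻³, 1−10⁻³] with three-point parabolic refinement of the
log-likelihood. With pooled per-group coverage around 90 the likelihood
is sharply peaked, so the grid resolution contributes ≪ 0.01 to the LRT.
2·(ℓ_alt − ℓ_null), clipped at 0, is referred to χ²₁. Sites with pooled
coverage below 10 in either group are skipped. Group mean levels are
pooled meth/total.

DM sites are flagged at BH-adjusted p < 0.05. Merging chains DM sites
whose site-to-site distance is strictly less than 100 bp (distance
exactly 100 starts a new candidate); non-DM sites inside the span are
recorded as members but never break the chain. Candidates are kept when
they contain at least 6 DM CpGs ("more than 5") and the absolute value
of the signed mean methylation difference over DM members exceeds 0.2.
An additional sign-consistency guard (≥ 80% of DM members share the
majority sign) suppresses mixed-direction candidates that the literal
rule would admit; it can be disabled for the strict rule. Region
direction is hyper for positive mean difference; the region's p/FDR are
the DM-member minima, and the mean difference doubles as the effect
size.

Whether the mean difference is signed-then-absolute or element-wise
absolute, and whether distance is measured site-to-site, are genuinely
open readings; both defaults are config parameters.

## Annotation and enrichment

Primary features are decided at the region midpoint with fixed
precedence promoter > 5'UTR > exon > 3'UTR > TTS > intron > intergenic.
The promoter window is TSS−2000..TSS+500 and the TTS window TES..TES+500
(strand-aware); both are stand-ins for an external annotator's defaults
and are config-exposed. CGI and repeat overlap are any-overlap flags
orthogonal to the primary feature. Chromatin states are consumed as a
generic labeled BED; per state, a 2×2 table of (query, background) ×
(overlaps, not) is tested with a two-sided Fisher exact test and BH
across states. Repeat elements overlapping calls of both directions are
classified by majority overlap length (ties count as gain).

## Concordance and gene-set overlap

DEG selection uses strict thresholds: base mean > 150 and log₂FC > 0.15
(up) or < −0.15 (down). Concordance gates regions on raw p < 0.05 by
default (matching the source definition) with an FDR option; genes
showing significant regions in both directions are resolved by the most
significant region and logged. The concordance expression filter is the
sign of log₂FC, not DEG membership, for the 5hmC sets; the 5mC sets pair
DMR direction with DEG membership. The binomial overlap test is
one-sided (enrichment): p = P(X ≥ k), X ~ Binomial(|query|,
|list|/|universe|), with the universe defaulting to all genes in the
expression table — the smallest defensible superset.

## IEG bin-matrix statistic

Bodies are TSS−1000..TES+1000 and promoters TSS−3000..TSS+1000,
strand-aware and clipped to the chromosome. Tiling drops terminal
partial tiles (< 500 bp) by default; a flag keeps them clipped. Each
tile's 2×10 matrix holds pooled per-group read counts in ten 50-bp
sub-bins (midpoint rule), scaled to CPM of the pooled group library —
one row per group, not per sample, so the t-test is across bins. The
t-test is pooled-variance Student's t (18 df) per the statistic's name,
with Welch optional. Per-gene mark log₂FC is the ratio of summed CPM
over tiles with a 0.5 pseudo-count. Raw p and within-gene BH columns are
both emitted since per-gene multiplicity handling is unspecified
upstream. The combined level is the convex combination with fixed
weights 0.28/0.72 (neuronal/non-neuronal cortex fractions — a fixed
assumption, not estimated). Cluster-level expression log₂FC uses
unweighted means over member clusters per compartment with a 0.01
pseudo-count; cluster names starting with Ex/In are neuronal by the
pipeline's naming convention.

## DEG burden

Downsampling draws 50 cells per cluster *per group* without replacement
(balanced; a pooled mode exists), 10 repetitions, each repetition seeded
by a (cluster, repetition) child of the master seed. The DE engine is a
two-sided Wilcoxon rank-sum on per-cell counts scaled to 10,000 and
log1p-transformed — a deliberate, pluggable stand-in for a hurdle-model
engine, named in output metadata; the burden procedure itself (sampling,
thresholds ≥ 0.15 inclusive and FDR < 0.01, counting, pairwise t-tests
on the 10-repetition vectors) is the contribution being exercised.
Identical all-constant repetition vectors compare at p = 1 by
convention.

## Synthetic-data generator

The generator emulates the study's data-generating structure, not its
sequences. Defaults define the package's study conditions:

- genome 2 × 5 Mb; 300 genes (10% short IEG-like), CpG islands at half
  the promoters plus random ones, 400 repeat elements in five classes,
  chromatin-state segments tied to promoters/bodies;
- 5hmC: 50 gain + 50 loss planted regions of 2 bins at fold f = 3, NB
  counts at depth 10⁶/sample, dispersion 0.05, sample depth factors
  0.85–1.15, 3 + 3 replicates; bin baselines log-normal (σ = 0.5);
- 5mC: 30 hyper + 30 hypo planted DMRs of 10 CpGs spaced 30 bp
  (CpG-island-like density — wider spacing interacts pathologically with
  the strict < 100 bp merge rule, because one failed site then always
  severs the chain), shift δ = 0.3, baseline level 0.1 in CGIs / 0.7
  outside with per-site jitter, Poisson coverage 30, beta-binomial
  precision 20; hyper DMRs sit in CGIs and hypo DMRs outside so the
  shift never saturates the [0, 1] scale;
- expression: log₂FC = planted effect + N(0, 0.1²), planted DEG effect
  1.0 (scaled 0.5–1.5×), log-normal base mean (median 200); p-values
  come from a one-sample z against the noise model — a synthetic
  stand-in for an upstream DE engine, not a modelled test;
- IEGs: expression effect +0.8–1.6, gene-body 5hmC log₂FC = 0.8×expr +
  N(0, 0.15²), promoter 5mC log₂FC = −0.5×expr + N(0, 0.15²), assigned
  before DMR planting so promoter DMRs never override IEG effects;
  read-level fragments are generated over IEG/control gene regions only;
- cells: four clusters (Ex1/In1 neuronal, Astro/Olig not), 80 cells per
  group each, planted DEG burdens 40/20/5/5 at log₂FC 1, NB counts
  (dispersion 0.3) at ~2000 counts/cell; neuronal clusters receive the
  IEG upregulation as part of their planted DEG quota.

One master seed fans out to stage-specific child seeds through a fixed
spawn-key table (truth 0, 5hmC 1, methylation 2, expression 3, cells 4,
reads 5/6), so any stage regenerates independently.

What the generator does **not** emulate: sequence composition, mapping
artifacts, input-control background, CpG density variation outside
planted regions, batch effects, doublets or ambient RNA. Passing
recovery tests therefore demonstrates the correctness of the estimators
under their assumed models, not performance on real libraries.

## Problem sizes and verification

The shipped conditions (20 000 bins, ~6 600 CpGs, 640 cells) were chosen
so that the full pipeline completes in well under a minute per run while
leaving planted effects identifiable with comfortable margins. Under
them the suite verifies: DhMR bin-level sensitivity ≥ 0.8 at empirical
FDR ≤ 0.1; null false-positive rate 0.05 ± 0.01 at raw p < 0.05 (2000
bins × 10 seeds); DMR region-level sensitivity ≥ 0.8 at empirical FDR
≤ 0.1; exact agreement (10⁻¹²) of the conditional binomial, Fisher and
binomial-tail routes with rational-arithmetic enumeration oracles; the
pooled t-test against the textbook formula on 1000 random matrices;
burden ordering 40-vs-5 in ≥ 19/20 seeds; and byte-identical outputs
across repeated seeded runs.

## Known limitations

- The library equalization is a normal-approximation; extreme library
  ratios or very low counts would warrant the full quantile transform.
- The common-dispersion model ignores mean-dispersion trends; strongly
  heteroskedastic data would miscalibrate tail bins.
- The beta-binomial LRT assumes a shared precision across sites within
  the profile step and uses a χ²₁ reference, which is mildly
  conservative at few replicates.
- No input-control correction for enrichment background in 5hmC data.
- The annotator's promoter/TTS windows are conventions, not inferred.
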