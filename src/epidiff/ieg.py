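"""Immediate-early-gene (IEG) bin-matrix statistics and cell-type weighting.

Gene bodies (TSS-1000 .. TES+1000) and promoters (TSS-3000 .. TSS+1000,
strand-aware) are tiled into 500-bp regions; each region is split into ten
50-bp sub-bins and pooled, library-normalized read counts per group form a
2x10 matrix tested with an unpaired Student's t-test (pooled variance,
18 df). Neuronal and non-neuronal signals are combined with fixed cortex
cell-type weights (28% neuronal, 72% non-neuronal).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genome import GeneModel, GenomeLayout, Interval

log = logging.getLogger(__name__)

MOCK, TREATED = "mock", "treated"

BODY_FLANK = 1000
PROMOTER_UP = 3000
PROMOTER_DOWN = 1000
TILE_WIDTH = 500
SUB_BIN = 50
N_SUB_BINS = TILE_WIDTH // SUB_BIN


@dataclass(frozen=True)
class CellTypeWeights:
    """Fixed cortex composition: fraction of neuronal cells."""

    f_neuron: float = 0.28

    def __post_init__(self):
        if not 0.0 <= self.f_neuron <= 1.0:
            raise ValueError("f_neuron must lie in [0, 1]")

    @property
    def f_non_neuron(self) -> float:
        return 1.0 - self.f_neuron


@dataclass
class RegionMatrix:
    """2 groups x 10 sub-bins of library-normalized read counts for one
    500-bp region. Row order is (treated, mock)."""

    region: Interval
    counts: np.ndarray  # (2, N_SUB_BINS), CPM-scaled

    def __post_init__(self):
        if self.counts.shape != (2, N_SUB_BINS):
            raise ValueError(f"expected 2x{N_SUB_BINS} matrix")


def build_gene_regions(
    g: GeneModel, layout: GenomeLayout | None = None
) -> tuple[Interval, Interval]:
    """Strand-aware gene body and promoter windows, clipped to the
    chromosome."""
    iv = g.interval
    body_lo, body_hi = iv.start - BODY_FLANK, iv.end + BODY_FLANK
    if iv.strand == "+":
        prom_lo, prom_hi = iv.start - PROMOTER_UP, iv.start + PROMOTER_DOWN
    else:
        prom_lo, prom_hi = iv.end - PROMOTER_DOWN, iv.end + PROMOTER_UP
    if layout is not None:
        L = layout.length_of(iv.chrom)
        clipped = body_lo < 0 or prom_lo < 0 or body_hi > L or prom_hi > L
        body_lo, prom_lo = max(0, body_lo), max(0, prom_lo)
        body_hi, prom_hi = min(L, body_hi), min(L, prom_hi)
        if clipped:
            log.info("gene %s windows clipped to chromosome bounds", g.gene_id)
    body = Interval(iv.chrom, body_lo, body_hi, iv.strand, g.gene_id)
    promoter = Interval(iv.chrom, prom_lo, prom_hi, iv.strand, g.gene_id)
    return body, promoter


def tile_region(region: Interval, tile: int = TILE_WIDTH, keep_partial: bool = False) -> list[Interval]:
    """Consecutive non-overlapping tiles from the region start.

    A terminal partial tile is dropped by default; regions shorter than
    one tile yield an empty list (warned).
    """
    if tile < 1:
        raise ValueError("tile width must be >= 1")
    tiles = []
    for s in range(region.start, region.end - tile + 1, tile):
        tiles.append(Interval(region.chrom, s, s + tile, region.strand, region.label))
    rem = (region.width % tile) if region.width >= tile else region.width
    if keep_partial and rem > 0:
        s = region.start + (region.width // tile) * tile
        tiles.append(Interval(region.chrom, s, region.end, region.strand, region.label))
    if not tiles:
        log.warning(
            "region %s:%d-%d shorter than one %d bp tile",
            region.chrom, region.start, region.end, tile,
        )
    return tiles


def region_matrix(
    tile: Interval,
    reads_by_group: dict[str, list[Interval]],
    group_library_sizes: dict[str, float],
) -> RegionMatrix:
    """Count pooled per-group reads into ten 50-bp sub-bins by fragment
    midpoint and scale to counts-per-million of the pooled group library."""
    if tile.width != TILE_WIDTH:
        raise ValueError(f"tile must be {TILE_WIDTH} bp wide")
    counts = np.zeros((2, N_SUB_BINS))
    for row, grp in enumerate((TREATED, MOCK)):
        lib = group_library_sizes[grp]
        for r in reads_by_group.get(grp, []):
            if r.chrom != tile.chrom:
                continue
            mid = r.midpoint
            if tile.start <= mid < tile.end:
                counts[row, (mid - tile.start) // SUB_BIN] += 1
        counts[row] *= 1e6 / lib
    return RegionMatrix(tile, counts)


def region_ttest(m: RegionMatrix, welch: bool = False) -> tuple[float, float]:
    """Unpaired Student's t-test (pooled variance) on the two 10-bin rows.

    Welch's correction is available by flag. Two identical constant rows
    give t = 0, p = 1.
    """
    a, b = m.counts[0], m.counts[1]
    if np.ptp(a) == 0 and np.ptp(b) == 0 and a[0] == b[0]:
        return 0.0, 1.0
    res = stats.ttest_ind(a, b, equal_var=not welch)
    return float(res.statistic), float(res.pvalue)


def combined_level(
    level_neuron: float, level_non_neuron: float, w: CellTypeWeights = CellTypeWeights()
) -> float:
    """Cell-type-weighted combined 5hmC/5mC level:
    level_neuron * f_neuron + level_non_neuron * (1 - f_neuron)."""
    if level_neuron < 0 or level_non_neuron < 0:
        raise ValueError("levels must be non-negative")
    return level_neuron * w.f_neuron + level_non_neuron * w.f_non_neuron


def celltype_logfc(
    cluster_means: pd.DataFrame,
    neuronal_clusters: set[str],
    pseudo_count: float = 0.01,
) -> pd.DataFrame:
    """Per-gene neuronal and non-neuronal expression log2FC.

    ``cluster_means`` has columns gene_id, cluster, group, mean_expr. Per
    compartment the unweighted mean over member clusters is taken per
    group; log2FC = log2((treated + c) / (mock + c)).
    """
    clusters = set(cluster_means["cluster"])
    non_neuronal = clusters - neuronal_clusters
    if not (clusters & neuronal_clusters) or not non_neuronal:
        raise ValueError("both compartments must contain at least one cluster")
    rows = []
    for gene_id, sub in cluster_means.groupby("gene_id", sort=True):
        row = {"gene_id": gene_id}
        for name, members in (("neuronal", clusters & neuronal_clusters),
                              ("non_neuronal", non_neuronal)):
            comp = sub[sub["cluster"].isin(members)]
            means = comp.groupby("group")["mean_expr"].mean()
            trt = float(means.get(TREATED, 0.0))
            mock = float(means.get(MOCK, 0.0))
            row[f"log2fc_{name}"] = float(
                np.log2((trt + pseudo_count) / (mock + pseudo_count))
            )
        rows.append(row)
    return pd.DataFrame(rows)


def gene_mark_logfc(
    gene: GeneModel,
    context: str,
    reads_by_group: dict[str, list[Interval]],
    group_library_sizes: dict[str, float],
    layout: GenomeLayout | None = None,
    pseudo_count: float = 0.5,
) -> pd.DataFrame:
    """Per-tile 2x10 matrices and t-tests for one gene in one context
    ('body' or 'promoter'); returns a per-tile table with a pooled
    gene-level log2FC of summed CPM."""
    body, promoter = build_gene_regions(gene, layout)
    region = body if context == "body" else promoter
    tiles = tile_region(region)
    rows = []
    sums = {TREATED: 0.0, MOCK: 0.0}
    for t in tiles:
        rm = region_matrix(t, reads_by_group, group_library_sizes)
        tstat, p = region_ttest(rm)
        sums[TREATED] += rm.counts[0].sum()
        sums[MOCK] += rm.counts[1].sum()
        rows.append(
            {
                "gene_id": gene.gene_id,
                "context": context,
                "chrom": t.chrom,
                "start": t.start,
                "end": t.end,
                "t": tstat,
                "p_value": p,
            }
        )
    df = pd.DataFrame(rows)
    df.attrs["log2_fc"] = float(
        np.log2((sums[TREATED] + pseudo_count) / (sums[MOCK] + pseudo_count))
    )
    return df


def ieg_summary(
    gene_table: pd.DataFrame,
) -> dict:
    """Correlate expression log2FC with 5hmC and 5mC log2FC across IEGs.

    ``gene_table`` columns: gene_id, is_ieg, expr_log2fc, hmc_log2fc,
    mc_log2fc. IEGs and non-IEG control genes are reported separately.
    Expected biology: positive 5hmC correlation (gene body), negative 5mC
    correlation (promoter).
    """
    out = {}
    for name, sub in (("ieg", gene_table[gene_table["is_ieg"]]),
                      ("control", gene_table[~gene_table["is_ieg"]])):
        entry = {"n": int(len(sub))}
        if len(sub) >= 3:
            for mark in ("hmc", "mc"):
                x = sub["expr_log2fc"].to_numpy(dtype=float)
                y = sub[f"{mark}_log2fc"].to_numpy(dtype=float)
                if np.ptp(x) > 0 and np.ptp(y) > 0:
                    entry[f"pearson_{mark}"] = float(stats.pearsonr(x, y).statistic)
                    entry[f"spearman_{mark}"] = float(stats.spearmanr(x, y).statistic)
                else:
                    entry[f"pearson_{mark}"] = float("nan")
                    entry[f"spearman_{mark}"] = float("nan")
        out[name] = entry
    return out
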