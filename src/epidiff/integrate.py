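"""Methylation-expression concordance and gene-set overlap enrichment.

Concordance classification pairs the sign of a gene's expression change
with the direction of epigenetic regions overlapping its gene body:
gain-of-5hmC activated genes (log2FC > 0 with a significant gain region),
loss-of-5hmC repressed genes (both negative), and the analogous 5mC sets
(hyper DMR with downregulation, hypo DMR with upregulation). Overlap of a
gene set with a disease list is scored with a one-sided exact binomial
test against the list's frequency in the gene universe.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .annotate import _IntervalIndex
from .genome import GeneModel, RegionCall

log = logging.getLogger(__name__)


def select_degs(
    expression: pd.DataFrame,
    min_base_mean: float = 150.0,
    lfc_threshold: float = 0.15,
) -> tuple[set[str], set[str]]:
    """Bulk DEG selection: mean normalized counts > 150 and |log2FC| > 0.15
    (both strict)."""
    e = expression
    expressed = e["base_mean"] > min_base_mean
    up = set(e.loc[expressed & (e["log2_fc"] > lfc_threshold), "gene_id"])
    down = set(e.loc[expressed & (e["log2_fc"] < -lfc_threshold), "gene_id"])
    return up, down


def assign_regions_to_genes(
    regions: list[RegionCall], genes: list[GeneModel]
) -> tuple[dict[str, list[RegionCall]], list[RegionCall]]:
    """Assign each region to every gene whose body (txStart..txEnd, no
    flanks) it overlaps by >= 1 bp; unassigned regions are returned
    separately."""
    ix = _IntervalIndex([g.interval for g in genes])
    genes_by_span: dict[tuple, list[GeneModel]] = {}
    for g in genes:
        key = (g.interval.chrom, g.interval.start, g.interval.end)
        genes_by_span.setdefault(key, []).append(g)
    assigned: dict[str, list[RegionCall]] = {}
    orphans: list[RegionCall] = []
    for call in regions:
        iv = call.interval
        spans = ix.overlapping(iv.chrom, iv.start, iv.end)
        if not spans:
            orphans.append(call)
            continue
        for sp in spans:
            for g in genes_by_span[(sp.chrom, sp.start, sp.end)]:
                assigned.setdefault(g.gene_id, []).append(call)
    return assigned, orphans


@dataclass
class ConcordanceSets:
    gain_activated: set[str] = field(default_factory=set)
    loss_repressed: set[str] = field(default_factory=set)
    hyper_down: set[str] = field(default_factory=set)
    hypo_up: set[str] = field(default_factory=set)
    supporting: dict[str, list[RegionCall]] = field(default_factory=dict)


def classify_concordance(
    expression: pd.DataFrame,
    gene_regions: dict[str, list[RegionCall]],
    mode: str,
    region_alpha: float = 0.05,
    use_adjusted: bool = False,
    deg_sets: tuple[set[str], set[str]] | None = None,
) -> ConcordanceSets:
    """Classify genes by concordant epigenetic and expression change.

    5hmC mode: gain_activated = genes with log2FC > 0 and at least one gain
    region with p < ``region_alpha`` (raw p by default, FDR with
    ``use_adjusted``); loss_repressed analogous with both negative. 5mC
    mode pairs hyper DMRs with downregulated DEGs and hypo DMRs with
    upregulated DEGs (``deg_sets`` = (up, down), defaulting to
    ``select_degs`` output). A gene with significant regions in both
    directions is assigned by its most significant region (conflict
    logged).
    """
    if mode not in {"5hmC", "5mC"}:
        raise ValueError("mode must be '5hmC' or '5mC'")
    out = ConcordanceSets()
    lfc = expression.set_index("gene_id")["log2_fc"]

    if mode == "5mC":
        up, down = deg_sets if deg_sets is not None else select_degs(expression)

    for gene_id, calls in gene_regions.items():
        if gene_id not in lfc.index:
            continue
        sig = [
            c for c in calls
            if (c.fdr if use_adjusted else c.p_value) < region_alpha
        ]
        if not sig:
            continue
        pos = [c for c in sig if c.direction in {"gain", "hyper"}]
        neg = [c for c in sig if c.direction in {"loss", "hypo"}]
        if pos and neg:
            best = min(sig, key=lambda c: c.p_value)
            log.info(
                "gene %s has significant regions in both directions; "
                "using most significant (%s)", gene_id, best.direction,
            )
            pos, neg = ([best], []) if best.direction in {"gain", "hyper"} else ([], [best])
        g_lfc = float(lfc.loc[gene_id])
        if mode == "5hmC":
            if pos and g_lfc > 0:
                out.gain_activated.add(gene_id)
                out.supporting[gene_id] = pos
            elif neg and g_lfc < 0:
                out.loss_repressed.add(gene_id)
                out.supporting[gene_id] = neg
        else:
            if pos and gene_id in down:
                out.hyper_down.add(gene_id)
                out.supporting[gene_id] = pos
            elif neg and gene_id in up:
                out.hypo_up.add(gene_id)
                out.supporting[gene_id] = neg
    return out


@dataclass
class OverlapEnrichment:
    n_query: int
    n_list: int
    n_universe: int
    overlap: int
    p_value: float


def geneset_overlap_binomial(
    query: set[str], disease_list: set[str], universe: set[str]
) -> OverlapEnrichment:
    """One-sided exact binomial test of gene-set overlap.

    k = |query & disease_list|, p0 = |disease_list| / |universe|,
    p = P(X >= k) for X ~ Binomial(|query|, p0).
    """
    if not universe:
        raise ValueError("empty gene universe")
    if not query <= universe or not disease_list <= universe:
        raise ValueError("query and disease list must be subsets of the universe")
    n = len(query)
    p0 = len(disease_list) / len(universe)
    k = len(query & disease_list)
    p = float(stats.binom.sf(k - 1, n, p0)) if k > 0 else 1.0
    return OverlapEnrichment(n, len(disease_list), len(universe), k, min(p, 1.0))


def methylation_expression_correlation(
    gene_lfc: np.ndarray, region_lfc: np.ndarray
) -> dict:
    """Pearson and Spearman correlation of expression vs region-aggregate
    methylation log-fold-changes across genes."""
    x = np.asarray(gene_lfc, dtype=float)
    y = np.asarray(region_lfc, dtype=float)
    if len(x) < 3 or len(x) != len(y):
        raise ValueError("need >= 3 paired genes")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        log.warning("constant vector in correlation; returning NaN")
        return {"pearson_r": float("nan"), "spearman_rho": float("nan"),
                "p_value": float("nan"), "n": len(x)}
    pr = stats.pearsonr(x, y)
    sr = stats.spearmanr(x, y)
    return {
        "pearson_r": float(pr.statistic),
        "spearman_rho": float(sr.statistic),
        "p_value": float(pr.pvalue),
        "n": len(x),
    }
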