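"""Seeded synthetic-data generator with planted ground truth.

Emulates the data-generating structure of a two-group (mock vs treated)
offspring-brain methylome study: negative-binomial 5hmC counts on a
binned toy genome with planted gain/loss regions, beta-binomial per-CpG
methylation with planted hyper/hypo DMRs, bulk expression log2FCs
stochastically concordant with the planted epigenetic changes, read-level
fragments over immediate-early-gene (IEG) bodies and promoters, and
clustered single-cell counts with planted per-cluster DEG burdens.

One master seed fans out to per-stage child seeds through a fixed
spawn-key table, so any stage can be regenerated independently.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import io as eio
from .genome import (
    BinCountMatrix,
    CpGSiteTable,
    GeneModel,
    GenomeLayout,
    Interval,
    _bin_offsets,
    make_genome_bins,
)

log = logging.getLogger(__name__)

MOCK, TREATED = "mock", "treated"

# stage -> spawn key for child seeds of the master seed
_STAGE_KEYS = {
    "truth": 0,
    "hmc": 1,
    "methylation": 2,
    "expression": 3,
    "cells": 4,
    "reads_hmc": 5,
    "reads_mc": 6,
}

REPEAT_CLASSES = ["SINE", "LINE", "LTR", "DNA", "other"]
_REPEAT_WEIGHTS = [0.35, 0.30, 0.15, 0.10, 0.10]
CHROM_STATES = [
    "StrongPromoter", "PoisedPromoter", "StrongEnhancer",
    "Transcribed", "Heterochrom", "Quiescent",
]


def stage_rng(master_seed: int, stage: str) -> np.random.Generator:
    """Child generator for one stage of the master seed."""
    return np.random.default_rng(
        np.random.SeedSequence(master_seed, spawn_key=(_STAGE_KEYS[stage],))
    )


@dataclass
class ClusterSpec:
    n_cells_per_group: int
    n_degs: int
    neuronal: bool


def _default_clusters() -> dict[str, ClusterSpec]:
    return {
        "Ex1": ClusterSpec(80, 40, True),
        "In1": ClusterSpec(80, 20, True),
        "Astro": ClusterSpec(80, 5, False),
        "Olig": ClusterSpec(80, 5, False),
    }


@dataclass
class SimulationConfig:
    """Generator settings; defaults define the package's study conditions."""

    chrom_lengths: tuple = (5_000_000, 5_000_000)
    bin_width: int = 500
    n_genes: int = 300
    ieg_fraction: float = 0.1
    n_controls: int = 20
    # planted 5hmC regions
    n_gain: int = 50
    n_loss: int = 50
    fold_hmc: float = 3.0
    dhmr_n_bins: int = 2
    frac_genic: float = 0.4
    frac_gain_repeat: float = 0.3
    frac_loss_repeat: float = 0.05
    concordant_fraction: float = 0.9
    # planted 5mC regions
    n_hyper: int = 30
    n_hypo: int = 30
    dmr_n_sites: int = 10
    dmr_site_spacing: int = 30  # CpG-island-like density; < merge_gap / 3
    meth_shift: float = 0.3
    n_background_sites: int = 6000
    # annotations
    n_cgi: int = 150
    n_repeats: int = 400
    # sequencing model
    n_per_group: int = 3
    depth: int = 1_000_000
    dispersion: float = 0.05
    treated_global_scale: float = 1.0
    coverage: float = 30.0
    bb_precision: float = 20.0
    noise_sd: float = 0.1
    deg_log2fc: float = 1.0
    n_extra_degs: int = 40
    # single-cell model
    n_cell_genes: int = 300
    cells_depth: float = 2000.0
    cell_dispersion: float = 0.3
    cluster_spec: dict = field(default_factory=_default_clusters)


@dataclass
class PlantedRegion:
    interval: Interval
    direction: str  # gain/loss or hyper/hypo
    effect: float  # fold (5hmC) or methylation shift delta (5mC)
    gene_id: str | None = None


@dataclass
class SyntheticTruth:
    config: SimulationConfig
    seed: int
    layout: GenomeLayout
    genes: list[GeneModel]
    cgi: list[Interval]
    repeats: list[Interval]
    chrom_states: list[Interval]
    planted_dhmrs: list[PlantedRegion]
    planted_dmrs: list[PlantedRegion]
    planted_degs: dict[str, float]
    ieg_effects: dict[str, dict[str, float]]  # gene -> expr/hmc/mc log2FC
    control_genes: list[str]
    cell_genes: list[str]
    cluster_degs: dict[str, dict[str, float]]  # cluster -> gene -> log2FC

    @property
    def ieg_genes(self) -> list[str]:
        return [g.gene_id for g in self.genes if g.is_ieg]


def _place_genes(cfg: SimulationConfig, layout: GenomeLayout, rng) -> list[GeneModel]:
    n_ieg = round(cfg.n_genes * cfg.ieg_fraction)
    ieg_ids = set(rng.choice(cfg.n_genes, size=n_ieg, replace=False).tolist())
    cursors = {c: 10_000 for c in layout.chrom_names}
    genes: list[GeneModel] = []
    chrom_cycle = list(layout.chrom_names)
    ci = 0
    for gi in range(cfg.n_genes):
        is_ieg = gi in ieg_ids
        length = int(rng.integers(2000, 4000) if is_ieg else rng.integers(5000, 15000))
        placed = False
        for _ in range(len(chrom_cycle)):
            chrom = chrom_cycle[ci % len(chrom_cycle)]
            ci += 1
            L = layout.length_of(chrom)
            start = cursors[chrom] + int(rng.integers(5000, 20000))
            if start + length + 10_000 > L:
                continue
            cursors[chrom] = start + length
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(_make_gene(f"g{gi:04d}", chrom, start, start + length,
                                    strand, is_ieg, rng))
            placed = True
            break
        if not placed:
            raise ValueError(
                f"genome too small for {cfg.n_genes} genes (placed {len(genes)})"
            )
    return genes


def _make_gene(gene_id, chrom, start, end, strand, is_ieg, rng) -> GeneModel:
    n_exons = int(rng.integers(3, 8))
    block = (end - start) // n_exons
    exons = []
    for k in range(n_exons):
        w = int(min(rng.integers(100, 300), max(block - 10, 50)))
        s = start + k * block
        exons.append(Interval(chrom, s, min(s + w, end), strand))
    exons.sort(key=lambda e: e.start)
    first = exons[0] if strand == "+" else exons[-1]
    last = exons[-1] if strand == "+" else exons[0]
    utr5 = Interval(chrom, first.start, min(first.start + 150, first.end), strand)
    utr3 = Interval(chrom, max(last.end - 300, last.start), last.end, strand)
    return GeneModel(gene_id, Interval(chrom, start, end, strand), is_ieg,
                     exons, utr5, utr3)


def _place_annotations(cfg, layout, genes, rng):
    cgi: list[Interval] = []
    promoter_cgis: list[tuple[Interval, str]] = []
    for g in genes:
        if rng.random() < 0.5:
            tss = g.tss
            iv = Interval(g.interval.chrom, max(0, tss - 500),
                          min(layout.length_of(g.interval.chrom), tss + 500),
                          label="CGI")
            cgi.append(iv)
            promoter_cgis.append((iv, g.gene_id))
    while len(cgi) < cfg.n_cgi:
        chrom = layout.chrom_names[int(rng.integers(len(layout.chrom_names)))]
        w = int(rng.integers(300, 1500))
        s = int(rng.integers(1000, layout.length_of(chrom) - w - 1000))
        cgi.append(Interval(chrom, s, s + w, label="CGI"))
    repeats = []
    for ri in range(cfg.n_repeats):
        chrom = layout.chrom_names[int(rng.integers(len(layout.chrom_names)))]
        w = int(rng.integers(150, 1000))
        s = int(rng.integers(1000, layout.length_of(chrom) - w - 1000))
        cls = rng.choice(REPEAT_CLASSES, p=_REPEAT_WEIGHTS)
        repeats.append(Interval(chrom, s, s + w, label=str(cls)))
    states = _chrom_states(layout, genes, rng)
    return cgi, promoter_cgis, repeats, states


def _chrom_states(layout, genes, rng, seg: int = 2000) -> list[Interval]:
    prom = {(g.interval.chrom, g.tss) for g in genes}
    out = []
    for chrom, L in zip(layout.chrom_names, layout.chrom_lengths):
        tsss = sorted(t for c, t in prom if c == chrom)
        gene_ivs = [g.interval for g in genes if g.interval.chrom == chrom]
        starts = [iv.start for iv in gene_ivs]
        ends = [iv.end for iv in gene_ivs]
        for s in range(0, L, seg):
            e = min(s + seg, L)
            label = None
            for t in tsss:
                if s <= t < e:
                    label = "StrongPromoter" if rng.random() < 0.6 else "PoisedPromoter"
                    break
            if label is None:
                inside = any(a < e and b > s for a, b in zip(starts, ends))
                if inside:
                    label = "Transcribed"
                else:
                    label = str(rng.choice(
                        ["StrongEnhancer", "Heterochrom", "Quiescent"],
                        p=[0.2, 0.3, 0.5],
                    ))
            out.append(Interval(chrom, s, e, label=label))
    return out


class _Occupancy:
    """Tracks claimed intervals so planted regions never overlap."""

    def __init__(self):
        self.by_chrom: dict[str, list[tuple[int, int]]] = {}

    def free(self, iv: Interval) -> bool:
        return all(
            not (a < iv.end and b > iv.start)
            for a, b in self.by_chrom.get(iv.chrom, [])
        )

    def claim(self, iv: Interval) -> None:
        self.by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))


def _plant_dhmrs(cfg, layout, genes, repeats, occ, rng):
    w = cfg.bin_width
    span = cfg.dhmr_n_bins * w
    planted: list[PlantedRegion] = []
    non_ieg = [g for g in genes if not g.is_ieg]

    def try_place(iv: Interval, direction: str, gene_id=None) -> bool:
        if iv.end > layout.length_of(iv.chrom) or not occ.free(iv):
            return False
        occ.claim(iv)
        planted.append(PlantedRegion(iv, direction, cfg.fold_hmc, gene_id))
        return True

    def random_binaligned(chrom=None) -> Interval:
        chrom = chrom or layout.chrom_names[int(rng.integers(len(layout.chrom_names)))]
        L = layout.length_of(chrom)
        b = int(rng.integers(2, (L - span) // w - 2)) * w
        return Interval(chrom, b, b + span)

    for direction, n_total, frac_rep in (
        ("gain", cfg.n_gain, cfg.frac_gain_repeat),
        ("loss", cfg.n_loss, cfg.frac_loss_repeat),
    ):
        n_genic = round(n_total * cfg.frac_genic)
        n_rep = round(n_total * frac_rep)
        placed = 0
        # gene-body regions
        order = rng.permutation(len(non_ieg))
        gi = 0
        while placed < n_genic and gi < len(order):
            g = non_ieg[order[gi]]
            gi += 1
            body = g.interval
            first_bin = -(-body.start // w)  # ceil
            last_bin = body.end // w - cfg.dhmr_n_bins
            if last_bin < first_bin:
                continue
            b = int(rng.integers(first_bin, last_bin + 1)) * w
            if try_place(Interval(body.chrom, b, b + span), direction, g.gene_id):
                placed += 1
        # repeat-overlapping regions
        rep_order = rng.permutation(len(repeats))
        ri = 0
        target = n_genic + n_rep
        while placed < target and ri < len(repeats):
            rep = repeats[rep_order[ri]]
            ri += 1
            b = (rep.midpoint // w) * w
            b = min(max(0, b - ((cfg.dhmr_n_bins - 1) // 2) * w),
                    layout.length_of(rep.chrom) - span)
            if try_place(Interval(rep.chrom, b, b + span), direction):
                placed += 1
        # intergenic filler
        attempts = 0
        while placed < n_total and attempts < 10_000:
            attempts += 1
            if try_place(random_binaligned(), direction):
                placed += 1
        if placed < n_total:
            raise ValueError(f"could not place all planted {direction} regions")
    return planted


def _plant_dmrs(cfg, layout, cgi, promoter_cgis, genes, occ, rng, planted_degs):
    span = cfg.dmr_n_sites * cfg.dmr_site_spacing
    planted: list[PlantedRegion] = []
    prom_map = {iv: gid for iv, gid in promoter_cgis}
    cgi_order = rng.permutation(len(cgi))

    def place_at(chrom, center, direction, gene_id=None) -> bool:
        s = max(0, center - span // 2)
        e = min(layout.length_of(chrom), s + span)
        iv = Interval(chrom, s, e)
        if not occ.free(iv):
            return False
        occ.claim(iv)
        delta = cfg.meth_shift if direction == "hyper" else -cfg.meth_shift
        planted.append(PlantedRegion(iv, direction, delta, gene_id))
        return True

    # hyper DMRs sit in CpG islands (low baseline, headroom to gain)
    placed = 0
    for k in cgi_order:
        if placed >= cfg.n_hyper:
            break
        iv = cgi[k]
        gid = prom_map.get(iv)
        if place_at(iv.chrom, iv.midpoint, "hyper", gid):
            placed += 1
            if gid is not None and gid not in planted_degs and rng.random() < cfg.concordant_fraction:
                planted_degs[gid] = -cfg.deg_log2fc * float(rng.uniform(0.5, 1.5))
    if placed < cfg.n_hyper:
        raise ValueError("not enough CpG islands for planted hyper DMRs")
    # hypo DMRs in non-CGI background (high baseline, room to lose); half
    # are placed in gene bodies with concordant upregulation
    placed = 0
    attempts = 0
    n_genic = cfg.n_hypo // 2
    gene_order = rng.permutation(len(genes))
    gi = 0
    while placed < n_genic and gi < len(genes):
        g = genes[gene_order[gi]]
        gi += 1
        body = g.interval
        if body.width < 3 * span:
            continue
        center = int(rng.integers(body.start + span, body.end - span))
        iv_probe = Interval(body.chrom, center - span, center + span)
        if any(c.overlaps(iv_probe) for c in cgi):
            continue
        if place_at(body.chrom, center, "hypo", g.gene_id):
            placed += 1
            if g.gene_id not in planted_degs and rng.random() < cfg.concordant_fraction:
                planted_degs[g.gene_id] = cfg.deg_log2fc * float(rng.uniform(0.5, 1.5))
    while placed < cfg.n_hypo and attempts < 20_000:
        attempts += 1
        chrom = layout.chrom_names[int(rng.integers(len(layout.chrom_names)))]
        center = int(rng.integers(span, layout.length_of(chrom) - span))
        iv_probe = Interval(chrom, center - span, center + span)
        if any(c.overlaps(iv_probe) for c in cgi):
            continue
        if place_at(chrom, center, "hypo"):
            placed += 1
    if placed < cfg.n_hypo:
        raise ValueError("could not place all planted hypo DMRs")
    return planted


def simulate_truth(config: SimulationConfig | None = None, seed: int = 0) -> SyntheticTruth:
    """Build the toy genome, annotations and all planted ground truth.

    Deterministic for fixed (config, seed). Raises if the requested
    regions cannot fit in the genome.
    """
    cfg = config or SimulationConfig()
    rng = stage_rng(seed, "truth")
    layout = GenomeLayout(
        tuple(f"chr{i + 1}" for i in range(len(cfg.chrom_lengths))),
        tuple(int(x) for x in cfg.chrom_lengths),
    )
    genes = _place_genes(cfg, layout, rng)
    cgi, promoter_cgis, repeats, states = _place_annotations(cfg, layout, genes, rng)

    occ = _Occupancy()
    planted_degs: dict[str, float] = {}
    dhmrs = _plant_dhmrs(cfg, layout, genes, repeats, occ, rng)
    # expression concordance for genic DhMRs
    for pr in dhmrs:
        if pr.gene_id is None or pr.gene_id in planted_degs:
            continue
        if rng.random() < cfg.concordant_fraction:
            sign = 1.0 if pr.direction == "gain" else -1.0
            planted_degs[pr.gene_id] = sign * cfg.deg_log2fc * float(rng.uniform(0.5, 1.5))
    # IEG effects: upregulated expression, gained gene-body 5hmC, lost
    # promoter 5mC, mutually correlated. Assigned before DMR planting so a
    # promoter DMR never overrides an IEG's expression effect.
    ieg_effects: dict[str, dict[str, float]] = {}
    for g in genes:
        if not g.is_ieg:
            continue
        expr = cfg.deg_log2fc * float(rng.uniform(0.8, 1.6))
        ieg_effects[g.gene_id] = {
            "expr": expr,
            "hmc": 0.8 * expr + float(rng.normal(0, 0.15)),
            "mc": -0.5 * expr + float(rng.normal(0, 0.15)),
        }
        planted_degs[g.gene_id] = expr

    dmrs = _plant_dmrs(cfg, layout, cgi, promoter_cgis, genes, occ, rng, planted_degs)
    non_ieg_ids = [g.gene_id for g in genes if not g.is_ieg]
    control_genes = [
        non_ieg_ids[i]
        for i in rng.choice(len(non_ieg_ids),
                            size=min(cfg.n_controls, len(non_ieg_ids)),
                            replace=False)
    ]
    for gid in control_genes:
        ieg_effects[gid] = {
            "expr": float(rng.normal(0, 0.05)),
            "hmc": float(rng.normal(0, 0.05)),
            "mc": float(rng.normal(0, 0.05)),
        }
    # extra unlinked DEGs
    free = [g.gene_id for g in genes if g.gene_id not in planted_degs]
    n_extra = min(cfg.n_extra_degs, len(free))
    for i in rng.choice(len(free), size=n_extra, replace=False):
        sign = 1.0 if rng.random() < 0.5 else -1.0
        planted_degs[free[i]] = sign * cfg.deg_log2fc * float(rng.uniform(0.5, 1.5))

    # single-cell genes and per-cluster planted DEGs
    ieg_ids = [g.gene_id for g in genes if g.is_ieg]
    cell_genes = list(dict.fromkeys(
        ieg_ids + control_genes + [g.gene_id for g in genes]
    ))[: cfg.n_cell_genes]
    cluster_degs: dict[str, dict[str, float]] = {}
    for name, spec in cfg.cluster_spec.items():
        if spec.n_cells_per_group < 60:
            log.warning("cluster %s has < 60 cells per group", name)
        chosen: dict[str, float] = {}
        if spec.neuronal:
            for gid in ieg_ids[: spec.n_degs]:
                chosen[gid] = ieg_effects[gid]["expr"]
        pool = [g for g in cell_genes if g not in chosen]
        need = min(spec.n_degs - len(chosen), len(pool))
        if need < spec.n_degs - len(chosen):
            log.warning("cluster %s: only %d genes available for planted DEGs",
                        name, len(chosen) + need)
        if need > 0:
            for i in rng.choice(len(pool), size=need, replace=False):
                sign = 1.0 if rng.random() < 0.5 else -1.0
                chosen[pool[i]] = sign * cfg.deg_log2fc * float(rng.uniform(0.8, 1.5))
        cluster_degs[name] = chosen

    return SyntheticTruth(
        cfg, seed, layout, genes, cgi, repeats, states, dhmrs, dmrs,
        planted_degs, ieg_effects, control_genes, cell_genes, cluster_degs,
    )


# ---------------------------------------------------------------------------
# stage simulators


def planted_bin_mask(truth: SyntheticTruth, direction: str | None = None) -> np.ndarray:
    """Boolean mask over genome bins covered by planted DhMRs."""
    cfg = truth.config
    offsets = _bin_offsets(truth.layout, cfg.bin_width)
    n_bins = sum(n for _, n in offsets.values())
    mask = np.zeros(n_bins, dtype=bool)
    for pr in truth.planted_dhmrs:
        if direction is not None and pr.direction != direction:
            continue
        off, n = offsets[pr.interval.chrom]
        b0 = pr.interval.start // cfg.bin_width
        b1 = -(-pr.interval.end // cfg.bin_width)
        mask[off + b0: off + min(b1, n)] = True
    return mask


def simulate_5hmc_counts(
    truth: SyntheticTruth,
    n_per_group: int | None = None,
    depth: float | None = None,
    dispersion: float | None = None,
    seed: int | None = None,
) -> BinCountMatrix:
    """NB-distributed bin counts with planted fold changes.

    Bin means are log-normal across the genome and scaled to the target
    depth; treated-group means are multiplied by the planted fold in gain
    regions and divided by it in loss regions. Dispersion 0 degenerates
    to Poisson.
    """
    cfg = truth.config
    n = n_per_group if n_per_group is not None else cfg.n_per_group
    depth = depth if depth is not None else cfg.depth
    phi = dispersion if dispersion is not None else cfg.dispersion
    if n < 2:
        raise ValueError("need >= 2 samples per group")
    if phi < 0:
        raise ValueError("dispersion must be >= 0")
    rng = stage_rng(seed if seed is not None else truth.seed, "hmc")
    bins = make_genome_bins(truth.layout, cfg.bin_width)
    rel = rng.lognormal(0.0, 0.5, size=len(bins))
    mu = rel / rel.sum() * depth
    mult = np.full(len(bins), cfg.treated_global_scale)
    gain = planted_bin_mask(truth, "gain")
    loss = planted_bin_mask(truth, "loss")
    mult[gain] = cfg.fold_hmc
    mult[loss] = 1.0 / cfg.fold_hmc

    sample_ids = [f"hmc_{g}_{i + 1}" for g in (MOCK, TREATED) for i in range(n)]
    group = np.array([MOCK] * n + [TREATED] * n, dtype=object)
    factors = rng.uniform(0.85, 1.15, size=2 * n)
    counts = np.empty((len(bins), 2 * n), dtype=np.int64)
    for j in range(2 * n):
        m = mu * factors[j] * (mult if group[j] == TREATED else 1.0)
        if phi == 0:
            counts[:, j] = rng.poisson(m)
        else:
            r = 1.0 / phi
            counts[:, j] = rng.negative_binomial(r, r / (r + m))
    libs = counts.sum(axis=0)
    return BinCountMatrix(bins, counts, sample_ids, group, libs, cfg.bin_width)


def simulate_methylation(
    truth: SyntheticTruth,
    coverage: float | None = None,
    precision: float | None = None,
    seed: int | None = None,
) -> CpGSiteTable:
    """Beta-binomial per-CpG counts with planted hyper/hypo level shifts.

    Baseline level is ~0.1 inside CpG islands and ~0.7 outside (with
    per-site jitter); treated levels shift by +/- delta inside planted
    DMRs, clipped to [0.01, 0.99]. Totals are Poisson around the mean
    coverage; precision -> infinity collapses to binomial sampling.
    """
    cfg = truth.config
    coverage = coverage if coverage is not None else cfg.coverage
    theta = precision if precision is not None else cfg.bb_precision
    if coverage < 1:
        raise ValueError("coverage must be >= 1")
    rng = stage_rng(seed if seed is not None else truth.seed, "methylation")

    pos_by_chrom: dict[str, set[int]] = {c: set() for c in truth.layout.chrom_names}
    per_chrom = cfg.n_background_sites // len(truth.layout.chrom_names)
    for chrom in truth.layout.chrom_names:
        L = truth.layout.length_of(chrom)
        pos_by_chrom[chrom].update(
            int(x) for x in rng.integers(100, L - 100, size=per_chrom)
        )
    for pr in truth.planted_dmrs:
        for k in range(cfg.dmr_n_sites):
            pos_by_chrom[pr.interval.chrom].add(
                pr.interval.start + k * cfg.dmr_site_spacing
            )

    chroms, poss = [], []
    for chrom in truth.layout.chrom_names:
        for p in sorted(pos_by_chrom[chrom]):
            chroms.append(chrom)
            poss.append(p)
    chrom_arr = np.array(chroms, dtype=object)
    pos_arr = np.array(poss, dtype=np.int64)
    n_sites = len(pos_arr)

    in_cgi = np.zeros(n_sites, dtype=bool)
    for iv in truth.cgi:
        sel = (chrom_arr == iv.chrom) & (pos_arr >= iv.start) & (pos_arr < iv.end)
        in_cgi |= sel
    base = np.where(in_cgi, 0.1, 0.7)
    pi_mock = np.clip(base + rng.normal(0, 0.05, size=n_sites), 0.01, 0.99)
    shift = np.zeros(n_sites)
    for pr in truth.planted_dmrs:
        sel = (
            (chrom_arr == pr.interval.chrom)
            & (pos_arr >= pr.interval.start)
            & (pos_arr < pr.interval.end)
        )
        shift[sel] = pr.effect
    pi_trt = np.clip(pi_mock + shift, 0.01, 0.99)
    clipped = (shift != 0) & (np.abs(pi_trt - pi_mock) < np.abs(shift) * 0.5)
    if clipped.any():
        log.warning("%d planted DMR sites lost > half their shift to clipping",
                    int(clipped.sum()))

    n_samp = 2 * cfg.n_per_group
    sample_ids = [f"mc_{g}_{i + 1}" for g in (MOCK, TREATED) for i in range(cfg.n_per_group)]
    group = np.array([MOCK] * cfg.n_per_group + [TREATED] * cfg.n_per_group, dtype=object)
    total = rng.poisson(coverage, size=(n_sites, n_samp))
    meth = np.zeros_like(total)
    for j in range(n_samp):
        pi = pi_trt if group[j] == TREATED else pi_mock
        if theta > 1e6:  # binomial limit
            pdraw = pi
        else:
            pdraw = rng.beta(pi * theta, (1 - pi) * theta)
        meth[:, j] = rng.binomial(total[:, j], pdraw)
    return CpGSiteTable(chrom_arr, pos_arr, meth, total, sample_ids, group)


def simulate_expression(
    truth: SyntheticTruth,
    noise_sd: float | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Gene-level expression table with log2FC = planted effect + noise.

    base_mean is log-normal; p-values come from a one-sample z-test
    against the noise model (a synthetic stand-in for an upstream
    differential-expression engine), BH-adjusted.
    """
    from scipy import stats as sps

    cfg = truth.config
    sd = noise_sd if noise_sd is not None else cfg.noise_sd
    if sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = stage_rng(seed if seed is not None else truth.seed, "expression")
    gene_ids = [g.gene_id for g in truth.genes]
    effect = np.array([truth.planted_degs.get(g, 0.0) for g in gene_ids])
    lfc = effect + (rng.normal(0, sd, size=len(gene_ids)) if sd > 0 else 0.0)
    base_mean = rng.lognormal(np.log(200.0), 1.0, size=len(gene_ids))
    z = lfc / max(sd, 1e-8)
    p = 2.0 * sps.norm.sf(np.abs(z))
    from .stats import bh_adjust

    return pd.DataFrame(
        {
            "gene_id": gene_ids,
            "base_mean": base_mean,
            "log2_fc": lfc,
            "p_value": p,
            "fdr": bh_adjust(p),
        }
    )


def simulate_region_reads(
    truth: SyntheticTruth,
    mark: str,
    base_rate: float = 2.0,
    read_len: int = 100,
    seed: int | None = None,
) -> tuple[dict[str, list[Interval]], pd.DataFrame]:
    """Read fragments over IEG/control gene regions for one mark.

    mark='hmc' covers gene bodies (TSS-1000..TES+1000); mark='mc' covers
    promoters (TSS-3000..TSS+1000). Treated sub-bin rates are scaled by
    2**(planted per-gene log2FC). Returns per-sample fragment lists and a
    sample sheet with nominal library sizes.
    """
    from .ieg import SUB_BIN, TILE_WIDTH, build_gene_regions, tile_region

    if mark not in {"hmc", "mc"}:
        raise ValueError("mark must be 'hmc' or 'mc'")
    cfg = truth.config
    rng = stage_rng(seed if seed is not None else truth.seed,
                    "reads_hmc" if mark == "hmc" else "reads_mc")
    n = cfg.n_per_group
    sample_ids = [f"{mark}r_{g}_{i + 1}" for g in (MOCK, TREATED) for i in range(n)]
    groups = [MOCK] * n + [TREATED] * n
    reads: dict[str, list[Interval]] = {s: [] for s in sample_ids}
    target = set(truth.ieg_effects)  # IEGs + controls
    for g in truth.genes:
        if g.gene_id not in target:
            continue
        body, promoter = build_gene_regions(g, truth.layout)
        region = body if mark == "hmc" else promoter
        lfc = truth.ieg_effects[g.gene_id][mark]
        for tile in tile_region(region, TILE_WIDTH):
            profile = rng.lognormal(0, 0.3, size=TILE_WIDTH // SUB_BIN)
            for sid, grp in zip(sample_ids, groups):
                rate = base_rate * profile * (2.0 ** lfc if grp == TREATED else 1.0)
                k = rng.poisson(rate)
                for b in np.flatnonzero(k):
                    mids = tile.start + b * SUB_BIN + rng.integers(0, SUB_BIN, size=k[b])
                    for m in mids:
                        s = max(0, int(m) - read_len // 2)
                        reads[sid].append(
                            Interval(tile.chrom, s, s + read_len)
                        )
    sheet = pd.DataFrame(
        {"sample_id": sample_ids, "group": groups,
         "library_size": [1_000_000] * len(sample_ids)}
    )
    return reads, sheet


def simulate_cells(truth: SyntheticTruth, seed: int | None = None) -> pd.DataFrame:
    """Clustered cells x genes NB counts with planted per-cluster DEGs.

    Cluster-specific gene means are log-normal; treated means are scaled
    by 2**log2FC for each cluster's planted DEGs. Per-cell scaling
    factors are log-normal and counts negative binomial.
    """
    cfg = truth.config
    rng = stage_rng(seed if seed is not None else truth.seed, "cells")
    genes = truth.cell_genes
    frames = []
    for name in sorted(cfg.cluster_spec):
        spec = cfg.cluster_spec[name]
        if spec.n_cells_per_group < 50:
            log.warning(
                "cluster %s has %d cells per group (< 50 downsample size)",
                name, spec.n_cells_per_group,
            )
        weights = rng.lognormal(0.0, 1.0, size=len(genes))
        base_mu = weights / weights.sum() * cfg.cells_depth
        degs = truth.cluster_degs.get(name, {})
        mult = np.ones(len(genes))
        for gi, gid in enumerate(genes):
            if gid in degs:
                mult[gi] = 2.0 ** degs[gid]
        for grp in (MOCK, TREATED):
            mu = base_mu * (mult if grp == TREATED else 1.0)
            n_cells = spec.n_cells_per_group
            sf = rng.lognormal(0.0, 0.2, size=n_cells)
            r = 1.0 / cfg.cell_dispersion
            m = mu[None, :] * sf[:, None]
            counts = rng.negative_binomial(r, r / (r + m))
            df = pd.DataFrame(counts, columns=genes)
            df.insert(0, "group", grp)
            df.insert(0, "cluster", name)
            df.insert(0, "cell_id", [f"{name}_{grp}_{i + 1}" for i in range(n_cells)])
            frames.append(df)
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# fixture writing


def truth_to_json(truth: SyntheticTruth) -> dict:
    def iv(i: Interval):
        return [i.chrom, int(i.start), int(i.end)]

    return {
        "seed": truth.seed,
        "chrom_lengths": list(truth.config.chrom_lengths),
        "planted_dhmrs": [
            {"interval": iv(p.interval), "direction": p.direction,
             "effect": p.effect, "gene_id": p.gene_id}
            for p in truth.planted_dhmrs
        ],
        "planted_dmrs": [
            {"interval": iv(p.interval), "direction": p.direction,
             "effect": p.effect, "gene_id": p.gene_id}
            for p in truth.planted_dmrs
        ],
        "planted_degs": truth.planted_degs,
        "ieg_effects": truth.ieg_effects,
        "control_genes": truth.control_genes,
        "cluster_degs": truth.cluster_degs,
    }


def write_fixture(outdir, truth: SyntheticTruth) -> dict:
    """Generate all pipeline inputs from the truth and write the fixture
    directory. Returns a manifest of written files."""
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = truth.config
    seed = truth.seed

    eio.write_layout(out / "layout.tsv", truth.layout)
    eio.write_gene_table(out / "genes.tsv", truth.genes)
    eio.write_bed(out / "cgi.bed", truth.cgi)
    eio.write_bed(out / "repeats.bed", truth.repeats)
    eio.write_bed(out / "states.bed", truth.chrom_states)

    m = simulate_5hmc_counts(truth)
    eio.write_bin_counts(out / "hmc_counts.tsv", m)
    sheets = [pd.DataFrame({"sample_id": m.sample_ids, "group": list(m.group),
                            "library_size": m.library_sizes})]

    sites = simulate_methylation(truth)
    eio.write_site_table(out / "sites.tsv", sites)
    sheets.append(pd.DataFrame({
        "sample_id": sites.sample_ids, "group": list(sites.group),
        "library_size": [int(sites.total[:, j].sum()) for j in range(len(sites.sample_ids))],
    }))

    expr = simulate_expression(truth)
    eio.write_expression_table(out / "expression.tsv", expr)

    cells = simulate_cells(truth)
    eio.write_cells(out / "cells.tsv", cells)

    for mark in ("hmc", "mc"):
        reads, sheet = simulate_region_reads(truth, mark)
        rows = []
        for sid in sheet["sample_id"]:
            for r in reads[sid]:
                rows.append((r.chrom, r.start, r.end, sid))
        rows.sort()
        with open(out / f"{mark}_reads.bed", "w") as fh:
            for chrom, s, e, sid in rows:
                fh.write(f"{chrom}\t{s}\t{e}\t{sid}\t0\t.\n")
        sheets.append(sheet)

    eio.write_sample_sheet(out / "samples.tsv", pd.concat(sheets, ignore_index=True))

    # disease gene lists: one enriched in planted concordant genes, one random
    rng = stage_rng(seed, "truth")
    lists_dir = out / "disease_lists"
    lists_dir.mkdir(exist_ok=True)
    affected = sorted(truth.planted_degs)
    n_risk = max(10, len(affected) // 2)
    risk = set(
        affected[i] for i in rng.choice(len(affected), size=min(n_risk, len(affected)),
                                        replace=False)
    )
    all_ids = [g.gene_id for g in truth.genes]
    risk |= {all_ids[i] for i in rng.choice(len(all_ids), size=10, replace=False)}
    rand = {all_ids[i] for i in rng.choice(len(all_ids), size=40, replace=False)}
    eio.write_gene_list(lists_dir / "neuro_risk.txt", risk)
    eio.write_gene_list(lists_dir / "random_set.txt", rand)

    with open(out / "truth.json", "w") as fh:
        json.dump(truth_to_json(truth), fh, indent=1, sort_keys=True)
    return {"outdir": str(out), "n_genes": len(truth.genes),
            "n_bins": m.n_bins, "n_sites": sites.n_sites, "n_cells": len(cells)}
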