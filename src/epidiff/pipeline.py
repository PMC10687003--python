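"""End-to-end orchestration over a fixture directory.

``run_all`` executes the seven stages (simulate, dhmr, dmr, annotate,
integrate, ieg, burden) in dependency order, writing per-stage artifacts
and a deterministic run manifest (parameters, seeds, input checksums,
record counts — no timestamps, so identical configs and seeds give
byte-identical output trees).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import annotate as ann
from . import burden as bd
from . import dhmr as dh
from . import dmr as dm
from . import ieg as ig
from . import integrate as it
from . import io as eio
from .genome import GeneModel, GenomeLayout, Interval
from .simulate import SimulationConfig, simulate_truth, write_fixture
from .stats import bh_adjust

log = logging.getLogger(__name__)

STAGES = ["simulate", "dhmr", "dmr", "annotate", "integrate", "ieg", "burden"]
NEURONAL_PREFIXES = ("Ex", "In")  # cluster-name convention for compartments


@dataclass
class RunConfig:
    """All stage parameters; defaults equal the published thresholds
    (500 bp bins, FDR 0.05, merge gap 100 bp, > 5 DM CpGs, mean diff 0.2,
    base mean 150, log2FC 0.15, downsample 50 x 10 reps, 28% neuronal)."""

    out_dir: str = "epidiff_out"
    fixture_dir: str | None = None  # None: simulate under out_dir/fixture
    seed: int = 0
    bin_width: int = 500
    fdr: float = 0.05
    merge_adjacent: bool = True
    site_alpha: float = 0.05
    min_total: int = 10
    merge_gap: int = 100
    min_dm_sites: int = 6
    min_mean_diff: float = 0.2
    min_base_mean: float = 150.0
    lfc_threshold: float = 0.15
    region_alpha: float = 0.05
    use_adjusted: bool = False
    f_neuron: float = 0.28
    burden_n: int = 50
    burden_reps: int = 10
    sc_lfc_threshold: float = 0.15
    sc_fdr: float = 0.01

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _split_reads_by_group(bed_path, samples: pd.DataFrame):
    group_of = samples.set_index("sample_id")["group"].to_dict()
    libs = samples.set_index("sample_id")["library_size"].to_dict()
    reads: dict[str, list[Interval]] = {}
    with open(bed_path) as fh:
        for line in fh:
            f = line.rstrip("\n").split("\t")
            sid = f[3]
            reads.setdefault(group_of[sid], []).append(
                Interval(f[0], int(f[1]), int(f[2]))
            )
    group_libs: dict[str, float] = {}
    for sid, grp in group_of.items():
        group_libs[grp] = group_libs.get(grp, 0.0) + float(libs[sid])
    return reads, group_libs


def stage_dhmr(fixture: Path, out: Path, cfg: RunConfig) -> dict:
    samples = eio.read_sample_sheet(fixture / "samples.tsv")
    m = eio.read_bin_counts(fixture / "hmc_counts.tsv", samples, cfg.bin_width)
    disp = dh.estimate_common_dispersion(m)
    res = dh.bin_exact_test(m, disp)
    calls = dh.call_dhmrs(res, fdr_threshold=cfg.fdr, merge_adjacent=cfg.merge_adjacent)
    eio.write_region_calls(out / "dhmr_regions.bed", calls)
    table = pd.DataFrame(
        {
            "chrom": [b.chrom for b in res.bins],
            "start": [b.start for b in res.bins],
            "end": [b.end for b in res.bins],
            "log_fc": res.log_fc,
            "p_value": res.p_value,
            "tested": res.tested,
        }
    )
    table.to_csv(out / "dhmr_bins.tsv", sep="\t", index=False, float_format="%.6g")
    nd = dh.normalize_cpm(m)
    reg = dh.global_regression(nd)
    genes = eio.read_gene_table(fixture / "genes.tsv")
    prof = dh.meta_profile(nd, [g.interval for g in genes], n_points=50)
    summary = {
        "common_dispersion": disp.common_dispersion,
        "n_gain": sum(c.direction == "gain" for c in calls),
        "n_loss": sum(c.direction == "loss" for c in calls),
        "global_regression": reg,
        "gene_body_fold_change": prof.fold_change,
        "gene_body_p": prof.p_value,
    }
    with open(out / "dhmr_summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
    return {"n_regions": len(calls), **summary}


def stage_dmr(fixture: Path, out: Path, cfg: RunConfig) -> dict:
    samples = eio.read_sample_sheet(fixture / "samples.tsv")
    sites = eio.read_site_table(fixture / "sites.tsv", samples)
    calls, res = dm.call_dmrs(
        sites, min_total=cfg.min_total, site_alpha=cfg.site_alpha,
        merge_gap=cfg.merge_gap, min_dm_sites=cfg.min_dm_sites,
        min_mean_diff=cfg.min_mean_diff,
    )
    eio.write_region_calls(out / "dmr_regions.bed", calls)
    res.to_csv(out / "dmr_sites.tsv", sep="\t", index=False, float_format="%.6g")
    return {
        "n_hyper": sum(c.direction == "hyper" for c in calls),
        "n_hypo": sum(c.direction == "hypo" for c in calls),
        "n_sites_tested": int(res["tested"].sum()),
    }


def _random_background(layout: GenomeLayout, widths: list[int], n_factor: int,
                       seed: int) -> list[Interval]:
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(97,)))
    out = []
    for _ in range(n_factor):
        for w in widths:
            chrom = layout.chrom_names[int(rng.integers(len(layout.chrom_names)))]
            L = layout.length_of(chrom)
            s = int(rng.integers(0, max(1, L - w)))
            out.append(Interval(chrom, s, s + w))
    return out


def stage_annotate(fixture: Path, out: Path, cfg: RunConfig) -> dict:
    layout = eio.read_layout(fixture / "layout.tsv")
    genes = eio.read_gene_table(fixture / "genes.tsv")
    cgi = eio.read_bed(fixture / "cgi.bed", layout)
    repeats = eio.read_bed(fixture / "repeats.bed", layout)
    states = eio.read_bed(fixture / "states.bed", layout)
    dhmrs = eio.read_region_calls(out / "dhmr_regions.bed")
    dmrs = eio.read_region_calls(out / "dmr_regions.bed")

    rows = []
    for label, calls in (("dhmr", dhmrs), ("dmr", dmrs)):
        assignments = ann.annotate_regions(calls, genes, cgi, repeats)
        for call, fa in zip(calls, assignments):
            rows.append(
                {
                    "set": label,
                    "chrom": fa.region.chrom,
                    "start": fa.region.start,
                    "end": fa.region.end,
                    "direction": call.direction,
                    "feature": fa.feature,
                    "gene_id": fa.gene_id or "",
                    "cgi_overlap": int(fa.cgi_overlap),
                    "repeat_class": fa.repeat_class or "",
                }
            )
    pd.DataFrame(
        rows, columns=["set", "chrom", "start", "end", "direction", "feature",
                       "gene_id", "cgi_overlap", "repeat_class"],
    ).to_csv(out / "annotations.tsv", sep="\t", index=False)

    summary: dict = {"n_dhmr": len(dhmrs), "n_dmr": len(dmrs)}
    if dmrs:
        bg = _random_background(layout, [c.interval.width for c in dmrs], 10, cfg.seed)
        enr = ann.state_enrichment([c.interval for c in dmrs], bg, states)
        enr.to_csv(out / "state_enrichment.tsv", sep="\t", index=False,
                   float_format="%.6g")
        summary["n_states_tested"] = len(enr)
    frac = ann.repeat_gain_fraction(dhmrs, repeats)
    with open(out / "repeat_gain_fraction.json", "w") as fh:
        json.dump(frac, fh, indent=1, sort_keys=True)
    summary["repeat_gain_fraction"] = frac["overall"]
    return summary


def stage_integrate(fixture: Path, out: Path, cfg: RunConfig) -> dict:
    expr = eio.read_expression_table(fixture / "expression.tsv")
    genes = eio.read_gene_table(fixture / "genes.tsv")
    dhmrs = eio.read_region_calls(out / "dhmr_regions.bed")
    dmrs = eio.read_region_calls(out / "dmr_regions.bed")
    up, down = it.select_degs(expr, cfg.min_base_mean, cfg.lfc_threshold)

    gene_hmc, _ = it.assign_regions_to_genes(dhmrs, genes)
    sets_hmc = it.classify_concordance(
        expr, gene_hmc, "5hmC", region_alpha=cfg.region_alpha,
        use_adjusted=cfg.use_adjusted,
    )
    # DMRs act through promoters as well as bodies: assign over promoter+body
    prom_genes = []
    for g in genes:
        body, promoter = ig.build_gene_regions(g)
        lo = min(body.start, promoter.start)
        hi = max(body.end, promoter.end)
        g2 = GeneModel(g.gene_id, Interval(g.interval.chrom, max(0, lo), hi,
                                           g.interval.strand), g.is_ieg)
        prom_genes.append(g2)
    gene_mc, _ = it.assign_regions_to_genes(dmrs, prom_genes)
    sets_mc = it.classify_concordance(
        expr, gene_mc, "5mC", region_alpha=cfg.region_alpha,
        use_adjusted=cfg.use_adjusted, deg_sets=(up, down),
    )

    rows = []
    for name, s in (
        ("deg_up", up), ("deg_down", down),
        ("gain_activated", sets_hmc.gain_activated),
        ("loss_repressed", sets_hmc.loss_repressed),
        ("hyper_down", sets_mc.hyper_down),
        ("hypo_up", sets_mc.hypo_up),
    ):
        for gid in sorted(s):
            rows.append({"set": name, "gene_id": gid})
    pd.DataFrame(rows, columns=["set", "gene_id"]).to_csv(
        out / "concordance_sets.tsv", sep="\t", index=False
    )

    universe = set(expr["gene_id"])
    enr_rows = []
    lists_dir = fixture / "disease_lists"
    query = sets_hmc.gain_activated | sets_hmc.loss_repressed
    for lp in sorted(lists_dir.glob("*.txt")):
        disease = eio.read_gene_list(lp) & universe
        if query and disease:
            e = it.geneset_overlap_binomial(query & universe, disease, universe)
            enr_rows.append(
                {"list": lp.stem, "n_query": e.n_query, "n_list": e.n_list,
                 "overlap": e.overlap, "p_binomial": e.p_value}
            )
    pd.DataFrame(enr_rows, columns=["list", "n_query", "n_list", "overlap",
                                    "p_binomial"]).to_csv(
        out / "disease_overlap.tsv", sep="\t", index=False, float_format="%.6g"
    )

    lfc = expr.set_index("gene_id")["log2_fc"]
    shared = [g for g in sorted(gene_hmc) if g in lfc.index]
    corr = {}
    if len(shared) >= 3:
        agg = [float(np.mean([c.log_fc for c in gene_hmc[g]])) for g in shared]
        corr = it.methylation_expression_correlation(
            lfc.loc[shared].to_numpy(), np.array(agg)
        )
    with open(out / "integration_summary.json", "w") as fh:
        json.dump({"correlation": corr}, fh, indent=1, sort_keys=True)
    return {
        "n_up": len(up), "n_down": len(down),
        "n_gain_activated": len(sets_hmc.gain_activated),
        "n_loss_repressed": len(sets_hmc.loss_repressed),
        "n_hyper_down": len(sets_mc.hyper_down),
        "n_hypo_up": len(sets_mc.hypo_up),
        "correlation": corr,
    }


def stage_ieg(fixture: Path, out: Path, cfg: RunConfig) -> dict:
    layout = eio.read_layout(fixture / "layout.tsv")
    genes = eio.read_gene_table(fixture / "genes.tsv")
    samples = eio.read_sample_sheet(fixture / "samples.tsv")
    expr = eio.read_expression_table(fixture / "expression.tsv").set_index("gene_id")
    hmc_reads, hmc_libs = _split_reads_by_group(
        fixture / "hmc_reads.bed",
        samples[samples["sample_id"].str.startswith("hmcr_")],
    )
    mc_reads, mc_libs = _split_reads_by_group(
        fixture / "mc_reads.bed",
        samples[samples["sample_id"].str.startswith("mcr_")],
    )
    # which genes have read coverage: those present in the read files
    covered = set()
    with open(fixture / "truth.json") as fh:
        covered = set(json.load(fh)["ieg_effects"])

    tile_frames = []
    gene_rows = []
    for g in genes:
        if g.gene_id not in covered:
            continue
        body_df = ig.gene_mark_logfc(g, "body", hmc_reads, hmc_libs, layout)
        prom_df = ig.gene_mark_logfc(g, "promoter", mc_reads, mc_libs, layout)
        for df in (body_df, prom_df):
            if not df.empty:
                df = df.copy()
                df["adj_p_within_gene"] = bh_adjust(df["p_value"].to_numpy())
                tile_frames.append(df)
        gene_rows.append(
            {
                "gene_id": g.gene_id,
                "is_ieg": g.is_ieg,
                "expr_log2fc": float(expr.loc[g.gene_id, "log2_fc"]),
                "hmc_log2fc": body_df.attrs["log2_fc"],
                "mc_log2fc": prom_df.attrs["log2_fc"],
            }
        )
    tiles = pd.concat(tile_frames, ignore_index=True) if tile_frames else pd.DataFrame()
    tiles.to_csv(out / "ieg_tiles.tsv", sep="\t", index=False, float_format="%.6g")
    gene_table = pd.DataFrame(gene_rows)
    gene_table.to_csv(out / "ieg_genes.tsv", sep="\t", index=False, float_format="%.6g")
    summary = ig.ieg_summary(gene_table)

    cells = eio.read_cells(fixture / "cells.tsv")
    meta_cols = ["cell_id", "cluster", "group"]
    gene_cols = [c for c in cells.columns if c not in meta_cols]
    means = (
        cells.melt(id_vars=["cluster", "group"], value_vars=gene_cols,
                   var_name="gene_id", value_name="expr")
        .groupby(["gene_id", "cluster", "group"], sort=True)["expr"].mean()
        .reset_index()
        .rename(columns={"expr": "mean_expr"})
    )
    neuronal = {c for c in cells["cluster"].unique()
                if c.startswith(NEURONAL_PREFIXES)}
    ct = ig.celltype_logfc(means, neuronal)
    ieg_ids = {g.gene_id for g in genes if g.is_ieg}
    ct["is_ieg"] = ct["gene_id"].isin(ieg_ids).astype(int)
    ct.to_csv(out / "celltype_logfc.tsv", sep="\t", index=False, float_format="%.6g")
    with open(out / "ieg_summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
    return {"n_genes": len(gene_rows), **{f"{k}": v for k, v in summary.items()}}


def stage_burden(fixture: Path, out: Path, cfg: RunConfig) -> dict:
    cells = eio.read_cells(fixture / "cells.tsv")
    res = bd.burden_analysis(
        cells, n=cfg.burden_n, reps=cfg.burden_reps, seed=cfg.seed,
        lfc_threshold=cfg.sc_lfc_threshold, fdr=cfg.sc_fdr,
    )
    df = res.counts.copy()
    df.insert(0, "cluster", df.index)
    df["mean"] = res.mean
    df["se"] = res.se
    df.to_csv(out / "burden_counts.tsv", sep="\t", index=False, float_format="%.6g")
    res.pairwise_p.rename_axis("cluster").reset_index().to_csv(
        out / "burden_pairwise.tsv", sep="\t", index=False, float_format="%.6g"
    )
    return {"clusters": list(res.counts.index),
            "mean_burden": {k: float(v) for k, v in res.mean.items()}}


def run_all(cfg: RunConfig, sim_config: SimulationConfig | None = None) -> dict:
    """Run all stages in dependency order; returns the manifest dict.

    Any stage failure leaves an ``<out>/<stage>.incomplete`` marker and
    re-raises.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if cfg.fixture_dir is None:
        fixture = out / "fixture"
    else:
        fixture = Path(cfg.fixture_dir)
        if not fixture.exists():
            raise FileNotFoundError(f"fixture directory not found: {fixture}")

    params = asdict(cfg)
    params.pop("out_dir")  # paths vary between runs; outputs must not
    params.pop("fixture_dir")
    manifest: dict = {"stages": [], "parameters": params, "seed": cfg.seed}
    for stage in STAGES:
        marker = out / f"{stage}.incomplete"
        marker.touch()
        t0 = time.perf_counter()
        try:
            if stage == "simulate":
                if cfg.fixture_dir is None:
                    truth = simulate_truth(sim_config or SimulationConfig(), cfg.seed)
                    info = write_fixture(fixture, truth)
                else:
                    info = {"provided": True}
                info.pop("outdir", None)  # no paths in the manifest
            else:
                info = globals()[f"stage_{stage}"](fixture, out, cfg)
        except Exception:
            log.error("stage %s failed", stage)
            raise
        marker.unlink()
        log.info("stage %s done (%.1fs)", stage, time.perf_counter() - t0)
        manifest["stages"].append({"name": stage, "info": info})
    manifest["input_checksums"] = {
        p.name: _sha256(p) for p in sorted(fixture.glob("*.tsv"))
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True, default=str)
    return manifest
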