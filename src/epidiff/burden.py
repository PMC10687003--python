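"""Per-cluster DEG-burden estimation for snRNA-seq by repeated downsampling.

For each cell cluster, 50 cells per group are drawn without replacement
ten times; each draw is tested for differential expression (Wilcoxon
rank-sum on log-normalized counts, BH across genes, DEG if FDR < 0.01 and
|log2FC| >= 0.15) and the DEG counts per repetition form the cluster's
burden distribution. Clusters are compared pairwise with unpaired t-tests
on the repetition vectors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .stats import bh_adjust

log = logging.getLogger(__name__)

MOCK, TREATED = "mock", "treated"
NORM_TARGET = 10_000.0  # per-cell scale before log1p


@dataclass
class BurdenResult:
    counts: pd.DataFrame  # clusters x repetitions DEG counts
    mean: pd.Series
    se: pd.Series
    pairwise_p: pd.DataFrame
    skipped_clusters: list[str]


def downsample_cells(n_cells: int, n: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform sample of ``n`` cell indices without replacement."""
    if n_cells < n:
        raise ValueError(f"cluster has {n_cells} cells, need >= {n}")
    if n_cells == n:
        return np.arange(n_cells)
    return np.sort(rng.choice(n_cells, size=n, replace=False))


def _normalize(counts: np.ndarray) -> np.ndarray:
    """Per-cell scaling to a common total followed by log1p."""
    totals = counts.sum(axis=1, keepdims=True)
    totals = np.where(totals > 0, totals, 1)
    return np.log1p(counts * NORM_TARGET / totals)


def cluster_de_test(
    treated: np.ndarray,
    mock: np.ndarray,
    gene_ids: list[str],
    lfc_threshold: float = 0.15,
    fdr: float = 0.01,
    pseudo_count: float = 0.01,
) -> set[str]:
    """Wilcoxon rank-sum DE between treated and mock cells of one cluster.

    Counts are library-normalized per cell and log1p-transformed for the
    rank test; the fold change is log2 of normalized group means with a
    pseudo-count. DEG iff BH-adjusted p < ``fdr`` and |log2FC| >=
    ``lfc_threshold`` (inclusive). All-zero genes are skipped.
    """
    if treated.shape[0] < 2 or mock.shape[0] < 2:
        raise ValueError("need >= 2 cells per side")
    xt, xm = _normalize(treated.astype(float)), _normalize(mock.astype(float))
    nt = treated * (NORM_TARGET / np.maximum(treated.sum(axis=1, keepdims=True), 1))
    nm = mock * (NORM_TARGET / np.maximum(mock.sum(axis=1, keepdims=True), 1))
    expressed = (treated.sum(axis=0) + mock.sum(axis=0)) > 0
    p = np.full(treated.shape[1], np.nan)
    if expressed.any():
        res = stats.mannwhitneyu(
            xt[:, expressed], xm[:, expressed], alternative="two-sided", axis=0
        )
        p[expressed] = res.pvalue
    adj = bh_adjust(p)
    lfc = np.log2((nt.mean(axis=0) + pseudo_count) / (nm.mean(axis=0) + pseudo_count))
    hit = expressed & (adj < fdr) & (np.abs(lfc) >= lfc_threshold)
    return {gene_ids[i] for i in np.flatnonzero(hit)}


def burden_analysis(
    cells: pd.DataFrame,
    n: int = 50,
    reps: int = 10,
    seed: int = 0,
    lfc_threshold: float = 0.15,
    fdr: float = 0.01,
    per_group: bool = True,
) -> BurdenResult:
    """Repeated fixed-size downsampling DEG burden per cluster.

    ``cells`` is a cells x genes frame with leading cell_id, cluster and
    group columns. By default ``n`` cells are drawn per cluster *per
    group* (balanced test); ``per_group=False`` draws ``n`` from the
    pooled cluster. Clusters too small for the draw are skipped with a
    warning. Each (cluster, repetition) uses an independent child seed of
    the master seed, so repetition order is deterministic.
    """
    meta_cols = ["cell_id", "cluster", "group"]
    gene_ids = [c for c in cells.columns if c not in meta_cols]
    mat = cells[gene_ids].to_numpy()
    clusters = sorted(cells["cluster"].unique())
    counts: dict[str, list[int]] = {}
    skipped: list[str] = []
    for ci, cl in enumerate(clusters):
        in_cl = cells["cluster"] == cl
        it = np.flatnonzero(in_cl & (cells["group"] == TREATED))
        im = np.flatnonzero(in_cl & (cells["group"] == MOCK))
        need = n if per_group else -(-n // 2)
        if len(it) < need or len(im) < need:
            log.warning("cluster %s smaller than downsample size; skipped", cl)
            skipped.append(cl)
            continue
        vec = []
        for rep in range(reps):
            rng = np.random.default_rng(
                np.random.SeedSequence(seed, spawn_key=(ci, rep))
            )
            if per_group:
                st = it[downsample_cells(len(it), n, rng)]
                sm = im[downsample_cells(len(im), n, rng)]
            else:
                pool = np.concatenate([it, im])
                sub = pool[downsample_cells(len(pool), n, rng)]
                st = sub[np.isin(sub, it)]
                sm = sub[np.isin(sub, im)]
            degs = cluster_de_test(
                mat[st], mat[sm], gene_ids, lfc_threshold=lfc_threshold, fdr=fdr
            )
            vec.append(len(degs))
        counts[cl] = vec
    if len(counts) < 2:
        raise ValueError("need >= 2 eligible clusters")
    df = pd.DataFrame(counts).T
    df.columns = [f"rep{r + 1}" for r in range(reps)]
    names = list(df.index)
    pw = pd.DataFrame(np.ones((len(names), len(names))), index=names, columns=names)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            va, vb = df.loc[a].to_numpy(), df.loc[b].to_numpy()
            if np.ptp(va) == 0 and np.ptp(vb) == 0:
                p = 1.0 if va[0] == vb[0] else 0.0
            else:
                p = float(stats.ttest_ind(va, vb, equal_var=True).pvalue)
            pw.loc[a, b] = pw.loc[b, a] = p
    return BurdenResult(
        counts=df,
        mean=df.mean(axis=1),
        se=df.std(axis=1, ddof=1) / np.sqrt(reps),
        pairwise_p=pw,
        skipped_clusters=skipped,
    )
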