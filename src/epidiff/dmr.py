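"""Per-CpG differential methylation testing and DMR construction.

Site-level testing uses a beta-binomial likelihood-ratio test: the null
model fits one common methylation level across both groups, the
alternative fits group-specific levels, both with a shared overdispersion
(precision) parameter profile-maximized over a grid. The LRT statistic is
referred to a chi-square with one degree of freedom.

Differentially methylated (DM) sites closer than ``merge_gap`` bp are
merged into DMR candidates, which are then filtered on the number of DM
CpGs (> 5 by default) and the absolute mean methylation difference over
DM sites (> 0.2 by default).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from .genome import CpGSiteTable, Interval, RegionCall
from .stats import bh_adjust

log = logging.getLogger(__name__)

MOCK, TREATED = "mock", "treated"

# precision (concentration) grid for the profile likelihood; spans near-
# binomial (large theta) to strongly overdispersed (small theta)
_THETA_GRID = np.array([2.0, 5.0, 10.0, 20.0, 50.0, 100.0, 300.0, 1000.0, 1e4])
_PI_GRID = np.concatenate([[1e-3], np.linspace(0.01, 0.99, 99), [1 - 1e-3]])


@dataclass
class DMRCandidate:
    interval: Interval
    site_index: np.ndarray  # indices into the SiteResult table (all member sites)
    n_dm_sites: int
    mean_meth_diff: float  # signed mean over DM member sites


def _group_loglik(meth: np.ndarray, total: np.ndarray, theta: float) -> np.ndarray:
    """Beta-binomial log-likelihood per (site, pi) summed over samples.

    meth/total: (n_sites, n_samples). Returns (n_sites, len(_PI_GRID)).
    Terms independent of pi (binomial coefficients, lgamma(theta),
    lgamma(total+theta)) are dropped: they cancel in the LRT.
    """
    pi = _PI_GRID
    a = pi * theta  # (P,)
    b = (1.0 - pi) * theta
    m = meth[:, :, None]
    t = total[:, :, None]
    ll = (
        gammaln(m + a[None, None, :])
        + gammaln(t - m + b[None, None, :])
        - gammaln(a)[None, None, :]
        - gammaln(b)[None, None, :]
    )
    return ll.sum(axis=1)


def _grid_max(ll: np.ndarray) -> np.ndarray:
    """Per-row maximum over the pi grid with 3-point parabolic refinement."""
    k = np.argmax(ll, axis=1)
    best = ll[np.arange(len(ll)), k]
    interior = (k > 0) & (k < ll.shape[1] - 1)
    ki = k[interior]
    rows = np.flatnonzero(interior)
    y0 = ll[rows, ki - 1]
    y1 = ll[rows, ki]
    y2 = ll[rows, ki + 1]
    denom = y0 - 2 * y1 + y2
    ok = denom < -1e-12
    gain = np.zeros(len(rows))
    gain[ok] = (y0[ok] - y2[ok]) ** 2 / (-8.0 * denom[ok])
    best[rows] += gain
    return best


def site_test(
    t: CpGSiteTable,
    min_total: int = 10,
) -> pd.DataFrame:
    """Beta-binomial LRT per CpG site.

    Sites whose pooled coverage in either group is below ``min_total`` are
    skipped (``tested`` False, p NaN). Group mean levels are pooled
    meth/total per group. Returns a DataFrame with one row per input site
    in the input order.
    """
    groups = [g for g in dict.fromkeys(t.group)]
    if len(groups) != 2:
        raise ValueError("exactly two groups required")
    g_mock = MOCK if MOCK in groups else groups[0]
    g_trt = TREATED if TREATED in groups else [g for g in groups if g != g_mock][0]
    im, it = t.group_idx(g_mock), t.group_idx(g_trt)
    if len(im) < 2 or len(it) < 2:
        raise ValueError("need >= 2 samples per group")

    pooled_m = {g: t.meth[:, i].sum(axis=1) for g, i in (("mock", im), ("treated", it))}
    pooled_t = {g: t.total[:, i].sum(axis=1) for g, i in (("mock", im), ("treated", it))}
    tested = (pooled_t["mock"] >= min_total) & (pooled_t["treated"] >= min_total)
    n_skipped = int((~tested).sum())
    if n_skipped:
        log.info("site_test: skipped %d low-coverage sites", n_skipped)

    with np.errstate(invalid="ignore"):
        m_mock = pooled_m["mock"] / np.where(pooled_t["mock"] > 0, pooled_t["mock"], 1)
        m_trt = pooled_m["treated"] / np.where(pooled_t["treated"] > 0, pooled_t["treated"], 1)
    m_mock[pooled_t["mock"] == 0] = np.nan
    m_trt[pooled_t["treated"] == 0] = np.nan

    idx = np.flatnonzero(tested)
    lrt = np.full(t.n_sites, np.nan)
    if len(idx):
        meth_m, tot_m = t.meth[idx][:, im].astype(float), t.total[idx][:, im].astype(float)
        meth_t, tot_t = t.meth[idx][:, it].astype(float), t.total[idx][:, it].astype(float)
        best_null = np.full(len(idx), -np.inf)
        best_alt = np.full(len(idx), -np.inf)
        for theta in _THETA_GRID:
            ll_m = _group_loglik(meth_m, tot_m, theta)
            ll_t = _group_loglik(meth_t, tot_t, theta)
            null_ll = _grid_max(ll_m + ll_t)
            alt_ll = _grid_max(ll_m) + _grid_max(ll_t)
            best_null = np.maximum(best_null, null_ll)
            best_alt = np.maximum(best_alt, alt_ll)
        lrt[idx] = np.clip(2.0 * (best_alt - best_null), 0.0, None)

    p = stats.chi2.sf(lrt, df=1)
    return pd.DataFrame(
        {
            "chrom": t.chrom.astype(str),
            "pos": t.pos,
            "m_mock": m_mock,
            "m_treated": m_trt,
            "meth_diff": m_trt - m_mock,
            "p_value": p,
            "tested": tested,
        }
    )


def flag_dm_sites(results: pd.DataFrame, site_alpha: float = 0.05) -> pd.DataFrame:
    """BH-adjust site p-values and flag DM sites at ``site_alpha``."""
    out = results.copy()
    out["adj_p"] = bh_adjust(out["p_value"].to_numpy())
    out["is_dm"] = (out["adj_p"] < site_alpha).fillna(False)
    return out


def merge_dm_sites(results: pd.DataFrame, merge_gap: int = 100) -> list[DMRCandidate]:
    """Chain DM sites closer than ``merge_gap`` bp into DMR candidates.

    Distance is site-to-site ("less than" is strict: sites exactly
    ``merge_gap`` apart start a new candidate). The candidate interval
    spans first to last member DM site (end exclusive = last pos + 1);
    non-DM sites inside the span are recorded as members but do not break
    the chain.
    """
    cands: list[DMRCandidate] = []
    res = results.reset_index(drop=True)
    for chrom in res["chrom"].unique():
        sub = res[res["chrom"] == chrom].sort_values("pos")
        dm = sub[sub["is_dm"]]
        if dm.empty:
            continue
        runs: list[list[int]] = [[dm.index[0]]]
        prev = int(dm["pos"].iloc[0])
        for i, pos in zip(dm.index[1:], dm["pos"].iloc[1:]):
            if int(pos) - prev < merge_gap:
                runs[-1].append(i)
            else:
                runs.append([i])
            prev = int(pos)
        for run in runs:
            lo = int(res["pos"][run[0]])
            hi = int(res["pos"][run[-1]]) + 1
            members = sub.index[(sub["pos"] >= lo) & (sub["pos"] < hi)].to_numpy()
            diffs = res["meth_diff"][run].to_numpy()
            cands.append(
                DMRCandidate(
                    Interval(chrom, lo, hi),
                    members,
                    len(run),
                    float(np.mean(diffs)),
                )
            )
    cands.sort(key=lambda c: (c.interval.chrom, c.interval.start))
    return cands


def filter_candidates(
    cands: list[DMRCandidate],
    results: pd.DataFrame,
    min_dm_sites: int = 6,
    min_mean_diff: float = 0.2,
    sign_consistency: float = 0.8,
) -> list[RegionCall]:
    """Retain candidates with >= ``min_dm_sites`` DM CpGs whose absolute
    signed mean methylation difference exceeds ``min_mean_diff``.

    A sign-consistency guard additionally requires that at least
    ``sign_consistency`` of DM member sites share the majority sign
    (set to 0 for the strict merge-and-filter rule only). Region p/FDR
    are the minimum over DM member sites.
    """
    res = results.reset_index(drop=True)
    calls: list[RegionCall] = []
    for c in cands:
        if c.n_dm_sites < min_dm_sites:
            continue
        if abs(c.mean_meth_diff) <= min_mean_diff:
            continue
        members = res.loc[c.site_index]
        dm = members[members["is_dm"]]
        signs = np.sign(dm["meth_diff"].to_numpy())
        majority = max((signs > 0).mean(), (signs < 0).mean())
        if majority < sign_consistency:
            continue
        direction = "hyper" if c.mean_meth_diff > 0 else "hypo"
        calls.append(
            RegionCall(
                c.interval,
                direction,
                float(c.mean_meth_diff),
                float(dm["p_value"].min()),
                float(dm["adj_p"].min()),
                n_dm_sites=c.n_dm_sites,
                mean_meth_diff=float(c.mean_meth_diff),
            )
        )
    return calls


def call_dmrs(
    t: CpGSiteTable,
    min_total: int = 10,
    site_alpha: float = 0.05,
    merge_gap: int = 100,
    min_dm_sites: int = 6,
    min_mean_diff: float = 0.2,
    sign_consistency: float = 0.8,
) -> tuple[list[RegionCall], pd.DataFrame]:
    """Full DMR pipeline: site test -> BH flagging -> merge -> filter."""
    res = flag_dm_sites(site_test(t, min_total=min_total), site_alpha=site_alpha)
    cands = merge_dm_sites(res, merge_gap=merge_gap)
    calls = filter_candidates(
        cands, res, min_dm_sites=min_dm_sites, min_mean_diff=min_mean_diff,
        sign_consistency=sign_consistency,
    )
    return calls, res
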