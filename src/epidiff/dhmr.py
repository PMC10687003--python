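"""Differential 5hmC calling on binned read counts.

The differential engine follows the quantile-adjusted conditional maximum
likelihood (qCML) approach for small-replicate count data: counts are
quantile-adjusted to a common (geometric-mean) library size, a single
common negative-binomial dispersion is estimated by maximizing the
conditional log-likelihood given per-group bin totals, and each bin is
tested with a two-sided exact test on the adjusted group sums conditional
on their total. At dispersion zero the conditional distribution is
binomial, so the test reduces to the conditional binomial exact test.

This is a deliberately simplified qCML: common dispersion only, no
tagwise/trended shrinkage, and a normal quantile-matching approximation
for the library-size adjustment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats
from scipy.special import gammaln

from .genome import BinCountMatrix, Interval, RegionCall
from .stats import bh_adjust

log = logging.getLogger(__name__)

MOCK, TREATED = "mock", "treated"
_PHI_BINOMIAL = 1e-10  # below this, use the exact binomial branch


@dataclass
class NormalizedDensity:
    """Counts-per-million per (bin, sample), with group labels."""

    bins: list[Interval]
    cpm: np.ndarray  # (n_bins, n_samples)
    sample_ids: list[str]
    group: np.ndarray
    width: int

    def group_mean(self, label: str) -> np.ndarray:
        idx = np.flatnonzero(self.group == label)
        if idx.size == 0:
            raise KeyError(f"no samples in group {label!r}")
        return self.cpm[:, idx].mean(axis=1)


@dataclass
class DispersionEstimate:
    common_dispersion: float
    pseudo_library_size: float


@dataclass
class BinTestResult:
    """Per-bin exact-test output aligned with the input bin order."""

    bins: list[Interval]
    p_value: np.ndarray
    log_fc: np.ndarray
    tested: np.ndarray  # bool mask (clipped terminal bins are excluded)


def normalize_cpm(m: BinCountMatrix) -> NormalizedDensity:
    """density(b, j) = counts(b, j) * 1e6 / library_size(j)."""
    if (m.library_sizes <= 0).any():
        raise ValueError("zero or negative library size")
    cpm = m.counts * 1e6 / m.library_sizes[None, :]
    return NormalizedDensity(m.bins, cpm, m.sample_ids, m.group, m.width)


def _equalize_counts(counts: np.ndarray, libs: np.ndarray, phi: float) -> tuple[np.ndarray, float]:
    """Quantile-adjust counts to the geometric-mean library size.

    Normal quantile matching under NB(mu, phi): an observation at z standard
    deviations from its library-specific mean is mapped to the same z under
    the common library size. Means are preserved exactly; adjusted counts
    are clipped at zero.
    """
    libs = np.asarray(libs, dtype=float)
    n_star = float(np.exp(np.mean(np.log(libs))))
    lam = counts.sum(axis=1, keepdims=True) / libs.sum()  # per-read rate per bin
    mu_in = lam * libs[None, :]
    mu_out = lam * n_star
    v_in = mu_in + phi * mu_in**2
    v_out = mu_out + phi * mu_out**2
    with np.errstate(invalid="ignore", divide="ignore"):
        scale = np.sqrt(np.where(v_in > 0, v_out / np.where(v_in > 0, v_in, 1.0), 0.0))
    adj = mu_out + (counts - mu_in) * scale
    return np.clip(adj, 0.0, None), n_star


def _cml_loglik(phi: float, y_by_group: list[np.ndarray]) -> float:
    """Conditional NB log-likelihood (common dispersion), summed over bins
    and groups, up to terms independent of phi."""
    r = 1.0 / phi
    ll = 0.0
    for y in y_by_group:
        n = y.shape[1]
        z = y.sum(axis=1)
        ll += float(
            gammaln(y + r).sum()
            - y.shape[0] * n * gammaln(r)
            + y.shape[0] * gammaln(n * r)
            - gammaln(z + n * r).sum()
        )
    return ll


def estimate_common_dispersion(m: BinCountMatrix, n_iter: int = 3) -> DispersionEstimate:
    """Estimate the common NB dispersion by qCML.

    Counts are equalized to the geometric-mean library size (iterating the
    adjustment with the current dispersion estimate), then the dispersion
    maximizing the summed conditional log-likelihood given per-group bin
    totals is found by bounded scalar optimization on delta = phi/(1+phi).
    """
    groups = m.groups
    if len(groups) != 2:
        raise ValueError("exactly two groups required")
    for g in groups:
        if m.group_idx(g).size < 2:
            raise ValueError(f"need >= 2 samples in group {g!r}")
    mask = m.testable_bins()
    counts = m.counts[mask].astype(float)
    if counts.sum() == 0:
        log.warning("all-zero count matrix; dispersion set to 0")
        return DispersionEstimate(0.0, float(np.exp(np.mean(np.log(m.library_sizes)))))
    phi = 0.0
    n_star = float(np.exp(np.mean(np.log(m.library_sizes))))
    for _ in range(n_iter):
        adj, n_star = _equalize_counts(counts, m.library_sizes, phi)
        y_by_group = [adj[:, m.group_idx(g)] for g in groups]

        def neg_ll(delta: float) -> float:
            return -_cml_loglik(delta / (1.0 - delta), y_by_group)

        res = optimize.minimize_scalar(
            neg_ll, bounds=(1e-6, 0.95), method="bounded",
            options={"xatol": 1e-7},
        )
        delta = float(res.x)
        phi = delta / (1.0 - delta)
        # boundary at the low end means no extra-Poisson variation
        if -res.fun <= -neg_ll(1e-6) + 1e-9 and delta < 2e-6:
            phi = 0.0
            break
    return DispersionEstimate(float(phi), n_star)


def _binom_logpmf(y: np.ndarray, t: np.ndarray, q: float) -> np.ndarray:
    return (
        gammaln(t + 1) - gammaln(y + 1) - gammaln(t - y + 1)
        + y * np.log(q) + (t - y) * np.log1p(-q)
    )


def _nb_logpmf_mean(y: np.ndarray, r: float, mean: np.ndarray) -> np.ndarray:
    return (
        gammaln(y + r) - gammaln(r) - gammaln(y + 1)
        + r * np.log(r / (r + mean)) + y * np.log(mean / (r + mean))
    )


def bin_exact_test(
    m: BinCountMatrix,
    d: DispersionEstimate,
    pseudo_count: float = 0.5,
    batch_elems: int = 2_000_000,
) -> BinTestResult:
    """Two-sided exact NB test per bin on adjusted group sums.

    Conditional on the total of the two adjusted group sums, the first
    group's sum follows a negative-binomial convolution law (binomial at
    dispersion 0). The two-sided p doubles the smaller tail, capped at 1.
    log_fc is log2 of the mean-adjusted-count ratio with a pseudo-count
    (applied to fold change only, never to the test).
    """
    groups = m.groups
    if len(groups) != 2:
        raise ValueError("exactly two groups required")
    g_mock = MOCK if MOCK in groups else groups[0]
    g_trt = TREATED if TREATED in groups else [g for g in groups if g != g_mock][0]
    i1, i2 = m.group_idx(g_trt), m.group_idx(g_mock)
    n1, n2 = len(i1), len(i2)
    phi = d.common_dispersion

    adj, _ = _equalize_counts(m.counts.astype(float), m.library_sizes, phi)
    s1 = np.rint(adj[:, i1].sum(axis=1)).astype(np.int64)
    s2 = np.rint(adj[:, i2].sum(axis=1)).astype(np.int64)
    t = s1 + s2

    nb = m.n_bins
    p = np.ones(nb)
    log_fc = np.log2((adj[:, i1].mean(axis=1) + pseudo_count) /
                     (adj[:, i2].mean(axis=1) + pseudo_count))
    log_fc[t == 0] = 0.0
    tested = m.testable_bins()

    todo = np.flatnonzero(tested & (t > 0))
    # process in batches of enumeration elements to bound memory
    order = todo[np.argsort(t[todo], kind="mergesort")]
    start = 0
    while start < len(order):
        stop = start
        acc = 0
        while stop < len(order) and (acc == 0 or acc + t[order[stop]] + 1 <= batch_elems):
            acc += t[order[stop]] + 1
            stop += 1
        idx = order[start:stop]
        p[idx] = _exact_pvals(s1[idx], t[idx], n1, n2, phi)
        start = stop
    return BinTestResult(m.bins, p, log_fc, tested)


def _exact_pvals(s1: np.ndarray, t: np.ndarray, n1: int, n2: int, phi: float) -> np.ndarray:
    """Vectorized segmented enumeration of the conditional exact test."""
    lens = t + 1
    offs = np.concatenate([[0], np.cumsum(lens)])
    seg = np.repeat(np.arange(len(t)), lens)
    y = np.arange(offs[-1]) - np.repeat(offs[:-1], lens)
    tt = t[seg].astype(float)
    if phi < _PHI_BINOMIAL:
        q = n1 / (n1 + n2)
        logp = _binom_logpmf(y.astype(float), tt, q)
    else:
        mu = tt / (n1 + n2)  # per-sample mean under the null
        r1, r2 = n1 / phi, n2 / phi
        m1 = np.maximum(n1 * mu, 1e-300)
        m2 = np.maximum(n2 * mu, 1e-300)
        logp = _nb_logpmf_mean(y.astype(float), r1, m1) + _nb_logpmf_mean(
            (tt - y).astype(float), r2, m2
        )
    # per-segment normalization via logsumexp
    seg_max = np.full(len(t), -np.inf)
    np.maximum.at(seg_max, seg, logp)
    probs = np.exp(logp - seg_max[seg])
    seg_sum = np.zeros(len(t))
    np.add.at(seg_sum, seg, probs)
    probs /= seg_sum[seg]
    cum = np.cumsum(probs)
    lo_idx = offs[:-1] + s1  # flat index of the observed value
    p_low = cum[lo_idx] - np.where(offs[:-1] > 0, cum[offs[:-1] - 1], 0.0)
    # tail >= observed: total (==1 per segment) minus P(Y < obs)
    p_below = np.where(s1 > 0, cum[lo_idx - 1] - np.where(offs[:-1] > 0, cum[offs[:-1] - 1], 0.0), 0.0)
    p_high = 1.0 - p_below
    return np.minimum(1.0, 2.0 * np.minimum(p_low, p_high))


def call_dhmrs(
    result: BinTestResult,
    fdr_threshold: float = 0.05,
    merge_adjacent: bool = True,
) -> list[RegionCall]:
    """BH-adjust per-bin p-values and emit significant bins as region calls.

    Adjacent significant bins (contiguous coordinates, same chromosome and
    direction) are merged into one region whose p/FDR are the member
    minimum and whose log_fc is taken from the most significant bin.
    ``merge_adjacent=False`` reports each significant bin as its own region.
    """
    fdr = bh_adjust(np.where(result.tested, result.p_value, np.nan))
    sig = np.flatnonzero(result.tested & (fdr < fdr_threshold) & (result.log_fc != 0))
    calls: list[RegionCall] = []
    run: list[int] = []

    def flush(run: list[int]) -> None:
        if not run:
            return
        best = min(run, key=lambda i: (result.p_value[i], i))
        lfc = float(result.log_fc[best])
        calls.append(
            RegionCall(
                Interval(result.bins[run[0]].chrom, result.bins[run[0]].start,
                         result.bins[run[-1]].end),
                "gain" if lfc > 0 else "loss",
                lfc,
                float(min(result.p_value[i] for i in run)),
                float(min(fdr[i] for i in run)),
            )
        )

    for i in sig:
        if (
            merge_adjacent
            and run
            and result.bins[i].chrom == result.bins[run[-1]].chrom
            and result.bins[i].start == result.bins[run[-1]].end
            and (result.log_fc[i] > 0) == (result.log_fc[run[-1]] > 0)
        ):
            run.append(i)
        else:
            flush(run)
            run = [i]
    flush(run)
    return calls


def global_regression(nd: NormalizedDensity) -> dict:
    """OLS of treated group-mean density on mock group-mean density over bins."""
    x = nd.group_mean(MOCK)
    y = nd.group_mean(TREATED)
    if len(x) < 3:
        raise ValueError("need >= 3 bins")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in mock densities")
    res = stats.linregress(x, y)
    return {
        "slope": float(res.slope),
        "intercept": float(res.intercept),
        "pearson_r": float(res.rvalue),
        "p_value": float(res.pvalue),
    }


@dataclass
class MetaProfile:
    positions: np.ndarray  # relative coordinates in [0, 1)
    profile: dict[str, np.ndarray]  # group -> mean density per position
    region_means: dict[str, np.ndarray]  # group -> per-region mean density
    fold_change: float  # treated / mock of region-set means
    t_stat: float
    p_value: float


def meta_profile(nd: NormalizedDensity, regions, n_points: int = 100) -> MetaProfile:
    """Length-normalized average density profile over a region set.

    Each region is sampled at ``n_points`` relative positions (strand-aware:
    minus-strand regions are flipped), each position reading the density of
    the bin containing it. Also returns per-region mean densities per group
    and a two-sided unpaired t-test between the groups' per-region means.
    """
    regions = list(regions)
    if not regions:
        raise ValueError("empty region set")
    width = nd.width
    # per-chromosome group-mean density arrays
    chrom_bins: dict[str, tuple[int, int]] = {}
    for i, b in enumerate(nd.bins):
        if b.chrom not in chrom_bins:
            chrom_bins[b.chrom] = (i, i + 1)
        else:
            s, _ = chrom_bins[b.chrom]
            chrom_bins[b.chrom] = (s, i + 1)
    means = {g: nd.group_mean(g) for g in (MOCK, TREATED)}
    prof = {g: np.zeros(n_points) for g in means}
    reg_means = {g: np.zeros(len(regions)) for g in means}
    rel = (np.arange(n_points) + 0.5) / n_points
    for ri, region in enumerate(regions):
        iv = region.interval if hasattr(region, "interval") else region
        lo, hi = chrom_bins[iv.chrom]
        pos = iv.start + rel * iv.width
        if iv.strand == "-":
            pos = pos[::-1]
        k = np.clip(lo + (pos // width).astype(int), lo, hi - 1)
        for g in means:
            vals = means[g][k]
            prof[g] += vals
            reg_means[g][ri] = vals.mean()
    for g in prof:
        prof[g] /= len(regions)
    mt, mm = reg_means[TREATED].mean(), reg_means[MOCK].mean()
    fold = float(mt / mm) if mm > 0 else float("nan")
    tres = stats.ttest_ind(reg_means[TREATED], reg_means[MOCK], equal_var=False)
    return MetaProfile(rel, prof, reg_means, fold, float(tres.statistic), float(tres.pvalue))
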