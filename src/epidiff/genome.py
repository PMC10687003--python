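"""Core genomic domain types: layouts, intervals, gene models, bin matrices.

All coordinates are 0-based half-open ([start, end)) throughout the package;
any 1-based input is converted at the reader boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

log = logging.getLogger(__name__)

STRANDS = {"+", "-", "."}


@dataclass(frozen=True)
class GenomeLayout:
    """Ordered chromosome names and lengths (bp).

    The ordering is stable and defines the sort order of every interval
    container in the package.
    """

    chrom_names: tuple[str, ...]
    chrom_lengths: tuple[int, ...]

    def __post_init__(self):
        if len(self.chrom_names) != len(self.chrom_lengths):
            raise ValueError("chrom_names and chrom_lengths differ in length")
        if len(set(self.chrom_names)) != len(self.chrom_names):
            raise ValueError("duplicate chromosome names")
        for L in self.chrom_lengths:
            if int(L) < 1:
                raise ValueError(f"chromosome length must be >= 1, got {L}")

    @property
    def lengths(self) -> dict[str, int]:
        return dict(zip(self.chrom_names, self.chrom_lengths))

    def length_of(self, chrom: str) -> int:
        try:
            return self.chrom_lengths[self.chrom_names.index(chrom)]
        except ValueError:
            raise KeyError(f"unknown chromosome {chrom!r}")

    def chrom_rank(self, chrom: str) -> int:
        return self.chrom_names.index(chrom)

    @property
    def total_length(self) -> int:
        return int(sum(self.chrom_lengths))


@dataclass(frozen=True)
class Interval:
    """Genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    label: str | None = None

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def width(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "Interval") -> bool:
        return self.chrom == other.chrom and self.start < other.end and other.start < self.end

    def overlap_len(self, other: "Interval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def validate_against(self, layout: GenomeLayout) -> "Interval":
        if self.chrom not in layout.chrom_names:
            raise ValueError(f"interval on unknown chromosome {self.chrom!r}")
        if self.end > layout.length_of(self.chrom):
            raise ValueError(
                f"interval {self.chrom}:{self.start}-{self.end} exceeds "
                f"chromosome length {layout.length_of(self.chrom)}"
            )
        return self


@dataclass
class GeneModel:
    """Gene with strandful body interval and optional substructure.

    ``utr5``/``utr3`` are optional annotations used by the feature
    annotator; exons (if present) must be non-overlapping and lie within
    the gene body.
    """

    gene_id: str
    interval: Interval
    is_ieg: bool = False
    exons: list[Interval] | None = None
    utr5: Interval | None = None
    utr3: Interval | None = None

    def __post_init__(self):
        if self.interval.strand not in {"+", "-"}:
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")
        if self.exons:
            self.exons = sorted(self.exons, key=lambda e: e.start)
            prev_end = self.interval.start - 1
            for e in self.exons:
                if e.start < self.interval.start or e.end > self.interval.end:
                    raise ValueError(f"gene {self.gene_id}: exon outside gene body")
                if e.start < prev_end:
                    raise ValueError(f"gene {self.gene_id}: overlapping exons")
                prev_end = e.end

    @property
    def tss(self) -> int:
        return self.interval.start if self.interval.strand == "+" else self.interval.end

    @property
    def tes(self) -> int:
        return self.interval.end if self.interval.strand == "+" else self.interval.start


@dataclass
class RegionCall:
    """A called differential region (DhMR or DMR)."""

    interval: Interval
    direction: str  # gain/loss (5hmC) or hyper/hypo (5mC)
    log_fc: float
    p_value: float
    fdr: float
    n_dm_sites: int | None = None
    mean_meth_diff: float | None = None

    def __post_init__(self):
        if self.direction not in {"gain", "loss", "hyper", "hypo"}:
            raise ValueError(f"invalid direction {self.direction!r}")
        positive = self.direction in {"gain", "hyper"}
        if self.log_fc != 0 and (self.log_fc > 0) != positive:
            raise ValueError(
                f"direction {self.direction} inconsistent with log_fc {self.log_fc}"
            )


@dataclass
class BinCountMatrix:
    """Uniform genome bins x samples of integer read counts.

    ``library_sizes`` are total mapped reads per sample and are always at
    least the column sums. Clipped terminal bins shorter than width/2 are
    excluded from differential testing via ``testable_bins``.
    """

    bins: list[Interval]
    counts: np.ndarray  # (n_bins, n_samples), int
    sample_ids: list[str]
    group: np.ndarray  # (n_samples,), str labels
    library_sizes: np.ndarray  # (n_samples,), int
    width: int

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        self.group = np.asarray(self.group, dtype=object)
        self.library_sizes = np.asarray(self.library_sizes)
        n_bins, n_samples = self.counts.shape
        if n_bins != len(self.bins) or n_samples != len(self.sample_ids):
            raise ValueError("counts dimensions inconsistent with bins/samples")
        if (self.counts < 0).any():
            raise ValueError("negative counts")
        if (self.library_sizes < self.counts.sum(axis=0)).any():
            raise ValueError("library sizes smaller than column sums")

    @property
    def n_bins(self) -> int:
        return len(self.bins)

    def group_idx(self, label: str) -> np.ndarray:
        idx = np.flatnonzero(self.group == label)
        if idx.size == 0:
            raise KeyError(f"no samples in group {label!r}")
        return idx

    @property
    def groups(self) -> list[str]:
        seen: list[str] = []
        for g in self.group:
            if g not in seen:
                seen.append(g)
        return seen

    def testable_bins(self) -> np.ndarray:
        """Boolean mask excluding clipped terminal bins shorter than width/2."""
        w = np.array([b.width for b in self.bins])
        return w >= self.width / 2


@dataclass
class CpGSiteTable:
    """Per-CpG (methylated, total) counts per sample, sorted by position."""

    chrom: np.ndarray  # (n_sites,), str
    pos: np.ndarray  # (n_sites,), int
    meth: np.ndarray  # (n_sites, n_samples)
    total: np.ndarray  # (n_sites, n_samples)
    sample_ids: list[str]
    group: np.ndarray

    def __post_init__(self):
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos)
        self.meth = np.asarray(self.meth)
        self.total = np.asarray(self.total)
        self.group = np.asarray(self.group, dtype=object)
        if self.meth.shape != self.total.shape:
            raise ValueError("meth/total shape mismatch")
        if (self.meth > self.total).any():
            raise ValueError("meth count exceeds total count")
        if (self.meth < 0).any() or (self.total < 0).any():
            raise ValueError("negative counts")
        # sorted, unique per chromosome
        for c in np.unique(self.chrom.astype(str)):
            p = self.pos[self.chrom == c]
            if np.any(np.diff(p) <= 0):
                raise ValueError(f"sites not sorted/unique on {c}")

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    def group_idx(self, label: str) -> np.ndarray:
        idx = np.flatnonzero(self.group == label)
        if idx.size == 0:
            raise KeyError(f"no samples in group {label!r}")
        return idx

    def level(self, site: int, sample: int) -> float:
        t = self.total[site, sample]
        return float(self.meth[site, sample] / t) if t > 0 else float("nan")


def make_genome_bins(layout: GenomeLayout, width: int) -> list[Interval]:
    """Tile each chromosome with consecutive ``width``-bp bins.

    The terminal bin is clipped to the chromosome length, so bins tile each
    chromosome exactly (no gaps, no overlaps).
    """
    if width <= 0:
        raise ValueError(f"bin width must be >= 1, got {width}")
    bins = []
    for chrom, L in zip(layout.chrom_names, layout.chrom_lengths):
        for s in range(0, L, width):
            bins.append(Interval(chrom, s, min(s + width, L)))
    return bins


def _bin_offsets(layout: GenomeLayout, width: int) -> dict[str, tuple[int, int]]:
    """chrom -> (first bin index, number of bins)."""
    out = {}
    off = 0
    for chrom, L in zip(layout.chrom_names, layout.chrom_lengths):
        n = -(-L // width)
        out[chrom] = (off, n)
        off += n
    return out


def count_reads_in_bins(
    reads_by_sample: dict[str, list[Interval]],
    bins: list[Interval],
    layout: GenomeLayout,
    width: int,
    group_of: dict[str, str],
    library_sizes: dict[str, int] | None = None,
) -> BinCountMatrix:
    """Assign each read to the single bin containing its fragment midpoint.

    Reads on chromosomes absent from ``layout`` are skipped with a logged
    count, so total counted + total skipped equals total input reads.
    Library sizes default to the per-sample total input read count.
    """
    offsets = _bin_offsets(layout, width)
    sample_ids = list(reads_by_sample)
    counts = np.zeros((len(bins), len(sample_ids)), dtype=np.int64)
    libs = np.zeros(len(sample_ids), dtype=np.int64)
    for j, sid in enumerate(sample_ids):
        reads = reads_by_sample[sid]
        skipped = 0
        for r in reads:
            loc = offsets.get(r.chrom)
            if loc is None:
                skipped += 1
                continue
            off, n = loc
            k = min(r.midpoint // width, n - 1)
            counts[k + off, j] += 1
        if skipped:
            log.warning("sample %s: skipped %d reads on unknown chromosomes", sid, skipped)
        libs[j] = len(reads) if library_sizes is None else library_sizes[sid]
    group = np.array([group_of[s] for s in sample_ids], dtype=object)
    return BinCountMatrix(bins, counts, sample_ids, group, libs, width)
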