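"""Genomic-feature annotation of region calls and enrichment testing.

Regions are assigned exactly one primary feature at their midpoint, by a
fixed precedence (promoter > 5'UTR > exon > 3'UTR > TTS > intron >
intergenic). CpG-island and repeat overlap are orthogonal any-overlap
flags. Feature and chromatin-state enrichment use two-sided Fisher's
exact tests of a query region set against a background set, BH-adjusted.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genome import GeneModel, Interval, RegionCall
from .stats import bh_adjust

FEATURES = ["promoter", "5'UTR", "exon", "3'UTR", "TTS", "intron", "intergenic"]

PROMOTER_UP = 2000  # bp upstream of TSS
PROMOTER_DOWN = 500  # bp downstream of TSS
TTS_DOWN = 500  # bp downstream of TES


@dataclass
class FeatureAssignment:
    region: Interval
    feature: str
    gene_id: str | None = None
    cgi_overlap: bool = False
    repeat_class: str | None = None


class _IntervalIndex:
    """Sorted-start interval lookup per chromosome (intervals may overlap)."""

    def __init__(self, intervals: list[Interval]):
        self._by_chrom: dict[str, tuple[list[int], list[Interval]]] = {}
        for iv in intervals:
            self._by_chrom.setdefault(iv.chrom, ([], []))
        for iv in sorted(intervals, key=lambda v: v.start):
            starts, ivs = self._by_chrom[iv.chrom]
            starts.append(iv.start)
            ivs.append(iv)
        self._max_width = {
            c: max((iv.width for iv in ivs), default=0)
            for c, (_, ivs) in self._by_chrom.items()
        }

    def overlapping(self, chrom: str, start: int, end: int) -> list[Interval]:
        entry = self._by_chrom.get(chrom)
        if entry is None:
            return []
        starts, ivs = entry
        lo = bisect_right(starts, start - self._max_width[chrom])
        hi = bisect_right(starts, end - 1)  # first start >= end
        return [iv for iv in ivs[lo:hi] if iv.end > start]

    def containing(self, chrom: str, pos: int) -> list[Interval]:
        return self.overlapping(chrom, pos, pos + 1)


def _promoter_window(g: GeneModel) -> tuple[int, int]:
    if g.interval.strand == "+":
        return g.tss - PROMOTER_UP, g.tss + PROMOTER_DOWN
    return g.tss - PROMOTER_DOWN, g.tss + PROMOTER_UP


def _tts_window(g: GeneModel) -> tuple[int, int]:
    if g.interval.strand == "+":
        return g.tes, g.tes + TTS_DOWN
    return g.tes - TTS_DOWN, g.tes


def annotate_regions(
    regions,
    genes: list[GeneModel],
    cgi: list[Interval] | None = None,
    repeats: list[Interval] | None = None,
) -> list[FeatureAssignment]:
    """Assign each region exactly one primary feature at its midpoint.

    Repeat intervals carry their class in ``label``; when a midpoint's
    region overlaps several repeats, the first by coordinate is reported.
    """
    gene_ix = _IntervalIndex([g.interval for g in genes])
    by_span = {}
    for g in genes:
        by_span.setdefault((g.interval.chrom, g.interval.start, g.interval.end), []).append(g)
    prom_ix = _IntervalIndex(
        [Interval(g.interval.chrom, max(0, _promoter_window(g)[0]),
                  max(1, _promoter_window(g)[1]), label=g.gene_id) for g in genes]
    )
    tts_ix = _IntervalIndex(
        [Interval(g.interval.chrom, max(0, _tts_window(g)[0]),
                  max(1, _tts_window(g)[1]), label=g.gene_id) for g in genes]
    )
    cgi_ix = _IntervalIndex(cgi or [])
    rep_ix = _IntervalIndex(repeats or [])

    out: list[FeatureAssignment] = []
    for region in regions:
        iv = region.interval if isinstance(region, RegionCall) else region
        mid = iv.midpoint
        feature, gene_id = "intergenic", None
        proms = prom_ix.containing(iv.chrom, mid)
        if proms:
            feature, gene_id = "promoter", proms[0].label
        else:
            host_spans = gene_ix.containing(iv.chrom, mid)
            hosts = [g for sp in host_spans for g in by_span[(sp.chrom, sp.start, sp.end)]]
            chosen = None
            for g in hosts:
                if g.utr5 and g.utr5.start <= mid < g.utr5.end:
                    chosen, feature = g, "5'UTR"
                    break
            if chosen is None:
                for g in hosts:
                    if any(e.start <= mid < e.end for e in (g.exons or [])):
                        chosen, feature = g, "exon"
                        break
            if chosen is None:
                for g in hosts:
                    if g.utr3 and g.utr3.start <= mid < g.utr3.end:
                        chosen, feature = g, "3'UTR"
                        break
            if chosen is None:
                tts = tts_ix.containing(iv.chrom, mid)
                if tts:
                    feature, gene_id = "TTS", tts[0].label
                elif hosts:
                    chosen, feature = hosts[0], "intron"
            if chosen is not None:
                gene_id = chosen.gene_id
        reps = rep_ix.overlapping(iv.chrom, iv.start, iv.end)
        out.append(
            FeatureAssignment(
                iv,
                feature,
                gene_id,
                cgi_overlap=bool(cgi_ix.overlapping(iv.chrom, iv.start, iv.end)),
                repeat_class=reps[0].label if reps else None,
            )
        )
    return out


def state_enrichment(
    query: list[Interval],
    background: list[Interval],
    states: list[Interval],
) -> pd.DataFrame:
    """Per-state Fisher's exact enrichment of query vs background regions.

    For each state label, the 2x2 table is (query, background) x
    (overlaps state, does not); p-values are two-sided Fisher exact,
    BH-adjusted across states. States never overlapped by either set get
    odds_ratio NA.
    """
    if not query:
        raise ValueError("empty query region set")
    if not background:
        raise ValueError("empty background region set")
    labels = sorted({s.label for s in states if s.label})
    ix_by_label = {
        lab: _IntervalIndex([s for s in states if s.label == lab]) for lab in labels
    }
    rows = []
    for lab in labels:
        ix = ix_by_label[lab]
        q_hit = sum(bool(ix.overlapping(r.chrom, r.start, r.end)) for r in query)
        b_hit = sum(bool(ix.overlapping(r.chrom, r.start, r.end)) for r in background)
        table = [[q_hit, len(query) - q_hit], [b_hit, len(background) - b_hit]]
        if q_hit + b_hit == 0:
            rows.append({"state": lab, "n_query": 0, "n_background": 0,
                         "odds_ratio": np.nan, "p_value": 1.0})
            continue
        odds, p = stats.fisher_exact(table, alternative="two-sided")
        rows.append({"state": lab, "n_query": q_hit, "n_background": b_hit,
                     "odds_ratio": float(odds), "p_value": float(p)})
    df = pd.DataFrame(rows)
    df["adj_p"] = bh_adjust(df["p_value"].to_numpy())
    return df


def repeat_gain_fraction(
    dhmrs: list[RegionCall], repeats: list[Interval]
) -> dict:
    """Among repeat elements overlapping any DhMR, the fraction whose calls
    are gain-of-5hmC (per class and overall).

    Elements overlapped by calls of both directions are counted by the
    majority of overlap length (ties count as gain, logged implicitly by
    the 0.5 threshold being inclusive).
    """
    call_ix = _IntervalIndex([c.interval for c in dhmrs])
    dir_by_span = {
        (c.interval.chrom, c.interval.start, c.interval.end): c.direction for c in dhmrs
    }
    per_class: dict[str, list[int]] = {}
    overall = []
    for rep in repeats:
        hits = call_ix.overlapping(rep.chrom, rep.start, rep.end)
        if not hits:
            continue
        gain_len = sum(
            rep.overlap_len(h)
            for h in hits
            if dir_by_span[(h.chrom, h.start, h.end)] == "gain"
        )
        total_len = sum(rep.overlap_len(h) for h in hits)
        is_gain = int(gain_len * 2 >= total_len)
        overall.append(is_gain)
        per_class.setdefault(rep.label or "other", []).append(is_gain)
    result = {
        "overall": float(np.mean(overall)) if overall else float("nan"),
        "n_elements": len(overall),
        "per_class": {
            k: {"fraction_gain": float(np.mean(v)), "n": len(v)}
            for k, v in sorted(per_class.items())
        },
    }
    return result


def crosstab_repeat_expression(
    repeat_calls: pd.DataFrame,
    repeat_expression: pd.DataFrame,
    lfc_threshold: float = 0.15,
) -> pd.DataFrame:
    """Expression-change categories for gain-of-5hmC repeat elements.

    ``repeat_calls`` has columns element_id, direction; ``repeat_expression``
    has element_id, log2_fc. Elements without expression go to an
    'unmeasured' bucket. Categories: up (log2_fc >= threshold), down
    (<= -threshold), unchanged otherwise.
    """
    gain = repeat_calls[repeat_calls["direction"] == "gain"]
    expr = repeat_expression.set_index("element_id")["log2_fc"]
    counts = {"up": 0, "down": 0, "unchanged": 0, "unmeasured": 0}
    for eid in gain["element_id"]:
        if eid not in expr.index:
            counts["unmeasured"] += 1
        else:
            lfc = float(expr.loc[eid])
            if lfc >= lfc_threshold:
                counts["up"] += 1
            elif lfc <= -lfc_threshold:
                counts["down"] += 1
            else:
                counts["unchanged"] += 1
    total = sum(counts.values())
    return pd.DataFrame(
        {
            "category": list(counts),
            "count": list(counts.values()),
            "fraction": [c / total if total else np.nan for c in counts.values()],
        }
    )
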