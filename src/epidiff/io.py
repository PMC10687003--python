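"""Readers and writers for every external format the pipeline touches.

Formats: BED3/BED6 (annotations, region calls), bedGraph (normalized
density export), headered TSV (site tables, count matrices, expression
tables, sample sheets, gene tables, cell matrices) and plain-text gene
lists. All output is tab-separated with deterministic row order (layout
chromosome order, then start).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .genome import (
    BinCountMatrix,
    CpGSiteTable,
    GeneModel,
    GenomeLayout,
    Interval,
    RegionCall,
)


class ParseError(ValueError):
    pass


# ---------------------------------------------------------------------------
# layout / sample sheet

def read_layout(path) -> GenomeLayout:
    df = pd.read_csv(path, sep="\t")
    return GenomeLayout(tuple(df["chrom"].astype(str)), tuple(int(x) for x in df["length"]))


def write_layout(path, layout: GenomeLayout) -> None:
    pd.DataFrame({"chrom": layout.chrom_names, "length": layout.chrom_lengths}).to_csv(
        path, sep="\t", index=False
    )


def read_sample_sheet(path) -> pd.DataFrame:
    """TSV with columns sample_id, group, library_size — the single source
    of group labels."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "group": str})
    for col in ("sample_id", "group", "library_size"):
        if col not in df.columns:
            raise ParseError(f"sample sheet missing column {col!r}")
    if df["sample_id"].duplicated().any():
        raise ParseError("duplicate sample_id in sample sheet")
    return df


def write_sample_sheet(path, df: pd.DataFrame) -> None:
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# BED

def read_bed(path, layout: GenomeLayout | None = None) -> list[Interval]:
    """Read BED3/BED6 (0-based half-open). Strand defaults to '.'."""
    out = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 3:
                raise ParseError(f"{path}:{ln}: expected >= 3 BED fields")
            try:
                start, end = int(f[1]), int(f[2])
            except ValueError as e:
                raise ParseError(f"{path}:{ln}: non-integer coordinate") from e
            label = f[3] if len(f) > 3 and f[3] != "." else None
            strand = f[5] if len(f) > 5 else "."
            try:
                iv = Interval(f[0], start, end, strand, label)
            except ValueError as e:
                raise ParseError(f"{path}:{ln}: {e}") from e
            if layout is not None:
                iv.validate_against(layout)
            out.append(iv)
    return out


def write_bed(path, intervals: list[Interval]) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.label or '.'}\t0\t{iv.strand}\n"
            )


def write_bedgraph(path, bins: list[Interval], values: np.ndarray) -> None:
    with open(path, "w") as fh:
        for iv, v in zip(bins, values):
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{v:.6g}\n")


# ---------------------------------------------------------------------------
# region calls (BED6+)

_CALL_COLS = ["chrom", "start", "end", "direction", "score", "strand",
              "log_fc", "p_value", "fdr", "n_dm_sites", "mean_meth_diff"]


def write_region_calls(path, calls: list[RegionCall]) -> None:
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(_CALL_COLS) + "\n")
        for c in calls:
            nd = "" if c.n_dm_sites is None else str(c.n_dm_sites)
            md = "" if c.mean_meth_diff is None else f"{c.mean_meth_diff:.6g}"
            fh.write(
                f"{c.interval.chrom}\t{c.interval.start}\t{c.interval.end}\t"
                f"{c.direction}\t0\t.\t{c.log_fc:.6g}\t{c.p_value:.6g}\t"
                f"{c.fdr:.6g}\t{nd}\t{md}\n"
            )


def read_region_calls(path) -> list[RegionCall]:
    out = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            out.append(
                RegionCall(
                    Interval(f[0], int(f[1]), int(f[2])),
                    f[3],
                    float(f[6]),
                    float(f[7]),
                    float(f[8]),
                    int(f[9]) if len(f) > 9 and f[9] else None,
                    float(f[10]) if len(f) > 10 and f[10] else None,
                )
            )
    return out


# ---------------------------------------------------------------------------
# gene table

def read_gene_table(path) -> list[GeneModel]:
    """BED-like TSV: gene_id, chrom, start, end, strand, is_ieg
    [, exon_starts, exon_ends as comma lists]."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chrom": str})
    genes = []
    for row in df.itertuples(index=False):
        iv = Interval(row.chrom, int(row.start), int(row.end), row.strand)
        exons = None
        if hasattr(row, "exon_starts") and isinstance(row.exon_starts, str) and row.exon_starts:
            ss = [int(x) for x in row.exon_starts.split(",") if x]
            ee = [int(x) for x in row.exon_ends.split(",") if x]
            exons = [Interval(row.chrom, s, e, row.strand) for s, e in zip(ss, ee)]
        genes.append(GeneModel(str(row.gene_id), iv, bool(row.is_ieg), exons))
    return genes


def write_gene_table(path, genes: list[GeneModel]) -> None:
    rows = []
    for g in genes:
        rows.append(
            {
                "gene_id": g.gene_id,
                "chrom": g.interval.chrom,
                "start": g.interval.start,
                "end": g.interval.end,
                "strand": g.interval.strand,
                "is_ieg": int(g.is_ieg),
                "exon_starts": ",".join(str(e.start) for e in g.exons) if g.exons else "",
                "exon_ends": ",".join(str(e.end) for e in g.exons) if g.exons else "",
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# bin count matrix

def write_bin_counts(path, m: BinCountMatrix) -> None:
    df = pd.DataFrame(
        {
            "chrom": [b.chrom for b in m.bins],
            "start": [b.start for b in m.bins],
            "end": [b.end for b in m.bins],
        }
    )
    for j, sid in enumerate(m.sample_ids):
        df[sid] = m.counts[:, j]
    df.to_csv(path, sep="\t", index=False)


def read_bin_counts(path, samples: pd.DataFrame, width: int) -> BinCountMatrix:
    """Read a per-bin count TSV; group labels and library sizes come from
    the sample sheet."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    sample_ids = [c for c in df.columns if c not in ("chrom", "start", "end")]
    sheet = samples.set_index("sample_id")
    missing = [s for s in sample_ids if s not in sheet.index]
    if missing:
        raise ParseError(f"samples {missing} absent from sample sheet")
    bins = [
        Interval(c, int(s), int(e))
        for c, s, e in zip(df["chrom"], df["start"], df["end"])
    ]
    counts = df[sample_ids].to_numpy(dtype=np.int64)
    group = np.array([sheet.loc[s, "group"] for s in sample_ids], dtype=object)
    libs = np.array([sheet.loc[s, "library_size"] for s in sample_ids], dtype=np.int64)
    return BinCountMatrix(bins, counts, sample_ids, group, libs, width)


# ---------------------------------------------------------------------------
# CpG site table

def write_site_table(path, t: CpGSiteTable) -> None:
    df = pd.DataFrame({"chrom": t.chrom.astype(str), "pos": t.pos})
    for j, sid in enumerate(t.sample_ids):
        df[f"meth_{sid}"] = t.meth[:, j]
        df[f"total_{sid}"] = t.total[:, j]
    df.to_csv(path, sep="\t", index=False)


def read_site_table(path, samples: pd.DataFrame) -> CpGSiteTable:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    sample_ids = [c[5:] for c in df.columns if c.startswith("meth_")]
    sheet = samples.set_index("sample_id")
    if df.duplicated(subset=["chrom", "pos"]).any():
        raise ParseError("duplicate CpG site in site table")
    # deterministic sort: chrom (lexical; layout order applied downstream), pos
    df = df.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    meth = df[[f"meth_{s}" for s in sample_ids]].to_numpy(dtype=np.int64)
    total = df[[f"total_{s}" for s in sample_ids]].to_numpy(dtype=np.int64)
    if (meth > total).any():
        bad = int(np.argmax((meth > total).any(axis=1)))
        raise ParseError(f"meth > total at {df['chrom'][bad]}:{df['pos'][bad]}")
    group = np.array([sheet.loc[s, "group"] for s in sample_ids], dtype=object)
    return CpGSiteTable(
        df["chrom"].to_numpy(dtype=object), df["pos"].to_numpy(np.int64),
        meth, total, sample_ids, group,
    )


# ---------------------------------------------------------------------------
# expression table

EXPRESSION_COLS = ["gene_id", "base_mean", "log2_fc", "p_value", "fdr"]


def read_expression_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    for col in EXPRESSION_COLS:
        if col not in df.columns:
            raise ParseError(f"expression table missing column {col!r}")
    if df["gene_id"].duplicated().any():
        raise ParseError("duplicate gene_id in expression table")
    if not np.isfinite(df[EXPRESSION_COLS[1:]].to_numpy(dtype=float)).all():
        raise ParseError("non-finite value in expression table")
    return df


def write_expression_table(path, df: pd.DataFrame) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


# ---------------------------------------------------------------------------
# gene lists and cells

def read_gene_list(path) -> set[str]:
    with open(path) as fh:
        return {ln.strip() for ln in fh if ln.strip()}


def write_gene_list(path, genes) -> None:
    with open(path, "w") as fh:
        for g in sorted(genes):
            fh.write(g + "\n")


def read_cells(path) -> pd.DataFrame:
    """Cells x genes TSV with leading cell_id, cluster, group columns."""
    df = pd.read_csv(path, sep="\t", dtype={"cell_id": str, "cluster": str, "group": str})
    for col in ("cell_id", "cluster", "group"):
        if col not in df.columns:
            raise ParseError(f"cell matrix missing column {col!r}")
    return df


def write_cells(path, df: pd.DataFrame) -> None:
    df.to_csv(path, sep="\t", index=False)
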