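"""Readers and writers for the pipeline's plain-text dialects.

Everything is TSV (tab, UTF-8, '.'-decimal; gzip transparently supported
via pandas).  Matrices are features x samples with a header row of sample
ids; annotation positions are 1-based; BED intervals are 0-based
half-open.  Missing values are never silently accepted: an NA token in a
matrix is an error naming the offending cell.  Chromosome names are
normalized to the "chr"-prefixed form at parse time.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

FLOAT_FMT = "%.10g"

INTERACTION_COLUMNS = ["bait_chrom", "bait_start", "bait_end",
                       "oe_chrom", "oe_start", "oe_end",
                       "bait_genes", "cell_state"]


def _norm_chrom(series: pd.Series) -> pd.Series:
    s = series.astype(str)
    return s.where(s.str.startswith("chr"), "chr" + s)


# ---------------------------------------------------------------------------
# matrices
# ---------------------------------------------------------------------------


def read_matrix_tsv(path) -> pd.DataFrame:
    """Read a feature x sample matrix; any non-numeric cell (including NA
    tokens) is an error naming the feature and sample."""
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str,
                      keep_default_na=False, na_values=[])
    try:
        return raw.astype(float)
    except ValueError:
        for i, row in enumerate(raw.to_numpy()):
            for j, cell in enumerate(row):
                try:
                    float(cell)
                except ValueError:
                    raise ValueError(
                        f"{path}: non-numeric cell {cell!r} at feature "
                        f"{raw.index[i]!r}, sample {raw.columns[j]!r}"
                    ) from None
        raise


def write_matrix_tsv(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t", float_format=FLOAT_FMT)


# ---------------------------------------------------------------------------
# annotations, sample sheet
# ---------------------------------------------------------------------------


def read_cpg_annotation(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df["chrom"] = _norm_chrom(df["chrom"])
    if "snp_flag" not in df.columns:
        df["snp_flag"] = False
    df["snp_flag"] = df["snp_flag"].astype(bool)
    return df


def read_gene_annotation(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df["chrom"] = _norm_chrom(df["chrom"])
    return df


def read_sample_sheet(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if "group" not in df.columns or df["group"].isna().any():
        raise ValueError(f"{path}: sample sheet must define 'group' for "
                         "every sample")
    return df


def write_table(df: pd.DataFrame, path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", float_format=FLOAT_FMT, index=index)


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------


def read_bed(path) -> pd.DataFrame:
    """BED3+ (0-based half-open); malformed lines are reported with their
    line number and text."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >=3 BED fields: "
                                 f"{line!r}")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates: "
                                 f"{line!r}") from None
            if end <= start:
                raise ValueError(f"{path}:{lineno}: end <= start: {line!r}")
            rows.append((fields[0], start, end))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    df["chrom"] = _norm_chrom(df["chrom"])
    return df


def write_bed(intervals: pd.DataFrame, path) -> None:
    intervals[["chrom", "start", "end"]].to_csv(
        path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# interactions, SNP links
# ---------------------------------------------------------------------------


def read_interactions(path) -> pd.DataFrame:
    """BEDPE-like interaction table.  An empty bait gene field is allowed
    only for erythroblast rows (non-promoter baits occur in that control
    set); everywhere else it is an error."""
    df = pd.read_csv(path, sep="\t", dtype={"bait_genes": str},
                     keep_default_na=False, na_values=[])
    missing = [c for c in INTERACTION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing interaction columns {missing}")
    df["bait_chrom"] = _norm_chrom(df["bait_chrom"])
    df["oe_chrom"] = _norm_chrom(df["oe_chrom"])
    empty = df["bait_genes"].astype(str).str.strip() == ""
    bad = empty & (df["cell_state"] != "Ery")
    if bad.any():
        lineno = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # header is line 1
        raise ValueError(f"{path}:{lineno}: empty bait gene field outside "
                         "the erythroblast set")
    return df


def write_interactions(interactions: pd.DataFrame, path) -> None:
    interactions[INTERACTION_COLUMNS].to_csv(path, sep="\t", index=False)


def read_snp_links(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    needed = {"rsid", "locus_gene", "target_genes"}
    if not needed.issubset(df.columns):
        raise ValueError(f"{path}: SNP link table needs columns {needed}")
    if df["rsid"].duplicated().any():
        dup = df.loc[df["rsid"].duplicated(), "rsid"].iloc[0]
        raise ValueError(f"{path}: duplicate rsid {dup!r}")
    return df


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
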