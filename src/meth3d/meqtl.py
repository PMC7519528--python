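"""Cis methylation-expression association within a 5 Mb window.

Candidate CpG-gene pairs share a chromosome and lie within the window of
the gene's TSS (inclusive boundary).  The association statistic is the
partial Pearson correlation of methylation (M values) and expression after
residualizing both on the covariates (sex and age by default) -- the
additive-linear-model reading of "Pearson correlation with covariates".
Significant pairs (raw p < 0.01; no further multiplicity correction at
this step) are intersected with the DMP and DEG call sets, classified as
promoter-proximal when the CpG falls in the strand-aware TSS-5kb/+1kb
window, and summarised by correlation sign.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

CIS_WINDOW = 5_000_000
PROMOTER_UPSTREAM = 5000
PROMOTER_DOWNSTREAM = 1000


def cis_pairs(
    cpg_annotation: pd.DataFrame,
    gene_annotation: pd.DataFrame,
    window: int = CIS_WINDOW,
) -> pd.DataFrame:
    """All same-chromosome (CpG, gene) pairs with |pos - TSS| <= window.

    Distance is anchored at the gene TSS; the boundary is inclusive.
    """
    rows = []
    for chrom in pd.unique(cpg_annotation["chrom"]):
        cpgs = cpg_annotation[cpg_annotation["chrom"] == chrom]
        genes = gene_annotation[gene_annotation["chrom"] == chrom]
        if cpgs.empty or genes.empty:
            continue
        pos = cpgs["pos"].to_numpy(np.int64)
        order = np.argsort(pos, kind="mergesort")
        pos_sorted = pos[order]
        ids_sorted = cpgs.index.to_numpy()[order]
        for gene, g in genes.iterrows():
            tss = int(g["tss"])
            lo = np.searchsorted(pos_sorted, tss - window, side="left")
            hi = np.searchsorted(pos_sorted, tss + window, side="right")
            for j in range(lo, hi):
                rows.append((ids_sorted[j], gene, chrom,
                             int(pos_sorted[j]), tss,
                             abs(int(pos_sorted[j]) - tss)))
    return pd.DataFrame(rows, columns=["cpg_id", "gene", "chrom",
                                       "cpg_pos", "tss", "distance"])


def _residualize(X: np.ndarray, C: np.ndarray | None) -> np.ndarray:
    """Residuals of each row of X on the covariate design (with intercept)."""
    n = X.shape[1]
    if C is None or C.size == 0:
        return X - X.mean(axis=1, keepdims=True)
    D = np.column_stack([np.ones(n), C])
    coef, *_ = np.linalg.lstsq(D, X.T, rcond=None)
    return X - (D @ coef).T


def fit_meqtl(
    pairs: pd.DataFrame,
    m_matrix: pd.DataFrame,
    expr_matrix: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Partial correlation and p-value for each candidate pair.

    Both matrices are residualized on the covariates across all samples;
    r is the Pearson correlation of the residuals and
    t = r sqrt((n - 2 - k) / (1 - r^2)) is referred to a t-distribution
    with n - 2 - k df (k covariates).  Pairs whose residual variance is
    zero are flagged and skipped.  With no covariates this is plain
    Pearson correlation.  Sample order never matters: columns are aligned
    by id.
    """
    if list(m_matrix.columns) != list(expr_matrix.columns):
        expr_matrix = expr_matrix[m_matrix.columns]
    n = m_matrix.shape[1]
    k = 0 if covariates is None else covariates.shape[1]
    C = None
    if covariates is not None:
        C = covariates.reindex(m_matrix.columns).to_numpy(float)
        if np.isnan(C).any():
            raise ValueError("covariate missing for some samples")

    Mr = _residualize(m_matrix.to_numpy(float), C)
    Er = _residualize(expr_matrix.to_numpy(float), C)
    m_norm = np.linalg.norm(Mr, axis=1)
    e_norm = np.linalg.norm(Er, axis=1)

    m_idx = m_matrix.index.get_indexer(pairs["cpg_id"])
    e_idx = expr_matrix.index.get_indexer(pairs["gene"])
    if (m_idx < 0).any() or (e_idx < 0).any():
        raise KeyError("pair refers to a feature absent from the matrices")

    num = np.einsum("ij,ij->i", Mr[m_idx], Er[e_idx])
    denom = m_norm[m_idx] * e_norm[e_idx]
    skipped = denom <= 0
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(skipped, np.nan, num / np.where(skipped, 1.0, denom))
    r = np.clip(r, -1.0, 1.0)
    df = n - 2 - k
    if df <= 0:
        raise ValueError("not enough samples for the covariate-adjusted test")
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(df / np.maximum(1.0 - r ** 2, 1e-300))
    p = 2.0 * stats.t.sf(np.abs(t), df)

    out = pairs.copy()
    out["r"] = r
    out["p"] = p
    out["sign"] = np.where(r < 0, "negative", "positive")
    out["skipped"] = skipped
    return out


def filter_to_dmp_deg(
    meqtl_records: pd.DataFrame,
    dmp_ids,
    deg_ids,
    p_thr: float = 0.01,
) -> pd.DataFrame:
    """Keep significant records whose CpG is a called DMP and whose gene is
    a called DEG.  Unique-feature counts and the sign split are attached
    to ``DataFrame.attrs['summary']``."""
    dmp_set, deg_set = set(dmp_ids), set(deg_ids)
    keep = meqtl_records[
        (meqtl_records["p"] < p_thr) &
        (~meqtl_records["skipped"].astype(bool)) &
        meqtl_records["cpg_id"].isin(dmp_set) &
        meqtl_records["gene"].isin(deg_set)
    ].copy()
    keep.attrs["summary"] = {
        "n_pairs": len(keep),
        "n_unique_cpgs": keep["cpg_id"].nunique(),
        "n_unique_genes": keep["gene"].nunique(),
        "n_negative": int((keep["sign"] == "negative").sum()),
        "n_positive": int((keep["sign"] == "positive").sum()),
    }
    return keep


def promoter_window(tss: int, strand: str,
                    upstream: int = PROMOTER_UPSTREAM,
                    downstream: int = PROMOTER_DOWNSTREAM) -> tuple[int, int]:
    """1-based inclusive promoter interval; upstream is 5' of the TSS in
    transcription orientation, so on the minus strand it has the higher
    coordinates."""
    if strand == "+":
        return max(tss - upstream, 1), tss + downstream
    return max(tss - downstream, 1), tss + upstream


def classify_promoter_proximal(
    records: pd.DataFrame,
    gene_annotation: pd.DataFrame,
) -> pd.Series:
    """True where the CpG lies inside the paired gene's promoter window
    (boundaries inclusive, strand-aware)."""
    genes = gene_annotation.loc[records["gene"]]
    tss = genes["tss"].to_numpy(np.int64)
    strand = genes["strand"].to_numpy()
    lo = np.where(strand == "+", tss - PROMOTER_UPSTREAM,
                  tss - PROMOTER_DOWNSTREAM)
    hi = np.where(strand == "+", tss + PROMOTER_DOWNSTREAM,
                  tss + PROMOTER_UPSTREAM)
    lo = np.maximum(lo, 1)
    pos = records["cpg_pos"].to_numpy(np.int64)
    return pd.Series((pos >= lo) & (pos <= hi), index=records.index,
                     name="promoter_proximal")


def sign_summary(pairs: pd.DataFrame) -> tuple[int, int, float | None]:
    """(n_total, n_negative, pct_negative rounded to one decimal);
    percentage is None for an empty table."""
    n = len(pairs)
    n_neg = int((pairs["sign"] == "negative").sum())
    pct = round(100.0 * n_neg / n, 1) if n else None
    return n, n_neg, pct
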