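"""Permutation-based enrichment of genomic region sets in peak sets.

Query regions (DMP positions or windows, DMR spans) are compared against a
peak set by resampling matched background sets from the array universe:
for each of B permutations a background of equal count (and, for region
queries, equal lengths anchored on random universe CpGs) is drawn, a 2x2
overlap table is formed, and the across-permutation averages of the
Haldane-corrected odds ratio and the two-sided Fisher exact p decide
significance (avg p < 0.01 and avg OR > 1).

All interval arithmetic is 0-based half-open (BED); 1-based annotation
positions are converted exactly once, at the query/universe boundary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

_CHROM_PAD = 20_000_000  # guard gap between chromosomes in global coords


# ---------------------------------------------------------------------------
# interval plumbing
# ---------------------------------------------------------------------------


def _validate_intervals(df: pd.DataFrame, name: str) -> None:
    if not {"chrom", "start", "end"}.issubset(df.columns):
        raise ValueError(f"{name}: expected chrom/start/end columns")
    bad = df.index[df["end"].to_numpy() <= df["start"].to_numpy()]
    if len(bad):
        raise ValueError(f"{name}: interval with end <= start at row {bad[0]}")


class _GlobalCoords:
    """Maps per-chromosome coordinates onto one padded global axis so a
    single sorted structure serves every chromosome."""

    def __init__(self, *frames: pd.DataFrame):
        chroms = sorted({c for f in frames for c in f["chrom"].unique()})
        spans = {}
        for c in chroms:
            hi = max(int(f.loc[f["chrom"] == c, "end"].max())
                     for f in frames if (f["chrom"] == c).any())
            spans[c] = hi
        self.offset = {}
        cum = 0
        for c in chroms:
            self.offset[c] = cum
            cum += spans[c] + _CHROM_PAD

    def starts_ends(self, df: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
        off = df["chrom"].map(self.offset).to_numpy(dtype=np.int64)
        return (df["start"].to_numpy(np.int64) + off,
                df["end"].to_numpy(np.int64) + off)


class PeakIndex:
    """Sorted-start + prefix-max-end index answering 'does this interval
    overlap any peak' in O(log n) per query."""

    def __init__(self, peaks: pd.DataFrame, coords: _GlobalCoords):
        _validate_intervals(peaks, "peaks")
        s, e = coords.starts_ends(peaks)
        order = np.argsort(s, kind="mergesort")
        self.starts = s[order]
        self.max_end = np.maximum.accumulate(e[order])

    def overlaps(self, q_start: np.ndarray, q_end: np.ndarray) -> np.ndarray:
        """Boolean per query interval: overlap >=1 bp with >=1 peak."""
        idx = np.searchsorted(self.starts, q_end, side="left")
        hit = idx > 0
        safe = np.maximum(idx - 1, 0)
        return hit & (self.max_end[safe] > q_start)


def overlap_count(query_intervals: pd.DataFrame, peak_set: pd.DataFrame) -> int:
    """Number of query intervals overlapping at least one peak (any overlap
    of >=1 bp, half-open convention: abutting intervals do not overlap)."""
    _validate_intervals(query_intervals, "query")
    if peak_set.empty or query_intervals.empty:
        return 0
    coords = _GlobalCoords(query_intervals, peak_set)
    index = PeakIndex(peak_set, coords)
    qs, qe = coords.starts_ends(query_intervals)
    return int(index.overlaps(qs, qe).sum())


def dmp_window(query_cpgs: pd.DataFrame, flank: int = 0) -> pd.DataFrame:
    """CpG positions (1-based ``pos``) to 0-based half-open intervals
    ``[pos-1-flank, pos+flank)``, clipped at the chromosome start."""
    pos0 = query_cpgs["pos"].to_numpy(np.int64) - 1
    return pd.DataFrame({
        "chrom": query_cpgs["chrom"].to_numpy(),
        "start": np.maximum(pos0 - flank, 0),
        "end": pos0 + flank + 1,
    }, index=query_cpgs.index)


# ---------------------------------------------------------------------------
# Fisher exact (two-sided, vectorized over tables with one fixed row)
# ---------------------------------------------------------------------------


def _fisher_two_sided(a: np.ndarray, c: np.ndarray, n_q: int) -> np.ndarray:
    """Two-sided Fisher exact p for tables [[a, n_q - a], [c, n_q - c]].

    Vectorized over paired (a, c): conditional on margins, the top-left
    cell is hypergeometric with M = 2 n_q, K = a + c, N = n_q; the
    two-sided p sums all outcomes with pmf <= pmf(observed) (with the
    customary 1+1e-7 relative slack, matching the exact test convention).
    """
    a = np.asarray(a, dtype=np.int64)
    c = np.asarray(c, dtype=np.int64)
    K = a + c
    support = np.arange(0, n_q + 1)
    # pmf matrix: rows = tables, cols = support
    pmf = stats.hypergeom.pmf(support[None, :], 2 * n_q, K[:, None], n_q)
    obs = pmf[np.arange(len(a)), a]
    p = (pmf * (pmf <= obs[:, None] * (1.0 + 1e-7))).sum(axis=1)
    return np.minimum(p, 1.0)


def _haldane_or(a: np.ndarray, c: np.ndarray, n_q: int) -> np.ndarray:
    a = np.asarray(a, dtype=float)
    c = np.asarray(c, dtype=float)
    return ((a + 0.5) * (n_q - c + 0.5)) / ((n_q - a + 0.5) * (c + 0.5))


# ---------------------------------------------------------------------------
# permutation enrichment
# ---------------------------------------------------------------------------


@dataclass
class EnrichmentResult:
    query_name: str
    peak_set_name: str
    n_query: int
    observed_overlap: int
    avg_odds_ratio: float
    avg_p: float
    B: int
    significant: bool
    p_sidedness: str = "two-sided"

    def to_dict(self) -> dict:
        return self.__dict__.copy()


def permutation_enrichment(
    query: pd.DataFrame,
    peak_set: pd.DataFrame,
    universe: pd.DataFrame,
    B: int = 1000,
    seed: int = 0,
    query_name: str = "query",
    peak_set_name: str = "peaks",
    length_matched: bool | None = None,
) -> EnrichmentResult:
    """Average-OR / average-p permutation enrichment.

    ``query`` is an interval frame (chrom/start/end, 0-based half-open);
    ``universe`` is the full array CpG annotation (chrom, 1-based pos).
    Per permutation a background of ``len(query)`` universe CpGs is drawn
    without replacement; for length-matched (region) queries each sampled
    CpG anchors the centre of a window of the corresponding query length.
    Significant iff avg_p < 0.01 AND avg_OR > 1 (a depleted query can
    never be called enriched).
    """
    _validate_intervals(query, "query")
    n_q = len(query)
    if n_q == 0:
        raise ValueError("empty query")
    if len(universe) < n_q:
        raise ValueError("universe smaller than the query set")
    lengths = (query["end"] - query["start"]).to_numpy(np.int64)
    if length_matched is None:
        length_matched = bool((lengths > 1).any())

    uni = pd.DataFrame({
        "chrom": universe["chrom"].to_numpy(),
        "start": universe["pos"].to_numpy(np.int64) - 1,
        "end": universe["pos"].to_numpy(np.int64),
    })
    coords = _GlobalCoords(query, peak_set, uni) if not peak_set.empty else None
    if peak_set.empty:
        observed = 0
        a = 0
        index = None
        upos = None
    else:
        index = PeakIndex(peak_set, coords)
        qs, qe = coords.starts_ends(query)
        a = int(index.overlaps(qs, qe).sum())
        observed = a
        upos, _ = coords.starts_ends(uni)

    rng = np.random.default_rng(seed)
    picks = np.empty((B, n_q), dtype=np.int64)
    for b in range(B):
        picks[b] = rng.choice(len(uni), size=n_q, replace=False)
    if index is None:
        c = np.zeros(B, dtype=np.int64)
    else:
        anchor = upos[picks]  # global 0-based CpG positions, (B, n_q)
        if length_matched:
            half = lengths // 2
            bs = anchor - half[None, :]
            be = bs + lengths[None, :]
        else:
            bs, be = anchor, anchor + 1
        hits = index.overlaps(bs.ravel(), be.ravel()).reshape(B, n_q)
        c = hits.sum(axis=1)

    ors = _haldane_or(np.full(B, a), c, n_q)
    ps = _fisher_two_sided(np.full(B, a), c, n_q)
    avg_or = float(ors.mean())
    avg_p = float(ps.mean())
    return EnrichmentResult(
        query_name=query_name, peak_set_name=peak_set_name, n_query=n_q,
        observed_overlap=observed, avg_odds_ratio=avg_or, avg_p=avg_p,
        B=B, significant=bool(avg_p < 0.01 and avg_or > 1.0))
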