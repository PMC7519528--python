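"""Bump-hunting detection of differentially methylated regions.

CpGs are grouped into clusters (consecutive probes within ``max_gap`` on
one chromosome); the per-CpG case-control beta difference is smoothed by a
running mean inside sufficiently dense clusters; maximal same-sign runs
exceeding a global |effect| quantile become candidate regions; and
candidate areas are ranked against a pooled permutation null obtained by
relabelling samples.  Regions with permutation p < 0.05 spanning at least
two CpGs are reported.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def cluster_probes(cpg_annotation: pd.DataFrame, max_gap: int = 500) -> pd.Series:
    """Assign cluster ids: consecutive CpGs on one chromosome at most
    ``max_gap`` bp apart share a cluster.  Input must be position-sorted
    per chromosome."""
    chroms = cpg_annotation["chrom"].to_numpy()
    pos = cpg_annotation["pos"].to_numpy()
    for c in pd.unique(chroms):
        p = pos[chroms == c]
        if np.any(np.diff(p) < 0):
            raise ValueError(f"CpG positions not sorted on {c}")
    new_chrom = np.empty(len(pos), dtype=bool)
    new_chrom[0] = True
    new_chrom[1:] = chroms[1:] != chroms[:-1]
    gap = np.empty(len(pos), dtype=bool)
    gap[0] = True
    gap[1:] = (pos[1:] - pos[:-1]) > max_gap
    breaks = new_chrom | gap
    return pd.Series(np.cumsum(breaks) - 1, index=cpg_annotation.index,
                     name="cluster")


def _smooth_in_clusters(effect: np.ndarray, clusters: np.ndarray,
                        smooth_width: int) -> np.ndarray:
    """Centered running mean of width ``smooth_width`` within clusters of at
    least ``smooth_width`` CpGs; smaller clusters keep raw effects."""
    out = effect.copy()
    # clusters are contiguous runs by construction
    boundaries = np.flatnonzero(np.diff(clusters)) + 1
    starts = np.concatenate([[0], boundaries])
    ends = np.concatenate([boundaries, [len(clusters)]])
    half = smooth_width // 2
    for s, e in zip(starts, ends):
        if e - s >= smooth_width:
            seg = effect[s:e]
            c = np.concatenate([[0.0], np.cumsum(seg)])
            idx = np.arange(len(seg))
            lo = np.maximum(idx - half, 0)
            hi = np.minimum(idx + half + 1, len(seg))
            out[s:e] = (c[hi] - c[lo]) / (hi - lo)
    return out


def _effect_vector(beta: np.ndarray, case_mask: np.ndarray) -> np.ndarray:
    n_case = case_mask.sum()
    n_ctrl = (~case_mask).sum()
    w = np.where(case_mask, 1.0 / n_case, -1.0 / n_ctrl)
    return beta @ w


def _candidates_from_effect(
    smoothed: np.ndarray,
    clusters: np.ndarray,
    cutoff: float,
) -> list[tuple[int, int]]:
    """Maximal same-sign runs with |effect| >= cutoff, never crossing a
    cluster boundary; returned as (start_idx, end_idx) inclusive."""
    above = np.abs(smoothed) >= cutoff
    sign = np.sign(smoothed)
    runs = []
    i, n = 0, len(smoothed)
    while i < n:
        if not above[i] or sign[i] == 0:
            i += 1
            continue
        j = i
        while (j + 1 < n and above[j + 1] and sign[j + 1] == sign[i]
               and clusters[j + 1] == clusters[i]):
            j += 1
        runs.append((i, j))
        i = j + 1
    return runs


def find_bumps(
    beta_matrix: pd.DataFrame,
    group_labels: pd.Series,
    clusters: pd.Series,
    cpg_annotation: pd.DataFrame,
    cutoff_quantile: float = 0.95,
    smooth_width: int = 3,
    cutoff: float | None = None,
) -> pd.DataFrame:
    """Candidate regions from smoothed case-control beta differences.

    The cutoff is the ``cutoff_quantile`` quantile of |smoothed effect|
    over all CpGs unless given explicitly.  Returns one row per candidate:
    chrom, start, end (1-based inclusive CpG span), n_cpgs, mean_effect,
    area (sum of |effect| over members), direction and member ids.
    """
    if beta_matrix.empty:
        return pd.DataFrame(columns=["chrom", "start", "end", "n_cpgs",
                                     "mean_effect", "area", "direction",
                                     "cpg_ids"])
    groups = pd.Series(group_labels).reindex(beta_matrix.columns)
    case_mask = (groups == "case").to_numpy()
    beta = beta_matrix.to_numpy(dtype=float)
    cl = clusters.reindex(beta_matrix.index).to_numpy()
    effect = _effect_vector(beta, case_mask)
    smoothed = _smooth_in_clusters(effect, cl, smooth_width)
    if cutoff is None:
        cutoff = float(np.quantile(np.abs(smoothed), cutoff_quantile))
    ann = cpg_annotation.loc[beta_matrix.index]
    pos = ann["pos"].to_numpy()
    chrom = ann["chrom"].to_numpy()
    rows = []
    for s, e in _candidates_from_effect(smoothed, cl, cutoff):
        seg = smoothed[s:e + 1]
        rows.append({
            "chrom": chrom[s], "start": int(pos[s]), "end": int(pos[e]),
            "n_cpgs": e - s + 1, "mean_effect": float(seg.mean()),
            "area": float(np.abs(seg).sum()),
            "direction": "hyper" if seg[0] > 0 else "hypo",
            "cpg_ids": ",".join(beta_matrix.index[s:e + 1]),
        })
    out = pd.DataFrame(rows, columns=["chrom", "start", "end", "n_cpgs",
                                      "mean_effect", "area", "direction",
                                      "cpg_ids"])
    out.attrs["cutoff"] = cutoff
    return out


def dmr_permutation_p(
    candidates: pd.DataFrame,
    beta_matrix: pd.DataFrame,
    group_labels: pd.Series,
    clusters: pd.Series,
    B: int = 200,
    seed: int = 0,
    smooth_width: int = 3,
    p_threshold: float = 0.05,
    min_cpgs: int = 2,
) -> pd.DataFrame:
    """Pooled-permutation p-values for candidate regions.

    For each of ``B`` group-label permutations the candidate extraction is
    re-run at the observed cutoff and all null areas are pooled;
    ``p = (1 + #{null areas >= area}) / (1 + N_null)``, the quantile of the
    observed area in the pooled null, which is invariant to candidate
    order.  Regions with ``p < p_threshold`` spanning at least ``min_cpgs``
    CpGs are returned.
    """
    if B < 100:
        raise ValueError("B must be >= 100 for usable p-value resolution")
    out = candidates.copy()
    if out.empty:
        out["p"] = pd.Series(dtype=float)
        return out
    cutoff = candidates.attrs.get("cutoff")
    if cutoff is None:
        raise ValueError("candidates must come from find_bumps (cutoff lost)")

    groups = pd.Series(group_labels).reindex(beta_matrix.columns)
    case_mask = (groups == "case").to_numpy()
    beta = beta_matrix.to_numpy(dtype=float)
    cl = clusters.reindex(beta_matrix.index).to_numpy()
    rng = np.random.default_rng(seed)

    null_areas: list[float] = []
    for _ in range(B):
        perm = rng.permutation(case_mask)
        eff = _effect_vector(beta, perm)
        sm = _smooth_in_clusters(eff, cl, smooth_width)
        for s, e in _candidates_from_effect(sm, cl, cutoff):
            null_areas.append(float(np.abs(sm[s:e + 1]).sum()))
    null = np.sort(np.asarray(null_areas))
    n_null = len(null)

    areas = out["area"].to_numpy(dtype=float)
    ge = n_null - np.searchsorted(null, areas, side="left")
    out["p"] = (1.0 + ge) / (1.0 + n_null)
    if n_null < 20:
        out.attrs["warning"] = (
            f"only {n_null} pooled null candidates; permutation p-values "
            "have coarse resolution")
    kept = out[(out["p"] < p_threshold) & (out["n_cpgs"] >= min_cpgs)]
    kept = kept.reset_index(drop=True)
    kept.attrs.update(out.attrs)
    return kept


def call_dmrs(
    beta_matrix: pd.DataFrame,
    group_labels: pd.Series,
    cpg_annotation: pd.DataFrame,
    max_gap: int = 500,
    cutoff_quantile: float = 0.95,
    smooth_width: int = 3,
    B: int = 200,
    seed: int = 0,
) -> pd.DataFrame:
    """Cluster -> find_bumps -> permutation filter, in one call."""
    ann = cpg_annotation.loc[beta_matrix.index]
    order = ann.sort_values(["chrom", "pos"]).index
    beta = beta_matrix.loc[order]
    ann = ann.loc[order]
    clusters = cluster_probes(ann, max_gap=max_gap)
    cands = find_bumps(beta, group_labels, clusters, ann,
                       cutoff_quantile=cutoff_quantile,
                       smooth_width=smooth_width)
    return dmr_permutation_p(cands, beta, group_labels, clusters,
                             B=B, seed=seed, smooth_width=smooth_width)
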