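"""Differential-variability calling (iEVORA-style) on beta values.

A CpG is a differentially variable position (DVP) when Bartlett's test of
equal group variances passes a strict FDR threshold AND a two-sample
t-test of the means passes a lenient nominal threshold; the t-test acts as
the algorithm's regularization step, guarding against variance hits driven
by a single outlier with no accompanying mean signal.  Direction follows
the case/control variance ratio.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .diffstats import bh_fdr


def bartlett_stat(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Bartlett's test for two groups (closed form): statistic and p.

    T = (N - k) ln(sp^2) - sum (n_i - 1) ln(s_i^2), divided by the usual
    correction 1 + (sum 1/(n_i-1) - 1/(N-k)) / (3(k-1)); chi-square with
    k - 1 = 1 df.
    """
    n1, n2 = len(a), len(b)
    s1, s2 = a.var(ddof=1), b.var(ddof=1)
    if s1 <= 0 or s2 <= 0:
        raise ValueError("zero variance in a group: Bartlett undefined")
    N, k = n1 + n2, 2
    sp = ((n1 - 1) * s1 + (n2 - 1) * s2) / (N - k)
    num = (N - k) * np.log(sp) - ((n1 - 1) * np.log(s1) + (n2 - 1) * np.log(s2))
    corr = 1.0 + (1.0 / (n1 - 1) + 1.0 / (n2 - 1) - 1.0 / (N - k)) / (3.0 * (k - 1))
    T = num / corr
    return float(T), float(stats.chi2.sf(T, k - 1))


def ievora(
    beta_matrix: pd.DataFrame,
    group_labels: pd.Series,
    var_fdr_thr: float = 0.001,
    t_p_thr: float = 0.05,
) -> pd.DataFrame:
    """Call DVPs: Bartlett q < ``var_fdr_thr`` AND t-test p < ``t_p_thr``.

    Returns the full per-CpG table (bartlett_p, bartlett_q, t_p,
    var_ratio, direction, is_dvp, skipped flag for zero-variance rows),
    with called DVPs ranked first by t_p.  Invariant to sample column
    order.
    """
    groups = pd.Series(group_labels).reindex(beta_matrix.columns)
    case = (groups == "case").to_numpy()
    ctrl = (groups == "control").to_numpy()
    if case.sum() < 2 or ctrl.sum() < 2:
        raise ValueError("each group needs >=2 samples")
    X = beta_matrix.to_numpy(dtype=float)
    A, B = X[:, case], X[:, ctrl]
    n1, n2 = A.shape[1], B.shape[1]

    s1 = A.var(axis=1, ddof=1)
    s2 = B.var(axis=1, ddof=1)
    skipped = (s1 <= 0) | (s2 <= 0)

    with np.errstate(divide="ignore", invalid="ignore"):
        N, k = n1 + n2, 2
        sp = ((n1 - 1) * s1 + (n2 - 1) * s2) / (N - k)
        num = (N - k) * np.log(sp) - ((n1 - 1) * np.log(s1) +
                                      (n2 - 1) * np.log(s2))
        corr = 1.0 + (1.0 / (n1 - 1) + 1.0 / (n2 - 1) - 1.0 / (N - k)) / 3.0
        bart_T = num / corr
        bart_p = stats.chi2.sf(bart_T, k - 1)
        var_ratio = s1 / s2

        # pooled-variance two-sample t on the means
        se = np.sqrt(sp * (1.0 / n1 + 1.0 / n2))
        tstat = (A.mean(axis=1) - B.mean(axis=1)) / se
        t_p = 2.0 * stats.t.sf(np.abs(tstat), N - 2)

    bart_p = np.where(skipped, np.nan, bart_p)
    valid = ~skipped
    bart_q = np.full(len(bart_p), np.nan)
    if valid.any():
        bart_q[valid] = bh_fdr(bart_p[valid])

    is_dvp = valid & (bart_q < var_fdr_thr) & (t_p < t_p_thr)
    out = pd.DataFrame({
        "bartlett_p": bart_p,
        "bartlett_q": bart_q,
        "t_p": t_p,
        "var_ratio": var_ratio,
        "direction": np.where(var_ratio > 1, "gain", "loss"),
        "is_dvp": is_dvp,
        "skipped": skipped,
    }, index=beta_matrix.index.rename("cpg_id"))
    # iEVORA ranking: called DVPs ordered by the t-test p-value
    out = out.sort_values(["is_dvp", "t_p"],
                          ascending=[False, True], kind="mergesort")
    return out


def classify_dvp_overlap(
    dvp_table: pd.DataFrame,
    dmp_ids,
) -> tuple[int, int, int]:
    """Overlap of called DVPs with a DMP id set.

    Returns (n_both, n_dvp_only, n_gain_among_dvp_only); the first two sum
    to the number of DVPs.
    """
    dvps = dvp_table[dvp_table["is_dvp"]]
    dmp_set = set(dmp_ids)
    both = dvps.index.isin(dmp_set)
    dvp_only = dvps[~both]
    n_gain = int((dvp_only["direction"] == "gain").sum())
    return int(both.sum()), len(dvp_only), n_gain
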