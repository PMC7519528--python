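"""Shared differential-testing engine.

Implements the empirical-Bayes moderated t-test (per-feature least-squares
group contrast, variance shrinkage toward a scaled inverse-chi-square prior
whose hyperparameters d0 and s0^2 come from the method of moments on
log s^2, i.e. the digamma/trigamma system), Benjamini-Hochberg step-up FDR,
threshold-based feature calling split by effect sign, and the
treatment-confounding checks (per-feature rank-sum tests plus principal
component vs covariate correlation).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

D0_CAP = 1e6  # represents an infinite prior df (complete shrinkage)


# ---------------------------------------------------------------------------
# hyperparameter estimation (method of moments on log s^2)
# ---------------------------------------------------------------------------


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y by Newton iteration (monotone, convex)."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def fit_f_dist(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Estimate (d0, s0^2) of the variance prior from observed residual
    variances ``s2`` with ``df`` degrees of freedom each.

    Moments of z = log(s2): E[z] = log(s0^2) + digamma(d/2) - log(d/2)
    - digamma(d0/2) + log(d0/2) and Var[z] = trigamma(d/2) + trigamma(d0/2);
    d0 solves the trigamma equation (Newton inverse) and is capped at
    ``D0_CAP`` to represent infinity.
    """
    s2 = np.asarray(s2, dtype=float)
    ok = s2 > 0
    if ok.sum() < 2:
        return D0_CAP, float(np.median(s2[ok])) if ok.any() else 1.0
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = e.mean()
    n = len(e)
    evar = ((e - emean) ** 2).mean() * n / (n - 1) - \
        float(special.polygamma(1, df / 2.0))
    if evar <= 0:
        return D0_CAP, float(np.exp(emean))
    d0 = 2.0 * _trigamma_inverse(evar)
    if not np.isfinite(d0) or d0 > D0_CAP:
        return D0_CAP, float(np.exp(emean))
    s0_sq = float(np.exp(emean + special.digamma(d0 / 2.0) -
                         np.log(d0 / 2.0)))
    return float(d0), s0_sq


# ---------------------------------------------------------------------------
# moderated t
# ---------------------------------------------------------------------------


def moderated_t(
    matrix: pd.DataFrame,
    group_labels: pd.Series,
    covariates: pd.DataFrame | None = None,
    prior_df: float | None = None,
) -> pd.DataFrame:
    """Per-feature moderated two-group contrast.

    Fits ``value ~ intercept + group (+ covariates)`` by least squares for
    every feature, shrinks the residual variances toward the empirical-
    Bayes prior, and tests the group coefficient with
    ``t = effect / (s_tilde * sqrt(v_g))`` on ``d_g + d0`` degrees of
    freedom.  ``prior_df`` overrides the estimated d0 (0 disables
    shrinkage; ``np.inf`` forces complete shrinkage).

    Returns a table indexed by feature with columns ``effect``,
    ``t_ordinary``, ``t_moderated``, ``df_residual``, ``df_total``, ``p``
    and attributes ``d0``/``s0_sq`` in ``DataFrame.attrs``.
    """
    groups = pd.Series(group_labels).reindex(matrix.columns)
    if groups.isna().any():
        raise ValueError("group label missing for some samples")
    levels = sorted(groups.unique())
    if len(levels) != 2:
        raise ValueError(f"need exactly 2 groups, got {levels}")
    if (groups.value_counts() < 2).any():
        raise ValueError("each group needs >=2 samples")
    # 'case' (or the second level) is the positive direction
    pos = "case" if "case" in levels else levels[1]
    ind = (groups == pos).to_numpy(float)

    n = len(groups)
    cols = [np.ones(n), ind]
    if covariates is not None:
        C = covariates.reindex(matrix.columns).to_numpy(float)
        if np.isnan(C).any():
            raise ValueError("covariate missing for some samples")
        cols.extend(C.T)
    D = np.column_stack(cols)
    p = D.shape[1]
    df_resid = n - p
    if df_resid <= 0:
        raise ValueError("zero residual degrees of freedom")

    X = matrix.to_numpy(dtype=float)
    DtD_inv = np.linalg.inv(D.T @ D)
    coef = DtD_inv @ D.T @ X.T  # (p, features)
    resid = X.T - D @ coef
    s2 = (resid ** 2).sum(axis=0) / df_resid
    v_g = DtD_inv[1, 1]
    effect = coef[1]

    with np.errstate(divide="ignore", invalid="ignore"):
        t_ord = effect / np.sqrt(s2 * v_g)

    if prior_df is not None:
        d0 = float(min(prior_df, D0_CAP))
        # prior scale still comes from the data even when d0 is imposed
        _, s0_sq = fit_f_dist(s2, df_resid)
    else:
        d0, s0_sq = fit_f_dist(s2, df_resid)

    if d0 >= D0_CAP:
        s2_tilde = np.full_like(s2, s0_sq)
        df_total = np.inf
    elif d0 == 0:
        s2_tilde = s2
        df_total = float(df_resid)
    else:
        s2_tilde = (d0 * s0_sq + df_resid * s2) / (d0 + df_resid)
        df_total = float(df_resid + d0)

    with np.errstate(divide="ignore", invalid="ignore"):
        t_mod = effect / np.sqrt(s2_tilde * v_g)
    if np.isinf(df_total):
        pvals = 2.0 * stats.norm.sf(np.abs(t_mod))
    else:
        pvals = 2.0 * stats.t.sf(np.abs(t_mod), df_total)

    out = pd.DataFrame({
        "effect": effect,
        "t_ordinary": t_ord,
        "t_moderated": t_mod,
        "df_residual": float(df_resid),
        "df_total": df_total,
        "p": pvals,
    }, index=matrix.index.rename("feature_id"))
    out["q"] = bh_fdr(out["p"].to_numpy())
    out.attrs["d0"] = d0
    out.attrs["s0_sq"] = s0_sq
    return out


# ---------------------------------------------------------------------------
# Benjamini-Hochberg
# ---------------------------------------------------------------------------


def bh_fdr(p_values) -> np.ndarray:
    """Step-up BH adjusted p-values, q_i = min_{j>=i} m p_(j) / j, mapped
    back to input order and clipped to [0, 1]."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([], dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values outside [0,1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


# ---------------------------------------------------------------------------
# calling
# ---------------------------------------------------------------------------


@dataclass
class CallSet:
    """Features passing both thresholds, one direction of effect."""

    records: pd.DataFrame
    direction: str  # 'hyper'/'up' vs 'hypo'/'down'
    p_thr: float
    fdr_thr: float

    @property
    def feature_ids(self) -> list[str]:
        return list(self.records.index)

    def __len__(self) -> int:
        return len(self.records)


def call_features(
    stats_table: pd.DataFrame,
    p_thr: float = 0.01,
    fdr_thr: float = 0.05,
    labels: tuple[str, str] = ("hyper", "hypo"),
) -> tuple[CallSet, CallSet]:
    """Split significant features (p < p_thr AND q < fdr_thr) by effect
    sign; the two sets are disjoint (zero effects are never called)."""
    sig = stats_table[(stats_table["p"] < p_thr) & (stats_table["q"] < fdr_thr)]
    up = sig[sig["effect"] > 0]
    down = sig[sig["effect"] < 0]
    return (CallSet(up, labels[0], p_thr, fdr_thr),
            CallSet(down, labels[1], p_thr, fdr_thr))


def annotate_calls(stats_table: pd.DataFrame, up: CallSet,
                   down: CallSet) -> pd.DataFrame:
    out = stats_table.copy()
    call = pd.Series("none", index=out.index)
    call[up.records.index] = up.direction
    call[down.records.index] = down.direction
    out["call"] = call
    return out


# ---------------------------------------------------------------------------
# confounding checks
# ---------------------------------------------------------------------------


@dataclass
class ConfoundReport:
    feature_tests: pd.DataFrame
    pc_correlations: pd.DataFrame
    skipped: bool = False
    reason: str = ""


def confound_check(
    matrix: pd.DataFrame,
    called_features: list[str],
    covariate: pd.Series,
    n_pcs: int = 3,
) -> ConfoundReport:
    """Test whether a binary covariate (e.g. treatment) confounds the calls.

    Within the samples the covariate is defined for: (a) per called
    feature, a two-sided rank-sum test between covariate strata, BH
    adjusted; (b) PCA of the called-feature submatrix and point-biserial
    correlation of each leading PC with the covariate, with each PC's
    share of total variance.  A covariate with a stratum of fewer than two
    samples is flagged and the tests are skipped.
    """
    cov = pd.Series(covariate).dropna()
    cols = [c for c in matrix.columns if c in cov.index]
    cov = cov.loc[cols]
    strata = cov.unique()
    empty = ConfoundReport(pd.DataFrame(), pd.DataFrame(), skipped=True)
    if len(strata) < 2:
        empty.reason = "covariate is constant (single stratum)"
        return empty
    counts = cov.value_counts()
    if (counts < 2).any():
        empty.reason = f"stratum with <2 samples: {counts.to_dict()}"
        return empty

    sub = matrix.loc[called_features, cols]
    a_mask = (cov == strata[0]).to_numpy()
    vals = sub.to_numpy(dtype=float)
    pvals = np.array([
        stats.mannwhitneyu(row[a_mask], row[~a_mask],
                           alternative="two-sided").pvalue
        for row in vals])
    feature_tests = pd.DataFrame({"p": pvals, "q": bh_fdr(pvals)},
                                 index=sub.index)

    centered = vals.T - vals.T.mean(axis=0)
    u, s, _ = np.linalg.svd(centered, full_matrices=False)
    total_var = (s ** 2).sum()
    rows = []
    x = a_mask.astype(float)
    for k in range(min(n_pcs, len(s))):
        pc = u[:, k] * s[k]
        if pc.std() == 0 or x.std() == 0:
            r, pv = 0.0, 1.0
        else:
            r, pv = stats.pearsonr(pc, x)
        rows.append({"pc": k + 1, "r": r, "p": pv,
                     "var_share": (s[k] ** 2) / total_var if total_var else 0.0})
    return ConfoundReport(feature_tests, pd.DataFrame(rows))
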