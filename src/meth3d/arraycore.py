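"""Probe-level preprocessing of normalized methylation matrices.

Covers the beta <-> M transforms, the ordered probe filter (detection p,
SNP-overlapping probes, top-|delta beta| retention) and a parametric
empirical-Bayes location/scale batch adjustment of the ComBat family,
operating on matrices that are already normalized.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class MethylationStudy:
    """A beta matrix (CpGs x samples) with its CpG annotation and sample
    sheet.  Row ids must be unique and the columns must match the sheet."""

    beta: pd.DataFrame
    cpg_annotation: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.beta.index.is_unique:
            raise ValueError("CpG ids are not unique")
        if list(self.beta.columns) != list(self.samples.index):
            raise ValueError("beta columns do not match the sample sheet")
        missing = self.beta.index.difference(self.cpg_annotation.index)
        if len(missing):
            raise ValueError(f"{len(missing)} CpGs missing from the annotation")


# ---------------------------------------------------------------------------
# transforms
# ---------------------------------------------------------------------------


def beta_to_m(beta_matrix: pd.DataFrame) -> pd.DataFrame:
    """M = log2(beta / (1 - beta)), elementwise.

    Raises a domain error naming the first offending CpG/sample when any
    value leaves the open interval (0, 1).
    """
    vals = beta_matrix.to_numpy(dtype=float)
    bad = ~((vals > 0.0) & (vals < 1.0))
    if bad.any():
        i, j = map(int, np.argwhere(bad)[0])
        raise ValueError(
            f"beta value {vals[i, j]!r} outside (0,1) at CpG "
            f"{beta_matrix.index[i]!r}, sample {beta_matrix.columns[j]!r}")
    return pd.DataFrame(np.log2(vals / (1.0 - vals)),
                        index=beta_matrix.index, columns=beta_matrix.columns)


def m_to_beta(m_matrix: pd.DataFrame) -> pd.DataFrame:
    """Inverse of :func:`beta_to_m`."""
    vals = m_matrix.to_numpy(dtype=float)
    return pd.DataFrame(1.0 / (1.0 + np.exp2(-vals)),
                        index=m_matrix.index, columns=m_matrix.columns)


# ---------------------------------------------------------------------------
# probe filtering
# ---------------------------------------------------------------------------


@dataclass
class FilterReport:
    steps: list[dict] = field(default_factory=list)

    def add(self, step: str, n_removed: int, n_remaining: int) -> None:
        self.steps.append({"step": step, "n_removed": int(n_removed),
                           "n_remaining": int(n_remaining)})

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.steps, columns=["step", "n_removed",
                                                 "n_remaining"])


def filter_probes(
    study: MethylationStudy,
    detection_p_table: pd.DataFrame | None = None,
    snp_exclusion: bool = True,
    top_fraction: float = 0.05,
    group_labels: pd.Series | None = None,
    detection_p_threshold: float = 0.01,
) -> tuple[MethylationStudy, FilterReport]:
    """Ordered probe filter: detection p -> SNP-overlap -> top-|delta beta|.

    A CpG fails detection when its detection p-value is >= the threshold in
    ANY sample (strictest reading; recorded in the report).  Probes flagged
    as overlapping a SNP are removed.  Remaining probes are ranked by the
    absolute case-control difference of group mean betas and the top
    ``ceil(top_fraction * n)`` are kept, with boundary ties all retained.
    """
    if not 0.0 < top_fraction <= 1.0:
        raise ValueError("top_fraction must lie in (0, 1]")
    report = FilterReport()
    beta = study.beta

    if detection_p_table is not None:
        det = detection_p_table.reindex(index=beta.index, columns=beta.columns)
        keep = (det.to_numpy() < detection_p_threshold).all(axis=1)
        report.add("detection_p(any sample fails)", (~keep).sum(), keep.sum())
        beta = beta.loc[keep]
    else:
        report.add("detection_p(no table supplied)", 0, len(beta))

    if snp_exclusion:
        flags = study.cpg_annotation.loc[beta.index, "snp_flag"].to_numpy(bool)
        report.add("snp_overlap", flags.sum(), (~flags).sum())
        beta = beta.loc[~flags]

    groups = group_labels if group_labels is not None \
        else study.samples["group"]
    case_cols = groups[groups == "case"].index
    ctrl_cols = groups[groups == "control"].index
    dbeta = (beta[case_cols].mean(axis=1) -
             beta[ctrl_cols].mean(axis=1)).abs()
    n_keep = int(np.ceil(top_fraction * len(beta)))
    if n_keep >= len(beta):
        keep_idx = beta.index
    else:
        cutoff = dbeta.sort_values(ascending=False).iloc[n_keep - 1]
        keep_idx = beta.index[dbeta >= cutoff]  # ties at the boundary stay
    report.add(f"top_delta_beta(top_fraction={top_fraction})",
               len(beta) - len(keep_idx), len(keep_idx))
    beta = beta.loc[keep_idx]

    if beta.empty:
        raise ValueError("all CpGs removed by filtering")
    filtered = MethylationStudy(
        beta=beta,
        cpg_annotation=study.cpg_annotation.loc[beta.index],
        samples=study.samples)
    return filtered, report


# ---------------------------------------------------------------------------
# empirical-Bayes batch adjustment
# ---------------------------------------------------------------------------


def _aprior(delta_hat: np.ndarray) -> float:
    m, s2 = delta_hat.mean(), delta_hat.var(ddof=1)
    return (2.0 * s2 + m ** 2) / s2


def _bprior(delta_hat: np.ndarray) -> float:
    m, s2 = delta_hat.mean(), delta_hat.var(ddof=1)
    return (m * s2 + m ** 3) / s2


def combat_adjust(
    matrix: pd.DataFrame,
    batch_labels: pd.Series,
    group_labels: pd.Series | None = None,
    max_iter: int = 200,
    tol: float = 1e-6,
) -> pd.DataFrame:
    """Parametric empirical-Bayes location/scale batch adjustment.

    Standardizes each feature under a design that protects the biological
    group contrast, shrinks per-batch location effects toward a normal
    prior and per-batch scale effects toward an inverse-gamma prior (both
    with method-of-moments hyperparameters), then back-transforms.  Input
    should be on the M or log2 scale.  A single batch returns the input
    unchanged; a batch with fewer than two samples is an error because its
    scale is not estimable.
    """
    X = matrix.to_numpy(dtype=float)
    batches = pd.Series(batch_labels).reindex(matrix.columns)
    if batches.isna().any():
        raise ValueError("batch label missing for some samples")
    levels = list(pd.unique(batches))
    if len(levels) == 1:
        return matrix.copy()
    n_batch = len(levels)
    counts = batches.value_counts()
    if (counts < 2).any():
        bad = counts[counts < 2].index.tolist()
        raise ValueError(f"batches with <2 samples: {bad}")
    n = X.shape[1]

    # design: batch indicators plus protected biological covariates
    B = np.zeros((n, n_batch))
    for j, lev in enumerate(levels):
        B[(batches == lev).to_numpy(), j] = 1.0
    design_parts = [B]
    if group_labels is not None:
        g = pd.Series(group_labels).reindex(matrix.columns)
        dummies = pd.get_dummies(g, drop_first=True).to_numpy(float)
        design_parts.append(dummies)
    D = np.hstack(design_parts)

    beta_hat, *_ = np.linalg.lstsq(D, X.T, rcond=None)  # (p, features)
    props = (counts.reindex(levels) / n).to_numpy()
    grand_mean = props @ beta_hat[:n_batch, :]
    resid = X.T - D @ beta_hat
    var_pooled = (resid ** 2).mean(axis=0)
    var_pooled = np.where(var_pooled <= 0, 1e-12, var_pooled)

    stand_mean = np.tile(grand_mean, (n, 1))
    if group_labels is not None and D.shape[1] > n_batch:
        stand_mean += D[:, n_batch:] @ beta_hat[n_batch:, :]
    Z = (X.T - stand_mean) / np.sqrt(var_pooled)  # samples x features

    adjusted = Z.copy()
    for j, lev in enumerate(levels):
        sel = (batches == lev).to_numpy()
        nj = int(sel.sum())
        Zb = Z[sel]
        gamma_hat = Zb.mean(axis=0)
        delta_hat = Zb.var(axis=0, ddof=1)
        delta_hat = np.where(delta_hat <= 0, 1e-12, delta_hat)
        gamma_bar, t2 = gamma_hat.mean(), gamma_hat.var(ddof=1)
        lam, theta = _aprior(delta_hat), _bprior(delta_hat)
        gamma_star = gamma_hat.copy()
        delta_star = delta_hat.copy()
        for _ in range(max_iter):
            g_new = (nj * t2 * gamma_hat + delta_star * gamma_bar) / \
                (nj * t2 + delta_star)
            ss = ((Zb - g_new) ** 2).sum(axis=0)
            d_new = (theta + 0.5 * ss) / (nj / 2.0 + lam - 1.0)
            change = max(np.abs(g_new - gamma_star).max(),
                         np.abs(d_new - delta_star).max())
            gamma_star, delta_star = g_new, d_new
            if change < tol:
                break
        adjusted[sel] = (Zb - gamma_star) / np.sqrt(delta_star)

    out = adjusted * np.sqrt(var_pooled) + stand_mean
    return pd.DataFrame(out.T, index=matrix.index, columns=matrix.columns)
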