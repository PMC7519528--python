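"""Promoter-capture Hi-C confirmation and GWAS risk-variant integration.

A significant DMP-DEG pair is 3D-confirmed in a cell state when some
interaction in that state has the gene among its bait (promoter) symbols
and the CpG inside the other-end fragment, and the CpG does not lie in any
gene's promoter window (promoter-proximal CpGs are the short-range case
and are excluded here).  Confirmed pairs are consolidated across the three
CD4 T-cell states, checked against an erythroblast interactome for
cell-type specificity, and intersected with SNP->target-gene links through
three sequential filters (target is a DEG; that DEG has a confirmed pair;
the DMP's host gene is also a target of the same SNP).  Risk-genotype
stratification uses a monotone trend test across allele dosage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .meqtl import promoter_window

CD4_STATES = ("nCD4", "tCD4Non", "tCD4Act")
ERY_STATE = "Ery"


def _norm_symbol(s: str) -> str:
    return s.strip().casefold()


def promoter_windows_frame(gene_annotation: pd.DataFrame) -> pd.DataFrame:
    """Strand-aware promoter windows (1-based inclusive) for all genes."""
    rows = []
    for gene, g in gene_annotation.iterrows():
        lo, hi = promoter_window(int(g["tss"]), g["strand"])
        rows.append((gene, g["chrom"], lo, hi))
    return pd.DataFrame(rows, columns=["gene", "chrom", "lo", "hi"])


def _in_any_promoter(cpg_pos: np.ndarray, cpg_chrom: np.ndarray,
                     windows: pd.DataFrame) -> np.ndarray:
    out = np.zeros(len(cpg_pos), dtype=bool)
    for chrom in pd.unique(windows["chrom"]):
        w = windows[windows["chrom"] == chrom]
        sel = cpg_chrom == chrom
        if not sel.any():
            continue
        lo = w["lo"].to_numpy(np.int64)
        hi = w["hi"].to_numpy(np.int64)
        pos = cpg_pos[sel]
        out[sel] = ((pos[:, None] >= lo[None, :]) &
                    (pos[:, None] <= hi[None, :])).any(axis=1)
    return out


def host_genes(cpg_annotation: pd.DataFrame, gene_annotation: pd.DataFrame,
               upstream: int = 5000) -> pd.Series:
    """Host gene per CpG: the first annotated gene whose extended span
    (TSS-5kb through transcript end, transcription orientation) contains
    the CpG; None when intergenic."""
    gtss = gene_annotation["tss"].to_numpy(np.int64)
    gstrand = gene_annotation["strand"].to_numpy()
    lo = np.where(gstrand == "+", gtss - upstream,
                  gene_annotation["tx_start"].to_numpy(np.int64))
    hi = np.where(gstrand == "+", gene_annotation["tx_end"].to_numpy(np.int64),
                  gtss + upstream)
    gchrom = gene_annotation["chrom"].to_numpy()
    pos = cpg_annotation["pos"].to_numpy(np.int64)
    chrom = cpg_annotation["chrom"].to_numpy()
    contain = (chrom[:, None] == gchrom[None, :]) & \
        (pos[:, None] >= lo[None, :]) & (pos[:, None] <= hi[None, :])
    idx = contain.argmax(axis=1)
    host = np.where(contain.any(axis=1),
                    gene_annotation.index.to_numpy()[idx], None)
    return pd.Series(host, index=cpg_annotation.index, name="host_gene")


# ---------------------------------------------------------------------------
# 3D confirmation
# ---------------------------------------------------------------------------


def confirm_pairs(
    dmp_deg_pairs: pd.DataFrame,
    interactions: pd.DataFrame,
    gene_annotation: pd.DataFrame,
    cpg_annotation: pd.DataFrame,
    states: tuple[str, ...] = CD4_STATES,
) -> pd.DataFrame:
    """Confirm DMP-DEG pairs inside per-state interactomes.

    A pair is confirmed in a state iff an interaction of that state has
    the gene among its bait symbols (matched case-insensitively) and the
    CpG's position inside the other-end fragment (0-based half-open), and
    the CpG is not inside any gene's promoter window.  Returns unique
    (cpg_id, gene) rows with ``states_present`` (semicolon-joined) and an
    ``in_ery`` flag; per-state and shared-by-all counts are attached to
    ``DataFrame.attrs``.  Gene symbols present in the pair table but never
    seen among bait annotations are listed in ``attrs['unmatched_genes']``.
    """
    pairs = dmp_deg_pairs.drop_duplicates(subset=["cpg_id", "gene"]).copy()
    windows = promoter_windows_frame(gene_annotation)
    cpg_pos = cpg_annotation.loc[pairs["cpg_id"], "pos"].to_numpy(np.int64)
    cpg_chrom = cpg_annotation.loc[pairs["cpg_id"], "chrom"].to_numpy()
    in_prom = _in_any_promoter(cpg_pos, cpg_chrom, windows)

    all_states = list(states) + [ERY_STATE]
    per_state_hits: dict[str, np.ndarray] = {}
    bait_symbols_seen: set[str] = set()
    for state in all_states:
        sub = interactions[interactions["cell_state"] == state]
        hit = np.zeros(len(pairs), dtype=bool)
        if not sub.empty:
            gene_to_rows: dict[str, list[int]] = {}
            for i, genes in enumerate(sub["bait_genes"].astype(str)):
                for g in genes.split(";"):
                    g = _norm_symbol(g)
                    if g:
                        gene_to_rows.setdefault(g, []).append(i)
                        bait_symbols_seen.add(g)
            oe_chrom = sub["oe_chrom"].to_numpy()
            oe_start = sub["oe_start"].to_numpy(np.int64)
            oe_end = sub["oe_end"].to_numpy(np.int64)
            for j, (gene, pos, chrom) in enumerate(
                    zip(pairs["gene"], cpg_pos, cpg_chrom)):
                if in_prom[j]:
                    continue
                rows = gene_to_rows.get(_norm_symbol(str(gene)), [])
                pos0 = pos - 1
                for i in rows:
                    if (oe_chrom[i] == chrom and
                            oe_start[i] <= pos0 < oe_end[i]):
                        hit[j] = True
                        break
        per_state_hits[state] = hit

    cd4_any = np.zeros(len(pairs), dtype=bool)
    for state in states:
        cd4_any |= per_state_hits[state]
    out = pairs[cd4_any].copy()
    out["states_present"] = [
        ";".join(s for s in states if per_state_hits[s][j])
        for j in np.flatnonzero(cd4_any)]
    out["in_ery"] = per_state_hits[ERY_STATE][cd4_any]
    out = out.reset_index(drop=True)

    per_state_counts = {s: int(per_state_hits[s].sum()) for s in states}
    shared = np.ones(len(pairs), dtype=bool)
    for s in states:
        shared &= per_state_hits[s]
    out.attrs["per_state_counts"] = per_state_counts
    out.attrs["n_union"] = int(cd4_any.sum())
    out.attrs["n_shared_all"] = int(shared.sum())
    pair_genes = {_norm_symbol(str(g)) for g in pairs["gene"]}
    out.attrs["unmatched_genes"] = sorted(pair_genes - bait_symbols_seen)
    return out


def specificity_check(confirmed_pairs: pd.DataFrame) -> float:
    """Fraction of confirmed pairs also present in the erythroblast set."""
    if confirmed_pairs.empty:
        return 0.0
    return float(confirmed_pairs["in_ery"].astype(bool).mean())


# ---------------------------------------------------------------------------
# SNP integration
# ---------------------------------------------------------------------------


@dataclass
class SnpIntegrationResult:
    hits: pd.DataFrame
    step_counts: dict = field(default_factory=dict)
    dmps_without_host: int = 0


def snp_integration(
    snp_links: pd.DataFrame,
    deg_ids,
    confirmed_pairs: pd.DataFrame,
    dmp_host: pd.Series,
) -> SnpIntegrationResult:
    """Three sequential filters mirroring the SNP->DEG->DMP chain.

    1. SNP target genes intersected with called DEGs;
    2. of those, DEGs possessing a 3D-confirmed DMP-DEG pair;
    3. of those, pairs whose DMP host gene is itself a target of the same
       SNP.  Hits carry all three evidence flags; step counts are monotone
       nonincreasing.  ``snp_links`` needs columns rsid, locus_gene,
       target_genes (';'-joined); ``dmp_host`` maps cpg_id -> host gene
       (None allowed, such DMPs can never pass step 3).
    """
    deg_set = {_norm_symbol(str(g)) for g in deg_ids}
    pairs_by_gene: dict[str, list[tuple[str, str]]] = {}
    for _, row in confirmed_pairs.iterrows():
        pairs_by_gene.setdefault(_norm_symbol(str(row["gene"])), []).append(
            (row["cpg_id"], row["gene"]))

    step1 = 0
    step2 = 0
    hits = []
    no_host = 0
    for _, link in snp_links.iterrows():
        targets = [t for t in str(link["target_genes"]).split(";") if t.strip()]
        tset = {_norm_symbol(t) for t in targets}
        deg_targets = tset & deg_set
        if not deg_targets:
            continue
        step1 += 1
        confirmed_here = []
        for g in sorted(deg_targets):
            confirmed_here.extend(pairs_by_gene.get(g, []))
        if not confirmed_here:
            continue
        step2 += 1
        passed = False
        for cpg_id, gene in confirmed_here:
            host = dmp_host.get(cpg_id)
            if host is None or (isinstance(host, float) and np.isnan(host)):
                no_host += 1
                continue
            if _norm_symbol(str(host)) in tset:
                hits.append({
                    "rsid": link["rsid"], "locus_gene": link["locus_gene"],
                    "cpg_id": cpg_id, "dmp_host_gene": host, "deg": gene,
                    "deg_is_snp_target": True, "pchic_confirmed": True,
                    "snp_interacts_dmp_host": True})
                passed = True
        # a SNP counts once per step regardless of how many pairs it carries
        _ = passed

    hits_df = pd.DataFrame(hits, columns=[
        "rsid", "locus_gene", "cpg_id", "dmp_host_gene", "deg",
        "deg_is_snp_target", "pchic_confirmed", "snp_interacts_dmp_host"])
    step3 = hits_df["rsid"].nunique() if len(hits_df) else 0
    counts = {"step1_deg_targets": step1,
              "step2_confirmed_pair": step2,
              "step3_dmp_host_in_targets": int(step3)}
    return SnpIntegrationResult(hits=hits_df, step_counts=counts,
                                dmps_without_host=no_host)


# ---------------------------------------------------------------------------
# genotype stratification
# ---------------------------------------------------------------------------


def jonckheere_terpstra(groups: list[np.ndarray]) -> tuple[float, float]:
    """Jonckheere-Terpstra monotone-trend test across ordered groups.

    JT = sum over ordered group pairs (i<j) of #{x in group i < y in
    group j} + 0.5 #ties; standardized with the no-tie null mean and
    variance and referred to the normal distribution (two-sided).
    Returns (z, p).
    """
    k = len(groups)
    jt = 0.0
    for i in range(k):
        for j in range(i + 1, k):
            a, b = groups[i][:, None], groups[j][None, :]
            jt += (a < b).sum() + 0.5 * (a == b).sum()
    n_i = np.array([len(g) for g in groups], dtype=float)
    N = n_i.sum()
    mean = (N ** 2 - (n_i ** 2).sum()) / 4.0
    var = (N ** 2 * (2 * N + 3) - (n_i ** 2 * (2 * n_i + 3)).sum()) / 72.0
    if var <= 0:
        return 0.0, 1.0
    z = (jt - mean) / np.sqrt(var)
    return float(z), float(2.0 * stats.norm.sf(abs(z)))


@dataclass
class TrendResult:
    trend_stat: float
    p: float
    direction: str
    n_groups: int
    tested: bool
    reason: str = ""


def genotype_stratify(values: pd.Series, genotype: pd.Series) -> TrendResult:
    """Monotone-trend test of a feature across risk-allele dosage (0/1/2).

    Jonckheere-Terpstra across the dosage groups present; rank-sum when
    only two dosage groups occur; flagged untested below two groups.
    """
    df = pd.DataFrame({"value": values, "dosage": genotype}).dropna()
    levels = sorted(df["dosage"].unique())
    groups = [df.loc[df["dosage"] == lv, "value"].to_numpy(float)
              for lv in levels]
    if len(groups) < 2:
        return TrendResult(0.0, 1.0, "none", len(groups), tested=False,
                           reason="fewer than 2 dosage groups present")
    if df["value"].nunique() == 1:
        return TrendResult(0.0, 1.0, "none", len(groups), tested=True)
    if len(groups) == 2:
        u = stats.mannwhitneyu(groups[0], groups[1],
                               alternative="two-sided")
        direction = "increasing" if groups[1].mean() > groups[0].mean() \
            else "decreasing"
        return TrendResult(float(u.statistic), float(u.pvalue), direction,
                           2, tested=True)
    z, p = jonckheere_terpstra(groups)
    direction = "increasing" if z > 0 else ("decreasing" if z < 0 else "none")
    return TrendResult(z, p, direction, len(groups), tested=True)
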