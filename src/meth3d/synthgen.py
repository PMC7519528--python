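"""Synthetic cohort generator with planted, recoverable effects.

Emulates a two-group methylation/expression case-control study (48 patients
vs 16 matched healthy donors by default) on a small artificial genome:

* a CpG annotation, a gene annotation (TSS, strand, transcript span) and a
  restriction-fragment map tiling each chromosome (median fragment ~5 kb,
  mimicking a HindIII digest);
* a beta-value matrix with bimodal baselines, logit-normal per-sample noise,
  batch structure, and planted mean-shift CpGs (DMPs), multi-CpG regions
  (DMRs) and differentially variable CpGs (DVPs);
* a log2 expression matrix with planted group fold changes (DEGs) and
  cis methylation->expression couplings within 5 Mb;
* fragment-level chromatin interactions (promoter bait <-> other end) for
  three CD4 T-cell states plus an erythroblast control set, carrying a
  chosen subset of the couplings;
* ChIP-seq-like peak sets and SNP->target-gene links whose risk-allele
  dosage perturbs the coupled methylation/expression values.

Every planted effect is recorded in a :class:`SyntheticTruth` so each
downstream stage has a parameter-recovery test.  All generators are
deterministic functions of ``config.seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

CD4_STATES = ("nCD4", "tCD4Non", "tCD4Act")
ERY_STATE = "Ery"

# spacing (bp) of the CpGs that make up a planted region; must stay below
# the region caller's max_gap so a planted region is a single probe cluster
DMR_CPG_SPACING = 150


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CouplingSpec:
    """A planted cis methylation->expression coupling.

    ``expression += slope * (beta[cpg] - mean(beta[cpg]))`` per sample.
    ``confirmed_3d`` couplings are additionally emitted as fragment-level
    interactions (bait at the gene promoter, other end at the CpG) in the
    listed cell states; ``in_ery`` controls erythroblast sharing (``None``
    defers to ``SimulationConfig.ery_share``).
    """

    cpg_index: int
    gene_index: int
    slope: float
    confirmed_3d: bool = False
    states: tuple[str, ...] = CD4_STATES
    in_ery: bool | None = None

    @property
    def sign(self) -> str:
        return "negative" if self.slope < 0 else "positive"


@dataclass(frozen=True)
class SnpLinkSpec:
    """A planted GWAS risk variant with chromatin-loop target genes.

    ``meth_effect`` / ``expr_effect`` are the per-risk-allele additive
    shifts applied to case samples at the coupled CpG (beta scale) and
    coupled gene (log2 scale); they make genotype dosage correlate with the
    planted molecular effects.  ``full_interactome=True`` marks links that
    should survive the whole SNP->DEG->DMP filter chain.
    """

    rsid: str
    locus_gene_index: int
    chrom: str
    start: int
    end: int
    target_gene_indices: tuple[int, ...]
    coupled_cpg_index: int | None = None
    coupled_gene_index: int | None = None
    meth_effect: float = 0.0
    expr_effect: float = 0.0
    maf: float = 0.3
    full_interactome: bool = False


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the synthetic study.

    Defaults mirror the emulated cohort: 48 cases vs 16 controls, two
    chromosomes of 50 Mb (so the 5 Mb cis window is non-trivial), two
    hybridization batches, bimodal beta baselines and M-scale noise.
    """

    n_cases: int = 48
    n_controls: int = 16
    n_cpgs: int = 2000
    n_genes: int = 200
    n_chroms: int = 2
    chrom_length: int = 50_000_000
    n_batches: int = 2
    batch_shift_sd: float = 0.0
    planted_dmps: tuple[tuple[int, float], ...] = ()
    planted_dmrs: tuple[tuple[str, int, int, float], ...] = ()
    planted_dvps: tuple[tuple[int, float], ...] = ()
    planted_degs: tuple[tuple[int, float], ...] = ()
    planted_couplings: tuple[CouplingSpec, ...] = ()
    planted_snp_links: tuple[SnpLinkSpec, ...] = ()
    fragment_size_mean: int = 5000
    noise_sd_m: float = 0.4
    expr_noise_sd: float = 0.3
    expr_baseline_mean: float = 7.0
    expr_baseline_sd: float = 1.5
    coupling_var_inflation: float = 2.0
    dvp_affected_fraction: float = 0.5
    snp_flag_fraction: float = 0.02
    n_decoy_interactions: int = 100
    ery_share: float = 0.1
    clip_margin: float = 0.001
    seed: int = 0

    # -- validation ---------------------------------------------------

    def validate(self) -> None:
        for name in ("n_cases", "n_controls", "n_cpgs", "n_genes",
                     "n_chroms", "chrom_length", "n_batches",
                     "fragment_size_mean"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        chroms = {f"chr{i + 1}" for i in range(self.n_chroms)}
        for idx, delta in self.planted_dmps:
            self._check_cpg(idx)
            if abs(delta) > 0.6:
                raise ValueError(
                    f"planted DMP delta_beta {delta} cannot keep betas in "
                    "(0,1) with the clipping margin")
        for chrom, start, k, delta in self.planted_dmrs:
            if chrom not in chroms:
                raise ValueError(f"planted DMR on unknown chromosome {chrom}")
            if k < 2:
                raise ValueError("a planted DMR needs >=2 CpGs")
            if start < 1 or start + (k - 1) * DMR_CPG_SPACING > self.chrom_length:
                raise ValueError("planted DMR does not fit on the chromosome")
            if abs(delta) > 0.6:
                raise ValueError(f"planted DMR delta_beta {delta} too large")
        for idx, ratio in self.planted_dvps:
            self._check_cpg(idx)
            if ratio <= 0:
                raise ValueError("variance_ratio must be > 0")
        for idx, _ in self.planted_degs:
            self._check_gene(idx)
        for c in self.planted_couplings:
            self._check_cpg(c.cpg_index)
            self._check_gene(c.gene_index)
        if not 0 <= self.ery_share <= 1:
            raise ValueError("ery_share must lie in [0,1]")
        if not 0 < self.clip_margin < 0.5:
            raise ValueError("clip_margin must lie in (0, 0.5)")

    def _check_cpg(self, idx: int) -> None:
        if not 0 <= idx < self.n_cpgs:
            raise ValueError(f"CpG index {idx} out of range")

    def _check_gene(self, idx: int) -> None:
        if not 0 <= idx < self.n_genes:
            raise ValueError(f"gene index {idx} out of range")

    @property
    def n_samples(self) -> int:
        return self.n_cases + self.n_controls

    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chroms)]


@dataclass
class SyntheticTruth:
    """Book-keeping of every planted effect, keyed by generated ids."""

    true_dmp_ids: list[str] = field(default_factory=list)
    true_dmr_intervals: list[dict] = field(default_factory=list)
    true_dvp_ids: list[str] = field(default_factory=list)
    true_deg_ids: list[str] = field(default_factory=list)
    true_coupling_pairs: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["cpg_id", "gene", "slope", "sign",
                     "confirmed_3d", "in_ery"]))
    true_interactome_hits: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["rsid", "locus_gene", "cpg_id", "dmp_host_gene", "deg"]))


# ---------------------------------------------------------------------------
# annotation, fragments
# ---------------------------------------------------------------------------


def _even_split(total: int, parts: int) -> list[int]:
    base = total // parts
    return [base + (1 if i < total % parts else 0) for i in range(parts)]


def simulate_annotation(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate the CpG annotation, gene annotation and fragment map.

    CpG positions are strictly increasing per chromosome (1-based); planted
    DMR positions are reserved exactly so the regions exist in the
    annotation.  Fragments tile each chromosome without gaps or overlaps
    (0-based half-open) with lognormal sizes whose median is
    ``fragment_size_mean``.  Deterministic under ``config.seed``; the
    annotation does not depend on which single-CpG effects are planted,
    only on the counts and the planted regions.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 1])
    chroms = config.chrom_names()

    # --- CpGs
    reserved: dict[str, np.ndarray] = {c: np.array([], dtype=np.int64) for c in chroms}
    for chrom, start, k, _delta in config.planted_dmrs:
        pos = start + DMR_CPG_SPACING * np.arange(k, dtype=np.int64)
        reserved[chrom] = np.concatenate([reserved[chrom], pos])
    counts = _even_split(config.n_cpgs, config.n_chroms)
    rows = []
    for chrom, n_on_chrom in zip(chroms, counts):
        res = np.unique(reserved[chrom])
        n_random = n_on_chrom - len(res)
        if n_random < 0:
            raise ValueError(
                f"chromosome {chrom}: more reserved DMR CpGs than its quota")
        margin = 2000
        span = config.chrom_length - 2 * margin
        if span < 4 * n_on_chrom:
            raise ValueError("chrom_length too small to place requested CpGs")
        pool = rng.choice(span, size=min(span, 2 * n_random + 10),
                          replace=False) + margin
        pool = pool[~np.isin(pool, res)][:n_random]
        if len(pool) < n_random:
            raise ValueError("could not place requested CpGs without collision")
        pos = np.sort(np.concatenate([res, pool.astype(np.int64)]))
        rows.append(pd.DataFrame({"chrom": chrom, "pos": pos}))
    cpg_ann = pd.concat(rows, ignore_index=True)
    cpg_ann.index = pd.Index(
        [f"cg{i + 1:08d}" for i in range(len(cpg_ann))], name="cpg_id")
    snp_flag = rng.random(len(cpg_ann)) < config.snp_flag_fraction
    # never flag a CpG that carries a planted effect: flagged probes are
    # removed before testing, which would make recovery tests ill-posed
    protected = {i for i, _ in config.planted_dmps}
    protected |= {i for i, _ in config.planted_dvps}
    protected |= {c.cpg_index for c in config.planted_couplings}
    protected |= {s.coupled_cpg_index for s in config.planted_snp_links
                  if s.coupled_cpg_index is not None}
    dmr_pos = {(c, int(p)) for c in chroms for p in reserved[c]}
    for i, (chrom, pos) in enumerate(zip(cpg_ann["chrom"], cpg_ann["pos"])):
        if i in protected or (chrom, int(pos)) in dmr_pos:
            snp_flag[i] = False
    cpg_ann["snp_flag"] = snp_flag

    # --- genes
    gcounts = _even_split(config.n_genes, config.n_chroms)
    grows = []
    for chrom, n_on_chrom in zip(chroms, gcounts):
        gmargin = min(100_000, config.chrom_length // 10)
        tss = np.sort(rng.choice(config.chrom_length - 2 * gmargin,
                                 size=n_on_chrom, replace=False) + gmargin)
        strand = rng.choice(["+", "-"], size=n_on_chrom)
        length = np.exp(rng.normal(np.log(30_000), 0.5, n_on_chrom)).astype(np.int64)
        tx_start = np.where(strand == "+", tss, np.maximum(tss - length, 1))
        tx_end = np.where(strand == "+",
                          np.minimum(tss + length, config.chrom_length), tss)
        grows.append(pd.DataFrame({
            "chrom": chrom, "strand": strand, "tss": tss,
            "tx_start": tx_start, "tx_end": tx_end}))
    gene_ann = pd.concat(grows, ignore_index=True)
    gene_ann.index = pd.Index(
        [f"G{i + 1:04d}" for i in range(len(gene_ann))], name="gene")

    # --- fragments
    frows = []
    for chrom in chroms:
        n_guess = int(config.chrom_length / config.fragment_size_mean * 1.6) + 10
        sizes = np.exp(rng.normal(np.log(config.fragment_size_mean), 0.35,
                                  n_guess)).astype(np.int64)
        sizes = np.maximum(sizes, 200)
        ends = np.cumsum(sizes)
        ends = ends[ends < config.chrom_length]
        edges = np.concatenate([[0], ends, [config.chrom_length]])
        frows.append(pd.DataFrame({
            "chrom": chrom, "start": edges[:-1], "end": edges[1:]}))
    fragments = pd.concat(frows, ignore_index=True)
    fragments.index = pd.Index(
        [f"F{i + 1:06d}" for i in range(len(fragments))], name="frag_id")
    return cpg_ann, gene_ann, fragments


# ---------------------------------------------------------------------------
# methylation
# ---------------------------------------------------------------------------


def _logit2(beta: np.ndarray) -> np.ndarray:
    return np.log2(beta / (1.0 - beta))


def _expit2(m: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp2(-m))


def _dmr_member_indices(config: SimulationConfig,
                        cpg_ann: pd.DataFrame) -> list[tuple[int, ...]]:
    pos_lookup = {(c, int(p)): i for i, (c, p) in
                  enumerate(zip(cpg_ann["chrom"], cpg_ann["pos"]))}
    out = []
    for chrom, start, k, _delta in config.planted_dmrs:
        idx = tuple(pos_lookup[(chrom, start + j * DMR_CPG_SPACING)]
                    for j in range(k))
        out.append(idx)
    return out


def simulate_methylation(
    config: SimulationConfig,
    cpg_ann: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Generate the beta matrix, the sample sheet and the planted truth.

    Baselines come from a two-component mixture (low ~0.1, high ~0.85,
    the usual array bimodality); per-sample noise and batch shifts are
    applied on the M (logit2) scale, group effects on the beta scale.
    CpGs that take part in a planted coupling are re-based to intermediate
    methylation with inflated inter-individual variance, the regime real
    cis-meQTL CpGs occupy.  Planted DVPs are modelled as a methylation
    shift in a random subset of case samples (``dvp_affected_fraction``),
    which inflates the case variance by the requested ratio -- the
    patient-heterogeneity mechanism differential-variability callers are
    built to detect.  All betas are clipped to
    ``(clip_margin, 1 - clip_margin)``.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 2])
    n_cpg, n_s = config.n_cpgs, config.n_samples
    n_case = config.n_cases

    # sample sheet -----------------------------------------------------
    ids = [f"SSc{i + 1:03d}" for i in range(n_case)] + \
          [f"HD{i + 1:03d}" for i in range(config.n_controls)]
    group = ["case"] * n_case + ["control"] * config.n_controls
    subtype = list(rng.choice(["dcSSc", "lcSSc", "ssSSc", "eSSc"],
                              p=[0.4, 0.4, 0.15, 0.05], size=n_case)) + \
        ["none"] * config.n_controls
    sex = np.where(rng.random(n_s) < 0.85, "F", "M")
    age = rng.integers(30, 71, size=n_s)
    batch = np.empty(n_s, dtype=object)
    for gval in ("case", "control"):
        cols = [i for i, g in enumerate(group) if g == gval]
        for j, i in enumerate(cols):
            batch[i] = f"B{j % config.n_batches + 1}"
    immunosuppressor = np.concatenate(
        [rng.random(n_case) < 0.5, np.zeros(config.n_controls, dtype=bool)])
    vasodilator = np.concatenate(
        [rng.random(n_case) < 0.5, np.zeros(config.n_controls, dtype=bool)])
    samples = pd.DataFrame({
        "group": group, "subtype": subtype, "sex": sex, "age": age,
        "batch": batch, "immunosuppressor": immunosuppressor,
        "vasodilator": vasodilator,
    }, index=pd.Index(ids, name="sample_id"))

    # genotypes: risk-allele dosage for cases, missing for controls
    for link in config.planted_snp_links:
        dosage = np.full(n_s, np.nan)
        dosage[:n_case] = rng.binomial(2, link.maf, size=n_case)
        samples[f"geno_{link.rsid}"] = dosage

    # baselines --------------------------------------------------------
    high = rng.random(n_cpg) < 0.6
    mu = np.where(
        high,
        np.clip(rng.normal(0.85, 0.05, n_cpg), 0.60, 0.97),
        np.clip(rng.normal(0.10, 0.03, n_cpg), 0.03, 0.25))

    dmr_members = _dmr_member_indices(config, cpg_ann)
    planted_shift = dict(config.planted_dmps)
    for (chrom, start, k, delta), idx in zip(config.planted_dmrs, dmr_members):
        for i in idx:
            planted_shift[i] = delta
    # re-base CpGs whose planted shift would leave (0,1)
    lo, hi = 0.05, 0.95
    for i, delta in planted_shift.items():
        if not lo < mu[i] + delta < hi:
            if delta >= 0:
                mu[i] = rng.uniform(lo + 0.03, hi - delta - 0.02)
            else:
                mu[i] = rng.uniform(lo - delta + 0.02, hi - 0.03)

    # coupling CpGs: intermediate, extra-variable (meQTL-like)
    noise_scale = np.ones(n_cpg)
    coupling_idx = sorted({c.cpg_index for c in config.planted_couplings} |
                          {s.coupled_cpg_index for s in config.planted_snp_links
                           if s.coupled_cpg_index is not None})
    for i in coupling_idx:
        if i not in planted_shift or not (0.3 < mu[i] < 0.7):
            mu[i] = rng.uniform(0.35, 0.65)
        noise_scale[i] = config.coupling_var_inflation

    m = _logit2(mu)[:, None] + \
        rng.normal(0.0, config.noise_sd_m, (n_cpg, n_s)) * noise_scale[:, None]

    # planted DVPs: shift a random case subset to inflate case variance
    for idx, ratio in config.planted_dvps:
        f = config.dvp_affected_fraction
        sd = config.noise_sd_m * noise_scale[idx]
        d = sd * np.sqrt(max(ratio - 1.0, 0.0) / (f * (1.0 - f)))
        n_aff = max(int(round(f * n_case)), 1)
        affected = rng.choice(n_case, size=n_aff, replace=False)
        direction = 1.0 if mu[idx] < 0.5 else -1.0
        m[idx, affected] += direction * d

    # batch shifts on the M scale
    if config.batch_shift_sd > 0:
        gamma = rng.normal(0.0, config.batch_shift_sd,
                           (config.n_batches, n_cpg))
        bidx = np.array([int(b[1:]) - 1 for b in batch])
        m += gamma[bidx, :].T

    beta = _expit2(m)

    # group effects on the beta scale (cases only)
    for i, delta in planted_shift.items():
        beta[i, :n_case] += delta
    for link in config.planted_snp_links:
        if link.coupled_cpg_index is not None and link.meth_effect != 0.0:
            dos = samples[f"geno_{link.rsid}"].to_numpy()[:n_case]
            beta[link.coupled_cpg_index, :n_case] += link.meth_effect * dos

    beta = np.clip(beta, config.clip_margin, 1.0 - config.clip_margin)
    beta_df = pd.DataFrame(beta, index=cpg_ann.index, columns=ids)

    # truth ------------------------------------------------------------
    truth = SyntheticTruth()
    truth.true_dmp_ids = [cpg_ann.index[i] for i, _ in config.planted_dmps]
    truth.true_dvp_ids = [cpg_ann.index[i] for i, _ in config.planted_dvps]
    for (chrom, start, k, delta), idx in zip(config.planted_dmrs, dmr_members):
        truth.true_dmr_intervals.append({
            "chrom": chrom, "start": start,
            "end": start + (k - 1) * DMR_CPG_SPACING,
            "n_cpgs": k, "delta_beta": delta,
            "cpg_ids": [cpg_ann.index[i] for i in idx]})
    return beta_df, samples, truth


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------


def simulate_expression(
    config: SimulationConfig,
    gene_ann: pd.DataFrame,
    cpg_ann: pd.DataFrame,
    beta_matrix: pd.DataFrame,
    samples: pd.DataFrame,
    truth: SyntheticTruth | None = None,
) -> pd.DataFrame:
    """Generate the log2 expression matrix (genes x samples).

    ``expr = baseline + noise + log2fc * is_case + slope * centred beta`` at
    coupled CpGs, plus per-allele dosage effects for planted SNP links.
    Raises if a planted coupling spans chromosomes or exceeds the 5 Mb cis
    window, so downstream recovery tests are well-posed.
    """
    config.validate()
    for c in config.planted_couplings:
        crow = cpg_ann.iloc[c.cpg_index]
        grow = gene_ann.iloc[c.gene_index]
        if crow["chrom"] != grow["chrom"]:
            raise ValueError(
                f"planted coupling CpG {cpg_ann.index[c.cpg_index]} and gene "
                f"{gene_ann.index[c.gene_index]} lie on different chromosomes")
        if abs(int(crow["pos"]) - int(grow["tss"])) > 5_000_000:
            raise ValueError(
                f"planted coupling {cpg_ann.index[c.cpg_index]}-"
                f"{gene_ann.index[c.gene_index]} exceeds the 5 Mb cis window")

    rng = np.random.default_rng([config.seed, 3])
    n_g, n_s = config.n_genes, config.n_samples
    baseline = rng.normal(config.expr_baseline_mean, config.expr_baseline_sd, n_g)
    expr = baseline[:, None] + rng.normal(0.0, config.expr_noise_sd, (n_g, n_s))

    is_case = (samples["group"] == "case").to_numpy()
    for idx, lfc in config.planted_degs:
        expr[idx, is_case] += lfc
    beta = beta_matrix.to_numpy()
    for c in config.planted_couplings:
        b = beta[c.cpg_index]
        expr[c.gene_index] += c.slope * (b - b.mean())
    n_case = int(is_case.sum())
    for link in config.planted_snp_links:
        if link.coupled_gene_index is not None and link.expr_effect != 0.0:
            dos = samples[f"geno_{link.rsid}"].to_numpy()[:n_case]
            expr[link.coupled_gene_index, :n_case] += link.expr_effect * dos

    if truth is not None:
        truth.true_deg_ids = [gene_ann.index[i] for i, _ in config.planted_degs]
        truth.true_coupling_pairs = pd.DataFrame({
            "cpg_id": [cpg_ann.index[c.cpg_index] for c in config.planted_couplings],
            "gene": [gene_ann.index[c.gene_index] for c in config.planted_couplings],
            "slope": [c.slope for c in config.planted_couplings],
            "sign": [c.sign for c in config.planted_couplings],
            "confirmed_3d": [c.confirmed_3d for c in config.planted_couplings],
            "in_ery": [bool(c.in_ery) for c in config.planted_couplings],
        })
    return pd.DataFrame(expr, index=gene_ann.index, columns=samples.index)


# ---------------------------------------------------------------------------
# interactions
# ---------------------------------------------------------------------------


def _fragment_of(fragments: pd.DataFrame, chrom: str, pos0: int) -> pd.Series:
    """Fragment (row) containing 0-based position ``pos0`` on ``chrom``."""
    sub = fragments[fragments["chrom"] == chrom]
    starts = sub["start"].to_numpy()
    i = int(np.searchsorted(starts, pos0, side="right")) - 1
    if i < 0 or pos0 >= int(sub["end"].iloc[i]):
        raise ValueError(f"position {chrom}:{pos0} outside the fragment map")
    return sub.iloc[i]


def _genes_in_fragment(gene_ann: pd.DataFrame, frag: pd.Series) -> list[str]:
    tss0 = gene_ann["tss"].to_numpy() - 1
    mask = (gene_ann["chrom"] == frag["chrom"]).to_numpy() & \
        (tss0 >= int(frag["start"])) & (tss0 < int(frag["end"]))
    return list(gene_ann.index[mask])


def promoter_window_of(tss: int, strand: str,
                       upstream: int = 5000, downstream: int = 1000) -> tuple[int, int]:
    """1-based inclusive promoter interval, strand-aware (upstream is 5')."""
    if strand == "+":
        return max(tss - upstream, 1), tss + downstream
    return max(tss - downstream, 1), tss + upstream


def simulate_interactions(
    cpg_ann: pd.DataFrame,
    gene_ann: pd.DataFrame,
    fragments: pd.DataFrame,
    config: SimulationConfig,
    truth: SyntheticTruth | None = None,
) -> pd.DataFrame:
    """Emit fragment-level interactions per cell state.

    Each 3D-confirmed coupling becomes an interaction whose bait fragment
    contains the target gene's TSS (bait annotated with every gene whose
    TSS falls in the fragment) and whose other end contains the CpG, in
    the coupling's cell states; decoy interactions are added on top.  A
    coupling whose CpG lies inside its target gene's promoter window
    cannot be marked confirmed (it would be excluded by the downstream
    promoter rule).  Erythroblast sharing follows each coupling's
    ``in_ery`` flag, falling back to a ``config.ery_share`` coin flip.
    """
    rng = np.random.default_rng([config.seed, 4])
    rows = []
    for c in config.planted_couplings:
        if not c.confirmed_3d:
            continue
        crow = cpg_ann.iloc[c.cpg_index]
        grow = gene_ann.iloc[c.gene_index]
        pw = promoter_window_of(int(grow["tss"]), grow["strand"])
        if crow["chrom"] == grow["chrom"] and pw[0] <= int(crow["pos"]) <= pw[1]:
            raise ValueError(
                f"coupling CpG {cpg_ann.index[c.cpg_index]} lies in the "
                f"promoter window of its target gene "
                f"{gene_ann.index[c.gene_index]}; it cannot be 3D-confirmed")
        bait = _fragment_of(fragments, grow["chrom"], int(grow["tss"]) - 1)
        oe = _fragment_of(fragments, crow["chrom"], int(crow["pos"]) - 1)
        genes = _genes_in_fragment(gene_ann, bait)
        if gene_ann.index[c.gene_index] not in genes:
            genes.append(gene_ann.index[c.gene_index])
        in_ery = c.in_ery if c.in_ery is not None \
            else bool(rng.random() < config.ery_share)
        states = list(c.states) + ([ERY_STATE] if in_ery else [])
        for state in states:
            rows.append((bait["chrom"], int(bait["start"]), int(bait["end"]),
                         oe["chrom"], int(oe["start"]), int(oe["end"]),
                         ";".join(genes), state))

    # decoys: promoter baits looped to random other ends
    frag_with_tss = []
    for chrom in config.chrom_names():
        sub = fragments[fragments["chrom"] == chrom]
        tss0 = gene_ann.loc[gene_ann["chrom"] == chrom, "tss"].to_numpy() - 1
        idx = np.searchsorted(sub["start"].to_numpy(), tss0, side="right") - 1
        frag_with_tss.extend(sub.index[np.unique(idx)])
    n_frag = len(fragments)
    for _ in range(config.n_decoy_interactions):
        bait = fragments.loc[rng.choice(frag_with_tss)]
        oe = fragments.iloc[int(rng.integers(n_frag))]
        genes = _genes_in_fragment(gene_ann, bait)
        states = [s for s in CD4_STATES if rng.random() < 0.7] or [CD4_STATES[0]]
        if rng.random() < 0.3:
            states.append(ERY_STATE)
        for state in states:
            rows.append((bait["chrom"], int(bait["start"]), int(bait["end"]),
                         oe["chrom"], int(oe["start"]), int(oe["end"]),
                         ";".join(genes), state))

    interactions = pd.DataFrame(rows, columns=[
        "bait_chrom", "bait_start", "bait_end",
        "oe_chrom", "oe_start", "oe_end", "bait_genes", "cell_state"])

    if truth is not None:
        hits = []
        for link in config.planted_snp_links:
            if not link.full_interactome:
                continue
            cpg_id = cpg_ann.index[link.coupled_cpg_index]
            host = find_host_gene(int(cpg_ann.iloc[link.coupled_cpg_index]["pos"]),
                                  cpg_ann.iloc[link.coupled_cpg_index]["chrom"],
                                  gene_ann)
            hits.append((link.rsid, gene_ann.index[link.locus_gene_index],
                         cpg_id, host, gene_ann.index[link.coupled_gene_index]))
        truth.true_interactome_hits = pd.DataFrame(
            hits, columns=["rsid", "locus_gene", "cpg_id",
                           "dmp_host_gene", "deg"])
    return interactions


def find_host_gene(pos: int, chrom: str, gene_ann: pd.DataFrame,
                   upstream: int = 5000) -> str | None:
    """Gene whose extended span (TSS-5kb through transcript end, in
    transcription orientation) contains the 1-based position; first match
    in annotation order, ``None`` when intergenic."""
    sub = gene_ann[gene_ann["chrom"] == chrom]
    for gene, row in sub.iterrows():
        if row["strand"] == "+":
            lo, hi = int(row["tss"]) - upstream, int(row["tx_end"])
        else:
            lo, hi = int(row["tx_start"]), int(row["tss"]) + upstream
        if lo <= pos <= hi:
            return gene
    return None


# ---------------------------------------------------------------------------
# peaks
# ---------------------------------------------------------------------------


def simulate_peaks(
    cpg_ann: pd.DataFrame,
    enriched_cpg_ids: Sequence[str],
    coverage_fraction: float,
    seed: int,
    background_rate: float = 0.0,
    halfwidth: int = 150,
) -> pd.DataFrame:
    """Place peaks covering ``coverage_fraction`` of the enriched CpGs and a
    ``background_rate`` of the remaining array CpGs (BED convention,
    0-based half-open)."""
    rng = np.random.default_rng([seed, 5])
    enriched = set(enriched_cpg_ids)
    rows = []
    for cpg_id, row in cpg_ann.iterrows():
        rate = coverage_fraction if cpg_id in enriched else background_rate
        if rate > 0 and rng.random() < rate:
            pos0 = int(row["pos"]) - 1
            rows.append((row["chrom"], max(pos0 - halfwidth, 0),
                         pos0 + halfwidth + 1))
    peaks = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    return peaks.sort_values(["chrom", "start"], kind="mergesort",
                             ignore_index=True)


# ---------------------------------------------------------------------------
# the default planted study ("design a cohort")
# ---------------------------------------------------------------------------


@dataclass
class SyntheticSuite:
    """A fully realised synthetic study: config, annotations, matrices,
    interactions, peaks, SNP links and the planted truth."""

    config: SimulationConfig
    cpg_ann: pd.DataFrame
    gene_ann: pd.DataFrame
    fragments: pd.DataFrame
    beta: pd.DataFrame
    samples: pd.DataFrame
    expr: pd.DataFrame
    interactions: pd.DataFrame
    snp_links: pd.DataFrame
    truth: SyntheticTruth


def default_config(seed: int = 0, **overrides) -> SimulationConfig:
    """Base configuration (counts and noise only) of the default study."""
    cfg = SimulationConfig(
        seed=seed,
        batch_shift_sd=0.5,
        planted_dmrs=(
            ("chr1", 10_000_000, 5, 0.2),
            ("chr1", 30_000_000, 5, -0.2),
            ("chr2", 20_000_000, 5, 0.2),
        ),
    )
    return replace(cfg, **overrides)


def design_cohort(seed: int = 0,
                  n_dmps: int = 30,
                  n_dvps: int = 10,
                  n_extra_degs: int = 20,
                  n_confirmed_couplings: int = 10,
                  n_unconfirmed_couplings: int = 10,
                  n_full_interactomes: int = 4,
                  n_decoy_snp_links: int = 40,
                  **config_overrides) -> SyntheticSuite:
    """Build the default planted study around a realised annotation.

    The annotation is generated first; planted single-CpG effects,
    couplings and SNP links are then chosen from the realised geometry so
    the structural constraints hold by construction: coupling CpGs sit
    outside every promoter window and within 5 Mb of the target gene's
    TSS, and full-interactome CpGs additionally sit inside a host gene
    whose symbol joins the SNP's target set.  The annotation itself does
    not depend on these choices, so re-simulating with the final config
    reproduces it exactly.
    """
    base = default_config(seed, **config_overrides)
    cpg_ann, gene_ann, fragments = simulate_annotation(base)
    rng = np.random.default_rng([seed, 6])

    pos = cpg_ann["pos"].to_numpy()
    chrom = cpg_ann["chrom"].to_numpy()

    # promoter membership and host genes for every CpG (vectorized)
    in_promoter = np.zeros(len(cpg_ann), dtype=bool)
    for _, g in gene_ann.iterrows():
        lo, hi = promoter_window_of(int(g["tss"]), g["strand"])
        in_promoter |= (chrom == g["chrom"]) & (pos >= lo) & (pos <= hi)

    gene_chrom = gene_ann["chrom"].to_numpy()
    gene_tss = gene_ann["tss"].to_numpy()
    gstrand = gene_ann["strand"].to_numpy()
    glo = np.where(gstrand == "+", gene_tss - 5000,
                   gene_ann["tx_start"].to_numpy())
    ghi = np.where(gstrand == "+", gene_ann["tx_end"].to_numpy(),
                   gene_tss + 5000)
    contain = (chrom[:, None] == gene_chrom[None, :]) & \
        (pos[:, None] >= glo[None, :]) & (pos[:, None] <= ghi[None, :])
    host = np.where(contain.any(axis=1),
                    gene_ann.index.to_numpy()[contain.argmax(axis=1)], None)

    dmr_member = np.zeros(len(cpg_ann), dtype=bool)
    for idx in _dmr_member_indices(base, cpg_ann):
        for i in idx:
            dmr_member[i] = True

    used_cpgs: set[int] = set()
    used_genes: set[int] = set()

    def pick_coupling(need_host: bool) -> tuple[int, int] | None:
        cand = np.flatnonzero(~in_promoter & ~dmr_member)
        cand = rng.permutation(cand)
        for ci in cand:
            if int(ci) in used_cpgs:
                continue
            if need_host and host[ci] is None:
                continue
            near = np.flatnonzero(
                (gene_chrom == chrom[ci]) &
                (np.abs(gene_tss - pos[ci]) <= 4_500_000))
            near = rng.permutation(near)
            for gi in near:
                if int(gi) in used_genes:
                    continue
                if need_host and gene_ann.index[gi] == host[ci]:
                    continue
                return int(ci), int(gi)
        return None

    couplings: list[CouplingSpec] = []
    snp_links: list[SnpLinkSpec] = []
    dmps: list[tuple[int, float]] = []
    degs: list[tuple[int, float]] = []

    def plant_pair(ci: int, gi: int, *, confirmed: bool,
                   states: tuple[str, ...], in_ery: bool) -> CouplingSpec:
        slope = float(rng.choice([-1, 1]) * rng.uniform(1.5, 2.5))
        spec = CouplingSpec(ci, gi, slope, confirmed_3d=confirmed,
                            states=states, in_ery=in_ery)
        couplings.append(spec)
        used_cpgs.add(ci)
        used_genes.add(gi)
        delta = float(rng.choice([-1, 1]) * 0.15)
        dmps.append((ci, delta))
        # the expression shift propagates through the methylation shift
        # (the causal chain group -> methylation -> expression), so its
        # sign must agree with slope * delta or the between-group component
        # would cancel the within-group coupling in the pooled correlation
        lfc = float(np.sign(slope * delta) * rng.uniform(0.8, 1.5))
        degs.append((gi, lfc))
        return spec, delta, lfc

    # full SNP-DMP-DEG interactomes
    for k in range(n_full_interactomes):
        got = pick_coupling(need_host=True)
        if got is None:
            raise RuntimeError("annotation too sparse for full interactomes")
        ci, gi = got
        spec, delta, lfc = plant_pair(ci, gi, confirmed=True,
                                      states=CD4_STATES, in_ery=False)
        hi = int(gene_ann.index.get_loc(host[ci]))
        used_genes.add(hi)
        snp_pos = int(gene_tss[hi])
        # risk-allele effects point in the disease direction so dosage,
        # methylation and expression stay monotonically associated
        snp_links.append(SnpLinkSpec(
            rsid=f"rs{9000 + k}", locus_gene_index=hi, chrom=chrom[ci],
            start=max(snp_pos - 500, 0), end=snp_pos + 500,
            target_gene_indices=(gi, hi),
            coupled_cpg_index=ci, coupled_gene_index=gi,
            meth_effect=0.08 * float(np.sign(delta)),
            expr_effect=0.4 * float(np.sign(lfc)), full_interactome=True))

    # further 3D-confirmed couplings (no SNP evidence)
    state_menu = [CD4_STATES, ("nCD4", "tCD4Non"), ("nCD4",), ("tCD4Act",)]
    for k in range(n_confirmed_couplings - n_full_interactomes):
        got = pick_coupling(need_host=False)
        if got is None:
            break
        states = state_menu[k % len(state_menu)]
        plant_pair(*got, confirmed=True, states=states,
                   in_ery=bool(rng.random() < base.ery_share))

    # couplings without 3D support
    for _ in range(n_unconfirmed_couplings):
        got = pick_coupling(need_host=False)
        if got is None:
            break
        plant_pair(*got, confirmed=False, states=(), in_ery=False)

    # standalone DMPs, DVPs, DEGs
    free = [i for i in range(base.n_cpgs)
            if i not in used_cpgs and not dmr_member[i]]
    rng.shuffle(free)
    for i in free[:n_dmps]:
        delta = float(rng.choice([1, 1, 1, -1]) * rng.uniform(0.12, 0.25))
        dmps.append((i, delta))
    dvps = [(i, 10.0) for i in free[n_dmps:n_dmps + n_dvps]]
    free_genes = [i for i in range(base.n_genes) if i not in used_genes]
    rng.shuffle(free_genes)
    deg_only = free_genes[:n_extra_degs]
    for i in deg_only:
        degs.append((i, float(rng.choice([-1, 1]) * rng.uniform(0.8, 1.5))))
        used_genes.add(i)
    non_degs = [i for i in range(base.n_genes) if i not in used_genes]

    # decoy SNP links: fail step 1 (no DEG target), step 2 (DEG without a
    # confirmed pair) or step 3 (confirmed DEG but host gene not targeted)
    confirmed_deg_idx = [c.gene_index for c in couplings if c.confirmed_3d
                         and not any(l.coupled_gene_index == c.gene_index
                                     for l in snp_links)]
    k1 = n_decoy_snp_links // 3
    k2 = n_decoy_snp_links // 3
    k3 = n_decoy_snp_links - k1 - k2
    decoy_id = 0

    def add_decoy(targets: tuple[int, ...]) -> None:
        nonlocal decoy_id
        li = int(rng.integers(base.n_genes))
        p = int(gene_tss[li])
        snp_links.append(SnpLinkSpec(
            rsid=f"rs{1000 + decoy_id}", locus_gene_index=li,
            chrom=gene_chrom[li], start=max(p - 500, 0), end=p + 500,
            target_gene_indices=targets))
        decoy_id += 1

    for _ in range(k1):
        add_decoy(tuple(int(x) for x in
                        rng.choice(non_degs, size=min(2, len(non_degs)),
                                   replace=False)))
    for _ in range(k2):
        add_decoy((int(rng.choice(deg_only)),))
    for j in range(k3):
        if confirmed_deg_idx:
            add_decoy((confirmed_deg_idx[j % len(confirmed_deg_idx)],))
        else:
            add_decoy((int(rng.choice(deg_only)),))

    config = replace(
        base,
        planted_dmps=tuple(dmps),
        planted_dvps=tuple(dvps),
        planted_degs=tuple(degs),
        planted_couplings=tuple(couplings),
        planted_snp_links=tuple(snp_links),
    )

    cpg_ann2, gene_ann2, fragments2 = simulate_annotation(config)
    beta, samples, truth = simulate_methylation(config, cpg_ann2)
    expr = simulate_expression(config, gene_ann2, cpg_ann2, beta, samples, truth)
    interactions = simulate_interactions(cpg_ann2, gene_ann2, fragments2,
                                         config, truth)
    snp_table = pd.DataFrame({
        "rsid": [l.rsid for l in snp_links],
        "locus_gene": [gene_ann2.index[l.locus_gene_index] for l in snp_links],
        "target_genes": [";".join(gene_ann2.index[i]
                                  for i in l.target_gene_indices)
                         for l in snp_links],
    })
    return SyntheticSuite(config=config, cpg_ann=cpg_ann2, gene_ann=gene_ann2,
                          fragments=fragments2, beta=beta, samples=samples,
                          expr=expr, interactions=interactions,
                          snp_links=snp_table, truth=truth)
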