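"""Pipeline orchestration: probe filter -> batch adjustment -> DMP/DEG ->
DMR -> DVP -> enrichment -> meQTL -> 3D confirmation -> SNP integration.

Every stage writes its table under the output directory; the run report
collects the count chain (probes filtered, hyper/hypo DMPs, up/down DEGs,
DMRs, DVPs, candidate and significant meQTL pairs, per-state confirmed
pairs, union/shared, SNP-filter step counts) plus the configuration echo
and the seed.  Runs are reproducible: one master seed spawns per-stage
child seeds deterministically, no stage mutates its inputs, and all output
is written with fixed float formatting so a rerun is byte-identical.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import arraycore, diffstats, dmr, dvp, integration3d, meqtl
from . import io as m3io
from . import regenrich, synthgen

__version__ = "0.1.0"


@dataclass
class PipelineConfig:
    """Thresholds, stage toggles and input paths of one run.

    With ``synthetic=True`` the inputs are generated by the planted-truth
    cohort designer; otherwise the path fields must point at existing
    files in the documented dialects.
    """

    seed: int = 0
    synthetic: bool = True
    # input paths (real-data mode)
    beta_path: str | None = None
    cpg_annotation_path: str | None = None
    expr_path: str | None = None
    gene_annotation_path: str | None = None
    sample_sheet_path: str | None = None
    interactions_path: str | None = None
    snp_links_path: str | None = None
    peaks_paths: dict = field(default_factory=dict)  # name -> BED path
    # thresholds
    p_thr: float = 0.01
    fdr_thr: float = 0.05
    top_fraction: float = 0.05
    cis_window: int = 5_000_000
    flank: int = 0
    max_gap: int = 500
    cutoff_quantile: float = 0.95
    smooth_width: int = 3
    dmr_B: int = 200
    enrich_B: int = 1000
    # stage toggles
    run_dmr: bool = True
    run_dvp: bool = True
    run_enrichment: bool = True
    run_meqtl: bool = True
    run_integration: bool = True

    def validate(self) -> None:
        for name in ("p_thr", "fdr_thr", "top_fraction", "cis_window",
                     "max_gap", "cutoff_quantile", "smooth_width",
                     "dmr_B", "enrich_B"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not self.synthetic:
            for name in ("beta_path", "cpg_annotation_path", "expr_path",
                         "gene_annotation_path", "sample_sheet_path"):
                p = getattr(self, name)
                if p is None or not Path(p).exists():
                    raise FileNotFoundError(f"{name}: {p}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


_STAGE_IDS = {"dmr": 11, "enrich": 13, "integrate": 17}


def _stage_seed(master: int, stage: str) -> int:
    return int(np.random.SeedSequence(
        [master, _STAGE_IDS.get(stage, 97)]).generate_state(1)[0] % (2 ** 31))


@dataclass
class RunReport:
    seed: int
    software_version: str = __version__
    config: dict = field(default_factory=dict)
    counts: dict = field(default_factory=dict)
    thresholds_used: dict = field(default_factory=dict)

    def check_consistency(self) -> None:
        c = self.counts
        if "n_dmps" in c:
            assert c["n_dmps"] == c["n_dmp_hyper"] + c["n_dmp_hypo"]
        if "n_degs" in c:
            assert c["n_degs"] == c["n_deg_up"] + c["n_deg_down"]
        if "n_confirmed_union" in c:
            per_state = c.get("confirmed_per_state", {})
            if per_state:
                assert c["n_confirmed_shared_all"] <= min(per_state.values())
                assert c["n_confirmed_union"] <= sum(per_state.values())
        sc = c.get("snp_step_counts", {})
        vals = list(sc.values())
        assert all(x >= y for x, y in zip(vals, vals[1:])), \
            "SNP filter step counts must be nonincreasing"

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True, default=str)
            fh.write("\n")


def run_pipeline(config: PipelineConfig, out_dir) -> RunReport:
    """Execute all enabled stages in order, writing every intermediate."""
    config.validate()
    out = m3io.ensure_dir(out_dir)
    report = RunReport(seed=config.seed, config=asdict(config))
    counts = report.counts

    # ---- inputs ------------------------------------------------------
    if config.synthetic:
        suite = synthgen.design_cohort(seed=config.seed)
        beta, samples = suite.beta, suite.samples
        cpg_ann, gene_ann = suite.cpg_ann, suite.gene_ann
        expr = suite.expr
        interactions = suite.interactions
        snp_links = suite.snp_links
        m3io.write_matrix_tsv(beta, out / "beta.tsv")
        m3io.write_matrix_tsv(expr, out / "expression.tsv")
        m3io.write_table(samples, out / "sample_sheet.tsv")
        m3io.write_table(cpg_ann, out / "cpg_annotation.tsv")
        m3io.write_table(gene_ann, out / "gene_annotation.tsv")
        m3io.write_interactions(interactions, out / "interactions.tsv")
        m3io.write_table(snp_links, out / "snp_links.tsv", index=False)
        peak_sets = {"planted_dmp_marks": synthgen.simulate_peaks(
            cpg_ann, suite.truth.true_dmp_ids, coverage_fraction=0.8,
            seed=config.seed, background_rate=0.05)}
    else:
        beta = m3io.read_matrix_tsv(config.beta_path)
        cpg_ann = m3io.read_cpg_annotation(config.cpg_annotation_path)
        expr = m3io.read_matrix_tsv(config.expr_path)
        gene_ann = m3io.read_gene_annotation(config.gene_annotation_path)
        samples = m3io.read_sample_sheet(config.sample_sheet_path)
        interactions = m3io.read_interactions(config.interactions_path) \
            if config.interactions_path else pd.DataFrame(
                columns=m3io.INTERACTION_COLUMNS)
        snp_links = m3io.read_snp_links(config.snp_links_path) \
            if config.snp_links_path else pd.DataFrame(
                columns=["rsid", "locus_gene", "target_genes"])
        peak_sets = {name: m3io.read_bed(path)
                     for name, path in config.peaks_paths.items()}

    groups = samples["group"]

    # ---- probe filter + batch adjustment -----------------------------
    study = arraycore.MethylationStudy(beta, cpg_ann, samples)
    filtered, filter_report = arraycore.filter_probes(
        study, top_fraction=config.top_fraction)
    m3io.write_table(filter_report.to_frame(), out / "filter_report.tsv",
                     index=False)
    counts["n_probes_input"] = len(beta)
    counts["n_probes_filtered"] = len(filtered.beta)

    m_full = arraycore.beta_to_m(beta)
    if samples["batch"].nunique() > 1:
        m_adj = arraycore.combat_adjust(m_full, samples["batch"], groups)
        expr_adj = arraycore.combat_adjust(expr, samples["batch"], groups)
    else:
        m_adj, expr_adj = m_full, expr
    beta_adj = arraycore.m_to_beta(m_adj)

    # ---- DMP / DEG calling -------------------------------------------
    dmp_stats = diffstats.moderated_t(m_adj.loc[filtered.beta.index], groups)
    hyper, hypo = diffstats.call_features(
        dmp_stats, config.p_thr, config.fdr_thr, labels=("hyper", "hypo"))
    dmp_table = diffstats.annotate_calls(dmp_stats, hyper, hypo)
    m3io.write_table(dmp_table, out / "dmp_stats.tsv")
    dmp_ids = hyper.feature_ids + hypo.feature_ids
    counts.update(n_dmp_hyper=len(hyper), n_dmp_hypo=len(hypo),
                  n_dmps=len(hyper) + len(hypo))

    deg_stats = diffstats.moderated_t(expr_adj, groups)
    up, down = diffstats.call_features(
        deg_stats, config.p_thr, config.fdr_thr, labels=("up", "down"))
    deg_table = diffstats.annotate_calls(deg_stats, up, down)
    m3io.write_table(deg_table, out / "deg_stats.tsv")
    deg_ids = up.feature_ids + down.feature_ids
    counts.update(n_deg_up=len(up), n_deg_down=len(down),
                  n_degs=len(up) + len(down))

    # ---- DMR ----------------------------------------------------------
    dmr_table = pd.DataFrame()
    if config.run_dmr:
        dmr_table = dmr.call_dmrs(
            beta_adj, groups, cpg_ann, max_gap=config.max_gap,
            cutoff_quantile=config.cutoff_quantile,
            smooth_width=config.smooth_width, B=config.dmr_B,
            seed=_stage_seed(config.seed, "dmr"))
        m3io.write_table(dmr_table.drop(columns=["cpg_ids"]),
                         out / "dmrs.tsv", index=False)
        if len(dmr_table):
            m3io.write_bed(pd.DataFrame({
                "chrom": dmr_table["chrom"],
                "start": dmr_table["start"] - 1,
                "end": dmr_table["end"]}), out / "dmrs.bed")
        counts["n_dmrs"] = len(dmr_table)

    # ---- DVP ----------------------------------------------------------
    if config.run_dvp:
        dvp_table = dvp.ievora(beta_adj, groups)
        m3io.write_table(dvp_table, out / "dvps.tsv")
        n_both, n_only, n_gain = dvp.classify_dvp_overlap(dvp_table, dmp_ids)
        counts.update(n_dvps=int(dvp_table["is_dvp"].sum()),
                      n_dvp_and_dmp=n_both, n_dvp_only=n_only,
                      n_dvp_only_gain=n_gain)

    # ---- enrichment ----------------------------------------------------
    if config.run_enrichment and dmp_ids and peak_sets:
        query = regenrich.dmp_window(cpg_ann.loc[dmp_ids], flank=config.flank)
        rows = []
        for name, peaks in peak_sets.items():
            res = regenrich.permutation_enrichment(
                query, peaks, cpg_ann, B=config.enrich_B,
                seed=_stage_seed(config.seed, "enrich"),
                query_name="DMPs", peak_set_name=name)
            rows.append(res.to_dict())
        enrich_table = pd.DataFrame(rows)
        m3io.write_table(enrich_table, out / "enrichment.tsv", index=False)
        counts["n_enrichment_significant"] = int(
            enrich_table["significant"].sum())

    # ---- meQTL ---------------------------------------------------------
    confirmed = pd.DataFrame()
    sig_pairs = pd.DataFrame()
    if config.run_meqtl:
        cand = meqtl.cis_pairs(cpg_ann, gene_ann, window=config.cis_window)
        covars = pd.DataFrame({
            "sex": (samples["sex"] == "F").astype(float),
            "age": samples["age"].astype(float)})
        fitted = meqtl.fit_meqtl(cand, m_adj, expr_adj, covariates=covars)
        counts["n_cis_candidate_pairs"] = len(cand)
        counts["n_meqtl_significant"] = int(
            (fitted["p"] < config.p_thr).sum())
        sig_pairs = meqtl.filter_to_dmp_deg(fitted, dmp_ids, deg_ids,
                                            p_thr=config.p_thr)
        sig_pairs["promoter_proximal"] = meqtl.classify_promoter_proximal(
            sig_pairs, gene_ann)
        m3io.write_table(sig_pairs, out / "meqtl_pairs.tsv", index=False)
        n_tot, n_neg, pct = meqtl.sign_summary(sig_pairs)
        counts.update(n_dmp_deg_pairs=n_tot, n_dmp_deg_negative=n_neg,
                      pct_dmp_deg_negative=pct,
                      **{f"meqtl_{k}": v
                         for k, v in sig_pairs.attrs["summary"].items()})

    # ---- 3D confirmation + SNP integration -----------------------------
    if config.run_integration and config.run_meqtl and len(sig_pairs):
        confirmed = integration3d.confirm_pairs(
            sig_pairs, interactions, gene_ann, cpg_ann)
        m3io.write_table(confirmed, out / "confirmed_pairs.tsv", index=False)
        counts["confirmed_per_state"] = confirmed.attrs["per_state_counts"]
        counts["n_confirmed_union"] = confirmed.attrs["n_union"]
        counts["n_confirmed_shared_all"] = confirmed.attrs["n_shared_all"]
        counts["ery_overlap_fraction"] = integration3d.specificity_check(
            confirmed)

        hosts = integration3d.host_genes(cpg_ann, gene_ann)
        result = integration3d.snp_integration(
            snp_links, deg_ids, confirmed, hosts)
        m3io.write_table(result.hits, out / "interactome_hits.tsv",
                         index=False)
        counts["snp_step_counts"] = result.step_counts
        counts["n_interactome_hits"] = len(result.hits)

        # risk-genotype stratification for the reported hits
        strat_rows = []
        for _, hit in result.hits.iterrows():
            col = f"geno_{hit['rsid']}"
            if col not in samples.columns:
                continue
            dosage = samples[col]
            for feature, matrix in (("cpg", beta_adj), ("gene", expr_adj)):
                fid = hit["cpg_id"] if feature == "cpg" else hit["deg"]
                if fid not in matrix.index:
                    continue
                tr = integration3d.genotype_stratify(matrix.loc[fid], dosage)
                strat_rows.append({
                    "rsid": hit["rsid"], "feature": fid, "kind": feature,
                    "trend_stat": tr.trend_stat, "p": tr.p,
                    "direction": tr.direction, "tested": tr.tested})
        if strat_rows:
            m3io.write_table(pd.DataFrame(strat_rows),
                             out / "genotype_stratification.tsv", index=False)

    report.thresholds_used = {
        "p_thr": config.p_thr, "fdr_thr": config.fdr_thr,
        "top_fraction": config.top_fraction,
        "cis_window": config.cis_window, "max_gap": config.max_gap,
        "cutoff_quantile": config.cutoff_quantile,
        "dmr_B": config.dmr_B, "enrich_B": config.enrich_B}
    report.check_consistency()
    report.write(out / "run_report.json")
    return report
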