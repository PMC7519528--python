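"""3D confirmation (vs a brute-force oracle), SNP filter chain, trend test."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from meth3d import integration3d, synthgen
from meth3d.integration3d import confirm_pairs, genotype_stratify, \
    host_genes, jonckheere_terpstra, snp_integration
from meth3d.meqtl import promoter_window

STATES = ("nCD4", "tCD4Non", "tCD4Act")


def _interaction(chrom, bait, oe, genes, state):
    return {"bait_chrom": chrom, "bait_start": bait[0], "bait_end": bait[1],
            "oe_chrom": chrom, "oe_start": oe[0], "oe_end": oe[1],
            "bait_genes": genes, "cell_state": state}


def _toy():
    """Three genes far apart; CpGs x/y/z in dedicated other-end fragments."""
    genes = pd.DataFrame({
        "chrom": "chr1", "strand": ["+", "+", "+"],
        "tss": [100_000, 300_000, 500_000],
        "tx_start": [100_000, 300_000, 500_000],
        "tx_end": [120_000, 320_000, 520_000],
    }, index=["GA", "GB", "GC"])
    cpgs = pd.DataFrame({
        "chrom": "chr1", "pos": [150_500, 350_500, 550_500]},
        index=["x", "y", "z"])
    pairs = pd.DataFrame({
        "cpg_id": ["x", "y", "z"], "gene": ["GA", "GB", "GC"]})
    return genes, cpgs, pairs


class TestConfirmPairs:
    def test_union_and_shared_counts(self):
        genes, cpgs, pairs = _toy()
        rows = []
        # A confirms {x,y}, B confirms {y,z}, C confirms {y}
        frag = {"x": (150_000, 151_000), "y": (350_000, 351_000),
                "z": (550_000, 551_000)}
        bait = {"GA": (99_000, 101_000), "GB": (299_000, 301_000),
                "GC": (499_000, 501_000)}
        for state, members in [("nCD4", ["x", "y"]), ("tCD4Non", ["y", "z"]),
                               ("tCD4Act", ["y"])]:
            for c in members:
                g = dict(x="GA", y="GB", z="GC")[c]
                rows.append(_interaction("chr1", bait[g], frag[c], g, state))
        inter = pd.DataFrame(rows)
        out = confirm_pairs(pairs, inter, genes, cpgs)
        assert out.attrs["n_union"] == 3
        assert out.attrs["n_shared_all"] == 1
        assert out.attrs["per_state_counts"] == {"nCD4": 2, "tCD4Non": 2,
                                                 "tCD4Act": 1}
        y_states = out.loc[out["cpg_id"] == "y", "states_present"].iloc[0]
        assert y_states == "nCD4;tCD4Non;tCD4Act"

    def test_promoter_cpg_excluded_despite_fragment_overlap(self):
        genes, cpgs, pairs = _toy()
        cpgs.loc["x", "pos"] = 99_500  # inside GA's promoter window
        inter = pd.DataFrame([_interaction(
            "chr1", (95_000, 101_000), (99_000, 100_000), "GA", "nCD4")])
        out = confirm_pairs(pairs, inter, genes, cpgs)
        assert "x" not in set(out["cpg_id"])

    def test_symbol_matching_case_insensitive(self):
        genes, cpgs, pairs = _toy()
        inter = pd.DataFrame([_interaction(
            "chr1", (99_000, 101_000), (150_000, 151_000), "ga;OTHER",
            "nCD4")])
        out = confirm_pairs(pairs, inter, genes, cpgs)
        assert set(out["cpg_id"]) == {"x"}

    def test_matches_brute_force_oracle(self, rng):
        for trial in range(15):
            n_genes, n_cpgs, n_inter = 8, 25, 60
            genes = pd.DataFrame({
                "chrom": rng.choice(["chr1", "chr2"], n_genes),
                "strand": rng.choice(["+", "-"], n_genes),
                "tss": rng.integers(50_000, 2_000_000, n_genes)},
                index=[f"G{i}" for i in range(n_genes)])
            genes["tx_start"] = genes["tss"] - 10_000
            genes["tx_end"] = genes["tss"] + 10_000
            cpgs = pd.DataFrame({
                "chrom": rng.choice(["chr1", "chr2"], n_cpgs),
                "pos": rng.integers(1, 2_000_000, n_cpgs)},
                index=[f"cg{i}" for i in range(n_cpgs)])
            pairs = pd.DataFrame({
                "cpg_id": rng.choice(cpgs.index, 15),
                "gene": rng.choice(genes.index, 15)}).drop_duplicates()
            rows = []
            for _ in range(n_inter):
                chrom = rng.choice(["chr1", "chr2"])
                b = int(rng.integers(1, 2_000_000))
                o = int(rng.integers(1, 2_000_000))
                gsel = ";".join(rng.choice(genes.index,
                                           rng.integers(1, 3),
                                           replace=False))
                rows.append({
                    "bait_chrom": chrom, "bait_start": b,
                    "bait_end": b + int(rng.integers(1000, 60_000)),
                    "oe_chrom": chrom, "oe_start": o,
                    "oe_end": o + int(rng.integers(1000, 60_000)),
                    "bait_genes": gsel,
                    "cell_state": rng.choice(list(STATES) + ["Ery"])})
            inter = pd.DataFrame(rows)
            got = confirm_pairs(pairs, inter, genes, cpgs)

            # oracle: triple loop over pairs x interactions x promoters
            def in_any_promoter(cpg):
                pos = cpgs.loc[cpg, "pos"]
                for _, g in genes.iterrows():
                    if g["chrom"] != cpgs.loc[cpg, "chrom"]:
                        continue
                    lo, hi = promoter_window(int(g["tss"]), g["strand"])
                    if lo <= pos <= hi:
                        return True
                return False

            expected = {}
            for _, pr in pairs.iterrows():
                if in_any_promoter(pr["cpg_id"]):
                    continue
                pos0 = cpgs.loc[pr["cpg_id"], "pos"] - 1
                chrom = cpgs.loc[pr["cpg_id"], "chrom"]
                for _, iv in inter.iterrows():
                    if iv["cell_state"] not in STATES:
                        continue
                    if (pr["gene"].casefold() in
                            [s.casefold() for s in
                             iv["bait_genes"].split(";")]
                            and iv["oe_chrom"] == chrom
                            and iv["oe_start"] <= pos0 < iv["oe_end"]):
                        expected.setdefault(
                            (pr["cpg_id"], pr["gene"]), set()).add(
                                iv["cell_state"])
            got_map = {(r["cpg_id"], r["gene"]):
                       set(r["states_present"].split(";"))
                       for _, r in got.iterrows()}
            assert got_map == expected, f"trial {trial}"

    def test_planted_confirmed_couplings_recovered_exactly(self, suite):
        truth = suite.truth.true_coupling_pairs
        out = confirm_pairs(truth.rename(columns={})[["cpg_id", "gene"]],
                            suite.interactions, suite.gene_ann,
                            suite.cpg_ann)
        got = set(zip(out["cpg_id"], out["gene"]))
        expected = set(zip(truth.loc[truth["confirmed_3d"], "cpg_id"],
                           truth.loc[truth["confirmed_3d"], "gene"]))
        assert got == expected


class TestSpecificity:
    def test_empty_and_full_ery(self):
        df = pd.DataFrame({"in_ery": [False, False]})
        assert integration3d.specificity_check(df) == 0.0
        df = pd.DataFrame({"in_ery": [True, True]})
        assert integration3d.specificity_check(df) == 1.0
        assert integration3d.specificity_check(pd.DataFrame()) == 0.0


class TestSnpIntegration:
    def _inputs(self):
        snp_links = pd.DataFrame({
            "rsid": ["rs1", "rs2", "rs3"],
            "locus_gene": ["LG1", "LG2", "LG3"],
            "target_genes": ["DEG1;HOST1", "DEG2;OTHER", "NOTDEG"],
        })
        confirmed = pd.DataFrame({
            "cpg_id": ["cgA", "cgB"], "gene": ["DEG1", "DEG2"]})
        host = pd.Series({"cgA": "HOST1", "cgB": "HOSTB"})
        return snp_links, confirmed, host

    def test_host_gene_filter_selects_single_hit(self):
        snp_links, confirmed, host = self._inputs()
        res = snp_integration(snp_links, ["DEG1", "DEG2"], confirmed, host)
        assert len(res.hits) == 1
        assert res.hits.iloc[0]["rsid"] == "rs1"
        assert res.step_counts == {"step1_deg_targets": 2,
                                   "step2_confirmed_pair": 2,
                                   "step3_dmp_host_in_targets": 1}

    def test_empty_links_empty_hits(self):
        res = snp_integration(pd.DataFrame(
            columns=["rsid", "locus_gene", "target_genes"]),
            ["DEG1"], pd.DataFrame(columns=["cpg_id", "gene"]), pd.Series())
        assert res.hits.empty

    def test_step_counts_monotone(self, suite):
        hosts = host_genes(suite.cpg_ann, suite.gene_ann)
        truth = suite.truth
        confirmed = truth.true_coupling_pairs[
            truth.true_coupling_pairs["confirmed_3d"]]
        res = snp_integration(suite.snp_links, truth.true_deg_ids,
                              confirmed, hosts)
        c = list(res.step_counts.values())
        assert c[0] >= c[1] >= c[2]

    def test_planted_interactomes_recovered_from_truth(self, suite):
        hosts = host_genes(suite.cpg_ann, suite.gene_ann)
        truth = suite.truth
        confirmed = truth.true_coupling_pairs[
            truth.true_coupling_pairs["confirmed_3d"]]
        res = snp_integration(suite.snp_links, truth.true_deg_ids,
                              confirmed, hosts)
        got = set(zip(res.hits["rsid"], res.hits["cpg_id"], res.hits["deg"]))
        expected = set(zip(truth.true_interactome_hits["rsid"],
                           truth.true_interactome_hits["cpg_id"],
                           truth.true_interactome_hits["deg"]))
        assert got == expected
        assert len(got) == 4


class TestGenotypeStratify:
    def test_identical_values_trend_zero(self):
        values = pd.Series(1.0, index=range(30))
        geno = pd.Series([0] * 10 + [1] * 10 + [2] * 10, index=range(30))
        res = genotype_stratify(values, geno)
        assert res.tested
        assert res.p == pytest.approx(1.0)
        assert res.trend_stat == 0.0

    def test_planted_monotone_effect_detected(self):
        rng = np.random.default_rng(0)
        geno = pd.Series([0] * 20 + [1] * 20 + [2] * 8)
        values = pd.Series(geno * 0.5 + rng.normal(0, 0.2, 48))
        res = genotype_stratify(values, geno)
        assert res.tested and res.p < 0.01
        assert res.direction == "increasing"

    def test_permuted_genotypes_give_uniform_p(self):
        rng = np.random.default_rng(1)
        ps = []
        for _ in range(200):
            geno = pd.Series(rng.integers(0, 3, 48))
            values = pd.Series(rng.normal(0, 1, 48))
            res = genotype_stratify(values, geno)
            if res.tested:
                ps.append(res.p)
        # two-sided normal-approximation p under the null: roughly uniform
        assert 0.01 <= np.mean(np.array(ps) < 0.05) <= 0.12

    def test_two_dosage_groups_use_rank_sum(self):
        rng = np.random.default_rng(2)
        geno = pd.Series([0] * 24 + [1] * 24)
        values = pd.Series(np.r_[rng.normal(0, 1, 24), rng.normal(2, 1, 24)])
        res = genotype_stratify(values, geno)
        assert res.n_groups == 2 and res.p < 0.01

    def test_single_group_flagged(self):
        res = genotype_stratify(pd.Series([1.0, 2.0]), pd.Series([1, 1]))
        assert not res.tested

    def test_jonckheere_matches_mannwhitney_for_two_groups(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(0, 1, 15), rng.normal(0.8, 1, 12)
        z, p = jonckheere_terpstra([a, b])
        u = sps.mannwhitneyu(b, a, alternative="two-sided",
                             method="asymptotic", use_continuity=False)
        assert p == pytest.approx(u.pvalue, rel=1e-6)


class TestHostGenes:
    def test_strand_aware_span(self):
        genes = pd.DataFrame({
            "chrom": ["chr1", "chr1"], "strand": ["+", "-"],
            "tss": [100_000, 500_000],
            "tx_start": [100_000, 480_000], "tx_end": [130_000, 500_000],
        }, index=["GP", "GM"])
        cpgs = pd.DataFrame({
            "chrom": "chr1",
            "pos": [96_000, 125_000, 131_000, 504_000, 506_000, 470_000]},
            index=[f"c{i}" for i in range(6)])
        out = host_genes(cpgs, genes)
        assert out.tolist() == ["GP", "GP", None, "GM", None, None]
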