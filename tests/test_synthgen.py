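"""Generator contracts: geometry, planted-effect magnitudes, determinism."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from meth3d import synthgen
from meth3d.synthgen import CouplingSpec, SimulationConfig


class TestAnnotation:
    def test_small_annotation_sorted_single_chrom(self):
        cfg = SimulationConfig(seed=1, n_cpgs=10, n_chroms=1,
                               chrom_length=1_000_000, n_genes=3)
        cpg, gene, frag = synthgen.simulate_annotation(cfg)
        assert len(cpg) == 10
        assert (cpg["chrom"] == "chr1").all()
        assert (np.diff(cpg["pos"]) > 0).all()

    def test_fragments_partition_chromosome(self):
        cfg = SimulationConfig(seed=2, n_cpgs=20, n_chroms=1,
                               chrom_length=100_000, n_genes=3,
                               fragment_size_mean=5000)
        _, _, frag = synthgen.simulate_annotation(cfg)
        f = frag[frag["chrom"] == "chr1"]
        assert f["start"].iloc[0] == 0
        assert f["end"].iloc[-1] == 100_000
        assert (f["start"].to_numpy()[1:] == f["end"].to_numpy()[:-1]).all()
        assert (f["end"] > f["start"]).all()

    def test_fragment_sizes_centered_on_mean(self):
        cfg = SimulationConfig(seed=3, n_cpgs=20)
        _, _, frag = synthgen.simulate_annotation(cfg)
        median = (frag["end"] - frag["start"]).median()
        assert 4000 < median < 6000

    def test_deterministic_under_seed(self):
        cfg = SimulationConfig(seed=7, n_cpgs=100, n_genes=20)
        a1 = synthgen.simulate_annotation(cfg)
        a2 = synthgen.simulate_annotation(cfg)
        for x, y in zip(a1, a2):
            pd.testing.assert_frame_equal(x, y)

    def test_chrom_too_small_raises(self):
        cfg = SimulationConfig(seed=1, n_cpgs=5000, n_chroms=1,
                               chrom_length=10_000, n_genes=2)
        with pytest.raises(ValueError):
            synthgen.simulate_annotation(cfg)

    def test_planted_dmr_positions_reserved(self):
        cfg = SimulationConfig(seed=4, n_cpgs=200,
                               planted_dmrs=(("chr1", 5_000_000, 5, 0.2),))
        cpg, _, _ = synthgen.simulate_annotation(cfg)
        expected = {5_000_000 + j * synthgen.DMR_CPG_SPACING for j in range(5)}
        got = set(cpg.loc[cpg["chrom"] == "chr1", "pos"])
        assert expected <= got


class TestMethylation:
    def test_null_group_difference_small(self):
        cfg = SimulationConfig(seed=5, n_cpgs=2000, n_batches=1)
        cpg, _, _ = synthgen.simulate_annotation(cfg)
        beta, samples, _ = synthgen.simulate_methylation(cfg, cpg)
        case = beta.loc[:, samples["group"] == "case"].to_numpy()
        ctrl = beta.loc[:, samples["group"] == "control"].to_numpy()
        diff = case.mean(axis=1) - ctrl.mean(axis=1)
        se = np.sqrt(case.var(axis=1, ddof=1) / case.shape[1] +
                     ctrl.var(axis=1, ddof=1) / ctrl.shape[1])
        z = np.abs(diff / se)
        # per-CpG 3-SE bound holds for essentially all CpGs; the tail obeys
        # the normal construction (no CpG beyond 5 SE)
        assert (z < 3).mean() > 0.99
        assert z.max() < 5

    def test_planted_dmp_delta_recovered(self):
        cfg = SimulationConfig(seed=6, n_cpgs=500, n_batches=1,
                               planted_dmps=((5, 0.2),))
        cpg, _, _ = synthgen.simulate_annotation(cfg)
        beta, samples, truth = synthgen.simulate_methylation(cfg, cpg)
        case = beta.iloc[5][samples["group"] == "case"].mean()
        ctrl = beta.iloc[5][samples["group"] == "control"].mean()
        assert case - ctrl == pytest.approx(0.2, abs=0.05)
        assert truth.true_dmp_ids == [cpg.index[5]]

    def test_planted_dvp_inflates_case_variance(self):
        hits = 0
        for s in range(100):
            cfg = SimulationConfig(seed=1000 + s, n_cpgs=60, n_batches=1,
                                   n_genes=5, planted_dvps=((7, 10.0),))
            cpg, _, _ = synthgen.simulate_annotation(cfg)
            beta, samples, _ = synthgen.simulate_methylation(cfg, cpg)
            case = beta.iloc[7][samples["group"] == "case"].var(ddof=1)
            ctrl = beta.iloc[7][samples["group"] == "control"].var(ddof=1)
            hits += (case / ctrl) > 3
        assert hits >= 95

    def test_betas_strictly_inside_unit_interval(self, suite):
        vals = suite.beta.to_numpy()
        assert vals.min() > 0 and vals.max() < 1

    def test_oversized_delta_rejected(self):
        cfg = SimulationConfig(seed=1, planted_dmps=((0, 0.9),))
        with pytest.raises(ValueError, match="delta_beta"):
            cfg.validate()

    def test_generator_honesty_raw_t_power(self):
        # paper-scale cohort: planted shifts of 0.1 are detectable by a
        # plain two-sample t at p < 0.01 for >=90% of planted CpGs
        planted = tuple((i, 0.1) for i in range(50))
        cfg = SimulationConfig(seed=8, n_cpgs=1000, n_batches=1,
                               planted_dmps=planted)
        cpg, _, _ = synthgen.simulate_annotation(cfg)
        beta, samples, _ = synthgen.simulate_methylation(cfg, cpg)
        case = beta.iloc[:50, (samples["group"] == "case").to_numpy()]
        ctrl = beta.iloc[:50, (samples["group"] == "control").to_numpy()]
        p = stats.ttest_ind(case, ctrl, axis=1).pvalue
        assert (p < 0.01).mean() >= 0.9


class TestExpression:
    def test_null_correlation_centered_on_zero(self):
        cfg = SimulationConfig(seed=9, n_cpgs=100, n_genes=100, n_batches=1)
        cpg, gene, _ = synthgen.simulate_annotation(cfg)
        beta, samples, _ = synthgen.simulate_methylation(cfg, cpg)
        expr = synthgen.simulate_expression(cfg, gene, cpg, beta, samples)
        assert np.isfinite(expr.to_numpy()).all()
        rs = [stats.pearsonr(beta.iloc[i], expr.iloc[i])[0] for i in range(60)]
        assert abs(np.mean(rs)) < 0.05

    def test_planted_coupling_power(self):
        detected = 0
        for s in range(20):
            # one 4 Mb chromosome keeps every pair inside the cis window
            cfg = SimulationConfig(
                seed=2000 + s, n_cpgs=50, n_genes=10, n_batches=1,
                n_chroms=1, chrom_length=4_000_000,
                planted_couplings=(CouplingSpec(3, 2, -2.0),))
            cpg, gene, _ = synthgen.simulate_annotation(cfg)
            beta, samples, _ = synthgen.simulate_methylation(cfg, cpg)
            expr = synthgen.simulate_expression(cfg, gene, cpg, beta, samples)
            r, p = stats.pearsonr(beta.iloc[3], expr.iloc[2])
            detected += (r < 0) and (p < 0.01)
        assert detected >= 19

    def test_planted_deg_log2fc_recovered(self):
        cfg = SimulationConfig(seed=10, n_cpgs=50, n_genes=20, n_batches=1,
                               planted_degs=((4, 1.5),))
        cpg, gene, _ = synthgen.simulate_annotation(cfg)
        beta, samples, _ = synthgen.simulate_methylation(cfg, cpg)
        expr = synthgen.simulate_expression(cfg, gene, cpg, beta, samples)
        diff = expr.iloc[4][samples["group"] == "case"].mean() - \
            expr.iloc[4][samples["group"] == "control"].mean()
        assert diff == pytest.approx(1.5, abs=0.2)

    def test_coupling_beyond_cis_window_rejected(self):
        cfg = SimulationConfig(seed=11, n_cpgs=50, n_genes=20, n_batches=1,
                               n_chroms=2,
                               planted_couplings=(CouplingSpec(0, 0, 1.0),))
        cpg, gene, _ = synthgen.simulate_annotation(cfg)
        # force a >5 Mb or cross-chromosome pair by construction
        cpg2 = cpg.copy()
        cpg2.iloc[0, cpg2.columns.get_loc("pos")] = 1
        gene2 = gene.copy()
        gene2.iloc[0, gene2.columns.get_loc("tss")] = 49_000_000
        gene2.iloc[0, gene2.columns.get_loc("chrom")] = cpg2.iloc[0]["chrom"]
        beta, samples, _ = synthgen.simulate_methylation(cfg, cpg2)
        with pytest.raises(ValueError, match="5 Mb"):
            synthgen.simulate_expression(cfg, gene2, cpg2, beta, samples)


class TestInteractions:
    def test_confirmed_coupling_present_in_requested_states(self, suite):
        truth = suite.truth.true_coupling_pairs
        cfg = suite.config
        inter = suite.interactions
        for spec in cfg.planted_couplings:
            if not spec.confirmed_3d:
                continue
            cpg = suite.cpg_ann.iloc[spec.cpg_index]
            pos0 = int(cpg["pos"]) - 1
            for state in spec.states:
                sub = inter[inter["cell_state"] == state]
                hit = ((sub["oe_chrom"] == cpg["chrom"]) &
                       (sub["oe_start"] <= pos0) & (pos0 < sub["oe_end"]))
                assert hit.any(), (spec, state)
        assert truth["confirmed_3d"].sum() == 10

    def test_zero_ery_share_keeps_confirmed_out_of_ery(self):
        cfg = SimulationConfig(
            seed=12, n_cpgs=300, n_genes=30, n_batches=1, ery_share=0.0,
            n_decoy_interactions=0,
            planted_couplings=(CouplingSpec(10, 3, 1.0, confirmed_3d=True),))
        cpg, gene, frag = synthgen.simulate_annotation(cfg)
        inter = synthgen.simulate_interactions(cpg, gene, frag, cfg)
        assert (inter["cell_state"] != "Ery").all()

    def test_interaction_count_includes_decoys(self, suite):
        # 10 confirmed couplings + 100 decoys, each emitted in >=1 state
        assert len(suite.interactions) >= 110

    def test_coupling_in_target_promoter_cannot_confirm(self):
        cfg = SimulationConfig(seed=13, n_cpgs=300, n_genes=30, n_batches=1)
        cpg, gene, frag = synthgen.simulate_annotation(cfg)
        # move a CpG into gene 0's promoter window
        tss = int(gene.iloc[0]["tss"])
        gchrom = gene.iloc[0]["chrom"]
        cpg2 = cpg.copy()
        loc = cpg2.columns.get_loc("pos")
        row = int(np.flatnonzero((cpg2["chrom"] == gchrom).to_numpy())[0])
        cpg2.iloc[row, loc] = tss - 100
        cpg2 = cpg2.sort_values(["chrom", "pos"])
        row2 = int(np.flatnonzero(((cpg2["chrom"] == gchrom) &
                                   (cpg2["pos"] == tss - 100)).to_numpy())[0])
        cfg2 = SimulationConfig(
            seed=13, n_cpgs=300, n_genes=30, n_batches=1,
            planted_couplings=(CouplingSpec(row2, 0, 1.0, confirmed_3d=True),))
        with pytest.raises(ValueError, match="promoter"):
            synthgen.simulate_interactions(cpg2, gene, frag, cfg2)


class TestPeaks:
    def test_full_coverage_hits_every_enriched_cpg(self, annotation):
        _, cpg_ann, _, _ = annotation
        enriched = list(cpg_ann.index[:40])
        peaks = synthgen.simulate_peaks(cpg_ann, enriched, 1.0, seed=1)
        from meth3d import regenrich
        query = regenrich.dmp_window(cpg_ann.loc[enriched])
        assert regenrich.overlap_count(query, peaks) == 40

    def test_zero_coverage_zero_background_is_empty(self, annotation):
        _, cpg_ann, _, _ = annotation
        peaks = synthgen.simulate_peaks(cpg_ann, list(cpg_ann.index[:10]),
                                        0.0, seed=1, background_rate=0.0)
        assert peaks.empty


class TestTruthBookkeeping:
    def test_every_planted_effect_recorded_once(self, suite):
        cfg, truth = suite.config, suite.truth
        assert len(truth.true_dmp_ids) == len(cfg.planted_dmps)
        assert len(set(truth.true_dmp_ids)) == len(truth.true_dmp_ids)
        assert len(truth.true_dvp_ids) == len(cfg.planted_dvps)
        assert len(truth.true_dmr_intervals) == len(cfg.planted_dmrs)
        assert len(truth.true_deg_ids) == len(cfg.planted_degs)
        assert len(truth.true_coupling_pairs) == len(cfg.planted_couplings)
        assert not truth.true_coupling_pairs.duplicated(
            subset=["cpg_id", "gene"]).any()
        # every id resolves in the annotations
        assert set(truth.true_dmp_ids) <= set(suite.cpg_ann.index)
        assert set(truth.true_deg_ids) <= set(suite.gene_ann.index)

    def test_full_cohort_deterministic(self):
        s1 = synthgen.design_cohort(seed=42)
        s2 = synthgen.design_cohort(seed=42)
        pd.testing.assert_frame_equal(s1.beta, s2.beta)
        pd.testing.assert_frame_equal(s1.expr, s2.expr)
        pd.testing.assert_frame_equal(s1.interactions, s2.interactions)
        pd.testing.assert_frame_equal(s1.snp_links, s2.snp_links)
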