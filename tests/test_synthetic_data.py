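"""Generator correctness: copula LD, model invariants, GWAS samplers."""

from __future__ import annotations

import json

import numpy as np
import pandas as pd
import pytest

from acatwas import synthetic_data as sd
from conftest import copula_dosage_corr


class TestSimGenotypes:
    def test_independent_snps_have_near_zero_correlation(self):
        spec = sd.LdSpec(n_blocks=1, block_size=10, rho=0.0, maf_range=(0.2, 0.5))
        panel = sd.sim_genotypes(4000, spec, seed=3)
        corr = np.corrcoef(panel.dosages, rowvar=False)
        off = corr[np.triu_indices(10, k=1)]
        assert np.abs(off).mean() < 3 / np.sqrt(4000)

    def test_pairwise_correlation_matches_copula_oracle(self):
        """Empirical within-pair dosage correlation vs the orthant-probability
        integration oracle, for tightly linked SNP pairs."""
        spec = sd.LdSpec(n_blocks=4, block_size=2, rho=0.9, maf_range=(0.1, 0.5))
        panel = sd.sim_genotypes(5000, spec, seed=5)
        mafs = panel.variants["MAF"].to_numpy()
        for b in range(4):
            i, j = 2 * b, 2 * b + 1
            expected = copula_dosage_corr(mafs[i], mafs[j], 0.9)
            empirical = np.corrcoef(panel.dosages[:, i], panel.dosages[:, j])[0, 1]
            assert empirical == pytest.approx(expected, abs=0.05)

    def test_same_seed_is_bit_identical(self):
        spec = sd.LdSpec(n_blocks=2, block_size=4, rho=0.4)
        a = sd.sim_genotypes(50, spec, seed=9)
        b = sd.sim_genotypes(50, spec, seed=9)
        assert np.array_equal(a.dosages, b.dosages)
        pd.testing.assert_frame_equal(a.variants, b.variants)

    def test_dosages_in_range_and_marginal_maf(self):
        spec = sd.LdSpec(n_blocks=1, block_size=5, rho=0.3, maf_range=(0.3, 0.4))
        panel = sd.sim_genotypes(5000, spec, seed=1)
        assert panel.dosages.min() >= 0 and panel.dosages.max() <= 2
        freq = panel.dosages.mean(axis=0) / 2
        assert np.allclose(freq, panel.variants["MAF"], atol=0.03)

    @pytest.mark.parametrize("bad", [dict(n=1), dict(spec_rho=1.0), dict(maf=(0.0, 0.5))])
    def test_invalid_arguments_raise(self, bad):
        if "n" in bad:
            with pytest.raises(ValueError):
                sd.sim_genotypes(bad["n"], sd.LdSpec(1, 2, 0.1), seed=0)
        elif "spec_rho" in bad:
            with pytest.raises(ValueError):
                sd.LdSpec(1, 2, bad["spec_rho"])
        else:
            with pytest.raises(ValueError):
                sd.LdSpec(1, 2, 0.1, maf_range=bad["maf"])


class TestSimModels:
    def test_zero_tissue_noise_gives_identical_weights(self, small_panel):
        modelset, _ = sd.sim_models(
            small_panel, n_genes=2, n_tissues=3, sparsity=1, weight_sd=0.0, seed=2
        )
        for feat in modelset.features():
            ws = [modelset.get(feat, t).weights for t in modelset.tissues_for(feat)]
            for w in ws[1:]:
                assert np.array_equal(w, ws[0])

    def test_more_causal_snps_than_block_raises(self, small_panel):
        with pytest.raises(ValueError, match="causal SNPs"):
            sd.sim_models(small_panel, n_genes=1, sparsity=10, seed=0)

    def test_model_invariants(self, small_models, small_panel):
        modelset, truth = small_models
        panel_snps = set(small_panel.variants["SNP"])
        for m in modelset.models.values():
            assert np.any(m.weights != 0)
            assert set(m.snps) <= panel_snps
        # every intron has a parent gene with expression models
        for intron, gene in truth.intron_parent.items():
            assert gene in modelset.genes_expression()


class TestSimGwas:
    def test_null_direct_mode_is_standard_normal_per_snp(self):
        spec = sd.LdSpec(n_blocks=1, block_size=4, rho=0.5)
        panel = sd.sim_genotypes(600, spec, seed=4)
        _, truth = sd.sim_models(panel, n_genes=1, seed=4)
        blocks = panel.ld_blocks()
        zs = np.array(
            [
                sd.sim_gwas(panel, truth, 5000, 5000, "direct", seed=s, blocks=blocks)["Z"]
                for s in range(400)
            ]
        )
        assert np.abs(zs.mean(axis=0)).max() < 0.2
        assert np.abs(zs.std(axis=0) - 1).max() < 0.2

    def test_direct_and_individual_modes_agree_at_causal_snp(self):
        """The closed-form z ~ N(R Lambda, R) sampler and an individually
        simulated logistic cohort give the same mean marginal z."""
        spec = sd.LdSpec(n_blocks=1, block_size=4, rho=0.5, maf_range=(0.2, 0.5))
        panel = sd.sim_genotypes(1500, spec, seed=6)
        modelset, truth = sd.sim_models(panel, n_genes=1, sparsity=1, weight_sd=0.0, seed=6)
        sd.set_effects(truth, {"GENE00000": 0.08})
        causal = truth.causal_snps["GENE00000"][0]
        blocks = panel.ld_blocks()
        reps = 150
        z_direct = np.empty(reps)
        z_indiv = np.empty(reps)
        for r in range(reps):
            d = sd.sim_gwas(panel, truth, 1500, 1500, "direct", seed=r, blocks=blocks)
            i = sd.sim_gwas(panel, truth, 1500, 1500, "individual", seed=10_000 + r)
            z_direct[r] = d.set_index("SNP").loc[causal, "Z"]
            z_indiv[r] = i.set_index("SNP").loc[causal, "Z"]
        # both means estimated with SE ~ 1/sqrt(reps); allow 4 combined SEs
        tol = 4 * np.sqrt(2 / reps)
        assert z_direct.mean() == pytest.approx(z_indiv.mean(), abs=tol)

    def test_effect_without_weights_is_inconsistent(self, small_panel):
        _, truth = sd.sim_models(small_panel, n_genes=1, seed=0)
        truth.alpha["GHOST"] = 0.3
        truth.feature_block["GHOST"] = "block0000"
        with pytest.raises(ValueError, match="without weights"):
            sd.sim_gwas(small_panel, truth, 1000, 1000, "direct", seed=0)

    def test_same_seed_gives_identical_tables(self, small_panel, small_models):
        _, truth = small_models
        a = sd.sim_gwas(small_panel, truth, 1000, 1000, "direct", seed=3)
        b = sd.sim_gwas(small_panel, truth, 1000, 1000, "direct", seed=3)
        pd.testing.assert_frame_equal(a, b)

    def test_records_pass_sumstat_validation(self, small_panel, small_models):
        from acatwas.summary_io import validate_sumstats

        _, truth = small_models
        for mode in ("direct", "individual"):
            table = sd.sim_gwas(small_panel, truth, 800, 800, mode, seed=1)
            clean, rejects = validate_sumstats(table)
            assert rejects.empty
            assert len(clean) == len(table)


class TestMakeFixtures:
    def test_unknown_scenario_raises(self, tmp_path):
        with pytest.raises(sd.ScenarioError):
            sd.make_fixtures(tmp_path, "nonsense", seed=0)

    def test_null_truth_lists_no_causal_genes(self, tmp_path):
        paths = sd.make_fixtures(tmp_path, "null", seed=1, n_genes=20)
        truth = json.loads(paths["truth"].read_text())
        assert truth["causal_genes"] == []

    def test_masked_snps_mask_at_least_20_percent(self, tmp_path):
        paths = sd.make_fixtures(tmp_path, "masked_snps", seed=2)
        truth = sd.TruthTable.from_json(paths["truth"])
        sumstats = pd.read_csv(paths["sumstats"], sep="\t")
        weights = pd.read_csv(paths["weights"], sep="\t")
        model_snps = set(weights["SNP"])
        absent = model_snps - set(sumstats["SNP"])
        assert absent == set(truth.masked_snps)
        assert len(absent) / len(model_snps) >= 0.20

    def test_finemap_pair_genes_are_genetically_correlated(self, tmp_path):
        """Predicted-expression correlation of the two genes, by exact
        w' Gamma w arithmetic on the written LD block, exceeds 0.5."""
        paths = sd.make_fixtures(tmp_path, "finemap_pair", seed=3)
        from acatwas.ld_reference import load_blocks
        from acatwas.model_registry import load_models

        blocks = load_blocks(paths["ld_dir"])
        modelset = load_models(paths["weights"])
        (bid, block), = blocks.items()
        ws = []
        for gene in ("GENE00000", "GENE00001"):
            m = modelset.get(gene, "breast")
            w = np.zeros(block.size)
            w[block.positions(m.snps)] = m.weights
            ws.append(w)
        cross = ws[0] @ block.cov @ ws[1]
        corr = cross / np.sqrt(
            (ws[0] @ block.cov @ ws[0]) * (ws[1] @ block.cov @ ws[1])
        )
        assert corr > 0.5
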