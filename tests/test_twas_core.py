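"""The summary-based TWAS statistic and its per-tissue runner."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from acatwas import synthetic_data as sd
from acatwas import twas_core
from conftest import analytic_ar1_block, make_model


def _snp(i: int) -> str:
    return f"snp_b0000_{i:03d}"


class TestTwasZscore:
    def test_single_snp_identity(self):
        block = analytic_ar1_block(1, 0.0)
        model = make_model([_snp(0)], [1.0])
        res = twas_core.twas_zscore(model, {_snp(0): 2.5}, block)
        assert res.z == pytest.approx(2.5)
        assert res.sigma_g == pytest.approx(1.0)

    def test_two_independent_snps_closed_form(self):
        """w = (1, 1), z = (2, 0), independent standardized SNPs:
        z_g = 2 / sqrt(2)."""
        block = analytic_ar1_block(2, 0.0)
        model = make_model([_snp(0), _snp(1)], [1.0, 1.0])
        res = twas_core.twas_zscore(model, {_snp(0): 2.0, _snp(1): 0.0}, block)
        assert res.z == pytest.approx(2.0 / np.sqrt(2.0), abs=1e-12)

    def test_scale_invariance_and_sign(self):
        rng = np.random.default_rng(3)
        block = analytic_ar1_block(5, 0.4)
        zmap = {_snp(i): float(z) for i, z in enumerate(rng.standard_normal(5))}
        w = rng.standard_normal(5)
        base = twas_core.twas_zscore(make_model(block.snps, w), zmap, block)
        scaled = twas_core.twas_zscore(make_model(block.snps, 7.3 * w), zmap, block)
        negated = twas_core.twas_zscore(make_model(block.snps, -w), zmap, block)
        assert scaled.z == pytest.approx(base.z, abs=1e-10)
        assert negated.z == pytest.approx(-base.z, abs=1e-10)

    def test_missing_snps_drop_and_renormalize(self):
        block = analytic_ar1_block(3, 0.0)
        model = make_model([_snp(0), _snp(1), _snp(2)], [1.0, 1.0, 1.0])
        res = twas_core.twas_zscore(model, {_snp(0): 2.0}, block)
        # only SNP 0 usable: behaves like the single-SNP model
        assert res.z == pytest.approx(2.0)
        assert res.n_snps_used == 1 and res.n_model_snps == 3
        assert "low_coverage" in res.flags

    def test_all_missing_is_untestable_not_an_exception(self):
        block = analytic_ar1_block(2, 0.0)
        model = make_model([_snp(0), _snp(1)], [1.0, -1.0])
        res = twas_core.twas_zscore(model, {}, block)
        assert not res.testable
        assert np.isnan(res.z)


class TestRunTissueTwas:
    def test_batched_and_per_model_paths_agree(self, small_panel, small_models, small_blocks):
        modelset, truth = small_models
        sumstats = sd.sim_gwas(small_panel, truth, 2000, 2000, "direct", seed=8,
                               blocks=small_blocks)
        zmap = dict(zip(sumstats["SNP"], sumstats["Z"]))
        table = twas_core.run_tissue_twas(modelset, zmap, small_blocks, "breast")
        block_of = twas_core.assign_blocks(modelset, small_blocks)
        for _, row in table.iterrows():
            m = modelset.models[(row["FEATURE"], "breast")]
            single = twas_core.twas_zscore(m, zmap, small_blocks[block_of[(row["FEATURE"], "breast")]])
            assert row["ZSCORE"] == pytest.approx(single.z, abs=1e-10)

    def test_null_pvalues_uniform(self):
        """Under the null the TWAS p across many features is Uniform(0,1):
        the 0.05-rejection rate stays inside its binomial 99% CI."""
        spec = sd.LdSpec(n_blocks=40, block_size=6, rho=0.5)
        panel = sd.sim_genotypes(600, spec, seed=31)
        modelset, truth = sd.sim_models(panel, n_genes=160, n_tissues=1,
                                        sparsity=2, seed=31, introns_per_gene=(1, 2))
        blocks = panel.ld_blocks()
        pvals = []
        for s in range(12):
            gw = sd.sim_gwas(panel, truth, 3000, 3000, "direct", seed=s, blocks=blocks)
            zmap = dict(zip(gw["SNP"], gw["Z"]))
            t = twas_core.run_tissue_twas(modelset, zmap, blocks, "breast")
            pvals.append(t["PVALUE"].to_numpy())
        p = np.concatenate(pvals)
        rate = (p < 0.05).mean()
        ci = 2.576 * np.sqrt(0.05 * 0.95 / p.size)
        # features within a block are correlated; allow double the iid CI
        assert abs(rate - 0.05) < max(2 * ci, 0.012)

    def test_causal_gene_attains_minimum_p(self):
        """With a strong expression effect the causal gene has the smallest
        p-value among all expression features in its tissue, across seeds."""
        spec = sd.LdSpec(n_blocks=5, block_size=8, rho=0.6)
        panel = sd.sim_genotypes(500, spec, seed=41)
        modelset, truth = sd.sim_models(panel, n_genes=25, n_tissues=1,
                                        sparsity=2, seed=41)
        sd.set_effects(truth, {"GENE00000": 0.12})
        blocks = panel.ld_blocks()
        wins = 0
        n_seeds = 40
        for s in range(n_seeds):
            gw = sd.sim_gwas(panel, truth, 10_000, 10_000, "direct", seed=s, blocks=blocks)
            zmap = dict(zip(gw["SNP"], gw["Z"]))
            t = twas_core.run_tissue_twas(modelset, zmap, blocks, "breast", "gene")
            if t.loc[t["PVALUE"].idxmin(), "FEATURE"] == "GENE00000":
                wins += 1
        assert wins >= 0.95 * n_seeds

    def test_rerun_is_deterministic(self, small_models, small_blocks, small_panel):
        modelset, truth = small_models
        gw = sd.sim_gwas(small_panel, truth, 2000, 2000, "direct", seed=2,
                         blocks=small_blocks)
        zmap = dict(zip(gw["SNP"], gw["Z"]))
        a = twas_core.run_all_tissues(modelset, zmap, small_blocks)
        b = twas_core.run_all_tissues(modelset, zmap, small_blocks)
        pd.testing.assert_frame_equal(a, b)


class TestIndividualLevelOracle:
    def test_summary_twas_matches_cohort_regression(self):
        """The summary statistic with reference-panel LD reproduces the
        z-score from regressing the simulated phenotype on the cohort's own
        genetic expression score, within 10% relative error."""
        spec = sd.LdSpec(n_blocks=1, block_size=8, rho=0.6, maf_range=(0.1, 0.5))
        ref_panel = sd.sim_genotypes(500, spec, seed=51)
        modelset, truth = sd.sim_models(ref_panel, n_genes=1, n_tissues=1,
                                        sparsity=3, weight_sd=0.0, seed=51)
        sd.set_effects(truth, {"GENE00000": 0.15})
        ref_blocks = ref_panel.ld_blocks()
        model = modelset.get("GENE00000", "breast")
        rel_errors = []
        for rep in range(25):
            cohort_stats = sd.sim_gwas(ref_panel, truth, 2500, 2500, "individual",
                                       seed=100 + rep)
            zmap = dict(zip(cohort_stats["SNP"], cohort_stats["Z"]))
            res = twas_core.twas_zscore(model, zmap, ref_blocks["block0000"])
            # oracle: score-test z of the phenotype on the expression score,
            # reproduced from the same cohort seed
            z_oracle = _cohort_expression_z(ref_panel.spec, truth, 2500, 2500,
                                            seed=100 + rep)
            rel_errors.append(abs(res.z - z_oracle) / abs(z_oracle))
        assert np.median(rel_errors) < 0.10


def _cohort_expression_z(spec, truth, n_cases, n_controls, seed):
    """Independent oracle: rebuild the same logistic cohort and score-test
    the phenotype against the individually computed expression score."""
    rng = np.random.default_rng(seed)
    n_total = n_cases + n_controls
    cohort = sd.sim_genotypes(n_total, spec, seed=int(rng.integers(2**31 - 1)))
    snps, w = truth.base_weights["GENE00000"]
    cols = [list(cohort.variants["SNP"]).index(s) for s in snps]
    score = cohort.dosages[:, cols] @ w
    score = (score - score.mean()) / score.std(ddof=1)
    phi = n_cases / n_total
    eta = np.log(phi / (1 - phi)) + truth.alpha["GENE00000"] * score
    y = (rng.random(n_total) < 1.0 / (1.0 + np.exp(-eta))).astype(float)
    ybar = y.mean()
    xc = score - score.mean()
    u = xc @ (y - ybar)
    v = ybar * (1 - ybar) * (xc**2).sum()
    return u / np.sqrt(v)
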