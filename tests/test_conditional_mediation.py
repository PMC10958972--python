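"""Conditioning on index variants and proportion-mediated classification."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from acatwas import conditional_mediation as cm
from acatwas import synthetic_data as sd
from acatwas.model_registry import load_models
from acatwas.ld_reference import load_blocks
from conftest import analytic_ar1_block


def _snp(i: int) -> str:
    return f"snp_b0000_{i:03d}"


class TestConditionalZ:
    def test_uncorrelated_index_leaves_z_unchanged(self):
        block = analytic_ar1_block(2, 0.0)
        adj, flags = cm.conditional_z({_snp(0): 4.0}, {_snp(1): 5.0}, block)
        assert adj[_snp(0)] == pytest.approx(4.0, abs=1e-9)
        assert not flags

    def test_two_snp_closed_form(self):
        """z = 4, index z = 5, r = 0.8: adjusted z = (4 - 4)/0.6 = 0."""
        block = analytic_ar1_block(2, 0.8)
        adj, _ = cm.conditional_z({_snp(0): 4.0}, {_snp(1): 5.0}, block)
        # exact up to the 1e-6 ridge on the index correlation matrix
        assert adj[_snp(0)] == pytest.approx(0.0, abs=1e-5)

    def test_self_conditioning_hits_collinearity_path(self):
        block = analytic_ar1_block(2, 0.3)
        adj, flags = cm.conditional_z({_snp(0): 4.0}, {_snp(0): 4.0}, block)
        assert adj[_snp(0)] == 0.0
        assert flags[_snp(0)] == "collinear"

    def test_empty_index_set_is_identity(self):
        block = analytic_ar1_block(3, 0.5)
        target = {_snp(i): float(i) for i in range(3)}
        adj, flags = cm.conditional_z(target, {}, block)
        assert adj == target and not flags

    def test_idempotent_when_indices_uncorrelated(self):
        rng = np.random.default_rng(7)
        block = analytic_ar1_block(6, 0.0)
        targets = {_snp(i): float(z) for i, z in enumerate(rng.standard_normal(4))}
        index = {_snp(4): 3.0, _snp(5): -1.0}
        once, _ = cm.conditional_z(targets, index, block)
        twice, _ = cm.conditional_z(once, index, block)
        for s in targets:
            assert twice[s] == pytest.approx(once[s], abs=1e-10)

    def test_adjusted_z_uncorrelated_with_index_z(self):
        """The substance of conditioning: across null replicates drawn from
        z ~ N(0, R), the adjusted target z carries no remaining correlation
        with the index z (so a second conditioning has nothing to remove)."""
        rng = np.random.default_rng(11)
        block = analytic_ar1_block(4, 0.7)
        chol = np.linalg.cholesky(block.corr + 1e-12 * np.eye(4))
        reps = 3000
        adj0 = np.empty(reps)
        idx_z = np.empty(reps)
        for r in range(reps):
            z = chol @ rng.standard_normal(4)
            adj, _ = cm.conditional_z(
                {_snp(0): z[0]}, {_snp(2): z[2], _snp(3): z[3]}, block
            )
            adj0[r] = adj[_snp(0)]
            idx_z[r] = z[2]
        assert abs(np.corrcoef(adj0, idx_z)[0, 1]) < 3 / np.sqrt(reps)
        # and the adjusted z remains standard normal
        assert adj0.std() == pytest.approx(1.0, abs=0.05)

    def test_near_duplicate_indices_are_pruned(self):
        block = analytic_ar1_block(3, 0.99)
        kept = cm.prune_indices([_snp(0), _snp(1), _snp(2)], block)
        assert kept == [_snp(0)]  # r^2 between neighbours = 0.98 > 0.9


class TestProportionMediated:
    @pytest.mark.parametrize(
        "total_or,direct_or,expected",
        [
            (1.3, 1.0, 1.0),   # adjusted effect null: full mediation
            (1.3, 1.3, 0.0),   # adjustment changes nothing
            (1.2, 1.1, 0.5),   # printed-formula midpoint
        ],
    )
    def test_or_scale_formula(self, total_or, direct_or, expected):
        assert cm.proportion_mediated_from_ors(total_or, direct_or) == pytest.approx(
            expected, abs=1e-9
        )

    def test_limits_invariant_to_case_control_swap(self):
        """Swapping case/control labels inverts all ORs; PM stays 1 at full
        mediation and 0 at none."""
        assert cm.proportion_mediated_from_ors(1 / 1.3, 1.0) == pytest.approx(1.0)
        assert cm.proportion_mediated_from_ors(1 / 1.3, 1 / 1.3) == pytest.approx(0.0)

    def test_null_total_effect_is_undefined(self):
        with pytest.raises(ValueError, match="undefined"):
            cm.proportion_mediated_from_ors(1.0, 1.0)


@pytest.fixture(scope="module")
def mediation_bundle(tmp_path_factory):
    outdir = tmp_path_factory.mktemp("mediation")
    paths = sd.make_fixtures(outdir, "mediation", seed=13)
    sumstats = pd.read_csv(paths["sumstats"], sep="\t", dtype={"SNP": str})
    return {
        "paths": paths,
        "sumstats": sumstats,
        "models": load_models(paths["weights"], paths["intron_map"]),
        "blocks": load_blocks(paths["ld_dir"]),
        "truth": sd.TruthTable.from_json(paths["truth"]),
        "index": pd.read_csv(paths["index_snps"], sep="\t", dtype={"SNP": str}),
    }


class TestOnFixtures:
    def test_conditioning_on_sole_eqtl_kills_the_gene_signal(self, mediation_bundle):
        """When the index SNP is the causal gene's only eQTL, the conditioned
        TWAS z collapses to ~0 and the joint p to ~1."""
        b = mediation_bundle
        index_set = cm.IndexSnpSet.load(b["index"], b["sumstats"])
        zmap = dict(zip(b["sumstats"]["SNP"], b["sumstats"]["Z"]))
        cond_table, cond_joint = cm.conditional_twas(
            b["models"], zmap, index_set, b["blocks"]
        )
        causal_snp = b["truth"].causal_snps["GENE00000"][0]
        if causal_snp in set(b["index"]["SNP"]):
            rows = cond_table[
                (cond_table["FEATURE"] == "GENE00000")
                & cond_table["FLAGS"].str.contains("conditioned")
            ]
            assert (rows["ZSCORE"].abs() < 1e-6).all()
            gene_joint = cond_joint[
                (cond_joint["GENE"] == "GENE00000")
                & (cond_joint["APPROACH"] == "expression")
            ]
            assert gene_joint["JOINT_P"].iloc[0] > 0.99

    def test_uncorrelated_indices_leave_twas_unchanged(self, mediation_bundle):
        """Index SNPs in a different LD block do not alter any conditioned
        p-value (features without nearby indices pass through)."""
        b = mediation_bundle
        other_block = [bid for bid in b["blocks"] if bid != "block0000"][0]
        fake_idx = b["sumstats"].iloc[:1].copy()
        # pick a SNP from the other block as a (forced) index variant
        snp = b["blocks"][other_block].snps[0]
        row = b["sumstats"][b["sumstats"]["SNP"] == snp]
        idx = pd.DataFrame(
            {"SNP": [snp], "CHR": row["CHR"].values, "POS": row["POS"].values,
             "LOCUS": [other_block], "SUBTYPE": ["ERpos"]}
        )
        index_set = cm.IndexSnpSet.load(idx, b["sumstats"], require_gws=False)
        zmap = dict(zip(b["sumstats"]["SNP"], b["sumstats"]["Z"]))
        sub_models = type(b["models"]).from_models(
            [m for m in b["models"].models.values()
             if b["truth"].feature_block[m.feature_id] == "block0000"]
        )
        cond_table, _ = cm.conditional_twas(sub_models, zmap, index_set, b["blocks"])
        from acatwas import twas_core
        plain = twas_core.run_all_tissues(sub_models, zmap, b["blocks"])
        merged = cond_table.merge(plain, on=["FEATURE", "TISSUE"], suffixes=("_c", "_p"))
        assert np.allclose(merged["PVALUE_c"], merged["PVALUE_p"], atol=1e-12)
        assert fake_idx is not None

    def test_mediation_fixture_flags_index_as_mediated(self, mediation_bundle):
        b = mediation_bundle
        index_set = cm.IndexSnpSet.load(b["index"], b["sumstats"])
        med = cm.mediation_analysis(
            b["models"], ["GENE00000"], index_set, b["blocks"], b["sumstats"]
        )
        causal_snp = b["truth"].causal_snps["GENE00000"][0]
        rec = med[med["SNP"] == causal_snp]
        if not rec.empty:
            assert bool(rec["MEDIATED"].iloc[0])
            assert rec["PROPORTION_MEDIATED"].iloc[0] > 0.5
            assert rec["ADJUSTED_P"].iloc[0] > 5e-8

    def test_index_snps_must_be_genome_wide_significant(self, mediation_bundle):
        b = mediation_bundle
        weak = b["sumstats"].nlargest(1, "P")[["SNP", "CHR", "POS"]].assign(
            LOCUS="x", SUBTYPE="ERpos"
        )
        with pytest.raises(ValueError, match="genome-wide"):
            cm.IndexSnpSet.load(weak, b["sumstats"])
        # override accepted
        cm.IndexSnpSet.load(weak, b["sumstats"], require_gws=False)
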