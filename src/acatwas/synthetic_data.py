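"""Synthetic LD-structured genotypes, multi-tissue SNP-weight models, and
case-control GWAS summary statistics with known truth labels.

The generator emulates the statistical structure a summary-based TWAS
assumes, at desk scale:

* **Genotypes** — a reference panel of dosages produced by thresholding a
  Gaussian copula with block-diagonal AR(1) latent correlation to per-
  haplotype allele indicators; dosage = sum of two independent haplotypes.
  Block structure keeps every downstream linear-algebra contract exactly
  checkable.
* **Weight models** — each gene receives a sparse weight vector over SNPs
  of one LD block, shared across tissues up to tissue-specific Gaussian
  noise (mimicking cross-tissue eQTL effect sharing in shrinkage-refined
  models), plus 1-5 intron-excision features per gene with their own
  sparse weights.
* **Summary statistics** — marginal case-control association z-scores,
  either sampled directly from the Gaussian model z ~ N(R * Lambda, R)
  (Lambda = joint standardized log-odds effects scaled by the case-control
  effective sample size), or computed from an individually simulated
  logistic cohort via per-SNP score tests.  The two modes agree in
  expectation at causal SNPs, which the test-suite exploits as an oracle.

Effects are parameterized as log-odds per standard deviation of the
genetic feature score (alpha); odds ratios are exp(alpha).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .ld_reference import LDBlock, build_ld, save_blocks
from .model_registry import ModelSet, WeightModel

#: the 11-tissue roster the multi-tissue analysis runs over: female-specific
#: tissues, connective/fat tissues, immune-cell tissues, and liver.
TISSUE_ROSTER = (
    "breast",
    "adipose_subcutaneous",
    "adipose_visceral",
    "fibroblasts",
    "whole_blood",
    "lymphocytes",
    "spleen",
    "liver",
    "ovary",
    "uterus",
    "vagina",
)

# non-palindromic allele pairs cycled over SNPs (strand-ambiguous A/T and
# C/G pairs would be dropped by harmonization)
_ALLELE_PAIRS = (("A", "G"), ("C", "T"), ("G", "A"), ("T", "C"))

_BLOCK_SPACING = 10_000_000  # bp between block starts: blocks are LD-isolated
_SNP_SPACING = 1_000


class ScenarioError(ValueError):
    """Unknown fixture scenario name."""


@dataclass(frozen=True)
class LdSpec:
    """Layout of the block-diagonal AR(1) LD model.

    Parameters
    ----------
    n_blocks : int
        Number of independent LD blocks.
    block_size : int
        SNPs per block (>= 1).
    rho : float
        Latent AR(1) correlation between adjacent SNPs within a block,
        in [0, 1).
    maf_range : tuple of float
        Minor-allele frequencies drawn uniformly from this interval,
        within (0, 0.5].
    """

    n_blocks: int
    block_size: int
    rho: float
    maf_range: tuple[float, float] = (0.05, 0.5)

    def __post_init__(self) -> None:
        if self.n_blocks < 1 or self.block_size < 1:
            raise ValueError("n_blocks and block_size must be >= 1")
        if not 0.0 <= self.rho < 1.0:
            raise ValueError("rho must lie in [0, 1)")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")

    @property
    def n_snps(self) -> int:
        return self.n_blocks * self.block_size


@dataclass
class GenotypePanel:
    """Dosage panel plus variant metadata (column BLOCK labels the LD block)."""

    dosages: np.ndarray
    variants: pd.DataFrame
    spec: LdSpec

    @property
    def n(self) -> int:
        return self.dosages.shape[0]

    def block_ids(self) -> list[str]:
        return list(dict.fromkeys(self.variants["BLOCK"]))

    def block_columns(self, block_id: str) -> np.ndarray:
        return np.flatnonzero((self.variants["BLOCK"] == block_id).to_numpy())

    def ld_blocks(self, ridge: float = 0.0) -> dict[str, LDBlock]:
        """Sample LD for every block of the panel."""
        out = {}
        for bid in self.block_ids():
            cols = self.block_columns(bid)
            out[bid] = build_ld(
                self.dosages[:, cols],
                self.variants.iloc[cols],
                ridge=ridge,
                block_id=bid,
            )
        return out


@dataclass
class TruthTable:
    """Ground truth for parameter-recovery tests.

    ``alpha`` maps a feature id (gene or intron) to its log-odds-per-SD
    trait effect; 0 for null features.  ``base_weights`` holds the
    cross-tissue shared weight vector through which a nonzero alpha acts.
    """

    alpha: dict[str, float] = field(default_factory=dict)
    base_weights: dict[str, tuple[list[str], np.ndarray]] = field(default_factory=dict)
    causal_snps: dict[str, list[str]] = field(default_factory=dict)
    feature_block: dict[str, str] = field(default_factory=dict)
    intron_parent: dict[str, str] = field(default_factory=dict)
    masked_snps: list[str] = field(default_factory=list)
    scenario: str = ""

    @property
    def causal_genes(self) -> list[str]:
        """Genes with a nonzero effect on themselves or any of their introns."""
        genes = set()
        for feat, a in self.alpha.items():
            if a != 0.0:
                genes.add(self.intron_parent.get(feat, feat))
        return sorted(genes)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "scenario": self.scenario,
            "alpha": self.alpha,
            "causal_genes": self.causal_genes,
            "causal_snps": self.causal_snps,
            "feature_block": self.feature_block,
            "intron_parent": self.intron_parent,
            "masked_snps": self.masked_snps,
            "base_weights": {
                f: {"snps": snps, "weights": list(map(float, w))}
                for f, (snps, w) in self.base_weights.items()
            },
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthTable":
        payload = json.loads(Path(path).read_text())
        return cls(
            alpha={k: float(v) for k, v in payload["alpha"].items()},
            base_weights={
                f: (rec["snps"], np.array(rec["weights"], float))
                for f, rec in payload["base_weights"].items()
            },
            causal_snps=payload["causal_snps"],
            feature_block=payload["feature_block"],
            intron_parent=payload["intron_parent"],
            masked_snps=payload.get("masked_snps", []),
            scenario=payload.get("scenario", ""),
        )


def effective_sample_size(n_cases: int, n_controls: int) -> float:
    """Case-control effective N: 4 / (1/n_cases + 1/n_controls)."""
    return 4.0 / (1.0 / n_cases + 1.0 / n_controls)


# --------------------------------------------------------------------------
# genotypes
# --------------------------------------------------------------------------

def _ar1_cholesky(m: int, rho: float) -> np.ndarray:
    idx = np.arange(m)
    corr = rho ** np.abs(idx[:, None] - idx[None, :])
    return np.linalg.cholesky(corr + 1e-12 * np.eye(m))


def sim_genotypes(n: int, spec: LdSpec, seed: int) -> GenotypePanel:
    """Simulate an ``n x m`` dosage panel under the block-AR(1) copula.

    Each haplotype's latent vector is multivariate normal with AR(1)
    correlation within a block; the allele indicator is latent < quantile
    of the SNP's minor-allele frequency, and the dosage is the sum of two
    independent haplotypes, so marginally dosage ~ Binomial(2, maf).

    Deterministic given ``seed``.
    """
    if n < 2:
        raise ValueError("need n >= 2 individuals")
    rng = np.random.default_rng(seed)
    m = spec.n_snps
    mafs = rng.uniform(spec.maf_range[0], spec.maf_range[1], size=m)
    thresholds = stats.norm.ppf(mafs)

    chol = _ar1_cholesky(spec.block_size, spec.rho)
    dosage = np.empty((n, m), dtype=np.int8)
    for b in range(spec.n_blocks):
        cols = slice(b * spec.block_size, (b + 1) * spec.block_size)
        # two haplotypes per individual, correlated across SNPs not haplotypes
        latent = rng.standard_normal((2 * n, spec.block_size)) @ chol.T
        alleles = (latent < thresholds[cols]).astype(np.int8)
        dosage[:, cols] = alleles[0::2] + alleles[1::2]

    rows = []
    for j in range(m):
        b, i = divmod(j, spec.block_size)
        a1, a2 = _ALLELE_PAIRS[j % len(_ALLELE_PAIRS)]
        rows.append(
            {
                "SNP": f"snp_b{b:04d}_{i:03d}",
                "CHR": 1,
                "POS": 1 + b * _BLOCK_SPACING + i * _SNP_SPACING,
                "A1": a1,
                "A2": a2,
                "MAF": mafs[j],
                "BLOCK": f"block{b:04d}",
            }
        )
    variants = pd.DataFrame(rows)
    return GenotypePanel(dosages=dosage.astype(float), variants=variants, spec=spec)


# --------------------------------------------------------------------------
# weight models
# --------------------------------------------------------------------------

def sim_models(
    panel: GenotypePanel,
    n_genes: int,
    n_tissues: int = len(TISSUE_ROSTER),
    sparsity: int = 2,
    weight_sd: float = 0.2,
    seed: int = 0,
    introns_per_gene: tuple[int, int] = (1, 5),
    positive_weights: bool = False,
    tissue_subset: dict[str, Sequence[str]] | None = None,
) -> tuple[ModelSet, TruthTable]:
    """Draw sparse multi-tissue weight models for genes and their introns.

    Genes are assigned to LD blocks round-robin.  Per feature, a base
    weight vector over ``sparsity`` SNPs of the block is drawn once and
    perturbed with N(0, weight_sd^2) noise per tissue, so tissues share
    eQTL/sQTL architecture.  ``tissue_subset`` restricts named genes (and
    their introns) to a subset of tissues.

    Returns the model set and an all-null :class:`TruthTable` (alpha = 0
    everywhere); scenario builders set effects afterwards.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    if sparsity < 1:
        raise ValueError("need >= 1 causal SNP per feature")
    if sparsity > panel.spec.block_size:
        raise ValueError(
            f"requested {sparsity} causal SNPs but blocks have only "
            f"{panel.spec.block_size} SNPs"
        )
    if not 1 <= n_tissues <= len(TISSUE_ROSTER):
        raise ValueError("n_tissues must be within the tissue roster size")
    lo_i, hi_i = introns_per_gene
    if not 1 <= lo_i <= hi_i:
        raise ValueError("introns_per_gene bounds must satisfy 1 <= lo <= hi")

    rng = np.random.default_rng(seed)
    tissues = list(TISSUE_ROSTER[:n_tissues])
    block_ids = panel.block_ids()
    truth = TruthTable()
    models: list[WeightModel] = []

    def _draw_base(block_snps: pd.DataFrame) -> tuple[list[str], pd.DataFrame, np.ndarray]:
        pick = rng.choice(len(block_snps), size=sparsity, replace=False)
        pick.sort()
        chosen = block_snps.iloc[pick]
        w = rng.standard_normal(sparsity)
        if positive_weights:
            w = np.abs(w) + 0.2
        # guard against an exactly-zero draw: models must be nonzero
        w[w == 0.0] = 0.1
        return list(chosen["SNP"]), chosen, w

    for g in range(n_genes):
        gene = f"GENE{g:05d}"
        bid = block_ids[g % len(block_ids)]
        cols = panel.block_columns(bid)
        block_snps = panel.variants.iloc[cols]
        gene_tissues = list(tissue_subset[gene]) if tissue_subset and gene in tissue_subset else tissues

        features = [(gene, "gene", gene)]
        n_introns = int(rng.integers(lo_i, hi_i + 1))
        for k in range(n_introns):
            features.append((f"{gene}:intron{k}", "intron", gene))

        for feat_id, feat_type, parent in features:
            snps, chosen, base = _draw_base(block_snps)
            truth.alpha[feat_id] = 0.0
            truth.base_weights[feat_id] = (snps, base)
            truth.causal_snps[feat_id] = snps
            truth.feature_block[feat_id] = bid
            if feat_type == "intron":
                truth.intron_parent[feat_id] = parent
            for tissue in gene_tissues:
                w = base + rng.normal(0.0, weight_sd, size=sparsity) if weight_sd > 0 else base.copy()
                w[w == 0.0] = base[w == 0.0] if np.any(base[w == 0.0]) else 0.1
                models.append(
                    WeightModel(
                        feature_id=feat_id,
                        feature_type=feat_type,
                        gene_id=parent,
                        tissue=tissue,
                        snps=snps,
                        a1=list(chosen["A1"]),
                        a2=list(chosen["A2"]),
                        weights=w,
                    )
                )
    return ModelSet.from_models(models), truth


def set_effects(truth: TruthTable, effects: dict[str, float]) -> TruthTable:
    """Assign trait effects (log-odds per SD of feature score) in place."""
    for feat, a in effects.items():
        if feat not in truth.base_weights:
            raise ValueError(f"effect assigned to unmodeled feature {feat}")
        truth.alpha[feat] = float(a)
    return truth


# --------------------------------------------------------------------------
# GWAS summary statistics
# --------------------------------------------------------------------------

def _joint_effects_per_block(
    truth: TruthTable, blocks: dict[str, LDBlock]
) -> dict[str, np.ndarray]:
    """Per-dosage joint log-odds effect vector c for each block.

    The trait model is logit P(case) = b0 + sum_f alpha_f * (X w_f) / sigma_f,
    so the per-dosage effect at SNP l is sum_f alpha_f w_fl / sigma_f.
    """
    out = {bid: np.zeros(blk.size) for bid, blk in blocks.items()}
    for feat, a in truth.alpha.items():
        if a == 0.0:
            continue
        if feat not in truth.base_weights:
            raise ValueError(f"nonzero effect for feature {feat} without weights")
        snps, w = truth.base_weights[feat]
        bid = truth.feature_block[feat]
        blk = blocks[bid]
        gamma = blk.cov_submatrix(snps)
        sigma_g = math.sqrt(float(w @ gamma @ w))
        if sigma_g <= 0:
            raise ValueError(f"feature {feat} has zero genetic variance")
        out[bid][blk.positions(snps)] += a * w / sigma_g
    return out


def sim_gwas(
    panel: GenotypePanel,
    truth: TruthTable,
    n_cases: int,
    n_controls: int,
    mode: str = "direct",
    seed: int = 0,
    blocks: dict[str, LDBlock] | None = None,
) -> pd.DataFrame:
    """Simulate one GWAS summary-statistic table.

    ``mode='direct'`` samples marginal z-scores per LD block from
    z ~ N(R * Lambda, R) with Lambda the joint standardized log-odds
    effects times sqrt(n_cases * n_controls / N); ``mode='individual'``
    simulates a logistic cohort of N = n_cases + n_controls individuals at
    the target case fraction and computes per-SNP 1-df score-test
    z-scores.  Betas are log odds ratios per effect-allele dosage.
    """
    if mode not in {"direct", "individual"}:
        raise ValueError(f"unknown mode {mode!r}")
    if n_cases < 1 or n_controls < 1:
        raise ValueError("need positive case and control counts")
    rng = np.random.default_rng(seed)
    n_total = n_cases + n_controls
    phi = n_cases / n_total

    if mode == "direct":
        if blocks is None:
            blocks = panel.ld_blocks(ridge=0.0)
        c_by_block = _joint_effects_per_block(truth, blocks)
        lam_scale = math.sqrt(n_cases * n_controls / n_total)  # = sqrt(Neff)/2
        frames = []
        for bid, blk in blocks.items():
            c = c_by_block[bid]
            lam = lam_scale * c * blk.sd  # standardized joint effects
            r = blk.corr
            mean = r @ lam
            chol = np.linalg.cholesky(r + 1e-10 * np.eye(blk.size))
            z = mean + chol @ rng.standard_normal(blk.size)
            se = 1.0 / (blk.sd * math.sqrt(n_total * phi * (1 - phi)))
            frames.append(_records(blk.variants, z, se, n_total, n_cases, n_controls))
        return pd.concat(frames, ignore_index=True)

    # individual mode: fresh cohort under the same LD spec
    cohort = sim_genotypes(n_total, panel.spec, seed=int(rng.integers(2**31 - 1)))
    cohort_blocks = cohort.ld_blocks(ridge=0.0)
    eta = np.full(n_total, math.log(phi / (1 - phi)))
    for feat, a in truth.alpha.items():
        if a == 0.0:
            continue
        if feat not in truth.base_weights:
            raise ValueError(f"nonzero effect for feature {feat} without weights")
        snps, w = truth.base_weights[feat]
        blk = cohort_blocks[truth.feature_block[feat]]
        cols = cohort.block_columns(truth.feature_block[feat])[blk.positions(snps)]
        score = cohort.dosages[:, cols] @ w
        sd = score.std(ddof=1)
        if sd <= 0:
            raise ValueError(f"feature {feat} has zero genetic variance in cohort")
        eta += a * (score - score.mean()) / sd
    y = (rng.random(n_total) < 1.0 / (1.0 + np.exp(-eta))).astype(float)
    ybar = y.mean()
    if ybar in (0.0, 1.0):
        raise RuntimeError("degenerate phenotype draw (all cases or all controls)")

    xc = cohort.dosages - cohort.dosages.mean(axis=0)
    u = xc.T @ (y - ybar)
    v = ybar * (1 - ybar) * (xc**2).sum(axis=0)
    v[v == 0] = np.nan
    z = u / np.sqrt(v)
    se = 1.0 / np.sqrt(v)
    table = _records(cohort.variants, z, se, n_total, n_cases, n_controls)
    return table.dropna(subset=["Z"]).reset_index(drop=True)


def _records(
    variants: pd.DataFrame,
    z: np.ndarray,
    se: np.ndarray,
    n: int,
    n_cases: int,
    n_controls: int,
) -> pd.DataFrame:
    p = 2.0 * stats.norm.sf(np.abs(z))
    return pd.DataFrame(
        {
            "SNP": variants["SNP"].to_numpy(),
            "CHR": variants["CHR"].to_numpy(),
            "POS": variants["POS"].to_numpy(),
            "A1": variants["A1"].to_numpy(),
            "A2": variants["A2"].to_numpy(),
            "BETA": z * se,
            "SE": se,
            "Z": z,
            "P": np.clip(p, np.finfo(float).tiny, 1.0),
            "N": n,
            "N_CASES": n_cases,
            "N_CONTROLS": n_controls,
        }
    )


# --------------------------------------------------------------------------
# fixture bundles
# --------------------------------------------------------------------------

SCENARIOS = (
    "null",
    "single_gene",
    "multi_tissue",
    "splicing_only",
    "mediation",
    "finemap_pair",
    "masked_snps",
)

#: study-like defaults shared by all scenarios
_BASE_PARAMS = dict(
    n_ref=500,
    rho=0.6,
    maf_range=(0.05, 0.5),
    block_size=8,
    genes_per_block=10,
    n_genes=50,
    n_tissues=len(TISSUE_ROSTER),
    sparsity=2,
    weight_sd=0.2,
    introns_per_gene=(1, 5),
    n_cases=10_000,
    n_controls=10_000,
    alpha=0.1,
    mode="direct",
)


def _scenario_params(scenario: str, overrides: dict) -> dict:
    params = dict(_BASE_PARAMS)
    if scenario == "null":
        params.update(n_genes=200)
    elif scenario == "mediation":
        params.update(n_genes=20, sparsity=1, alpha=0.15)
    elif scenario == "finemap_pair":
        params.update(
            n_genes=2, genes_per_block=2, block_size=10, rho=0.8,
            sparsity=3, alpha=0.12, weight_sd=0.1,
        )
    elif scenario == "masked_snps":
        params.update(n_genes=40, sparsity=3, mask_fraction=0.25)
    params.update(overrides)
    return params


def make_fixtures(outdir: str | Path, scenario: str, seed: int, **overrides) -> dict[str, Path]:
    """Write the full input bundle for one named scenario.

    Produces ``sumstats.tsv``, ``weights.tsv``, ``intron_map.tsv``, an
    ``ld/`` directory of per-block matrices, ``index_snps.tsv`` (top
    genome-wide-significant SNP per block), and ``truth.json``.
    """
    if scenario not in SCENARIOS:
        raise ScenarioError(f"unknown scenario {scenario!r}; choose from {SCENARIOS}")
    params = _scenario_params(scenario, overrides)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    n_blocks = max(1, math.ceil(params["n_genes"] / params["genes_per_block"]))
    spec = LdSpec(
        n_blocks=n_blocks,
        block_size=params["block_size"],
        rho=params["rho"],
        maf_range=tuple(params["maf_range"]),
    )
    panel = sim_genotypes(params["n_ref"], spec, seed=int(rng.integers(2**31 - 1)))

    tissue_subset = None
    if scenario == "multi_tissue":
        # causal gene modeled in a strict subset of tissues (no breast model)
        tissue_subset = {"GENE00000": list(TISSUE_ROSTER[1:6])}
    modelset, truth = sim_models(
        panel,
        n_genes=params["n_genes"],
        n_tissues=params["n_tissues"],
        sparsity=params["sparsity"],
        weight_sd=params["weight_sd"],
        seed=int(rng.integers(2**31 - 1)),
        introns_per_gene=params["introns_per_gene"],
        positive_weights=(scenario == "finemap_pair"),
        tissue_subset=tissue_subset,
    )
    truth.scenario = scenario

    if scenario in {"single_gene", "multi_tissue", "mediation", "masked_snps"}:
        set_effects(truth, {"GENE00000": params["alpha"]})
    elif scenario == "splicing_only":
        set_effects(truth, {"GENE00000:intron0": params["alpha"]})
    elif scenario == "finemap_pair":
        set_effects(truth, {"GENE00000": params["alpha"]})

    sumstats = sim_gwas(
        panel,
        truth,
        n_cases=params["n_cases"],
        n_controls=params["n_controls"],
        mode=params["mode"],
        seed=int(rng.integers(2**31 - 1)),
    )

    if scenario == "masked_snps":
        model_snps = sorted({s for m in modelset.models.values() for s in m.snps})
        n_mask = max(1, int(params["mask_fraction"] * len(model_snps)))
        masked = list(rng.choice(model_snps, size=n_mask, replace=False))
        truth.masked_snps = sorted(masked)
        sumstats = sumstats[~sumstats["SNP"].isin(masked)].reset_index(drop=True)

    # index SNPs: top genome-wide-significant variant per block
    index_rows = []
    tagged = sumstats.merge(panel.variants[["SNP", "BLOCK"]], on="SNP")
    for bid, grp in tagged.groupby("BLOCK"):
        hit = grp.loc[grp["P"].idxmin()]
        if hit["P"] < 5e-8:
            index_rows.append(
                {"SNP": hit["SNP"], "CHR": hit["CHR"], "POS": hit["POS"],
                 "LOCUS": bid, "SUBTYPE": "ERpos"}
            )
    index_df = pd.DataFrame(index_rows, columns=["SNP", "CHR", "POS", "LOCUS", "SUBTYPE"])

    paths = {
        "sumstats": outdir / "sumstats.tsv",
        "weights": outdir / "weights.tsv",
        "intron_map": outdir / "intron_map.tsv",
        "ld_dir": outdir / "ld",
        "index_snps": outdir / "index_snps.tsv",
        "truth": outdir / "truth.json",
    }
    sumstats.to_csv(paths["sumstats"], sep="\t", index=False)
    modelset.to_table().to_csv(paths["weights"], sep="\t", index=False)
    pd.DataFrame(
        [{"INTRON": i, "GENE": g} for i, g in sorted(truth.intron_parent.items())]
    ).to_csv(paths["intron_map"], sep="\t", index=False)
    save_blocks(list(panel.ld_blocks(ridge=0.0).values()), paths["ld_dir"])
    index_df.to_csv(paths["index_snps"], sep="\t", index=False)
    truth.to_json(paths["truth"])
    return paths
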