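"""Summary-based per-(feature, tissue) TWAS z-scores (S-PrediXcan statistic).

For a feature with model weights w over SNPs l, GWAS z-scores z_l, and a
reference LD block with dosage covariance Gamma and per-SNP dosage SDs
sigma_l, the association z-score of the genetically predicted feature is

    z_g = sum_l w_l (sigma_l / sigma_g) z_l,   sigma_g^2 = w' Gamma w

which is N(0, 1) under the null.  Scaling all weights by c > 0 leaves z_g
unchanged (sigma_g absorbs it); negating the weights negates z_g.

Missing-SNP policy: model SNPs without a usable z-score are dropped and
sigma_g is recomputed over the SNPs actually used (drop-and-renormalize);
the SNP coverage is recorded so low-coverage results can be filtered.  A
feature with no usable SNPs, or a non-positive predicted variance, is
flagged untestable rather than raising.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .ld_reference import LDBlock
from .model_registry import ModelSet, WeightModel
from .summary_io import zscore_to_p

logger = logging.getLogger(__name__)

#: coverage below which a testable result is flagged for review
LOW_COVERAGE = 0.5

RESULT_COLUMNS = [
    "FEATURE", "TYPE", "GENE", "TISSUE", "ZSCORE", "PVALUE",
    "NSNP_MODEL", "NSNP_USED", "SIGMA_G", "FLAGS",
]


@dataclass
class TwasResult:
    """One feature-tissue association."""

    feature_id: str
    feature_type: str
    gene_id: str
    tissue: str
    z: float
    p: float
    n_model_snps: int
    n_snps_used: int
    sigma_g: float
    flags: str = ""

    @property
    def testable(self) -> bool:
        return "untestable" not in self.flags

    def to_row(self) -> dict:
        return {
            "FEATURE": self.feature_id,
            "TYPE": self.feature_type,
            "GENE": self.gene_id,
            "TISSUE": self.tissue,
            "ZSCORE": self.z,
            "PVALUE": self.p,
            "NSNP_MODEL": self.n_model_snps,
            "NSNP_USED": self.n_snps_used,
            "SIGMA_G": self.sigma_g,
            "FLAGS": self.flags,
        }


def _untestable(model: WeightModel, reason: str) -> TwasResult:
    return TwasResult(
        feature_id=model.feature_id,
        feature_type=model.feature_type,
        gene_id=model.gene_id,
        tissue=model.tissue,
        z=float("nan"),
        p=float("nan"),
        n_model_snps=model.n_snps,
        n_snps_used=0,
        sigma_g=float("nan"),
        flags=f"untestable:{reason}",
    )


def twas_zscore(
    model: WeightModel, zmap: Mapping[str, float], block: LDBlock
) -> TwasResult:
    """Association z-score of one weight model against GWAS z-scores.

    ``zmap`` maps variant id to harmonized z (model-orientation).  SNPs
    absent from ``zmap`` or from the block are dropped; coverage and flags
    record what happened.
    """
    used_idx = [
        i for i, s in enumerate(model.snps) if s in zmap and s in block
    ]
    if not used_idx:
        return _untestable(model, "no_usable_z")

    snps = [model.snps[i] for i in used_idx]
    w = model.weights[np.array(used_idx)]
    z = np.array([zmap[s] for s in snps], dtype=float)
    gamma = block.cov_submatrix(snps)
    sigma = block.sd_for(snps)
    var_g = float(w @ gamma @ w)
    if var_g <= 0 or not math.isfinite(var_g):
        return _untestable(model, "nonpositive_variance")
    sigma_g = math.sqrt(var_g)
    zg = float(np.dot(w * sigma, z) / sigma_g)

    coverage = len(used_idx) / model.n_snps
    flags = [] if coverage == 1.0 else ["partial_coverage"]
    if coverage < LOW_COVERAGE:
        flags.append("low_coverage")
    return TwasResult(
        feature_id=model.feature_id,
        feature_type=model.feature_type,
        gene_id=model.gene_id,
        tissue=model.tissue,
        z=zg,
        p=float(zscore_to_p(zg)),
        n_model_snps=model.n_snps,
        n_snps_used=len(used_idx),
        sigma_g=sigma_g,
        flags=";".join(flags),
    )


def _batch_block_tissue(
    models: list[WeightModel], zmap: Mapping[str, float], block: LDBlock
) -> list[TwasResult]:
    """Vectorized z_g for models that are fully covered within one block.

    Stacks the weight vectors into a features-by-SNPs matrix so one matrix
    product serves the whole (block, tissue) group; models with missing
    SNPs fall back to the per-model path.
    """
    full, partial = [], []
    for m in models:
        if all(s in zmap for s in m.snps) and all(s in block for s in m.snps):
            full.append(m)
        else:
            partial.append(m)

    results = [twas_zscore(m, zmap, block) for m in partial]
    if not full:
        return results

    snps = block.snps
    pos = {s: i for i, s in enumerate(snps)}
    W = np.zeros((len(full), block.size))
    for r, m in enumerate(full):
        W[r, [pos[s] for s in m.snps]] = m.weights
    z = np.array([zmap.get(s, 0.0) for s in snps], dtype=float)
    var_g = np.einsum("ij,jk,ik->i", W, block.cov, W)
    num = (W * block.sd) @ z
    ok = (var_g > 0) & np.isfinite(var_g)
    sigma_g = np.sqrt(np.where(ok, var_g, 1.0))
    zg = num / sigma_g
    pg = np.asarray(zscore_to_p(np.where(ok, zg, 0.0)))
    for r, m in enumerate(full):
        if not ok[r]:
            results.append(_untestable(m, "nonpositive_variance"))
            continue
        results.append(
            TwasResult(
                feature_id=m.feature_id,
                feature_type=m.feature_type,
                gene_id=m.gene_id,
                tissue=m.tissue,
                z=float(zg[r]),
                p=float(pg[r]),
                n_model_snps=m.n_snps,
                n_snps_used=m.n_snps,
                sigma_g=float(sigma_g[r]),
                flags="",
            )
        )
    return results


def assign_blocks(
    modelset: ModelSet, blocks: Mapping[str, LDBlock]
) -> dict[tuple[str, str], str]:
    """Map each (feature, tissue) model to the LD block holding its SNPs.

    A model's SNPs must live in a single block (regions never straddle
    block boundaries); models whose SNPs match no block are skipped with a
    logged reason.
    """
    snp_block: dict[str, str] = {}
    for bid, blk in blocks.items():
        for s in blk.snps:
            snp_block[s] = bid
    out: dict[tuple[str, str], str] = {}
    for key, m in modelset.models.items():
        bids = {snp_block[s] for s in m.snps if s in snp_block}
        if not bids:
            logger.warning("model %s/%s: no LD block covers its SNPs; skipped", *key)
            continue
        if len(bids) > 1:
            logger.warning("model %s/%s: SNPs straddle blocks %s; skipped", *key, sorted(bids))
            continue
        out[key] = bids.pop()
    return out


def run_tissue_twas(
    modelset: ModelSet,
    zmap: Mapping[str, float],
    blocks: Mapping[str, LDBlock],
    tissue: str,
    feature_type: str | None = None,
) -> pd.DataFrame:
    """TWAS for every model of one tissue; deterministic feature order.

    ``zmap`` holds harmonized (and imputed, quality-filtered) z-scores.
    Returns one row per (feature, tissue) in the tabular schema
    ``RESULT_COLUMNS``; untestable features are present with NaN z and a
    reason flag.
    """
    block_of = assign_blocks(modelset, blocks)
    by_block: dict[str, list[WeightModel]] = {}
    for m in modelset.models_in_tissue(tissue, feature_type):
        bid = block_of.get((m.feature_id, m.tissue))
        if bid is None:
            continue
        by_block.setdefault(bid, []).append(m)

    results: list[TwasResult] = []
    for bid in sorted(by_block):
        results.extend(_batch_block_tissue(by_block[bid], zmap, blocks[bid]))
    results.sort(key=lambda r: r.feature_id)
    return pd.DataFrame([r.to_row() for r in results], columns=RESULT_COLUMNS)


def run_all_tissues(
    modelset: ModelSet,
    zmap: Mapping[str, float],
    blocks: Mapping[str, LDBlock],
    feature_type: str | None = None,
) -> pd.DataFrame:
    """Concatenate :func:`run_tissue_twas` over the model set's tissue roster."""
    frames = [
        run_tissue_twas(modelset, zmap, blocks, tissue, feature_type)
        for tissue in modelset.tissues
    ]
    frames = [f for f in frames if not f.empty]
    if not frames:
        return pd.DataFrame(columns=RESULT_COLUMNS)
    return pd.concat(frames, ignore_index=True)
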