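"""Conditioning of z-scores on GWAS index variants, and mediation analysis.

Forward direction (is a TWAS signal independent of known GWAS hits?):
model-SNP z-scores are residualized on the genome-wide-significant index
variants within +/- 2 Mb of the feature, using the standardized
conditional-and-joint (COJO) algebra

    z_adj_j = (z_j - R_jI R_II^{-1} z_I) / sqrt(1 - R_jI R_II^{-1} R_Ij)

and the TWAS + ACAT stages are re-run unchanged on the adjusted z-scores
(weights are never modified).

Reverse direction (is a GWAS hit explained by nearby TWAS genes?): the
index variant's z is conditioned on the model SNPs of the nearby genes;
the adjusted log odds ratio is reconstructed as z_adj * SE_total (the SE
changes little under the standardized-genotype approximation), the
indirect effect is total/direct on the OR scale, and the proportion
mediated is

    PM = direct * (indirect - 1) / (total - 1)     (OR scale)

which is 1 when the adjusted effect is null (full mediation) and 0 when
adjustment changes nothing.  An index variant is classified *mediated*
when PM > 0.5 and its adjusted p-value is no longer genome-wide
significant (> 5e-8).

Numerical safeguards: a 1e-6 ridge on R_II before inversion; the variance
denominator is floored at 1e-4 (collinear targets get z_adj = 0 with a
flag); index variants are LD-pruned at r^2 > 0.9 before conditioning so
near-duplicate indices cannot make R_II singular.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import linalg

from . import acat_combine, twas_core
from .ld_reference import LDBlock
from .model_registry import ModelSet
from .summary_io import zscore_to_p

logger = logging.getLogger(__name__)

RIDGE_II = 1e-6
DENOM_FLOOR = 1e-4
PRUNE_R2 = 0.9
GWS_P = 5e-8
DEFAULT_WINDOW = 2_000_000

INDEX_COLUMNS = ["SNP", "CHR", "POS", "LOCUS", "SUBTYPE"]

MEDIATION_COLUMNS = [
    "SNP", "LOCUS", "TOTAL_OR", "DIRECT_OR", "INDIRECT_OR",
    "PROPORTION_MEDIATED", "ADJUSTED_P", "MEDIATED", "FLAGS",
]


@dataclass
class IndexSnpSet:
    """Genome-wide significant index variants, one row per variant.

    ``table`` columns: SNP, CHR, POS, LOCUS, SUBTYPE plus Z, BETA, SE
    merged from the summary statistics at load time.
    """

    table: pd.DataFrame
    window: int = DEFAULT_WINDOW

    @classmethod
    def load(
        cls,
        path_or_df: str | pd.DataFrame,
        sumstats: pd.DataFrame,
        window: int = DEFAULT_WINDOW,
        require_gws: bool = True,
    ) -> "IndexSnpSet":
        if isinstance(path_or_df, pd.DataFrame):
            idx = path_or_df.copy()
        else:
            idx = pd.read_csv(path_or_df, sep="\t", dtype={"SNP": str})
        merged = idx.merge(sumstats[["SNP", "Z", "BETA", "SE", "P"]], on="SNP", how="left")
        missing = merged["Z"].isna()
        if missing.any():
            logger.warning(
                "index variants absent from summary statistics dropped: %s",
                merged.loc[missing, "SNP"].tolist()[:5],
            )
            merged = merged[~missing]
        if require_gws:
            weak = merged["P"] >= GWS_P
            if weak.any():
                raise ValueError(
                    "index variants not genome-wide significant (p >= 5e-8): "
                    f"{merged.loc[weak, 'SNP'].tolist()[:5]}; "
                    "pass require_gws=False to override"
                )
        return cls(table=merged.reset_index(drop=True), window=window)

    def in_block(self, block: LDBlock) -> pd.DataFrame:
        return self.table[self.table["SNP"].isin(block.snps)].reset_index(drop=True)


def prune_indices(snps: Sequence[str], block: LDBlock, r2_max: float = PRUNE_R2) -> list[str]:
    """Greedy LD pruning: drop later indices with r^2 > r2_max to a kept one."""
    kept: list[str] = []
    for s in snps:
        r = np.array([block.corr_submatrix([s], [k])[0, 0] for k in kept])
        if kept and np.any(r**2 > r2_max):
            continue
        kept.append(s)
    return kept


def conditional_z(
    target_z: Mapping[str, float],
    index_z: Mapping[str, float],
    block: LDBlock,
) -> tuple[dict[str, float], dict[str, str]]:
    """Residualize target z-scores on index-variant z-scores within a block.

    Returns the adjusted z per target and a per-target flag dict
    (``collinear`` when the variance denominator hit the floor).  An empty
    index set is the identity map.  Idempotent: conditioning the adjusted
    vector on the same indices again changes nothing.
    """
    targets = list(target_z)
    indices = prune_indices(list(index_z), block)
    if not indices:
        return dict(target_z), {}

    z_i = np.array([index_z[s] for s in indices], dtype=float)
    r_ii = block.corr_submatrix(indices) + RIDGE_II * np.eye(len(indices))
    r_ti = block.corr_submatrix(targets, indices)
    solve = linalg.solve(r_ii, np.column_stack([z_i[:, None], r_ti.T]), assume_a="sym")
    fitted = r_ti @ solve[:, 0]
    explained = np.einsum("ij,ji->i", r_ti, solve[:, 1:])
    denom2 = 1.0 - explained

    adjusted: dict[str, float] = {}
    flags: dict[str, str] = {}
    for t, zt, fit, d2 in zip(targets, (target_z[t] for t in targets), fitted, denom2):
        if d2 <= DENOM_FLOOR:
            adjusted[t] = 0.0
            flags[t] = "collinear"
        else:
            adjusted[t] = float((zt - fit) / math.sqrt(d2))
    return adjusted, flags


def conditional_twas(
    modelset: ModelSet,
    zmap: Mapping[str, float],
    index_set: IndexSnpSet,
    blocks: Mapping[str, LDBlock],
    window: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Re-run both TWAS approaches with model-SNP z conditioned on index SNPs.

    For each feature, the index variants within ``window`` bp of the
    feature's model-SNP span are conditioned out of that feature's SNP
    z-scores; weights are untouched.  Features with no nearby index SNPs
    pass through unconditioned (flag ``no_nearby_index``).

    Returns (per-feature-tissue conditioned TWAS table, conditioned joint
    gene table for both approaches).
    """
    window = index_set.window if window is None else window
    block_of = twas_core.assign_blocks(modelset, blocks)

    results = []
    for (feat, tissue), bid in sorted(block_of.items()):
        model = modelset.models[(feat, tissue)]
        block = blocks[bid]
        idx_here = index_set.in_block(block)
        model_pos = block.variants.set_index("SNP")["POS"]
        covered = [s for s in model.snps if s in zmap and s in block]
        if not covered:
            results.append(twas_core.twas_zscore(model, zmap, block))
            continue
        lo = min(model_pos[s] for s in covered) - window
        hi = max(model_pos[s] for s in covered) + window
        nearby = idx_here[(idx_here["POS"] >= lo) & (idx_here["POS"] <= hi)]
        if nearby.empty:
            res = twas_core.twas_zscore(model, zmap, block)
            res.flags = ";".join(filter(None, [res.flags, "no_nearby_index"]))
            results.append(res)
            continue
        index_z = dict(zip(nearby["SNP"], nearby["Z"].astype(float)))
        target_z = {s: zmap[s] for s in covered}
        adj, cflags = conditional_z(target_z, index_z, block)
        res = twas_core.twas_zscore(model, adj, block)
        extra = ["conditioned"] + (["collinear_snps"] if cflags else [])
        res.flags = ";".join(filter(None, [res.flags, *extra]))
        results.append(res)

    results.sort(key=lambda r: (r.tissue, r.feature_id))
    table = pd.DataFrame([r.to_row() for r in results], columns=twas_core.RESULT_COLUMNS)

    joint_frames = []
    for approach in ("expression", "splicing"):
        combined = acat_combine.combine_twas_results(table, approach)
        if combined:
            joint_frames.append(acat_combine.joint_table(combined))
    joint = (
        pd.concat(joint_frames, ignore_index=True)
        if joint_frames
        else pd.DataFrame(columns=acat_combine.JOINT_COLUMNS)
    )
    return table, joint


@dataclass
class MediationRecord:
    """Mediation classification of one GWAS index variant."""

    snp: str
    locus: str
    total_or: float
    direct_or: float
    indirect_or: float
    proportion_mediated: float
    adjusted_p: float
    mediated: bool
    flags: str = ""

    def to_row(self) -> dict:
        return {
            "SNP": self.snp,
            "LOCUS": self.locus,
            "TOTAL_OR": self.total_or,
            "DIRECT_OR": self.direct_or,
            "INDIRECT_OR": self.indirect_or,
            "PROPORTION_MEDIATED": self.proportion_mediated,
            "ADJUSTED_P": self.adjusted_p,
            "MEDIATED": self.mediated,
            "FLAGS": self.flags,
        }


def proportion_mediated_from_ors(total_or: float, direct_or: float) -> float:
    """PM = direct * (indirect - 1) / (total - 1) with indirect = total/direct."""
    if total_or <= 0 or direct_or <= 0:
        raise ValueError("odds ratios must be positive")
    if abs(total_or - 1.0) < 1e-6:
        raise ValueError("proportion mediated undefined at a null total effect")
    indirect = total_or / direct_or
    return direct_or * (indirect - 1.0) / (total_or - 1.0)


def proportion_mediated(
    index_snp: str,
    locus: str,
    adjusting_snps: Sequence[str],
    block: LDBlock,
    sumstats: pd.DataFrame,
) -> MediationRecord:
    """Mediation record for one index variant against a set of model SNPs.

    The direct (adjusted) effect comes from conditioning the index
    variant's z on the adjusting SNPs: adjusted beta = z_adj * SE_total,
    adjusted SE = SE_total.  When the index variant is itself one of the
    adjusting eQTL/sQTL, the collinearity floor drives its adjusted
    effect to zero — the full-mediation limit.
    """
    if len(adjusting_snps) == 0:
        raise ValueError("adjusting SNP set is empty")
    row = sumstats.loc[sumstats["SNP"] == index_snp]
    if row.empty:
        raise KeyError(f"index variant {index_snp} absent from summary statistics")
    beta_total = float(row["BETA"].iloc[0])
    se_total = float(row["SE"].iloc[0])
    total_or = math.exp(beta_total)

    zmap = dict(zip(sumstats["SNP"], sumstats["Z"].astype(float)))
    adjusters = {
        s: zmap[s] for s in adjusting_snps if s in zmap and s in block
    }
    flags = []
    if adjusters:
        adj, cflags = conditional_z({index_snp: zmap[index_snp]}, adjusters, block)
        z_adj = adj[index_snp]
        if cflags:
            flags.append("collinear")
    else:
        z_adj = float(zmap.get(index_snp, 0.0))
        flags.append("no_usable_adjusters")

    beta_direct = z_adj * se_total
    direct_or = math.exp(beta_direct)
    adjusted_p = float(zscore_to_p(z_adj))

    if abs(total_or - 1.0) < 1e-6:
        return MediationRecord(
            snp=index_snp, locus=locus, total_or=total_or, direct_or=direct_or,
            indirect_or=float("nan"), proportion_mediated=float("nan"),
            adjusted_p=adjusted_p, mediated=False,
            flags=";".join(filter(None, [*flags, "undefined_pm"])),
        )
    pm = proportion_mediated_from_ors(total_or, direct_or)
    return MediationRecord(
        snp=index_snp,
        locus=locus,
        total_or=total_or,
        direct_or=direct_or,
        indirect_or=total_or / direct_or,
        proportion_mediated=pm,
        adjusted_p=adjusted_p,
        mediated=bool(pm > 0.5 and adjusted_p > GWS_P),
        flags=";".join(flags),
    )


def mediation_analysis(
    modelset: ModelSet,
    genes: Sequence[str],
    index_set: IndexSnpSet,
    blocks: Mapping[str, LDBlock],
    sumstats: pd.DataFrame,
    per_gene: bool = False,
) -> pd.DataFrame:
    """Mediation records for every index variant near the given TWAS genes.

    Default mode adjusts each index variant jointly for the model SNPs of
    *all* listed genes in its LD block (per-locus adjustment); ``per_gene``
    instead emits one record per (index variant, gene) pair adjusted for
    that gene's SNPs only.
    """
    gene_set = set(genes)
    snps_by_block: dict[str, dict[str, set[str]]] = {}
    block_of = twas_core.assign_blocks(modelset, blocks)
    for (feat, tissue), bid in block_of.items():
        m = modelset.models[(feat, tissue)]
        if m.gene_id in gene_set:
            snps_by_block.setdefault(bid, {}).setdefault(m.gene_id, set()).update(m.snps)

    records = []
    for bid, per_gene_snps in sorted(snps_by_block.items()):
        block = blocks[bid]
        idx_here = index_set.in_block(block)
        for _, row in idx_here.iterrows():
            if per_gene:
                for gene, snps in sorted(per_gene_snps.items()):
                    rec = proportion_mediated(row["SNP"], row["LOCUS"], sorted(snps), block, sumstats)
                    rec.flags = ";".join(filter(None, [rec.flags, f"gene:{gene}"]))
                    records.append(rec)
            else:
                joint = sorted(set().union(*per_gene_snps.values()))
                records.append(
                    proportion_mediated(row["SNP"], row["LOCUS"], joint, block, sumstats)
                )
    return pd.DataFrame([r.to_row() for r in records], columns=MEDIATION_COLUMNS)
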