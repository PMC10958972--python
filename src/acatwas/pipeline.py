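"""End-to-end orchestration: harmonize -> impute -> per-tissue TWAS ->
two-step ACAT -> Bonferroni gate -> conditional TWAS -> mediation ->
fine-mapping, with per-stage artifacts and a JSON manifest.

Two separate Bonferroni universes are used, matching the two approaches:
alpha divided by the number of expression-tested genes, and alpha divided
by the number of splicing-tested genes.  A gene is *identified* when it is
significant by either approach (the union rule).  Conditional, mediation
and fine-mapping stages run on the loci of identified genes by default
(``finemap_all`` widens fine-mapping to every region with models).

Per-feature failures are logged and flagged, never fatal; a missing stage
input is fatal with the stage name.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import acat_combine, conditional_mediation, finemap, impute_z, twas_core
from .ld_reference import load_blocks
from .model_registry import ModelSet, load_models, model_coverage
from .summary_io import harmonize, read_sumstats

logger = logging.getLogger(__name__)

REPORT_COLUMNS = [
    "GENE", "SUBTYPE", "EXPR_P", "SPLICE_P", "EXPR_BREAST_P", "SPLICE_BREAST_P",
    "EXPR_N_TISSUES", "SPLICE_N_TISSUES", "EXPR_SIG", "SPLICE_SIG",
    "EXPR_BREAST_SIG", "IDENTIFIED", "EXPR_P_COND", "SPLICE_P_COND",
    "MAX_PIP_EXPR", "MAX_PIP_SPLICE", "LOCUS",
]


@dataclass
class PipelineConfig:
    """Validated configuration for one pipeline run."""

    sumstats: str
    weights: str
    ld_dir: str
    outdir: str
    subtype: str = "ERpos"
    intron_map: str | None = None
    index_snps: str | None = None
    alpha: float = 0.05
    window: int = conditional_mediation.DEFAULT_WINDOW
    acat_weight_mode: str = "equal"  # or "sqrt_n"
    tissue_sample_sizes: dict[str, float] = field(default_factory=dict)
    breast_tissue: str = "breast"
    impute_ridge: float = impute_z.DEFAULT_RIDGE
    impute_r2_floor: float = impute_z.DEFAULT_R2_FLOOR
    finemap_pi0: float = finemap.DEFAULT_PI0
    finemap_prior_var: float = finemap.DEFAULT_PRIOR_VAR
    finemap_max_causal: int = finemap.DEFAULT_MAX_CAUSAL
    finemap_ridge: float = finemap.DEFAULT_RIDGE
    finemap_all: bool = False
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        payload = yaml.safe_load(Path(path).read_text())
        return cls(**payload)

    def validate(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.acat_weight_mode not in {"equal", "sqrt_n"}:
            raise ValueError("acat_weight_mode must be 'equal' or 'sqrt_n'")
        for name in ("sumstats", "weights", "ld_dir"):
            p = getattr(self, name)
            if not Path(p).exists():
                raise FileNotFoundError(f"config path {name} does not exist: {p}")
        for name in ("intron_map", "index_snps"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"config path {name} does not exist: {p}")


def _tissue_weights(config: PipelineConfig) -> Mapping[str, float] | None:
    if config.acat_weight_mode == "equal":
        return None
    if not config.tissue_sample_sizes:
        raise ValueError("sqrt_n weighting requires tissue_sample_sizes")
    return {t: float(np.sqrt(n)) for t, n in config.tissue_sample_sizes.items()}


def _joint_to_frame(joints: Sequence[acat_combine.GeneJointResult]) -> pd.DataFrame:
    rows = []
    for j in joints:
        row = j.to_row()
        rows.append(row)
    return pd.DataFrame(rows, columns=acat_combine.JOINT_COLUMNS)


def build_gene_report(
    expr_joint: Sequence[acat_combine.GeneJointResult],
    splice_joint: Sequence[acat_combine.GeneJointResult],
    thresholds: Mapping[str, float],
    subtype: str,
    locus_map: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Assemble the per-gene report with significance flags and the union rule."""
    expr = {j.gene_id: j for j in expr_joint}
    splice = {j.gene_id: j for j in splice_joint}
    locus_map = locus_map or {}
    rows = []
    for gene in sorted(set(expr) | set(splice)):
        e, s = expr.get(gene), splice.get(gene)
        expr_p = e.joint_p if e else float("nan")
        splice_p = s.joint_p if s else float("nan")
        expr_breast = e.breast_p if e and e.breast_p is not None else float("nan")
        splice_breast = s.breast_p if s and s.breast_p is not None else float("nan")
        expr_sig = bool(e and e.joint_p < thresholds["expression"])
        splice_sig = bool(s and s.joint_p < thresholds["splicing"])
        breast_thr = thresholds.get("expression_breast")
        expr_breast_sig = bool(
            breast_thr is not None and np.isfinite(expr_breast) and expr_breast < breast_thr
        )
        rows.append(
            {
                "GENE": gene,
                "SUBTYPE": subtype,
                "EXPR_P": expr_p,
                "SPLICE_P": splice_p,
                "EXPR_BREAST_P": expr_breast,
                "SPLICE_BREAST_P": splice_breast,
                "EXPR_N_TISSUES": e.n_tissues if e else 0,
                "SPLICE_N_TISSUES": s.n_tissues if s else 0,
                "EXPR_SIG": expr_sig,
                "SPLICE_SIG": splice_sig,
                "EXPR_BREAST_SIG": expr_breast_sig,
                "IDENTIFIED": expr_sig or splice_sig,
                "EXPR_P_COND": float("nan"),
                "SPLICE_P_COND": float("nan"),
                "MAX_PIP_EXPR": float("nan"),
                "MAX_PIP_SPLICE": float("nan"),
                "LOCUS": locus_map.get(gene, ""),
            }
        )
    return pd.DataFrame(rows, columns=REPORT_COLUMNS)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage; write artifacts under ``config.outdir``.

    Returns a dict of in-memory stage outputs, including ``report`` (the
    per-gene table), ``twas`` (per feature-tissue), ``expr_joint``,
    ``splice_joint``, ``conditional``, ``mediation``, ``finemap_expr``,
    ``finemap_splice``, ``thresholds`` and ``manifest``.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"subtype": config.subtype, "stages": {}}

    # ---- load inputs -----------------------------------------------------
    sumstats = read_sumstats(config.sumstats)
    modelset = load_models(config.weights, config.intron_map)
    blocks = load_blocks(config.ld_dir)
    if not blocks:
        raise FileNotFoundError(f"stage ld_reference: no LD blocks under {config.ld_dir}")
    manifest["stages"]["inputs"] = {
        "n_sumstat_records": int(len(sumstats)),
        "n_models": len(modelset.models),
        "n_tissues": len(modelset.tissues),
        "n_blocks": len(blocks),
        "genes_expression": len(modelset.genes_expression()),
        "genes_splicing": len(modelset.genes_splicing()),
    }

    # ---- harmonize -------------------------------------------------------
    reference = pd.concat([b.variants for b in blocks.values()], ignore_index=True)
    harmonized = harmonize(sumstats, reference)
    kept = harmonized.kept
    manifest["stages"]["harmonize"] = {
        "n_in": int(len(sumstats)),
        "n_kept": int(len(kept)),
        "flags": harmonized.table["harmonize_flag"].value_counts().to_dict(),
    }

    # ---- impute missing model SNPs --------------------------------------
    zmap_obs = harmonized.zmap()
    model_snps_by_block: dict[str, list[str]] = {}
    block_of = twas_core.assign_blocks(modelset, blocks)
    for key, bid in block_of.items():
        m = modelset.models[key]
        bucket = model_snps_by_block.setdefault(bid, [])
        bucket.extend(s for s in m.snps if s not in bucket)
    imputed = impute_z.impute_for_models(
        zmap_obs, blocks, model_snps_by_block,
        ridge=config.impute_ridge, r2_floor=config.impute_r2_floor,
    )
    zmap = impute_z.usable_zmap(imputed)
    coverage = model_coverage(modelset, list(zmap))
    manifest["stages"]["impute"] = {
        "n_targets": int(len(imputed)),
        "n_imputed": int((imputed["SOURCE"] == "imputed").sum()),
        "n_low_quality": int(imputed["LOW_QUALITY"].astype(bool).sum()),
    }

    # ---- per-tissue TWAS, both approaches -------------------------------
    twas = twas_core.run_all_tissues(modelset, zmap, blocks)
    manifest["stages"]["twas"] = {
        "n_results": int(len(twas)),
        "n_untestable": int(twas["FLAGS"].str.contains("untestable").sum()),
    }

    # ---- two-step ACAT and Bonferroni gate ------------------------------
    weights = _tissue_weights(config)
    expr_joint = acat_combine.combine_twas_results(
        twas, "expression", config.breast_tissue, weights
    )
    splice_joint = acat_combine.combine_twas_results(
        twas, "splicing", config.breast_tissue, weights
    )
    n_expr = max(1, len(modelset.genes_expression()))
    n_splice = max(1, len(modelset.genes_splicing()))
    breast_models = [
        m for m in modelset.models.values()
        if m.tissue == config.breast_tissue and m.feature_type == "gene"
    ]
    n_breast = len({m.gene_id for m in breast_models})
    thresholds = {
        "expression": acat_combine.bonferroni_threshold(n_expr, config.alpha)[0],
        "splicing": acat_combine.bonferroni_threshold(n_splice, config.alpha)[0],
    }
    if n_breast:
        thresholds["expression_breast"] = acat_combine.bonferroni_threshold(
            n_breast, config.alpha
        )[0]
    manifest["stages"]["acat"] = {
        "genes_expression_tested": n_expr,
        "genes_splicing_tested": n_splice,
        "thresholds": thresholds,
    }

    # ---- gene report -----------------------------------------------------
    locus_map: dict[str, str] = {}
    index_set = None
    if config.index_snps is not None:
        index_df = pd.read_csv(config.index_snps, sep="\t", dtype={"SNP": str})
        if len(index_df):
            index_set = conditional_mediation.IndexSnpSet.load(
                index_df, kept, window=config.window
            )
    for key, bid in block_of.items():
        gene = modelset.models[key].gene_id
        locus_map.setdefault(gene, bid)
    report = build_gene_report(expr_joint, splice_joint, thresholds, config.subtype, locus_map)
    identified = report.loc[report["IDENTIFIED"], "GENE"].tolist()
    manifest["stages"]["report"] = {
        "genes_reported": int(len(report)),
        "genes_identified": len(identified),
    }

    # ---- conditional TWAS + mediation on identified loci ----------------
    cond_twas = pd.DataFrame(columns=twas_core.RESULT_COLUMNS)
    cond_joint = pd.DataFrame(columns=acat_combine.JOINT_COLUMNS)
    mediation = pd.DataFrame(columns=conditional_mediation.MEDIATION_COLUMNS)
    if index_set is not None and identified:
        id_models = ModelSet.from_models(
            [m for m in modelset.models.values() if m.gene_id in set(identified)]
        )
        cond_twas, cond_joint = conditional_mediation.conditional_twas(
            id_models, zmap, index_set, blocks, window=config.window
        )
        mediation = conditional_mediation.mediation_analysis(
            modelset, identified, index_set, blocks, kept
        )
        for _, row in cond_joint.iterrows():
            col = "EXPR_P_COND" if row["APPROACH"] == "expression" else "SPLICE_P_COND"
            report.loc[report["GENE"] == row["GENE"], col] = row["JOINT_P"]
    manifest["stages"]["conditional"] = {
        "n_conditioned_results": int(len(cond_twas)),
        "n_mediation_records": int(len(mediation)),
        "n_mediated": int(mediation["MEDIATED"].sum()) if len(mediation) else 0,
    }

    # ---- fine-mapping ----------------------------------------------------
    finite = np.isfinite(twas["ZSCORE"].to_numpy(float))
    zmap_by_feature = {
        (f, t): float(z)
        for f, t, z, ok in zip(
            twas["FEATURE"], twas["TISSUE"], twas["ZSCORE"], finite
        )
        if ok
    }
    if config.finemap_all:
        regions = None
    else:
        regions = sorted(
            {
                bid for key, bid in block_of.items()
                if modelset.models[key].gene_id in set(identified)
            }
        )
    fm_kwargs = dict(
        pi0=config.finemap_pi0, prior_var=config.finemap_prior_var,
        max_causal=config.finemap_max_causal, ridge=config.finemap_ridge,
    )
    if regions is None or regions:
        fm_expr = finemap.finemap_regions(
            modelset, zmap_by_feature, blocks, "gene", regions=regions, **fm_kwargs
        )
        fm_splice = finemap.finemap_regions(
            modelset, zmap_by_feature, blocks, "intron", regions=regions, **fm_kwargs
        )
    else:
        fm_expr = pd.DataFrame(columns=finemap.FINEMAP_COLUMNS)
        fm_splice = pd.DataFrame(columns=finemap.FINEMAP_COLUMNS)
    for fm, col, by_gene in ((fm_expr, "MAX_PIP_EXPR", False), (fm_splice, "MAX_PIP_SPLICE", True)):
        if fm.empty:
            continue
        tagged = fm.copy()
        if by_gene:
            parents = {
                m.feature_id: m.gene_id for m in modelset.models.values()
                if m.feature_type == "intron"
            }
            tagged["GENE"] = tagged["FEATURE"].map(parents)
        else:
            tagged["GENE"] = tagged["FEATURE"]
        max_pip = tagged.groupby("GENE")["PIP"].max()
        report[col] = report["GENE"].map(max_pip).fillna(report[col])
    manifest["stages"]["finemap"] = {
        "n_expression_records": int(len(fm_expr)),
        "n_splicing_records": int(len(fm_splice)),
        "n_candidate_causal": int(fm_expr["CANDIDATE_CAUSAL"].sum() + fm_splice["CANDIDATE_CAUSAL"].sum())
        if len(fm_expr) or len(fm_splice) else 0,
    }

    # ---- write artifacts -------------------------------------------------
    artifacts = {
        "harmonized.tsv": harmonized.table,
        "imputed_z.tsv": imputed,
        "coverage.tsv": coverage.assign(missing=coverage["missing"].map(lambda v: ",".join(v))),
        "twas.tsv": twas,
        "expr_joint.tsv": _joint_to_frame(expr_joint),
        "splice_joint.tsv": _joint_to_frame(splice_joint),
        "conditional_twas.tsv": cond_twas,
        "conditional_joint.tsv": cond_joint,
        "mediation.tsv": mediation,
        "finemap_expression.tsv": fm_expr,
        "finemap_splicing.tsv": fm_splice,
        "gene_report.tsv": report,
    }
    for name, frame in artifacts.items():
        frame.to_csv(outdir / name, sep="\t", index=False)
    manifest["artifacts"] = sorted(artifacts)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))

    return {
        "report": report,
        "twas": twas,
        "expr_joint": expr_joint,
        "splice_joint": splice_joint,
        "conditional": cond_joint,
        "mediation": mediation,
        "finemap_expr": fm_expr,
        "finemap_splice": fm_splice,
        "thresholds": thresholds,
        "manifest": manifest,
    }


def subtype_overlap(report_a: pd.DataFrame, report_b: pd.DataFrame) -> dict:
    """Unique/shared identified-gene counts between two subtype reports."""
    a = set(report_a.loc[report_a["IDENTIFIED"], "GENE"])
    b = set(report_b.loc[report_b["IDENTIFIED"], "GENE"])
    shared = a & b
    return {
        "n_first": len(a),
        "n_second": len(b),
        "n_shared": len(shared),
        "n_unique_first": len(a - shared),
        "n_unique_second": len(b - shared),
        "unique_first": sorted(a - shared),
        "unique_second": sorted(b - shared),
        "shared": sorted(shared),
    }


def breast_only_summary(report: pd.DataFrame) -> dict:
    """Among identified genes, how many the breast-tissue expression TWAS
    alone would have found, with the share as a whole-number percentage."""
    identified = report[report["IDENTIFIED"]]
    n_total = int(len(identified))
    n_breast = int(identified["EXPR_BREAST_SIG"].sum())
    share = round(100.0 * n_breast / n_total) if n_total else 0
    return {"n_identified": n_total, "n_breast_only": n_breast, "percent": share}
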