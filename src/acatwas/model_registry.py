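"""Load and index per-tissue SNP-weight prediction models.

A :class:`WeightModel` is one feature's (gene's or intron-excision
event's) sparse weight vector in one tissue; the genetically predicted
feature is the dosage linear combination ``sum_l w_l x_l``.  Weights are
stored on the "effect allele adds weight" convention: harmonization flips
GWAS z-scores onto the model orientation, never the model weights.

A :class:`ModelSet` indexes models by (feature id, tissue), carries the
tissue roster and the gene -> intron map, and reports the bookkeeping the
analysis needs (genes with any model, per-tissue counts, SNP coverage
against available summary statistics).
"""

from __future__ import annotations

import logging
import sqlite3
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

FEATURE_TYPES = ("gene", "intron")

#: weight-table schema
WEIGHT_COLUMNS = ["feature_id", "feature_type", "gene_id", "tissue", "SNP", "A1", "A2", "weight"]


class ModelFormatError(ValueError):
    """Fatal structural problem in a weight table (e.g. intron with no gene)."""


@dataclass
class WeightModel:
    """One feature's SNP weight vector in one tissue."""

    feature_id: str
    feature_type: str
    gene_id: str
    tissue: str
    snps: list[str]
    a1: list[str]
    a2: list[str]
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.feature_type not in FEATURE_TYPES:
            raise ModelFormatError(f"bad feature type {self.feature_type!r}")
        if self.feature_type == "intron" and not self.gene_id:
            raise ModelFormatError(f"intron {self.feature_id} lacks a parent gene")
        if len(self.snps) != len(self.weights) or len(self.snps) == 0:
            raise ModelFormatError(f"model {self.feature_id}/{self.tissue}: empty or ragged")
        if len(set(self.snps)) != len(self.snps):
            raise ModelFormatError(f"model {self.feature_id}/{self.tissue}: duplicate variants")
        if not np.any(self.weights != 0):
            raise ModelFormatError(f"model {self.feature_id}/{self.tissue}: all-zero weights")

    @property
    def n_snps(self) -> int:
        return len(self.snps)


@dataclass
class ModelSet:
    """Indexed collection of weight models."""

    models: dict[tuple[str, str], WeightModel] = field(default_factory=dict)
    tissues: list[str] = field(default_factory=list)
    gene_introns: dict[str, list[str]] = field(default_factory=dict)

    @classmethod
    def from_models(cls, models: Iterable[WeightModel]) -> "ModelSet":
        out = cls()
        for m in models:
            key = (m.feature_id, m.tissue)
            if key in out.models:
                raise ModelFormatError(f"duplicate model for {key}")
            out.models[key] = m
            if m.tissue not in out.tissues:
                out.tissues.append(m.tissue)
            if m.feature_type == "intron":
                kids = out.gene_introns.setdefault(m.gene_id, [])
                if m.feature_id not in kids:
                    kids.append(m.feature_id)
        out.tissues.sort()
        for kids in out.gene_introns.values():
            kids.sort()
        return out

    # ------------------------------------------------------------ queries
    def get(self, feature_id: str, tissue: str) -> WeightModel | None:
        return self.models.get((feature_id, tissue))

    def features(self, feature_type: str | None = None) -> list[str]:
        seen: dict[str, None] = {}
        for m in self.models.values():
            if feature_type is None or m.feature_type == feature_type:
                seen.setdefault(m.feature_id, None)
        return sorted(seen)

    def genes(self) -> list[str]:
        """Genes with any model in any tissue (expression or splicing)."""
        return sorted({m.gene_id for m in self.models.values()})

    def genes_expression(self) -> list[str]:
        return sorted({m.gene_id for m in self.models.values() if m.feature_type == "gene"})

    def genes_splicing(self) -> list[str]:
        return sorted({m.gene_id for m in self.models.values() if m.feature_type == "intron"})

    def tissues_for(self, feature_id: str) -> list[str]:
        return sorted(t for (f, t) in self.models if f == feature_id)

    def models_in_tissue(self, tissue: str, feature_type: str | None = None) -> list[WeightModel]:
        return [
            m
            for (f, t), m in sorted(self.models.items())
            if t == tissue and (feature_type is None or m.feature_type == feature_type)
        ]

    def counts(self) -> pd.DataFrame:
        """Per-tissue model counts by feature type (bookkeeping report)."""
        rows = [
            {"tissue": m.tissue, "feature_type": m.feature_type}
            for m in self.models.values()
        ]
        if not rows:
            return pd.DataFrame(columns=["tissue", "feature_type", "n_models"])
        return (
            pd.DataFrame(rows)
            .groupby(["tissue", "feature_type"])
            .size()
            .rename("n_models")
            .reset_index()
        )

    # ---------------------------------------------------------------- I/O
    def to_table(self) -> pd.DataFrame:
        rows = []
        for (feat, tissue) in sorted(self.models):
            m = self.models[(feat, tissue)]
            for s, a1, a2, w in zip(m.snps, m.a1, m.a2, m.weights):
                rows.append(
                    {
                        "feature_id": feat,
                        "feature_type": m.feature_type,
                        "gene_id": m.gene_id,
                        "tissue": tissue,
                        "SNP": s,
                        "A1": a1,
                        "A2": a2,
                        "weight": w,
                    }
                )
        return pd.DataFrame(rows, columns=WEIGHT_COLUMNS)


def load_models(
    weights: str | Path | pd.DataFrame,
    intron_map: str | Path | pd.DataFrame | None = None,
) -> ModelSet:
    """Build a :class:`ModelSet` from a tab-separated weight table.

    The table carries one row per (feature, tissue, SNP) with columns
    ``feature_id, feature_type, gene_id, tissue, SNP, A1, A2, weight``.
    An optional intron map (columns INTRON, GENE) fills or overrides the
    parent gene of intron features.  Zero-weight rows are dropped with a
    warning; an intron feature without a parent gene is a fatal error.
    Loading is order-independent: SNPs are ordered by variant id within a
    model.
    """
    if isinstance(weights, (str, Path)):
        table = pd.read_csv(weights, sep="\t", dtype={"SNP": str, "A1": str, "A2": str})
    else:
        table = weights.copy()
    missing = [c for c in WEIGHT_COLUMNS if c not in table.columns]
    if missing:
        raise ModelFormatError(f"weight table lacks columns: {missing}")

    imap: dict[str, str] = {}
    if intron_map is not None:
        if isinstance(intron_map, (str, Path)):
            intron_map = pd.read_csv(intron_map, sep="\t")
        imap = dict(zip(intron_map["INTRON"].astype(str), intron_map["GENE"].astype(str)))

    zero = table["weight"] == 0
    if zero.any():
        logger.warning("dropping %d zero-weight rows", int(zero.sum()))
        table = table[~zero]

    table = table.copy()
    table["gene_id"] = table["gene_id"].astype("string")
    is_intron = table["feature_type"] == "intron"
    mapped = table.loc[is_intron, "feature_id"].map(imap)
    table.loc[is_intron, "gene_id"] = mapped.fillna(table.loc[is_intron, "gene_id"])
    bad = is_intron & (table["gene_id"].isna() | (table["gene_id"].str.len() == 0))
    if bad.any():
        raise ModelFormatError(
            f"intron features without parent gene: "
            f"{sorted(table.loc[bad, 'feature_id'].unique())[:5]}"
        )

    # one global sort, then contiguous slices per (feature, tissue) group:
    # orders of magnitude faster than per-group pandas operations on large
    # weight tables
    table = table.sort_values(["feature_id", "tissue", "SNP"], kind="mergesort")
    feats = table["feature_id"].to_numpy(str)
    tissues_arr = table["tissue"].to_numpy(str)
    ftypes = table["feature_type"].to_numpy(str)
    gene_ids = table["gene_id"].to_numpy(str)
    snps = table["SNP"].to_numpy(str)
    a1 = table["A1"].to_numpy(str)
    a2 = table["A2"].to_numpy(str)
    w = table["weight"].to_numpy(float)

    keys = np.char.add(np.char.add(feats, "\x00"), tissues_arr)
    boundaries = np.flatnonzero(np.r_[True, keys[1:] != keys[:-1], True])
    models = []
    for start, stop in zip(boundaries[:-1], boundaries[1:]):
        grp_types = set(ftypes[start:stop])
        if len(grp_types) != 1:
            raise ModelFormatError(
                f"feature {feats[start]} has conflicting types {sorted(grp_types)}"
            )
        models.append(
            WeightModel(
                feature_id=feats[start],
                feature_type=ftypes[start],
                gene_id=gene_ids[start],
                tissue=tissues_arr[start],
                snps=list(snps[start:stop]),
                a1=list(a1[start:stop]),
                a2=list(a2[start:stop]),
                weights=w[start:stop],
            )
        )
    return ModelSet.from_models(models)


def load_predictdb(path: str | Path, tissue: str, feature_type: str = "gene") -> ModelSet:
    """Ingest a PredictDB-style SQLite weight database for one tissue.

    Expects the conventional ``weights`` table (columns gene, rsid,
    ref_allele, eff_allele, weight); the ``extra`` table is ignored beyond
    existence.  Rows are mapped onto the package's flat weight schema with
    the effect allele as A1.
    """
    con = sqlite3.connect(str(path))
    try:
        w = pd.read_sql_query(
            "SELECT gene, rsid, ref_allele, eff_allele, weight FROM weights", con
        )
    finally:
        con.close()
    table = pd.DataFrame(
        {
            "feature_id": w["gene"],
            "feature_type": feature_type,
            "gene_id": w["gene"],
            "tissue": tissue,
            "SNP": w["rsid"],
            "A1": w["eff_allele"],
            "A2": w["ref_allele"],
            "weight": w["weight"],
        }
    )
    return load_models(table)


def model_coverage(
    modelset: ModelSet, available_snps: Iterable[str] | pd.DataFrame
) -> pd.DataFrame:
    """Fraction of each model's SNPs with a usable GWAS z-score.

    ``available_snps`` is either an iterable of variant ids or a harmonized
    summary-statistic table with an SNP column.  Returns one row per
    (feature, tissue) with the coverage fraction in [0, 1] and the list of
    missing variant ids; an empty intersection yields coverage 0.
    """
    if isinstance(available_snps, pd.DataFrame):
        avail = set(available_snps["SNP"])
    else:
        avail = set(available_snps)
    rows = []
    for (feat, tissue) in sorted(modelset.models):
        m = modelset.models[(feat, tissue)]
        missing = [s for s in m.snps if s not in avail]
        rows.append(
            {
                "feature_id": feat,
                "tissue": tissue,
                "coverage": 1.0 - len(missing) / m.n_snps,
                "missing": missing,
            }
        )
    return pd.DataFrame(rows, columns=["feature_id", "tissue", "coverage", "missing"])
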