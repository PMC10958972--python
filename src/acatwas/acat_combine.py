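"""Aggregated Cauchy association test (ACAT) and the two-step aggregation.

ACAT combines K p-values with nonnegative weights summing to one via

    T = sum_k w_k tan((0.5 - p_k) pi),    p_combined = 0.5 - arctan(T) / pi.

Because tan((0.5 - p) pi) is the quantile of a standard Cauchy, T is
Cauchy-distributed under the null for any weights, and the combination is
robust to dependence among the p-values.  Identical inputs are a fixed
point: ACAT(x, ..., x) = x under equal weights.

For very small p the tangent overflows, so p < 1e-15 contributes the
asymptotically equivalent term w / (p pi); symmetrically, a huge T maps to
p ~ 1 / (pi T), keeping combined p-values finite and positive down to the
smallest representable doubles.  Inputs are clipped to at most 1 - 1e-16
(p = 1 gives an infinite negative tangent).

The two-step scheme: per tissue, intron p-values of a gene combine with
equal weights into a gene-level splicing p; then per gene, the per-tissue
p-values (expression-based or splicing-based) combine with equal weights
1/K over the K tissues in which the gene has a testable model.  A
sample-size-weighted variant (weights proportional to the square root of
the prediction-model sample size) is available as a sensitivity option.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

_P_TINY = 1e-15  # below this, use the asymptotic tangent term
_P_MAX = 1.0 - 1e-16
_T_HUGE = 1e15  # above this, use p ~ 1/(pi T)


def acat_statistic(p: np.ndarray, weights: np.ndarray) -> float:
    """The Cauchy combination statistic T (weights assumed normalized)."""
    p = np.asarray(p, dtype=float)
    small = p < _P_TINY
    terms = np.empty_like(p)
    terms[~small] = np.tan((0.5 - p[~small]) * math.pi)
    terms[small] = 1.0 / (p[small] * math.pi)
    return float(np.dot(weights, terms))


def acat_pvalue(
    pvalues: Sequence[float], weights: Sequence[float] | None = None
) -> float:
    """Combine p-values by the aggregated Cauchy association test.

    Parameters
    ----------
    pvalues : sequence of float
        p-values in (0, 1]; p = 1 is clipped just below 1.  NaN or
        out-of-range values raise ``ValueError``.
    weights : sequence of float, optional
        Nonnegative weights; renormalized to sum to one.  Default equal.
    """
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        raise ValueError("need at least one p-value")
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must be finite and in (0, 1]")
    if weights is None:
        w = np.full(p.size, 1.0 / p.size)
    else:
        w = np.asarray(list(weights), dtype=float)
        if w.size != p.size or np.any(w < 0) or not np.any(w > 0):
            raise ValueError("weights must be nonnegative, not all zero, one per p")
        w = w / w.sum()
    p = np.minimum(p, _P_MAX)
    t = acat_statistic(p, w)
    if t > _T_HUGE:
        combined = 1.0 / (math.pi * t)
    else:
        combined = 0.5 - math.atan(t) / math.pi
    # keep the result inside (0, 1] despite floating-point rounding
    return float(min(max(combined, np.nextafter(0.0, 1.0)), 1.0))


def acat_rows(pmatrix: np.ndarray) -> np.ndarray:
    """Row-wise equal-weight ACAT over a replicates-by-K matrix (vectorized)."""
    p = np.minimum(np.asarray(pmatrix, dtype=float), _P_MAX)
    if np.any(p <= 0):
        raise ValueError("p-values must be positive")
    small = p < _P_TINY
    terms = np.where(small, 1.0 / (np.where(small, p, 1.0) * math.pi),
                     np.tan((0.5 - np.where(small, 0.25, p)) * math.pi))
    t = terms.mean(axis=1)
    out = 0.5 - np.arctan(t) / math.pi
    huge = t > _T_HUGE
    out[huge] = 1.0 / (math.pi * t[huge])
    return np.clip(out, np.nextafter(0.0, 1.0), 1.0)


@dataclass
class GeneJointResult:
    """Cross-tissue combined association for one gene and one approach."""

    gene_id: str
    approach: str  # "expression" or "splicing"
    joint_p: float
    tissue_p: dict[str, float]
    n_tissues: int
    breast_p: float | None = None
    min_tissue: str = ""
    flags: str = ""

    def to_row(self) -> dict:
        return {
            "GENE": self.gene_id,
            "APPROACH": self.approach,
            "JOINT_P": self.joint_p,
            "N_TISSUES": self.n_tissues,
            "BREAST_P": self.breast_p if self.breast_p is not None else float("nan"),
            "MIN_TISSUE": self.min_tissue,
            "FLAGS": self.flags,
        }


JOINT_COLUMNS = ["GENE", "APPROACH", "JOINT_P", "N_TISSUES", "BREAST_P", "MIN_TISSUE", "FLAGS"]


def splice_gene_pvalue(intron_pvalues: Sequence[float]) -> float:
    """Gene-level splicing p in one tissue: equal-weight ACAT over introns."""
    return acat_pvalue(intron_pvalues)


def multi_tissue_pvalue(
    tissue_pvalues: Mapping[str, float],
    gene_id: str,
    approach: str,
    breast_tissue: str = "breast",
    tissue_weights: Mapping[str, float] | None = None,
) -> GeneJointResult:
    """Cross-tissue joint p for one gene: ACAT over its testable tissues.

    Tissues without a testable p (no model, or an untestable TWAS) are
    simply absent from ``tissue_pvalues``: weights are equal, 1/K, over
    the K tissues present (the roster-wide 1/11 when all are modeled).
    ``tissue_weights`` switches to the sample-size-weighted sensitivity
    scheme (values are renormalized over the tissues present).
    """
    clean = {t: p for t, p in tissue_pvalues.items() if np.isfinite(p)}
    if not clean:
        raise ValueError(f"gene {gene_id}: no testable tissue p-values")
    tissues = sorted(clean)
    pvals = [clean[t] for t in tissues]
    if tissue_weights is None:
        weights = None
    else:
        weights = [tissue_weights[t] for t in tissues]
    joint = acat_pvalue(pvals, weights)
    min_tissue = min(tissues, key=lambda t: clean[t])
    return GeneJointResult(
        gene_id=gene_id,
        approach=approach,
        joint_p=joint,
        tissue_p=clean,
        n_tissues=len(tissues),
        breast_p=clean.get(breast_tissue),
        min_tissue=min_tissue,
    )


def combine_twas_results(
    results: pd.DataFrame,
    approach: str,
    breast_tissue: str = "breast",
    tissue_weights: Mapping[str, float] | None = None,
) -> list[GeneJointResult]:
    """Two-step aggregation of a per-(feature, tissue) TWAS table.

    ``approach='expression'``: per gene per tissue take the gene model's
    p directly; ``approach='splicing'``: first combine the gene's intron
    p-values within each tissue (equal weights), then across tissues.
    Untestable rows (NaN p) drop out of the weighting; genes untestable
    everywhere are omitted.
    """
    if approach == "expression":
        rows = results[(results["TYPE"] == "gene") & np.isfinite(results["PVALUE"])]
        per_tissue: dict[str, dict[str, float]] = {}
        for gene, tissue, p in zip(rows["GENE"], rows["TISSUE"], rows["PVALUE"]):
            per_tissue.setdefault(gene, {})[tissue] = float(p)
    elif approach == "splicing":
        rows = results[(results["TYPE"] == "intron") & np.isfinite(results["PVALUE"])]
        per_tissue = {}
        if len(rows):
            # vectorized equal-weight ACAT per (gene, tissue): mean of the
            # Cauchy-quantile terms, then the arctan back-transform
            p = np.minimum(rows["PVALUE"].to_numpy(float), _P_MAX)
            small = p < _P_TINY
            terms = np.where(
                small,
                1.0 / (np.where(small, p, 1.0) * math.pi),
                np.tan((0.5 - np.where(small, 0.25, p)) * math.pi),
            )
            t = (
                pd.DataFrame({"GENE": rows["GENE"].to_numpy(),
                              "TISSUE": rows["TISSUE"].to_numpy(), "term": terms})
                .groupby(["GENE", "TISSUE"], sort=True)["term"]
                .mean()
            )
            tvals = t.to_numpy()
            combined = 0.5 - np.arctan(tvals) / math.pi
            huge = tvals > _T_HUGE
            combined[huge] = 1.0 / (math.pi * tvals[huge])
            combined = np.clip(combined, np.nextafter(0.0, 1.0), 1.0)
            for (gene, tissue), pj in zip(t.index, combined):
                per_tissue.setdefault(gene, {})[tissue] = float(pj)
    else:
        raise ValueError(f"unknown approach {approach!r}")

    return [
        multi_tissue_pvalue(tp, gene, approach, breast_tissue, tissue_weights)
        for gene, tp in sorted(per_tissue.items())
    ]


def joint_table(results: Sequence[GeneJointResult]) -> pd.DataFrame:
    return pd.DataFrame([r.to_row() for r in results], columns=JOINT_COLUMNS)


def bonferroni_threshold(n_tests: int, alpha: float = 0.05) -> tuple[float, float]:
    """Family-wise threshold alpha / n, with a 2-significant-figure display form.

    Returns ``(exact, display)``; e.g. 19,288 genes at alpha = 0.05 give
    (2.5923e-06, 2.6e-06).
    """
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    exact = alpha / n_tests
    if exact == 0:
        return exact, exact
    digits = -int(math.floor(math.log10(abs(exact)))) + 1
    return exact, round(exact, digits)
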