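"""Per-region SNP covariance/correlation matrices from a dosage reference panel.

An :class:`LDBlock` carries, for one contiguous region, the ordered variant
metadata, the sample dosage covariance ``cov`` (Gamma), the correlation
matrix ``corr`` (R, after optional ridge regularization), and the per-SNP
dosage standard deviations ``sd``.  The correlation matrix is the ``S`` of
the Gaussian model under which marginal association z-scores at a locus are
jointly N(0, S) in the absence of signal; the covariance provides the
predicted-feature variance ``w' Gamma w`` of the TWAS statistic.

Ridge convention: ``corr`` is replaced by ``(1 - lam) * R + lam * I``.
``lam = 0`` keeps the raw sample correlation (default for TWAS variance);
``lam = 1`` is the identity.  Imputation contexts conventionally use a
small positive ridge (see :mod:`acatwas.impute_z`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: columns required in a variant metadata table
VARIANT_COLUMNS = ["SNP", "CHR", "POS", "A1", "A2"]


@dataclass
class LDBlock:
    """SNP covariance/correlation for one contiguous region.

    Attributes
    ----------
    variants : pandas.DataFrame
        Ordered variant metadata with columns SNP, CHR, POS, A1, A2.
    cov : numpy.ndarray
        Sample dosage covariance matrix (Gamma), unregularized.
    corr : numpy.ndarray
        Correlation matrix (R) after the ridge ``(1-lam) R + lam I``.
    sd : numpy.ndarray
        Per-SNP dosage standard deviation; strictly positive.
    ridge : float
        The ridge parameter applied to ``corr``.
    block_id : str
        Region label used in outputs.
    """

    variants: pd.DataFrame
    cov: np.ndarray
    corr: np.ndarray
    sd: np.ndarray
    ridge: float = 0.0
    block_id: str = "region"
    _index: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self.variants = self.variants.reset_index(drop=True)
        self._index = {s: i for i, s in enumerate(self.variants["SNP"])}
        m = len(self.variants)
        if self.cov.shape != (m, m) or self.corr.shape != (m, m):
            raise ValueError("matrix dimensions do not match variant table")

    @property
    def snps(self) -> list[str]:
        return list(self.variants["SNP"])

    @property
    def size(self) -> int:
        return len(self.variants)

    def __contains__(self, snp: str) -> bool:
        return snp in self._index

    def positions(self, snps: Sequence[str]) -> np.ndarray:
        """Integer indices of ``snps`` within the block (KeyError if absent)."""
        return np.array([self._index[s] for s in snps], dtype=int)

    def corr_submatrix(self, rows: Sequence[str], cols: Sequence[str] | None = None) -> np.ndarray:
        i = self.positions(rows)
        j = i if cols is None else self.positions(cols)
        return self.corr[np.ix_(i, j)]

    def cov_submatrix(self, rows: Sequence[str], cols: Sequence[str] | None = None) -> np.ndarray:
        i = self.positions(rows)
        j = i if cols is None else self.positions(cols)
        return self.cov[np.ix_(i, j)]

    def sd_for(self, snps: Sequence[str]) -> np.ndarray:
        return self.sd[self.positions(snps)]

    # ---------------------------------------------------------------- I/O
    def save(self, prefix: str | Path) -> None:
        """Write ``<prefix>.cov.tsv``, ``<prefix>.corr.tsv``, ``<prefix>.vars.tsv``."""
        prefix = Path(prefix)
        prefix.parent.mkdir(parents=True, exist_ok=True)
        np.savetxt(f"{prefix}.cov.tsv", self.cov, delimiter="\t")
        np.savetxt(f"{prefix}.corr.tsv", self.corr, delimiter="\t")
        meta = self.variants.copy()
        meta["SD"] = self.sd
        meta["RIDGE"] = self.ridge
        meta["BLOCK"] = self.block_id
        meta.to_csv(f"{prefix}.vars.tsv", sep="\t", index=False)

    @classmethod
    def load(cls, prefix: str | Path) -> "LDBlock":
        prefix = Path(prefix)
        meta = pd.read_csv(f"{prefix}.vars.tsv", sep="\t", dtype={"SNP": str, "A1": str, "A2": str})
        cov = np.atleast_2d(np.loadtxt(f"{prefix}.cov.tsv", delimiter="\t"))
        corr = np.atleast_2d(np.loadtxt(f"{prefix}.corr.tsv", delimiter="\t"))
        return cls(
            variants=meta[VARIANT_COLUMNS],
            cov=cov,
            corr=corr,
            sd=meta["SD"].to_numpy(float),
            ridge=float(meta["RIDGE"].iloc[0]) if len(meta) else 0.0,
            block_id=str(meta["BLOCK"].iloc[0]) if len(meta) else "region",
        )


def build_ld(
    dosages: np.ndarray,
    variants: pd.DataFrame,
    subset: Sequence[str] | None = None,
    ridge: float = 0.0,
    block_id: str = "region",
) -> LDBlock:
    """Estimate an :class:`LDBlock` from an ``n x m`` dosage matrix.

    Parameters
    ----------
    dosages : numpy.ndarray
        ``n x m`` dosage panel (individuals by SNPs), values in [0, 2].
    variants : pandas.DataFrame
        Metadata for the m columns (columns SNP, CHR, POS, A1, A2).
    subset : sequence of str, optional
        Variant ids to retain, in the given order; default all.
    ridge : float
        Ridge weight in [0, 1] applied to the correlation matrix.

    Monomorphic SNPs (zero dosage variance) are dropped with a warning.

    Raises
    ------
    ValueError
        For fewer than 2 individuals, an empty subset, or an unknown
        subset variant.
    """
    dosages = np.asarray(dosages, dtype=float)
    if dosages.ndim != 2 or dosages.shape[0] < 2:
        raise ValueError("need a 2-D dosage matrix with >= 2 individuals")
    if not 0.0 <= ridge <= 1.0:
        raise ValueError("ridge must lie in [0, 1]")
    variants = variants.reset_index(drop=True)
    if subset is not None:
        if len(subset) == 0:
            raise ValueError("empty variant subset")
        lookup = {s: i for i, s in enumerate(variants["SNP"])}
        missing = [s for s in subset if s not in lookup]
        if missing:
            raise ValueError(f"subset variants absent from panel: {missing[:5]}")
        cols = [lookup[s] for s in subset]
        dosages = dosages[:, cols]
        variants = variants.iloc[cols].reset_index(drop=True)

    sd = dosages.std(axis=0, ddof=1)
    poly = sd > 0
    if not poly.all():
        dropped = variants.loc[~poly, "SNP"].tolist()
        logger.warning("dropping %d monomorphic SNPs: %s", len(dropped), dropped[:5])
        dosages = dosages[:, poly]
        variants = variants.loc[poly].reset_index(drop=True)
        sd = sd[poly]
    if variants.empty:
        raise ValueError("no polymorphic variants left in subset")

    cov = np.cov(dosages, rowvar=False, ddof=1)
    cov = np.atleast_2d(cov)
    corr = cov / np.outer(sd, sd)
    np.fill_diagonal(corr, 1.0)
    if ridge > 0:
        corr = (1.0 - ridge) * corr + ridge * np.eye(len(sd))
    return LDBlock(
        variants=variants[VARIANT_COLUMNS],
        cov=cov,
        corr=corr,
        sd=sd,
        ridge=ridge,
        block_id=block_id,
    )


def save_blocks(blocks: Sequence[LDBlock], outdir: str | Path) -> list[Path]:
    """Write each block under ``outdir`` as ``<block_id>.{cov,corr,vars}.tsv``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    prefixes = []
    for blk in blocks:
        prefix = outdir / blk.block_id
        blk.save(prefix)
        prefixes.append(prefix)
    return prefixes


def load_blocks(outdir: str | Path) -> dict[str, LDBlock]:
    """Load all blocks saved by :func:`save_blocks`, keyed by block id."""
    outdir = Path(outdir)
    blocks: dict[str, LDBlock] = {}
    for vars_file in sorted(outdir.glob("*.vars.tsv")):
        prefix = str(vars_file)[: -len(".vars.tsv")]
        blk = LDBlock.load(prefix)
        blocks[blk.block_id] = blk
    return blocks
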