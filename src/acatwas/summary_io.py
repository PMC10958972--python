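"""Read, validate, allele-harmonize, and meta-analyze GWAS summary statistics.

Summary statistics are tab-separated tables with one row per variant:
``SNP, CHR, POS, A1, A2, BETA, SE, Z, P, N`` (A1 = effect allele; BETA is
the log odds ratio; an ``OR`` column is accepted and converted).  All
downstream stages consume a :class:`HarmonizedSet`, in which every kept
record has its z and beta expressed on the reference allele orientation
(the orientation of the prediction-model weights), so orientation is
resolved exactly once.

Harmonization policy: records whose alleles are swapped relative to the
reference have z and beta negated (``sign_flipped``); strand-ambiguous
palindromic SNPs (A/T, C/G) are dropped; allele sets matching neither
orientation are dropped.  Matching is primarily by variant id, with a
(chr, pos) fallback for id-less records.

Meta-analysis is inverse-variance fixed effects (the METAL effect-size
scheme): beta = (sum b_i / se_i^2) / (sum 1 / se_i^2), se = (sum
1/se_i^2)^{-1/2}; z and p are recomputed from the combined effect, and
per-study case/control counts are pooled by addition when present.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

SUMSTAT_COLUMNS = ["SNP", "CHR", "POS", "A1", "A2", "BETA", "SE", "Z", "P", "N"]

_VALID_ALLELES = {"A", "C", "G", "T"}
_PALINDROMIC = {frozenset({"A", "T"}), frozenset({"C", "G"})}

#: harmonization outcome flags
KEPT = "kept"
SIGN_FLIPPED = "sign_flipped"
DROPPED_AMBIGUOUS = "dropped_ambiguous"
DROPPED_MISMATCH = "dropped_mismatch"


def zscore_to_p(z: np.ndarray | float) -> np.ndarray | float:
    """Two-sided normal tail probability, floored at the smallest positive float."""
    p = 2.0 * stats.norm.sf(np.abs(z))
    return np.clip(p, np.finfo(float).tiny, 1.0)


def read_sumstats(path: str | Path, validate: bool = True) -> pd.DataFrame:
    """Read a summary-statistic TSV; tolerates an OR column (beta = ln OR)."""
    df = pd.read_csv(path, sep="\t", dtype={"SNP": str, "A1": str, "A2": str})
    if "BETA" not in df.columns and "OR" in df.columns:
        df["BETA"] = np.log(df["OR"].astype(float))
    if "Z" not in df.columns and {"BETA", "SE"} <= set(df.columns):
        df["Z"] = df["BETA"] / df["SE"]
    if "P" not in df.columns and "Z" in df.columns:
        df["P"] = zscore_to_p(df["Z"].to_numpy(float))
    missing = [c for c in SUMSTAT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"summary statistics lack columns: {missing}")
    return validate_sumstats(df)[0] if validate else df


def write_sumstats(df: pd.DataFrame, path: str | Path) -> None:
    extra = [c for c in df.columns if c not in SUMSTAT_COLUMNS]
    df[SUMSTAT_COLUMNS + extra].to_csv(path, sep="\t", index=False)


def validate_sumstats(df: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split a table into valid records and rejects with reasons.

    Checks: SE > 0; p in (0, 1]; alleles in {A,C,G,T}; z consistent with
    beta/SE within 1e-6 when both are present; no duplicate variant ids.
    Invalid rows are dropped per record (with a logged reason), never
    fatally.
    """
    df = df.copy()
    reasons = pd.Series("", index=df.index, dtype=object)

    def _flag(mask: pd.Series, reason: str) -> None:
        sel = mask & (reasons == "")
        reasons[sel] = reason

    _flag(~(df["SE"].astype(float) > 0), "nonpositive SE")
    _flag(~df["P"].astype(float).between(0, 1, inclusive="right"), "p outside (0,1]")
    _flag(
        ~(df["A1"].isin(_VALID_ALLELES) & df["A2"].isin(_VALID_ALLELES)),
        "malformed alleles",
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        zimp = df["BETA"].astype(float) / df["SE"].astype(float)
    scale = np.maximum(1.0, np.abs(zimp))
    _flag(
        pd.Series(np.abs(df["Z"].astype(float) - zimp) > 1e-6 * scale, index=df.index),
        "z inconsistent with beta/SE",
    )
    _flag(df["SNP"].duplicated(keep="first"), "duplicate variant id")

    bad = reasons != ""
    if bad.any():
        logger.warning(
            "dropping %d invalid summary records (first: %s)",
            int(bad.sum()),
            reasons[bad].iloc[0],
        )
    rejects = df[bad].assign(reason=reasons[bad])
    return df[~bad].reset_index(drop=True), rejects.reset_index(drop=True)


@dataclass
class HarmonizedSet:
    """Summary statistics on the reference allele orientation.

    ``table`` holds every input record with a ``harmonize_flag`` column;
    kept and sign-flipped records already carry the re-oriented z/beta.
    """

    table: pd.DataFrame

    @property
    def kept(self) -> pd.DataFrame:
        """Records usable downstream (flags kept or sign_flipped)."""
        mask = self.table["harmonize_flag"].isin([KEPT, SIGN_FLIPPED])
        return self.table[mask].reset_index(drop=True)

    def zmap(self) -> dict[str, float]:
        k = self.kept
        return dict(zip(k["SNP"], k["Z"].astype(float)))

    def __len__(self) -> int:
        return len(self.kept)


def harmonize(sumstats: pd.DataFrame, reference: pd.DataFrame) -> HarmonizedSet:
    """Orient summary statistics onto a reference variant table.

    ``reference`` needs columns SNP, A1, A2 (and optionally CHR, POS for
    the positional fallback).  Outcomes per record:

    * alleles equal the reference orientation -> ``kept``;
    * alleles swapped -> z and beta negated, ``sign_flipped``;
    * palindromic A/T or C/G pair -> ``dropped_ambiguous``;
    * allele set matches neither orientation, or the variant is absent
      from the reference -> ``dropped_mismatch``.

    Idempotent on kept records: re-harmonizing the output against the
    same reference changes nothing.
    """
    df = sumstats.copy().reset_index(drop=True)
    ref = reference.drop_duplicates(subset="SNP").set_index("SNP")

    ref_a1 = df["SNP"].map(ref["A1"])
    ref_a2 = df["SNP"].map(ref["A2"])
    if {"CHR", "POS"} <= set(ref.columns) and {"CHR", "POS"} <= set(df.columns):
        unmatched = ref_a1.isna()
        if unmatched.any():
            by_pos = reference.drop_duplicates(subset=["CHR", "POS"]).set_index(["CHR", "POS"])
            key = pd.MultiIndex.from_frame(df.loc[unmatched, ["CHR", "POS"]])
            ref_a1[unmatched] = by_pos["A1"].reindex(key).to_numpy()
            ref_a2[unmatched] = by_pos["A2"].reindex(key).to_numpy()

    a1 = df["A1"].astype(str)
    a2 = df["A2"].astype(str)
    palindromic = pd.Series(
        [frozenset({x, y}) in _PALINDROMIC for x, y in zip(a1, a2)], index=df.index
    )
    same = (a1 == ref_a1) & (a2 == ref_a2)
    swapped = (a1 == ref_a2) & (a2 == ref_a1)

    flag = pd.Series(DROPPED_MISMATCH, index=df.index, dtype=object)
    flag[same] = KEPT
    flag[swapped] = SIGN_FLIPPED
    flag[palindromic] = DROPPED_AMBIGUOUS

    flip = flag == SIGN_FLIPPED
    df.loc[flip, "Z"] = -df.loc[flip, "Z"].astype(float)
    df.loc[flip, "BETA"] = -df.loc[flip, "BETA"].astype(float)
    df.loc[flip, ["A1", "A2"]] = df.loc[flip, ["A2", "A1"]].to_numpy()
    df["harmonize_flag"] = flag

    n_flip = int(flip.sum())
    n_drop = int((~flag.isin([KEPT, SIGN_FLIPPED])).sum())
    if n_flip or n_drop:
        logger.info("harmonize: %d sign-flipped, %d dropped", n_flip, n_drop)
    return HarmonizedSet(table=df)


def meta_fixed_effects(study1: pd.DataFrame, study2: pd.DataFrame) -> pd.DataFrame:
    """Inverse-variance fixed-effects meta-analysis of two harmonized studies.

    Shared variants get the precision-weighted combined beta and SE with z
    and p recomputed; variants present in only one study carry that
    study's values, flagged ``study1_only`` / ``study2_only``.  Records
    with SE <= 0 are rejected.  Sample sizes (and case/control counts when
    present) are pooled by addition.  Symmetric in study order.
    """
    frames = []
    for tag, df in (("study1", study1), ("study2", study2)):
        df = df.copy()
        bad = ~(df["SE"].astype(float) > 0)
        if bad.any():
            logger.warning("%s: rejecting %d records with SE <= 0", tag, int(bad.sum()))
            df = df[~bad]
        frames.append(df.set_index("SNP"))
    s1, s2 = frames

    merged = s1.join(s2, how="outer", lsuffix="_1", rsuffix="_2")
    both = merged["SE_1"].notna() & merged["SE_2"].notna()

    out = pd.DataFrame(index=merged.index)
    for col in ("CHR", "POS", "A1", "A2"):
        out[col] = merged[f"{col}_1"].where(merged[f"{col}_1"].notna(), merged[f"{col}_2"])

    w1 = 1.0 / merged["SE_1"].astype(float) ** 2
    w2 = 1.0 / merged["SE_2"].astype(float) ** 2
    beta = merged["BETA_1"].astype(float).where(merged["BETA_1"].notna(), merged["BETA_2"])
    se = merged["SE_1"].astype(float).where(merged["SE_1"].notna(), merged["SE_2"])
    beta[both] = (
        merged.loc[both, "BETA_1"].astype(float) * w1[both]
        + merged.loc[both, "BETA_2"].astype(float) * w2[both]
    ) / (w1[both] + w2[both])
    se[both] = 1.0 / np.sqrt(w1[both] + w2[both])

    out["BETA"] = beta
    out["SE"] = se
    out["Z"] = beta / se
    out["P"] = zscore_to_p(out["Z"].to_numpy(float))
    for col in ("N", "N_CASES", "N_CONTROLS"):
        if f"{col}_1" in merged.columns or f"{col}_2" in merged.columns:
            c1 = merged.get(f"{col}_1", pd.Series(np.nan, index=merged.index))
            c2 = merged.get(f"{col}_2", pd.Series(np.nan, index=merged.index))
            out[col] = c1.fillna(0).astype(float) + c2.fillna(0).astype(float)
    out["meta_flag"] = np.where(both, "both", np.where(merged["SE_1"].notna(), "study1_only", "study2_only"))
    out = out.reset_index().rename(columns={"index": "SNP"})
    # integer columns come back as float after the outer join
    for col in ("CHR", "POS", "N", "N_CASES", "N_CONTROLS"):
        if col in out.columns:
            out[col] = out[col].astype(float).round().astype("Int64")
    return out.sort_values("SNP").reset_index(drop=True)
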