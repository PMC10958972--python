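"""Gene-level fine-mapping of TWAS signals (FOCUS-style PIPs, credible sets).

LD can make a non-causal gene's predicted expression correlate with a
causal gene's, producing spurious TWAS hits.  Within one LD region and
one tissue, the vector of TWAS z-scores over m features is modeled as
multivariate normal; the predicted-feature correlation

    Omega_ij = (w_i' Gamma w_j) / (sigma_i sigma_j)

(induced jointly by LD and the model weights) is the null covariance.  A
causal configuration C (a subset of features, |C| <= k) inflates the
covariance to

    Omega + v * Omega_C Omega_C'

where Omega_C stacks the columns of Omega for the features in C and v is
a scalar prior effect variance.  With an independent per-feature prior
inclusion probability pi0, the posterior over configurations (including
the empty, null configuration) follows from Bayes' rule, and the marginal
posterior inclusion probability of feature i is the posterior mass of all
configurations containing i.

Credible sets rank features by PIP and accumulate normalized posterior
mass until the target level rho (default 0.9); the null configuration's
mass stays in the denominator, so a region with no signal can yield an
empty set.  Features with PIP >= 0.9 are flagged candidate causal.

Expression and splicing features are fine-mapped in separate runs.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .ld_reference import LDBlock
from .model_registry import ModelSet, WeightModel
from . import twas_core

logger = logging.getLogger(__name__)

DEFAULT_PI0 = 1e-3
DEFAULT_PRIOR_VAR = 30.0
DEFAULT_MAX_CAUSAL = 3
DEFAULT_RIDGE = 0.1
DEFAULT_LEVEL = 0.9
CANDIDATE_PIP = 0.9

FINEMAP_COLUMNS = [
    "REGION", "TISSUE", "FEATURE", "TYPE", "PIP",
    "IN_CREDIBLE_SET", "CANDIDATE_CAUSAL", "NULL_POSTERIOR",
]


@dataclass
class ExprCorr:
    """Predicted-feature correlation matrix for one region and tissue."""

    features: list[str]
    omega: np.ndarray
    ridge: float
    excluded: list[str]

    @property
    def size(self) -> int:
        return len(self.features)


@dataclass
class FinemapRecord:
    """Per-feature fine-mapping outcome within one region."""

    feature_id: str
    feature_type: str
    tissue: str
    region: str
    pip: float
    in_credible_set: bool
    null_posterior: float

    @property
    def candidate_causal(self) -> bool:
        return self.pip >= CANDIDATE_PIP

    def to_row(self) -> dict:
        return {
            "REGION": self.region,
            "TISSUE": self.tissue,
            "FEATURE": self.feature_id,
            "TYPE": self.feature_type,
            "PIP": self.pip,
            "IN_CREDIBLE_SET": self.in_credible_set,
            "CANDIDATE_CAUSAL": self.candidate_causal,
            "NULL_POSTERIOR": self.null_posterior,
        }


def expr_correlation(
    models: Sequence[WeightModel],
    block: LDBlock,
    ridge: float = DEFAULT_RIDGE,
) -> ExprCorr:
    """Predicted-feature correlation Omega over a region's weight models.

    Omega_ij = (w_i' Gamma w_j) / (sigma_i sigma_j) over each model's SNPs
    in the block; the ridge is added to the diagonal and the matrix is
    re-standardized to unit diagonal.  Features with non-positive
    predicted variance are excluded with a logged flag.
    """
    kept: list[WeightModel] = []
    excluded: list[str] = []
    W_rows = []
    pos = {s: i for i, s in enumerate(block.snps)}
    for m in models:
        if not all(s in pos for s in m.snps):
            excluded.append(m.feature_id)
            logger.warning("feature %s: model SNPs not all in region; excluded", m.feature_id)
            continue
        row = np.zeros(block.size)
        row[[pos[s] for s in m.snps]] = m.weights
        var = float(row @ block.cov @ row)
        if var <= 0 or not math.isfinite(var):
            excluded.append(m.feature_id)
            logger.warning("feature %s: non-positive predicted variance; excluded", m.feature_id)
            continue
        kept.append(m)
        W_rows.append(row)
    if not kept:
        return ExprCorr(features=[], omega=np.zeros((0, 0)), ridge=ridge, excluded=excluded)

    W = np.vstack(W_rows)
    raw = W @ block.cov @ W.T
    sd = np.sqrt(np.diag(raw))
    omega = raw / np.outer(sd, sd)
    if ridge > 0:
        omega = omega + ridge * np.eye(len(kept))
        d = np.sqrt(np.diag(omega))
        omega = omega / np.outer(d, d)
    np.fill_diagonal(omega, 1.0)
    return ExprCorr(
        features=[m.feature_id for m in kept],
        omega=omega,
        ridge=ridge,
        excluded=excluded,
    )


def _config_posteriors(
    z: np.ndarray,
    omega: np.ndarray,
    pi0: float,
    prior_var: float,
    max_causal: int,
) -> tuple[list[tuple[int, ...]], np.ndarray]:
    """Log-posterior over causal configurations |C| <= max_causal (incl. empty)."""
    m = len(z)
    configs: list[tuple[int, ...]] = []
    logposts: list[float] = []
    base_eye = 1e-10 * np.eye(m)
    for size in range(0, max_causal + 1):
        for combo in itertools.combinations(range(m), size):
            cov = omega + base_eye
            if combo:
                oc = omega[:, list(combo)]
                cov = cov + prior_var * (oc @ oc.T)
            try:
                ll = stats.multivariate_normal.logpdf(z, mean=np.zeros(m), cov=cov)
            except (np.linalg.LinAlgError, ValueError):
                logger.warning("non-PSD covariance for configuration %s; skipped", combo)
                continue
            logprior = size * math.log(pi0) + (m - size) * math.log1p(-pi0)
            configs.append(combo)
            logposts.append(ll + logprior)
    lp = np.asarray(logposts)
    lp -= lp.max()
    post = np.exp(lp)
    post /= post.sum()
    return configs, post


def marginal_pips(
    z: Mapping[str, float] | Sequence[float],
    corr: ExprCorr,
    pi0: float = DEFAULT_PI0,
    prior_var: float = DEFAULT_PRIOR_VAR,
    max_causal: int = DEFAULT_MAX_CAUSAL,
    region: str = "region",
    tissue: str = "",
    feature_types: Mapping[str, str] | None = None,
) -> list[FinemapRecord]:
    """Marginal posterior inclusion probabilities for one region and tissue.

    ``z`` gives the observed TWAS z-score per feature (mapping keyed by
    feature id, or a sequence aligned with ``corr.features``).  All causal
    configurations up to ``max_causal`` features are enumerated, including
    the empty (null) configuration; posteriors are normalized over the
    enumerated set and PIP_i sums the posterior of configurations
    containing feature i.
    """
    if not 0.0 < pi0 < 1.0:
        raise ValueError("pi0 must lie in (0, 1)")
    m = corr.size
    if m == 0:
        return []
    if max_causal > m:
        raise ValueError("max_causal cannot exceed the number of features")
    if isinstance(z, Mapping):
        zvec = np.array([z[f] for f in corr.features], dtype=float)
    else:
        zvec = np.asarray(list(z), dtype=float)
        if zvec.size != m:
            raise ValueError("z length does not match feature count")

    configs, post = _config_posteriors(zvec, corr.omega, pi0, prior_var, max_causal)
    pips = np.zeros(m)
    null_post = 0.0
    for combo, pr in zip(configs, post):
        if combo:
            pips[list(combo)] += pr
        else:
            null_post = float(pr)

    ftypes = feature_types or {}
    records = [
        FinemapRecord(
            feature_id=f,
            feature_type=ftypes.get(f, "gene"),
            tissue=tissue,
            region=region,
            pip=float(pips[i]),
            in_credible_set=False,
            null_posterior=null_post,
        )
        for i, f in enumerate(corr.features)
    ]
    return credible_set(records)


def credible_set(records: list[FinemapRecord], level: float = DEFAULT_LEVEL) -> list[FinemapRecord]:
    """Flag the rho-level credible set among a region's records (in place).

    Features are ranked by PIP (ties broken by feature id for
    determinism); cumulative PIP mass, normalized by total feature mass
    plus the null posterior, accrues until it reaches ``level``.  When the
    null configuration holds more than 1 - level of the mass no set of
    features can reach the level and the credible set is empty.
    """
    if not records:
        return records
    null_post = records[0].null_posterior
    total = sum(r.pip for r in records) + null_post
    if total <= 0:
        return records
    ranked = sorted(records, key=lambda r: (-r.pip, r.feature_id))
    if sum(r.pip for r in records) / total < level:
        return records  # null absorbs the mass: empty credible set
    cum = 0.0
    for r in ranked:
        r.in_credible_set = True
        cum += r.pip / total
        if cum >= level:
            break
    return records


def finemap_regions(
    modelset: ModelSet,
    zmap_by_feature: Mapping[tuple[str, str], float],
    blocks: Mapping[str, LDBlock],
    feature_type: str = "gene",
    tissues: Sequence[str] | None = None,
    regions: Sequence[str] | None = None,
    pi0: float = DEFAULT_PI0,
    prior_var: float = DEFAULT_PRIOR_VAR,
    max_causal: int = DEFAULT_MAX_CAUSAL,
    ridge: float = DEFAULT_RIDGE,
) -> pd.DataFrame:
    """Fine-map every (region, tissue) with >= 1 feature of the given type.

    ``zmap_by_feature`` maps (feature id, tissue) to the observed TWAS z.
    ``regions`` restricts to named LD blocks (default: all with models).
    Expression (``feature_type='gene'``) and splicing (``'intron'``)
    features are processed in separate calls.
    """
    block_of = twas_core.assign_blocks(modelset, blocks)
    tissues = list(tissues) if tissues is not None else modelset.tissues
    wanted = set(regions) if regions is not None else None

    rows = []
    for tissue in tissues:
        by_region: dict[str, list[WeightModel]] = {}
        for m in modelset.models_in_tissue(tissue, feature_type):
            bid = block_of.get((m.feature_id, m.tissue))
            if bid is None or (wanted is not None and bid not in wanted):
                continue
            if (m.feature_id, tissue) in zmap_by_feature:
                by_region.setdefault(bid, []).append(m)
        for bid in sorted(by_region):
            models = by_region[bid]
            corr = expr_correlation(models, blocks[bid], ridge=ridge)
            if corr.size == 0:
                continue
            zmap = {f: zmap_by_feature[(f, tissue)] for f in corr.features}
            k = min(max_causal, corr.size)
            ftypes = {m.feature_id: m.feature_type for m in models}
            recs = marginal_pips(
                zmap, corr, pi0=pi0, prior_var=prior_var, max_causal=k,
                region=bid, tissue=tissue, feature_types=ftypes,
            )
            rows.extend(r.to_row() for r in recs)
    return pd.DataFrame(rows, columns=FINEMAP_COLUMNS)
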