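# Methods

## Statistical model

All stages work on marginal GWAS association z-scores. At a locus with LD
correlation matrix `R` (estimated from a reference dosage panel), the null
model is `z ~ N(0, R)`; a vector of joint standardized log-odds effects
`b` shifts the mean to `R·Λ` with `Λ = b·√(n_ca n_co / N)` (the usual
case-control score-test scaling; `N = n_ca + n_co`). Everything downstream
is a linear or Bayesian functional of this model:

* **Imputation** is the Gaussian conditional mean of unobserved z given
  observed z, with quality `r2pred` equal to the explained variance; it is
  linear in the observed vector, and under the null the imputed z has
  variance exactly `r2pred` (a property the tests check empirically).
* **The TWAS statistic** for a feature with weights `w` is
  `z_g = Σ_l w_l (σ_l/σ_g) z_l` with `σ_g² = wᵀΓw`, where `Γ` and the
  dosage SDs `σ_l` come from the reference panel, never from GWAS allele
  frequencies; `z_g ~ N(0,1)` under the null, is invariant to rescaling
  `w` and flips sign with it. Model SNPs without a usable z are dropped
  and `σ_g` is recomputed over the SNPs actually used
  (drop-and-renormalize); coverage below 0.5 is flagged, zero usable SNPs
  or non-positive variance yields an *untestable* flag rather than an
  error.
* **ACAT** combines K p-values as `T = Σ w_k tan((0.5−p_k)π)`,
  `p = 0.5 − arctan(T)/π`. For `p_k < 1e-15` the term is replaced by its
  asymptote `w_k/(p_k π)`, and for `T > 1e15` the result by `1/(πT)`, so
  the combination is stable down to the smallest representable doubles;
  inputs are clipped at `1 − 1e-16`. Identical inputs are a fixed point
  and decreasing any input never increases the result. The splicing
  approach applies ACAT twice: equal weights over a gene's introns within
  a tissue, then equal weights `1/K` over the K tissues in which the gene
  is testable (tissues with no model or an untestable result simply drop
  out of K). Square-root-of-model-sample-size weighting is available as a
  sensitivity option; equal weighting is the default.
* **Conditioning** residualizes target z on index-variant z:
  `z_adj = (z_t − R_tI R_II⁻¹ z_I)/√(1 − R_tI R_II⁻¹ R_It)`. A ridge of
  1e-6 is added to `R_II`; index variants are greedily LD-pruned at
  r² > 0.9 first; a variance denominator at or below 1e-4 marks the
  target collinear and sets `z_adj = 0`. Note the map is *not* idempotent
  when target–index LD is nonzero — it always subtracts the LD-predicted
  fit — but its defining property holds: the adjusted z-scores carry no
  residual correlation with the index z-scores and remain standard normal
  under the null (both tested).
* **Mediation** reconstructs the adjusted (direct) effect of an index
  variant as `β_direct = z_adj · SE_total` with `SE` unchanged (a
  standardized-genotype approximation under which conditioning changes
  the SE little); the indirect effect is `total/direct` on the OR scale —
  the only definition under which the printed proportion-mediated formula
  `PM = direct·(indirect−1)/(total−1)` reaches exactly 1 when the direct
  effect is null and 0 when adjustment changes nothing. A variant is
  *mediated* when PM > 0.5 and its adjusted p exceeds 5×10⁻⁸. The
  adjusting set is, per locus, the union of model SNPs of all TWAS-
  identified genes in the LD block (a per-gene mode is available); the
  index variant itself stays in the set when it is one of the eQTL/sQTL,
  so a hit whose signal flows entirely through a modeled variant lands on
  the collinearity path and is classified fully mediated.
* **Fine-mapping** treats the region's TWAS z-vector as
  `z | C ~ N(0, Ω + v·Ω_C Ω_Cᵀ)` for a causal configuration `C`, with
  `Ω_ij = wᵢᵀΓw_j/(σᵢσ_j)` the predicted-feature correlation and an
  independent per-feature prior `π0`. All configurations with
  `|C| ≤ k` (including the empty one) are enumerated; PIPs are the
  posterior mass of configurations containing each feature, verified
  against a full `2^m` brute-force posterior in the tests. Credible sets
  rank features by PIP and accumulate mass normalized by total feature
  mass plus the null posterior until the 0.9 level; when the null holds
  more than 10% of the mass no feature set can reach the level and the
  set is empty. Expression and splicing features are fine-mapped in
  separate runs; per-tissue PIPs are reported with a per-gene maximum in
  the gene report.

## Tunable parameters

| parameter | default | meaning / rationale |
| --- | --- | --- |
| imputation ridge λ | 0.1 | conditions the observed-SNP correlation; conventional for this estimator |
| r2pred floor | 0.6 | imputed z below this quality are flagged, not used in TWAS |
| TWAS LD ridge | 0 | keeps `σ_g²` unbiased; raise only if Γ is singular |
| conditioning ridge / collinearity floor | 1e-6 / 1e-4 | numerical safeguards on `R_II` and the variance denominator |
| index-SNP prune r² | 0.9 | prevents near-duplicate indices from making `R_II` singular |
| conditioning window | ±2 Mb | index variants considered near a feature |
| α | 0.05 | family-wise level; two Bonferroni universes (expression genes, splicing genes) |
| fine-mapping π0 / v / k | 1e-3 / 30 / 3 | per-feature prior inclusion, scalar prior effect variance, max causal features; deferred defaults documented as assumptions |
| fine-mapping Ω ridge | 0.1 | added to the diagonal then re-standardized |

The imputation ridge/floor and the fine-mapping prior triple are
assumptions (the upstream methods defer or leave them unstated); all are
configurable per run.

## What the synthetic data emulates — and what it does not

The generator reproduces the *statistical structure* the analysis
assumes: LD (block-diagonal AR(1) Gaussian copula, thresholded to
binomial(2, maf) dosages — the implied pairwise dosage correlation is
checked against an orthant-probability integration oracle), sparse
cis-architecture with cross-tissue effect sharing (a shared base weight
vector plus tissue noise, mimicking shrinkage-refined multi-tissue
models), 1–5 intron features per gene with their own weights, and
case-control marginal z-scores either sampled directly from `N(RΛ, R)`
(effective sample size `4/(1/n_ca + 1/n_co)`) or computed from an
individually simulated logistic cohort via per-SNP score tests — the two
samplers agree in expectation, which the tests use as an oracle.

It does **not** emulate: realistic human LD maps (no long-range LD, no
varying block sizes), allele-frequency-dependent effect sizes,
imputation-panel error, X-chromosome dosages, population stratification,
or sample overlap between meta-analyzed studies. Passing tests therefore
demonstrate correctness of the statistical machinery under the model's
own assumptions, not robustness to the ways real data violate them.

Scenario defaults are fixed study conditions: a 500-individual reference
panel, 11 tissues, within-block AR(1) ρ = 0.6, MAF ∈ (0.05, 0.5), 8-SNP
blocks housing 10 genes each, 10,000 cases / 10,000 controls, and a
causal log-odds of 0.1 per SD of expression (0.15 for the
single-eQTL mediation scenario, 0.12 for the two-gene fine-mapping
scenario) — strong enough that a correctly implemented pipeline resolves
them, small enough that the marginal per-SNP effects stay in the regime
where the score-test approximation holds.

## Numerical choices and degenerate inputs

* p-values are recomputed from z as two-sided normal tails throughout and
  floored at the smallest positive double; combined p-values are clipped
  into `(0, 1]`.
* Harmonization drops strand-ambiguous palindromic (A/T, C/G) records
  rather than resolving them by frequency (conservative; the generator
  never emits them). Variant matching is by id with a (chr, pos)
  fallback. Sign flips apply to GWAS z and beta only — model weights are
  the single source of orientation truth and are never modified.
* Meta-analysis uses effect-size (inverse-variance) weighting; records
  with SE ≤ 0 are rejected per record.
* Fine-mapping ties in the credible-set ranking break by feature id;
  feature order permutations permute outputs consistently.
* Monomorphic reference SNPs are dropped when building LD; a singular
  observed-correlation matrix during imputation raises an error that
  names the fix (a positive ridge).
* The per-tissue TWAS runner batches fully covered models of one LD block
  and tissue into a single matrix product; partially covered models take
  the per-model path. Both paths are asserted equal in the tests.

## Problem sizes used by the checks

The test and acceptance runs use: 20,000 null replicates for ACAT type-I
error (K = 11); 100 replicate cohorts of n = 5,000 for the TWAS
individual-level oracle and ≥5,000 features for null calibration; 3,000
null replicates for imputation variance calibration; 100 replicate GWAS
draws each for mediation detection and credible-set coverage; and 20
replicate null pipelines of 2,000 genes for family-wise error. These
sizes put Monte-Carlo error comfortably inside the asserted tolerances
while keeping a full run on one CPU in minutes.

## Known limitations

* Conditional analysis residualizes on a fixed index list; the full COJO
  stepwise model-selection of independent signals is out of scope.
* The conditional-z map is applied once per feature; iterating it is not
  supported (see the idempotence note above).
* Fine-mapping enumerates configurations (fine for regions up to tens of
  features at k ≤ 3); no genome-wide block inference is provided —
  regions are the fixture LD blocks or externally supplied boundaries.
* Effect-size imputation (beta/SE) is deliberately not offered: only z is
  imputed.
* The splicing gene-level test combines only introns mapped to a gene;
  unmapped introns are reported separately, never silently dropped.
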