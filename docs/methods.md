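# Methods

## Model and hypotheses

The data are an expression block `X` (n subjects × p genes, the members of
one predefined gene set) and a phenotype block `Y` (n × q continuous
phenotypes). All columns are centered and scaled across subjects (sample SD,
n − 1 denominator), so covariance and correlation coincide and a single
matrix per block serves as both.

LCT tests the linear null — *no association between any linear combination
of the genes and any linear combination of the phenotypes* — with the
statistic

    T²* = max_{A,B} (Aᵀ Σ_XY B)² / (Aᵀ Σ*_XX A · Bᵀ Σ*_YY B).

This is a canonical-correlation-type quantity in which only the two
within-block covariances are replaced by shrinkage estimates; the
cross-covariance `Σ_XY` is the plain sample estimate. NLCT first replaces
each gene column by a natural cubic spline basis expansion and then applies
the identical machinery, which widens the null to *no relationship of any
form* between genes and phenotypes (phenotypes are deliberately left
untransformed — expanding both blocks would square the flexibility and the
sample-size demands).

Both tests are *self-contained*: significance is calibrated by permuting
subjects, which preserves the correlation structure within the gene set and
within the phenotype block.

## Shrinkage estimator

Off-diagonal entries of each within-block correlation matrix are contracted
toward zero by the common factor `min(1, max(0, 1 − λ*))`, with

    λ* = Σ_{i≠j} Var̂(ρᵢⱼ) / Σ_{i≠j} ρᵢⱼ² ,
    Var̂(ρᵢⱼ) = n / (n−1)³ · Σ_k (w_kij − w̄ᵢⱼ)² ,   w_kij = x̃_ki x̃_kj ,

computed on the standardized data. The diagonal stays at exactly 1. For a
single-column block the matrix is `[1]`. When all off-diagonal sample
correlations are exactly zero the ratio is undefined and λ* is set to 1
(full shrinkage to the identity — the limit the estimator approaches as
correlations vanish). λ* is reported clipped to [0, 1]. The implementation
evaluates the sums through the closed forms `Σ_k w_kij = (n−1) ρᵢⱼ` and
`Σ_k w²_kij = (X̃∘X̃)ᵀ(X̃∘X̃)`, avoiding any n × m × m intermediate; the test
suite checks it against a literal loop transcription.

Zero-variance columns are a hard error at standardization: silently dropping
a gene would change gene-set membership invisibly. The GSA runner is the one
place where zero-variance genes are dropped, with a logged warning.

## Whitening and the two-step solution

Eigen-decomposing `Σ* = U Λ Uᵀ` gives the whitening transform
`W = U Λ^(−1/2)` (eigenvalues sorted descending; those below 1e-12 × the
largest are dropped — a purely defensive threshold, since shrinkage makes
the matrices positive definite). With `X̃ = XW_X`, `Ỹ = YW_Y` and
`D = X̃ᵀỸ/(n−1)`, the maximization reduces to the largest eigenvalue of
`DᵀD` (equivalently `DDᵀ`); the smaller of the two is solved. The reported
directions are `B ∝ W_Y β` and `A ∝ W_X D β` for the top eigenvector `β`,
each normalized to unit length with the first nonzero coordinate positive
(the statistic itself is invariant to sign and scale; the normalization only
makes reporting deterministic; under an exactly tied top eigenvalue the
eigensolver's vector is taken as is).

### Scale of the statistic

T²* is a squared correlation only when the shrinkage matrices are close to
the sample ones. Because the numerator keeps the unshrunken `Σ_XY` while the
denominators shrink toward the identity, T²* is **not bounded by 1**: with
p ≈ n and weakly correlated genes, λ* ≈ 1 and T²* concentrates around the
largest squared singular value of the raw cross-correlation matrix, which
exceeds 1 under the null (e.g. ≈ 2.9 for n = 20, p = 20, q = 10). This is
harmless — the permutation test compares the statistic to its own
permutation distribution — but the value should not be read as a variance
fraction. In the p = q = 1 reduction the shrinkage matrices are `[1]` and
T²* is exactly the squared Pearson correlation.

## Fast permutation scheme

Sample permutation changes neither within-block correlation structure, so
shrinkage and whitening are computed **once** from the observed data. Each
permutation π reshuffles the rows of `Ỹ` only and recomputes the largest
eigenvalue of `Ỹ[π]ᵀ G Ỹ[π]/(n−1)²`, where `G = X̃X̃ᵀ` is the n × n Gram
matrix — so the per-permutation cost is independent of p (which NLCT
multiplies by the spline df). Permutations are uniform random subject
permutations from a seeded generator; the identity is not excluded. The
p-value is `(b + 1)/(B + 1)`, which cannot be zero and is valid under
exchangeability; the test is one-sided (large T²* rejects). The observed
statistic entering the `≥` comparison is recomputed through the same Gram
route as the permuted ones, so ties are resolved consistently. The suite
verifies the shortcut is *exactly* equivalent — permutation for permutation
— to naive recomputation of the full statistic from permuted raw phenotypes
with frozen shrinkage.

Always the phenotype block is permuted, never the gene block, so the
equivalence holds regardless of whether q < p. For the statistic itself the
roles of `X` and `Y` are exchangeable (asserted in the suite).

## Spline expansion (NLCT)

Each gene is expanded into `df` natural cubic spline basis functions
(default df = 5; at least 2; requires n > df + 1), evaluated with the
cubic-regression-spline construction used by mgcv-style smoothers (via
patsy): `df` knots at equally spaced quantiles of the gene's values, the
outermost two at the observed min/max, basis functions linear beyond them.
There is no explicit intercept column; the expanded columns are re-centered
and re-scaled so the shrinkage estimator again sees unit-variance inputs
(the constant direction inside the basis span is annihilated by centering,
so the centered expansion has rank df − 1 per gene — unproblematic, since
shrinkage keeps the correlation matrix positive definite). The test suite
checks the span of the expansion, after centering, against an independent
truncated-power natural-spline construction on the same knots.

Genes with fewer than df + 1 distinct values get a reduced basis
(df_eff = #distinct − 1, minimum 1) with a logged warning; for df_eff ≤ 2 a
polynomial basis of that degree stands in, since a cubic spline needs at
least three knots. This keeps heavily discretized expression values from
producing singular expansions.

## Synthetic data generator

The generator draws `X` (n × p) from a multivariate normal with zero mean,
unit variances and *exchangeable* correlation ρ (construction:
`√ρ·shared + √(1−ρ)·idiosyncratic`), an error block `ε` (n × q) from the
same family with the same ρ, and sets `Y = Xβ + ε`. Under the null β = 0.
Under the alternative, 5 rows and 3 columns of β are chosen at random
(without replacement) and the 15 intersection entries are set to a common
effect μ; defaults q = 10, ρ ∈ {0, 0.3, 0.6, 0.9}, μ on a 0–5 grid. Each
replicate derives its seed deterministically from (master seed, cell,
replicate index), so whole experiment grids are bit-reproducible.

What it does *not* emulate about real expression data: heavy tails and
skewness, mean–variance dependence, platform/batch effects, non-exchangeable
(block or decaying) gene–gene correlation, and missingness. Passing size and
power checks on this design therefore demonstrates correctness of the
statistic and its calibration under exchangeable Gaussian nulls, not
robustness to microarray artifacts.

The GSA fixture generator plants one associated set among decoys: each set
gets its own genes (exchangeable within the set, independent across sets)
and only the planted set's genes enter the β block driving the phenotypes.

## Experiment profiles and problem sizes

The full-scale study design is 1000 replicates × 1000 permutations per cell.
The package's default profile is 200 × 200, the bundled acceptance runs use
300 × 300 for size and 150 × 150 for power curves — sizes chosen so the
whole suite re-runs in a few minutes while keeping binomial Monte-Carlo
error small (SE ≈ 0.013 at 300 replicates for a rate near 0.05); tolerances
in the tests are set to ≈ 2–3 binomial SEs. The planted-set experiment uses
999 permutations so that the minimal attainable p-value (0.001) remains
significant after a 20-set BH adjustment.

## GSA runner

Gene sets are read from GMT (name, description, members per line; duplicate
members deduplicated with a warning), intersected with the measured-gene
universe, and kept when the *matched* size falls in [5, 500] (defaults).
Matching is exact-string after whitespace trimming, case-sensitive — alias
resolution is out of scope. Each set is tested with a seed derived from
(master seed, CRC32 of the set name), so per-set results are independent of
set ordering and of which other sets are included. Sets with fewer than two
usable (non-constant) matched genes are reported with an `untested` status
and excluded from the FDR adjustment rather than silently dropped.
Multiple-testing adjustment is Benjamini–Hochberg step-up by default, with a
single-λ Storey q-value (λ = 0.5) behind a flag.

## Known limitations

- No covariate adjustment (continuous or categorical confounders).
- Self-contained testing means a handful of strong genes can carry a set;
  no post-hoc core-subset reduction is provided.
- Permutation p-values have resolution 1/(B + 1); FDR-significant calls at
  small B are limited by that granularity.
- The exchangeable-correlation generator is a deliberately idealized null;
  see above.
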