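# Methods

This note records the statistical model behind `cismr`, the conventions and
numerical choices the implementation makes where the literature leaves room,
and what the synthetic benchmark does and does not establish.

## Data model and harmonization

A region holds `P` biallelic variants with effect-allele frequencies `f_j`,
marginal exposure associations `(bX_j, sX_j, pX_j)` estimated on `N1`
individuals, marginal outcome associations `(bY_j, sY_j)` on an
independent sample of `N2`, and a reference correlation matrix `R`
(`rho_ij`).  Harmonization intersects the three sources on variant id
(exposure-file order is canonical), flips outcome betas coded on the
opposite allele, sign-flips LD rows/columns coded on the opposite allele,
and optionally drops palindromic (A/T, C/G) variants.  An allele pair that
neither matches nor swaps drops the variant; LD files without allele
information are trusted as already aligned.

The correlated-instruments weighting matrix is taken as

    Omega_ij = sY_i sY_j rho_ij .

This is the standard generalized-least-squares weighting and the only
convention consistent with the PCA transform below (the alternative
reading, the raw genotype covariance `Cov(G_i, G_j)`, would make the
`Psi`/`Omega` identity fail).  Omega is PSD by construction (a diagonal
congruence of `R`).

## Estimators

* **Wald ratio** `bY_j / bX_j` with first-order `se = sY_j / |bX_j|`;
  exposure-side uncertainty is ignored, the usual convention for a strong
  single instrument (it is what makes the top-SNP estimator winner's-curse
  prone but unbiased at strong F).
* **IVW** (fixed-effect only; no random-effects inflation):
  diagonal weights `sY_j^-2`, or the full `Omega^-1` for correlated
  instruments.  Linear systems are solved via Cholesky after an explicit
  eigenvalue-based condition check (default ceiling 1e8); an
  ill-conditioned Omega raises with the condition number rather than
  falling back to a pseudo-inverse, because silently regularizing is
  exactly the numerical instability the selection methods exist to avoid.
* Confidence intervals use the normal quantile 1.959964; p-values are
  two-sided normal.

## Instrument selection

**LD-pruning** selects by ascending exposure p-value (ties: smaller `sX`,
then lexicographic id — fully deterministic), discarding everything with
`|r| >= rho` to a selection; with a threshold `tau` set, sub-threshold
variants are never selected.  Note the selected set is *not* monotone in
`rho` (a looser threshold can admit a variant that then shadows a
different one), so sensitivity analysis across `rho` values is genuinely
informative; the guaranteed invariants are the pairwise `|r| < rho` bound
and the exact partition of the input into selected/discarded.

**CoJo-style conditional selection** reconstructs joint fits from marginal
statistics under Hardy-Weinberg genotype variances `d_j = 2 f_j (1-f_j)`:
`X'X ~ N1 D^1/2 R D^1/2`, `X'y_j ~ N1 d_j bX_j`, residual variance
re-estimated after each joint fit (floored at 1e-8), exposure variance
`var_y` defaulting to 1 (standardized trait).  A candidate's conditional
p-value is its p-value in the joint fit with the current selection; the
same `rho` screens collinear candidates and a selected variant is dropped
again when its joint p-value rises above `tau`.  A single per-SNP sample
size `N1` is assumed throughout.

## PCA-IVW

`Psi_ij = bX_i bX_j sY_i^-1 sY_j^-1 rho_ij` is symmetrized before the
eigendecomposition; numerically negative eigenvalues are clamped to zero
(Psi is PSD in exact arithmetic).  `k` is the smallest number of leading
components reaching the variance threshold of Psi's trace (floored at 1),
and the IVW formula is evaluated on `(W_k' bX, W_k' bY, W_k' Omega W_k)`.
At `k = P` this equals correlated IVW algebraically; the test suite
verifies the identity to 1e-8.

## JAM

The exposure model `X ~ N(G b, sigma^2)` is fitted from summary data via
`z_j = 2 f_j (1-f_j) N1 bX_j` (an approximation to `G'X` for centered
data under HWE) and `X'X = N1 D^1/2 R D^1/2` from the reference panel.
Model evidence for a variant subset is the closed-form conjugate
normal-inverse-gamma g-prior marginal likelihood of the `N1`-observation
linear model, with residual sum of squares
`s = y'y - g/(1+g) z_g' (X'X)_gg^-1 z_g` and `y'y = N1 * Var(X)` (trait
standardized, `Var(X) = 1`).  Hyperparameters: unit-information `g = N1`;
inverse-gamma shape/rate 0.01/0.01; beta-binomial model prior `a = 1`,
`b = P` (prior mean model size about one variant, the usual fine-mapping
sparsity choice).  Submatrices with condition number above 1e8 make a
model unvisitable (evidence `-inf`).

The reversible-jump chain starts from the smallest-p variant and proposes
add/delete/swap with probability 1/3 each (an infeasible move at the
boundary counts as a rejection); the Hastings correction accounts for the
add/delete asymmetry.  The input is pre-pruned at `rho = 0.9` by default
with no significance threshold.  Post-burn-in (default 10%) visit
frequencies define the model posterior; on 5-variant problems the chain
matches exhaustive enumeration to total-variation distance < 0.01 at
200,000 iterations.  Each non-empty model contributes its correlated-IVW
estimate, combined by the law of total variance with weights renormalized
over non-empty models; the empty-model mass is reported separately, and an
all-empty posterior is an error rather than an estimate.  The library
default chain length is 1,000,000 iterations; the benchmark harness uses
5,000 per replicate, which is indistinguishable in the tabulated medians
because the post-pruning model space of the 60-variant region is small
(verified against 50,000-iteration runs and enumeration).

For binary traits, `logodds_to_linear` maps a log-odds ratio to the
linear-probability-scale effect `beta * phi (1-phi)` at case fraction
`phi` (first-order; accurate within ~10% for |log-OR| <= 0.2).

## Factor-based methods

Loadings are the leading eigenvectors of `S = diag(s) R diag(s)`,
`s_j = sqrt(2 f_j (1-f_j))`; auto-`k` keeps 99% of the trace (a simple
empirical rule; information-criterion-based factor counts are out of
scope).  The moment function is `g(theta) = a - theta c` with
`a = (1/P) L' D bY`, `c = (1/P) L' D bX`, and — the weighting being left
open by the literature — the implementation uses the delta-method moment
covariance under two independent samples,

    V(theta) = (1/P^2) L' D Omega_Y D L + theta^2 (1/P^2) L' D Omega_X D L,

with `Omega_X = diag(sX) R diag(sX)`, `Omega_Y = diag(sY) R diag(sY)`.
A single reference panel supplies both `D` matrices.  F-LIML minimizes the
continuously-updating criterion `Q(theta) = g'V^-1g` (coarse grid on
[-5, 5], then bounded refinement to 1e-10); its standard error is
`sqrt(2/Q'')` by central differences, with the analytic GMM curvature
`(c'V^-1c)^-1` as fallback.  The acceptance surface for this method family
is calibration (type-I error, coverage, median bias), not coefficient-level
reproduction of any particular implementation.

AR uses `Q(theta0) ~ chi2_k`; LM orthogonalizes the Jacobian estimate
(`q = c + theta Vc V^-1 g`) and refers the squared score to `chi2_1`; CLR
combines them through the identification statistic
`r = q' Var(q|g)^-1 q` as
`CLR = (AR - r + sqrt((AR+r)^2 - 4r(AR-LM)))/2`, with the conditional
p-value simulated (10,000 seeded draws of `(chi2_1, chi2_{k-1})`); at
`k = 1` CLR collapses exactly to AR and the p-value is analytic.  The CLR
confidence set inverts the test over a grid (default 801 points on
[-2, 2]) reusing one set of Monte Carlo draws across the grid so the
p-value curve is smooth; sets touching the grid boundary are flagged
unbounded, multi-interval sets disjoint.

## Synthetic regions and the benchmark

The generator emulates a cis region as LD blocks of biallelic variants.
Haplotypes are latent-Gaussian threshold variables; because thresholding
attenuates correlation, the latent correlation is calibrated pairwise by
tetrachoric inversion so that the *dosage* correlations actually equal the
target `decay^|i-j|` within blocks (realized pool correlations match to
~1e-3).  Allele frequencies are assigned per block (base frequencies
0.10-0.45 with a +-0.004 within-block gradient): variants in tight LD must
have nearly equal frequencies, since the attainable correlation between
binaries is capped at `sqrt(p1 q2 / (p2 q1))`.

Two named regions are shipped, both 60 variants in 6 blocks of 10:
`shbg` (decay 0.95, dense LD; strong scenario `vg = 3%`, causal effects
`|N(0, 0.2)| + 0.1`) and `hmgcr` (decay 0.85; strong `vg = 2%`, effects
`|N(0, 0.03)| + 0.03`); weak-instrument variants divide `vg` by ten.  Six
causal variants sit at the block centers (configurable to 1 or 3).  Effects
are redrawn each replicate and rescaled against the pool genotype
covariance so the causal variants explain exactly `vg` of exposure
variance.

Phenotypes follow the confounded two-sample model
`X = G b + U + eps_X`, `Y = theta X + U + eps_Y` with
`U, eps_X, eps_Y ~ N(0, sigma0^2)` i.i.d.; confounder loadings are 1 and
`sigma0^2 = (1 - vg)/2` closes the variance budget at `Var(X) = 1` (only
`vg` is pinned by the design; the results are insensitive to how the
residual splits between confounding and noise).  Default sample sizes
`n1 = 10,000`, `n2 = 180,000`, 1000 replicates.

A fixed genotype pool (default 400,000 individuals) is generated once per
region; each replicate takes **disjoint** row subsets for the exposure and
outcome samples, and the reference correlation comes from the whole pool
(or an `nref`-row subsample per replicate, emulating a small reference
panel).  This mirrors a bootstrap-from-one-population design and keeps a
1000-replicate battery around 1.5 minutes on one CPU.  Per-replicate
randomness derives from `SeedSequence((scenario seed, replicate index))`,
so any replicate is reproducible in isolation and all methods compare on
identical data within a replicate.

Marginal summary statistics come from mass-vectorized per-variant simple
regressions (integer-exact dosage cross-products; verified against
`statsmodels` OLS), with p-values from the t distribution.  The oracle F
statistic — the overall F of regressing the exposure on the six causal
dosages — tracks the design value `1 + n1 vg / ((1 - vg) k)`: about 52,
35 and 6.0 for the strong-SHBG, strong-HMGCR and weak-SHBG settings.

### What the benchmark does not emulate

* Real UK-Biobank-scale LD (717/590 variants): the desk-scale 60-variant
  region preserves the many-correlated-variants/few-causal regime but has
  a flatter correlation spectrum than a dense genotyped region, so
  dimension-reduction tunings calibrated to real data (PCA at 99.9% of
  trace) retain proportionally more weak directions here and show slightly
  stronger attenuation at nonzero effects than they would on a real
  region.  Null calibration is unaffected.
* Binary outcomes: `Y` is continuous; the outcome sample size plays the
  role of a large case-control consortium.
* Pleiotropy, winner's-curse two-stage designs, sample overlap and
  per-SNP missingness are all absent by design.

Passing benchmarks therefore establish internal statistical correctness
(calibration, equivariances, oracle equivalences) under the stated
generative model, not performance guarantees on any particular real data
set.

## Numerical conventions

* Condition ceilings: 1e8 for Omega, projected Omega, CoJo joint fits and
  JAM submatrices.
* Eigendecompositions always symmetrize their input first; negative
  eigenvalues of PSD-by-construction matrices are clamped to zero.
* p-values are floored at the smallest positive double so they stay in
  (0, 1].
* Ties in p-value ordering break on smaller exposure SE, then variant id.
* Degenerate inputs fail loudly: zero exposure effect (Wald), all-zero
  exposure effects (IVW, F-LIML identification), constant dosage columns,
  empty harmonization intersections, only-empty-model JAM posteriors.
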