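# cismr

Two-sample summary-data Mendelian randomization (MR) for a **single gene
region** with correlated genetic instruments.

## The problem

Cis-MR studies instrument a protein (or a downstream biomarker) with
variants from the encoding gene region to test whether the protein causally
affects a disease outcome — the statistical core of genetic drug-target
validation.  Unlike genome-wide MR, all candidate instruments come from one
locus and are correlated through linkage disequilibrium (LD), so the
analyst must either select a subset of variants or model the full
correlation structure, and weak-instrument bias looms whenever the region
explains little exposure variance.

Inputs are the standard summary-data triplet: marginal SNP-exposure
associations (beta, SE, p), marginal SNP-outcome associations from a
non-overlapping sample, and a reference LD correlation matrix `R`.

## Methods implemented

With marginal effects `bX`, `bY`, outcome standard errors `sY` and the
weighting matrix `Omega = diag(sY) R diag(sY)`:

* **Top-SNP Wald ratio** — `theta = bY_j / bX_j` at the smallest exposure
  p-value; `se = sY_j / |bX_j|`.
* **IVW**, standard and correlated-instruments:
  `theta = (bX' Omega^-1 bX)^-1 bX' Omega^-1 bY`,
  `se^2 = (bX' Omega^-1 bX)^-1`.
* **LD-pruning** (greedy, ascending p, correlation ceiling `rho`) and
  **conditional-and-joint (CoJo) selection** from summary statistics, each
  feeding the correlated IVW estimator.
* **PCA-IVW** — eigendecompose
  `Psi_ij = bX_i bX_j sY_i^-1 sY_j^-1 rho_ij`, keep components explaining
  99/99.9% of the trace, estimate in the projected coordinates.
* **JAM** — Bayesian variable selection from the transformed statistics
  `z_j = 2 f_j (1 - f_j) N1 bX_j` under a conjugate NIG g-prior and
  beta-binomial model prior, explored by reversible-jump MCMC
  (add/delete/swap), with a posterior-model-averaged IVW estimate.
* **Factor-based methods** — latent factors from the leading eigenvectors
  of `diag(s) R diag(s)`, `s_j = sqrt(2 f_j (1 - f_j))`; F-LIML point
  estimation by continuously-updated GMM on
  `g(theta) = (1/P) L' D (bY - theta bX)`, and weak-instrument-robust
  Anderson-Rubin, Lagrange-multiplier and conditional-likelihood-ratio
  tests with CLR confidence sets by test inversion.
* **Simulation benchmark** — synthetic LD blocks (Gaussian-copula
  haplotypes calibrated so dosage correlations hit their target), a
  confounded two-sample generative model, and a harness tabulating median
  estimates, type-I error, coverage, power and the oracle F statistic.

## Worked example

```python
import numpy as np
from cismr import (SelectionConfig, ivw_correlated, ld_prune, pca_ivw_estimate,
                   top_snp)
from cismr.simulate import get_simulator, harmonized_from_replicate, scenario

cfg = scenario("shbg-strong", theta=0.1)          # 3% exposure variance, F ~ 52
stats, ld, oracle_f = get_simulator(cfg).replicate(1)
data = harmonized_from_replicate(stats, ld)

sel = ld_prune(data, SelectionConfig(rho=0.3, tau=5e-8))
print("selected:", sel.selected)
print("oracle F: %.1f" % oracle_f)
for est in (top_snp(data), ivw_correlated(data, subset=sel.selected),
            pca_ivw_estimate(data, threshold=0.999)):
    print(f"{est.method:15s} theta={est.theta:+.3f} se={est.se:.3f} "
          f"95% CI ({est.ci_low:+.3f}, {est.ci_high:+.3f})")
```

prints

```
selected: ['snp_0056', 'snp_0036', 'snp_0016']
oracle F: 46.5
top_snp         theta=+0.100 se=0.021 95% CI (+0.059, +0.142)
ivw_correlated  theta=+0.101 se=0.017 95% CI (+0.068, +0.134)
pca_ivw         theta=+0.102 se=0.014 95% CI (+0.075, +0.130)
```

The true causal effect is 0.1: LD-pruning kept three approximately
independent genome-wide-significant variants, every interval covers the
truth, and the multi-variant estimators are visibly more precise than the
single top SNP.  The same pipeline runs from the shell on
summary-statistics files:

```sh
cismr fit --method ivw-corr --exposure exp.tsv --outcome out.tsv --ld ld.txt
cismr prune --rho 0.3 --tau 5e-8 --exposure exp.tsv --outcome out.tsv --ld ld.txt
cismr benchmark --scenario shbg-strong --theta 0 --reps 200 --methods top-snp,prune:0.3,pca:0.999
```

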