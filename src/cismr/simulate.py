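"""Synthetic cis-regions and the two-sample simulation benchmark.

The generator emulates a single gene region with blocks of correlated
biallelic variants.  Haplotypes are drawn from a latent Gaussian with a
block-diagonal AR(1)-decay correlation and thresholded at the allele
frequency quantile; a dosage is the sum of two independent haplotypes.  A
fixed genotype pool (default 400,000 individuals) is generated once per
scenario; every replicate then takes disjoint row subsets of the pool as the
exposure sample (size n1), the outcome sample (size n2) and, optionally, a
small reference panel (nref rows; by default the reference correlation is
computed from the whole pool).  This mirrors a two-sample design in which
both GWAS and the LD reference are drawn from one underlying population.

Phenotypes follow a confounded linear model: with causal effects b (zero
outside the causal set, |half-normal| + offset inside, rescaled so the
causal variants explain a fraction ``vg`` of exposure variance),

    X = G b + alpha_x U + eps_X
    Y = theta X + alpha_y U + eps_Y,   U, eps_X, eps_Y ~ N(0, sigma0^2).

Per-variant simple regressions of X on each dosage column (exposure sample)
and of Y on each column (outcome sample) give the marginal summary
statistics.  The oracle F statistic -- the overall F of regressing X on the
causal dosages, the standard weak-instrument diagnostic -- is recorded for
every replicate.

Two named regions are shipped: ``shbg`` (dense LD, decay 0.95; strong
scenario vg=3%, effects |N(0,0.2)|+0.1) and ``hmgcr`` (decay 0.85; strong
vg=2%, effects |N(0,0.03)|+0.03); the weak-instrument variants divide vg by
ten.  Sample sizes default to n1=10,000 and n2=180,000 with 1000 replicates.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import linalg, stats as sps

from .estimators import top_snp, ivw_correlated
from .factors import clr_test, f_liml, fit_factors
from .jam import JamConfig, rjmcmc_search
from .pca import pca_ivw_estimate
from .selection import SelectionConfig, cojo_select, ld_prune
from .summary_data import (HarmonizedDataset, LDReference, SummaryStats,
                           VariantRecord)

__all__ = [
    "RegionSpec",
    "ScenarioConfig",
    "BenchmarkTable",
    "shbg_region",
    "hmgcr_region",
    "scenario",
    "generate_genotypes",
    "draw_effects",
    "TwoSampleSimulator",
    "get_simulator",
    "simulate_two_sample",
    "oracle_f_stat",
    "run_benchmark",
    "aggregate_replicates",
    "scenario_from_yaml",
]


def _bivariate_orthant(t1: float, t2: float, r: float) -> float:
    """P(Z1 < t1, Z2 < t2) for standard bivariate normal with correlation r."""
    if r >= 1.0 - 1e-12:
        return float(sps.norm.cdf(min(t1, t2)))
    if r <= -1.0 + 1e-12:
        return float(max(sps.norm.cdf(t1) + sps.norm.cdf(t2) - 1.0, 0.0))
    return float(sps.multivariate_normal.cdf(
        [t1, t2], mean=[0.0, 0.0], cov=[[1.0, r], [r, 1.0]]))


def _latent_corr_for(maf1: float, maf2: float, rho: float,
                     _cache: dict = {}) -> float:
    """Latent Gaussian correlation giving allele correlation ``rho``.

    Thresholding a bivariate normal attenuates correlation, so the latent r
    solving the tetrachoric equation
    Phi2(t1, t2; r) = p1 p2 + rho sqrt(p1 q1 p2 q2) exceeds rho.
    """
    key = (round(maf1, 10), round(maf2, 10), round(rho, 10))
    if key in _cache:
        return _cache[key]
    if rho >= 1.0 - 1e-9 and abs(maf1 - maf2) < 1e-12:
        _cache[key] = 1.0
        return 1.0
    t1, t2 = sps.norm.ppf(maf1), sps.norm.ppf(maf2)
    target = maf1 * maf2 + rho * np.sqrt(
        maf1 * (1 - maf1) * maf2 * (1 - maf2))
    from scipy.optimize import brentq

    lo, hi = -0.9999, 0.999999
    f = lambda r: _bivariate_orthant(t1, t2, r) - target
    if f(hi) < 0:        # target unattainable (frequency mismatch); saturate
        out = hi
    elif f(lo) > 0:
        out = lo
    else:
        out = brentq(f, lo, hi, xtol=1e-10)
    _cache[key] = float(out)
    return float(out)


@dataclass
class RegionSpec:
    """Block-structured LD region with dosage correlation decay^|i-j| in blocks.

    ``target_corr`` is the intended *dosage* correlation matrix; the latent
    Gaussian correlation used by the haplotype generator is calibrated
    pairwise (tetrachoric inversion) so the thresholded alleles actually
    reach it.
    """

    p: int
    maf: np.ndarray
    block_sizes: tuple
    within_block_decay: tuple   # one decay per block
    name: str = "region"
    chrom: str = "NA"

    def __post_init__(self):
        self.maf = np.asarray(self.maf, dtype=float)
        self.block_sizes = tuple(int(b) for b in self.block_sizes)
        if np.isscalar(self.within_block_decay) or isinstance(
                self.within_block_decay, float):
            self.within_block_decay = (float(self.within_block_decay),) * len(
                self.block_sizes)
        self.within_block_decay = tuple(float(d) for d in self.within_block_decay)
        if sum(self.block_sizes) != self.p:
            raise ValueError("block sizes must sum to p")
        if len(self.maf) != self.p:
            raise ValueError("maf must have length p")
        if np.any(self.maf < 0.01) or np.any(self.maf > 0.5):
            raise ValueError("minor allele frequencies must lie in [0.01, 0.5]")
        for blk in self._block_corrs():
            # PSD required; exactly singular allowed (perfect correlates)
            if np.linalg.eigvalsh(blk)[0] < -1e-8:
                raise ValueError("target correlation block is not positive semi-definite")
        self._latent_blocks_cache = None

    def _block_corrs(self):
        return [d ** np.abs(np.subtract.outer(np.arange(b), np.arange(b)))
                for b, d in zip(self.block_sizes, self.within_block_decay)]

    def _latent_blocks(self):
        """Per-block latent Gaussian correlation matrices for the generator."""
        if self._latent_blocks_cache is not None:
            return self._latent_blocks_cache
        out, i = [], 0
        for blk in self._block_corrs():
            b = blk.shape[0]
            lat = np.eye(b)
            for u in range(b):
                for v in range(u + 1, b):
                    lat[u, v] = lat[v, u] = _latent_corr_for(
                        self.maf[i + u], self.maf[i + v], blk[u, v])
            # pairwise calibration can leave the block slightly indefinite
            vals = np.linalg.eigvalsh(lat)
            if vals[0] < -1e-8:
                w, vecs = np.linalg.eigh(lat)
                lat = (vecs * np.maximum(w, 0.0)) @ vecs.T
                d = np.sqrt(np.diag(lat))
                lat = lat / np.outer(d, d)
            out.append(lat)
            i += b
        self._latent_blocks_cache = out
        return out

    @property
    def target_corr(self) -> np.ndarray:
        out = np.zeros((self.p, self.p))
        i = 0
        for blk in self._block_corrs():
            b = blk.shape[0]
            out[i:i + b, i:i + b] = blk
            i += b
        return out

    def block_centers(self):
        centers, i = [], 0
        for b in self.block_sizes:
            centers.append(i + b // 2)
            i += b
        return centers

    def variant_records(self, eaf=None) -> list:
        freq = self.maf if eaf is None else np.asarray(eaf)
        return [
            VariantRecord(f"snp_{j + 1:04d}", self.chrom, 1000 * (j + 1),
                          "A", "G", float(freq[j]))
            for j in range(self.p)
        ]


def _block_maf(sizes, lo: float = 0.10, hi: float = 0.45,
               jitter: float = 0.004) -> np.ndarray:
    """Per-block allele frequencies: variants in tight LD share their MAF.

    High pairwise correlation between binary variants is only attainable
    when their frequencies are close (the ceiling is sqrt(p1 q2 / (p2 q1))),
    so each block gets a common base frequency with a small within-block
    gradient.
    """
    bases = np.linspace(lo, hi, len(sizes))
    parts = [base + np.linspace(-jitter, jitter, b)
             for base, b in zip(bases, sizes)]
    return np.concatenate(parts)


def shbg_region(p: int = 60, n_blocks: int = 6, decay: float = 0.95) -> RegionSpec:
    """Dense high-LD region (SHBG-like), 6 blocks of 10 by default."""
    sizes = [p // n_blocks] * n_blocks
    sizes[-1] += p - sum(sizes)
    return RegionSpec(p=p, maf=_block_maf(sizes), block_sizes=sizes,
                      within_block_decay=(decay,) * n_blocks,
                      name="shbg", chrom="17")


def hmgcr_region(p: int = 60, n_blocks: int = 6, decay: float = 0.85) -> RegionSpec:
    """Moderately correlated region (HMGCR-like)."""
    sizes = [p // n_blocks] * n_blocks
    sizes[-1] += p - sum(sizes)
    return RegionSpec(p=p, maf=_block_maf(sizes), block_sizes=sizes,
                      within_block_decay=(decay,) * n_blocks,
                      name="hmgcr", chrom="5")


@dataclass
class ScenarioConfig:
    region: RegionSpec
    causal_idx: tuple
    effect_scale: float      # half-normal scale s of |N(0, s)| + c
    effect_offset: float     # the offset c
    vg: float                # fraction of exposure variance explained by G b
    theta: float = 0.0
    alpha_x: float = 1.0
    alpha_y: float = 1.0
    sigma0_sq: float | None = None   # None -> (1 - vg) / (1 + alpha_x^2)
    n1: int = 10_000
    n2: int = 180_000
    nref: int | None = None          # None -> reference LD from the whole pool
    pool_n: int = 400_000
    reps: int = 1000
    seed: int = 0
    name: str = "scenario"

    def __post_init__(self):
        self.causal_idx = tuple(int(i) for i in self.causal_idx)
        if len(set(self.causal_idx)) != len(self.causal_idx):
            raise ValueError("causal_idx must be distinct")
        if any(not 0 <= i < self.region.p for i in self.causal_idx):
            raise ValueError("causal_idx out of range")
        if not 0 < self.vg < 1:
            raise ValueError("vg must lie in (0, 1)")
        if min(self.n1, self.n2) < 2 or (self.nref is not None and self.nref < 2):
            raise ValueError("sample sizes must be at least 2")
        need = self.n1 + self.n2 + (self.nref or 0)
        if self.pool_n < need:
            raise ValueError(f"pool_n={self.pool_n} smaller than n1+n2+nref={need}")

    @property
    def sigma0_sq_resolved(self) -> float:
        # chosen so Var(X) = vg + (alpha_x^2 + 1) sigma0^2 = 1
        if self.sigma0_sq is not None:
            return self.sigma0_sq
        return (1.0 - self.vg) / (1.0 + self.alpha_x ** 2)

    def cache_key(self):
        r = self.region
        return (r.p, r.maf.tobytes(), r.block_sizes, r.within_block_decay,
                self.causal_idx, self.effect_scale, self.effect_offset,
                self.vg, self.theta, self.alpha_x, self.alpha_y,
                self.sigma0_sq, self.n1, self.n2, self.nref,
                self.pool_n, self.seed)


_SCENARIOS = {
    ("shbg", "strong"): dict(vg=0.03, effect_scale=0.2, effect_offset=0.1),
    ("shbg", "weak"): dict(vg=0.003, effect_scale=0.2, effect_offset=0.1),
    ("hmgcr", "strong"): dict(vg=0.02, effect_scale=0.03, effect_offset=0.03),
    ("hmgcr", "weak"): dict(vg=0.002, effect_scale=0.03, effect_offset=0.03),
}


def scenario(name: str, theta: float = 0.0, n_causal: int = 6,
             **overrides) -> ScenarioConfig:
    """Named scenario, e.g. ``scenario('shbg-strong', theta=0.1)``.

    Names are ``{shbg,hmgcr}-{strong,weak}``; ``n_causal`` of 1, 3 or 6
    places causal variants at the first ``n_causal`` block centers.
    """
    try:
        region_name, strength = name.split("-")
        base = _SCENARIOS[(region_name, strength)]
    except (ValueError, KeyError):
        raise ValueError(
            f"unknown scenario {name!r}; expected one of "
            + ", ".join(f"{a}-{b}" for a, b in _SCENARIOS)) from None
    region = shbg_region() if region_name == "shbg" else hmgcr_region()
    causal = tuple(region.block_centers()[:n_causal])
    cfg = ScenarioConfig(region=region, causal_idx=causal, theta=theta,
                         name=name, **base)
    return replace(cfg, **overrides) if overrides else cfg


def generate_genotypes(region: RegionSpec, n: int, seed) -> np.ndarray:
    """Draw an n x P int8 dosage matrix (two thresholded latent haplotypes)."""
    rng = np.random.default_rng(seed)
    thresholds = sps.norm.ppf(region.maf).astype(np.float32)
    out = np.empty((n, region.p), dtype=np.int8)
    i = 0
    for blk in region._latent_blocks():
        b = blk.shape[0]
        # eigen factor rather than Cholesky: tolerates exactly singular
        # blocks (perfectly correlated variants duplicate exactly)
        w, vecs = np.linalg.eigh(blk)
        factor = (vecs * np.sqrt(np.maximum(w, 0.0))).astype(np.float32)
        dose = np.zeros((n, b), dtype=np.int8)
        for _hap in range(2):
            latent = rng.standard_normal((n, b), dtype=np.float32) @ factor.T
            dose += (latent < thresholds[i:i + b]).astype(np.int8)
        out[:, i:i + b] = dose
        i += b
    return out


def draw_effects(config: ScenarioConfig, rng, genotype_cov=None) -> np.ndarray:
    """Causal effects |N(0, s)| + c, rescaled so Var(G b) = vg (Var(X) = 1).

    ``genotype_cov`` is the covariance matrix of the causal dosages; when
    omitted it is approximated from the region's target correlation and
    Hardy-Weinberg variances 2 maf (1 - maf).
    """
    idx = list(config.causal_idx)
    raw = np.abs(rng.normal(0.0, config.effect_scale, len(idx))) + config.effect_offset
    if genotype_cov is None:
        d = np.sqrt(2 * config.region.maf * (1 - config.region.maf))
        genotype_cov = (config.region.target_corr * np.outer(d, d))[np.ix_(idx, idx)]
    var_gb = float(raw @ genotype_cov @ raw)
    if var_gb <= 0:
        raise ValueError("degenerate causal genotype covariance")
    b = np.zeros(config.region.p)
    b[idx] = raw * np.sqrt(config.vg / var_gb)
    return b


def _marginal_regression(G: np.ndarray, y: np.ndarray):
    """Simple-regression beta, se and p for every dosage column at once.

    Column sums of the 0/1/2 dosages are accumulated in exact integer
    arithmetic; only the G'y product runs in float32 BLAS.
    """
    n = len(y)
    ones = (G == 1).sum(axis=0, dtype=np.int64)
    twos = (G == 2).sum(axis=0, dtype=np.int64)
    colsum = ones + 2 * twos
    colsq = ones + 4 * twos
    m = colsum / n
    sgg = colsq - n * m ** 2
    if np.any(sgg <= 0):
        j = int(np.argmax(sgg <= 0))
        raise ValueError(f"constant dosage column at index {j}")
    yc = (y - y.mean()).astype(np.float32)
    gy = (G.astype(np.float32).T @ yc).astype(np.float64)
    beta = gy / sgg
    syy = float(yc.astype(np.float64) @ yc.astype(np.float64))
    rss = np.maximum(syy - beta ** 2 * sgg, 0.0)
    sigma2 = rss / (n - 2)
    se = np.sqrt(np.maximum(sigma2 / sgg, 1e-300))
    pval = np.maximum(2 * sps.t.sf(np.abs(beta / se), n - 2), 5e-324)
    return beta, se, pval


def oracle_f_stat(X: np.ndarray, G_causal: np.ndarray) -> float:
    """Overall F of the least-squares regression of X on the causal dosages."""
    G_causal = np.asarray(G_causal, dtype=float)
    n, k = G_causal.shape
    if n <= k + 1:
        raise ValueError("need n > k + 1 observations")
    design = sm.add_constant(G_causal)
    if np.linalg.matrix_rank(design) < k + 1:
        raise ValueError("collinear causal dosages; F statistic undefined")
    return float(sm.OLS(np.asarray(X, dtype=float), design).fit().fvalue)


_POOL_CACHE: dict = {}


def _pooled_genotypes(region: RegionSpec, pool_n: int, seed: int):
    """Build (or reuse) the fixed genotype pool for one region/seed.

    The pool does not depend on theta, effect sizes or sample sizes, so
    scenarios sharing a region reuse it.  Only one pool is kept at a time.
    """
    key = (region.p, region.maf.tobytes(), region.block_sizes,
           region.within_block_decay, pool_n, seed)
    hit = _POOL_CACHE.get(key)
    if hit is not None:
        return hit
    pool_ss, _ = np.random.SeedSequence(seed).spawn(2)
    chunks = []
    chunk_seeds = pool_ss.spawn(max(1, -(-pool_n // 100_000)))
    remaining = pool_n
    for cs in chunk_seeds:
        m = min(100_000, remaining)
        chunks.append(generate_genotypes(region, m, cs))
        remaining -= m
    pool = np.vstack(chunks)
    eaf = pool.mean(axis=0) / 2
    corr = np.corrcoef(pool, rowvar=False)
    if len(_POOL_CACHE) >= 4:
        _POOL_CACHE.clear()
    _POOL_CACHE[key] = (pool, eaf, corr)
    return pool, eaf, corr


class TwoSampleSimulator:
    """Fixed-pool two-sample simulator for one scenario.

    The pool and its reference correlation are built once; ``replicate``
    returns per-replicate summary statistics, an LD reference and the oracle
    F statistic.  Deterministic: the same (scenario seed, rep_seed) pair
    always reproduces the same replicate.
    """

    def __init__(self, config: ScenarioConfig):
        self.config = config
        self.pool, self.eaf, self.pool_corr = _pooled_genotypes(
            config.region, config.pool_n, config.seed)
        self.variants = config.region.variant_records(eaf=self.eaf)
        idx = list(config.causal_idx)
        self.causal_cov = np.cov(self.pool[:, idx].astype(float), rowvar=False)
        if self.causal_cov.ndim == 0:
            self.causal_cov = self.causal_cov.reshape(1, 1)

    def replicate(self, rep_seed: int):
        cfg = self.config
        rng = np.random.default_rng(
            np.random.SeedSequence((cfg.seed, int(rep_seed))))
        b = draw_effects(cfg, rng, genotype_cov=self.causal_cov)
        idx = list(cfg.causal_idx)
        b_causal = b[idx]
        perm = rng.permutation(cfg.pool_n)
        rows1 = perm[:cfg.n1]
        rows2 = perm[cfg.n1:cfg.n1 + cfg.n2]
        G1 = self.pool[rows1]
        G2 = self.pool[rows2]
        sigma0 = np.sqrt(cfg.sigma0_sq_resolved)

        G1c = G1[:, idx].astype(np.float64)
        U1 = rng.standard_normal(cfg.n1) * sigma0
        X1 = G1c @ b_causal + cfg.alpha_x * U1 + rng.standard_normal(cfg.n1) * sigma0
        G2c = G2[:, idx].astype(np.float64)
        U2 = rng.standard_normal(cfg.n2) * sigma0
        X2 = G2c @ b_causal + cfg.alpha_x * U2 + rng.standard_normal(cfg.n2) * sigma0
        Y2 = cfg.theta * X2 + cfg.alpha_y * U2 + rng.standard_normal(cfg.n2) * sigma0

        beta_x, se_x, p_x = _marginal_regression(G1, X1)
        beta_y, se_y, _ = _marginal_regression(G2, Y2)
        stats = SummaryStats(
            variants=self.variants,
            beta_x=beta_x, se_x=se_x, p_x=p_x,
            beta_y=beta_y, se_y=se_y,
            n_x=cfg.n1, n_y=cfg.n2,
        )
        if cfg.nref is not None:
            ref_rows = perm[cfg.n1 + cfg.n2:cfg.n1 + cfg.n2 + cfg.nref]
            corr = np.corrcoef(self.pool[ref_rows], rowvar=False)
            corr = np.clip((corr + corr.T) / 2, -1, 1)
            np.fill_diagonal(corr, 1.0)
            ld = LDReference(self.variants, corr, n_ref=cfg.nref)
        else:
            ld = LDReference(self.variants, self.pool_corr, n_ref=cfg.pool_n)
        oracle_f = oracle_f_stat(X1, G1[:, idx])
        return stats, ld, oracle_f

    def replicate_exposure_only(self, rep_seed: int):
        """Fast path for instrument-strength studies: (X1, causal G1, F)."""
        cfg = self.config
        rng = np.random.default_rng(
            np.random.SeedSequence((cfg.seed, int(rep_seed))))
        b = draw_effects(cfg, rng, genotype_cov=self.causal_cov)
        idx = list(cfg.causal_idx)
        rows1 = rng.permutation(cfg.pool_n)[:cfg.n1]
        G1c = self.pool[rows1][:, idx]
        sigma0 = np.sqrt(cfg.sigma0_sq_resolved)
        U1 = rng.standard_normal(cfg.n1) * sigma0
        X1 = (G1c.astype(np.float64) @ b[idx]
              + cfg.alpha_x * U1 + rng.standard_normal(cfg.n1) * sigma0)
        return X1, G1c, oracle_f_stat(X1, G1c)


_SIMULATOR_CACHE: dict = {}


def get_simulator(config: ScenarioConfig) -> TwoSampleSimulator:
    key = config.cache_key()
    sim = _SIMULATOR_CACHE.get(key)
    if sim is None:
        sim = TwoSampleSimulator(config)  # pool itself is cached and shared
        _SIMULATOR_CACHE[key] = sim
    return sim


def simulate_two_sample(config: ScenarioConfig, rep_seed: int):
    """One replicate of two-sample summary data: (SummaryStats, LDReference, F)."""
    return get_simulator(config).replicate(rep_seed)


def harmonized_from_replicate(stats: SummaryStats, ld: LDReference) -> HarmonizedDataset:
    omega = ld.corr * np.outer(stats.se_y, stats.se_y)
    return HarmonizedDataset(stats=stats, ld=ld, omega=omega)


# ---------------------------------------------------------------------------
# benchmark harness


@dataclass
class BenchmarkTable:
    table: pd.DataFrame
    theta: float
    reps_used: int

    def to_tsv(self, path):
        self.table.to_csv(path, sep="\t", index=False, float_format="%.4g")


def _parse_method(spec: str, tau, jam_iterations, clr_ndraws):
    """Map a 'name[:tuning]' string to (label, tuning, runner).

    A runner takes (HarmonizedDataset, true theta, rep index) and returns a
    dict with theta, se, reject, cover (theta/se may be NaN for pure tests).
    """
    name, _, arg = spec.partition(":")

    if name == "top-snp":
        def run(data, theta0, rep):
            est = top_snp(data)
            return dict(theta=est.theta, se=est.se,
                        reject=est.rejects_null, cover=est.covers(theta0))
        return "top_snp", "", run

    if name == "prune":
        rho = float(arg) if arg else 0.3
        cfg = SelectionConfig(rho=rho, tau=tau)

        def run(data, theta0, rep):
            sel = ld_prune(data, cfg)
            if not sel.selected:
                raise ValueError("empty selection")
            est = ivw_correlated(data, subset=sel.selected)
            return dict(theta=est.theta, se=est.se,
                        reject=est.rejects_null, cover=est.covers(theta0))
        return "pruning", f"rho={rho}", run

    if name == "cojo":
        rho = float(arg) if arg else 0.9
        cfg = SelectionConfig(rho=rho, tau=tau)

        def run(data, theta0, rep):
            sel = cojo_select(data, cfg)
            if not sel.selected:
                raise ValueError("empty selection")
            est = ivw_correlated(data, subset=sel.selected)
            return dict(theta=est.theta, se=est.se,
                        reject=est.rejects_null, cover=est.covers(theta0))
        return "cojo", f"rho={rho}", run

    if name == "pca":
        thr = float(arg) if arg else 0.999

        def run(data, theta0, rep):
            est = pca_ivw_estimate(data, threshold=thr)
            return dict(theta=est.theta, se=est.se,
                        reject=est.rejects_null, cover=est.covers(theta0))
        return "pca", f"k={thr}", run

    if name == "jam":
        rho = float(arg) if arg else 0.9

        def run(data, theta0, rep):
            cfg = JamConfig(preprune_rho=rho, iterations=jam_iterations,
                            seed=rep)
            post = rjmcmc_search(data, cfg)
            est = post.averaged
            return dict(theta=est.theta, se=est.se,
                        reject=est.rejects_null, cover=est.covers(theta0))
        return "jam", f"rho={rho}", run

    if name == "fliml":
        def run(data, theta0, rep):
            model = fit_factors(data, k="auto")
            est = f_liml(data, model)
            return dict(theta=est.theta, se=est.se,
                        reject=est.rejects_null, cover=est.covers(theta0))
        return "f_liml", "", run

    if name == "clr":
        def run(data, theta0, rep):
            model = fit_factors(data, k="auto")
            null = clr_test(data, model, 0.0, seed=rep, ndraws=clr_ndraws)
            at_truth = (null if theta0 == 0.0 else
                        clr_test(data, model, theta0, seed=rep, ndraws=clr_ndraws))
            return dict(theta=np.nan, se=np.nan,
                        reject=null.p_value < 0.05,
                        cover=at_truth.p_value >= 0.05)
        return "clr", "", run

    raise ValueError(f"unknown method spec {spec!r}")


def aggregate_replicates(records, theta: float, mean_oracle_f=np.nan,
                         method="", tuning="") -> dict:
    """Collapse per-replicate results into one benchmark row.

    ``records`` is a list of dicts with theta, se, reject, cover; failed
    replicates are represented by None entries and excluded with a count.
    """
    ok = [r for r in records if r is not None]
    n_ok, n_fail = len(ok), len(records) - len(ok)
    if not ok:
        return dict(method=method, tuning=tuning, median_theta=np.nan,
                    median_se=np.nan, type1=np.nan, power=np.nan,
                    coverage=np.nan, mean_oracle_F=mean_oracle_f,
                    reps_used=0, n_failed=n_fail, valid=False)
    thetas = np.array([r["theta"] for r in ok], dtype=float)
    ses = np.array([r["se"] for r in ok], dtype=float)
    reject = np.mean([bool(r["reject"]) for r in ok])
    cover = np.mean([bool(r["cover"]) for r in ok])
    med = lambda a: float(np.median(a[~np.isnan(a)])) if np.any(~np.isnan(a)) else np.nan
    return dict(
        method=method, tuning=tuning,
        median_theta=med(thetas),
        median_se=med(ses),
        type1=float(reject) if theta == 0 else np.nan,
        power=float(reject) if theta != 0 else np.nan,
        coverage=float(cover),
        mean_oracle_F=mean_oracle_f,
        reps_used=n_ok, n_failed=n_fail, valid=True,
    )


def run_benchmark(config: ScenarioConfig, methods, tau: float = 5e-8,
                  jam_iterations: int = 5000, clr_ndraws: int = 2000,
                  reps: int | None = None) -> BenchmarkTable:
    """Run every method on shared replicates and tabulate the metrics.

    Per replicate all methods see the same summary data, so rows are
    directly comparable.  A method failing on a replicate (e.g. empty
    selection) is excluded from its row with a failure count; a method
    failing everywhere yields an invalid row rather than a crash.
    """
    parsed = [_parse_method(m, tau, jam_iterations, clr_ndraws) for m in methods]
    sim = get_simulator(config)
    n_reps = config.reps if reps is None else reps
    per_method = {label + tuning: [] for label, tuning, _ in parsed}
    fvals = []
    for rep in range(n_reps):
        stats, ld, fstat = sim.replicate(rep)
        fvals.append(fstat)
        data = harmonized_from_replicate(stats, ld)
        for label, tuning, run in parsed:
            try:
                per_method[label + tuning].append(run(data, config.theta, rep))
            except (ValueError, np.linalg.LinAlgError, linalg.LinAlgError):
                per_method[label + tuning].append(None)
    mean_f = float(np.mean(fvals))
    rows = [
        aggregate_replicates(per_method[label + tuning], config.theta,
                             mean_oracle_f=mean_f, method=label, tuning=tuning)
        for label, tuning, _ in parsed
    ]
    return BenchmarkTable(table=pd.DataFrame(rows), theta=config.theta,
                          reps_used=n_reps)


def scenario_from_yaml(path) -> ScenarioConfig:
    """Load a ScenarioConfig from a YAML file.

    Either ``name: shbg-strong`` plus overrides, or a full specification
    with a ``region`` block (p, maf or maf_range, block_sizes, decay).
    """
    import yaml

    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if "name" in doc:
        name = doc.pop("name")
        theta = doc.pop("theta", 0.0)
        n_causal = doc.pop("n_causal", 6)
        return scenario(name, theta=theta, n_causal=n_causal, **doc)
    rdoc = doc.pop("region")
    if "maf" in rdoc:
        maf = np.asarray(rdoc["maf"], dtype=float)
    else:
        lo, hi = rdoc.get("maf_range", (0.05, 0.5))
        maf = np.linspace(lo, hi, rdoc["p"])
    region = RegionSpec(p=rdoc["p"], maf=maf,
                        block_sizes=rdoc["block_sizes"],
                        within_block_decay=rdoc.get("decay", 0.9),
                        name=rdoc.get("name", "region"),
                        chrom=str(rdoc.get("chrom", "NA")))
    doc["region"] = region
    doc["causal_idx"] = tuple(doc["causal_idx"])
    return ScenarioConfig(**doc)
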