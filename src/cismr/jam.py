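"""JAM: joint analysis of marginal statistics with reversible-jump model search.

JAM recasts fine-mapping from marginal GWAS statistics as Bayesian variable
selection in the linear model X ~ N(G b, sigma^2).  The sufficient statistics
are reconstructed from summary data under Hardy-Weinberg equilibrium:

    z_j    = 2 f_j (1 - f_j) N1 beta_Xj          (approximates G' X)
    (G'G)  = N1 * D^1/2 R D^1/2,  D = diag(2 f (1 - f))

with R from the reference panel.  Writing G'G = U'U (upper-triangular
Cholesky factor U) and whitening z~ = U^-T z gives P pseudo-observations
z~ ~ N(U b, sigma^2 I).  Under a conjugate normal-inverse-gamma g-prior for
(b, sigma^2) and a beta-binomial prior on the model indicator gamma, the
marginal likelihood of any variant subset is available in closed form, and a
reversible-jump Metropolis-Hastings chain with add/delete/swap proposals
explores the model space.  Each visited non-empty model yields a
correlated-IVW causal estimate; the model-averaged estimate combines them by
posterior visit frequency with a law-of-total-variance standard error.

Because near-collinear variants make G'G ill-conditioned, the search is run
on a pre-pruned variant set (default correlation threshold 0.9, no
significance threshold).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg
from scipy.special import betaln

from .estimators import MREstimate, ivw_correlated
from .selection import SelectionConfig, ld_prune
from .summary_data import HarmonizedDataset, SummaryStats

__all__ = [
    "JamConfig",
    "JamSufficientStats",
    "JamPosterior",
    "compute_z",
    "build_sufficient_stats",
    "log_evidence",
    "rjmcmc_search",
    "model_averaged_estimate",
    "logodds_to_linear",
]


@dataclass(frozen=True)
class JamConfig:
    """Priors and chain settings for the stochastic search.

    ``g=None`` means the unit-information scale g = N1.  The beta-binomial
    defaults (a=1, b=P) put the prior mean model size near one variant, the
    usual sparsity prior in fine-mapping; ``bb_b=None`` resolves to P at run
    time.
    """

    preprune_rho: float = 0.9
    g: float | None = None
    bb_a: float = 1.0
    bb_b: float | None = None
    iterations: int = 1_000_000
    burn_in: int | None = None   # None -> iterations // 10
    seed: int = 0

    def __post_init__(self):
        if self.g is not None and self.g <= 0:
            raise ValueError("g must be positive")
        if self.bb_a <= 0 or (self.bb_b is not None and self.bb_b <= 0):
            raise ValueError("beta-binomial hyperparameters must be positive")
        burn = self.iterations // 10 if self.burn_in is None else self.burn_in
        if not 0 <= burn < self.iterations:
            raise ValueError("require iterations > burn_in >= 0")

    def resolved_burn_in(self) -> int:
        return self.iterations // 10 if self.burn_in is None else self.burn_in


# weakly informative inverse-gamma prior on the residual variance
_NIG_SHAPE = 0.01
_NIG_RATE = 0.01


@dataclass
class JamSufficientStats:
    z: np.ndarray          # length P
    xtx: np.ndarray        # P x P scaled cross-product, N1 D^1/2 R D^1/2
    chol: np.ndarray       # upper-triangular U with U'U = xtx
    n1: float
    yty: float             # trait sum of squares, N1 * Var(X)
    ztilde_sq: float       # z' (xtx)^-1 z, the fully-saturated fit

    @property
    def n_variants(self) -> int:
        return len(self.z)


def compute_z(stats: SummaryStats) -> np.ndarray:
    """z_j = 2 f_j (1 - f_j) N1 beta_Xj."""
    if stats.n_x is None:
        raise ValueError("JAM requires the exposure sample size n_x")
    if stats.beta_x is None:
        raise ValueError("exposure effects are required")
    eaf = stats.eaf
    if np.any(eaf <= 0) or np.any(eaf >= 1):
        raise ValueError("effect allele frequencies must lie in (0, 1)")
    return 2 * eaf * (1 - eaf) * stats.n_x * stats.beta_x


def build_sufficient_stats(stats: SummaryStats, corr: np.ndarray,
                           trait_var: float = 1.0) -> JamSufficientStats:
    """Assemble (z, G'G, Cholesky factor) from summary data and reference LD.

    ``trait_var`` is the phenotypic variance of the exposure (1 for a
    standardized trait); it fixes the trait sum of squares y'y = N1 *
    trait_var that the marginal likelihood needs.
    """
    z = compute_z(stats)
    eaf = stats.eaf
    s = np.sqrt(2 * eaf * (1 - eaf))
    xtx = stats.n_x * corr * np.outer(s, s)
    xtx = (xtx + xtx.T) / 2
    try:
        chol = linalg.cholesky(xtx, lower=False)
    except linalg.LinAlgError as exc:
        raise ValueError(
            "G'G is not positive definite; pre-prune the variant set") from exc
    w = linalg.solve_triangular(chol.T, z, lower=True)
    return JamSufficientStats(z=z, xtx=xtx, chol=chol, n1=float(stats.n_x),
                              yty=float(stats.n_x) * trait_var,
                              ztilde_sq=float(w @ w))


def log_evidence(gamma, suff: JamSufficientStats, config: JamConfig) -> float:
    """Log marginal likelihood of model ``gamma`` plus its log prior mass.

    Conjugate normal-inverse-gamma g-prior evidence of the linear model
    restricted to ``gamma``: with n = N1 observations, residual sum of
    squares s = y'y - g/(1+g) z_g' (G'G)_gg^-1 z_g,

        log m = -(n/2) log 2pi - (|g|/2) log(1+g) + a log r
                + lgamma(a + n/2) - lgamma(a) - (a + n/2) log(r + s/2).

    ``gamma`` is an iterable of variant indices; the empty set (null model)
    is allowed.  Returns ``-inf`` when the model's G'G submatrix is
    ill-conditioned (condition number above 1e8), marking it unvisitable.
    """
    idx = sorted(gamma)
    p = suff.n_variants
    k = len(idx)
    g = suff.n1 if config.g is None else config.g
    bb_b = float(p) if config.bb_b is None else config.bb_b

    if k == 0:
        fit = 0.0
    else:
        sub = suff.xtx[np.ix_(idx, idx)]
        eig = np.linalg.eigvalsh(sub)
        if eig[0] <= 0 or eig[-1] / eig[0] > 1e8:
            return -np.inf
        c = linalg.cho_factor(sub, lower=True)
        fit = float(suff.z[idx] @ linalg.cho_solve(c, suff.z[idx]))
    s = max(suff.yty - g / (1 + g) * fit, 1e-8 * suff.yty)

    n = suff.n1
    a, r = _NIG_SHAPE, _NIG_RATE
    log_ml = (
        -0.5 * n * math.log(2 * math.pi)
        - 0.5 * k * math.log(1 + g)
        + a * math.log(r)
        + math.lgamma(a + 0.5 * n) - math.lgamma(a)
        - (a + 0.5 * n) * math.log(r + 0.5 * s)
    )
    log_prior = betaln(config.bb_a + k, bb_b + p - k) - betaln(config.bb_a, bb_b)
    return log_ml + float(log_prior)


@dataclass
class JamPosterior:
    model_probs: dict                    # frozenset(snp_ids) -> visit frequency
    inclusion_probs: dict                # snp_id -> marginal inclusion probability
    model_estimates: dict = field(default_factory=dict)  # model -> MREstimate
    averaged: MREstimate | None = None
    accept_rate: float = 0.0
    empty_model_prob: float = 0.0
    pruned_ids: list = field(default_factory=list)

    def top_models(self, n: int = 10):
        return sorted(self.model_probs.items(), key=lambda kv: -kv[1])[:n]


def _propose(state: frozenset, all_idx: tuple, rng):
    """Add/delete/swap proposal; returns (new_state, log q_back/q_forward)."""
    k, p = len(state), len(all_idx)
    move = rng.integers(3)
    present = sorted(state)
    absent = [j for j in all_idx if j not in state]
    if move == 0:  # add
        if not absent:
            return None
        j = absent[rng.integers(len(absent))]
        # forward: (1/3)/(p-k); backward delete: (1/3)/(k+1)
        return state | {j}, math.log((p - k) / (k + 1))
    if move == 1:  # delete
        if not present:
            return None
        j = present[rng.integers(len(present))]
        return state - {j}, math.log(k / (p - k + 1))
    if not present or not absent:  # swap impossible at the boundary
        return None
    i = present[rng.integers(len(present))]
    j = absent[rng.integers(len(absent))]
    return (state - {i}) | {j}, 0.0


def rjmcmc_search(data: HarmonizedDataset, config: JamConfig) -> JamPosterior:
    """Reversible-jump stochastic search over variant subsets.

    The input is pre-pruned internally at ``config.preprune_rho`` (no
    significance threshold).  The chain starts from the single variant with
    the smallest exposure p-value and proposes add/delete/swap moves with
    equal probability; an infeasible move counts as a rejection.  Post
    burn-in visit frequencies define the model posterior, and the
    model-averaged causal estimate is attached.
    """
    prune = ld_prune(data, SelectionConfig(rho=config.preprune_rho, tau=None))
    if not prune.selected:
        raise ValueError("pre-pruning removed every variant")
    sub = data.subset_by_id(prune.selected)
    suff = build_sufficient_stats(sub.stats, sub.ld.corr)
    p = suff.n_variants
    all_idx = tuple(range(p))
    rng = np.random.default_rng(config.seed)

    cache: dict = {}

    def ev(state: frozenset) -> float:
        val = cache.get(state)
        if val is None:
            val = log_evidence(state, suff, config)
            cache[state] = val
        return val

    # start at the smallest exposure p-value within the pruned set
    start = frozenset({int(np.argmin(sub.stats.p_x))})
    state = start
    cur = ev(state)
    if cur == -np.inf:
        state = frozenset()
        cur = ev(state)

    burn = config.resolved_burn_in()
    counts: dict = {}
    accepted = 0
    for it in range(config.iterations):
        prop = _propose(state, all_idx, rng)
        if prop is not None:
            new_state, log_q = prop
            new_ev = ev(new_state)
            if new_ev > -np.inf and math.log(rng.random()) < new_ev - cur + log_q:
                state, cur = new_state, new_ev
                accepted += 1
        if it >= burn:
            counts[state] = counts.get(state, 0) + 1

    total = sum(counts.values())
    ids = sub.stats.snp_ids
    model_probs = {
        frozenset(ids[j] for j in s): c / total for s, c in counts.items()
    }
    inclusion = {sid: 0.0 for sid in ids}
    for model, w in model_probs.items():
        for sid in model:
            inclusion[sid] += w

    posterior = JamPosterior(
        model_probs=model_probs,
        inclusion_probs=inclusion,
        accept_rate=accepted / config.iterations,
        empty_model_prob=model_probs.get(frozenset(), 0.0),
        pruned_ids=list(prune.selected),
    )
    posterior.averaged = model_averaged_estimate(posterior, data)
    return posterior


def model_averaged_estimate(posterior: JamPosterior,
                            data: HarmonizedDataset) -> MREstimate:
    """Posterior-weighted IVW estimate across visited non-empty models.

    Each model contributes its correlated-IVW estimate; weights are the
    posterior visit frequencies renormalized over non-empty models.  The
    averaged variance uses the law of total variance,
    se^2 = sum_m w_m (se_m^2 + theta_m^2) - theta^2.
    """
    items = [(m, w) for m, w in posterior.model_probs.items() if len(m) > 0]
    if not items:
        raise ValueError("no instruments selected: only the empty model was visited")
    wsum = sum(w for _, w in items)
    thetas, ses, weights = [], [], []
    for model, w in items:
        est = posterior.model_estimates.get(model)
        if est is None:
            est = ivw_correlated(data, subset=sorted(model))
            posterior.model_estimates[model] = est
        thetas.append(est.theta)
        ses.append(est.se)
        weights.append(w / wsum)
    thetas, ses, weights = map(np.array, (thetas, ses, weights))
    theta = float(weights @ thetas)
    var = float(weights @ (ses ** 2 + thetas ** 2) - theta ** 2)
    var = max(var, 1e-300)
    est = MREstimate.from_theta_se(
        theta, math.sqrt(var), "jam", len(posterior.inclusion_probs),
        empty_model_prob=posterior.empty_model_prob,
        mean_model_size=float(sum(w * len(m) for m, w in posterior.model_probs.items())),
    )
    return est


def logodds_to_linear(beta: float, case_fraction: float,
                      eaf: float | None = None, n: float | None = None) -> float:
    """First-order map of a log-odds ratio to the linear-probability effect.

    A logistic effect beta on a 0/1 outcome with case fraction phi would be
    estimated by linear regression as approximately beta * phi * (1 - phi).
    ``eaf`` and ``n`` are accepted for interface symmetry with the other
    summary-statistic transforms but do not enter the first-order mapping.
    """
    if not 0 < case_fraction < 1:
        raise ValueError("case_fraction must lie in (0, 1)")
    return beta * case_fraction * (1 - case_fraction)
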