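"""Factor-based MR: latent-factor instruments, F-LIML, and weak-IV-robust tests.

The genotypes are modelled as G = Lambda f + eps with k < P latent factors.
The loadings are estimated by the leading eigenvectors of the rescaled LD
covariance S = diag(s) R diag(s), s_j = sqrt(2 f_j (1 - f_j)).  The factors
serve as instruments through the moment function

    g(theta) = (1/P) Lambda' D_Y beta_Y - theta (1/P) Lambda' D_X beta_X,

where D_X, D_Y are the diagonal matrices of genotype variances from the
reference panel (a single panel serves both roles here, so D_X = D_Y).
Writing g(theta) = a - theta c, the sampling covariance of the moment under
two independent samples is

    V(theta) = Va + theta^2 Vc,
    Va = (1/P^2) Lambda' D Omega_Y D Lambda,   Omega_Y = diag(se_y) R diag(se_y)
    Vc = (1/P^2) Lambda' D Omega_X D Lambda,   Omega_X = diag(se_x) R diag(se_x).

F-LIML minimizes the continuously-updating criterion Q(theta) =
g(theta)' V(theta)^-1 g(theta).  The same building blocks give the
Anderson-Rubin (chi^2_k), Kleibergen Lagrange-multiplier (chi^2_1) and
Moreira conditional-likelihood-ratio tests of a hypothesized theta, all of
which remain valid with weak instruments; the CLR confidence set is obtained
by test inversion over a theta grid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import linalg, optimize
from scipy import stats as sps

from .estimators import MREstimate
from .summary_data import HarmonizedDataset

__all__ = [
    "FactorModel",
    "WeakIVTest",
    "fit_factors",
    "f_liml",
    "ar_test",
    "lm_test",
    "clr_test",
    "clr_confidence_set",
]


@dataclass
class FactorModel:
    loadings: np.ndarray     # P x k, orthonormal columns
    k: int
    dx: np.ndarray           # genotype variances used on the exposure side
    dy: np.ndarray           # and the outcome side (same reference panel)
    eigenvalues: np.ndarray  # full spectrum of the rescaled covariance


def fit_factors(data: HarmonizedDataset, k="auto",
                trace_threshold: float = 0.99) -> FactorModel:
    """Eigendecompose diag(s) R diag(s) and retain the first k eigenvectors.

    ``k='auto'`` keeps the smallest k whose eigenvalues reach
    ``trace_threshold`` of the trace.
    """
    eaf = data.stats.eaf
    d = 2 * eaf * (1 - eaf)
    s = np.sqrt(d)
    cov = data.ld.corr * np.outer(s, s)
    cov = (cov + cov.T) / 2
    vals, vecs = np.linalg.eigh(cov)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    vals[vals < 0] = 0.0
    p = len(vals)
    if k == "auto":
        frac = np.cumsum(vals) / vals.sum()
        k_use = int(np.searchsorted(frac, trace_threshold - 1e-12) + 1)
        k_use = max(1, min(k_use, p))
    else:
        k_use = int(k)
        if not 1 <= k_use <= p:
            raise ValueError(f"k must lie in [1, {p}], got {k_use}")
    return FactorModel(loadings=vecs[:, :k_use], k=k_use, dx=d, dy=d.copy(),
                       eigenvalues=vals)


@dataclass
class WeakIVTest:
    statistic: float
    p_value: float
    test: str            # AR | LM | CLR
    theta0: float
    k: int


class _MomentSystem:
    """Precomputed pieces of g(theta) = a - theta c and V(theta) = Va + theta^2 Vc."""

    def __init__(self, data: HarmonizedDataset, model: FactorModel):
        stats_ = data.stats
        if stats_.beta_x is None or stats_.beta_y is None:
            raise ValueError("both exposure and outcome statistics are required")
        lam = model.loadings
        p = data.n_variants
        self.k = model.k
        self.a = lam.T @ (model.dy * stats_.beta_y) / p
        self.c = lam.T @ (model.dx * stats_.beta_x) / p
        corr = data.ld.corr
        ey = model.dy * stats_.se_y
        ex = model.dx * stats_.se_x
        self.va = (lam.T * ey) @ corr @ (lam.T * ey).T / p ** 2
        self.vc = (lam.T * ex) @ corr @ (lam.T * ex).T / p ** 2
        self.va = (self.va + self.va.T) / 2
        self.vc = (self.vc + self.vc.T) / 2

    def g(self, theta):
        return self.a - theta * self.c

    def v(self, theta):
        return self.va + theta ** 2 * self.vc

    def _solve(self, theta, rhs):
        v = self.v(theta)
        try:
            cf = linalg.cho_factor(v, lower=True)
        except linalg.LinAlgError as exc:
            raise ValueError("moment covariance V(theta) is singular") from exc
        return linalg.cho_solve(cf, rhs)

    def quadratic(self, theta):
        g = self.g(theta)
        return float(g @ self._solve(theta, g))

    def pieces(self, theta):
        """AR statistic, LM statistic and the identification statistic r."""
        g = self.g(theta)
        vinv_g = self._solve(theta, g)
        ar = float(g @ vinv_g)
        # orthogonalized Jacobian estimate: c is correlated with g through
        # Cov(g, c) = -theta Vc
        qt = self.c + theta * (self.vc @ vinv_g)
        vinv_q = self._solve(theta, qt)
        denom = float(qt @ vinv_q)
        lm = float((g @ vinv_q) ** 2 / denom) if denom > 0 else 0.0
        var_q = self.vc - theta ** 2 * (self.vc @ self._solve(theta, self.vc))
        var_q = (var_q + var_q.T) / 2
        try:
            cf = linalg.cho_factor(var_q, lower=True)
            r = float(qt @ linalg.cho_solve(cf, qt))
        except linalg.LinAlgError:
            r = float("inf")
        return ar, lm, r


def _clr_stat(ar, lm, r):
    if not np.isfinite(r):
        return lm
    disc = max((ar + r) ** 2 - 4 * r * (ar - lm), 0.0)
    return 0.5 * (ar - r + math.sqrt(disc))


def ar_test(data: HarmonizedDataset, model: FactorModel, theta0: float) -> WeakIVTest:
    """Anderson-Rubin test of theta = theta0; chi^2 with k degrees of freedom."""
    ms = _MomentSystem(data, model)
    stat = ms.quadratic(theta0)
    p = max(float(sps.chi2.sf(stat, ms.k)), 5e-324)
    return WeakIVTest(stat, p, "AR", theta0, ms.k)


def lm_test(data: HarmonizedDataset, model: FactorModel, theta0: float) -> WeakIVTest:
    """Kleibergen score test of theta = theta0; chi^2 with 1 degree of freedom."""
    ms = _MomentSystem(data, model)
    _, lm, _ = ms.pieces(theta0)
    p = max(float(sps.chi2.sf(lm, 1)), 5e-324)
    return WeakIVTest(lm, p, "LM", theta0, ms.k)


def _clr_pvalue(clr, r, k, rng, ndraws):
    """Monte Carlo conditional p-value given the identification statistic r."""
    if k == 1 or not np.isfinite(r):
        # 1-df degeneracy: CLR coincides with AR
        return max(float(sps.chi2.sf(clr, 1)), 5e-324)
    q1 = rng.chisquare(1, ndraws)
    qk = rng.chisquare(k - 1, ndraws)
    ar_sim = q1 + qk
    disc = np.maximum((ar_sim + r) ** 2 - 4 * r * qk, 0.0)
    clr_sim = 0.5 * (ar_sim - r + np.sqrt(disc))
    return (1.0 + np.sum(clr_sim >= clr)) / (ndraws + 1.0)


def clr_test(data: HarmonizedDataset, model: FactorModel, theta0: float,
             seed: int = 0, ndraws: int = 10_000) -> WeakIVTest:
    """Moreira conditional likelihood ratio test of theta = theta0.

    The conditional null distribution given the identification statistic is
    simulated with ``ndraws`` seeded Monte Carlo draws; at k = 1 the test
    reduces exactly to Anderson-Rubin.
    """
    ms = _MomentSystem(data, model)
    ar, lm, r = ms.pieces(theta0)
    clr = _clr_stat(ar, lm, r)
    rng = np.random.default_rng(seed)
    p = _clr_pvalue(clr, r, ms.k, rng, ndraws)
    return WeakIVTest(clr, p, "CLR", theta0, ms.k)


def clr_confidence_set(data: HarmonizedDataset, model: FactorModel,
                       grid=None, level: float = 0.95, seed: int = 0,
                       ndraws: int = 10_000):
    """Invert the CLR test over a theta grid.

    Returns ``(intervals, flags)``: a list of (low, high) grid-resolution
    interval endpoints where the CLR p-value stays above 1 - level, and a
    dict with ``unbounded``/``disjoint`` flags.  The same Monte Carlo draws
    are reused across the grid so the p-value curve is smooth in theta.
    """
    if grid is None:
        grid = np.linspace(-2.0, 2.0, 801)
    grid = np.asarray(grid, dtype=float)
    ms = _MomentSystem(data, model)
    rng = np.random.default_rng(seed)
    q1 = rng.chisquare(1, ndraws)
    qk = rng.chisquare(ms.k - 1, ndraws) if ms.k > 1 else np.zeros(ndraws)
    alpha = 1 - level
    accept = np.zeros(len(grid), dtype=bool)
    for i, t0 in enumerate(grid):
        ar, lm, r = ms.pieces(t0)
        clr = _clr_stat(ar, lm, r)
        if ms.k == 1 or not np.isfinite(r):
            p = float(sps.chi2.sf(clr, 1))
        else:
            ar_sim = q1 + qk
            disc = np.maximum((ar_sim + r) ** 2 - 4 * r * qk, 0.0)
            clr_sim = 0.5 * (ar_sim - r + np.sqrt(disc))
            p = (1.0 + np.sum(clr_sim >= clr)) / (ndraws + 1.0)
        accept[i] = p >= alpha
    intervals = []
    i = 0
    while i < len(grid):
        if accept[i]:
            j = i
            while j + 1 < len(grid) and accept[j + 1]:
                j += 1
            intervals.append((float(grid[i]), float(grid[j])))
            i = j + 1
        else:
            i += 1
    flags = {
        "unbounded": bool(accept[0] or accept[-1]),
        "disjoint": len(intervals) > 1,
        "empty": len(intervals) == 0,
    }
    return intervals, flags


def f_liml(data: HarmonizedDataset, model: FactorModel,
           bracket=(-5.0, 5.0)) -> MREstimate:
    """Factor LIML: minimize the continuously-updating criterion Q(theta).

    Q is scanned on a coarse grid over ``bracket`` and refined with bounded
    scalar minimization; the standard error comes from the curvature of Q at
    the minimum, se = sqrt(2 / Q''), with the analytic GMM expression
    (c' V^-1 c)^-1 as a fallback when the numerical curvature degenerates.
    """
    ms = _MomentSystem(data, model)
    scale = float(np.sqrt(ms.c @ ms.c))
    ref = float(np.sqrt(ms.a @ ms.a)) + float(np.sqrt(np.trace(ms.vc)))
    if scale <= 1e-12 * max(ref, 1e-300):
        raise ValueError("unidentified: all factor-projected exposure effects are ~0")

    lo, hi = bracket
    grid = np.linspace(lo, hi, 201)
    qvals = [ms.quadratic(t) for t in grid]
    j = int(np.argmin(qvals))
    left = grid[max(j - 1, 0)]
    right = grid[min(j + 1, len(grid) - 1)]
    res = optimize.minimize_scalar(ms.quadratic, bounds=(left, right),
                                   method="bounded",
                                   options={"xatol": 1e-10})
    theta = float(res.x)

    h = 1e-4 * (1 + abs(theta))
    q0, qm, qp = ms.quadratic(theta), ms.quadratic(theta - h), ms.quadratic(theta + h)
    curv = (qp - 2 * q0 + qm) / h ** 2
    if curv > 0:
        se = math.sqrt(2.0 / curv)
    else:
        vinv_c = ms._solve(theta, ms.c)
        se = float(ms.c @ vinv_c) ** -0.5
    est = MREstimate.from_theta_se(theta, se, "f_liml", data.n_variants,
                                   k=model.k, criterion=q0)
    return est
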