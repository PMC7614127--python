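"""Causal effect estimators: Wald ratio, standard IVW, correlated-instruments IVW.

Given marginal SNP-exposure effects ``beta_x`` and SNP-outcome effects
``beta_y`` with standard errors ``se_y``, the fixed-effect IVW estimate is

    theta = sum(beta_x * beta_y / se_y^2) / sum(beta_x^2 / se_y^2)

and its correlated-instruments generalization replaces the diagonal weights
by the full weighting matrix Omega = diag(se_y) R diag(se_y):

    theta = (beta_x' Omega^-1 beta_x)^-1 beta_x' Omega^-1 beta_y
    se^2  = (beta_x' Omega^-1 beta_x)^-1

The linear systems are solved through a Cholesky factorization of Omega;
an ill-conditioned Omega (the numerically unstable regime that motivates
pruning / PCA / factor methods) raises rather than silently pseudo-inverting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, stats

from .summary_data import HarmonizedDataset, SummaryStats

__all__ = [
    "MREstimate",
    "wald_ratio",
    "ivw_standard",
    "ivw_correlated",
    "top_snp",
    "Z_95",
]

Z_95 = 1.959964  # normal 97.5% quantile used for all 95% intervals

_TINY_P = 5e-324  # p-values are reported in (0, 1]


@dataclass
class MREstimate:
    """A causal effect estimate with normal-theory inference and provenance."""

    theta: float
    se: float
    ci_low: float
    ci_high: float
    p_value: float
    method: str
    n_instruments: int
    extra: dict = field(default_factory=dict)

    @classmethod
    def from_theta_se(cls, theta, se, method, n_instruments, **extra):
        if not np.isfinite(se) or se <= 0:
            raise ValueError(f"{method}: standard error must be positive, got {se}")
        z = theta / se
        p = max(2 * stats.norm.sf(abs(z)), _TINY_P)
        return cls(theta=float(theta), se=float(se),
                   ci_low=float(theta - Z_95 * se), ci_high=float(theta + Z_95 * se),
                   p_value=float(p), method=method,
                   n_instruments=int(n_instruments), extra=dict(extra))

    @property
    def rejects_null(self) -> bool:
        return self.p_value < 0.05

    def covers(self, theta0: float) -> bool:
        return self.ci_low <= theta0 <= self.ci_high


def wald_ratio(beta_x: float, se_x: float, beta_y: float, se_y: float) -> MREstimate:
    """Single-variant ratio estimate theta = beta_y / beta_x.

    The standard error is first-order: se_y / |beta_x| (uncertainty in
    beta_x ignored, as is conventional for strong single instruments).
    """
    if beta_x == 0:
        raise ValueError("undefined ratio: beta_x is zero")
    theta = beta_y / beta_x
    se = se_y / abs(beta_x)
    return MREstimate.from_theta_se(theta, se, "wald_ratio", 1)


def ivw_standard(stats_in: SummaryStats) -> MREstimate:
    """Fixed-effect IVW assuming independent instruments."""
    bx, by, sy = stats_in.beta_x, stats_in.beta_y, stats_in.se_y
    if bx is None or by is None:
        raise ValueError("both exposure and outcome statistics are required")
    if np.all(bx == 0):
        raise ValueError("all exposure effects are zero; IVW undefined")
    w = sy ** -2.0
    denom = np.sum(bx ** 2 * w)
    theta = np.sum(bx * by * w) / denom
    se = denom ** -0.5
    return MREstimate.from_theta_se(theta, se, "ivw", stats_in.n_variants)


def _solve_spd(omega: np.ndarray, rhs: np.ndarray, max_condition: float, label: str):
    """Solve omega @ x = rhs through Cholesky, guarding the condition number."""
    omega = (omega + omega.T) / 2
    eig = np.linalg.eigvalsh(omega)
    if eig[0] <= 0:
        raise ValueError(f"{label}: weighting matrix is singular "
                         f"(min eigenvalue {eig[0]:.3g})")
    cond = eig[-1] / eig[0]
    if cond > max_condition:
        raise ValueError(
            f"{label}: weighting matrix condition number {cond:.3g} exceeds "
            f"{max_condition:.3g}; prune or reduce the instrument set")
    c, low = linalg.cho_factor(omega, lower=True)
    return linalg.cho_solve((c, low), rhs)


def ivw_correlated(data: HarmonizedDataset, max_condition: float = 1e8,
                   subset=None) -> MREstimate:
    """Correlated-instruments IVW using the LD weighting matrix Omega.

    ``subset`` optionally restricts the analysis to a list of snp_ids (used
    by model averaging); the weighting submatrix is taken from the
    harmonized Omega.
    """
    if subset is not None:
        data = data.subset_by_id(list(subset))
    bx = data.stats.beta_x
    by = data.stats.beta_y
    if bx is None or by is None:
        raise ValueError("both exposure and outcome statistics are required")
    sol = _solve_spd(data.omega, np.column_stack([bx, by]), max_condition,
                     "ivw_correlated")
    denom = bx @ sol[:, 0]
    if denom <= 0:
        raise ValueError("ivw_correlated: non-positive precision; "
                         "exposure effects carry no information")
    theta = (bx @ sol[:, 1]) / denom
    se = denom ** -0.5
    return MREstimate.from_theta_se(theta, se, "ivw_correlated", data.n_variants)


def top_snp(data: HarmonizedDataset) -> MREstimate:
    """Wald ratio at the variant with the smallest exposure p-value."""
    px = data.stats.p_x
    if px is None:
        raise ValueError("exposure p-values are required to pick the top SNP")
    sx = data.stats.se_x
    ids = data.stats.snp_ids
    order = sorted(range(len(ids)), key=lambda j: (px[j], abs(sx[j]), ids[j]))
    j = order[0]
    est = wald_ratio(data.stats.beta_x[j], data.stats.se_x[j],
                     data.stats.beta_y[j], data.stats.se_y[j])
    est.method = "top_snp"
    est.extra["snp_id"] = ids[j]
    return est
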