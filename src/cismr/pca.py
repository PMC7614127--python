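"""Principal-components IVW for correlated instruments.

Instead of selecting variants, this method builds orthogonal linear
combinations of all variants and uses the leading ones as instruments.
PCA is applied to the precision-weighted matrix

    Psi_ij = beta_Xi beta_Xj se_Yi^-1 se_Yj^-1 rho_ij

so that, of two near-duplicate variants, the more precisely measured one is
prioritized.  With W~ the first k eigenvector columns, the summary
statistics and the weighting matrix are projected,

    bX~ = W~' beta_X,  bY~ = W~' beta_Y,  Omega~ = W~' Omega W~,

and the correlated IVW formula is evaluated in the projected coordinates.
At full rank (k = P) this is algebraically identical to the correlated IVW
estimate; truncating k stabilizes it when Omega is near-singular.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .estimators import MREstimate, _solve_spd
from .summary_data import HarmonizedDataset

__all__ = ["PCADecomposition", "build_psi", "choose_k", "pca_ivw_estimate"]


@dataclass
class PCADecomposition:
    psi: np.ndarray            # P x P precision-weighted LD matrix
    eigenvalues: np.ndarray    # descending, negatives clamped to 0
    eigenvectors: np.ndarray   # columns, ordered to match eigenvalues
    k: int | None = None       # retained components (set by choose_k)
    variance_prop: float | None = None


def build_psi(data: HarmonizedDataset) -> PCADecomposition:
    """Build Psi and its symmetric eigendecomposition (descending order)."""
    bx = data.stats.beta_x
    sy = data.stats.se_y
    if bx is None or sy is None:
        raise ValueError("exposure betas and outcome SEs are required")
    if np.any(sy == 0):
        raise ValueError("zero outcome standard error; Psi undefined")
    a = bx / sy
    psi = np.outer(a, a) * data.ld.corr
    psi = (psi + psi.T) / 2
    vals, vecs = np.linalg.eigh(psi)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    # numerically negative eigenvalues of a PSD-by-construction matrix
    vals[vals < 0] = 0.0
    return PCADecomposition(psi=psi, eigenvalues=vals, eigenvectors=vecs)


def choose_k(decomp: PCADecomposition, threshold: float) -> int:
    """Smallest k whose leading eigenvalues reach ``threshold`` of the trace."""
    if not 0 < threshold <= 1:
        raise ValueError(f"threshold must lie in (0, 1], got {threshold}")
    total = decomp.eigenvalues.sum()
    if total <= 0:
        return 1
    frac = np.cumsum(decomp.eigenvalues) / total
    k = int(np.searchsorted(frac, threshold - 1e-12) + 1)
    return max(1, min(k, len(decomp.eigenvalues)))


def pca_ivw_estimate(data: HarmonizedDataset, threshold: float = 0.999,
                     max_condition: float = 1e8) -> MREstimate:
    """IVW estimate on the principal components explaining ``threshold`` of Psi."""
    decomp = build_psi(data)
    k = choose_k(decomp, threshold)
    decomp.k = k
    total = decomp.eigenvalues.sum()
    decomp.variance_prop = float(
        decomp.eigenvalues[:k].sum() / total) if total > 0 else 1.0

    w = decomp.eigenvectors[:, :k]
    bx = w.T @ data.stats.beta_x
    by = w.T @ data.stats.beta_y
    omega = w.T @ data.omega @ w
    sol = _solve_spd(omega, np.column_stack([bx, by]), max_condition, "pca_ivw")
    denom = bx @ sol[:, 0]
    if denom <= 0:
        raise ValueError("pca_ivw: non-positive precision")
    theta = (bx @ sol[:, 1]) / denom
    se = denom ** -0.5
    return MREstimate.from_theta_se(
        theta, se, "pca_ivw", data.n_variants,
        k=k, variance_prop=decomp.variance_prop, threshold=threshold)
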