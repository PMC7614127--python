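"""Instrument selection: greedy LD-pruning and conditional-and-joint (CoJo) selection.

Both selectors take a harmonized dataset and return an ordered set of
variants intended for the correlated-instruments IVW estimator.

* :func:`ld_prune` iterates "pick the remaining variant with the smallest
  exposure p-value, discard everything correlated with it above rho".
* :func:`cojo_select` performs stepwise conditional selection from marginal
  summary statistics: candidates are evaluated by their p-value conditional
  on the already-selected set (reconstructed through the reference LD and
  Hardy-Weinberg genotype variances 2f(1-f)), and selected variants whose
  joint-model p-value rises above tau are dropped again.

Ties on p-value are broken by smaller se_x, then lexicographic snp_id, so
both selectors are fully deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .summary_data import HarmonizedDataset

__all__ = ["SelectionConfig", "SelectionResult", "ld_prune", "cojo_select"]


@dataclass(frozen=True)
class SelectionConfig:
    """rho: pairwise correlation ceiling; tau: significance threshold (None = no threshold)."""

    rho: float = 0.3
    tau: float | None = 5e-8

    def __post_init__(self):
        if not 0 < self.rho <= 1:
            raise ValueError(f"rho must lie in (0, 1], got {self.rho}")
        if self.tau is not None and not 0 < self.tau <= 1:
            raise ValueError(f"tau must lie in (0, 1] or None, got {self.tau}")


@dataclass
class SelectionResult:
    selected: list = field(default_factory=list)          # snp_ids in selection order
    discarded: list = field(default_factory=list)         # (snp_id, reason)
    trace: list = field(default_factory=list)             # per-iteration log strings

    @property
    def n_selected(self) -> int:
        return len(self.selected)


def _rank_key(px, sx, ids):
    return lambda j: (px[j], abs(sx[j]), ids[j])


def ld_prune(data: HarmonizedDataset, config: SelectionConfig) -> SelectionResult:
    """Greedy p-value-ordered pruning at correlation threshold ``config.rho``.

    Variants with p >= tau are never selected (reason ``below_tau``); a
    variant correlated at |r| >= rho with an earlier selection is discarded
    with reason ``pruned_by:<id>``.  An empty selection is a valid result.
    """
    px, sx = data.stats.p_x, data.stats.se_x
    if px is None:
        raise ValueError("exposure p-values are required for pruning")
    ids = data.stats.snp_ids
    corr = data.ld.corr
    result = SelectionResult()
    remaining = sorted(range(len(ids)), key=_rank_key(px, sx, ids))
    discarded = {}
    for j in remaining:
        if j in discarded:
            continue
        if config.tau is not None and px[j] >= config.tau:
            # everything after j in p-value order is also below threshold
            for k in remaining:
                if k not in discarded and k != j and px[k] >= config.tau:
                    discarded[k] = "below_tau"
            discarded[j] = "below_tau"
            continue
        result.selected.append(ids[j])
        result.trace.append(f"select {ids[j]} (p={px[j]:.3g})")
        for k in remaining:
            if k not in discarded and k != j and abs(corr[j, k]) >= config.rho:
                discarded[k] = f"pruned_by:{ids[j]}"
    result.discarded = [(ids[k], discarded[k]) for k in sorted(discarded)]
    return result


class _SummaryLeastSquares:
    """Joint/conditional fits reconstructed from marginal statistics.

    Under Hardy-Weinberg the genotype variance of variant j is
    d_j = 2 f_j (1 - f_j); with n individuals the cross-product matrix of
    the selected genotypes is approximated by
    X'X = n * D^1/2 R D^1/2 and X'y_j = n * d_j * beta_j, with y the
    exposure (variance ``var_y``, 1 for a standardized trait).
    """

    def __init__(self, data: HarmonizedDataset, var_y: float):
        if data.stats.n_x is None:
            raise ValueError("cojo_select requires the exposure sample size n_x")
        self.n = float(data.stats.n_x)
        eaf = data.stats.eaf
        self.d = 2 * eaf * (1 - eaf)
        self.corr = data.ld.corr
        self.beta = data.stats.beta_x
        self.var_y = var_y
        s = np.sqrt(self.d)
        self.xtx = self.n * self.corr * np.outer(s, s)
        self.xty = self.n * self.d * self.beta

    def joint_fit(self, idx):
        """Joint effects, SEs and p-values of the variants in ``idx``."""
        idx = list(idx)
        A = self.xtx[np.ix_(idx, idx)]
        eig = np.linalg.eigvalsh((A + A.T) / 2)
        if eig[0] <= 0 or eig[-1] / eig[0] > 1e8:
            raise np.linalg.LinAlgError("near-singular selected-set LD submatrix")
        rhs = self.xty[idx]
        b = np.linalg.solve(A, rhs)
        df = max(self.n - len(idx) - 1, 1)
        rss = max(self.n * self.var_y - b @ rhs, 1e-8)
        sigma2 = max(rss / df, 1e-8)
        se = np.sqrt(sigma2 * np.diag(np.linalg.inv(A)))
        p = 2 * stats.t.sf(np.abs(b / se), df)
        return b, se, np.maximum(p, 5e-324)


def cojo_select(data: HarmonizedDataset, config: SelectionConfig,
                var_y: float = 1.0) -> SelectionResult:
    """Stepwise conditional-and-joint selection from summary statistics.

    Starts from the smallest marginal-p variant; each iteration adds the
    candidate with the smallest conditional p-value (its p-value in the
    joint fit together with the selected set) if below tau, then refits the
    joint model and drops the selected variant with the largest joint
    p-value if above tau.  Candidates correlated at |r| >= rho with any
    selected variant are screened out, as are candidates whose inclusion
    makes the selected-set LD submatrix near-singular.
    """
    px, sx = data.stats.p_x, data.stats.se_x
    if px is None:
        raise ValueError("exposure p-values are required for cojo_select")
    ids = data.stats.snp_ids
    corr = data.ld.corr
    tau = config.tau if config.tau is not None else 1.0
    ls = _SummaryLeastSquares(data, var_y)
    result = SelectionResult()

    order = sorted(range(len(ids)), key=_rank_key(px, sx, ids))
    first = order[0]
    if px[first] >= tau:
        result.discarded = [(ids[j], "below_tau") for j in sorted(order)]
        return result
    selected = [first]
    reasons = {}
    result.trace.append(f"start {ids[first]} (p={px[first]:.3g})")

    for _ in range(2 * len(ids)):  # CoJo terminates; bound defensively
        changed = False
        # -- add step: smallest conditional p among screened candidates
        best_j, best_p = None, tau
        for j in order:
            if j in selected or j in reasons:
                continue
            if any(abs(corr[j, s]) >= config.rho for s in selected):
                continue
            try:
                _, _, pj = ls.joint_fit(selected + [j])
            except np.linalg.LinAlgError:
                reasons[j] = "ill_conditioned"
                continue
            if pj[-1] < best_p:
                best_j, best_p = j, pj[-1]
        if best_j is not None:
            selected.append(best_j)
            result.trace.append(f"add {ids[best_j]} (cond p={best_p:.3g})")
            changed = True
        # -- drop step: largest joint p above tau
        if len(selected) > 1:
            _, _, pj = ls.joint_fit(selected)
            worst = int(np.argmax(pj))
            if pj[worst] > tau:
                j = selected.pop(worst)
                reasons[j] = "dropped_joint"
                result.trace.append(f"drop {ids[j]} (joint p={pj[worst]:.3g})")
                changed = True
        if not changed:
            break

    result.selected = [ids[j] for j in selected]
    sel_set = set(selected)
    for j in range(len(ids)):
        if j in sel_set:
            continue
        if j in reasons:
            result.discarded.append((ids[j], reasons[j]))
        elif any(abs(corr[j, s]) >= config.rho for s in selected):
            result.discarded.append((ids[j], "screened_rho"))
        else:
            result.discarded.append((ids[j], "below_tau"))
    return result
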