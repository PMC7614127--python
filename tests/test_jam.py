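import itertools

import numpy as np
import pytest
import statsmodels.api as sm
from scipy.special import logsumexp

from cismr.jam import (JamConfig, build_sufficient_stats, compute_z,
                       log_evidence, logodds_to_linear,
                       model_averaged_estimate, rjmcmc_search, JamPosterior)
from cismr.summary_data import SummaryStats

from conftest import make_dataset, make_variants


def _stats(beta_x, eaf=0.3, n_x=10_000):
    beta_x = np.asarray(beta_x, dtype=float)
    p = len(beta_x)
    return SummaryStats(make_variants(p, eaf=eaf), beta_x=beta_x,
                        se_x=np.full(p, 0.01), p_x=np.full(p, 0.01), n_x=n_x)


class TestComputeZ:
    def test_direct_substitution(self):
        s = _stats([0.2], eaf=0.5, n_x=100)
        assert compute_z(s)[0] == pytest.approx(10.0)

    def test_zero_beta_gives_zero(self):
        assert compute_z(_stats([0.0]))[0] == 0.0

    def test_frequency_scaling_ratio(self):
        z_rare = compute_z(_stats([0.2], eaf=0.1))[0]
        z_common = compute_z(_stats([0.2], eaf=0.5))[0]
        assert z_rare / z_common == pytest.approx(0.18 / 0.5)

    def test_missing_n_is_error(self):
        s = _stats([0.2])
        s.n_x = None
        with pytest.raises(ValueError, match="n_x"):
            compute_z(s)


class TestLogEvidence:
    def test_null_data_prefers_empty_model(self):
        stats = _stats([0.0, 0.0, 0.0])
        suff = build_sufficient_stats(stats, np.eye(3))
        cfg = JamConfig(seed=0)
        empty = log_evidence((), suff, cfg)
        for j in range(3):
            assert empty > log_evidence((j,), suff, cfg)

    def test_duplicated_variant_pair_is_unvisitable(self):
        stats = _stats([0.1, 0.1])
        corr = np.array([[1.0, 1.0], [1.0, 1.0]])
        suff = build_sufficient_stats(stats, corr + np.eye(2) * 1e-12)
        assert log_evidence((0, 1), suff, JamConfig(seed=0)) == -np.inf

    def test_invariant_to_variant_relabeling(self):
        rng = np.random.default_rng(4)
        bx = rng.normal(0, 0.05, 4)
        corr = 0.3 ** np.abs(np.subtract.outer(np.arange(4), np.arange(4)))
        stats = _stats(bx)
        perm = [2, 0, 3, 1]
        stats_p = _stats(bx[perm])
        suff = build_sufficient_stats(stats, corr)
        suff_p = build_sufficient_stats(stats_p, corr[np.ix_(perm, perm)])
        # model {0,3} in original indexing = {1,2} after the permutation
        orig = log_evidence((0, 3), suff, JamConfig(seed=0))
        relab = log_evidence((perm.index(0), perm.index(3)), suff_p,
                             JamConfig(seed=0))
        assert orig == pytest.approx(relab, rel=1e-12)


def _enumeration_posterior(data, cfg):
    suff = build_sufficient_stats(data.stats, data.ld.corr)
    p = len(suff.z)
    models, vals = [], []
    for k in range(p + 1):
        for comb in itertools.combinations(range(p), k):
            models.append(frozenset(data.stats.snp_ids[i] for i in comb))
            vals.append(log_evidence(comb, suff, cfg))
    w = np.exp(np.asarray(vals) - logsumexp(vals))
    return dict(zip(models, w))


def _search_dataset(seed=42):
    rng = np.random.default_rng(seed)
    p = 5
    corr = 0.4 ** np.abs(np.subtract.outer(np.arange(p), np.arange(p)))
    bx = np.array([0.15, 0.02, 0.01, 0.12, 0.0]) + rng.normal(0, 0.005, p)
    by = 0.1 * bx + rng.normal(0, 0.005, p)
    from scipy import stats as sps
    px = np.clip(2 * sps.norm.sf(np.abs(bx / 0.01)), 1e-300, 1.0)
    return make_dataset(bx, by, se_y=np.full(p, 0.005), corr=corr, p_x=px)


class TestRJMCMC:
    def test_stationary_distribution_matches_enumeration(self):
        """Post-burn-in visit frequencies reproduce the exact posterior over
        all 32 models of a 5-variant region (detailed-balance check)."""
        data = _search_dataset()
        cfg = JamConfig(preprune_rho=0.99, iterations=200_000, seed=7)
        exact = _enumeration_posterior(data, cfg)
        post = rjmcmc_search(data, cfg)
        all_models = set(exact) | set(post.model_probs)
        tv = 0.5 * sum(abs(exact.get(m, 0.0) - post.model_probs.get(m, 0.0))
                       for m in all_models)
        assert tv <= 0.03

    def test_same_seed_is_bit_identical(self):
        data = _search_dataset()
        cfg = JamConfig(preprune_rho=0.99, iterations=20_000, seed=3)
        a, b = rjmcmc_search(data, cfg), rjmcmc_search(data, cfg)
        assert a.model_probs == b.model_probs
        assert a.averaged.theta == b.averaged.theta
        assert a.accept_rate == b.accept_rate

    def test_single_causal_variant_has_top_inclusion(self):
        rng = np.random.default_rng(9)
        p = 5
        corr = 0.5 ** np.abs(np.subtract.outer(np.arange(p), np.arange(p)))
        bx = corr[:, 2] * 0.12 + rng.normal(0, 0.002, p)  # causal at index 2
        from scipy import stats as sps
        px = np.clip(2 * sps.norm.sf(np.abs(bx / 0.01)), 1e-300, 1.0)
        data = make_dataset(bx, 0.1 * bx, se_y=np.full(p, 0.005), corr=corr,
                            p_x=px)
        post = rjmcmc_search(data, JamConfig(preprune_rho=0.99,
                                             iterations=50_000, seed=5))
        best = max(post.inclusion_probs, key=post.inclusion_probs.get)
        assert best == "snp2"

    def test_inclusion_probs_are_model_prob_marginals(self):
        data = _search_dataset()
        post = rjmcmc_search(data, JamConfig(preprune_rho=0.99,
                                             iterations=20_000, seed=1))
        for sid, ip in post.inclusion_probs.items():
            marg = sum(w for m, w in post.model_probs.items() if sid in m)
            assert ip == pytest.approx(marg, abs=1e-12)
        assert sum(post.model_probs.values()) == pytest.approx(1.0, abs=1e-9)

    def test_robust_to_preprune_threshold(self):
        """Strong-signal averaged estimate moves < 1 SE across pre-pruning
        thresholds 0.6-0.95 (the method's advertised robustness)."""
        from cismr.simulate import (get_simulator, harmonized_from_replicate,
                                    scenario)
        cfg = scenario("shbg-strong", theta=0.1)
        stats, ld, _ = get_simulator(cfg).replicate(12345)
        data = harmonized_from_replicate(stats, ld)
        ests = [rjmcmc_search(data, JamConfig(preprune_rho=rho,
                                              iterations=20_000,
                                              seed=11)).averaged
                for rho in (0.6, 0.8, 0.9, 0.95)]
        thetas = [e.theta for e in ests]
        min_se = min(e.se for e in ests)
        assert max(thetas) - min(thetas) < min_se


class TestModelAveraging:
    def test_degenerate_mixture_equals_component(self, toy_dataset):
        from cismr.estimators import ivw_correlated
        post = JamPosterior(model_probs={frozenset(["snp0", "snp1"]): 1.0},
                            inclusion_probs={"snp0": 1.0, "snp1": 1.0,
                                             "snp2": 0.0})
        est = model_averaged_estimate(post, toy_dataset)
        ref = ivw_correlated(toy_dataset, subset=["snp0", "snp1"])
        assert est.theta == pytest.approx(ref.theta)
        assert est.se == pytest.approx(ref.se)

    def test_law_of_total_variance_arithmetic(self, toy_dataset):
        from cismr.estimators import MREstimate
        post = JamPosterior(model_probs={frozenset(["snp0"]): 0.5,
                                         frozenset(["snp1"]): 0.5},
                            inclusion_probs={"snp0": 0.5, "snp1": 0.5})
        post.model_estimates = {
            frozenset(["snp0"]): MREstimate.from_theta_se(1.0, 1.0, "m", 1),
            frozenset(["snp1"]): MREstimate.from_theta_se(3.0, 1.0, "m", 1),
        }
        est = model_averaged_estimate(post, toy_dataset)
        assert est.theta == pytest.approx(2.0)
        assert est.se == pytest.approx(np.sqrt(2.0))

    def test_equal_components_widen_not_shrink(self, toy_dataset):
        from cismr.estimators import MREstimate
        post = JamPosterior(model_probs={frozenset(["snp0"]): 0.5,
                                         frozenset(["snp1"]): 0.5},
                            inclusion_probs={})
        post.model_estimates = {
            frozenset(["snp0"]): MREstimate.from_theta_se(1.0, 0.5, "m", 1),
            frozenset(["snp1"]): MREstimate.from_theta_se(1.0, 0.7, "m", 1),
        }
        est = model_averaged_estimate(post, toy_dataset)
        assert est.theta == pytest.approx(1.0)
        assert est.se >= 0.5

    def test_only_empty_model_is_error(self, toy_dataset):
        post = JamPosterior(model_probs={frozenset(): 1.0}, inclusion_probs={})
        with pytest.raises(ValueError, match="no instruments"):
            model_averaged_estimate(post, toy_dataset)


class TestLogOddsMapping:
    def test_zero_maps_to_zero(self):
        assert logodds_to_linear(0.0, 0.5) == 0.0

    def test_balanced_case_fraction(self):
        assert logodds_to_linear(1.0, 0.5) == pytest.approx(0.25)

    def test_simulation_consistency(self):
        """Logistic log-OR mapped to the linear-probability scale agrees
        with a direct linear fit of the 0/1 outcome within 10%."""
        rng = np.random.default_rng(21)
        n = 60_000
        g = rng.binomial(2, 0.3, n).astype(float)
        beta = 0.2
        logit = beta * (g - g.mean())
        y = rng.random(n) < 1 / (1 + np.exp(-logit))
        logit_fit = sm.Logit(y, sm.add_constant(g)).fit(disp=0)
        lin_fit = sm.OLS(y.astype(float), sm.add_constant(g)).fit()
        mapped = logodds_to_linear(logit_fit.params[1], float(y.mean()))
        assert lin_fit.params[1] == pytest.approx(mapped, rel=0.10)
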