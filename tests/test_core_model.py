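import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import multivariate_normal

from bts.core_model import (
    CausalConfig,
    ModelConfig,
    build_bf_store,
    config_log_prior,
    count_configurations,
    credible_set,
    enumerate_configurations,
    log_bayes_factor,
    pairwise_mismatch_bf,
    variant_posteriors,
    variant_prior,
)
from tests.conftest import make_region, random_correlation


def density_ratio_log_bf(config, region, W):
    """Independent oracle: direct log ratio of the two full n-dimensional
    normal densities (marginal-likelihood covariance vs null covariance)."""
    n = region.n
    ic = np.zeros(n)
    ic[list(config)] = 1.0
    cov_alt = region.ld + W * region.ld @ np.diag(ic) @ region.ld
    num = multivariate_normal.logpdf(region.z, mean=np.zeros(n), cov=cov_alt)
    den = multivariate_normal.logpdf(region.z, mean=np.zeros(n), cov=region.ld)
    return num - den


class TestEnumerate:
    def test_power_set_of_two(self):
        cfgs = enumerate_configurations(2, 2)
        assert [c.indices for c in cfgs] == [(), (0,), (1,), (0, 1)]

    def test_binomial_count_n10_d2(self):
        # oracle: 1 + C(10,1) + C(10,2)
        assert len(enumerate_configurations(10, 2)) == 1 + 10 + 45 == 56

    def test_null_plus_singletons(self):
        cfgs = enumerate_configurations(3, 1)
        assert [c.indices for c in cfgs] == [(), (0,), (1,), (2,)]

    def test_order_by_size_then_lex(self):
        cfgs = enumerate_configurations(4, 3)
        sizes = [len(c) for c in cfgs]
        assert sizes == sorted(sizes)
        for size in set(sizes):
            group = [c.indices for c in cfgs if len(c) == size]
            assert group == sorted(group)

    def test_d_larger_than_n(self):
        assert len(enumerate_configurations(3, 5)) == 8

    def test_cap_refused_with_actionable_message(self):
        with pytest.raises(ValueError, match="reduce d"):
            enumerate_configurations(1000, 3, cap=1000)

    @given(st.integers(1, 12), st.integers(1, 5))
    def test_count_matches_enumeration(self, n, d):
        assert len(enumerate_configurations(n, d)) == count_configurations(n, d)


class TestCausalConfig:
    def test_rejects_unsorted(self):
        with pytest.raises(ValueError):
            CausalConfig((2, 1))

    def test_rejects_duplicates(self):
        with pytest.raises(ValueError):
            CausalConfig((1, 1))

    def test_null_config(self):
        assert CausalConfig(()).is_null


class TestLogBayesFactor:
    def test_null_is_exactly_zero(self, two_indep_region):
        assert log_bayes_factor((), two_indep_region, 1.0) == 0.0

    def test_single_variant_closed_form(self):
        region = make_region("s", [5.0], [[1.0]])
        expected = -0.5 * math.log(2.0) + 25.0 / 4.0  # ~5.9034
        assert log_bayes_factor((0,), region, 1.0) == pytest.approx(expected, rel=1e-12)
        assert log_bayes_factor((0,), region, 1.0) == pytest.approx(
            density_ratio_log_bf((0,), region, 1.0), rel=1e-10
        )

    def test_perfect_ld_pair_closed_form(self):
        # singular sigma11: the direct density ratio cannot be evaluated,
        # the reduced form agrees with the pairwise closed form instead
        region = make_region("p", [5.0, 5.0], [[1.0, 1.0], [1.0, 1.0]])
        expected = -0.5 * math.log(3.0) + 25.0 / 3.0  # ~7.7840
        got = log_bayes_factor((0, 1), region, 1.0)
        assert got == pytest.approx(expected, rel=1e-12)
        assert got == pytest.approx(pairwise_mismatch_bf(5.0, 5.0, 1.0), rel=1e-12)

    def test_oracle_equivalence_random_regions(self, rng):
        # full-density oracle at <=1e-8 relative error, n <= 8
        for _ in range(25):
            n = int(rng.integers(2, 9))
            ld = random_correlation(n, rng)
            region = make_region("r", rng.normal(0, 3, n), ld)
            W = float(rng.uniform(0.1, 4.0))
            size = int(rng.integers(1, min(n, 4) + 1))
            cfg = tuple(sorted(rng.choice(n, size=size, replace=False)))
            got = log_bayes_factor(cfg, region, W)
            want = density_ratio_log_bf(cfg, region, W)
            assert got == pytest.approx(want, rel=1e-8, abs=1e-8)

    def test_lemma1_depends_only_on_causal_subset(self, rng):
        n = 6
        ld = random_correlation(n, rng)
        z = rng.normal(0, 2, n)
        region = make_region("a", z, ld)
        cfg = (1, 4)
        ref = log_bayes_factor(cfg, region, 1.0)
        z2 = z.copy()
        z2[[0, 2, 3, 5]] = rng.normal(0, 5, 4)  # perturb non-causal only
        assert log_bayes_factor(cfg, make_region("b", z2, ld), 1.0) == ref

    def test_independence_additivity(self, rng):
        n = 5
        z = rng.normal(0, 2, n)
        region = make_region("i", z, np.eye(n))
        for cfg in [(0, 1), (0, 2, 4), (1, 2, 3, 4)]:
            total = sum(log_bayes_factor((i,), region, 1.0) for i in cfg)
            assert log_bayes_factor(cfg, region, 1.0) == pytest.approx(total, rel=1e-12)

    def test_out_of_range_config(self, two_indep_region):
        with pytest.raises(IndexError):
            log_bayes_factor((5,), two_indep_region, 1.0)


class TestPairwiseMismatch:
    def test_zero_scores(self):
        for W in (0.0, 0.5, 1.0, 3.0):
            assert pairwise_mismatch_bf(0.0, 0.0, W) == pytest.approx(
                -0.5 * math.log1p(2 * W), rel=1e-12
            )

    def test_mismatch_spurious_term(self):
        # a=6, b=0, W=1: exponent (1/6)*(36 + 36) = 12, half from W(a-b)^2
        assert pairwise_mismatch_bf(6.0, 0.0, 1.0) == pytest.approx(
            -0.5 * math.log(3.0) + 12.0, rel=1e-12
        )

    @given(
        st.floats(-8, 8),
        st.floats(-8, 8),
        st.floats(0.01, 5.0),
    )
    @settings(max_examples=60, deadline=None)
    def test_agrees_with_generic_bf_on_perfect_ld_pair(self, a, b, W):
        region = make_region("pp", [a, b], [[1.0, 1.0], [1.0, 1.0]])
        assert pairwise_mismatch_bf(a, b, W) == pytest.approx(
            log_bayes_factor((0, 1), region, W), rel=1e-10, abs=1e-10
        )


class TestBfStore:
    def test_symmetric_independent_region(self):
        region = make_region("sym", [0.0, 0.0, 0.0], np.eye(3))
        store = build_bf_store(region, ModelConfig(W=1.0, d=2, t=float("inf")))
        assert len(store) == 7
        singles = [store.log_bf_of((i,)) for i in range(3)]
        assert np.allclose(singles, -0.5 * math.log(2.0))
        pairs = [store.log_bf_of(c) for c in [(0, 1), (0, 2), (1, 2)]]
        assert np.allclose(pairs, -math.log(2.0))  # additivity under identity LD

    def test_pruning_threshold(self):
        # magnitudes 1e20, 1e9, 1e7 with t=12: 1e7 dropped
        lbfs = np.array([20.0, 9.0, 7.0]) * math.log(10.0)
        cutoff = lbfs.max() - 12.0 * math.log(10.0)
        assert (lbfs >= cutoff).tolist() == [True, True, False]

    def test_pruned_store_respects_threshold(self, rng):
        ld = random_correlation(12, rng)
        z = rng.normal(0, 3, 12)
        region = make_region("pr", z, ld)
        store = build_bf_store(region, ModelConfig(d=3, t=4.0))
        assert store.pruned
        retained = store.log_bf[1:]  # null is exempt
        assert np.all(retained >= store.max_log_bf - 4.0 * math.log(10.0) - 1e-12)
        assert store.configs[0] == ()
        assert store.log_bf[0] == 0.0
        assert store.config_count_total == count_configurations(12, 3)

    def test_t_zero_keeps_argmax_and_null(self, rng):
        region = make_region("t0", [6.0, 1.0, 0.5], np.eye(3))
        store = build_bf_store(region, ModelConfig(d=2, t=0.0))
        assert () in store
        assert len(store) <= 1 + 1  # null + argmax (possibly equal)

    def test_store_immutable(self, two_indep_region, default_config):
        store = build_bf_store(two_indep_region, default_config)
        with pytest.raises((ValueError, RuntimeError)):
            store.log_bf[0] = 5.0


class TestPriors:
    def test_logistic_at_zero(self):
        assert variant_prior([1, 0], [0.0, 0.0]) == 0.5

    def test_logistic_inverse_of_point_one(self):
        assert variant_prior([1, 0], [-math.log(9.0), 0.0]) == pytest.approx(0.1)

    def test_coefficients_cancel(self):
        assert variant_prior([1, 1], [-math.log(9.0), math.log(9.0)]) == pytest.approx(0.5)

    def test_monotone_in_coefficient(self):
        lo = variant_prior([1, 1], [0.0, 0.1])
        hi = variant_prior([1, 1], [0.0, 0.5])
        assert hi > lo

    def test_config_log_prior_examples(self):
        p = [0.1, 0.1, 0.1]
        assert config_log_prior((), p) == pytest.approx(math.log(0.729), rel=1e-12)
        assert config_log_prior((0,), p) == pytest.approx(math.log(0.081), rel=1e-12)
        assert config_log_prior((0, 1), p) == pytest.approx(math.log(0.009), rel=1e-12)

    def test_rejects_degenerate_priors(self):
        with pytest.raises(ValueError):
            config_log_prior((0,), [0.0, 0.5])
        with pytest.raises(ValueError):
            config_log_prior((0,), [1.0, 0.5])

    @given(st.data())
    @settings(max_examples=40, deadline=None)
    def test_incremental_equals_direct_product(self, data):
        n = data.draw(st.integers(1, 12))
        p = np.array(
            data.draw(
                st.lists(st.floats(1e-6, 1 - 1e-6), min_size=n, max_size=n)
            )
        )
        idx = tuple(
            sorted(data.draw(st.sets(st.integers(0, n - 1), max_size=min(n, 5))))
        )
        # direct product over all variants (the defining formula)
        direct = sum(
            math.log(p[i]) if i in idx else math.log1p(-p[i]) for i in range(n)
        )
        assert config_log_prior(idx, p) == pytest.approx(direct, rel=1e-10, abs=1e-10)


class TestPosteriors:
    def test_two_independent_strong_signals(self, two_indep_region, default_config):
        store = build_bf_store(two_indep_region, default_config)
        post = variant_posteriors(store, [0.1, 0.1])
        assert post.marginal[0] >= 0.999
        assert post.marginal[1] >= 0.999

    def test_perfect_ld_symmetric_split(self, perfect_ld_region):
        store = build_bf_store(perfect_ld_region, ModelConfig(d=1))
        post = variant_posteriors(store, [0.1, 0.1])
        assert post.marginal[0] == pytest.approx(0.5, abs=1e-6)
        assert post.marginal[1] == pytest.approx(0.5, abs=1e-6)

    def test_single_variant_hand_enumeration(self):
        region = make_region("one", [0.0], [[1.0]])
        store = build_bf_store(region, ModelConfig())
        post = variant_posteriors(store, [0.1])
        bf1 = 2.0 ** -0.5
        expected = (bf1 * 0.1) / (0.9 + bf1 * 0.1)  # ~0.0729
        assert post.marginal[0] == pytest.approx(expected, rel=1e-12)

    def test_factorization_bit_identical(self, rng):
        ld = random_correlation(8, rng)
        region = make_region("f", rng.normal(0, 2, 8), ld)
        params = ModelConfig(d=2, t=float("inf"))
        cached = build_bf_store(region, params)
        for _ in range(5):
            priors = rng.uniform(0.01, 0.4, 8)
            from_cache = variant_posteriors(cached, priors)
            fresh = variant_posteriors(build_bf_store(region, params), priors)
            assert np.array_equal(from_cache.marginal, fresh.marginal)
            assert from_cache.log_relative_likelihood == fresh.log_relative_likelihood

    def test_bounds_and_prior_monotonicity(self, rng):
        ld = random_correlation(6, rng)
        region = make_region("m", rng.normal(0, 2, 6), ld)
        store = build_bf_store(region, ModelConfig(d=2, t=float("inf")))
        priors = np.full(6, 0.1)
        base = variant_posteriors(store, priors)
        assert np.all(base.marginal >= 0.0) and np.all(base.marginal <= 1.0)
        for i in range(6):
            bumped = priors.copy()
            bumped[i] = 0.3
            post = variant_posteriors(store, bumped)
            assert post.marginal[i] >= base.marginal[i] - 1e-12

    def test_exchangeable_symmetry(self):
        ld = np.full((3, 3), 0.4)
        np.fill_diagonal(ld, 1.0)
        region = make_region("sym2", [3.0, 3.0, 3.0], ld)
        store = build_bf_store(region, ModelConfig(d=2, t=float("inf")))
        post = variant_posteriors(store, [0.1, 0.1, 0.1])
        assert post.marginal[0] == pytest.approx(post.marginal[1], rel=1e-12)
        assert post.marginal[1] == pytest.approx(post.marginal[2], rel=1e-12)

    def test_store_not_mutated(self, two_indep_region, default_config):
        store = build_bf_store(two_indep_region, default_config)
        before = store.log_bf.copy()
        variant_posteriors(store, [0.2, 0.2])
        assert np.array_equal(store.log_bf, before)

    def test_length_mismatch(self, two_indep_region, default_config):
        store = build_bf_store(two_indep_region, default_config)
        with pytest.raises(ValueError):
            variant_posteriors(store, [0.1, 0.1, 0.1])

    def test_top_posterior_is_max(self, rng):
        ld = random_correlation(5, rng)
        region = make_region("tp", rng.normal(0, 2, 5), ld)
        store = build_bf_store(region, ModelConfig())
        post = variant_posteriors(store, np.full(5, 0.1))
        assert post.top_posterior == post.marginal.max()


class TestCredibleSet:
    def test_prefix_example(self):
        idx, mass = credible_set(np.array([0.6, 0.35, 0.05]), 0.9)
        assert idx == [0, 1]
        assert mass == pytest.approx(0.95)

    def test_single_variant(self):
        idx, mass = credible_set(np.array([0.3]), 0.9)
        assert idx == [0]
        assert mass == pytest.approx(1.0)

    def test_uniform_ten_variants(self):
        idx, _ = credible_set(np.full(10, 0.1), 0.9)
        assert len(idx) == 9  # ceil(0.9 * 10)

    def test_all_zero_warns_and_empty(self):
        with pytest.warns(UserWarning):
            idx, mass = credible_set(np.zeros(4), 0.9)
        assert idx == [] and mass == 0.0

    def test_ties_broken_by_genomic_order(self):
        idx, _ = credible_set(np.array([0.2, 0.2, 0.2, 0.2]), 0.5)
        assert idx == [0, 1]


class TestModelConfig:
    def test_defaults(self):
        cfg = ModelConfig()
        assert cfg.W == 1.0
        assert cfg.d == 2
        assert cfg.t == 12.0
        assert cfg.credible_level == 0.9
        assert cfg.top_posterior_threshold == 0.5
        assert cfg.delta_flag_threshold == 0.2

    def test_d_above_five_warns(self):
        with pytest.warns(UserWarning):
            ModelConfig(d=6)

    def test_invalid_values(self):
        with pytest.raises(ValueError):
            ModelConfig(W=-1.0)
        with pytest.raises(ValueError):
            ModelConfig(d=0)
        with pytest.raises(ValueError):
            ModelConfig(t=-1.0)
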