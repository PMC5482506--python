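"""Spike-and-slab mixture sampler: full-conditional pieces and small chains.

The large-scale oracles (exact enumeration, 1000-instance weight checks,
conjugacy pin at acceptance criterion tolerances) live in
test_acceptance.py; here we exercise the same surfaces at unit scale.
"""

import numpy as np
import pytest

from pleioprs.ld import LDBlock, LDBlockSet
from pleioprs.noninfinitesimal import (
    MixturePrior,
    component_weights,
    residual_stats,
    run_gibbs,
    run_gibbs_single,
    sample_effect,
    shrink_factor,
    shrink_weights,
    update_pvec,
)


def _indep_blocks(m):
    return LDBlockSet([LDBlock(i, i + 1, np.eye(1)) for i in range(m)], m)


def _weights_oracle(delta1, delta2, p, s1, s2, n1, n2):
    """Independent derivation: per-margin Gaussian evidence ratio
    slab/spike = (N sigma_slab + 1)^(-1/2) exp(N C delta^2 / 2)."""
    q1, q2 = p[0] + p[1], p[0] + p[2]
    slab1, slab2 = s1 / q1, s2 / q2
    c1 = n1 / (n1 + q1 / s1)
    c2 = n2 / (n2 + q2 / s2)
    lr1 = -0.5 * np.log(n1 * slab1 + 1) + 0.5 * n1 * c1 * delta1**2
    lr2 = -0.5 * np.log(n2 * slab2 + 1) + 0.5 * n2 * c2 * delta2**2
    logw = np.array([
        np.log(p[0]) + lr1 + lr2,
        np.log(p[1]) + lr1,
        np.log(p[2]) + lr2,
        np.log(p[3]),
    ])
    w = np.exp(logw - logw.max())
    return w / w.sum()


class TestWeights:
    def test_matches_independent_density_ratio_form(self, rng):
        for _ in range(50):
            p = rng.dirichlet(np.ones(4))
            d1, d2 = rng.normal(0, 0.03, 2)
            s1, s2 = rng.uniform(1e-5, 1e-3, 2)
            n1, n2 = rng.uniform(2e3, 5e4, 2)
            q1, q2 = p[0] + p[1], p[0] + p[2]
            c1 = n1 / (n1 + q1 / s1)
            c2 = n2 / (n2 + q2 / s2)
            w = component_weights(d1, d2, c1, c2, p, s1, s2, n1, n2)
            np.testing.assert_allclose(
                w, _weights_oracle(d1, d2, p, s1, s2, n1, n2), rtol=1e-10)

    def test_weights_are_a_distribution(self, rng):
        p = np.array([0.1, 0.2, 0.3, 0.4])
        w = component_weights(0.05, -0.02, 0.9, 0.8, p, 1e-4, 1e-4, 1e4, 1e4)
        assert np.all(w >= 0)
        assert w.sum() == pytest.approx(1.0, abs=1e-12)

    def test_null_data_favors_null_component(self):
        p = np.full(4, 0.25)
        w = component_weights(0.0, 0.0, 0.9, 0.9, p, 1e-4, 1e-4, 1e5, 1e5)
        assert w[3] == w.max()

    def test_one_sided_signal_selects_that_margin(self):
        p = np.full(4, 0.25)
        w = component_weights(0.1, 0.0, 0.99, 0.99, p, 1e-4, 1e-4, 1e5, 1e5)
        # causal-in-1 mass (11 + 10) dominates, and within it 10 > 11
        assert w[0] + w[1] > 0.99
        assert w[1] > w[0]

    def test_zero_causal_probability_rejected(self):
        p = np.array([0.0, 0.0, 0.5, 0.5])
        with pytest.raises(ValueError):
            component_weights(0.0, 0.0, 0.9, 0.9, p, 1e-4, 1e-4, 1e4, 1e4)

    def test_extreme_delta_no_overflow(self):
        p = np.full(4, 0.25)
        w = component_weights(50.0, -50.0, 0.999, 0.999, p,
                              1e-4, 1e-4, 1e6, 1e6)
        assert np.all(np.isfinite(w))
        assert w[0] == pytest.approx(1.0)


class TestResidualStats:
    def test_leave_one_out_residual(self):
        beta_tilde = np.array([0.1, 0.2, 0.3])
        d_row = np.array([0.5, 1.0, 0.5])  # SNP i = 1
        beta = np.array([0.02, 0.05, 0.04])
        gamma = np.zeros(3)
        p = np.full(4, 0.25)
        d1, d2, c1, c2 = residual_stats(
            1, beta_tilde, np.zeros(3), d_row, beta, gamma,
            p, 1e-4, 1e-4, 1e4, 2e4)
        # delta1 = 0.2 - (0.5*0.02 + 0.5*0.04) = 0.17
        assert d1 == pytest.approx(0.17)
        assert d2 == pytest.approx(0.0)
        assert c1 == pytest.approx(1e4 / (1e4 + 0.5 / 1e-4))
        assert c2 == pytest.approx(2e4 / (2e4 + 0.5 / 1e-4))


class TestShrink:
    def test_no_shrink_below_heritability(self):
        assert shrink_factor(np.array([0.01]), np.array([0.01]), 0.5, 0.5) == 1.0

    def test_shrink_ratio(self):
        beta = np.array([0.6, 0.8])  # sum sq = 1.0
        assert shrink_factor(beta, np.zeros(2), 0.25, 0.5) == pytest.approx(0.25)

    def test_binding_trait_wins(self):
        b = np.array([1.0])
        g = np.array([2.0])  # sum sq = 4
        assert shrink_factor(b, g, 0.5, 0.4) == pytest.approx(0.1)

    def test_shrink_weights_preserves_total_and_reroutes(self):
        w = np.array([0.2, 0.3, 0.1, 0.4])
        out = shrink_weights(w, 0.5)
        assert out.sum() == pytest.approx(1.0)
        np.testing.assert_allclose(out[:3], [0.1, 0.15, 0.05])
        assert out[3] == pytest.approx(0.7)

    def test_shrink_one_is_identity(self):
        w = np.array([0.2, 0.3, 0.1, 0.4])
        np.testing.assert_array_equal(shrink_weights(w, 1.0), w)


class TestSampleEffect:
    def test_spike_margins_are_exact_zero(self, rng):
        for k_target, w in [(1, [0, 1, 0, 0]), (2, [0, 0, 1, 0]),
                            (3, [0, 0, 0, 1])]:
            k, b, g = sample_effect(np.array(w, dtype=float),
                                    0.1, 0.2, 0.9, 0.9, 1e4, 1e4, rng)
            assert k == k_target
            if k in (1, 3):
                assert g == 0.0
            if k in (2, 3):
                assert b == 0.0

    def test_causal_draw_centered_at_c_delta(self, rng):
        w = np.array([1.0, 0, 0, 0])
        draws = np.array([
            sample_effect(w, 0.1, -0.05, 0.8, 0.6, 1e4, 1e4, rng)[1:]
            for _ in range(4000)
        ])
        assert draws[:, 0].mean() == pytest.approx(0.08, abs=3 * 0.009 / 63)
        assert draws[:, 1].mean() == pytest.approx(-0.03, abs=3 * 0.008 / 63)
        assert draws[:, 0].std() == pytest.approx(np.sqrt(0.8 / 1e4), rel=0.1)


class TestUpdateP:
    def test_conjugate_case_always_accepts(self, rng):
        """With p-independent slab variances the Dirichlet proposal is the
        exact conditional, so the MH ratio is identically 1."""
        beta = rng.normal(0, 0.01, 20)
        gamma = rng.normal(0, 0.01, 20)
        s = np.full(20, 1e-4)
        p = np.full(4, 0.25)
        for _ in range(25):
            counts = rng.multinomial(20, [0.25] * 4)
            p, accepted, prob = update_pvec(
                p, counts, np.ones(4), beta, gamma, s, s, rng,
                p_dependent_slabs=False)
            assert prob == pytest.approx(1.0, abs=1e-12)
            assert accepted

    def test_output_stays_on_simplex(self, rng):
        beta = rng.normal(0, 0.01, 10)
        gamma = np.zeros(10)
        s = np.full(10, 1e-4)
        p = np.full(4, 0.25)
        for _ in range(50):
            p, _, _ = update_pvec(p, [2, 3, 1, 4], np.ones(4),
                                  beta, gamma, s, s, rng)
            assert p.min() > 0
            assert p.sum() == pytest.approx(1.0, abs=1e-12)

    def test_counts_dominate_posterior_location(self, rng):
        """Heavy null counts pull p toward the null corner."""
        s = np.full(5, 1e-4)
        zero = np.zeros(5)
        p = np.full(4, 0.25)
        draws = []
        for _ in range(200):
            p, _, _ = update_pvec(p, [1, 1, 1, 997], np.ones(4),
                                  zero, zero, s, s, rng)
            draws.append(p[3])
        assert np.mean(draws) > 0.95


class TestPriorValidation:
    def test_bad_alpha_rejected(self):
        with pytest.raises(ValueError):
            MixturePrior(np.array([1.0, 1.0, 1.0]))
        with pytest.raises(ValueError):
            MixturePrior(np.array([1.0, 0.0, 1.0, 1.0]))

    def test_initial_p_normalized(self):
        p = MixturePrior(np.array([1.0, 2.0, 3.0, 4.0])).initial_p()
        assert p.sum() == pytest.approx(1.0)


class TestChains:
    def _data(self, rng, m=60, n=20000, h2=0.2, k=6):
        beta = np.zeros(m)
        idx = rng.choice(m, k, replace=False)
        beta[idx] = rng.normal(0, np.sqrt(h2 / k), k)
        bt = beta + rng.normal(0, 1 / np.sqrt(n), m)
        return beta, bt

    def test_same_seed_reproduces_exactly(self, rng):
        _, bt = self._data(rng)
        gt = bt[::-1].copy()
        m = bt.size
        s = np.full(m, 0.2 / m)
        kw = dict(n1=2e4, n2=2e4, h2_1=0.2, h2_2=0.2, n_iter=40, burn_in=10)
        r1 = run_gibbs(bt, gt, _indep_blocks(m), s, s, seed=7, **kw)
        r2 = run_gibbs(bt, gt, _indep_blocks(m), s, s, seed=7, **kw)
        np.testing.assert_array_equal(r1.post_mean1, r2.post_mean1)
        np.testing.assert_array_equal(r1.p_trace, r2.p_trace)
        r3 = run_gibbs(bt, gt, _indep_blocks(m), s, s, seed=8, **kw)
        assert not np.array_equal(r1.post_mean1, r3.post_mean1)

    def test_fixed_p_mode_freezes_proportions(self, rng):
        _, bt = self._data(rng)
        m = bt.size
        s = np.full(m, 0.2 / m)
        fp = np.array([0.05, 0.05, 0.05, 0.85])
        r = run_gibbs(bt, bt, _indep_blocks(m), s, s, 2e4, 2e4, 0.2, 0.2,
                      n_iter=30, burn_in=5, seed=1,
                      update_p=False, fixed_p=fp)
        np.testing.assert_array_equal(r.p_trace, np.tile(fp, (30, 1)))
        assert np.isnan(r.accept_rate)

    def test_null_data_yields_near_zero_posterior(self, rng):
        m, n = 80, 20000
        bt = rng.normal(0, 1 / np.sqrt(n), m)
        s = np.full(m, 0.2 / m)
        r = run_gibbs(bt, bt * 0, _indep_blocks(m), s, s, n, n, 0.2, 0.2,
                      n_iter=120, burn_in=20, seed=3)
        assert np.abs(r.post_mean1).max() < 0.01
        # sampled genetic variance stays far below the h2 = 0.2 prior scale
        # (p itself may not move at this size: the exact MH correction for
        # the p-dependent slab can reject every Dirichlet(alpha + counts)
        # proposal when the data carry no signal, so we do not assert on p)
        assert r.h2_trace1[20:].mean() < 0.05

    def test_strong_signal_recovered(self, rng):
        m, n = 120, 50000
        beta, bt = self._data(rng, m=m, n=n, h2=0.3, k=10)
        s = np.full(m, 0.3 / m)
        r = run_gibbs(bt, bt, _indep_blocks(m), s, s, n, n, 0.3, 0.3,
                      n_iter=200, burn_in=50, seed=5)
        cor = np.corrcoef(r.post_mean1, beta)[0, 1]
        assert cor > 0.8

    def test_single_trait_sampler_runs_and_recovers(self, rng):
        m, n = 120, 50000
        beta, bt = self._data(rng, m=m, n=n, h2=0.3, k=10)
        s = np.full(m, 0.3 / m)
        r = run_gibbs_single(bt, _indep_blocks(m), s, n, 0.3,
                             n_iter=200, burn_in=50, seed=5)
        assert r.post_mean2 is None
        assert r.p_trace.shape == (200, 2)
        assert np.corrcoef(r.post_mean1, beta)[0, 1] > 0.8

    def test_invalid_chain_lengths_rejected(self, rng):
        bt = rng.normal(0, 0.01, 4)
        s = np.full(4, 0.05)
        with pytest.raises(ValueError):
            run_gibbs(bt, bt, _indep_blocks(4), s, s, 1e4, 1e4, 0.2, 0.2,
                      n_iter=10, burn_in=10)
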