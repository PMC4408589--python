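"""Recombination/crossover kernels, emissions and forward-backward."""

import itertools

import numpy as np
import pytest

from aldmix.hmm_engine import (
    crossover_prob,
    emission_prob,
    forward_backward,
    recomb_prob,
    sample_states,
    transition_prior,
)


class TestKernels:
    def test_recomb_zero_distance(self):
        assert recomb_prob(0.0, 3.0) == 0.0

    def test_recomb_single_generation_identity(self):
        # at lambda = 1 the multi-generation map function reduces to the
        # single-generation Haldane-type form over the whole d grid
        d = np.linspace(0, 300, 5000)
        lhs = recomb_prob(d, 1.0)
        rhs = (1 - np.exp(-2 * d / 100)) / 2
        np.testing.assert_allclose(lhs, rhs, rtol=0, atol=1e-15)

    def test_recomb_reference_value(self):
        # direct evaluation at lambda=6, d=10
        import mpmath

        expect = float(1 - ((1 + mpmath.e ** (-2 * mpmath.mpf(10) / 100)) / 2) ** 6)
        assert recomb_prob(10.0, 6.0) == pytest.approx(expect, abs=1e-12)
        assert recomb_prob(10.0, 6.0) == pytest.approx(0.43453, abs=5e-5)

    def test_recomb_negative_error(self):
        with pytest.raises(ValueError):
            recomb_prob(-1.0, 2.0)

    def test_crossover_values_and_monotonicity(self):
        assert crossover_prob(0.0, 6.0) == 0.0
        assert crossover_prob(0.1, 6.0) == pytest.approx(1 - np.exp(-0.006), rel=1e-12)
        assert crossover_prob(0.1, 6.0) == pytest.approx(0.005982, abs=1e-6)
        w = np.linspace(0.01, 50, 100)
        assert np.all(crossover_prob(2 * w, 3.0) > crossover_prob(w, 3.0))


class TestTransitionPrior:
    def test_endpoints(self):
        gamma_prev = np.array([0.9, 0.1])
        A = np.array([0.8, 0.2])
        np.testing.assert_allclose(transition_prior(gamma_prev, A, 1.0), A)
        np.testing.assert_allclose(transition_prior(gamma_prev, A, 0.0), gamma_prev)

    def test_hand_arithmetic(self):
        out = transition_prior([0.9, 0.1], [0.8, 0.2], 0.3)
        np.testing.assert_allclose(out, [0.87, 0.13])
        assert out.sum() == pytest.approx(1.0)


class TestEmission:
    def test_missing_observation_contributes_one(self):
        assert emission_prob([-1], 0, [0.3]) == 1.0

    def test_single_marker_allele_frequency(self):
        p = np.array([[0.3, 0.8]])
        assert emission_prob([1], 0, p[:, 0]) == pytest.approx(0.3)
        assert emission_prob([0], 1, p[:, 1]) == pytest.approx(0.2)

    def test_certain_crossover_collapses_to_frequency_term(self, rng):
        # as lambda*w grows the PCR term vanishes and the emission equals
        # the normalized member-frequency evidence
        H = np.array([[0.5, 2.0]])
        proj = np.array([0.7])
        p = np.array([[0.2, 0.9], [0.4, 0.6]])
        x = np.array([1, 0])
        big = emission_prob(x, 0, p, lam=1e9, w=5.0, H=H, projected=proj)
        like = np.array([0.2 * 0.6, 0.9 * 0.4])
        np.testing.assert_allclose(big, like[0] / like.sum(), atol=1e-9)

    def test_compositional_oracle(self):
        # f = pbar * Px + q * (1 - Px), assembled independently
        from scipy.special import expit

        H = np.array([[-0.3, 1.2, -0.8]])
        proj = np.array([0.5, -0.25])
        p = np.array([[0.2, 0.7]])
        x = np.array([1])
        lam, w = 6.0, 2.0
        px = 1 - np.exp(-lam * w / 100)
        q1 = expit(H[0, 0] + H[0, 1] * proj[0] + H[0, 2] * proj[1])
        like = np.array([0.2, 0.7])
        pbar = like / like.sum()
        expect_k1 = pbar[1] * px + q1 * (1 - px)
        got = emission_prob(x, 1, p, lam=lam, w=w, H=H, projected=proj)
        assert got == pytest.approx(expect_k1, abs=1e-12)
        got0 = emission_prob(x, 0, p, lam=lam, w=w, H=H, projected=proj)
        assert got + got0 == pytest.approx(1.0, abs=1e-12)


class TestEmissionModelConsistency:
    def test_vectorized_emissions_match_scalar_composition(self, small_panels, small_windows):
        # the batched engine must agree with the scalar emission assembled
        # window by window (same crossover blend, projection and tempering)
        from aldmix.ancestral_model import compute_priors
        from aldmix.hmm_engine import EmissionModel

        panels, _, _ = small_panels
        prior = compute_priors(panels, small_windows)
        X = panels[0][:3]
        em = EmissionModel(X, prior)
        p = prior.P.copy()
        beta = [wp.H for wp in prior.window_priors]
        lam = np.full(3, 6.0)
        E = em.emissions(p, beta, lam)
        for j in (1, 5, 20):
            wp = prior.window_priors[j]
            if not wp.use_pcr:
                continue
            s, e = em.starts[j], em.stops[j]
            for h in range(3):
                f1 = emission_prob(
                    X[h, s:e], 1, p[s:e], lam=6.0, w=wp.support_span_cm,
                    H=wp.H, projected=em.proj[j][h], temper=em.temper[j],
                )
                # engine rows are on the same normalized scale (f sums to 1)
                row = E[h, j] / E[h, j].sum()
                assert row[1] == pytest.approx(f1, abs=1e-10)


def enumeration_marginals(E, pr, A):
    """Exhaustive-path oracle for the window chain.

    The chain has transition matrix T_j(k* -> k) = pr_j * A_k +
    (1 - pr_j) * 1[k = k*] and initial distribution A; every one of the
    K^J ancestral paths is weighted by its full emission x transition
    product and the weights are marginalized window by window.
    """
    J, K = E.shape
    post = np.zeros((J, K))
    for path in itertools.product(range(K), repeat=J):
        w = A[path[0]] * E[0, path[0]]
        for t in range(1, J):
            trans = pr[t] * A[path[t]] + (1 - pr[t]) * (path[t] == path[t - 1])
            w *= trans * E[t, path[t]]
        for t in range(J):
            post[t, path[t]] += w
    return post / post.sum(axis=1, keepdims=True)


class TestForwardBackward:
    def test_single_window_missing_returns_global(self):
        E = np.ones((1, 1, 2))
        gamma = forward_backward(E, np.ones((1, 1)), np.array([0.7, 0.3]))
        np.testing.assert_allclose(gamma[0, 0], [0.7, 0.3])

    def test_uniform_emissions_return_global(self):
        E = np.full((1, 5, 3), 0.2)
        A = np.array([0.5, 0.3, 0.2])
        pr = np.column_stack([np.ones(1), np.full((1, 4), 0.3)])
        gamma = forward_backward(E, pr, A)
        for j in range(5):
            np.testing.assert_allclose(gamma[0, j], A, atol=1e-12)

    @pytest.mark.parametrize("J,K", [(2, 2), (3, 2), (4, 2), (2, 3), (3, 3), (4, 3)])
    def test_matches_exhaustive_enumeration(self, J, K, rng):
        for _ in range(5):
            E = rng.random((J, K)) + 0.05
            A = rng.dirichlet(np.ones(K))
            pr = np.r_[1.0, rng.random(J - 1)]
            gamma = forward_backward(E[None], pr[None], A)
            expect = enumeration_marginals(E, pr, A)
            np.testing.assert_allclose(gamma[0], expect, atol=1e-10)

    def test_reversal_symmetry(self, rng):
        J, K = 8, 2
        E = rng.random((J, K)) + 0.05
        A = np.array([0.6, 0.4])
        prs = rng.random(J - 1)
        pr = np.r_[1.0, prs]
        pr_flip = np.r_[1.0, prs[::-1]]
        g1 = forward_backward(E[None], pr[None], A)[0]
        g2 = forward_backward(E[None, ::-1], pr_flip[None], A)[0]
        np.testing.assert_allclose(g1, g2[::-1], atol=1e-10)

    def test_large_distance_decouples_windows(self, rng):
        J, K = 6, 2
        E = rng.random((J, K)) + 0.05
        A = np.array([0.7, 0.3])
        pr = np.r_[1.0, np.full(J - 1, 1.0 - 1e-14)]
        gamma = forward_backward(E[None], pr[None], A)[0]
        expect = E * A
        expect /= expect.sum(axis=1, keepdims=True)
        np.testing.assert_allclose(gamma, expect, atol=1e-6)

    def test_gamma_rows_normalized(self, rng):
        E = rng.random((10, 50, 2)) + 0.01
        pr = np.column_stack([np.ones(10), rng.random((10, 49))])
        A = rng.dirichlet(np.ones(2), size=10)
        gamma = forward_backward(E, pr, A)
        np.testing.assert_allclose(gamma.sum(axis=2), 1.0, atol=1e-10)

    def test_zero_emission_everywhere_errors(self):
        E = np.zeros((1, 2, 2))
        with pytest.raises(FloatingPointError, match="window"):
            forward_backward(E, np.ones((1, 2)), np.array([0.5, 0.5]))


class TestSampleStates:
    def test_degenerate_distribution(self, rng):
        gamma = np.zeros((1, 4, 2))
        gamma[..., 0] = 1.0
        G = sample_states(gamma, rng)
        assert np.all(G == 0)

    def test_empirical_frequency(self):
        rng = np.random.default_rng(7)
        gamma = np.full((1, 100000, 2), 0.5)
        G = sample_states(gamma, rng)
        assert abs(G.mean() - 0.5) < 0.005

    def test_seed_determinism(self, rng):
        gamma = np.random.default_rng(3).dirichlet(np.ones(3), size=(5, 20))
        a = sample_states(gamma, np.random.default_rng(42))
        b = sample_states(gamma, np.random.default_rng(42))
        np.testing.assert_array_equal(a, b)
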