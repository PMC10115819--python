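"""Energy, exact distribution, Gibbs sampling and likelihood fitting."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import expit

from calfscape import (FitSettings, MaxEntParams, energy, exact_distribution,
                       fit, gibbs_sample, significance)
from calfscape.maxent import _truncated_exp_sample
from calfscape.synthetic import generate_community, random_ground_truth


def random_params(n: int, seed: int, scale: float = 1.0) -> MaxEntParams:
    return random_ground_truth(n, seed, scale=scale).params


class TestEnergy:
    def test_zero_params_zero_energy(self):
        p = MaxEntParams.zeros(4)
        s = np.array([1.0, 0.0, 1.0, 1.0])
        assert energy(s, (0.3, 0.7), p) == 0.0

    def test_single_component_bias(self):
        p = MaxEntParams(np.array([0.5]), np.zeros((1, 1)),
                         np.zeros(1), np.zeros(1))
        assert energy(np.array([1.0]), (0.0, 0.0), p) == pytest.approx(-0.5)

    def test_two_component_hand_value(self, two_component_params):
        e = energy(np.array([1.0, 1.0]), (0.0, 0.0), two_component_params)
        assert e == pytest.approx(-0.8)

    def test_environment_terms(self):
        p = MaxEntParams(np.array([0.0]), np.zeros((1, 1)),
                         np.array([2.0]), np.array([-1.0]))
        # E = -(eps_a*2 - eps_s*1) for sigma = 1
        assert energy(np.array([1.0]), (1.0, 0.5), p) == pytest.approx(-1.5)

    def test_dimension_mismatch_raises(self):
        p = MaxEntParams.zeros(3)
        with pytest.raises(ValueError):
            energy(np.array([1.0, 0.0]), (0, 0), p)

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None)
    def test_permutation_invariance(self, seed):
        """Relabeling components together with parameters leaves the
        energy of the correspondingly relabeled state unchanged."""
        rng = np.random.default_rng(seed)
        n = 5
        p = random_params(n, seed)
        s = (rng.random(n) < 0.5).astype(float)
        order = rng.permutation(n)
        e_orig = energy(s, (1.0, 0.5), p)
        e_perm = energy(s[order], (1.0, 0.5), p.permuted(order))
        assert e_perm == pytest.approx(e_orig)


class TestExactDistribution:
    def test_uniform_when_params_zero(self):
        states, probs = exact_distribution(MaxEntParams.zeros(2), (0, 0))
        assert np.allclose(probs, 0.25)

    @pytest.mark.parametrize("n", [3, 6, 10])
    def test_normalisation(self, n):
        _, probs = exact_distribution(random_params(n, seed=n), (1.0, 0.53))
        assert probs.sum() == pytest.approx(1.0, abs=1e-10)

    def test_boltzmann_ratio_cancels_partition_function(self):
        p = MaxEntParams(np.zeros(2), np.array([[0.0, 2.0], [2.0, 0.0]]),
                         np.zeros(2), np.zeros(2))
        states, probs = exact_distribution(p, (0, 0))
        # states indexed by bit pattern: 0 = (0,0), 3 = (1,1)
        assert probs[3] / probs[0] == pytest.approx(np.exp(2.0))

    def test_refuses_large_systems(self):
        with pytest.raises(ValueError):
            exact_distribution(MaxEntParams.zeros(21), (0, 0))


class TestGibbs:
    def test_isolated_component_marginal_half(self):
        p = MaxEntParams.zeros(1)
        s = gibbs_sample(p, (0, 0), n_sweeps=20_000, seed=3, burn_in=100)
        assert s.mean() == pytest.approx(0.5, abs=0.02)

    def test_clamped_component_never_moves(self):
        p = random_params(4, seed=5)
        init = np.array([1.0, 0.0, 1.0, 0.0])
        s = gibbs_sample(p, (0, 0), n_sweeps=200, seed=5, init=init,
                         clamped=np.array([True, False, True, False]))
        assert np.all(s[:, 0] == 1.0)
        assert np.all(s[:, 2] == 1.0)

    def test_same_seed_same_samples(self):
        p = random_params(3, seed=8)
        a = gibbs_sample(p, (1, 0.5), n_sweeps=50, seed=11)
        b = gibbs_sample(p, (1, 0.5), n_sweeps=50, seed=11)
        assert np.array_equal(a, b)

    def test_truncated_exponential_moments(self):
        """The continuous conditional matches its closed-form mean:
        E[x] = 1/(1-e^-r) - 1/r for density prop. to exp(r x) on [0,1]."""
        rng = np.random.default_rng(0)
        for r in (-3.0, 1e-12, 2.5):
            u = rng.random(200_000)
            x = _truncated_exp_sample(np.full_like(u, r), u)
            assert np.all((x >= 0) & (x <= 1))
            if abs(r) < 1e-9:
                expected = 0.5
            else:
                expected = 1.0 / (1.0 - np.exp(-r)) - 1.0 / r
            assert x.mean() == pytest.approx(expected, abs=0.005)


class TestFit:
    def test_half_present_component_has_zero_bias(self):
        states = np.array([[1.0], [0.0]] * 20)
        env = np.zeros((40, 2))
        res = fit(states, env, settings=FitSettings(backend="exact"))
        assert res.params.h[0] == pytest.approx(0.0, abs=1e-6)

    def test_g_frozen_without_environmental_contrast(self):
        model = random_ground_truth(4, seed=2, environments=[(0.0, 0.0)])
        comp, env = generate_community(model, 500, seed=3)
        res = fit(comp, env, settings=FitSettings(backend="exact"))
        assert np.all(res.params.g_a == 0)
        assert np.all(res.params.g_s == 0)

    def test_sa_and_exact_backends_agree(self):
        model = random_ground_truth(4, seed=4)
        comp, env = generate_community(model, 400, seed=5)
        exact = fit(comp, env, settings=FitSettings(backend="exact"))
        sa = fit(comp, env, seed=6,
                 settings=FitSettings(backend="sa", n_iter=4000,
                                      n_chains=60))
        pooled_exact = exact.params.as_vector()
        pooled_sa = sa.params.as_vector()
        assert np.corrcoef(pooled_exact, pooled_sa)[0, 1] > 0.98

    def test_degenerate_component_capped_with_warning(self):
        states = np.ones((30, 1))
        env = np.zeros((30, 2))
        with pytest.warns(UserWarning, match="always present"):
            res = fit(states, env, settings=FitSettings(backend="exact"))
        assert abs(res.params.h[0]) <= 10.0

    def test_sa_trace_decreases(self):
        model = random_ground_truth(5, seed=9)
        comp, env = generate_community(model, 500, seed=10)
        res = fit(comp, env, seed=11,
                  settings=FitSettings(backend="sa", n_iter=2000))
        head = res.trace[:100].mean()
        tail = res.trace[-100:].mean()
        assert tail < head


class TestSignificance:
    def test_p_value_floor_and_range(self):
        rng = np.random.default_rng(0)
        states = (rng.random((120, 1)) < 0.95).astype(float)
        env = np.zeros((120, 2))
        res = significance(states, env, n_reps=2000, seed=1,
                           settings=FitSettings(backend="exact"))
        p = res.p_values.h[0]
        assert p == pytest.approx(1.0 / 2001)

    def test_small_n_reps_warns(self):
        states = np.array([[1.0], [0.0]] * 10)
        env = np.zeros((20, 2))
        with pytest.warns(UserWarning, match="unstable"):
            significance(states, env, n_reps=50, seed=0,
                         settings=FitSettings(backend="exact"))

    def test_strong_coupling_detected(self):
        p = MaxEntParams(np.zeros(2), np.array([[0.0, 2.5], [2.5, 0.0]]),
                         np.zeros(2), np.zeros(2))
        model = random_ground_truth(2, 0)
        model.params = p
        comp, env = generate_community(model, 200, seed=2)
        res = significance(comp, env, n_reps=200, seed=3,
                           settings=FitSettings(backend="exact"))
        assert res.p_values.J[0, 1] <= 0.05
        assert res.params.J[0, 1] > 0
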