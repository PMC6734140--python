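"""State estimation: oracle equivalences, bounds and uncertainty dynamics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import perceptsim as ps
import perceptsim.generative_model as gm
from perceptsim.generative_model import apply_precision
from perceptsim.inference import free_energy, infer_states

from conftest import random_stochastic, single_factor_model, two_factor_model


def brute_force_evidence(model, obs, policy):
    """-ln P(o) by exhaustive enumeration over all joint state trajectories."""
    dims = model.state_dims
    t_obs = len(obs)
    states = [np.array(i) for i in np.ndindex(*dims)]
    # joint prob over trajectories, built recursively
    def emit(s):
        p = 1.0
        for m in range(model.n_modalities):
            p *= model.likelihood(m)[(int(obs[t][m]), *s)]
        return p
    probs = {}
    for s in np.ndindex(*dims):
        p = 1.0
        for f in range(model.n_factors):
            p *= model.D[f][s[f]]
        probs[s] = p
    t = 0
    total_tables = []
    for t in range(t_obs):
        if t > 0:
            new = {}
            for s in np.ndindex(*dims):
                acc = 0.0
                for sp, pp in probs.items():
                    trans = 1.0
                    for f in range(model.n_factors):
                        trans *= model.transition(f, policy[t - 1])[s[f], sp[f]]
                    acc += pp * trans
                new[s] = acc
            probs = new
        for s in list(probs):
            probs[s] = probs[s] * emit(s)
    return -np.log(sum(probs.values()))


class TestSingleStepBayes:
    def test_deterministic_likelihood_pins_the_state(self):
        model = single_factor_model(0, zeta=np.inf)
        model.A[0] = np.eye(3)
        model.D[0] = np.full(3, 1 / 3)
        model._cache.clear()
        bs = infer_states(model, [(2,)], ())
        # one-hot up to the e^-16 log-floor leakage on impossible states
        assert np.allclose(bs.beliefs[0][0], [0, 0, 1], atol=1e-6)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_exact_bayes_oracle(self, seed):
        model = single_factor_model(seed)
        rng = np.random.default_rng(seed + 100)
        o = int(rng.integers(3))
        bs = infer_states(model, [(o,)], ())
        Ah = apply_precision(model.A[0], 1.0)
        exact = model.D[0] * Ah[o]
        exact = exact / exact.sum()
        assert np.abs(bs.beliefs[0][0] - exact).max() < 1e-8
        # and the free energy equals the negative log evidence at the posterior
        assert bs.F == pytest.approx(-np.log(model.D[0] @ Ah[o]), abs=1e-8)


class TestUncertaintyDynamics:
    def test_fixation_blurs_unobserved_quadrants_to_uniform(self):
        model, env = ps.build_troxler_model(ps.TroxlerSpec(condition="fixate"))
        env.reset()
        obs = [env.observe()]
        for _ in range(16):
            obs.append(env.step(0))
        bs = infer_states(model, obs, (0,) * 16)
        for f in range(4):
            assert np.abs(bs.beliefs[16][f] - 0.25).max() < 1e-3

    def test_repeated_observations_sharpen_static_factor(self):
        # omega infinite: the world cannot change, evidence accumulates
        model = single_factor_model(3, zeta=0.8, omega=np.inf)
        model.B[0] = np.eye(3)[:, :, None]
        model._cache.clear()
        obs = [(1,)] * 8
        conf = []
        for t in range(1, 9):
            bs = infer_states(model, obs[:t], (0,) * (t - 1))
            conf.append(bs.beliefs[t - 1][0].max())
        assert np.all(np.diff(conf) >= -1e-10)

    def test_uninformative_observations_let_entropy_grow(self):
        # zeta = 0: observations say nothing; a finite omega on otherwise
        # static (identity) dynamics leaks certainty towards uniform
        model = single_factor_model(4, zeta=0.0, omega=1.0)
        model.B[0] = np.eye(3)[:, :, None]
        model.D[0] = np.eye(3)[0]
        model._cache.clear()
        obs = [(0,)] * 10
        bs = infer_states(model, obs, (0,) * 9)
        ent = [-(q := bs.beliefs[t][0]) @ np.log(np.maximum(q, 1e-30))
               for t in range(10)]
        assert np.all(np.diff(ent) >= -1e-9)


class TestFreeEnergy:
    @pytest.mark.parametrize("seed", range(6))
    def test_bounds_negative_log_evidence(self, seed):
        model = two_factor_model(seed)
        rng = np.random.default_rng(seed + 7)
        obs = [tuple(rng.integers(3, size=1)) for _ in range(3)]
        policy = tuple(rng.integers(2, size=2))
        neg_log_ev = brute_force_evidence(model, obs, policy)
        # arbitrary normalised product beliefs satisfy the bound ...
        q = [[rng.dirichlet(np.ones(3)) for _ in range(2)] for _ in range(3)]
        fe = free_energy(model, obs, policy, q)
        assert fe.total >= neg_log_ev - 1e-10
        assert fe.total == pytest.approx(fe.energy - fe.entropy, abs=1e-10)
        # ... and the optimised beliefs give a tighter value, still a bound
        bs = infer_states(model, obs, policy, max_iters=64)
        assert neg_log_ev - 1e-10 <= bs.F <= fe.total + 1e-10

    def test_uniform_model_costs_log_outcomes_per_observation(self):
        model = gm.GenerativeModel(
            factors=[gm.Factor("s", 3)], modalities=[gm.Modality("o", 4)],
            A=[np.full((4, 3), 0.25)], B=[np.full((3, 3, 1), 1 / 3)],
            C=[np.zeros(4)], D=[np.full(3, 1 / 3)], zeta=[1.0], omega=[1.0])
        bs = infer_states(model, [(0,), (3,), (1,)], (0, 0))
        assert bs.F == pytest.approx(3 * np.log(4), abs=1e-10)

    def test_impossible_observation_is_finitely_surprising(self):
        model = single_factor_model(9, zeta=np.inf)
        model.A[0] = np.eye(3)
        model.D[0] = np.eye(3)[0]
        model._cache.clear()
        bs = infer_states(model, [(2,)], ())
        assert np.isfinite(bs.F) and bs.F > 10


class TestIterationScheme:
    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 2**20))
    def test_beliefs_stay_on_simplex(self, seed):
        model = two_factor_model(seed)
        rng = np.random.default_rng(seed)
        obs = [tuple(rng.integers(3, size=1)) for _ in range(3)]
        bs = infer_states(model, obs, tuple(rng.integers(2, size=3)))
        for t in range(4):
            for f in range(2):
                q = bs.beliefs[t][f]
                assert np.all(q >= 0) and q.sum() == pytest.approx(1, abs=1e-8)

    @pytest.mark.parametrize("seed", range(5))
    def test_sweeps_never_increase_free_energy(self, seed):
        model = two_factor_model(seed)
        rng = np.random.default_rng(seed + 1)
        obs = [tuple(rng.integers(3, size=1)) for _ in range(4)]
        bs = infer_states(model, obs, tuple(rng.integers(2, size=3)),
                          max_iters=32, track_free_energy=True)
        assert np.all(np.diff(bs.F_trace) <= 1e-6)
        assert bs.converged

    def test_non_convergence_is_flagged_not_fatal(self):
        model = two_factor_model(11)
        bs = infer_states(model, [(0,), (1,)], (0,), max_iters=1)
        assert not bs.converged
        assert np.isfinite(bs.F)

    def test_malformed_observations_rejected(self):
        model = single_factor_model(12)
        with pytest.raises(ValueError, match="out of range"):
            infer_states(model, [(7,)], ())
        with pytest.raises(ValueError, match="time steps"):
            infer_states(model, [(0,), (1,)], ())

    def test_warm_start_reaches_same_fixed_point(self):
        model = two_factor_model(13)
        obs = [(0,), (2,), (1,)]
        cold = infer_states(model, obs, (0, 1), max_iters=64)
        warm0 = infer_states(model, obs[:2], (0,), max_iters=64)
        warm = infer_states(model, obs, (0, 1), init=warm0, max_iters=64)
        for t in range(3):
            for f in range(2):
                assert np.allclose(cold.beliefs[t][f], warm.beliefs[t][f],
                                   atol=1e-5)
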