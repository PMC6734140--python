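"""Expected free energy: enumeration oracles and uncertainty-driven selection."""

import numpy as np
import pytest
from scipy.special import xlogy

import perceptsim as ps
from perceptsim.generative_model import apply_precision
from perceptsim.inference import infer_states
from perceptsim.planning import expected_free_energy, policy_posterior, \
    select_action

from conftest import single_factor_model, two_factor_model


def efe_oracle(Ah, q_pred, C):
    """Exhaustive-sum expected free energy for one step, one modality."""
    n_states = q_pred.size
    Qo = sum(q_pred[s] * Ah[:, s] for s in range(n_states))
    ambiguity = sum(q_pred[s] * -(xlogy(Ah[:, s], Ah[:, s])).sum()
                    for s in range(n_states))
    neg_pred_entropy = sum(Qo[o] * np.log(Qo[o]) for o in range(Qo.size))
    preference = -sum(Qo[o] * C[o] for o in range(Qo.size))
    return ambiguity, neg_pred_entropy, preference, Qo


class TestExpectedFreeEnergy:
    @pytest.mark.parametrize("seed", range(8))
    def test_terms_match_enumeration_oracle(self, seed):
        model = single_factor_model(seed, n_states=2, n_outcomes=2, zeta=1.3)
        rng = np.random.default_rng(seed)
        o = int(rng.integers(2))
        bs = infer_states(model, [(o,)], ())
        efe = expected_free_energy(model, bs, (0,))

        Ah = apply_precision(model.A[0], 1.3)
        Bw = apply_precision(model.B[0][:, :, 0], 1.0)
        q_pred = Bw @ bs.beliefs[0][0]
        amb, neg_h, pref, Qo = efe_oracle(Ah, q_pred, model.C[0])
        assert efe.ambiguity == pytest.approx(amb, abs=1e-10)
        assert efe.neg_predictive_entropy == pytest.approx(neg_h, abs=1e-10)
        assert efe.preference == pytest.approx(pref, abs=1e-10)
        assert efe.total == pytest.approx(amb + neg_h + pref, abs=1e-10)
        assert np.allclose(efe.predictive_outcomes[0][0], Qo, atol=1e-12)
        assert efe.predictive_outcomes[0][0].sum() == pytest.approx(1, abs=1e-10)

    def test_multi_factor_terms_match_oracle(self):
        model = two_factor_model(3)
        rng = np.random.default_rng(3)
        bs = infer_states(model, [(1,)], ())
        efe = expected_free_energy(model, bs, (1,))
        # mean-field joint over the two factors, enumerated explicitly
        Ah = model.likelihood(0)
        q0 = model.transition(0, 1) @ bs.beliefs[0][0]
        q1 = model.transition(1, 1) @ bs.beliefs[0][1]
        amb = neg_h = 0.0
        Qo = np.zeros(3)
        for i in range(3):
            for j in range(3):
                w = q0[i] * q1[j]
                col = Ah[:, i, j]
                amb += w * -(xlogy(col, col)).sum()
                Qo += w * col
        neg_h = float(xlogy(Qo, Qo).sum())
        assert efe.ambiguity == pytest.approx(amb, abs=1e-10)
        assert efe.neg_predictive_entropy == pytest.approx(neg_h, abs=1e-10)

    def test_uniform_preferences_make_preference_term_constant(
            self, troxler_explore):
        model, env = troxler_explore
        env.reset()
        bs = infer_states(model, [env.observe()], ())
        prefs = [expected_free_energy(model, bs, (u,)).preference
                 for u in range(5)]
        assert np.allclose(prefs, prefs[0], atol=1e-12)

    def test_deterministic_likelihood_has_zero_ambiguity(self):
        model = single_factor_model(1, zeta=np.inf)
        model.A[0] = np.eye(3)
        model._cache.clear()
        bs = infer_states(model, [(0,)], ())
        efe = expected_free_energy(model, bs, (0,))
        assert abs(efe.ambiguity) < 1e-8

    def test_policy_without_future_steps_rejected(self):
        model = single_factor_model(2)
        bs = infer_states(model, [(0,)], ())
        with pytest.raises(ValueError, match="future"):
            expected_free_energy(model, bs, ())


class TestPolicyPosterior:
    def test_equal_G_gives_uniform(self):
        assert np.allclose(policy_posterior([1.0, 1.0, 1.0]), 1 / 3)

    def test_softmax_of_negative_G(self):
        p = policy_posterior([1.0, 2.0], gamma=1.0)
        assert np.allclose(p, [0.7311, 0.2689], atol=1e-4)
        # independent evaluation
        assert p[0] == pytest.approx(1 / (1 + np.exp(-1)), abs=1e-12)

    def test_bias_shifts_the_posterior(self):
        p = policy_posterior([1.0, 1.0], bias=[0.0, 2.0])
        assert p[1] > p[0]
        assert p[1] / p[0] == pytest.approx(np.exp(2.0), rel=1e-10)

    def test_non_finite_G_rejected(self):
        with pytest.raises(ValueError):
            policy_posterior([np.inf, 1.0])


class TestSelectAction:
    def test_one_hot_posterior_selects_that_action(self):
        assert select_action([0, 1, 0], "argmax") == 1
        assert select_action([0, 1, 0], "sample", seed=0) == 1

    def test_exact_tie_breaks_to_lowest_index(self):
        assert select_action([0.25, 0.25, 0.25, 0.25], "argmax") == 0

    def test_sampling_reproducible_for_fixed_seed(self):
        p = [0.3, 0.3, 0.4]
        a = [select_action(p, "sample", seed=42) for _ in range(10)]
        b = [select_action(p, "sample", seed=42) for _ in range(10)]
        assert a == b

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            select_action([1.0], "greedy")


class TestUncertaintyDrivenSelection:
    def test_explore_targets_the_most_uncertain_quadrant(self, troxler_explore):
        model, env = troxler_explore
        record = ps.run_simulation(model, env, 12)
        for t in range(1, 12):
            a = record.actions[t]
            assert a >= 1  # the uninformative centre is never chosen
            quadrant_H = record.entropies[t, :4]
            assert quadrant_H[a - 1] >= quadrant_H.max() - 1e-9

    def test_just_fixated_location_loses_salience(self, troxler_explore):
        model, env = troxler_explore
        record = ps.run_simulation(model, env, 50)
        assert all(record.actions[t] != record.actions[t - 1]
                   for t in range(1, 50))

    def test_rivalry_attends_the_most_uncertain_feature(self, rivalry_record):
        rec = rivalry_record
        for t in range(1, rec.horizon):
            assert rec.actions[t] == int(np.argmax(rec.entropies[t, :2]))
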