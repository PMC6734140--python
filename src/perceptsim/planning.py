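"""Expected free energy and policy selection.

Candidate policies are scored by the expected free energy ``G``, which splits
into three terms per future time step and outcome modality:

* **ambiguity** — the expected conditional entropy of the likelihood mapping
  under the predicted states; a noisy mapping yields little information no
  matter what is observed;
* **negative predictive entropy** — minus the entropy of the predicted outcome
  distribution; outcomes the agent cannot yet predict carry epistemic value, so
  high predictive entropy lowers ``G``;
* **preference** — minus the expected log-preference ``C`` of predicted
  outcomes (pragmatic value).

Policies are a priori more probable when ``G`` is low: the policy posterior is
a softmax of ``-gamma * G`` plus any fixed log-prior bias over actions (the
device used to model a rightward saccade bias in neglect).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import softmax, xlogy

from .generative_model import GenerativeModel, expect_states
from .inference import BeliefState

__all__ = ["EFEDecomposition", "expected_free_energy", "policy_posterior",
           "select_action"]


@dataclass
class EFEDecomposition:
    """Expected free energy of one policy, decomposed (all in nats).

    ``total = ambiguity + neg_predictive_entropy + preference`` summed over the
    policy's future time steps and all outcome modalities.
    """

    ambiguity: float
    neg_predictive_entropy: float
    preference: float
    total: float
    predictive_states: list[list[np.ndarray]]
    predictive_outcomes: list[list[np.ndarray]]

    @property
    def predictive_entropy(self) -> float:
        return -self.neg_predictive_entropy


def expected_free_energy(model: GenerativeModel, beliefs: BeliefState,
                         policy=None) -> EFEDecomposition:
    """Score a policy's future steps by expected free energy.

    Predictive state distributions for times beyond the observed horizon are
    obtained by forward propagation through the precision-weighted transitions,
    starting from the last observed beliefs.
    """
    policy = beliefs.policy if policy is None else tuple(int(u) for u in policy)
    n_obs = beliefs.n_observed
    T = len(policy)
    future = list(range(n_obs, T + 1))
    if not future:
        raise ValueError("policy has no future steps beyond the observed horizon")
    if n_obs > 0:
        if policy[:n_obs - 1] != beliefs.policy[:n_obs - 1]:
            raise ValueError("policy disagrees with beliefs over observed steps")
        q_prev = beliefs.beliefs[n_obs - 1]
    else:
        q_prev = None

    ambiguity = 0.0
    neg_pred_entropy = 0.0
    preference = 0.0
    pred_states: list[list[np.ndarray]] = []
    pred_outcomes: list[list[np.ndarray]] = []
    for t in future:
        if t == 0:
            q_t = [model.D[f].copy() for f in range(model.n_factors)]
        else:
            q_t = [model.transition(f, policy[t - 1]) @ q_prev[f]
                   for f in range(model.n_factors)]
        o_t = []
        for m in range(model.n_modalities):
            Qo = expect_states(model.likelihood(m), q_t, leading=1)
            ambiguity += float(expect_states(model.column_entropy(m), q_t))
            neg_pred_entropy += float(xlogy(Qo, Qo).sum())
            preference -= float(model.C[m] @ Qo)
            o_t.append(Qo)
        pred_states.append(q_t)
        pred_outcomes.append(o_t)
        q_prev = q_t

    return EFEDecomposition(
        ambiguity=ambiguity,
        neg_predictive_entropy=neg_pred_entropy,
        preference=preference,
        total=ambiguity + neg_pred_entropy + preference,
        predictive_states=pred_states,
        predictive_outcomes=pred_outcomes)


def policy_posterior(G, bias=None, gamma: float = 1.0) -> np.ndarray:
    """Softmax policy posterior ``sigma(-gamma * G + bias)``."""
    G = np.asarray(G, dtype=float)
    if not np.all(np.isfinite(G)):
        raise ValueError("expected free energies must be finite")
    if gamma < 0:
        raise ValueError("gamma must be non-negative")
    if bias is None:
        bias = np.zeros_like(G)
    return softmax(-gamma * G + np.asarray(bias, dtype=float))


def select_action(posterior, mode: str = "argmax", rng=None, seed=None) -> int:
    """Pick an action from a policy posterior.

    ``argmax`` is deterministic; exact ties resolve to the lowest action index.
    ``sample`` draws from the posterior with the provided generator or seed.
    """
    p = np.asarray(posterior, dtype=float)
    if mode == "argmax":
        return int(np.argmax(p))
    if mode == "sample":
        if rng is None:
            rng = np.random.default_rng(seed)
        return int(rng.choice(p.size, p=p / p.sum()))
    raise ValueError(f"unknown selection mode {mode!r}")
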