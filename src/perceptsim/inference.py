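"""Variational state estimation for policy-conditioned categorical models.

Perception is cast as free-energy minimisation under a structured mean-field
posterior: beliefs factorise across hidden-state factors, but each factor
keeps its full temporal chain.  One update solves a factor's chain exactly by
forward-backward message passing, with the likelihood evidence at each
observed time marginalised over the *current* beliefs about the other factors
(an expected log-likelihood, turned back into an evidence vector).  Each such
update is the exact coordinate minimiser of the variational free energy, so
sweeps over factors can never increase the objective; iteration stops when no
marginal moves by more than ``tol``.

Times beyond the last observation carry no evidence, so their beliefs are the
forward-propagated predictive distributions — exactly what expected free
energy (the planning quantity) needs.  A one-time-step problem reduces to
Bayes' rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import xlogy

from .generative_model import GenerativeModel, expect_states, log_stable

__all__ = ["BeliefState", "FreeEnergy", "infer_states", "free_energy"]


@dataclass
class FreeEnergy:
    """Variational free energy and its energy/entropy decomposition (nats).

    ``total = energy - entropy`` where ``energy = -E_Q[ln P(o, s | policy)]``
    and ``entropy = H[Q]``, both accumulated over observed time steps.
    """

    total: float
    energy: float
    entropy: float


@dataclass
class BeliefState:
    """Posterior beliefs under one policy, with convergence diagnostics.

    ``beliefs[t][f]`` is the marginal over factor ``f`` at time ``t``; times
    at or beyond ``n_observed`` are predictive.  ``pairwise[t][f]`` (``t >=
    1``) is the joint over factor ``f`` at times ``(t-1, t)``, used for the
    chain entropy in the free energy.  ``epsilon[t][f]`` holds the final
    log-space belief updates (free-energy gradients, zero at a fixed point).
    ``F_trace`` records the variational objective after each sweep when
    tracking is enabled; it includes the predictive-horizon terms and
    coincides with ``F`` when every time step is observed.
    """

    beliefs: list[list[np.ndarray]]
    policy: tuple[int, ...]
    n_observed: int
    pairwise: list[list[np.ndarray | None]] | None = None
    F: float = np.nan
    energy: float = np.nan
    entropy: float = np.nan
    epsilon: list[list[np.ndarray]] = field(default_factory=list)
    F_trace: np.ndarray | None = None
    iterations: int = 0
    converged: bool = False
    max_delta: float = np.inf

    @property
    def horizon(self) -> int:
        return len(self.beliefs) - 1

    def marginal(self, t: int, f: int) -> np.ndarray:
        return self.beliefs[t][f]


def _check_observations(model: GenerativeModel, observations) -> np.ndarray:
    obs = np.asarray(observations, dtype=int)
    if obs.size == 0:
        return obs.reshape(0, model.n_modalities)
    obs = np.atleast_2d(obs)
    if obs.shape[1] != model.n_modalities:
        raise ValueError(
            f"observations must have one column per modality "
            f"({model.n_modalities}), got shape {obs.shape}")
    for m, mod in enumerate(model.modalities):
        col = obs[:, m]
        if col.min() < 0 or col.max() >= mod.cardinality:
            raise ValueError(f"observation out of range for modality {mod.name!r}")
    return obs


def _init_beliefs(model: GenerativeModel, policy: tuple[int, ...],
                  init: "BeliefState | None") -> list[list[np.ndarray]]:
    n_times = len(policy) + 1
    q: list[list[np.ndarray]] = []
    prev = init.beliefs if init is not None else []
    for t in range(n_times):
        if t < len(prev) and all(prev[t][f].shape == (model.factors[f].cardinality,)
                                 for f in range(model.n_factors)):
            q.append([prev[t][f].copy() for f in range(model.n_factors)])
        elif t == 0:
            q.append([model.D[f].copy() for f in range(model.n_factors)])
        else:
            q.append([model.transition(f, policy[t - 1]) @ q[t - 1][f]
                      for f in range(model.n_factors)])
    return q


def _normalise(v: np.ndarray) -> np.ndarray:
    s = v.sum()
    if s <= 0:
        return np.full_like(v, 1.0 / v.size)
    return v / s


def _log_evidence(model: GenerativeModel, obs_t: np.ndarray,
                  q_t: list[np.ndarray], f: int) -> np.ndarray:
    msg = np.zeros(model.factors[f].cardinality)
    for m in range(model.n_modalities):
        lnA = model.log_likelihood(m)[int(obs_t[m])]
        msg += expect_states(lnA, q_t, keep=(f,))
    return msg


def _chain_update(model: GenerativeModel, f: int, policy: tuple[int, ...],
                  ev: list[np.ndarray | None], n_times: int
                  ) -> tuple[list[np.ndarray], list[np.ndarray | None]]:
    """Exact smoothing of factor ``f``'s chain given evidence vectors ``ev``."""
    Bs = [model.transition(f, policy[t - 1]) for t in range(1, n_times)]
    alpha: list[np.ndarray] = []
    a = model.D[f] * ev[0] if ev[0] is not None else model.D[f].copy()
    alpha.append(_normalise(a))
    for t in range(1, n_times):
        a = Bs[t - 1] @ alpha[t - 1]
        if ev[t] is not None:
            a = a * ev[t]
        alpha.append(_normalise(a))
    beta = [None] * n_times
    beta[n_times - 1] = np.ones(model.factors[f].cardinality)
    marginals = [None] * n_times
    pairwise: list[np.ndarray | None] = [None] * n_times
    marginals[n_times - 1] = alpha[n_times - 1]
    for t in range(n_times - 2, -1, -1):
        c = beta[t + 1] if ev[t + 1] is None else beta[t + 1] * ev[t + 1]
        beta[t] = _normalise(Bs[t].T @ c)
        marginals[t] = _normalise(alpha[t] * beta[t])
    for t in range(1, n_times):
        c = beta[t] if ev[t] is None else beta[t] * ev[t]
        M = Bs[t - 1] * alpha[t - 1][None, :] * c[:, None]
        pairwise[t] = M / M.sum()
    return marginals, pairwise


def infer_states(model: GenerativeModel, observations, policy,
                 *, tol: float = 1e-6, max_iters: int = 16,
                 init: BeliefState | None = None,
                 track_free_energy: bool = False) -> BeliefState:
    """Estimate posteriors over hidden states under one policy.

    Parameters
    ----------
    observations
        Sequence of outcome-index tuples for times ``0 .. T_obs - 1``.
    policy
        Action sequence; beliefs are computed for times ``0 .. len(policy)``,
        with times at or beyond ``T_obs`` purely predictive.
    init
        Optional previous :class:`BeliefState` used as a warm start.
    track_free_energy
        If true, evaluate the variational objective after every sweep
        (``F_trace``).

    Non-convergence within ``max_iters`` sweeps is flagged on the returned
    state, not raised.  Evidence vectors are cached per time step and only
    recomputed when another factor's belief there has moved; the fixed point
    is unaffected.
    """
    obs = _check_observations(model, observations)
    policy = tuple(int(u) for u in policy)
    n_actions = model.n_actions
    for u in policy:
        if not 0 <= u < n_actions:
            raise ValueError(f"action {u} out of range (n_actions={n_actions})")
    n_times = len(policy) + 1
    t_obs = obs.shape[0]
    if t_obs > n_times:
        raise ValueError(
            f"{t_obs} observations but only {n_times} time steps under this policy")

    nf = model.n_factors
    q = _init_beliefs(model, policy, init)
    pair: list[list[np.ndarray | None]] = [[None] * nf for _ in range(n_times)]
    eps = [[np.zeros(model.factors[f].cardinality) for f in range(nf)]
           for _ in range(n_times)]
    ev_cache: list[list[np.ndarray | None]] = [[None] * nf for _ in range(t_obs)]
    stale = [[True] * nf for _ in range(t_obs)]

    F_trace: list[float] = []
    converged = False
    delta = np.inf
    it = 0
    for it in range(1, max_iters + 1):
        delta = 0.0
        for f in range(nf):
            ev: list[np.ndarray | None] = [None] * n_times
            for t in range(t_obs):
                if stale[t][f] or ev_cache[t][f] is None:
                    lg = _log_evidence(model, obs[t], q[t], f)
                    ev_cache[t][f] = np.exp(lg - lg.max())
                    stale[t][f] = False
                ev[t] = ev_cache[t][f]
            marginals, pairwise = _chain_update(model, f, policy, ev, n_times)
            for t in range(n_times):
                change = float(np.abs(marginals[t] - q[t][f]).max())
                if change > 0.1 * tol and t < t_obs:
                    for g in range(nf):
                        if g != f:
                            stale[t][g] = True
                eps[t][f] = log_stable(marginals[t]) - log_stable(q[t][f])
                delta = max(delta, change)
                q[t][f] = marginals[t]
                pair[t][f] = pairwise[t]
        if track_free_energy:
            F_trace.append(_objective(model, obs, policy, q, pair, n_times))
        if delta < tol:
            converged = True
            break

    fe = free_energy(model, obs, policy,
                     BeliefState(beliefs=q, policy=policy, n_observed=t_obs,
                                 pairwise=pair))
    return BeliefState(
        beliefs=q, policy=policy, n_observed=t_obs, pairwise=pair,
        F=fe.total, energy=fe.energy, entropy=fe.entropy,
        epsilon=eps, F_trace=np.asarray(F_trace) if track_free_energy else None,
        iterations=it, converged=converged, max_delta=delta)


def _entropy(p: np.ndarray) -> float:
    return -float(xlogy(p, p).sum())


def _accumulate(model: GenerativeModel, obs: np.ndarray, policy: tuple[int, ...],
                q, pair, n_times: int) -> tuple[float, float]:
    """(energy, entropy) of the variational objective over ``n_times`` steps.

    When pairwise chain marginals are available the entropy is the exact chain
    entropy of the structured posterior; otherwise the fully factorised
    (mean-field) expressions are used.
    """
    t_obs = obs.shape[0]
    energy = 0.0
    entropy = 0.0
    for f in range(model.n_factors):
        q0 = q[0][f]
        entropy += _entropy(q0)
        energy -= float(q0 @ log_stable(model.D[f]))
        for t in range(1, n_times):
            lnB = log_stable(model.transition(f, policy[t - 1]))
            xi = pair[t][f] if pair is not None else None
            if xi is not None:
                entropy += _entropy(xi.ravel()) - _entropy(q[t - 1][f])
                energy -= float((xi * lnB).sum())
            else:
                entropy += _entropy(q[t][f])
                energy -= float(q[t][f] @ (lnB @ q[t - 1][f]))
    for t in range(min(t_obs, n_times)):
        for m in range(model.n_modalities):
            lnA = model.log_likelihood(m)[int(obs[t, m])]
            energy -= float(expect_states(lnA, q[t]))
    return energy, entropy


def _objective(model: GenerativeModel, obs, policy, q, pair, n_times: int) -> float:
    energy, entropy = _accumulate(model, obs, policy, q, pair, n_times)
    return energy - entropy


def free_energy(model: GenerativeModel, observations, policy, beliefs) -> FreeEnergy:
    """Variational free energy of ``beliefs`` given the observations (nats).

    ``F = E_Q[ln Q - ln P(o, s | policy)]`` accumulated over observed time
    steps.  ``beliefs`` may be a :class:`BeliefState` (whose chain structure is
    used exactly) or a nested ``[t][f]`` list of marginals, in which case the
    fully factorised mean-field expression is evaluated.  ``F`` upper-bounds
    the negative log evidence ``-ln P(o)``, with equality at the exact
    posterior.  Observations that are impossible under the model contribute a
    large finite surprise through the ``e^-16`` log floor.
    """
    obs = _check_observations(model, observations)
    policy = tuple(int(u) for u in policy)
    if isinstance(beliefs, BeliefState):
        q, pair = beliefs.beliefs, beliefs.pairwise
    else:
        q, pair = beliefs, None
    t_obs = obs.shape[0]
    if t_obs > len(q):
        raise ValueError("beliefs do not cover all observed time steps")
    energy, entropy = _accumulate(model, obs, policy, q, pair, t_obs)
    return FreeEnergy(total=energy - entropy, energy=energy, entropy=entropy)
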