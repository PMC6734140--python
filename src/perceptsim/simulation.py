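"""The generative process and the perception–action loop.

The :class:`Environment` is the *true* mechanics producing observations,
deliberately distinct from the agent's generative model: its mappings are
deterministic one-hot arrays with no precision degradation, so the stimulus is
static throughout a trial and only the agent's beliefs are uncertain.  Each
simulation step observes the environment, infers hidden states, scores every
candidate action by expected free energy, selects an action, and applies it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import xlogy

from .generative_model import Factor, GenerativeModel, Modality
from .inference import BeliefState, infer_states
from .planning import EFEDecomposition, expected_free_energy, policy_posterior, \
    select_action

__all__ = ["Environment", "SimulationRecord", "env_step", "run_simulation"]

#: Nominal duration of one discrete time step, in seconds.  Used only by the
#: analysis conversions to continuous time (a theta cycle is ~250 ms).
DEFAULT_DT = 0.25


@dataclass(eq=False)
class Environment:
    """The true generative process: deterministic mappings, true hidden states."""

    factors: list[Factor]
    modalities: list[Modality]
    A: list[np.ndarray]
    B: list[np.ndarray]
    initial_states: tuple[int, ...]
    name: str = "custom"

    def __post_init__(self) -> None:
        self.A = [np.asarray(a, dtype=float) for a in self.A]
        self.B = [np.asarray(b, dtype=float) for b in self.B]
        for m, A in enumerate(self.A):
            cols = A.reshape(A.shape[0], -1)
            if not (np.isclose(cols.max(axis=0), 1.0).all()
                    and np.isclose(cols.sum(axis=0), 1.0).all()):
                raise ValueError(f"environment mapping A[{m}] must have one-hot columns")
        self.states: list[int] = list(self.initial_states)
        self.t = 0

    def reset(self) -> None:
        self.states = list(self.initial_states)
        self.t = 0

    def observe(self) -> tuple[int, ...]:
        """Outcome indices emitted by the true mappings at the current state."""
        return tuple(int(np.argmax(A[(slice(None), *self.states)])) for A in self.A)

    def step(self, action: int) -> tuple[int, ...]:
        """Apply the true transitions and emit the next observation."""
        n_u = max(b.shape[2] for b in self.B)
        if not 0 <= int(action) < n_u:
            raise ValueError(f"action {action} out of range")
        new = []
        for f, (fac, B) in enumerate(zip(self.factors, self.B)):
            u = int(action) if fac.controllable else 0
            new.append(int(np.argmax(B[:, self.states[f], u])))
        self.states = new
        self.t += 1
        return self.observe()


def env_step(env: Environment, action: int) -> tuple[int, ...]:
    """Advance the generative process by one action; returns outcome indices."""
    return env.step(action)


@dataclass(eq=False)
class SimulationRecord:
    """Everything observed, believed and chosen during one trial.

    ``beliefs[t][f]`` is the agent's marginal over factor ``f`` at time ``t``
    (computed online, i.e. from observations up to and including ``t``).
    ``efe_terms[t, u]`` holds ``(ambiguity, -predictive entropy, preference,
    total G)`` for candidate action ``u`` evaluated at time ``t``.
    """

    paradigm: str
    factors: list[Factor]
    modalities: list[Modality]
    observations: np.ndarray
    actions: np.ndarray
    beliefs: list[list[np.ndarray]]
    entropies: np.ndarray
    efe_terms: np.ndarray
    policy_posteriors: np.ndarray
    free_energies: np.ndarray
    dt: float
    mode: str
    seed: int
    gamma: float
    action_labels: list[str] | None = None
    metadata: dict = field(default_factory=dict)

    @property
    def horizon(self) -> int:
        return len(self.actions)

    def belief_array(self, f: int) -> np.ndarray:
        """Beliefs about factor ``f`` stacked over time, shape (T, cardinality)."""
        return np.stack([self.beliefs[t][f] for t in range(self.horizon)])

    # -- tidy exports ----------------------------------------------------
    def steps_frame(self) -> pd.DataFrame:
        rows = {}
        rows["time"] = np.arange(self.horizon)
        for m, mod in enumerate(self.modalities):
            rows[f"obs_{mod.name}"] = self.observations[:, m]
        rows["action"] = self.actions
        if self.action_labels:
            rows["action_label"] = [self.action_labels[a] for a in self.actions]
        rows["free_energy"] = self.free_energies
        n_u = self.policy_posteriors.shape[1]
        for u in range(n_u):
            label = self.action_labels[u] if self.action_labels else str(u)
            rows[f"G_{label}"] = self.efe_terms[:, u, 3]
            rows[f"p_{label}"] = self.policy_posteriors[:, u]
        return pd.DataFrame(rows)

    def beliefs_frame(self) -> pd.DataFrame:
        recs = []
        for t in range(self.horizon):
            for f, fac in enumerate(self.factors):
                q = self.beliefs[t][f]
                for s in range(fac.cardinality):
                    label = fac.labels[s] if fac.labels else str(s)
                    recs.append((t, fac.name, s, label, q[s], self.entropies[t, f]))
        return pd.DataFrame(recs, columns=["time", "factor", "state", "state_label",
                                           "probability", "entropy"])

    def manifest(self) -> dict:
        import perceptsim
        import scipy
        return {
            "paradigm": self.paradigm,
            "horizon": int(self.horizon),
            "seed": int(self.seed),
            "mode": self.mode,
            "gamma": float(self.gamma),
            "dt": float(self.dt),
            "metadata": self.metadata,
            "versions": {
                "perceptsim": perceptsim.__version__,
                "numpy": np.__version__,
                "scipy": scipy.__version__,
                "pandas": pd.__version__,
            },
        }

    def save(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.steps_frame().to_csv(outdir / "steps.csv", index=False)
        self.beliefs_frame().to_csv(outdir / "beliefs.csv", index=False)
        (outdir / "manifest.json").write_text(
            json.dumps(self.manifest(), indent=2, sort_keys=True))


def run_simulation(model: GenerativeModel, env: Environment, horizon: int,
                   *, mode: str = "argmax", seed: int = 0, gamma: float = 16.0,
                   tol: float = 1e-6, max_iters: int = 16,
                   dt: float = DEFAULT_DT, metadata: dict | None = None
                   ) -> SimulationRecord:
    """Run one closed-loop trial of ``horizon`` steps.

    Each step runs observe -> infer_states -> expected_free_energy per
    candidate action -> policy_posterior -> select_action -> env_step.  The
    result is bit-reproducible for a given seed and mode.
    """
    report = model.validate()
    if not report:
        raise ValueError("invalid model: " + "; ".join(report.violations))
    if horizon < 1:
        raise ValueError("horizon must be at least 1")

    rng = np.random.default_rng(seed)
    env.reset()
    n_u = model.n_actions
    nf = model.n_factors

    observations: list[tuple[int, ...]] = [env.observe()]
    actions: list[int] = []
    beliefs: list[list[np.ndarray]] = []
    entropies = np.zeros((horizon, nf))
    efe_terms = np.zeros((horizon, n_u, 4))
    posteriors = np.zeros((horizon, n_u))
    free_energies = np.zeros(horizon)

    bs: BeliefState | None = None
    for t in range(horizon):
        bs = infer_states(model, observations, tuple(actions),
                          tol=tol, max_iters=max_iters, init=bs)
        q_t = [bs.beliefs[t][f].copy() for f in range(nf)]
        beliefs.append(q_t)
        entropies[t] = [-float(xlogy(q, q).sum()) for q in q_t]
        free_energies[t] = bs.F

        G = np.zeros(n_u)
        for u in range(n_u):
            efe: EFEDecomposition = expected_free_energy(
                model, bs, tuple(actions) + (u,))
            efe_terms[t, u] = (efe.ambiguity, efe.neg_predictive_entropy,
                               efe.preference, efe.total)
            G[u] = efe.total
        posteriors[t] = policy_posterior(G, model.policy_bias, gamma)
        a = select_action(posteriors[t], mode=mode, rng=rng)
        actions.append(a)
        if t < horizon - 1:
            observations.append(env.step(a))

    return SimulationRecord(
        paradigm=model.name,
        factors=list(model.factors),
        modalities=list(model.modalities),
        observations=np.asarray(observations, dtype=int),
        actions=np.asarray(actions, dtype=int),
        beliefs=beliefs,
        entropies=entropies,
        efe_terms=efe_terms,
        policy_posteriors=posteriors,
        free_energies=free_energies,
        dt=dt, mode=mode, seed=seed, gamma=gamma,
        action_labels=list(model.action_labels) if model.action_labels else None,
        metadata=metadata or {})
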