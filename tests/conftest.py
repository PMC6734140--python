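"""Shared fixtures and small model factories."""

from __future__ import annotations

import numpy as np
import pytest

import perceptsim as ps
import perceptsim.generative_model as gm


def random_stochastic(rng, n_rows: int, n_cols: int) -> np.ndarray:
    """A random column-stochastic matrix with strictly positive entries."""
    return rng.dirichlet(np.ones(n_rows), size=n_cols).T


def single_factor_model(seed: int, n_states: int = 3, n_outcomes: int = 3,
                        zeta: float = 1.0, omega: float = 1.0
                        ) -> gm.GenerativeModel:
    """A one-factor, one-modality model with random positive A, B and D."""
    rng = np.random.default_rng(seed)
    return gm.GenerativeModel(
        factors=[gm.Factor("state", n_states)],
        modalities=[gm.Modality("outcome", n_outcomes)],
        A=[random_stochastic(rng, n_outcomes, n_states)],
        B=[random_stochastic(rng, n_states, n_states)[:, :, None]],
        C=[rng.normal(size=n_outcomes)],
        D=[rng.dirichlet(np.ones(n_states))],
        zeta=[zeta], omega=[omega])


def two_factor_model(seed: int, n_states: int = 3, n_outcomes: int = 3,
                     n_actions: int = 2) -> gm.GenerativeModel:
    """A two-factor model (first factor controllable) with random mappings."""
    rng = np.random.default_rng(seed)
    dims = (n_states, n_states)
    A = rng.dirichlet(np.ones(n_outcomes), size=dims)
    A = np.moveaxis(A, -1, 0)
    B0 = np.stack([random_stochastic(rng, n_states, n_states)
                   for _ in range(n_actions)], axis=2)
    B1 = random_stochastic(rng, n_states, n_states)[:, :, None]
    return gm.GenerativeModel(
        factors=[gm.Factor("ctrl", n_states, controllable=True),
                 gm.Factor("stim", n_states)],
        modalities=[gm.Modality("outcome", n_outcomes)],
        A=[A], B=[B0, B1],
        C=[np.zeros(n_outcomes)],
        D=[rng.dirichlet(np.ones(n_states)) for _ in range(2)],
        zeta=[1.5], omega=[1.0, 1.0])


@pytest.fixture(scope="session")
def troxler_explore():
    model, env = ps.build_troxler_model(ps.TroxlerSpec(condition="explore"))
    return model, env


@pytest.fixture(scope="session")
def troxler_fixate_record():
    model, env = ps.build_troxler_model(ps.TroxlerSpec(condition="fixate"))
    return ps.run_simulation(model, env, 16)


@pytest.fixture(scope="session")
def rivalry_record():
    model, env = ps.build_rivalry_model(ps.RivalrySpec())
    return ps.run_simulation(model, env, 16)
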