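"""Builders for the three study paradigms.

Each builder turns a small parameter set into a matched pair: the agent's
:class:`~perceptsim.generative_model.GenerativeModel` (precision-weighted
beliefs) and the :class:`~perceptsim.simulation.Environment` (the deterministic
true process).  The two share structure and initial states; only the model
carries precisions.

* **Troxler** — four peripheral colour patches and a central fixation cross.
  Five hidden factors (one colour per quadrant plus fixation location), one
  visual modality.  Saccades choose which quadrant's colour is observed.
  Conditions: ``explore`` (uniform preferences, free visual foraging),
  ``fixate`` (a preference boost for seeing the cross keeps gaze central and
  the periphery fades), ``neglect`` (a log-prior bias towards rightward
  saccades starves the left visual field of fixations).
* **Rivalry** — two stimulus-presence factors ("L" and "R") plus a covert
  attentional factor.  Attention has no effect on the data; it selects which
  modality's likelihood the agent treats as precise.  The unattended modality
  is imprecise (default precision 0, i.e. fully uninformative).
* **Necker** — structurally identical to rivalry with states and outcomes
  relabelled as cube-from-above / cube-from-below and their telltale vertices.
"""

from __future__ import annotations

from typing import Literal

import numpy as np
from pydantic import BaseModel, ConfigDict, Field

from .generative_model import Factor, GenerativeModel, Modality, StatePrecision
from .simulation import Environment

__all__ = ["TroxlerSpec", "RivalrySpec", "build_troxler_model",
           "build_rivalry_model", "build_necker_model", "QUADRANTS"]

#: Quadrant order used for the Troxler factors (left pair first, then right).
QUADRANTS = ("upper-left", "lower-left", "upper-right", "lower-right")
#: Indices (into the action set, after the centre action) of rightward saccades.
RIGHTWARD_ACTIONS = (3, 4)


class TroxlerSpec(BaseModel):
    """Parameters of the Troxler-fading paradigm.

    ``omega_stim`` is the transition precision the agent ascribes to the colour
    factors (lower = a more changeable world = faster fading); the fixation
    factor's transitions are always treated as infinitely precise.
    ``fixate_preference`` (nats) is added to the preference for the central
    cross in the ``fixate`` condition; ``neglect_bias`` (nats) is added to the
    log-prior of rightward saccade actions in the ``neglect`` condition.
    """

    model_config = ConfigDict(extra="forbid")

    n_colours: int = Field(default=4, ge=2)
    omega_stim: float = Field(default=0.5, ge=0)
    zeta_vis: float = Field(default=8.0, ge=0)
    condition: Literal["explore", "fixate", "neglect"] = "explore"
    fixate_preference: float = Field(default=4.0, ge=0)
    neglect_bias: float = Field(default=2.0, ge=0)
    horizon: int = Field(default=16, ge=2)
    seed: int = 0


class RivalrySpec(BaseModel):
    """Parameters of the binocular-rivalry (and Necker) paradigm.

    ``zeta_L``/``zeta_R`` are the likelihood precisions of each modality when
    its stimulus is attended; ``zeta_unattended`` applies otherwise (0 means
    the unattended signal is treated as pure noise).  ``include_attend_away``
    adds a third attentional policy directed at neither stimulus.
    """

    model_config = ConfigDict(extra="forbid")

    zeta_L: float = Field(default=4.0, ge=0)
    zeta_R: float = Field(default=4.0, ge=0)
    zeta_unattended: float = Field(default=0.0, ge=0)
    omega_stim: float = Field(default=0.5, ge=0)
    include_attend_away: bool = False
    horizon: int = Field(default=16, ge=2)
    seed: int = 0


def _deterministic_control(n_states: int, n_actions: int) -> np.ndarray:
    """Transitions sending every state to the action's target with probability 1."""
    B = np.zeros((n_states, n_states, n_actions))
    for u in range(n_actions):
        B[u, :, u] = 1.0
    return B


def build_troxler_model(spec: TroxlerSpec) -> tuple[GenerativeModel, Environment]:
    """Construct the Troxler generative model and its environment."""
    n = spec.n_colours
    colour_labels = tuple(f"colour-{c}" for c in range(n))
    fix_labels = ("centre",) + QUADRANTS
    factors = [Factor(f"{q}-colour", n, labels=colour_labels) for q in QUADRANTS]
    factors.append(Factor("fixation", 5, controllable=True, labels=fix_labels))
    outcome_labels = colour_labels + ("cross",)
    modalities = [Modality("visual", n + 1, labels=outcome_labels)]
    cross = n

    # Visual outcome: the fixated quadrant's colour, or the cross at centre.
    A = np.zeros((n + 1,) + (n,) * 4 + (5,))
    A[cross, ..., 0] = 1.0
    for q in range(4):
        for c in range(n):
            idx: list = [slice(None)] * 4
            idx[q] = c
            A[(c, *idx, q + 1)] = 1.0

    B = [np.eye(n)[:, :, None] for _ in range(4)]
    B.append(_deterministic_control(5, 5))

    C = np.zeros(n + 1)
    if spec.condition == "fixate":
        C[cross] = spec.fixate_preference

    true_colours = [q % n for q in range(4)]
    D = [np.eye(n)[c] for c in true_colours]
    D.append(np.eye(5)[0])

    policy_bias = np.zeros(5)
    if spec.condition == "neglect":
        for u in RIGHTWARD_ACTIONS:
            policy_bias[u] = spec.neglect_bias

    action_labels = ["saccade-centre"] + [f"saccade-{q}" for q in QUADRANTS]
    model = GenerativeModel(
        factors=factors, modalities=modalities,
        A=[A], B=B, C=[C], D=D,
        zeta=[spec.zeta_vis],
        omega=[spec.omega_stim] * 4 + [np.inf],
        policy_bias=policy_bias,
        action_labels=action_labels,
        name="troxler")
    env = Environment(
        factors=factors, modalities=modalities,
        A=[A.copy()], B=[b.copy() for b in B],
        initial_states=tuple(true_colours) + (0,),
        name="troxler")
    return model, env


def _build_attention_model(spec: RivalrySpec, *, name: str,
                           factor_names: tuple[str, str],
                           modality_names: tuple[str, str],
                           attend_labels: tuple[str, str, str]
                           ) -> tuple[GenerativeModel, Environment]:
    n_att = 3 if spec.include_attend_away else 2
    att_labels = attend_labels[:n_att]
    presence = ("absent", "present")
    factors = [
        Factor(factor_names[0], 2, labels=presence),
        Factor(factor_names[1], 2, labels=presence),
        Factor("attention", n_att, controllable=True, labels=att_labels),
    ]
    modalities = [Modality(modality_names[0], 2, labels=presence),
                  Modality(modality_names[1], 2, labels=presence)]

    # Identity from each presence factor to its signal; attention only enters
    # through the state-dependent likelihood precisions.
    A0 = np.zeros((2, 2, 2, n_att))
    A1 = np.zeros((2, 2, 2, n_att))
    for o in range(2):
        A0[o, o, :, :] = 1.0
        A1[o, :, o, :] = 1.0

    B = [np.eye(2)[:, :, None], np.eye(2)[:, :, None],
         _deterministic_control(n_att, n_att)]
    C = [np.zeros(2), np.zeros(2)]
    D = [np.eye(2)[1], np.eye(2)[1], np.eye(n_att)[0]]

    unatt = spec.zeta_unattended
    zeta = [
        StatePrecision("attention", (spec.zeta_L, unatt, unatt)[:n_att]),
        StatePrecision("attention", (unatt, spec.zeta_R, unatt)[:n_att]),
    ]

    model = GenerativeModel(
        factors=factors, modalities=modalities,
        A=[A0, A1], B=B, C=C, D=D,
        zeta=zeta, omega=[spec.omega_stim, spec.omega_stim, np.inf],
        policy_bias=np.zeros(n_att),
        action_labels=list(att_labels),
        name=name)
    env = Environment(
        factors=factors, modalities=modalities,
        A=[A0.copy(), A1.copy()], B=[b.copy() for b in B],
        initial_states=(1, 1, 0),
        name=name)
    return model, env


def build_rivalry_model(spec: RivalrySpec) -> tuple[GenerativeModel, Environment]:
    """Construct the binocular-rivalry model: both stimuli are truly present."""
    return _build_attention_model(
        spec, name="rivalry",
        factor_names=("L-presence", "R-presence"),
        modality_names=("L-signal", "R-signal"),
        attend_labels=("attend-L", "attend-R", "attend-away"))


def build_necker_model(spec: RivalrySpec) -> tuple[GenerativeModel, Environment]:
    """The rivalry model relabelled for Necker-cube multi-stable perception."""
    return _build_attention_model(
        spec, name="necker",
        factor_names=("cube-above", "cube-below"),
        modality_names=("above-vertex", "below-vertex"),
        attend_labels=("attend-above", "attend-below", "attend-away"))
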