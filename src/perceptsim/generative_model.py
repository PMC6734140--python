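"""Categorical generative models with precision-weighted likelihoods and transitions.

A model couples hidden-state *factors* (independent latent dimensions such as the
colour shown in one visual quadrant, the current fixation target, or an attentional
focus) to outcome *modalities* (observation channels) through four kinds of
probability array:

``A``
    per modality, the likelihood of each outcome given the joint hidden-state
    configuration (columns over outcomes are normalised);
``B``
    per factor, the state-transition probabilities from one time step to the next,
    with one slice per action for factors under the agent's control;
``C``
    per modality, log-preferences over outcomes (pragmatic value);
``D``
    per factor, the prior over the initial state.

Likelihoods and transitions additionally carry precision (inverse-temperature)
parameters ``zeta`` and ``omega``.  The mapping the agent actually uses is a
column-wise softmax of ``p * ln(M + e^-4)``: high precision sharpens the base
array towards determinism, ``p = 0`` flattens it to uniform, and an infinite
precision leaves the array untouched.  A finite transition precision therefore
encodes the belief that the world can change from one moment to the next, which
is the mechanism behind uncertainty accumulating for unobserved states.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence, Union

import numpy as np
import yaml
from scipy.special import softmax, xlogy

__all__ = [
    "PRECISION_FLOOR",
    "LOG_FLOOR",
    "Factor",
    "Modality",
    "StatePrecision",
    "GenerativeModel",
    "ValidationReport",
    "apply_precision",
    "joint_likelihood",
    "validate_model",
    "log_stable",
    "expect_states",
]

#: Additive floor inside the precision transform, exactly e^-4.
PRECISION_FLOOR = float(np.exp(-4.0))

#: Probabilities are clipped to this value (e^-16) before taking logarithms,
#: so that impossible events contribute a large but finite surprise.
LOG_FLOOR = float(np.exp(-16.0))

_STOCHASTIC_TOL = 1e-10


def log_stable(x: np.ndarray) -> np.ndarray:
    """Elementwise ``log`` with probabilities clipped at ``LOG_FLOOR``."""
    return np.log(np.maximum(x, LOG_FLOOR))


def apply_precision(M, p: float, floor: float = PRECISION_FLOOR) -> np.ndarray:
    """Sharpen or flatten a column-stochastic array with precision ``p``.

    Returns the column-wise softmax of ``p * ln(M + floor)``.  Columns are the
    trailing axes (the conditioning variables); rows (axis 0) hold the
    conditioned variable and are normalised.  ``p = 0`` maps every column to the
    uniform distribution, ``p = inf`` returns ``M`` unchanged.

    Raises
    ------
    ValueError
        if ``p`` is negative or ``M`` is not column-stochastic.
    """
    M = np.asarray(M, dtype=float)
    if M.ndim < 2:
        raise ValueError("expected an array with at least two dimensions")
    if p < 0:
        raise ValueError(f"precision must be non-negative, got {p}")
    cols = M.reshape(M.shape[0], -1)
    if not np.allclose(cols.sum(axis=0), 1.0, atol=_STOCHASTIC_TOL):
        raise ValueError("columns of the input array must sum to 1")
    if np.isinf(p):
        return M.copy()
    out = softmax(p * np.log(cols + floor), axis=0)
    return out.reshape(M.shape)


def expect_states(tensor: np.ndarray, dists: Sequence[np.ndarray],
                  keep: Sequence[int] = (), leading: int = 0) -> np.ndarray:
    """Contract the trailing state axes of ``tensor`` against per-factor beliefs.

    ``tensor`` has ``leading`` non-state axes followed by one axis per factor.
    Every factor axis not listed in ``keep`` is summed out, weighted by the
    corresponding distribution in ``dists`` (mean-field expectation).
    """
    nf = len(dists)
    labels = list(range(leading + nf))
    args: list = [tensor, labels]
    keep = tuple(keep)
    for g, d in enumerate(dists):
        if g in keep:
            continue
        args.extend([np.asarray(d, dtype=float), [leading + g]])
    args.append(list(range(leading)) + [leading + g for g in range(nf) if g in keep])
    return np.einsum(*args)


@dataclass(frozen=True)
class Factor:
    """One hidden-state dimension (e.g. a quadrant's colour, fixation location)."""

    name: str
    cardinality: int
    controllable: bool = False
    labels: tuple[str, ...] | None = None


@dataclass(frozen=True)
class Modality:
    """One observation channel (e.g. the visual input, the L-signal)."""

    name: str
    cardinality: int
    labels: tuple[str, ...] | None = None


@dataclass(frozen=True)
class StatePrecision:
    """A likelihood precision that depends on the state of one factor.

    Used for covert attention: the precision applied to a modality's likelihood
    is ``values[k]`` when the named factor (the attentional state) is in state
    ``k``.  A scalar precision is the special case with identical entries.
    """

    factor: str
    values: tuple[float, ...]


ZetaLike = Union[float, StatePrecision]


@dataclass
class ValidationReport:
    passed: bool
    violations: list[str] = field(default_factory=list)

    def __bool__(self) -> bool:
        return self.passed


@dataclass(eq=False)
class GenerativeModel:
    """An agent's beliefs about how hidden states generate observations.

    Treated as immutable after construction: the precision-transformed
    likelihood and transition arrays are cached lazily.
    """

    factors: list[Factor]
    modalities: list[Modality]
    A: list[np.ndarray]
    B: list[np.ndarray]
    C: list[np.ndarray]
    D: list[np.ndarray]
    zeta: list[ZetaLike]
    omega: list[float]
    policy_bias: np.ndarray | None = None
    action_labels: list[str] | None = None
    name: str = "custom"
    precision_floor: float = PRECISION_FLOOR

    def __post_init__(self) -> None:
        self.A = [np.asarray(a, dtype=float) for a in self.A]
        self.B = [np.asarray(b, dtype=float) for b in self.B]
        self.C = [np.asarray(c, dtype=float) for c in self.C]
        self.D = [np.asarray(d, dtype=float) for d in self.D]
        if self.policy_bias is None:
            self.policy_bias = np.zeros(self.n_actions)
        else:
            self.policy_bias = np.asarray(self.policy_bias, dtype=float)
        self._cache: dict = {}

    # -- descriptors -----------------------------------------------------
    @property
    def n_factors(self) -> int:
        return len(self.factors)

    @property
    def n_modalities(self) -> int:
        return len(self.modalities)

    @property
    def state_dims(self) -> tuple[int, ...]:
        return tuple(f.cardinality for f in self.factors)

    @property
    def n_actions(self) -> int:
        sizes = [b.shape[2] for f, b in zip(self.factors, self.B) if f.controllable]
        return max(sizes) if sizes else 1

    def factor_index(self, name: str) -> int:
        for i, f in enumerate(self.factors):
            if f.name == name:
                return i
        raise KeyError(f"no factor named {name!r}")

    def modality_index(self, name: str) -> int:
        for i, m in enumerate(self.modalities):
            if m.name == name:
                return i
        raise KeyError(f"no modality named {name!r}")

    # -- precision-transformed mappings ----------------------------------
    def likelihood(self, m: int) -> np.ndarray:
        """The precision-weighted likelihood array A^zeta for modality ``m``."""
        key = ("A", m)
        if key not in self._cache:
            A, z = self.A[m], self.zeta[m]
            if isinstance(z, StatePrecision):
                axis = 1 + self.factor_index(z.factor)
                out = np.empty_like(A)
                for k, zk in enumerate(z.values):
                    sl = [slice(None)] * A.ndim
                    sl[axis] = k
                    out[tuple(sl)] = apply_precision(A[tuple(sl)], zk, self.precision_floor)
            else:
                out = apply_precision(A, float(z), self.precision_floor)
            self._cache[key] = out
        return self._cache[key]

    def log_likelihood(self, m: int) -> np.ndarray:
        key = ("lnA", m)
        if key not in self._cache:
            self._cache[key] = log_stable(self.likelihood(m))
        return self._cache[key]

    def column_entropy(self, m: int) -> np.ndarray:
        """Entropy of each likelihood column (the ambiguity of the mapping)."""
        key = ("HA", m)
        if key not in self._cache:
            Ah = self.likelihood(m)
            self._cache[key] = -xlogy(Ah, Ah).sum(axis=0)
        return self._cache[key]

    def _transition_block(self, f: int) -> np.ndarray:
        key = ("B", f)
        if key not in self._cache:
            B, w = self.B[f], self.omega[f]
            out = np.empty_like(B)
            for u in range(B.shape[2]):
                out[:, :, u] = apply_precision(B[:, :, u], float(w), self.precision_floor)
            self._cache[key] = out
        return self._cache[key]

    def transition(self, f: int, action: int = 0) -> np.ndarray:
        """B^omega slice for factor ``f`` under ``action`` (ignored if uncontrollable)."""
        u = action if self.factors[f].controllable else 0
        return self._transition_block(f)[:, :, u]

    # -- validation ------------------------------------------------------
    def validate(self) -> ValidationReport:
        return validate_model(self)

    # -- serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        def _zeta(z: ZetaLike):
            if isinstance(z, StatePrecision):
                return {"factor": z.factor, "values": [float(v) for v in z.values]}
            return float(z)

        return {
            "name": self.name,
            "factors": [
                {"name": f.name, "cardinality": f.cardinality,
                 "controllable": f.controllable,
                 "labels": list(f.labels) if f.labels else None}
                for f in self.factors
            ],
            "modalities": [
                {"name": m.name, "cardinality": m.cardinality,
                 "labels": list(m.labels) if m.labels else None}
                for m in self.modalities
            ],
            "A": [a.tolist() for a in self.A],
            "B": [b.tolist() for b in self.B],
            "C": [c.tolist() for c in self.C],
            "D": [d.tolist() for d in self.D],
            "zeta": [_zeta(z) for z in self.zeta],
            "omega": [float(w) for w in self.omega],
            "policy_bias": self.policy_bias.tolist(),
            "action_labels": list(self.action_labels) if self.action_labels else None,
            "precision_floor": self.precision_floor,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GenerativeModel":
        def _zeta(z) -> ZetaLike:
            if isinstance(z, dict):
                return StatePrecision(z["factor"], tuple(float(v) for v in z["values"]))
            return float(z)

        return cls(
            factors=[Factor(f["name"], f["cardinality"], f.get("controllable", False),
                            tuple(f["labels"]) if f.get("labels") else None)
                     for f in d["factors"]],
            modalities=[Modality(m["name"], m["cardinality"],
                                 tuple(m["labels"]) if m.get("labels") else None)
                        for m in d["modalities"]],
            A=[np.asarray(a, dtype=float) for a in d["A"]],
            B=[np.asarray(b, dtype=float) for b in d["B"]],
            C=[np.asarray(c, dtype=float) for c in d["C"]],
            D=[np.asarray(x, dtype=float) for x in d["D"]],
            zeta=[_zeta(z) for z in d["zeta"]],
            omega=[float(w) for w in d["omega"]],
            policy_bias=np.asarray(d["policy_bias"], dtype=float),
            action_labels=list(d["action_labels"]) if d.get("action_labels") else None,
            name=d.get("name", "custom"),
            precision_floor=d.get("precision_floor", PRECISION_FLOOR),
        )

    def save(self, path) -> None:
        path = Path(path)
        d = self.to_dict()
        if path.suffix == ".json":
            path.write_text(json.dumps(d, indent=2))
        else:
            path.write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def load(cls, path) -> "GenerativeModel":
        path = Path(path)
        text = path.read_text()
        d = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls.from_dict(d)


def joint_likelihood(model: GenerativeModel, modality: int,
                     joint_state: Sequence[int]) -> np.ndarray:
    """Precision-weighted outcome distribution for one joint state configuration."""
    joint_state = tuple(int(s) for s in joint_state)
    if len(joint_state) != model.n_factors:
        raise IndexError(
            f"expected {model.n_factors} state indices, got {len(joint_state)}")
    for s, f in zip(joint_state, model.factors):
        if not 0 <= s < f.cardinality:
            raise IndexError(f"state {s} out of range for factor {f.name!r}")
    return model.likelihood(modality)[(slice(None), *joint_state)].copy()


def validate_model(model: GenerativeModel) -> ValidationReport:
    """Check the probabilistic structure of a model; failures are itemised."""
    v: list[str] = []
    dims = model.state_dims
    n_actions = model.n_actions

    if len(model.A) != model.n_modalities:
        v.append(f"expected {model.n_modalities} A arrays, got {len(model.A)}")
    for m, (mod, A) in enumerate(zip(model.modalities, model.A)):
        if A.shape != (mod.cardinality, *dims):
            v.append(f"A[{m}] ({mod.name}): shape {A.shape} != {(mod.cardinality, *dims)}")
            continue
        sums = A.reshape(A.shape[0], -1).sum(axis=0)
        bad = np.flatnonzero(~np.isclose(sums, 1.0, atol=_STOCHASTIC_TOL))
        if bad.size:
            v.append(f"A[{m}] ({mod.name}): {bad.size} column(s) do not sum to 1 "
                     f"(first at flat column {bad[0]}, sum {sums[bad[0]]:.6g})")

    if len(model.B) != model.n_factors:
        v.append(f"expected {model.n_factors} B arrays, got {len(model.B)}")
    for f, (fac, B) in enumerate(zip(model.factors, model.B)):
        n_u = n_actions if fac.controllable else 1
        if B.ndim != 3 or B.shape[0] != fac.cardinality or B.shape[1] != fac.cardinality:
            v.append(f"B[{f}] ({fac.name}): shape {B.shape} incompatible with "
                     f"cardinality {fac.cardinality}")
            continue
        if B.shape[2] != n_u:
            v.append(f"B[{f}] ({fac.name}): {B.shape[2]} action slice(s), expected {n_u}")
        for u in range(B.shape[2]):
            sums = B[:, :, u].sum(axis=0)
            bad = np.flatnonzero(~np.isclose(sums, 1.0, atol=_STOCHASTIC_TOL))
            if bad.size:
                v.append(f"B[{f}] ({fac.name}), action {u}: column {bad[0]} sums to "
                         f"{sums[bad[0]]:.6g}")

    for m, (mod, C) in enumerate(zip(model.modalities, model.C)):
        if C.shape != (mod.cardinality,):
            v.append(f"C[{m}] ({mod.name}): length {C.shape} != {mod.cardinality}")
    for f, (fac, D) in enumerate(zip(model.factors, model.D)):
        if D.shape != (fac.cardinality,):
            v.append(f"D[{f}] ({fac.name}): length {D.shape} != {fac.cardinality}")
        elif not np.isclose(D.sum(), 1.0, atol=_STOCHASTIC_TOL):
            v.append(f"D[{f}] ({fac.name}): sums to {D.sum():.6g}")

    for m, z in enumerate(model.zeta):
        if isinstance(z, StatePrecision):
            try:
                fi = model.factor_index(z.factor)
            except KeyError:
                v.append(f"zeta[{m}]: unknown factor {z.factor!r}")
                continue
            if len(z.values) != model.factors[fi].cardinality:
                v.append(f"zeta[{m}]: {len(z.values)} values for factor "
                         f"{z.factor!r} of cardinality {model.factors[fi].cardinality}")
            if any(val < 0 for val in z.values):
                v.append(f"zeta[{m}]: negative precision value")
        elif z < 0:
            v.append(f"zeta[{m}]: negative precision {z}")
    for f, w in enumerate(model.omega):
        if w < 0:
            v.append(f"omega[{f}]: negative precision {w}")

    if model.policy_bias.shape != (n_actions,):
        v.append(f"policy_bias: length {model.policy_bias.shape} != {n_actions}")

    return ValidationReport(passed=not v, violations=v)
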