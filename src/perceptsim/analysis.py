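"""Readouts derived from simulation records.

Entropy traces quantify how uncertain the agent is about each stimulus over
time; fade times locate the step at which that uncertainty effectively reaches
its maximum (the point at which a Troxler stimulus has perceptually vanished);
percept traces weight the true stimulus by its posterior probability; switch
records describe perceptual alternation in the attentional paradigms; and a
simple log-normal observation model converts discrete dominance run-lengths
into continuous dominance times.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .simulation import SimulationRecord

__all__ = ["PerceptTrace", "SwitchRecord", "entropy_trace", "time_to_fade",
           "render_percept", "detect_switches", "dominance_durations",
           "max_entropy"]

_ATTENTION_PARADIGMS = ("rivalry", "necker")


@dataclass
class PerceptTrace:
    """Posterior-weighted stimulus intensities, one column per factor.

    ``values[t, j]`` is the posterior probability assigned to the true state of
    the j-th rendered factor at time ``t`` — 1 for a vivid, certain percept and
    ``1/cardinality`` for one that has completely faded to the background.
    """

    values: np.ndarray
    factor_names: list[str]


@dataclass
class SwitchRecord:
    """Perceptual switch times and dominance run-lengths after a warm-up.

    ``attended`` is the attended-identity (action) sequence from ``warmup``
    onwards; a switch occurs whenever consecutive entries differ.  Run-lengths
    partition the post-warmup steps, so they sum to ``horizon - warmup``.
    """

    switch_times: list[int]
    run_lengths: list[int]
    attended: list[int]
    warmup: int

    @property
    def n_switches(self) -> int:
        return len(self.switch_times)

    @property
    def rate_per_step(self) -> float:
        n = len(self.attended) - 1
        return self.n_switches / n if n > 0 else 0.0

    def rate_hz(self, dt: float) -> float:
        return self.rate_per_step / dt


def _resolve_factors(record: SimulationRecord, factors) -> list[int]:
    if factors is None:
        return list(range(len(record.factors)))
    names = [f.name for f in record.factors]
    out = []
    for f in factors:
        out.append(names.index(f) if isinstance(f, str) else int(f))
    if not out:
        raise ValueError("factor subset must not be empty")
    return out


def max_entropy(record: SimulationRecord, factors=None) -> float:
    """Upper bound sum(ln cardinality) for the selected factors, in nats."""
    idx = _resolve_factors(record, factors)
    return float(sum(np.log(record.factors[f].cardinality) for f in idx))


def entropy_trace(record: SimulationRecord, factors=None) -> np.ndarray:
    """Shannon entropy (nats) of the posterior beliefs, summed over factors."""
    idx = _resolve_factors(record, factors)
    return record.entropies[:, idx].sum(axis=1)


def time_to_fade(trace, threshold_fraction: float, max_entropy: float):
    """First step at which a (summed) entropy trace reaches the fade criterion.

    Returns the first index where ``trace >= threshold_fraction * max_entropy``
    or ``None`` if the criterion is never reached within the trace.
    """
    if not 0 < threshold_fraction <= 1:
        raise ValueError("threshold_fraction must lie in (0, 1]")
    trace = np.asarray(trace, dtype=float)
    hits = np.flatnonzero(trace >= threshold_fraction * max_entropy)
    return int(hits[0]) if hits.size else None


def render_percept(record: SimulationRecord, true_states: dict) -> PerceptTrace:
    """Intensity of each true stimulus as its posterior probability over time.

    ``true_states`` maps factor name (or index) to the true state whose
    posterior probability is read out.  The identity is used as the monotonic
    map from probability to intensity.
    """
    names = [f.name for f in record.factors]
    cols, labels = [], []
    for key, s in true_states.items():
        f = names.index(key) if isinstance(key, str) else int(key)
        cols.append(record.belief_array(f)[:, int(s)])
        labels.append(names[f])
    return PerceptTrace(values=np.column_stack(cols), factor_names=labels)


def detect_switches(record: SimulationRecord, warmup: int = 1) -> SwitchRecord:
    """Perceptual switches in an attentional paradigm.

    The attended identity at each step is the selected attentional action; a
    switch is registered whenever it differs from the previous step's (after
    the warm-up, which by default excludes the deterministic tie resolution at
    the first step).
    """
    if record.paradigm not in _ATTENTION_PARADIGMS:
        raise ValueError(
            f"switch detection requires an attentional paradigm "
            f"({'/'.join(_ATTENTION_PARADIGMS)}), got {record.paradigm!r}")
    if not 0 <= warmup < record.horizon:
        raise ValueError("warmup must lie within the horizon")
    attended = [int(a) for a in record.actions[warmup:]]
    switch_times = [warmup + i for i in range(1, len(attended))
                    if attended[i] != attended[i - 1]]
    run_lengths: list[int] = []
    run = 1
    for i in range(1, len(attended)):
        if attended[i] == attended[i - 1]:
            run += 1
        else:
            run_lengths.append(run)
            run = 1
    run_lengths.append(run)
    return SwitchRecord(switch_times=switch_times, run_lengths=run_lengths,
                        attended=attended, warmup=warmup)


def dominance_durations(switches: SwitchRecord, dt: float = 0.25,
                        sigma_log: float = 0.5, n_samples: int = 1,
                        seed=None) -> np.ndarray:
    """Continuous dominance times from discrete run-lengths (seconds).

    Each run of ``n`` steps is mapped to ``n * dt`` seconds and jittered with
    log-normal noise: samples are ``exp(Normal(ln(n * dt), sigma_log))``, which
    guarantees positive durations and a heavy right tail.  ``sigma_log = 0``
    returns the noiseless durations exactly.
    """
    if sigma_log < 0:
        raise ValueError("sigma_log must be non-negative")
    runs = np.asarray(switches.run_lengths if isinstance(switches, SwitchRecord)
                      else switches, dtype=float)
    if runs.size == 0:
        raise ValueError("run-lengths must be non-empty")
    base = np.repeat(runs * dt, n_samples)
    if sigma_log == 0:
        return base
    rng = np.random.default_rng(seed)
    return base * np.exp(rng.normal(0.0, sigma_log, size=base.size))
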