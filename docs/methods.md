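# Methods

## Generative models

Each agent is a categorical partially observed Markov decision process.
Hidden-state factors are independent a priori; outcome modalities depend on
the joint state through likelihood arrays `A` (stored over the full joint
state space, factor order fixed by declaration order).  Transitions `B` are
per-factor; factors flagged *controllable* hold one transition slice per
action, all others exactly one.  Columns always index the conditioning
variable and are normalised over rows.

Precisions enter through the column-wise transform
`M^p = softmax(p · ln(M + e⁻⁴))`.  The additive floor `e⁻⁴` is exposed as
`precision_floor` but never changed by the built paradigms.  The softmax is
applied independently per column — the only reading that preserves
stochasticity.  `p = 0` yields uniform columns, `p → ∞` is treated as the
identity transform (used for all control factors: the agent is certain its
saccades and attentional selections succeed).  A likelihood precision may be
a table keyed by the state of one factor (`StatePrecision`); this is how
covert attention modulates the believed fidelity of each sensory channel
without touching the data themselves.  The scalar case is the table with
identical entries.

The *environment* (generative process) shares the structural arrays but is
precision-free and deterministic: one-hot mappings, static stimulus states,
control transitions applied exactly.  Changing the agent's `ζ` or `ω` can
therefore never change what is observed under a given action sequence — only
what is believed and, through action, which observations are sought.  The
agent's initial priors `D` match the true initial states: simulations start
from the beliefs an observer would hold after free exploration, which is what
gives fading something to fade *from*.

## State inference

The posterior is a structured mean-field distribution: it factorises across
hidden-state factors, but each factor keeps its full temporal chain
`Q(s) = Π_f Q_f(s^f_0 … s^f_T)`.  One update recomputes a single factor's
chain exactly by forward–backward message passing, with the evidence at each
observed time given by the expected log-likelihood under the current beliefs
about the other factors (mean-field marginalisation, exponentiated back into
an evidence vector).  Sweeps iterate over factors in declaration order until
no marginal moves by more than `tol` (default 1e-6, `max_iters` 16).

Because every update is the exact coordinate minimiser of the variational
free energy of this posterior family, sweeps can never increase the
objective; the iteration is a true descent and the property is asserted
throughout the test suite.  An earlier design used damped per-time fixed
point updates (forward and backward messages averaged with weight 1/2); it
was abandoned because its fixed point neither minimises the variational
objective (iterates can ascend it) nor — in its fully factorised form —
recovers the correct blurring of unobserved chains towards uniform, which is
the mechanism the whole exercise rests on.  Exact per-factor smoothing gives
both properties at the same asymptotic cost.

Numerical choices:

- all logarithms of probabilities clip their argument at `e⁻¹⁶`, so an
  impossible observation is finitely (rather than infinitely) surprising;
  the clip (not an additive offset) keeps single-time-step inference equal to
  exact Bayes to machine precision on non-degenerate problems;
- times beyond the last observation carry no evidence, so their beliefs are
  the forward-propagated predictive distributions — exactly the inputs the
  planner needs;
- evidence vectors are cached per time step and recomputed only when another
  factor's belief at that time has moved by more than `0.1·tol`; warm starts
  reuse the previous step's beliefs.  Neither shortcut changes the fixed
  point at the stated tolerance.

`free_energy` reports `F = E_Q[ln Q − ln P(o, s | π)]` over observed time
steps, with the chain entropy used when pairwise marginals are available and
the fully factorised expression otherwise (the latter is what external
callers get when they hand in raw marginals, and is still a valid bound on
`−ln P(o)`).

## Planning

Policies are single-step action sets re-evaluated greedily at every step: all
of the simulated behaviours are per-step selections, and depth-1 re-planning
reproduces them at a fraction of the cost of a policy tree.  For each
candidate action the predictive state distribution is obtained by one step of
forward propagation through `B^ω` from the current posterior; the expected
free energy sums, over future steps and modalities,

- **ambiguity**: the expected column entropy of `A^ζ` under predicted states;
- **negative predictive entropy**: `−H[Q(o|π)]` of the predicted outcome
  distribution;
- **preference**: `−E[C]` under predicted outcomes.

The policy posterior is `softmax(−γ·G + bias)`.  `γ` defaults to 16 — large
enough that `argmax` and `sample` modes agree except near ties, while leaving
sample mode meaningful for the neglect simulations; it is config-exposed.
Exact ties under `argmax` resolve to the lowest action index.  In the
symmetric rivalry model the first step is such a tie in structure, but the
initial attentional state (attend-L, inherited from `D`) leaves the R-channel
marginally less certain, so the first selected action is attend-R and strict
alternation follows; everything is deterministic and seed-insensitive in
`argmax` mode.

## Paradigm parameters

| parameter | default | role |
|---|---|---|
| `n_colours` | 4 | colour states per quadrant |
| `omega_stim` | 0.5 | stimulus transition precision; sets the fading rate |
| `zeta_vis` | 8.0 | visual likelihood precision (sharp but finite) |
| `fixate_preference` | 4.0 nats | boost of the cross outcome in `fixate` |
| `neglect_bias` | 2.0 nats | rightward log-prior bias in `neglect` |
| `zeta_L`, `zeta_R` | 4.0 | attended-channel likelihood precisions |
| `zeta_unattended` | 0.0 | unattended channel: exactly uninformative |
| `horizon` | 16 | trial length (discrete steps) |
| `dt` | 0.25 s | nominal step duration (theta cycle), analysis only |

Magnitudes for the preference boost and the neglect bias are design choices:
4 nats makes staying at the cross dominate the at most `ln 4 ≈ 1.4` nats of
epistemic value a saccade can offer, and 2 nats of rightward bias reliably
skews sampled exploration without extinguishing leftward saccades entirely.
`ω = 0.5` makes a percept fade within a 16-step trial; the fade time grows
steeply with `ω` (about 5 steps at 0.5, 33 at 1.0, beyond any practical
horizon at 2 and 4), which is the basis of the precision-estimation sweep.
The strongest reading of an unattended channel — precision exactly 0 —
is the default; partial values produce graded suppression.

Two documented rivalry regimes beyond the symmetric default:

- **streetlight** (`zeta_L = 1.5, zeta_R = 0.5`): the more reliable channel
  offers more resolvable uncertainty than the noisy one ever accumulates, so
  attention locks onto it and switching stops;
- **subtle asymmetry** (`zeta_L = 0.3, zeta_R = 0.2, omega_stim = 1.0`): with
  weak likelihoods a single attended step only partially resolves a channel,
  so attention dwells for more than one step and switching becomes irregular
  (rate ≈ 0.77 per step at these values) while remaining step-locked.

The Necker builder is a pure relabelling of the rivalry arrays
(cube-from-above / cube-from-below, vertex outcomes); its structural equality
is asserted in the tests.

## What the simulations do and do not show

The generative process emulates idealised psychophysics: perfectly static
stimuli, noiseless deterministic optics, a discrete time base of one fixation
or attentional commitment per 250 ms, and truthful initial beliefs.  Passing
tests therefore demonstrate the internal consistency of the
uncertainty-accumulation account — fading, foraging, inhibition of return,
neglect-like asymmetry and rivalry-like alternation all following from one
mechanism — not a fit to any empirical data set.  Real Troxler displays
involve retinal eccentricity, luminance matching and micro-saccades, none of
which are modelled; empirical dominance-time distributions are matched only
in form (log-normal), via an explicit observation model on run lengths
(`exp(Normal(ln(n·dt), σ_log))`), not fitted.

## Known limitations

- Single-step policies: behaviours requiring genuine multi-step planning or
  hierarchical (deep temporal) structure are out of scope.
- Precisions are fixed within a trial; there is no learning of `ζ` or `ω`,
  and no learning of `A`, `B` or `D`.
- The likelihood arrays are stored over the full joint state space, which is
  adequate for these models (≤ 6400 entries) but would not scale to many
  factors.
- Continuous time, continuous outcomes and image-level stimulus rendering are
  not modelled; percept read-outs are posterior probabilities.
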