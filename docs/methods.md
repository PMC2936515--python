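# Methods

## Task model

The observing task is a small episodic semi-Markov process. Every trial
starts in a pre-target state `START`, whose outgoing branch is pinned by
the trial type (equal thirds of forced-informative, forced-random and
free-choice trials by default, giving 160 free choices per 480-trial
session in expectation). Forced trials enter one of two targets;
free-choice trials pass through an instantaneous choice state whose branch
is drawn from the choice policy. `TGT_INFO` leads to a discriminative cue
(`CUE_LARGE` with probability q, else `CUE_SMALL`) that predicts the
reward deterministically; `TGT_RAND` leads to one of two
non-discriminative cues (half each) whose exit reward is drawn
independently of cue identity (r_large with probability q). Reward is
delivered on the transition into the terminal state — one reward event per
trial. The intertrial interval is not simulated: trial initiation always
re-engages the system, so nothing learnable happens there.

Default parameters (all config-exposed):

| parameter | default | units | meaning |
|---|---|---|---|
| q | 0.5 | — | probability of the large reward |
| r_large, r_small | 1.0, 0.04 | reward units | 1 ml vs 0.04 ml water |
| target duration | 1.0 | s | fixation of the chosen/forced target |
| cue duration | 2.25 | s | cue-to-reward delay ("a couple of seconds") |
| START, CHOICE duration | 0 | s | instantaneous bookkeeping states |
| α | 0.1 | — | TD learning rate |
| β | 10 | (reward units)⁻¹ | softmax inverse temperature |
| a, b | 0.1, 0.5 | s⁻¹, reward units | hazard scale and value scale |
| v_d | 0 | reward units | value of the disengaged state |

Exact stimulus timings are experiment-specific; the durations are config
fields, and only their order of magnitude matters for the phenomena (the
cue period must be long enough for disengagement to accumulate).

Giving `START` zero duration is deliberate. The target-period dopamine
prediction is δ = V(target) − V(START), with V(START) learning the
average over upcoming trial types. If `START` itself could be disengaged
from, its value would fall below that average and the forced-random
target response would lose its negative sign. With τ_START = 0 the
asymptotic responses are δ_info = Δ(2−p)/3 and δ_rand = −Δ(1+p)/3
(Δ the target-value gap, p the observing bias), so the random-target
depression exceeds the informative-target excitation exactly when p > 0.5
— the recorded pattern.

Initial values default to the task's objective expectations (computed by
path enumeration), emulating subjects already familiar with the
contingencies; mis-initialisation is an explicit manipulation
(`run_initial_values`).

## Learning rule and the modelled dopamine signal

Tabular TD(0), no within-trial discounting, terminal value 0. The TD error
stream, time-stamped by event (`choice`, `target`, `cue`, `reward`, plus
`disengage`), is the model's stand-in for phasic dopamine. During a state
occupied for τ seconds the system disengages with probability
1 − (1 − ρ(V))^τ, where ρ(V) = min(1, a·e^(−V/b)) per second — monotone
non-increasing in value, so high-value states protect engagement. The
hazard is evaluated once per state at its value on entry and is a
pluggable function object; a `salience` family applies the same form to
|V| for aversive tasks. On disengagement the current state is trained
toward the fixed disengaged value (δ = v_d − V(s)) and the system coasts,
externally, through the remaining states: those elicit no prediction
errors (recorded as δ = 0) until reward delivery re-engages it with
δ = r − v_d. That re-engagement error is recorded for the dopamine trace
but trains nothing, because the disengaged state is non-updating. For
visual comparison with recorded neurons — whose firing-rate decreases have
less dynamic range than increases — `truncate_signal` clips negative
responses at 25% of the peak positive response; the truncation is
presentational and never feeds back into learning.

## Choice

Two-option softmax on the target values: difference-based
p = 1/(1+e^(−βΔV)) by default (shift-invariant), or applied to log-values
(scale-invariant, i.e. ratio-based) for the reward-rate analysis. During
simulation the log rule floors values at 10⁻⁶ before the logarithm, since
early learning can transiently produce non-positive values; the strict
(raising) form is used everywhere else. β defaults to 10: the
disengagement-induced target gap is only a few hundredths of a reward
unit, and an inverse temperature of that order is needed for the model to
express a distinct preference, consistent with the more strongly biased of
the two recorded subjects.

## Fixed-point analysis

As α → 0 each state's value settles at the expectation of its own update
targets: with the state's disengagement probability the target is v_d,
otherwise the one-step backup; the choice state's branches are weighted by
the softmax at the current iterate. The solver uses damped iteration
(new ← (1−γ)·old + γ·backup, γ = 0.5 by default — the softmax coupling can
oscillate undamped), tolerance 10⁻¹⁰ on the undamped residual, at most
10⁵ iterations, from the objective-value initialisation plus five random
restarts; distinct solutions are all reported so non-uniqueness is flagged
rather than hidden (defaults yield a unique solution). The asymptotic
observing bias is the softmax probability at the solution.
`bias_vs_reward_prob` sweeps q under both choice rules with the full
trial-type mixture in the training distribution.

## What the simulations do and do not show

The generator reproduces the study conditions — 480-trial sessions, equal
trial-type mixture, q = 0.5, 1.0/0.04 reward magnitudes — and the model's
qualitative claims are all recovered at the defaults: an asymptotic
observing bias above chance that is monotone in β, positive/negative
target-period dopamine responses with the random-target depression the
larger once observing is preferred, slow reversal without value reset,
less (and inverted) observing under a salience hazard with punishments but
more under a valence hazard, a difference-rule bias asymmetric in q
against a log-rule bias that keeps growing as rewards thin, and transient
over-/under-observation from mis-initialised values. It does not model
eye movements, intertrial intervals, reward-magnitude adaptation,
prediction-error-driven or partial disengagement, or real spike trains;
quantitative firing rates are outside its scope.

Two finite-learning-rate effects deserve explicit mention because they are
easy to mistake for bugs (or for the mechanism itself):

* **Hot-stove sampling bias.** With a sharp softmax (β = 10) and constant
  α = 0.1, free choices preferentially sample whichever target is
  transiently overvalued. The occupied values then deviate from the
  objective expectations even with the hazard off: the choice state's
  stationary mean inflates by ≈ +0.02 (it backs up the value of the
  *chosen*, hence higher, target) and the informative target — whose
  update targets are the more variable — deflates by ≈ −0.017. Both
  vanish at β = 0 and shrink as α → 0. Convergence checks against the
  enumeration oracle are therefore run with choices sampled at the
  oracle's reference probability (β = 0); at full defaults the null model
  still shows no reliable observing preference (bias 0.49 ± 0.01 across
  20 seeds), and the same stickiness (an undervalued target is chosen and
  hence updated less often) gives session biases a long correlation time,
  which is why headline biases are reported pooled over seeds.

* **Small-α dopamine probe.** The asymptotic target-period response is of
  order 0.01 reward units, while at α = 0.1 the value fluctuations and
  the choice–value covariance above mask it. `dopamine_probe` therefore
  trains at the default α and then anneals to α = 0.01 before recording —
  the same small-α regime used when comparing long-run simulated values
  with the fixed point (α = 0.02, time-averaged after burn-in, which
  agrees within 0.02 reward units).

## Numerical and bookkeeping choices

Engagement draws consume no randomness when the hazard is zero, so
disabling the mechanism leaves the remaining stream unchanged. Sessions
get independent child streams of the master seed (`SeedSequence` spawn),
making runs reproducible per session; identical config and seed give
byte-identical CSV outputs. Reward lotteries with a single outcome skip
the random draw. τ = 0 states cannot disengage ((1−ρ)⁰ = 1 even at
ρ = 1). Clopper–Pearson intervals use the beta-quantile construction with
the exact conventions low = 0 at k = 0 and high = 1 at k = n; sessions
with no free-choice trials report an explicitly undefined bias rather
than a silent zero. Validation never raises — it returns a list of
violations naming state and rule — while builders raise on invalid
arguments, naming the offending field.

## Known limitations

The hazard's exponential form is a contract-faithful choice (two fixed
parameters, per-second rate, decreasing in value), not a uniquely
determined one; conclusions that depend on its curvature rather than its
monotonicity should be checked against alternatives via the pluggable
hazard. The hazard is evaluated at the value on state entry, not
continuously against the evolving within-state value. Re-engagement is
tied to reward delivery and trial initiation only. Asymptotic biases at
the defaults are small (≈ 0.53–0.56), so empirical comparisons need
pooled sessions; matching an individual subject's larger bias requires
raising β or the hazard scale in the config.
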