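"""Value-dependent Pavlovian disengagement.

Maintaining the task state across the cue-reward delay requires working
memory, and we assume the engagement that sustains it is itself under
Pavlovian control: states predicting little reward are disengaged from more
readily.  Disengagement is modelled as a per-second hazard ρ(V(s)) that is
monotone non-increasing in the state's current predicted value, compounded
over the τ seconds spent in the state, so the probability of maintaining a
correct update through a state is (1 − ρ)^τ.

Two hazard families are provided for the aversive variants of the task:

* ``valence`` (default) — ρ decreases in the *signed* value, so predicted
  punishments disengage even more readily than small rewards;
* ``salience`` — ρ decreases in |value|, so a predicted large punishment
  protects engagement symmetrically with a large reward.

The hazard's algebraic form, ρ(v) = min(1, a·e^{−v/b}), is a pluggable
function object: any callable with the same (value, params) contract can be
substituted without touching callers.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np

from .td_engine import ValueTable

__all__ = [
    "EngagementParams",
    "EngagementOutcome",
    "disengage_hazard",
    "p_disengage_state",
    "sample_engagement",
    "cumulative_disengagement",
    "HAZARD_FAMILIES",
]

HAZARD_FAMILIES = ("valence", "salience")


@dataclass
class EngagementParams:
    """Hazard family, its two fixed parameters, and the disengaged value.

    Parameters
    ----------
    hazard_family
        ``"valence"`` (hazard decreasing in signed value) or ``"salience"``
        (decreasing in absolute value).
    param_a
        Hazard scale: the per-second disengagement probability at value 0
        (dimensionless, in [0, 1]).
    param_b
        Value scale of the hazard, in reward units (> 0).
    v_disengaged
        Value of the fixed, non-updating disengaged state, in reward units.
    hazard_fn
        Optional replacement hazard ``f(v, params) -> rho``; overrides the
        built-in exponential form.
    """

    hazard_family: str = "valence"
    param_a: float = 0.1
    param_b: float = 0.5
    v_disengaged: float = 0.0
    hazard_fn: Optional[Callable[[float, "EngagementParams"], float]] = None

    def __post_init__(self):
        if self.hazard_family not in HAZARD_FAMILIES:
            raise ValueError(
                f"hazard_family must be one of {HAZARD_FAMILIES}, got '{self.hazard_family}'"
            )
        if not 0.0 <= self.param_a <= 1.0:
            raise ValueError(f"param_a must lie in [0, 1], got {self.param_a}")
        if self.param_b <= 0:
            raise ValueError(f"param_b must be > 0, got {self.param_b}")

    @classmethod
    def off(cls) -> "EngagementParams":
        """Parameters that disable disengagement entirely (hazard scale 0)."""
        return cls(param_a=0.0)


@dataclass(frozen=True)
class EngagementOutcome:
    """Result of one within-trial engagement draw."""

    disengaged: bool
    state_of_disengagement: str | None = None

    def __post_init__(self):
        if self.disengaged != (self.state_of_disengagement is not None):
            raise ValueError("state_of_disengagement must be set iff disengaged")


def disengage_hazard(v: float, params: EngagementParams) -> float:
    """Per-second disengagement probability ρ(v) ∈ [0, 1].

    High predicted value protects engagement; under the salience family the
    protection depends on |v| instead of v.
    """
    if params.hazard_fn is not None:
        rho = params.hazard_fn(v, params)
    else:
        x = abs(v) if params.hazard_family == "salience" else v
        rho = params.param_a * np.exp(-x / params.param_b)
    return float(min(1.0, max(0.0, rho)))


def p_disengage_state(rho: float, tau: float) -> float:
    """Probability of disengaging at some point during a τ-second state.

    Per-second Bernoulli compounding generalised to real τ:
    1 − (1 − ρ)^τ.  The complement is the probability of a correct update.
    """
    if not 0.0 <= rho <= 1.0:
        raise ValueError(f"rho must lie in [0, 1], got {rho}")
    if tau < 0:
        raise ValueError(f"tau must be >= 0, got {tau}")
    if tau == 0.0:
        return 0.0
    return float(1.0 - (1.0 - rho) ** tau)


def sample_engagement(
    V: ValueTable,
    s: str,
    tau: float,
    params: EngagementParams,
    rng: np.random.Generator,
) -> EngagementOutcome:
    """Bernoulli draw of whether engagement is lost during state ``s``.

    The hazard is evaluated at the state's value on entry.  Once disengaged
    the system remains in the disengaged state until reward delivery.
    """
    p = p_disengage_state(disengage_hazard(V.get(s), params), tau)
    if p > 0 and rng.random() < p:
        return EngagementOutcome(disengaged=True, state_of_disengagement=s)
    return EngagementOutcome(disengaged=False)


def cumulative_disengagement(
    trial_path: Sequence[tuple[str, float]],
    V: ValueTable,
    params: EngagementParams,
) -> np.ndarray:
    """Total probability of having disengaged by the end of each path prefix.

    Analytic (no sampling): 1 − Π_i (1 − p_i) over the states (s_i, τ_i)
    visited so far.  Monotone non-decreasing along the path.
    """
    survival = 1.0
    out = np.empty(len(trial_path))
    for i, (s, tau) in enumerate(trial_path):
        p = p_disengage_state(disengage_hazard(V.get(s), params), tau)
        survival *= 1.0 - p
        out[i] = 1.0 - survival
    return out
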