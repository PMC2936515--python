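"""Action selection on free-choice trials.

Two-option softmax (Luce) rule over the learned values of the informative
and random targets.  The default rule acts on the *difference* of values,

    p(info) = 1 / (1 + exp(−β (v_info − v_rand))),

and is invariant to adding a constant to both values.  The variant rule
acts on the logarithms of the values and therefore depends only on their
*ratio* — p(info) = v_info^β / (v_info^β + v_rand^β) — which changes how
the observing bias behaves as rewards thin (low reward probability).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

__all__ = ["PolicyParams", "choice_prob", "sample_choice", "CHOICE_RULES"]

CHOICE_RULES = ("softmax_difference", "softmax_log")

#: Floor applied to values before taking logarithms during simulation,
#: where early learning can transiently produce non-positive values.
LOG_VALUE_FLOOR = 1e-6


@dataclass
class PolicyParams:
    """Inverse temperature β (≥ 0) and the softmax rule."""

    beta: float = 10.0
    rule: str = "softmax_difference"

    def __post_init__(self):
        if self.beta < 0:
            raise ValueError(f"beta must be >= 0, got {self.beta}")
        if self.rule not in CHOICE_RULES:
            raise ValueError(f"rule must be one of {CHOICE_RULES}, got '{self.rule}'")


def choice_prob(
    v_info: float,
    v_rand: float,
    params: PolicyParams,
    clamp: bool = False,
) -> float:
    """Probability of choosing the informative option.

    For the log rule both values must be strictly positive; with
    ``clamp=True`` (used during simulation) they are floored at a small
    positive value instead of raising.
    """
    if params.rule == "softmax_log":
        if clamp:
            v_info = max(v_info, LOG_VALUE_FLOOR)
            v_rand = max(v_rand, LOG_VALUE_FLOOR)
        elif v_info <= 0 or v_rand <= 0:
            raise ValueError(
                "softmax_log requires strictly positive values "
                f"(got v_info={v_info}, v_rand={v_rand})"
            )
        dv = np.log(v_info) - np.log(v_rand)
    else:
        dv = v_info - v_rand
    return float(expit(params.beta * dv))


def sample_choice(p: float, rng: np.random.Generator) -> str:
    """Bernoulli draw between ``"informative"`` and ``"random"``."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p must lie in [0, 1], got {p}")
    return "informative" if rng.random() < p else "random"
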