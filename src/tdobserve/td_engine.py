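"""Tabular TD(0) value learning and the modelled dopamine signal.

The learner maintains one value per task state, V(s), estimating the
expected future reward from that state, and updates it from the temporal
difference error

    δ = r + V(s′) − V(s),        V(s) ← V(s) + α·δ

with no within-trial discounting (trials are a few seconds long).  The
terminal state is pinned at 0.  A special *disengaged* state with fixed
value ``v_disengaged`` is never updated: when engagement is lost during a
state s, s is instead trained toward the disengaged value
(δ = v_disengaged − V(s)), and the system sits in the disengaged state
until reward delivery re-engages it, producing a prediction error
δ = r − v_disengaged relative to the fixed state that trains nothing.

The sequence of δ values, time-stamped by trial event, is the model's
stand-in for phasic dopamine activity.  For comparison with recorded
neurons — whose firing-rate decreases have less dynamic range than their
increases — negative responses are truncated at a fraction of the maximal
positive response; the truncation is presentational only and never feeds
back into learning.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .task_model import TaskSpec

__all__ = [
    "DISENGAGED_STATE",
    "ValueTable",
    "PredictionError",
    "td_error",
    "td_update",
    "td_error_disengaged",
    "td_error_reengage",
    "dopamine_trace",
    "truncate_signal",
    "EVENT_LABELS",
]

#: Identifier of the fixed, non-updating state entered on disengagement.
DISENGAGED_STATE = "DISENGAGED"

#: Event labels carried by prediction errors, in within-trial order.
EVENT_LABELS = ("choice", "target", "cue", "reward", "disengage")


@dataclass
class ValueTable:
    """Learned value per state plus the fixed disengaged-state value.

    Terminal states are pinned at value 0 and, like the disengaged state,
    are never updated.
    """

    values: dict[str, float]
    v_disengaged: float = 0.0
    terminal: frozenset = frozenset({"TERMINAL"})

    @classmethod
    def from_task(cls, task: TaskSpec, v0: float | dict[str, float] = 0.0,
                  v_disengaged: float = 0.0) -> "ValueTable":
        """Initialise a table over the task's updatable states.

        ``v0`` may be a scalar (all states start there) or a per-state map.
        """
        if isinstance(v0, dict):
            vals = {s: float(v0.get(s, 0.0)) for s in task.updatable_states()}
        else:
            vals = {s: float(v0) for s in task.updatable_states()}
        term = frozenset(s for s, sp in task.states.items() if sp.is_terminal)
        return cls(values=vals, v_disengaged=float(v_disengaged), terminal=term)

    def get(self, state_id: str) -> float:
        """Value lookup; unknown states raise a lookup error."""
        if state_id == DISENGAGED_STATE:
            return self.v_disengaged
        if state_id in self.terminal:
            return 0.0
        if state_id in self.values:
            return self.values[state_id]
        raise KeyError(f"unknown state '{state_id}' in value table")

    def copy(self) -> "ValueTable":
        return ValueTable(values=dict(self.values), v_disengaged=self.v_disengaged,
                          terminal=self.terminal)

    def as_dict(self) -> dict[str, float]:
        return dict(self.values)


@dataclass
class PredictionError:
    """One time-stamped TD error (the modelled phasic dopamine response)."""

    trial_index: int
    event_label: str
    state_id: str
    delta: float
    engaged: bool = True


def td_error(V: ValueTable, s: str, r: float, s_next: str) -> float:
    """δ = r + V(s′) − V(s); terminal successors contribute value 0."""
    return r + V.get(s_next) - V.get(s)


def td_update(V: ValueTable, s: str, delta: float, alpha: float) -> ValueTable:
    """Apply V(s) ← V(s) + α·δ in place and return the table.

    The disengaged state and the terminal state are not updatable.
    """
    if not 0.0 < alpha <= 1.0:
        raise ValueError(f"learning rate must be in (0, 1], got {alpha}")
    if s == DISENGAGED_STATE:
        raise ValueError("the disengaged state is fixed and never updated")
    if s not in V.values:
        raise KeyError(f"state '{s}' is not updatable")
    V.values[s] += alpha * delta
    return V


def td_error_disengaged(V: ValueTable, s: str) -> float:
    """Update signal for s when engagement is lost during s.

    The successor becomes the fixed disengaged state and no reward is
    delivered on that transition, so δ = v_disengaged − V(s).
    """
    return V.v_disengaged - V.get(s)


def td_error_reengage(V: ValueTable, r: float) -> float:
    """Prediction error at reward delivery while disengaged: δ = r − v_disengaged.

    Recorded for the dopamine trace; trains no state value, since the
    disengaged state is non-updating.
    """
    return r - V.v_disengaged


class EmptyConditionError(ValueError):
    """No recorded prediction errors match the requested condition."""


def dopamine_trace(records, condition=None) -> dict[str, float]:
    """Mean δ per event label over trials matching a condition.

    Parameters
    ----------
    records
        Iterable of :class:`PredictionError`, or of objects with an
        ``errors`` attribute (trial records), flattened in order.
    condition
        Optional predicate applied per prediction error, or a
        ``(trial_type, outcome)`` pair applied to trial records, where
        ``trial_type`` is a trial-type label or ``None`` and ``outcome`` is
        a reward amount or ``None``.

    Averages run across engaged and disengaged trials alike.  Raises
    :class:`EmptyConditionError` when nothing matches rather than returning
    silent zeros.
    """
    errors: list[PredictionError] = []
    for rec in records:
        if hasattr(rec, "errors"):
            if isinstance(condition, tuple):
                ttype, outcome = condition
                if ttype is not None and rec.trial_type != ttype:
                    continue
                if outcome is not None and not np.isclose(rec.reward, outcome):
                    continue
            errors.extend(rec.errors)
        else:
            errors.append(rec)
    if callable(condition):
        errors = [e for e in errors if condition(e)]
    if not errors:
        raise EmptyConditionError("no prediction errors match the condition")
    out: dict[str, float] = {}
    for label in EVENT_LABELS:
        deltas = [e.delta for e in errors if e.event_label == label]
        if deltas:
            out[label] = float(np.mean(deltas))
    return out


def truncate_signal(trace, floor_fraction: float = 0.25) -> np.ndarray:
    """Clip negative responses at −``floor_fraction``·max(positive response).

    Mimics the limited dynamic range of dopamine firing-rate decreases.
    Positives are untouched; presentation only, never used in learning.
    """
    arr = np.asarray(trace, dtype=float)
    if arr.size == 0 or arr.max() <= 0:
        raise ValueError(
            "truncation floor undefined: trace contains no positive response"
        )
    floor = -floor_fraction * arr.max()
    return np.maximum(arr, floor)
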