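"""Semi-Markov state graphs for the observing task and its variants.

The observing task confronts a subject with three sorts of trials.  On
*forced-informative* trials a single target leads to one of two
discriminative cues, each of which deterministically predicts whether the
upcoming reward is large or small.  On *forced-random* trials the target
leads to one of two non-discriminative cues whose identity carries no
information about the reward.  On *free-choice* trials the subject picks
which of the two targets (and hence which family of cues) it will see.
Either way the reward itself is drawn with probability ``q`` for the large
amount, so observing confers no instrumental advantage.

A task is a small directed graph of :class:`StateSpec` nodes.  Every trial
starts in a common pre-target state (``START``), whose outgoing branch is
pinned by the sampled trial type; free-choice trials pass through an
instantaneous choice state.  Reward is delivered on the transition into the
terminal state, drawn from the exiting cue's reward lottery.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field, replace

import numpy as np
import yaml

__all__ = [
    "StateSpec",
    "TaskSpec",
    "TrialType",
    "TaskValidationError",
    "build_observing_task",
    "build_delayed_task",
    "apply_reversal",
    "sample_trial_type",
    "validate_task",
    "enumerate_paths",
    "objective_values",
    "expected_terminal_reward",
    "save_task",
    "load_task",
    "TRIAL_TYPE_LABELS",
    "DEFAULT_DURATIONS",
]

TRIAL_TYPE_LABELS = ("forced_informative", "forced_random", "free_choice")

#: Default state dwell times in seconds.  Targets are fixated for about a
#: second; the cue-to-reward delay is a couple of seconds.  The pre-target
#: and choice moments are treated as instantaneous bookkeeping states, so
#: no disengagement can occur there.
DEFAULT_DURATIONS = {
    "start": 0.0,
    "choice": 0.0,
    "target": 1.0,
    "cue": 2.25,
}


class TaskValidationError(ValueError):
    """Raised when a task specification violates its structural contract."""


@dataclass(frozen=True)
class StateSpec:
    """One node of the task graph.

    Parameters
    ----------
    state_id
        Symbolic identifier, unique within the task.
    duration
        Seconds spent in the state; disengagement compounds over this time.
    successors
        Tuple of ``(state_id, probability)`` pairs.  For the choice state the
        probabilities are placeholders — the branch is drawn from the choice
        policy at run time.
    reward_on_exit
        Lottery of ``(amount, probability)`` pairs resolved on leaving the
        state.  Non-zero only for cue states (reward is delivered on the
        transition into the terminal state).
    role
        One of ``{"start", "choice", "target", "cue", "terminal"}``; drives
        event labelling of prediction errors.
    """

    state_id: str
    duration: float = 0.0
    successors: tuple[tuple[str, float], ...] = ()
    reward_on_exit: tuple[tuple[float, float], ...] = ((0.0, 1.0),)
    role: str = "cue"
    is_choice_state: bool = False
    is_terminal: bool = False

    def expected_reward_on_exit(self) -> float:
        return float(sum(a * p for a, p in self.reward_on_exit))


@dataclass(frozen=True)
class TrialType:
    """A trial-type label and the state the pre-target state branches to."""

    label: str
    start_state: str


@dataclass
class TaskSpec:
    """A complete observing-task variant.

    ``option_info`` / ``option_rand`` name the two physical targets offered
    at the choice state.  A contingency reversal rewires what the targets
    lead to but keeps these labels attached to the same physical targets, so
    the observing bias (fraction of choices of ``option_info``) is measured
    against a fixed option before and after the switch.
    """

    states: dict[str, StateSpec]
    trial_types: dict[str, float]
    q: float
    r_large: float
    r_small: float
    variant_tag: str = "standard"
    start_state: str = "START"
    choice_state: str = "CHOICE"
    option_info: str = "TGT_INFO"
    option_rand: str = "TGT_RAND"
    trial_start: dict[str, str] = field(default_factory=dict)

    def state(self, state_id: str) -> StateSpec:
        return self.states[state_id]

    def trial_type(self, label: str) -> TrialType:
        return TrialType(label=label, start_state=self.trial_start[label])

    def updatable_states(self) -> list[str]:
        return [s for s, spec in self.states.items() if not spec.is_terminal]

    def copy(self) -> "TaskSpec":
        return copy.deepcopy(self)


def _mk_lottery(value) -> tuple[tuple[float, float], ...]:
    if isinstance(value, (int, float)):
        return ((float(value), 1.0),)
    return tuple((float(a), float(p)) for a, p in value)


def build_observing_task(
    q: float = 0.5,
    r_large: float = 1.0,
    r_small: float = 0.04,
    durations: dict | None = None,
    trial_types: dict[str, float] | None = None,
    variant_tag: str = "standard",
) -> TaskSpec:
    """Build the standard observing task graph.

    ``START → {TGT_INFO, TGT_RAND, CHOICE}`` according to the trial-type
    mixture; ``TGT_INFO → CUE_LARGE (q) | CUE_SMALL (1−q)``;
    ``TGT_RAND → CUE_RAND_A | CUE_RAND_B`` (half each); every cue leads to
    the terminal state.  Discriminative cues pay their reward
    deterministically; random cues pay ``r_large`` with probability ``q``
    independent of cue identity, so both options have expected reward
    ``q·r_large + (1−q)·r_small``.

    Negative rewards (aversive variants) are permitted when ``variant_tag``
    is ``"aversive"``.
    """
    if not 0.0 <= q <= 1.0:
        raise TaskValidationError(f"q must lie in [0, 1], got q={q}")
    if variant_tag != "aversive" and r_large <= r_small:
        raise TaskValidationError(
            f"appetitive task requires r_large > r_small, got r_large={r_large}, r_small={r_small}"
        )
    dur = dict(DEFAULT_DURATIONS)
    if durations:
        dur.update(durations)
    for k, v in dur.items():
        if v < 0:
            raise TaskValidationError(f"duration for '{k}' must be >= 0, got {v}")
    mixture = trial_types or {label: 1.0 / 3.0 for label in TRIAL_TYPE_LABELS}

    rand_lottery = ((r_large, q), (r_small, 1.0 - q))
    states = {
        "START": StateSpec(
            "START",
            duration=dur["start"],
            role="start",
            successors=(
                ("TGT_INFO", mixture.get("forced_informative", 0.0)),
                ("TGT_RAND", mixture.get("forced_random", 0.0)),
                ("CHOICE", mixture.get("free_choice", 0.0)),
            ),
        ),
        "CHOICE": StateSpec(
            "CHOICE",
            duration=dur["choice"],
            role="choice",
            is_choice_state=True,
            successors=(("TGT_INFO", 0.5), ("TGT_RAND", 0.5)),
        ),
        "TGT_INFO": StateSpec(
            "TGT_INFO",
            duration=dur["target"],
            role="target",
            successors=(("CUE_LARGE", q), ("CUE_SMALL", 1.0 - q)),
        ),
        "TGT_RAND": StateSpec(
            "TGT_RAND",
            duration=dur["target"],
            role="target",
            successors=(("CUE_RAND_A", 0.5), ("CUE_RAND_B", 0.5)),
        ),
        "CUE_LARGE": StateSpec(
            "CUE_LARGE",
            duration=dur["cue"],
            role="cue",
            successors=(("TERMINAL", 1.0),),
            reward_on_exit=((r_large, 1.0),),
        ),
        "CUE_SMALL": StateSpec(
            "CUE_SMALL",
            duration=dur["cue"],
            role="cue",
            successors=(("TERMINAL", 1.0),),
            reward_on_exit=((r_small, 1.0),),
        ),
        "CUE_RAND_A": StateSpec(
            "CUE_RAND_A",
            duration=dur["cue"],
            role="cue",
            successors=(("TERMINAL", 1.0),),
            reward_on_exit=rand_lottery,
        ),
        "CUE_RAND_B": StateSpec(
            "CUE_RAND_B",
            duration=dur["cue"],
            role="cue",
            successors=(("TERMINAL", 1.0),),
            reward_on_exit=rand_lottery,
        ),
        "TERMINAL": StateSpec("TERMINAL", role="terminal", is_terminal=True),
    }
    task = TaskSpec(
        states=states,
        trial_types=dict(mixture),
        q=q,
        r_large=r_large,
        r_small=r_small,
        variant_tag=variant_tag,
        trial_start={
            "forced_informative": "TGT_INFO",
            "forced_random": "TGT_RAND",
            "free_choice": "CHOICE",
        },
    )
    violations = validate_task(task)
    if violations:
        raise TaskValidationError("; ".join(violations))
    return task


def build_delayed_task(
    q: float = 0.5,
    r_large: float = 1.0,
    r_small: float = 0.04,
    durations: dict | None = None,
    trial_types: dict[str, float] | None = None,
) -> TaskSpec:
    """Immediate-vs-delayed information variant.

    The "immediate" option reveals a discriminative cue at cue time; the
    "delayed" option presents a non-informative hold state for the cue
    period, the reward size becoming apparent only at reward delivery.  The
    immediate option plays the informative role for bias bookkeeping.
    """
    task = build_observing_task(q, r_large, r_small, durations, trial_types, variant_tag="delayed")
    dur_cue = task.state("CUE_RAND_A").duration
    # Replace the two random cues with a single non-informative hold state.
    states = dict(task.states)
    for cue in ("CUE_RAND_A", "CUE_RAND_B"):
        del states[cue]
    states["HOLD"] = StateSpec(
        "HOLD",
        duration=dur_cue,
        role="cue",
        successors=(("TERMINAL", 1.0),),
        reward_on_exit=((r_large, q), (r_small, 1.0 - q)),
    )
    states["TGT_RAND"] = replace(task.state("TGT_RAND"), successors=(("HOLD", 1.0),))
    task.states = states
    violations = validate_task(task)
    if violations:
        raise TaskValidationError("; ".join(violations))
    return task


def apply_reversal(spec: TaskSpec) -> TaskSpec:
    """Swap the two targets' contingencies without touching learned values.

    The state that previously led to discriminative cues now leads to the
    non-discriminative ones and vice versa.  Applied to the environment
    only; applying it twice restores the original contingencies.
    """
    out = spec.copy()
    a, b = spec.option_info, spec.option_rand
    sa, sb = out.states[a], out.states[b]
    out.states[a] = replace(sa, successors=sb.successors)
    out.states[b] = replace(sb, successors=sa.successors)
    if out.variant_tag.endswith("-reversed"):
        out.variant_tag = out.variant_tag[: -len("-reversed")]
    else:
        out.variant_tag = out.variant_tag + "-reversed"
    return out


def sample_trial_type(spec: TaskSpec, rng: np.random.Generator) -> TrialType:
    """Draw a trial type from the task's mixture."""
    labels = list(spec.trial_types)
    probs = np.array([spec.trial_types[l] for l in labels], dtype=float)
    label = labels[rng.choice(len(labels), p=probs)]
    return spec.trial_type(label)


def validate_task(spec: TaskSpec) -> list[str]:
    """Return a list of invariant violations (empty iff the task is valid).

    Never raises: every violation names the offending state and rule.
    """
    out: list[str] = []
    if not np.isclose(sum(spec.trial_types.values()), 1.0):
        out.append("trial_types: mixture probabilities must sum to 1")
    if not 0.0 <= spec.q <= 1.0:
        out.append(f"q: must lie in [0, 1], got {spec.q}")

    n_choice = sum(1 for s in spec.states.values() if s.is_choice_state)
    if n_choice != 1:
        out.append(f"task: exactly one choice state required, found {n_choice}")

    for sid, s in spec.states.items():
        if s.duration < 0:
            out.append(f"{sid}: duration must be >= 0")
        if s.is_terminal and s.successors:
            out.append(f"{sid}: terminal states have no successors")
        if not s.is_terminal and not s.is_choice_state:
            total = sum(p for _, p in s.successors)
            if not np.isclose(total, 1.0):
                out.append(f"{sid}: successor probabilities sum to {total:g}, not 1")
        for nxt, p in s.successors:
            if nxt not in spec.states:
                out.append(f"{sid}: successor '{nxt}' is not a state")
            if not 0.0 <= p <= 1.0:
                out.append(f"{sid}: successor probability {p:g} outside [0, 1]")
        total_rp = sum(p for _, p in s.reward_on_exit)
        if not np.isclose(total_rp, 1.0):
            out.append(f"{sid}: reward lottery probabilities sum to {total_rp:g}, not 1")

    # Every trial type's start state must reach the terminal with prob. 1
    # (choice branches treated as possible).
    if not any(o for o in out if "successor" in o or "not a state" in o):
        for label, start in spec.trial_start.items():
            if start not in spec.states:
                out.append(f"{label}: start state '{start}' is not a state")
                continue
            reached, frontier = set(), {start}
            while frontier:
                sid = frontier.pop()
                reached.add(sid)
                for nxt, p in spec.states[sid].successors:
                    if (p > 0 or spec.states[sid].is_choice_state) and nxt not in reached:
                        frontier.add(nxt)
            if not any(spec.states[sid].is_terminal for sid in reached):
                out.append(f"{label}: start state '{start}' cannot reach a terminal state")

    # Forced-random cues must have reward statistics independent of identity.
    rand_start = spec.trial_start.get("forced_random")
    if rand_start in spec.states:
        lotteries = {
            tuple(sorted(spec.states[nxt].reward_on_exit))
            for nxt, p in spec.states[rand_start].successors
            if p > 0
        }
        if len(lotteries) > 1:
            out.append(
                f"{rand_start}: non-discriminative cues must share one reward lottery"
            )
    return out


def enumerate_paths(
    spec: TaskSpec,
    start: str,
    choice_probs: dict[str, float] | None = None,
) -> list[tuple[tuple[str, ...], float, float]]:
    """Brute-force enumeration of all trial paths from ``start``.

    Returns ``(path, probability, expected reward along the path)`` triples;
    probabilities sum to 1.  Choice-state branches are weighted by
    ``choice_probs`` (default: half each).  Used as the independent oracle
    for expected-value computations.
    """
    results = []

    def walk(sid: str, path: tuple[str, ...], prob: float, reward: float):
        s = spec.states[sid]
        if s.is_terminal:
            results.append((path, prob, reward))
            return
        r_exp = s.expected_reward_on_exit()
        if s.is_choice_state:
            p_info = (choice_probs or {}).get(sid, 0.5)
            branches = [(spec.option_info, p_info), (spec.option_rand, 1.0 - p_info)]
        else:
            branches = list(s.successors)
        for nxt, p in branches:
            if p > 0:
                walk(nxt, path + (nxt,), prob * p, reward + r_exp)

    walk(start, (start,), 1.0, 0.0)
    return results


def objective_values(
    spec: TaskSpec, choice_probs: dict[str, float] | None = None
) -> dict[str, float]:
    """Disengagement-free expected future reward of every state.

    Computed by backward induction on the acyclic graph; the choice state is
    weighted by ``choice_probs`` (default half each).  This is the value
    function a standard TD learner converges to.
    """
    memo: dict[str, float] = {}

    def value(sid: str) -> float:
        if sid in memo:
            return memo[sid]
        s = spec.states[sid]
        if s.is_terminal:
            memo[sid] = 0.0
            return 0.0
        if s.is_choice_state:
            p_info = (choice_probs or {}).get(sid, 0.5)
            branches = [(spec.option_info, p_info), (spec.option_rand, 1.0 - p_info)]
        else:
            branches = s.successors
        memo[sid] = s.expected_reward_on_exit() + sum(p * value(nxt) for nxt, p in branches)
        return memo[sid]

    return {sid: value(sid) for sid in spec.states}


def expected_terminal_reward(spec: TaskSpec) -> float:
    """Expected reward per trial, identical for every option by design."""
    return spec.q * spec.r_large + (1.0 - spec.q) * spec.r_small


# ---------------------------------------------------------------------------
# Serialization

_TASK_KEYS = {"states", "trial_types", "q", "r_large", "r_small", "variant_tag"}


def task_to_dict(spec: TaskSpec) -> dict:
    return {
        "q": spec.q,
        "r_large": spec.r_large,
        "r_small": spec.r_small,
        "variant_tag": spec.variant_tag,
        "trial_types": dict(spec.trial_types),
        "start_state": spec.start_state,
        "choice_state": spec.choice_state,
        "option_info": spec.option_info,
        "option_rand": spec.option_rand,
        "trial_start": dict(spec.trial_start),
        "states": {
            sid: {
                "duration": s.duration,
                "successors": [[n, p] for n, p in s.successors],
                "reward_on_exit": [[a, p] for a, p in s.reward_on_exit],
                "role": s.role,
                "is_choice_state": s.is_choice_state,
                "is_terminal": s.is_terminal,
            }
            for sid, s in spec.states.items()
        },
    }


def task_from_dict(doc: dict) -> TaskSpec:
    missing = _TASK_KEYS - set(doc)
    if missing:
        raise TaskValidationError(f"task document missing keys: {sorted(missing)}")
    states = {
        sid: StateSpec(
            state_id=sid,
            duration=float(d.get("duration", 0.0)),
            successors=tuple((n, float(p)) for n, p in d.get("successors", [])),
            reward_on_exit=_mk_lottery(d.get("reward_on_exit", 0.0)),
            role=d.get("role", "cue"),
            is_choice_state=bool(d.get("is_choice_state", False)),
            is_terminal=bool(d.get("is_terminal", False)),
        )
        for sid, d in doc["states"].items()
    }
    task = TaskSpec(
        states=states,
        trial_types={k: float(v) for k, v in doc["trial_types"].items()},
        q=float(doc["q"]),
        r_large=float(doc["r_large"]),
        r_small=float(doc["r_small"]),
        variant_tag=doc.get("variant_tag", "standard"),
        start_state=doc.get("start_state", "START"),
        choice_state=doc.get("choice_state", "CHOICE"),
        option_info=doc.get("option_info", "TGT_INFO"),
        option_rand=doc.get("option_rand", "TGT_RAND"),
        trial_start=dict(doc.get("trial_start", {})),
    )
    violations = validate_task(task)
    if violations:
        raise TaskValidationError("; ".join(violations))
    return task


def save_task(spec: TaskSpec, path) -> None:
    """Write a task document as YAML (or JSON for a ``.json`` path)."""
    doc = task_to_dict(spec)
    path = str(path)
    with open(path, "w") as fh:
        if path.endswith(".json"):
            json.dump(doc, fh, indent=2)
        else:
            yaml.safe_dump(doc, fh, sort_keys=False)


def load_task(path) -> TaskSpec:
    """Read and validate a YAML or JSON task document."""
    path = str(path)
    with open(path) as fh:
        doc = json.load(fh) if path.endswith(".json") else yaml.safe_load(fh)
    return task_from_dict(doc)
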