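"""Trial and session simulation loops and the in-silico experiments.

A session is 480 trials under an equal three-way mixture of
forced-informative, forced-random and free-choice trials (so 160 choice
trials in expectation).  Learning proceeds on all three sorts of trials;
per-session observing bias — the fraction of free choices of the
informative option — is banded with exact Clopper-Pearson 95% intervals.

The experiment runners reproduce the model's behavioural phenomena:
acquisition of the observing bias and its dependence on the softmax
inverse temperature, the glacial reversal after a contingency switch,
aversive variants under salience vs. valence hazards, and the transient
over-/under-observation induced by mis-initialised values.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .choice_policy import PolicyParams, choice_prob, sample_choice
from .engagement import EngagementParams, sample_engagement
from .task_model import (
    TaskSpec,
    TrialType,
    apply_reversal,
    build_delayed_task,
    build_observing_task,
    objective_values,
    sample_trial_type,
)
from .td_engine import (
    DISENGAGED_STATE,
    PredictionError,
    ValueTable,
    td_error,
    td_error_disengaged,
    td_error_reengage,
    td_update,
)

__all__ = [
    "TrialRecord",
    "SessionSummary",
    "DEFAULT_TRIALS_PER_SESSION",
    "run_trial",
    "run_session",
    "run_acquisition",
    "run_reversal",
    "run_aversive",
    "run_initial_values",
    "clopper_pearson",
    "initial_values",
    "pooled_bias",
    "trials_to_frame",
    "events_to_frame",
    "write_outputs",
]

DEFAULT_TRIALS_PER_SESSION = 480
DEFAULT_ALPHA = 0.1


@dataclass
class TrialRecord:
    """Everything that happened on one trial."""

    trial_index: int
    trial_type: str
    chosen_option: str  # "informative" | "random" | "none" (forced trials)
    cue_shown: str | None
    reward: float
    disengaged_at: str | None
    errors: list[PredictionError] = field(default_factory=list)


@dataclass
class SessionSummary:
    """Per-session observing bias with its exact binomial interval.

    ``bias_defined`` is False (and bias/CI are NaN) when the session
    happened to contain no free-choice trials.
    """

    session_index: int
    n_choice: int
    n_info: int
    bias: float
    ci_low: float
    ci_high: float
    bias_defined: bool = True


def _draw(pairs, rng: np.random.Generator):
    """Draw an item from (item, probability) pairs."""
    u = rng.random()
    acc = 0.0
    for item, p in pairs:
        acc += p
        if u < acc:
            return item
    return pairs[-1][0]


def run_trial(
    V: ValueTable,
    task: TaskSpec,
    eng: EngagementParams,
    policy: PolicyParams,
    rng: np.random.Generator,
    alpha: float = DEFAULT_ALPHA,
    trial_index: int = 0,
    trial_type: TrialType | None = None,
    record_errors: bool = True,
) -> TrialRecord:
    """Simulate one trial, updating ``V`` in place.

    The walk starts in the pre-target state, whose branch is pinned by the
    sampled trial type; on free-choice trials the branch out of the choice
    state is drawn from the softmax on the current target values.  At each
    state with non-zero duration an engagement draw is made: on
    disengagement the state is trained toward the disengaged value and the
    system freezes in the (external stimuli keep arriving but elicit no
    prediction errors) disengaged state until the reward re-engages it with
    δ = r − v_disengaged, which trains nothing.
    """
    if trial_type is None:
        trial_type = sample_trial_type(task, rng)
    errors: list[PredictionError] = []
    engaged = True
    disengaged_at: str | None = None
    chosen = "none"
    cue_shown: str | None = None
    reward = 0.0
    current = task.start_state

    while True:
        s = task.states[current]
        if engaged and s.duration > 0:
            out = sample_engagement(V, current, s.duration, eng, rng)
            if out.disengaged:
                delta = td_error_disengaged(V, current)
                td_update(V, current, delta, alpha)
                if record_errors:
                    errors.append(PredictionError(
                        trial_index, "disengage", current, delta, engaged=False))
                engaged = False
                disengaged_at = current

        if s.is_choice_state:
            p = choice_prob(V.get(task.option_info), V.get(task.option_rand),
                            policy, clamp=True)
            chosen = sample_choice(p, rng)
            nxt = task.option_info if chosen == "informative" else task.option_rand
        elif current == task.start_state:
            nxt = trial_type.start_state
        else:
            nxt = _draw(s.successors, rng)

        lottery = s.reward_on_exit
        r = lottery[0][0] if len(lottery) == 1 else _draw(lottery, rng)
        next_spec = task.states[nxt]
        if next_spec.role == "cue" and cue_shown is None:
            cue_shown = nxt
        label = "reward" if next_spec.is_terminal else next_spec.role

        if engaged:
            delta = td_error(V, current, r, nxt)
            td_update(V, current, delta, alpha)
            if record_errors:
                errors.append(PredictionError(trial_index, label, current, delta))
        elif next_spec.is_terminal:
            delta = td_error_reengage(V, r)
            if record_errors:
                errors.append(PredictionError(
                    trial_index, "reward", DISENGAGED_STATE, delta, engaged=False))
        elif record_errors:
            errors.append(PredictionError(
                trial_index, label, DISENGAGED_STATE, 0.0, engaged=False))

        if next_spec.is_terminal:
            reward = r
            break
        current = nxt

    return TrialRecord(
        trial_index=trial_index,
        trial_type=trial_type.label,
        chosen_option=chosen,
        cue_shown=cue_shown,
        reward=reward,
        disengaged_at=disengaged_at,
        errors=errors,
    )


def clopper_pearson(k: int, n: int, conf: float = 0.95) -> tuple[float, float]:
    """Exact (Clopper-Pearson) binomial confidence interval for k/n.

    Beta-quantile construction; the lower bound is exactly 0 at k = 0 and
    the upper exactly 1 at k = n.
    """
    if n < 1 or not 0 <= k <= n or k != int(k) or n != int(n):
        raise ValueError(f"need integers 0 <= k <= n with n >= 1, got k={k}, n={n}")
    a = 1.0 - conf
    low = 0.0 if k == 0 else float(stats.beta.ppf(a / 2.0, k, n - k + 1))
    high = 1.0 if k == n else float(stats.beta.ppf(1.0 - a / 2.0, k + 1, n - k))
    return low, high


def summarize_session(records, session_index: int = 0, conf: float = 0.95) -> SessionSummary:
    """Observing bias over a session's free-choice trials with its CI."""
    n_choice = sum(1 for r in records if r.trial_type == "free_choice")
    n_info = sum(1 for r in records if r.chosen_option == "informative")
    if n_choice == 0:
        return SessionSummary(session_index, 0, 0, math.nan, math.nan, math.nan,
                              bias_defined=False)
    low, high = clopper_pearson(n_info, n_choice, conf)
    return SessionSummary(session_index, n_choice, n_info, n_info / n_choice, low, high)


def run_session(
    task: TaskSpec,
    eng: EngagementParams,
    policy: PolicyParams,
    rng: np.random.Generator,
    n_trials: int = DEFAULT_TRIALS_PER_SESSION,
    V: ValueTable | None = None,
    alpha: float = DEFAULT_ALPHA,
    session_index: int = 0,
    trial_offset: int = 0,
    record_errors: bool = True,
) -> tuple[list[TrialRecord], SessionSummary]:
    """Run one session of ``n_trials`` trials, carrying values in ``V``.

    ``V`` defaults to a fresh table at the task's objective values and is
    updated in place so sessions can be chained.
    """
    if n_trials <= 0:
        raise ValueError(f"n_trials must be > 0, got {n_trials}")
    if V is None:
        V = initial_values(task, eng)
    records = [
        run_trial(V, task, eng, policy, rng, alpha=alpha,
                  trial_index=trial_offset + i, record_errors=record_errors)
        for i in range(n_trials)
    ]
    return records, summarize_session(records, session_index)


def initial_values(task: TaskSpec, eng: EngagementParams,
                   v0: float | dict | None = None) -> ValueTable:
    """Fresh value table for a run.

    By default states start at the task's objective (disengagement-free)
    expectations, emulating subjects pre-trained on the contingencies; a
    scalar or per-state ``v0`` overrides this for mis-initialisation
    experiments.
    """
    if v0 is None:
        v0 = {s: v for s, v in objective_values(task).items()}
    return ValueTable.from_task(task, v0=v0, v_disengaged=eng.v_disengaged)


def _session_rngs(seed: int, n: int) -> list[np.random.Generator]:
    # Counter-style derivation: each session gets an independent child
    # stream of the master seed, so runs are reproducible per session.
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def _run_sessions(task_per_session, eng, policy, n_sessions, seed, n_trials,
                  alpha, v0, record_errors=False, collect_records=False):
    V = initial_values(task_per_session(1), eng, v0=v0)
    rngs = _session_rngs(seed, n_sessions)
    rows, all_records = [], []
    for k in range(1, n_sessions + 1):
        task = task_per_session(k)
        records, summary = run_session(
            task, eng, policy, rngs[k - 1], n_trials=n_trials, V=V, alpha=alpha,
            session_index=k, trial_offset=(k - 1) * n_trials,
            record_errors=record_errors,
        )
        rows.append(summary.__dict__)
        if collect_records:
            all_records.extend(records)
    df = pd.DataFrame(rows).rename(columns={"session_index": "session"})
    return (df, V, all_records) if collect_records else (df, V, None)


def run_acquisition(
    n_sessions: int = 25,
    beta: float = 10.0,
    seed: int = 0,
    task: TaskSpec | None = None,
    eng: EngagementParams | None = None,
    policy: PolicyParams | None = None,
    n_trials: int = DEFAULT_TRIALS_PER_SESSION,
    alpha: float = DEFAULT_ALPHA,
    v0: float | dict | None = None,
    full_output: bool = False,
):
    """Acquisition of the observing bias over sessions.

    Values are fresh at session 1 and persist across sessions; returns one
    row per session with the bias and its Clopper-Pearson interval.  With
    disengagement on and a reasonably high β the bias climbs from 0.5
    toward an asymptote above it.
    """
    task = task or build_observing_task()
    eng = eng if eng is not None else EngagementParams()
    policy = policy or PolicyParams(beta=beta)
    df, V, _ = _run_sessions(lambda k: task, eng, policy, n_sessions, seed,
                             n_trials, alpha, v0)
    return (df, V) if full_output else df


def run_reversal(
    n_sessions: int = 30,
    switch_session: int = 16,
    beta: float = 10.0,
    seed: int = 0,
    task: TaskSpec | None = None,
    eng: EngagementParams | None = None,
    policy: PolicyParams | None = None,
    n_trials: int = DEFAULT_TRIALS_PER_SESSION,
    alpha: float = DEFAULT_ALPHA,
    v0: float | dict | None = None,
) -> pd.DataFrame:
    """Contingency reversal without warning: bias trajectory across sessions.

    The targets' contingencies are swapped at the start of
    ``switch_session`` (1-based) while learned values are carried over
    untouched, so the preference reverses at the same glacial pace as it
    was acquired.  Defaults to the immediate-vs-delayed information task.
    """
    base = task or build_delayed_task()
    reversed_task = apply_reversal(base)

    def task_for(k: int) -> TaskSpec:
        return reversed_task if k >= switch_session else base

    df, _, _ = _run_sessions(task_for, eng if eng is not None else EngagementParams(),
                             policy or PolicyParams(beta=beta),
                             n_sessions, seed, n_trials, alpha, v0)
    df["reversed"] = df["session"] >= switch_session
    return df


def pooled_bias(df: pd.DataFrame, last: int = 5, conf: float = 0.95) -> SessionSummary:
    """Bias pooled over the final ``last`` sessions of a trajectory."""
    tail = df.tail(last)
    n = int(tail["n_choice"].sum())
    k = int(tail["n_info"].sum())
    return summarize_session([], 0) if n == 0 else SessionSummary(
        0, n, k, k / n, *clopper_pearson(k, n, conf))


def run_aversive(
    hazard_family: str = "salience",
    n_seeds: int = 20,
    n_sessions: int = 10,
    beta: float = 10.0,
    seed: int = 0,
    r_large: float = -1.0,
    r_small: float = -0.04,
    q: float = 0.5,
    eng: EngagementParams | None = None,
    n_trials: int = DEFAULT_TRIALS_PER_SESSION,
    alpha: float = DEFAULT_ALPHA,
) -> pd.DataFrame:
    """Observing with aversive outcomes under a salience or valence hazard.

    Outcomes are punishments (negative rewards).  A salience-shaped hazard
    (symmetric in |value|) lets disengagement inflate the subjective value
    of the non-discriminative cues toward the disengaged value, so subjects
    prefer the random option (bias < 0.5); a valence-shaped (asymmetric)
    hazard instead disengages hardest from the large-punishment cue and
    supports observing.  Returns asymptotic bias per seed.
    """
    task = build_observing_task(q=q, r_large=r_large, r_small=r_small,
                                variant_tag="aversive")
    if eng is None:
        eng = EngagementParams(hazard_family=hazard_family)
    rows = []
    for i in range(n_seeds):
        df = run_acquisition(n_sessions=n_sessions, beta=beta,
                             seed=seed + 1000 + i, task=task, eng=eng,
                             policy=PolicyParams(beta=beta),
                             n_trials=n_trials, alpha=alpha)
        tail = pooled_bias(df, last=max(1, n_sessions // 2))
        rows.append({"seed": seed + 1000 + i, "hazard_family": eng.hazard_family,
                     "bias": tail.bias, "n_choice": tail.n_choice})
    return pd.DataFrame(rows)


def run_initial_values(
    v0: float,
    q: float,
    n_sessions: int = 20,
    beta: float = 10.0,
    seed: int = 0,
    eng: EngagementParams | None = None,
    n_trials: int = DEFAULT_TRIALS_PER_SESSION,
    alpha: float = DEFAULT_ALPHA,
) -> pd.DataFrame:
    """Bias trajectory when all states start at value ``v0``.

    Far-from-correct initial values create transients: low v0 with a rich
    reward schedule (high q) produces early over-observation, high v0 with
    a lean schedule early under-observation, relative to the run's own
    long-run level.
    """
    task = build_observing_task(q=q)
    return run_acquisition(n_sessions=n_sessions, beta=beta, seed=seed,
                           task=task, eng=eng, n_trials=n_trials, alpha=alpha,
                           v0=float(v0))


def long_run_values(
    task: TaskSpec,
    eng: EngagementParams,
    policy: PolicyParams,
    n_trials: int = 100_000,
    alpha: float = 0.02,
    seed: int = 0,
    burn_in: int | None = None,
    v0: float | dict | None = None,
) -> dict[str, float]:
    """Time-averaged state values over a long simulated run.

    With a constant learning rate the values fluctuate around their
    stationary means; the post-burn-in time average is the consistent
    estimator of the long-run value and is what the fixed-point solution
    should be compared against.
    """
    V = initial_values(task, eng, v0=v0)
    rng = np.random.default_rng(seed)
    burn_in = n_trials // 5 if burn_in is None else burn_in
    sums = {s: 0.0 for s in V.values}
    count = 0
    for i in range(n_trials):
        run_trial(V, task, eng, policy, rng, alpha=alpha, trial_index=i,
                  record_errors=False)
        if i >= burn_in:
            for s in sums:
                sums[s] += V.values[s]
            count += 1
    return {s: total / count for s, total in sums.items()}


def dopamine_probe(
    task: TaskSpec | None = None,
    eng: EngagementParams | None = None,
    policy: PolicyParams | None = None,
    seeds=range(12),
    n_train: int = 4,
    n_anneal: int = 2,
    n_probe: int = 5,
    alpha_train: float = DEFAULT_ALPHA,
    alpha_probe: float = 0.01,
    n_trials: int = DEFAULT_TRIALS_PER_SESSION,
) -> pd.DataFrame:
    """Mean modelled dopamine response per trial type and event after learning.

    Trains at the learning-rate default, then anneals to a small probe
    learning rate before recording: the asymptotic target-event response is
    of order 0.01 reward units, and at large α it is masked by value
    fluctuation (free choices preferentially sample whichever target is
    transiently overvalued, inflating the pre-target value).  Returns the
    across-seed mean δ per (trial_type, event).
    """
    task = task or build_observing_task()
    eng = eng if eng is not None else EngagementParams()
    policy = policy or PolicyParams()
    sums: dict[tuple[str, str], list[float]] = {}
    for seed in seeds:
        _, V = run_acquisition(n_sessions=n_train, seed=seed, task=task, eng=eng,
                               policy=policy, n_trials=n_trials,
                               alpha=alpha_train, full_output=True)
        rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
        for _ in range(n_anneal):
            run_session(task, eng, policy, rng, n_trials=n_trials, V=V,
                        alpha=alpha_probe, record_errors=False)
        for _ in range(n_probe):
            records, _ = run_session(task, eng, policy, rng, n_trials=n_trials,
                                     V=V, alpha=alpha_probe, record_errors=True)
            for rec in records:
                for e in rec.errors:
                    sums.setdefault((rec.trial_type, e.event_label), []).append(e.delta)
    rows = [
        {"trial_type": tt, "event": ev, "delta": float(np.mean(d)), "n_events": len(d)}
        for (tt, ev), d in sorted(sums.items())
    ]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Tabular output

def trials_to_frame(records) -> pd.DataFrame:
    return pd.DataFrame([
        {
            "trial": r.trial_index,
            "trial_type": r.trial_type,
            "chosen_option": r.chosen_option,
            "cue_shown": r.cue_shown,
            "reward": r.reward,
            "disengaged_at": r.disengaged_at,
        }
        for r in records
    ])


def events_to_frame(records) -> pd.DataFrame:
    """Prediction-error stream in deterministic (trial, event-time) order."""
    rows = []
    for r in records:
        for e in r.errors:
            rows.append({
                "trial": e.trial_index,
                "event": e.event_label,
                "state": e.state_id,
                "delta": e.delta,
                "engaged": e.engaged,
            })
    return pd.DataFrame(rows)


def write_outputs(out_dir, sessions: pd.DataFrame | None = None,
                  trials=None, events=None, fixed_point: pd.DataFrame | None = None,
                  config: dict | None = None, seed: int | None = None,
                  fmt: str = "csv") -> Path:
    """Write result tables plus a ``run_manifest.json`` to ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    def dump(df: pd.DataFrame, name: str):
        if fmt == "json":
            df.to_json(out / f"{name}.json", orient="records", indent=2)
        else:
            df.to_csv(out / f"{name}.csv", index=False)

    if sessions is not None:
        dump(sessions, "sessions")
    if trials is not None:
        dump(trials_to_frame(trials) if not isinstance(trials, pd.DataFrame) else trials,
             "trials")
    if events is not None:
        dump(events_to_frame(events) if not isinstance(events, pd.DataFrame) else events,
             "td_events")
    if fixed_point is not None:
        dump(fixed_point, "fixed_point")

    from . import __version__
    cfg = config or {}
    manifest = {
        "config_sha256": hashlib.sha256(
            json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest(),
        "seed": seed,
        "package_version": __version__,
    }
    (out / "run_manifest.json").write_text(json.dumps(manifest, indent=2))
    return out
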