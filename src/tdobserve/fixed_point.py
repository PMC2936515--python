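"""Self-consistent asymptotic values under disengagement.

In the small-learning-rate limit every state's learned value settles where
it equals the expectation of its own update targets.  A state s that is
occupied for τ_s seconds disengages during that occupancy with probability
P_s = 1 − (1 − ρ(V(s)))^{τ_s}, in which case its update target is the
disengaged value; otherwise the target is the usual one-step backup.  The
asymptotic values therefore solve

    V(s) = (1 − P_s(V(s))) · ( E[r_exit] + Σ_{s'} p(s'|s) V(s') ) + P_s(V(s)) · v_d

with the choice state's branch probabilities given by the softmax on the
current values — a nonlinear fixed point solved here by damped iteration,
from several initialisations so non-uniqueness is flagged rather than
silently hidden.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .choice_policy import PolicyParams, choice_prob
from .engagement import EngagementParams, disengage_hazard, p_disengage_state
from .task_model import TaskSpec, build_observing_task, objective_values

__all__ = [
    "FixedPointResult",
    "FixedPointNonConvergence",
    "solve_self_consistent",
    "bias_vs_reward_prob",
]


class FixedPointNonConvergence(RuntimeError):
    """Damped iteration failed to reach tolerance.

    Carries the final residual; persistent oscillation usually responds to
    a smaller damping factor.
    """

    def __init__(self, residual: float, max_iter: int):
        self.residual = residual
        super().__init__(
            f"fixed-point iteration did not converge within {max_iter} iterations "
            f"(residual {residual:.3e}); consider a smaller damping factor"
        )


@dataclass
class FixedPointResult:
    """Solution of the self-consistency equations.

    ``values`` and ``bias`` come from the deterministic (objective-value)
    initialisation; ``solutions`` lists every distinct solution found across
    initialisations (length > 1 flags non-uniqueness).
    """

    values: dict[str, float]
    bias: float
    iterations: int
    residual: float
    solutions: list[dict[str, float]] = field(default_factory=list)


def _backup(task: TaskSpec, eng: EngagementParams, policy: PolicyParams,
            V: dict[str, float]) -> tuple[dict[str, float], float]:
    """One application of the disengagement-weighted expectation operator."""
    def value(sid):
        return 0.0 if task.states[sid].is_terminal else V[sid]

    p_info = choice_prob(V[task.option_info], V[task.option_rand], policy, clamp=True)
    out = {}
    for sid, s in task.states.items():
        if s.is_terminal:
            continue
        if s.is_choice_state:
            branches = [(task.option_info, p_info), (task.option_rand, 1.0 - p_info)]
        else:
            branches = s.successors
        engaged_target = s.expected_reward_on_exit() + sum(
            p * value(nxt) for nxt, p in branches
        )
        p_dis = p_disengage_state(disengage_hazard(V[sid], eng), s.duration)
        out[sid] = (1.0 - p_dis) * engaged_target + p_dis * eng.v_disengaged
    return out, p_info


def _iterate(task, eng, policy, V0, tol, max_iter, damping):
    V = dict(V0)
    for it in range(1, max_iter + 1):
        target, p_info = _backup(task, eng, policy, V)
        residual = max(abs(target[s] - V[s]) for s in target)
        V = {s: (1.0 - damping) * V[s] + damping * target[s] for s in target}
        if residual < tol:
            return V, p_info, it, residual
    raise FixedPointNonConvergence(residual, max_iter)


def solve_self_consistent(
    task: TaskSpec,
    eng: EngagementParams,
    policy: PolicyParams,
    tol: float = 1e-10,
    max_iter: int = 100_000,
    damping: float = 0.5,
    n_init: int = 5,
    seed: int = 0,
) -> FixedPointResult:
    """Solve the asymptotic value equations by damped fixed-point iteration.

    Runs once from the disengagement-free objective values and ``n_init``
    times from random initialisations; all distinct solutions are reported.
    The returned ``bias`` is the asymptotic probability of choosing the
    informative option at the solution.
    """
    if tol <= 0:
        raise ValueError(f"tol must be > 0, got {tol}")
    V0 = {s: v for s, v in objective_values(task).items()
          if not task.states[s].is_terminal}
    V, p_info, iterations, residual = _iterate(task, eng, policy, V0, tol, max_iter, damping)

    solutions = [V]
    rng = np.random.default_rng(seed)
    scale = max(abs(task.r_large), abs(task.r_small), abs(eng.v_disengaged), 1.0)
    lo = min(0.0, task.r_large, task.r_small)
    hi = max(0.0, task.r_large, task.r_small)
    for _ in range(n_init):
        Vr = {s: float(rng.uniform(lo - 0.1 * scale, hi + 0.1 * scale)) for s in V0}
        Vs, _, _, _ = _iterate(task, eng, policy, Vr, tol, max_iter, damping)
        if not any(
            max(abs(Vs[s] - sol[s]) for s in Vs) < 1e3 * tol for sol in solutions
        ):
            solutions.append(Vs)
    return FixedPointResult(
        values=V, bias=p_info, iterations=iterations, residual=residual,
        solutions=solutions,
    )


def bias_vs_reward_prob(
    q_grid,
    eng: EngagementParams,
    policy: PolicyParams,
    r_large: float = 1.0,
    r_small: float = 0.04,
    rules: tuple[str, ...] = ("softmax_difference", "softmax_log"),
    **solver_kwargs,
) -> pd.DataFrame:
    """Asymptotic observing bias as a function of the large-reward rate q.

    Solves the fixed point at each q on the grid under each softmax rule
    (same β), returning a tidy frame with columns ``(q, rule, bias)``.  The
    difference rule yields a bias curve asymmetric about q = 0.5 that fades
    as values shrink; the ratio (log) rule keeps growing as rewards thin.
    """
    rows = []
    for q in q_grid:
        if not 0.0 < q < 1.0:
            raise ValueError(f"q grid values must lie in (0, 1), got {q}")
        task = build_observing_task(q=q, r_large=r_large, r_small=r_small)
        for rule in rules:
            pol = PolicyParams(beta=policy.beta, rule=rule)
            try:
                res = solve_self_consistent(task, eng, pol, **solver_kwargs)
            except FixedPointNonConvergence as exc:
                exc.args = (f"at q={q} under rule '{rule}': {exc}",)
                raise
            rows.append({"q": q, "rule": rule, "bias": res.bias})
    return pd.DataFrame(rows)
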