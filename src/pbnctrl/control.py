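"""Minimax finite-horizon control of a PBN by backward dynamic programming.

Given terminal costs ``C(z)`` over the ``2**n`` states, a horizon ``M`` and an
initial state ``z0``, the controller picks at every step a control value
``u in [1, 2**m]`` so that the *worst case* terminal cost over all
trajectories the PBN may follow is minimized:

    J_M(z) = C(z)
    J_t(z) = min_u  max_{z' in F(z, u)}  J_{t+1}(z')

where ``F(z, u)`` is the one-step successor set (support of the unperturbed
transition column).  The value of the problem is ``J_0(z0)``; the argmin
(smallest control index on ties) is the feedback policy.

Two independent brute-force oracles are provided: a memoization-free
game-tree recursion and an open-loop enumeration over fixed control
sequences (which can only do worse than feedback).  ``compare_original_reduced``
runs the solver on a network and on its state-reduced version and checks the
two values agree.
"""

from __future__ import annotations

import itertools
import time
from dataclasses import dataclass, field

import numpy as np

from .model import (
    ControlledTransitionModel,
    InvalidInputError,
    ProbabilisticBooleanNetwork,
    reachable_set,
)
from .reduction import ReductionConfig, ReductionResult, critical_states, reduce_network


class ReducedModelInconsistencyError(RuntimeError):
    """A successor escaped the supplied state set: the reduction was unsound."""


class InstanceTooLargeError(ValueError):
    """Brute-force oracle invoked on an instance beyond its guard."""


@dataclass
class ControlProblem:
    """Horizon ``M``, terminal cost vector (index ``z-1``), initial state and
    the optional control-switch budget (None = unlimited switches)."""

    M: int
    terminal_cost: np.ndarray
    z0: int
    switch_budget: int | None = None

    def __post_init__(self) -> None:
        self.terminal_cost = np.asarray(self.terminal_cost, dtype=float)
        if self.M < 1:
            raise InvalidInputError("horizon M must be >= 1")

    @classmethod
    def identity_cost(cls, n: int, M: int, z0: int, **kw) -> "ControlProblem":
        """The experimental setup ``C(z) = z`` on ``2**n`` states."""
        return cls(M=M, terminal_cost=np.arange(1, (1 << n) + 1, dtype=float),
                   z0=z0, **kw)


@dataclass
class MinimaxSolution:
    """Value ``J_0(z0)``, per-time value tables, feedback policy and the
    realized worst-case control sequence."""

    value: float
    policy: dict[tuple[int, int], int]          # (state, t) -> u
    value_tables: list[dict[int, float]]        # t -> {state: J_t(state)}
    realized_sequence: list[int]
    states: tuple[int, ...]
    budget_policy: dict[tuple[int, int, int], int] | None = None  # (state, h, t)


def _successor_table(
    model: ControlledTransitionModel, states: tuple[int, ...]
) -> list[list[np.ndarray]]:
    """succ[u-1][k] = indices (into ``states``) of F(states[k], u); raises if
    any successor leaves ``states``."""
    index = {z: k for k, z in enumerate(states)}
    table: list[list[np.ndarray]] = []
    for u in range(1, model.n_controls + 1):
        per_state = []
        for z in states:
            F = reachable_set(model, z, u)
            missing = F - index.keys()
            if missing:
                raise ReducedModelInconsistencyError(
                    f"F({z},{u}) contains deleted state(s) {sorted(missing)}"
                )
            per_state.append(np.asarray(sorted(index[s] for s in F), dtype=np.intp))
        table.append(per_state)
    return table


def minimax_dp(
    model: ControlledTransitionModel,
    problem: ControlProblem,
    states: tuple[int, ...] | None = None,
) -> MinimaxSolution:
    """Backward minimax DP on the full state space or a reduced state set."""
    if states is None:
        states = tuple(range(1, model.n_states + 1))
    else:
        states = tuple(sorted(int(s) for s in states))
    if problem.z0 not in states:
        raise InvalidInputError(f"initial state {problem.z0} not in the state set")
    succ = _successor_table(model, states)
    cost = np.asarray([problem.terminal_cost[z - 1] for z in states], dtype=float)

    if problem.switch_budget is not None:
        return _minimax_dp_budget(model, problem, states, succ, cost)

    J = cost.copy()
    tables = [dict(zip(states, J))]
    policy: dict[tuple[int, int], int] = {}
    for t in range(problem.M - 1, -1, -1):
        newJ = np.empty_like(J)
        for k in range(len(states)):
            best_u, best_v = 1, np.inf
            for u in range(1, model.n_controls + 1):
                v = J[succ[u - 1][k]].max()
                if v < best_v:  # strict: smallest u wins ties
                    best_u, best_v = u, v
            newJ[k] = best_v
            policy[(states[k], t)] = best_u
        J = newJ
        tables.append(dict(zip(states, J)))
    tables.reverse()  # tables[t] = J_t
    value = float(J[states.index(problem.z0)])
    sol = MinimaxSolution(
        value=value, policy=policy, value_tables=tables,
        realized_sequence=[], states=states,
    )
    traj, _ = rollout_worst_case(model, sol, problem)
    return sol


def _minimax_dp_budget(model, problem, states, succ, cost) -> MinimaxSolution:
    """Switch-budget variant: keeping the control chosen downstream is free,
    changing it spends one unit of the budget ``h``; at ``h = 0`` no further
    changes are allowed (infeasible branches cost +inf)."""
    H = problem.switch_budget
    S, U = len(states), model.n_controls
    INF = np.inf
    # J[h, k]; Upol[h, k] with 0 = "no downstream commitment" (terminal layer)
    J = np.tile(cost, (H + 1, 1))
    Upol = np.zeros((H + 1, S), dtype=np.intp)
    tables = [ {s: float(cost[k]) for k, s in enumerate(states)} ]
    budget_policy: dict[tuple[int, int, int], int] = {}
    policy: dict[tuple[int, int], int] = {}
    for t in range(problem.M - 1, -1, -1):
        newJ = np.full((H + 1, S), INF)
        newU = np.zeros((H + 1, S), dtype=np.intp)
        for h in range(H + 1):
            for k in range(S):
                best_u, best_v = 0, INF
                for u in range(1, U + 1):
                    worst = -INF
                    for k2 in succ[u - 1][k]:
                        match = Upol[h, k2] in (0, u)
                        if match:
                            v = J[h, k2]
                        elif h >= 1:
                            v = J[h - 1, k2]
                        else:
                            v = INF
                        worst = max(worst, v)
                    if worst < best_v:
                        best_u, best_v = u, worst
                newJ[h, k], newU[h, k] = best_v, best_u
                budget_policy[(states[k], h, t)] = best_u
        J, Upol = newJ, newU
        tables.append({s: float(J[H, k]) for k, s in enumerate(states)})
        for k, s in enumerate(states):
            policy[(s, t)] = int(Upol[H, k])
    tables.reverse()
    value = float(J[H, states.index(problem.z0)])
    return MinimaxSolution(
        value=value, policy=policy, value_tables=tables,
        realized_sequence=[], states=states, budget_policy=budget_policy,
    )


def rollout_worst_case(
    model: ControlledTransitionModel,
    solution: MinimaxSolution,
    problem: ControlProblem,
) -> tuple[list[int], float]:
    """Follow the policy, letting the adversary pick the successor with the
    largest next-stage value (smallest state on ties).  Fills in
    ``solution.realized_sequence`` and returns (trajectory, terminal cost)."""
    z = problem.z0
    traj = [z]
    seq: list[int] = []
    for t in range(problem.M):
        u = solution.policy[(z, t)]
        F = sorted(reachable_set(model, z, u))
        nxt_table = solution.value_tables[t + 1]
        z = max(F, key=lambda s: (nxt_table[s], -s))
        seq.append(u)
        traj.append(z)
    solution.realized_sequence = seq
    return traj, float(problem.terminal_cost[traj[-1] - 1])


def game_tree_value(
    model: ControlledTransitionModel,
    problem: ControlProblem,
    states: tuple[int, ...] | None = None,
    max_nodes: int = 5_000_000,
) -> float:
    """Memoization-free recursive minimax value — the independent oracle.

    ``V(z, t) = C(z)`` at ``t = M``, else ``min_u max_{z' in F(z,u)} V(z', t+1)``.
    Guarded against blow-up via a rough node-count estimate.
    """
    if states is None:
        states = tuple(range(1, model.n_states + 1))
    maxF = max(
        len(reachable_set(model, z, u))
        for z in states for u in range(1, model.n_controls + 1)
    )
    if (model.n_controls * maxF) ** problem.M > max_nodes:
        raise InstanceTooLargeError("game tree too deep/broad for brute force")

    def V(z: int, t: int) -> float:
        if t == problem.M:
            return float(problem.terminal_cost[z - 1])
        return min(
            max(V(z2, t + 1) for z2 in sorted(reachable_set(model, z, u)))
            for u in range(1, model.n_controls + 1)
        )

    return V(problem.z0, 0)


def open_loop_bruteforce(
    model: ControlledTransitionModel, problem: ControlProblem
) -> float:
    """Best fixed control sequence: min over ``u_0..u_{M-1}`` of the worst
    terminal cost over all trajectories the sequence allows."""
    if model.m * problem.M > 20:
        raise InstanceTooLargeError("2^(m*M) control sequences is too many")
    best = np.inf
    controls = range(1, model.n_controls + 1)
    for seq in itertools.product(controls, repeat=problem.M):
        reach = {problem.z0}
        for u in seq:
            reach = set().union(*(reachable_set(model, z, u) for z in reach))
        worst = max(problem.terminal_cost[z - 1] for z in reach)
        best = min(best, worst)
    return float(best)


def compare_original_reduced(
    pbn: ProbabilisticBooleanNetwork,
    problem: ControlProblem,
    config: ReductionConfig | None = None,
) -> dict:
    """Solve the minimax problem on the original and the reduced network.

    Reduction preserves the critical states (recurrent states plus ``z0``)
    unless an explicit config is given.  The two values must agree whenever
    the reduced support never escapes the kept set (the reduction guard);
    an escape raises :class:`ReducedModelInconsistencyError`.
    """
    model = ControlledTransitionModel.from_pbn(pbn)
    if config is None:
        preserve = critical_states(model, problem.z0)
        config = ReductionConfig(preserve=frozenset(preserve))
    t0 = time.perf_counter()
    sol_orig = minimax_dp(model, problem)
    t1 = time.perf_counter()
    result = reduce_network(model, config)
    sol_red = minimax_dp(model, problem, states=result.kept)
    t2 = time.perf_counter()
    return {
        "value_original": sol_orig.value,
        "value_reduced": sol_red.value,
        "equal": sol_orig.value == sol_red.value,
        "size_original": model.n_states,
        "size_reduced": result.n_kept,
        "time_original": t1 - t0,
        "time_reduced": t2 - t1,
        "reduction": result,
        "solution_original": sol_orig,
        "solution_reduced": sol_red,
    }
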