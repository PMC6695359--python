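"""Model-based (MB) learner.

The MB system estimates the task's transition function T(s, a, s') and
reward function R(s, a) from experience, then plans by solving the Bellman
equation for action values Q and acting on the *advantage*
A(s, a) = Q(s, a) - max_j Q(s, a_j), which is 0 for the best action(s) and
negative otherwise.  T is updated only on the observed triple (no row
renormalization): in this deterministic task every visited transition
converges to 1 and impossible ones stay at 0, but transiently T — and hence
the advantages — are biased by the agent's own choice history.
"""

from __future__ import annotations

from .errors import StgtSimError
from .task import TaskGraph

__all__ = [
    "WorldModel",
    "QTable",
    "update_transition",
    "update_reward",
    "solve_q",
    "advantage",
]


class WorldModel:
    """Learned transition and reward functions, both initialized at zero.

    ``T[(s, a)]`` maps observed successor states to pseudo-probabilities in
    [0, 1]; unobserved triples are simply absent (i.e. 0).
    """

    __slots__ = ("T", "R")

    def __init__(self) -> None:
        self.T: dict[tuple[str, str], dict[str, float]] = {}
        self.R: dict[tuple[str, str], float] = {}

    def transition(self, s: str, a: str, s_next: str) -> float:
        return self.T.get((s, a), {}).get(s_next, 0.0)

    def reward(self, s: str, a: str) -> float:
        return self.R.get((s, a), 0.0)

    def copy(self) -> "WorldModel":
        out = WorldModel()
        out.T = {sa: dict(row) for sa, row in self.T.items()}
        out.R = dict(self.R)
        return out


def update_transition(
    model: WorldModel, s: str, a: str, s_next: str, alpha: float
) -> WorldModel:
    """T(s,a,s') <- (1-alpha) T(s,a,s') + alpha for the observed triple only."""
    row = model.T.setdefault((s, a), {})
    row[s_next] = (1.0 - alpha) * row.get(s_next, 0.0) + alpha
    return model


def update_reward(
    model: WorldModel, s: str, a: str, r: float, alpha: float
) -> WorldModel:
    """R(s,a) <- R(s,a) + alpha (r - R(s,a))."""
    sa = (s, a)
    model.R[sa] = model.R.get(sa, 0.0) + alpha * (r - model.R.get(sa, 0.0))
    return model


class QTable:
    """Bellman action values and derived advantages on a task graph."""

    __slots__ = ("q",)

    def __init__(self, q: dict[tuple[str, str], float]):
        self.q = q

    def value(self, s: str, a: str) -> float:
        return self.q[(s, a)]

    def state_value(self, graph: TaskGraph, s: str) -> float:
        return max(self.q[(s, a)] for a in graph.actions(s))

    def advantages(self, graph: TaskGraph, s: str) -> dict[str, float]:
        actions = graph.actions(s)
        best = max(self.q[(s, a)] for a in actions)
        return {a: self.q[(s, a)] - best for a in actions}


def solve_q(
    model: WorldModel,
    graph: TaskGraph,
    gamma: float,
    tol: float = 1e-9,
    max_iter: int = 10_000,
    q_init: QTable | None = None,
) -> QTable:
    """Fixed point of Q(s,a) = R(s,a) + gamma * sum_s' T(s,a,s') max_a' Q(s',a').

    Synchronous value iteration until the largest absolute change drops
    below ``tol``.  Episode end contributes zero continuation value (the
    ``eat`` transition has no successor and no T entry), so
    Q(terminal action) converges to R exactly.  ``q_init`` warm-starts the
    iteration; the fixed point is unique for gamma < 1 so the start only
    affects speed.
    """
    pairs = list(graph.state_action_pairs())
    if q_init is not None:
        q = {sa: q_init.q.get(sa, 0.0) for sa in pairs}
    else:
        q = {sa: 0.0 for sa in pairs}
    R = model.R
    T = model.T
    states = graph.states
    action_map = graph.action_map
    for _ in range(max_iter):
        v = {
            s: max(q[(s, a)] for a in action_map[s])
            for s in states
        }
        delta = 0.0
        new_q = {}
        for sa in pairs:
            total = R.get(sa, 0.0)
            row = T.get(sa)
            if row:
                total += gamma * sum(p * v[s2] for s2, p in row.items())
            new_q[sa] = total
            d = abs(total - q[sa])
            if d > delta:
                delta = d
        q = new_q
        if delta < tol:
            return QTable(q)
    raise StgtSimError(
        f"value iteration did not converge within {max_iter} iterations"
    )


def advantage(q: QTable, graph: TaskGraph, s: str) -> dict[str, float]:
    """A(s,a) = Q(s,a) - max_j Q(s,a_j) for every action available in s."""
    return q.advantages(graph, s)
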