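"""Dual-system agent: FMF + MB integration, softmax choice, trial execution.

Both learners update from every observed transition regardless of the
integration weight ``omega``; omega only gates how much each system
contributes to behaviour.  omega = 1 is a pure feature-model-free
(sign-tracking-prone) controller, omega = 0 a pure model-based
(goal-tracking-prone) one.  Decisions use the estimates held *before* the
transition being decided (learn-after-act).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .errors import ConfigurationError, StructuralError
from .fmf import FeatureValues, apply_iti_revision, compute_rpe, update_value
from .mb import QTable, WorldModel, solve_q, update_reward, update_transition
from .task import Feature, TaskGraph

__all__ = [
    "AgentParams",
    "Agent",
    "TransitionRecord",
    "TrialRecord",
    "integrate",
    "softmax_probs",
]

_PATH_LABELS = {"goL": "sign", "goM": "goal", "goE": "explore"}


@dataclass(frozen=True)
class AgentParams:
    """Model parameters.

    alpha   shared learning rate of both systems (dimensionless, [0, 1])
    gamma   discount factor per MDP step ([0, 1))
    tau     softmax temperature (> 0); larger means more random choice
    u_iti   per-trial down-revision of magazine/environment value
            (0.01 encodes a short ITI, 0.1 a long one)
    omega   FMF weight in the behavioural mixture ([0, 1]); fixed per subject
    """

    alpha: float = 0.03
    gamma: float = 0.8
    tau: float = 0.15
    u_iti: float = 0.01
    omega: float = 0.5

    def __post_init__(self) -> None:
        checks = [
            ("alpha", self.alpha, 0.0, 1.0),
            ("gamma", self.gamma, 0.0, 1.0),
            ("u_iti", self.u_iti, 0.0, 1.0),
            ("omega", self.omega, 0.0, 1.0),
        ]
        for name, value, lo, hi in checks:
            if not (lo <= value <= hi):
                raise ConfigurationError(
                    f"{name} must lie in [{lo}, {hi}], got {value}"
                )
        if self.gamma >= 1.0:
            raise ConfigurationError(f"gamma must be < 1, got {self.gamma}")
        if self.tau <= 0.0:
            raise ConfigurationError(f"tau must be > 0, got {self.tau}")


def integrate(
    advantages: Mapping[str, float],
    feature_values_of_actions: Mapping[str, float],
    omega: float,
) -> dict[str, float]:
    """Weighted blend P(s,a) = (1-omega) A(s,a) + omega V(f(s,a))."""
    if set(advantages) != set(feature_values_of_actions):
        raise StructuralError(
            "advantage and feature-value maps cover different action sets"
        )
    return {
        a: (1.0 - omega) * advantages[a] + omega * feature_values_of_actions[a]
        for a in advantages
    }


def softmax_probs(integrated: Mapping[str, float], tau: float) -> dict[str, float]:
    """Boltzmann choice probabilities p(a) proportional to exp(P(s,a)/tau)."""
    actions = list(integrated)
    top = max(integrated.values())
    expd = [math.exp((integrated[a] - top) / tau) for a in actions]
    z = sum(expd)
    return {a: e / z for a, e in zip(actions, expd)}


@dataclass
class TransitionRecord:
    from_state: str
    action: str
    to_state: str | None
    reward: float
    delta: float
    event_tag: str  # "CS" | "US" | "eat" | "other"
    probs: dict[str, float]


@dataclass
class TrialRecord:
    """One trial's choices, tagged RPEs and post-trial value snapshot."""

    subject_id: int
    omega: float
    session: int
    trial: int
    cs_choice: str
    second_cs_choice: str | None
    path: str
    rpe_cs: float
    rpe_us: float
    rpe_eat: float
    p_lever_cs: float
    p_mag_cs: float
    p_explore_cs: float
    p_lever_mid: float
    p_mag_mid: float
    adv_lever_cs: float
    adv_mag_cs: float
    v_E: float
    v_L: float
    v_M: float
    transitions: list[TransitionRecord] = field(default_factory=list, repr=False)

    def to_row(self) -> dict:
        return {
            "subject": self.subject_id,
            "omega": self.omega,
            "session": self.session,
            "trial": self.trial,
            "cs_choice": self.cs_choice,
            "second_cs_choice": self.second_cs_choice,
            "path": self.path,
            "rpe_cs": self.rpe_cs,
            "rpe_us": self.rpe_us,
            "rpe_eat": self.rpe_eat,
            "p_lever_cs": self.p_lever_cs,
            "p_mag_cs": self.p_mag_cs,
            "p_explore_cs": self.p_explore_cs,
            "p_lever_mid": self.p_lever_mid,
            "p_mag_mid": self.p_mag_mid,
            "adv_lever_cs": self.adv_lever_cs,
            "adv_mag_cs": self.adv_mag_cs,
            "v_E": self.v_E,
            "v_L": self.v_L,
            "v_M": self.v_M,
        }


class Agent:
    """A single simulated subject tied to one task graph.

    Holds the FMF value table, the MB world model, and a private random
    stream; :meth:`run_trial` executes one complete trial with all updates
    and returns the trial's record.
    """

    def __init__(
        self,
        graph: TaskGraph,
        params: AgentParams,
        rng: np.random.Generator | int | None = None,
        subject_id: int = 0,
        q_tol: float = 1e-9,
    ) -> None:
        self.graph = graph
        self.params = params
        self.subject_id = subject_id
        self.values = FeatureValues()
        self.model = WorldModel()
        self.q_tol = q_tol
        self._q_cache: QTable | None = None
        if isinstance(rng, np.random.Generator):
            self.rng = rng
        else:
            self.rng = np.random.default_rng(rng)

    # -- decision pipeline ----------------------------------------------
    def decision(self, state: str):
        """Compute (advantages, feature values, integrated, probabilities)
        for ``state`` from the agent's current estimates."""
        q = solve_q(
            self.model,
            self.graph,
            self.params.gamma,
            tol=self.q_tol,
            q_init=self._q_cache,
        )
        self._q_cache = q
        adv = q.advantages(self.graph, state)
        fv = {
            a: self.values[self.graph.feature(state, a)]
            for a in self.graph.actions(state)
        }
        integrated = integrate(adv, fv, self.params.omega)
        probs = softmax_probs(integrated, self.params.tau)
        return adv, fv, integrated, probs

    def _sample(self, probs: dict[str, float]) -> str:
        u = self.rng.random()
        acc = 0.0
        actions = list(probs)
        for a in actions:
            acc += probs[a]
            if u < acc:
                return a
        return actions[-1]

    # -- trial execution -------------------------------------------------
    def run_trial(self, session: int = 1, trial: int = 1) -> TrialRecord:
        p = self.params
        graph = self.graph
        state: str | None = graph.start_state
        cs_state = graph.cs_state
        transitions: list[TransitionRecord] = []
        cs_choice = second_choice = None
        rpe_cs = rpe_us = rpe_eat = math.nan
        p_lever_cs = p_mag_cs = p_explore_cs = math.nan
        p_lever_mid = p_mag_mid = math.nan
        adv_lever_cs = adv_mag_cs = math.nan

        while state is not None:
            adv, fv, _, probs = self.decision(state)
            action = self._sample(probs)
            nxt, r = graph.step(state, action)

            # log decision-time quantities at the two CS decision points
            if state == cs_state:
                cs_choice = action
                p_lever_cs = probs.get("goL", 0.0)
                p_mag_cs = probs.get("goM", 0.0)
                p_explore_cs = probs.get("goE", 0.0)
                adv_lever_cs = adv.get("goL", math.nan)
                adv_mag_cs = adv.get("goM", math.nan)
            elif state in graph.mid_cs_states:
                feature_of = {a: graph.feature(state, a) for a in probs}
                p_lever_mid = sum(
                    pr for a, pr in probs.items() if feature_of[a].value == "L"
                )
                p_mag_mid = sum(
                    pr for a, pr in probs.items() if feature_of[a].value == "M"
                )
                second_choice = (
                    "magazine" if feature_of[action].value == "M" else "lever"
                )

            # learn-after-act: updates use the post-decision observation
            chosen_feature = graph.feature(state, action)
            if nxt is None:
                next_features = None
            else:
                next_features = [
                    graph.feature(nxt, a2) for a2 in graph.actions(nxt)
                ]
            delta = compute_rpe(self.values, r, chosen_feature, next_features, p.gamma)
            update_value(self.values, chosen_feature, delta, p.alpha)
            if nxt is not None:
                update_transition(self.model, state, action, nxt, p.alpha)
            update_reward(self.model, state, action, r, p.alpha)

            if state == graph.start_state:
                tag = "CS"
                rpe_cs = delta
            elif nxt is None:
                tag = "eat"
                rpe_eat = delta
            elif (state, action) in graph.us_transitions:
                tag = "US"
                rpe_us = delta
            else:
                tag = "other"
            transitions.append(
                TransitionRecord(state, action, nxt, r, delta, tag, probs)
            )
            state = nxt

        apply_iti_revision(self.values, p.u_iti)
        assert cs_choice is not None
        v = self.values.as_dict()
        return TrialRecord(
            subject_id=self.subject_id,
            omega=p.omega,
            session=session,
            trial=trial,
            cs_choice=cs_choice,
            second_cs_choice=second_choice,
            path=_PATH_LABELS[cs_choice],
            rpe_cs=rpe_cs,
            rpe_us=rpe_us,
            rpe_eat=rpe_eat,
            p_lever_cs=p_lever_cs,
            p_mag_cs=p_mag_cs,
            p_explore_cs=p_explore_cs,
            p_lever_mid=p_lever_mid,
            p_mag_mid=p_mag_mid,
            adv_lever_cs=adv_lever_cs,
            adv_mag_cs=adv_mag_cs,
            v_E=v[Feature.E],
            v_L=v[Feature.L],
            v_M=v[Feature.M],
            transitions=transitions,
        )
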