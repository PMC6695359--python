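"""Autoshaping trial MDPs.

A single Pavlovian autoshaping trial is modelled as a small deterministic
Markov decision process: the lever is inserted for 8 s (the CS), a food
pellet drops into the magazine at lever retraction (the US), the animal
eats, and the inter-trial interval follows.  States encode the stimulus
configuration and the animal's position (near the lever or the food cup);
actions move the animal between them.  Every state-action pair is focused
on one of four *features* — the environment, the lever, the magazine or
the food itself — which is what the feature-model-free learner attaches
value to.

Two task variants are provided:

``standard``
    One behavioural choice per CS period.  Three paths exist from trial
    start to the terminal ``eat`` action: a sign-tracking path (approach
    and engage the lever), a goal-tracking path (approach and engage the
    magazine) and an exploration path.  The goal path is one step shorter
    because an animal engaged with the magazine is already at the food cup
    when the pellet drops.

``split_cs``
    The 8-s CS period is split into two 4-s halves with a decision at CS
    onset and a second one mid-CS, at which the animal may stay with the
    stimulus it approached or switch to the other one.  Exploration is
    removed.  Being at the magazine at US delivery again skips the
    retrieval step.

The feature function itself has two variants: the terminal ``eat`` action
may be focused on the food (``food``, the original convention) or on the
magazine (``magazine``, the corrected convention used for reward-prediction
-error analyses, which lets magazine value update even on sign-tracking
trials).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterator

from .errors import ConfigurationError, InvalidActionError

__all__ = [
    "Feature",
    "TaskGraph",
    "build_standard_task",
    "build_split_cs_task",
    "build_task",
    "step",
    "FEATURE_VARIANTS",
    "TASK_VARIANTS",
]


class Feature(str, Enum):
    """One of the four environmental features the FMF system values."""

    E = "E"  # the experimental chamber / context
    L = "L"  # the retractable lever (the CS)
    M = "M"  # the food magazine / cup
    F = "F"  # the food pellet itself

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


FEATURE_VARIANTS = ("food", "magazine")
TASK_VARIANTS = ("standard", "split_cs")


@dataclass(frozen=True)
class TaskGraph:
    """Deterministic per-trial MDP.

    ``transitions[(s, a)]`` is the successor state, or ``None`` for episode
    end (the ``eat`` action).  ``us_transitions`` marks the state-action
    pairs on which the food pellet appears; they are used to tag
    reward-prediction errors as US events.
    """

    variant: str
    feature_variant: str
    start_state: str
    states: tuple[str, ...]
    action_map: dict[str, tuple[str, ...]]
    transitions: dict[tuple[str, str], str | None]
    rewards: dict[tuple[str, str], float]
    features: dict[tuple[str, str], Feature]
    us_transitions: frozenset[tuple[str, str]]
    mid_cs_states: frozenset[str] = field(default_factory=frozenset)

    # -- basic queries ---------------------------------------------------
    def actions(self, state: str) -> tuple[str, ...]:
        try:
            return self.action_map[state]
        except KeyError:
            raise InvalidActionError(f"unknown state {state!r}") from None

    def next_state(self, state: str, action: str) -> str | None:
        self._check(state, action)
        return self.transitions[(state, action)]

    def reward(self, state: str, action: str) -> float:
        self._check(state, action)
        return self.rewards[(state, action)]

    def feature(self, state: str, action: str) -> Feature:
        self._check(state, action)
        return self.features[(state, action)]

    def step(self, state: str, action: str) -> tuple[str | None, float]:
        """Deterministic transition: returns (next state or None, reward)."""
        self._check(state, action)
        return self.transitions[(state, action)], self.rewards[(state, action)]

    def _check(self, state: str, action: str) -> None:
        if action not in self.action_map.get(state, ()):
            raise InvalidActionError(
                f"action {action!r} is not available in state {state!r}"
            )

    @property
    def cs_state(self) -> str:
        """The state in which the CS-onset choice is made."""
        (first_action,) = self.action_map[self.start_state]
        nxt = self.transitions[(self.start_state, first_action)]
        assert nxt is not None
        return nxt

    # -- whole-graph views ----------------------------------------------
    def state_action_pairs(self) -> Iterator[tuple[str, str]]:
        for s in self.states:
            for a in self.action_map[s]:
                yield s, a

    def trial_paths(self) -> list[list[tuple[str, str]]]:
        """Enumerate every action path from trial start to episode end."""
        paths: list[list[tuple[str, str]]] = []

        def walk(state: str, prefix: list[tuple[str, str]]) -> None:
            for a in self.action_map[state]:
                nxt = self.transitions[(state, a)]
                step = prefix + [(state, a)]
                if nxt is None:
                    paths.append(step)
                else:
                    walk(nxt, step)

        walk(self.start_state, [])
        return paths

    def describe(self) -> str:
        """Plain-text audit dump of states, transitions, rewards, features."""
        lines = [
            f"variant: {self.variant}",
            f"feature_variant: {self.feature_variant}",
            f"start_state: {self.start_state}",
            f"states: {' '.join(self.states)}",
            "transitions:",
        ]
        for s, a in self.state_action_pairs():
            nxt = self.transitions[(s, a)]
            tag = " [US]" if (s, a) in self.us_transitions else ""
            lines.append(
                f"  {s} --{a}--> {nxt if nxt is not None else 'END'}"
                f"  r={self.rewards[(s, a)]:g}  f={self.features[(s, a)].value}{tag}"
            )
        return "\n".join(lines)


def _check_feature_variant(feature_variant: str) -> Feature:
    if feature_variant not in FEATURE_VARIANTS:
        raise ConfigurationError(
            f"feature_variant must be one of {FEATURE_VARIANTS}, "
            f"got {feature_variant!r}"
        )
    return Feature.F if feature_variant == "food" else Feature.M


def build_standard_task(feature_variant: str = "food") -> TaskGraph:
    """Canonical single-choice trial graph.

    States: s0 ITI/pre-CS, s1 CS onset, s2 lever approached, s3 exploring,
    s4 magazine engaged, s5/s6 US delivered while away from the cup,
    s7 at the cup with food available.
    """
    eat_feature = _check_feature_variant(feature_variant)
    F, E, L, M = Feature.F, Feature.E, Feature.L, Feature.M
    spec: list[tuple[str, str, str | None, float, Feature]] = [
        ("s0", "goE", "s1", 0.0, E),
        ("s1", "goL", "s2", 0.0, L),
        ("s1", "goE", "s3", 0.0, E),
        ("s1", "goM", "s4", 0.0, M),
        ("s2", "eng", "s5", 0.0, L),
        ("s3", "wait", "s6", 0.0, E),
        ("s4", "eng", "s7", 0.0, M),
        ("s5", "goM", "s7", 0.0, F),
        ("s6", "goM", "s7", 0.0, F),
        ("s7", "eat", None, 1.0, eat_feature),
    ]
    return _assemble(
        variant="standard",
        feature_variant=feature_variant,
        start_state="s0",
        spec=spec,
        us_pairs=(("s2", "eng"), ("s3", "wait"), ("s4", "eng")),
        mid_cs=(),
    )


def build_split_cs_task(feature_variant: str = "magazine") -> TaskGraph:
    """Two-decision CS-period variant.

    s1 is CS onset (goL/goM only); s2 and s3 are the mid-CS decision states
    near the lever and the magazine, each offering a stay (``eng``) and a
    switch action; s6 is "at the lever when the US drops" and requires a
    retrieval step, while staying at (or switching to) the magazine leads
    straight to s7.
    """
    eat_feature = _check_feature_variant(feature_variant)
    F, E, L, M = Feature.F, Feature.E, Feature.L, Feature.M
    spec: list[tuple[str, str, str | None, float, Feature]] = [
        ("s0", "goE", "s1", 0.0, E),
        ("s1", "goL", "s2", 0.0, L),
        ("s1", "goM", "s3", 0.0, M),
        ("s2", "eng", "s6", 0.0, L),   # stay with the lever
        ("s2", "goM", "s7", 0.0, M),   # switch lever -> magazine
        ("s3", "eng", "s7", 0.0, M),   # stay at the magazine
        ("s3", "goL", "s6", 0.0, L),   # switch magazine -> lever
        ("s6", "goM", "s7", 0.0, F),   # post-US retrieval from the lever
        ("s7", "eat", None, 1.0, eat_feature),
    ]
    return _assemble(
        variant="split_cs",
        feature_variant=feature_variant,
        start_state="s0",
        spec=spec,
        us_pairs=(("s2", "eng"), ("s2", "goM"), ("s3", "eng"), ("s3", "goL")),
        mid_cs=("s2", "s3"),
    )


def build_task(task_variant: str, feature_variant: str) -> TaskGraph:
    if task_variant == "standard":
        return build_standard_task(feature_variant)
    if task_variant == "split_cs":
        return build_split_cs_task(feature_variant)
    raise ConfigurationError(
        f"task_variant must be one of {TASK_VARIANTS}, got {task_variant!r}"
    )


def _assemble(
    variant: str,
    feature_variant: str,
    start_state: str,
    spec: list[tuple[str, str, str | None, float, Feature]],
    us_pairs: tuple[tuple[str, str], ...],
    mid_cs: tuple[str, ...],
) -> TaskGraph:
    states: list[str] = []
    action_map: dict[str, list[str]] = {}
    transitions: dict[tuple[str, str], str | None] = {}
    rewards: dict[tuple[str, str], float] = {}
    features: dict[tuple[str, str], Feature] = {}
    for s, a, nxt, r, f in spec:
        if s not in action_map:
            states.append(s)
            action_map[s] = []
        action_map[s].append(a)
        transitions[(s, a)] = nxt
        rewards[(s, a)] = r
        features[(s, a)] = f
    graph = TaskGraph(
        variant=variant,
        feature_variant=feature_variant,
        start_state=start_state,
        states=tuple(states),
        action_map={s: tuple(v) for s, v in action_map.items()},
        transitions=transitions,
        rewards=rewards,
        features=features,
        us_transitions=frozenset(us_pairs),
        mid_cs_states=frozenset(mid_cs),
    )
    # structural sanity: every path reaches eat exactly once with reward 1
    for path in graph.trial_paths():
        total = sum(rewards[sa] for sa in path)
        assert total == 1.0 and path[-1][1] == "eat"
    return graph


def step(graph: TaskGraph, state: str, action: str) -> tuple[str | None, float]:
    """Functional alias for :meth:`TaskGraph.step`."""
    return graph.step(state, action)
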