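"""Feature-model-free (FMF) learner.

The FMF system is a temporal-difference learner that attaches value not to
states or actions but to the *feature* an action is focused on, so the
magazine's value generalizes across every state in which the animal attends
to it.  The value of the food feature is pinned at 1 (the reward magnitude):
treating it as learnable produces an artefactual ramp in terminal
reward-prediction errors over the first sessions.

Between trials the magazine and environment values are down-revised by a
factor ``1 - u_iti``, standing in for unrewarded magazine visits during the
inter-trial interval; a longer ITI is modelled as a larger ``u_iti``.  This
revision is the sole mechanism through which ITI duration reaches behaviour.
"""

from __future__ import annotations

from typing import Iterable, Mapping

from .errors import ConfigurationError, StructuralError
from .task import Feature

__all__ = ["FeatureValues", "compute_rpe", "update_value", "apply_iti_revision"]

_LEARNABLE = (Feature.E, Feature.L, Feature.M)


class FeatureValues:
    """Value table V over the four features, with V(F) pinned at 1."""

    __slots__ = ("_v",)

    def __init__(self, initial: Mapping[Feature, float] | None = None):
        self._v: dict[Feature, float] = {
            Feature.E: 0.0,
            Feature.L: 0.0,
            Feature.M: 0.0,
            Feature.F: 1.0,
        }
        if initial:
            for f, v in initial.items():
                f = Feature(f)
                if f is Feature.F:
                    if v != 1.0:
                        raise ConfigurationError("V(F) is pinned at 1")
                    continue
                self._v[f] = float(v)

    def __getitem__(self, feature: Feature) -> float:
        return self._v[Feature(feature)]

    def as_dict(self) -> dict[Feature, float]:
        return dict(self._v)

    def copy(self) -> "FeatureValues":
        return FeatureValues(
            {f: v for f, v in self._v.items() if f is not Feature.F}
        )

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        vals = ", ".join(f"V({f.value})={v:.4f}" for f, v in self._v.items())
        return f"FeatureValues({vals})"


def compute_rpe(
    values: FeatureValues,
    r: float,
    chosen_feature: Feature,
    next_features: Iterable[Feature] | None,
    gamma: float,
) -> float:
    """TD reward-prediction error for one transition.

    delta = r + gamma * max_j V(f(s', a_j)) - V(f(s, a)); at episode end
    (``next_features is None``) the continuation term is 0, so the terminal
    error reduces to r - V(f(s, a)).
    """
    if next_features is None:
        continuation = 0.0
    else:
        feats = list(next_features)
        if not feats:
            raise StructuralError("non-terminal next state offers no actions")
        continuation = gamma * max(values[f] for f in feats)
    return r + continuation - values[chosen_feature]


def update_value(
    values: FeatureValues,
    chosen_feature: Feature,
    delta: float,
    alpha: float,
) -> FeatureValues:
    """V(f) <- V(f) + alpha * delta, in place; a no-op for the food feature."""
    chosen_feature = Feature(chosen_feature)
    if chosen_feature is not Feature.F:
        values._v[chosen_feature] += alpha * delta
    return values


def apply_iti_revision(values: FeatureValues, u_iti: float) -> FeatureValues:
    """Down-revise magazine and environment values once per completed trial.

    V(M) <- (1 - u_iti) V(M); V(E) <- (1 - u_iti) V(E).  The lever is
    retracted during the ITI and its value is untouched.
    """
    values._v[Feature.M] *= 1.0 - u_iti
    values._v[Feature.E] *= 1.0 - u_iti
    return values
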