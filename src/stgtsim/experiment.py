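"""Protocol runner: sessions x trials, ITI conditions, populations, presets.

The default protocol is the autoshaping schedule the model was built for:
ten sessions of fifty trials, with no reset of any learner between sessions
(the between-trial value revision is the only inter-trial event).  ITI
duration enters only through ``u_iti``: 0.01 for the short condition, 0.1
for the long one.  Population simulations draw a fixed per-subject omega —
by default from a beta(2, 1) distribution, whose density increases toward 1
to reflect the reported prevalence of sign-trackers — and reuse the *same*
omega vector (and per-subject random streams) in both ITI conditions so the
ITI effect can be tested within subject.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .agent import Agent, AgentParams, TrialRecord
from .errors import ConfigurationError
from .task import build_task

__all__ = [
    "U_ITI",
    "ProtocolConfig",
    "PopulationSpec",
    "PairedResult",
    "parse_omega_dist",
    "format_omega_dist",
    "sample_omegas",
    "run_subject",
    "run_population",
    "run_paired_population",
    "records_to_frame",
    "preset",
    "run_preset",
    "PRESETS",
]

U_ITI = {"short": 0.01, "long": 0.1}

ITI_CONDITIONS = ("short", "long")


@dataclass(frozen=True)
class ProtocolConfig:
    """A fully specified single-condition simulation protocol."""

    n_sessions: int = 10
    trials_per_session: int = 50
    iti_condition: str = "short"
    task_variant: str = "standard"
    feature_variant: str = "food"
    seed: int = 0
    u_iti: float | None = None  # resolved from iti_condition when None

    def __post_init__(self) -> None:
        if self.n_sessions < 1 or self.trials_per_session < 1:
            raise ConfigurationError(
                "n_sessions and trials_per_session must be >= 1"
            )
        if self.iti_condition not in ITI_CONDITIONS and self.u_iti is None:
            raise ConfigurationError(
                f"iti_condition {self.iti_condition!r} requires an explicit u_iti"
            )

    @property
    def resolved_u_iti(self) -> float:
        if self.u_iti is not None:
            return self.u_iti
        return U_ITI[self.iti_condition]

    def build_graph(self):
        return build_task(self.task_variant, self.feature_variant)


@dataclass(frozen=True)
class PopulationSpec:
    """How many subjects and how their omega weights are distributed.

    ``omega_dist`` is ``("beta", a, b)``, ``("uniform",)`` or
    ``("fixed", w)``.
    """

    n_subjects: int = 20
    omega_dist: tuple = ("beta", 2.0, 1.0)
    omega_seed: int | None = None


def parse_omega_dist(text: str) -> tuple:
    """Parse 'beta(2,1)', 'uniform' or 'fixed(0.5)' into a dist tuple."""
    text = text.strip().lower()
    if text == "uniform" or text == "uniform(0,1)":
        return ("uniform",)
    for name in ("beta", "fixed"):
        if text.startswith(name + "(") and text.endswith(")"):
            args = [float(x) for x in text[len(name) + 1 : -1].split(",")]
            return (name, *args)
    raise ConfigurationError(f"cannot parse omega distribution {text!r}")


def format_omega_dist(dist: tuple) -> str:
    name, *args = dist
    if not args:
        return name
    return f"{name}({','.join(f'{a:g}' for a in args)})"


def sample_omegas(
    spec: PopulationSpec, seed: int | None = None
) -> np.ndarray:
    """Draw the per-subject omega vector; deterministic given the seed.

    ``spec.omega_seed`` wins over the ``seed`` argument.
    """
    use_seed = spec.omega_seed if spec.omega_seed is not None else seed
    rng = np.random.default_rng(use_seed)
    name, *args = spec.omega_dist
    n = spec.n_subjects
    if name == "fixed":
        (w,) = args
        if not 0.0 <= w <= 1.0:
            raise ConfigurationError(f"fixed omega must lie in [0, 1], got {w}")
        return np.full(n, float(w))
    if name == "uniform":
        return rng.uniform(0.0, 1.0, size=n)
    if name == "beta":
        a, b = args
        if a <= 0 or b <= 0:
            raise ConfigurationError(
                f"beta parameters must be positive, got a={a}, b={b}"
            )
        return rng.beta(a, b, size=n)
    raise ConfigurationError(f"unknown omega distribution {name!r}")


def run_subject(
    params: AgentParams,
    protocol: ProtocolConfig,
    subject_id: int = 0,
    rng: np.random.Generator | int | None = None,
) -> list[TrialRecord]:
    """Simulate one subject through the whole protocol.

    The agent's learners persist across sessions; sessions are purely a
    bookkeeping partition of contiguous training.
    """
    graph = protocol.build_graph()
    if rng is None:
        rng = protocol.seed
    agent = Agent(graph, params, rng=rng, subject_id=subject_id)
    records: list[TrialRecord] = []
    for session in range(1, protocol.n_sessions + 1):
        for trial in range(1, protocol.trials_per_session + 1):
            records.append(agent.run_trial(session=session, trial=trial))
    return records


def records_to_frame(
    records: Sequence[TrialRecord], **extra: object
) -> pd.DataFrame:
    """Tidy one-row-per-trial log; ``extra`` adds constant columns
    (e.g. condition or task metadata)."""
    df = pd.DataFrame([r.to_row() for r in records])
    for k, v in extra.items():
        df[k] = v
    return df


def _subject_streams(seed: int, n_subjects: int) -> list[np.random.SeedSequence]:
    root = np.random.SeedSequence(seed)
    return root.spawn(n_subjects + 1)  # child 0 reserved for omega sampling


def run_population(
    pop: PopulationSpec,
    protocol: ProtocolConfig,
    seed: int | None = None,
    params: AgentParams | None = None,
    omegas: np.ndarray | None = None,
    streams: Sequence[np.random.SeedSequence] | None = None,
) -> pd.DataFrame:
    """Simulate a whole population under one condition; returns the tidy log."""
    if seed is None:
        seed = protocol.seed
    if streams is None:
        children = _subject_streams(seed, pop.n_subjects)
        omega_ss, streams = children[0], children[1:]
    else:
        omega_ss = None
    if omegas is None:
        omega_seed = (
            pop.omega_seed
            if pop.omega_seed is not None
            else (omega_ss.generate_state(1)[0] % (2**31) if omega_ss is not None else seed)
        )
        omegas = sample_omegas(replace(pop, omega_seed=int(omega_seed)))
    base = params or AgentParams()
    frames = []
    for sid, (w, ss) in enumerate(zip(omegas, streams)):
        p = replace(
            base, omega=float(w), u_iti=protocol.resolved_u_iti
        )
        rng = np.random.default_rng(np.random.PCG64(ss))
        recs = run_subject(p, protocol, subject_id=sid, rng=rng)
        frames.append(records_to_frame(recs))
    out = pd.concat(frames, ignore_index=True)
    out["condition"] = protocol.iti_condition
    out["task_variant"] = protocol.task_variant
    out["feature_variant"] = protocol.feature_variant
    return out


@dataclass
class PairedResult:
    """The same population run under both ITI conditions."""

    short: pd.DataFrame
    long: pd.DataFrame
    omegas: np.ndarray

    def combined(self) -> pd.DataFrame:
        return pd.concat([self.short, self.long], ignore_index=True)


def run_paired_population(
    pop: PopulationSpec,
    base_protocol: ProtocolConfig,
    seed: int | None = None,
    params: AgentParams | None = None,
) -> PairedResult:
    """Run every subject under u_iti = 0.01 and 0.1 with identical omega
    values and identical per-subject choice-noise streams, enabling
    within-subject ITI contrasts."""
    if seed is None:
        seed = base_protocol.seed
    children = _subject_streams(seed, pop.n_subjects)
    omega_ss, streams = children[0], children[1:]
    omega_seed = (
        pop.omega_seed
        if pop.omega_seed is not None
        else int(omega_ss.generate_state(1)[0] % (2**31))
    )
    omegas = sample_omegas(replace(pop, omega_seed=omega_seed))
    frames = {}
    for condition in ITI_CONDITIONS:
        protocol = replace(base_protocol, iti_condition=condition, u_iti=None)
        frames[condition] = run_population(
            pop,
            protocol,
            seed=seed,
            params=params,
            omegas=omegas,
            streams=streams,
        )
    return PairedResult(short=frames["short"], long=frames["long"], omegas=omegas)


# ---------------------------------------------------------------------------
# presets: one fully-bound configuration per simulation experiment
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Preset:
    name: str
    description: str
    population: PopulationSpec
    protocol: ProtocolConfig


PRESETS: dict[str, Preset] = {
    "fig3_fmf_only": Preset(
        name="fig3_fmf_only",
        description="Pure feature-model-free population (omega = 1), both ITI "
        "conditions; shows the ITI-driven sign/goal-tracking switch.",
        population=PopulationSpec(n_subjects=20, omega_dist=("fixed", 1.0)),
        protocol=ProtocolConfig(feature_variant="magazine"),
    ),
    "fig3_mb_only": Preset(
        name="fig3_mb_only",
        description="Pure model-based population (omega = 0), both ITI "
        "conditions; behaviour is insensitive to ITI duration.",
        population=PopulationSpec(n_subjects=20, omega_dist=("fixed", 0.0)),
        protocol=ProtocolConfig(feature_variant="magazine"),
    ),
    "fig4_population": Preset(
        name="fig4_population",
        description="Twenty subjects with omega ~ beta(2,1), paired short/long "
        "ITI; behavioural scores and the statistical battery.",
        population=PopulationSpec(n_subjects=20, omega_dist=("beta", 2.0, 1.0)),
        protocol=ProtocolConfig(feature_variant="magazine"),
    ),
    "fig5_rpe": Preset(
        name="fig5_rpe",
        description="Same population with the corrected (magazine) eat "
        "feature; CS/US reward-prediction-error contrasts.",
        population=PopulationSpec(n_subjects=20, omega_dist=("beta", 2.0, 1.0)),
        protocol=ProtocolConfig(feature_variant="magazine"),
    ),
    "fig6_split_cs": Preset(
        name="fig6_split_cs",
        description="Split-CS-period task (two decisions per CS) with the "
        "magazine eat feature; first- vs second-half approach.",
        population=PopulationSpec(n_subjects=20, omega_dist=("beta", 2.0, 1.0)),
        protocol=ProtocolConfig(task_variant="split_cs", feature_variant="magazine"),
    ),
    "supp_uniform": Preset(
        name="supp_uniform",
        description="Population with omega ~ uniform(0,1) instead of the "
        "biased beta; robustness of the behavioural results.",
        population=PopulationSpec(n_subjects=20, omega_dist=("uniform",)),
        protocol=ProtocolConfig(feature_variant="magazine"),
    ),
    "supp_extended_sessions": Preset(
        name="supp_extended_sessions",
        description="Thirty-session run (magazine eat feature); shows the "
        "short-ITI lever value slowly catching up with the magazine.",
        population=PopulationSpec(n_subjects=20, omega_dist=("beta", 2.0, 1.0)),
        protocol=ProtocolConfig(n_sessions=30, feature_variant="magazine"),
    ),
}


def preset(name: str) -> Preset:
    try:
        return PRESETS[name]
    except KeyError:
        raise ConfigurationError(
            f"unknown preset {name!r}; known presets: {', '.join(PRESETS)}"
        ) from None


def run_preset(p: Preset | str, seed: int) -> PairedResult:
    """Run a preset under both ITI conditions with the given master seed."""
    if isinstance(p, str):
        p = preset(p)
    return run_paired_population(p.population, p.protocol, seed=seed)
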