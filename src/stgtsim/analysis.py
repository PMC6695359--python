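"""Behavioural scores, RPE summaries and the statistical battery.

All analyses consume the tidy one-row-per-trial logs produced by the
experiment runner.  The behavioural index is the normalized approach score
(p_L - p_M) / (p_L + p_M), ranging from -1 (pure goal-tracking) to +1
(pure sign-tracking); it is computed both from softmax probabilities and
from realized choice frequencies.  Reward-prediction errors stand in for
phasic dopamine: the CS-tagged error is the trial-start transition, the
US-tagged error is the food-appearance transition under the original food
eat-feature and the eat transition under the corrected magazine
eat-feature.  Sessions 1-3 are "early" and the remainder "late" for the
acquisition contrasts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import StructuralError

__all__ = [
    "normalized_approach_score",
    "approach_summary",
    "score_table",
    "subject_scores",
    "us_rpe",
    "rpe_summary",
    "rpe_contrasts",
    "feature_value_trajectories",
    "split_cs_contrast",
    "welch_ttest",
    "paired_ttest",
    "signed_rank",
    "rm_anova_two_within",
    "stat_battery",
]

EARLY_SESSIONS = 3  # sessions 1..3 are "early", the rest "late"


# ---------------------------------------------------------------------------
# scores
# ---------------------------------------------------------------------------


def normalized_approach_score(p_lever, p_magazine):
    """(p_L - p_M) / (p_L + p_M); NaN (with a warning) when both are zero.

    Accepts scalars or array-likes.
    """
    p_l = np.asarray(p_lever, dtype=float)
    p_m = np.asarray(p_magazine, dtype=float)
    denom = p_l + p_m
    both_zero = denom == 0
    if np.any(both_zero):
        warnings.warn(
            "normalized approach score undefined where lever and magazine "
            "approach are both zero; emitting NaN",
            stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(both_zero, np.nan, (p_l - p_m) / np.where(both_zero, 1.0, denom))
    if out.ndim == 0:
        return float(out)
    return out


def approach_summary(df: pd.DataFrame) -> pd.DataFrame:
    """Per subject x session: CS-onset choice counts and mean softmax
    probabilities of approaching lever and magazine."""
    counts = (
        df.pivot_table(
            index=["subject", "session"],
            columns="cs_choice",
            values="trial",
            aggfunc="count",
            fill_value=0,
        )
        .reindex(columns=["goL", "goM", "goE"], fill_value=0)
        .rename(columns={"goL": "n_goL", "goM": "n_goM", "goE": "n_goE"})
    )
    counts.columns.name = None
    probs = df.groupby(["subject", "session"])[
        ["p_lever_cs", "p_mag_cs", "omega"]
    ].mean()
    return counts.join(probs).reset_index()


def score_table(df: pd.DataFrame) -> pd.DataFrame:
    """Per subject x session normalized approach scores.

    ``prob_score`` uses mean softmax probabilities (always defined, softmax
    probabilities are strictly positive); ``freq_score`` uses realized
    choice counts and is NaN if the subject neither sign- nor goal-tracked
    in a session.
    """
    summ = approach_summary(df)
    summ["prob_score"] = normalized_approach_score(
        summ["p_lever_cs"], summ["p_mag_cs"]
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        summ["freq_score"] = normalized_approach_score(
            summ["n_goL"], summ["n_goM"]
        )
    return summ


def subject_scores(df: pd.DataFrame) -> pd.DataFrame:
    """Per-subject scores averaged over sessions."""
    return (
        score_table(df)
        .groupby("subject")[["prob_score", "freq_score", "omega"]]
        .mean()
        .reset_index()
    )


# ---------------------------------------------------------------------------
# reward-prediction errors
# ---------------------------------------------------------------------------


def us_rpe(df: pd.DataFrame) -> pd.Series:
    """US-tagged RPE series under the log's active feature variant."""
    if "feature_variant" not in df.columns:
        raise StructuralError("log lacks a feature_variant column")
    variants = df["feature_variant"].unique()
    if len(variants) != 1:
        raise StructuralError("log mixes feature variants")
    return df["rpe_eat"] if variants[0] == "magazine" else df["rpe_us"]


def _phase(df: pd.DataFrame, early_sessions: int) -> pd.Series:
    return np.where(df["session"] <= early_sessions, "early", "late")


def rpe_summary(
    df: pd.DataFrame, early_sessions: int = EARLY_SESSIONS
) -> pd.DataFrame:
    """Mean and s.e.m. of CS- and US-tagged RPEs per phase (early/late)."""
    work = df.assign(phase=_phase(df, early_sessions), rpe_us_active=us_rpe(df))
    out = []
    for event, col in (("CS", "rpe_cs"), ("US", "rpe_us_active")):
        g = work.groupby("phase")[col]
        res = g.agg(["mean", "sem", "count"]).reset_index()
        res.insert(0, "event", event)
        out.append(res)
    return pd.concat(out, ignore_index=True)


@dataclass
class TestResult:
    name: str
    statistic: float
    df: float | None
    pvalue: float

    def as_dict(self) -> dict:
        return {
            "name": self.name,
            "statistic": self.statistic,
            "df": self.df,
            "pvalue": self.pvalue,
        }


def _subject_means(df: pd.DataFrame, col: str) -> pd.Series:
    return df.groupby("subject")[col].mean().sort_index()


def rpe_contrasts(
    short_df: pd.DataFrame,
    long_df: pd.DataFrame,
    early_sessions: int = EARLY_SESSIONS,
) -> dict:
    """Between-condition and early/late RPE comparisons.

    Returns a dict with per-condition all-session means, Welch tests
    comparing conditions on per-subject mean CS and US errors, and paired
    early-vs-late tests within each condition.
    """
    subjects_short = set(short_df["subject"].unique())
    subjects_long = set(long_df["subject"].unique())
    if subjects_short != subjects_long:
        raise StructuralError("short and long logs cover different subjects")

    out: dict = {"means": {}, "tests": []}
    per_subject = {}
    for cond, df in (("short", short_df), ("long", long_df)):
        work = df.assign(rpe_us_active=us_rpe(df), phase=_phase(df, early_sessions))
        per_subject[cond] = {
            "cs_all": _subject_means(work, "rpe_cs"),
            "us_all": _subject_means(work, "rpe_us_active"),
            "cs_early": _subject_means(work[work["phase"] == "early"], "rpe_cs"),
            "cs_late": _subject_means(work[work["phase"] == "late"], "rpe_cs"),
            "us_early": _subject_means(
                work[work["phase"] == "early"], "rpe_us_active"
            ),
            "us_late": _subject_means(work[work["phase"] == "late"], "rpe_us_active"),
        }
        out["means"][cond] = {
            k: float(v.mean()) for k, v in per_subject[cond].items()
        }

    for event in ("cs", "us"):
        t = welch_ttest(
            per_subject["long"][f"{event}_all"],
            per_subject["short"][f"{event}_all"],
            name=f"welch_{event}_long_vs_short",
        )
        out["tests"].append(t)
    for cond in ("short", "long"):
        for event in ("cs", "us"):
            late = per_subject[cond][f"{event}_late"]
            early = per_subject[cond][f"{event}_early"]
            if late.empty or early.empty:
                # protocol too short to split into phases; skip the contrast
                continue
            t = paired_ttest(
                late,
                early,
                name=f"paired_{cond}_{event}_late_vs_early",
            )
            out["tests"].append(t)
    return out


def feature_value_trajectories(df: pd.DataFrame) -> pd.DataFrame:
    """Session-wise mean feature values, per condition when present."""
    keys = ["session"]
    if "condition" in df.columns:
        keys = ["condition", "session"]
    return df.groupby(keys)[["v_L", "v_M", "v_E"]].mean().reset_index()


def split_cs_contrast(
    df: pd.DataFrame, late_from: int = EARLY_SESSIONS + 1
) -> dict:
    """First- vs second-CS-half magazine approach over late sessions.

    Per subject: mean softmax probability of approaching the magazine at CS
    onset versus at the mid-CS decision, paired Wilcoxon signed-rank across
    subjects.
    """
    if "task_variant" not in df.columns or not (
        df["task_variant"] == "split_cs"
    ).all():
        raise StructuralError("split-CS contrast requires a split_cs-task log")
    late = df[df["session"] >= late_from]
    if late.empty:
        raise StructuralError(
            f"no trials in sessions >= {late_from}; cannot form the late window"
        )
    per_subject = late.groupby("subject")[["p_mag_cs", "p_mag_mid"]].mean()
    test = signed_rank(
        per_subject["p_mag_mid"],
        per_subject["p_mag_cs"],
        name="wilcoxon_second_vs_first_half_magazine",
    )
    return {
        "per_subject": per_subject.rename(
            columns={"p_mag_cs": "first_half", "p_mag_mid": "second_half"}
        ).reset_index(),
        "mean_first_half": float(per_subject["p_mag_cs"].mean()),
        "mean_second_half": float(per_subject["p_mag_mid"].mean()),
        "test": test,
    }


# ---------------------------------------------------------------------------
# statistical battery
# ---------------------------------------------------------------------------


def welch_ttest(x, y, name: str = "welch") -> TestResult:
    """Unequal-variance two-sample t test (Welch-Satterthwaite df)."""
    res = stats.ttest_ind(np.asarray(x), np.asarray(y), equal_var=False)
    return TestResult(name, float(res.statistic), float(res.df), float(res.pvalue))


def paired_ttest(x, y, name: str = "paired_t") -> TestResult:
    x = np.asarray(x)
    y = np.asarray(y)
    if x.shape != y.shape:
        raise StructuralError("paired samples must have equal length")
    if np.allclose(x, y):
        return TestResult(name, 0.0, float(len(x) - 1), 1.0)
    res = stats.ttest_rel(x, y)
    return TestResult(name, float(res.statistic), float(len(x) - 1), float(res.pvalue))


def signed_rank(x, y=None, name: str = "wilcoxon") -> TestResult:
    """Wilcoxon signed-rank test; one-sample against zero when y is None.

    Identical paired samples (all differences zero) return statistic 0,
    p = 1 instead of raising.
    """
    x = np.asarray(x, dtype=float)
    d = x if y is None else x - np.asarray(y, dtype=float)
    if np.all(d == 0):
        return TestResult(name, 0.0, None, 1.0)
    res = stats.wilcoxon(d)
    return TestResult(name, float(res.statistic), None, float(res.pvalue))


def rm_anova_two_within(
    data: pd.DataFrame,
    depvar: str,
    subject: str = "subject",
    within: tuple[str, str] = ("condition", "session"),
) -> pd.DataFrame:
    """Two-within-factor repeated-measures ANOVA (no sphericity correction).

    Requires a balanced design: exactly one observation per subject x cell.
    """
    from statsmodels.stats.anova import AnovaRM

    cell_sizes = data.groupby([subject, *within]).size()
    if (cell_sizes != 1).any():
        raise StructuralError(
            "repeated-measures ANOVA needs exactly one observation per "
            "subject x cell; aggregate first"
        )
    res = AnovaRM(
        data, depvar=depvar, subject=subject, within=list(within)
    ).fit()
    return res.anova_table


def stat_battery(
    short_df: pd.DataFrame, long_df: pd.DataFrame
) -> pd.DataFrame:
    """The full report: repeated-measures ANOVAs on approach counts,
    signed-rank tests on score distributions, Welch tests on approach
    probabilities.  P-values are raw (uncorrected)."""
    results: list[TestResult] = []

    counts = []
    for cond, df in (("short", short_df), ("long", long_df)):
        s = approach_summary(df)
        s["condition"] = cond
        counts.append(s)
    counts = pd.concat(counts, ignore_index=True)

    for depvar, label in (("n_goL", "lever"), ("n_goM", "magazine")):
        tbl = rm_anova_two_within(counts, depvar)
        for effect, row in tbl.iterrows():
            results.append(
                TestResult(
                    f"rm_anova_{label}_{effect.replace(':', 'x').replace(' ', '')}",
                    float(row["F Value"]),
                    float(row["Num DF"]),
                    float(row["Pr > F"]),
                )
            )

    scores = {cond: subject_scores(df) for cond, df in
              (("short", short_df), ("long", long_df))}
    for cond in ("short", "long"):
        for col in ("prob_score", "freq_score"):
            results.append(
                signed_rank(scores[cond][col], name=f"wilcoxon_{cond}_{col}")
            )
    for col in ("prob_score", "freq_score"):
        results.append(
            signed_rank(
                scores["long"][col],
                scores["short"][col],
                name=f"wilcoxon_long_minus_short_{col}",
            )
        )

    for col, label in (("p_mag_cs", "p_magazine"), ("p_lever_cs", "p_lever")):
        results.append(
            welch_ttest(
                _subject_means(short_df, col),
                _subject_means(long_df, col),
                name=f"welch_short_vs_long_{label}",
            )
        )

    return pd.DataFrame([r.as_dict() for r in results])
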