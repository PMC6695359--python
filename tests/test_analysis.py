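import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stgtsim import StructuralError
from stgtsim.analysis import (
    approach_summary,
    feature_value_trajectories,
    normalized_approach_score,
    paired_ttest,
    rm_anova_two_within,
    rpe_contrasts,
    score_table,
    signed_rank,
    split_cs_contrast,
    stat_battery,
    welch_ttest,
)


def make_log(
    n_subjects=3,
    n_sessions=2,
    trials=5,
    task_variant="standard",
    feature_variant="magazine",
    seed=0,
):
    """Small synthetic trial log with the experiment runner's columns."""
    rng = np.random.default_rng(seed)
    rows = []
    for subj in range(n_subjects):
        for sess in range(1, n_sessions + 1):
            for t in range(1, trials + 1):
                p_l, p_m = rng.dirichlet([1, 1, 1])[:2]
                rows.append(
                    {
                        "subject": subj,
                        "omega": 0.5,
                        "session": sess,
                        "trial": t,
                        "cs_choice": rng.choice(["goL", "goM", "goE"]),
                        "second_cs_choice": None,
                        "path": "sign",
                        "rpe_cs": rng.normal(0.2, 0.05),
                        "rpe_us": rng.normal(0.5, 0.05),
                        "rpe_eat": rng.normal(0.4, 0.05),
                        "p_lever_cs": p_l,
                        "p_mag_cs": p_m,
                        "p_explore_cs": 1 - p_l - p_m,
                        "p_lever_mid": 1 - p_m,
                        "p_mag_mid": p_m,
                        "adv_lever_cs": -0.1,
                        "adv_mag_cs": 0.0,
                        "v_E": 0.1,
                        "v_L": 0.5,
                        "v_M": 0.4,
                        "condition": "short",
                        "task_variant": task_variant,
                        "feature_variant": feature_variant,
                    }
                )
    return pd.DataFrame(rows)


class TestNormalizedScore:
    def test_symmetric_probabilities_score_zero(self):
        assert normalized_approach_score(0.4, 0.4) == 0.0

    def test_pure_sign_tracking_scores_one(self):
        assert normalized_approach_score(0.3, 0.0) == 1.0

    def test_worked_example(self):
        assert normalized_approach_score(0.6, 0.2) == pytest.approx(0.5)

    def test_both_zero_yields_nan_with_warning(self):
        with pytest.warns(UserWarning):
            out = normalized_approach_score(0.0, 0.0)
        assert np.isnan(out)

    @settings(deadline=None, derandomize=True)
    @given(
        p_l=st.floats(min_value=0.0, max_value=1.0),
        p_m=st.floats(min_value=0.0, max_value=1.0),
    )
    def test_swapping_inputs_negates_the_score(self, p_l, p_m):
        if p_l + p_m == 0:
            return
        s = normalized_approach_score(p_l, p_m)
        assert normalized_approach_score(p_m, p_l) == pytest.approx(-s)
        assert -1.0 <= s <= 1.0


class TestApproachSummary:
    def test_counts_conserve_trials_per_session(self):
        df = make_log(trials=7)
        summ = approach_summary(df)
        totals = summ[["n_goL", "n_goM", "n_goE"]].sum(axis=1)
        assert (totals == 7).all()

    def test_score_table_has_both_scores(self):
        tbl = score_table(make_log())
        assert {"prob_score", "freq_score"} <= set(tbl.columns)
        assert tbl["prob_score"].between(-1, 1).all()


class TestRpeContrasts:
    def test_identical_logs_give_zero_contrasts(self):
        df = make_log(n_sessions=4)
        out = rpe_contrasts(df, df.copy())
        for t in out["tests"]:
            if t.name.startswith("welch"):
                assert t.statistic == pytest.approx(0.0, abs=1e-12)
        assert out["means"]["short"] == out["means"]["long"]

    def test_mismatched_subjects_rejected(self):
        df = make_log(n_subjects=3)
        other = make_log(n_subjects=2)
        with pytest.raises(StructuralError):
            rpe_contrasts(df, other)

    def test_us_column_follows_feature_variant(self):
        food = make_log(feature_variant="food", n_sessions=4)
        mag = make_log(feature_variant="magazine", n_sessions=4)
        out_food = rpe_contrasts(food, food.copy())
        out_mag = rpe_contrasts(mag, mag.copy())
        assert out_food["means"]["short"]["us_all"] == pytest.approx(
            food["rpe_us"].groupby(food["subject"]).mean().mean()
        )
        assert out_mag["means"]["short"]["us_all"] == pytest.approx(
            mag["rpe_eat"].groupby(mag["subject"]).mean().mean()
        )


class TestTrajectories:
    def test_all_zero_logs_give_zero_trajectories(self):
        df = make_log()
        df[["v_E", "v_L", "v_M"]] = 0.0
        traj = feature_value_trajectories(df)
        assert (traj[["v_L", "v_M", "v_E"]] == 0.0).all().all()

    def test_one_row_per_condition_session(self):
        df = make_log(n_sessions=3)
        traj = feature_value_trajectories(df)
        assert len(traj) == 3


class TestSplitContrast:
    def test_requires_split_task_log(self):
        with pytest.raises(StructuralError):
            split_cs_contrast(make_log(task_variant="standard"))

    def test_never_switching_subject_gives_identical_pair(self):
        df = make_log(task_variant="split_cs", n_sessions=5)
        df["p_mag_mid"] = df["p_mag_cs"]
        out = split_cs_contrast(df)
        assert out["mean_first_half"] == pytest.approx(out["mean_second_half"])
        assert out["test"].statistic == 0.0
        assert out["test"].pvalue == 1.0

    def test_empty_late_window_is_an_error(self):
        df = make_log(task_variant="split_cs", n_sessions=2)
        with pytest.raises(StructuralError):
            split_cs_contrast(df, late_from=4)


class TestStatHelpers:
    def test_welch_df_matches_hand_computation(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([2.0, 4.0, 6.0])
        res = welch_ttest(x, y)
        vx, vy = x.var(ddof=1) / len(x), y.var(ddof=1) / len(y)
        df_hand = (vx + vy) ** 2 / (
            vx**2 / (len(x) - 1) + vy**2 / (len(y) - 1)
        )
        assert res.df == pytest.approx(df_hand)

    def test_equal_samples_give_null_statistics(self):
        x = np.arange(10.0)
        assert paired_ttest(x, x.copy()).statistic == 0.0
        w = signed_rank(x, x.copy())
        assert w.statistic == 0.0 and w.pvalue == 1.0

    def test_welch_near_zero_under_the_null(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, 4000)
        y = rng.normal(0, 1, 4000)
        assert abs(welch_ttest(x, y).statistic) < 2.5

    def test_anova_requires_balanced_design(self):
        df = make_log(n_subjects=4, n_sessions=2)
        summ = approach_summary(df)
        summ["condition"] = "short"
        unbalanced = pd.concat([summ, summ.iloc[[0]]], ignore_index=True)
        with pytest.raises(StructuralError):
            rm_anova_two_within(unbalanced, "n_goL")

    def test_anova_returns_three_effects(self):
        frames = []
        for cond, offset in (("short", 0.0), ("long", 2.0)):
            df = make_log(n_subjects=6, n_sessions=3, seed=4)
            summ = approach_summary(df)
            summ["condition"] = cond
            summ["n_goL"] = summ["n_goL"] + offset
            frames.append(summ)
        tbl = rm_anova_two_within(pd.concat(frames, ignore_index=True), "n_goL")
        assert set(tbl.index) == {"condition", "session", "condition:session"}
        assert ((tbl["Pr > F"] >= 0) & (tbl["Pr > F"] <= 1)).all()


def test_stat_battery_report_shape():
    short = make_log(n_subjects=5, n_sessions=3, seed=1)
    long = make_log(n_subjects=5, n_sessions=3, seed=2)
    long["condition"] = "long"
    report = stat_battery(short, long)
    assert {"name", "statistic", "pvalue"} <= set(report.columns)
    assert report["pvalue"].between(0, 1).all()
    assert report["name"].str.startswith("rm_anova").sum() == 6
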