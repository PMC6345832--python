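import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats

import wmosc
from wmosc import TrialOutcomes
from wmosc.behavior import (
    compute_dprime,
    planned_pairwise_tests,
    rm_anova,
    sd_outlier_mask,
    summarize_behavior,
    summarize_rt,
)


def outcomes_from_counts(nh, nm, nfa, ncr):
    counts = pd.DataFrame(
        [{"subject_id": "S00", "load": "high", "nh": nh, "nm": nm, "nfa": nfa, "ncr": ncr}]
    )
    rts = {("S00", "high"): np.full(nh + ncr, 500.0)}
    return TrialOutcomes(counts, rts)


# ---------------------------------------------------------------------------
# d'


def test_symmetric_counts_give_exactly_zero_dprime():
    dp = compute_dprime(outcomes_from_counts(15, 15, 15, 15))
    assert dp["hr"].iloc[0] == pytest.approx(15.5 / 31)
    assert dp["far"].iloc[0] == pytest.approx(15.5 / 31)
    assert dp["dprime"].iloc[0] == 0.0


def test_swapping_hit_and_rejection_counts_preserves_dprime():
    a = compute_dprime(outcomes_from_counts(22, 8, 5, 25))["dprime"].iloc[0]
    b = compute_dprime(outcomes_from_counts(25, 5, 8, 22))["dprime"].iloc[0]
    assert a == pytest.approx(b, abs=1e-12)


def test_perfect_performance_matches_quantile_oracle():
    d = compute_dprime(outcomes_from_counts(30, 0, 0, 30))["dprime"].iloc[0]
    assert d == pytest.approx(2 * stats.norm.ppf(30.5 / 31), abs=1e-12)
    assert d == pytest.approx(4.282, abs=1e-3)


@given(nh=st.integers(0, 29), nfa=st.integers(0, 30))
def test_dprime_monotone_in_hits_and_false_alarms(nh, nfa):
    d0 = compute_dprime(outcomes_from_counts(nh, 30 - nh, nfa, 30 - nfa))["dprime"].iloc[0]
    d1 = compute_dprime(outcomes_from_counts(nh + 1, 29 - nh, nfa, 30 - nfa))["dprime"].iloc[0]
    assert d1 > d0
    if nfa < 30:
        d2 = compute_dprime(outcomes_from_counts(nh, 30 - nh, nfa + 1, 29 - nfa))["dprime"].iloc[0]
        assert d2 < d0


def test_zero_trial_cells_rejected():
    with pytest.raises(ValueError, match="zero"):
        compute_dprime(outcomes_from_counts(0, 0, 10, 10))


def test_balanced_null_behavior_has_zero_mean_dprime():
    rng = np.random.default_rng(0)
    rows = []
    for i in range(1000):
        nh = rng.binomial(30, 0.5)
        nfa = rng.binomial(30, 0.5)
        rows.append(
            {"subject_id": f"S{i}", "load": "m", "nh": nh, "nm": 30 - nh, "nfa": nfa, "ncr": 30 - nfa}
        )
    out = TrialOutcomes(pd.DataFrame(rows), {})
    assert abs(compute_dprime(out)["dprime"].mean()) < 0.02


# ---------------------------------------------------------------------------
# reaction time


def test_median_rt_odd_and_even_cases():
    counts = pd.DataFrame(
        [
            {"subject_id": "a", "load": "x", "nh": 2, "nm": 0, "nfa": 0, "ncr": 1},
            {"subject_id": "b", "load": "x", "nh": 1, "nm": 0, "nfa": 0, "ncr": 1},
        ]
    )
    rts = {("a", "x"): [300.0, 500.0, 400.0], ("b", "x"): [300.0, 500.0]}
    out = summarize_rt(TrialOutcomes(counts, rts))
    assert out.set_index("subject_id")["median_rt"].to_dict() == {"a": 400.0, "b": 400.0}


def test_median_matches_sort_oracle():
    rng = np.random.default_rng(1)
    rts = rng.lognormal(6, 0.3, 1000)
    counts = pd.DataFrame([{"subject_id": "a", "load": "x", "nh": 500, "nm": 0, "nfa": 0, "ncr": 500}])
    med = summarize_rt(TrialOutcomes(counts, {("a", "x"): rts}))["median_rt"].iloc[0]
    s = np.sort(rts)
    assert med == (s[499] + s[500]) / 2


def test_empty_correct_cell_flagged_missing(caplog):
    counts = pd.DataFrame([{"subject_id": "a", "load": "x", "nh": 0, "nm": 5, "nfa": 5, "ncr": 0}])
    with caplog.at_level("WARNING"):
        out = summarize_rt(TrialOutcomes(counts, {("a", "x"): []}))
    assert np.isnan(out["median_rt"].iloc[0])
    assert "excluded" in caplog.text


# ---------------------------------------------------------------------------
# repeated-measures ANOVA


def test_zero_condition_effect_gives_zero_f():
    x = np.tile(np.array([[1.0], [5.0], [3.0], [2.0]]), (1, 3))
    res = rm_anova(x)
    assert res["F"] == 0.0 and res["p"] == 1.0
    assert res["ss_condition"] == 0.0 and res["ss_subject"] > 0


def test_two_condition_f_equals_squared_paired_t():
    rng = np.random.default_rng(2)
    x = rng.normal(size=(10, 2))
    res = rm_anova(x)
    t = stats.ttest_rel(x[:, 0], x[:, 1])
    assert res["F"] == pytest.approx(t.statistic**2, abs=1e-9)
    assert res["p"] == pytest.approx(t.pvalue, abs=1e-12)


def test_toy_table_matches_hand_sums_of_squares():
    x = np.array([[3.0, 4.0, 6.0], [2.0, 4.0, 5.0], [1.0, 3.0, 4.0], [4.0, 6.0, 7.0]])
    n, k = x.shape
    grand = x.mean()
    ss_cond = n * sum((x[:, j].mean() - grand) ** 2 for j in range(k))
    ss_subj = k * sum((x[i].mean() - grand) ** 2 for i in range(n))
    ss_err = sum(
        (x[i, j] - x[i].mean() - x[:, j].mean() + grand) ** 2
        for i in range(n)
        for j in range(k)
    )
    res = rm_anova(x)
    assert res["ss_condition"] == pytest.approx(ss_cond, rel=1e-9)
    assert res["ss_error"] == pytest.approx(ss_err, rel=1e-9)
    f = (ss_cond / (k - 1)) / (ss_err / ((k - 1) * (n - 1)))
    assert res["F"] == pytest.approx(f, rel=1e-9)
    assert (res["df1"], res["df2"]) == (2, 6)


def test_f_invariant_to_per_subject_constant():
    rng = np.random.default_rng(3)
    x = rng.normal(size=(8, 3))
    shifted = x + rng.normal(size=(8, 1)) * 10
    assert rm_anova(x)["F"] == pytest.approx(rm_anova(shifted)["F"], abs=1e-9)


def test_rm_anova_agrees_with_pingouin():
    pg = pytest.importorskip("pingouin")
    rng = np.random.default_rng(4)
    x = rng.normal(size=(9, 3)) + np.array([0.0, 0.3, 0.6])
    df = pd.DataFrame(x, columns=["a", "b", "c"]).reset_index().melt("index")
    res = pg.rm_anova(data=df, dv="value", within="variable", subject="index")
    mine = rm_anova(x)
    assert mine["F"] == pytest.approx(res["F"].iloc[0], rel=1e-6)
    assert mine["p"] == pytest.approx(res["p_unc"].iloc[0], rel=1e-6)


def test_greenhouse_geisser_option_matches_pingouin():
    pg = pytest.importorskip("pingouin")
    rng = np.random.default_rng(21)
    x = rng.normal(size=(10, 3)) * np.array([1.0, 2.0, 0.5])  # sphericity violated
    mine = rm_anova(x, sphericity_correction=True)
    assert 1.0 / 2 <= mine["epsilon"] <= 1.0
    df = pd.DataFrame(x, columns=["a", "b", "c"]).reset_index().melt("index")
    ref = pg.rm_anova(data=df, dv="value", within="variable", subject="index", correction=True)
    assert mine["epsilon"] == pytest.approx(ref["eps"].iloc[0], abs=1e-6)
    assert mine["p_gg"] == pytest.approx(ref["p_GG_corr"].iloc[0], rel=1e-6)


def test_missing_cells_and_single_condition_rejected():
    with pytest.raises(ValueError):
        rm_anova(np.array([[1.0, np.nan], [2.0, 3.0]]))
    with pytest.raises(ValueError):
        rm_anova(np.ones((5, 1)))


# ---------------------------------------------------------------------------
# planned contrasts


def test_identical_columns_give_t_zero_p_one():
    x = pd.DataFrame({"low": [1.0, 2, 3, 4], "high": [1.0, 2, 3, 4]})
    (res,) = planned_pairwise_tests(x)
    assert res["t"] == 0.0 and res["p"] == 1.0 and not res["degenerate"]


def test_constant_nonzero_difference_is_degenerate():
    x = pd.DataFrame({"low": [1.0, 2, 3, 4], "high": [2.0, 3, 4, 5]})
    (res,) = planned_pairwise_tests(x)
    assert res["degenerate"] and np.isnan(res["p"])
    assert not res["significant_at_corrected_alpha"]


def test_six_subject_pair_matches_textbook_formula():
    a = np.array([2.1, 2.5, 1.8, 2.9, 2.2, 2.6])
    b = np.array([1.5, 2.0, 1.9, 2.1, 1.7, 2.2])
    d = a - b
    t_hand = d.mean() / (d.std(ddof=1) / np.sqrt(6))
    p_hand = 2 * stats.t.sf(abs(t_hand), 5)
    (res,) = planned_pairwise_tests(pd.DataFrame({"a": a, "b": b}))
    assert res["t"] == pytest.approx(t_hand, abs=1e-12)
    assert res["p"] == pytest.approx(p_hand, abs=1e-12)


def test_familywise_error_controlled_under_global_null():
    """Bonferroni at 0.05/3 keeps the family-wise rate at or below 0.05."""
    rng = np.random.default_rng(5)
    alpha = 0.05 / 3
    n_rej = 0
    reps = 2000
    for _ in range(reps):
        x = pd.DataFrame(rng.normal(size=(12, 3)), columns=["l", "m", "h"])
        res = planned_pairwise_tests(x, corrected_alpha=alpha)
        n_rej += any(r["significant_at_corrected_alpha"] for r in res)
    upper = 0.05 + 1.96 * np.sqrt(0.05 * 0.95 / reps)
    assert n_rej / reps <= upper


# ---------------------------------------------------------------------------
# outlier rule


def test_outlier_rule_cases():
    assert sd_outlier_mask([1.0, 1, 1, 1]).all()
    rng = np.random.default_rng(6)
    x = np.append(rng.normal(size=30), 100.0)
    mask = sd_outlier_mask(x)
    assert (~mask).sum() == 1 and not mask[-1]
    assert sd_outlier_mask(x, k=1e9).all()
    with pytest.raises(ValueError):
        sd_outlier_mask([1.0, 2.0])
    with pytest.raises(ValueError):
        sd_outlier_mask([1.0, np.nan, 2.0, 3.0])


# ---------------------------------------------------------------------------
# end-to-end scoring


def test_summarize_behavior_detects_load_effect():
    cfg = wmosc.SimulationConfig(n_subjects=12, trials_per_load=20, seed=9)
    summary = summarize_behavior(wmosc.generate_behavior(cfg))
    means = summary["dprime"].table.mean(axis=0)
    assert means["low"] > means["medium"] > means["high"]
    assert summary["dprime"].anova["p"] < 0.001
    assert summary["dprime"].anova["df1"] == 2
    assert summary["dprime"].anova["df2"] == 2 * (12 - 1)
    # RT increases with load
    rts = summary["median_rt"].table.mean(axis=0)
    assert rts["low"] < rts["high"]
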