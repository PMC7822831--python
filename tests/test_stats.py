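import numpy as np
import pandas as pd
import pytest

from eegstates import stats as st

# ---------------------------------------------------------------------------
# TANOVA


def test_tanova_identical_condition_maps_give_p_one():
    rng = np.random.default_rng(0)
    base = rng.standard_normal((10, 63))
    maps = np.stack([base, base, base], axis=1)  # 3 identical conditions
    res = st.tanova(maps, factors=("condition",), n_perm=200, seed=1)
    assert res["condition"].p == pytest.approx(1.0)


def test_tanova_is_reproducible_under_fixed_seed():
    rng = np.random.default_rng(2)
    maps = rng.standard_normal((8, 3, 63))
    a = st.tanova(maps, n_perm=300, seed=11)["condition"]
    b = st.tanova(maps, n_perm=300, seed=11)["condition"]
    assert a.p == b.p and a.statistic == b.statistic


def test_tanova_add_one_estimator_bounds():
    rng = np.random.default_rng(3)
    maps = rng.standard_normal((8, 3, 63))
    p = st.tanova(maps, n_perm=200, seed=0)["condition"].p
    assert 1 / 201 <= p <= 1.0


def test_two_factor_tanova_reports_three_effects():
    rng = np.random.default_rng(4)
    maps = rng.standard_normal((6, 4, 6, 63))
    res = st.tanova(maps, factors=("condition", "class"), n_perm=150, seed=5)
    assert set(res) == {"condition", "class", "condition*class"}
    for r in res.values():
        assert 0 < r.p <= 1


def test_tanova_rejects_incomplete_design():
    maps = np.random.default_rng(5).standard_normal((5, 3, 63))
    maps[2, 1] = np.nan
    with pytest.raises(ValueError, match="incomplete"):
        st.tanova(maps, n_perm=150, seed=0)


def test_paired_tanova_identical_sets_give_p_one():
    rng = np.random.default_rng(6)
    A = rng.standard_normal((12, 63))
    res = st.paired_tanova(A, A.copy(), n_perm=300, seed=0)
    assert res.p == pytest.approx(1.0)
    assert res.statistic == pytest.approx(0.0, abs=1e-12)


def test_paired_tanova_detects_planted_shift():
    rng = np.random.default_rng(7)
    A = rng.standard_normal((20, 63))
    shift = rng.standard_normal(63) * 1.5
    B = A + shift
    res = st.paired_tanova(A, B, n_perm=5000, seed=1)
    assert res.p < 0.01


def test_paired_tanova_invariant_to_global_rescaling():
    rng = np.random.default_rng(8)
    A = rng.standard_normal((10, 63))
    B = rng.standard_normal((10, 63))
    p1 = st.paired_tanova(A, B, n_perm=400, seed=3).p
    p2 = st.paired_tanova(10.0 * A, 10.0 * B, n_perm=400, seed=3).p
    assert p1 == p2


# ---------------------------------------------------------------------------
# Repeated-measures ANOVA


def _long(Y, factors):
    """Subject x cells array -> long dataframe."""
    n = Y.shape[0]
    rows = []
    for s in range(n):
        for idx in np.ndindex(*Y.shape[1:]):
            row = {"participant": s, "value": Y[(s, *idx)]}
            for f, lv in zip(factors, idx):
                row[f] = f"l{lv}"
            rows.append(row)
    return pd.DataFrame(rows)


def test_rm_anova_no_variance_gives_zero_F():
    Y = np.full((5, 3), 2.5)
    df = _long(Y, ["condition"])
    res = st.rm_anova_gg(df, dv="value", within=["condition"])
    assert res["F"].iloc[0] == 0.0
    assert res["eta_p2"].iloc[0] == 0.0


def test_two_level_factor_has_unit_epsilon():
    rng = np.random.default_rng(9)
    df = _long(rng.standard_normal((6, 2)), ["condition"])
    res = st.rm_anova_gg(df, dv="value", within=["condition"])
    assert res["epsilon"].iloc[0] == 1.0


def test_rm_anova_matches_hand_computed_sums_of_squares():
    # 3 participants x 3 levels
    Y = np.array([[1.0, 2.0, 4.0], [2.0, 3.0, 3.0], [0.0, 2.0, 5.0]])
    grand = Y.mean()
    level_means = Y.mean(axis=0)
    subj_means = Y.mean(axis=1)
    ss_effect = 3 * np.sum((level_means - grand) ** 2)
    resid = Y - level_means[None] - subj_means[:, None] + grand
    ss_err = np.sum(resid**2)
    F_hand = (ss_effect / 2) / (ss_err / 4)
    res = st.rm_anova_gg(_long(Y, ["condition"]), dv="value", within=["condition"])
    assert res["F"].iloc[0] == pytest.approx(F_hand, abs=1e-10)
    assert res["eta_p2"].iloc[0] == pytest.approx(ss_effect / (ss_effect + ss_err), abs=1e-10)


@pytest.mark.parametrize("shape", [(8, 3), (6, 3, 2), (6, 3, 4, 2)])
def test_rm_anova_agrees_with_statsmodels_oracle(shape):
    """Uncorrected F of every effect matches statsmodels AnovaRM on random
    complete within-subject tables."""
    from statsmodels.stats.anova import AnovaRM

    factors = ["condition", "area", "hemisphere"][: len(shape) - 1]
    rng = np.random.default_rng(hash(shape) % 2**31)
    for _ in range(7):
        Y = rng.standard_normal(shape)
        df = _long(Y, factors)
        ours = st.rm_anova_gg(df, dv="value", within=factors)
        oracle = AnovaRM(df, depvar="value", subject="participant", within=factors).fit()
        tab = oracle.anova_table
        for _, row in ours.iterrows():
            name = row["effect"].replace("*", ":")
            assert row["F"] == pytest.approx(tab.loc[name, "F Value"], abs=1e-8)


def test_rm_anova_missing_cell_is_an_error():
    df = _long(np.random.default_rng(1).standard_normal((4, 3)), ["condition"])
    with pytest.raises(ValueError, match="missing"):
        st.rm_anova_gg(df.iloc[:-1], dv="value", within=["condition"])


# ---------------------------------------------------------------------------
# Paired t-tests and Bonferroni


def test_paired_t_hand_value():
    x = np.array([2.0, 3.0, 4.0])
    y = np.array([1.0, 1.0, 1.0])  # differences 1, 2, 3
    res = st.paired_tests_bonferroni([("d", x, y)])[0]
    assert res.statistic == pytest.approx(2 * np.sqrt(3), abs=1e-12)
    assert res.df == (2,)
    lo, hi = res.ci
    assert lo < 2.0 < hi


def test_identical_pairs_report_undefined_t():
    res = st.paired_tests_bonferroni([("same", np.ones(5), np.ones(5))])[0]
    assert np.isnan(res.statistic)
    assert res.p == 1.0


def test_bonferroni_caps_at_one():
    rng = np.random.default_rng(10)
    contrasts = [(f"c{i}", rng.standard_normal(10), rng.standard_normal(10)) for i in range(6)]
    results = st.paired_tests_bonferroni(contrasts)
    for r in results:
        if r.p_adj is not None:
            assert r.p_adj == pytest.approx(min(1.0, 6 * r.p))
            assert r.p_adj >= r.p


# ---------------------------------------------------------------------------
# Completion-time normalization


def _times(n=6, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for pid in range(n):
        for cond, mu in (("generation", 54.0), ("evolution", 92.8), ("evaluation", 16.5)):
            for run in (1, 2, 3):
                rows.append(
                    {
                        "participant": pid,
                        "condition": cond,
                        "run": run,
                        "seconds": max(2.0, rng.normal(mu, mu / 4)),
                    }
                )
    return pd.DataFrame(rows)


def test_normalized_groups_have_zero_mean_unit_sd():
    out = st.normalize_times(_times(), family="condition")
    for _, g in out.groupby(["participant", "condition"]):
        assert g["normalized"].mean() == pytest.approx(0.0, abs=1e-10)
        assert g["normalized"].std(ddof=1) == pytest.approx(1.0, abs=1e-10)


def test_normalization_preserves_rank_order():
    out = st.normalize_times(_times(seed=3), family="all")
    for _, g in out.groupby("participant"):
        assert np.array_equal(
            np.argsort(g["seconds"].to_numpy()), np.argsort(g["normalized"].to_numpy())
        )


def test_zero_variance_group_is_an_error():
    df = _times()
    df.loc[df["participant"] == 0, "seconds"] = 5.0
    with pytest.raises(ValueError, match="participant"):
        st.normalize_times(df, family="all")


def test_condition_effect_detected_on_planted_time_ordering():
    """With the emulated behavioural means the between-condition ANOVA on
    normalized, averaged times is significant for nearly every draw."""
    from eegstates.synth import StudyConfig, generate_study

    hits = 0
    for seed in range(10):
        cfg = StudyConfig(n_participants=28, rest_seconds=8.0, max_render_seconds=0.01)
        study = generate_study(cfg, seed=seed)
        norm = st.normalize_times(study.completion_times, family="all", average=True)
        res = st.rm_anova_gg(norm, dv="normalized", within=["condition"])
        hits += res["p"].iloc[0] < 0.05
    assert hits >= 9
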