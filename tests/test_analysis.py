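"""Analysis pipeline vs independent closed-form / normal-equations oracles."""

import numpy as np
import pytest
from scipy import stats

from cogbattery.analysis import (
    AGE_BIN_LABELS,
    ParticipantGameSummary,
    adherence_filter,
    age_bin,
    age_stratified_anova,
    flag_outliers,
    gender_ancova,
    meq_summary,
    mood_performance_analysis,
    pearson_r,
    plays_t_test,
    practice_curve,
    summarize_by_participant,
    trim_outliers,
)
from cogbattery.records import GameScore, SessionRecord


def _summary(pid, n_plays=5, mean=10.0, gender=None, age=None, meq=None,
             early=None, game="spin"):
    return ParticipantGameSummary(
        participant_id=pid, game=game, n_plays=n_plays, mean_score=mean,
        early_mean_score=early, age=age, gender=gender, meq_total=meq,
        plays=[mean] * n_plays)


def _record(pid, si, games=(), mood=None, age=None, gender=None, meq=None):
    return SessionRecord(
        participant_id=pid, session_index=si,
        timestamp=f"2015-03-{si:02d}T10:00:00+00:00", mood=mood,
        age=age, gender=gender, meq_total=meq,
        games=[GameScore(game=g, score=s, n_correct=0) for g, s in games])


class TestSummarize:
    def test_hand_built_fixture_matches_manual_means(self):
        records = [
            _record("a", 1, [("spin", 10.0)], age=30, gender="male", meq=12),
            _record("a", 2, [("spin", 20.0)]),
            _record("a", 3, [("spin", 30.0)]),
            _record("b", 1, [("spin", 5.0), ("react", 400.0)], gender="female"),
            _record("c", 1, [("react", 300.0)]),
        ]
        out = summarize_by_participant(records, "spin")
        assert [s.participant_id for s in out] == ["a", "b"]
        a = out[0]
        assert a.n_plays == 3 and a.mean_score == pytest.approx(20.0)
        assert a.age == 30 and a.gender == "male" and a.meq_total == 12
        assert a.early_mean_score is None  # needs plays 4-6

    def test_early_mean_uses_plays_4_to_6_only(self):
        records = [_record("a", i, [("spin", float(10 * i))])
                   for i in range(1, 9)]
        s = summarize_by_participant(records, "spin")[0]
        assert s.early_mean_score == pytest.approx(50.0)  # mean of 40,50,60

    def test_five_plays_has_no_early_mean(self):
        records = [_record("a", i, [("spin", 1.0)]) for i in range(1, 6)]
        assert summarize_by_participant(records, "spin")[0] \
            .early_mean_score is None


class TestFilters:
    def test_adherence_boundary(self):
        s4, s3 = _summary("a", n_plays=4), _summary("b", n_plays=3)
        assert adherence_filter([s4, s3]) == [s4]
        assert adherence_filter([]) == []

    def test_adherence_counting_oracle(self, rng):
        counts = rng.integers(1, 12, size=200)
        summaries = [_summary(f"p{i}", n_plays=int(c))
                     for i, c in enumerate(counts)]
        kept = adherence_filter(summaries, min_plays=4)
        assert len(kept) == int((counts >= 4).sum())

    def test_trim_removes_5_per_tail_of_1000(self, rng):
        scores = rng.standard_normal(1000)
        summaries = [_summary(f"p{i:04d}", mean=float(x))
                     for i, x in enumerate(scores)]
        kept = trim_outliers(summaries, fraction=0.01)
        assert len(kept) == 990
        kept_scores = [s.mean_score for s in kept]
        order = np.sort(scores)
        assert min(kept_scores) == pytest.approx(order[5])
        assert max(kept_scores) == pytest.approx(order[-6])

    def test_ties_broken_deterministically(self):
        summaries = [_summary(f"p{i:03d}", mean=1.0) for i in range(200)]
        flagged = flag_outliers(summaries, fraction=0.01)
        assert flagged == {"p000", "p199"}  # forced count, id-ordered

    def test_fraction_zero_is_identity(self):
        summaries = [_summary(f"p{i}", mean=float(i)) for i in range(50)]
        assert trim_outliers(summaries, fraction=0.0) == summaries

    def test_filter_by_fixed_flags_is_idempotent(self, rng):
        summaries = [_summary(f"p{i:03d}", mean=float(x))
                     for i, x in enumerate(rng.standard_normal(400))]
        flags = flag_outliers(summaries, fraction=0.01)
        once = [s for s in summaries if s.participant_id not in flags]
        twice = [s for s in once if s.participant_id not in flags]
        assert once == twice


def _ancova_oracle(scores, genders, plays):
    """Type-II two-term ANCOVA by explicit least squares."""
    y = np.asarray(scores, float)
    g = np.asarray([1.0 if x == "male" else 0.0 for x in genders])
    c = np.asarray(plays, float)
    n = len(y)

    def rss(X):
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        r = y - X @ beta
        return float(r @ r)

    ones = np.ones(n)
    rss_full = rss(np.column_stack([ones, g, c]))
    ss_gender = rss(np.column_stack([ones, c])) - rss_full
    ss_cov = rss(np.column_stack([ones, g])) - rss_full
    dfe = n - 3
    out = {}
    for name, ss in (("gender", ss_gender), ("covariate", ss_cov)):
        F = (ss / 1) / (rss_full / dfe)
        out[name] = {
            "F": F,
            "p": float(stats.f.sf(F, 1, dfe)),
            "partial_eta2": ss / (ss + rss_full),
        }
    return out, rss_full


class TestGenderAncova:
    def test_identical_groups_give_zero_F(self):
        summaries = []
        plays = [5, 6, 7, 9]  # not collinear with the scores
        for i, (p, score) in enumerate(zip(plays, [1.0, 2.0, 3.0, 4.0])):
            summaries.append(_summary(f"m{i}", n_plays=p, mean=score,
                                      gender="male"))
            summaries.append(_summary(f"f{i}", n_plays=p, mean=score,
                                      gender="female"))
        res = gender_ancova(summaries)
        assert res.gender.value == pytest.approx(0.0, abs=1e-10)

    def test_matches_normal_equations_oracle(self, rng):
        genders = ["male"] * 5 + ["female"] * 7
        plays = list(rng.integers(4, 15, size=12))
        scores = list(rng.normal(20, 5, size=12))
        summaries = [_summary(f"p{i}", n_plays=int(p), mean=float(s),
                              gender=g)
                     for i, (g, p, s) in enumerate(zip(genders, plays,
                                                       scores))]
        res = gender_ancova(summaries)
        oracle, _ = _ancova_oracle(scores, genders,
                                   [p - 4 for p in plays])
        assert res.gender.value == pytest.approx(oracle["gender"]["F"],
                                                 rel=1e-8)
        assert res.gender.p_value == pytest.approx(oracle["gender"]["p"],
                                                   rel=1e-8)
        assert res.gender.effect_size == pytest.approx(
            oracle["gender"]["partial_eta2"], rel=1e-8)
        assert res.covariate.value == pytest.approx(
            oracle["covariate"]["F"], rel=1e-8)
        assert res.gender.df == (1, 9)

    def test_orthogonal_null_covariate_reduces_to_oneway_ss(self):
        # same plays values in both groups and scores orthogonal to plays:
        # the gender SS equals the one-way between-groups SS exactly
        plays = [5, 6, 7, 8]
        m_scores = [10.0, 12.0, 12.0, 10.0]  # orthogonal to centered plays
        f_scores = [14.0, 16.0, 16.0, 14.0]
        summaries = [
            *[_summary(f"m{i}", n_plays=p, mean=s, gender="male")
              for i, (p, s) in enumerate(zip(plays, m_scores))],
            *[_summary(f"f{i}", n_plays=p, mean=s, gender="female")
              for i, (p, s) in enumerate(zip(plays, f_scores))],
        ]
        res = gender_ancova(summaries)
        y = np.array(m_scores + f_scores)
        ss_between = 4 * (np.mean(m_scores) - y.mean()) ** 2 \
            + 4 * (np.mean(f_scores) - y.mean()) ** 2
        rss = ((y - y.mean()) ** 2).sum() - ss_between
        # F uses the ANCOVA error df (n - 3)
        assert res.gender.value == pytest.approx(ss_between / (rss / 5),
                                                 rel=1e-8)

    def test_sequential_ss_decomposition_is_exact(self, rng):
        genders = ["male"] * 6 + ["female"] * 6
        plays = list(rng.integers(4, 20, size=12))
        scores = list(rng.normal(0, 1, size=12))
        y = np.asarray(scores)
        g = np.array([1.0] * 6 + [0.0] * 6)
        c = np.asarray(plays, float) - 4
        ones = np.ones(12)

        def rss(X):
            beta, *_ = np.linalg.lstsq(X, y, rcond=None)
            r = y - X @ beta
            return float(r @ r)

        tss = rss(ones[:, None])
        ss_seq_gender = tss - rss(np.column_stack([ones, g]))
        ss_seq_cov = rss(np.column_stack([ones, g])) \
            - rss(np.column_stack([ones, g, c]))
        resid = rss(np.column_stack([ones, g, c]))
        assert tss == pytest.approx(ss_seq_gender + ss_seq_cov + resid,
                                    rel=1e-8)

    def test_single_gender_rejected(self):
        with pytest.raises(ValueError):
            gender_ancova([_summary(f"m{i}", gender="male")
                           for i in range(5)])


class TestPlaysTTest:
    def test_identical_groups(self):
        summaries = [_summary(f"m{i}", n_plays=p, gender="male")
                     for i, p in enumerate([4, 5, 6])] + \
                    [_summary(f"f{i}", n_plays=p, gender="female")
                     for i, p in enumerate([4, 5, 6])]
        res = plays_t_test(summaries)
        assert res.value == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_hand_computed_pooled_formula(self):
        summaries = [_summary(f"m{i}", n_plays=p, gender="male")
                     for i, p in enumerate([3, 4, 5])] + \
                    [_summary(f"f{i}", n_plays=p, gender="female")
                     for i, p in enumerate([4, 5, 6])]
        res = plays_t_test(summaries)
        # pooled s^2 = 1, t = -1 / sqrt(1/3 + 1/3)
        assert res.value == pytest.approx(-1 / np.sqrt(2 / 3), rel=1e-10)
        assert res.df == 4  # n1 + n2 - 2


class TestAgeAnova:
    @pytest.mark.parametrize("age,label", [
        (18, "<20"), (19, "<20"), (20, "20-29"), (29, "20-29"),
        (69, "60-69"), (70, ">70"), (85, ">70"),
    ])
    def test_decade_bin_edges(self, age, label):
        assert age_bin(age) == label

    def test_equal_bin_means_give_near_zero_F(self):
        summaries = []
        for b, age in enumerate([19, 25, 35, 45]):
            for j, delta in enumerate([-1.0, 0.0, 1.0]):
                summaries.append(_summary(f"p{b}{j}", n_plays=7,
                                          age=age, early=10.0 + delta))
        res = age_stratified_anova(summaries)
        assert res.value == pytest.approx(0.0, abs=1e-10)
        assert res.effect_size == pytest.approx(0.0, abs=1e-10)

    def test_two_bins_equal_t_squared(self, rng):
        a = rng.normal(10, 2, size=8)
        b = rng.normal(12, 2, size=9)
        summaries = [_summary(f"a{i}", n_plays=7, age=25, early=float(x))
                     for i, x in enumerate(a)] + \
                    [_summary(f"b{i}", n_plays=7, age=45, early=float(x))
                     for i, x in enumerate(b)]
        res = age_stratified_anova(summaries)
        t, _ = stats.ttest_ind(a, b, equal_var=True)
        assert res.value == pytest.approx(t**2, rel=1e-10)
        assert res.df == (1, 15)

    def test_empty_bins_dropped_with_warning(self):
        summaries = [_summary(f"a{i}", n_plays=7, age=25, early=float(i))
                     for i in range(5)] + \
                    [_summary(f"b{i}", n_plays=7, age=75, early=float(i))
                     for i in range(5)]
        dropped = []
        res = age_stratified_anova(summaries, warn=dropped)
        assert set(dropped) == {"<20", "30-39", "40-49", "50-59", "60-69"}
        assert res.df == (1, 8)

    def test_eta2_is_between_over_total(self, rng):
        vals = {19: rng.normal(0, 1, 6), 33: rng.normal(1, 1, 7),
                55: rng.normal(2, 1, 5)}
        summaries = [_summary(f"{age}_{i}", n_plays=7, age=age,
                              early=float(x))
                     for age, xs in vals.items() for i, x in enumerate(xs)]
        res = age_stratified_anova(summaries)
        allv = np.concatenate(list(vals.values()))
        grand = allv.mean()
        ss_b = sum(len(v) * (v.mean() - grand) ** 2 for v in vals.values())
        ss_t = ((allv - grand) ** 2).sum()
        assert res.effect_size == pytest.approx(ss_b / ss_t, rel=1e-10)


class TestPearson:
    def test_perfect_correlations(self):
        x = [1.0, 2.0, 3.0, 4.0]
        assert pearson_r(x, x).value == pytest.approx(1.0)
        assert pearson_r(x, [-v for v in x]).value == pytest.approx(-1.0)

    def test_matches_covariance_formula(self, rng):
        x = rng.normal(size=10)
        y = rng.normal(size=10)
        r_hand = (np.mean(x * y) - x.mean() * y.mean()) / (x.std() * y.std())
        assert pearson_r(x, y).value == pytest.approx(r_hand, rel=1e-10)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson_r([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestMood:
    def test_constant_mood_skips_everyone(self):
        records = []
        for pid in ("a", "b"):
            for i in range(1, 6):
                records.append(_record(pid, i, [("spin", float(i))],
                                       mood=5.0))
        # group-level r needs variation across participants, so perturb one
        records.append(_record("c", 1, [("spin", 2.0)], mood=6.0))
        for i in range(2, 6):
            records.append(_record("c", i, [("spin", float(2 * i))],
                                   mood=6.0))
        out = mood_performance_analysis(records, "spin")
        assert out.n_individual == 0
        assert out.n_skipped == 3
        assert np.isnan(out.mean_individual_rho)

    def test_null_coupling_mean_rho_near_zero(self, small_dataset):
        _, records = small_dataset
        out = mood_performance_analysis(records, "spin")
        assert out.n_individual > 20
        assert abs(out.mean_individual_rho) < 0.15

    def test_positive_coupling_recovered(self):
        from cogbattery.cohort_sim import SimConfig, simulate_dataset
        cfg = SimConfig(seed=11, n_participants=120, games=("supersnap",),
                        mood_performance_coupling=1.2, p_mood_skip=0.0)
        records = simulate_dataset(cfg)
        out = mood_performance_analysis(records, "supersnap")
        assert out.mean_individual_rho > 0.1
        assert out.group_r.value > 0.0


class TestPracticeCurveTable:
    def test_single_participant_curve(self):
        records = [_record("a", i, [("spin", float(v))])
                   for i, v in enumerate([1, 2, 3], start=1)]
        df = practice_curve(records, "spin")
        assert list(df["mean_score"]) == [1.0, 2.0, 3.0]
        assert list(df["n_remaining"]) == [1, 1, 1]

    def test_n_remaining_non_increasing(self, small_dataset):
        _, records = small_dataset
        df = practice_curve(records, "react")
        n = list(df["n_remaining"])
        assert n == sorted(n, reverse=True)


class TestMeqSummary:
    def test_one_per_total_gives_class_widths(self):
        df = meq_summary(range(4, 26))
        assert list(df["count"]) == [4, 4, 6, 4, 4]
        assert df["proportion"].sum() == pytest.approx(1.0)

    def test_single_class(self):
        df = meq_summary([12, 12, 12])
        assert df.set_index("label").loc["neither", "count"] == 3
        assert df["proportion"].sum() == pytest.approx(1.0)

    def test_accepts_summaries(self):
        df = meq_summary([_summary("a", meq=5), _summary("b", meq=20),
                          _summary("c", meq=None)])
        assert df["count"].sum() == 2
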