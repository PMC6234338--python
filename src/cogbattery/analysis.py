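"""Cohort-analysis protocol over session records.

Implements the study's analysis pipeline: per-participant-per-game
summaries, the minimum-4-plays adherence filter, extreme-1% outlier
exclusion, gender ANCOVA with the number of plays beyond 4 as covariate
(partial eta-squared effect sizes), gender t tests on play counts,
age-stratified one-way ANOVA over decade bins of the mean score from plays
4-6, age and mood correlations, chronotype category summaries, and
practice curves.

Degrees of freedom follow the standard linear-model conventions
(``(1, n - 3)`` for the two-term ANCOVA, ``(k - 1, n - k)`` for the one-way
ANOVA); results also echo the ``(k - 1, n - 1)`` print convention some
reports use, in the ``df_print`` field.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .meq import classify_meq, load_key, CLASS_LABELS
from .records import SessionRecord

__all__ = [
    "ParticipantGameSummary",
    "AnalysisResult",
    "AncovaResult",
    "AGE_BIN_LABELS",
    "age_bin",
    "summarize_by_participant",
    "adherence_filter",
    "flag_outliers",
    "trim_outliers",
    "gender_ancova",
    "plays_t_test",
    "age_stratified_anova",
    "pearson_r",
    "mood_performance_analysis",
    "practice_curve",
    "meq_summary",
]


@dataclass
class ParticipantGameSummary:
    """Per-participant aggregate for one game.

    ``early_mean_score`` is the mean of plays 4-6 only, present only when
    the participant played at least 6 times; it gives a practice-controlled
    performance snapshot for the age-stratified analysis.
    """

    participant_id: str
    game: str
    n_plays: int
    mean_score: float
    early_mean_score: Optional[float] = None
    age: Optional[int] = None
    gender: Optional[str] = None
    meq_total: Optional[int] = None
    mean_mood: Optional[float] = None
    plays: list[float] = field(default_factory=list)
    moods: list[Optional[float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.n_plays < 1:
            raise ValueError("n_plays must be >= 1")
        if self.early_mean_score is not None and self.n_plays < 6:
            raise ValueError("early_mean_score requires >= 6 plays")


@dataclass
class AnalysisResult:
    """A single test statistic with df, p value and effect size."""

    statistic_name: str        # "F", "t", "r" or "rho"
    value: float
    df: tuple | float
    p_value: float
    effect_size_name: str = "none"   # "eta2", "partial_eta2" or "none"
    effect_size: Optional[float] = None
    n: int = 0
    df_print: Optional[tuple] = None  # (k-1, n-1) echo convention

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p_value must lie in [0, 1]")
        if self.statistic_name == "F" and self.value < 0:
            raise ValueError("F statistic must be non-negative")


@dataclass
class AncovaResult:
    """Gender ANCOVA output: the factor effect plus the covariate effect."""

    gender: AnalysisResult
    covariate: AnalysisResult
    n: int


def summarize_by_participant(records: Sequence[SessionRecord],
                             game: str) -> list[ParticipantGameSummary]:
    """One summary per participant who played ``game`` at least once.

    Plays are ordered by session index; demographics are taken from the
    participant's first session carrying them.
    """
    per: dict[str, dict] = {}
    for rec in records:
        if not isinstance(rec, SessionRecord):
            raise TypeError(f"malformed record: {rec!r}")
        entry = per.setdefault(rec.participant_id, {
            "sessions": [], "age": None, "gender": None, "meq": None})
        if rec.age is not None and entry["age"] is None:
            entry["age"] = rec.age
        if rec.gender is not None and entry["gender"] is None:
            entry["gender"] = rec.gender
        if rec.meq_total is not None and entry["meq"] is None:
            entry["meq"] = rec.meq_total
        for gs in rec.games:
            if gs.game == game:
                entry["sessions"].append(
                    (rec.session_index, gs.score, rec.mood))
    out = []
    for pid in sorted(per):
        entry = per[pid]
        if not entry["sessions"]:
            continue
        entry["sessions"].sort(key=lambda t: t[0])
        scores = [s for _, s, _ in entry["sessions"]]
        moods = [m for _, _, m in entry["sessions"]]
        early = (float(np.mean(scores[3:6])) if len(scores) >= 6 else None)
        present_moods = [m for m in moods if m is not None]
        out.append(ParticipantGameSummary(
            participant_id=pid, game=game, n_plays=len(scores),
            mean_score=float(np.mean(scores)), early_mean_score=early,
            age=entry["age"], gender=entry["gender"],
            meq_total=entry["meq"],
            mean_mood=(float(np.mean(present_moods))
                       if present_moods else None),
            plays=[float(s) for s in scores], moods=moods,
        ))
    return out


def adherence_filter(summaries: Iterable[ParticipantGameSummary],
                     min_plays: int = 4) -> list[ParticipantGameSummary]:
    """Keep participants with at least ``min_plays`` plays of the game."""
    if min_plays < 1:
        raise ValueError("min_plays must be >= 1")
    return [s for s in summaries if s.n_plays >= min_plays]


def flag_outliers(summaries: Sequence[ParticipantGameSummary],
                  fraction: float = 0.01,
                  method: str = "two_tail") -> set[str]:
    """Participant ids of the most extreme ``fraction`` of mean scores.

    ``two_tail`` removes ``fraction/2`` from each tail of the mean-score
    distribution; ``mad`` ranks by absolute deviation from the median and
    removes the top ``fraction``. Ties are broken by participant id so the
    selection is deterministic.
    """
    if not 0.0 <= fraction < 0.5:
        raise ValueError("fraction must lie in [0, 0.5)")
    n = len(summaries)
    if n == 0 or fraction == 0.0:
        return set()
    if method == "two_tail":
        k = int(round(n * fraction / 2.0))
        if k == 0:
            return set()
        ranked = sorted(summaries, key=lambda s: (s.mean_score,
                                                  s.participant_id))
        return {s.participant_id for s in ranked[:k]} | \
               {s.participant_id for s in ranked[-k:]}
    if method == "mad":
        k = int(round(n * fraction))
        if k == 0:
            return set()
        med = float(np.median([s.mean_score for s in summaries]))
        ranked = sorted(summaries,
                        key=lambda s: (-abs(s.mean_score - med),
                                       s.participant_id))
        return {s.participant_id for s in ranked[:k]}
    raise ValueError(f"unknown method {method!r}")


def trim_outliers(summaries: Sequence[ParticipantGameSummary],
                  fraction: float = 0.01,
                  method: str = "two_tail") -> list[ParticipantGameSummary]:
    """Drop the flagged extreme fraction (computed on the given set once).

    To re-apply after further filtering, recompute flags on the original
    set and filter by id; filtering by a fixed flag set is idempotent.
    """
    flagged = flag_outliers(summaries, fraction, method)
    return [s for s in summaries if s.participant_id not in flagged]


def _require_both_genders(summaries: Sequence[ParticipantGameSummary]):
    by_gender = {"male": [], "female": []}
    for s in summaries:
        if s.gender in by_gender:
            by_gender[s.gender].append(s)
    if min(len(v) for v in by_gender.values()) < 2:
        raise ValueError("need at least 2 participants of each gender")
    return by_gender


def gender_ancova(summaries: Sequence[ParticipantGameSummary],
                  min_plays: int = 4,
                  covariate: str = "plays_beyond_min"
                  ) -> AncovaResult:
    """ANCOVA: mean score ~ gender + number of plays beyond the cutoff.

    Fits the two-term linear model with Type-II sums of squares and reports
    the gender and covariate F tests with partial eta-squared
    (``SS_effect / (SS_effect + SS_residual)``).
    """
    _require_both_genders(summaries)
    rows = [(s.mean_score, s.gender,
             s.n_plays - (min_plays if covariate == "plays_beyond_min" else 0))
            for s in summaries if s.gender is not None]
    df = pd.DataFrame(rows, columns=["mean_score", "gender", "plays"])
    n = len(df)
    model = smf.ols("mean_score ~ C(gender) + plays", data=df).fit()
    table = sm.stats.anova_lm(model, typ=2)
    ss_resid = float(table.loc["Residual", "sum_sq"])
    out = {}
    for term, name in (("C(gender)", "gender"), ("plays", "covariate")):
        ss = float(table.loc[term, "sum_sq"])
        F = float(table.loc[term, "F"])
        p = float(table.loc[term, "PR(>F)"])
        out[name] = AnalysisResult(
            statistic_name="F", value=F,
            df=(1, n - 3), p_value=p,
            effect_size_name="partial_eta2",
            effect_size=ss / (ss + ss_resid), n=n,
            df_print=(1, n - 1),
        )
    return AncovaResult(gender=out["gender"], covariate=out["covariate"], n=n)


def plays_t_test(summaries: Sequence[ParticipantGameSummary]
                 ) -> AnalysisResult:
    """Pooled two-sample t test of play counts between genders.

    Confirms the number-of-plays covariate is not confounded with gender;
    df follows the pooled convention ``n1 + n2 - 2``.
    """
    by_gender = _require_both_genders(summaries)
    a = np.array([s.n_plays for s in by_gender["male"]], dtype=float)
    b = np.array([s.n_plays for s in by_gender["female"]], dtype=float)
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        if a.mean() == b.mean():
            t, p = 0.0, 1.0
        else:
            t, p = math.inf if a.mean() > b.mean() else -math.inf, 0.0
    else:
        t, p = stats.ttest_ind(a, b, equal_var=True)
    df = len(a) + len(b) - 2
    return AnalysisResult(statistic_name="t", value=float(t), df=float(df),
                          p_value=float(p), n=len(a) + len(b))


AGE_BIN_LABELS = ("<20", "20-29", "30-39", "40-49", "50-59", "60-69", ">70")


def age_bin(age: int) -> str:
    """Decade bin label; ages 70 and above fall in the top bin."""
    if age < 20:
        return "<20"
    if age >= 70:
        return ">70"
    lo = (age // 10) * 10
    return f"{lo}-{lo + 9}"


def age_stratified_anova(summaries: Sequence[ParticipantGameSummary],
                         warn: Optional[list] = None) -> AnalysisResult:
    """One-way ANOVA of the plays-4-6 mean score across 7 decade age bins.

    Participants lacking age or an early mean (fewer than 6 plays) are
    excluded. Empty bins are dropped (optionally reported through ``warn``)
    with the degrees of freedom adjusted. Effect size is classical
    eta-squared, ``SS_between / SS_total``.
    """
    groups: dict[str, list[float]] = {lab: [] for lab in AGE_BIN_LABELS}
    for s in summaries:
        if s.age is None or s.early_mean_score is None:
            continue
        groups[age_bin(s.age)].append(s.early_mean_score)
    kept = {lab: np.asarray(v, float) for lab, v in groups.items() if v}
    dropped = [lab for lab in AGE_BIN_LABELS if not groups[lab]]
    if warn is not None:
        warn.extend(dropped)
    if len(kept) < 2:
        raise ValueError("need at least 2 non-empty age bins")
    values = list(kept.values())
    n = sum(len(v) for v in values)
    k = len(values)
    grand = np.concatenate(values).mean()
    ss_between = sum(len(v) * (v.mean() - grand) ** 2 for v in values)
    ss_total = float(((np.concatenate(values) - grand) ** 2).sum())
    F, p = stats.f_oneway(*values)
    return AnalysisResult(
        statistic_name="F", value=float(F), df=(k - 1, n - k),
        p_value=float(p), effect_size_name="eta2",
        effect_size=(ss_between / ss_total if ss_total > 0 else 0.0),
        n=n, df_print=(k - 1, n - 1),
    )


def pearson_r(x: Sequence[float], y: Sequence[float]) -> AnalysisResult:
    """Pearson correlation with the usual t-based two-sided p value."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D sequences")
    if len(x) < 3:
        raise ValueError("need at least 3 pairs")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance input")
    r, p = stats.pearsonr(x, y)
    return AnalysisResult(statistic_name="r", value=float(r),
                          df=float(len(x) - 2), p_value=float(p), n=len(x))


@dataclass
class MoodAnalysis:
    """Group- and individual-level mood-performance association."""

    group_r: AnalysisResult
    mean_individual_rho: float
    n_individual: int
    n_skipped: int


def mood_performance_analysis(records: Sequence[SessionRecord], game: str,
                              min_plays: int = 4) -> MoodAnalysis:
    """Mood-performance association at two levels.

    (a) group: Pearson r between per-participant average mood and average
    score over participants with at least ``min_plays`` plays; (b)
    individual: per-participant Spearman rho between session mood and
    session score, averaged over participants, skipping (and counting)
    those with zero variance or too few mood-score pairs.
    """
    summaries = adherence_filter(summarize_by_participant(records, game),
                                 min_plays)
    with_mood = [s for s in summaries if s.mean_mood is not None]
    group_r = pearson_r([s.mean_mood for s in with_mood],
                        [s.mean_score for s in with_mood])
    rhos = []
    skipped = 0
    for s in summaries:
        pairs = [(m, sc) for m, sc in zip(s.moods, s.plays) if m is not None]
        if len(pairs) < 3:
            skipped += 1
            continue
        m = np.array([p[0] for p in pairs])
        sc = np.array([p[1] for p in pairs])
        if np.std(m) == 0 or np.std(sc) == 0:
            skipped += 1
            continue
        rho, _ = stats.spearmanr(m, sc)
        rhos.append(rho)
    mean_rho = float(np.mean(rhos)) if rhos else float("nan")
    return MoodAnalysis(group_r=group_r, mean_individual_rho=mean_rho,
                        n_individual=len(rhos), n_skipped=skipped)


def practice_curve(records: Sequence[SessionRecord],
                   game: str) -> pd.DataFrame:
    """Group mean score at each play index, with participants remaining.

    Returns a DataFrame with columns ``play_index`` (1-based),
    ``mean_score`` over the participants who reached that play, and
    ``n_remaining`` (non-increasing).
    """
    summaries = summarize_by_participant(records, game)
    max_plays = max((s.n_plays for s in summaries), default=0)
    rows = []
    for i in range(max_plays):
        at = [s.plays[i] for s in summaries if s.n_plays > i]
        rows.append({"play_index": i + 1,
                     "mean_score": float(np.mean(at)),
                     "n_remaining": len(at)})
    return pd.DataFrame(rows)


def meq_summary(totals_or_summaries: Iterable) -> pd.DataFrame:
    """Counts and proportions of the five chronotype classes.

    Accepts raw questionnaire totals or participant summaries (entries
    lacking a total are ignored).
    """
    counts = {lab: 0 for lab in CLASS_LABELS}
    n = 0
    for item in totals_or_summaries:
        t = getattr(item, "meq_total", item)
        if t is None:
            continue
        counts[classify_meq(int(t)).label] += 1
        n += 1
    rows = [{"label": lab, "count": c,
             "proportion": (c / n if n else float("nan"))}
            for lab, c in counts.items()]
    return pd.DataFrame(rows)
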