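"""Synthetic participants and longitudinal app histories.

The simulator emulates the study conditions of a self-selected mobile-app
cohort: ages floored at 18 with a selectable-minimum spike, chronotype
totals positively correlated with age, heavy-tailed per-participant session
counts whose latent engagement also rises with age, per-game latent
abilities with saturating practice curves, small male advantages in the
spatial/speeded games, age-related decline strongest in the speeded and
working-memory games, and AR(1) session mood uncoupled from performance by
default.

Behavioral response models are deliberately simple parametric forms — a
shifted-lognormal latency for the vigilance and rotation games, logistic
hit/false-alarm probabilities driven by a latent discriminability for the
2-back, a binomial tracking capacity for the object-tracking game, and an
exponential search time for the action-acquisition game. They are the
minimum structure needed for the downstream analyses to have recoverable
signal, not a cognitive model.

Everything is driven by a single master seed threaded through
``numpy.random.SeedSequence`` spawns, so a dataset is bit-reproducible.
"""

from __future__ import annotations

import datetime as _dt
import json
import math
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np

from .engines import DEFAULT_CONFIG, EngineConfig, Responder, run_session
from .records import GAMES, ResponderEvent, SessionRecord

__all__ = [
    "SimConfig",
    "ParticipantProfile",
    "SimulatedGameResponder",
    "sample_cohort",
    "sample_session_count",
    "make_responder",
    "simulate_dataset",
    "practice_gap",
]


def _default_gender_effects() -> dict:
    # Cohen's d (male - female) in latent-skill SD units per game; the
    # 2-back shows none, the rotation game the largest.
    return {"hotspot": 0.30, "react": 0.12, "spin": 0.45,
            "supersnap": 0.0, "track": 0.10}


def _default_age_effects() -> dict:
    # latent-skill change (SD units) per decade of age beyond 35
    return {"hotspot": 0.0, "react": -0.30, "spin": -0.27,
            "supersnap": -0.25, "track": -0.09}


def _default_practice_rates() -> dict:
    # exponential learning rate per play; the vigilance game is too simple
    # to show practice and stays flat
    return {"hotspot": 0.35, "react": 0.0, "spin": 0.35,
            "supersnap": 0.35, "track": 0.35}


@dataclass
class SimConfig:
    """All simulator knobs. Defaults define the emulated study conditions."""

    seed: int
    n_participants: int = 500
    games: tuple[str, ...] = GAMES

    # demographics
    p_age_floor: float = 0.05      # extra mass at the 18-year selectable floor
    age_gamma_shape: float = 2.2   # age = 18 + Gamma(shape, scale), rounded
    age_gamma_scale: float = 8.0
    p_missing_age: float = 0.074
    p_missing_gender: float = 0.017
    p_male: float = 0.40           # of participants reporting gender

    # chronotype
    meq_mean: float = 13.2
    meq_sd: float = 4.0
    age_meq_corr: float = 0.298    # latent age-chronotype correlation

    # engagement / attrition
    age_engagement_corr: float = 0.32  # latent; observed age-plays r ~ 0.2
    mean_sessions: float = 5.0
    nb_dispersion: float = 1.5     # gamma shape of the mixed Poisson
    engagement_sd_log: float = 0.6
    max_sessions: int = 60         # practical ceiling on app engagement

    # effect structure
    gender_effects: dict = field(default_factory=_default_gender_effects)
    age_effects: dict = field(default_factory=_default_age_effects)
    practice_rates: dict = field(default_factory=_default_practice_rates)
    practice_depth: float = 0.8    # SD units below asymptote on first play
    ability_sd: float = 1.0
    session_noise_sd: float = 0.3

    # mood
    mood_baseline_mean: float = 6.5
    mood_baseline_sd: float = 1.2
    mood_ar: float = 0.5
    mood_noise_sd: float = 1.0
    p_mood_skip: float = 0.02
    mood_performance_coupling: float = 0.0

    # hooks / misc
    tod_performance_coupling: float = 0.0  # reserved for time-of-day studies
    skip_prob: float = 0.05        # per-game per-session skip probability
    start_date: str = "2015-02-01"
    recruitment_days: int = 540
    mean_gap_days: float = 3.0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")
        for name in ("p_age_floor", "p_missing_age", "p_missing_gender",
                     "p_male", "p_mood_skip", "skip_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        for name in ("age_meq_corr", "age_engagement_corr"):
            v = getattr(self, name)
            if not -1.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (-1, 1), got {v}")
        unknown = set(self.games) - set(GAMES)
        if unknown:
            raise ValueError(f"unknown games in config: {sorted(unknown)}")

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        return cls(**{k: (tuple(v) if k == "games" else v)
                      for k, v in d.items()})

    @classmethod
    def from_json(cls, path) -> "SimConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["games"] = list(self.games)
        return d


@dataclass
class ParticipantProfile:
    """Simulator-side ground truth for one participant."""

    id: str
    age: Optional[int]             # reported (None if declined)
    gender: Optional[str]          # reported (None if declined)
    meq_total: int
    latent_ability: dict           # game -> standardized ability
    engagement: float              # latent z driving expected session count
    mood_baseline: float
    true_age: int = 18             # pre-missingness age, drives couplings

    def __post_init__(self) -> None:
        if self.age is not None and self.age < 18:
            raise ValueError("reported age must be >= 18")
        if not 4 <= self.meq_total <= 25:
            raise ValueError("meq_total must lie in [4, 25]")


def practice_gap(cfg: SimConfig, game: str, play_index: int) -> float:
    """Expected skill deficit (SD units) below asymptote at a given play.

    The learning curve is ``asymptote - depth * exp(-rate * (play - 1))``;
    this returns the ``depth * exp(...)`` gap term. A zero rate means the
    game shows no practice effect: performance starts at asymptote.
    """
    rate = cfg.practice_rates.get(game, 0.0)
    if rate == 0.0:
        return 0.0
    return cfg.practice_depth * math.exp(-rate * (play_index - 1))


def sample_cohort(cfg: SimConfig,
                  rng: Optional[np.random.Generator] = None
                  ) -> list[ParticipantProfile]:
    """Draw the participant pool.

    Ages are 18-floored with a configurable spike at the floor (the lowest
    selectable age). Chronotype totals are built from a latent that is
    linear in standardized age with slope ``age_meq_corr``, so the sample
    age-chronotype correlation matches the configured coupling up to
    rounding/clipping attenuation. Engagement shares a latent with age the
    same way. Missingness is applied independently afterwards.
    """
    cfg.validate()
    rng = rng or np.random.default_rng(np.random.SeedSequence(cfg.seed))
    n = cfg.n_participants

    ages = 18 + np.round(rng.gamma(cfg.age_gamma_shape, cfg.age_gamma_scale,
                                   size=n)).astype(int)
    ages[rng.random(n) < cfg.p_age_floor] = 18
    z_age = (ages - ages.mean()) / (ages.std() if ages.std() > 0 else 1.0)

    rho = cfg.age_meq_corr
    meq_latent = rho * z_age + math.sqrt(1 - rho**2) * rng.standard_normal(n)
    meq = np.clip(np.round(cfg.meq_mean + cfg.meq_sd * meq_latent),
                  4, 25).astype(int)

    c = cfg.age_engagement_corr
    engagement = c * z_age + math.sqrt(1 - c**2) * rng.standard_normal(n)

    genders = np.where(rng.random(n) < cfg.p_male, "male", "female")
    miss_gender = rng.random(n) < cfg.p_missing_gender
    miss_age = rng.random(n) < cfg.p_missing_age

    abilities = rng.standard_normal((n, len(GAMES)))
    mood_base = np.clip(
        rng.normal(cfg.mood_baseline_mean, cfg.mood_baseline_sd, size=n),
        1.0, 10.0)

    profiles = []
    for i in range(n):
        profiles.append(ParticipantProfile(
            id=f"p{i:06d}",
            age=None if miss_age[i] else int(ages[i]),
            gender=None if miss_gender[i] else str(genders[i]),
            meq_total=int(meq[i]),
            latent_ability={g: float(abilities[i, j])
                            for j, g in enumerate(GAMES)},
            engagement=float(engagement[i]),
            mood_baseline=float(mood_base[i]),
            true_age=int(ages[i]),
        ))
    return profiles


def sample_session_count(p: ParticipantProfile, cfg: SimConfig,
                         rng: np.random.Generator) -> int:
    """Heavy-tailed session count: zero-truncated gamma-mixed Poisson.

    The expected count scales log-linearly with latent engagement (itself
    age-correlated), producing the steep attrition funnel and a positive
    age-plays correlation.
    """
    s = cfg.engagement_sd_log
    mu = cfg.mean_sessions * math.exp(s * p.engagement - s * s / 2.0)
    lam = rng.gamma(cfg.nb_dispersion, mu / cfg.nb_dispersion)
    return min(cfg.max_sessions, max(1, int(rng.poisson(lam))))


def _sigmoid(x: float) -> float:
    return 1.0 / (1.0 + math.exp(-x))


class SimulatedGameResponder(Responder):
    """One participant playing one game at one practice level.

    ``skill`` is a standardized latent combining ability, demographic
    shifts, the practice curve, and session noise; each game maps it onto
    behavior through a simple parametric response model.
    """

    def __init__(self, game: str, skill: float):
        if game not in GAMES:
            raise ValueError(f"unknown game {game!r}")
        self.game = game
        self.skill = float(skill)

    # -- react: shifted-lognormal choice latency -------------------------
    P_PREMATURE = 0.01
    P_WRONG = 0.02

    def react_response(self, trial_index, interval_s, correct_button, rng):
        if rng.random() < self.P_PREMATURE:
            return ResponderEvent("tap", latency_ms=0.0,
                                  payload={"button": int(rng.integers(4)),
                                           "premature": True})
        latency = 130.0 + rng.lognormal(math.log(140.0) - 0.18 * self.skill,
                                        0.20)
        button = correct_button
        if rng.random() < self.P_WRONG:
            button = int((correct_button + 1 + rng.integers(3)) % 4)
        return ResponderEvent("tap", latency_ms=float(latency),
                              payload={"button": int(button),
                                       "premature": False})

    # -- supersnap: logistic hit / false-alarm probabilities -------------
    def supersnap_response(self, position, shape, is_match, rng):
        if is_match:
            p = _sigmoid(2.2 + 0.9 * self.skill)
        else:
            p = _sigmoid(-3.3 - 0.9 * self.skill)
        return bool(rng.random() < p)

    # -- spin: logistic accuracy, lognormal decision latency -------------
    def spin_response(self, trial, rng):
        latency = max(600.0, rng.lognormal(math.log(2600.0)
                                           - 0.15 * self.skill, 0.30))
        if rng.random() < _sigmoid(1.5 + 0.9 * self.skill):
            return trial.correct_index, latency
        foils = [i for i in range(3) if i != trial.correct_index]
        return int(foils[int(rng.integers(2))]), latency

    # -- track: binomial tracking capacity over the 3 targets ------------
    def track_response(self, state, rng):
        set_size = state.n_balls
        p = _sigmoid(1.1 + 0.7 * self.skill - 0.06 * (set_size - 8))
        k = int(rng.binomial(3, p))
        targets = list(state.target_ids)
        non_targets = [i for i in range(set_size) if i not in targets]
        kept = list(rng.choice(targets, size=k, replace=False)) if k else []
        n_wrong = 3 - k
        wrong = list(rng.choice(non_targets, size=n_wrong, replace=False)) \
            if n_wrong else []
        return [int(i) for i in kept + wrong]

    # -- hotspot: exponential search time, then settle in the target -----
    def hotspot_path(self, target, n_ticks, tick_s, rng):
        horizon = n_ticks * tick_s
        t_find = 0.3 + rng.exponential(5.0 * math.exp(-0.35 * self.skill))
        start = np.array([0.0 if target.center[0] > 0.5 else 1.0,
                          0.0 if target.center[1] > 0.5 else 1.0])
        path = np.tile(start, (n_ticks, 1))
        if t_find < horizon - 0.6:
            k = int(t_find / tick_s)
            path[k:] = np.asarray(target.center)
        return path


def make_responder(p: ParticipantProfile, game: str, play_index: int,
                   rng: np.random.Generator,
                   cfg: Optional[SimConfig] = None,
                   mood: Optional[float] = None) -> SimulatedGameResponder:
    """Build the participant's responder for one play of one game.

    Expected performance follows the saturating learning curve
    ``asymptote - depth * exp(-rate * (play_index - 1))`` on the latent
    skill scale, with gender and age shifts applied per the configured
    effect sizes and optional mood coupling.
    """
    if play_index < 1:
        raise ValueError("play_index must be >= 1")
    cfg = cfg or SimConfig(seed=0)
    skill = cfg.ability_sd * p.latent_ability[game]
    d = cfg.gender_effects.get(game, 0.0)
    if p.gender == "male":
        skill += d / 2.0
    elif p.gender == "female":
        skill -= d / 2.0
    skill += cfg.age_effects.get(game, 0.0) * (p.true_age - 35) / 10.0
    skill -= practice_gap(cfg, game, play_index)
    if mood is not None and cfg.mood_performance_coupling:
        skill += cfg.mood_performance_coupling * (mood - 5.5) / 2.25
    skill += cfg.session_noise_sd * rng.standard_normal()
    return SimulatedGameResponder(game, skill)


class _SessionResponder(Responder):
    """Dispatches one session's game plays to per-game responders."""

    def __init__(self, per_game: dict, cfg: SimConfig, mood: Optional[float],
                 wake: Optional[str], sleep: Optional[float]):
        self.per_game = per_game
        self.cfg = cfg
        self._mood = mood
        self._wake = wake
        self._sleep = sleep

    def react_response(self, *a):
        return self.per_game["react"].react_response(*a)

    def supersnap_response(self, *a):
        return self.per_game["supersnap"].supersnap_response(*a)

    def spin_response(self, *a):
        return self.per_game["spin"].spin_response(*a)

    def track_response(self, state, rng):
        return self.per_game["track"].track_response(state, rng)

    def hotspot_path(self, target, n_ticks, tick_s, rng):
        return self.per_game["hotspot"].hotspot_path(target, n_ticks,
                                                     tick_s, rng)

    def wants_to_play(self, game, rng):
        return bool(rng.random() >= self.cfg.skip_prob)

    def mood(self, rng):
        return self._mood

    def wake_time(self, rng):
        return self._wake

    def sleep_hours(self, rng):
        return self._sleep


def _session_timestamps(n: int, meq_total: int, cfg: SimConfig,
                        rng: np.random.Generator) -> list[_dt.datetime]:
    """Session datetimes: recruitment day, geometric gaps, chronotype-shifted
    time of day (morning types play earlier)."""
    start = _dt.date.fromisoformat(cfg.start_date)
    day = int(rng.integers(cfg.recruitment_days))
    out = []
    peak_hour = float(np.clip(19.0 - 0.45 * (meq_total - 13), 7.0, 23.0))
    for _ in range(n):
        hour = float(np.clip(rng.normal(peak_hour, 2.5), 0.0, 23.983))
        h = int(hour)
        m = int((hour - h) * 60)
        out.append(_dt.datetime.combine(start + _dt.timedelta(days=day),
                                        _dt.time(h, m),
                                        tzinfo=_dt.timezone.utc))
        day += 1 + int(rng.geometric(1.0 / cfg.mean_gap_days) - 1)
    return out


def simulate_dataset(cfg: SimConfig,
                     engine_cfg: EngineConfig = DEFAULT_CONFIG
                     ) -> list[SessionRecord]:
    """Simulate the full cohort's longitudinal session records.

    For each participant: a session count from the attrition model, then
    each session executed through :func:`cogbattery.engines.run_session`
    with per-game responders at the participant's current practice level.
    Bit-reproducible from ``cfg.seed``.
    """
    cfg.validate()
    ss = np.random.SeedSequence(cfg.seed)
    cohort_rng = np.random.default_rng(ss.spawn(1)[0])
    profiles = sample_cohort(cfg, cohort_rng)
    records: list[SessionRecord] = []
    child_seeds = ss.spawn(len(profiles))
    for p, child in zip(profiles, child_seeds):
        rng = np.random.default_rng(child)
        n_sessions = sample_session_count(p, cfg, rng)
        stamps = _session_timestamps(n_sessions, p.meq_total, cfg, rng)
        play_index = {g: 0 for g in cfg.games}
        mood_state = p.mood_baseline
        prev_date = None
        for si in range(1, n_sessions + 1):
            mood_state = (p.mood_baseline
                          + cfg.mood_ar * (mood_state - p.mood_baseline)
                          + cfg.mood_noise_sd * rng.standard_normal())
            mood_state = float(np.clip(mood_state, 1.0, 10.0))
            mood = None if rng.random() < cfg.p_mood_skip else round(
                mood_state, 2)
            ts = stamps[si - 1]
            first_of_day = prev_date != ts.date()
            prev_date = ts.date()
            wake = sleep = None
            if first_of_day and rng.random() > 0.1:
                wake_h = float(np.clip(
                    rng.normal(7.5 - 0.12 * (p.meq_total - 13), 1.0),
                    4.0, 12.0))
                wake = f"{int(wake_h):02d}:{int((wake_h % 1) * 60):02d}"
                sleep = round(float(np.clip(rng.normal(7.5, 1.0), 3.0, 12.0)),
                              1)
            per_game = {
                g: make_responder(p, g, play_index[g] + 1, rng, cfg,
                                  mood=mood)
                for g in cfg.games
            }
            responder = _SessionResponder(per_game, cfg, mood, wake, sleep)
            rec = run_session(
                responder, cfg.games, rng, engine_cfg,
                participant_id=p.id, session_index=si,
                timestamp=ts.isoformat(), first_of_day=first_of_day,
                age=p.age if si == 1 else None,
                gender=p.gender if si == 1 else None,
                meq_total=p.meq_total if si == 1 else None,
            )
            for g in {gs.game for gs in rec.games}:
                play_index[g] += 1
            records.append(rec)
    return records
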