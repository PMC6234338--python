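"""Headless, tick-based execution and scoring of the five games.

Each engine is a pure function of a responder and a seeded random generator:
replaying with the same responder and seed reproduces the run bit-for-bit.
Responders implement the :class:`Responder` protocol; simulated participants
live in :mod:`cogbattery.cohort_sim`, scripted ones (oracle, passive) below.

Scoring rules
-------------
* **react** (4-choice vigilance): 8 trials; a uniformly chosen button turns
  "go" after a uniform 2-7 s foreperiod; a correct tap within the 600 ms
  response window scores ``S_trial * (1 - (latency - 100)/500)`` after the
  100 ms grace period (full points at or below 100 ms); premature taps,
  wrong buttons and timeouts score 0. ``S_trial`` defaults to 62.5 so a
  perfect session scores 500.
* **supersnap** (2-back): the session starts at 60 points and loses 6 per
  miss or false alarm (floored at 0); it ends when 10 matches have been
  presented or 10 responses made, whichever is first.
* **spin** (mental rotation): all 18 patterns in random order without
  replacement; 45 s to answer as many as possible; score is 2.5 per correct
  judgment (``n_correct`` is always reported alongside).
* **track** (multiple object tracking): six trials at set sizes 8,8,9,9,11,11
  with 3 targets each; 2.5 points per correctly tapped target, maximum 45.
* **hotspot** (action acquisition): 5 attempts; half the attempt maximum for
  discovering the hidden target, the rest decaying linearly with the time
  taken to keep the ball in the target for a cumulative 500 ms within a 1 s
  sliding window; the feedback signal lags the true in-target state by 100 ms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .records import GAMES, GameScore, ResponderEvent, SessionRecord
from .stimuli import (
    HotspotTarget,
    SpinTrial,
    TrackState,
    generate_shape_stream,
    init_track_array,
    load_pattern_set,
    make_spin_trial,
    place_hotspot_target,
    sample_react_interval,
    SHAPES,
)

__all__ = [
    "EngineConfig",
    "Responder",
    "OracleResponder",
    "PassiveResponder",
    "score_react_trial",
    "run_react_session",
    "run_supersnap_session",
    "run_spin_session",
    "step_track_physics",
    "run_track_session",
    "run_hotspot_attempt",
    "run_hotspot_session",
    "run_session",
    "HotspotAttempt",
]


@dataclass(frozen=True)
class EngineConfig:
    """All engine constants in one place.

    Score scales not fixed by the published rules (``react_s_trial``,
    ``spin_points_per_correct``, ``hotspot_a_max``, ``hotspot_t_limit``) are
    package defaults chosen to make plausible cohort means feasible; they are
    configurable and documented in the methods note.
    """

    # react
    react_n_trials: int = 8
    react_s_trial: float = 62.5
    react_grace_ms: float = 100.0
    react_window_ms: float = 600.0
    # supersnap
    snap_start_score: int = 60
    snap_penalty: int = 6
    snap_max_matches: int = 10
    snap_max_responses: int = 10
    snap_exposure_s: float = 1.5
    snap_isi_s: float = 1.5
    # spin
    spin_time_limit_s: float = 45.0
    spin_points_per_correct: float = 2.5
    # track
    track_set_sizes: tuple[int, ...] = (8, 8, 9, 9, 11, 11)
    track_points_per_ball: float = 2.5
    track_preview_s: float = 3.0
    track_motion_s: float = 5.0
    track_tick_hz: float = 60.0
    track_radius: float = 0.035
    track_base_speed: float = 0.25
    track_speed_jitter: tuple[float, float] = (0.9, 1.1)
    track_heading_jitter_deg: float = 10.0
    track_speed_clamp: tuple[float, float] = (0.1, 0.4)
    # hotspot
    hotspot_attempts: int = 5
    hotspot_a_max: float = 10.0
    hotspot_t_limit_s: float = 15.0
    hotspot_tick_hz: float = 60.0
    hotspot_dwell_s: float = 0.5
    hotspot_window_s: float = 1.0
    hotspot_feedback_delay_s: float = 0.1


DEFAULT_CONFIG = EngineConfig()


class Responder:
    """Protocol for anything that can play the battery.

    Engines call exactly one method per trial; every method receives the rng
    so that responder noise shares the session's seeded stream.
    """

    def react_response(self, trial_index: int, interval_s: float,
                       correct_button: int,
                       rng: np.random.Generator) -> ResponderEvent:
        raise NotImplementedError

    def supersnap_response(self, position: int, shape: str, is_match: bool,
                           rng: np.random.Generator) -> bool:
        """Return True to tap (``is_match`` is ground truth, for oracles)."""
        raise NotImplementedError

    def spin_response(self, trial: SpinTrial,
                      rng: np.random.Generator) -> tuple[int, float]:
        """Return (chosen option index, latency in ms)."""
        raise NotImplementedError

    def track_response(self, state: TrackState,
                       rng: np.random.Generator) -> Sequence[int]:
        """Return up to 3 tapped ball indices after the motion phase."""
        raise NotImplementedError

    def hotspot_path(self, target: HotspotTarget, n_ticks: int, tick_s: float,
                     rng: np.random.Generator) -> np.ndarray:
        """Return an (n_ticks, 2) ball trajectory sampled at the tick rate."""
        raise NotImplementedError

    def wants_to_play(self, game: str, rng: np.random.Generator) -> bool:
        return True

    def mood(self, rng: np.random.Generator) -> Optional[float]:
        return None

    def wake_time(self, rng: np.random.Generator) -> Optional[str]:
        return None

    def sleep_hours(self, rng: np.random.Generator) -> Optional[float]:
        return None


class OracleResponder(Responder):
    """Plays every game perfectly and instantaneously (upper-bound scores)."""

    def react_response(self, trial_index, interval_s, correct_button, rng):
        return ResponderEvent("tap", latency_ms=0.0,
                              payload={"button": correct_button,
                                       "premature": False})

    def supersnap_response(self, position, shape, is_match, rng):
        return is_match

    def spin_response(self, trial, rng):
        return trial.correct_index, 0.0

    def track_response(self, state, rng):
        return list(state.target_ids)

    def hotspot_path(self, target, n_ticks, tick_s, rng):
        return np.tile(np.asarray(target.center), (n_ticks, 1))


class PassiveResponder(Responder):
    """Never responds: lower-bound scores for every game."""

    def react_response(self, trial_index, interval_s, correct_button, rng):
        return ResponderEvent("no_response")

    def supersnap_response(self, position, shape, is_match, rng):
        return False

    def spin_response(self, trial, rng):
        # picks a fixed wrong option with a latency that never fills 45 s
        wrong = 0 if trial.correct_index != 0 else 1
        return wrong, 2500.0

    def track_response(self, state, rng):
        return []

    def hotspot_path(self, target, n_ticks, tick_s, rng):
        # parks in the corner furthest from the target, never entering it
        corner = np.array([0.0 if target.center[0] > 0.5 else 1.0,
                           0.0 if target.center[1] > 0.5 else 1.0])
        return np.tile(corner, (n_ticks, 1))


# ---------------------------------------------------------------------------
# react
# ---------------------------------------------------------------------------

def score_react_trial(
    latency_ms: Optional[float],
    chosen_button: Optional[int],
    correct_button: int,
    premature: bool,
    cfg: EngineConfig = DEFAULT_CONFIG,
) -> float:
    """Score one vigilance trial.

    Premature responses, wrong buttons, timeouts and non-responses score 0;
    a correct response at or under the 100 ms grace period scores the trial
    maximum, decaying linearly to 0 at the 600 ms window edge.
    """
    if premature or chosen_button is None or latency_ms is None:
        return 0.0
    if chosen_button != correct_button:
        return 0.0
    if latency_ms > cfg.react_window_ms:
        return 0.0
    if latency_ms <= cfg.react_grace_ms:
        return cfg.react_s_trial
    frac = (latency_ms - cfg.react_grace_ms) / (
        cfg.react_window_ms - cfg.react_grace_ms
    )
    return cfg.react_s_trial * (1.0 - frac)


def run_react_session(
    responder: Responder,
    rng: np.random.Generator,
    cfg: EngineConfig = DEFAULT_CONFIG,
) -> GameScore:
    """Run the 8-trial 4-choice vigilance session."""
    detail = []
    total = 0.0
    n_correct = 0
    for i in range(cfg.react_n_trials):
        interval = sample_react_interval(rng)
        correct = int(rng.integers(4))
        ev = responder.react_response(i, interval, correct, rng)
        if ev.kind == "no_response":
            chosen, latency, premature = None, None, False
        elif ev.kind == "tap":
            chosen = int(ev.payload["button"])
            premature = bool(ev.payload.get("premature", False))
            latency = float(ev.latency_ms)
        else:
            raise ValueError(f"unexpected event kind {ev.kind!r} in react")
        pts = score_react_trial(latency, chosen, correct, premature, cfg)
        correct_hit = pts > 0 or (
            chosen == correct and not premature
            and latency is not None and latency <= cfg.react_window_ms
        )
        n_correct += bool(correct_hit)
        total += pts
        detail.append({
            "trial": i, "interval_s": interval, "correct_button": correct,
            "chosen_button": chosen, "latency_ms": latency,
            "premature": premature, "points": pts,
        })
    return GameScore(game="react", score=total, n_correct=n_correct,
                     trial_detail=detail)


# ---------------------------------------------------------------------------
# supersnap
# ---------------------------------------------------------------------------

def run_supersnap_session(
    responder: Responder,
    rng: np.random.Generator,
    cfg: EngineConfig = DEFAULT_CONFIG,
) -> GameScore:
    """Run one 2-back session over an i.i.d. uniform shape stream.

    Shapes are drawn one at a time (1.5 s exposure / 1.5 s ISI recorded as
    metadata); the session ends once 10 matches have been presented or 10
    responses made, whichever comes first.
    """
    shapes: list[str] = []
    detail = []
    matches_presented = 0
    responses_made = 0
    hits = misses = false_alarms = 0
    position = 0
    while True:
        shape = SHAPES[int(rng.integers(len(SHAPES)))]
        is_match = position >= 2 and shapes[position - 2] == shape
        shapes.append(shape)
        tapped = bool(responder.supersnap_response(position, shape, is_match, rng))
        if tapped:
            responses_made += 1
            if is_match:
                hits += 1
            else:
                false_alarms += 1
        elif is_match:
            misses += 1
        if is_match:
            matches_presented += 1
        detail.append({
            "position": position, "shape": shape, "is_match": is_match,
            "tapped": tapped, "onset_s": position * (cfg.snap_exposure_s
                                                     + cfg.snap_isi_s),
        })
        position += 1
        if matches_presented >= cfg.snap_max_matches:
            break
        if responses_made >= cfg.snap_max_responses:
            break
    score = max(0, cfg.snap_start_score - cfg.snap_penalty
                * (false_alarms + misses))
    return GameScore(game="supersnap", score=float(score), n_correct=hits,
                     trial_detail=detail)


# ---------------------------------------------------------------------------
# spin
# ---------------------------------------------------------------------------

_PATTERNS = None


def _patterns():
    global _PATTERNS
    if _PATTERNS is None:
        _PATTERNS = load_pattern_set()
    return _PATTERNS


def run_spin_session(
    responder: Responder,
    rng: np.random.Generator,
    cfg: EngineConfig = DEFAULT_CONFIG,
) -> GameScore:
    """Run one 45 s mental-rotation session.

    All 18 patterns are shuffled and presented without replacement; a trial
    counts if its response completes within the time limit.
    """
    patterns = _patterns()
    order = rng.permutation(len(patterns))
    t = 0.0
    n_correct = 0
    detail = []
    for idx in order:
        if t >= cfg.spin_time_limit_s:
            break
        trial = make_spin_trial(patterns[int(idx)], rng)
        choice, latency_ms = responder.spin_response(trial, rng)
        end_t = t + latency_ms / 1000.0
        if end_t > cfg.spin_time_limit_s + 1e-9:
            break  # time ran out mid-trial; response not recorded
        correct = int(choice) == trial.correct_index
        n_correct += correct
        detail.append({
            "pattern_code": patterns[int(idx)].code,
            "rotation_deg": trial.rotation_deg, "choice": int(choice),
            "correct": correct, "latency_ms": float(latency_ms),
            "t_start_s": t,
        })
        t = end_t
    return GameScore(game="spin",
                     score=cfg.spin_points_per_correct * n_correct,
                     n_correct=n_correct, trial_detail=detail)


# ---------------------------------------------------------------------------
# track
# ---------------------------------------------------------------------------

_TRIU: dict[int, tuple[np.ndarray, np.ndarray]] = {}


def _triu_cache(n: int) -> tuple[np.ndarray, np.ndarray]:
    if n not in _TRIU:
        _TRIU[n] = np.triu_indices(n, k=1)
    return _TRIU[n]


def step_track_physics(
    state: TrackState,
    dt: float,
    rng: np.random.Generator,
    cfg: EngineConfig = DEFAULT_CONFIG,
) -> TrackState:
    """Advance the ball array by ``dt`` with per-frame random jitter.

    Speed is multiplied by a uniform factor and the heading perturbed by a
    uniform angle each frame; ball-ball and ball-wall collisions are resolved
    by reflection plus positional correction so the non-overlap and
    in-bounds invariants hold exactly after every step.
    """
    n = state.n_balls
    r = state.radius
    pos = state.positions.copy()
    vel = state.velocities.copy()
    # random per-frame speed/heading adjustment
    speed = np.hypot(vel[:, 0], vel[:, 1])
    heading = np.arctan2(vel[:, 1], vel[:, 0])
    speed = np.clip(speed * rng.uniform(*cfg.track_speed_jitter, size=n),
                    *cfg.track_speed_clamp)
    jitter = math.radians(cfg.track_heading_jitter_deg)
    heading = heading + rng.uniform(-jitter, jitter, size=n)
    vel = np.column_stack([speed * np.cos(heading), speed * np.sin(heading)])
    pos = pos + vel * dt

    iu, ju = _triu_cache(n)
    min_d2 = (2 * r) ** 2
    for _ in range(100):
        dirty = False
        # walls: reflect position and velocity
        low = pos < r
        high = pos > 1.0 - r
        if low.any():
            pos[low] = 2 * r - pos[low]
            vel[low] = np.abs(vel[low])
            dirty = True
        if high.any():
            pos[high] = 2 * (1.0 - r) - pos[high]
            vel[high] = -np.abs(vel[high])
            dirty = True
        # ball-ball: symmetric separation plus elastic swap of normal speed
        diff = pos[iu] - pos[ju]
        d2 = diff[:, 0] ** 2 + diff[:, 1] ** 2
        hits = np.nonzero(d2 < min_d2)[0]
        if hits.size:
            dirty = True
            for h in hits:
                i, j = int(iu[h]), int(ju[h])
                delta = pos[i] - pos[j]
                d = math.hypot(delta[0], delta[1])
                normal = (delta / d if d > 1e-12 else np.array([1.0, 0.0]))
                push = (2 * r - d) / 2 + 1e-9
                pos[i] += push * normal
                pos[j] -= push * normal
                vn = float((vel[i] - vel[j]) @ normal)
                if vn < 0:  # approaching: exchange normal components
                    vel[i] -= vn * normal
                    vel[j] += vn * normal
        if not dirty:
            break
    np.clip(pos, r, 1.0 - r, out=pos)
    return TrackState(positions=pos, velocities=vel, radius=r,
                      target_ids=state.target_ids, t=state.t + dt)


def run_track_session(
    responder: Responder,
    rng: np.random.Generator,
    cfg: EngineConfig = DEFAULT_CONFIG,
) -> GameScore:
    """Run six tracking trials (set sizes 8,8,9,9,11,11, increasing order)."""
    total = 0.0
    n_correct = 0
    detail = []
    dt = 1.0 / cfg.track_tick_hz
    n_steps = int(round(cfg.track_motion_s * cfg.track_tick_hz))
    for trial_i, set_size in enumerate(cfg.track_set_sizes):
        state = init_track_array(set_size, rng, radius=cfg.track_radius,
                                 base_speed=cfg.track_base_speed)
        # 3 s static preview with targets highlighted, then 5 s of motion
        for _ in range(n_steps):
            state = step_track_physics(state, dt, rng, cfg)
        taps = list(dict.fromkeys(int(t) for t in responder.track_response(state, rng)))
        if len(taps) > 3:
            raise ValueError("at most 3 taps per tracking trial")
        if any(not 0 <= t < set_size for t in taps):
            raise ValueError("tap index out of range")
        hit = len(set(taps) & set(state.target_ids))
        pts = cfg.track_points_per_ball * hit
        total += pts
        n_correct += hit
        detail.append({"trial": trial_i, "set_size": set_size,
                       "targets": list(state.target_ids), "taps": taps,
                       "n_hit": hit, "points": pts})
    return GameScore(game="track", score=total, n_correct=n_correct,
                     trial_detail=detail)


# ---------------------------------------------------------------------------
# hotspot
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HotspotAttempt:
    """Outcome of one action-acquisition attempt.

    ``feedback`` is the delayed in-target signal shown to the player: the
    true in-target indicator shifted by the 100 ms feedback delay.
    """

    found: bool
    success: bool
    points: float
    t_found_s: Optional[float]
    t_success_s: Optional[float]
    in_target: np.ndarray = field(repr=False, default=None)
    feedback: np.ndarray = field(repr=False, default=None)

    def __iter__(self):
        return iter((self.found, self.points))


def run_hotspot_attempt(
    responder: Responder,
    target: HotspotTarget,
    rng: np.random.Generator,
    cfg: EngineConfig = DEFAULT_CONFIG,
) -> HotspotAttempt:
    """Score one attempt from a tick-sampled ball trajectory.

    Success requires a cumulative 500 ms in-target within some sliding 1 s
    window. Half the attempt maximum is awarded for discovery (any target
    entry); the other half decays linearly with the success time over the
    attempt limit.
    """
    tick = 1.0 / cfg.hotspot_tick_hz
    n_ticks = int(round(cfg.hotspot_t_limit_s * cfg.hotspot_tick_hz))
    path = np.asarray(responder.hotspot_path(target, n_ticks, tick, rng),
                      dtype=float)
    if path.shape != (n_ticks, 2):
        raise ValueError(f"trajectory must have shape {(n_ticks, 2)}")
    in_target = target.contains(path)
    delay_ticks = int(round(cfg.hotspot_feedback_delay_s * cfg.hotspot_tick_hz))
    feedback = np.zeros_like(in_target)
    if delay_ticks < n_ticks:
        feedback[delay_ticks:] = in_target[: n_ticks - delay_ticks]

    found = bool(in_target.any())
    t_found = float(np.argmax(in_target) * tick) if found else None

    window = int(round(cfg.hotspot_window_s * cfg.hotspot_tick_hz))
    need = int(round(cfg.hotspot_dwell_s * cfg.hotspot_tick_hz))
    csum = np.concatenate([[0], np.cumsum(in_target)])
    starts = np.maximum(0, np.arange(1, n_ticks + 1) - window)
    in_window = csum[1:] - csum[starts]
    success_ticks = np.nonzero(in_window >= need)[0]
    success = success_ticks.size > 0
    t_success = float((success_ticks[0] + 1) * tick) if success else None

    points = 0.0
    if found:
        points += 0.5 * cfg.hotspot_a_max
    if success:
        points += 0.5 * cfg.hotspot_a_max * (1.0 - t_success
                                             / cfg.hotspot_t_limit_s)
    if not found:
        points = 0.0
    return HotspotAttempt(found=found, success=success, points=points,
                          t_found_s=t_found, t_success_s=t_success,
                          in_target=in_target, feedback=feedback)


def run_hotspot_session(
    responder: Responder,
    rng: np.random.Generator,
    cfg: EngineConfig = DEFAULT_CONFIG,
) -> GameScore:
    """Run 5 attempts, each with a freshly placed random target."""
    total = 0.0
    n_success = 0
    detail = []
    for i in range(cfg.hotspot_attempts):
        target = place_hotspot_target(rng)
        attempt = run_hotspot_attempt(responder, target, rng, cfg)
        total += attempt.points
        n_success += attempt.success
        detail.append({
            "attempt": i, "center": list(target.center),
            "found": attempt.found, "success": attempt.success,
            "t_success_s": attempt.t_success_s, "points": attempt.points,
        })
    return GameScore(game="hotspot", score=total, n_correct=n_success,
                     trial_detail=detail)


# ---------------------------------------------------------------------------
# session
# ---------------------------------------------------------------------------

_RUNNERS = {
    "hotspot": run_hotspot_session,
    "react": run_react_session,
    "spin": run_spin_session,
    "supersnap": run_supersnap_session,
    "track": run_track_session,
}


def run_session(
    responder: Responder,
    games_to_play: Sequence[str],
    rng: np.random.Generator,
    cfg: EngineConfig = DEFAULT_CONFIG,
    *,
    participant_id: str = "anonymous",
    session_index: int = 1,
    timestamp: str = "1970-01-01T00:00:00+00:00",
    first_of_day: bool = True,
    age: Optional[int] = None,
    gender: Optional[str] = None,
    meq_total: Optional[int] = None,
) -> SessionRecord:
    """Run one full app session: mood item, then the games in random order.

    ``games_to_play`` must be a subset of the five games; the presentation
    order is shuffled from ``rng`` and the responder may still decline
    (skip) any game. Wake-time and sleep questions are asked only on the
    first session of a calendar day; demographics are echoed only when
    provided (conventionally on session 1).
    """
    games_to_play = list(games_to_play)
    unknown = set(games_to_play) - set(GAMES)
    if unknown:
        raise ValueError(f"unknown games: {sorted(unknown)}")
    if len(set(games_to_play)) != len(games_to_play):
        raise ValueError("duplicate games in games_to_play")

    mood = responder.mood(rng)
    wake = responder.wake_time(rng) if first_of_day else None
    sleep = responder.sleep_hours(rng) if first_of_day else None

    ordered = [games_to_play[int(i)]
               for i in rng.permutation(len(games_to_play))]
    scores = []
    for game in ordered:
        if not responder.wants_to_play(game, rng):
            continue
        scores.append(_RUNNERS[game](responder, rng, cfg))
    return SessionRecord(
        participant_id=participant_id, session_index=session_index,
        timestamp=timestamp, mood=mood, wake_time=wake, sleep_hours=sleep,
        age=age, gender=gender, meq_total=meq_total, games=scores,
    )
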