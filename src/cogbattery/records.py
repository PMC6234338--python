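"""Shared record types: per-game scores, responder events, session records."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Any, Optional

GAMES = ("hotspot", "react", "spin", "supersnap", "track")


@dataclass
class ResponderEvent:
    """A single responder action inside a game trial.

    ``kind`` is one of ``tap``, ``tilt``, ``option_choice``, ``no_response``;
    ``latency_ms`` is measured from stimulus onset and must be non-negative;
    ``payload`` carries the game-specific content (button index, option
    index, tap coordinate, ...).
    """

    kind: str
    latency_ms: float = 0.0
    payload: Any = None

    def __post_init__(self) -> None:
        if self.kind not in ("tap", "tilt", "option_choice", "no_response"):
            raise ValueError(f"unknown event kind {self.kind!r}")
        if self.latency_ms < 0:
            raise ValueError("latency_ms must be non-negative")


@dataclass
class GameScore:
    """Score summary for one play of one game within a session."""

    game: str
    score: float
    n_correct: int
    trial_detail: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.game not in GAMES:
            raise ValueError(f"unknown game {self.game!r}")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "GameScore":
        return cls(
            game=d["game"],
            score=float(d["score"]),
            n_correct=int(d["n_correct"]),
            trial_detail=list(d.get("trial_detail", [])),
        )


@dataclass
class SessionRecord:
    """One participant-session: metadata, mood, and played-game scores.

    ``games`` lists the games actually played, in play order (skipped games
    are simply absent). ``wake_time`` (``HH:MM``) and ``sleep_hours`` are
    present only when the session was the first on its calendar day and the
    participant answered. Demographics (``age``, ``gender``, ``meq_total``)
    are echoed on the first session and may be absent (declined).
    """

    participant_id: str
    session_index: int
    timestamp: str
    mood: Optional[float] = None
    wake_time: Optional[str] = None
    sleep_hours: Optional[float] = None
    age: Optional[int] = None
    gender: Optional[str] = None
    meq_total: Optional[int] = None
    games: list[GameScore] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.session_index < 1:
            raise ValueError("session_index must be >= 1")
        if self.gender is not None and self.gender not in ("male", "female"):
            raise ValueError(f"gender must be 'male'/'female'/None, got {self.gender!r}")
        if self.mood is not None and not 1.0 <= self.mood <= 10.0:
            raise ValueError("mood must lie in [1, 10]")
        names = [g.game for g in self.games]
        if len(names) != len(set(names)):
            raise ValueError("duplicate game within session")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["games"] = [g.to_dict() for g in self.games]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SessionRecord":
        return cls(
            participant_id=str(d["participant_id"]),
            session_index=int(d["session_index"]),
            timestamp=str(d["timestamp"]),
            mood=None if d.get("mood") is None else float(d["mood"]),
            wake_time=d.get("wake_time"),
            sleep_hours=(
                None if d.get("sleep_hours") is None else float(d["sleep_hours"])
            ),
            age=None if d.get("age") is None else int(d["age"]),
            gender=d.get("gender"),
            meq_total=None if d.get("meq_total") is None else int(d["meq_total"]),
            games=[GameScore.from_dict(g) for g in d.get("games", [])],
        )
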