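"""Session-record serialization: JSONL (canonical) and flattened CSV.

JSONL schema v1: the first line is a header object
``{"format": "cogbattery-sessions", "version": 1}``; every following line
is one :class:`~cogbattery.records.SessionRecord` as JSON. The CSV export
is one row per participant-session-game (session-level fields repeated,
``trial_detail`` JSON-encoded in its column) so both formats round-trip to
identical in-memory datasets.

Readers validate and reject malformed input with the offending line number
rather than silently coercing.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import pandas as pd

from .records import GameScore, SessionRecord

__all__ = ["SCHEMA_NAME", "SCHEMA_VERSION", "RecordFormatError",
           "write_records", "read_records",
           "write_records_csv", "read_records_csv"]

SCHEMA_NAME = "cogbattery-sessions"
SCHEMA_VERSION = 1

_SESSION_FIELDS = ["participant_id", "session_index", "timestamp", "mood",
                   "wake_time", "sleep_hours", "age", "gender", "meq_total"]
_CSV_COLUMNS = _SESSION_FIELDS + ["n_games_in_session", "game_order",
                                  "game", "score", "n_correct",
                                  "trial_detail"]


class RecordFormatError(ValueError):
    """A schema violation, carrying the 1-based line (or row) number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        where = f" (line {line})" if line is not None else ""
        super().__init__(message + where)


def write_records(records: Sequence[SessionRecord], path) -> None:
    """Write records as schema-versioned JSONL (header line first)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(json.dumps({"format": SCHEMA_NAME,
                             "version": SCHEMA_VERSION}) + "\n")
        for rec in records:
            fh.write(json.dumps(rec.to_dict()) + "\n")


def read_records(path) -> list[SessionRecord]:
    """Read and validate a JSONL record file."""
    path = Path(path)
    records = []
    with path.open() as fh:
        header_line = fh.readline()
        if not header_line:
            raise RecordFormatError("empty file: missing header", line=1)
        try:
            header = json.loads(header_line)
        except json.JSONDecodeError as e:
            raise RecordFormatError(f"invalid header: {e}", line=1) from e
        if not isinstance(header, dict) or header.get("format") != SCHEMA_NAME:
            raise RecordFormatError("not a session-record file", line=1)
        if header.get("version") != SCHEMA_VERSION:
            raise RecordFormatError(
                f"unknown schema version {header.get('version')!r}", line=1)
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            try:
                records.append(SessionRecord.from_dict(json.loads(line)))
            except (json.JSONDecodeError, KeyError, TypeError,
                    ValueError) as e:
                raise RecordFormatError(f"malformed record: {e}",
                                        line=lineno) from e
    return records


def write_records_csv(records: Sequence[SessionRecord], path) -> None:
    """Write the flattened one-row-per-participant-session-game CSV.

    Sessions with no games played still contribute one row with an empty
    ``game`` column so the round trip is lossless.
    """
    rows = []
    for rec in records:
        base = {f: getattr(rec, f) for f in _SESSION_FIELDS}
        base["n_games_in_session"] = len(rec.games)
        if rec.games:
            for order, gs in enumerate(rec.games):
                rows.append({**base, "game_order": order, "game": gs.game,
                             "score": gs.score, "n_correct": gs.n_correct,
                             "trial_detail": json.dumps(gs.trial_detail)})
        else:
            rows.append({**base, "game_order": None, "game": None,
                         "score": None, "n_correct": None,
                         "trial_detail": None})
    pd.DataFrame(rows, columns=_CSV_COLUMNS).to_csv(path, index=False)


def read_records_csv(path) -> list[SessionRecord]:
    """Read the flattened CSV back into session records."""
    df = pd.read_csv(path, dtype=object)
    missing = set(_CSV_COLUMNS) - set(df.columns)
    if missing:
        raise RecordFormatError(f"missing columns: {sorted(missing)}")
    sessions: dict[tuple, dict] = {}
    order: list[tuple] = []
    for i, row in df.iterrows():
        lineno = i + 2  # header is line 1
        try:
            key = (str(row["participant_id"]), int(row["session_index"]))
            if key not in sessions:
                order.append(key)
                sessions[key] = {
                    "participant_id": key[0], "session_index": key[1],
                    "timestamp": str(row["timestamp"]),
                    "mood": _opt_float(row["mood"]),
                    "wake_time": _opt_str(row["wake_time"]),
                    "sleep_hours": _opt_float(row["sleep_hours"]),
                    "age": _opt_int(row["age"]),
                    "gender": _opt_str(row["gender"]),
                    "meq_total": _opt_int(row["meq_total"]),
                    "games": [],
                }
            if not pd.isna(row["game"]):
                sessions[key]["games"].append((
                    int(row["game_order"]),
                    GameScore(game=str(row["game"]),
                              score=float(row["score"]),
                              n_correct=int(row["n_correct"]),
                              trial_detail=json.loads(row["trial_detail"]))))
        except (TypeError, ValueError, KeyError,
                json.JSONDecodeError) as e:
            raise RecordFormatError(f"malformed row: {e}",
                                    line=lineno) from e
    records = []
    for key in order:
        d = sessions[key]
        games = [g for _, g in sorted(d.pop("games"), key=lambda t: t[0])]
        records.append(SessionRecord(**d, games=games))
    return records


def _opt_float(v):
    return None if pd.isna(v) else float(v)


def _opt_int(v):
    return None if pd.isna(v) else int(float(v))


def _opt_str(v):
    return None if pd.isna(v) else str(v)
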