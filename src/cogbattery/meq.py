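"""Reduced Morningness-Eveningness questionnaire (rMEQ) scoring.

The 5-item reduced scale totals 4-25 and maps onto five chronotype classes,
from definitely evening (4-7) through neither (12-17) to definitely morning
(22-25). Item wording and per-item admissible scores live in a packaged JSON
config (``data/rmeq.json``) so an alternative key can be swapped in without
code changes; all downstream analysis depends only on the total and class.

Also hosts the session mood item: a visual-analog slider in [0, 1] mapped
affinely onto the 1-10 mood scale (10 = happiest).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from typing import Optional, Sequence

__all__ = [
    "MeqKey",
    "MeqResponse",
    "ChronotypeClass",
    "CLASS_LABELS",
    "load_key",
    "score_meq",
    "classify_meq",
    "record_mood",
]

CLASS_LABELS = (
    "definitely evening",
    "moderately evening",
    "neither",
    "moderately morning",
    "definitely morning",
)


@dataclass(frozen=True)
class MeqKey:
    """Admissible per-item scores and class cutoffs for the reduced scale."""

    admissible: tuple[tuple[int, ...], ...]
    class_bins: tuple[tuple[str, int, int], ...]  # (label, min, max)

    @property
    def min_total(self) -> int:
        return sum(min(a) for a in self.admissible)

    @property
    def max_total(self) -> int:
        return sum(max(a) for a in self.admissible)


_KEY: Optional[MeqKey] = None


def load_key() -> MeqKey:
    """Load the packaged rMEQ scoring key."""
    global _KEY
    if _KEY is None:
        raw = resources.files("cogbattery.data").joinpath("rmeq.json").read_text()
        cfg = json.loads(raw)
        _KEY = MeqKey(
            admissible=tuple(tuple(item["admissible"]) for item in cfg["items"]),
            class_bins=tuple(
                (c["label"], int(c["min"]), int(c["max"])) for c in cfg["classes"]
            ),
        )
    return _KEY


@dataclass(frozen=True)
class MeqResponse:
    """One participant's five item scores."""

    item_scores: tuple[int, int, int, int, int]


@dataclass(frozen=True)
class ChronotypeClass:
    """A chronotype category determined solely by the questionnaire total."""

    label: str

    def __post_init__(self) -> None:
        if self.label not in CLASS_LABELS:
            raise ValueError(f"unknown chronotype label {self.label!r}")


def score_meq(response: MeqResponse | Sequence[int],
              key: Optional[MeqKey] = None) -> int:
    """Sum the five item scores after validating each against the key.

    Raises ``ValueError`` naming the offending item index (0-based) on a
    missing or out-of-range item score.
    """
    key = key or load_key()
    scores = (response.item_scores if isinstance(response, MeqResponse)
              else tuple(response))
    if len(scores) != len(key.admissible):
        raise ValueError(f"expected {len(key.admissible)} item scores, "
                         f"got {len(scores)}")
    for i, (s, adm) in enumerate(zip(scores, key.admissible)):
        if s is None or int(s) not in adm:
            raise ValueError(f"item {i}: score {s!r} not in admissible set {adm}")
    total = int(sum(scores))
    assert key.min_total <= total <= key.max_total
    return total


def classify_meq(total: int, key: Optional[MeqKey] = None) -> ChronotypeClass:
    """Map a questionnaire total onto one of the five chronotype classes."""
    key = key or load_key()
    if not key.min_total <= total <= key.max_total:
        raise ValueError(
            f"total {total} outside [{key.min_total}, {key.max_total}]")
    for label, lo, hi in key.class_bins:
        if lo <= total <= hi:
            return ChronotypeClass(label)
    raise ValueError(f"total {total} not covered by class bins")  # pragma: no cover


def record_mood(slider: Optional[float]) -> Optional[float]:
    """Map a VAS slider position in [0, 1] onto the 1-10 mood scale.

    A skipped item (``None``) is recorded as absent.
    """
    if slider is None:
        return None
    if not 0.0 <= slider <= 1.0:
        raise ValueError(f"slider position must lie in [0, 1], got {slider}")
    return 1.0 + 9.0 * float(slider)
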