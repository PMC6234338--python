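"""Stimulus generation for the five-game battery.

Covers the mental-rotation pattern set and trial construction, 2-back shape
streams, vigilance-task inter-stimulus intervals, action-acquisition target
placement, and initial arrays for the multiple-object-tracking task.

Conventions
-----------
* Grids are 3x3 booleans indexed ``(row, col)`` with row 0 at the top.
* Rotation angles are clockwise degrees (90/180/270).
* ``vertical`` reflection mirrors about the vertical axis (left-right swap);
  ``horizontal`` mirrors about the horizontal axis (top-bottom swap).
* The game arena is the unit square ``[0, 1] x [0, 1]``.
* All randomness is drawn from an explicitly passed ``numpy.random.Generator``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "SHAPES",
    "Pattern3x3",
    "SpinTrial",
    "ShapeStream",
    "HotspotTarget",
    "TrackState",
    "rotate_pattern",
    "reflect_pattern",
    "enumerate_pattern_set",
    "load_pattern_set",
    "make_spin_trial",
    "generate_shape_stream",
    "sample_react_interval",
    "place_hotspot_target",
    "init_track_array",
]

#: The six 2-back stimulus symbols, alphabetical.
SHAPES = ("circle", "hexagon", "rhombus", "square", "star", "triangle")

Cells = tuple[tuple[bool, bool, bool], ...]


def _count_groups(cells: Cells) -> int:
    """Number of 4-connected groups of filled cells."""
    seen: set[tuple[int, int]] = set()
    groups = 0
    for r in range(3):
        for c in range(3):
            if not cells[r][c] or (r, c) in seen:
                continue
            groups += 1
            stack = [(r, c)]
            while stack:
                rr, cc = stack.pop()
                if (rr, cc) in seen:
                    continue
                seen.add((rr, cc))
                for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                    nr, nc = rr + dr, cc + dc
                    if 0 <= nr < 3 and 0 <= nc < 3 and cells[nr][nc]:
                        stack.append((nr, nc))
    return groups


@dataclass(frozen=True)
class Pattern3x3:
    """A mental-rotation stimulus: a 3x3 grid of filled/unfilled cells.

    Valid stimulus patterns have 1-3 connected groups of filled cells and no
    rotational symmetry (the pattern differs from each of its own 90/180/270
    degree rotations), so that a rotated copy is always distinguishable from
    the original.
    """

    cells: Cells

    def __post_init__(self) -> None:
        if len(self.cells) != 3 or any(len(row) != 3 for row in self.cells):
            raise ValueError("cells must be a 3x3 grid")

    @classmethod
    def from_array(cls, a: np.ndarray | Sequence[Sequence[int]]) -> "Pattern3x3":
        arr = np.asarray(a, dtype=bool)
        return cls(tuple(tuple(bool(x) for x in row) for row in arr))

    @classmethod
    def from_code(cls, code: int) -> "Pattern3x3":
        """Decode a 9-bit integer, bit ``3*row + col`` giving cell (row, col)."""
        return cls(
            tuple(
                tuple(bool((code >> (3 * r + c)) & 1) for c in range(3))
                for r in range(3)
            )
        )

    @property
    def code(self) -> int:
        return sum(
            1 << (3 * r + c) for r in range(3) for c in range(3) if self.cells[r][c]
        )

    @property
    def n_filled(self) -> int:
        return sum(cell for row in self.cells for cell in row)

    @property
    def group_count(self) -> int:
        return _count_groups(self.cells)

    def as_array(self) -> np.ndarray:
        return np.array(self.cells, dtype=bool)

    def is_valid_stimulus(self) -> bool:
        """True if the pattern satisfies all stimulus-set invariants."""
        if not 1 <= self.n_filled <= 8:
            return False
        if self.group_count not in (1, 2, 3):
            return False
        return all(rotate_pattern(self, d) != self for d in (90, 180, 270))


def rotate_pattern(p: Pattern3x3, deg: int) -> Pattern3x3:
    """Rotate a pattern clockwise by a multiple of 90 degrees."""
    if deg % 90 != 0:
        raise ValueError(f"rotation must be a multiple of 90 degrees, got {deg}")
    k = (deg // 90) % 4
    # np.rot90 rotates counterclockwise; negate for clockwise.
    return Pattern3x3.from_array(np.rot90(p.as_array(), k=-k))


def reflect_pattern(p: Pattern3x3, axis: str) -> Pattern3x3:
    """Mirror a pattern about the vertical or horizontal axis."""
    if axis == "vertical":
        return Pattern3x3.from_array(np.fliplr(p.as_array()))
    if axis == "horizontal":
        return Pattern3x3.from_array(np.flipud(p.as_array()))
    raise ValueError(f"axis must be 'vertical' or 'horizontal', got {axis!r}")


def enumerate_pattern_set(n: int = 18) -> list[Pattern3x3]:
    """Deterministically enumerate the canonical stimulus set.

    Scans all 3x3 grids in ascending 9-bit code order and keeps the first
    ``n`` that (a) have 2-6 filled cells forming 1-3 connected groups,
    (b) have no rotational symmetry, (c) differ under both reflections from
    every rotated copy (so reflection foils can never equal the rotated
    target), and (d) are not a rotation of an already-selected pattern.
    """
    selected: list[Pattern3x3] = []
    rotation_codes: set[int] = set()
    for code in range(1, 512):
        p = Pattern3x3.from_code(code)
        if not 2 <= p.n_filled <= 6:
            continue
        if p.group_count not in (1, 2, 3):
            continue
        rots = [rotate_pattern(p, d) for d in (90, 180, 270)]
        if any(r == p for r in rots):
            continue
        refls = [reflect_pattern(p, ax) for ax in ("vertical", "horizontal")]
        if any(f == r for f in refls for r in rots):
            continue
        if p.code in rotation_codes:
            continue
        selected.append(p)
        rotation_codes.update(r.code for r in [p, *rots])
        if len(selected) == n:
            break
    if len(selected) < n:
        raise RuntimeError(f"only {len(selected)} admissible patterns found")
    return selected


def load_pattern_set() -> list[Pattern3x3]:
    """Load the packaged 18-pattern stimulus set and verify its integrity.

    The fixture is a JSON list of 9-bit grid codes produced by
    :func:`enumerate_pattern_set`; any deviation from the stimulus invariants
    raises ``ValueError``.
    """
    raw = resources.files("cogbattery.data").joinpath("patterns.json").read_text()
    codes = json.loads(raw)["codes"]
    if len(codes) != 18 or len(set(codes)) != 18:
        raise ValueError("pattern fixture corrupted: expected 18 unique codes")
    patterns = [Pattern3x3.from_code(c) for c in codes]
    seen_rot: set[int] = set()
    for p in patterns:
        if not p.is_valid_stimulus():
            raise ValueError(f"pattern fixture corrupted: invalid pattern {p.code}")
        rots = {rotate_pattern(p, d).code for d in (0, 90, 180, 270)}
        if rots & seen_rot:
            raise ValueError("pattern fixture corrupted: rotation-equivalent pair")
        seen_rot |= rots
    return patterns


@dataclass(frozen=True)
class SpinTrial:
    """One mental-rotation trial: a target, a rotation, and three options.

    Exactly one option is the target rotated by ``rotation_deg``; the two
    foils are the vertical and horizontal reflections of the target.
    """

    target: Pattern3x3
    rotation_deg: int
    options: tuple[Pattern3x3, Pattern3x3, Pattern3x3]
    correct_index: int

    def __post_init__(self) -> None:
        if self.rotation_deg not in (90, 180, 270):
            raise ValueError("rotation_deg must be 90, 180 or 270")
        if not 0 <= self.correct_index <= 2:
            raise ValueError("correct_index must be 0-2")


def make_spin_trial(p: Pattern3x3, rng: np.random.Generator) -> SpinTrial:
    """Build a rotation trial: rotated target plus two reflection foils."""
    deg = int(rng.choice((90, 180, 270)))
    correct = rotate_pattern(p, deg)
    foils = [reflect_pattern(p, "vertical"), reflect_pattern(p, "horizontal")]
    options = [correct, *foils]
    order = rng.permutation(3)
    shuffled = tuple(options[i] for i in order)
    correct_index = int(np.argmax(order == 0))
    return SpinTrial(target=p, rotation_deg=deg, options=shuffled,
                     correct_index=correct_index)


@dataclass(frozen=True)
class ShapeStream:
    """An ordered 2-back shape sequence with per-position match flags."""

    shapes: tuple[str, ...]
    match_flags: tuple[bool, ...]

    def __post_init__(self) -> None:
        if len(self.shapes) != len(self.match_flags):
            raise ValueError("shapes and match_flags must have equal length")
        for i, flag in enumerate(self.match_flags):
            expected = i >= 2 and self.shapes[i] == self.shapes[i - 2]
            if flag != expected:
                raise ValueError(f"match flag inconsistent at position {i}")

    @property
    def n_matches(self) -> int:
        return sum(self.match_flags)


def generate_shape_stream(
    rng: np.random.Generator, max_matches: int = 10, max_len: int = 400
) -> ShapeStream:
    """Draw i.i.d. uniform shapes until ``max_matches`` 2-back matches occur.

    Truncates at the item carrying the ``max_matches``-th match flag, or at
    ``max_len`` items as a safety bound.
    """
    if max_matches < 1:
        raise ValueError("max_matches must be >= 1")
    shapes: list[str] = []
    flags: list[bool] = []
    matches = 0
    while matches < max_matches and len(shapes) < max_len:
        s = SHAPES[int(rng.integers(len(SHAPES)))]
        flag = len(shapes) >= 2 and shapes[-2] == s
        shapes.append(s)
        flags.append(flag)
        matches += flag
    return ShapeStream(tuple(shapes), tuple(flags))


def sample_react_interval(rng: np.random.Generator) -> float:
    """Foreperiod before the vigilance stimulus: uniform on [2, 7] seconds."""
    return float(rng.uniform(2.0, 7.0))


@dataclass(frozen=True)
class HotspotTarget:
    """Circular target region covering 5% of the unit-square arena."""

    center: tuple[float, float]
    radius: float

    AREA_FRACTION = 0.05

    @property
    def area_fraction(self) -> float:
        return math.pi * self.radius**2

    def contains(self, xy: np.ndarray) -> np.ndarray:
        """Boolean in-target indicator for an (n, 2) array of positions."""
        xy = np.atleast_2d(xy)
        d2 = (xy[:, 0] - self.center[0]) ** 2 + (xy[:, 1] - self.center[1]) ** 2
        return d2 <= self.radius**2


def place_hotspot_target(rng: np.random.Generator) -> HotspotTarget:
    """Place a circular target of exactly 5% arena area, uniformly at random.

    The radius is analytic (``sqrt(0.05/pi)``) and the center is uniform over
    the feasible region keeping the circle fully inside the arena.
    """
    radius = math.sqrt(HotspotTarget.AREA_FRACTION / math.pi)
    lo, hi = radius, 1.0 - radius
    cx = float(rng.uniform(lo, hi))
    cy = float(rng.uniform(lo, hi))
    return HotspotTarget(center=(cx, cy), radius=radius)


@dataclass
class TrackState:
    """State of one multiple-object-tracking trial.

    Invariants: no two ball centers closer than ``2 * radius``, and every
    ball lies fully inside the unit-square arena.
    """

    positions: np.ndarray  # (n, 2) arena units
    velocities: np.ndarray  # (n, 2) arena units / s
    radius: float
    target_ids: tuple[int, int, int]
    t: float = 0.0

    @property
    def n_balls(self) -> int:
        return int(self.positions.shape[0])

    def copy(self) -> "TrackState":
        return TrackState(
            positions=self.positions.copy(),
            velocities=self.velocities.copy(),
            radius=self.radius,
            target_ids=self.target_ids,
            t=self.t,
        )

    def check_invariants(self) -> None:
        r = self.radius
        pos = self.positions
        if np.any(pos < r - 1e-12) or np.any(pos > 1.0 - r + 1e-12):
            raise ValueError("ball outside arena")
        if self.n_balls > 1:
            d = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=-1)
            np.fill_diagonal(d, np.inf)
            if np.any(d < 2 * r - 1e-9):
                raise ValueError("overlapping balls")


def init_track_array(
    set_size: int,
    rng: np.random.Generator,
    radius: float = 0.035,
    base_speed: float = 0.25,
) -> TrackState:
    """Place ``set_size`` non-overlapping balls with 3 marked as targets.

    Positions are rejection-sampled uniformly over the feasible square;
    initial headings are uniform with common speed ``base_speed``.
    """
    if set_size not in (8, 9, 11):
        raise ValueError(f"set_size must be one of 8, 9, 11, got {set_size}")
    lo, hi = radius, 1.0 - radius
    positions = np.empty((set_size, 2))
    placed = 0
    attempts = 0
    while placed < set_size:
        attempts += 1
        if attempts > 100_000:
            raise RuntimeError("could not place balls without overlap")
        cand = rng.uniform(lo, hi, size=2)
        if placed and np.any(
            np.linalg.norm(positions[:placed] - cand, axis=1) < 2 * radius
        ):
            continue
        positions[placed] = cand
        placed += 1
    headings = rng.uniform(0.0, 2 * math.pi, size=set_size)
    velocities = base_speed * np.column_stack([np.cos(headings), np.sin(headings)])
    target_ids = tuple(int(i) for i in rng.choice(set_size, size=3, replace=False))
    state = TrackState(
        positions=positions, velocities=velocities, radius=radius,
        target_ids=target_ids,
    )
    state.check_invariants()
    return state
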