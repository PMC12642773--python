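"""Intrinsic viability of the Game-of-Life glider.

Where the continuous modules impose viability constraints from outside, a
cellular automaton lets the limits of an individual emerge from its own
self-maintenance: a glider persists exactly as long as the local update rule
keeps regenerating its pattern.  This module provides the CA engine
(birth-on-3, survive-on-2-or-3, synchronous update, quiescent exterior),
the four glider phases with their off-cell membranes, glider identity
testing up to translation, enumeration of glider-environment perturbations,
and the partition of those configurations into the viability region's
interior (the glider survives), its boundary (the perturbation triggers a
terminal disintegration), and nonmembers (no glider present at all).
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, Union

import numpy as np
from scipy.signal import convolve2d

__all__ = [
    "Grid",
    "GliderPhase",
    "CAConfiguration",
    "ClassificationRecord",
    "PartitionSummary",
    "WindowOverflow",
    "step",
    "glider_phases",
    "match_glider",
    "enumerate_perturbations",
    "classify_configuration",
    "viability_partition",
    "read_rle",
    "write_rle",
    "read_cells",
    "write_cells",
    "DEFAULT_HORIZON_STEPS",
    "MAX_WINDOW",
]

Cell = tuple[int, int]

#: identity is checked at period-4 boundaries up to this many steps
DEFAULT_HORIZON_STEPS = 64

#: auto-grow increment (cells per side) and hard cap on window size
GROW_MARGIN = 8
MAX_WINDOW = 512

_NEIGHBOR_KERNEL = np.array([[1, 1, 1], [1, 0, 1], [1, 1, 1]], dtype=np.uint8)


class WindowOverflow(RuntimeError):
    """Live cells reached the window edge and growth is disabled or capped."""


@dataclass(frozen=True)
class Grid:
    """A bounded binary lattice with quiescent (all-off) exterior.

    ``array[r, c]`` is the world cell ``(origin[0] + r, origin[1] + c)``.
    The window must keep at least one dead ring around the live cells so a
    synchronous update cannot write outside it; :func:`step` grows the
    window on demand (capped at :data:`MAX_WINDOW` per side).
    """

    array: np.ndarray
    origin: Cell = (0, 0)

    def __post_init__(self):
        arr = np.asarray(self.array, dtype=bool)
        object.__setattr__(self, "array", arr)
        if arr.ndim != 2:
            raise ValueError("grid array must be 2-D")

    @staticmethod
    def from_cells(cells: Iterable[Cell], margin: int = 2) -> "Grid":
        """Smallest window containing ``cells`` with a dead margin."""
        cells = set(cells)
        if not cells:
            return Grid(np.zeros((2 * margin + 1, 2 * margin + 1), dtype=bool))
        rs = [r for r, _ in cells]
        cs = [c for _, c in cells]
        r0, c0 = min(rs) - margin, min(cs) - margin
        arr = np.zeros(
            (max(rs) - r0 + margin + 1, max(cs) - c0 + margin + 1), dtype=bool
        )
        for r, c in cells:
            arr[r - r0, c - c0] = True
        return Grid(arr, (r0, c0))

    def live_cells(self) -> frozenset[Cell]:
        rs, cs = np.nonzero(self.array)
        r0, c0 = self.origin
        return frozenset((int(r) + r0, int(c) + c0) for r, c in zip(rs, cs))

    @property
    def population(self) -> int:
        return int(self.array.sum())

    def touches_edge(self) -> bool:
        a = self.array
        if a.size == 0 or not a.any():
            return False
        return bool(
            a[0, :].any() or a[-1, :].any() or a[:, 0].any() or a[:, -1].any()
        )

    def grown(self, pad: int) -> "Grid":
        arr = np.pad(self.array, pad)
        return Grid(arr, (self.origin[0] - pad, self.origin[1] - pad))


def step(grid: Grid, autogrow: bool = True) -> Grid:
    """One synchronous update: birth on 3 live Moore neighbors, survival on
    2 or 3.  Grows the window by :data:`GROW_MARGIN` per side when live
    cells touch its edge; raises :class:`WindowOverflow` if growth is off or
    the cap is hit."""
    if grid.touches_edge():
        if not autogrow:
            raise WindowOverflow("live cell at window edge")
        if max(grid.array.shape) + 2 * GROW_MARGIN > MAX_WINDOW:
            raise WindowOverflow(f"window cap {MAX_WINDOW} exceeded")
        grid = grid.grown(GROW_MARGIN)
    alive = grid.array
    counts = convolve2d(alive.astype(np.uint8), _NEIGHBOR_KERNEL, mode="same")
    new = (counts == 3) | (alive & (counts == 2))
    return Grid(new, grid.origin)


# ---------------------------------------------------------------------------
# Glider identity
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GliderPhase:
    """One glider phase: its on-cells (normalized to min corner (0, 0)) and
    the one-cell-thick off membrane surrounding them."""

    index: int
    on_cells: frozenset[Cell]
    membrane: frozenset[Cell]


def _membrane_of(cells: frozenset[Cell]) -> frozenset[Cell]:
    ring = {
        (r + dr, c + dc)
        for r, c in cells
        for dr in (-1, 0, 1)
        for dc in (-1, 0, 1)
    }
    return frozenset(ring - cells)


# The four phases of the southeast-heading glider, each normalized so its
# minimal row and column are zero.  Stepping phase k yields phase k+1 (at a
# phase-dependent offset); four steps translate the pattern by (+1, +1).
_PHASE_CELLS: tuple[frozenset[Cell], ...] = (
    frozenset({(0, 1), (1, 2), (2, 0), (2, 1), (2, 2)}),
    frozenset({(0, 0), (0, 2), (1, 1), (1, 2), (2, 1)}),
    frozenset({(0, 2), (1, 0), (1, 2), (2, 1), (2, 2)}),
    frozenset({(0, 0), (1, 1), (1, 2), (2, 0), (2, 1)}),
)

def glider_phases() -> tuple[GliderPhase, ...]:
    """The four canonical phases of one chirality/heading (southeast), with
    per-phase membranes.  Phase ``t + 4`` equals phase ``t`` translated by
    ``(1, 1)``."""
    return tuple(
        GliderPhase(i, cells, _membrane_of(cells))
        for i, cells in enumerate(_PHASE_CELLS)
    )


def _translate(cells: frozenset[Cell], off: Cell) -> frozenset[Cell]:
    return frozenset((r + off[0], c + off[1]) for r, c in cells)


def match_glider(
    grid: Grid, mode: str = "exact"
) -> Optional[tuple[int, Cell]]:
    """Locate a glider in the grid, up to translation.

    ``exact`` mode requires the live set to equal one phase pattern at some
    offset.  ``windowed`` mode requires some translate of a phase pattern to
    be present with its entire membrane off; other live cells are permitted
    outside the membrane.  Returns ``(phase index, offset)`` or ``None``;
    with several windowed matches the lexicographically smallest
    ``(phase, offset)`` wins (deterministic).
    """
    if mode not in ("exact", "windowed"):
        raise ValueError("mode must be 'exact' or 'windowed'")
    live = grid.live_cells()
    if len(live) < 5:
        return None
    if mode == "exact":
        if len(live) != 5:
            return None
        r0 = min(r for r, _ in live)
        c0 = min(c for _, c in live)
        norm = frozenset((r - r0, c - c0) for r, c in live)
        for phase in glider_phases():
            if norm == phase.on_cells:
                return phase.index, (r0, c0)
        return None
    # windowed: candidate offsets come from anchoring any pattern cell on
    # any live cell
    matches: list[tuple[int, Cell]] = []
    for phase in glider_phases():
        offsets = {
            (lr - pr, lc - pc)
            for (lr, lc) in live
            for (pr, pc) in phase.on_cells
        }
        for off in offsets:
            if not _translate(phase.on_cells, off) <= live:
                continue
            if _translate(phase.membrane, off) & live:
                continue
            matches.append((phase.index, off))
    if not matches:
        return None
    return min(matches)


# ---------------------------------------------------------------------------
# Glider-environment configurations
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CAConfiguration:
    """A glider (phase + position) plus environment on-cells.

    The environment must be disjoint from the glider's on-cells *and* its
    off-cell membrane — the membrane belongs to the individual.  ``window``
    optionally records the perturbation region the environment was drawn
    from, so results can be reported against it.
    """

    phase: int
    position: Cell
    environment: frozenset[Cell] = frozenset()
    window: Optional[tuple[Cell, ...]] = None

    def __post_init__(self):
        if not 0 <= self.phase <= 3:
            raise ValueError("phase must be 0..3")
        ph = glider_phases()[self.phase]
        forbidden = _translate(ph.on_cells | ph.membrane, self.position)
        if self.environment & forbidden:
            raise ValueError(
                "environment cells overlap the glider or its membrane"
            )

    def glider_cells(self) -> frozenset[Cell]:
        return _translate(glider_phases()[self.phase].on_cells, self.position)

    def to_grid(self, margin: int = 4) -> Grid:
        return Grid.from_cells(self.glider_cells() | self.environment, margin)


def enumerate_perturbations(
    base: CAConfiguration,
    window: Sequence[Cell],
    max_flips: int,
) -> list[CAConfiguration]:
    """All configurations obtained by switching on up to ``max_flips``
    window cells (including the unperturbed base).

    The window must be disjoint from the glider's on-cells and membrane.
    The count is ``sum_{j<=max_flips} C(|window|, j)``.
    """
    if max_flips < 0:
        raise ValueError("max_flips must be >= 0")
    window = sorted(set(window))
    ph = glider_phases()[base.phase]
    forbidden = _translate(ph.on_cells | ph.membrane, base.position)
    overlap = set(window) & forbidden
    if overlap:
        raise ValueError(f"window overlaps the glider/membrane at {overlap}")
    configs: list[CAConfiguration] = []
    for j in range(min(max_flips, len(window)) + 1):
        for combo in itertools.combinations(window, j):
            configs.append(
                CAConfiguration(
                    base.phase,
                    base.position,
                    base.environment | frozenset(combo),
                    window=tuple(window),
                )
            )
    return configs


@dataclass(frozen=True)
class ClassificationRecord:
    """Outcome of classifying one configuration.

    ``label`` is ``interior``, ``boundary`` or ``nonmember``;
    ``steps_to_disintegration`` is the first period-4 checkpoint at which
    the glider identity was missing (boundary, or interior with
    ``recovered`` when a later checkpoint matched again)."""

    config: Union[CAConfiguration, Grid]
    label: str
    steps_to_disintegration: Optional[int] = None
    recovered: bool = False
    final_offset: Optional[Cell] = None


def classify_configuration(
    config: Union[CAConfiguration, Grid],
    horizon: int = DEFAULT_HORIZON_STEPS,
    mode: str = "windowed",
) -> ClassificationRecord:
    """Classify one glider-environment configuration (or bare grid).

    *nonmember* when no glider is present at t=0 (the complement of the
    viable set is every configuration that does not contain the glider);
    otherwise the grid is simulated and the glider identity checked at
    every multiple of 4 steps up to ``horizon``.  *interior* when every
    checkpoint matches (or identity is lost and later regained — flagged
    ``recovered``; only a terminal loss counts as the boundary).
    *boundary* when the identity is lost and never recovered by the
    horizon, with the first failing checkpoint recorded.
    """
    if horizon < 1:
        raise ValueError("horizon must be >= 1")
    grid = config.to_grid() if isinstance(config, CAConfiguration) else config
    m0 = match_glider(grid, mode)
    if m0 is None:
        return ClassificationRecord(config, "nonmember")
    checks: list[tuple[int, Optional[tuple[int, Cell]]]] = []
    for s in range(1, horizon + 1):
        grid = step(grid)
        if s % 4 == 0:
            checks.append((s, match_glider(grid, mode)))
    if not checks:  # horizon < 4: identity held at t=0, nothing more to test
        return ClassificationRecord(config, "interior", final_offset=m0[1])
    failures = [s for s, m in checks if m is None]
    last_step, last_match = checks[-1]
    if not failures:
        return ClassificationRecord(
            config, "interior", final_offset=last_match[1]
        )
    if last_match is not None:  # lost, then regained: not a terminal loss
        return ClassificationRecord(
            config,
            "interior",
            steps_to_disintegration=failures[0],
            recovered=True,
            final_offset=last_match[1],
        )
    return ClassificationRecord(
        config, "boundary", steps_to_disintegration=failures[0]
    )


@dataclass
class PartitionSummary:
    """Counts and per-configuration records of a viability partition."""

    counts: dict[str, int]
    records: list[ClassificationRecord]
    horizon: int
    mode: str

    @property
    def total(self) -> int:
        return len(self.records)


def viability_partition(
    configs: Sequence[CAConfiguration],
    horizon: int = DEFAULT_HORIZON_STEPS,
    mode: str = "windowed",
) -> PartitionSummary:
    """Partition configurations into interior / boundary / nonmember."""
    if len(configs) == 0:
        raise ValueError("need at least one configuration")
    records = [classify_configuration(c, horizon, mode) for c in configs]
    counts = {"interior": 0, "boundary": 0, "nonmember": 0}
    for rec in records:
        counts[rec.label] += 1
    return PartitionSummary(counts, records, horizon, mode)


# ---------------------------------------------------------------------------
# Pattern file formats
# ---------------------------------------------------------------------------


def read_rle(text: str) -> frozenset[Cell]:
    """Parse an RLE pattern (``b`` dead, ``o`` alive, ``$`` newline, ``!``
    end; ``#`` comment lines and the ``x = .., y = ..`` header ignored)."""
    cells: set[Cell] = set()
    body_lines = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if re.match(r"^x\s*=", line):
            continue
        body_lines.append(line)
    body = "".join(body_lines)
    r = c = 0
    count = ""
    for ch in body:
        if ch.isdigit():
            count += ch
            continue
        n = int(count) if count else 1
        count = ""
        if ch == "b":
            c += n
        elif ch == "o":
            for k in range(n):
                cells.add((r, c + k))
            c += n
        elif ch == "$":
            r += n
            c = 0
        elif ch == "!":
            break
        elif ch.isspace():
            continue
        else:
            raise ValueError(f"unexpected RLE character {ch!r}")
    return frozenset(cells)


def write_rle(cells: Iterable[Cell], comment: Optional[str] = None) -> str:
    """Serialize cells to RLE, normalized to min corner (0, 0)."""
    cells = set(cells)
    lines = []
    if comment:
        lines.append(f"#C {comment}")
    if not cells:
        lines.append("x = 0, y = 0, rule = B3/S23")
        lines.append("!")
        return "\n".join(lines) + "\n"
    r0 = min(r for r, _ in cells)
    c0 = min(c for _, c in cells)
    norm = {(r - r0, c - c0) for r, c in cells}
    h = max(r for r, _ in norm) + 1
    w = max(c for _, c in norm) + 1
    lines.append(f"x = {w}, y = {h}, rule = B3/S23")
    runs: list[str] = []
    for r in range(h):
        row = "".join("o" if (r, c) in norm else "b" for c in range(w)).rstrip("b")
        enc = ""
        for ch, grp in itertools.groupby(row):
            n = len(list(grp))
            enc += (str(n) if n > 1 else "") + ch
        runs.append(enc)
    lines.append("$".join(runs) + "!")
    return "\n".join(lines) + "\n"


def read_cells(text: str) -> frozenset[Cell]:
    """Parse plain-text ``.cells`` format (``.`` dead, ``O`` alive, ``!``
    comment lines)."""
    cells: set[Cell] = set()
    r = 0
    for line in text.splitlines():
        if line.startswith("!"):
            continue
        for c, ch in enumerate(line):
            if ch == "O":
                cells.add((r, c))
            elif ch not in (".", " "):
                raise ValueError(f"unexpected .cells character {ch!r}")
        r += 1
    return frozenset(cells)


def write_cells(cells: Iterable[Cell], comment: Optional[str] = None) -> str:
    """Serialize cells to ``.cells`` text, normalized to min corner (0, 0)."""
    cells = set(cells)
    lines = []
    if comment:
        lines.append(f"! {comment}")
    if cells:
        r0 = min(r for r, _ in cells)
        c0 = min(c for _, c in cells)
        norm = {(r - r0, c - c0) for r, c in cells}
        h = max(r for r, _ in norm) + 1
        w = max(c for _, c in norm) + 1
        for r in range(h):
            lines.append(
                "".join("O" if (r, c) in norm else "." for c in range(w))
            )
    return "\n".join(lines) + "\n"
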