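"""Humphrey field analyzer test-point grids and their index maps.

All grids are expressed in the right-eye (OD) frame: x > 0 temporal,
y > 0 superior, units degrees of visual angle.  Point order is
deterministic: row-major from the most superior row downward, and within
a row from nasal (most negative x) to temporal.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

__all__ = [
    "Pattern",
    "VFGrid",
    "build_grid",
    "horizontal_flip_permutation",
    "vertical_flip_permutation",
]


class Pattern(str, enum.Enum):
    """Supported HFA test patterns."""

    P24_2 = "24-2"
    P10_2 = "10-2"
    P30_2 = "30-2"


# Literal 10-2 chart (x, y) in degrees, OD frame, row-major superior to
# inferior.  Row sizes 2,6,8,8,10,10,8,8,6,2 (= 68 points); validated in
# tests only through count and mirror symmetry.
_10_2_POINTS: tuple[tuple[int, int], ...] = (
    (-1, 9), (1, 9),
    (-5, 7), (-3, 7), (-1, 7), (1, 7), (3, 7), (5, 7),
    (-7, 5), (-5, 5), (-3, 5), (-1, 5), (1, 5), (3, 5), (5, 5), (7, 5),
    (-7, 3), (-5, 3), (-3, 3), (-1, 3), (1, 3), (3, 3), (5, 3), (7, 3),
    (-9, 1), (-7, 1), (-5, 1), (-3, 1), (-1, 1), (1, 1), (3, 1), (5, 1), (7, 1), (9, 1),
    (-9, -1), (-7, -1), (-5, -1), (-3, -1), (-1, -1), (1, -1), (3, -1), (5, -1), (7, -1), (9, -1),
    (-7, -3), (-5, -3), (-3, -3), (-1, -3), (1, -3), (3, -3), (5, -3), (7, -3),
    (-7, -5), (-5, -5), (-3, -5), (-1, -5), (1, -5), (3, -5), (5, -5), (7, -5),
    (-5, -7), (-3, -7), (-1, -7), (1, -7), (3, -7), (5, -7),
    (-1, -9), (1, -9),
)


def _grid_24_2() -> tuple[tuple[int, int], ...]:
    # Rows at y = +-21, +-15, +-9, +-3 with half-extents 9, 15, 21, 21;
    # rows |y| = 3 additionally carry the nasal points at x = -27.
    half = {21: 9, 15: 15, 9: 21, 3: 21}
    pts: list[tuple[int, int]] = []
    for y in (21, 15, 9, 3, -3, -9, -15, -21):
        xs = list(range(-half[abs(y)], half[abs(y)] + 1, 6))
        if abs(y) == 3:
            xs = [-27] + xs
        pts.extend((x, y) for x in xs)
    return tuple(pts)


def _grid_30_2() -> tuple[tuple[int, int], ...]:
    half = {27: 9, 21: 15, 15: 21, 9: 27, 3: 27}
    pts: list[tuple[int, int]] = []
    for y in (27, 21, 15, 9, 3, -3, -9, -15, -21, -27):
        pts.extend((x, y) for x in range(-half[abs(y)], half[abs(y)] + 1, 6))
    return tuple(pts)


@dataclass(frozen=True)
class VFGrid:
    """Test-point geometry of one HFA pattern.

    Attributes
    ----------
    pattern : Pattern
    points : tuple of (x, y)
        Degrees, OD frame, deterministic row-major order.
    blind_spot_indices : frozenset of int
        Indices of the physiologic blind-spot points (24-2/30-2 only).
    row_index : tuple of int
        Row number of each point, rows counted from the most superior.
    lattice_step : int
        Inter-point spacing in degrees (6 for 24-2/30-2, 2 for 10-2).
    """

    pattern: Pattern
    points: tuple[tuple[int, int], ...]
    blind_spot_indices: frozenset[int]
    row_index: tuple[int, ...]
    lattice_step: int
    _index: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self):
        object.__setattr__(
            self, "_index", {p: i for i, p in enumerate(self.points)}
        )

    @property
    def n_points(self) -> int:
        return len(self.points)

    @property
    def non_blind_indices(self) -> np.ndarray:
        """Indices of analysed points, blind spot excluded, in grid order."""
        return np.array(
            [i for i in range(self.n_points) if i not in self.blind_spot_indices],
            dtype=np.intp,
        )

    def index_of(self, x: int, y: int) -> int:
        """Index of the point at (x, y); KeyError if absent."""
        return self._index[(x, y)]

    def contains(self, x: int, y: int) -> bool:
        return (x, y) in self._index

    def xy(self) -> np.ndarray:
        """(n_points, 2) integer coordinate array."""
        return np.asarray(self.points, dtype=np.intp)

    def rows(self) -> list[list[int]]:
        """Point indices grouped by row, superior to inferior."""
        n_rows = max(self.row_index) + 1
        out: list[list[int]] = [[] for _ in range(n_rows)]
        for i, r in enumerate(self.row_index):
            out[r].append(i)
        return out

    def to_records(self) -> list[dict]:
        """JSON-friendly export: one record per point."""
        return [
            {
                "index": i,
                "x": x,
                "y": y,
                "blind_spot": i in self.blind_spot_indices,
                "row": self.row_index[i],
            }
            for i, (x, y) in enumerate(self.points)
        ]


@lru_cache(maxsize=None)
def build_grid(pattern: Pattern | str) -> VFGrid:
    """Construct the grid for one pattern.

    Raises
    ------
    ValueError
        If the pattern is not one of 24-2, 10-2, 30-2.
    """
    pattern = Pattern(pattern)
    if pattern is Pattern.P24_2:
        points = _grid_24_2()
        blind = frozenset(
            i for i, p in enumerate(points) if p in ((15, 3), (15, -3))
        )
        step = 6
    elif pattern is Pattern.P30_2:
        points = _grid_30_2()
        blind = frozenset(
            i for i, p in enumerate(points) if p in ((15, 3), (15, -3))
        )
        step = 6
    elif pattern is Pattern.P10_2:
        points = _10_2_POINTS
        blind = frozenset()
        step = 2
    else:  # pragma: no cover - Pattern() already raises
        raise ValueError(f"unknown pattern: {pattern}")

    ys = sorted({y for _, y in points}, reverse=True)
    row_of = {y: r for r, y in enumerate(ys)}
    row_index = tuple(row_of[y] for _, y in points)
    return VFGrid(pattern, points, blind, row_index, step)


def _mirror_permutation(grid: VFGrid, mirror) -> np.ndarray:
    perm = np.empty(grid.n_points, dtype=np.intp)
    for i, (x, y) in enumerate(grid.points):
        mx, my = mirror(x, y)
        try:
            perm[i] = grid.index_of(mx, my)
        except KeyError as exc:  # pragma: no cover - supported grids symmetric
            raise ValueError(
                f"grid {grid.pattern.value} not symmetric: no point at {(mx, my)}"
            ) from exc
    return perm


def horizontal_flip_permutation(grid: VFGrid) -> np.ndarray:
    """Index permutation that mirrors each row left-right.

    Used to re-index left-eye (OS) data into the OD frame.  Implemented
    as within-row index reversal, which on x-symmetric rows equals the
    coordinate map (x, y) -> (-x, y) and on the 24-2 rows carrying the
    nasal extension pairs nasal with nasal and blind spot with blind
    spot (the standard chart-flip convention).  Involution.
    """
    perm = np.empty(grid.n_points, dtype=np.intp)
    xy = grid.xy()
    for row in grid.rows():
        order = sorted(row, key=lambda i: xy[i, 0])
        for a, b in zip(order, reversed(order)):
            perm[a] = b
    return perm


def vertical_flip_permutation(grid: VFGrid) -> np.ndarray:
    """Index permutation mapping each point (x, y) to (x, -y).

    Paired with a superior-inferior volume flip during augmentation and
    test-time averaging.  Involution; maps blind spot onto blind spot.
    """
    return _mirror_permutation(grid, lambda x, y: (x, -y))
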