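"""24-2 visual-field test grid: geometry, quadrants, blind-spot handling.

The 24-2 pattern is the standard 54-point Humphrey grid covering the
central 24 degrees (27 degrees nasally), with 6-degree spacing and every
coordinate an odd multiple of 3 degrees.  Coordinates are degrees of
visual angle in visual-field space: x positive temporal for the right
eye, y positive superior, fixation at the origin.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator

import pandas as pd

__all__ = ["GridLocation", "TestGrid", "build_24_2", "distance", "same_quadrant"]

# Quadrant labels are arbitrary but fixed: A = superior-temporal (x>0, y>0)
# for the right eye, proceeding counter-clockwise.
_QUADRANT_BY_SIGNS = {
    (1, 1): "A",
    (-1, 1): "B",
    (-1, -1): "C",
    (1, -1): "D",
}


@dataclass(frozen=True)
class GridLocation:
    """One test point of the grid.

    Attributes
    ----------
    x, y:
        Visual-field coordinates in degrees.  Every 24-2 offset is an odd
        multiple of 3 degrees, so neither coordinate is ever zero and the
        sign pair assigns a unique quadrant.
    index:
        Position in the grid's canonical ordering.
    blind_spot_adjacent:
        True for the two points straddling the physiologic blind spot
        ((15, +-3) for a right eye).
    """

    x: float
    y: float
    index: int
    blind_spot_adjacent: bool = False

    @property
    def r(self) -> float:
        """Eccentricity: Euclidean distance from fixation, degrees."""
        return math.hypot(self.x, self.y)

    @property
    def quadrant(self) -> str:
        if self.x == 0 or self.y == 0:
            raise ValueError(f"location on a meridian has no quadrant: {self}")
        signs = (int(math.copysign(1, self.x)), int(math.copysign(1, self.y)))
        return _QUADRANT_BY_SIGNS[signs]


@dataclass(frozen=True)
class TestGrid:
    """An ordered set of test locations for one eye."""

    locations: tuple[GridLocation, ...]
    eye: str = "right"

    def __len__(self) -> int:
        return len(self.locations)

    def __iter__(self) -> Iterator[GridLocation]:
        return iter(self.locations)

    def __getitem__(self, i: int) -> GridLocation:
        return self.locations[i]

    def find(self, x: float, y: float) -> GridLocation:
        """Return the location with the given coordinates."""
        for loc in self.locations:
            if loc.x == x and loc.y == y:
                return loc
        raise KeyError(f"no location ({x}, {y}) on this grid")

    @property
    def eccentricities(self) -> list[float]:
        return [loc.r for loc in self.locations]

    def quadrant_indices(self, label: str) -> list[int]:
        return [loc.index for loc in self.locations if loc.quadrant == label]

    def to_frame(self) -> pd.DataFrame:
        """Export as a data frame (x_deg, y_deg, quadrant, blind_spot_adjacent)."""
        return pd.DataFrame(
            {
                "x_deg": [loc.x for loc in self.locations],
                "y_deg": [loc.y for loc in self.locations],
                "quadrant": [loc.quadrant for loc in self.locations],
                "blind_spot_adjacent": [loc.blind_spot_adjacent for loc in self.locations],
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _right_eye_points() -> list[tuple[float, float]]:
    # Row layout of the 24-2 pattern, right eye, visual-field coordinates
    # (temporal positive x).  Rows at y odd multiples of 3 deg with counts
    # 4/6/8/9 from |y|=21 down to |y|=3; the y = +-3 rows carry the extra
    # nasal column at x = -27; the blind spot sits temporally at x = +15.
    pts: list[tuple[float, float]] = []
    for y in (21, 15, 9, 3, -3, -9, -15, -21):
        half = {21: 9, 15: 15, 9: 21, 3: 21}[abs(y)]
        xs = list(range(-half, half + 1, 6))
        if abs(y) == 3:
            xs = [-27] + xs  # nasal extension
        for x in xs:
            pts.append((float(x), float(y)))
    return pts


def build_24_2(eye: str = "right") -> TestGrid:
    """Build the canonical 54-point 24-2 grid.

    Parameters
    ----------
    eye:
        "right" or "left".  The left-eye grid is the mirror image
        (x -> -x) of the right-eye grid.

    Returns
    -------
    TestGrid
        54 locations; the two points adjacent to the blind spot
        ((15, +-3) on a right eye, (-15, +-3) on a left) are flagged.
    """
    if eye not in ("right", "left"):
        raise ValueError(f"unknown eye label {eye!r}; expected 'right' or 'left'")
    pts = _right_eye_points()
    if eye == "left":
        pts = [(-x, y) for x, y in pts]
    bs_x = 15.0 if eye == "right" else -15.0
    locs = tuple(
        GridLocation(x, y, i, blind_spot_adjacent=(x == bs_x and abs(y) == 3.0))
        for i, (x, y) in enumerate(pts)
    )
    return TestGrid(locations=locs, eye=eye)


def distance(a: GridLocation, b: GridLocation) -> float:
    """Euclidean distance between two grid locations, degrees."""
    return math.hypot(a.x - b.x, a.y - b.y)


def same_quadrant(a: GridLocation, b: GridLocation) -> bool:
    """True iff both locations lie in the same quadrant (sign pair)."""
    return a.quadrant == b.quadrant


def grid_from_frame(df: pd.DataFrame, eye: str = "right") -> TestGrid:
    """Rebuild a grid from a frame written by :meth:`TestGrid.to_frame`."""
    locs = tuple(
        GridLocation(
            float(row.x_deg),
            float(row.y_deg),
            i,
            blind_spot_adjacent=bool(row.blind_spot_adjacent),
        )
        for i, row in enumerate(df.itertuples())
    )
    return TestGrid(locations=locs, eye=eye)
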