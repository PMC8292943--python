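"""Ternary simplex placement and tribin binning of H-I-T scores.

Each scored article is a barycentric point (h, i, t), h+i+t = 1, on a
triangle whose apexes are the pure-H, pure-I and pure-T compositions.
Subdividing each edge into *n* equal parts in the three directions cuts the
triangle into n² congruent sub-triangles ("tribins"): for every row there is
one more upward- than downward-pointing cell.  Because all tribins have equal
area, uniform sampling on the simplex yields statistically uniform counts.

Cell indexing is fixed so grids serialize stably: ``row`` counts lattice
steps from the T-free (H-I) edge toward the T apex, ``position`` counts steps
from the H side toward I within the row, and ``orientation`` is ``"up"`` or
``"down"``.  Internally a cell is the lattice triple (a, b, c) of floored
scaled coordinates with a+b+c = n-1 (up) or n-2 (down); then row = c and
position = b.

Boundary tie-breaking: scores are small-denominator rationals and often sit
exactly on lattice lines.  Scaled coordinates within ``1e-9`` of an integer
are snapped to it; if the floored triple then overshoots (sum n), the
highest-priority (h, then i, then t) snapped coordinate with a positive floor
is decremented.  The rule is deterministic and always returns a cell whose
closure contains the point; in particular each vertex belongs to its corner
cell.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .scoring import HITScore

_SNAP = 1e-9

#: Default vertex placement: equilateral triangle, H apex on top, the H-I
#: edge on the left (50% H / 50% I sits at that edge's midpoint).
DEFAULT_LAYOUT: dict[str, tuple[float, float]] = {
    "H": (0.5, math.sqrt(3.0) / 2.0),
    "I": (0.0, 0.0),
    "T": (1.0, 0.0),
}


class TernaryError(ValueError):
    pass


@dataclass(frozen=True)
class TernaryPoint:
    """Barycentric coordinates on the H-I-T simplex."""

    h: float
    i: float
    t: float

    def __post_init__(self) -> None:
        if min(self.h, self.i, self.t) < -1e-9:
            raise TernaryError(f"negative barycentric coordinate: {self}")
        if abs(self.h + self.i + self.t - 1.0) > 1e-9:
            raise TernaryError(
                f"coordinates must sum to 1, got {self.h + self.i + self.t!r}")


@dataclass(frozen=True)
class Cell:
    """One tribin: row (steps from the H-I edge), position (steps toward I),
    orientation ('up' or 'down')."""

    row: int
    position: int
    orientation: str

    def lattice(self, n: int) -> tuple[int, int, int]:
        """The (a, b, c) floored-coordinate triple of this cell."""
        c = self.row
        b = self.position
        a = (n - 1 - b - c) if self.orientation == "up" else (n - 2 - b - c)
        return (a, b, c)

    def vertices(self, n: int) -> list[tuple[float, float, float]]:
        """Barycentric corners of the cell."""
        a, b, c = self.lattice(n)
        if self.orientation == "up":
            corners = [(a + 1, b, c), (a, b + 1, c), (a, b, c + 1)]
        else:
            corners = [(a + 1, b + 1, c), (a + 1, b, c + 1), (a, b + 1, c + 1)]
        return [(x / n, y / n, z / n) for x, y, z in corners]


def all_cells(n: int) -> list[Cell]:
    """The n² cells of the grid in canonical (row, position, orientation) order."""
    cells = []
    for row in range(n):
        for pos in range(n - row):
            cells.append(Cell(row, pos, "up"))
        for pos in range(n - 1 - row):
            cells.append(Cell(row, pos, "down"))
    return cells


def to_point(score: HITScore) -> TernaryPoint:
    """Place a fractional score on the simplex (identity with a norm check)."""
    return TernaryPoint(score.h, score.i, score.t)


def to_cartesian(
    point: TernaryPoint,
    layout: Mapping[str, tuple[float, float]] | None = None,
) -> tuple[float, float]:
    """Affine barycentric interpolation of the three vertex placements."""
    layout = layout or DEFAULT_LAYOUT
    (hx, hy), (ix, iy), (tx, ty) = layout["H"], layout["I"], layout["T"]
    area2 = (ix - hx) * (ty - hy) - (tx - hx) * (iy - hy)
    if abs(area2) < 1e-12:
        raise TernaryError("degenerate layout: collinear vertices")
    return (point.h * hx + point.i * ix + point.t * tx,
            point.h * hy + point.i * iy + point.t * ty)


def from_cartesian(
    xy: tuple[float, float],
    layout: Mapping[str, tuple[float, float]] | None = None,
) -> TernaryPoint:
    """Invert :func:`to_cartesian` (solves the 2x2 affine system)."""
    layout = layout or DEFAULT_LAYOUT
    (hx, hy), (ix, iy), (tx, ty) = layout["H"], layout["I"], layout["T"]
    x, y = xy
    det = (ix - hx) * (ty - hy) - (tx - hx) * (iy - hy)
    if abs(det) < 1e-12:
        raise TernaryError("degenerate layout: collinear vertices")
    i = ((x - hx) * (ty - hy) - (tx - hx) * (y - hy)) / det
    t = ((ix - hx) * (y - hy) - (x - hx) * (iy - hy)) / det
    return TernaryPoint(1.0 - i - t, i, t)


def _snapped_floor(x: float) -> tuple[int, bool]:
    """Floor of a scaled coordinate with near-integer snapping.

    Returns (floor, snapped?): values within 1e-9 of an integer floor to that
    integer and are marked snapped (candidates for the overshoot repair).
    """
    r = round(x)
    if abs(x - r) <= _SNAP:
        return int(r), True
    return int(math.floor(x)), False


def bin_point(point: TernaryPoint, n: int) -> Cell:
    """The tribin containing *point* on the n-subdivided grid."""
    if n < 1:
        raise TernaryError(f"subdivision count must be >= 1, got {n}")
    scaled = (point.h * n, point.i * n, point.t * n)
    floors = []
    snapped = []
    for x in scaled:
        f, s = _snapped_floor(x)
        floors.append(f)
        snapped.append(s)
    total = sum(floors)
    # Overshoot repair: a point on a lattice line (or vertex) may floor to
    # sum n; push the first snapped positive coordinate into the cell below.
    while total > n - 1:
        for k in range(3):
            if snapped[k] and floors[k] > 0:
                floors[k] -= 1
                total -= 1
                break
        else:  # pragma: no cover - unreachable for valid points
            raise TernaryError(f"cannot bin {point} at n={n}")
    a, b, c = floors
    if total == n - 1:
        return Cell(row=c, position=b, orientation="up")
    if total == n - 2:
        return Cell(row=c, position=b, orientation="down")
    raise TernaryError(  # pragma: no cover - defensive
        f"invalid lattice sum {total} for {point} at n={n}")


@dataclass
class TribinGrid:
    """Counts of binned points per tribin of an n-subdivided simplex."""

    n: int
    cells: dict[Cell, int]

    @property
    def total(self) -> int:
        return sum(self.cells.values())

    def count(self, cell: Cell) -> int:
        return self.cells.get(cell, 0)

    def to_rows(self) -> list[tuple[int, int, str, int]]:
        """(row, position, orientation, count) for all n² cells, zeros included."""
        return [(c.row, c.position, c.orientation, self.count(c))
                for c in all_cells(self.n)]


def bin_corpus(scores: Iterable[HITScore], n: int) -> TribinGrid:
    """Bin a corpus of scores; counts over all n² cells sum to the input size."""
    counts = {cell: 0 for cell in all_cells(n)}
    for score in scores:
        counts[bin_point(to_point(score), n)] += 1
    return TribinGrid(n=n, cells=counts)


# ---------------------------------------------------------------------------
# Plotting adapter (pure-geometry core above never imports matplotlib)

def plot_tribin(grid: TribinGrid, ax=None, cmap: str = "viridis",
                layout: Mapping[str, tuple[float, float]] | None = None,
                annotate: bool = False):
    """Draw the tribin grid as colored triangles; returns the matplotlib Axes."""
    import matplotlib.pyplot as plt
    from matplotlib.patches import Polygon
    from matplotlib import colormaps

    layout = layout or DEFAULT_LAYOUT
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 5.5))
    vmax = max(grid.cells.values(), default=1) or 1
    cm = colormaps[cmap]
    for cell in all_cells(grid.n):
        corners = [to_cartesian(TernaryPoint(*v), layout)
                   for v in cell.vertices(grid.n)]
        count = grid.count(cell)
        ax.add_patch(Polygon(corners, closed=True,
                             facecolor=cm(count / vmax),
                             edgecolor="white", linewidth=0.4))
        if annotate and count:
            cx = sum(x for x, _ in corners) / 3
            cy = sum(y for _, y in corners) / 3
            ax.text(cx, cy, str(count), ha="center", va="center", fontsize=6)
    for label, (x, y) in layout.items():
        ax.annotate(label, (x, y), fontsize=12, fontweight="bold",
                    ha="center", va="bottom" if y > 0.1 else "top")
    ax.set_xlim(-0.08, 1.08)
    ax.set_ylim(-0.08, 1.0)
    ax.set_aspect("equal")
    ax.axis("off")
    return ax
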