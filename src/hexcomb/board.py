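"""Hexagonal playfield geometry.

Cells are axial coordinates ``(q, r)`` on a pointy/flat-agnostic hex lattice
(cube coordinates are ``(x, y, z) = (q, -q - r, r)``).  The default playfield,
``"honeycomb97"``, is a centred hexagon of radius 5 (91 cells) with six extra
cells appended outward at the six cube-diagonal directions of ring 6.  Those
six extremal cells carry the money depots; one of them additionally carries
the high-value reward visible only to informed players.  This placement makes
every depot equidistant from the central start cell and leaves exactly two
distance-reducing first steps from the centre toward each depot.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import pandas as pd

Cell = tuple[int, int]

#: The six axial neighbour offsets, in clockwise order.
AXIAL_DIRECTIONS: tuple[Cell, ...] = (
    (1, 0), (1, -1), (0, -1), (-1, 0), (-1, 1), (0, 1),
)

#: Cube-diagonal directions expressed axially; ``3 * d`` lands on the midpoint
#: of an edge of ring 6.
_DIAGONALS: tuple[Cell, ...] = (
    (2, -1), (1, -2), (-1, -1), (-2, 1), (-1, 2), (1, 1),
)


class BoardError(ValueError):
    """A board layout violates a structural invariant."""


def hex_distance(a: Cell, b: Cell) -> int:
    """Hex-lattice distance between two axial cells.

    Equals the minimum number of single-cell steps between ``a`` and ``b``
    on an unbounded lattice; symmetric and satisfies the triangle inequality.
    """
    dq = a[0] - b[0]
    dr = a[1] - b[1]
    return (abs(dq) + abs(dr) + abs(dq + dr)) // 2


def neighbours(cell: Cell) -> list[Cell]:
    """The six lattice neighbours of ``cell`` (board membership not checked)."""
    return [(cell[0] + dq, cell[1] + dr) for dq, dr in AXIAL_DIRECTIONS]


@dataclass(frozen=True)
class HexBoard:
    """Immutable playfield: cell set, six depots, one high-value depot, start.

    Attributes
    ----------
    cells : frozenset of (q, r)
        All playable cells.
    depot_cells : tuple of (q, r)
        The six money depots, in canonical (sorted) order.
    ee_cell : (q, r)
        The depot that additionally carries the high-value reward shown to
        informed players.
    start_cell : (q, r)
        The common start cell; equidistant from all six depots by default.
    name : str
        Layout identifier recorded in serialised game logs.
    """

    cells: frozenset
    depot_cells: tuple
    ee_cell: Cell
    start_cell: Cell
    name: str = "custom"

    def __post_init__(self) -> None:
        if len(self.depot_cells) != 6:
            raise BoardError(f"expected 6 depots, got {len(self.depot_cells)}")
        if not set(self.depot_cells) <= self.cells:
            raise BoardError("depot cells must be on the board")
        if self.ee_cell not in self.depot_cells:
            raise BoardError("high-value cell must be one of the depots")
        if self.start_cell not in self.cells:
            raise BoardError("start cell must be on the board")
        if not self._connected():
            raise BoardError("board is not edge-connected")

    def _connected(self) -> bool:
        seen = {self.start_cell}
        frontier = [self.start_cell]
        while frontier:
            c = frontier.pop()
            for n in neighbours(c):
                if n in self.cells and n not in seen:
                    seen.add(n)
                    frontier.append(n)
        return len(seen) == len(self.cells)

    def on_board_neighbours(self, cell: Cell) -> list[Cell]:
        return [n for n in neighbours(cell) if n in self.cells]

    def with_ee(self, cell: Cell) -> "HexBoard":
        """A copy of the board with the high-value reward on ``cell``."""
        if cell not in self.depot_cells:
            raise BoardError(f"{cell} is not a depot")
        return replace(self, ee_cell=cell)


def shortest_step_options(pos: Cell, goal: Cell, board: HexBoard) -> set:
    """On-board neighbours of ``pos`` one step closer to ``goal``.

    These are the first moves of a shortest route; from the default board's
    start cell toward any depot there are exactly two.
    """
    d = hex_distance(pos, goal)
    return {
        n for n in board.on_board_neighbours(pos)
        if hex_distance(n, goal) == d - 1
    }


def _honeycomb97_layout() -> pd.DataFrame:
    rows = []
    for q in range(-5, 6):
        for r in range(-5, 6):
            if abs(q + r) <= 5:
                rows.append((q, r, "start" if (q, r) == (0, 0) else "plain"))
    for i, (dq, dr) in enumerate(_DIAGONALS):
        rows.append((3 * dq, 3 * dr, "ee_depot" if i == 0 else "depot"))
    return pd.DataFrame(rows, columns=["q", "r", "role"])


def build_board(layout: "str | Path | pd.DataFrame" = "honeycomb97") -> HexBoard:
    """Construct a :class:`HexBoard` from a named default or a layout table.

    Parameters
    ----------
    layout : str, Path or DataFrame
        ``"honeycomb97"`` for the default 97-cell field, a path to a layout
        CSV, or a DataFrame; layout tables have columns ``q``, ``r``,
        ``role`` with role in ``{plain, depot, ee_depot, start}``.

    Raises
    ------
    BoardError
        On duplicate coordinates, a depot count other than six, a missing or
        duplicated start or high-value cell, or a disconnected board.
    """
    name = "custom"
    if isinstance(layout, str) and layout == "honeycomb97":
        layout = _honeycomb97_layout()
        name = "honeycomb97"
    elif isinstance(layout, (str, Path)):
        name = Path(layout).stem
        layout = pd.read_csv(layout)

    missing = {"q", "r", "role"} - set(layout.columns)
    if missing:
        raise BoardError(f"layout table missing columns {sorted(missing)}")
    coords = list(zip(layout["q"].astype(int), layout["r"].astype(int)))
    if len(coords) != len(set(coords)):
        raise BoardError("duplicate coordinates in layout")
    roles = layout["role"].tolist()
    bad = set(roles) - {"plain", "depot", "ee_depot", "start"}
    if bad:
        raise BoardError(f"unknown roles {sorted(bad)}")

    depots = sorted(c for c, role in zip(coords, roles) if role in ("depot", "ee_depot"))
    ee = [c for c, role in zip(coords, roles) if role == "ee_depot"]
    starts = [c for c, role in zip(coords, roles) if role == "start"]
    if len(ee) != 1:
        raise BoardError(f"expected exactly one ee_depot, got {len(ee)}")
    if len(starts) != 1:
        raise BoardError(f"expected exactly one start cell, got {len(starts)}")
    return HexBoard(
        cells=frozenset(coords),
        depot_cells=tuple(depots),
        ee_cell=ee[0],
        start_cell=starts[0],
        name=name,
    )


def layout_table(board: HexBoard) -> pd.DataFrame:
    """Serialise a board back to the layout-CSV schema."""
    rows = []
    for q, r in sorted(board.cells):
        cell = (q, r)
        if cell == board.ee_cell:
            role = "ee_depot"
        elif cell in board.depot_cells:
            role = "depot"
        elif cell == board.start_cell:
            role = "start"
        else:
            role = "plain"
        rows.append((q, r, role))
    return pd.DataFrame(rows, columns=["q", "r", "role"])
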