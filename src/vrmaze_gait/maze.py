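"""Grid-maze generation, representation and completion timing.

The navigation environment is a rows × cols grid of square blocks
(default 7 × 8 blocks of 0.56 m, i.e. 56 blocks).  Passages are carved
as a spanning tree of the grid graph, which guarantees that the simple
path between any two cells — in particular between the entry corner and
the exit — is unique.  Wall edges are the grid edges not in the tree.

Cell coordinates are (row, col); cell (0, 0) has its center at
(block_size/2, block_size/2), rows extend along +Y and columns along +X.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

DEFAULT_ROWS = 7
DEFAULT_COLS = 8
DEFAULT_BLOCK_SIZE = 0.56  # meters

Cell = tuple[int, int]
Edge = frozenset  # frozenset of two Cells


class MazeError(ValueError):
    pass


class IncompleteTraversal(RuntimeError):
    """Raised when a trajectory never reaches the maze exit cell."""


@dataclass
class Maze:
    """A grid maze whose open passages form a spanning tree.

    ``passages`` holds the carved edges (each a frozenset of two adjacent
    cells); every grid edge not in ``passages`` is a wall.
    """

    rows: int
    cols: int
    block_size: float
    entry_cell: Cell
    exit_cell: Cell
    passages: set[Edge] = field(default_factory=set)
    maze_id: str = ""

    @property
    def n_blocks(self) -> int:
        return self.rows * self.cols

    @property
    def walls(self) -> set[Edge]:
        """Blocked edges between adjacent cells."""
        return self._all_edges() - self.passages

    def _all_edges(self) -> set[Edge]:
        edges = set()
        for r in range(self.rows):
            for c in range(self.cols):
                if r + 1 < self.rows:
                    edges.add(frozenset({(r, c), (r + 1, c)}))
                if c + 1 < self.cols:
                    edges.add(frozenset({(r, c), (r, c + 1)}))
        return edges

    def neighbors(self, cell: Cell) -> list[Cell]:
        r, c = cell
        out = []
        for nb in ((r - 1, c), (r + 1, c), (r, c - 1), (r, c + 1)):
            if frozenset({cell, nb}) in self.passages:
                out.append(nb)
        return out

    def cell_center(self, cell: Cell) -> np.ndarray:
        r, c = cell
        return np.array([(c + 0.5) * self.block_size, (r + 0.5) * self.block_size])

    def cell_of(self, xy: np.ndarray) -> Cell:
        """Grid cell containing a horizontal position (may lie off-grid)."""
        c = int(np.floor(xy[0] / self.block_size))
        r = int(np.floor(xy[1] / self.block_size))
        return (r, c)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "rows": self.rows,
            "cols": self.cols,
            "block_size": self.block_size,
            "entry_cell": list(self.entry_cell),
            "exit_cell": list(self.exit_cell),
            "passages": sorted(sorted(map(list, e)) for e in self.passages),
            "maze_id": self.maze_id,
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "Maze":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        d = json.loads(text)
        passages = {frozenset({tuple(a), tuple(b)}) for a, b in d["passages"]}
        return cls(
            rows=d["rows"],
            cols=d["cols"],
            block_size=d["block_size"],
            entry_cell=tuple(d["entry_cell"]),
            exit_cell=tuple(d["exit_cell"]),
            passages=passages,
            maze_id=d.get("maze_id", ""),
        )


def generate_maze(
    rows: int = DEFAULT_ROWS,
    cols: int = DEFAULT_COLS,
    block_size: float = DEFAULT_BLOCK_SIZE,
    seed: int | None = None,
) -> Maze:
    """Generate a random spanning-tree maze with a corner entry.

    The passages are carved by a randomized depth-first search from the
    entry corner, producing a uniform-degree spanning tree of the grid
    graph; because the open passages form a tree, the simple path from
    entry to exit is unique.  The exit is a random perimeter cell
    distinct from the entry.  Deterministic for a fixed seed.
    """
    if rows < 2 or cols < 2:
        raise MazeError(f"degenerate maze dimensions {rows}x{cols}; need at least 2x2")
    if block_size <= 0:
        raise MazeError("block_size must be positive")
    rng = np.random.default_rng(seed)

    corners = [(0, 0), (0, cols - 1), (rows - 1, 0), (rows - 1, cols - 1)]
    entry = corners[int(rng.integers(len(corners)))]

    # iterative randomized DFS spanning tree
    passages: set[Edge] = set()
    visited = {entry}
    stack = [entry]
    while stack:
        cell = stack[-1]
        r, c = cell
        nbrs = [
            (nr, nc)
            for nr, nc in ((r - 1, c), (r + 1, c), (r, c - 1), (r, c + 1))
            if 0 <= nr < rows and 0 <= nc < cols and (nr, nc) not in visited
        ]
        if not nbrs:
            stack.pop()
            continue
        nxt = nbrs[int(rng.integers(len(nbrs)))]
        passages.add(frozenset({cell, nxt}))
        visited.add(nxt)
        stack.append(nxt)

    # exit: a seed-chosen perimeter cell whose unique path spans the grid,
    # so every generated maze has comparable navigational complexity
    from collections import deque

    depth = {entry: 1}
    q = deque([entry])
    tmp = Maze(rows, cols, block_size, entry, entry, passages)
    while q:
        cell = q.popleft()
        for nb in tmp.neighbors(cell):
            if nb not in depth:
                depth[nb] = depth[cell] + 1
                q.append(nb)
    perimeter = [
        (r, c)
        for r in range(rows)
        for c in range(cols)
        if (r in (0, rows - 1) or c in (0, cols - 1)) and (r, c) != entry
    ]
    spanning = [c for c in perimeter if depth[c] >= max(rows, cols)]
    candidates = spanning or perimeter
    exit_cell = candidates[int(rng.integers(len(candidates)))]

    maze_id = f"maze_{rows}x{cols}_{seed}" if seed is not None else f"maze_{rows}x{cols}"
    return Maze(rows, cols, block_size, entry, exit_cell, passages, maze_id)


def solution_cells(maze: Maze) -> list[Cell]:
    """The unique simple entry→exit cell sequence (BFS on the passage tree)."""
    from collections import deque

    prev: dict[Cell, Cell] = {}
    seen = {maze.entry_cell}
    q = deque([maze.entry_cell])
    while q:
        cell = q.popleft()
        if cell == maze.exit_cell:
            break
        for nb in maze.neighbors(cell):
            if nb not in seen:
                seen.add(nb)
                prev[nb] = cell
                q.append(nb)
    if maze.exit_cell not in seen:
        raise MazeError("exit cell unreachable from entry — maze invariant violated")
    path = [maze.exit_cell]
    while path[-1] != maze.entry_cell:
        path.append(prev[path[-1]])
    return path[::-1]


def solution_path(maze: Maze) -> np.ndarray:
    """Ordered (n, 2) array of cell-center coordinates of the solution path."""
    return np.array([maze.cell_center(c) for c in solution_cells(maze)])


def count_simple_paths(maze: Maze) -> int:
    """Exhaustively count simple entry→exit paths (independent oracle).

    Walks every simple path by backtracking over the passage graph; on a
    7×8 spanning tree this is instant but it is written for correctness,
    not speed.
    """
    count = 0
    target = maze.exit_cell
    visited = {maze.entry_cell}

    def walk(cell: Cell) -> None:
        nonlocal count
        if cell == target:
            count += 1
            return
        for nb in maze.neighbors(cell):
            if nb not in visited:
                visited.add(nb)
                walk(nb)
                visited.remove(nb)

    walk(maze.entry_cell)
    return count


def completion_time(session, maze: Maze) -> float:
    """Maze completion time from the navel trajectory.

    Defined as the time from the first navel sample inside the entry
    cell to the first subsequent navel sample inside the exit cell.
    Raises :class:`IncompleteTraversal` if the trajectory never reaches
    the exit cell (or never enters the entry cell).
    """
    navel = session.streams["navel"]
    xy = navel.pos[:, :2]
    b = maze.block_size
    cols = np.floor(xy[:, 0] / b).astype(int)
    rows = np.floor(xy[:, 1] / b).astype(int)
    in_entry = (rows == maze.entry_cell[0]) & (cols == maze.entry_cell[1])
    in_exit = (rows == maze.exit_cell[0]) & (cols == maze.exit_cell[1])
    if not in_entry.any():
        raise IncompleteTraversal("trajectory never enters the maze entry cell")
    i0 = int(np.argmax(in_entry))
    later_exit = in_exit & (np.arange(len(xy)) >= i0)
    if not later_exit.any():
        raise IncompleteTraversal("trajectory never reaches the maze exit cell")
    i1 = int(np.argmax(later_exit))
    return float(navel.t[i1] - navel.t[i0])
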