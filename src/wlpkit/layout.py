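"""Rectangular multi-electrode-array geometry and its rook adjacency graph."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ElectrodeLayout"]


@dataclass(frozen=True)
class ElectrodeLayout:
    """A rows x cols electrode grid with uniform pitch.

    Channels are numbered row-major: channel k sits at row k // n_cols,
    column k % n_cols, position (col * pitch, row * pitch) in mm.  The
    default pitch is 0.1 mm (100 um), the MEA geometry this package
    emulates.  Adjacency is rook (4-neighbor): interior channels have 4
    neighbors, edges 3, corners 2.
    """

    n_rows: int
    n_cols: int
    pitch: float = 0.1

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and one column")
        if self.pitch <= 0:
            raise ValueError("pitch must be positive")

    @property
    def n_channels(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def positions(self) -> np.ndarray:
        """(n_channels, 2) array of (x, y) positions in mm, row-major order."""
        rows, cols = np.divmod(np.arange(self.n_channels), self.n_cols)
        return np.column_stack([cols * self.pitch, rows * self.pitch]).astype(float)

    def row_col(self, channel: int) -> tuple[int, int]:
        return divmod(channel, self.n_cols)

    def neighbors(self, channel: int) -> list[int]:
        """Rook neighbors of a channel (shared grid edge)."""
        r, c = self.row_col(channel)
        out = []
        for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
            rr, cc = r + dr, c + dc
            if 0 <= rr < self.n_rows and 0 <= cc < self.n_cols:
                out.append(rr * self.n_cols + cc)
        return out

    def adjacency(self) -> list[list[int]]:
        return [self.neighbors(k) for k in range(self.n_channels)]

    def distances_from(self, point: np.ndarray) -> np.ndarray:
        """Euclidean distance (mm) of every channel from a 2D point."""
        pos = self.positions
        point = np.asarray(point, dtype=float)
        return np.hypot(pos[:, 0] - point[0], pos[:, 1] - point[1])
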