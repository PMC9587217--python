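"""Electrode lattice geometry.

Utah-style microelectrode arrays are square lattices of penetrating
electrodes (8x8 contacts over 3.2 mm x 3.2 mm, or 10x10 over 4 mm x 4 mm
with the four corner sites unused).  All spatial analyses downstream
(radius of gyration, convex hulls, boundary pairs) work on the planar
coordinates stored here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ArrayLayout", "make_layout", "drop_corners"]


@dataclass(frozen=True)
class ArrayLayout:
    """Planar electrode lattice.

    Attributes
    ----------
    rows, cols : int
        Lattice dimensions.
    pitch : float
        Nearest-neighbour spacing in millimetres.
    coords : ndarray, shape (n_electrodes, 2)
        (x, y) position of each electrode in millimetres, row-major
        (electrode ``r * cols + c`` sits at ``(c * pitch, r * pitch)``).
    """

    rows: int
    cols: int
    pitch: float
    coords: np.ndarray = field(repr=False)

    @property
    def n_electrodes(self) -> int:
        return self.coords.shape[0]

    def lattice_neighbors(self, idx: int) -> list[int]:
        """Indices of the 4-neighbourhood of ``idx`` (one pitch away)."""
        d = np.linalg.norm(self.coords - self.coords[idx], axis=1)
        near = np.nonzero(np.abs(d - self.pitch) < 1e-9 * max(1.0, self.pitch))[0]
        return [int(i) for i in near]

    def neighbor_pairs(self) -> np.ndarray:
        """All unordered lattice nearest-neighbour pairs, shape (m, 2)."""
        diff = self.coords[:, None, :] - self.coords[None, :, :]
        d = np.linalg.norm(diff, axis=-1)
        i, j = np.nonzero(np.triu(np.abs(d - self.pitch) < 1e-9, k=1))
        return np.column_stack([i, j])


def make_layout(rows: int, cols: int, pitch: float) -> ArrayLayout:
    """Build a row-major rectangular electrode lattice.

    Parameters
    ----------
    rows, cols : int
        Number of lattice rows and columns; both must be >= 2.
    pitch : float
        Inter-electrode spacing in mm; must be positive.
    """
    if rows < 2 or cols < 2:
        raise ValueError(f"lattice must be at least 2x2, got {rows}x{cols}")
    if pitch <= 0:
        raise ValueError(f"pitch must be positive, got {pitch}")
    rr, cc = np.mgrid[0:rows, 0:cols]
    coords = np.column_stack([cc.ravel() * pitch, rr.ravel() * pitch]).astype(float)
    coords.setflags(write=False)
    return ArrayLayout(rows=rows, cols=cols, pitch=float(pitch), coords=coords)


def drop_corners(layout: ArrayLayout) -> tuple[ArrayLayout, np.ndarray]:
    """Remove the four corner sites of a rectangular lattice.

    Emulates the 96-contact arrays, which leave the corners of the 10x10
    grid unwired.  Returns the reduced layout and the retained indices
    into the original layout.
    """
    corners = {
        0,
        layout.cols - 1,
        (layout.rows - 1) * layout.cols,
        layout.rows * layout.cols - 1,
    }
    keep = np.array([i for i in range(layout.n_electrodes) if i not in corners])
    coords = layout.coords[keep].copy()
    coords.setflags(write=False)
    reduced = ArrayLayout(rows=layout.rows, cols=layout.cols, pitch=layout.pitch, coords=coords)
    return reduced, keep
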