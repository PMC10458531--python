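"""Spherically symmetric finite-volume grid for the two-region domain.

The domain is the radial interval [r_n, R2]: an inner needle cavity of
radius r_n, the tumor out to R1 and healthy tissue out to R2.  Cells are
spherical shells; the tumor/healthy interface R1 is always placed on a cell
face so material properties are uniform within every cell.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["RadialGrid"]


@dataclass
class RadialGrid:
    inner_radius: float  # r_n, m
    interface_radius: float  # R1, m
    outer_radius: float  # R2, m
    edges: np.ndarray  # (N+1,), strictly increasing, edges[0]=r_n, edges[-1]=R2
    centers: np.ndarray  # (N,)

    @classmethod
    def make(cls, inner_radius: float, interface_radius: float,
             outer_radius: float, n_cells: int) -> "RadialGrid":
        """Near-uniform grid with a face exactly at the interface radius."""
        if not (0 < inner_radius < interface_radius < outer_radius):
            raise ValueError(
                "radii must satisfy 0 < r_n < R1 < R2 "
                f"(got {inner_radius}, {interface_radius}, {outer_radius})"
            )
        if n_cells < 4:
            raise ValueError(f"need at least 4 cells (got {n_cells})")
        frac = (interface_radius - inner_radius) / (outer_radius - inner_radius)
        n_in = min(max(int(round(n_cells * frac)), 2), n_cells - 2)
        edges = np.concatenate([
            np.linspace(inner_radius, interface_radius, n_in + 1),
            np.linspace(interface_radius, outer_radius, n_cells - n_in + 1)[1:],
        ])
        centers = 0.5 * (edges[:-1] + edges[1:])
        return cls(inner_radius=inner_radius, interface_radius=interface_radius,
                   outer_radius=outer_radius, edges=edges, centers=centers)

    @property
    def n_cells(self) -> int:
        return self.centers.size

    @property
    def cell_volumes(self) -> np.ndarray:
        """Shell volumes (4/3) pi (r_out^3 - r_in^3)."""
        return 4.0 / 3.0 * np.pi * np.diff(self.edges**3)

    @property
    def face_areas(self) -> np.ndarray:
        """Sphere areas 4 pi r^2 at every face, shape (N+1,)."""
        return 4.0 * np.pi * self.edges**2

    @property
    def tumor_mask(self) -> np.ndarray:
        """Boolean per cell: centre inside the tumor region."""
        return self.centers < self.interface_radius

    def per_cell(self, tumor_value: float, healthy_value: float) -> np.ndarray:
        """Broadcast a (tumor, healthy) property pair onto the cells."""
        return np.where(self.tumor_mask, tumor_value, healthy_value)
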