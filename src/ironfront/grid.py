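"""Uniform finite-volume discretization of the agar disc in the radial coordinate."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["RadialGrid"]


@dataclass(frozen=True)
class RadialGrid:
    """Cell-centered uniform grid on [0, R_dish].

    Cell i spans [i*dr, (i+1)*dr] with center r_i = (i + 1/2)*dr.  The annulus
    area of cell i is exactly 2*pi*r_i*dr (per unit agar depth), so the
    discrete mass functional 2*pi*sum(r_i * f_i)*dr is an exact annular
    quadrature of a piecewise-constant field.
    """

    n_cells: int
    dr: float

    def __post_init__(self) -> None:
        if self.n_cells < 2:
            raise ValueError("need at least 2 radial cells")
        if not self.dr > 0:
            raise ValueError("dr must be > 0")

    @classmethod
    def from_radius(cls, R_dish: float, n_cells: int) -> "RadialGrid":
        return cls(n_cells=n_cells, dr=R_dish / n_cells)

    @property
    def R_dish(self) -> float:
        return self.n_cells * self.dr

    @property
    def r(self) -> np.ndarray:
        """Cell centers."""
        return (np.arange(self.n_cells) + 0.5) * self.dr

    @property
    def edges(self) -> np.ndarray:
        """Cell edges, r=0 .. R_dish inclusive."""
        return np.arange(self.n_cells + 1) * self.dr

    @property
    def cell_areas(self) -> np.ndarray:
        """Exact annulus areas 2*pi*r_i*dr (per unit depth)."""
        return 2.0 * np.pi * self.r * self.dr

    def total(self, f: np.ndarray) -> float:
        """Annular quadrature 2*pi*sum(r_i * f_i * dr) of a cell field."""
        return float(np.dot(self.cell_areas, f))

    def coverage(self, s: float) -> np.ndarray:
        """Fraction of each cell's annulus area covered by the disc r < s.

        Sub-cell front position is resolved by exact partial-annulus areas,
        used to weight biomass-dependent source terms.
        """
        edges = self.edges
        r_in, r_out = edges[:-1], edges[1:]
        covered = np.clip(s, r_in, r_out) ** 2 - r_in**2
        return covered / (r_out**2 - r_in**2)
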