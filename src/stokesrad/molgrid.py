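"""Grid-based molecular shape: occupancy grids, van der Waals volume, r_g.

A conformer's shape is discretized as the set of cubic-grid points whose
centers fall inside at least one atomic van der Waals sphere (the union of
spheres).  The occupied-point count gives the van der Waals volume
(n * spacing^3) and, treating mass as evenly distributed over the points,
the radius of gyration

    r_g = sqrt( sum_i |p_i - centroid|^2 / n ).

Both quantities converge as the spacing shrinks; at 0.1 Å spacing the
volume and r_g of analytic spheres agree with the closed forms to well
under 1%.  The default spacing of 0.2 Å keeps the volume error of
molecule-sized solids at or below the 1% level at desk-scale cost.

``make_analytic_solid`` builds grids for spheres and sphere unions so that
closed-form values (sphere volume 4/3 pi R^3, sphere r_g = sqrt(3/5) R, the
two-sphere union volume) can serve as test oracles.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .chem_input import InputError
from .conformers import Conformer

__all__ = [
    "BONDI_RADII",
    "OccupancyGrid",
    "VdwRadiiTable",
    "UnsupportedElementError",
    "build_grid",
    "vdw_volume",
    "gyration_radius",
    "make_analytic_solid",
    "sphere_volume",
    "sphere_gyration_radius",
    "two_sphere_union_volume",
    "DEFAULT_SPACING_A",
]

#: Default grid spacing in Å.
DEFAULT_SPACING_A = 0.2

#: Bondi (1964) van der Waals radii, Å.
BONDI_RADII: dict[str, float] = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "F": 1.47,
    "P": 1.80,
    "S": 1.80,
    "Cl": 1.75,
    "Br": 1.85,
    "I": 1.98,
}


class UnsupportedElementError(KeyError):
    """Raised when no van der Waals radius is available for an element."""


@dataclass(frozen=True)
class VdwRadiiTable:
    """Element symbol -> van der Waals radius (Å); radii must lie in (0.5, 3.0)."""

    radii: Mapping[str, float]
    name: str = "custom"

    def __post_init__(self) -> None:
        for elem, r in self.radii.items():
            if not (0.5 < r < 3.0):
                raise InputError(f"implausible vdW radius {r} Å for {elem!r}")
        missing = {"H", "C", "N", "O", "S", "Cl"} - set(self.radii)
        if missing:
            raise InputError(f"radii table must cover at least H,C,N,O,S,Cl; missing {sorted(missing)}")

    def __getitem__(self, element: str) -> float:
        try:
            return self.radii[element]
        except KeyError:
            raise UnsupportedElementError(
                f"no van der Waals radius for element {element!r}"
            ) from None


BONDI_TABLE = VdwRadiiTable(BONDI_RADII, name="bondi1964")


@dataclass(frozen=True)
class OccupancyGrid:
    """Grid points (centers) inside the van der Waals envelope of one solid."""

    spacing: float
    origin: np.ndarray
    occupied_points: np.ndarray  # (n, 3) Å

    @property
    def n_occupied(self) -> int:
        return int(self.occupied_points.shape[0])

    @property
    def volume(self) -> float:
        return self.n_occupied * self.spacing**3


def _occupancy(
    centers: np.ndarray, radii: np.ndarray, spacing: float
) -> OccupancyGrid:
    """Mark grid-point centers inside the union of spheres (centers, radii)."""
    rmax = radii.max()
    lo = (centers - radii[:, None]).min(axis=0) - spacing
    hi = (centers + radii[:, None]).max(axis=0) + spacing
    axes = [np.arange(lo[d], hi[d] + 0.5 * spacing, spacing) for d in range(3)]
    shape = tuple(len(ax) for ax in axes)
    occupied = np.zeros(shape, dtype=bool)
    # Per-atom sub-box test keeps memory at O(grid) and work at O(atoms * r^3).
    for c, r in zip(centers, radii):
        idx_lo = [np.searchsorted(axes[d], c[d] - r) for d in range(3)]
        idx_hi = [np.searchsorted(axes[d], c[d] + r, side="right") for d in range(3)]
        sub = [axes[d][idx_lo[d]: idx_hi[d]] for d in range(3)]
        if any(len(s) == 0 for s in sub):
            continue
        dx2 = (sub[0] - c[0]) ** 2
        dy2 = (sub[1] - c[1]) ** 2
        dz2 = (sub[2] - c[2]) ** 2
        inside = (
            dx2[:, None, None] + dy2[None, :, None] + dz2[None, None, :]
        ) <= r * r
        occupied[
            idx_lo[0]: idx_hi[0], idx_lo[1]: idx_hi[1], idx_lo[2]: idx_hi[2]
        ] |= inside
    ii, jj, kk = np.nonzero(occupied)
    points = np.column_stack([axes[0][ii], axes[1][jj], axes[2][kk]])
    return OccupancyGrid(spacing=spacing, origin=lo.copy(), occupied_points=points)


def build_grid(
    conformer: Conformer,
    spacing: float = DEFAULT_SPACING_A,
    radii: VdwRadiiTable = BONDI_TABLE,
) -> OccupancyGrid:
    """Occupancy grid of a conformer's van der Waals envelope.

    A grid point is occupied iff its center lies within the vdW radius of at
    least one atom.  Hydrogens are included in the envelope.
    """
    if spacing <= 0:
        raise InputError("grid spacing must be positive")
    if len(conformer.elements) == 0:
        raise InputError("conformer has no atoms")
    r = np.array([radii[e] for e in conformer.elements])
    return _occupancy(np.asarray(conformer.coords, dtype=float), r, spacing)


def vdw_volume(grid: OccupancyGrid) -> float:
    """Van der Waals volume in ų: occupied-point count times cell volume."""
    if grid.n_occupied == 0:
        raise InputError("empty occupancy grid")
    return grid.volume


def gyration_radius(grid: OccupancyGrid) -> float:
    """Radius of gyration (Å) of the grid points with unit mass per point."""
    if grid.n_occupied == 0:
        raise InputError("empty occupancy grid")
    pts = grid.occupied_points
    centroid = pts.mean(axis=0)
    return float(np.sqrt(((pts - centroid) ** 2).sum(axis=1).mean()))


def make_analytic_solid(
    shape: str,
    radii: Sequence[float],
    centers: Sequence[Sequence[float]] | None = None,
    spacing: float = DEFAULT_SPACING_A,
) -> OccupancyGrid:
    """Occupancy grid of an analytic solid (``"sphere"`` or ``"sphere-union"``).

    Uses the same occupancy rule as :func:`build_grid`; intended as a
    fixture generator for oracle tests against closed-form volumes.
    """
    radii = np.asarray(radii, dtype=float)
    if np.any(radii <= 0):
        raise InputError("sphere radii must be positive")
    if shape == "sphere":
        if radii.size != 1:
            raise InputError("a sphere takes exactly one radius")
        centers = np.zeros((1, 3)) if centers is None else np.asarray(centers, float)
    elif shape == "sphere-union":
        if centers is None:
            raise InputError("sphere-union requires centers")
        centers = np.asarray(centers, dtype=float)
        if centers.shape != (radii.size, 3):
            raise InputError("centers must be (n_spheres, 3)")
    else:
        raise InputError(f"unknown shape {shape!r}")
    if spacing <= 0:
        raise InputError("grid spacing must be positive")
    return _occupancy(centers, radii, spacing)


def sphere_volume(r: float) -> float:
    """Closed-form sphere volume 4/3 pi r^3 (test oracle)."""
    return 4.0 / 3.0 * np.pi * r**3


def sphere_gyration_radius(r: float) -> float:
    """Closed-form r_g of a uniform solid sphere, sqrt(3/5) r (test oracle)."""
    return np.sqrt(3.0 / 5.0) * r


def two_sphere_union_volume(r1: float, r2: float, d: float) -> float:
    """Closed-form volume of the union of two spheres at center distance d.

    Subtracts the lens-shaped intersection from the summed volumes; handles
    the disjoint and fully-contained limits.  Test oracle only.
    """
    v = sphere_volume(r1) + sphere_volume(r2)
    if d >= r1 + r2:
        return v
    if d <= abs(r1 - r2):
        return sphere_volume(max(r1, r2))
    lens = (
        np.pi
        * (r1 + r2 - d) ** 2
        * (d**2 + 2 * d * (r1 + r2) - 3 * (r1 - r2) ** 2)
        / (12 * d)
    )
    return v - lens
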