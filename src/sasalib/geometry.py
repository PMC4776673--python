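"""Spatial primitives: cell-list neighbor search and sphere point sets.

Contact detection bins atoms into a cubic grid whose cell side is at least
twice the largest extended radius (atom radius + probe), so every pair of
intersecting extended spheres lies in the same or adjacent cells and a
neighbor query only scans the 3x3x3 cell neighborhood.  This makes contact
finding O(N) in atom count for bounded-density systems.

The golden-angle (Fibonacci) spiral provides near-uniform test-point sets
of arbitrary size on the unit sphere for the test-point SASA algorithm.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "CellList",
    "SpherePoints",
    "build_cell_list",
    "neighbors",
    "all_neighbors",
    "fibonacci_sphere",
]

#: golden angle, radians
_GOLDEN_ANGLE = np.pi * (3.0 - np.sqrt(5.0))


@dataclass
class CellList:
    """Cubic spatial hash of atom indices."""

    cell_side: float
    origin: np.ndarray
    grid_shape: tuple[int, int, int]
    cell_membership: dict[tuple[int, int, int], np.ndarray]

    def cell_of(self, point: np.ndarray) -> tuple[int, int, int]:
        idx = np.floor((np.asarray(point) - self.origin) / self.cell_side).astype(int)
        idx = np.clip(idx, 0, np.array(self.grid_shape) - 1)
        return tuple(int(i) for i in idx)


@dataclass
class SpherePoints:
    """A deterministic set of unit vectors approximating uniform coverage."""

    points: np.ndarray
    count: int


def build_cell_list(
    coordinates: np.ndarray, radii: np.ndarray, probe_radius: float
) -> CellList:
    """Bin atoms into cells of side 2*(max radius + probe).

    With that side, any two extended spheres that intersect have centers
    closer than one cell side, hence lie in the same or adjacent cells.
    """
    coordinates = np.asarray(coordinates, dtype=float)
    radii = np.asarray(radii, dtype=float)
    if coordinates.ndim != 2 or coordinates.shape[1] != 3 or coordinates.shape[0] == 0:
        raise ValueError("coordinates must be a non-empty (n, 3) array")
    if radii.shape[0] != coordinates.shape[0]:
        raise ValueError("radii length must match coordinates")
    if np.any(radii < 0) or probe_radius < 0:
        raise ValueError("radii and probe radius must be non-negative")

    cell_side = 2.0 * (float(radii.max()) + probe_radius)
    if cell_side <= 0.0:
        cell_side = 1.0  # all-zero radii: any positive side works
    origin = coordinates.min(axis=0)
    extent = coordinates.max(axis=0) - origin
    grid_shape = tuple(int(n) for n in np.maximum(np.floor(extent / cell_side) + 1, 1))

    idx = np.floor((coordinates - origin) / cell_side).astype(int)
    idx = np.clip(idx, 0, np.array(grid_shape) - 1)
    membership: dict[tuple[int, int, int], list[int]] = {}
    for atom_index, cell in enumerate(map(tuple, idx)):
        membership.setdefault(cell, []).append(atom_index)
    return CellList(
        cell_side=cell_side,
        origin=origin,
        grid_shape=grid_shape,
        cell_membership={c: np.array(v, dtype=int) for c, v in membership.items()},
    )


def _candidate_indices(cell_list: CellList, cell: tuple[int, int, int]) -> np.ndarray:
    chunks = []
    cx, cy, cz = cell
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                members = cell_list.cell_membership.get((cx + dx, cy + dy, cz + dz))
                if members is not None:
                    chunks.append(members)
    return np.concatenate(chunks) if chunks else np.empty(0, dtype=int)


def neighbors(
    cell_list: CellList,
    coordinates: np.ndarray,
    radii: np.ndarray,
    probe_radius: float,
    atom_index: int,
) -> set[int]:
    """Indices j != i with ||x_i - x_j|| < r_i + r_j + 2*probe.

    The inequality is strict: tangent extended spheres overlap in a set of
    measure zero and are not neighbors.
    """
    coordinates = np.asarray(coordinates, dtype=float)
    radii = np.asarray(radii, dtype=float)
    n = coordinates.shape[0]
    if not 0 <= atom_index < n:
        raise IndexError(f"atom index {atom_index} out of range for {n} atoms")
    candidates = _candidate_indices(cell_list, cell_list.cell_of(coordinates[atom_index]))
    candidates = candidates[candidates != atom_index]
    if candidates.size == 0:
        return set()
    delta = coordinates[candidates] - coordinates[atom_index]
    cutoff = radii[atom_index] + radii[candidates] + 2.0 * probe_radius
    hits = np.einsum("ij,ij->i", delta, delta) < cutoff**2
    return set(int(j) for j in candidates[hits])


def all_neighbors(
    coordinates: np.ndarray, radii: np.ndarray, probe_radius: float
) -> list[np.ndarray]:
    """Neighbor lists for every atom (sorted index arrays), via one cell list."""
    coordinates = np.asarray(coordinates, dtype=float)
    radii = np.asarray(radii, dtype=float)
    cell_list = build_cell_list(coordinates, radii, probe_radius)
    out: list[np.ndarray] = []
    for i in range(coordinates.shape[0]):
        candidates = _candidate_indices(cell_list, cell_list.cell_of(coordinates[i]))
        candidates = candidates[candidates != i]
        if candidates.size == 0:
            out.append(np.empty(0, dtype=int))
            continue
        delta = coordinates[candidates] - coordinates[i]
        cutoff = radii[i] + radii[candidates] + 2.0 * probe_radius
        hits = candidates[np.einsum("ij,ij->i", delta, delta) < cutoff**2]
        hits.sort()
        out.append(hits)
    return out


def fibonacci_sphere(n: int) -> SpherePoints:
    """n unit vectors on the golden-angle spiral.

    Point k has z = 1 - (2k+1)/n (band midpoints, so poles are avoided)
    and azimuth k times the golden angle.  Deterministic in n.
    """
    if n < 1:
        raise ValueError(f"need at least one point, got {n}")
    k = np.arange(n, dtype=float)
    z = 1.0 - (2.0 * k + 1.0) / n
    rho = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    phi = k * _GOLDEN_ANGLE
    points = np.column_stack((rho * np.cos(phi), rho * np.sin(phi), z))
    return SpherePoints(points=points, count=n)
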