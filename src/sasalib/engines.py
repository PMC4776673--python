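"""Solvent accessible surface area engines.

Two classical approximations of the surface traced by the center of a
spherical probe rolling over a set of spheres:

* **Lee & Richards slicing** — every extended sphere (atom radius + probe)
  is cut into ``n_slices`` equal slabs along z; in each slab-midplane the
  exposed fraction of the atom's circle is found by merging the angular
  intervals buried by neighboring circles, and contributes
  ``f * 2*pi*R * dz`` (the Archimedes strip area, which makes an isolated
  sphere exact at any slice count).

* **Shrake & Rupley test points** — ``n_points`` golden-angle spiral
  points are placed on every extended sphere; the accessible fraction is
  the fraction of points lying strictly outside every neighbor's extended
  sphere.

Both engines treat each atom independently after a shared cell-list
contact search, so the per-atom loop can be partitioned over workers
without changing any result: accumulation order within an atom is fixed
(ascending slice/point index) and atoms are written by index.

Degenerate configurations are resolved deterministically: tangent spheres
do not occlude each other, and of two atoms with coincident centers and
equal extended radii only the higher-index one counts as buried.
"""

from __future__ import annotations

from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field, replace
from enum import Enum

import numpy as np

from .geometry import all_neighbors, fibonacci_sphere
from .structure import Structure

__all__ = [
    "Algorithm",
    "Parameters",
    "SasaResult",
    "calc_structure",
    "calc_coordinates",
    "sasa_lee_richards",
    "sasa_shrake_rupley",
    "error_per_atom",
]


class Algorithm(str, Enum):
    LEE_RICHARDS = "lee_richards"
    SHRAKE_RUPLEY = "shrake_rupley"


#: default probe radius, Å (water)
DEFAULT_PROBE_RADIUS = 1.4
#: default slices per atom for Lee & Richards
DEFAULT_N_SLICES = 20
#: default test points per atom for Shrake & Rupley
DEFAULT_N_POINTS = 100
#: default worker count for the per-atom loop
DEFAULT_N_WORKERS = 2


@dataclass(frozen=True)
class Parameters:
    """Calculation parameters with the library defaults."""

    algorithm: Algorithm = Algorithm.LEE_RICHARDS
    probe_radius: float = DEFAULT_PROBE_RADIUS
    n_slices: int = DEFAULT_N_SLICES
    n_points: int = DEFAULT_N_POINTS
    n_workers: int = DEFAULT_N_WORKERS

    def __post_init__(self) -> None:
        object.__setattr__(self, "algorithm", Algorithm(self.algorithm))
        if self.probe_radius < 0:
            raise ValueError("probe radius must be non-negative")
        if self.n_slices < 1 or self.n_points < 1 or self.n_workers < 1:
            raise ValueError("n_slices, n_points and n_workers must be >= 1")

    @property
    def resolution(self) -> int:
        """Slices (L&R) or test points (S&R), whichever is in effect."""
        if self.algorithm is Algorithm.LEE_RICHARDS:
            return self.n_slices
        return self.n_points

    def with_resolution(self, n: int) -> "Parameters":
        if self.algorithm is Algorithm.LEE_RICHARDS:
            return replace(self, n_slices=n)
        return replace(self, n_points=n)


@dataclass
class SasaResult:
    """Per-atom areas (Å², matching input atom order) plus their total."""

    per_atom_area: np.ndarray
    parameters_used: Parameters = field(default_factory=Parameters)

    def __post_init__(self) -> None:
        self.per_atom_area = np.asarray(self.per_atom_area, dtype=float)

    @property
    def total(self) -> float:
        return float(np.sum(self.per_atom_area))

    def __len__(self) -> int:
        return int(self.per_atom_area.shape[0])


def _merged_arc_length(intervals: list[tuple[float, float]]) -> float:
    """Total length of the union of angular intervals on [0, 2*pi).

    Intervals may extend past the branch cut; each is normalized to start
    in [0, 2*pi) and split there if it wraps.
    """
    two_pi = 2.0 * np.pi
    segments: list[tuple[float, float]] = []
    for start, end in intervals:
        length = end - start
        if length >= two_pi:
            return two_pi
        start %= two_pi
        end = start + length
        if end > two_pi:
            segments.append((start, two_pi))
            segments.append((0.0, end - two_pi))
        else:
            segments.append((start, end))
    segments.sort()
    total = 0.0
    current_start, current_end = segments[0]
    for start, end in segments[1:]:
        if start > current_end:
            total += current_end - current_start
            current_start, current_end = start, end
        elif end > current_end:
            current_end = end
    total += current_end - current_start
    return min(total, two_pi)


def _filter_occluders(
    i: int, nbrs: np.ndarray, coordinates: np.ndarray, extended: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Neighbor positions/radii that may occlude atom i.

    Drops higher-index neighbors that coincide with atom i at equal
    extended radius (the deterministic tie-break: only the higher-index
    twin is buried).
    """
    delta = coordinates[nbrs] - coordinates[i]
    d2 = np.einsum("ij,ij->i", delta, delta)
    coincident_twin = (d2 == 0.0) & (extended[nbrs] == extended[i]) & (nbrs > i)
    keep = ~coincident_twin
    return nbrs[keep], delta[keep]


def _lr_atom_area(
    i: int,
    coordinates: np.ndarray,
    extended: np.ndarray,
    nbrs: np.ndarray,
    n_slices: int,
) -> float:
    r_i = extended[i]
    dz = 2.0 * r_i / n_slices
    strip = 2.0 * np.pi * r_i * dz  # full-circle strip area, any slab
    if nbrs.size == 0:
        return strip * n_slices  # telescopes to exactly 4*pi*R^2
    nbrs, delta = _filter_occluders(i, nbrs, coordinates, extended)
    if nbrs.size == 0:
        return strip * n_slices

    delta_xy = np.hypot(delta[:, 0], delta[:, 1])  # in-plane center distance
    beta = np.arctan2(delta[:, 1], delta[:, 0])  # in-plane center azimuth
    r_j = extended[nbrs]

    # Slab midplanes relative to atom center.
    z_mid = (np.arange(n_slices) + 0.5) * dz - r_i
    rho_i = np.sqrt(np.maximum(0.0, r_i * r_i - z_mid * z_mid))

    dz_j = z_mid[:, None] - delta[None, :, 2]  # (slices, neighbors)
    disc = r_j[None, :] ** 2 - dz_j**2
    in_plane = disc > 0.0
    rho_j = np.sqrt(np.where(in_plane, disc, 0.0))

    full = in_plane & (delta_xy[None, :] + rho_i[:, None] <= rho_j)
    partial = (
        in_plane
        & ~full
        & (delta_xy[None, :] < rho_i[:, None] + rho_j)
        & (delta_xy[None, :] + rho_j > rho_i[:, None])
    )

    # Buried angular half-widths for all partially-overlapping pairs at
    # once; the per-slice work below is only interval merging.
    with np.errstate(divide="ignore", invalid="ignore"):
        cos_alpha = (delta_xy[None, :] ** 2 + rho_i[:, None] ** 2 - rho_j**2) / (
            2.0 * delta_xy[None, :] * rho_i[:, None]
        )
    alpha = np.arccos(np.clip(cos_alpha, -1.0, 1.0))
    lo = (beta[None, :] - alpha).tolist()
    hi = (beta[None, :] + alpha).tolist()

    slice_fully_buried = full.any(axis=1)
    partial_lists = [np.flatnonzero(row) for row in partial]

    area = 0.0
    two_pi = 2.0 * np.pi
    for s in range(n_slices):
        if slice_fully_buried[s]:
            continue
        js = partial_lists[s]
        if js.size == 0:
            area += strip
            continue
        lo_s, hi_s = lo[s], hi[s]
        buried = _merged_arc_length([(lo_s[j], hi_s[j]) for j in js])
        area += strip * (1.0 - buried / two_pi)
    return area


def _sr_atom_area(
    i: int,
    coordinates: np.ndarray,
    extended: np.ndarray,
    nbrs: np.ndarray,
    unit_points: np.ndarray,
) -> float:
    r_i = extended[i]
    sphere_area = 4.0 * np.pi * r_i * r_i
    if nbrs.size == 0:
        return sphere_area
    nbrs, delta = _filter_occluders(i, nbrs, coordinates, extended)
    if nbrs.size == 0:
        return sphere_area
    # A coincident occluder of equal or larger extended radius buries the
    # whole sphere; decide it exactly rather than through the point test,
    # where d == R_j would be at the mercy of rounding.
    coincident = np.einsum("ij,ij->i", delta, delta) == 0.0
    if np.any(coincident & (extended[nbrs] >= r_i)):
        return 0.0
    points = unit_points * r_i  # relative to atom center
    # (points, neighbors) squared distances; accessible iff strictly
    # outside every neighbor sphere.
    diff = points[:, None, :] - delta[None, :, :]
    d2 = np.einsum("pnk,pnk->pn", diff, diff)
    accessible = np.all(d2 > (extended[nbrs] ** 2)[None, :], axis=1)
    return sphere_area * (int(accessible.sum()) / unit_points.shape[0])


def _run_per_atom(worker, n_atoms: int, n_workers: int) -> np.ndarray:
    """Run `worker(i) -> area` over all atoms, assembling by index.

    The partition over workers cannot affect values: atoms are independent
    and each area is written to its own slot.
    """
    areas = np.empty(n_atoms, dtype=float)

    def run_chunk(indices: np.ndarray) -> None:
        for i in indices:
            areas[i] = worker(int(i))

    if n_workers <= 1 or n_atoms < 2:
        run_chunk(np.arange(n_atoms))
    else:
        chunks = np.array_split(np.arange(n_atoms), min(n_workers, n_atoms))
        with ThreadPoolExecutor(max_workers=len(chunks)) as pool:
            for future in [pool.submit(run_chunk, c) for c in chunks]:
                future.result()
    return areas


def _validate_inputs(coordinates, radii, probe_radius) -> tuple[np.ndarray, np.ndarray]:
    coordinates = np.ascontiguousarray(coordinates, dtype=float)
    radii = np.asarray(radii, dtype=float)
    if coordinates.ndim != 2 or coordinates.shape[1] != 3 or coordinates.shape[0] < 1:
        raise ValueError("coordinates must be a non-empty (n, 3) array")
    if radii.shape != (coordinates.shape[0],):
        raise ValueError("radii must match coordinates in length")
    if np.any(radii < 0) or probe_radius < 0:
        raise ValueError("radii and probe radius must be non-negative")
    return coordinates, radii


def sasa_lee_richards(
    coordinates,
    radii,
    probe_radius: float = DEFAULT_PROBE_RADIUS,
    n_slices: int = DEFAULT_N_SLICES,
    n_workers: int = 1,
) -> np.ndarray:
    """Per-atom SASA (Å²) by per-atom slicing with ``n_slices`` slabs each.

    Small atoms automatically get thinner slabs than large ones because the
    slab thickness is 2R/n_slices per atom.
    """
    if n_slices < 1:
        raise ValueError("n_slices must be >= 1")
    coordinates, radii = _validate_inputs(coordinates, radii, probe_radius)
    extended = radii + probe_radius
    nbr_lists = all_neighbors(coordinates, radii, probe_radius)

    def worker(i: int) -> float:
        return _lr_atom_area(i, coordinates, extended, nbr_lists[i], n_slices)

    return _run_per_atom(worker, coordinates.shape[0], n_workers)


def sasa_shrake_rupley(
    coordinates,
    radii,
    probe_radius: float = DEFAULT_PROBE_RADIUS,
    n_points: int = DEFAULT_N_POINTS,
    n_workers: int = 1,
) -> np.ndarray:
    """Per-atom SASA (Å²) from ``n_points`` spiral test points per atom."""
    if n_points < 1:
        raise ValueError("n_points must be >= 1")
    coordinates, radii = _validate_inputs(coordinates, radii, probe_radius)
    extended = radii + probe_radius
    nbr_lists = all_neighbors(coordinates, radii, probe_radius)
    unit_points = fibonacci_sphere(n_points).points

    def worker(i: int) -> float:
        return _sr_atom_area(i, coordinates, extended, nbr_lists[i], unit_points)

    return _run_per_atom(worker, coordinates.shape[0], n_workers)


def calc_coordinates(coordinates, radii, parameters: Parameters | None = None) -> SasaResult:
    """SASA of a bare sphere set (no classification involved)."""
    params = parameters or Parameters()
    if params.algorithm is Algorithm.LEE_RICHARDS:
        areas = sasa_lee_richards(
            coordinates, radii, params.probe_radius, params.n_slices, params.n_workers
        )
    else:
        areas = sasa_shrake_rupley(
            coordinates, radii, params.probe_radius, params.n_points, params.n_workers
        )
    return SasaResult(per_atom_area=areas, parameters_used=params)


def calc_structure(structure: Structure, parameters: Parameters | None = None) -> SasaResult:
    """SASA of a structure whose atoms already carry assigned radii.

    Result order matches atom order.  Raises if any radius is unassigned.
    """
    return calc_coordinates(structure.coordinates(), structure.radii(), parameters)


def error_per_atom(total_area: float, reference_area: float, n_atoms: int) -> float:
    """|A - A_ref| / N in Å² per atom, the standard precision measure.

    The conventional reference is the Lee & Richards result at 1000 slices
    per atom.
    """
    if n_atoms < 1:
        raise ValueError("n_atoms must be >= 1")
    return abs(total_area - reference_area) / n_atoms
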