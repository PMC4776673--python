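"""Shared fixtures and independent oracles.

The oracles here deliberately avoid the library's own code paths: neighbor
sets by an all-pairs scan, sphere areas by Monte-Carlo surface sampling.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

import sasalib

settings.register_profile("suite", deadline=None, derandomize=True)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def protor():
    return sasalib.builtin_protor_classifier()


@pytest.fixture(scope="session")
def complex_structure(protor):
    """A classified synthetic protein/RNA complex (chains A, B, X, Y)."""
    from sasalib.synthetic import protein_rna_complex_pdb

    structure = sasalib.read_pdb(protein_rna_complex_pdb(seed=7), source_label="complex")
    sasalib.assign(protor, structure)
    return structure


def brute_force_neighbors(coordinates, radii, probe, i):
    """All-pairs neighbor oracle: strict cutoff r_i + r_j + 2*probe."""
    coordinates = np.asarray(coordinates, float)
    radii = np.asarray(radii, float)
    out = set()
    for j in range(coordinates.shape[0]):
        if j == i:
            continue
        d = np.linalg.norm(coordinates[i] - coordinates[j])
        if d < radii[i] + radii[j] + 2.0 * probe:
            out.add(j)
    return out


def monte_carlo_sphere_areas(coordinates, radii, probe, n_points, seed):
    """Per-sphere accessible area by uniform random surface sampling.

    Returns (areas, standard_errors).  Independent of the deterministic
    engines: points are sampled from an isotropic Gaussian, not a spiral.
    """
    rng = np.random.default_rng(seed)
    coordinates = np.asarray(coordinates, float)
    extended = np.asarray(radii, float) + probe
    n = coordinates.shape[0]
    areas = np.empty(n)
    errors = np.empty(n)
    for i in range(n):
        directions = rng.normal(size=(n_points, 3))
        directions /= np.linalg.norm(directions, axis=1, keepdims=True)
        points = coordinates[i] + extended[i] * directions
        accessible = np.ones(n_points, dtype=bool)
        for j in range(n):
            if j == i:
                continue
            d2 = np.sum((points - coordinates[j]) ** 2, axis=1)
            accessible &= d2 > extended[j] ** 2
        fraction = accessible.mean()
        full = 4.0 * np.pi * extended[i] ** 2
        areas[i] = fraction * full
        errors[i] = full * np.sqrt(max(fraction * (1 - fraction), 1e-12) / n_points)
    return areas, errors


@pytest.fixture
def two_atom_case():
    """The canonical two-sphere configuration used throughout."""
    return (
        np.array([[1.0, 1.0, 1.0], [2.0, 2.0, 2.0]]),
        np.array([2.0, 3.0]),
        1.4,
    )
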