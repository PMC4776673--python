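"""The two SASA engines against closed-form and each other."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from sasalib import (
    Algorithm,
    Parameters,
    calc_coordinates,
    calc_structure,
    error_per_atom,
    read_pdb,
    sasa_lee_richards,
    sasa_shrake_rupley,
)
from sasalib.engines import _merged_arc_length
from sasalib.synthetic import random_packing, two_sphere_analytic

ENGINES = {
    "lee_richards": lambda c, r, p, n: sasa_lee_richards(c, r, p, n),
    "shrake_rupley": lambda c, r, p, n: sasa_shrake_rupley(c, r, p, n),
}


@pytest.mark.parametrize("engine", ENGINES)
@pytest.mark.parametrize("resolution", [1, 7, 20, 128])
def test_isolated_sphere_is_exact_at_any_resolution(engine, resolution):
    area = ENGINES[engine](np.array([[3.0, -2.0, 7.0]]), np.array([2.0]), 1.4, resolution)
    assert area[0] == pytest.approx(4.0 * np.pi * 3.4**2, rel=1e-12)


def test_two_sphere_high_resolution_matches_cap_formula(two_atom_case):
    coords, radii, probe = two_atom_case
    expected = two_sphere_analytic(coords[0], radii[0], coords[1], radii[1], probe)
    lr = sasa_lee_richards(coords, radii, probe, 1000)
    sr = sasa_shrake_rupley(coords, radii, probe, 5000)
    for k in range(2):
        assert lr[k] == pytest.approx(expected[k], rel=1e-3)
        assert sr[k] == pytest.approx(expected[k], rel=5e-3)


@pytest.mark.parametrize("engine", ENGINES)
def test_fully_contained_sphere_has_zero_area(engine):
    coords = np.zeros((2, 3))
    radii = np.array([1.0, 3.0])
    areas = ENGINES[engine](coords, radii, 1.4, 200)
    assert areas[0] == 0.0
    assert areas[1] == pytest.approx(4.0 * np.pi * 4.4**2, rel=1e-12)


@pytest.mark.parametrize("engine", ENGINES)
def test_coincident_equal_spheres_bury_higher_index(engine):
    coords = np.zeros((2, 3))
    radii = np.array([2.0, 2.0])
    areas = ENGINES[engine](coords, radii, 1.4, 200)
    assert areas[0] == pytest.approx(4.0 * np.pi * 3.4**2, rel=1e-12)
    assert areas[1] == 0.0


@pytest.mark.parametrize("engine", ENGINES)
@pytest.mark.parametrize("seed", [0, 1])
def test_per_atom_bounds(engine, seed):
    packing = random_packing(150, seed=seed)
    areas = ENGINES[engine](packing.coordinates, packing.radii, 1.4, 40)
    upper = 4.0 * np.pi * (packing.radii + 1.4) ** 2
    assert np.all(areas >= 0.0)
    assert np.all(areas <= upper * (1 + 1e-12))


@pytest.mark.parametrize("engine", ENGINES)
def test_monotonic_burial_on_atom_insertion(engine):
    packing = random_packing(60, box_side=18.0, seed=5)
    before = ENGINES[engine](packing.coordinates, packing.radii, 1.4, 50)
    coords = np.vstack([packing.coordinates, [[9.0, 9.0, 9.0]]])
    radii = np.append(packing.radii, 2.0)
    after = ENGINES[engine](coords, radii, 1.4, 50)
    assert np.all(after[:60] <= before + 1e-12)


@pytest.mark.parametrize("engine", ENGINES)
def test_translation_invariance_bitwise(engine):
    # Coordinates on a dyadic grid translated by integers: the arithmetic
    # is exact, so areas must be bit-identical.
    packing = random_packing(80, seed=2)
    coords = np.round(packing.coordinates * 2**20) / 2**20
    translated = coords + np.array([8.0, -16.0, 4.0])
    a = ENGINES[engine](coords, packing.radii, 1.4, 30)
    b = ENGINES[engine](translated, packing.radii, 1.4, 30)
    np.testing.assert_array_equal(a, b)


@pytest.mark.parametrize("engine", ENGINES)
def test_rotation_invariance_within_discretization(engine):
    packing = random_packing(100, seed=3)
    theta = 0.7
    rot = np.array(
        [[np.cos(theta), -np.sin(theta), 0.0],
         [np.sin(theta), np.cos(theta), 0.0],
         [0.0, 0.0, 1.0]]
    ) @ np.array(
        [[1.0, 0.0, 0.0],
         [0.0, np.cos(0.4), -np.sin(0.4)],
         [0.0, np.sin(0.4), np.cos(0.4)]]
    )
    resolution = 20 if engine == "lee_richards" else 100  # library defaults
    a = ENGINES[engine](packing.coordinates, packing.radii, 1.4, resolution)
    b = ENGINES[engine](packing.coordinates @ rot.T, packing.radii, 1.4, resolution)
    assert abs(a.sum() - b.sum()) / a.sum() < 0.01


@pytest.mark.parametrize("algorithm", list(Algorithm))
def test_worker_count_never_changes_results(algorithm):
    packing = random_packing(120, seed=4)
    results = [
        calc_coordinates(
            packing.coordinates,
            packing.radii,
            Parameters(algorithm=algorithm, n_workers=w),
        ).per_atom_area
        for w in (1, 4)
    ]
    np.testing.assert_array_equal(results[0], results[1])


def test_probe_monotonicity_on_single_atom():
    areas = [
        sasa_lee_richards(np.zeros((1, 3)), np.array([1.5]), probe, 20)[0]
        for probe in (0.0, 0.7, 1.4, 2.0)
    ]
    assert all(a < b for a, b in zip(areas, areas[1:]))


def test_result_total_is_sum_and_order_matches(complex_structure):
    result = calc_structure(complex_structure, Parameters(n_slices=10))
    assert len(result) == len(complex_structure)
    assert result.total == pytest.approx(result.per_atom_area.sum(), rel=1e-12)


def test_unassigned_radii_rejected():
    structure = read_pdb(
        "ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C\n"
    )
    with pytest.raises(ValueError, match="radius"):
        calc_structure(structure)


def test_error_per_atom_arithmetic():
    assert error_per_atom(100.0, 100.0, 10) == 0.0
    assert error_per_atom(110.0, 100.0, 10) == pytest.approx(1.0)
    with pytest.raises(ValueError):
        error_per_atom(1.0, 1.0, 0)


@given(
    st.lists(
        st.tuples(
            st.floats(-10.0, 10.0),
            st.floats(0.0, 2 * np.pi),
        ),
        min_size=1,
        max_size=8,
    )
)
def test_merged_arc_length_matches_dense_sampling(raw):
    """Union length of angular intervals vs a 40000-point membership scan."""
    intervals = [(start, start + width) for start, width in raw]
    expected_mask = np.zeros(40000, dtype=bool)
    grid = np.linspace(0.0, 2.0 * np.pi, 40000, endpoint=False)
    for start, end in intervals:
        expected_mask |= ((grid - start) % (2.0 * np.pi)) < (end - start)
    expected = expected_mask.mean() * 2.0 * np.pi
    assert _merged_arc_length(intervals) == pytest.approx(expected, abs=2e-3)


def test_default_parameters():
    params = Parameters()
    assert params.algorithm is Algorithm.LEE_RICHARDS
    assert params.probe_radius == 1.4
    assert params.n_slices == 20
    assert params.n_workers == 2
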