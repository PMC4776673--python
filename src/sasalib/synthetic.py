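"""Synthetic inputs and closed-form references.

Everything here is seeded and reproducible: random sphere packings for
stress-testing the engines, a closed-form two-sphere SASA for verifying
them, and generators of valid fixed-column PDB text — generic packings,
poly-alanine chains, and a multi-chain protein/RNA complex whose residue
and atom names all resolve against the builtin radius tables.

The generated "molecules" have realistic atom densities and radii but make
no attempt at chemically valid bond geometry; they exercise parsing,
classification, geometry and aggregation, not force-field plausibility.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "Packing",
    "random_packing",
    "two_sphere_analytic",
    "toy_pdb",
    "poly_alanine_pdb",
    "protein_rna_complex_pdb",
]


@dataclass
class Packing:
    """A seeded random set of spheres in a cubic box."""

    coordinates: np.ndarray
    radii: np.ndarray
    seed: int


def random_packing(
    n: int,
    box_side: float = 30.0,
    radius_range: tuple[float, float] = (1.5, 2.0),
    seed: int = 0,
) -> Packing:
    """Uniform sphere centers in a box with uniform radii.

    The defaults (200 spheres of 1.5-2.0 Å in a 30 Å box, when called with
    ``n=200``) give a protein-like density with both deeply buried and
    nearly free atoms.
    """
    if n < 1:
        raise ValueError("need at least one sphere")
    if box_side <= 0:
        raise ValueError("box side must be positive")
    rng = np.random.default_rng(seed)
    coordinates = rng.uniform(0.0, box_side, size=(n, 3))
    radii = rng.uniform(radius_range[0], radius_range[1], size=n)
    return Packing(coordinates=coordinates, radii=radii, seed=seed)


def two_sphere_analytic(
    c1, r1: float, c2, r2: float, probe: float = 0.0
) -> tuple[float, float]:
    """Exact SASA of two spheres (spherical-cap geometry), Å².

    Each sphere's accessible area is its full extended-sphere area minus
    the cap cut off by the radical plane: exposed = 2*pi*R*(2R - h) with
    buried-cap height h = R - (d^2 + R^2 - R'^2) / (2d).  Disjoint spheres
    are fully exposed; a sphere inside the other contributes zero.
    """
    if r1 <= 0 or r2 <= 0:
        raise ValueError("radii must be positive")
    big_r1 = r1 + probe
    big_r2 = r2 + probe
    d = float(np.linalg.norm(np.asarray(c2, dtype=float) - np.asarray(c1, dtype=float)))
    full1 = 4.0 * np.pi * big_r1**2
    full2 = 4.0 * np.pi * big_r2**2
    if d >= big_r1 + big_r2:
        return full1, full2
    if d + big_r1 <= big_r2:
        return 0.0, full2
    if d + big_r2 <= big_r1:
        return full1, 0.0
    a1 = (d * d + big_r1**2 - big_r2**2) / (2.0 * d)
    a2 = (d * d + big_r2**2 - big_r1**2) / (2.0 * d)
    h1 = big_r1 - a1
    h2 = big_r2 - a2
    return (
        2.0 * np.pi * big_r1 * (2.0 * big_r1 - h1),
        2.0 * np.pi * big_r2 * (2.0 * big_r2 - h2),
    )


def _atom_line(
    serial: int,
    name: str,
    residue_name: str,
    chain_id: str,
    residue_number: int,
    xyz,
    element: str,
    hetatm: bool = False,
) -> str:
    record = "HETATM" if hetatm else "ATOM  "
    if len(name) < 4 and len(element) == 1:
        name_field = f" {name:<3s}"
    else:
        name_field = f"{name:<4s}"
    x, y, z = xyz
    return (
        f"{record}{serial:>5d} {name_field} {residue_name:>3s} {chain_id}"
        f"{residue_number:>4d}    {x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00"
        f"          {element:>2s}"
    )


def toy_pdb(packing: Packing, residue_name: str = "UNK", chain_id: str = "A") -> str:
    """Valid PDB text for a packing: one carbon pseudo-atom per sphere.

    The stored radii are not representable in PDB columns, so re-parsing a
    toy file and classifying it gives element radii, not the packing's;
    use the packing arrays directly when the radii matter.
    """
    lines = []
    for i, xyz in enumerate(packing.coordinates):
        lines.append(
            _atom_line(i + 1, "C", residue_name, chain_id, i + 1, xyz, "C")
        )
    lines.append("END")
    return "\n".join(lines) + "\n"


#: heavy atoms of an alanine residue with (name, element, local offset)
_ALA_TEMPLATE = [
    ("N", "N", (0.0, 0.0, 0.0)),
    ("CA", "C", (1.46, 0.0, 0.0)),
    ("C", "C", (2.0, 1.42, 0.0)),
    ("O", "O", (1.3, 2.4, 0.0)),
    ("CB", "C", (2.0, -0.77, 1.2)),
]


def poly_alanine_pdb(
    n_residues: int = 5,
    chain_id: str = "A",
    offset=(0.0, 0.0, 0.0),
    start_serial: int = 1,
    include_extra_hydrogen: bool = False,
) -> str:
    """An extended poly-alanine chain; classifiable with zero fallbacks."""
    lines = []
    serial = start_serial
    ox, oy, oz = offset
    for res in range(n_residues):
        base = np.array([ox + 3.6 * res, oy, oz])
        for name, element, local in _ALA_TEMPLATE:
            lines.append(
                _atom_line(serial, name, "ALA", chain_id, res + 1, base + local, element)
            )
            serial += 1
        if include_extra_hydrogen:
            lines.append(
                _atom_line(serial, "HB1", "ALA", chain_id, res + 1, base + (2.5, -1.2, 1.8), "H")
            )
            serial += 1
    lines.append("END")
    return "\n".join(lines) + "\n"


_PROTEIN_RESIDUES = {
    "ALA": _ALA_TEMPLATE,
    "GLY": [t for t in _ALA_TEMPLATE if t[0] != "CB"],
    "SER": _ALA_TEMPLATE[:4] + [("CB", "C", (2.0, -0.77, 1.2)), ("OG", "O", (1.6, -0.3, 2.45))],
}

_BACKBONE_RNA = [
    ("P", "P"), ("OP1", "O"), ("OP2", "O"), ("O5'", "O"), ("C5'", "C"),
    ("C4'", "C"), ("O4'", "O"), ("C3'", "C"), ("O3'", "O"), ("C2'", "C"),
    ("O2'", "O"), ("C1'", "C"),
]
_BASES = {
    "A": [("N9", "N"), ("C8", "C"), ("N7", "N"), ("C5", "C"), ("C6", "C"),
          ("N6", "N"), ("N1", "N"), ("C2", "C"), ("N3", "N"), ("C4", "C")],
    "G": [("N9", "N"), ("C8", "C"), ("N7", "N"), ("C5", "C"), ("C6", "C"),
          ("O6", "O"), ("N1", "N"), ("C2", "C"), ("N2", "N"), ("N3", "N"), ("C4", "C")],
    "C": [("N1", "N"), ("C2", "C"), ("O2", "O"), ("N3", "N"), ("C4", "C"),
          ("N4", "N"), ("C5", "C"), ("C6", "C")],
    "U": [("N1", "N"), ("C2", "C"), ("O2", "O"), ("N3", "N"), ("C4", "C"),
          ("O4", "O"), ("C5", "C"), ("C6", "C")],
}


def protein_rna_complex_pdb(
    protein_chains: tuple[str, ...] = ("A", "B"),
    rna_chains: tuple[str, ...] = ("X", "Y"),
    residues_per_chain: int = 12,
    seed: int = 0,
) -> str:
    """A compact multi-chain protein/RNA complex as PDB text.

    Protein chains cycle through ALA/GLY/SER; RNA chains cycle through
    A/U/G/C with full heavy-atom nucleotides.  Chains are laid out as
    jittered strands packed around a common core so that chains bury
    surface against each other (chain-group recalculations then show the
    interface).  Deterministic per seed.
    """
    rng = np.random.default_rng(seed)
    lines: list[str] = []
    serial = 1
    n_chains = len(protein_chains) + len(rna_chains)
    for chain_index, chain_id in enumerate(list(protein_chains) + list(rna_chains)):
        is_rna = chain_id in rna_chains
        angle = 2.0 * np.pi * chain_index / max(n_chains, 1)
        chain_origin = np.array([7.0 * np.cos(angle), 7.0 * np.sin(angle), 0.0])
        direction = np.array([0.0, 0.0, 1.0])
        for res in range(residues_per_chain):
            center = chain_origin + direction * 4.5 * res + rng.normal(0.0, 0.35, 3)
            if is_rna:
                resn = "AUGC"[res % 4]
                atoms = _BACKBONE_RNA + _BASES[resn]
                spread = 2.6
            else:
                resn = ["ALA", "GLY", "SER"][res % 3]
                atoms = [(n, e) for n, e, _ in _PROTEIN_RESIDUES[resn]]
                spread = 1.6
            for name, element in atoms:
                xyz = center + rng.normal(0.0, spread, 3)
                lines.append(
                    _atom_line(serial, name, resn, chain_id, res + 1, xyz, element)
                )
                serial += 1
    lines.append("END")
    return "\n".join(lines) + "\n"
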