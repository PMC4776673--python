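"""PDB structure reading and writing.

Parses fixed-column ATOM/HETATM records into a :class:`Structure` and writes
structures back out with per-atom radii and SASA values stored in the
occupancy and temperature-factor columns (the conventional way of attaching
a per-atom scalar to a PDB file).

Only the first model of a multi-model file is read, and only the primary
alternate-location conformer (altloc blank or 'A') is accepted, so every
atom position is unique.  Hydrogen/deuterium atoms and HETATM records are
skipped by default; both filters can be switched off.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import IO, Iterable

import numpy as np

__all__ = [
    "Atom",
    "Structure",
    "PdbError",
    "PdbParseError",
    "NoAtomsError",
    "read_pdb",
    "write_pdb_with_sasa",
]

APOLAR = "apolar"
POLAR = "polar"
UNKNOWN = "unknown"

#: altloc codes accepted as the primary conformer
_PRIMARY_ALTLOCS = (" ", "", "A")


class PdbError(ValueError):
    """Base class for PDB reading problems."""


class PdbParseError(PdbError):
    """A malformed fixed-column record; carries the 1-based line number."""

    def __init__(self, message: str, line_number: int):
        super().__init__(f"line {line_number}: {message}")
        self.line_number = line_number


class NoAtomsError(PdbError):
    """The input contained no acceptable atom records."""


@dataclass
class Atom:
    """One accepted ATOM/HETATM record.

    ``radius`` and ``polarity`` start unassigned (``None`` / ``"unknown"``)
    and are filled in by a classifier before any SASA calculation.
    """

    serial: int
    name: str
    residue_name: str
    residue_number: int
    insertion_code: str
    chain_id: str
    element: str
    coordinates: np.ndarray
    is_hetatm: bool = False
    radius: float | None = None
    polarity: str = UNKNOWN

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.shape != (3,) or not np.all(np.isfinite(self.coordinates)):
            raise ValueError(f"atom {self.serial}: coordinates must be 3 finite reals")
        if self.radius is not None and self.radius < 0:
            raise ValueError(f"atom {self.serial}: negative radius")

    @property
    def residue_key(self) -> tuple[str, int, str]:
        """(chain, residue number, insertion code) — the aggregation key."""
        return (self.chain_id, self.residue_number, self.insertion_code)


@dataclass
class Structure:
    """An ordered collection of atoms, in file order."""

    atoms: list[Atom] = field(default_factory=list)
    source_label: str = ""

    @property
    def chain_ids(self) -> list[str]:
        """Distinct chain identifiers in first-appearance order."""
        seen: dict[str, None] = {}
        for atom in self.atoms:
            seen.setdefault(atom.chain_id, None)
        return list(seen)

    def __len__(self) -> int:
        return len(self.atoms)

    def __iter__(self):
        return iter(self.atoms)

    def coordinates(self) -> np.ndarray:
        """(n, 3) array of atom positions in Å."""
        return np.array([a.coordinates for a in self.atoms], dtype=float)

    def radii(self) -> np.ndarray:
        """(n,) array of assigned radii; raises if any atom is unassigned."""
        values = []
        for atom in self.atoms:
            if atom.radius is None:
                raise ValueError(
                    f"atom {atom.serial} ({atom.residue_name} {atom.name}) has no "
                    "assigned radius; run a classifier first"
                )
            values.append(atom.radius)
        return np.array(values, dtype=float)

    def subset(self, indices: Iterable[int], source_label: str | None = None) -> "Structure":
        """New Structure containing the given atoms (file order preserved)."""
        idx = sorted(set(indices))
        label = self.source_label if source_label is None else source_label
        return Structure(atoms=[self.atoms[i] for i in idx], source_label=label)


def _is_hydrogen(name: str, element: str) -> bool:
    if element:
        return element in ("H", "D")
    # Legacy files without an element column: strip leading digits from the
    # atom name ("1HB2" -> "HB2") and look at the first letter.
    stripped = name.lstrip("0123456789")
    return bool(stripped) and stripped[0] in ("H", "D")


def _parse_atom_line(line: str, line_number: int, is_hetatm: bool) -> Atom:
    # PDB v3 fixed columns (0-based slices).
    if len(line) < 54:
        raise PdbParseError("record too short for coordinate fields", line_number)
    try:
        serial = int(line[6:11])
    except ValueError:
        # Hybrid-36 / overflowing serials are tolerated as sequence position 0.
        serial = 0
    name = line[12:16].strip()
    altloc = line[16:17]
    residue_name = line[17:20].strip()
    chain_id = line[21:22].strip()
    try:
        residue_number = int(line[22:26])
    except ValueError as exc:
        raise PdbParseError(f"bad residue number {line[22:26]!r}", line_number) from exc
    insertion_code = line[26:27].strip()
    try:
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
    except ValueError as exc:
        raise PdbParseError(f"bad coordinate field: {exc}", line_number) from exc
    element = line[76:78].strip().upper() if len(line) >= 78 else ""
    if not name:
        raise PdbParseError("empty atom name", line_number)
    atom = Atom(
        serial=serial,
        name=name,
        residue_name=residue_name,
        residue_number=residue_number,
        insertion_code=insertion_code,
        chain_id=chain_id,
        element=element,
        coordinates=np.array([x, y, z]),
        is_hetatm=is_hetatm,
    )
    atom._altloc = altloc  # kept transiently for filtering
    return atom


def read_pdb(
    source: IO[str] | str,
    include_hydrogens: bool = False,
    include_hetatm: bool = False,
    source_label: str | None = None,
) -> Structure:
    """Parse PDB text into a :class:`Structure`.

    Parameters
    ----------
    source:
        A text stream or a string of PDB text.
    include_hydrogens:
        Keep hydrogen/deuterium atoms (default: drop them).
    include_hetatm:
        Keep HETATM records (default: drop them).

    Raises
    ------
    NoAtomsError
        If no acceptable atom record is found.
    PdbParseError
        On a malformed fixed-column record (reports the line number).
    """
    if isinstance(source, str):
        stream: IO[str] = io.StringIO(source)
        label = source_label or "<string>"
    else:
        stream = source
        label = source_label or getattr(stream, "name", "<stream>")

    atoms: list[Atom] = []
    for line_number, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n").rstrip("\r")
        if line.startswith("ENDMDL"):
            break  # first model only
        if line[:4] != "ATOM" and line[:6] != "HETATM":
            continue
        is_hetatm = line.startswith("HETATM")
        if is_hetatm and not include_hetatm:
            continue
        atom = _parse_atom_line(line, line_number, is_hetatm)
        if atom._altloc not in _PRIMARY_ALTLOCS:
            continue
        del atom._altloc
        if not include_hydrogens and _is_hydrogen(atom.name, atom.element):
            continue
        atoms.append(atom)

    if not atoms:
        raise NoAtomsError(f"{label}: no atoms found with the current filters")
    return Structure(atoms=atoms, source_label=label)


def _format_atom_name(atom: Atom) -> str:
    """PDB column-13..16 atom-name alignment.

    Names of one- or two-letter elements start in column 14 unless the name
    already fills four characters.
    """
    name = atom.name
    if len(name) >= 4:
        return name[:4]
    element = atom.element or name.lstrip("0123456789")[:1]
    if len(element) == 2:
        return f"{name:<4}"
    return f" {name:<3}"


def write_pdb_with_sasa(structure: Structure, result, stream: IO[str]) -> None:
    """Write one ATOM/HETATM line per atom.

    Identity columns are preserved; the occupancy column carries the assigned
    radius and the temperature-factor column the per-atom SASA, both as
    fixed-width ``%6.2f`` numbers.
    """
    per_atom = np.asarray(result.per_atom_area, dtype=float)
    if per_atom.shape[0] != len(structure):
        raise ValueError(
            f"result has {per_atom.shape[0]} areas for {len(structure)} atoms"
        )
    for atom, area in zip(structure.atoms, per_atom):
        record = "HETATM" if atom.is_hetatm else "ATOM  "
        radius = 0.0 if atom.radius is None else atom.radius
        x, y, z = atom.coordinates
        stream.write(
            f"{record}{atom.serial:>5d} {_format_atom_name(atom)} "
            f"{atom.residue_name:>3s} {atom.chain_id:1s}"
            f"{atom.residue_number:>4d}{atom.insertion_code:1s}   "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{radius:6.2f}{area:6.2f}"
            f"          {atom.element:>2s}\n"
        )
    stream.write("END\n")
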