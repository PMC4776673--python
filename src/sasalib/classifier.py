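"""Atomic radius and polarity assignment.

The default radius set is the ProtOr group-radius parameterization, which
treats each heavy atom together with its bonded hydrogens as one sphere.
It covers the 20 standard amino acids (plus selenocysteine and
pyrrolysine), the standard ribo- and deoxyribonucleotides, the acetyl and
NH2 capping groups, and water.  Phosphorus and selenium, absent from the
original protein tables, are given 1.8 Å and 1.9 Å.

Atoms that no (residue, atom) entry matches fall back to the van der Waals
radius of their element, taken from the Mantina et al. main-group table;
polarity is then apolar for carbon and polar otherwise, and the fallback is
reported on the module logger so silent misassignment cannot happen.

Users can supply their own radius sets as plain-text configuration files::

    # comment
    types:
    C_ALI 2.00 apolar      # class  radius  polarity
    atoms:
    ALA CB C_ALI           # residue  atom  class

A NACCESS-compatible set using the same atom typing ships alongside the
ProtOr default.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from importlib import resources
from typing import IO

from .structure import APOLAR, POLAR, Structure

__all__ = [
    "AtomClassEntry",
    "Classifier",
    "ClassifierError",
    "ClassifierConfigError",
    "UnknownAtomError",
    "builtin_protor_classifier",
    "builtin_naccess_classifier",
    "parse_classifier_config",
    "assign",
    "VDW_RADII",
]

logger = logging.getLogger("sasalib")


class ClassifierError(ValueError):
    """Base class for classification problems."""


class ClassifierConfigError(ClassifierError):
    """Invalid configuration file; carries the 1-based line number."""

    def __init__(self, message: str, line_number: int):
        super().__init__(f"line {line_number}: {message}")
        self.line_number = line_number


class UnknownAtomError(ClassifierError):
    """An atom whose residue, atom name and element are all unrecognized."""


#: Main-group van der Waals radii (Å), Mantina et al. 2009.
VDW_RADII: dict[str, float] = {
    "H": 1.10, "HE": 1.40,
    "LI": 1.81, "BE": 1.53, "B": 1.92, "C": 1.70, "N": 1.55, "O": 1.52,
    "F": 1.47, "NE": 1.54,
    "NA": 2.27, "MG": 1.73, "AL": 1.84, "SI": 2.10, "P": 1.80, "S": 1.80,
    "CL": 1.75, "AR": 1.88,
    "K": 2.75, "CA": 2.31, "GA": 1.87, "GE": 2.11, "AS": 1.85, "SE": 1.90,
    "BR": 1.83, "KR": 2.02,
    "RB": 3.03, "SR": 2.49, "IN": 1.93, "SN": 2.17, "SB": 2.06, "TE": 2.06,
    "I": 1.98, "XE": 2.16,
    "CS": 3.43, "BA": 2.68, "TL": 1.96, "PB": 2.02, "BI": 2.07, "PO": 1.97,
    "AT": 2.02, "RN": 2.20,
    "FR": 3.48, "RA": 2.83,
}

#: deuterium shares the hydrogen radius
VDW_RADII["D"] = VDW_RADII["H"]


@dataclass(frozen=True)
class AtomClassEntry:
    """A named atom class: radius in Å plus polarity."""

    class_name: str
    radius: float
    polarity: str

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError(f"class {self.class_name}: radius must be positive")
        if self.polarity not in (APOLAR, POLAR):
            raise ValueError(f"class {self.class_name}: bad polarity {self.polarity!r}")


@dataclass
class Classifier:
    """Maps (residue, atom) to a radius class, with element vdW fallback.

    Lookups are case-insensitive; legacy primed atom names written with
    ``*`` (e.g. ``O5*``) are normalized to ``'``.
    """

    residue_atom_map: dict[tuple[str, str], AtomClassEntry] = field(default_factory=dict)
    element_fallback: dict[str, float] = field(default_factory=lambda: dict(VDW_RADII))
    name: str = "custom"

    @staticmethod
    def _key(residue_name: str, atom_name: str) -> tuple[str, str]:
        return (residue_name.strip().upper(), atom_name.strip().upper().replace("*", "'"))

    def add(self, residue_name: str, atom_name: str, entry: AtomClassEntry) -> None:
        self.residue_atom_map[self._key(residue_name, atom_name)] = entry

    def lookup(self, residue_name: str, atom_name: str) -> AtomClassEntry | None:
        return self.residue_atom_map.get(self._key(residue_name, atom_name))

    def known_residues(self) -> set[str]:
        return {res for res, _ in self.residue_atom_map}

    def element_radius(self, element: str) -> float | None:
        return self.element_fallback.get(element.strip().upper())


_NUCLEOTIDE_RESIDUES = frozenset(
    {"A", "C", "G", "U", "DA", "DC", "DG", "DT", "DU"}
)


def parse_classifier_config(source: IO[str] | str, name: str = "custom") -> Classifier:
    """Parse a radius-configuration file into a :class:`Classifier`.

    Duplicate (residue, atom) entries keep the last occurrence (with a
    warning).  An atom line that references an undeclared class, a
    non-positive radius, or a malformed line raises
    :class:`ClassifierConfigError` with the line number.
    """
    stream = io.StringIO(source) if isinstance(source, str) else source
    classifier = Classifier(residue_atom_map={}, name=name)
    types: dict[str, AtomClassEntry] = {}
    section = None
    for line_number, raw in enumerate(stream, start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        lowered = line.lower().rstrip(":")
        if line.endswith(":") and lowered in ("types", "atoms"):
            section = lowered
            continue
        fields = line.split()
        if section == "types":
            if len(fields) != 3:
                raise ClassifierConfigError(
                    f"expected 'class radius polarity', got {line!r}", line_number
                )
            class_name, radius_text, polarity = fields
            try:
                radius = float(radius_text)
            except ValueError as exc:
                raise ClassifierConfigError(f"bad radius {radius_text!r}", line_number) from exc
            if radius <= 0:
                raise ClassifierConfigError(
                    f"radius must be positive, got {radius}", line_number
                )
            if polarity.lower() not in (APOLAR, POLAR):
                raise ClassifierConfigError(
                    f"polarity must be 'apolar' or 'polar', got {polarity!r}", line_number
                )
            types[class_name.upper()] = AtomClassEntry(
                class_name=class_name, radius=radius, polarity=polarity.lower()
            )
        elif section == "atoms":
            if len(fields) != 3:
                raise ClassifierConfigError(
                    f"expected 'residue atom class', got {line!r}", line_number
                )
            residue_name, atom_name, class_name = fields
            entry = types.get(class_name.upper())
            if entry is None:
                raise ClassifierConfigError(
                    f"atom references undeclared type {class_name!r}", line_number
                )
            if classifier.lookup(residue_name, atom_name) is not None:
                logger.warning(
                    "config %s line %d: duplicate entry for (%s, %s); last wins",
                    name, line_number, residue_name, atom_name,
                )
            classifier.add(residue_name, atom_name, entry)
        else:
            raise ClassifierConfigError(
                "content before a 'types:' or 'atoms:' section header", line_number
            )
    return classifier


def _load_packaged(filename: str, name: str) -> Classifier:
    text = resources.files("sasalib.data").joinpath(filename).read_text()
    return parse_classifier_config(text, name=name)


def builtin_protor_classifier() -> Classifier:
    """The default ProtOr radius set (P 1.8 Å, Se 1.9 Å)."""
    return _load_packaged("protor.config", "protor")


def builtin_naccess_classifier() -> Classifier:
    """A NACCESS-compatible radius subset on the same atom typing."""
    return _load_packaged("naccess.config", "naccess")


def _element_polarity(element: str) -> str:
    return APOLAR if element.upper() == "C" else POLAR


def _guess_element(atom) -> str:
    if atom.element:
        return atom.element
    stripped = atom.name.lstrip("0123456789")
    if len(stripped) >= 2 and stripped[:2].upper() in VDW_RADII and atom.is_hetatm:
        return stripped[:2].upper()
    return stripped[:1].upper()


def assign(
    classifier: Classifier,
    structure: Structure,
    on_unknown: str = "error",
) -> Structure:
    """Fill in radius and polarity for every atom of *structure*.

    Resolution order per atom:

    1. the classifier's (residue, atom) table;
    2. for residues absent from the table whose atoms *all* carry standard
       nucleotide atom names, the corresponding nucleotide entries
       (covers nonstandard nucleotides);
    3. the van der Waals radius of the element (polarity: apolar for
       carbon, polar otherwise), reported as a warning.

    An atom whose element is also unknown raises :class:`UnknownAtomError`
    under the default policy; with ``on_unknown="skip"`` it keeps an
    unassigned radius and a warning is emitted instead.

    Returns the same structure, mutated; assignment is deterministic in
    (classifier, structure).
    """
    if on_unknown not in ("error", "skip"):
        raise ValueError(f"on_unknown must be 'error' or 'skip', got {on_unknown!r}")

    known = classifier.known_residues()
    nucleotide_names: dict[str, AtomClassEntry] = {}
    for (res, atom_name), entry in classifier.residue_atom_map.items():
        if res in _NUCLEOTIDE_RESIDUES:
            nucleotide_names.setdefault(atom_name, entry)

    # Residues not in the table but entirely composed of nucleotide atom
    # names are treated as (modified) nucleotides.
    residue_atoms: dict[tuple, list] = {}
    for atom in structure:
        residue_atoms.setdefault(atom.residue_key, []).append(atom)
    nucleotide_like: set[tuple] = set()
    for key, atoms in residue_atoms.items():
        resn = atoms[0].residue_name.upper()
        if resn in known or not nucleotide_names:
            continue
        names = {Classifier._key(resn, a.name)[1] for a in atoms}
        if names and names <= set(nucleotide_names):
            nucleotide_like.add(key)

    for atom in structure:
        entry = classifier.lookup(atom.residue_name, atom.name)
        if entry is None and atom.residue_key in nucleotide_like:
            entry = nucleotide_names.get(Classifier._key("", atom.name)[1])
        if entry is not None:
            atom.radius = entry.radius
            atom.polarity = entry.polarity
            continue
        element = _guess_element(atom)
        radius = classifier.element_radius(element)
        if radius is not None:
            atom.radius = radius
            atom.polarity = _element_polarity(element)
            logger.warning(
                "atom %s %s %s/%s%s: no (residue, atom) entry; using %s vdW radius "
                "%.2f A", atom.serial, atom.name, atom.residue_name,
                atom.residue_number, atom.insertion_code, element, radius,
            )
            continue
        message = (
            f"atom {atom.serial} {atom.name} in {atom.residue_name}: unknown "
            f"residue/atom and unknown element {element!r}"
        )
        if on_unknown == "error":
            raise UnknownAtomError(message)
        logger.warning("%s; skipped (radius left unassigned)", message)
    return structure
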