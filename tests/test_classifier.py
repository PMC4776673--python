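"""Radius/polarity assignment: ProtOr defaults, fallbacks, config files."""

import logging

import pytest

from sasalib import (
    ClassifierConfigError,
    UnknownAtomError,
    assign,
    builtin_naccess_classifier,
    builtin_protor_classifier,
    parse_classifier_config,
    read_pdb,
)
from sasalib.classifier import VDW_RADII
from sasalib.synthetic import poly_alanine_pdb

AA20 = [
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
]


@pytest.mark.parametrize(
    "residue,atom,radius,polarity",
    [
        ("ALA", "CA", 1.88, "apolar"),  # ProtOr tetrahedral carbon C4H1
        ("ALA", "N", 1.64, "polar"),
        ("ALA", "O", 1.42, "polar"),
        ("SER", "OG", 1.46, "polar"),  # hydroxyl oxygen
        ("MET", "SD", 1.77, "polar"),
        ("PHE", "CD1", 1.76, "apolar"),  # aromatic CH
        ("DA", "P", 1.80, "polar"),  # phosphorus
        ("A", "P", 1.80, "polar"),
        ("MSE", "SE", 1.90, "polar"),  # selenium
        ("SEC", "SE", 1.90, "polar"),
        ("HOH", "O", 1.46, "polar"),  # water recognized among HETATM
        ("ACE", "CH3", 1.88, "apolar"),  # capping group
        ("NH2", "N", 1.64, "polar"),
    ],
)
def test_protor_entries(protor, residue, atom, radius, polarity):
    entry = protor.lookup(residue, atom)
    assert entry is not None, f"({residue}, {atom}) missing"
    assert entry.radius == pytest.approx(radius)
    assert entry.polarity == polarity


def test_protor_covers_standard_residue_set(protor):
    known = protor.known_residues()
    expected = set(AA20) | {"SEC", "PYL"} | {"A", "C", "G", "U", "DA", "DC", "DG", "DT"}
    expected |= {"ACE", "NH2", "HOH"}
    assert expected <= known


def test_lookups_case_insensitive_and_star_normalized(protor):
    assert protor.lookup("ala", "cb") is not None
    assert protor.lookup("A", "O5*").radius == protor.lookup("A", "O5'").radius


def test_all_builtin_radii_within_sanity_bounds(protor):
    radii = {e.radius for e in protor.residue_atom_map.values()}
    radii |= {e.radius for e in builtin_naccess_classifier().residue_atom_map.values()}
    assert all(1.0 <= r <= 2.5 for r in radii)


def test_poly_alanine_assigned_without_fallback(protor, caplog):
    structure = read_pdb(poly_alanine_pdb(5))
    with caplog.at_level(logging.WARNING, logger="sasalib"):
        assign(protor, structure)
    assert not caplog.records
    assert all(a.radius is not None and a.radius > 0 for a in structure)
    assert all(a.polarity in ("apolar", "polar") for a in structure)


def test_unknown_residue_falls_back_to_element_vdw(protor, caplog):
    text = "ATOM      1  NQ  XYZ A   1       0.000   0.000   0.000  1.00  0.00           N\n"
    structure = read_pdb(text)
    with caplog.at_level(logging.WARNING, logger="sasalib"):
        assign(protor, structure)
    atom = structure.atoms[0]
    assert atom.radius == pytest.approx(VDW_RADII["N"])  # Mantina main-group value
    assert atom.polarity == "polar"
    assert len(caplog.records) == 1


def test_unknown_element_policy(protor):
    text = "ATOM      1 ZZ1  XYZ A   1       0.000   0.000   0.000  1.00  0.00          ZZ\n"
    structure = read_pdb(text)
    with pytest.raises(UnknownAtomError):
        assign(protor, structure)
    structure = read_pdb(text)
    assign(protor, structure, on_unknown="skip")
    assert structure.atoms[0].radius is None


def test_modified_nucleotide_recognized_by_atom_names(protor, caplog):
    # Residue name unknown to the table, atoms all standard nucleotide names.
    lines = [
        "ATOM      1  C1' 5MU A   1       0.000   0.000   0.000  1.00  0.00           C",
        "ATOM      2  N1  5MU A   1       1.400   0.000   0.000  1.00  0.00           N",
        "ATOM      3  O2' 5MU A   1       0.000   1.400   0.000  1.00  0.00           O",
    ]
    structure = read_pdb("\n".join(lines) + "\n")
    with caplog.at_level(logging.WARNING, logger="sasalib"):
        assign(protor, structure)
    assert not caplog.records
    assert structure.atoms[2].radius == pytest.approx(1.46)


class TestConfigParsing:
    def test_declared_type_and_atom(self):
        config = "types:\nC_ALI 2.00 apolar\natoms:\nALA CB C_ALI\n"
        classifier = parse_classifier_config(config)
        entry = classifier.lookup("ALA", "CB")
        assert entry.radius == 2.0 and entry.polarity == "apolar"

    def test_empty_file_gives_fallback_only_classifier(self):
        classifier = parse_classifier_config("")
        assert classifier.residue_atom_map == {}
        assert classifier.element_radius("C") == pytest.approx(1.70)

    def test_undeclared_type_is_error_with_line_number(self):
        with pytest.raises(ClassifierConfigError) as err:
            parse_classifier_config("types:\natoms:\nALA CB NOPE\n")
        assert err.value.line_number == 3

    def test_nonpositive_radius_rejected(self):
        with pytest.raises(ClassifierConfigError):
            parse_classifier_config("types:\nBAD 0.0 polar\n")

    def test_duplicate_entry_last_wins(self, caplog):
        config = (
            "types:\nT1 1.50 polar\nT2 2.00 apolar\n"
            "atoms:\nALA CB T1\nALA CB T2\n"
        )
        with caplog.at_level(logging.WARNING, logger="sasalib"):
            classifier = parse_classifier_config(config)
        assert classifier.lookup("ALA", "CB").radius == 2.0
        assert any("duplicate" in r.message for r in caplog.records)

    def test_comments_and_blank_lines_ignored(self):
        config = "# header\n\ntypes:\nT1 1.50 polar  # inline\natoms:\nGLY N T1\n"
        assert parse_classifier_config(config).lookup("GLY", "N").radius == 1.5
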