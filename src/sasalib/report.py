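"""Aggregation of per-atom areas and plain-text reporting.

Per-atom SASA values are rolled up into polarity classes (apolar / polar,
plus a separate "unknown" bucket for element-fallback atoms so the class
partition stays auditable), per-chain, per-residue and per-residue-type
totals.  Chain groups re-run the whole calculation on a structure from
which the other chains have been *removed* — the difference against the
full complex is the surface buried at the interface.

The text log mirrors the classic command-line layout: a header line,
PARAMETERS, INPUT, RESULTS (A^2) and optional SELECTIONS sections, all
byte-deterministic for fixed input and flags.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import IO

import numpy as np

from . import __version__
from .engines import Algorithm, Parameters, SasaResult, calc_structure
from .structure import APOLAR, POLAR, Structure

__all__ = ["AreaReport", "aggregate", "chain_groups", "format_log", "per_residue_tsv"]


@dataclass
class AreaReport:
    """Aggregated areas, all in Å²."""

    total: float = 0.0
    polar: float = 0.0
    apolar: float = 0.0
    unknown: float = 0.0
    per_chain: dict[str, float] = field(default_factory=dict)
    per_residue: dict[tuple[str, int, str], float] = field(default_factory=dict)
    per_residue_type: dict[str, float] = field(default_factory=dict)


def aggregate(structure: Structure, result: SasaResult) -> AreaReport:
    """Roll per-atom areas up into an :class:`AreaReport`.

    Invariants: apolar + polar + unknown = total, and the per-chain and
    per-residue maps each partition the total (within accumulation
    round-off).
    """
    per_atom = np.asarray(result.per_atom_area, dtype=float)
    if per_atom.shape[0] != len(structure):
        raise ValueError("result does not match structure")
    report = AreaReport()
    for chain_id in structure.chain_ids:
        report.per_chain[chain_id] = 0.0
    for atom, area in zip(structure.atoms, per_atom):
        area = float(area)
        report.total += area
        if atom.polarity == APOLAR:
            report.apolar += area
        elif atom.polarity == POLAR:
            report.polar += area
        else:
            report.unknown += area
        report.per_chain[atom.chain_id] += area
        key = atom.residue_key
        report.per_residue[key] = report.per_residue.get(key, 0.0) + area
        report.per_residue_type[atom.residue_name] = (
            report.per_residue_type.get(atom.residue_name, 0.0) + area
        )
    return report


def chain_groups(
    structure: Structure,
    group_spec: str,
    parameters: Parameters | None = None,
) -> list[tuple[str, Structure, SasaResult, AreaReport]]:
    """Recalculate SASA for each '+'-separated chain group in isolation.

    ``"ABCD+XY"`` yields two entries: one structure containing only chains
    A-D and one with only X and Y, each fully recalculated (atoms of other
    chains removed, not merely hidden from reporting).
    """
    valid = set(structure.chain_ids)
    groups = [g for g in group_spec.split("+") if g]
    if not groups:
        raise ValueError(f"empty chain-group spec {group_spec!r}")
    for group in groups:
        bad = [c for c in group if c not in valid]
        if bad:
            raise ValueError(
                f"chain(s) {''.join(bad)!r} not in structure "
                f"(valid chains: {''.join(structure.chain_ids)})"
            )
    out = []
    for group in groups:
        wanted = set(group)
        indices = [i for i, atom in enumerate(structure.atoms) if atom.chain_id in wanted]
        sub = structure.subset(indices, source_label=f"{structure.source_label}:{group}")
        result = calc_structure(sub, parameters)
        out.append((group, sub, result, aggregate(sub, result)))
    return out


_ALGORITHM_LABELS = {
    Algorithm.LEE_RICHARDS: "Lee & Richards",
    Algorithm.SHRAKE_RUPLEY: "Shrake & Rupley",
}


def format_log(
    structure: Structure,
    result: SasaResult,
    report: AreaReport,
    selections: list[tuple[str, float]] | None = None,
    header: bool = True,
    show_residue_types: bool = False,
) -> str:
    """The standard plain-text log for one calculation."""
    params = result.parameters_used
    lines: list[str] = []
    if header:
        lines += [f"## sasalib {__version__} ##", ""]
    lines += [
        "PARAMETERS",
        f"algorithm    : {_ALGORITHM_LABELS[params.algorithm]}",
        f"probe-radius : {params.probe_radius:.3f}",
        f"threads      : {params.n_workers}",
    ]
    if params.algorithm is Algorithm.LEE_RICHARDS:
        lines.append(f"slices       : {params.n_slices}")
    else:
        lines.append(f"testpoints   : {params.n_points}")
    lines += [
        "",
        "INPUT",
        f"source  : {structure.source_label}",
        f"chains  : {''.join(structure.chain_ids)}",
        f"atoms   : {len(structure)}",
        "",
        "RESULTS (A^2)",
        f"Total   : {report.total:8.2f}",
        f"Apolar  : {report.apolar:8.2f}",
        f"Polar   : {report.polar:8.2f}",
    ]
    if report.unknown:
        lines.append(f"Unknown : {report.unknown:8.2f}")
    for chain_id, area in report.per_chain.items():
        lines.append(f"CHAIN {chain_id} : {area:8.2f}")
    if show_residue_types:
        lines.append("")
        lines.append("RESIDUE TYPES (A^2)")
        for residue_name, area in sorted(report.per_residue_type.items()):
            lines.append(f"{residue_name:<3s} : {area:8.2f}")
    if selections:
        lines += ["", "SELECTIONS"]
        for label, area in selections:
            lines.append(f"{label} : {area:10.2f}")
    lines.append("")
    return "\n".join(lines)


def per_residue_tsv(structure: Structure, report: AreaReport, stream: IO[str]) -> None:
    """Tab-separated per-residue areas (chain, number, icode, name, Å²)."""
    names = {}
    for atom in structure:
        names.setdefault(atom.residue_key, atom.residue_name)
    stream.write("chain\tresidue_number\tinsertion_code\tresidue_name\tsasa\n")
    for key, area in report.per_residue.items():
        chain_id, number, icode = key
        stream.write(f"{chain_id}\t{number}\t{icode}\t{names[key]}\t{area:.2f}\n")
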