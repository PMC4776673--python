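"""Named atom selections in a small Pymol-style syntax.

A selection string is ``"label, expression"``; the expression combines the
primitives ``resn``, ``resi``, ``chain``, ``name`` and ``symbol`` with
``and``, ``or``, ``not`` and parentheses.  Primitive values are
``+``-separated lists (binding tighter than the boolean operators) and
``resi`` values may be dash ranges::

    RNA, resn A+U+G+C
    s1, chain A and resi 1-10
    tips, name OG+OH or (symbol S and not chain B)

Keywords and values are case-insensitive.  ``resi`` matches the residue
number ignoring insertion codes unless the value carries one (``10A``).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

import numpy as np

from .structure import Structure

__all__ = ["SelectionExpr", "SelectionError", "parse_selection", "evaluate_selection"]

logger = logging.getLogger("sasalib")

_KEYWORDS = ("resn", "resi", "chain", "name", "symbol")
_OPERATORS = ("and", "or", "not")

_TOKEN_RE = re.compile(r"\(|\)|[^\s()]+")


class SelectionError(ValueError):
    """Malformed selection string."""


@dataclass(frozen=True)
class _Primitive:
    keyword: str
    values: tuple[str, ...]

    def mask(self, structure: Structure) -> np.ndarray:
        out = np.zeros(len(structure), dtype=bool)
        for i, atom in enumerate(structure):
            out[i] = self._matches(atom)
        return out

    def _matches(self, atom) -> bool:
        if self.keyword == "resn":
            return atom.residue_name.upper() in self.values
        if self.keyword == "chain":
            return atom.chain_id.upper() in self.values
        if self.keyword == "name":
            return atom.name.upper() in self.values
        if self.keyword == "symbol":
            element = atom.element or atom.name.lstrip("0123456789")[:1]
            return element.upper() in self.values
        # resi: plain numbers, dash ranges, or number+insertion-code
        for value in self.values:
            if "-" in value[1:]:
                lo, hi = value[1:].split("-", 1)
                lo = value[0] + lo
                try:
                    if int(lo) <= atom.residue_number <= int(hi):
                        return True
                except ValueError:
                    raise SelectionError(f"bad resi range {value!r}")
                continue
            match = re.fullmatch(r"(-?\d+)([A-Z]?)", value)
            if match is None:
                raise SelectionError(f"bad resi value {value!r}")
            number, icode = int(match.group(1)), match.group(2)
            if atom.residue_number == number and (
                not icode or atom.insertion_code.upper() == icode
            ):
                return True
        return False


@dataclass(frozen=True)
class _Not:
    operand: object

    def mask(self, structure: Structure) -> np.ndarray:
        return ~self.operand.mask(structure)


@dataclass(frozen=True)
class _BinOp:
    op: str
    left: object
    right: object

    def mask(self, structure: Structure) -> np.ndarray:
        left = self.left.mask(structure)
        right = self.right.mask(structure)
        return left & right if self.op == "and" else left | right


@dataclass(frozen=True)
class SelectionExpr:
    """A parsed, named selection: evaluate with :func:`evaluate_selection`."""

    name: str
    tree: object

    def mask(self, structure: Structure) -> np.ndarray:
        """Boolean per-atom membership array."""
        return self.tree.mask(structure)


class _Parser:
    """Recursive descent over tokens; precedence not > and > or."""

    def __init__(self, tokens: list[str]):
        self.tokens = tokens
        self.pos = 0

    def peek(self) -> str | None:
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def take(self) -> str:
        token = self.peek()
        if token is None:
            raise SelectionError("unexpected end of selection expression")
        self.pos += 1
        return token

    def parse(self):
        tree = self.or_expr()
        if self.peek() is not None:
            raise SelectionError(f"unexpected token {self.peek()!r}")
        return tree

    def or_expr(self):
        node = self.and_expr()
        while self.peek() is not None and self.peek().lower() == "or":
            self.take()
            node = _BinOp("or", node, self.and_expr())
        return node

    def and_expr(self):
        node = self.unary()
        while self.peek() is not None and self.peek().lower() == "and":
            self.take()
            node = _BinOp("and", node, self.unary())
        return node

    def unary(self):
        token = self.peek()
        if token is not None and token.lower() == "not":
            self.take()
            return _Not(self.unary())
        return self.atom()

    def atom(self):
        token = self.take()
        if token == "(":
            node = self.or_expr()
            if self.take() != ")":
                raise SelectionError("missing closing parenthesis")
            return node
        keyword = token.lower()
        if keyword not in _KEYWORDS:
            raise SelectionError(
                f"unknown keyword {token!r} (expected one of {', '.join(_KEYWORDS)})"
            )
        value_token = self.take()
        if value_token in ("(", ")") or value_token.lower() in _OPERATORS:
            raise SelectionError(f"keyword {keyword!r} needs a value list")
        values = tuple(v.upper() for v in value_token.split("+") if v)
        if not values:
            raise SelectionError(f"empty value list for {keyword!r}")
        return _Primitive(keyword, values)


def parse_selection(text: str) -> SelectionExpr:
    """Parse ``"label, expression"`` into a :class:`SelectionExpr`."""
    if "," not in text:
        raise SelectionError(
            f"selection {text!r} lacks the 'label, expression' comma"
        )
    label, expression = text.split(",", 1)
    label = label.strip()
    if not label:
        raise SelectionError("empty selection label")
    tokens = _TOKEN_RE.findall(expression)
    if not tokens:
        raise SelectionError(f"selection {label!r} has an empty expression")
    return SelectionExpr(name=label, tree=_Parser(tokens).parse())


def evaluate_selection(expr: SelectionExpr, structure: Structure, result) -> float:
    """Summed SASA (Å²) of the atoms matching *expr*.

    An empty match yields 0 with a warning.
    """
    per_atom = np.asarray(result.per_atom_area, dtype=float)
    if per_atom.shape[0] != len(structure):
        raise ValueError("result does not match structure")
    mask = expr.mask(structure)
    if not mask.any():
        logger.warning("selection %r matches no atoms", expr.name)
        return 0.0
    return float(per_atom[mask].sum())
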