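"""Linear-notation glycan structures: parsing, serialization, classification.

N-glycans are rooted labeled trees of monosaccharide residues.  The linear
notation writes the tree from the reducing-end GlcNAc outward: each residue
is a sugar token preceded by its linkage code (``<acceptor>.<anomeric>``,
e.g. ``4.1`` for a beta-1,4 bond written acceptor-first), brackets open
separate branches, a colon terminates each branch, an underscore plus the
lowercase initial of the next sugar marks the continuation of the chain that
the bracket group interrupted, and ``@`` ends the string.  The two reference
structures::

    GlcNAc4.1GlcNAc4.1Man(3.1Man:)_m6.1Man(3.1Man:)_m6.1Man:@
    GlcNAc4.1GlcNAc4.1Man(3.1Man2.1GlcNAc4.1Gal:)_m6.1Man2.1GlcNAc4.1Gal6.2Sia:@

are Man5GlcNAc2 (oligomannose) and NeuAc1Gal2GlcNAc2Man3GlcNAc2 (complex).

The module provides a canonical form (sibling branches sorted by linkage
code, ties broken on the canonical serialization of the subtree) so that
structural comparisons are deterministic, plus composition counting and the
oligomannose / hybrid / complex classification.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterator, Optional

__all__ = [
    "GlycanStructure",
    "GlycanComposition",
    "GlycanClass",
    "GlycanParseError",
    "parse_linear",
    "serialize",
    "canonicalize",
    "composition",
    "classify",
    "composition_key",
    "profile_key",
    "count_sugar",
    "antenna_count",
    "anatomy",
]

# Notation token -> internal sugar identity. The printed strings use "Sia"
# for N-acetylneuraminic acid; internally we name it NeuAc.
_TOKEN_TO_SUGAR = {
    "GlcNAc": "GlcNAc",
    "Man": "Man",
    "Gal": "Gal",
    "Fuc": "Fuc",
    "Sia": "NeuAc",
    "Glc": "Glc",
}
_SUGAR_TO_TOKEN = {v: k for k, v in _TOKEN_TO_SUGAR.items()}
SUGARS = tuple(_TOKEN_TO_SUGAR.values())

# longest-first so GlcNAc wins over Glc
_TOKENS = sorted(_TOKEN_TO_SUGAR, key=len, reverse=True)
_LINKAGE_RE = re.compile(r"\d\.\d")


class GlycanParseError(ValueError):
    """Malformed linear-notation string; carries the offending index."""

    def __init__(self, message: str, index: int):
        super().__init__(f"{message} (at index {index})")
        self.index = index


class GlycanClass(Enum):
    OLIGOMANNOSE = "oligomannose"
    HYBRID = "hybrid"
    COMPLEX = "complex"
    OTHER = "other"


@dataclass
class GlycanStructure:
    """A residue and its ordered (linkage, subtree) children.

    ``quenched`` is meaningful on the root only: it marks a glycan that has
    been made terminally unprocessable (the oligomannose-quench event, which
    lumps Man-6-phosphate tagging and retrograde ER retrieval).
    """

    sugar: str
    children: list[tuple[str, "GlycanStructure"]] = field(default_factory=list)
    quenched: bool = False

    def copy(self) -> "GlycanStructure":
        return GlycanStructure(
            self.sugar,
            [(lk, child.copy()) for lk, child in self.children],
            self.quenched,
        )

    def walk(self) -> Iterator["GlycanStructure"]:
        yield self
        for _, child in self.children:
            yield from child.walk()

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        q = ", quenched" if self.quenched else ""
        return f"<GlycanStructure {serialize(self)}{q}>"


@dataclass(frozen=True)
class GlycanComposition:
    """Residue counts by mass-spectrometric class (Man and Gal are both Hex)."""

    hex: int = 0
    hexnac: int = 0
    fuc: int = 0
    neuac: int = 0
    glc: int = 0

    def fold_glc(self) -> "GlycanComposition":
        """Fold Glc into Hex (MS cannot distinguish hexoses)."""
        return GlycanComposition(self.hex + self.glc, self.hexnac, self.fuc, self.neuac, 0)


def _read_sugar(s: str, i: int) -> tuple[str, int]:
    for tok in _TOKENS:
        if s.startswith(tok, i):
            return _TOKEN_TO_SUGAR[tok], i + len(tok)
    raise GlycanParseError(f"unknown sugar token at {s[i:i+8]!r}", i)


def _read_linkage(s: str, i: int) -> tuple[str, int]:
    m = _LINKAGE_RE.match(s, i)
    if not m:
        raise GlycanParseError("expected linkage code <digit>.<digit>", i)
    return m.group(0), m.end()


def _parse_chain(s: str, i: int) -> tuple[GlycanStructure, int]:
    """Parse one branch chain; consumes the terminating ':'."""
    sugar, i = _read_sugar(s, i)
    node = GlycanStructure(sugar)
    while True:
        if i >= len(s):
            raise GlycanParseError("unterminated branch (missing ':')", i)
        c = s[i]
        if c == ":":
            return node, i + 1
        if c == "(":
            # one or more bracket groups, then a continuation or ':'
            while i < len(s) and s[i] == "(":
                i += 1
                while True:
                    if i >= len(s):
                        raise GlycanParseError("unclosed bracket", i)
                    if s[i] == ")":
                        raise GlycanParseError("empty branch in brackets", i)
                    link, i = _read_linkage(s, i)
                    child, i = _parse_chain(s, i)
                    node.children.append((link, child))
                    if i < len(s) and s[i] == ")":
                        i += 1
                        break
            if i < len(s) and s[i] == "_":
                i += 1
                if i >= len(s) or not s[i].islower():
                    raise GlycanParseError("expected lowercase continuation marker", i)
                marker, i = s[i], i + 1
                link, i = _read_linkage(s, i)
                sugar_peek, _ = _read_sugar(s, i)
                if _SUGAR_TO_TOKEN[sugar_peek][0].lower() != marker:
                    raise GlycanParseError(
                        f"continuation marker '_{marker}' does not match sugar", i
                    )
                child, i = _parse_chain(s, i)
                node.children.append((link, child))
                return node, i
            if i < len(s) and s[i] == ":":
                return node, i + 1
            raise GlycanParseError("expected continuation '_' or ':' after brackets", i)
        # otherwise: inline single continuation "linkage sugar ..."
        link, i = _read_linkage(s, i)
        child, i = _parse_chain(s, i)
        node.children.append((link, child))
        return node, i


def parse_linear(notation: str) -> GlycanStructure:
    """Parse a linear-notation string into a :class:`GlycanStructure`.

    Raises :class:`GlycanParseError` (with the offending index) on any
    grammar violation: missing ``@``, unbalanced brackets, unknown sugar
    token, unterminated branch, trailing characters.
    """
    if not notation.endswith("@"):
        raise GlycanParseError("string must end with '@'", max(len(notation) - 1, 0))
    root, i = _parse_chain(notation, 0)
    if i != len(notation) - 1:
        raise GlycanParseError("trailing characters after main chain terminator", i)
    return root


def _canonical_children(g: GlycanStructure) -> list[tuple[str, GlycanStructure]]:
    kids = [(lk, canonicalize(child)) for lk, child in g.children]
    kids.sort(key=lambda p: (p[0], _emit(p[1])))
    return kids


def canonicalize(g: GlycanStructure) -> GlycanStructure:
    """Sibling branches sorted by (linkage code, canonical subtree). Idempotent."""
    return GlycanStructure(g.sugar, _canonical_children(g), g.quenched)


def _emit(g: GlycanStructure) -> str:
    """Emit the chain rooted at ``g`` including its terminating ':'."""
    out = _SUGAR_TO_TOKEN[g.sugar]
    if not g.children:
        return out + ":"
    *head, (last_lk, last) = g.children
    for lk, child in head:
        out += "(" + lk + _emit(child) + ")"
    if head:
        out += "_" + _SUGAR_TO_TOKEN[last.sugar][0].lower()
    return out + last_lk + _emit(last)


def serialize(g: GlycanStructure) -> str:
    """Canonical linear-notation string for ``g`` (ends with ``:@``)."""
    return _emit(canonicalize(g)) + "@"


def count_sugar(g: GlycanStructure, sugar: str) -> int:
    return sum(1 for node in g.walk() if node.sugar == sugar)


def composition(g: GlycanStructure) -> GlycanComposition:
    """Count residues by MS class: Hex = Man + Gal; Glc kept separate."""
    n = {s: 0 for s in SUGARS}
    for node in g.walk():
        n[node.sugar] += 1
    return GlycanComposition(
        hex=n["Man"] + n["Gal"],
        hexnac=n["GlcNAc"],
        fuc=n["Fuc"],
        neuac=n["NeuAc"],
        glc=n["Glc"],
    )


@dataclass(frozen=True)
class Anatomy:
    """Landmark residues of the conserved N-glycan core, if present."""

    root: GlycanStructure
    core_glcnac2: Optional[GlycanStructure]
    core_man: Optional[GlycanStructure]
    arm3: Optional[GlycanStructure]  # 3.1-linked core-arm mannose
    arm6: Optional[GlycanStructure]  # 6.1-linked core-arm mannose


def _child(g: GlycanStructure, linkage: str, sugar: str) -> Optional[GlycanStructure]:
    for lk, child in g.children:
        if lk == linkage and child.sugar == sugar:
            return child
    return None


def anatomy(g: GlycanStructure) -> Anatomy:
    core_g2 = _child(g, "4.1", "GlcNAc") if g.sugar == "GlcNAc" else None
    core_man = _child(core_g2, "4.1", "Man") if core_g2 is not None else None
    arm3 = _child(core_man, "3.1", "Man") if core_man is not None else None
    arm6 = _child(core_man, "6.1", "Man") if core_man is not None else None
    return Anatomy(g, core_g2, core_man, arm3, arm6)


def _antennae(g: GlycanStructure) -> list[GlycanStructure]:
    """GlcNAc-initiated antennae: GlcNAc children of the two core-arm mannoses."""
    a = anatomy(g)
    out = []
    for arm in (a.arm3, a.arm6):
        if arm is None:
            continue
        out.extend(child for _, child in arm.children if child.sugar == "GlcNAc")
    return out


def antenna_count(g: GlycanStructure) -> int:
    return len(_antennae(g))


def classify(g: GlycanStructure) -> GlycanClass:
    """Oligomannose (5-9 Man, no antenna), hybrid (antenna + 5 Man),
    complex (antenna + trimannosyl core), else other (transient intermediates
    such as the 4-Man state mid mannosidase-II trimming)."""
    man = count_sugar(g, "Man")
    ant = antenna_count(g)
    if ant == 0 and 5 <= man <= 9:
        return GlycanClass.OLIGOMANNOSE
    if ant >= 1 and man == 5:
        return GlycanClass.HYBRID
    if ant >= 1 and man == 3:
        return GlycanClass.COMPLEX
    return GlycanClass.OTHER


def composition_key(c: GlycanComposition, fold_glc: bool = False) -> str:
    """Deterministic composition label, components in fixed order
    Fuc, NeuAc, Hex, HexNAc, Glc with zero counts omitted.

    The all-zero composition has no meaningful label and returns the
    sentinel ``"empty"`` (profiles never contain it).
    """
    if fold_glc:
        c = c.fold_glc()
    parts = []
    for name, n in (
        ("Fuc", c.fuc),
        ("NeuAc", c.neuac),
        ("Hex", c.hex),
        ("HexNAc", c.hexnac),
        ("Glc", c.glc),
    ):
        if n:
            parts.append(f"{name}{n}")
    return "".join(parts) or "empty"


def profile_key(g: GlycanStructure) -> str:
    """Composition key as reported in profiles: Glc folded into Hex,
    because mass spectrometry cannot distinguish Glc from other hexoses
    (Man9Glc reports as Hex10HexNAc2)."""
    return composition_key(composition(g), fold_glc=True)
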