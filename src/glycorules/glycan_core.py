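"""Glycan structures, compositions, and monoisotopic mass arithmetic.

This module is the mass-calculus foundation of the package.  It parses a
condensed structure dialect (``"Gal(b1-3)[Neu5Ac(a2-6)]GalNAc"``) into rooted
residue trees, derives monosaccharide-class compositions, and computes
theoretical m/z values for singly deprotonated ([M-H]-) glycans, optionally
reduced to the alditol at the reducing end (the state produced by reductive
beta-elimination of O-glycans).

Mass conventions
----------------
Residue masses are *dehydrated* monoisotopic masses computed from elemental
formulas (Hex = C6H10O5 etc.).  An intact glycan is the sum of its residue
masses plus one water (the reducing-end terminus); an alditol adds H2.
Deprotonation subtracts the mass of a proton (not of a hydrogen atom).
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field, replace

__all__ = [
    "ATOMIC_MASS",
    "NOMINAL_MASS",
    "PROTON_MASS",
    "WATER_MASS",
    "Composition",
    "GlycanStructure",
    "GlycanParseError",
    "Linkage",
    "Monosaccharide",
    "composition_of",
    "formula_mass",
    "formula_nominal_mass",
    "parse_composition",
    "parse_structure",
    "precursor_mz",
    "residue_mass",
    "serialize",
    "topology_key",
]

# ---------------------------------------------------------------------------
# Atomic and residue masses
# ---------------------------------------------------------------------------

ATOMIC_MASS = {
    "C": 12.0,
    "H": 1.00782503207,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "S": 31.97207100,
    "P": 30.97376163,
}

NOMINAL_MASS = {"C": 12, "H": 1, "N": 14, "O": 16, "S": 32, "P": 31}

PROTON_MASS = 1.007276466879

# Dehydrated residue formulas per monosaccharide class.
_CLASS_FORMULA = {
    "Hex": "C6H10O5",
    "HexNAc": "C8H13NO5",
    "dHex": "C6H10O4",
    "Neu5Ac": "C11H17NO8",
    "Neu5Gc": "C11H17NO9",
    "Kdn": "C9H14O8",
}

# Specific residue name -> monosaccharide class.
_NAME_TO_CLASS = {
    "Gal": "Hex",
    "Glc": "Hex",
    "Man": "Hex",
    "GalNAc": "HexNAc",
    "GlcNAc": "HexNAc",
    "Fuc": "dHex",
    "Hex": "Hex",
    "HexNAc": "HexNAc",
    "dHex": "dHex",
    "Neu5Ac": "Neu5Ac",
    "Neu5Gc": "Neu5Gc",
    "Kdn": "Kdn",
}

#: Generic class tokens, accepted wherever specific residues are but carrying
#: no residue identity (rejected by structure-resolved operations such as
#: fragment enumeration).
GENERIC_TOKENS = frozenset({"Hex", "HexNAc", "dHex"})

_MOD_FORMULA = {"S": "SO3", "P": "HPO3"}  # sulfate / phosphate adducts

_FORMULA_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


class GlycanParseError(ValueError):
    """Raised for malformed structure or composition strings."""


def formula_mass(formula: str) -> float:
    """Monoisotopic mass of an elemental formula over C, H, N, O, S, P.

    >>> round(formula_mass("H2O"), 4)
    18.0106
    """
    return _formula_mass(formula, ATOMIC_MASS)


def formula_nominal_mass(formula: str) -> int:
    """Nominal (integer) mass of an elemental formula (C=12, H=1, ...)."""
    return _formula_mass(formula, NOMINAL_MASS)


def _formula_mass(formula: str, table):
    if not formula or not re.fullmatch(r"(?:[A-Z][a-z]?\d*)+", formula):
        raise GlycanParseError(f"unparseable elemental formula: {formula!r}")
    total = 0
    for element, count in _FORMULA_RE.findall(formula):
        if not element:
            continue
        if element not in table:
            raise GlycanParseError(
                f"unsupported element {element!r} in formula {formula!r}"
            )
        total += table[element] * (int(count) if count else 1)
    return total


WATER_MASS = formula_mass("H2O")
_H2_MASS = formula_mass("H2")
_SULFATE_MASS = formula_mass(_MOD_FORMULA["S"])
_PHOSPHATE_MASS = formula_mass(_MOD_FORMULA["P"])


def residue_mass(name: str) -> float:
    """Dehydrated monoisotopic residue mass of a class or specific residue.

    Specific residues map to their class mass (Gal/Glc/Man share the Hex
    formula).  Raises :class:`GlycanParseError` for unknown names.
    """
    if name not in _NAME_TO_CLASS:
        raise GlycanParseError(f"unknown monosaccharide: {name!r}")
    return formula_mass(_CLASS_FORMULA[_NAME_TO_CLASS[name]])


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Monosaccharide:
    """A residue: a name from the supported vocabulary plus S/P modifications.

    ``modifications`` is a tuple of (kind, position) pairs with kind in
    {"S", "P"} and position an int or None (unknown position, e.g. "GalS").
    """

    name: str
    modifications: tuple[tuple[str, int | None], ...] = ()

    def __post_init__(self):
        if self.name not in _NAME_TO_CLASS:
            raise GlycanParseError(f"unknown monosaccharide: {self.name!r}")
        for kind, _pos in self.modifications:
            if kind not in _MOD_FORMULA:
                raise GlycanParseError(f"unknown modification: {kind!r}")

    @property
    def cls(self) -> str:
        return _NAME_TO_CLASS[self.name]

    @property
    def is_generic(self) -> bool:
        return self.name in GENERIC_TOKENS

    @property
    def mass(self) -> float:
        m = residue_mass(self.name)
        for kind, _pos in self.modifications:
            m += formula_mass(_MOD_FORMULA[kind])
        return m

    def token(self, wildcard_mod_positions: bool = False) -> str:
        parts = [self.name]
        for kind, pos in sorted(
            self.modifications, key=lambda kp: (kp[0], kp[1] is None, kp[1] or 0)
        ):
            if pos is None or wildcard_mod_positions:
                parts.append(kind)
            else:
                parts.append(f"{pos}{kind}")
        return "".join(parts)


@dataclass(frozen=True)
class Linkage:
    """Glycosidic linkage annotation; '?' marks unknown fields."""

    anomericity: str = "?"  # {a, b, ?}
    donor_position: str = "?"  # {1, 2, ?}
    acceptor_position: str = "?"  # {1..9, ?}

    def __post_init__(self):
        if self.anomericity not in ("a", "b", "?"):
            raise GlycanParseError(f"bad anomericity: {self.anomericity!r}")
        if self.donor_position not in ("1", "2", "?"):
            raise GlycanParseError(f"bad donor position: {self.donor_position!r}")
        if self.acceptor_position not in tuple("123456789?"):
            raise GlycanParseError(
                f"bad acceptor position: {self.acceptor_position!r}"
            )

    def token(self) -> str:
        return f"({self.anomericity}{self.donor_position}-{self.acceptor_position})"


Linkage.WILDCARD = Linkage("?", "?", "?")


@dataclass(frozen=True)
class GlycanStructure:
    """Rooted residue tree; the root is the (possibly reduced) reducing end."""

    root: Monosaccharide
    children: tuple[tuple[Linkage, "GlycanStructure"], ...] = ()
    reduced: bool = True

    @property
    def residues(self) -> list[Monosaccharide]:
        out = [self.root]
        for _lk, child in self.children:
            out.extend(child.residues)
        return out

    @property
    def residue_mass_sum(self) -> float:
        return sum(r.mass for r in self.residues)

    def has_generic(self) -> bool:
        return any(r.is_generic for r in self.residues)

    def canonical(self) -> "GlycanStructure":
        """Children sorted by (descending branch mass, lexicographic form)."""
        kids = tuple(
            (lk, child.canonical()) for lk, child in self.children
        )
        kids = tuple(
            sorted(
                kids,
                key=lambda lc: (-lc[1].residue_mass_sum, _serialize(lc[1]) + lc[0].token()),
            )
        )
        return replace(self, children=kids)


def _serialize(g: GlycanStructure, wildcard: bool = False) -> str:
    """Serialize an (already canonical) subtree, without the -ol suffix."""
    kids = g.children
    parts = []
    for i, (lk, child) in enumerate(kids):
        lk_tok = Linkage.WILDCARD.token() if wildcard else lk.token()
        sub = _serialize(child, wildcard) + lk_tok
        parts.append(sub if i == 0 else f"[{sub}]")
    parts.append(g.root.token(wildcard_mod_positions=wildcard))
    return "".join(parts)


def serialize(g: GlycanStructure) -> str:
    """Canonical string form; appends ``-ol`` when the glycan is reduced."""
    text = _serialize(g.canonical())
    return text + "-ol" if g.reduced else text


def topology_key(g: GlycanStructure) -> str:
    """Linkage-erased canonical form: the topology label of a structure.

    All linkage fields (anomericity and positions) and modification positions
    are wildcarded, so linkage isomers (e.g. Lewis A vs Lewis X, or Gal3S vs
    Gal6S) collapse to one key, while residue identity and connectivity
    still separate topologies (core 1 Gal-GalNAc vs core 3 GlcNAc-GalNAc).
    """
    text = _serialize(g.canonical(), wildcard=True)
    return text + "-ol" if g.reduced else text


# ---------------------------------------------------------------------------
# Structure grammar
# ---------------------------------------------------------------------------

_RESIDUE_RE = re.compile(
    r"(Neu5Ac|Neu5Gc|Kdn|GalNAc|GlcNAc|Gal|Glc|Man|Fuc|HexNAc|dHex|Hex)"
    r"((?:\d?[SP])*)"
)
_LINKAGE_RE = re.compile(r"\(([ab?])([12?])-([1-9?])\)")
_MOD_RE = re.compile(r"(\d?)([SP])")


def _parse_residue_token(match: re.Match) -> Monosaccharide:
    name, mods_text = match.group(1), match.group(2)
    mods = tuple(
        (kind, int(pos) if pos else None) for pos, kind in _MOD_RE.findall(mods_text)
    )
    return Monosaccharide(name, mods)


def parse_structure(text: str) -> GlycanStructure:
    """Parse the condensed structure dialect into a rooted residue tree.

    The rightmost residue is the root (reducing end); each residue carries a
    linkage to the residue on its right; bracketed groups are side branches
    of the residue following them.  An optional ``-ol`` suffix marks the
    alditol; reduced defaults to True (the package targets glycans released
    by reductive beta-elimination).

    >>> g = parse_structure("Gal(b1-3)[Neu5Ac(a2-6)]GalNAc")
    >>> g.root.name
    'GalNAc'
    """
    raw = text.strip()
    if not raw:
        raise GlycanParseError("empty structure string")
    reduced = True
    if raw.endswith("-ol"):
        raw = raw[:-3]

    pos = 0
    n = len(raw)

    def error(msg, at):
        raise GlycanParseError(f"{msg} at position {at} in {text!r}")

    def parse_chain(depth):
        # Returns (tree, dangling_linkage_or_None, stopped_at_bracket_close)
        nonlocal pos
        pending: list[tuple[Linkage, GlycanStructure]] = []
        current: tuple[Linkage, GlycanStructure] | None = None
        while pos < n:
            ch = raw[pos]
            if ch == "[":
                pos += 1
                branch, dangling, closed = parse_chain(depth + 1)
                if not closed:
                    error("unbalanced bracket", pos)
                if dangling is None:
                    error("branch missing linkage before ']'", pos)
                pending.append((dangling, branch))
                continue
            if ch == "]":
                if depth == 0:
                    error("unbalanced ']'", pos)
                pos += 1
                if current is None:
                    error("empty bracket group", pos)
                lk, tree = current
                if pending:
                    error("dangling branch inside bracket", pos)
                return tree, lk, True
            m = _RESIDUE_RE.match(raw, pos)
            if not m:
                error(f"unknown residue token {raw[pos:pos + 12]!r}", pos)
            residue = _parse_residue_token(m)
            pos = m.end()
            kids = []
            if current is not None:
                kids.append(current)
            kids.extend(pending)
            pending = []
            node = GlycanStructure(residue, tuple(kids), reduced=False)
            lm = _LINKAGE_RE.match(raw, pos)
            if lm:
                pos = lm.end()
                current = (Linkage(lm.group(1), lm.group(2), lm.group(3)), node)
            else:
                if pos < n and raw[pos] == "(":
                    error("malformed linkage", pos)
                if pos < n and raw[pos] not in "]":
                    error(f"unexpected character {raw[pos]!r}", pos)
                current = (None, node)
                if pos < n and raw[pos] == "]":
                    continue  # handled by ']' branch
                break
        if current is None:
            error("empty structure", pos)
        lk, tree = current
        if pending:
            error("branch group not followed by a residue", pos)
        return tree, lk, False

    tree, dangling, _closed = parse_chain(0)
    if pos < n:
        error("unbalanced bracket", pos)
    if dangling is not None:
        error("dangling linkage at reducing end", pos)
    return replace(tree, reduced=reduced).canonical()


# ---------------------------------------------------------------------------
# Compositions
# ---------------------------------------------------------------------------

_CLASS_ORDER = ("Hex", "HexNAc", "dHex", "Neu5Ac", "Neu5Gc", "Kdn")


@dataclass(frozen=True)
class Composition:
    """Counts of monosaccharide classes plus sulfate/phosphate counts."""

    counts: tuple[tuple[str, int], ...]
    sulfates: int = 0
    phosphates: int = 0

    def __post_init__(self):
        if any(c <= 0 for _n, c in self.counts) or not self.counts:
            raise GlycanParseError("composition must have >= 1 residue")
        for name, _c in self.counts:
            if name not in _CLASS_FORMULA:
                raise GlycanParseError(f"unknown residue class: {name!r}")

    @classmethod
    def from_dict(cls, counts: dict, sulfates: int = 0, phosphates: int = 0):
        ordered = tuple(
            (name, counts[name]) for name in _CLASS_ORDER if counts.get(name)
        )
        return cls(ordered, sulfates, phosphates)

    def as_dict(self) -> dict:
        return dict(self.counts)

    @property
    def total_residues(self) -> int:
        return sum(c for _n, c in self.counts)

    @property
    def residue_mass_sum(self) -> float:
        return sum(residue_mass(name) * c for name, c in self.counts)

    def to_string(self) -> str:
        """Concatenated dialect, e.g. ``"Hex1HexNAc2dHex1S1"``."""
        text = "".join(f"{name}{c}" for name, c in self.counts)
        if self.sulfates:
            text += f"S{self.sulfates}"
        if self.phosphates:
            text += f"P{self.phosphates}"
        return text


_COMP_TOKEN_RE = re.compile(r"(Hex(?!NAc)|HexNAc|dHex|Neu5Ac|Neu5Gc|Kdn|S|P)(\d+)")


def parse_composition(text: str) -> Composition:
    """Parse the ``"Hex1HexNAc2dHex1S1"`` composition dialect (round-trips)."""
    stripped = text.strip()
    matched = "".join(t + c for t, c in _COMP_TOKEN_RE.findall(stripped))
    if not stripped or matched != stripped:
        raise GlycanParseError(f"unparseable composition string: {text!r}")
    counts: Counter = Counter()
    sulfates = phosphates = 0
    for token, count in _COMP_TOKEN_RE.findall(stripped):
        c = int(count)
        if token == "S":
            sulfates += c
        elif token == "P":
            phosphates += c
        else:
            counts[token] += c
    return Composition.from_dict(counts, sulfates, phosphates)


def composition_of(g: GlycanStructure) -> Composition:
    """Class-level composition of a structure (Gal/Glc/Man->Hex, etc.)."""
    counts: Counter = Counter()
    sulfates = phosphates = 0
    for r in g.residues:
        counts[r.cls] += 1
        for kind, _pos in r.modifications:
            if kind == "S":
                sulfates += 1
            else:
                phosphates += 1
    return Composition.from_dict(counts, sulfates, phosphates)


def label_to_composition(label: str) -> Composition:
    """Composition of an annotation label (structure or composition string)."""
    try:
        return parse_composition(label)
    except GlycanParseError:
        return composition_of(parse_structure(label))


# ---------------------------------------------------------------------------
# Precursor m/z
# ---------------------------------------------------------------------------


def precursor_mz(c: Composition, reduced: bool = True, charge: int = -1) -> float:
    """Theoretical m/z of the singly deprotonated glycan of composition *c*.

    Sum of dehydrated residue masses + H2O (reducing-end water) + H2 for the
    alditol, minus one proton.  Only charge -1 is supported (the rule sets
    this package mines are stated on singly deprotonated ions).
    """
    if charge != -1:
        raise ValueError("only charge -1 is supported")
    mass = c.residue_mass_sum + WATER_MASS
    if reduced:
        mass += _H2_MASS
    mass += c.sulfates * _SULFATE_MASS + c.phosphates * _PHOSPHATE_MASS
    return mass - PROTON_MASS
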