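"""Theoretical Domon-Costello fragment enumeration and m/z annotation.

Candidate fragments of a glycan structure are enumerated over glycosidic
cleavages: B/C ions retain the non-reducing side, Y/Z ions the reducing
side; double cleavages yield composite fragments (internal B/Y-style pieces
and double branch losses).  Each base fragment can combine with configured
neutral losses, and the intact ion gets loss-only "M-X" entries — the
chemistry behind diagnostic losses such as M-78 (C2H6O3) and M-94 (C2H6O4)
from sialylated, reduced glycans.  A-type cross-ring candidates on the
reducing-end alditol are modeled as specific neutral losses (0,2A as
-C2H4O2, 2,4A as -C4H8O4) applied to the intact ion or to Y fragments,
rather than by general ring-bond combinatorics.

Mass bookkeeping (singly deprotonated, 1- charge throughout): a fragment's
neutral mass starts from the free-molecule form of its residue set (sum of
dehydrated residue masses + H2O, plus H2 when it retains the reduced root);
each B-type or Z-type terminus subtracts one water, C-type and Y-type
termini add nothing.  This reproduces B = sum(residues) - proton,
C = B + H2O, Y = substructure alditol [M-H]-, Z = Y - H2O, and the
complementarity mz(B) + mz(Y) = precursor_mz - proton for every single
cleavage.

Branch letters follow the heaviest-branch-is-alpha convention inherited
from the canonical branch order of ``glycan_core``; at any branching node
the children receive alpha, beta, gamma in canonical (descending-mass)
order.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from itertools import combinations

from .glycan_core import (
    GlycanStructure,
    PROTON_MASS,
    WATER_MASS,
    formula_mass,
)

__all__ = [
    "DEFAULT_LOSSES",
    "FragmentCatalog",
    "FragmentLabel",
    "annotate_mz",
    "enumerate_fragments",
    "loss_variants",
]

#: Default neutral-loss set: water losses, CO2 (carboxylate), and the
#: C2-unit losses implicated in sialic-acid fragmentation (acetyl loss
#: paired with one or two water losses -> C2H6O3 at nominal 78,
#: C2H6O4 at 94 for the N-glycolyl analog).
DEFAULT_LOSSES: tuple[tuple[str, ...], ...] = (
    ("H2O",),
    ("H2O", "H2O"),
    ("CO2",),
    ("C2H4O2",),
    ("C2H6O3",),
    ("C2H6O4",),
)

#: A-type cross-ring candidates on the reducing-end alditol.
A_TYPE_LOSSES: tuple[tuple[str, str], ...] = (("0,2A", "C2H4O2"), ("2,4A", "C4H8O4"))

DEFAULT_MATCH_TOLERANCE = 0.2  # Da; unit-resolution ion-trap CID data

_GREEK = "αβγδε"
_H2_MASS = formula_mass("H2")


@dataclass(frozen=True)
class FragmentLabel:
    """Human-readable candidate assignment for an m/z value."""

    ion_series: str  # {"M", "B", "C", "Y", "Z", "A-type", "composite"}
    label: str  # e.g. "B1α", "Y1β-H2O", "M-C2H6O3", "Y1α/Y1β"
    neutral_losses: tuple[str, ...]
    retained_residues: tuple[str, ...]  # residue tokens of the fragment
    mz: float
    n_cleavages: int

    def __post_init__(self):
        if self.mz <= 0:
            raise ValueError("fragment m/z must be positive")


@dataclass(frozen=True)
class FragmentCatalog:
    structure: GlycanStructure
    entries: tuple[FragmentLabel, ...]  # sorted by mz
    max_cleavages: int

    def within(self, mz: float, tol: float) -> list[FragmentLabel]:
        return [e for e in self.entries if abs(e.mz - mz) <= tol]


# ---------------------------------------------------------------------------
# Tree helpers (operate on one canonical tree; subtree identity by object)
# ---------------------------------------------------------------------------


def _edges(g: GlycanStructure) -> list[dict]:
    """Glycosidic edges of an (already canonical) tree.

    Each entry: 'id' (path tuple), 'subtree' (detached non-reducing side),
    'depth' (bonds from root, 1-based), 'branch' (greek letter at the
    nearest branching ancestor, '' on unbranched chains).
    """
    out = []

    def walk(node, depth, branch, path):
        branching = len(node.children) > 1
        for ci, (_lk, child) in enumerate(node.children):
            b = _GREEK[ci] if branching and ci < len(_GREEK) else branch
            edge_id = path + (ci,)
            out.append(
                {"id": edge_id, "subtree": child, "depth": depth + 1, "branch": b}
            )
            walk(child, depth + 1, b, edge_id)

    walk(g, 0, "", ())
    return out


def _subtree_depth(g: GlycanStructure) -> int:
    return 1 + max((_subtree_depth(c) for _lk, c in g.children), default=0)


def _residue_tokens(g: GlycanStructure) -> tuple[str, ...]:
    return tuple(r.token() for r in g.residues)


def _tokens_minus(g: GlycanStructure, *removed: GlycanStructure) -> tuple[str, ...]:
    gone = {id(r) for sub in removed for r in sub.residues}
    return tuple(r.token() for r in g.residues if id(r) not in gone)


def _mass_minus(g: GlycanStructure, *removed: GlycanStructure) -> float:
    gone = {id(r) for sub in removed for r in sub.residues}
    return sum(r.mass for r in g.residues if id(r) not in gone)


def _is_ancestor(a: tuple, b: tuple) -> bool:
    return len(a) < len(b) and b[: len(a)] == a


# ---------------------------------------------------------------------------
# Enumeration
# ---------------------------------------------------------------------------


def _loss_mass(losses: tuple[str, ...]) -> float:
    return sum(formula_mass(f) for f in losses)


def _loss_suffix(losses: tuple[str, ...]) -> str:
    return "".join(f"-{f}" for f in losses)


def enumerate_fragments(
    g: GlycanStructure,
    max_cleavages: int = 2,
    losses: tuple[tuple[str, ...], ...] = DEFAULT_LOSSES,
) -> FragmentCatalog:
    """Enumerate candidate fragments up to ``max_cleavages`` glycosidic cuts.

    Requires fully specified residues; generic class tokens (Hex, HexNAc,
    dHex) carry no connectivity and are rejected — match against
    compositions instead.
    """
    if max_cleavages not in (1, 2):
        raise ValueError("max_cleavages must be 1 or 2")
    if g.has_generic():
        raise ValueError(
            "structure contains generic residue tokens; fragment enumeration "
            "needs fully specified residues (use composition-level matching)"
        )
    g = g.canonical()
    reduced_term = _H2_MASS if g.reduced else 0.0
    intact_neutral = g.residue_mass_sum + WATER_MASS + reduced_term
    all_tokens = _residue_tokens(g)
    edges = _edges(g)
    loss_options: list[tuple[str, ...]] = [()] + [tuple(l) for l in losses]

    raw: list[FragmentLabel] = []

    def add(series, label, loss_tuple, residues, neutral, n_cleave,
            suffix_in_label=True):
        mz = neutral - _loss_mass(loss_tuple) - PROTON_MASS
        if mz <= 0:
            return
        raw.append(
            FragmentLabel(
                ion_series=series,
                label=label + (_loss_suffix(loss_tuple) if suffix_in_label else ""),
                neutral_losses=loss_tuple,
                retained_residues=residues,
                mz=mz,
                n_cleavages=n_cleave,
            )
        )

    # Intact ion and loss-only "M-X" entries.
    for lt in loss_options:
        add("M", "M", lt, all_tokens, intact_neutral, 0)
    for a_label, a_formula in A_TYPE_LOSSES:
        add("A-type", a_label, (a_formula,), all_tokens, intact_neutral, 0,
            suffix_in_label=False)

    # Single cleavages: B/C (non-reducing side) and Y/Z (reducing side).
    for edge in edges:
        sub = edge["subtree"]
        sub_tokens = _residue_tokens(sub)
        root_tokens = _tokens_minus(g, sub)
        root_mass = _mass_minus(g, sub)
        suffix = f"{edge['depth']}{edge['branch']}"
        b_idx = f"{_subtree_depth(sub)}{edge['branch']}"
        b_neutral = sub.residue_mass_sum  # free form - H2O
        y_neutral = root_mass + WATER_MASS + reduced_term
        pieces = [
            ("B", f"B{b_idx}", sub_tokens, b_neutral),
            ("C", f"C{b_idx}", sub_tokens, b_neutral + WATER_MASS),
            ("Y", f"Y{suffix}", root_tokens, y_neutral),
            ("Z", f"Z{suffix}", root_tokens, y_neutral - WATER_MASS),
        ]
        for series, label, tokens, neutral in pieces:
            for lt in loss_options:
                add(series, label, lt, tokens, neutral, 1)
            if series == "Y":
                for a_label, a_formula in A_TYPE_LOSSES:
                    add("A-type", f"{label}-{a_label}", (a_formula,), tokens,
                        neutral, 1, suffix_in_label=False)

    # Double cleavages.
    if max_cleavages == 2:
        for e1, e2 in combinations(edges, 2):
            nested = _is_ancestor(e1["id"], e2["id"]) or _is_ancestor(
                e2["id"], e1["id"]
            )
            if nested:
                outer, inner = (
                    (e1, e2) if _is_ancestor(e1["id"], e2["id"]) else (e2, e1)
                )
                mid_tokens = _tokens_minus(outer["subtree"], inner["subtree"])
                mid_mass = _mass_minus(outer["subtree"], inner["subtree"])
                out_b = f"{_subtree_depth(outer['subtree'])}{outer['branch']}"
                in_yz = f"{inner['depth']}{inner['branch']}"
                for up, up_adj in (("Y", 0.0), ("Z", -WATER_MASS)):
                    for lo, lo_adj in (("B", -WATER_MASS), ("C", 0.0)):
                        neutral = mid_mass + WATER_MASS + up_adj + lo_adj
                        label = f"{up}{in_yz}/{lo}{out_b}"
                        for lt in loss_options:
                            add("composite", label, lt, mid_tokens, neutral, 2)
            else:
                root_tokens = _tokens_minus(g, e1["subtree"], e2["subtree"])
                base = (
                    _mass_minus(g, e1["subtree"], e2["subtree"])
                    + WATER_MASS
                    + reduced_term
                )
                for s1, adj1 in (("Y", 0.0), ("Z", -WATER_MASS)):
                    for s2, adj2 in (("Y", 0.0), ("Z", -WATER_MASS)):
                        label = (
                            f"{s1}{e1['depth']}{e1['branch']}/"
                            f"{s2}{e2['depth']}{e2['branch']}"
                        )
                        for lt in loss_options:
                            add("composite", label, lt, root_tokens,
                                base + adj1 + adj2, 2)

    # Deduplicate on (label, rounded mz); sort by mz.
    seen = set()
    entries = []
    for e in sorted(raw, key=lambda e: (e.mz, e.label)):
        key = (e.label, round(e.mz, 6))
        if key not in seen:
            seen.add(key)
            entries.append(e)
    return FragmentCatalog(
        structure=g, entries=tuple(entries), max_cleavages=max_cleavages
    )


def loss_variants(
    precursor: float, losses: tuple[tuple[str, ...], ...] = DEFAULT_LOSSES
) -> list[tuple[str, float]]:
    """Intact-ion-minus-loss entries ``[("M", mz), ("M-C2H6O3", mz), ...]``."""
    out = [("M", precursor)]
    for lt in losses:
        lt = (lt,) if isinstance(lt, str) else tuple(lt)
        out.append((f"M{_loss_suffix(lt)}", precursor - _loss_mass(lt)))
    return out


def annotate_mz(
    mz: float,
    candidates: list[GlycanStructure],
    tol: float = DEFAULT_MATCH_TOLERANCE,
    max_cleavages: int = 2,
    losses: tuple[tuple[str, ...], ...] = DEFAULT_LOSSES,
) -> list[FragmentLabel] | str:
    """All candidate fragment assignments within ``tol`` of an m/z value.

    Matches are pooled over all candidate structures and sorted by
    (|delta mz|, fewer cleavages, fewer losses).  An empty result returns
    the string ``"unassigned"`` — a legitimate outcome; plenty of
    diagnostic ions have no accepted structural assignment.
    """
    if tol <= 0:
        raise ValueError("tolerance must be positive")
    hits: list[FragmentLabel] = []
    for g in candidates:
        if g.has_generic():
            continue
        catalog = enumerate_fragments(g, max_cleavages=max_cleavages, losses=losses)
        hits.extend(catalog.within(mz, tol))
    if not hits:
        return "unassigned"
    hits.sort(
        key=lambda e: (abs(e.mz - mz), e.n_cleavages, len(e.neutral_losses), e.label)
    )
    return hits
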