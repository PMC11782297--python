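"""Shared fixtures: random glycan structures and small synthetic corpora."""

from __future__ import annotations

import numpy as np
import pytest

from glycorules.glycan_core import (
    GlycanStructure,
    Linkage,
    Monosaccharide,
)

# Residues with full identity (no generic class tokens) for structure-level
# operations such as fragment enumeration.
SPECIFIC_RESIDUES = (
    "Gal", "Glc", "Man", "GalNAc", "GlcNAc", "Fuc", "Neu5Ac", "Neu5Gc", "Kdn",
)


def random_structure(
    rng: np.random.Generator,
    max_residues: int = 6,
    reduced: bool = True,
) -> GlycanStructure:
    """A random rooted glycan tree with 1..max_residues specific residues."""
    n = int(rng.integers(1, max_residues + 1))

    def make(budget: int) -> tuple[GlycanStructure, int]:
        name = str(rng.choice(SPECIFIC_RESIDUES))
        node_budget = budget - 1
        children = []
        while node_budget > 0 and rng.random() < 0.55 and len(children) < 3:
            child, node_budget = make(node_budget)
            lk = Linkage(
                anomericity=str(rng.choice(["a", "b", "?"])),
                donor_position=str(rng.choice(["1", "2"])),
                acceptor_position=str(rng.choice(list("23468?"))),
            )
            children.append((lk, child))
        return (
            GlycanStructure(
                Monosaccharide(name), tuple(children), reduced=False
            ),
            node_budget,
        )

    tree, _ = make(n)
    return GlycanStructure(tree.root, tree.children, reduced=reduced).canonical()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
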