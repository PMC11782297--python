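"""Mass grouping and experiment-disjoint stratified train/val/test splitting.

One model is trained per *mass group*: all annotated spectra whose labeled
composition has a theoretical [M-H]- within +/-0.5 Da of a common value.
Each group's spectra are split 70/20/10 into train/validation/test at the
granularity of whole provenance keys (dataset_id, filename), so that rules
are always evaluated on experiments never seen during training, while a
stratification repair pass guarantees every class is present in every split.
This is a greedy key-level assignment; it enforces the two properties the
split exists for — experiment-level disjointness and class presence — with
deterministic output for a given seed.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .glycan_core import GlycanParseError, label_to_composition, precursor_mz
from .spectra_prep import AnnotatedSpectrum

__all__ = [
    "MassGroup",
    "SplitAssignment",
    "SplitError",
    "assign_mass_groups",
    "grouped_stratified_split",
    "write_split_manifest",
]

logger = logging.getLogger(__name__)

DEFAULT_FRACTIONS = (0.7, 0.2, 0.1)
SPLIT_NAMES = ("train", "val", "test")
MASS_GROUP_TOLERANCE = 0.5  # Da around the theoretical composition mass
DEFAULT_MIN_CLASS_SPECTRA = 10


class SplitError(ValueError):
    """Raised when a stratified, key-disjoint split cannot be guaranteed."""


@dataclass
class MassGroup:
    """All spectra whose labeled composition is isobaric within 0.5 Da."""

    center_mz: float
    members: list[AnnotatedSpectrum]
    trainable: bool = True
    untrainable_reason: str = ""

    @property
    def classes(self) -> list[str]:
        return sorted({m.label for m in self.members})

    def class_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for m in self.members:
            out[m.label] = out.get(m.label, 0) + 1
        return out


@dataclass
class SplitAssignment:
    train: list[AnnotatedSpectrum]
    validation: list[AnnotatedSpectrum]
    test: list[AnnotatedSpectrum]
    key_to_split: dict[tuple[str, str], str] = field(default_factory=dict)

    def as_dict(self) -> dict[str, list[AnnotatedSpectrum]]:
        return {"train": self.train, "val": self.validation, "test": self.test}


def assign_mass_groups(
    spectra: Sequence[AnnotatedSpectrum],
    min_class_spectra: int = DEFAULT_MIN_CLASS_SPECTRA,
    tolerance: float = MASS_GROUP_TOLERANCE,
) -> list[MassGroup]:
    """Group spectra by the theoretical reduced [M-H]- of their labels.

    Labels within ``tolerance`` Da of each other (isobaric compositions)
    merge into one group.  Spectra with unparseable labels are skipped with
    a logged warning.  Groups with fewer than two classes, or with any class
    under ``min_class_spectra`` spectra, are flagged untrainable.
    """
    labeled: list[tuple[float, AnnotatedSpectrum]] = []
    n_skipped = 0
    for sp in spectra:
        try:
            mz = precursor_mz(label_to_composition(sp.label))
        except GlycanParseError as exc:
            n_skipped += 1
            logger.warning("skipping spectrum %s: unparseable label %r (%s)",
                           sp.spectrum.scan_id, sp.label, exc)
            continue
        labeled.append((mz, sp))
    if n_skipped:
        logger.warning("%d spectra skipped for unparseable labels", n_skipped)

    labeled.sort(key=lambda t: (t[0], t[1].spectrum.scan_id))
    groups: list[MassGroup] = []
    cluster: list[tuple[float, AnnotatedSpectrum]] = []

    def close(cluster):
        mzs = [m for m, _s in cluster]
        center = float(np.mean(mzs))
        group = MassGroup(center_mz=center, members=[s for _m, s in cluster])
        counts = group.class_counts()
        if len(counts) < 2:
            group.trainable = False
            group.untrainable_reason = "fewer than 2 classes"
        else:
            small = {c: n for c, n in counts.items() if n < min_class_spectra}
            if small:
                group.trainable = False
                group.untrainable_reason = (
                    f"classes below {min_class_spectra} spectra: {small}"
                )
        groups.append(group)

    for mz, sp in labeled:
        if cluster and mz - cluster[0][0] > tolerance:
            close(cluster)
            cluster = []
        cluster.append((mz, sp))
    if cluster:
        close(cluster)
    return groups


# ---------------------------------------------------------------------------
# Greedy stratified key-level split
# ---------------------------------------------------------------------------


def grouped_stratified_split(
    group: MassGroup,
    fractions: tuple[float, float, float] = DEFAULT_FRACTIONS,
    seed: int = 0,
) -> SplitAssignment:
    """Split a mass group into train/val/test by whole provenance keys.

    Whole (dataset_id, filename) keys are assigned to splits — never split
    across them — targeting the requested spectrum-count fractions.  A
    seeding pass first guarantees each class a key in each split; remaining
    keys then fill the most-deficient split; a repair pass fixes any class
    absences the filling introduced.  Deterministic given the seed and
    invariant to the input ordering of spectra.
    """
    if len(fractions) != 3 or abs(sum(fractions) - 1.0) > 1e-9:
        raise SplitError("fractions must be three values summing to 1")
    members = sorted(
        group.members,
        key=lambda m: (m.spectrum.dataset_id, m.spectrum.filename,
                       m.spectrum.scan_id, m.label),
    )
    key_spectra: dict[tuple[str, str], list[AnnotatedSpectrum]] = {}
    key_classes: dict[tuple[str, str], set[str]] = {}
    for m in members:
        k = m.spectrum.provenance_key
        key_spectra.setdefault(k, []).append(m)
        key_classes.setdefault(k, set()).add(m.label)

    classes = group.classes
    for c in classes:
        n_keys = sum(1 for ks in key_classes.values() if c in ks)
        if n_keys < 3:
            raise SplitError(
                f"class {c!r} occurs in only {n_keys} provenance key(s); "
                "cannot guarantee presence in all splits"
            )

    rng = np.random.default_rng(seed)
    keys = sorted(key_spectra)
    order = list(rng.permutation(len(keys)))
    keys = [keys[i] for i in order]
    # seeded tie-break rank: all later ordering decisions use it, so the
    # seed genuinely randomizes the assignment while staying reproducible
    rank = {k: i for i, k in enumerate(keys)}

    total = len(members)
    targets = [f * total for f in fractions]
    counts = [0.0, 0.0, 0.0]
    assignment: dict[tuple[str, str], int] = {}

    def split_classes(si: int) -> set[str]:
        out: set[str] = set()
        for k, s in assignment.items():
            if s == si:
                out |= key_classes[k]
        return out

    # Seeding: one key per class per split, scarcest classes first.
    class_order = sorted(classes, key=lambda c: (
        sum(1 for ks in key_classes.values() if c in ks), c))
    for c in class_order:
        for si in (0, 1, 2):
            if c in split_classes(si):
                continue
            candidates = [k for k in keys if k not in assignment and c in key_classes[k]]
            if not candidates:
                continue  # repaired later
            # prefer small keys for val/test, large for train
            candidates.sort(key=lambda k: (len(key_spectra[k]), rank[k]))
            k = candidates[-1] if si == 0 else candidates[0]
            assignment[k] = si
            counts[si] += len(key_spectra[k])

    # Fill: largest keys first into the split with the largest remaining
    # absolute spectrum deficit (ties toward train, the largest quota).
    remaining = sorted(
        (k for k in keys if k not in assignment),
        key=lambda k: (-len(key_spectra[k]), rank[k]),
    )
    for k in remaining:
        deficits = [targets[si] - counts[si] for si in range(3)]
        si = int(np.argmax(deficits))
        assignment[k] = si
        counts[si] += len(key_spectra[k])

    # Repair: ensure class presence everywhere.
    for _pass in range(2 * len(classes) + 1):
        missing = [
            (c, si)
            for c in classes
            for si in (0, 1, 2)
            if c not in split_classes(si)
        ]
        if not missing:
            break
        c, si = missing[0]
        movable = []
        for k, s in assignment.items():
            if s == si or c not in key_classes[k]:
                continue
            donor_classes_after = set()
            for k2, s2 in assignment.items():
                if s2 == s and k2 != k:
                    donor_classes_after |= key_classes[k2]
            if key_classes[k] <= donor_classes_after:
                movable.append((len(key_spectra[k]), rank[k], k))
        if not movable:
            raise SplitError(
                f"cannot establish class {c!r} in split "
                f"{SPLIT_NAMES[si]!r} without breaking stratification"
            )
        _n, _r, k = min(movable)
        counts[assignment[k]] -= len(key_spectra[k])
        assignment[k] = si
        counts[si] += len(key_spectra[k])
    else:
        raise SplitError("stratification repair did not converge")

    splits: list[list[AnnotatedSpectrum]] = [[], [], []]
    for m in members:
        splits[assignment[m.spectrum.provenance_key]].append(m)
    return SplitAssignment(
        train=splits[0],
        validation=splits[1],
        test=splits[2],
        key_to_split={k: SPLIT_NAMES[si] for k, si in sorted(assignment.items())},
    )


def write_split_manifest(split: SplitAssignment, path: str | Path) -> None:
    """Write the split manifest TSV (scan_id, dataset_id, filename, label, split)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["scan_id", "dataset_id", "filename", "label", "split"])
        for name, members in zip(SPLIT_NAMES, (split.train, split.validation, split.test)):
            for m in members:
                writer.writerow(
                    [m.spectrum.scan_id, m.spectrum.dataset_id,
                     m.spectrum.filename, m.label, name]
                )
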