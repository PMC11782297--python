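"""Rule mining: trees -> decision-path rules with confidence and coverage.

This module orchestrates the divide-and-conquer hierarchy for one mass
group: when the group's classes span more than one topology *and* at least
one topology contains several isomers, a topology tree is trained first and
separate isomer trees are trained per topology; when every topology holds a
single isomer (so classifying topology already decides the isomer) a single
flat tree is trained.  Each tree is depth-selected on validation data.

From every fitted tree, the best root-to-leaf decision path per class is
extracted as an annotation rule — a conjunction of threshold conditions on
bin or ratio features — scored by confidence x coverage on held-out test
spectra from experiments never seen in training:

* confidence — among test spectra satisfying all conditions, the fraction
  whose true label equals the rule's isomer (the rule's precision);
* coverage — the fraction of the isomer's test spectra that satisfy the
  conditions (the rule's recall).

Bins referenced by rule conditions are mapped back to exact m/z values via
the training spectra's intensity-weighted bin offsets, and annotated with
candidate Domon-Costello fragments of the group's structures.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from . import __version__ as _pkg_version
from .config import RunConfig
from .dataset_split import MassGroup, SplitAssignment
from .entropy_tree import DecisionTree, TreeNode, predict_batch, select_depth
from .fragment_annotation import annotate_mz
from .glycan_core import GlycanParseError, parse_structure, topology_key
from .spectra_prep import (
    AnnotatedSpectrum,
    BinnedSpectrum,
    FeatureSpec,
    Spectrum,
    apply_feature_specs,
    build_feature_matrix,
    evaluate_feature,
    preprocess,
)

__all__ = [
    "AnnotationResult",
    "MassGroupMismatch",
    "Rule",
    "RuleCondition",
    "RuleSet",
    "RuleSetSchemaError",
    "annotate",
    "confidence",
    "coverage",
    "extract_best_paths",
    "load_ruleset",
    "map_rule_mz",
    "rule_matches",
    "serialize_ruleset",
    "train_group",
]

SCHEMA_VERSION = 1
LOW_PERFORMANCE_FLOOR = 0.6  # confidence/coverage reporting floor
NEAR_THRESHOLD_MARGIN = 0.1  # relative margin for borderline warnings


class RuleSetSchemaError(ValueError):
    """Raised when a rule-set JSON does not match the expected schema."""


class MassGroupMismatch(ValueError):
    """Raised when a spectrum's precursor lies outside a rule set's group."""


@dataclass(frozen=True)
class RuleCondition:
    feature: FeatureSpec
    comparator: str  # {"<=", ">"}
    threshold: float | None  # None only for transcribed literature rules

    def __post_init__(self):
        if self.comparator not in ("<=", ">"):
            raise RuleSetSchemaError(f"bad comparator: {self.comparator!r}")
        if self.threshold is not None and not np.isfinite(self.threshold):
            raise ValueError("threshold must be finite")

    def holds(self, value: float) -> bool:
        if self.threshold is None:
            raise ValueError("condition has no threshold (transcribed rule)")
        return value <= self.threshold if self.comparator == "<=" else value > self.threshold

    def describe(self) -> str:
        t = "?" if self.threshold is None else f"{self.threshold:.4g}"
        return f"{self.feature.describe()} {self.comparator} {t}"


@dataclass(frozen=True)
class Rule:
    rule_id: str
    isomer: str  # class label (isomer rules) or topology key (topology rules)
    conditions: tuple[RuleCondition, ...]
    confidence: float | None
    coverage: float | None
    n_test_spectra: int
    fragment_annotations: tuple[str, ...] = ()
    flags: tuple[str, ...] = ()

    @property
    def score(self) -> float:
        if self.confidence is None or self.coverage is None:
            return -1.0
        return self.confidence * self.coverage

    @property
    def executable(self) -> bool:
        return all(c.threshold is not None for c in self.conditions)


@dataclass
class RuleSet:
    center_mz: float
    topology_rules: list[Rule]  # empty for flat groups
    isomer_rules: dict[str, list[Rule]]  # topology key ("" for flat) -> rules
    provenance: dict = field(default_factory=dict)
    ruleless_classes: list[str] = field(default_factory=list)

    def all_rules(self) -> list[Rule]:
        out = list(self.topology_rules)
        for rules in self.isomer_rules.values():
            out.extend(rules)
        return out


# ---------------------------------------------------------------------------
# Rule evaluation, confidence and coverage
# ---------------------------------------------------------------------------


def rule_matches(rule: Rule, binned: BinnedSpectrum) -> bool:
    """True when the binned spectrum satisfies every condition."""
    return all(c.holds(evaluate_feature(c.feature, binned)) for c in rule.conditions)


def _binned(test: Sequence[AnnotatedSpectrum], width: float) -> list[BinnedSpectrum]:
    return [preprocess(a.spectrum, width) for a in test]


def confidence(
    rule: Rule, test: Sequence[AnnotatedSpectrum], bin_width: float = 0.5
) -> float | None:
    """Fraction of rule-matching test spectra truly of the rule's isomer.

    Returns None (undefined) when no test spectrum satisfies the conditions.
    """
    if not test:
        raise ValueError("test set must be nonempty")
    matched = correct = 0
    for a, bs in zip(test, _binned(test, bin_width)):
        if rule_matches(rule, bs):
            matched += 1
            if a.label == rule.isomer:
                correct += 1
    return None if matched == 0 else correct / matched


def coverage(
    rule: Rule, test: Sequence[AnnotatedSpectrum], bin_width: float = 0.5
) -> float:
    """Fraction of the isomer's test spectra that the rule matches."""
    own = [a for a in test if a.label == rule.isomer]
    if not own:
        raise ValueError(f"no test spectra of isomer {rule.isomer!r}")
    hit = sum(1 for a in own if rule_matches(rule, preprocess(a.spectrum, bin_width)))
    return hit / len(own)


# ---------------------------------------------------------------------------
# Path extraction
# ---------------------------------------------------------------------------


def _paths(tree: DecisionTree, specs: Sequence[FeatureSpec]):
    """Yield (conditions, leaf) for every root-to-leaf path (DFS, left first)."""

    def rec(node: TreeNode, conds: tuple[RuleCondition, ...]):
        if node.is_leaf:
            yield conds, node
            return
        spec = specs[node.split.feature]
        yield from rec(
            node.left, conds + (RuleCondition(spec, "<=", node.split.threshold),)
        )
        yield from rec(
            node.right, conds + (RuleCondition(spec, ">", node.split.threshold),)
        )

    yield from rec(tree.root, ())


def extract_best_paths(
    tree: DecisionTree,
    specs: Sequence[FeatureSpec],
    test_matrix: np.ndarray,
    test_labels: Sequence[str],
    rule_prefix: str = "R",
) -> tuple[list[Rule], list[str]]:
    """Best decision path per class, scored on independent test data.

    For each class, all root-to-leaf paths whose leaf predicts that class
    become candidate rules; the one maximizing confidence x coverage on the
    test data is kept (DFS order breaks ties).  Rules whose conditions match
    no test spectrum keep confidence None and are flagged "unvalidated"
    rather than dropped.  Returns (rules, classes never predicted by any
    leaf).
    """
    test_labels = list(test_labels)
    classes = sorted(set(test_labels)) or sorted(
        {leaf.prediction for _c, leaf in _paths(tree, specs)}
    )
    n_test = len(test_labels)
    class_totals = {c: test_labels.count(c) for c in classes}

    per_class: dict[str, Rule] = {}
    counter = 0
    for conds, leaf in _paths(tree, specs):
        cls = leaf.prediction
        counter += 1
        if n_test:
            mask = np.ones(n_test, dtype=bool)
            for cond in conds:
                col = test_matrix[:, specs.index(cond.feature)]
                mask &= (col <= cond.threshold) if cond.comparator == "<=" else (
                    col > cond.threshold
                )
            matched = int(mask.sum())
            correct = int(
                sum(1 for i in np.flatnonzero(mask) if test_labels[i] == cls)
            )
            conf = None if matched == 0 else correct / matched
            cov = (
                correct / class_totals[cls] if class_totals.get(cls) else None
            )
        else:
            conf = cov = None
        flags = []
        if conf is None:
            flags.append("unvalidated")
        elif conf < LOW_PERFORMANCE_FLOOR or (cov or 0.0) < LOW_PERFORMANCE_FLOOR:
            flags.append("low-performance")
        rule = Rule(
            rule_id=f"{rule_prefix}{counter}",
            isomer=cls,
            conditions=conds,
            confidence=conf,
            coverage=cov,
            n_test_spectra=class_totals.get(cls, 0),
            flags=tuple(flags),
        )
        incumbent = per_class.get(cls)
        if incumbent is None or rule.score > incumbent.score:
            per_class[cls] = rule

    ruleless = [c for c in classes if c not in per_class]
    return [per_class[c] for c in sorted(per_class)], ruleless


def map_rule_mz(
    rule: Rule, training: Sequence[BinnedSpectrum], width: float = 0.5
) -> Rule:
    """Set each condition's display m/z from training-set bin offsets.

    Bins never populated in training fall back to the bin center and flag
    the rule "unmapped-bin".
    """
    from .spectra_prep import _display_mz

    flags = list(rule.flags)
    new_conds = []
    for cond in rule.conditions:
        spec = cond.feature
        mz, ok = _display_mz(training, spec.numerator_bin, width)
        den_mz = None
        if spec.kind == "ratio":
            den_mz, ok2 = _display_mz(training, spec.denominator_bin, width)
            ok = ok and ok2
        if not ok and "unmapped-bin" not in flags:
            flags.append("unmapped-bin")
        new_conds.append(
            replace(
                cond,
                feature=replace(
                    spec, display_mz=mz, display_denominator_mz=den_mz
                ),
            )
        )
    return replace(rule, conditions=tuple(new_conds), flags=tuple(flags))


# ---------------------------------------------------------------------------
# Group training
# ---------------------------------------------------------------------------


def _topology_of(label: str) -> str:
    """Topology key of a class label; composition-only labels are their own
    'topology' (no structure to erase linkages from)."""
    try:
        return topology_key(parse_structure(label))
    except GlycanParseError:
        return label


def train_group(
    group: MassGroup, split: SplitAssignment, config: RunConfig = RunConfig()
) -> RuleSet:
    """Train the (possibly hierarchical) model for one mass group and
    extract its annotation rules."""
    if not group.trainable:
        raise ValueError(
            f"mass group at m/z {group.center_mz:.2f} is untrainable "
            f"({group.untrainable_reason}); class counts: {group.class_counts()}"
        )
    width = config.bin_width
    train, val, test = split.train, split.validation, split.test
    train_binned = _binned(train, width)
    val_binned = _binned(val, width)
    test_binned = _binned(test, width)

    labels = {a.label for a in group.members}
    topo_of = {lab: _topology_of(lab) for lab in labels}
    topologies: dict[str, list[str]] = {}
    for lab, topo in sorted(topo_of.items()):
        topologies.setdefault(topo, []).append(lab)
    hierarchical = len(topologies) > 1 and any(
        len(v) > 1 for v in topologies.values()
    )

    candidate_structures = []
    for lab in sorted(labels):
        try:
            g = parse_structure(lab)
            if not g.has_generic():
                candidate_structures.append(g)
        except GlycanParseError:
            pass

    provenance = {
        "software": f"glycorules {_pkg_version}",
        "config_hash": config.hash(),
        "seed": config.seed,
        "fractions": list(config.fractions),
        "n_train": len(train),
        "n_val": len(val),
        "n_test": len(test),
    }

    def fit_and_extract(idx_train, idx_val, idx_test, y_train, y_val, y_test, prefix):
        sub_train = [train_binned[i] for i in idx_train]
        X_train, specs = build_feature_matrix(
            sub_train, config.ratio_min_mean
        )
        X_val = apply_feature_specs([val_binned[i] for i in idx_val], specs)
        X_test = apply_feature_specs([test_binned[i] for i in idx_test], specs)
        tree = select_depth(
            X_train, y_train, X_val, y_val,
            depths=config.depths, min_leaf=config.min_leaf,
        )
        rules, ruleless = extract_best_paths(
            tree, specs, X_test, y_test, rule_prefix=prefix
        )
        rules = [map_rule_mz(r, sub_train, width) for r in rules]
        rules = [_attach_fragments(r, candidate_structures, config) for r in rules]
        return tree, rules, ruleless

    all_idx = {
        "train": list(range(len(train))),
        "val": list(range(len(val))),
        "test": list(range(len(test))),
    }
    ruleless_classes: list[str] = []

    if not hierarchical:
        _tree, rules, ruleless = fit_and_extract(
            all_idx["train"], all_idx["val"], all_idx["test"],
            [a.label for a in train], [a.label for a in val],
            [a.label for a in test], prefix="R",
        )
        ruleless_classes.extend(ruleless)
        return RuleSet(
            center_mz=group.center_mz,
            topology_rules=[],
            isomer_rules={"": rules},
            provenance=provenance,
            ruleless_classes=ruleless_classes,
        )

    # Topology tree over topology labels.
    _topo_tree, topo_rules, topo_ruleless = fit_and_extract(
        all_idx["train"], all_idx["val"], all_idx["test"],
        [topo_of[a.label] for a in train],
        [topo_of[a.label] for a in val],
        [topo_of[a.label] for a in test],
        prefix="T",
    )
    ruleless_classes.extend(topo_ruleless)

    isomer_rules: dict[str, list[Rule]] = {}
    for ti, (topo, topo_labels) in enumerate(sorted(topologies.items())):
        idx_train = [i for i, a in enumerate(train) if topo_of[a.label] == topo]
        idx_val = [i for i, a in enumerate(val) if topo_of[a.label] == topo]
        idx_test = [i for i, a in enumerate(test) if topo_of[a.label] == topo]
        if len(topo_labels) == 1:
            # The topology rule already decides the isomer; an empty-condition
            # rule records its test-set purity within this topology.
            lab = topo_labels[0]
            y_test = [test[i].label for i in idx_test]
            conf = (
                sum(1 for y in y_test if y == lab) / len(y_test) if y_test else None
            )
            isomer_rules[topo] = [
                Rule(
                    rule_id=f"I{ti}",
                    isomer=lab,
                    conditions=(),
                    confidence=conf,
                    coverage=1.0 if y_test else None,
                    n_test_spectra=sum(1 for y in y_test if y == lab),
                    flags=("implied-by-topology",)
                    + (("unvalidated",) if conf is None else ()),
                )
            ]
            continue
        _t, rules, ruleless = fit_and_extract(
            idx_train, idx_val, idx_test,
            [train[i].label for i in idx_train],
            [val[i].label for i in idx_val],
            [test[i].label for i in idx_test],
            prefix=f"I{ti}-",
        )
        ruleless_classes.extend(ruleless)
        isomer_rules[topo] = rules

    return RuleSet(
        center_mz=group.center_mz,
        topology_rules=topo_rules,
        isomer_rules=isomer_rules,
        provenance=provenance,
        ruleless_classes=ruleless_classes,
    )


def _attach_fragments(
    rule: Rule, candidates, config: RunConfig
) -> Rule:
    if not candidates:
        return rule
    notes = []
    for cond in rule.conditions:
        mzs = [cond.feature.display_mz]
        if cond.feature.kind == "ratio":
            mzs.append(cond.feature.display_denominator_mz)
        for mz in mzs:
            hits = annotate_mz(
                mz, candidates, tol=config.match_tolerance,
                losses=config.losses,
            )
            if hits == "unassigned":
                notes.append(f"m/z {mz:.1f}: unassigned")
            else:
                top = hits[0]
                notes.append(f"m/z {mz:.1f}: {top.label} ({top.mz:.3f})")
    return replace(rule, fragment_annotations=tuple(notes))


# ---------------------------------------------------------------------------
# Annotation of new spectra
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AnnotationResult:
    status: str  # {"ok", "unclassified"}
    isomer: str | None = None
    confidence: float | None = None
    rule_id: str | None = None
    topology: str | None = None
    near_threshold: bool = False


def _near(cond: RuleCondition, value: float) -> bool:
    t = cond.threshold
    scale = abs(t) if t else 1.0
    return abs(value - t) <= NEAR_THRESHOLD_MARGIN * scale


def annotate(
    spectrum: Spectrum, rs: RuleSet, config: RunConfig = RunConfig()
) -> AnnotationResult:
    """Annotate one spectrum with the rule set's best matching rule.

    Topology rules are evaluated first and route to that topology's isomer
    rules; among satisfied rules the highest confidence x coverage wins.
    Values within 10% of any threshold raise the near-threshold flag (rules
    near their cut-off deserve caution).  A precursor outside the rule
    set's mass group is an error.
    """
    if abs(spectrum.precursor_mz - rs.center_mz) > 0.5:
        raise MassGroupMismatch(
            f"precursor {spectrum.precursor_mz:.3f} outside mass group "
            f"{rs.center_mz:.3f} +/- 0.5"
        )
    binned = preprocess(spectrum, config.bin_width)

    def evaluate(rules):
        hits = []
        near = False
        for r in rules:
            if not r.executable:
                continue
            values = [evaluate_feature(c.feature, binned) for c in r.conditions]
            if all(c.holds(v) for c, v in zip(r.conditions, values)):
                hits.append(r)
                near |= any(_near(c, v) for c, v in zip(r.conditions, values))
        hits.sort(key=lambda r: (-r.score, r.rule_id))
        return hits, near

    near_flag = False
    if rs.topology_rules:
        topo_hits, near1 = evaluate(rs.topology_rules)
        near_flag |= near1
        if not topo_hits:
            return AnnotationResult(status="unclassified", near_threshold=near_flag)
        topo = topo_hits[0].isomer
        rules = rs.isomer_rules.get(topo, [])
    else:
        topo = None
        rules = [r for rr in rs.isomer_rules.values() for r in rr]

    iso_hits, near2 = evaluate(rules)
    near_flag |= near2
    if not iso_hits:
        return AnnotationResult(
            status="unclassified", topology=topo, near_threshold=near_flag
        )
    best = iso_hits[0]
    return AnnotationResult(
        status="ok",
        isomer=best.isomer,
        confidence=best.confidence,
        rule_id=best.rule_id,
        topology=topo,
        near_threshold=near_flag,
    )


# ---------------------------------------------------------------------------
# JSON serialization
# ---------------------------------------------------------------------------


def _cond_to_dict(c: RuleCondition) -> dict:
    d = {
        "feature_kind": c.feature.kind,
        "bin": c.feature.numerator_bin,
        "mz": c.feature.display_mz,
        "comparator": c.comparator,
        "threshold": c.threshold,
    }
    if c.feature.kind == "ratio":
        d["denominator_bin"] = c.feature.denominator_bin
        d["denominator_mz"] = c.feature.display_denominator_mz
    return d


def _cond_from_dict(d: dict) -> RuleCondition:
    try:
        spec = FeatureSpec(
            kind=d["feature_kind"],
            numerator_bin=int(d["bin"]),
            denominator_bin=(
                int(d["denominator_bin"]) if d.get("denominator_bin") is not None else None
            ),
            display_mz=d.get("mz"),
            display_denominator_mz=d.get("denominator_mz"),
        )
        comparator = d["comparator"]
        if comparator not in ("<=", ">"):
            raise RuleSetSchemaError(f"bad comparator token: {comparator!r}")
        return RuleCondition(
            spec, comparator,
            float(d["threshold"]) if d["threshold"] is not None else None,
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise RuleSetSchemaError(f"malformed condition: {exc}") from exc


def _rule_to_dict(r: Rule) -> dict:
    return {
        "rule_id": r.rule_id,
        "isomer": r.isomer,
        "conditions": [_cond_to_dict(c) for c in r.conditions],
        "confidence": r.confidence,
        "coverage": r.coverage,
        "n_test": r.n_test_spectra,
        "fragments": list(r.fragment_annotations),
        "flags": list(r.flags),
    }


def _rule_from_dict(d: dict) -> Rule:
    try:
        return Rule(
            rule_id=str(d["rule_id"]),
            isomer=str(d["isomer"]),
            conditions=tuple(_cond_from_dict(c) for c in d["conditions"]),
            confidence=d.get("confidence"),
            coverage=d.get("coverage"),
            n_test_spectra=int(d.get("n_test", 0)),
            fragment_annotations=tuple(d.get("fragments", ())),
            flags=tuple(d.get("flags", ())),
        )
    except (KeyError, TypeError) as exc:
        raise RuleSetSchemaError(f"malformed rule: {exc}") from exc


def serialize_ruleset(rs: RuleSet, path: str | Path | None = None) -> str:
    """Dump a rule set to schema-versioned JSON (sorted keys, lossless)."""
    payload = {
        "schema_version": SCHEMA_VERSION,
        "mass_group": rs.center_mz,
        "topology_rules": [_rule_to_dict(r) for r in rs.topology_rules],
        "isomer_rules": {
            k: [_rule_to_dict(r) for r in v] for k, v in rs.isomer_rules.items()
        },
        "ruleless_classes": rs.ruleless_classes,
        "provenance": rs.provenance,
    }
    text = json.dumps(payload, sort_keys=True, indent=1, ensure_ascii=False)
    if path is not None:
        Path(path).write_text(text, encoding="utf-8")
    return text


def load_ruleset(source: str | Path) -> RuleSet:
    """Load a rule set from a JSON file path or a JSON string."""
    text = (
        Path(source).read_text(encoding="utf-8")
        if isinstance(source, Path) or (isinstance(source, str) and "\n" not in source and source.endswith(".json"))
        else str(source)
    )
    try:
        payload = json.loads(text)
    except json.JSONDecodeError as exc:
        raise RuleSetSchemaError(f"not valid JSON: {exc}") from exc
    return ruleset_from_payload(payload)


def ruleset_from_payload(payload: dict) -> RuleSet:
    """Build a RuleSet from an already-parsed JSON payload (schema-checked)."""
    version = payload.get("schema_version")
    if version != SCHEMA_VERSION:
        raise RuleSetSchemaError(
            f"unsupported schema_version {version!r}; this build reads "
            f"version {SCHEMA_VERSION}"
        )
    try:
        return RuleSet(
            center_mz=float(payload["mass_group"]),
            topology_rules=[_rule_from_dict(r) for r in payload["topology_rules"]],
            isomer_rules={
                k: [_rule_from_dict(r) for r in v]
                for k, v in payload["isomer_rules"].items()
            },
            provenance=payload.get("provenance", {}),
            ruleless_classes=list(payload.get("ruleless_classes", [])),
        )
    except (KeyError, TypeError) as exc:
        raise RuleSetSchemaError(f"malformed rule set: {exc}") from exc
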