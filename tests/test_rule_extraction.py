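"""Rule extraction: confidence/coverage, best paths, hierarchy, annotation."""

import json

import numpy as np
import pytest

from glycorules.config import RunConfig
from glycorules.dataset_split import assign_mass_groups, grouped_stratified_split
from glycorules.entropy_tree import fit_tree
from glycorules.rule_extraction import (
    AnnotationResult,
    MassGroupMismatch,
    Rule,
    RuleCondition,
    RuleSet,
    RuleSetSchemaError,
    annotate,
    confidence,
    coverage,
    extract_best_paths,
    load_ruleset,
    map_rule_mz,
    rule_matches,
    serialize_ruleset,
    train_group,
)
from glycorules.spectra_prep import (
    AnnotatedSpectrum,
    FeatureSpec,
    Peak,
    Spectrum,
    bin_spectrum,
    build_feature_matrix,
    normalize,
)
from glycorules.synthetic_data import (
    fig1c_like_fixture,
    generate_corpus,
    three_topology_fixture,
)

K365, K317 = int(365.13 / 0.5), int(317.10 / 0.5)

RATIO_SPEC = FeatureSpec(
    "ratio", K365, K317, display_mz=365.1, display_denominator_mz=317.1
)


def spectrum_with_ratio(ratio, scan="s", label="B"):
    peaks = [Peak(204.09, 1.0), Peak(317.10, 0.2), Peak(365.13, 0.2 * ratio)]
    s = Spectrum(
        peaks=tuple(peaks), precursor_mz=425.18,
        dataset_id="GPST900000", filename="f.mzML", scan_id=scan,
    )
    return AnnotatedSpectrum(spectrum=s, label=label)


def ratio_rule(threshold=1.5, isomer="B", comparator=">"):
    return Rule(
        rule_id="r1", isomer=isomer,
        conditions=(RuleCondition(RATIO_SPEC, comparator, threshold),),
        confidence=None, coverage=None, n_test_spectra=0,
    )


class TestConfidenceCoverage:
    def test_confidence_direct_count(self):
        test = [spectrum_with_ratio(2.0, f"hi{i}", "B") for i in range(9)]
        test += [spectrum_with_ratio(3.0, "hi9", "A")]  # matching, wrong class
        test += [spectrum_with_ratio(0.5, f"lo{i}", "A") for i in range(5)]
        assert confidence(ratio_rule(), test) == pytest.approx(0.9)

    def test_confidence_only_own_class_matches(self):
        test = [spectrum_with_ratio(2.0, f"b{i}", "B") for i in range(4)]
        test += [spectrum_with_ratio(0.5, f"a{i}", "A") for i in range(4)]
        assert confidence(ratio_rule(), test) == 1.0

    def test_confidence_undefined_when_no_match(self):
        test = [spectrum_with_ratio(0.5, f"a{i}", "A") for i in range(4)]
        assert confidence(ratio_rule(), test) is None

    def test_coverage_direct_count(self):
        test = [spectrum_with_ratio(2.0, f"b{i}", "B") for i in range(17)]
        test += [spectrum_with_ratio(0.5, f"m{i}", "B") for i in range(3)]
        assert coverage(ratio_rule(), test) == pytest.approx(0.85)

    def test_empty_conditions_cover_everything(self):
        rule = Rule(
            rule_id="r0", isomer="B", conditions=(),
            confidence=None, coverage=None, n_test_spectra=0,
        )
        test = [spectrum_with_ratio(0.5, f"b{i}", "B") for i in range(5)]
        assert coverage(rule, test) == 1.0

    def test_coverage_errors_without_own_spectra(self):
        test = [spectrum_with_ratio(0.5, f"a{i}", "A") for i in range(4)]
        with pytest.raises(ValueError):
            coverage(ratio_rule(), test)

    def test_appending_conditions_never_raises_score(self):
        test = [spectrum_with_ratio(r, f"s{i}", "B" if r > 1.5 else "A")
                for i, r in enumerate([0.2, 0.4, 2.0, 2.4, 3.0, 0.9, 1.7])]
        short = ratio_rule(threshold=1.0)
        binspec = FeatureSpec("bin", K365, display_mz=365.1)
        longer = Rule(
            rule_id="r2", isomer="B",
            conditions=short.conditions
            + (RuleCondition(binspec, ">", 0.5),),
            confidence=None, coverage=None, n_test_spectra=0,
        )
        cov_short = coverage(short, test)
        cov_long = coverage(longer, test)
        assert cov_long <= cov_short


class TestExtractBestPaths:
    def make_tree_and_specs(self, rng, n=120):
        # one informative ratio-like feature + one noise feature
        X = np.column_stack([
            np.concatenate([rng.uniform(0.1, 1.0, n // 2),
                            rng.uniform(2.0, 4.0, n // 2)]),
            rng.normal(size=n),
        ])
        y = ["A"] * (n // 2) + ["B"] * (n // 2)
        specs = [RATIO_SPEC, FeatureSpec("bin", 100, display_mz=50.1)]
        return X, y, specs

    def test_depth1_two_single_condition_rules(self, rng):
        X, y, specs = self.make_tree_and_specs(rng)
        tree = fit_tree(X, y, max_depth=1)
        rules, ruleless = extract_best_paths(tree, specs, X, y)
        assert not ruleless
        assert sorted(r.isomer for r in rules) == ["A", "B"]
        assert all(len(r.conditions) == 1 for r in rules)
        assert {r.conditions[0].comparator for r in rules} == {"<=", ">"}

    def test_higher_scoring_duplicate_leaf_retained(self):
        """Two leaves predict "B" with different purity: the better-scoring
        decision path is the one kept (tree constructed by hand)."""
        from glycorules.entropy_tree import (
            ClassDistribution,
            DecisionTree,
            SplitCandidate,
            TreeNode,
        )

        specs = [RATIO_SPEC, FeatureSpec("bin", 100, display_mz=50.1)]
        # root splits feature 0 at 1.5; left child splits feature 1 at 0.5.
        # Leaves: (f0<=1.5, f1<=0.5) -> B (impure); (f0<=1.5, f1>0.5) -> A;
        # f0>1.5 -> B (pure).
        leaf_b_impure = TreeNode(ClassDistribution((("A", 2), ("B", 3))))
        leaf_a = TreeNode(ClassDistribution((("A", 5),)))
        leaf_b_pure = TreeNode(ClassDistribution((("B", 10),)))
        left = TreeNode(
            ClassDistribution((("A", 7), ("B", 3))),
            split=SplitCandidate(1, 0.5, 0.5),
            left=leaf_b_impure, right=leaf_a,
        )
        root = TreeNode(
            ClassDistribution((("A", 7), ("B", 13))),
            split=SplitCandidate(0, 1.5, 0.5),
            left=left, right=leaf_b_pure,
        )
        tree = DecisionTree(root=root, max_depth=2, n_features=2)

        # test data matching the leaf populations
        X = np.array(
            [[0.5, 0.2]] * 5 + [[0.5, 0.9]] * 5 + [[2.5, 0.2]] * 10
        )
        y = ["B", "B", "B", "A", "A"] + ["A"] * 5 + ["B"] * 10
        rules, _ = extract_best_paths(tree, specs, X, y)
        best_b = next(r for r in rules if r.isomer == "B")
        # the pure right leaf (single condition f0 > 1.5) must win
        assert len(best_b.conditions) == 1
        assert best_b.conditions[0].comparator == ">"
        assert best_b.confidence == 1.0
        assert best_b.coverage == pytest.approx(10 / 13)

    def test_unmatched_rule_flagged_unvalidated(self, rng):
        X, y, specs = self.make_tree_and_specs(rng)
        tree = fit_tree(X, y, max_depth=1)
        # test data that never satisfies the right branch
        X_test = np.full((5, 2), 0.2)
        rules, _ = extract_best_paths(tree, specs, X_test, ["A"] * 5)
        b_rule = next(r for r in rules if r.isomer == "B")
        assert b_rule.confidence is None
        assert "unvalidated" in b_rule.flags


def _score_path(conds, X, y, cls):
    mask = np.ones(len(y), dtype=bool)
    for c in conds:
        col = X[:, 0 if c.feature.kind == "ratio" else 1]
        mask &= (col <= c.threshold) if c.comparator == "<=" else (col > c.threshold)
    matched = mask.sum()
    correct = sum(1 for i in np.flatnonzero(mask) if y[i] == cls)
    total = sum(1 for v in y if v == cls)
    if matched == 0 or total == 0:
        return -1.0
    return (correct / matched) * (correct / total)


class TestMapRuleMz:
    def test_display_from_training_offsets(self):
        train = [
            bin_spectrum(normalize(spectrum_with_ratio(2.0, "t1").spectrum)),
            bin_spectrum(normalize(spectrum_with_ratio(1.0, "t2").spectrum)),
        ]
        rule = ratio_rule()
        mapped = map_rule_mz(rule, train)
        cond = mapped.conditions[0]
        assert cond.feature.display_mz == pytest.approx(365.13, abs=0.01)
        assert cond.feature.display_denominator_mz == pytest.approx(
            317.10, abs=0.01
        )
        assert "unmapped-bin" not in mapped.flags

    def test_unpopulated_bin_flagged_center(self):
        spec = FeatureSpec("bin", 1000, display_mz=None)
        rule = Rule(
            rule_id="rx", isomer="B",
            conditions=(RuleCondition(spec, ">", 0.1),),
            confidence=None, coverage=None, n_test_spectra=0,
        )
        train = [bin_spectrum(normalize(spectrum_with_ratio(2.0).spectrum))]
        mapped = map_rule_mz(rule, train)
        assert mapped.conditions[0].feature.display_mz == pytest.approx(500.25)
        assert "unmapped-bin" in mapped.flags


import functools


@functools.lru_cache(maxsize=4)
def _trained(seed, n):
    cfg = fig1c_like_fixture(n_spectra=n, seed=seed)
    corpus = generate_corpus(cfg)
    group = assign_mass_groups(corpus)[0]
    split = grouped_stratified_split(group, seed=seed)
    return train_group(group, split), tuple(corpus), split


def trained_ruleset(seed=0, n=200):
    return _trained(seed, n)


class TestTrainGroup:
    def test_two_isomer_group_single_ratio_tree(self):
        rs, _corpus, _split = trained_ruleset()
        assert rs.topology_rules == []  # each topology has one isomer -> flat
        rules = rs.isomer_rules[""]
        assert sorted(r.isomer for r in rules) == [
            "GalNAc(a1-3)GalNAc", "GlcNAc(b1-3)GalNAc",
        ]
        core5 = next(r for r in rules if r.isomer == "GalNAc(a1-3)GalNAc")
        assert any(
            c.feature.kind == "ratio"
            and {c.feature.numerator_bin, c.feature.denominator_bin}
            == {K365, K317}
            for c in core5.conditions
        )

    def test_three_topology_group_hierarchy(self):
        cfg = three_topology_fixture(n_spectra=120, seed=3)
        corpus = generate_corpus(cfg)
        group = assign_mass_groups(corpus)[0]
        split = grouped_stratified_split(group, seed=3)
        rs = train_group(group, split)
        assert len(rs.topology_rules) == 3
        assert len(rs.isomer_rules) == 3
        for rules in rs.isomer_rules.values():
            assert len(rules) == 2

    def test_untrainable_group_errors(self):
        cfg = fig1c_like_fixture(n_spectra=50, seed=0)
        corpus = generate_corpus(cfg)
        group = assign_mass_groups(corpus)[0]
        group.trainable = False
        group.untrainable_reason = "fewer than 2 classes"
        split = grouped_stratified_split(
            assign_mass_groups(corpus)[0], seed=0
        )
        with pytest.raises(ValueError, match="untrainable"):
            train_group(group, split)

    def test_rules_reproduce_tree_predictions_on_training(self):
        rs, corpus, split = trained_ruleset(seed=2)
        rules = rs.isomer_rules[""]
        for a in split.train[:40]:
            from glycorules.spectra_prep import preprocess

            binned = preprocess(a.spectrum, 0.5)
            matching = [r for r in rules if rule_matches(r, binned)]
            if matching:
                best = max(matching, key=lambda r: r.score)
                res = annotate(a.spectrum, rs)
                assert res.isomer == best.isomer

    def test_test_experiments_never_in_training(self):
        _rs, _corpus, split = trained_ruleset(seed=7)
        train_keys = {a.spectrum.provenance_key for a in split.train}
        train_keys |= {a.spectrum.provenance_key for a in split.validation}
        test_keys = {a.spectrum.provenance_key for a in split.test}
        assert train_keys.isdisjoint(test_keys)


class TestAnnotate:
    # n=500: the regime in which the mined rule is the single planted ratio
    # condition, so hand-built probe spectra carry every referenced bin
    def test_high_ratio_routes_to_core5(self):
        rs, _c, _s = trained_ruleset(seed=1, n=500)
        probe = spectrum_with_ratio(2.0, "probe").spectrum
        res = annotate(probe, rs)
        assert res.status == "ok"
        assert res.isomer == "GalNAc(a1-3)GalNAc"
        assert res.confidence is not None and res.confidence > 0.5

    def test_wrong_mass_group_errors(self):
        rs, _c, _s = trained_ruleset(seed=1, n=500)
        probe = Spectrum(
            peaks=(Peak(200.0, 1.0),), precursor_mz=733.0,
            dataset_id="d", filename="f", scan_id="x",
        )
        with pytest.raises(MassGroupMismatch):
            annotate(probe, rs)

    def test_near_threshold_flagged(self):
        rs, _c, _s = trained_ruleset(seed=1, n=500)
        rules = rs.isomer_rules[""]
        thr = next(
            c.threshold for r in rules for c in r.conditions
            if c.feature.kind == "ratio"
        )
        res = annotate(
            spectrum_with_ratio(thr * 1.01, "edge").spectrum, rs
        )
        assert res.near_threshold

    def test_unclassified_when_nothing_matches(self):
        # single-condition ">" rules on both branches always partition the
        # space, so drop the low branch to leave an unmatchable region
        rs, _c, _s = trained_ruleset(seed=1, n=500)
        rules = [r for r in rs.isomer_rules[""]
                 if r.conditions and r.conditions[0].comparator == ">"]
        rs2 = RuleSet(
            center_mz=rs.center_mz, topology_rules=[],
            isomer_rules={"": rules}, provenance=rs.provenance,
        )
        res = annotate(spectrum_with_ratio(0.01, "low").spectrum, rs2)
        assert res.status == "unclassified"


class TestSerialization:
    def test_roundtrip(self, tmp_path):
        rs, _c, _s = trained_ruleset(seed=4)
        path = tmp_path / "rules.json"
        text = serialize_ruleset(rs, path)
        again = load_ruleset(path)
        assert serialize_ruleset(again) == text

    def test_packaged_examples_load(self):
        import glycorules

        rulesets = glycorules.load_example_ruleset()
        centers = sorted(rs.center_mz for rs in rulesets)
        assert centers == [425.18, 530.21, 733.29]
        ratio_rule_ = rulesets[0].isomer_rules[""][0]
        cond = ratio_rule_.conditions[0]
        assert cond.threshold == 1.5 and cond.comparator == ">"
        assert "transcribed" in ratio_rule_.flags

    def test_tampered_comparator_rejected(self, tmp_path):
        rs, _c, _s = trained_ruleset(seed=4)
        payload = json.loads(serialize_ruleset(rs))
        payload["isomer_rules"][""][0]["conditions"][0]["comparator"] = ">="
        bad = tmp_path / "bad.json"
        bad.write_text(json.dumps(payload))
        with pytest.raises(RuleSetSchemaError):
            load_ruleset(bad)

    def test_wrong_schema_version_rejected(self, tmp_path):
        rs, _c, _s = trained_ruleset(seed=4)
        payload = json.loads(serialize_ruleset(rs))
        payload["schema_version"] = 99
        bad = tmp_path / "v99.json"
        bad.write_text(json.dumps(payload))
        with pytest.raises(RuleSetSchemaError, match="version"):
            load_ruleset(bad)


class TestScaleInvariance:
    def test_arbitrary_key_scaling_preserves_rules_semantically(self):
        """Non-dyadic per-key intensity scaling leaves extracted rules
        semantically identical (features, comparators, thresholds, scores)."""
        cfg = fig1c_like_fixture(n_spectra=120, seed=6)
        corpus = generate_corpus(cfg)

        def scaled(corpus, key, factor):
            out = []
            for a in corpus:
                if a.spectrum.provenance_key == key:
                    s = a.spectrum
                    peaks = tuple(Peak(p.mz, p.intensity * factor)
                                  for p in s.peaks)
                    s = Spectrum(peaks=peaks, precursor_mz=s.precursor_mz,
                                 dataset_id=s.dataset_id, filename=s.filename,
                                 scan_id=s.scan_id)
                    out.append(AnnotatedSpectrum(spectrum=s, label=a.label))
                else:
                    out.append(a)
            return out

        key = corpus[0].spectrum.provenance_key
        for factor in (0.1, 3.7):
            c2 = scaled(corpus, key, factor)
            rs1 = train_group(
                assign_mass_groups(corpus)[0],
                grouped_stratified_split(assign_mass_groups(corpus)[0], seed=0),
            )
            rs2 = train_group(
                assign_mass_groups(c2)[0],
                grouped_stratified_split(assign_mass_groups(c2)[0], seed=0),
            )
            r1 = {r.isomer: r for r in rs1.isomer_rules[""]}
            r2 = {r.isomer: r for r in rs2.isomer_rules[""]}
            assert r1.keys() == r2.keys()
            for iso in r1:
                a, b = r1[iso], r2[iso]
                assert a.confidence == b.confidence
                assert a.coverage == b.coverage
                assert len(a.conditions) == len(b.conditions)
                for ca, cb in zip(a.conditions, b.conditions):
                    assert ca.comparator == cb.comparator
                    assert ca.feature.kind == cb.feature.kind
                    assert ca.feature.numerator_bin == cb.feature.numerator_bin
                    assert ca.threshold == pytest.approx(cb.threshold, abs=1e-9)
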