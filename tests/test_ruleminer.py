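"""Rule growing, pruning, sequential covering, and decision-list application."""

import itertools
import math

import numpy as np
import pytest

from cnvrules import (
    Condition,
    HET_DEL,
    HOM_DEL,
    LabeledDataset,
    Rule,
    RuleLearnerConfig,
    RuleList,
    SignalMatrix,
    SimulationConfig,
    SNPMarker,
    WILD_TYPE,
    annotate_rule_list,
    grow_rule,
    learn_ruleset,
    load_published_macrod2_rules,
    parse_rule_text,
    predict_rule_list,
    prune_rule,
    rule_support_accuracy,
    serialize_rule_list,
    simulate_dataset,
)


def foil_gain(p, n, P, N):
    if p == 0:
        return -math.inf
    return p * (math.log2(p / (p + n)) - math.log2(P / (P + N)))


def _dataset(X, y, class_names=None):
    X = np.asarray(X, float)
    matrix = SignalMatrix(
        [f"S{i}" for i in range(len(X))],
        [SNPMarker(f"f{j}") for j in range(X.shape[1])],
        X,
        "LRR",
    )
    return LabeledDataset(matrix, list(y), tuple(class_names or dict.fromkeys(y)))


class TestGrowRule:
    def test_separable_threshold(self):
        X = np.array([[-0.9], [-0.8], [0.1], [0.2]])
        y = ["pos", "pos", "neg", "neg"]
        rule = grow_rule(X, y, "pos")
        assert len(rule.conditions) == 1
        cond = rule.conditions[0]
        assert cond.op == "<="
        assert -0.8 < cond.threshold < 0.1

    def test_identical_values_give_empty_rule_signal(self):
        X = np.ones((6, 2))
        y = ["pos"] * 3 + ["neg"] * 3
        assert grow_rule(X, y, "pos") is None

    def test_each_condition_maximizes_foil_gain(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(10, 3))
        y = np.where(X[:, 0] + 0.5 * X[:, 1] > 0, "pos", "neg")
        rule = grow_rule(X, y, "pos")
        assert rule is not None

        covered = np.ones(len(y), dtype=bool)
        for cond in rule.conditions:
            # oracle: enumerate every midpoint condition on the covered set
            P = (y[covered] == "pos").sum()
            N = covered.sum() - P
            best_gain = 0.0
            for j in range(3):
                vals = np.sort(np.unique(X[covered, j]))
                for lo, hi in zip(vals[:-1], vals[1:]):
                    thr = (lo + hi) / 2
                    for op in ("<=", ">="):
                        mask = (X[:, j] <= thr) if op == "<=" else (X[:, j] >= thr)
                        mask = mask & covered
                        p = (y[mask] == "pos").sum()
                        n = mask.sum() - p
                        g = foil_gain(p, n, P, N)
                        best_gain = max(best_gain, g)
            j = int(cond.marker_id[1:])
            mask = (X[:, j] <= cond.threshold) if cond.op == "<=" else (
                X[:, j] >= cond.threshold
            )
            p = (y[mask & covered] == "pos").sum()
            n = (mask & covered).sum() - p
            assert foil_gain(p, n, P, N) == pytest.approx(best_gain)
            covered &= mask

    def test_no_positives_rejected(self):
        with pytest.raises(ValueError, match="no samples"):
            grow_rule(np.zeros((3, 1)), ["a"] * 3, "b")


class TestPruneRule:
    def test_harmful_last_condition_removed(self):
        rule = Rule(
            (Condition("f0", "<=", 0.0), Condition("f1", "<=", -5.0)), "pos"
        )
        # on the prune set the second condition only excludes positives
        X = np.array([[-1.0, 0.0], [-2.0, 0.0], [1.0, 0.0], [2.0, 0.0]])
        y = ["pos", "pos", "neg", "neg"]
        pruned = prune_rule(rule, X, y, "pos")
        assert pruned.conditions == rule.conditions[:1]

    def test_matches_exhaustive_suffix_oracle(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(12, 4))
        y = rng.choice(["pos", "neg"], 12)
        conds = (
            Condition("f0", "<=", 0.5),
            Condition("f1", ">=", -0.5),
            Condition("f2", "<=", 0.8),
            Condition("f3", ">=", -0.9),
        )
        rule = Rule(conds, "pos")
        pruned = prune_rule(rule, X, y, "pos")

        def worth(prefix):
            mask = np.ones(len(y), dtype=bool)
            for c in prefix:
                j = int(c.marker_id[1:])
                mask &= (X[:, j] <= c.threshold) if c.op == "<=" else (
                    X[:, j] >= c.threshold
                )
            p = (y[mask] == "pos").sum()
            n = mask.sum() - p
            return -1.0 if p + n == 0 else (p - n) / (p + n)

        worths = [worth(conds[:j]) for j in range(1, 5)]
        best = max(worths)
        expected_len = worths.index(best) + 1  # shortest among ties
        assert len(pruned.conditions) == expected_len
        assert worth(pruned.conditions) == pytest.approx(best)

    def test_never_adds_conditions(self):
        rng = np.random.default_rng(4)
        for trial in range(10):
            X = rng.normal(size=(10, 2))
            y = rng.choice(["pos", "neg"], 10)
            conds = (Condition("f0", "<=", 0.0), Condition("f1", ">=", 0.0))
            pruned = prune_rule(Rule(conds, "pos"), X, y, "pos")
            assert 1 <= len(pruned.conditions) <= 2
            assert pruned.conditions == conds[: len(pruned.conditions)]


class TestLearnRuleset:
    def test_noiseless_homozygous_rules_have_negative_le_thresholds(
        self, noiseless_dataset, noiseless_config
    ):
        dataset, _ = noiseless_dataset
        lo, hi = noiseless_config.gene_region
        region = {m.marker_id for m in dataset.signal.markers[lo:hi]}
        rules = learn_ruleset(dataset, RuleLearnerConfig(seed=1))
        hom_rules = [r for r in rules.conditioned if r.consequent == HOM_DEL]
        assert hom_rules
        for rule in hom_rules:
            for cond in rule.conditions:
                assert cond.marker_id in region
                assert cond.op == "<="
                assert cond.threshold < 0

    def test_three_gaussians_in_2d(self):
        rng = np.random.default_rng(6)
        centers = [(0, 0), (6, 0), (0, 6)]
        X = np.vstack([rng.normal(c, 0.8, size=(20, 2)) for c in centers])
        y = np.repeat(["a", "b", "c"], 20)
        ds = _dataset(X, y)
        rules = learn_ruleset(ds, RuleLearnerConfig(seed=0))
        preds = predict_rule_list(rules, ds.signal)
        assert (preds == y).mean() >= 0.95
        assert len(rules) <= 6

    def test_default_rule_is_last_ordered_class(self, small_dataset):
        dataset, _ = small_dataset
        rules = learn_ruleset(dataset, RuleLearnerConfig(seed=0))
        # smallest-first ordering: the largest class becomes the default
        sizes = dataset.class_sizes()
        assert rules.default_class == max(sizes, key=sizes.get)
        cfg = RuleLearnerConfig(
            class_ordering="fixed",
            class_order=(HOM_DEL, WILD_TYPE, HET_DEL),
            seed=0,
        )
        rules_fixed = learn_ruleset(dataset, cfg)
        assert rules_fixed.default_class == HET_DEL

    def test_single_class_rejected(self):
        ds = _dataset(np.zeros((4, 2)), ["a"] * 4, class_names=("a", "b"))
        with pytest.raises(ValueError, match="two classes"):
            learn_ruleset(ds)

    def test_deterministic_given_seed(self, small_dataset):
        dataset, _ = small_dataset
        a = learn_ruleset(dataset, RuleLearnerConfig(seed=3))
        b = learn_ruleset(dataset, RuleLearnerConfig(seed=3))
        assert a == b


class TestPredict:
    def test_published_rule_one_fires(self):
        rules = load_published_macrod2_rules()
        matrix = SignalMatrix(
            ["S0"],
            [SNPMarker(m) for m in rules.marker_ids],
            np.zeros((1, len(rules.marker_ids))),
            "LRR",
        )
        matrix.values[0, matrix.marker_ids.index("rs353149")] = -0.5
        matrix.values[0, matrix.marker_ids.index("rs6034087")] = -0.3
        # avoid the wild-type rules firing first is not possible: rule 1 wins by order
        preds = predict_rule_list(rules, matrix)
        assert preds[0] == "Homozygous deletion"

    def test_unmatched_sample_takes_default(self):
        rules = load_published_macrod2_rules()
        matrix = SignalMatrix(
            ["S0"],
            [SNPMarker(m) for m in rules.marker_ids],
            np.full((1, len(rules.marker_ids)), -0.2),
            "LRR",
        )
        # -0.2 everywhere satisfies no conditioned rule of the fixture
        preds = predict_rule_list(rules, matrix)
        assert preds[0] == "Heterozygous deletion"

    def test_order_wins_on_overlap(self):
        rules = RuleList(
            (
                Rule((Condition("f0", "<=", 1.0),), "first"),
                Rule((Condition("f0", "<=", 2.0),), "second"),
                Rule((), "default"),
            )
        )
        matrix = SignalMatrix(["S0", "S1"], [SNPMarker("f0")], [[0.5], [1.5]], "LRR")
        assert predict_rule_list(rules, matrix).tolist() == ["first", "second"]

    def test_missing_marker_named(self):
        rules = RuleList(
            (Rule((Condition("rs_missing", "<=", 0.0),), "a"), Rule((), "b"))
        )
        matrix = SignalMatrix(["S0"], [SNPMarker("rs_other")], [[0.0]], "LRR")
        with pytest.raises(KeyError, match="rs_missing"):
            predict_rule_list(rules, matrix)

    def test_invariant_to_unused_markers(self):
        rules = RuleList(
            (Rule((Condition("f1", ">=", 0.0),), "hi"), Rule((), "lo"))
        )
        m_small = SignalMatrix(["S0"], [SNPMarker("f1")], [[0.3]], "LRR")
        m_big = SignalMatrix(
            ["S0"], [SNPMarker("f0"), SNPMarker("f1"), SNPMarker("f2")],
            [[9.0, 0.3, -9.0]], "LRR",
        )
        assert predict_rule_list(rules, m_small)[0] == predict_rule_list(rules, m_big)[0]


class TestSupportAccuracy:
    def test_direct_ratios(self):
        X = np.array([[v] for v in np.linspace(-1, 1, 20)])
        y = ["pos" if v <= -0.6 else "neg" for v in X[:, 0]]
        y[0] = "neg"  # one mistake inside the covered range
        ds = _dataset(X, y, class_names=("pos", "neg"))
        rules = RuleList(
            (Rule((Condition("f0", "<=", X[3, 0] + 1e-9),), "pos"), Rule((), "neg"))
        )
        (support, accuracy), _ = rule_support_accuracy(rules, ds)
        assert support == pytest.approx(20.0)
        assert accuracy == pytest.approx(75.0)

    def test_always_true_condition_has_full_support(self):
        ds = _dataset(np.zeros((5, 1)), ["a", "a", "a", "b", "b"], ("a", "b"))
        rules = RuleList((Rule((Condition("f0", "<=", 99.0),), "a"), Rule((), "b")))
        (support, _), (d_support, d_acc) = rule_support_accuracy(rules, ds)
        assert support == 100.0
        assert d_support == 0.0 and math.isnan(d_acc)

    def test_noiseless_sequential_accuracies_are_perfect(self, noiseless_dataset):
        dataset, _ = noiseless_dataset
        rules = learn_ruleset(dataset, RuleLearnerConfig(seed=1))
        preds = predict_rule_list(rules, dataset.signal)
        assert (preds == np.asarray(dataset.labels, dtype=object)).all()
        stats = rule_support_accuracy(rules, dataset, sequential=True)
        for support, accuracy in stats:
            if support > 0:
                assert accuracy == pytest.approx(100.0)

    def test_annotated_round_trip_predicts_identically(self, noiseless_dataset):
        dataset, _ = noiseless_dataset
        rules = annotate_rule_list(learn_ruleset(dataset, RuleLearnerConfig(seed=1)),
                                   dataset)
        reparsed = parse_rule_text(serialize_rule_list(rules))
        a = predict_rule_list(rules, dataset.signal)
        b = predict_rule_list(reparsed, dataset.signal)
        assert (a == b).all()

    def test_overlapping_supports_can_exceed_class_share(self, noiseless_dataset):
        # independent per-rule evaluation: supports may overlap and need not
        # partition the cohort
        dataset, _ = noiseless_dataset
        rules = annotate_rule_list(learn_ruleset(dataset, RuleLearnerConfig(seed=1)),
                                   dataset)
        total_support = sum(r.support_pct for r in rules.conditioned)
        default_support = rules.rules[-1].support_pct
        assert total_support + default_support >= 100.0 - 1e-9
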