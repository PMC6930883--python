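"""RIPPER-style ordered rule induction over continuous SNP-array signals.

Sequential covering: classes are processed smallest-first (configurable);
for each class, rules are grown greedily by FOIL information gain on a
grow split, pruned by worth (p - n)/(p + n) on a prune split, and accepted
until the minimum-description-length (MDL) stopping criterion fires or the
class's positives are exhausted. Accepted rules then undergo optimization
rounds in which each rule competes against a freshly grown replacement and
a revised extension, scored by total description length. The final class
becomes the conditionless default rule, giving an ordered decision list
applied with first-match semantics.

Rule conditions are inclusive threshold comparisons (``<=`` / ``>=``) with
candidate thresholds at midpoints between sorted distinct feature values.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.special import gammaln

from .dataio import Condition, LabeledDataset, Rule, RuleList, SignalMatrix

__all__ = [
    "RuleLearnerConfig",
    "grow_rule",
    "prune_rule",
    "learn_ruleset",
    "predict_rule_list",
    "rule_support_accuracy",
    "annotate_rule_list",
    "RuleListClassifier",
]

_LN2 = math.log(2.0)


@dataclass(frozen=True)
class RuleLearnerConfig:
    """Tunables of the rule learner."""

    grow_fraction: float = 2.0 / 3.0  # share of data used to grow (rest prunes)
    min_coverage: int = 2  # rules covering fewer samples are rejected
    mdl_slack_bits: float = 64.0  # stop when DL exceeds the best seen by this much
    optimization_rounds: int = 2
    class_ordering: str = "by_increasing_size"  # or "fixed"
    class_order: tuple[str, ...] | None = None  # explicit order when "fixed"
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.grow_fraction < 1.0):
            raise ValueError("grow_fraction must lie in (0, 1)")
        if self.optimization_rounds < 0:
            raise ValueError("optimization_rounds must be >= 0")
        if self.class_ordering not in ("by_increasing_size", "fixed"):
            raise ValueError("class_ordering must be 'by_increasing_size' or 'fixed'")


# ---------------------------------------------------------------------------
# Condition arithmetic on arrays
# ---------------------------------------------------------------------------


def _cond_mask(X: np.ndarray, cond: tuple[int, str, float]) -> np.ndarray:
    j, op, thr = cond
    col = X[:, j]
    return col <= thr if op == "<=" else col >= thr


def _rule_mask(X: np.ndarray, conds: Sequence[tuple[int, str, float]]) -> np.ndarray:
    mask = np.ones(X.shape[0], dtype=bool)
    for c in conds:
        mask &= _cond_mask(X, c)
    return mask


def _foil_gain(p: float, n: float, P: float, N: float) -> float:
    if p == 0:
        return -math.inf
    return p * (math.log2(p / (p + n)) - math.log2(P / (P + N)))


def _best_condition(
    X: np.ndarray, pos: np.ndarray, covered: np.ndarray
) -> tuple[tuple[int, str, float], float] | None:
    """Exhaustive midpoint search for the FOIL-gain-maximizing condition."""
    idx = np.nonzero(covered)[0]
    P = float(pos[idx].sum())
    N = float(len(idx) - P)
    if P == 0:
        return None
    best_gain = 0.0
    best: tuple[int, str, float] | None = None
    for j in range(X.shape[1]):
        vals = X[idx, j]
        order = np.argsort(vals, kind="stable")
        sv = vals[order]
        sp = pos[idx][order].astype(float)
        cum_p = np.cumsum(sp)
        distinct = np.nonzero(sv[:-1] < sv[1:])[0]
        for i in distinct:
            thr = 0.5 * (sv[i] + sv[i + 1])
            p_le = cum_p[i]
            n_le = (i + 1) - p_le
            g = _foil_gain(p_le, n_le, P, N)
            if g > best_gain:
                best_gain, best = g, (j, "<=", float(thr))
            p_ge = P - p_le
            n_ge = N - n_le
            g = _foil_gain(p_ge, n_ge, P, N)
            if g > best_gain:
                best_gain, best = g, (j, ">=", float(thr))
    if best is None:
        return None
    return best, best_gain


def _grow(X: np.ndarray, y: np.ndarray, target) -> list[tuple[int, str, float]] | None:
    """Greedy FOIL growth until no negatives remain or no positive gain.

    Returns None when no first condition has positive gain (empty-rule
    signal: the class is not separable on the grow set).
    """
    pos = y == target
    covered = np.ones(len(y), dtype=bool)
    conds: list[tuple[int, str, float]] = []
    while True:
        n_cov = int((~pos & covered).sum())
        if n_cov == 0 and conds:
            return conds
        found = _best_condition(X, pos, covered)
        if found is None:
            return conds if conds else None
        cond, _gain = found
        conds.append(cond)
        covered &= _cond_mask(X, cond)
        if not (~pos & covered).any():
            return conds


def _prune_worth(p: float, n: float) -> float:
    if p + n == 0:
        return -1.0
    return (p - n) / (p + n)


def _prune(
    conds: Sequence[tuple[int, str, float]], X: np.ndarray, y: np.ndarray, target
) -> list[tuple[int, str, float]]:
    """Keep the prefix of conditions maximizing (p - n)/(p + n) on the prune
    set; among ties the shorter rule wins."""
    pos = y == target
    best_j, best_w = None, -math.inf
    mask = np.ones(len(y), dtype=bool)
    for j, cond in enumerate(conds, start=1):
        mask &= _cond_mask(X, cond)
        p = float(pos[mask].sum())
        n = float(mask.sum() - p)
        w = _prune_worth(p, n)
        if w > best_w:  # strict: earlier (shorter) prefix wins ties
            best_w, best_j = w, j
    return list(conds[:best_j])


# ---------------------------------------------------------------------------
# Description length
# ---------------------------------------------------------------------------


def _log2_binom(n: float, k: float) -> float:
    if k < 0 or k > n:
        return 0.0
    return float((gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)) / _LN2)


def _theory_dl(n_conds: int, n_features: int) -> float:
    # 0.5 redundancy factor, as conventional for attribute-value rule sets
    if n_conds == 0:
        return 0.0
    return 0.5 * (math.log2(n_conds) + n_conds * math.log2(max(2 * n_features, 2)))


def _ruleset_dl(
    rule_conds: Sequence[Sequence[tuple[int, str, float]]],
    X: np.ndarray,
    pos: np.ndarray,
) -> float:
    """Total DL (theory + exceptions) of a binary one-class ruleset."""
    covered = np.zeros(X.shape[0], dtype=bool)
    theory = 0.0
    for conds in rule_conds:
        covered |= _rule_mask(X, conds)
        theory += _theory_dl(len(conds), X.shape[1])
    fp = float((covered & ~pos).sum())
    fn = float((~covered & pos).sum())
    exceptions = _log2_binom(float(covered.sum()), fp) + _log2_binom(
        float((~covered).sum()), fn
    )
    return theory + exceptions


# ---------------------------------------------------------------------------
# Sequential covering
# ---------------------------------------------------------------------------


def _grow_prune_split(
    idx: np.ndarray, pos: np.ndarray, frac: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    perm = idx[rng.permutation(len(idx))]
    cut = max(1, int(math.ceil(frac * len(perm))))
    grow, prune = perm[:cut], perm[cut:]
    if not pos[grow].any() or len(prune) == 0:
        # too little data to hold out a prune split: use everything for both
        return idx, idx
    if not pos[prune].any():
        return idx, idx
    return grow, prune


def _build_class_rules(
    X: np.ndarray,
    y: np.ndarray,
    target,
    active: np.ndarray,
    config: RuleLearnerConfig,
    rng: np.random.Generator,
) -> list[list[tuple[int, str, float]]]:
    pos_all = y == target
    remaining = active.copy()
    accepted: list[list[tuple[int, str, float]]] = []
    best_dl = math.inf
    while (pos_all & remaining).any():
        idx = np.nonzero(remaining)[0]
        grow_idx, prune_idx = _grow_prune_split(idx, pos_all, config.grow_fraction, rng)
        conds = _grow(X[grow_idx], y[grow_idx], target)
        if conds is None:
            break
        conds = _prune(conds, X[prune_idx], y[prune_idx], target)
        cov = _rule_mask(X, conds) & remaining
        p_cov = int((pos_all & cov).sum())
        n_cov = int(cov.sum()) - p_cov
        if cov.sum() < config.min_coverage or p_cov <= n_cov:
            break  # error rate >= 50% on its own coverage: not worth keeping
        accepted.append(conds)
        dl = _ruleset_dl(accepted, X[active], pos_all[active])
        if dl < best_dl:
            best_dl = dl
        elif dl > best_dl + config.mdl_slack_bits:
            accepted.pop()
            break
        remaining &= ~cov
    return accepted


def _optimize_class_rules(
    rules: list[list[tuple[int, str, float]]],
    X: np.ndarray,
    y: np.ndarray,
    target,
    active: np.ndarray,
    config: RuleLearnerConfig,
    rng: np.random.Generator,
) -> list[list[tuple[int, str, float]]]:
    pos_all = y == target
    for _ in range(config.optimization_rounds):
        for i in range(len(rules)):
            context = active.copy()
            for prev in rules[:i]:
                context &= ~_rule_mask(X, prev)
            if not (pos_all & context).any():
                continue
            idx = np.nonzero(context)[0]
            grow_idx, prune_idx = _grow_prune_split(idx, pos_all, config.grow_fraction, rng)
            candidates = [rules[i]]
            repl = _grow(X[grow_idx], y[grow_idx], target)
            if repl is not None:
                candidates.append(_prune(repl, X[prune_idx], y[prune_idx], target))
            # revision: extend the current rule where it still covers, then re-prune
            rev_scope = grow_idx[_rule_mask(X[grow_idx], rules[i])]
            if (pos_all[rev_scope]).any() and (~pos_all[rev_scope]).any():
                ext = _grow(X[rev_scope], y[rev_scope], target)
                if ext is not None:
                    candidates.append(
                        _prune(list(rules[i]) + ext, X[prune_idx], y[prune_idx], target)
                    )
            best, best_dl = rules[i], math.inf
            for cand in candidates:
                if not cand:
                    continue
                trial = rules[:i] + [cand] + rules[i + 1 :]
                dl = _ruleset_dl(trial, X[active], pos_all[active])
                if dl < best_dl:
                    best, best_dl = cand, dl
            rules[i] = list(best)
    return rules


def _class_processing_order(
    class_names: Sequence[str], y: np.ndarray, config: RuleLearnerConfig
) -> list[str]:
    present = [c for c in class_names if (y == c).any()]
    if config.class_ordering == "fixed":
        order = list(config.class_order) if config.class_order else list(present)
        missing = [c for c in present if c not in order]
        return [c for c in order if c in present] + missing
    counts = {c: int((y == c).sum()) for c in present}
    return sorted(present, key=lambda c: (counts[c], class_names.index(c)))


def _learn_arrays(
    X: np.ndarray,
    y: np.ndarray,
    feature_names: Sequence[str],
    class_names: Sequence[str],
    config: RuleLearnerConfig,
) -> RuleList:
    order = _class_processing_order(list(class_names), y, config)
    if len(order) < 2:
        raise ValueError("rule learning needs at least two classes present")
    rng = np.random.default_rng(config.seed)
    active = np.ones(len(y), dtype=bool)
    out: list[Rule] = []
    for cls in order[:-1]:
        conds_list = _build_class_rules(X, y, cls, active, config, rng)
        conds_list = _optimize_class_rules(conds_list, X, y, cls, active, config, rng)
        for conds in conds_list:
            out.append(
                Rule(
                    tuple(Condition(feature_names[j], op, thr) for j, op, thr in conds),
                    cls,
                )
            )
            active &= ~_rule_mask(X, conds)
    out.append(Rule((), order[-1]))  # last-ordered class is the default
    return RuleList(tuple(out))


def grow_rule(
    X: np.ndarray,
    y: Sequence,
    target_class,
    feature_names: Sequence[str] | None = None,
) -> Rule | None:
    """Grow a single rule for ``target_class`` on the given grow set.

    Returns None when no condition achieves positive FOIL gain.
    """
    X = np.asarray(X, float)
    y = np.asarray(y)
    if not (y == target_class).any():
        raise ValueError(f"grow set contains no samples of class {target_class!r}")
    names = list(feature_names) if feature_names is not None else [
        f"f{j}" for j in range(X.shape[1])
    ]
    conds = _grow(X, y, target_class)
    if conds is None:
        return None
    return Rule(tuple(Condition(names[j], op, thr) for j, op, thr in conds), target_class)


def prune_rule(
    rule: Rule, X: np.ndarray, y: Sequence, target_class,
    feature_names: Sequence[str] | None = None,
) -> Rule:
    """Drop a final run of conditions to maximize (p - n)/(p + n) on the
    prune set; ties keep the shorter rule."""
    if rule.is_default:
        raise ValueError("cannot prune the default rule")
    X = np.asarray(X, float)
    y = np.asarray(y)
    names = list(feature_names) if feature_names is not None else [
        f"f{j}" for j in range(X.shape[1])
    ]
    lookup = {n: j for j, n in enumerate(names)}
    conds = [(lookup[c.marker_id], c.op, c.threshold) for c in rule.conditions]
    kept = _prune(conds, X, y, target_class)
    return Rule(tuple(rule.conditions[: len(kept)]), rule.consequent)


def learn_ruleset(
    dataset: LabeledDataset,
    config: RuleLearnerConfig | None = None,
    feature_subset: Sequence[str] | None = None,
) -> RuleList:
    """Learn an ordered decision list with a default class from a labeled panel."""
    config = config or RuleLearnerConfig()
    data = dataset.subset_features(feature_subset) if feature_subset is not None else dataset
    return _learn_arrays(
        data.signal.values, data.y, data.signal.marker_ids, data.class_names, config
    )


def _predict_arrays(
    rules: RuleList, X: np.ndarray, col_of: dict[str, int]
) -> np.ndarray:
    missing = [m for m in rules.marker_ids if m not in col_of]
    if missing:
        raise KeyError(f"marker {missing[0]!r} not present in matrix")
    n = X.shape[0]
    out = np.full(n, rules.default_class, dtype=object)
    unassigned = np.ones(n, dtype=bool)
    for rule in rules.conditioned:
        mask = np.ones(n, dtype=bool)
        for c in rule.conditions:
            col = X[:, col_of[c.marker_id]]
            mask &= (col <= c.threshold) if c.op == "<=" else (col >= c.threshold)
        fire = mask & unassigned
        out[fire] = rule.consequent
        unassigned &= ~fire
    return out


def predict_rule_list(rules: RuleList, matrix: SignalMatrix) -> np.ndarray:
    """Apply an ordered decision list: the first rule whose conditions all
    hold fires; unmatched samples take the default class."""
    col_of = {m: j for j, m in enumerate(matrix.marker_ids)}
    return _predict_arrays(rules, matrix.values, col_of)


def rule_support_accuracy(
    rules: RuleList, dataset: LabeledDataset, sequential: bool = False
) -> list[tuple[float, float]]:
    """Per-rule (support %, accuracy %).

    By default each rule is evaluated independently: support is the
    percentage of all samples whose values satisfy the rule's conditions,
    regardless of earlier rules (rules may overlap, so supports need not
    sum to 100), and accuracy is the share of satisfying samples whose
    label equals the consequent. With ``sequential=True`` a rule is scored
    only on the samples it actually fires on under first-match prediction.
    Either way the default rule is scored on the samples matched by no
    conditioned rule. A rule satisfied by no sample reports support 0 and
    NaN accuracy.
    """
    X = dataset.signal.values
    y = dataset.y
    col_of = {m: j for j, m in enumerate(dataset.signal.marker_ids)}
    missing = [m for m in rules.marker_ids if m not in col_of]
    if missing:
        raise KeyError(f"marker {missing[0]!r} not present in dataset")
    n = len(y)
    out: list[tuple[float, float]] = []
    matched_any = np.zeros(n, dtype=bool)
    for rule in rules.conditioned:
        mask = np.ones(n, dtype=bool)
        for c in rule.conditions:
            col = X[:, col_of[c.marker_id]]
            mask &= (col <= c.threshold) if c.op == "<=" else (col >= c.threshold)
        if sequential:
            mask &= ~matched_any
        matched_any |= mask
        cov = int(mask.sum())
        support = 100.0 * cov / n
        accuracy = 100.0 * float((y[mask] == rule.consequent).sum()) / cov if cov else math.nan
        out.append((support, accuracy))
    default_mask = ~matched_any
    cov = int(default_mask.sum())
    support = 100.0 * cov / n
    accuracy = (
        100.0 * float((y[default_mask] == rules.default_class).sum()) / cov if cov else math.nan
    )
    out.append((support, accuracy))
    return out


def annotate_rule_list(rules: RuleList, dataset: LabeledDataset) -> RuleList:
    """Return a copy of the rule list with support/accuracy percentages filled in."""
    stats = rule_support_accuracy(rules, dataset)
    annotated = tuple(
        replace(rule, support_pct=s, accuracy_pct=a)
        for rule, (s, a) in zip(rules.rules, stats)
    )
    return RuleList(annotated)


class RuleListClassifier:
    """fit/predict adapter so the rule learner plugs into cross-validation."""

    def __init__(
        self,
        feature_names: Sequence[str],
        class_names: Sequence[str],
        config: RuleLearnerConfig | None = None,
        seed: int = 0,
    ):
        self.feature_names = list(feature_names)
        self.class_names = list(class_names)
        base = config or RuleLearnerConfig()
        self.config = replace(base, seed=seed)

    def fit(self, X: np.ndarray, y: Sequence) -> "RuleListClassifier":
        self.rules_ = _learn_arrays(
            np.asarray(X, float), np.asarray(y), self.feature_names, self.class_names,
            self.config,
        )
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        col_of = {m: j for j, m in enumerate(self.feature_names)}
        return _predict_arrays(self.rules_, np.asarray(X, float), col_of)
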