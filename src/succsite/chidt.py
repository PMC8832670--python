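"""ChiDT: the chi-square decision table classifier for imbalanced data.

Retained features are discretized by adjacent-column chi-square compression
of their 2 x m value tables.  Features are then introduced one by one: the
next feature is the one with the highest gain ratio among candidates whose
information gain is at least average, where a candidate must keep at least
two bins in some leaf after per-leaf recompression.  Each introduction splits
every leaf where the feature remains informative, so rules (leaf condition
conjunctions) have variable length.  The leaf class counts form a decision
table whose negative row is rebalanced by theta = total positives / total
negatives; a sample is classified by hypothetically adding it to its matched
rule as positive vs negative and comparing the two resulting table
chi-squares (ties go to the negative, majority-prior class).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .contingency import ContingencyTable, chi2_stat, compress_table

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# information measures


def entropy(labels: Sequence[int]) -> float:
    """Shannon entropy of a binary label multiset, in bits (0*log0 = 0)."""
    labels = np.asarray(labels)
    if labels.size == 0:
        raise ValueError("empty sample set")
    p = float(np.mean(labels == 1))
    out = 0.0
    for q in (p, 1 - p):
        if q > 0:
            out -= q * math.log2(q)
    return out


def gain_and_ratio(
    labels: Sequence[int], bin_ids: Sequence[int]
) -> tuple[float, float | None]:
    """Information gain and gain ratio of a discretized feature.

    Returns ``(gain, ratio)``; ``ratio`` is None when the intrinsic value is
    zero (all samples in one bin), signalling the feature is not a usable
    split rather than raising.
    """
    labels = np.asarray(labels)
    bin_ids = np.asarray(bin_ids)
    if labels.shape != bin_ids.shape:
        raise ValueError("labels and bin ids must align")
    n = labels.size
    gain = entropy(labels)
    iv = 0.0
    for b in np.unique(bin_ids):
        mask = bin_ids == b
        w = mask.sum() / n
        gain -= w * entropy(labels[mask])
        iv -= w * math.log2(w)
    if iv <= 0:
        return gain, None
    return gain, gain / iv


# ---------------------------------------------------------------------------
# discretization


@dataclass(frozen=True)
class FeatureDiscretization:
    """Adjacent-merge discretization of one feature.

    ``values`` are the sorted distinct training values; ``bin_of_value[k]``
    maps distinct value k to its bin; ``edges`` are the cut points (midpoints
    between the bounding values of adjacent bins), so boundary bins extend to
    +-infinity at prediction time.
    """

    feature: str
    values: tuple[float, ...]
    bin_of_value: tuple[int, ...]
    edges: tuple[float, ...]

    @property
    def n_bins(self) -> int:
        return len(self.edges) + 1

    def assign(self, x: np.ndarray) -> np.ndarray:
        """Bin index for arbitrary values (unseen values fall in the
        containing extended interval)."""
        return np.searchsorted(np.asarray(self.edges), x, side="left")

    def bin_value_range(self, b: int) -> tuple[float, float]:
        vals = [v for v, g in zip(self.values, self.bin_of_value) if g == b]
        return (min(vals), max(vals))


def discretize_feature(
    name: str, x: np.ndarray, y: np.ndarray, alpha: float = 0.05
) -> FeatureDiscretization:
    """Compress the 2 x m distinct-value table in adjacent mode (floor 2)."""
    values = np.unique(x)
    if values.size < 2:
        return FeatureDiscretization(name, tuple(values), (0,) * values.size, ())
    idx = np.searchsorted(values, x)
    table = ContingencyTable.from_observations(idx, y, status_order=range(values.size))
    comp = compress_table(table, alpha=alpha, mode="adjacent", min_groups=2)
    bin_of_value = [0] * values.size
    # adjacent groups are contiguous; order them by their first value index
    groups = sorted(comp.groups, key=lambda g: min(g))
    edges = []
    for b, group in enumerate(groups):
        for k in group:
            bin_of_value[k] = b
        if b + 1 < len(groups):
            left = values[max(group)]
            right = values[min(groups[b + 1])]
            edges.append(float((left + right) / 2))
    return FeatureDiscretization(
        name, tuple(map(float, values)), tuple(bin_of_value), tuple(edges)
    )


# ---------------------------------------------------------------------------
# rules and decision table


@dataclass(frozen=True)
class Condition:
    """One conjunct of a rule: feature confined to [low, high] training values."""

    feature: str
    low: float
    high: float

    def __str__(self) -> str:
        if self.low == self.high:
            return f"({self.feature} = {self.low:g})"
        return f"({self.low:g} <= {self.feature} <= {self.high:g})"


@dataclass(frozen=True)
class Rule:
    conditions: tuple[Condition, ...]
    pos_count: float
    neg_count: float
    weighted_neg: float | None = None

    def __str__(self) -> str:
        return " ^ ".join(map(str, self.conditions)) or "(always)"


@dataclass(frozen=True)
class RuleTable:
    rules: tuple[Rule, ...]
    total_pos: float
    total_neg: float

    @property
    def theta(self) -> float:
        return self.total_pos / self.total_neg


def balance_table(rule_table: RuleTable, theta: float | None = None) -> RuleTable:
    """Weight each rule's negative count by theta (positives untouched)."""
    if rule_table.total_pos <= 0 or rule_table.total_neg <= 0:
        raise ValueError("both class totals must be positive")
    theta = rule_table.theta if theta is None else theta
    rules = tuple(
        Rule(r.conditions, r.pos_count, r.neg_count, r.neg_count * theta)
        for r in rule_table.rules
    )
    return RuleTable(rules, rule_table.total_pos, rule_table.total_neg)


def decide_from_counts(pos: np.ndarray, wneg: np.ndarray, k: int) -> bool:
    """Incremental-chi-square decision for the rule at column k.

    The sample is hypothetically added to the balanced 2 x R table as a
    positive, then as a negative; it is predicted positive iff the positive
    hypothesis yields the strictly larger table chi-square.
    """
    labels = tuple(range(len(pos)))
    pos_h = pos.copy(); pos_h[k] += 1
    neg_h = wneg.copy(); neg_h[k] += 1
    chi_pos = chi2_stat(ContingencyTable(labels, pos_h, wneg))
    chi_neg = chi2_stat(ContingencyTable(labels, pos, neg_h))
    if math.isclose(chi_pos, chi_neg, rel_tol=1e-9, abs_tol=1e-12):
        return False  # ties go to the majority-prior (negative) class
    return chi_pos > chi_neg


# ---------------------------------------------------------------------------
# the classifier


@dataclass
class _Leaf:
    indices: np.ndarray
    conditions: list[Condition]
    rule_index: int = -1


@dataclass
class _Node:
    feature: str
    edges: tuple[float, ...]  # routing cut values at this node
    children: list


class ChiDTClassifier:
    """Fit/predict interface around the decision-table construction.

    Fitted attributes: ``discretizations_`` (per feature),
    ``feature_order_`` (introduction order), ``rule_table_`` (balanced),
    ``tree_`` (routing structure), ``rule_decisions_`` (precomputed
    per-rule labels, since the incremental-chi-square decision depends only
    on the matched rule).
    """

    def __init__(self, alpha: float = 0.05):
        if not 0 < alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        self.alpha = alpha

    # -- fitting ----------------------------------------------------------

    def fit(self, X: pd.DataFrame, y: Sequence[int]) -> "ChiDTClassifier":
        X = pd.DataFrame(X)
        y = np.asarray(y, dtype=int)
        if len(X) != len(y):
            raise ValueError("X and y must align")
        if set(np.unique(y)) != {0, 1}:
            raise ValueError("training data must contain both classes")

        self.feature_names_ = list(map(str, X.columns))
        self.discretizations_ = {}
        global_bins = {}  # feature -> per-sample global bin id
        for name in self.feature_names_:
            col = X[name].to_numpy(dtype=float)
            disc = discretize_feature(name, col, y, alpha=self.alpha)
            self.discretizations_[name] = disc
            global_bins[name] = disc.assign(col)

        root = _Leaf(indices=np.arange(len(y)), conditions=[])
        leaves: list[_Leaf] = [root]
        self.tree_: _Node | _Leaf = root
        parent_slots: dict[int, tuple] = {id(root): None}  # leaf -> (node, child_pos)

        remaining = [
            n for n in self.feature_names_ if self.discretizations_[n].n_bins >= 2
        ]
        introduced: list[str] = []

        while remaining:
            further = bool(introduced)
            candidates = {}
            for name in remaining:
                per_leaf = {}
                for li, leaf in enumerate(leaves):
                    groups = self._leaf_groups(
                        global_bins[name][leaf.indices], y[leaf.indices],
                        self.discretizations_[name].n_bins, further,
                    )
                    if len(groups) >= 2:
                        per_leaf[li] = groups
                if per_leaf:
                    candidates[name] = per_leaf
            if not candidates:
                break

            stats = {}
            n_total = len(y)
            for name, per_leaf in candidates.items():
                gain = iv = 0.0
                for li, groups in per_leaf.items():
                    leaf = leaves[li]
                    gb = global_bins[name][leaf.indices]
                    group_of = self._group_lookup(groups)
                    bins = group_of[gb]
                    g, _ = gain_and_ratio(y[leaf.indices], bins)
                    w = len(leaf.indices) / n_total
                    gain += w * g
                    iv += w * self._intrinsic_value(bins)
                stats[name] = (gain, iv)

            mean_gain = float(np.mean([g for g, _ in stats.values()]))
            pool = [n for n in candidates if stats[n][0] >= mean_gain]
            chosen = max(
                pool,
                key=lambda n: (
                    stats[n][0] / stats[n][1],
                    -self.feature_names_.index(n),
                ),
            )

            leaves = self._split_leaves(
                leaves, chosen, candidates[chosen], global_bins[chosen], parent_slots
            )
            introduced.append(chosen)
            remaining.remove(chosen)

        if not introduced:
            raise ValueError("no feature can be introduced (no informative split)")

        self.feature_order_ = introduced
        rules = []
        for k, leaf in enumerate(leaves):
            leaf.rule_index = k
            rules.append(
                Rule(
                    conditions=tuple(leaf.conditions),
                    pos_count=float((y[leaf.indices] == 1).sum()),
                    neg_count=float((y[leaf.indices] == 0).sum()),
                )
            )
        raw = RuleTable(tuple(rules), float((y == 1).sum()), float((y == 0).sum()))
        self.rule_table_ = balance_table(raw)
        pos = np.array([r.pos_count for r in self.rule_table_.rules])
        wneg = np.array([r.weighted_neg for r in self.rule_table_.rules])
        self.rule_decisions_ = np.array(
            [decide_from_counts(pos, wneg, k) for k in range(len(pos))], dtype=int
        )
        self._finalize_tree()
        return self

    def _leaf_groups(self, gb, y_leaf, n_bins, further):
        """Contiguous global-bin groups alive in a leaf.

        Restricted to the leaf's samples the feature's bins are recompressed
        (adjacent mode, floor 1: the final pair may merge too).  Before any
        feature is introduced the single leaf is the full training set and
        the globally compressed bins are used as-is.
        """
        present = np.unique(gb)
        if not further:
            return [[b] for b in range(n_bins)]
        if present.size < 2 or np.unique(y_leaf).size < 2:
            # a single-valued or single-class leaf offers nothing to split:
            # every local test is vacuous, the table collapses to one column
            return [sorted(range(n_bins))]
        table = ContingencyTable.from_observations(
            gb, y_leaf, status_order=range(n_bins)
        )
        comp = compress_table(table, alpha=self.alpha, mode="adjacent", min_groups=1)
        # empty bins were absorbed into a neighboring group (local p = 1) and
        # stay there, so routing edges stay consistent at prediction time
        return sorted((sorted(g) for g in comp.groups), key=lambda g: g[0])

    @staticmethod
    def _group_lookup(groups):
        size = max(b for g in groups for b in g) + 1
        lookup = np.zeros(size, dtype=int)
        for gi, g in enumerate(groups):
            for b in g:
                lookup[b] = gi
        return lookup

    @staticmethod
    def _intrinsic_value(bins: np.ndarray) -> float:
        iv = 0.0
        n = bins.size
        for b in np.unique(bins):
            w = (bins == b).sum() / n
            iv -= w * math.log2(w)
        return iv

    def _split_leaves(self, leaves, feature, per_leaf, gb_all, parent_slots):
        disc = self.discretizations_[feature]
        new_leaves = []
        for li, leaf in enumerate(leaves):
            if li not in per_leaf:
                new_leaves.append(leaf)
                continue
            groups = per_leaf[li]
            group_of = self._group_lookup(groups)
            # routing edges between consecutive groups use the global cuts
            edges = tuple(disc.edges[max(g)] for g in groups[:-1])
            node = _Node(feature=feature, edges=edges, children=[])
            slot = parent_slots.pop(id(leaf))
            if slot is None:
                self.tree_ = node
            else:
                pnode, pos = slot
                pnode.children[pos] = node
            bins = group_of[gb_all[leaf.indices]]
            for gi, group in enumerate(groups):
                lo = min(disc.bin_value_range(b)[0] for b in group)
                hi = max(disc.bin_value_range(b)[1] for b in group)
                child = _Leaf(
                    indices=leaf.indices[bins == gi],
                    conditions=leaf.conditions + [Condition(feature, lo, hi)],
                )
                node.children.append(child)
                parent_slots[id(child)] = (node, gi)
                new_leaves.append(child)
        return new_leaves

    def _finalize_tree(self) -> None:
        """Replace per-leaf sample indices by rule indices (frees training data)."""

        def strip(node):
            if isinstance(node, _Leaf):
                return {"rule": node.rule_index}
            return {
                "feature": node.feature,
                "edges": list(node.edges),
                "children": [strip(c) for c in node.children],
            }

        self.tree_spec_ = strip(self.tree_)

    # -- prediction -------------------------------------------------------

    def match_rule(self, sample: Mapping[str, float]) -> int:
        """Index of the rule a feature mapping falls into."""
        node = self.tree_spec_
        while "rule" not in node:
            name = node["feature"]
            if name not in sample:
                raise KeyError(f"sample lacks feature {name!r}")
            k = int(np.searchsorted(node["edges"], float(sample[name]), side="left"))
            node = node["children"][k]
        return node["rule"]

    def predict_sample(self, sample: Mapping[str, float]) -> int:
        try:
            k = self.match_rule(sample)
        except KeyError:
            raise
        return int(self.rule_decisions_[k])

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        X = pd.DataFrame(X)
        missing = [n for n in self.feature_order_ if n not in X.columns]
        if missing:
            raise ValueError(f"feature matrix lacks model features {missing}")
        return np.array(
            [self.predict_sample(row) for row in X.to_dict("records")], dtype=int
        )


def grow_rules(
    X: pd.DataFrame, y: Sequence[int], alpha: float = 0.05
) -> RuleTable:
    """Fit the decision-table structure and return the raw (unweighted)
    rule table; a convenience wrapper over :class:`ChiDTClassifier`."""
    clf = ChiDTClassifier(alpha=alpha).fit(X, y)
    rules = tuple(
        Rule(r.conditions, r.pos_count, r.neg_count) for r in clf.rule_table_.rules
    )
    return RuleTable(rules, clf.rule_table_.total_pos, clf.rule_table_.total_neg)
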