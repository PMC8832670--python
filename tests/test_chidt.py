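"""ChiDT classifier: discretization, rule growth, weighting, decisions."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import chi2_contingency

from succsite.chidt import (
    ChiDTClassifier,
    Rule,
    RuleTable,
    balance_table,
    decide_from_counts,
    discretize_feature,
    entropy,
    gain_and_ratio,
    grow_rules,
)


def _pearson_chi2(pos, neg):
    obs = np.array([pos, neg], dtype=float)
    obs = obs[:, obs.sum(axis=0) > 0]
    if obs.shape[1] < 2:
        return 0.0
    stat, _, _, _ = chi2_contingency(obs, correction=False)
    return stat


class TestInformationMeasures:
    def test_entropy_values(self):
        assert entropy([0, 1]) == pytest.approx(1.0)
        assert entropy([1, 1, 1]) == 0.0
        p = 0.25
        expected = -(p * math.log2(p) + (1 - p) * math.log2(1 - p))
        assert entropy([1, 0, 0, 0]) == pytest.approx(expected)

    def test_perfect_split_gain_and_ratio_one(self):
        y = [1] * 10 + [0] * 10
        bins = [0] * 10 + [1] * 10
        gain, ratio = gain_and_ratio(y, bins)
        assert gain == pytest.approx(1.0)
        assert ratio == pytest.approx(1.0)

    def test_uninformative_bins_zero_gain(self):
        y = [1, 0] * 10
        bins = [0, 0, 1, 1] * 5
        gain, _ = gain_and_ratio(y, bins)
        assert gain == pytest.approx(0.0, abs=1e-12)

    def test_single_bin_signals_unusable(self):
        gain, ratio = gain_and_ratio([1, 0, 1, 0], [0, 0, 0, 0])
        assert ratio is None

    def test_matches_hand_rolled_oracle(self, rng):
        for _ in range(10):
            n = 40
            y = rng.integers(0, 2, size=n)
            if y.min() == y.max():
                continue
            bins = rng.integers(0, 3, size=n)
            gain, ratio = gain_and_ratio(y, bins)
            # independent evaluation
            def h(v):
                out = 0.0
                for k in (0, 1):
                    q = np.mean(v == k)
                    if q > 0:
                        out -= q * math.log2(q)
                return out

            expected_gain = h(y) - sum(
                (bins == b).mean() * h(y[bins == b]) for b in np.unique(bins)
            )
            iv = -sum(
                (bins == b).mean() * math.log2((bins == b).mean())
                for b in np.unique(bins)
            )
            assert gain == pytest.approx(expected_gain)
            if ratio is not None:
                assert ratio == pytest.approx(expected_gain / iv)


class TestDiscretization:
    def test_bins_cover_and_order(self, rng):
        x = rng.normal(size=300)
        y = (x + rng.normal(scale=0.5, size=300) > 0).astype(int)
        disc = discretize_feature("f", x, y)
        assert disc.n_bins >= 2
        bins = disc.assign(x)
        assert bins.min() == 0 and bins.max() == disc.n_bins - 1
        # assignment is monotone in the value
        order = np.argsort(x)
        assert (np.diff(bins[order]) >= 0).all()

    def test_boundary_bins_extend_to_infinity(self, rng):
        x = np.array([0.0, 1.0, 2.0, 3.0] * 20)
        y = np.array([0, 0, 1, 1] * 20)
        disc = discretize_feature("f", x, y)
        assert disc.assign(np.array([-100.0]))[0] == 0
        assert disc.assign(np.array([100.0]))[0] == disc.n_bins - 1


class TestRuleGrowth:
    def test_perfect_binary_feature_two_pure_rules(self):
        y = np.array([1] * 20 + [0] * 200)
        X = pd.DataFrame({"a": y.astype(float)})
        rt = grow_rules(X, y)
        assert len(rt.rules) == 2
        counts = sorted((r.pos_count, r.neg_count) for r in rt.rules)
        assert counts == [(0.0, 200.0), (20.0, 0.0)]

    def test_variable_rule_lengths(self):
        # the f1=0 leaf is pure, so f2 only splits the f1=1 leaf
        f1 = np.array([0, 0, 0, 0, 1, 1, 1, 1] * 30, dtype=float)
        f2 = np.array([0, 1, 0, 1, 0, 0, 1, 1] * 30, dtype=float)
        y = np.array([0, 0, 0, 0, 0, 0, 1, 1] * 30)
        rt = grow_rules(pd.DataFrame({"f1": f1, "f2": f2}), y)
        lengths = sorted(len(r.conditions) for r in rt.rules)
        assert lengths == [1, 2, 2]
        # brute-force sample routing reproduces every rule's counts
        def matches(rule, xf1, xf2):
            vals = {"f1": xf1, "f2": xf2}
            return all(c.low <= vals[c.feature] <= c.high for c in rule.conditions)

        for rule in rt.rules:
            mask = np.array([matches(rule, a, b) for a, b in zip(f1, f2)])
            assert rule.pos_count == (y[mask] == 1).sum()
            assert rule.neg_count == (y[mask] == 0).sum()

    def test_partition_and_conservation_invariants(self, trained_model,
                                                    train_fragments):
        clf = trained_model.classifier
        rt = clf.rule_table_
        y = np.array([f.label for f in train_fragments])
        X = trained_model.encode(train_fragments)[list(trained_model.selected_features)]
        matched = np.array([clf.match_rule(row) for row in X.to_dict("records")])
        # every training sample matches exactly one rule; counts add up
        for k, rule in enumerate(rt.rules):
            mask = matched == k
            assert rule.pos_count == (y[mask] == 1).sum()
            assert rule.neg_count == (y[mask] == 0).sum()
        assert sum(r.pos_count for r in rt.rules) == rt.total_pos == (y == 1).sum()
        assert sum(r.neg_count for r in rt.rules) == rt.total_neg == (y == 0).sum()

    def test_single_class_errors(self):
        X = pd.DataFrame({"a": [1.0, 2.0, 3.0, 4.0]})
        with pytest.raises(ValueError):
            ChiDTClassifier().fit(X, [1, 1, 1, 1])


class TestBalancedTable:
    def test_published_theta_weighting(self):
        rt = RuleTable(
            (Rule((), 23, 2907), Rule((), 32, 83), Rule((), 4693, 47561)),
            total_pos=4748,
            total_neg=50551,
        )
        bt = balance_table(rt)
        assert round(bt.rules[0].weighted_neg, 2) == 273.04
        assert round(bt.rules[1].weighted_neg, 2) == 7.80

    def test_theta_one_is_identity(self):
        rt = RuleTable((Rule((), 5, 7),), total_pos=5, total_neg=7)
        bt = balance_table(rt, theta=1.0)
        assert bt.rules[0].weighted_neg == 7

    def test_weighted_negatives_sum_to_positives(self, trained_model):
        rt = trained_model.classifier.rule_table_
        total_w = sum(r.weighted_neg for r in rt.rules)
        assert total_w == pytest.approx(rt.total_pos, rel=1e-6)


class TestDecision:
    def test_pure_positive_rule_predicts_positive(self):
        pos = np.array([10.0, 2.0])
        wneg = np.array([0.0, 8.0])
        assert decide_from_counts(pos, wneg, 0)

    def test_symmetric_tie_goes_negative(self):
        pos = np.array([5.0, 3.0])
        wneg = np.array([5.0, 3.0])
        assert not decide_from_counts(pos, wneg, 0)

    def test_agrees_with_independent_evaluation(self, rng):
        for _ in range(20):
            r = int(rng.integers(2, 7))
            pos = rng.integers(0, 30, size=r).astype(float)
            wneg = rng.uniform(0, 30, size=r)
            pos[0] = max(pos[0], 1)
            wneg[0] = max(wneg[0], 1e-6)
            k = int(rng.integers(0, r))
            pos_h = pos.copy(); pos_h[k] += 1
            neg_h = wneg.copy(); neg_h[k] += 1
            expected = _pearson_chi2(pos_h, wneg) > _pearson_chi2(pos, neg_h)
            assert decide_from_counts(pos, wneg, k) == expected

    def test_class_flip_inverts_tie_free_decisions(self, rng):
        for _ in range(20):
            pos = rng.uniform(1, 20, size=4)
            wneg = rng.uniform(1, 20, size=4)
            k = int(rng.integers(0, 4))
            fwd = decide_from_counts(pos, wneg, k)
            rev = decide_from_counts(wneg, pos, k)
            if fwd or rev:  # skip exact ties (both negative)
                assert fwd != rev


class TestEndToEndImbalance:
    def test_sensitivity_beats_majority_baseline(self, trained_model,
                                                 test_fragments):
        y = np.array([f.label for f in test_fragments])
        pred = trained_model.predict(test_fragments)
        sn = ((pred == 1) & (y == 1)).sum() / (y == 1).sum()
        assert sn > 0.5
        # the majority-class rule never finds a positive
        majority_sn = 0.0
        assert majority_sn == 0.0 and sn > majority_sn
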