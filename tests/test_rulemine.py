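"""Mining: occurrence semantics, support/confidence, and equivalence of the
level-wise miners with brute-force enumeration oracles."""

from collections import Counter
from itertools import combinations

import numpy as np
import pytest

from conftest import make_seq_transactions, make_set_transactions
from zonerule.depstruct import normalise
from zonerule.rulemine import (
    SEQUENCE_MODE,
    SET_MODE,
    AssociationRule,
    Transaction,
    confidence,
    frequent_patterns,
    mine_per_type,
    mine_rules,
    occurs,
    support,
)
from zonerule.serialise import BAG1, SET, Serialisation, serialise

# --------------------------------------------------------------------------
# Brute-force oracles (independent of the miner: exhaustive enumeration,
# and a backtracking matcher for sequence occurrence)


def oracle_set_frequent(label_sets, min_support):
    """All frequent itemsets by enumerating every subset of the universe."""
    universe = sorted(set().union(*label_sets)) if label_sets else []
    n = len(label_sets)
    out = {}
    for k in range(1, len(universe) + 1):
        for itemset in combinations(universe, k):
            cnt = sum(set(itemset) <= s for s in label_sets)
            if cnt / n >= min_support - 1e-12:
                out[itemset] = cnt / n
    return out


def oracle_set_rules(label_sets, min_support):
    """Every bipartition of every frequent itemset, with exact measures."""
    freq = oracle_set_frequent(label_sets, min_support)
    rules = {}
    for itemset, sup in freq.items():
        if len(itemset) < 2:
            continue
        for r in range(1, len(itemset)):
            for ante in combinations(itemset, r):
                cons = tuple(l for l in itemset if l not in ante)
                rules[((ante,), (cons,))] = (sup, sup / freq[ante])
    return rules


def oracle_seq_occurs(pattern, groups):
    """Backtracking (exhaustive) injective increasing embedding check."""

    def rec(pi, start):
        if pi == len(pattern):
            return True
        bc = Counter(pattern[pi])
        for j in range(start, len(groups)):
            gc = Counter(groups[j])
            if all(gc.get(l, 0) >= m for l, m in bc.items()):
                if rec(pi + 1, j + 1):
                    return True
        return False

    return rec(0, 0)


def oracle_seq_frequent(group_lists, min_support, max_items):
    """All frequent bag-subsequence patterns up to ``max_items`` total labels.

    Candidate patterns are enumerated from the transactions themselves:
    every subsequence of groups combined with every non-empty sub-multiset
    of each chosen group.
    """

    def submultisets(group):
        outs = set()
        for r in range(1, len(group) + 1):
            for combo in combinations(sorted(group), r):
                outs.add(combo)
        return outs

    candidates = set()

    def extend(groups, gi, prefix, items):
        if prefix:
            candidates.add(tuple(prefix))
        if gi == len(groups) or items >= max_items:
            return
        # skip this group
        extend(groups, gi + 1, prefix, items)
        for bag in submultisets(groups[gi]):
            if items + len(bag) <= max_items:
                extend(groups, gi + 1, prefix + [bag], items + len(bag))

    for groups in group_lists:
        extend(list(groups), 0, [], 0)

    n = len(group_lists)
    out = {}
    for pattern in candidates:
        cnt = sum(oracle_seq_occurs(pattern, g) for g in group_lists)
        if cnt / n >= min_support - 1e-12:
            out[pattern] = cnt / n
    return out


def random_set_corpus(rng, max_tx=12, max_labels=8):
    labels = [chr(97 + i) for i in range(rng.integers(2, max_labels + 1))]
    n = rng.integers(2, max_tx + 1)
    sets = []
    for _ in range(n):
        k = rng.integers(1, len(labels) + 1)
        sets.append(set(rng.choice(labels, size=k, replace=False)))
    return sets


def random_seq_corpus(rng, max_tx=8, max_groups=4, max_labels=5):
    labels = [chr(97 + i) for i in range(rng.integers(2, max_labels + 1))]
    n = rng.integers(2, max_tx + 1)
    out = []
    for _ in range(n):
        groups = []
        for _ in range(rng.integers(1, max_groups + 1)):
            size = rng.integers(1, 3)
            groups.append([str(l) for l in rng.choice(labels, size=size)])
        out.append(groups)
    return out


# --------------------------------------------------------------------------
# Occurrence semantics


class TestOccurs:
    def test_set_membership(self, tradd_merged):
        ser = serialise(tradd_merged, SET)
        assert occurs([("det",)], ser, SET_MODE)
        assert occurs([("det", "nsubj", "abbrev")], ser, SET_MODE)
        assert not occurs([("xcomp",)], ser, SET_MODE)

    def test_sequence_respects_order(self, tradd_merged):
        ser = serialise(tradd_merged, BAG1)
        assert occurs([("nsubj",), ("advmod",)], ser, SEQUENCE_MODE)
        # advmod appears only before nsubj's sole occurrence
        assert not occurs([("advmod",), ("nsubj",)], ser, SEQUENCE_MODE)

    def test_sequence_bag_needs_whole_group(self):
        t = make_seq_transactions([[["a", "b"], ["c"]]])[0]
        assert occurs([("a", "b")], t, SEQUENCE_MODE)
        assert not occurs([("a", "c")], t, SEQUENCE_MODE)  # split across groups

    def test_empty_pattern_raises(self, toy_set_transactions):
        with pytest.raises(ValueError):
            occurs([], toy_set_transactions[0], SET_MODE)

    def test_greedy_matches_backtracking_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(200):
            corpus = random_seq_corpus(rng)
            groups = [tuple(tuple(g) for g in t) for t in corpus]
            pat_src = groups[rng.integers(len(groups))]
            # random sub-pattern of a transaction plus random noise patterns
            take = [g[: rng.integers(1, len(g) + 1)] for g in pat_src]
            idx = sorted(
                rng.choice(len(take), size=rng.integers(1, len(take) + 1), replace=False)
            )
            pattern = tuple(take[i] for i in idx)
            for g in groups:
                assert occurs(pattern, g, SEQUENCE_MODE) == oracle_seq_occurs(pattern, g)


class TestSupportConfidence:
    def test_toy_support(self, toy_set_transactions):
        assert support([("a", "b")], toy_set_transactions, SET_MODE) == pytest.approx(2 / 3)
        assert support([("a",)], toy_set_transactions, SET_MODE) == 1.0
        assert support([("z",)], toy_set_transactions, SET_MODE) == 0.0

    def test_empty_transactions_raise(self):
        with pytest.raises(ValueError):
            support([("a",)], [], SET_MODE)

    def test_toy_confidence(self, toy_set_transactions):
        r = AssociationRule((("a",),), (("b",),), 2 / 3, 0.0, SET)
        assert confidence(r, toy_set_transactions) == pytest.approx(2 / 3)
        r2 = AssociationRule((("b",),), (("a",),), 2 / 3, 0.0, SET)
        assert confidence(r2, toy_set_transactions) == pytest.approx(1.0)

    def test_zero_antecedent_support_raises(self, toy_set_transactions):
        r = AssociationRule((("z",),), (("a",),), 0.0, 0.0, SET)
        with pytest.raises(ZeroDivisionError):
            confidence(r, toy_set_transactions)


class TestRuleInvariants:
    def test_sides_must_be_disjoint(self):
        with pytest.raises(ValueError):
            AssociationRule((("a",),), (("a", "b"),), 0.5, 0.5, SET)

    def test_sides_must_be_nonempty(self):
        with pytest.raises(ValueError):
            AssociationRule((), (("a",),), 0.5, 0.5, SET)


# --------------------------------------------------------------------------
# Mining


class TestMineSet:
    def test_toy_corpus_exact(self, toy_set_transactions):
        rules = mine_rules(toy_set_transactions, SET_MODE, 0.6)
        freq = frequent_patterns(toy_set_transactions, SET_MODE, 0.6)
        assert set(freq) == {("a",), ("b",), ("c",), ("a", "b"), ("a", "c")}
        got = {(r.antecedent, r.consequent): (r.support, r.confidence) for r in rules}
        assert got == {
            ((("a",),), (("b",),)): (pytest.approx(2 / 3), pytest.approx(2 / 3)),
            ((("b",),), (("a",),)): (pytest.approx(2 / 3), pytest.approx(1.0)),
            ((("a",),), (("c",),)): (pytest.approx(2 / 3), pytest.approx(2 / 3)),
            ((("c",),), (("a",),)): (pytest.approx(2 / 3), pytest.approx(1.0)),
        }

    def test_single_transaction_all_support_one(self):
        txs = make_set_transactions([{"a", "b", "c"}])
        rules = mine_rules(txs, SET_MODE, 0.5)
        assert rules and all(r.support == 1.0 for r in rules)

    def test_disjoint_labels_no_rules_at_full_support(self):
        txs = make_set_transactions([{"a"}, {"b"}, {"c"}])
        assert mine_rules(txs, SET_MODE, 1.0) == []

    def test_bad_min_support_raises(self, toy_set_transactions):
        with pytest.raises(ValueError):
            mine_rules(toy_set_transactions, SET_MODE, 0.0)
        with pytest.raises(ValueError):
            mine_rules(toy_set_transactions, SET_MODE, 1.5)

    def test_matches_bruteforce_oracle_on_random_corpora(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            sets = random_set_corpus(rng)
            min_sup = float(rng.choice([0.2, 0.3, 0.5]))
            txs = make_set_transactions(sets)
            freq = frequent_patterns(txs, SET_MODE, min_sup, max_len=10)
            assert freq == pytest.approx(oracle_set_frequent(sets, min_sup))
            got = {
                (r.antecedent, r.consequent): (r.support, r.confidence)
                for r in mine_rules(txs, SET_MODE, min_sup, max_len=10)
            }
            assert got == pytest.approx(oracle_set_rules(sets, min_sup))


class TestMineSequence:
    def test_matches_exhaustive_enumeration_up_to_four_items(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            corpus = random_seq_corpus(rng)
            min_sup = float(rng.choice([0.3, 0.5]))
            txs = make_seq_transactions(corpus)
            mined = frequent_patterns(txs, SEQUENCE_MODE, min_sup, max_len=4)
            mined4 = {
                p: s for p, s in mined.items() if sum(len(b) for b in p) <= 4
            }
            oracle = oracle_seq_frequent(
                [t.groups for t in txs], min_sup, max_items=4
            )
            assert mined4 == pytest.approx(oracle)

    def test_rules_are_prefix_suffix_splits_with_exact_measures(self):
        txs = make_seq_transactions(
            [[["a"], ["b"], ["c"]], [["a"], ["b"]], [["a"], ["c"]]]
        )
        rules = mine_rules(txs, SEQUENCE_MODE, 0.6)
        got = {(r.antecedent, r.consequent): (r.support, r.confidence) for r in rules}
        # same toy as the set corpus, but order-aware
        assert got[((("a",),), (("b",),))] == (pytest.approx(2 / 3), pytest.approx(2 / 3))
        assert ((("b",),), (("a",),)) not in got  # b never precedes a

    def test_reports_differ_between_bag_sizes(self):
        # the same structures serialised with different bag sizes yield
        # different rule sets (order/grouping restrictions bind)
        from zonerule.synthcorpus import default_spec, generate

        spec = default_spec(seed=3)
        spec.sentences_per_type = 30
        spec.max_length = 12
        corpus = [normalise(s) for s in generate(spec)][:30]
        counts = {}
        for strat in ("bag1", "bag2"):
            sers = [serialise(s, strat) for s in corpus]
            counts[strat] = len(mine_rules(sers, SEQUENCE_MODE, 0.3, max_len=3))
        assert counts["bag1"] != counts["bag2"]


class TestMiningProperties:
    def test_anti_monotonicity_both_modes(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            sets = random_set_corpus(rng)
            txs = make_set_transactions(sets)
            freq = frequent_patterns(txs, SET_MODE, 0.2, max_len=10)
            for itemset, sup in freq.items():
                for sub_len in range(1, len(itemset)):
                    for sub in combinations(itemset, sub_len):
                        assert freq[sub] >= sup - 1e-12
        for _ in range(20):
            corpus = random_seq_corpus(rng)
            txs = make_seq_transactions(corpus)
            freq = frequent_patterns(txs, SEQUENCE_MODE, 0.3, max_len=4)
            for pattern, sup in freq.items():
                # dropping any whole bag gives a sub-pattern
                for i in range(len(pattern)):
                    sub = pattern[:i] + pattern[i + 1 :]
                    if sub:
                        assert freq.get(sub, 1.0) >= sup - 1e-12

    def test_sequence_support_bounded_by_set_support(self, tradd_merged):
        rng = np.random.default_rng(13)
        bag1 = serialise(tradd_merged, BAG1)
        set_ser = serialise(tradd_merged, SET)
        labels = list(set_ser.label_set())
        for _ in range(50):
            k = rng.integers(1, 4)
            pat_labels = list(rng.choice(labels, size=k, replace=False))
            seq_pattern = [(l,) for l in pat_labels]
            seq_sup = support([tuple(b) for b in seq_pattern], [bag1], SEQUENCE_MODE)
            set_sup = support([tuple(pat_labels)], [set_ser], SET_MODE)
            assert seq_sup <= set_sup + 1e-12

    def test_deterministic_output(self, toy_set_transactions):
        a = mine_rules(toy_set_transactions, SET_MODE, 0.3)
        b = mine_rules(toy_set_transactions, SET_MODE, 0.3)
        assert a == b

    def test_mixed_strategies_raise(self, tradd_merged):
        sers = [serialise(tradd_merged, SET), serialise(tradd_merged, BAG1)]
        with pytest.raises(ValueError):
            mine_rules(sers, SET_MODE, 0.5)


def test_mine_per_type_partitions(tradd_merged):
    a = Transaction(serialise(tradd_merged, SET), "BAC")
    b = Transaction(serialise(tradd_merged, SET), "RES")
    out = mine_per_type([a, b, a], min_support=0.5)
    assert set(out) == {"BAC", "RES"}
    assert all(r.type_label == "BAC" for r in out["BAC"])
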