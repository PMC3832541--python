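"""Association-rule mining over serialised dependency structures.

Transactions are sentences (one serialisation each).  Two pattern
semantics are supported:

``set`` mode
    classical Apriori over the sentence's label set: a pattern is a label
    set, and it occurs in a transaction when every label is present.
    Rules are formed from every antecedent/consequent bipartition of each
    frequent itemset.

``sequence`` mode
    level-wise (GSP-style) growth of *bag sequences*: a pattern is an
    ordered list of label bags; it occurs in a transaction when its bags
    map injectively onto transaction groups at strictly increasing
    positions, each bag contained (as a multiset) in its matched group.
    Rules are every split of a frequent pattern into a non-empty bag
    prefix (antecedent) and suffix (consequent).

Support is the fraction of transactions in which the joint pattern occurs;
confidence is joint support over antecedent support.  Antecedent and
consequent are disjoint as flattened label multisets.  Each emitted rule
also carries the Kulczynski measure and the imbalance ratio (see
:mod:`zonerule.ruleselect`), computed exactly from the frequent-pattern
supports.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Sequence

from zonerule.serialise import SET, Serialisation

SET_MODE = "set"
SEQUENCE_MODE = "sequence"

Bags = tuple[tuple[str, ...], ...]


@dataclass(frozen=True, slots=True)
class Transaction:
    """One sentence's serialisation tagged with its rhetorical type."""

    serialisation: Serialisation
    type_label: str


@dataclass(frozen=True, slots=True)
class AssociationRule:
    """antecedent => consequent, with its interestingness measures.

    Both sides are ordered lists of label bags; set-origin rules have a
    single order-free bag on each side.  Canonical form: labels inside a
    bag are sorted; bag order is preserved for sequence rules.
    """

    antecedent: Bags
    consequent: Bags
    support: float
    confidence: float
    strategy: str
    type_label: str = ""
    kulc: float | None = None
    ir: float | None = None

    def __post_init__(self) -> None:
        if not self.antecedent or not self.consequent:
            raise ValueError("antecedent and consequent must be non-empty")
        a = Counter(l for b in self.antecedent for l in b)
        c = Counter(l for b in self.consequent for l in b)
        if a & c:
            raise ValueError("antecedent and consequent must be disjoint")

    @property
    def key(self) -> tuple[Bags, Bags]:
        """Identity for overlap analysis: both sides, measures ignored."""
        return (self.antecedent, self.consequent)

    @property
    def flat_labels(self) -> frozenset[str]:
        return frozenset(
            l for side in (self.antecedent, self.consequent) for b in side for l in b
        )


def canonical_bag(labels: Iterable[str]) -> tuple[str, ...]:
    return tuple(sorted(labels))


def canonical_pattern(bags: Iterable[Iterable[str]]) -> Bags:
    return tuple(canonical_bag(b) for b in bags)


# --------------------------------------------------------------------------
# Pattern occurrence and support


def _groups_of(t) -> Bags:
    if isinstance(t, Transaction):
        return t.serialisation.groups
    if isinstance(t, Serialisation):
        return t.groups
    return tuple(tuple(g) for g in t)


def _bag_contained(bag: Counter, group: Counter) -> bool:
    return all(group.get(l, 0) >= n for l, n in bag.items())


def occurs(pattern: Sequence[Iterable[str]], t, mode: str) -> bool:
    """Does the pattern occur in the transaction?

    Set mode: every pattern label is a member of the transaction's label
    set.  Sequence mode: greedy left-to-right injective matching of the
    pattern's bags onto transaction groups at strictly increasing
    positions, each bag multiset-contained in its matched group (greedy
    leftmost matching is complete for existence).
    """
    if not pattern:
        raise ValueError("pattern must be non-empty")
    groups = _groups_of(t)
    if mode == SET_MODE:
        labels = {l for g in groups for l in g}
        return all(l in labels for b in pattern for l in b)
    if mode == SEQUENCE_MODE:
        counters = [Counter(g) for g in groups]
        cursor = 0
        for bag in pattern:
            bc = Counter(bag)
            for j in range(cursor, len(counters)):
                if _bag_contained(bc, counters[j]):
                    cursor = j + 1
                    break
            else:
                return False
        return True
    raise ValueError(f"unknown mode {mode!r}")


def support(pattern: Sequence[Iterable[str]], transactions: Sequence, mode: str) -> float:
    """Fraction of transactions in which the pattern occurs."""
    if not transactions:
        raise ValueError("transaction list must be non-empty")
    hits = sum(occurs(pattern, t, mode) for t in transactions)
    return hits / len(transactions)


def joint_pattern(rule: AssociationRule) -> Bags:
    """Antecedent (+) consequent: set union for set rules, bag concatenation otherwise."""
    if rule.strategy == SET:
        labels = [l for b in rule.antecedent for l in b] + [
            l for b in rule.consequent for l in b
        ]
        return (canonical_bag(set(labels)),)
    return rule.antecedent + rule.consequent


def confidence(rule: AssociationRule, transactions: Sequence) -> float:
    """Joint support over antecedent support."""
    mode = SET_MODE if rule.strategy == SET else SEQUENCE_MODE
    sup_a = support(rule.antecedent, transactions, mode)
    if sup_a == 0:
        raise ZeroDivisionError("antecedent has zero support; confidence undefined")
    return support(joint_pattern(rule), transactions, mode) / sup_a


# --------------------------------------------------------------------------
# Set-mode Apriori

Itemset = tuple[str, ...]


def _apriori_itemsets(
    label_sets: list[frozenset[str]], min_support: float, max_len: int
) -> dict[Itemset, int]:
    """All frequent itemsets with their absolute counts.

    Candidate counting uses per-label transaction bitmasks; the mask of an
    itemset is the AND of its labels' masks, reused incrementally.
    """
    n = len(label_sets)
    # tolerance so a support exactly at the threshold is kept
    min_count = min_support * n - 1e-9
    masks: dict[str, int] = {}
    for i, s in enumerate(label_sets):
        bit = 1 << i
        for lab in s:
            masks[lab] = masks.get(lab, 0) | bit

    frequent: dict[Itemset, int] = {}
    level_masks: dict[Itemset, int] = {}
    for lab, m in masks.items():
        c = m.bit_count()
        if c >= min_count:
            frequent[(lab,)] = c
            level_masks[(lab,)] = m

    k = 1
    while level_masks and k < max_len:
        prev = sorted(level_masks)
        next_masks: dict[Itemset, int] = {}
        # classic join: two frequent k-itemsets sharing a (k-1)-prefix
        for i, a in enumerate(prev):
            for b in prev[i + 1 :]:
                if a[:-1] != b[:-1]:
                    break
                cand = a + (b[-1],)
                # prune: every (k)-subset must be frequent
                if any(
                    cand[:j] + cand[j + 1 :] not in level_masks for j in range(len(cand))
                ):
                    continue
                m = level_masks[a] & masks[b[-1]]
                c = m.bit_count()
                if c >= min_count:
                    next_masks[cand] = m
        frequent.update({cand: m.bit_count() for cand, m in next_masks.items()})
        level_masks = next_masks
        k += 1
    return frequent


def _measures(sup_a: float, sup_b: float, sup_ab: float) -> tuple[float, float]:
    kulc = 0.5 * sup_ab * (1.0 / sup_a + 1.0 / sup_b)
    denom = sup_a + sup_b - sup_ab
    ir = abs(sup_a - sup_b) / denom
    return kulc, ir


def _set_rules(
    frequent: Mapping[Itemset, int], n: int, strategy: str, type_label: str
) -> list[AssociationRule]:
    rules = []
    for itemset, count in frequent.items():
        if len(itemset) < 2:
            continue
        sup_ab = count / n
        for r in range(1, len(itemset)):
            for ante in combinations(itemset, r):
                cons = tuple(l for l in itemset if l not in ante)
                sup_a = frequent[ante] / n
                sup_b = frequent[cons] / n
                kulc, ir = _measures(sup_a, sup_b, sup_ab)
                rules.append(
                    AssociationRule(
                        antecedent=(ante,),
                        consequent=(cons,),
                        support=sup_ab,
                        confidence=sup_ab / sup_a,
                        strategy=strategy,
                        type_label=type_label,
                        kulc=kulc,
                        ir=ir,
                    )
                )
    return rules


# --------------------------------------------------------------------------
# Sequence-mode GSP-style mining


def _sequence_patterns(
    transactions: list[Bags], min_support: float, max_len: int
) -> dict[Bags, int]:
    """All frequent bag-sequence patterns (canonical form) with counts.

    Growth is complete for the canonical form: a frequent pattern is
    reachable from the frequent pattern obtained by deleting the
    lexicographically-last label of its last bag (or the last bag when it
    is a singleton), extending either inside the last bag or with a new
    trailing bag.  ``max_len`` caps the number of bags.
    """
    n = len(transactions)
    min_count = min_support * n - 1e-9

    def count(pattern: Bags) -> int:
        return sum(occurs(pattern, t, SEQUENCE_MODE) for t in transactions)

    label_counts: Counter = Counter()
    for t in transactions:
        for lab in {l for g in t for l in g}:
            label_counts[lab] += 1
    freq_labels = sorted(l for l, c in label_counts.items() if c >= min_count)

    frequent: dict[Bags, int] = {}
    level: list[Bags] = []
    for lab in freq_labels:
        p: Bags = ((lab,),)
        c = label_counts[lab]
        if c >= min_count:
            frequent[p] = c
            level.append(p)

    while level:
        candidates: set[Bags] = set()
        for p in level:
            for lab in freq_labels:
                # grow inside the last bag
                grown = p[:-1] + (canonical_bag(p[-1] + (lab,)),)
                candidates.add(grown)
                # or open a new trailing bag
                if len(p) < max_len:
                    candidates.add(p + ((lab,),))
        next_level = []
        for cand in candidates:
            if cand in frequent:
                continue
            c = count(cand)
            if c >= min_count:
                frequent[cand] = c
                next_level.append(cand)
        level = next_level
    return frequent


def _sequence_rules(
    frequent: Mapping[Bags, int], n: int, strategy: str, type_label: str
) -> list[AssociationRule]:
    rules = []
    for pattern, count in frequent.items():
        if len(pattern) < 2:
            continue
        sup_ab = count / n
        for split in range(1, len(pattern)):
            ante, cons = pattern[:split], pattern[split:]
            a = Counter(l for b in ante for l in b)
            c = Counter(l for b in cons for l in b)
            if a & c:  # flattened multisets must be disjoint
                continue
            sup_a = frequent[ante] / n
            sup_b = frequent[cons] / n
            kulc, ir = _measures(sup_a, sup_b, sup_ab)
            rules.append(
                AssociationRule(
                    antecedent=ante,
                    consequent=cons,
                    support=sup_ab,
                    confidence=sup_ab / sup_a,
                    strategy=strategy,
                    type_label=type_label,
                    kulc=kulc,
                    ir=ir,
                )
            )
    return rules


# --------------------------------------------------------------------------
# Entry points


def frequent_patterns(
    serialisations: Sequence[Serialisation],
    mode: str,
    min_support: float,
    max_len: int = 6,
) -> dict:
    """Frequent patterns with relative supports.

    Set mode returns ``{itemset tuple: support}``; sequence mode returns
    ``{bag sequence: support}`` in canonical form.
    """
    if not serialisations:
        raise ValueError("no transactions to mine")
    n = len(serialisations)
    if mode == SET_MODE:
        label_sets = [frozenset(s.label_set()) for s in serialisations]
        return {
            k: c / n for k, c in _apriori_itemsets(label_sets, min_support, max_len).items()
        }
    if mode == SEQUENCE_MODE:
        groups = [s.groups for s in serialisations]
        return {
            k: c / n for k, c in _sequence_patterns(groups, min_support, max_len).items()
        }
    raise ValueError(f"unknown mode {mode!r}")


def mine_rules(
    serialisations: Sequence[Serialisation],
    mode: str,
    min_support: float,
    max_len: int = 6,
    type_label: str = "",
) -> list[AssociationRule]:
    """Mine all rules above ``min_support`` from one type's transactions.

    ``max_len`` bounds the itemset size (set mode) / number of bags
    (sequence mode); it is a tractability guard, not part of the pattern
    semantics.  Output is deterministic: rules are sorted by canonical
    form.
    """
    if not 0 < min_support <= 1:
        raise ValueError(f"min_support must be in (0, 1], got {min_support}")
    if not serialisations:
        raise ValueError("no transactions to mine")
    strategies = {s.strategy for s in serialisations}
    if len(strategies) > 1:
        raise ValueError(f"mixed serialisation strategies: {sorted(strategies)}")
    strategy = strategies.pop()
    n = len(serialisations)
    if mode == SET_MODE:
        label_sets = [frozenset(s.label_set()) for s in serialisations]
        frequent = _apriori_itemsets(label_sets, min_support, max_len)
        rules = _set_rules(frequent, n, strategy, type_label)
    elif mode == SEQUENCE_MODE:
        groups = [s.groups for s in serialisations]
        frequent = _sequence_patterns(groups, min_support, max_len)
        rules = _sequence_rules(frequent, n, strategy, type_label)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    rules.sort(key=lambda r: (r.antecedent, r.consequent))
    return rules


def mode_for_strategy(strategy: str) -> str:
    return SET_MODE if strategy == SET else SEQUENCE_MODE


def mine_per_type(
    transactions: Sequence[Transaction],
    min_support: float = 0.05,
    max_len: int = 6,
) -> dict[str, list[AssociationRule]]:
    """Partition transactions by rhetorical type and mine each independently."""
    by_type: dict[str, list[Serialisation]] = {}
    for t in transactions:
        by_type.setdefault(t.type_label, []).append(t.serialisation)
    return {
        lab: mine_rules(
            sers,
            mode_for_strategy(sers[0].strategy),
            min_support,
            max_len=max_len,
            type_label=lab,
        )
        for lab, sers in sorted(by_type.items())
    }
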