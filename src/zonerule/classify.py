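"""Sentence scoring against per-type rule sets.

A sentence is scored against a rhetorical type by aggregating, over that
type's ranked rules, a combination of each rule's *cover* of the sentence
and a per-rule weight:

    score(s, R) = f_{r in R}( g(w_r, cover(r, s)) )

where ``w`` is 1, support, confidence or Kulc; ``g`` is multiplication,
arithmetic mean or harmonic mean; and ``f`` is the mean, the max, or the
mean of values within one standard deviation of the mean.  All 4 x 3 x 3 =
36 combinations map [0,1] inputs to a score in [0,1].

The rule cover adapts the Jaccard idea to the antecedent/consequent
structure: it is the average of the matched fractions of the two sides.
Set-origin rules match by membership; sequence-origin rules are matched
order-aware with prefix semantics — items are consumed left-to-right
against the group sequence and the first item that cannot be matched at or
after the cursor terminates matching for that side.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np

from zonerule.rulemine import AssociationRule, Bags
from zonerule.ruleselect import RankedRuleSet
from zonerule.serialise import SET, Serialisation

W_ONE = "one"
W_SUPPORT = "support"
W_CONFIDENCE = "confidence"
W_KULC = "kulc"
W_OPTIONS = (W_ONE, W_SUPPORT, W_CONFIDENCE, W_KULC)

G_MULT = "mult"
G_AMEAN = "amean"
G_HMEAN = "hmean"
G_OPTIONS = (G_MULT, G_AMEAN, G_HMEAN)

F_MEAN = "mean"
F_MAX = "max"
F_SDBAND = "sdband"
F_OPTIONS = (F_MEAN, F_MAX, F_SDBAND)


@dataclass(frozen=True, slots=True)
class ScoreConfig:
    """The (w, g, f) triple parameterising score aggregation."""

    w: str = W_CONFIDENCE
    g: str = G_AMEAN
    f: str = F_MEAN

    def __post_init__(self) -> None:
        if self.w not in W_OPTIONS:
            raise ValueError(f"w must be one of {W_OPTIONS}, got {self.w!r}")
        if self.g not in G_OPTIONS:
            raise ValueError(f"g must be one of {G_OPTIONS}, got {self.g!r}")
        if self.f not in F_OPTIONS:
            raise ValueError(f"f must be one of {F_OPTIONS}, got {self.f!r}")


@dataclass(slots=True)
class TypeRanking:
    """Per-type scores for one sentence, plus the induced type ranking."""

    sentence_id: str
    scores: dict[str, float]
    ranked_types: list[str]

    def top(self, k: int) -> list[str]:
        return self.ranked_types[:k]


# --------------------------------------------------------------------------
# Rule cover


def _seq_matched(bags: Bags, groups: Bags) -> int:
    """Items consumed by prefix-terminating order-aware matching.

    Each rule bag must be wholly contained (as a multiset) in a group at
    or after the cursor.  When no such group exists, the best partial
    containment at or after the cursor contributes its labels and
    matching terminates.
    """
    counters = [Counter(g) for g in groups]
    cursor = 0
    matched = 0
    for bag in bags:
        bc = Counter(bag)
        hit = None
        for j in range(cursor, len(counters)):
            if all(counters[j].get(l, 0) >= n for l, n in bc.items()):
                hit = j
                break
        if hit is None:
            best = 0
            for j in range(cursor, len(counters)):
                inter = sum((bc & counters[j]).values())
                if inter > best:
                    best = inter
            return matched + best
        matched += len(bag)
        cursor = hit + 1
    return matched


def rule_cover(rule: AssociationRule, s: Serialisation) -> float:
    """Average of the matched fractions of antecedent and consequent.

    Set-origin rules count label membership in the sentence's label set
    and may score any serialisation.  Sequence-origin rules require a
    sequence serialisation; each side starts its own cursor at the
    beginning of the group sequence.
    """
    if not rule.antecedent or not rule.consequent:
        raise ValueError("rule must have non-empty antecedent and consequent")
    len_a = sum(len(b) for b in rule.antecedent)
    len_b = sum(len(b) for b in rule.consequent)
    if rule.strategy == SET:
        labels = s.label_set()
        m_a = sum(l in labels for b in rule.antecedent for l in b)
        m_b = sum(l in labels for b in rule.consequent for l in b)
    else:
        if s.strategy == SET:
            raise ValueError("sequence-origin rules require a sequence serialisation")
        m_a = _seq_matched(rule.antecedent, s.groups)
        m_b = _seq_matched(rule.consequent, s.groups)
    return 0.5 * (m_a / len_a + m_b / len_b)


# --------------------------------------------------------------------------
# Score aggregation


def _weight(rule: AssociationRule, w: str) -> float:
    if w == W_ONE:
        return 1.0
    if w == W_SUPPORT:
        return rule.support
    if w == W_CONFIDENCE:
        return rule.confidence
    if rule.kulc is None:
        raise ValueError("rule lacks a Kulc value for w=kulc")
    return rule.kulc


def _combine(w: float, c: float, g: str) -> float:
    if g == G_MULT:
        return w * c
    if g == G_AMEAN:
        return 0.5 * (w + c)
    return 2.0 * w * c / (w + c) if (w + c) > 0 else 0.0


def _aggregate(values: list[float], f: str) -> float:
    if f == F_MAX:
        return max(values)
    mean = sum(values) / len(values)
    if f == F_MEAN:
        return mean
    sd = float(np.std(values))  # population SD
    band = [v for v in values if abs(v - mean) <= sd + 1e-12]
    return sum(band) / len(band)


def type_score(s: Serialisation, rs: RankedRuleSet, cfg: ScoreConfig) -> float:
    """Aggregate the rule set's weighted covers into one score in [0, 1].

    An empty rule set scores 0: a type with no surviving rules cannot
    claim a sentence.
    """
    if not rs.rules:
        return 0.0
    values = [
        _combine(_weight(r, cfg.w), rule_cover(r, s), cfg.g) for r in rs.rules
    ]
    return _aggregate(values, cfg.f)


def classify_top_k(
    s: Serialisation,
    rulesets: dict[str, RankedRuleSet],
    cfg: ScoreConfig,
    k: int = 1,
) -> TypeRanking:
    """Score every type and rank them; the top-k slice is the prediction set.

    Ties break lexicographically by type label for determinism.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if not rulesets:
        raise ValueError("empty ruleset mapping")
    scores = {lab: type_score(s, rs, cfg) for lab, rs in rulesets.items()}
    ranked = sorted(scores, key=lambda lab: (-scores[lab], lab))
    return TypeRanking(sentence_id=s.sentence_id, scores=scores, ranked_types=ranked)


# --------------------------------------------------------------------------
# Vectorised scorer for set-origin rule sets (used by the evaluator on
# larger corpora; numerically identical to type_score / rule_cover)


class SetRuleScorer:
    """Score many sentences against one set-origin rule set at once.

    Each rule side becomes a 0/1 row over the label vocabulary; matched
    counts for a batch of sentences are two matrix products, after which
    the (w, g, f) aggregation is applied columnwise.
    """

    def __init__(self, rs: RankedRuleSet, cfg: ScoreConfig):
        if any(r.strategy != SET for r in rs.rules):
            raise ValueError("SetRuleScorer handles set-origin rules only")
        self.cfg = cfg
        self.empty = not rs.rules
        if self.empty:
            return
        vocab = sorted({l for r in rs.rules for l in r.flat_labels})
        self.vocab_index = {l: i for i, l in enumerate(vocab)}
        n_rules, n_lab = len(rs.rules), len(vocab)
        self.A = np.zeros((n_rules, n_lab), dtype=np.float32)
        self.B = np.zeros((n_rules, n_lab), dtype=np.float32)
        for i, r in enumerate(rs.rules):
            for b in r.antecedent:
                for l in b:
                    self.A[i, self.vocab_index[l]] = 1.0
            for b in r.consequent:
                for l in b:
                    self.B[i, self.vocab_index[l]] = 1.0
        self.len_a = self.A.sum(axis=1)
        self.len_b = self.B.sum(axis=1)
        self.w = np.array([_weight(r, cfg.w) for r in rs.rules], dtype=np.float64)

    def presence_matrix(self, sentences: list[Serialisation]) -> np.ndarray:
        P = np.zeros((len(sentences), len(self.vocab_index)), dtype=np.float32)
        for i, s in enumerate(sentences):
            for l in s.label_set():
                j = self.vocab_index.get(l)
                if j is not None:
                    P[i, j] = 1.0
        return P

    def scores(self, sentences: list[Serialisation]) -> np.ndarray:
        if self.empty:
            return np.zeros(len(sentences))
        P = self.presence_matrix(sentences)
        cover = 0.5 * (P @ self.A.T / self.len_a + P @ self.B.T / self.len_b)
        cover = cover.astype(np.float64)
        g = self.cfg.g
        if g == G_MULT:
            v = self.w * cover
        elif g == G_AMEAN:
            v = 0.5 * (self.w + cover)
        else:
            denom = self.w + cover
            with np.errstate(divide="ignore", invalid="ignore"):
                v = np.where(denom > 0, 2.0 * self.w * cover / denom, 0.0)
        f = self.cfg.f
        if f == F_MAX:
            return v.max(axis=1)
        mean = v.mean(axis=1)
        if f == F_MEAN:
            return mean
        sd = v.std(axis=1)
        mask = np.abs(v - mean[:, None]) <= sd[:, None] + 1e-12
        return (v * mask).sum(axis=1) / mask.sum(axis=1)
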