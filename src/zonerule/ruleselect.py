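"""Rule interestingness measures, ranking and filtering.

Mining at a 5% support floor still leaves enormous rule sets; the useful
patterns are isolated by ranking on an interestingness measure and keeping
a small top fraction.  Measures:

Kulczynski (Kulc)
    the average of the two directed confidences,
    ``0.5 * (conf(A=>B) + conf(B=>A))``.  Null-invariant: unaffected by
    transactions containing neither side.

Imbalance ratio (IR)
    ``|sup(A) - sup(B)| / (sup(A) + sup(B) - sup(AB))`` — 0 for perfectly
    balanced sides, approaching 1 for highly skewed ones.  Rules with IR
    in a mid band (default [0.40, 0.60]) are the "almost perfectly
    balanced" ones.

Five ranking mechanisms are available: plain support, plain confidence,
and three that first keep only the IR band and then rank by Kulc, by
confidence, or by the product confidence x Kulc ("mixed").  The kept
fraction is one of 1%, 5%, 10%, 15% by convention (any fraction works).
Optionally, rules touching near-ubiquitous labels (``det``, ``prep``) are
excluded first.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from zonerule.rulemine import (
    SEQUENCE_MODE,
    SET_MODE,
    AssociationRule,
    joint_pattern,
    support,
)
from zonerule.serialise import SET

log = logging.getLogger(__name__)

SUPPORT = "support"
CONFIDENCE = "confidence"
IR_KULC = "ir-kulc"
IR_CONFIDENCE = "ir-confidence"
IR_MIXED = "ir-mixed"
RANKINGS = (SUPPORT, CONFIDENCE, IR_KULC, IR_CONFIDENCE, IR_MIXED)

TOP_FRACTIONS = (0.01, 0.05, 0.10, 0.15)
DEFAULT_IR_BAND = (0.40, 0.60)
COMMON_LABELS = frozenset({"det", "prep"})


class UndefinedMeasure(ValueError):
    """A measure's precondition (positive / non-degenerate supports) fails."""


def _side_supports(rule: AssociationRule, transactions: Sequence) -> tuple[float, float, float]:
    mode = SET_MODE if rule.strategy == SET else SEQUENCE_MODE
    sup_a = support(rule.antecedent, transactions, mode)
    sup_b = support(rule.consequent, transactions, mode)
    sup_ab = support(joint_pattern(rule), transactions, mode)
    return sup_a, sup_b, sup_ab


def kulc(rule: AssociationRule, transactions: Sequence) -> float:
    """Kulczynski measure: 0.5 * sup(AB) * (1/sup(A) + 1/sup(B))."""
    sup_a, sup_b, sup_ab = _side_supports(rule, transactions)
    if sup_a == 0 or sup_b == 0:
        raise UndefinedMeasure("Kulc undefined: a rule side has zero support")
    return 0.5 * sup_ab * (1.0 / sup_a + 1.0 / sup_b)


def imbalance_ratio(rule: AssociationRule, transactions: Sequence) -> float:
    """IR: |sup(A) - sup(B)| / (sup(A) + sup(B) - sup(AB))."""
    sup_a, sup_b, sup_ab = _side_supports(rule, transactions)
    denom = sup_a + sup_b - sup_ab
    if denom <= 0:
        raise UndefinedMeasure("IR undefined: degenerate denominator")
    return abs(sup_a - sup_b) / denom


def annotate_measures(
    rules: Iterable[AssociationRule], transactions: Sequence
) -> list[AssociationRule]:
    """Fill kulc/ir on rules that lack them (mined rules already carry both)."""
    out = []
    for r in rules:
        if r.kulc is None or r.ir is None:
            out.append(
                AssociationRule(
                    r.antecedent,
                    r.consequent,
                    r.support,
                    r.confidence,
                    r.strategy,
                    r.type_label,
                    kulc=kulc(r, transactions),
                    ir=imbalance_ratio(r, transactions),
                )
            )
        else:
            out.append(r)
    return out


@dataclass(slots=True)
class RankedRuleSet:
    """The ranked, truncated rule collection acting as one type's classifier."""

    type_label: str
    strategy: str
    ranking: str
    top_fraction: float
    rules: list[AssociationRule] = field(default_factory=list)
    exclude_common: bool = False

    def __len__(self) -> int:
        return len(self.rules)

    def keys(self) -> set:
        return {r.key for r in self.rules}


def _canonical_str(rule: AssociationRule) -> str:
    fmt = lambda side: "|".join("+".join(b) for b in side)
    return fmt(rule.antecedent) + "=>" + fmt(rule.consequent)


def _measure_value(rule: AssociationRule, ranking: str, mixed_key: str) -> float:
    if ranking == SUPPORT:
        return rule.support
    if ranking == CONFIDENCE:
        return rule.confidence
    if rule.kulc is None or rule.ir is None:
        raise UndefinedMeasure("rule lacks kulc/ir; call annotate_measures first")
    if ranking == IR_KULC:
        return rule.kulc
    if ranking == IR_CONFIDENCE:
        return rule.confidence
    if ranking == IR_MIXED:
        if mixed_key == "confidence":
            return rule.confidence
        if mixed_key == "kulc":
            return rule.kulc
        return rule.confidence * rule.kulc
    raise ValueError(f"unknown ranking {ranking!r}; expected one of {RANKINGS}")


def rank_and_filter(
    rules: Sequence[AssociationRule],
    ranking: str,
    top_fraction: float,
    ir_band: tuple[float, float] = DEFAULT_IR_BAND,
    mixed_key: str = "product",
    type_label: str | None = None,
    strategy: str | None = None,
    exclude_common_flag: bool = False,
) -> RankedRuleSet:
    """Rank rules by one mechanism and keep the top fraction.

    IR-based rankings first drop rules with IR outside the closed band.
    Ties break by higher support, then by canonical form, so output is
    deterministic.  ``ceil`` truncation never empties a non-empty set.
    """
    if not 0 < top_fraction <= 1:
        raise ValueError(f"top_fraction must be in (0, 1], got {top_fraction}")
    pool = list(rules)
    if ranking in (IR_KULC, IR_CONFIDENCE, IR_MIXED):
        lo, hi = ir_band
        pool = [r for r in pool if r.ir is not None and lo <= r.ir <= hi]
    pool.sort(
        key=lambda r: (
            -_measure_value(r, ranking, mixed_key),
            -r.support,
            _canonical_str(r),
        )
    )
    if not pool:
        log.warning("rank_and_filter: empty rule set after filtering (%s)", ranking)
    keep = pool[: math.ceil(top_fraction * len(pool))]
    return RankedRuleSet(
        type_label=type_label or (keep[0].type_label if keep else ""),
        strategy=strategy or (keep[0].strategy if keep else ""),
        ranking=ranking,
        top_fraction=top_fraction,
        rules=keep,
        exclude_common=exclude_common_flag,
    )


def exclude_common(
    rules: Iterable[AssociationRule], labels: frozenset[str] = COMMON_LABELS
) -> list[AssociationRule]:
    """Drop every rule whose antecedent or consequent touches an excluded label."""
    return [r for r in rules if not (r.flat_labels & labels)]


# --------------------------------------------------------------------------
# Rule TSV (bags as ``a+b|c``: `|` separates bags, `+` in-bag labels)

_COLUMNS = (
    "type_label",
    "strategy",
    "antecedent",
    "consequent",
    "support",
    "confidence",
    "kulc",
    "ir",
)


def _fmt_side(side) -> str:
    return "|".join("+".join(b) for b in side)


def _parse_side(text: str):
    return tuple(tuple(b.split("+")) for b in text.split("|"))


def write_rules_tsv(rules: Iterable[AssociationRule], path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(_COLUMNS)
        for r in rules:
            w.writerow(
                [
                    r.type_label,
                    r.strategy,
                    _fmt_side(r.antecedent),
                    _fmt_side(r.consequent),
                    f"{r.support:.10g}",
                    f"{r.confidence:.10g}",
                    "" if r.kulc is None else f"{r.kulc:.10g}",
                    "" if r.ir is None else f"{r.ir:.10g}",
                ]
            )


def read_rules_tsv(path: str | Path) -> list[AssociationRule]:
    out = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            out.append(
                AssociationRule(
                    antecedent=_parse_side(row["antecedent"]),
                    consequent=_parse_side(row["consequent"]),
                    support=float(row["support"]),
                    confidence=float(row["confidence"]),
                    strategy=row["strategy"],
                    type_label=row["type_label"],
                    kulc=float(row["kulc"]) if row["kulc"] else None,
                    ir=float(row["ir"]) if row["ir"] else None,
                )
            )
    return out
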