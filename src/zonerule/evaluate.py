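"""Evaluation: cross-validated classification, pairwise discrimination,
rule-set overlap analytics, and the cross-corpus threshold procedure.

Classification quality is reported as macro precision / recall / F1 under
stratified k-fold cross-validation (nine folds by convention) with top-K
prediction sets: a test sentence contributes a true positive to its true
type when that type appears in the K highest-scoring types, and a false
positive to every other type in the set.

Rule-set comparisons are uni-directional (rule sets rarely share size or
content): overlap(X -> Y) is the fraction of X's rules, identified by
their canonical antecedent/consequent, that also appear in Y.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from zonerule.classify import ScoreConfig, SetRuleScorer, classify_top_k, type_score
from zonerule.depstruct import DependencyStructure, normalise
from zonerule.rulemine import mine_rules, mode_for_strategy
from zonerule.ruleselect import (
    CONFIDENCE,
    COMMON_LABELS,
    DEFAULT_IR_BAND,
    RankedRuleSet,
    exclude_common,
    rank_and_filter,
)
from zonerule.serialise import SET, Serialisation, serialise

log = logging.getLogger(__name__)


@dataclass(slots=True)
class PipelineConfig:
    """Everything between a labelled corpus and a per-type classifier."""

    strategy: str = SET
    min_support: float = 0.05
    max_len: int = 6
    ranking: str = CONFIDENCE
    top_fraction: float = 0.01
    exclude: bool = False
    exclude_labels: frozenset[str] = COMMON_LABELS
    ir_band: tuple[float, float] = DEFAULT_IR_BAND
    mixed_key: str = "product"
    score: ScoreConfig = field(default_factory=ScoreConfig)


@dataclass(slots=True)
class MacroMetrics:
    """Per-type precision/recall/F1 plus their macro averages."""

    per_type: dict[str, tuple[float, float, float]]
    macro_precision: float
    macro_recall: float
    macro_f1: float
    k: int


@dataclass(frozen=True, slots=True)
class OverlapReport:
    source: str
    target: str
    overlap: float

    @property
    def direction(self) -> str:
        return f"{self.source}->{self.target}"


# --------------------------------------------------------------------------
# Pipeline pieces


def serialise_corpus(
    structures: Sequence[DependencyStructure], strategy: str
) -> list[tuple[Serialisation, str | None]]:
    """Normalise (prep/conj merged) and serialise every sentence."""
    out = []
    for s in structures:
        ns = normalise(s, merge_prep_conj=True)
        out.append((serialise(ns, strategy), s.label))
    return out


def build_rulesets(
    structures: Sequence[DependencyStructure], cfg: PipelineConfig
) -> dict[str, RankedRuleSet]:
    """Mine, optionally exclude common labels, and rank — one set per type."""
    by_type: dict[str, list[Serialisation]] = {}
    for ser, lab in serialise_corpus(structures, cfg.strategy):
        if lab is None:
            raise ValueError(f"unlabelled sentence {ser.sentence_id} in training data")
        by_type.setdefault(lab, []).append(ser)
    mode = mode_for_strategy(cfg.strategy)
    rulesets = {}
    for lab in sorted(by_type):
        rules = mine_rules(
            by_type[lab], mode, cfg.min_support, max_len=cfg.max_len, type_label=lab
        )
        if cfg.exclude:
            rules = exclude_common(rules, cfg.exclude_labels)
        rulesets[lab] = rank_and_filter(
            rules,
            cfg.ranking,
            cfg.top_fraction,
            ir_band=cfg.ir_band,
            mixed_key=cfg.mixed_key,
            type_label=lab,
            strategy=cfg.strategy,
            exclude_common_flag=cfg.exclude,
        )
    return rulesets


def score_matrix(
    sentences: Sequence[Serialisation],
    rulesets: Mapping[str, RankedRuleSet],
    cfg: ScoreConfig,
) -> pd.DataFrame:
    """Scores of every sentence (rows) against every type's rule set (columns).

    Set-origin rule sets go through the vectorised scorer; sequence-origin
    sets use the reference per-rule path.
    """
    sentences = list(sentences)
    data = {}
    for lab in sorted(rulesets):
        rs = rulesets[lab]
        if rs.rules and all(r.strategy == SET for r in rs.rules):
            data[lab] = SetRuleScorer(rs, cfg).scores(list(sentences))
        else:
            data[lab] = np.array([type_score(s, rs, cfg) for s in sentences])
    return pd.DataFrame(data, index=[s.sentence_id for s in sentences])


def _topk_from_scores(scores: pd.DataFrame, k: int) -> list[list[str]]:
    cols = list(scores.columns)
    out = []
    for _, row in scores.iterrows():
        ranked = sorted(cols, key=lambda c: (-row[c], c))
        out.append(ranked[:k])
    return out


def topk_metrics(
    records: Sequence[tuple[str, Sequence[str]]], types: Sequence[str], k: int
) -> MacroMetrics:
    """Macro metrics from (true_label, top-k prediction set) records.

    TP for the true type when it is in the set; FP for every other type in
    the set; FN for the true type otherwise.  Precision/recall are 0 when
    their denominator is 0, and F1 is the harmonic mean (0 when p+r=0).
    """
    tp = {t: 0 for t in types}
    fp = {t: 0 for t in types}
    fn = {t: 0 for t in types}
    for true, topk in records:
        pred = list(topk)[:k]
        if true in pred:
            tp[true] += 1
        else:
            fn[true] += 1
        for t in pred:
            if t != true:
                fp[t] += 1
    per_type = {}
    for t in types:
        p = tp[t] / (tp[t] + fp[t]) if tp[t] + fp[t] else 0.0
        r = tp[t] / (tp[t] + fn[t]) if tp[t] + fn[t] else 0.0
        f1 = 2 * p * r / (p + r) if p + r else 0.0
        per_type[t] = (p, r, f1)
    n = len(types)
    return MacroMetrics(
        per_type=per_type,
        macro_precision=sum(v[0] for v in per_type.values()) / n,
        macro_recall=sum(v[1] for v in per_type.values()) / n,
        macro_f1=sum(v[2] for v in per_type.values()) / n,
        k=k,
    )


# --------------------------------------------------------------------------
# Cross-validation


def stratified_folds(
    structures: Sequence[DependencyStructure], folds: int, seed: int
) -> list[int]:
    """Fold index per sentence: per-type proportional, keyed on sentence id.

    Sentences are sorted by id within each type before the seeded shuffle,
    so the assignment is invariant to corpus order.
    """
    by_type: dict[str, list[int]] = {}
    for i, s in enumerate(structures):
        by_type.setdefault(s.label or "", []).append(i)
    assign = [0] * len(structures)
    rng = np.random.default_rng(seed)
    for lab in sorted(by_type):
        idx = sorted(by_type[lab], key=lambda i: structures[i].sentence_id)
        if len(idx) < folds:
            raise ValueError(
                f"type {lab!r} has {len(idx)} sentences, fewer than {folds} folds"
            )
        order = rng.permutation(len(idx))
        for pos, j in enumerate(order):
            assign[idx[j]] = pos % folds
    return assign


def cross_validate_grid(
    structures: Sequence[DependencyStructure],
    cfg: PipelineConfig,
    folds: int = 9,
    ks: Sequence[int] = (1,),
    top_fractions: Sequence[float] | None = None,
    seed: int = 0,
) -> dict[tuple[float, int], MacroMetrics]:
    """Cross-validate over a grid of top fractions and rank depths.

    Each fold's training split is mined once per type; ranking at each
    top fraction is a pure truncation of the same rule list, so results
    are identical to independent runs while folds x fractions share the
    mining cost.  Returns metrics keyed by (top_fraction, k); per-type
    metrics are averaged over folds.
    """
    fractions = list(top_fractions) if top_fractions is not None else [cfg.top_fraction]
    assign = stratified_folds(structures, folds, seed)
    types = sorted({s.label for s in structures if s.label is not None})
    records: dict[float, list[tuple[str, list[str]]]] = {fr: [] for fr in fractions}
    fold_metrics: dict[tuple[float, int], list[MacroMetrics]] = {
        (fr, k): [] for fr in fractions for k in ks
    }
    max_k = max(ks)
    for fold in range(folds):
        train = [s for s, a in zip(structures, assign) if a != fold]
        test = [s for s, a in zip(structures, assign) if a == fold]
        test_sers = [ser for ser, _ in serialise_corpus(test, cfg.strategy)]
        test_labels = [s.label for s in test]
        base = build_rulesets(
            train,
            PipelineConfig(
                strategy=cfg.strategy,
                min_support=cfg.min_support,
                max_len=cfg.max_len,
                ranking=cfg.ranking,
                top_fraction=1.0,
                exclude=cfg.exclude,
                exclude_labels=cfg.exclude_labels,
                ir_band=cfg.ir_band,
                mixed_key=cfg.mixed_key,
                score=cfg.score,
            ),
        )
        for fr in fractions:
            rulesets = {
                lab: RankedRuleSet(
                    type_label=rs.type_label,
                    strategy=rs.strategy,
                    ranking=rs.ranking,
                    top_fraction=fr,
                    rules=rs.rules[: math.ceil(fr * len(rs.rules))],
                    exclude_common=rs.exclude_common,
                )
                for lab, rs in base.items()
            }
            scores = score_matrix(test_sers, rulesets, cfg.score)
            topk = _topk_from_scores(scores, max_k)
            recs = list(zip(test_labels, topk))
            records[fr].extend(recs)
            for k in ks:
                fold_metrics[(fr, k)].append(topk_metrics(recs, types, k))
    out = {}
    for key, ms in fold_metrics.items():
        per_type = {
            t: tuple(
                float(np.mean([m.per_type[t][j] for m in ms])) for j in range(3)
            )
            for t in types
        }
        out[key] = MacroMetrics(
            per_type=per_type,
            macro_precision=float(np.mean([m.macro_precision for m in ms])),
            macro_recall=float(np.mean([m.macro_recall for m in ms])),
            macro_f1=float(np.mean([m.macro_f1 for m in ms])),
            k=key[1],
        )
    return out


def cross_validate(
    structures: Sequence[DependencyStructure],
    cfg: PipelineConfig,
    folds: int = 9,
    k: int = 1,
    seed: int = 0,
) -> MacroMetrics:
    """Nine-fold (by default) stratified cross-validation at one rank depth."""
    grid = cross_validate_grid(
        structures, cfg, folds=folds, ks=(k,), top_fractions=[cfg.top_fraction], seed=seed
    )
    return grid[(cfg.top_fraction, k)]


# --------------------------------------------------------------------------
# Pairwise discrimination


def pairwise_discrimination(
    structures: Sequence[DependencyStructure],
    rulesets: Mapping[str, RankedRuleSet],
    cfg: ScoreConfig,
    strategy: str = SET,
) -> dict[tuple[str, str], tuple[float, float]]:
    """Sensitivity/specificity for every ordered type pair.

    Restricted to sentences of the two types, each sentence is predicted
    as whichever of the two scores higher (ties to the lexicographically
    smaller label); sensitivity is the recall of the first type,
    specificity the recall of the second.  The degenerate (A, A) pair is
    reported as (1, 1).
    """
    sers = serialise_corpus(structures, strategy)
    labels = [lab for _, lab in sers]
    scores = score_matrix([s for s, _ in sers], rulesets, cfg)
    types = sorted(rulesets)
    out: dict[tuple[str, str], tuple[float, float]] = {}
    for a in types:
        for b in types:
            if a == b:
                out[(a, b)] = (1.0, 1.0)  # degenerate self-pair, tie-break convention
                continue
            rec = {a: [0, 0], b: [0, 0]}  # correct, total
            for lab, (_, row) in zip(labels, scores.iterrows()):
                if lab not in (a, b):
                    continue
                pred = min((a, b), key=lambda t: (-row[t], t))
                rec[lab][1] += 1
                if pred == lab:
                    rec[lab][0] += 1
            sens = rec[a][0] / rec[a][1] if rec[a][1] else 0.0
            spec = rec[b][0] / rec[b][1] if rec[b][1] else 0.0
            out[(a, b)] = (sens, spec)
    return out


# --------------------------------------------------------------------------
# Rule-set overlap analytics


def ruleset_overlap(source: RankedRuleSet, target: RankedRuleSet) -> OverlapReport:
    """Uni-directional overlap: fraction of source rules present in target."""
    if not source.rules:
        raise ValueError("overlap undefined for an empty source rule set")
    target_keys = target.keys()
    shared = sum(r.key in target_keys for r in source.rules)
    return OverlapReport(
        source=f"{source.type_label}/{source.strategy}",
        target=f"{target.type_label}/{target.strategy}",
        overlap=shared / len(source.rules),
    )


def overlap_diversity(
    overlaps: Mapping[str, Mapping[object, Mapping[str, float]]],
    ddof: int = 0,
) -> dict[str, float]:
    """Average (over type pairs) SD of overlaps across serialisations.

    ``overlaps[ranking][pair][strategy]`` is one overlap value; the SD is
    the population SD by default.  The result summarises how much each
    ranking mechanism diversifies the rule sets across serialisations.
    """
    out = {}
    for ranking, pairs in overlaps.items():
        sds = []
        for vals in pairs.values():
            arr = np.asarray(list(vals.values()), dtype=float)
            if arr.size < 2:
                raise ValueError("overlap diversity needs >= 2 serialisations")
            sds.append(float(np.std(arr, ddof=ddof)))
        out[ranking] = float(np.mean(sds)) if sds else float("nan")
    return out


# --------------------------------------------------------------------------
# Cross-corpus threshold procedure


@dataclass(slots=True)
class CrossCorpusResult:
    """Precision table at the best-discriminating threshold."""

    threshold: float
    #: scorer type -> ({target type -> precision} or None when no sentence
    #: scored above the threshold)
    table: dict[str, dict[str, float] | None]
    #: scorer type -> population SD of the precisions across target types
    sd: dict[str, float | None]


def cross_corpus_threshold(
    scores: pd.DataFrame,
    thresholds: Iterable[float] | None = None,
) -> tuple[CrossCorpusResult, dict[float, CrossCorpusResult]]:
    """Sweep a score threshold per scorer type and report discrimination.

    ``scores`` has a ``true_type`` column plus one column per scorer type
    (rule sets of the source corpus applied to the target corpus's
    sentences).  For each scorer type and threshold, among sentences
    scoring above the threshold, the fraction belonging to each target
    type is that type's precision; the SD of those precisions across
    target types measures how discriminating the scorer is.  Returns the
    result at the threshold with the best (largest) mean SD, plus the
    full sweep.
    """
    if thresholds is None:
        thresholds = np.arange(0.0, 1.0001, 0.05)
    target_types = sorted(scores["true_type"].unique())
    scorer_types = [c for c in scores.columns if c != "true_type"]
    sweep: dict[float, CrossCorpusResult] = {}
    for th in thresholds:
        table: dict[str, dict[str, float] | None] = {}
        sd: dict[str, float | None] = {}
        for a in scorer_types:
            above = scores.loc[scores[a] > th, "true_type"]
            if above.empty:
                table[a] = None  # flagged: nothing above threshold
                sd[a] = None
                continue
            frac = {t: float((above == t).mean()) for t in target_types}
            table[a] = frac
            sd[a] = float(np.std(list(frac.values())))
        sweep[float(th)] = CrossCorpusResult(float(th), table, sd)

    def mean_sd(res: CrossCorpusResult) -> float:
        vals = [v for v in res.sd.values() if v is not None]
        return float(np.mean(vals)) if vals else -1.0

    best = max(sweep.values(), key=mean_sd)
    return best, sweep
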