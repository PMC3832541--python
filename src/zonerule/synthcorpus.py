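"""Synthetic labelled dependency-structure corpora.

Real rhetorical-zone corpora pair each sentence with a dependency parse
and a zone label.  This generator emulates the statistical shape of such
data with full control: every sentence draws background relation labels
from a Zipf-like distribution over the Stanford label inventory (so
``det``/``prep``/``amod``/``nn`` are near-ubiquitous, as in real text),
and each rhetorical type injects its own ordered *signature motifs* with
a configurable probability.  Motif splicing preserves the motif's
internal order but not adjacency, so order-aware sequence mining is
exercised without reducing to contiguous n-grams.

Tokens are attached into a random projective tree rooted at a head token,
so the flat-list and graph views are mutually consistent and all five
serialisers are non-trivial.  Generation is fully reproducible from the
seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from zonerule.depstruct import (
    ROOT_TOKEN,
    DependencyRelation,
    DependencyStructure,
    Token,
)

#: The Stanford typed-dependency inventory (58 labels), ordered by the
#: Zipf-like background weight used here: the near-ubiquitous determiner /
#: preposition / adjectival / noun-compound modifiers first, rare clausal
#: relations last.  Labels are opaque strings downstream, so alternative
#: inventories work unchanged.
STANFORD_LABELS: tuple[str, ...] = (
    "det", "prep", "amod", "nn", "nsubj", "dobj", "advmod", "aux",
    "conj", "cc", "pobj", "dep", "cop", "mark", "ccomp", "xcomp",
    "poss", "num", "appos", "rcmod", "neg", "iobj", "attr", "prt",
    "tmod", "complm", "partmod", "infmod", "quantmod", "npadvmod",
    "number", "abbrev", "purpcl", "possessive", "mwe", "rel", "ref",
    "punct", "obj", "subj", "comp", "mod", "arg", "sdep", "xsubj",
    "pcomp", "measure", "advcl", "nsubjpass", "auxpass", "agent",
    "expl", "parataxis", "csubj", "csubjpass", "preconj", "predet",
    "acomp",
)

DEFAULT_SIGNATURES: dict[str, list[list[str]]] = {
    # passive-voice construction, typical of procedure descriptions
    "method": [["nsubjpass", "auxpass", "agent"]],
    # expletive + clausal subject + adjectival complement ("it is evident that ...")
    "result": [["expl", "csubj", "acomp"]],
    # discourse-level attachment of framing clauses
    "background": [["advcl", "parataxis", "preconj"]],
}


@dataclass(slots=True)
class GeneratorSpec:
    """Study conditions for one synthetic corpus."""

    types: list[str]
    signatures: dict[str, list[list[str]]]
    p_sig: float = 0.8
    background_motif_rate: float = 0.1
    background_labels: tuple[str, ...] = STANFORD_LABELS
    background_weights: tuple[float, ...] | None = None  # default: 1/rank
    min_length: int = 8
    max_length: int = 24
    sentences_per_type: int = 300
    seed: int = 1

    def __post_init__(self) -> None:
        if not self.types:
            raise ValueError("type list must be non-empty")
        if len(set(self.types)) != len(self.types):
            raise ValueError("type labels must be distinct")
        if not 0 <= self.p_sig <= 1 or not 0 <= self.background_motif_rate <= 1:
            raise ValueError("probabilities must lie in [0, 1]")
        if self.min_length > self.max_length:
            raise ValueError("min_length must not exceed max_length")

    def weights(self) -> np.ndarray:
        if self.background_weights is not None:
            w = np.asarray(self.background_weights, dtype=float)
        else:
            w = 1.0 / np.arange(1, len(self.background_labels) + 1)
        return w / w.sum()


def default_spec(seed: int = 1) -> GeneratorSpec:
    """The default study conditions: 3 types, one 3-label motif each,
    injection probability 0.8, background motif rate 0.1, 300 sentences
    per type."""
    return GeneratorSpec(
        types=sorted(DEFAULT_SIGNATURES),
        signatures={t: [list(m) for m in DEFAULT_SIGNATURES[t]] for t in DEFAULT_SIGNATURES},
        seed=seed,
    )


def _splice(seq: list[str], motif: Sequence[str], rng: np.random.Generator) -> None:
    """Insert motif labels at random positions, preserving their order."""
    prev = 0
    for lab in motif:
        pos = int(rng.integers(prev, len(seq) + 1))
        seq.insert(pos, lab)
        prev = pos + 1


def _projective_tree(
    n_tokens: int, head: int, rng: np.random.Generator
) -> dict[int, int]:
    """Governor index per non-head token of a random projective tree.

    The head governs its interval; each side interval picks a uniform
    sub-head governed by the parent and recurses, giving O(log n) expected
    depth so the breadth-first serialiser sees several levels.
    """
    governor: dict[int, int] = {}

    def attach(lo: int, hi: int, parent: int) -> None:
        if lo > hi:
            return
        sub = int(rng.integers(lo, hi + 1))
        governor[sub] = parent
        attach(lo, sub - 1, sub)
        attach(sub + 1, hi, sub)

    attach(1, head - 1, head)
    attach(head + 1, n_tokens, head)
    return governor


def generate(spec: GeneratorSpec) -> list[DependencyStructure]:
    """Generate the labelled corpus described by the spec.

    A motif belonging to the sentence's own type is present with
    probability ``1 - (1 - p_sig)(1 - background_motif_rate)``; any other
    type's motif appears at the background rate alone.
    """
    rng = np.random.default_rng(spec.seed)
    labels = np.asarray(spec.background_labels)
    weights = spec.weights()
    all_motifs = [
        (t, tuple(m)) for t in sorted(spec.signatures) for m in spec.signatures[t]
    ]
    corpus: list[DependencyStructure] = []
    for type_label in spec.types:
        for i in range(spec.sentences_per_type):
            length = int(rng.integers(spec.min_length, spec.max_length + 1))
            injected: list[tuple[str, ...]] = []
            for owner, motif in all_motifs:
                p_own = spec.p_sig if owner == type_label else 0.0
                p = 1.0 - (1.0 - p_own) * (1.0 - spec.background_motif_rate)
                if rng.random() < p:
                    injected.append(motif)
            n_inj = sum(len(m) for m in injected)
            n_bg = max(length - n_inj, 1)
            seq = [str(l) for l in rng.choice(labels, size=n_bg, p=weights)]
            for motif in injected:
                _splice(seq, motif, rng)
            n_tokens = len(seq) + 1  # one head token plus one per label
            head = int(rng.integers(1, n_tokens + 1))
            governor = _projective_tree(n_tokens, head, rng)
            tokens = {j: Token(f"tok{j}", j) for j in range(1, n_tokens + 1)}
            relations = [DependencyRelation("root", ROOT_TOKEN, tokens[head])]
            it = iter(seq)
            for j in range(1, n_tokens + 1):
                if j == head:
                    continue
                relations.append(
                    DependencyRelation(next(it), tokens[governor[j]], tokens[j])
                )
            relations.sort(key=lambda r: r.dependent.index)
            corpus.append(
                DependencyStructure(
                    sentence_id=f"{type_label}-{i:04d}",
                    relations=relations,
                    label=type_label,
                )
            )
    return corpus


def spike_scores(
    means: Mapping[str, Mapping[str, float]],
    sd: float,
    n_per_type: int,
    seed: int = 1,
) -> pd.DataFrame:
    """Hand-parameterised per-type score tables for evaluator unit tests.

    ``means[true_type][scorer_type]`` is the mean score the ``scorer_type``
    rule set assigns to sentences of ``true_type``; Gaussian noise with the
    given SD is added and scores are clipped to [0, 1].  Returns a frame
    with a ``true_type`` column plus one score column per scorer type.
    """
    rng = np.random.default_rng(seed)
    scorer_types = sorted({a for row in means.values() for a in row})
    records = []
    for true_type in sorted(means):
        for _ in range(n_per_type):
            row = {"true_type": true_type}
            for a in scorer_types:
                mu = means[true_type].get(a, 0.0)
                row[a] = float(np.clip(rng.normal(mu, sd), 0.0, 1.0))
            records.append(row)
    return pd.DataFrame.from_records(records)
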