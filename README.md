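# zonerule

Recognising the **rhetorical zone** of a sentence in scientific text — is it
background, a method statement, a result? — from nothing but the sentence's
**typed-dependency structure**. `zonerule` serialises dependency parses in
five ways, mines per-zone association rules from the serialisations, filters
them with interestingness measures, and classifies unseen sentences by
aggregating order-aware rule covers.

It is aimed at researchers in scientific-discourse analysis and biomedical
literature mining who want a transparent, feature-inspectable alternative to
opaque sentence classifiers: the learned model *is* a ranked list of
grammatical-relation patterns that can be read, compared across zones, and
compared across corpora.

## The method

A parsed sentence is a labelled digraph of grammatical relations
`rel(governor, dependent)` — e.g. `nsubj(mediates-3, TRADD-1)`. After
collapsing specialised `prep_*`/`conj_*` labels to their generic types, the
structure is serialised as a transaction:

* **set** — the distinct relation labels (root removed);
* **bag-of-1/2/3** — the flat-list label sequence chunked into consecutive
  groups of 1, 2 or 3 (order meaningful between groups, not within);
* **BF-bag** — sibling bags from a breadth-first walk of the graph, each
  node visited once (safe on re-entrant parses).

Per zone *t*, association rules A ⇒ B are mined from that zone's
transactions (Apriori for sets, level-wise bag-sequence growth for
sequences) and kept when

    sup(A ⇒ B) = P(A ∪ B) ≥ 0.05,    conf(A ⇒ B) = sup(A ∪ B) / sup(A).

Rules are then ranked by support, confidence, or — after keeping only the
"almost balanced" rules with imbalance ratio IR ∈ [0.40, 0.60] — by the
Kulczynski measure

    Kulc(A, B) = ½ (conf(A⇒B) + conf(B⇒A)),
    IR(A, B)   = |sup(A) − sup(B)| / (sup(A) + sup(B) − sup(A∪B)),

and truncated to a top fraction (1–15%). A sentence *s* is scored against a
zone's ranked rule set R by

    score(s, R) = f_{r ∈ R} ( g(w_r, cover(r, s)) )

with w ∈ {1, sup, conf, Kulc}, g ∈ {product, arithmetic mean, harmonic
mean}, f ∈ {mean, max, mean within one SD} — 36 configurations. The
**rule cover** is the average matched fraction of antecedent and
consequent; for sequence-origin rules matching is order-aware with prefix
semantics (the first out-of-order item terminates the match). The predicted
zone(s) are the top-K scorers.

## Worked example

The package ships a synthetic-corpus generator that emulates labelled
parsed corpora: Zipf-weighted background relations (so `det`/`prep` are
near-ubiquitous, as in real text) plus per-zone ordered signature motifs
injected with probability 0.8.

```bash
zonerule synth --out corpus.jsonl                 # 3 zones x 300 sentences
zonerule mine --corpus corpus.jsonl --strategy set --min-support 0.05 --out rules.tsv
zonerule rank --rules rules.tsv --ranking confidence --top 0.01 --out ranked.tsv
zonerule evaluate --corpus corpus.jsonl --folds 9 --k 1 --seed 1 --report report.json
```

The last command prints

```
macro F1 @ K=1: 0.794
```

meaning: under nine-fold cross-validation, mining top-1% confidence-ranked
set rules per zone and scoring with (w=confidence, g=arithmetic mean,
f=mean), the classifier recovers the true zone of held-out sentences with
macro F1 ≈ 0.79 — essentially the generative ceiling of this corpus, where
a zone's own motif is present in 82% of its sentences and in 10% of the
others'. The same pipeline with signature injection disabled scores ≈ 0.24,
i.e. chance for three balanced classes; and the top-1% rule budget performs
identically to the 10× larger top-10% budget ("less is more").

Library use mirrors the CLI:

```python
from zonerule import default_spec, generate
from zonerule.evaluate import PipelineConfig, cross_validate

corpus = generate(default_spec(seed=1))
metrics = cross_validate(corpus, PipelineConfig(), folds=9, k=1, seed=1)
print(round(metrics.macro_f1, 3))   # 0.794
```

## Layout

| module        | role |
| ------------- | ---- |
| `depstruct`   | parse Stanford listings / CoNLL-U / JSON-lines; normalisation |
| `serialise`   | the five serialisation strategies |
| `rulemine`    | Apriori (sets) and bag-sequence mining; support/confidence |
| `ruleselect`  | Kulc, IR, rankings, top-fraction filtering, rule TSV I/O |
| `classify`    | rule covers, the 36 score aggregations, top-K prediction |
| `evaluate`    | stratified CV, pairwise discrimination, overlap analytics |
| `synthcorpus` | reproducible synthetic labelled corpora |

See `docs/methods.md` for modelling assumptions, parameter defaults and
known limitations.
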