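# Methods

## Model

`zonerule` treats rhetorical-zone recognition as associative
classification over grammatical relations. The working hypothesis is that
zones (background, method, result, ...) leave a footprint in *how*
sentences are constructed — which typed dependencies they use and in what
order — independently of lexical content. The pipeline is therefore built
entirely on dependency labels: tokens are carried through parsing but never
used as features.

A sentence's parse is kept in two equivalent views: the **flat list** of
relations in listing order (mirroring token order) and the **graph** rooted
at a virtual ROOT node. Parses are accepted even when they are not trees —
re-entrant edges (e.g. a `conj` relation into an already-attached token)
are common in collapsed-dependency output — and flagged rather than
rejected; only the breadth-first serialiser needs to care, and it visits
each node once, dropping re-entrant edges.

### Serialisations

Five reductions of a structure to an ordered list of label bags define the
mining transactions: `set`, `bag1`, `bag2`, `bag3`, `bfbag` (see README).
Root handling is deliberately asymmetric: the root label is removed from
`set` and `bfbag` (it appears exactly once in every parse, so it carries no
variance) but retained in the chunked `bag-of-k` sequences, where it
occupies a position and shifts the grouping. Within a group, order carries
no meaning: groups are multisets, and group-level order is the only order
the sequence semantics sees.

### Mining

Set-mode mining is classical Apriori with relative support; support at
exactly the threshold is kept (the filter removes rules *below* it).
Candidate counting uses per-label transaction bitmasks, so each itemset's
transaction set is an AND of integers. Rules are every bipartition of every
frequent itemset of size ≥ 2; no confidence floor is applied.

Sequence-mode mining grows bag-sequence patterns level-wise (GSP-style):
each frequent pattern is extended by one frequent label, either into its
last bag or as a new trailing bag; canonical form (sorted labels within a
bag) deduplicates candidates, and deleting the last label of a canonical
pattern always yields a canonical frequent predecessor, which makes the
growth complete. A pattern occurs in a transaction when its bags map
injectively onto transaction groups at strictly increasing positions with
multiset containment; greedy leftmost matching is used, which is complete
for existence (verified in the tests against a backtracking matcher).
Rules are prefix/suffix splits at bag boundaries, with antecedent and
consequent disjoint as flattened label multisets — mirroring the set-rule
disjointness constraint.

Mining is always per zone: transactions are partitioned by label and mined
independently, so supports are relative to the zone, not the corpus.

### Interestingness and filtering

Support and confidence alone select either the ubiquitous or the merely
lucky. The Kulczynski measure (mean of the two directed confidences) is
null-invariant, and the imbalance ratio isolates rules whose two sides have
comparable supports. Five rankings are implemented: support, confidence,
and IR-band-filtered (closed band, default [0.40, 0.60]) rankings by Kulc,
by confidence, and by the product confidence x Kulc ("mixed"). The mixed
variant has no canonical definition in the literature of this pipeline;
the product is this package's choice — it must differ from the other two
IR variants to be worth a separate name — and is isolated behind the
`mixed_key` configuration ("product", "confidence" or "kulc"). Ranking is
fully deterministic: measure descending, support descending, canonical rule
form ascending; truncation uses ceil so a non-empty pool never empties.

Both Kulc and IR are computed exactly from the frequent-pattern support
table at mining time (every rule side is itself a frequent pattern), not
re-estimated later.

### Scoring and classification

The rule cover adapts the Jaccard idea to directed rules: the average of
the matched fractions of antecedent and consequent. Set-origin rules match
by membership and may score any serialisation. Sequence-origin rules are
matched order-aware with *prefix semantics*: rule bags are consumed
left-to-right against the group sequence behind a cursor; a bag must be
wholly contained in some group at or after the cursor, and the first bag
that cannot be placed terminates the side's match (a partially containable
bag contributes its best partial containment at or after the cursor before
terminating — the natural extension of the item-level rule to grouped
rules). Antecedent and consequent each start their own cursor at the
beginning of the sentence; for the worked single-label case both the
shared-cursor and independent-cursor readings give the same value, and the
independent contract is the simpler one.

Aggregation follows score(s, R) = f(g(w, cover)) with the 4 x 3 x 3
options listed in the README; all 36 keep scores in [0, 1] since w and
cover live there and each g, f preserves the interval. The SD band uses the
population SD (divisor n), and at least one value always lies within one SD
of the mean, so the band mean is well defined. An empty rule set scores 0 —
a zone with no surviving rules cannot claim a sentence. Type ties break
lexicographically.

A vectorised scorer (rule sides as 0/1 rows over the label vocabulary;
matched counts as matrix products) is used for set-origin rule sets on
larger corpora; a dedicated test asserts numerical equality with the
per-rule reference path across all 36 configurations.

## Evaluation conventions

Cross-validation is stratified per zone with a seeded shuffle keyed on
sentence ids, so fold assignment is invariant to corpus order. Nine folds
is the package convention. At rank depth K, a test sentence yields a true
positive for its zone when the zone is among the K best scores and a false
positive for every *other* zone in that set; this makes precision fall as K
grows, which is the behaviour one wants from a top-K prediction set.
Per-type metrics are averaged over folds, and macro averages weight zones
equally. Pairwise discrimination restricts scoring to two zones and reports
sensitivity/specificity per ordered pair. Rule-set overlap is
uni-directional (|source rules found in target| / |source|) because ranked
sets rarely share size; the SD of overlaps across serialisations (population
SD), averaged over zone pairs, summarises how much a ranking mechanism
diversifies the rule sets. The cross-corpus procedure sweeps a score
threshold (default grid 0 to 1, step 0.05), computes per-target-type
precision among sentences scoring strictly above it, and selects the
threshold with the largest mean SD across target types — SD, not raw
precision, is the discrimination signal.

## Synthetic corpus: what it emulates, and what it does not

The generator produces labelled parses with three controllable properties:

* **Background realism** — relation labels are drawn from the 58-label
  Stanford inventory with Zipf-like weights (1/rank), ordered so that
  `det`, `prep`, `amod`, `nn` dominate; with default sentence lengths of
  8–24 relations, `det` is present in >90% of sentences, matching the
  near-ubiquity of determiners and prepositions in real corpora.
* **Zone signal** — each zone owns an ordered 3-label motif built from
  rare relations (e.g. the passive construction `nsubjpass, auxpass,
  agent` for the method zone). A sentence receives its own zone's motif
  with probability 1 − (1 − p_sig)(1 − b) and any other zone's motif at
  the background rate b alone; defaults p_sig = 0.8, b = 0.1 give an
  own-zone motif support of 0.82 and a cross-zone support of 0.10.
  Splicing preserves motif order but not adjacency, so order-aware mining
  is exercised without collapsing into contiguous n-grams.
* **Structural non-triviality** — tokens are attached into a random
  projective tree by recursive interval splitting (O(log n) expected
  depth), so the graph and flat-list views genuinely differ and the
  breadth-first serialiser sees several levels.

Default problem sizes — 300 sentences per zone, nine folds, set
serialisation for the cross-validated runs — keep a full evaluation grid
(two rule budgets, three rank depths, plus the chance control) around a
minute on one core; sequence-mode mining is exercised on smaller corpora
where its exhaustive enumeration oracle is feasible.

What passing tests on this corpus do **not** show: real rhetorical zones
are not marked by clean injected motifs; their signal is weaker,
distributed, and entangled with sentence length and vocabulary. The
generator also makes no attempt at English syntax — label sequences and
tree shapes are statistically, not linguistically, plausible. Results on
the synthetic corpus validate the machinery (mining correctness, ranking
determinism, cover semantics, metric plumbing) and the qualitative
behaviours (signature recovery, chance-level control, small rule budgets
sufficing), not real-corpus performance.

A useful calibration point: under the default conditions the only
class-discriminative evidence is full-motif presence (0.82 own vs 0.10
foreign; the background is identical across zones), and a Bayes-optimal
oracle that knows the generative model reaches macro F1 ≈ 0.80 on the
seed-1 corpus. The mined classifier's cross-validated 0.794 therefore sits
at the generative ceiling: the pipeline extracts essentially all the signal
the corpus contains.

## Numerical choices and degenerate inputs

* Support thresholds compare counts against `min_support * n − 1e-9` so
  boundary supports are kept.
* Hyphenated token surfaces split at the last hyphen before the trailing
  index (`factor-2-23` → surface `factor-2`, index 23).
* Unparseable corpus blocks are skipped with a warning at load time rather
  than failing the load — real corpora contain chemical formulae and other
  parser-breaking material.
* Empty structures serialise to empty transactions; empty transaction
  lists are an error for support computation.
* The maximum pattern size (itemset size / bag count, default 6) is a
  tractability guard, configurable, and not part of the pattern semantics.
* Mining, ranking, scoring and fold assignment are deterministic given
  their inputs and seeds; identical inputs produce identical rule lists,
  byte-for-byte.

## Known limitations

* Sequence-mode mining enumerates candidate patterns level-wise with a
  full corpus scan per candidate; it is meant for moderate corpora and
  short patterns, not the 10^5-transaction scale the set-mode bitmask
  Apriori handles comfortably.
* The IR-mixed ranking is this package's construction (see above); results
  under that ranking should be reported with its definition.
* Enhanced CoNLL-U dependency graphs (the DEPS column) are ignored; only
  HEAD/DEPREL are read.
* No ensemble over (serialisation, ranking, score) configurations is
  provided; the grid is exposed for independent runs instead.
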