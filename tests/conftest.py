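"""Shared fixtures: the worked passive-construction example sentence and
small helper builders used across the suite."""

from __future__ import annotations

import pytest
from hypothesis import HealthCheck, settings

from zonerule.depstruct import DependencyStructure, normalise, parse_stanford_listing
from zonerule.serialise import Serialisation, serialise

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

# The 20-relation parse of: "TRADD also mediates the binding of the protein
# kinase RIP (receptor-interacting protein) and the ring/zinc finger
# protein, TNF receptor-associated factor-2 (TRAF2)."
TRADD_LISTING = (
    "nsubj(mediates-3, TRADD-1) advmod(mediates-3, also-2) "
    "root(ROOT-0, mediates-3) det(factor-2-23, the-4) "
    "amod(factor-2-23, binding-5) det(RIP-10, the-7) nn(RIP-10, protein-8) "
    "nn(RIP-10, kinase-9) prep_of(binding-5, RIP-10) "
    "amod(protein-13, receptor-interacting-12) appos(RIP-10, protein-13) "
    "det(protein-19, the-16) amod(protein-19, ring/zinc-17) "
    "nn(protein-19, finger-18) prep_of(binding-5, protein-19) "
    "conj_and(RIP-10, protein-19) appos(protein-19, TNF-21) "
    "amod(factor-2-23, receptor-associated-22) dobj(mediates-3, factor-2-23) "
    "abbrev(factor-2-23, TRAF2-25)."
)

# Flat-list label sequence after prep/conj merging (root retained).
TRADD_FLAT = [
    "nsubj", "advmod", "root", "det", "amod", "det", "nn", "nn", "prep",
    "amod", "appos", "det", "amod", "nn", "prep", "conj", "appos", "amod",
    "dobj", "abbrev",
]


@pytest.fixture
def tradd() -> DependencyStructure:
    return parse_stanford_listing(TRADD_LISTING, sentence_id="tradd")


@pytest.fixture
def tradd_merged(tradd) -> DependencyStructure:
    return normalise(tradd, merge_prep_conj=True)


def make_set_transactions(label_sets: list[set[str]]) -> list[Serialisation]:
    """Set serialisations from raw label sets (helper for toy corpora)."""
    return [
        Serialisation("set", (tuple(sorted(s)),) if s else (), f"t{i}")
        for i, s in enumerate(label_sets)
    ]


def make_seq_transactions(
    group_lists: list[list[list[str]]], strategy: str = "bag1"
) -> list[Serialisation]:
    """Sequence serialisations from raw group lists."""
    return [
        Serialisation(strategy, tuple(tuple(g) for g in groups), f"t{i}")
        for i, groups in enumerate(group_lists)
    ]


@pytest.fixture
def toy_set_transactions() -> list[Serialisation]:
    """The 3-transaction toy: T1={a,b,c}, T2={a,b}, T3={a,c}."""
    return make_set_transactions([{"a", "b", "c"}, {"a", "b"}, {"a", "c"}])
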