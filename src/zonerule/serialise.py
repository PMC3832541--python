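"""The five serialisations of a dependency structure.

A serialisation reduces a sentence's dependency structure to an ordered
list of label bags; it is the transaction unit for rule mining and the
target of rule covers.  Strategies:

``set``
    the distinct relation labels, order discarded, root removed.
``bag1`` / ``bag2`` / ``bag3``
    the flat-list label sequence chunked left-to-right into consecutive
    groups of 1, 2 or 3 labels (root retained; the final group may be
    short).
``bfbag``
    a breadth-first walk of the graph from the root's child, emitting one
    bag per visited node containing the labels of its outgoing edges
    (sibling bags); each node is visited once, so an edge into an
    already-visited node is dropped, which makes the traversal safe on
    re-entrant graphs.  The root relation label is removed.

Order is meaningful *between* groups, not within a group: groups are bags.
"""

from __future__ import annotations

import json
import logging
from collections import deque
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from zonerule.depstruct import ROOT_INDEX, ROOT_LABEL, DependencyStructure

log = logging.getLogger(__name__)

SET = "set"
BAG1 = "bag1"
BAG2 = "bag2"
BAG3 = "bag3"
BFBAG = "bfbag"
STRATEGIES = (SET, BAG1, BAG2, BAG3, BFBAG)

#: strategies whose group order carries meaning for mining and covers
SEQUENCE_STRATEGIES = (BAG1, BAG2, BAG3, BFBAG)


@dataclass(frozen=True, slots=True)
class Serialisation:
    """An ordered list of label bags produced by one strategy."""

    strategy: str
    groups: tuple[tuple[str, ...], ...]
    sentence_id: str

    def label_set(self) -> frozenset[str]:
        return frozenset(l for g in self.groups for l in g)

    def label_multiset(self) -> list[str]:
        return [l for g in self.groups for l in g]

    def to_json_obj(self) -> dict:
        return {
            "id": self.sentence_id,
            "strategy": self.strategy,
            "groups": [list(g) for g in self.groups],
        }

    @classmethod
    def from_json_obj(cls, obj: dict) -> "Serialisation":
        return cls(
            strategy=obj["strategy"],
            groups=tuple(tuple(g) for g in obj["groups"]),
            sentence_id=str(obj["id"]),
        )


def serialise_set(s: DependencyStructure) -> Serialisation:
    """Distinct labels in first-occurrence order, root removed."""
    seen: list[str] = []
    for lab in s.labels():
        if lab != ROOT_LABEL and lab not in seen:
            seen.append(lab)
    return Serialisation(SET, (tuple(seen),) if seen else (), s.sentence_id)


def serialise_bag_k(s: DependencyStructure, k: int) -> Serialisation:
    """Chunk the flat-list label sequence into consecutive groups of size k.

    The root label is retained here (unlike set/bfbag) and the final group
    may hold fewer than k labels.
    """
    if k not in (1, 2, 3):
        raise ValueError(f"k must be 1, 2 or 3, got {k}")
    labels = s.labels()
    groups = tuple(tuple(labels[i : i + k]) for i in range(0, len(labels), k))
    return Serialisation({1: BAG1, 2: BAG2, 3: BAG3}[k], groups, s.sentence_id)


def serialise_bf_bag(s: DependencyStructure) -> Serialisation:
    """Breadth-first sibling bags, each node touched once, root label removed.

    Parents are dequeued in discovery order; within a bag, labels follow
    the flat-list order of their relations.  Relations not reachable from
    the root sentinel are ignored (with a warning).
    """
    adj = s.children()
    groups: list[tuple[str, ...]] = []
    visited: set[int] = {ROOT_INDEX}
    queue: deque[int] = deque([ROOT_INDEX])
    used = 0
    while queue:
        node = queue.popleft()
        bag: list[str] = []
        for rel in adj.get(node, []):
            used += 1
            dep = rel.dependent.index
            if dep in visited:
                continue  # re-entrant edge: dependent already claimed
            visited.add(dep)
            queue.append(dep)
            if rel.label != ROOT_LABEL:
                bag.append(rel.label)
        if bag:
            groups.append(tuple(bag))
    if used < len(s.relations):
        log.warning(
            "sentence %s: %d relation(s) unreachable from the root, ignored",
            s.sentence_id,
            len(s.relations) - used,
        )
    return Serialisation(BFBAG, tuple(groups), s.sentence_id)


def serialise(s: DependencyStructure, strategy: str) -> Serialisation:
    """Dispatch to one of the five strategies."""
    if strategy == SET:
        return serialise_set(s)
    if strategy in (BAG1, BAG2, BAG3):
        return serialise_bag_k(s, int(strategy[-1]))
    if strategy == BFBAG:
        return serialise_bf_bag(s)
    raise ValueError(f"unknown strategy {strategy!r}; expected one of {STRATEGIES}")


def read_serialisations(path: str | Path) -> list[Serialisation]:
    out = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if line.strip():
                out.append(Serialisation.from_json_obj(json.loads(line)))
    return out


def write_serialisations(items: Iterable[Serialisation], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for item in items:
            fh.write(json.dumps(item.to_json_obj()) + "\n")
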