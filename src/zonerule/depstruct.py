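"""Typed-dependency structures: parsing, representation, normalisation.

A sentence's grammatical analysis is a labelled directed graph whose nodes
are the sentence tokens and whose edges are typed grammatical relations
(``nsubj``, ``dobj``, ``prep_of`` ...) pointing from governor to dependent.
The same structure can be read as a *flat list* of relations, ordered as
they appear in the listing (mirroring token order), or as a *graph* rooted
at a virtual ROOT node.  Both views feed the serialisation strategies in
:mod:`zonerule.serialise`.

Supported inputs: Stanford-style textual relation listings
(``rel(gov-i, dep-j)`` entries), CoNLL-U sentence blocks, and a JSON-lines
corpus format used as the canonical interchange for all downstream stages.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

log = logging.getLogger(__name__)

ROOT_SURFACE = "ROOT"
ROOT_INDEX = 0
ROOT_LABEL = "root"


class ParseError(ValueError):
    """Raised when a relation listing or CoNLL-U block is malformed."""


@dataclass(frozen=True, slots=True)
class Token:
    """A sentence token: surface form plus 1-based position.

    Index 0 is reserved for the virtual root sentinel.
    """

    surface: str
    index: int

    def __post_init__(self) -> None:
        if self.index < 0:
            raise ValueError(f"token index must be >= 0, got {self.index}")
        if self.index == ROOT_INDEX and self.surface != ROOT_SURFACE:
            raise ValueError("index 0 is reserved for the root sentinel")


ROOT_TOKEN = Token(ROOT_SURFACE, ROOT_INDEX)


@dataclass(frozen=True, slots=True)
class DependencyRelation:
    """A typed grammatical relation ``label(governor, dependent)``."""

    label: str
    governor: Token
    dependent: Token

    def __post_init__(self) -> None:
        if not self.label:
            raise ValueError("relation label must be non-empty")
        if self.governor.index == self.dependent.index:
            raise ValueError(
                f"self-loop on token index {self.governor.index} ({self.label})"
            )

    def as_tuple(self) -> tuple[str, str, int, str, int]:
        g, d = self.governor, self.dependent
        return (self.label, g.surface, g.index, d.surface, d.index)


@dataclass(slots=True)
class DependencyStructure:
    """A sentence's dependency graph in flat-list order.

    ``relations`` keeps the order of appearance in the source listing,
    which mirrors token order; the graph view is derived on demand.
    ``label`` is the sentence's rhetorical-type annotation, when known.
    """

    sentence_id: str
    relations: list[DependencyRelation] = field(default_factory=list)
    label: str | None = None

    def labels(self) -> list[str]:
        """Flat-list sequence of relation labels."""
        return [r.label for r in self.relations]

    def root_relation(self) -> DependencyRelation | None:
        for r in self.relations:
            if r.label == ROOT_LABEL:
                return r
        return None

    def children(self) -> dict[int, list[DependencyRelation]]:
        """Adjacency (governor index -> outgoing relations, flat-list order)."""
        adj: dict[int, list[DependencyRelation]] = {}
        for r in self.relations:
            adj.setdefault(r.governor.index, []).append(r)
        return adj

    @property
    def well_formed(self) -> bool:
        """True when the graph is a tree rooted at the sentinel.

        Requires exactly one root relation and every dependent to be
        covered exactly once by a walk from the sentinel.  Structures
        failing this are still usable (the breadth-first serialiser
        tolerates re-entrancy) but are flagged.
        """
        roots = [r for r in self.relations if r.label == ROOT_LABEL]
        if len(roots) != 1:
            return False
        dependents = [r.dependent.index for r in self.relations]
        if len(set(dependents)) != len(dependents):
            return False
        adj = self.children()
        seen: set[int] = {ROOT_INDEX}
        queue = [ROOT_INDEX]
        covered = 0
        while queue:
            node = queue.pop(0)
            for rel in adj.get(node, []):
                if rel.dependent.index in seen:
                    return False
                seen.add(rel.dependent.index)
                covered += 1
                queue.append(rel.dependent.index)
        return covered == len(self.relations)

    def to_json_obj(self) -> dict:
        return {
            "id": self.sentence_id,
            "label": self.label,
            "relations": [list(r.as_tuple()) for r in self.relations],
        }

    @classmethod
    def from_json_obj(cls, obj: dict) -> "DependencyStructure":
        rels = [
            DependencyRelation(lab, Token(gs, gi), Token(ds, di))
            for lab, gs, gi, ds, di in obj["relations"]
        ]
        return cls(sentence_id=str(obj["id"]), relations=rels, label=obj.get("label"))


# --------------------------------------------------------------------------
# Stanford-style listings


_ENTRY_RE = re.compile(r"[^()\s]+\([^()]*\)")
_REL_RE = re.compile(r"^(?P<label>[^\s(),]+)\((?P<gov>[^,]+),\s*(?P<dep>[^,]+)\)$")
_TOKEN_RE = re.compile(r"^(?P<surface>.+)-(?P<index>\d+)$")


def _parse_token(text: str, entry: str) -> Token:
    m = _TOKEN_RE.match(text.strip())
    if m is None:
        raise ParseError(f"malformed token {text!r} in entry {entry!r}")
    return Token(m.group("surface"), int(m.group("index")))


def parse_stanford_listing(
    text: str, sentence_id: str = "s0", label: str | None = None
) -> DependencyStructure:
    """Parse a whitespace/newline-separated listing of ``rel(gov-i, dep-j)`` entries.

    Token surfaces may themselves contain hyphens; the split between
    surface and index happens at the *last* hyphen preceding the trailing
    integer, so ``factor-2-23`` parses as surface ``factor-2``, index 23.
    """
    entries = _ENTRY_RE.findall(text)
    leftover = _ENTRY_RE.sub(" ", text).replace(".", " ").strip()
    if leftover:
        raise ParseError(f"malformed entry near {leftover.split()[0]!r}")
    relations = []
    for entry in entries:
        m = _REL_RE.match(entry)
        if m is None:
            raise ParseError(f"malformed entry {entry!r}")
        relations.append(
            DependencyRelation(
                label=m.group("label"),
                governor=_parse_token(m.group("gov"), entry),
                dependent=_parse_token(m.group("dep"), entry),
            )
        )
    return DependencyStructure(sentence_id=sentence_id, relations=relations, label=label)


def format_stanford_listing(s: DependencyStructure) -> str:
    """Serialise back to the textual listing (round-trip inverse of the parser)."""
    return " ".join(
        f"{r.label}({r.governor.surface}-{r.governor.index}, "
        f"{r.dependent.surface}-{r.dependent.index})"
        for r in s.relations
    )


# --------------------------------------------------------------------------
# CoNLL-U


def parse_conllu(
    block: str, sentence_id: str | None = None, label: str | None = None
) -> DependencyStructure:
    """Parse one CoNLL-U sentence block into a dependency structure.

    One relation per ordinary token row, ordered by token id; a row with
    HEAD 0 becomes the root relation against the sentinel.  Multiword
    (``1-2``) and empty (``1.1``) rows are skipped; enhanced DEPS are
    ignored.
    """
    sid = sentence_id
    rows: list[tuple[int, str, int, str]] = []
    surfaces: dict[int, str] = {}
    for raw in block.splitlines():
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            m = re.match(r"#\s*sent_id\s*=\s*(\S+)", line)
            if m and sid is None:
                sid = m.group(1)
            continue
        cols = line.split("\t")
        if len(cols) < 8:
            raise ParseError(f"CoNLL-U row with {len(cols)} columns: {line!r}")
        tok_id = cols[0]
        if "-" in tok_id or "." in tok_id:
            continue
        idx = int(tok_id)
        head, deprel = cols[6], cols[7]
        if head == "_" or deprel == "_":
            raise ParseError(f"missing HEAD/DEPREL for token {tok_id}")
        rows.append((idx, cols[1], int(head), deprel))
        surfaces[idx] = cols[1]
    if not rows:
        raise ParseError("empty CoNLL-U block")
    relations = []
    for idx, surface, head, deprel in rows:
        if head == 0:
            gov = ROOT_TOKEN
        else:
            gov = Token(surfaces.get(head, f"tok{head}"), head)
        relations.append(DependencyRelation(deprel, gov, Token(surface, idx)))
    return DependencyStructure(
        sentence_id=sid if sid is not None else "s0", relations=relations, label=label
    )


# --------------------------------------------------------------------------
# Normalisation


def normalise(
    s: DependencyStructure,
    merge_prep_conj: bool = True,
    drop_root: bool = False,
) -> DependencyStructure:
    """Collapse specialised prep/conj labels and optionally drop the root relation.

    ``prep_of``/``prep_in`` ... become ``prep`` and ``conj_and``/``conj_or``
    ... become ``conj``; relation order is otherwise preserved.  Idempotent.
    """
    relations = []
    for r in s.relations:
        lab = r.label
        if merge_prep_conj:
            if lab.startswith("prep_"):
                lab = "prep"
            elif lab.startswith("conj_"):
                lab = "conj"
        if drop_root and lab == ROOT_LABEL:
            continue
        relations.append(
            r if lab == r.label else DependencyRelation(lab, r.governor, r.dependent)
        )
    return DependencyStructure(
        sentence_id=s.sentence_id, relations=relations, label=s.label
    )


# --------------------------------------------------------------------------
# Corpus I/O (JSON-lines is the canonical interchange)


def read_jsonl(path: str | Path) -> list[DependencyStructure]:
    out = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line:
                out.append(DependencyStructure.from_json_obj(json.loads(line)))
    return out


def write_jsonl(structures: Iterable[DependencyStructure], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for s in structures:
            fh.write(json.dumps(s.to_json_obj()) + "\n")


def _blocks(text: str) -> Iterator[str]:
    for block in re.split(r"\n\s*\n", text):
        if block.strip():
            yield block


def read_stanford_corpus(path: str | Path) -> list[DependencyStructure]:
    """Read blank-line-separated listings; unparseable blocks are skipped with a warning."""
    out = []
    text = Path(path).read_text(encoding="utf-8")
    for i, block in enumerate(_blocks(text)):
        try:
            out.append(parse_stanford_listing(block, sentence_id=f"s{i}"))
        except ParseError as exc:  # e.g. chemical formulae that defeat the parser
            log.warning("skipping unparseable sentence block %d: %s", i, exc)
    return out


def read_conllu_corpus(path: str | Path) -> list[DependencyStructure]:
    out = []
    text = Path(path).read_text(encoding="utf-8")
    for i, block in enumerate(_blocks(text)):
        try:
            out.append(parse_conllu(block, sentence_id=None))
        except ParseError as exc:
            log.warning("skipping unparseable CoNLL-U block %d: %s", i, exc)
            continue
        if out[-1].sentence_id == "s0":
            out[-1].sentence_id = f"s{i}"
    return out
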