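"""ICD10-style code parsing, hierarchical clusters and the knowledge base.

A code such as ``R50.800`` splits into a three-character *category* (``R50``)
and a *subclassification* (``800``).  Entities sharing the category and the
first sub-classification (the first two characters after the decimal by
default, i.e. ``R50.80``) form a *cluster*; clusters drive candidate
generation for multi-instance learning.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

from milink.tokenize import Tokenizer, char_tokenizer

logger = logging.getLogger(__name__)

#: Default length of the "first sub-classification" used for cluster keys.
#: Configurable because localized code editions append extra classification
#: characters after the sub-classification.
DEFAULT_FIRST_SUB_LEN = 2

_CODE_RE = re.compile(r"^[A-Za-z][0-9A-Za-z]{2}(?:\.([0-9A-Za-z]{1,4}))?$")


class CodeError(ValueError):
    """Raised for malformed codes or malformed KB files."""


@dataclass(frozen=True)
class CodeParts:
    """A structured code: ``raw == category`` or ``category + "." + subclassification``."""

    raw: str
    category: str
    subclassification: str

    def __post_init__(self) -> None:
        if len(self.category) != 3:
            raise CodeError(f"category must be 3 characters, got {self.category!r}")
        expected = (
            self.category
            if not self.subclassification
            else f"{self.category}.{self.subclassification}"
        )
        if self.raw != expected:
            raise CodeError(f"inconsistent code parts: raw={self.raw!r}, expected {expected!r}")


def parse_code(code: str) -> CodeParts:
    """Split a code string into category and subclassification.

    The category is a letter followed by two alphanumerics; an optional
    decimal part of 1-4 alphanumerics follows (localized editions allow an
    extra classification character).  Placeholder characters such as ``x``
    in ``R11.x02`` are literal and carry no wildcard semantics.

    >>> parse_code("R50.800")
    CodeParts(raw='R50.800', category='R50', subclassification='800')
    """
    if not isinstance(code, str) or not code:
        raise CodeError(f"empty or non-string code: {code!r}")
    m = _CODE_RE.match(code)
    if m is None:
        raise CodeError(f"malformed code: {code!r}")
    sub = m.group(1) or ""
    return CodeParts(raw=code, category=code[:3], subclassification=sub)


def cluster_key(code: CodeParts, first_sub_len: int = DEFAULT_FIRST_SUB_LEN) -> str:
    """Cluster key: category + "." + first sub-classification.

    The first sub-classification is the first ``first_sub_len`` characters
    after the decimal (``R50.800`` -> ``R50.80``).  Codes whose
    subclassification is shorter than that (including codes without a
    decimal) key their own singleton-style cluster by the raw code.
    """
    if first_sub_len < 1:
        raise ValueError("first_sub_len must be >= 1")
    sub = code.subclassification
    if len(sub) < first_sub_len:
        return code.raw
    return f"{code.category}.{sub[:first_sub_len]}"


@dataclass(frozen=True)
class Entity:
    """A KB record: structured code, name string, name tokens, cluster key."""

    code: CodeParts
    name: str
    tokens: tuple[str, ...]
    cluster: str

    def __post_init__(self) -> None:
        if not self.tokens:
            raise CodeError(f"entity {self.code.raw} has an empty name")


class KnowledgeBase:
    """An ordered collection of entities, unique by raw code, with a cluster index.

    The cluster index partitions the entities: every entity belongs to
    exactly one bucket and the union of buckets is the whole KB.
    """

    def __init__(self, entities: Iterable[Entity]):
        self.entities: list[Entity] = list(entities)
        self.by_code: dict[str, Entity] = {}
        self.cluster_index: dict[str, list[str]] = {}
        dupes = []
        for ent in self.entities:
            if ent.code.raw in self.by_code:
                dupes.append(ent.code.raw)
                continue
            self.by_code[ent.code.raw] = ent
            self.cluster_index.setdefault(ent.cluster, []).append(ent.code.raw)
        if dupes:
            raise CodeError(f"duplicate codes in knowledge base: {sorted(set(dupes))}")
        if not self.entities:
            logger.warning("knowledge base is empty")

    def __len__(self) -> int:
        return len(self.entities)

    def __iter__(self) -> Iterator[Entity]:
        return iter(self.entities)

    def __contains__(self, code: str) -> bool:
        return code in self.by_code

    def codes(self) -> list[str]:
        return [e.code.raw for e in self.entities]

    def cluster_members(self, key: str) -> set[Entity]:
        """Entities in the bucket for ``key``; empty set for unknown keys."""
        return {self.by_code[c] for c in self.cluster_index.get(key, ())}


def cluster_members(kb: KnowledgeBase, key: str) -> set[Entity]:
    """Module-level alias of :meth:`KnowledgeBase.cluster_members`."""
    return kb.cluster_members(key)


def load_kb(
    path: str | Path,
    tokenizer: Tokenizer = char_tokenizer,
    first_sub_len: int = DEFAULT_FIRST_SUB_LEN,
) -> KnowledgeBase:
    """Load a TSV knowledge base (``code<TAB>name``, UTF-8).

    Lines starting with ``#`` are comments.  A header line whose first
    column is literally ``code`` is skipped.  Errors (unparsable code,
    empty name, duplicate code) report the offending line.
    """
    path = Path(path)
    entities: list[Entity] = []
    with path.open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.split("\t")
            if lineno == 1 and cols[0].strip().lower() == "code":
                continue
            if len(cols) < 2:
                raise CodeError(f"{path}:{lineno}: expected 'code<TAB>name', got {line!r}")
            code_str, name = cols[0].strip(), cols[1].strip()
            if not name:
                raise CodeError(f"{path}:{lineno}: empty entity name for code {code_str!r}")
            try:
                code = parse_code(code_str)
            except CodeError as exc:
                raise CodeError(f"{path}:{lineno}: {exc}") from exc
            entities.append(
                Entity(
                    code=code,
                    name=name,
                    tokens=tuple(tokenizer(name)),
                    cluster=cluster_key(code, first_sub_len),
                )
            )
    return KnowledgeBase(entities)


def save_kb(kb: KnowledgeBase, path: str | Path) -> None:
    """Write a KB back to TSV (round-trip counterpart of :func:`load_kb`)."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("code\tname\n")
        for ent in kb:
            fh.write(f"{ent.code.raw}\t{ent.name}\n")
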