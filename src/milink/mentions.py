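"""Dictionary-based symptom mention detection.

Matching is a greedy left-to-right longest-match scan over token sequences:
at each position the longest dictionary term wins, matched spans never
overlap, and scanning resumes after each match.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from milink.kb import CodeError, parse_code
from milink.tokenize import Tokenizer, char_tokenizer

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MentionSpan:
    """A detected mention: 0-based, half-open token span within a sentence."""

    sentence_id: str
    start: int
    end: int
    surface: tuple[str, ...]

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid span [{self.start}, {self.end})")
        if len(self.surface) != self.end - self.start:
            raise ValueError("surface length does not match span width")


class TermDictionary:
    """A set of term token sequences with an optional canonical code map."""

    def __init__(
        self,
        terms: Iterable[Sequence[str]] = (),
        canonical: dict[tuple[str, ...], str] | None = None,
    ):
        self.terms: set[tuple[str, ...]] = set()
        self.canonical: dict[tuple[str, ...], str] = {}
        for term in terms:
            self.add(term)
        if canonical:
            for term, code in canonical.items():
                self.add(term, code)
        self._max_len = max((len(t) for t in self.terms), default=0)

    def add(self, term: Sequence[str], code: str | None = None) -> None:
        term = tuple(term)
        if not term:
            raise ValueError("empty term")
        self.terms.add(term)
        if code is not None:
            self.canonical[term] = code
        self._max_len = max(getattr(self, "_max_len", 0), len(term))

    def __contains__(self, term: Sequence[str]) -> bool:
        return tuple(term) in self.terms

    def __len__(self) -> int:
        return len(self.terms)

    @property
    def max_term_len(self) -> int:
        return self._max_len


def load_dictionary(path: str | Path, tokenizer: Tokenizer = char_tokenizer) -> TermDictionary:
    """Load a term dictionary: one term per line, optional ``<TAB>code`` column.

    Empty lines are skipped with a warning; a malformed code in the second
    column is an error.
    """
    path = Path(path)
    d = TermDictionary()
    with path.open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                logger.warning("%s:%d: empty line skipped", path, lineno)
                continue
            cols = line.split("\t")
            term = tuple(tokenizer(cols[0].strip()))
            if not term:
                logger.warning("%s:%d: term tokenized to nothing, skipped", path, lineno)
                continue
            code = None
            if len(cols) > 1 and cols[1].strip():
                try:
                    code = parse_code(cols[1].strip()).raw
                except CodeError as exc:
                    raise CodeError(f"{path}:{lineno}: {exc}") from exc
            d.add(term, code)
    if len(d) == 0:
        logger.warning("%s: dictionary is empty", path)
    return d


def save_dictionary(d: TermDictionary, path: str | Path, tokenizer: Tokenizer = char_tokenizer) -> None:
    """Write a dictionary back to TSV (terms sorted for stable output)."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for term in sorted(d.terms):
            surface = tokenizer.join(term)
            code = d.canonical.get(term)
            fh.write(f"{surface}\t{code}\n" if code else f"{surface}\n")


def detect_mentions(
    sentence: Sequence[str], dictionary: TermDictionary, sentence_id: str = ""
) -> list[MentionSpan]:
    """Greedy left-to-right longest-match scan of ``sentence`` against the dictionary.

    Returns non-overlapping spans sorted by start; every occurrence of a
    term is emitted (no per-sentence deduplication).
    """
    tokens = tuple(sentence)
    spans: list[MentionSpan] = []
    i = 0
    n = len(tokens)
    max_len = dictionary.max_term_len
    while i < n:
        matched = False
        for width in range(min(max_len, n - i), 0, -1):
            cand = tokens[i : i + width]
            if cand in dictionary:
                spans.append(
                    MentionSpan(sentence_id=sentence_id, start=i, end=i + width, surface=cand)
                )
                i += width
                matched = True
                break
        if not matched:
            i += 1
    return spans
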