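"""Pluggable tokenization shared by the KB, dictionary and corpus readers.

Every component that compares token sequences (mention detection, entity
name encoding, exact-surface-match exclusion) must use the *same* tokenizer,
so the tokenizer is an explicit object passed around rather than a global.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence


@dataclass(frozen=True)
class Tokenizer:
    """A reversible tokenizer: ``tokenize`` splits, ``join`` detokenizes.

    ``join(tokenize(s)) == s`` is only guaranteed for strings the tokenizer
    considers canonical (e.g. no double spaces for the whitespace variant).
    """

    name: str
    tokenize: Callable[[str], list[str]]
    join: Callable[[Sequence[str]], str]

    def __call__(self, text: str) -> list[str]:
        return self.tokenize(text)


#: Character-level tokenizer.  Robust default for Chinese text, where no
#: segmenter is required and dictionary matching works on characters.
char_tokenizer = Tokenizer(
    name="char",
    tokenize=lambda s: [c for c in s if not c.isspace()],
    join=lambda toks: "".join(toks),
)

#: Whitespace tokenizer, used by the synthetic data generator whose tokens
#: are ASCII words.
whitespace_tokenizer = Tokenizer(
    name="whitespace",
    tokenize=lambda s: s.split(),
    join=lambda toks: " ".join(toks),
)

_REGISTRY = {t.name: t for t in (char_tokenizer, whitespace_tokenizer)}


def get_tokenizer(name: str) -> Tokenizer:
    """Look up a tokenizer by name (``char`` or ``whitespace``)."""
    try:
        return _REGISTRY[name]
    except KeyError:
        raise ValueError(
            f"unknown tokenizer {name!r}; available: {sorted(_REGISTRY)}"
        ) from None
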