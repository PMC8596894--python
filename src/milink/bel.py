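"""Basic Entity Linking (BEL): token-average embeddings + cosine retrieval.

The mention and every entity name are represented by the arithmetic mean of
their token vectors; candidates are ranked by cosine similarity.  Entity
vectors are computed once per (table, kb) pair and cached in a
:class:`BELIndex`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from milink.kb import Entity, KnowledgeBase

logger = logging.getLogger(__name__)

OOV_POLICIES = ("zero_vector", "skip_token")


class EmbeddingTable:
    """Vocabulary -> vector map with a fixed dimension and an OOV policy.

    ``oov_policy`` is one of:

    * ``zero_vector`` -- out-of-vocabulary tokens contribute a zero vector
      to the average;
    * ``skip_token`` -- OOV tokens are dropped before averaging.
    """

    def __init__(
        self,
        dimension: int,
        vectors: dict[str, np.ndarray] | None = None,
        oov_policy: str = "zero_vector",
    ):
        if dimension <= 0:
            raise ValueError("dimension must be positive")
        if oov_policy not in OOV_POLICIES:
            raise ValueError(f"oov_policy must be one of {OOV_POLICIES}")
        self.dimension = int(dimension)
        self.oov_policy = oov_policy
        self.vectors: dict[str, np.ndarray] = {}
        if vectors:
            for tok, vec in vectors.items():
                self[tok] = vec

    def __setitem__(self, token: str, vec: np.ndarray) -> None:
        vec = np.asarray(vec, dtype=np.float64)
        if vec.shape != (self.dimension,):
            raise ValueError(
                f"vector for {token!r} has shape {vec.shape}, expected ({self.dimension},)"
            )
        self.vectors[token] = vec

    def __contains__(self, token: str) -> bool:
        return token in self.vectors

    def __len__(self) -> int:
        return len(self.vectors)

    def get(self, token: str) -> np.ndarray | None:
        return self.vectors.get(token)


def load_word2vec_text(path: str | Path, oov_policy: str = "zero_vector") -> EmbeddingTable:
    """Read embeddings in word2vec text format.

    First line: ``vocab_size dim``; then one ``token v1 ... vdim`` per line.
    """
    path = Path(path)
    with path.open(encoding="utf-8") as fh:
        header = fh.readline().split()
        if len(header) != 2:
            raise ValueError(f"{path}: malformed word2vec header {header!r}")
        vocab_size, dim = int(header[0]), int(header[1])
        table = EmbeddingTable(dim, oov_policy=oov_policy)
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split(" ")
            if len(parts) != dim + 1:
                raise ValueError(f"{path}:{lineno}: expected {dim + 1} fields, got {len(parts)}")
            table[parts[0]] = np.array(parts[1:], dtype=np.float64)
    if len(table) != vocab_size:
        logger.warning(
            "word2vec header declared %d tokens but %d were read", vocab_size, len(table)
        )
    return table


def save_word2vec_text(table: EmbeddingTable, path: str | Path, precision: int = 6) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write(f"{len(table)} {table.dimension}\n")
        for tok, vec in table.vectors.items():
            vals = " ".join(f"{v:.{precision}f}" for v in vec)
            fh.write(f"{tok} {vals}\n")


def average_embed(
    table: EmbeddingTable, tokens: Sequence[str], with_flag: bool = False
) -> np.ndarray | tuple[np.ndarray, bool]:
    """Arithmetic mean of token vectors under the table's OOV policy.

    If ``skip_token`` leaves no tokens (or every token is OOV under
    ``zero_vector`` — the mean of zero vectors), the result is the zero
    vector; ``with_flag=True`` additionally returns whether the output was
    forced to zero by OOV handling.
    """
    if len(tokens) == 0:
        raise ValueError("cannot average an empty token sequence")
    vecs = []
    n_oov = 0
    for tok in tokens:
        vec = table.get(tok)
        if vec is None:
            n_oov += 1
            if table.oov_policy == "zero_vector":
                vecs.append(np.zeros(table.dimension))
        else:
            vecs.append(vec)
    all_oov = n_oov == len(tokens)
    if not vecs:
        out = np.zeros(table.dimension)
    else:
        out = np.mean(vecs, axis=0)
    if with_flag:
        return out, all_oov
    return out


def cosine_sim(u: np.ndarray, v: np.ndarray) -> float:
    """Cosine similarity; defined as 0.0 when either vector has zero norm."""
    u = np.asarray(u, dtype=np.float64)
    v = np.asarray(v, dtype=np.float64)
    if u.shape != v.shape:
        raise ValueError(f"dimension mismatch: {u.shape} vs {v.shape}")
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        return 0.0
    return float(np.dot(u, v) / (nu * nv))


@dataclass(frozen=True)
class ScoredCandidate:
    entity: Entity
    score: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.score):
            raise ValueError(f"non-finite score for {self.entity.code.raw}")


class BELIndex:
    """Precomputed, L2-normalized entity matrix for one (table, kb) pair."""

    def __init__(self, table: EmbeddingTable, kb: KnowledgeBase):
        if len(kb) == 0:
            raise ValueError("cannot build a BEL index over an empty knowledge base")
        self.table = table
        self.kb = kb
        mat = np.stack([average_embed(table, ent.tokens) for ent in kb])
        norms = np.linalg.norm(mat, axis=1, keepdims=True)
        norms[norms == 0.0] = 1.0  # zero-norm rows stay zero -> cosine 0
        self._unit = mat / norms
        self._codes = kb.codes()
        # sort order for deterministic ties: ascending raw code
        self._code_rank = np.argsort(np.argsort(self._codes))

    def rank(self, mention_tokens: Sequence[str], n: int) -> list[ScoredCandidate]:
        if n < 1:
            raise ValueError("n must be >= 1")
        mvec = average_embed(self.table, mention_tokens)
        norm = np.linalg.norm(mvec)
        if norm == 0.0:
            scores = np.zeros(len(self._codes))
        else:
            scores = self._unit @ (mvec / norm)
        # descending score, ties by ascending raw code
        order = np.lexsort((self._code_rank, -scores))[: min(n, len(self._codes))]
        return [
            ScoredCandidate(entity=self.kb.entities[i], score=float(scores[i])) for i in order
        ]


def rank_entities(
    table: EmbeddingTable,
    kb: KnowledgeBase,
    mention_tokens: Sequence[str],
    n: int,
    index: BELIndex | None = None,
) -> list[ScoredCandidate]:
    """Top-``n`` entities by cosine to the mention's average embedding.

    Returns the ``min(n, |kb|)`` best candidates in descending score order,
    ties broken by ascending raw code.  Pass a prebuilt :class:`BELIndex` to
    reuse the cached entity matrix across calls.
    """
    if index is None:
        index = BELIndex(table, kb)
    elif index.table is not table or index.kb is not kb:
        raise ValueError("supplied index was built for a different table/kb pair")
    return index.rank(mention_tokens, n)
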