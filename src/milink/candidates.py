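"""MIL data point construction: positive and negative candidate selection.

Positive candidate sets (``E+``) come from the BEL ranking, either as the
plain top-``k`` (*TopK*) or by sweeping the top-``N`` pool and pulling in
whole clusters until ``k`` distinct clusters are covered (*ClusterK*).
Negative sets (``E-``) are sampled uniformly either from the whole KB
(*Random All*) or from the pool minus ``E+`` (*Random TopN* — harder
negatives).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from milink.bel import BELIndex, EmbeddingTable, ScoredCandidate
from milink.kb import KnowledgeBase
from milink.mentions import MentionSpan, TermDictionary, detect_mentions
from milink.tokenize import Tokenizer, char_tokenizer

logger = logging.getLogger(__name__)

POSITIVE_STRATEGIES = ("topk", "clusterk")
NEGATIVE_STRATEGIES = ("random_all", "random_topn")


@dataclass(frozen=True)
class MILDataPoint:
    """One training tuple ``<mention, context, E+, E->`` plus optional gold code."""

    mention: MentionSpan
    context: tuple[str, ...]
    positives: tuple[str, ...]
    negatives: tuple[str, ...]
    gold: str | None = None

    def __post_init__(self) -> None:
        if not self.positives:
            raise ValueError("E+ must be non-empty")
        if set(self.positives) & set(self.negatives):
            raise ValueError("E+ and E- must be disjoint")


@dataclass(frozen=True)
class CandidateConfig:
    positive_strategy: str = "topk"
    negative_strategy: str = "random_topn"
    k: int = 3
    pool_n: int = 20
    seed: int = 0
    #: number of sampled negatives; defaults to ``k`` (the symmetric choice)
    neg_k: int | None = None

    def __post_init__(self) -> None:
        if self.positive_strategy not in POSITIVE_STRATEGIES:
            raise ValueError(f"positive_strategy must be one of {POSITIVE_STRATEGIES}")
        if self.negative_strategy not in NEGATIVE_STRATEGIES:
            raise ValueError(f"negative_strategy must be one of {NEGATIVE_STRATEGIES}")
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.pool_n <= self.k:
            raise ValueError("pool_n must exceed k")
        if self.neg_k is not None and self.neg_k < 1:
            raise ValueError("neg_k must be >= 1")

    @property
    def effective_neg_k(self) -> int:
        return self.k if self.neg_k is None else self.neg_k


def select_positives_topk(ranked: Sequence[ScoredCandidate], k: int) -> list[str]:
    """First ``min(k, |ranked|)`` codes of a descending-score ranking."""
    if not ranked:
        raise ValueError("ranked candidate list is empty")
    if k < 1:
        raise ValueError("k must be >= 1")
    if len(ranked) < k:
        logger.warning("ranked list has %d < k=%d candidates", len(ranked), k)
    return [c.entity.code.raw for c in ranked[:k]]


def select_positives_clusterk(
    pool: Sequence[ScoredCandidate], kb: KnowledgeBase, k: int
) -> list[str]:
    """Sweep the pool by descending score, pulling in whole clusters.

    Each time an entity of a not-yet-covered cluster is reached, it and all
    pool members sharing its cluster key are selected; the sweep stops once
    ``k`` distinct clusters are covered.  If the pool holds fewer than ``k``
    clusters, all pool entities are returned with a warning.
    """
    if not pool:
        raise ValueError("candidate pool is empty")
    if k < 1:
        raise ValueError("k must be >= 1")
    covered: set[str] = set()
    selected: list[str] = []
    chosen: set[str] = set()
    for cand in pool:
        cluster = cand.entity.cluster
        if cluster in covered:
            continue
        covered.add(cluster)
        for mate in pool:
            if mate.entity.cluster == cluster and mate.entity.code.raw not in chosen:
                selected.append(mate.entity.code.raw)
                chosen.add(mate.entity.code.raw)
        if len(covered) >= k:
            break
    if len(covered) < k:
        logger.warning("pool holds only %d clusters < k=%d; returning whole pool", len(covered), k)
    return selected


def select_negatives_random_all(
    kb: KnowledgeBase,
    positives: Sequence[str],
    k: int,
    rng: np.random.Generator | int,
) -> list[str]:
    """``k`` codes sampled uniformly without replacement from KB minus ``E+``."""
    rng = np.random.default_rng(rng) if isinstance(rng, int) else rng
    pos = set(positives)
    eligible = [c for c in kb.codes() if c not in pos]
    if len(eligible) < k:
        raise ValueError(f"only {len(eligible)} entities remain outside E+, need {k}")
    idx = rng.choice(len(eligible), size=k, replace=False)
    return [eligible[i] for i in idx]


def select_negatives_random_topn(
    pool: Sequence[ScoredCandidate],
    positives: Sequence[str],
    k: int,
    rng: np.random.Generator | int,
) -> list[str]:
    """``k`` codes sampled uniformly from pool members not in ``E+``.

    If fewer than ``k`` are eligible, all of them are returned (with a
    warning); an empty eligible set is an error.
    """
    rng = np.random.default_rng(rng) if isinstance(rng, int) else rng
    pos = set(positives)
    eligible = [c.entity.code.raw for c in pool if c.entity.code.raw not in pos]
    if not eligible:
        raise ValueError("candidate pool is entirely contained in E+")
    if len(eligible) < k:
        logger.warning("only %d eligible negatives < k=%d; returning all", len(eligible), k)
        return list(eligible)
    idx = rng.choice(len(eligible), size=k, replace=False)
    return [eligible[i] for i in idx]


@dataclass(frozen=True)
class CorpusSentence:
    """One corpus record: token sequence plus optional gold annotation."""

    sentence_id: str
    tokens: tuple[str, ...]
    gold: str | None = None
    mention_start: int | None = None
    mention_end: int | None = None


def read_corpus(path: str | Path, tokenizer: Tokenizer = char_tokenizer) -> list[CorpusSentence]:
    """Read a JSONL corpus; each record has ``id`` and ``tokens`` or ``text``."""
    path = Path(path)
    sentences = []
    with path.open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            rec = json.loads(line)
            if "tokens" in rec:
                tokens = tuple(rec["tokens"])
            elif "text" in rec:
                tokens = tuple(tokenizer(rec["text"]))
            else:
                raise ValueError(f"{path}:{lineno}: record has neither 'tokens' nor 'text'")
            sentences.append(
                CorpusSentence(
                    sentence_id=str(rec.get("id", lineno)),
                    tokens=tokens,
                    gold=rec.get("gold"),
                    mention_start=rec.get("mention_start"),
                    mention_end=rec.get("mention_end"),
                )
            )
    return sentences


def build_mil_dataset(
    corpus: Iterable[CorpusSentence],
    dictionary: TermDictionary,
    kb: KnowledgeBase,
    table: EmbeddingTable,
    config: CandidateConfig,
    tokenizer: Tokenizer = char_tokenizer,
) -> list[MILDataPoint]:
    """Build MIL data points for every detected mention in the corpus.

    Mentions whose untokenized surface string exactly equals an entity name
    are excluded (they are solvable by plain string match).  The gold code
    is attached when the sentence carries one and the detected span matches
    the annotated span (or the sentence has a single detected mention).
    """
    index = BELIndex(table, kb)
    rng = np.random.default_rng(config.seed)
    entity_names = {ent.name for ent in kb}
    points: list[MILDataPoint] = []
    for sent in corpus:
        spans = detect_mentions(sent.tokens, dictionary, sentence_id=sent.sentence_id)
        for span in spans:
            surface_str = tokenizer.join(span.surface)
            if surface_str in entity_names:
                continue
            try:
                pool = index.rank(span.surface, config.pool_n)
                if config.positive_strategy == "topk":
                    positives = select_positives_topk(pool, config.k)
                else:
                    positives = select_positives_clusterk(pool, kb, config.k)
                if config.negative_strategy == "random_all":
                    negatives = select_negatives_random_all(
                        kb, positives, config.effective_neg_k, rng
                    )
                else:
                    negatives = select_negatives_random_topn(
                        pool, positives, config.effective_neg_k, rng
                    )
            except ValueError as exc:
                raise ValueError(f"sentence {sent.sentence_id}: {exc}") from exc
            gold = None
            if sent.gold is not None:
                annotated = (sent.mention_start, sent.mention_end)
                if annotated == (span.start, span.end) or (
                    sent.mention_start is None and len(spans) == 1
                ):
                    gold = sent.gold
            points.append(
                MILDataPoint(
                    mention=span,
                    context=sent.tokens,
                    positives=tuple(positives),
                    negatives=tuple(negatives),
                    gold=gold,
                )
            )
    return points


def write_mil_dataset(points: Iterable[MILDataPoint], path: str | Path) -> None:
    """Serialize data points to JSONL."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for p in points:
            rec = {
                "sentence_id": p.mention.sentence_id,
                "tokens": list(p.context),
                "mention_start": p.mention.start,
                "mention_end": p.mention.end,
                "positives": list(p.positives),
                "negatives": list(p.negatives),
                "gold": p.gold,
            }
            fh.write(json.dumps(rec, ensure_ascii=False, sort_keys=True) + "\n")


def read_mil_dataset(path: str | Path) -> list[MILDataPoint]:
    path = Path(path)
    points = []
    with path.open(encoding="utf-8") as fh:
        for line in fh:
            if not line.strip():
                continue
            rec = json.loads(line)
            tokens = tuple(rec["tokens"])
            span = MentionSpan(
                sentence_id=str(rec["sentence_id"]),
                start=rec["mention_start"],
                end=rec["mention_end"],
                surface=tokens[rec["mention_start"] : rec["mention_end"]],
            )
            points.append(
                MILDataPoint(
                    mention=span,
                    context=tokens,
                    positives=tuple(rec["positives"]),
                    negatives=tuple(rec["negatives"]),
                    gold=rec.get("gold"),
                )
            )
    return points
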