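"""Synthetic generators for the four framework inputs.

Everything needed to exercise the pipeline without external downloads:

* a toy hierarchical KB whose codes follow the ICD10-like grammar
  (``letter + 2 digits . 2-digit first sub-classification + 1 digit``);
* an embedding table in which cluster-mates are geometrically close
  (per-cluster centroids, within-cluster dispersion set by
  ``cluster_tightness``);
* a term dictionary holding canonical entity names plus noisy colloquial
  variants that never equal an entity name string;
* a gold-labeled sentence corpus embedding those terms, with
  cluster-indicative context tokens injected at rate ``context_signal``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from milink.bel import EmbeddingTable, save_word2vec_text
from milink.candidates import CorpusSentence
from milink.kb import CodeError, Entity, KnowledgeBase, cluster_key, parse_code, save_kb
from milink.mentions import TermDictionary, save_dictionary
from milink.tokenize import whitespace_tokenizer


@dataclass(frozen=True)
class SynthConfig:
    n_categories: int = 2
    clusters_per_category: int = 3
    entities_per_cluster: int = 4
    embed_dim: int = 16
    cluster_tightness: float = 0.3
    variant_rate: float = 0.9
    context_signal: float = 0.9
    n_sentences: int = 2000
    seed: int = 0
    # generator shape knobs
    variants_per_entity: int = 2
    variant_noise: float = 0.6
    #: probability that a variant mention uses the entity's *ambiguous*
    #: surface — a colloquialism shared with a partner entity in a different
    #: cluster, resolvable only from context
    ambiguous_rate: float = 0.7
    #: dispersion of ambiguous-variant vectors around the midpoint of the
    #: two entities they stand for
    ambiguous_noise: float = 0.25
    n_background_tokens: int = 40
    background_per_sentence: tuple[int, int] = (3, 6)
    ctx_tokens_per_cluster: int = 1
    ctx_per_sentence: int = 2

    def __post_init__(self) -> None:
        for name in (
            "n_categories", "clusters_per_category", "entities_per_cluster",
            "embed_dim", "n_sentences", "variants_per_entity",
            "n_background_tokens", "ctx_tokens_per_cluster",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0.0 < self.cluster_tightness <= 1.0):
            raise ValueError("cluster_tightness must be in (0, 1]")
        for name in ("variant_rate", "context_signal", "ambiguous_rate"):
            if not (0.0 <= getattr(self, name) <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")

    @property
    def n_clusters(self) -> int:
        return self.n_categories * self.clusters_per_category

    @property
    def n_entities(self) -> int:
        return self.n_clusters * self.entities_per_cluster


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def generate_kb(config: SynthConfig) -> KnowledgeBase:
    """Deterministic toy KB; codes like ``A00.010`` round-trip to their cluster."""
    if config.n_categories > 26 * 100:
        raise CodeError("n_categories exceeds the code space (26 letters x 100 numbers)")
    if config.clusters_per_category > 100:
        raise CodeError("clusters_per_category exceeds the 2-digit sub-classification space")
    if config.entities_per_cluster > 10:
        raise CodeError("entities_per_cluster exceeds the 1-digit extension space")
    entities = []
    gcid = 0
    for cat_idx in range(config.n_categories):
        category = f"{chr(ord('A') + cat_idx % 26)}{cat_idx // 26:02d}"
        for cl in range(config.clusters_per_category):
            for e in range(config.entities_per_cluster):
                raw = f"{category}.{cl:02d}{e}"
                code = parse_code(raw)
                tokens = (f"sym{gcid}", f"kind{e}")
                entities.append(
                    Entity(
                        code=code,
                        name=whitespace_tokenizer.join(tokens),
                        tokens=tokens,
                        cluster=cluster_key(code),
                    )
                )
            gcid += 1
    return KnowledgeBase(entities)


def _cluster_ids(kb: KnowledgeBase) -> dict[str, int]:
    return {key: i for i, key in enumerate(kb.cluster_index)}


def generate_embeddings(kb: KnowledgeBase, config: SynthConfig) -> EmbeddingTable:
    """Embeddings with per-cluster centroids.

    Tokens tied to a cluster (name heads, variants, context-signal tokens)
    are unit vectors ``unit((1 - t) * centroid + t * noise)`` where
    ``t = cluster_tightness``; as ``t`` approaches 1 the within/between
    cluster separation vanishes.  Variants additionally mix in
    ``variant_noise`` so that surface similarity alone is unreliable.
    """
    rng = np.random.default_rng([config.seed, 1])
    d = config.embed_dim
    t = config.cluster_tightness
    table = EmbeddingTable(d)

    centroids = {key: _unit(rng.standard_normal(d)) for key in kb.cluster_index}

    def near(centroid: np.ndarray, spread: float) -> np.ndarray:
        return _unit((1.0 - spread) * centroid + spread * _unit(rng.standard_normal(d)))

    # shared per-slot "kind" tokens (broad, cluster-independent)
    for e in range(config.entities_per_cluster):
        table[f"kind{e}"] = _unit(rng.standard_normal(d))

    gold_dirs: list[np.ndarray] = []
    gcid = 0
    for key in kb.cluster_index:
        centroid = centroids[key]
        table[f"sym{gcid}"] = near(centroid, t)
        for j in range(config.ctx_tokens_per_cluster):
            table[f"ctx{gcid}_{j}"] = near(centroid, t)
        for e in range(config.entities_per_cluster):
            gold_dir = _unit(table.get(f"sym{gcid}") + table.get(f"kind{e}"))
            gold_dirs.append(gold_dir)
            for v in range(config.variants_per_entity):
                noise = _unit(rng.standard_normal(d))
                table[f"var{gcid}_{e}_{v}"] = _unit(
                    (1.0 - config.variant_noise) * gold_dir + config.variant_noise * noise
                )
        gcid += 1

    # ambiguous colloquialisms: one shared surface per cross-cluster entity
    # pair, embedded near the midpoint of its two referents so that surface
    # similarity alone cannot resolve it; only context can
    for i, j in _ambiguous_pairs(len(kb)):
        mid = _unit(gold_dirs[i] + gold_dirs[j])
        noise = _unit(rng.standard_normal(d))
        table[f"amb{i}"] = _unit(
            (1.0 - config.ambiguous_noise) * mid + config.ambiguous_noise * noise
        )

    for b in range(config.n_background_tokens):
        table[f"bg{b}"] = _unit(rng.standard_normal(d))
    return table


def _ambiguous_pairs(n_entities: int) -> list[tuple[int, int]]:
    """Cross-KB entity pairs sharing an ambiguous surface: (i, i + n/2)."""
    half = n_entities // 2
    return [(i, i + half) for i in range(half)]


def generate_corpus(
    kb: KnowledgeBase, table: EmbeddingTable, config: SynthConfig
) -> tuple[list[CorpusSentence], TermDictionary]:
    """Gold-labeled sentences plus the matching term dictionary.

    Each sentence holds one contiguous mention — the canonical entity name
    with probability ``1 - variant_rate``, otherwise a colloquial variant —
    surrounded by background tokens and, with probability
    ``context_signal``, tokens indicative of the gold entity's cluster.
    """
    rng = np.random.default_rng([config.seed, 2])
    cluster_of = _cluster_ids(kb)

    dictionary = TermDictionary()
    variants: dict[str, list[tuple[str, ...]]] = {}
    for ent in kb:
        dictionary.add(ent.tokens, ent.code.raw)
        gcid = cluster_of[ent.cluster]
        e = int(ent.code.raw[-1])
        ent_variants = [
            (f"var{gcid}_{e}_{v}",) for v in range(config.variants_per_entity)
        ]
        for var in ent_variants:
            dictionary.add(var, ent.code.raw)
        variants[ent.code.raw] = ent_variants

    # ambiguous surfaces have two referents, so they carry no canonical code
    codes = kb.codes()
    ambiguous: dict[str, tuple[str, ...]] = {}
    for i, j in _ambiguous_pairs(len(kb)):
        surface = (f"amb{i}",)
        if surface[0] in table.vectors:
            dictionary.add(surface)
            ambiguous[codes[i]] = surface
            ambiguous[codes[j]] = surface

    entities = list(kb)
    lo, hi = config.background_per_sentence
    sentences: list[CorpusSentence] = []
    for i in range(config.n_sentences):
        ent = entities[rng.integers(len(entities))]
        gcid = cluster_of[ent.cluster]
        if rng.random() < config.variant_rate:
            if ent.code.raw in ambiguous and rng.random() < config.ambiguous_rate:
                mention = ambiguous[ent.code.raw]
            else:
                mention = variants[ent.code.raw][rng.integers(config.variants_per_entity)]
        else:
            mention = ent.tokens
        n_bg = int(rng.integers(lo, hi + 1))
        filler = [f"bg{b}" for b in rng.integers(config.n_background_tokens, size=n_bg)]
        pos = int(rng.integers(len(filler) + 1))
        before, after = filler[:pos], filler[pos:]
        if rng.random() < config.context_signal:
            # cluster-indicative tokens flank the mention, as colloquial
            # qualifiers do ("stomach keeps ...", "... since last night")
            ctx = [
                f"ctx{gcid}_{j}"
                for j in rng.integers(config.ctx_tokens_per_cluster, size=config.ctx_per_sentence)
            ]
            split = int(rng.integers(len(ctx) + 1))
            before = before + ctx[:split]
            after = ctx[split:] + after
            pos = len(before)
        tokens = tuple(before) + mention + tuple(after)
        sentences.append(
            CorpusSentence(
                sentence_id=str(i),
                tokens=tokens,
                gold=ent.code.raw,
                mention_start=pos,
                mention_end=pos + len(mention),
            )
        )
    return sentences, dictionary


@dataclass
class SyntheticData:
    config: SynthConfig
    kb: KnowledgeBase
    table: EmbeddingTable
    corpus: list[CorpusSentence]
    dictionary: TermDictionary


def generate_all(config: SynthConfig) -> SyntheticData:
    """Run the full generator chain for one config."""
    kb = generate_kb(config)
    table = generate_embeddings(kb, config)
    corpus, dictionary = generate_corpus(kb, table, config)
    return SyntheticData(config=config, kb=kb, table=table, corpus=corpus, dictionary=dictionary)


def write_corpus(corpus: list[CorpusSentence], path: str | Path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for sent in corpus:
            rec = {
                "id": sent.sentence_id,
                "tokens": list(sent.tokens),
                "gold": sent.gold,
                "mention_start": sent.mention_start,
                "mention_end": sent.mention_end,
            }
            fh.write(json.dumps(rec, ensure_ascii=False) + "\n")


def write_all(data: SyntheticData, outdir: str | Path) -> dict[str, str]:
    """Emit kb.tsv, embeddings.vec, dict.tsv, corpus.jsonl and a manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    save_kb(data.kb, outdir / "kb.tsv")
    save_word2vec_text(data.table, outdir / "embeddings.vec")
    save_dictionary(data.dictionary, outdir / "dict.tsv", tokenizer=whitespace_tokenizer)
    write_corpus(data.corpus, outdir / "corpus.jsonl")
    manifest = {"seed": data.config.seed, "config": asdict(data.config),
                "n_entities": len(data.kb), "n_sentences": len(data.corpus)}
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return {name: str(outdir / name) for name in
            ("kb.tsv", "embeddings.vec", "dict.tsv", "corpus.jsonl", "manifest.json")}
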