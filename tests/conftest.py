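import numpy as np
import pytest

from milink.bel import EmbeddingTable
from milink.kb import Entity, KnowledgeBase, cluster_key, parse_code
from milink.tokenize import whitespace_tokenizer


def make_entity(code: str, name: str) -> Entity:
    parts = parse_code(code)
    return Entity(
        code=parts,
        name=name,
        tokens=tuple(name.split()),
        cluster=cluster_key(parts),
    )


def make_kb(records: list[tuple[str, str]]) -> KnowledgeBase:
    return KnowledgeBase([make_entity(code, name) for code, name in records])


def random_kb(rng: np.random.Generator, n_entities: int) -> KnowledgeBase:
    """A KB of up to ``n_entities`` with random hierarchical codes."""
    records = {}
    while len(records) < n_entities:
        cat = f"{chr(ord('A') + rng.integers(26))}{rng.integers(100):02d}"
        sub = f"{rng.integers(100):02d}{rng.integers(10)}"
        code = f"{cat}.{sub}"
        records[code] = f"name{len(records)} tok{rng.integers(5)}"
    return make_kb(sorted(records.items()))


def random_table(rng: np.random.Generator, tokens: list[str], dim: int) -> EmbeddingTable:
    return EmbeddingTable(
        dim, vectors={t: rng.standard_normal(dim) for t in tokens}
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_kb() -> KnowledgeBase:
    return make_kb(
        [
            ("R50.800", "fever other"),
            ("R50.801", "fever specified"),
            ("R50.900", "fever unspecified"),
            ("K52.916", "diarrhea common"),
            ("R11.x02", "nausea plain"),
        ]
    )


@pytest.fixture
def tiny_table() -> EmbeddingTable:
    vecs = {
        "fever": [1.0, 0.0, 0.0],
        "other": [0.9, 0.1, 0.0],
        "specified": [0.8, 0.2, 0.0],
        "unspecified": [0.7, 0.3, 0.0],
        "diarrhea": [0.0, 1.0, 0.0],
        "common": [0.1, 0.9, 0.0],
        "nausea": [0.0, 0.0, 1.0],
        "plain": [0.0, 0.1, 0.9],
        "hot": [0.95, 0.05, 0.0],
        "runs": [0.05, 0.95, 0.0],
    }
    return EmbeddingTable(3, vectors={k: np.array(v) for k, v in vecs.items()})
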