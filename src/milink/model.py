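"""The neural entity ranker.

Architecture: every context token is embedded as word-embedding (+)
positional-embedding; a multi-layer bidirectional LSTM encodes the
sentence; the context-mention representation is the concatenation of the
last-layer forward/backward states at the token immediately before the
mention and at the mention's last token.  An entity is the token-average of
its name's word embeddings.  A one-hidden-layer feed-forward network scores
the concatenated pair, and training minimizes the triplet max-margin loss

    sum over points of [ max_{e in E-} s(e,m,c) + margin - max_{e in E+} s(e,m,c) ]_+
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from milink import autograd as ag
from milink.autograd import Tensor, concat
from milink.bel import EmbeddingTable
from milink.candidates import MILDataPoint
from milink.kb import Entity, KnowledgeBase
from milink.mentions import MentionSpan

ACTIVATIONS = ("relu", "tanh")
BOUNDARY_MODES = ("zero", "sentinel")

#: Reserved embedding row for out-of-vocabulary tokens (kept at zero and
#: excluded from updates under the ``zero_vector`` policy).
OOV_ID = 0


@dataclass(frozen=True)
class ModelConfig:
    word_dim: int
    pos_dim: int = 20
    hidden_dim: int = 100
    layers: int = 2
    ffn_hidden: int = 100
    margin: float = 0.1
    max_len: int = 100
    activation: str = "relu"
    boundary_mode: str = "zero"
    finetune_embeddings: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("word_dim", "pos_dim", "hidden_dim", "layers", "ffn_hidden", "max_len"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.margin < 0:
            raise ValueError("margin must be >= 0")
        if self.activation not in ACTIVATIONS:
            raise ValueError(f"activation must be one of {ACTIVATIONS}")
        if self.boundary_mode not in BOUNDARY_MODES:
            raise ValueError(f"boundary_mode must be one of {BOUNDARY_MODES}")


def triplet_margin_loss(
    pos_scores: Sequence[float], neg_scores: Sequence[float], margin: float
) -> float:
    """The per-data-point loss on raw scores: ``[max E- + margin - max E+]_+``."""
    if len(pos_scores) == 0 or len(neg_scores) == 0:
        raise ValueError("both E+ and E- scores must be non-empty")
    return max(max(neg_scores) + margin - max(pos_scores), 0.0)


class LinkingModel:
    """Parameters of the context-mention encoder, entity encoder and scorer."""

    def __init__(self, config: ModelConfig, table: EmbeddingTable):
        if table.dimension != config.word_dim:
            raise ValueError(
                f"word_dim {config.word_dim} does not match embedding dimension {table.dimension}"
            )
        self.config = config
        self.oov_policy = table.oov_policy
        self.pretrained = False
        rng = np.random.default_rng(config.seed)

        # vocabulary: row 0 reserved for OOV, remaining rows sorted for determinism
        self.vocab: dict[str, int] = {}
        emb = [np.zeros(config.word_dim)]
        for tok in sorted(table.vectors):
            self.vocab[tok] = len(emb)
            emb.append(table.vectors[tok])
        self.word_emb = Tensor(np.stack(emb), requires_grad=config.finetune_embeddings)

        def init(*shape):
            bound = 1.0 / np.sqrt(shape[0])
            return Tensor(rng.uniform(-bound, bound, size=shape), requires_grad=True)

        self.pos_emb = init(config.max_len, config.pos_dim)

        h = config.hidden_dim
        self.lstm: list[dict[str, dict[str, Tensor]]] = []
        for layer in range(config.layers):
            in_dim = config.word_dim + config.pos_dim if layer == 0 else 2 * h
            layer_params = {}
            for direction in ("fwd", "bwd"):
                layer_params[direction] = {
                    "Wx": init(in_dim, 4 * h),
                    "Wh": init(h, 4 * h),
                    "b": Tensor(np.zeros(4 * h), requires_grad=True),
                }
            self.lstm.append(layer_params)

        if config.boundary_mode == "sentinel":
            self.sentinel_f = Tensor(rng.uniform(-0.1, 0.1, size=h), requires_grad=True)
            self.sentinel_b = Tensor(rng.uniform(-0.1, 0.1, size=h), requires_grad=True)

        scorer_in = config.word_dim + 4 * h
        self.ffn_W1 = init(scorer_in, config.ffn_hidden)
        self.ffn_b1 = Tensor(np.zeros(config.ffn_hidden), requires_grad=True)
        self.ffn_W2 = init(config.ffn_hidden, 1)
        self.ffn_b2 = Tensor(np.zeros(1), requires_grad=True)

    # -- parameter plumbing ---------------------------------------------

    def parameters(self) -> list[Tensor]:
        params = [self.pos_emb, self.ffn_W1, self.ffn_b1, self.ffn_W2, self.ffn_b2]
        if self.word_emb.requires_grad:
            params.append(self.word_emb)
        if self.config.boundary_mode == "sentinel":
            params += [self.sentinel_f, self.sentinel_b]
        for layer in self.lstm:
            for direction in layer.values():
                params += [direction["Wx"], direction["Wh"], direction["b"]]
        return params

    def zero_grads(self) -> None:
        ag.zero_grads(self.parameters())

    def token_ids(self, tokens: Sequence[str]) -> list[int]:
        """Map tokens to embedding rows under the OOV policy."""
        if self.oov_policy == "skip_token":
            ids = [self.vocab[t] for t in tokens if t in self.vocab]
            return ids if ids else [OOV_ID]
        return [self.vocab.get(t, OOV_ID) for t in tokens]

    # -- encoders --------------------------------------------------------

    def _lstm_direction(
        self, inputs: list[Tensor], mask: np.ndarray, params: dict[str, Tensor], reverse: bool
    ) -> list[Tensor]:
        """Run one LSTM direction over step inputs; padded steps hold state."""
        batch = inputs[0].shape[0]
        h_dim = self.config.hidden_dim
        h = Tensor(np.zeros((batch, h_dim)))
        c = Tensor(np.zeros((batch, h_dim)))
        steps = range(len(inputs) - 1, -1, -1) if reverse else range(len(inputs))
        outputs: list[Tensor | None] = [None] * len(inputs)
        for t in steps:
            gates = inputs[t] @ params["Wx"] + h @ params["Wh"] + params["b"]
            i = gates[:, 0 * h_dim : 1 * h_dim].sigmoid()
            f = gates[:, 1 * h_dim : 2 * h_dim].sigmoid()
            g = gates[:, 2 * h_dim : 3 * h_dim].tanh()
            o = gates[:, 3 * h_dim : 4 * h_dim].sigmoid()
            c_new = f * c + i * g
            h_new = o * c_new.tanh()
            m = Tensor(mask[:, t : t + 1])
            keep = Tensor(1.0 - mask[:, t : t + 1])
            c = m * c_new + keep * c
            h = m * h_new + keep * h
            outputs[t] = h
        return outputs  # type: ignore[return-value]

    def encode_contexts(
        self, contexts: Sequence[Sequence[str]], spans: Sequence[tuple[int, int]]
    ) -> Tensor:
        """Batched context-mention encoding; returns ``(batch, 4*hidden_dim)``.

        For each sample the output is ``[f_(h-1), b_(h-1), f_k, b_k]`` from
        the last BiLSTM layer; a mention starting the sentence gets zeros
        (or the learned sentinel) in the two pre-mention slots.
        """
        batch = len(contexts)
        if batch == 0:
            raise ValueError("empty batch")
        lengths = [len(c) for c in contexts]
        for ctx, (s, e) in zip(contexts, spans):
            if not (0 <= s < e <= len(ctx)):
                raise ValueError(f"mention span [{s}, {e}) out of bounds for length {len(ctx)}")
        T = max(lengths)
        ids = np.full((batch, T), OOV_ID, dtype=np.intp)
        mask = np.zeros((batch, T))
        for j, ctx in enumerate(contexts):
            row = [self.vocab.get(t, OOV_ID) for t in ctx]
            ids[j, : len(row)] = row
            mask[j, : len(row)] = 1.0

        inputs: list[Tensor] = []
        for t in range(T):
            w = self.word_emb.take_rows(ids[:, t])
            p_idx = np.full(batch, min(t, self.config.max_len - 1), dtype=np.intp)
            p = self.pos_emb.take_rows(p_idx)
            inputs.append(concat([w, p], axis=1))

        fwd = bwd = inputs
        for layer_params in self.lstm:
            fwd = self._lstm_direction(inputs, mask, layer_params["fwd"], reverse=False)
            bwd = self._lstm_direction(inputs, mask, layer_params["bwd"], reverse=True)
            inputs = [concat([f, b], axis=1) for f, b in zip(fwd, bwd)]

        # one-hot gather of boundary states across variable time indices
        w_prev = np.zeros((batch, T))
        w_last = np.zeros((batch, T))
        at_start = np.zeros((batch, 1))
        for j, (s, e) in enumerate(spans):
            if s > 0:
                w_prev[j, s - 1] = 1.0
            else:
                at_start[j, 0] = 1.0
            w_last[j, e - 1] = 1.0

        def gather(states: list[Tensor], weights: np.ndarray) -> Tensor:
            acc = Tensor(np.zeros((batch, self.config.hidden_dim)))
            for t in range(T):
                col = weights[:, t : t + 1]
                if col.any():
                    acc = acc + Tensor(col) * states[t]
            return acc

        f_prev = gather(fwd, w_prev)
        b_prev = gather(bwd, w_prev)
        if self.config.boundary_mode == "sentinel":
            f_prev = f_prev + Tensor(at_start) * self.sentinel_f.reshape(1, -1)
            b_prev = b_prev + Tensor(at_start) * self.sentinel_b.reshape(1, -1)
        f_k = gather(fwd, w_last)
        b_k = gather(bwd, w_last)
        return concat([f_prev, b_prev, f_k, b_k], axis=1)

    def encode_entity_batch(self, token_seqs: Sequence[Sequence[str]]) -> Tensor:
        """Token-average entity encoding for a batch; ``(n, word_dim)``."""
        rows = []
        for tokens in token_seqs:
            if len(tokens) == 0:
                raise ValueError("entity name must be non-empty")
            ids = self.token_ids(tokens)
            rows.append(self.word_emb.take_rows(ids).mean(axis=0, keepdims=True))
        return concat(rows, axis=0) if len(rows) > 1 else rows[0]

    def score_pairs(self, ctx: Tensor, ents: Tensor) -> Tensor:
        """FNN score for row-aligned (context-mention, entity) pairs; ``(n, 1)``."""
        x = concat([ents, ctx], axis=1)
        hidden = x @ self.ffn_W1 + self.ffn_b1
        hidden = hidden.relu() if self.config.activation == "relu" else hidden.tanh()
        return hidden @ self.ffn_W2 + self.ffn_b2

    # -- persistence -----------------------------------------------------

    def save(self, prefix: str | Path) -> None:
        """Write ``<prefix>.npz`` (parameters + vocab) and ``<prefix>.json`` (config)."""
        prefix = Path(prefix)
        arrays = {f"param_{i}": p.data for i, p in enumerate(self._all_tensors())}
        arrays["vocab_tokens"] = np.array(list(self.vocab.keys()))
        np.savez(str(prefix) + ".npz", **arrays)
        sidecar = {"config": asdict(self.config), "pretrained": self.pretrained,
                   "oov_policy": self.oov_policy}
        Path(str(prefix) + ".json").write_text(json.dumps(sidecar, indent=2))

    def _all_tensors(self) -> list[Tensor]:
        tensors = [self.word_emb, self.pos_emb, self.ffn_W1, self.ffn_b1, self.ffn_W2, self.ffn_b2]
        if self.config.boundary_mode == "sentinel":
            tensors += [self.sentinel_f, self.sentinel_b]
        for layer in self.lstm:
            for direction in layer.values():
                tensors += [direction["Wx"], direction["Wh"], direction["b"]]
        return tensors

    @classmethod
    def load(cls, prefix: str | Path, table: EmbeddingTable) -> "LinkingModel":
        """Load a checkpoint, validating compatibility with ``table``."""
        prefix = Path(prefix)
        sidecar = json.loads(Path(str(prefix) + ".json").read_text())
        config = ModelConfig(**sidecar["config"])
        if table.dimension != config.word_dim:
            raise ValueError(
                f"checkpoint word_dim {config.word_dim} does not match "
                f"embedding dimension {table.dimension}"
            )
        model = cls(config, table)
        data = np.load(str(prefix) + ".npz", allow_pickle=False)
        saved_vocab = [str(t) for t in data["vocab_tokens"]]
        if saved_vocab != list(model.vocab.keys()):
            raise ValueError("checkpoint vocabulary does not match the supplied embedding file")
        for i, tensor in enumerate(model._all_tensors()):
            arr = data[f"param_{i}"]
            if arr.shape != tensor.data.shape:
                raise ValueError(f"checkpoint parameter {i} has shape {arr.shape}, "
                                 f"expected {tensor.data.shape}")
            tensor.data = arr
        model.pretrained = bool(sidecar["pretrained"])
        model.oov_policy = sidecar["oov_policy"]
        return model


# -- single-sample convenience wrappers (the batched paths above are what
#    training uses; these keep the public per-sample contracts) -----------


def encode_context_mention(
    model: LinkingModel, context: Sequence[str], span: MentionSpan
) -> np.ndarray:
    """Context-mention vector ``[f_(h-1), b_(h-1), f_k, b_k]`` of length 4*hidden."""
    return model.encode_contexts([list(context)], [(span.start, span.end)]).data[0]


def encode_entity(model: LinkingModel, entity: Entity) -> np.ndarray:
    """Token-average embedding of the entity name (length ``word_dim``)."""
    return model.encode_entity_batch([entity.tokens]).data[0]


def score_candidate(
    model: LinkingModel, entity: Entity, context: Sequence[str], span: MentionSpan
) -> float:
    """Scalar compatibility score ``s(e, m, c)``."""
    ctx = model.encode_contexts([list(context)], [(span.start, span.end)])
    ent = model.encode_entity_batch([entity.tokens])
    return float(model.score_pairs(ctx, ent).data[0, 0])


def _batch_loss(
    model: LinkingModel, batch: Sequence[MILDataPoint], kb: KnowledgeBase, margin: float
) -> Tensor:
    """Differentiable total loss over a batch of MIL data points."""
    for p in batch:
        if not p.positives or not p.negatives:
            raise ValueError(f"data point {p.mention.sentence_id} has empty E+ or E-")
    ctx = model.encode_contexts(
        [list(p.context) for p in batch], [(p.mention.start, p.mention.end) for p in batch]
    )
    unique_codes = sorted({c for p in batch for c in (*p.positives, *p.negatives)})
    code_pos = {c: i for i, c in enumerate(unique_codes)}
    ents = model.encode_entity_batch([kb.by_code[c].tokens for c in unique_codes])

    ctx_rows: list[int] = []
    ent_rows: list[int] = []
    slots: list[tuple[list[int], list[int]]] = []
    cursor = 0
    for j, p in enumerate(batch):
        cands = [*p.positives, *p.negatives]
        ctx_rows += [j] * len(cands)
        ent_rows += [code_pos[c] for c in cands]
        pos_idx = list(range(cursor, cursor + len(p.positives)))
        neg_idx = list(range(cursor + len(p.positives), cursor + len(cands)))
        slots.append((pos_idx, neg_idx))
        cursor += len(cands)

    scores = model.score_pairs(ctx.take_rows(ctx_rows), ents.take_rows(ent_rows))
    hinges = []
    for pos_idx, neg_idx in slots:
        max_pos = scores.take_rows(pos_idx).max()
        max_neg = scores.take_rows(neg_idx).max()
        hinges.append((max_neg + margin - max_pos).relu())
    total = hinges[0]
    for h in hinges[1:]:
        total = total + h
    return total


def mil_margin_loss(
    model: LinkingModel,
    batch: Sequence[MILDataPoint],
    kb: KnowledgeBase,
    margin: float | None = None,
) -> float:
    """Total triplet max-margin loss of a batch (non-negative scalar)."""
    if margin is None:
        margin = model.config.margin
    if not batch:
        return 0.0
    return float(_batch_loss(model, batch, kb, margin).data)
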