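"""Two-stage training curriculum, inference ranking and evaluation.

Stage 1 (*pretraining*) fits the ranker to the BEL signal: each data point
carries the BEL top-1 entity as a pseudo-gold singleton ``E+``.  Stage 2
(*MIL training*) continues from the pretrained parameters on data points
with multi-entity positive bags.  Inference ranks the BEL top-``pool_n``
candidates by the model score.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from milink.bel import BELIndex, EmbeddingTable, ScoredCandidate
from milink.candidates import CorpusSentence, MILDataPoint
from milink.kb import KnowledgeBase
from milink.mentions import MentionSpan
from milink.model import LinkingModel, _batch_loss

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TrainConfig:
    batch_size: int = 100
    learning_rate: float = 1e-3
    optimizer: str = "adam"
    margin: float = 0.1
    epochs_pretrain: int = 10
    epochs_mil: int = 10
    seed: int = 0
    patience: int = 3
    #: minimum metric improvement that resets early-stopping patience;
    #: a positive value stops training at the metric's plateau
    min_delta: float = 0.0

    def __post_init__(self) -> None:
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.optimizer != "adam":
            raise ValueError("only the adam optimizer is supported")


@dataclass
class EvaluationReport:
    n_total: int
    n_correct: int
    accuracy: float
    recall_at_n: dict[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_total > 0 and abs(self.accuracy - self.n_correct / self.n_total) > 1e-12:
            raise ValueError("accuracy inconsistent with counts")


@dataclass(frozen=True)
class LabeledMention:
    """One evaluation example: a sentence, a mention span and the gold code."""

    context: tuple[str, ...]
    span: MentionSpan
    gold: str


def labeled_from_corpus(corpus: Iterable[CorpusSentence]) -> list[LabeledMention]:
    """Collect gold-annotated mentions from corpus records that carry spans."""
    labeled = []
    for sent in corpus:
        if sent.gold is None or sent.mention_start is None or sent.mention_end is None:
            continue
        span = MentionSpan(
            sentence_id=sent.sentence_id,
            start=sent.mention_start,
            end=sent.mention_end,
            surface=sent.tokens[sent.mention_start : sent.mention_end],
        )
        labeled.append(LabeledMention(context=sent.tokens, span=span, gold=sent.gold))
    return labeled


class Adam:
    """Adam with bias correction; operates on the model's parameter tensors."""

    def __init__(self, params, lr: float = 1e-3, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            m_hat = self.m[i] / (1 - self.b1**self.t)
            v_hat = self.v[i] / (1 - self.b2**self.t)
            p.data = p.data - self.lr * m_hat / (np.sqrt(v_hat) + self.eps)


def _train_epochs(
    model: LinkingModel,
    dataset: Sequence[MILDataPoint],
    kb: KnowledgeBase,
    config: TrainConfig,
    epochs: int,
    stage: str,
    validation: Sequence[LabeledMention] | None = None,
    table: EmbeddingTable | None = None,
    pool_n: int = 20,
) -> LinkingModel:
    """Shared minibatch loop with patience-based early stopping.

    Stopping watches validation accuracy when a labeled set (plus the BEL
    table) is supplied, otherwise the epoch training loss.  The best
    parameters seen are restored at the end.
    """
    if epochs <= 0:
        return model
    rng = np.random.default_rng(config.seed)
    optimizer = Adam(model.parameters(), lr=config.learning_rate)
    use_val = validation is not None and table is not None and len(validation) > 0
    best_metric = -np.inf
    best_state: list[np.ndarray] | None = None
    stale = 0
    for epoch in range(epochs):
        order = rng.permutation(len(dataset))
        epoch_loss = 0.0
        for lo in range(0, len(order), config.batch_size):
            batch = [dataset[i] for i in order[lo : lo + config.batch_size]]
            model.zero_grads()
            loss = _batch_loss(model, batch, kb, config.margin)
            epoch_loss += float(loss.data)
            loss.backward()
            if model.word_emb.requires_grad and model.word_emb.grad is not None:
                model.word_emb.grad[0] = 0.0  # OOV row stays the zero vector
            optimizer.step()
        if use_val:
            report = evaluate_accuracy(model, validation, kb, table, pool_n=pool_n)
            metric = report.accuracy
        else:
            metric = -epoch_loss
        logger.info(
            "stage=%s epoch=%d loss=%.6f metric=%.6f", stage, epoch, epoch_loss, metric
        )
        if metric > best_metric + max(config.min_delta, 1e-12):
            best_metric = metric
            best_state = [p.data.copy() for p in model.parameters()]
            stale = 0
        else:
            if metric > best_metric:
                best_metric = metric
                best_state = [p.data.copy() for p in model.parameters()]
            stale += 1
            if stale > config.patience:
                logger.info("stage=%s early stop at epoch=%d", stage, epoch)
                break
    if best_state is not None:
        for p, data in zip(model.parameters(), best_state):
            p.data = data
    return model


def pretrain_model(
    model: LinkingModel,
    dataset: Sequence[MILDataPoint],
    kb: KnowledgeBase,
    config: TrainConfig,
    validation: Sequence[LabeledMention] | None = None,
    table: EmbeddingTable | None = None,
) -> LinkingModel:
    """Stage-1 training on BEL pseudo-gold singletons (``|E+| == 1``)."""
    for p in dataset:
        if len(p.positives) != 1:
            raise ValueError(
                f"pretraining requires singleton E+ (BEL top-1 pseudo-gold); "
                f"data point {p.mention.sentence_id} has {len(p.positives)}"
            )
    model = _train_epochs(
        model, dataset, kb, config, config.epochs_pretrain, "pretrain",
        validation=validation, table=table,
    )
    model.pretrained = True
    return model


def train_mil(
    model: LinkingModel,
    dataset: Sequence[MILDataPoint],
    kb: KnowledgeBase,
    config: TrainConfig,
    validation: Sequence[LabeledMention] | None = None,
    table: EmbeddingTable | None = None,
    allow_unpretrained: bool = False,
) -> LinkingModel:
    """Stage-2 MIL training, continuing from a pretrained checkpoint."""
    if not model.pretrained and not allow_unpretrained:
        raise ValueError(
            "model has not been pretrained; pass allow_unpretrained=True to override"
        )
    return _train_epochs(
        model, dataset, kb, config, config.epochs_mil, "mil",
        validation=validation, table=table,
    )


def link_mention(
    model: LinkingModel,
    context: Sequence[str],
    span: MentionSpan,
    kb: KnowledgeBase,
    table: EmbeddingTable,
    pool_n: int = 20,
    index: BELIndex | None = None,
) -> list[ScoredCandidate]:
    """Rank the BEL top-``pool_n`` candidates by the model score.

    Output is descending by model score, ties broken by ascending raw code;
    the first element is the predicted link.
    """
    if len(kb) == 0:
        raise ValueError("empty knowledge base")
    if index is None:
        index = BELIndex(table, kb)
    pool = index.rank(span.surface, pool_n)
    ctx = model.encode_contexts([list(context)], [(span.start, span.end)])
    ents = model.encode_entity_batch([c.entity.tokens for c in pool])
    ctx_rows = ctx.take_rows([0] * len(pool))
    scores = model.score_pairs(ctx_rows, ents).data[:, 0]
    order = sorted(range(len(pool)), key=lambda i: (-scores[i], pool[i].entity.code.raw))
    return [ScoredCandidate(entity=pool[i].entity, score=float(scores[i])) for i in order]


def evaluate_accuracy(
    model: LinkingModel,
    labeled: Sequence[LabeledMention],
    kb: KnowledgeBase,
    table: EmbeddingTable,
    pool_n: int = 20,
) -> EvaluationReport:
    """Top-1 accuracy of the model over a gold-labeled mention set."""
    if not labeled:
        raise ValueError("empty labeled set")
    index = BELIndex(table, kb)
    n_correct = 0
    for ex in labeled:
        if ex.gold not in kb:
            raise ValueError(f"gold code {ex.gold} not in knowledge base")
        ranked = link_mention(model, ex.context, ex.span, kb, table, pool_n, index=index)
        if ranked and ranked[0].entity.code.raw == ex.gold:
            n_correct += 1
    return EvaluationReport(
        n_total=len(labeled),
        n_correct=n_correct,
        accuracy=n_correct / len(labeled),
    )


def bel_top1_agreement(
    model: LinkingModel,
    labeled: Sequence[LabeledMention],
    kb: KnowledgeBase,
    table: EmbeddingTable,
    pool_n: int = 20,
) -> float:
    """Fraction of mentions where the model's top-1 equals the BEL top-1."""
    if not labeled:
        raise ValueError("empty labeled set")
    index = BELIndex(table, kb)
    agree = 0
    for ex in labeled:
        bel_top = index.rank(ex.span.surface, 1)[0].entity.code.raw
        ranked = link_mention(model, ex.context, ex.span, kb, table, pool_n, index=index)
        if ranked[0].entity.code.raw == bel_top:
            agree += 1
    return agree / len(labeled)


def candidate_recall_at_n(
    table: EmbeddingTable,
    kb: KnowledgeBase,
    labeled: Sequence[LabeledMention],
    n_values: Sequence[int],
) -> dict[int, float]:
    """For each N, the fraction of mentions whose gold is in the BEL top-N pool."""
    if any(n < 1 for n in n_values):
        raise ValueError("n_values must be positive")
    if not labeled:
        return {int(n): 0.0 for n in n_values}
    index = BELIndex(table, kb)
    max_n = max(n_values)
    hits = {int(n): 0 for n in n_values}
    for ex in labeled:
        pool = index.rank(ex.span.surface, max_n)
        codes = [c.entity.code.raw for c in pool]
        try:
            rank = codes.index(ex.gold) + 1
        except ValueError:
            rank = max_n + 1
        for n in n_values:
            if rank <= n:
                hits[int(n)] += 1
    return {n: hits[n] / len(labeled) for n in hits}
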