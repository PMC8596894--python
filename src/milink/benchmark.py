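"""End-to-end synthetic benchmark: generate, build datasets, train, evaluate.

Used by the acceptance tests and the acceptance report script to measure
the qualitative effects the framework is built around: the pretrained
ranker converging to BEL, and MIL training improving on it when context
carries signal that surface similarity lacks.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from milink.candidates import CandidateConfig, CorpusSentence, build_mil_dataset
from milink.kb import KnowledgeBase
from milink.model import LinkingModel, ModelConfig
from milink.synthetic import SynthConfig, generate_all
from milink.tokenize import whitespace_tokenizer
from milink.train_eval import (
    LabeledMention,
    TrainConfig,
    bel_top1_agreement,
    candidate_recall_at_n,
    evaluate_accuracy,
    labeled_from_corpus,
    pretrain_model,
    train_mil,
)


def exclude_exact_surfaces(
    labeled: list[LabeledMention], kb: KnowledgeBase, tokenizer=whitespace_tokenizer
) -> list[LabeledMention]:
    """Drop mentions whose surface string equals an entity name verbatim.

    Mirrors the evaluation protocol: exact matches are solvable by plain
    string lookup and are excluded from both training and test sets.
    """
    names = {ent.name for ent in kb}
    return [ex for ex in labeled if tokenizer.join(ex.span.surface) not in names]


@dataclass
class BenchmarkResult:
    seed: int
    bel_accuracy: float
    pretrain_accuracy: float
    mil_accuracy: float
    bel_agreement: float
    n_test: int

    @property
    def mil_gain(self) -> float:
        return self.mil_accuracy - self.pretrain_accuracy


DEFAULT_MODEL = dict(pos_dim=8, hidden_dim=32, layers=2, ffn_hidden=64, max_len=40)


def run_benchmark(
    seed: int,
    synth: SynthConfig | None = None,
    positive_strategy: str = "clusterk",
    k: int = 3,
    pool_n: int = 20,
    epochs_pretrain: int = 5,
    epochs_mil: int = 60,
    pretrain_neg_k: int = 5,
    pretrain_lr: float = 3e-3,
    mil_lr: float = 1.5e-3,
    model_overrides: dict | None = None,
) -> BenchmarkResult:
    """One full pipeline run on a fresh synthetic world.

    The corpus is split 70/15/15 into train/validation/test; exact-surface
    mentions are excluded from evaluation.  Returns BEL, pretrained and
    MIL-trained accuracies on the test split.

    The pretraining stage is deliberately short (the paper's stopping
    criterion is validation accuracy reaching BEL's level, far before the
    margin loss is fully minimized); the MIL stage continues from that
    underfit state with validation-accuracy early stopping and best-state
    restoration.
    """
    synth = replace(synth or SynthConfig(), seed=seed)
    data = generate_all(synth)
    kb, table, corpus, dictionary = data.kb, data.table, data.corpus, data.dictionary

    n = len(corpus)
    n_train, n_val = int(0.7 * n), int(0.15 * n)
    train_sents = corpus[:n_train]
    val_sents = corpus[n_train : n_train + n_val]
    test_sents = corpus[n_train + n_val :]

    labeled_val = exclude_exact_surfaces(labeled_from_corpus(val_sents), kb)
    labeled_test = exclude_exact_surfaces(labeled_from_corpus(test_sents), kb)

    bel_acc = candidate_recall_at_n(table, kb, labeled_test, [1])[1]

    pretrain_cfg = CandidateConfig(
        positive_strategy="topk", negative_strategy="random_topn",
        k=1, pool_n=pool_n, seed=seed, neg_k=pretrain_neg_k,
    )
    mil_cfg = CandidateConfig(
        positive_strategy=positive_strategy, negative_strategy="random_topn",
        k=k, pool_n=pool_n, seed=seed,
    )
    pretrain_data = build_mil_dataset(
        train_sents, dictionary, kb, table, pretrain_cfg, tokenizer=whitespace_tokenizer
    )
    mil_data = build_mil_dataset(
        train_sents, dictionary, kb, table, mil_cfg, tokenizer=whitespace_tokenizer
    )

    model_kwargs = dict(DEFAULT_MODEL)
    if model_overrides:
        model_kwargs.update(model_overrides)
    model = LinkingModel(ModelConfig(word_dim=synth.embed_dim, seed=seed, **model_kwargs), table)

    pre_cfg = TrainConfig(
        seed=seed, epochs_pretrain=epochs_pretrain,
        learning_rate=pretrain_lr, patience=epochs_pretrain,
    )
    model = pretrain_model(model, pretrain_data, kb, pre_cfg)
    pre_report = evaluate_accuracy(model, labeled_test, kb, table, pool_n=pool_n)
    agreement = bel_top1_agreement(model, labeled_test, kb, table, pool_n=pool_n)

    mil_train_cfg = TrainConfig(
        seed=seed, epochs_mil=epochs_mil, learning_rate=mil_lr, patience=10,
    )
    model = train_mil(
        model, mil_data, kb, mil_train_cfg, validation=labeled_val, table=table,
    )
    mil_report = evaluate_accuracy(model, labeled_test, kb, table, pool_n=pool_n)

    return BenchmarkResult(
        seed=seed,
        bel_accuracy=bel_acc,
        pretrain_accuracy=pre_report.accuracy,
        mil_accuracy=mil_report.accuracy,
        bel_agreement=agreement,
        n_test=len(labeled_test),
    )
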