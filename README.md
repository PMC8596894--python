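# milink

Unsupervised medical entity linking with multi-instance learning (MIL).

`milink` links symptom mentions found in colloquial text to entities of an
ICD10-like knowledge base, with no labeled training data:

1. **BEL** (basic entity linking): mentions and entity names are embedded as
   token-average word vectors and matched by cosine similarity.
2. **Mention detection**: greedy longest-match scan against a term
   dictionary.
3. **MIL dataset construction**: for every detected mention, a data point
   `⟨mention, context, E+, E−⟩` is built from the BEL ranking — positive
   candidate bags via *TopK* or *ClusterK* (which exploits the hierarchical
   code structure: entities sharing a category and first sub-classification
   form a cluster), negative bags via *Random All* or *Random TopN* (hard
   negatives from the candidate pool).
4. **Neural ranker**: word + positional embeddings → multi-layer BiLSTM;
   the context-mention representation is the concatenation of the
   forward/backward states at the token before the mention and at its last
   token; entities are token-average embeddings; a one-hidden-layer
   feed-forward network scores each (entity, mention, context) pair.
5. **Training**: the ranker is first pretrained on BEL top-1 pseudo-gold
   singletons, then trained on the MIL bags by minimizing the triplet
   max-margin loss `Σ [max s(E−) + δ − max s(E+)]₊`.

A synthetic data module generates all four inputs (hierarchical KB,
cluster-structured embeddings, dictionary with noisy colloquial variants,
gold-labeled corpus) so the whole pipeline is testable offline.

## Tests

```bash
python -m pytest tests/
```

`tests/test_acceptance.py` contains the acceptance criteria, including the
end-to-end training benchmarks (a few minutes each on one CPU).

## CLI

```bash
# generate a synthetic world (kb.tsv, embeddings.vec, dict.tsv, corpus.jsonl)
milink synth --seed 1 --out data/

# construct MIL data points
milink build-dataset --kb data/kb.tsv --embeddings data/embeddings.vec \
    --dict data/dict.tsv --corpus data/corpus.jsonl \
    --pos clusterk --neg random_topn --k 3 --pool-n 20 --seed 1 \
    --tokenizer whitespace --out mil.jsonl

# stage 1: pretrain on BEL pseudo-gold (k=1 dataset)
milink pretrain --kb data/kb.tsv --embeddings data/embeddings.vec \
    --dataset pre.jsonl --model-out ckpt_pre --epochs 20 --tokenizer whitespace

# stage 2: MIL training from the pretrained checkpoint
milink train --kb data/kb.tsv --embeddings data/embeddings.vec \
    --dataset mil.jsonl --model-in ckpt_pre --model-out ckpt_mil \
    --epochs 30 --tokenizer whitespace

# link, evaluate, and measure candidate-pool recall
milink link --kb data/kb.tsv --embeddings data/embeddings.vec \
    --dict data/dict.tsv --model ckpt_mil --input data/corpus.jsonl \
    --output links.jsonl --tokenizer whitespace
milink eval --kb data/kb.tsv --embeddings data/embeddings.vec \
    --model ckpt_mil --labeled data/corpus.jsonl --tokenizer whitespace
milink recall --kb data/kb.tsv --embeddings data/embeddings.vec \
    --labeled data/corpus.jsonl --n 1,5,10,20 --tokenizer whitespace
```

## Layout

```
src/milink/
  kb.py          code parsing, cluster keys, knowledge base
  bel.py         embedding table, cosine retrieval, BEL index
  mentions.py    term dictionary, longest-match mention detection
  candidates.py  TopK/ClusterK positives, random negatives, MIL dataset
  autograd.py    minimal reverse-mode autodiff (numpy, float64)
  model.py       BiLSTM context-mention encoder, entity encoder, scorer, loss
  train_eval.py  pretraining, MIL training, linking, evaluation, recall@N
  synthetic.py   generators for KB / embeddings / dictionary / corpus
  benchmark.py   end-to-end synthetic benchmark used by acceptance tests
  cli.py         `milink` command group
```
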