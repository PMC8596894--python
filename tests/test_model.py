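import numpy as np
import pytest

from milink.bel import EmbeddingTable, average_embed
from milink.candidates import MILDataPoint
from milink.kb import Entity, cluster_key, parse_code
from milink.mentions import MentionSpan
from milink.model import (
    LinkingModel,
    ModelConfig,
    _batch_loss,
    encode_context_mention,
    encode_entity,
    mil_margin_loss,
    score_candidate,
    triplet_margin_loss,
)

from .conftest import make_kb, random_table


@pytest.fixture
def table(rng):
    tokens = [f"t{i}" for i in range(12)]
    return random_table(rng, tokens, 4)


@pytest.fixture
def config():
    return ModelConfig(word_dim=4, pos_dim=3, hidden_dim=5, layers=2, ffn_hidden=6, seed=7)


@pytest.fixture
def model(config, table):
    return LinkingModel(config, table)


@pytest.fixture
def kb():
    return make_kb(
        [
            ("R50.800", "t0 t1"),
            ("R50.801", "t2"),
            ("K52.916", "t3 t4"),
            ("R11.x02", "t5"),
        ]
    )


def span(start, end, tokens):
    return MentionSpan(sentence_id="s", start=start, end=end, surface=tuple(tokens[start:end]))


class TestEncodeContextMention:
    def test_output_length(self, model):
        ctx = ["t0", "t1", "t2", "t3"]
        vec = encode_context_mention(model, ctx, span(1, 3, ctx))
        assert vec.shape == (4 * model.config.hidden_dim,)

    def test_mention_at_start_zero_boundary(self, model):
        ctx = ["t0", "t1", "t2"]
        vec = encode_context_mention(model, ctx, span(0, 2, ctx))
        h = model.config.hidden_dim
        np.testing.assert_array_equal(vec[: 2 * h], np.zeros(2 * h))
        assert np.any(vec[2 * h :] != 0)

    def test_deterministic(self, model):
        ctx = ["t0", "t4", "t2", "t9"]
        v1 = encode_context_mention(model, ctx, span(2, 4, ctx))
        v2 = encode_context_mention(model, ctx, span(2, 4, ctx))
        np.testing.assert_array_equal(v1, v2)

    def test_out_of_bounds_span(self, model):
        ctx = ["t0", "t1"]
        with pytest.raises(ValueError):
            model.encode_contexts([ctx], [(1, 3)])

    def test_batched_equals_single(self, model):
        ctxs = [["t0", "t1", "t2"], ["t3", "t4", "t5", "t6"], ["t7", "t8"]]
        spans = [(0, 2), (1, 3), (1, 2)]
        batched = model.encode_contexts(ctxs, spans).data
        for j, (ctx, (s, e)) in enumerate(zip(ctxs, spans)):
            single = model.encode_contexts([ctx], [(s, e)]).data[0]
            np.testing.assert_allclose(batched[j], single, atol=1e-12)

    def test_sentinel_boundary_mode(self, table):
        cfg = ModelConfig(
            word_dim=4, pos_dim=2, hidden_dim=3, layers=1, ffn_hidden=4,
            boundary_mode="sentinel", seed=0,
        )
        m = LinkingModel(cfg, table)
        ctx = ["t0", "t1"]
        vec = encode_context_mention(m, ctx, span(0, 1, ctx))
        h = cfg.hidden_dim
        np.testing.assert_array_equal(vec[:h], m.sentinel_f.data)
        np.testing.assert_array_equal(vec[h : 2 * h], m.sentinel_b.data)


class TestEncodeEntity:
    def test_single_token_identity(self, model, table):
        ent = make_kb([("R50.800", "t3")]).entities[0]
        np.testing.assert_allclose(encode_entity(model, ent), table.vectors["t3"])

    def test_two_token_mean(self, config):
        table = EmbeddingTable(4, vectors={"a": [2, 0, 0, 0], "b": [0, 2, 0, 0]})
        m = LinkingModel(config, table)
        ent = Entity(
            code=parse_code("R50.800"), name="a b", tokens=("a", "b"),
            cluster=cluster_key(parse_code("R50.800")),
        )
        np.testing.assert_allclose(encode_entity(m, ent), [1, 1, 0, 0])

    def test_all_oov_zero(self, model):
        ent = Entity(
            code=parse_code("R50.800"), name="zz yy", tokens=("zz", "yy"),
            cluster=cluster_key(parse_code("R50.800")),
        )
        np.testing.assert_array_equal(encode_entity(model, ent), np.zeros(4))

    def test_matches_bel_average_embed(self, model, table, kb):
        # cross-module consistency: same table -> same entity vector
        for ent in kb:
            np.testing.assert_allclose(
                encode_entity(model, ent), average_embed(table, ent.tokens), atol=1e-12
            )


class TestScoreCandidate:
    def test_scalar_output(self, model, kb):
        ctx = ["t0", "t1", "t2"]
        s = score_candidate(model, kb.entities[0], ctx, span(1, 2, ctx))
        assert isinstance(s, float) and np.isfinite(s)

    def test_name_order_free(self, model):
        code = parse_code("R50.800")
        e1 = Entity(code=code, name="t0 t1", tokens=("t0", "t1"), cluster=cluster_key(code))
        e2 = Entity(code=code, name="t1 t0", tokens=("t1", "t0"), cluster=cluster_key(code))
        ctx = ["t2", "t3", "t4"]
        assert score_candidate(model, e1, ctx, span(0, 2, ctx)) == pytest.approx(
            score_candidate(model, e2, ctx, span(0, 2, ctx))
        )

    def test_hand_computed_forward_pass(self):
        """Oracle: replicate the whole forward pass with plain numpy."""
        table = EmbeddingTable(2, vectors={"m": [0.3, -0.2], "c": [0.1, 0.4]})
        cfg = ModelConfig(word_dim=2, pos_dim=1, hidden_dim=2, layers=1, ffn_hidden=2, seed=3)
        m = LinkingModel(cfg, table)
        ctx = ["c", "m"]
        got = score_candidate(m, make_kb([("R50.800", "c")]).entities[0], ctx, span(1, 2, ctx))

        def sigmoid(x):
            return 1 / (1 + np.exp(-x))

        def lstm(xs, p):
            h = np.zeros(2)
            c = np.zeros(2)
            out = []
            for x in xs:
                g = x @ p["Wx"].data + h @ p["Wh"].data + p["b"].data
                i, f, gg, o = g[0:2], g[2:4], g[4:6], g[6:8]
                c = sigmoid(f) * c + sigmoid(i) * np.tanh(gg)
                h = sigmoid(o) * np.tanh(c)
                out.append(h)
            return out

        xs = [
            np.concatenate([table.vectors["c"], m.pos_emb.data[0]]),
            np.concatenate([table.vectors["m"], m.pos_emb.data[1]]),
        ]
        fwd = lstm(xs, m.lstm[0]["fwd"])
        bwd = lstm(xs[::-1], m.lstm[0]["bwd"])[::-1]
        ctx_vec = np.concatenate([fwd[0], bwd[0], fwd[1], bwd[1]])
        ent_vec = table.vectors["c"]
        x = np.concatenate([ent_vec, ctx_vec])
        hidden = np.maximum(x @ m.ffn_W1.data + m.ffn_b1.data, 0.0)
        expected = (hidden @ m.ffn_W2.data + m.ffn_b2.data).item()
        assert got == pytest.approx(expected, rel=1e-12)


class TestTripletMarginLoss:
    def test_satisfied_pair_zero(self):
        assert triplet_margin_loss([0.9], [0.3], 0.1) == pytest.approx(0.0)

    def test_violating_pair(self):
        assert triplet_margin_loss([0.35], [0.3], 0.1) == pytest.approx(0.05)

    def test_max_within_bags(self):
        assert triplet_margin_loss([0.2, 0.6], [0.55, 0.1], 0.1) == pytest.approx(0.05)

    def test_permutation_invariant(self):
        assert triplet_margin_loss([0.6, 0.2], [0.1, 0.55], 0.1) == triplet_margin_loss(
            [0.2, 0.6], [0.55, 0.1], 0.1
        )

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            triplet_margin_loss([], [0.1], 0.1)


def make_point(ctx, s, e, positives, negatives):
    return MILDataPoint(
        mention=MentionSpan(sentence_id="s", start=s, end=e, surface=tuple(ctx[s:e])),
        context=tuple(ctx),
        positives=tuple(positives),
        negatives=tuple(negatives),
    )


class TestMilMarginLoss:
    def test_non_negative(self, model, kb):
        p = make_point(["t0", "t1", "t2"], 0, 2, ["R50.800"], ["K52.916"])
        assert mil_margin_loss(model, [p], kb) >= 0.0

    def test_zero_iff_margin_met(self, model, kb):
        p = make_point(["t0", "t1", "t2"], 0, 2, ["R50.800", "R50.801"], ["K52.916"])
        ctx = model.encode_contexts([list(p.context)], [(0, 2)])
        scores = {
            c: model.score_pairs(
                ctx, model.encode_entity_batch([kb.by_code[c].tokens])
            ).data.item()
            for c in ("R50.800", "R50.801", "K52.916")
        }
        expected = triplet_margin_loss(
            [scores["R50.800"], scores["R50.801"]], [scores["K52.916"]], model.config.margin
        )
        assert mil_margin_loss(model, [p], kb) == pytest.approx(expected, rel=1e-10)

    def test_sums_over_points(self, model, kb):
        p1 = make_point(["t0", "t1"], 0, 1, ["R50.800"], ["K52.916"])
        p2 = make_point(["t2", "t3"], 1, 2, ["R50.801"], ["R11.x02"])
        total = mil_margin_loss(model, [p1, p2], kb)
        assert total == pytest.approx(
            mil_margin_loss(model, [p1], kb) + mil_margin_loss(model, [p2], kb), rel=1e-10
        )

    def test_bag_permutation_invariant(self, model, kb):
        a = make_point(["t0", "t1"], 0, 1, ["R50.800", "R50.801"], ["K52.916", "R11.x02"])
        b = make_point(["t0", "t1"], 0, 1, ["R50.801", "R50.800"], ["R11.x02", "K52.916"])
        assert mil_margin_loss(model, [a], kb) == pytest.approx(
            mil_margin_loss(model, [b], kb), rel=1e-12
        )

    def test_empty_bag_errors(self, model, kb):
        p = make_point(["t0", "t1"], 0, 1, ["R50.800"], [])
        with pytest.raises(ValueError):
            mil_margin_loss(model, [p], kb)

    def test_gradient_check_small_model(self, kb):
        """Finite differences vs backprop through the full loss, 2-dim model."""
        table = EmbeddingTable(
            2, vectors={f"t{i}": [0.1 * i, -0.05 * i] for i in range(6)}
        )
        cfg = ModelConfig(word_dim=2, pos_dim=2, hidden_dim=2, layers=2, ffn_hidden=3,
                          margin=0.5, seed=11)
        m = LinkingModel(cfg, table)
        points = [
            make_point(["t0", "t1", "t2"], 1, 2, ["R50.800"], ["K52.916", "R11.x02"]),
            make_point(["t3", "t4"], 0, 1, ["R50.801", "R50.800"], ["R11.x02"]),
        ]
        loss = _batch_loss(m, points, kb, cfg.margin)
        assert float(loss.data) > 0  # margin 0.5 guarantees active hinges
        m.zero_grads()
        loss.backward()
        eps = 1e-6
        for p_idx, param in enumerate(m.parameters()):
            flat = param.data.reshape(-1)
            for slot in range(0, flat.size, max(1, flat.size // 5)):
                orig = flat[slot]
                flat[slot] = orig + eps
                hi = float(_batch_loss(m, points, kb, cfg.margin).data)
                flat[slot] = orig - eps
                lo = float(_batch_loss(m, points, kb, cfg.margin).data)
                flat[slot] = orig
                num = (hi - lo) / (2 * eps)
                ana = param.grad.reshape(-1)[slot] if param.grad is not None else 0.0
                assert ana == pytest.approx(num, rel=1e-4, abs=1e-7), (p_idx, slot)


class TestCheckpoint:
    def test_round_trip(self, model, table, tmp_path, kb):
        model.pretrained = True
        prefix = tmp_path / "ckpt"
        model.save(prefix)
        loaded = LinkingModel.load(prefix, table)
        assert loaded.pretrained
        ctx = ["t0", "t1", "t2"]
        s = span(0, 2, ctx)
        assert score_candidate(loaded, kb.entities[0], ctx, s) == pytest.approx(
            score_candidate(model, kb.entities[0], ctx, s), rel=1e-12
        )

    def test_dimension_validation(self, model, tmp_path, rng):
        prefix = tmp_path / "ckpt"
        model.save(prefix)
        wrong = random_table(rng, [f"t{i}" for i in range(12)], 7)
        with pytest.raises(ValueError):
            LinkingModel.load(prefix, wrong)

    def test_vocab_validation(self, model, tmp_path, rng):
        prefix = tmp_path / "ckpt"
        model.save(prefix)
        other = random_table(rng, ["completely", "different"], 4)
        with pytest.raises(ValueError):
            LinkingModel.load(prefix, other)


class TestModelConfig:
    def test_margin_non_negative(self):
        with pytest.raises(ValueError):
            ModelConfig(word_dim=4, margin=-0.1)

    def test_dims_positive(self):
        with pytest.raises(ValueError):
            ModelConfig(word_dim=0)

    def test_word_dim_must_match_table(self, table):
        with pytest.raises(ValueError):
            LinkingModel(ModelConfig(word_dim=5), table)
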