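"""Attention correctness, causality, conditioning, and checkpointing."""

import math

import numpy as np
import pytest

import condsmiles as cs
from condsmiles.model import forward_batch
from conftest import naive_multi_head_attention, rand_layer_weights


class TestMultiHeadAttention:
    def test_zero_values_give_zero_output(self):
        rng = np.random.default_rng(0)
        w = rand_layer_weights(rng, 2, 6, 3, 3)
        q = rng.normal(size=(4, 6))
        out = cs.multi_head_attention(q, q, np.zeros((4, 6)), w)
        assert np.allclose(out, 0.0)

    def test_single_head_scalar_oracle(self):
        # softmax(1/sqrt(2), 0) = (0.6698, 0.3302); weighted sum of V = 0.6698
        w = {"Wq": np.eye(2)[None], "Wk": np.eye(2)[None],
             "Wv": np.eye(1)[None], "Wo": np.eye(1)}
        out = cs.multi_head_attention([[1.0, 0.0]], [[1.0, 0.0], [0.0, 1.0]],
                                      [[1.0], [0.0]], w)
        e = math.exp(1.0 / math.sqrt(2.0))
        assert out[0, 0] == pytest.approx(e / (e + 1.0), abs=1e-4)
        assert out[0, 0] == pytest.approx(0.6698, abs=1e-4)

    def test_matches_naive_loop_oracle(self):
        rng = np.random.default_rng(7)
        for trial in range(20):
            n, m = rng.integers(1, 9, size=2)
            h, dk, dv, d = 2, 3, 2, 8
            w = rand_layer_weights(rng, h, d, dk, dv)
            q, k, v = (rng.normal(size=(n, d)), rng.normal(size=(m, d)),
                       rng.normal(size=(m, d)))
            mask = None
            if n == m and trial % 2:
                mask = cs.causal_mask(int(n))
            got = cs.multi_head_attention(q, k, v, w, mask)
            want = naive_multi_head_attention(q, k, v, w, mask)
            assert np.allclose(got, want, atol=1e-6)

    def test_rows_sum_to_one_over_unmasked(self):
        # with V = ones and identity output path, each row returns the
        # attention-weight row sum, which must be exactly 1
        rng = np.random.default_rng(1)
        d = 4
        w = {"Wq": rng.normal(size=(1, d, 2)), "Wk": rng.normal(size=(1, d, 2)),
             "Wv": np.ones((1, 1, 1)), "Wo": np.eye(1)}
        q = rng.normal(size=(5, d))
        out = cs.multi_head_attention(q, q, np.ones((5, 1)), w,
                                      mask=cs.causal_mask(5))
        assert np.allclose(out, 1.0, atol=1e-9)

    def test_masked_positions_get_exactly_zero_weight(self):
        # V selects the masked key: its contribution must vanish identically
        w = {"Wq": np.eye(2)[None], "Wk": np.eye(2)[None],
             "Wv": np.eye(1)[None], "Wo": np.eye(1)}
        out = cs.multi_head_attention([[5.0, 5.0]], [[1.0, 0.0], [9.0, 9.0]],
                                      [[0.0], [1.0]], w,
                                      mask=np.array([[True, False]]))
        assert out[0, 0] == 0.0

    def test_fully_masked_row_is_an_error(self):
        w = {"Wq": np.eye(2)[None], "Wk": np.eye(2)[None],
             "Wv": np.eye(2)[None], "Wo": np.eye(2)}
        with pytest.raises(ValueError, match="masked"):
            cs.multi_head_attention(np.ones((1, 2)), np.ones((2, 2)),
                                    np.ones((2, 2)), w,
                                    mask=np.array([[False, False]]))


class TestCausalMask:
    def test_shapes_and_pattern(self):
        assert cs.causal_mask(1).tolist() == [[True]]
        m = cs.causal_mask(3)
        assert m.sum(axis=1).tolist() == [1, 2, 3]
        assert not m[0, 2]

    def test_invalid_size(self):
        with pytest.raises(ValueError):
            cs.causal_mask(0)


class TestDecoderForward:
    def test_causality_probes(self, tiny_params, tiny_config):
        rng = np.random.default_rng(3)
        V, L = tiny_config.vocab_size, 12
        for _ in range(100):
            seq = rng.integers(3, V, size=L)
            j = int(rng.integers(1, L))
            before = cs.decoder_forward(seq, None, tiny_params)
            seq2 = seq.copy()
            seq2[j] = (seq2[j] - 3 + 1) % (V - 3) + 3
            after = cs.decoder_forward(seq2, None, tiny_params)
            assert np.array_equal(before[:j], after[:j])

    def test_base_mode_equals_reduced_stack_exactly(self, tiny_params):
        seq = [1, 5, 6, 7, 4]
        full = cs.decoder_forward(seq, None, tiny_params)
        reduced = cs.decoder_forward(seq, None, tiny_params,
                                     use_condition_sublayer=False)
        assert np.array_equal(full, reduced)

    def test_zero_memory_condition_sublayer_outputs_zero(self, tiny_params):
        # attention over an all-zero memory is a weighted sum of zeros
        from condsmiles.model import _mha
        from condsmiles._autodiff import Tensor
        z = Tensor(np.random.default_rng(0).normal(size=(1, 4, 64)))
        mem = Tensor(np.zeros((1, 1, 64)))
        out = _mha(z, mem, mem, tiny_params["l0.cond.Wq"],
                   tiny_params["l0.cond.Wk"], tiny_params["l0.cond.Wv"],
                   tiny_params["l0.cond.Wo"], None, 16)
        assert np.all(out.data == 0.0)

    def test_distinct_conditions_change_logits(self, tiny_params):
        seq = [1, 5, 6, 7]
        a = cs.decoder_forward(seq, 0, tiny_params)
        b = cs.decoder_forward(seq, 1, tiny_params)
        assert not np.allclose(a, b)

    def test_condition_out_of_range(self, tiny_params):
        with pytest.raises(ValueError):
            cs.decoder_forward([1, 5], 2, tiny_params)

    def test_token_index_out_of_range(self, tiny_params, tiny_config):
        with pytest.raises(ValueError):
            cs.decoder_forward([1, tiny_config.vocab_size], None, tiny_params)

    def test_sequence_longer_than_max_len(self, tiny_params, tiny_config):
        with pytest.raises(ValueError):
            forward_batch(tiny_params,
                          np.ones((1, tiny_config.max_len + 1), dtype=int),
                          None)


class TestInitAndCheckpoint:
    def test_init_deterministic_and_seed_sensitive(self, tiny_config):
        a = cs.init_params(tiny_config, 42)
        b = cs.init_params(tiny_config, 42)
        c = cs.init_params(tiny_config, 43)
        assert a.allclose(b)
        assert not a.allclose(c)

    def test_init_shapes_match_config(self, tiny_config):
        p = cs.init_params(tiny_config, 0)
        cfg = tiny_config
        assert p["tok_emb"].shape == (cfg.vocab_size, cfg.d_model)
        assert p["cond_emb"].shape == (cfg.n_conditions, cfg.cond_memory_len,
                                       cfg.d_model)
        assert p["l0.self.Wq"].shape == (cfg.n_heads, cfg.d_model, cfg.d_k)
        assert p["l0.self.Wo"].shape == (cfg.n_heads * cfg.d_v, cfg.d_model)
        assert np.all(p["l0.ln1.g"].data == 1.0)
        assert np.all(p["l0.ffn.b1"].data == 0.0)

    def test_checkpoint_roundtrip(self, tiny_params, tmp_path):
        path = tmp_path / "model.npz"
        cs.save_checkpoint(path, tiny_params, meta={"vocab": {"<pad>": 0}})
        loaded, meta = cs.load_checkpoint(path)
        assert loaded.allclose(tiny_params)
        assert loaded.config == tiny_params.config
        assert meta["vocab"] == {"<pad>": 0}

    def test_config_validation(self):
        with pytest.raises(ValueError):
            cs.ModelConfig(vocab_size=0)
        with pytest.raises(ValueError):
            cs.ModelConfig(vocab_size=10, dropout=1.0)
        with pytest.raises(ValueError):
            cs.ModelConfig(vocab_size=10, n_conditions=-1)

    def test_base_only_model_rejects_conditions(self, toy_vocab):
        cfg = cs.ModelConfig.tiny(len(toy_vocab), n_conditions=0)
        p = cs.init_params(cfg, 0)
        with pytest.raises(ValueError):
            cs.decoder_forward([1, 4], 0, p)
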