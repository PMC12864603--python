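"""Tokenizer and xLSTM cells against hand-coded transcripts of the update rules."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from aopfusion import _autodiff as ad
from aopfusion._autodiff import Tensor
from aopfusion.data import AMINO_ACIDS
from aopfusion.nn import rng_for
from aopfusion.sequence import (MAX_LEN, PAD_INDEX, XLSTMConfig,
                                count_sequence_params, encode_sequence,
                                forward_sequence_batch, init_mlstm_state,
                                init_sequence_params, init_slstm_state,
                                lstm_cell_step, make_lstm_cell_params,
                                make_mlstm_cell_params, make_slstm_cell_params,
                                mlstm_step, mlstm_update, slstm_step,
                                slstm_update, tokenize, tokenize_batch)


# ---------------------------------------------------------------------------
# tokenizer
# ---------------------------------------------------------------------------

class TestTokenize:
    def test_alphabetical_mapping_and_padding(self):
        tok = tokenize("ACDE")
        assert tok.values.tolist()[:4] == [0, 1, 2, 3]
        assert all(v == PAD_INDEX for v in tok.values[4:])
        assert len(tok.values) == MAX_LEN and tok.true_length == 4

    def test_full_length_sequence_has_no_padding(self):
        tok = tokenize("Y" * 50)
        assert tok.true_length == 50
        assert set(tok.values.tolist()) == {19}

    def test_unvalidated_character_raises(self):
        with pytest.raises(ValueError, match="X"):
            tokenize("GXG")

    @given(st.lists(st.text(alphabet=AMINO_ACIDS, min_size=2, max_size=50),
                    min_size=2, max_size=10, unique=True))
    def test_injective_on_distinct_sequences(self, seqs):
        vecs = {tuple(tokenize(s).values.tolist()) for s in seqs}
        assert len(vecs) == len(seqs)


# ---------------------------------------------------------------------------
# plain LSTM cell: hand evaluation of the gate equations
# ---------------------------------------------------------------------------

class TestLSTMCell:
    def test_zero_weights_give_half_gates(self, rng):
        params = make_lstm_cell_params(rng, input_dim=2, hidden_dim=3,
                                       forget_bias=0.0)
        for key in params:
            params[key].data[:] = 0.0
        v = np.array([[0.4, -1.2, 2.0]])
        state = lstm_cell_step(params, Tensor(np.zeros((1, 3))), Tensor(v),
                               Tensor(np.zeros((1, 2))))
        np.testing.assert_allclose(state.f.data, 0.5)
        np.testing.assert_allclose(state.i.data, 0.5)
        np.testing.assert_allclose(state.o.data, 0.5)
        np.testing.assert_allclose(state.c_tilde.data, 0.0)
        np.testing.assert_allclose(state.c.data, 0.5 * v)
        np.testing.assert_allclose(state.h.data, 0.5 * np.tanh(0.5 * v))

    def test_saturated_gates_preserve_memory(self, rng):
        params = make_lstm_cell_params(rng, input_dim=2, hidden_dim=3)
        for key in params:
            params[key].data[:] = 0.0
        params["b_f"].data[:] = 30.0     # f ~= 1
        params["b_i"].data[:] = -30.0    # i ~= 0
        c_prev = np.array([[1.0, -0.5, 0.25]])
        state = lstm_cell_step(params, Tensor(np.zeros((1, 3))),
                               Tensor(c_prev), Tensor(np.zeros((1, 2))))
        np.testing.assert_allclose(state.c.data, c_prev, atol=1e-6)

    def test_matches_independent_transcript(self, rng):
        """Random weights, one step, against a from-scratch numpy transcript."""
        d_in, d_h = 3, 4
        params = make_lstm_cell_params(rng, d_in, d_h)
        h_prev = rng.normal(size=(2, d_h))
        c_prev = rng.normal(size=(2, d_h))
        x = rng.normal(size=(2, d_in))
        state = lstm_cell_step(params, Tensor(h_prev), Tensor(c_prev), Tensor(x))

        def sig(v):
            return 1.0 / (1.0 + np.exp(-v))

        hx = np.concatenate([h_prev, x], axis=1)
        f = sig(hx @ params["W_f"].data + params["b_f"].data)
        i = sig(hx @ params["W_i"].data + params["b_i"].data)
        ct = np.tanh(hx @ params["W_c"].data + params["b_c"].data)
        c = f * c_prev + i * ct
        o = sig(hx @ params["W_o"].data + params["b_o"].data)
        h = o * np.tanh(c)
        np.testing.assert_allclose(state.h.data, h, atol=1e-10)
        np.testing.assert_allclose(state.c.data, c, atol=1e-10)

    def test_gates_in_unit_interval(self, rng):
        params = make_lstm_cell_params(rng, 2, 3)
        state = lstm_cell_step(params, Tensor(rng.normal(size=(4, 3))),
                               Tensor(rng.normal(size=(4, 3))),
                               Tensor(rng.normal(size=(4, 2))))
        for gate in (state.f, state.i, state.o):
            assert np.all((gate.data > 0) & (gate.data < 1))
        assert np.all(np.abs(state.c_tilde.data) < 1)


# ---------------------------------------------------------------------------
# sLSTM
# ---------------------------------------------------------------------------

def _consts(*arrays):
    return [Tensor(np.asarray(a, dtype=np.float64)) for a in arrays]


class TestSLSTM:
    def test_zero_preactivations_give_unit_gates(self):
        z = np.zeros((1, 2))
        c, n = _consts(z, z)
        state = slstm_update(c, n, z.copy(), *_consts(z, z, z, z))
        # f = i = e^0 = 1 and m = max(0 + 0, 0) = 0
        assert np.allclose(state.m, 0.0)
        np.testing.assert_allclose(state.n.data, 1.0)  # n = f*0 + i

    def test_stabilizer_takes_max_of_branches(self):
        z = np.zeros((1, 1))
        c, n = _consts(z, z)
        f_pre, i_pre = _consts(np.full((1, 1), 10.0), z)
        state = slstm_update(c, n, z.copy(), f_pre, i_pre, *_consts(z, z))
        assert np.allclose(state.m, 10.0)

    @pytest.mark.parametrize("mag", [40.0, 50.0, 100.0])
    def test_stabilized_finite_at_large_preactivations(self, mag):
        big = np.full((1, 1), mag, dtype=np.float64)
        z = np.zeros((1, 1))
        c, n = _consts(z, z)
        state = slstm_update(c, n, z.copy(), *_consts(big, big,
                                                      np.full((1, 1), 0.3), z))
        assert np.all(np.isfinite(state.h.data))
        assert np.all(np.isfinite(state.c.data))
        # from zero history, c/n = tanh(z) regardless of the huge gates
        assert state.h.data == pytest.approx(0.5 * np.tanh(0.3), abs=1e-12)

    def test_naive_exponential_gate_overflows_where_stabilized_does_not(self):
        with np.errstate(over="ignore"):
            assert not np.isfinite(np.exp(np.float32(100.0)))  # naive i = e^100
        big = np.full((1, 1), 100.0)
        z = np.zeros((1, 1))
        state = slstm_update(*_consts(z, z), z.copy(),
                             *_consts(big, big, z, z))
        assert np.all(np.isfinite(state.h.data))

    def test_matches_unstabilized_reference_chain(self, rng):
        """Three steps with moderate gates equal the naive exponential-gate
        recursion evaluated in float64."""
        d = 3
        c = n = np.zeros((1, d))
        state = slstm_update(*_consts(c, n), np.zeros((1, d)),
                             *_consts(*rng.normal(size=(4, 1, d))))
        c_ref = np.zeros((1, d))
        n_ref = np.zeros((1, d))
        rng2 = np.random.Generator(np.random.PCG64(7))
        state = None
        cur_c, cur_n, cur_m = _consts(c, n) + [np.zeros((1, d))]
        for _ in range(3):
            f_pre, i_pre, z_pre, o_pre = rng2.normal(size=(4, 1, d))
            state = slstm_update(cur_c, cur_n, cur_m,
                                 *_consts(f_pre, i_pre, z_pre, o_pre))
            cur_c, cur_n, cur_m = state.c, state.n, state.m
            c_ref = np.exp(f_pre) * c_ref + np.exp(i_pre) * np.tanh(z_pre)
            n_ref = np.exp(f_pre) * n_ref + np.exp(i_pre)
            h_ref = (1 / (1 + np.exp(-o_pre))) * c_ref / n_ref
        np.testing.assert_allclose(state.h.data, h_ref, atol=1e-10)

    @pytest.mark.parametrize("shift", [-5.0, -1.0, 2.5, 8.0])
    def test_step_invariant_to_common_gate_shift(self, rng, shift):
        """One update from a fixed state: adding the same constant to the
        exponential-gate pre-activations changes neither h, c nor n - the
        shift is absorbed entirely by the stabilizer state."""
        d = 4
        c0 = Tensor(rng.normal(size=(1, d)))
        n0 = Tensor(np.abs(rng.normal(size=(1, d))) + 0.5)
        m0 = rng.normal(size=(1, d))
        f_pre, i_pre, z_pre, o_pre = rng.normal(size=(4, 1, d))
        base = slstm_update(c0, n0, m0, *_consts(f_pre, i_pre, z_pre, o_pre))
        moved = slstm_update(c0, n0, m0, *_consts(f_pre + shift, i_pre + shift,
                                                  z_pre, o_pre))
        np.testing.assert_allclose(base.h.data, moved.h.data, atol=1e-5)
        np.testing.assert_allclose(base.c.data, moved.c.data, atol=1e-5)
        np.testing.assert_allclose(base.m + shift, moved.m, atol=1e-12)

    def test_chain_invariant_to_stabilizer_offset(self, rng):
        """The whole multi-step output sequence is unchanged by an arbitrary
        offset of the initial stabilizer state (the rescaling cancels)."""
        d, steps, offset = 3, 6, 4.0
        gates = rng.normal(size=(steps, 4, 1, d))
        outs = {}
        for label, m_init in (("zero", 0.0), ("offset", offset)):
            cur_c, cur_n = _consts(np.zeros((1, d)), np.zeros((1, d)))
            cur_m = np.full((1, d), m_init)
            hs = []
            for s in range(steps):
                f_pre, i_pre, z_pre, o_pre = gates[s]
                state = slstm_update(cur_c, cur_n, cur_m,
                                     *_consts(f_pre, i_pre, z_pre, o_pre))
                cur_c, cur_n, cur_m = state.c, state.n, state.m
                hs.append(state.h.data)
            outs[label] = np.stack(hs)
        np.testing.assert_allclose(outs["zero"], outs["offset"], atol=1e-5)

    def test_step_rejects_nonfinite_input(self, rng):
        params = make_slstm_cell_params(rng, 2, 3)
        state = init_slstm_state(1, 3)
        with pytest.raises(ValueError, match="non-finite"):
            slstm_step(params, state, Tensor(np.array([[np.nan, 0.0]])))


# ---------------------------------------------------------------------------
# mLSTM
# ---------------------------------------------------------------------------

def _mlstm_inputs(rng, d=3, fill_f=None, fill_i=None):
    shape = (1, 1, d, 1)
    v = Tensor(rng.normal(size=shape))
    k = Tensor(rng.normal(size=shape))
    q = Tensor(rng.normal(size=shape))
    log_f = Tensor(np.full((1, 1, 1, 1), fill_f))
    log_i = Tensor(np.full((1, 1, 1, 1), fill_i))
    return log_f, log_i, v, k, q


class TestMLSTM:
    def test_pure_write_gives_rank_one_memory(self, rng):
        d = 3
        C = Tensor(rng.normal(size=(1, 1, d, d)))
        n = Tensor(rng.normal(size=(1, 1, d, 1)))
        log_f, log_i, v, k, q = _mlstm_inputs(rng, d, fill_f=-1e9, fill_i=0.0)
        state = mlstm_update(C, n, np.zeros((1, 1, 1, 1)), log_f, log_i, v, k, q)
        np.testing.assert_allclose(state.C.data,
                                   v.data @ np.swapaxes(k.data, -1, -2),
                                   atol=1e-10)

    def test_pure_retain_keeps_memory(self, rng):
        d = 3
        C = Tensor(rng.normal(size=(1, 1, d, d)))
        n = Tensor(rng.normal(size=(1, 1, d, 1)))
        log_f, log_i, v, k, q = _mlstm_inputs(rng, d, fill_f=0.0, fill_i=-1e9)
        state = mlstm_update(C, n, np.zeros((1, 1, 1, 1)), log_f, log_i, v, k, q)
        np.testing.assert_allclose(state.C.data, C.data, atol=1e-10)

    def test_two_steps_accumulate_outer_products(self, rng):
        """f = 1 throughout: C_2 must equal v1 k1^T + v2 k2^T exactly."""
        d = 3
        C = Tensor(np.zeros((1, 1, d, d)))
        n = Tensor(np.zeros((1, 1, d, 1)))
        m = np.zeros((1, 1, 1, 1))
        vs, ks, qs = rng.normal(size=(3, 2, 1, 1, d, 1))
        expected = np.zeros((d, d))
        state = None
        for s in range(2):
            state = mlstm_update(C, n, m, Tensor(np.zeros((1, 1, 1, 1))),
                                 Tensor(np.zeros((1, 1, 1, 1))),
                                 Tensor(vs[s]), Tensor(ks[s]), Tensor(qs[s]))
            C, n, m = state.C, state.n, state.m
            expected += (vs[s][0, 0] @ ks[s][0, 0].T)
        np.testing.assert_allclose(state.C.data[0, 0], expected, atol=1e-10)

    def test_step_depends_only_on_carried_state(self, rng):
        """Same parameters, same state, same input: identical output whatever
        happened before (no positional dependence)."""
        params = make_mlstm_cell_params(rng, input_dim=4, inner_dim=4, heads=2)
        x = Tensor(rng.normal(size=(1, 4)))
        s0 = init_mlstm_state(1, heads=2, head_dim=2)
        out_a = mlstm_step(params, s0, x, heads=2)
        s0b = init_mlstm_state(1, heads=2, head_dim=2)
        out_b = mlstm_step(params, s0b, x, heads=2)
        np.testing.assert_array_equal(out_a.h.data, out_b.h.data)


# ---------------------------------------------------------------------------
# full encoder
# ---------------------------------------------------------------------------

SMALL_CONFIG = XLSTMConfig(model_dim=16, heads=2, mlstm_inner=16,
                           slstm_hidden=12)


class TestEncoder:
    def test_output_dimension_is_128_in_reference_config(self):
        config = XLSTMConfig()
        params = init_sequence_params(config, rng_for(0, "t"), dtype=np.float32)
        emb = encode_sequence(config, params, tokenize("GGWYH"))
        assert emb.shape == (128,)
        assert np.all(np.isfinite(emb))

    def test_padding_invariance(self, rng):
        """Junk beyond true_length and longer batch companions do not change
        a record's embedding."""
        params = init_sequence_params(SMALL_CONFIG, rng_for(3, "t"))
        seqs = ["".join(rng.choice(list(AMINO_ACIDS), size=rng.integers(2, 20)))
                for _ in range(10)]
        tokens, lengths = tokenize_batch(seqs)
        solo = forward_sequence_batch(params, SMALL_CONFIG, tokens, lengths).data
        # companion of length 50 forces every position to be computed
        tokens2 = np.vstack([tokens, tokenize("A" * 50).values[None]])
        lengths2 = np.append(lengths, 50)
        tokens2_junk = tokens2.copy()
        for i, L in enumerate(lengths):
            tokens2_junk[i, L:] = (i * 7) % 20  # junk instead of the pad index
        batched = forward_sequence_batch(params, SMALL_CONFIG, tokens2_junk,
                                         lengths2).data[:-1]
        np.testing.assert_allclose(solo, batched, atol=1e-6)

    def test_deterministic_for_fixed_params(self):
        params = init_sequence_params(SMALL_CONFIG, rng_for(5, "t"))
        a = encode_sequence(SMALL_CONFIG, params, tokenize("WYHCG"))
        b = encode_sequence(SMALL_CONFIG, params, tokenize("WYHCG"))
        np.testing.assert_array_equal(a, b)

    def test_parallel_mlstm_block_equals_recurrent_steps(self, rng):
        """The attention-form mLSTM block must reproduce iterating the
        recurrent step exactly (same stabilizer, same normalizer floor)."""
        from aopfusion.nn import layer_norm, linear
        from aopfusion.sequence import _block_params, _run_mlstm_block

        config = SMALL_CONFIG
        params = init_sequence_params(config, rng_for(9, "t"))
        bp = _block_params(params, "block0")
        T, B, d = 6, 2, config.model_dim
        x = Tensor(rng.normal(size=(B, T, d)) * 0.5)
        parallel = _run_mlstm_block(bp, config, x).data

        heads = config.heads
        d_h = config.mlstm_inner // heads
        state = init_mlstm_state(B, heads, d_h)
        outs = []
        for t in range(T):
            x_t = Tensor(x.data[:, t])
            xn = layer_norm(bp, "norm", x_t)
            state = mlstm_step(bp, state, xn, heads)
            o = ad.sigmoid(linear(bp, "Wo", xn))
            h_flat = ad.reshape(ad.transpose(state.h, (0, 1, 2, 3)),
                                (B, config.mlstm_inner))
            outs.append(ad.add(x_t, linear(bp, "Wdown", ad.mul(o, h_flat))).data)
        recurrent = np.stack(outs, axis=1)
        np.testing.assert_allclose(parallel, recurrent, atol=1e-10)

    def test_scalar_one_step_transcript(self):
        """d=1 single-step encoder against a pencil-and-paper evaluation of the
        LSTM-family update rules (one mLSTM block, scalar memory)."""
        config = XLSTMConfig(model_dim=1, n_blocks=1, block_pattern=("mlstm",),
                             heads=1, mlstm_inner=1, slstm_hidden=1)
        params = init_sequence_params(config, rng_for(2, "t"))
        tokens = np.array([[0] + [PAD_INDEX] * 49])
        out = forward_sequence_batch(params, config, tokens,
                                     np.array([1])).data[0, 0]

        p = {k: float(v.data.ravel()[0]) if v.data.size == 1 else v.data
             for k, v in params.items()}
        e = float(params["embed.E"].data[0, 0])
        gamma = float(params["block0.norm.gamma"].data[0])
        beta = float(params["block0.norm.beta"].data[0])
        xn = 0.0 * gamma + beta   # LayerNorm of a single feature: (x-mu)/std = 0
        q = xn * p["block0.Wq.W"] + p["block0.Wq.b"]
        k = (xn * p["block0.Wk.W"] + p["block0.Wk.b"]) * 1.0  # d_h = 1 scale
        v = xn * p["block0.Wv.W"] + p["block0.Wv.b"]
        gates = xn * params["block0.Wif.W"].data[0] + params["block0.Wif.b"].data
        log_i, f_pre = float(gates[0]), float(gates[1])
        log_f = -np.log1p(np.exp(-f_pre))
        m = max(log_f + -np.inf, log_i)   # first step: m = log i
        i_eff = np.exp(log_i - m)
        C = i_eff * v * k
        n = i_eff * k
        h = (C * q) / max(abs(n * q), 1.0)
        o = 1.0 / (1.0 + np.exp(-(xn * p["block0.Wo.W"] + p["block0.Wo.b"])))
        expected = e + (o * h) * p["block0.Wdown.W"] + p["block0.Wdown.b"]
        assert out == pytest.approx(float(expected), abs=1e-10)


class TestParameterCount:
    def test_single_linear_map_counts_weights_plus_bias(self):
        from aopfusion.nn import ParamDict, add_linear, count_params
        params: ParamDict = {}
        add_linear(params, "lin", rng_for(0, "x"), 10, 5)
        assert count_params(params) == 55

    def test_reference_configuration_is_070_million(self):
        config = XLSTMConfig()
        params = init_sequence_params(config, rng_for(0, "t"), dtype=np.float32)
        count = count_sequence_params(config, params)
        assert round(count / 1e6, 2) == 0.70
        assert abs(count - 700_000) <= 5_000

    def test_count_monotone_in_model_dim(self):
        small = XLSTMConfig(model_dim=64, heads=4, mlstm_inner=64,
                            slstm_hidden=64)
        big = XLSTMConfig(model_dim=128, heads=4, mlstm_inner=128,
                          slstm_hidden=128)
        cs = count_sequence_params(small, init_sequence_params(small, rng_for(0, "a")))
        cb = count_sequence_params(big, init_sequence_params(big, rng_for(0, "b")))
        assert cb > cs
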