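"""Peptide tokenization and the xLSTM sequence encoder.

A peptide is tokenized to a fixed-length integer vector (A=0 ... Y=19,
alphabetical; padding symbol 20) and encoded by three residually stacked
recurrent blocks - matrix-memory (mLSTM), scalar exponential-gated (sLSTM),
matrix-memory - followed by a masked mean over the true sequence positions,
yielding a 128-dimensional embedding.

Exponential gates are stabilized in the log domain with the running state

    m_t = max(log f_t + m_{t-1}, log i_t)

so the effectively applied gates exp(log f_t + m_{t-1} - m_t) and
exp(log i_t - m_t) stay bounded; the hidden output, a ratio of two
identically rescaled accumulators, is unchanged by the rescaling.

A plain LSTM cell (sigmoid gates throughout) is provided as the baseline
recurrence the extended cells are measured against.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _autodiff as ad
from ._autodiff import Tensor
from .data import AMINO_ACIDS
from .nn import (ParamDict, add_layer_norm, add_linear, count_params,
                 layer_norm, linear, uniform_init, zeros_init, constant_init)

PAD_INDEX = 20
N_TOKENS = 21
MAX_LEN = 50
TOKEN_TABLE = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

NORMALIZER_FLOOR = 1e-6     # sLSTM normalizer floor (ratio is bounded)
MLSTM_DENOM_FLOOR = 1.0     # mLSTM readout |n.q| floor, bounds the readout


@dataclass(frozen=True)
class TokenVector:
    """Fixed-length integer encoding of one peptide."""

    values: np.ndarray
    true_length: int


@dataclass(frozen=True)
class XLSTMConfig:
    """Reference architecture: 3 blocks, 128-dim output, ~0.70 M parameters.

    ``mlstm_inner`` and ``slstm_hidden`` are the free widths; the defaults
    place the total trainable count at the 0.70 M budget.
    """

    model_dim: int = 128
    n_blocks: int = 3
    block_pattern: tuple[str, ...] = ("mlstm", "slstm", "mlstm")
    heads: int = 4
    mlstm_inner: int = 128
    slstm_hidden: int = 291
    pad_index: int = PAD_INDEX
    max_len: int = MAX_LEN

    def __post_init__(self):
        if len(self.block_pattern) != self.n_blocks:
            raise ValueError("block_pattern length must equal n_blocks")
        if self.mlstm_inner % self.heads:
            raise ValueError("mlstm_inner must be divisible by heads")


# ---------------------------------------------------------------------------
# tokenization
# ---------------------------------------------------------------------------

def tokenize(sequence: str) -> TokenVector:
    """Map a validated peptide to indices 0-19, right-padded with 20 to 50."""
    if not (1 <= len(sequence) <= MAX_LEN):
        raise ValueError(f"sequence length {len(sequence)} outside [1, {MAX_LEN}]")
    try:
        idx = [TOKEN_TABLE[a] for a in sequence]
    except KeyError as err:
        raise ValueError(f"unvalidated residue {err.args[0]!r}") from err
    values = np.full(MAX_LEN, PAD_INDEX, dtype=np.int64)
    values[:len(idx)] = idx
    return TokenVector(values=values, true_length=len(idx))


def tokenize_batch(sequences) -> tuple[np.ndarray, np.ndarray]:
    toks = [tokenize(s) for s in sequences]
    return (np.stack([t.values for t in toks]),
            np.array([t.true_length for t in toks]))


# ---------------------------------------------------------------------------
# plain LSTM baseline cell
# ---------------------------------------------------------------------------

@dataclass
class LSTMCellState:
    h: Tensor
    c: Tensor
    f: Tensor
    i: Tensor
    o: Tensor
    c_tilde: Tensor


def make_lstm_cell_params(rng, input_dim: int, hidden_dim: int,
                          forget_bias: float = 1.0, dtype=np.float64) -> ParamDict:
    params: ParamDict = {}
    for gate in ("f", "i", "c", "o"):
        params[f"W_{gate}"] = uniform_init(rng, (input_dim + hidden_dim, hidden_dim),
                                           dtype=dtype)
        params[f"b_{gate}"] = (constant_init((hidden_dim,), forget_bias, dtype=dtype)
                               if gate == "f" else zeros_init((hidden_dim,), dtype=dtype))
    return params


def lstm_cell_step(params: ParamDict, h_prev: Tensor, c_prev: Tensor,
                   x_t: Tensor) -> LSTMCellState:
    """One classical LSTM step: sigmoid f/i/o gates, tanh candidate."""
    hx = ad.concat([h_prev, x_t], axis=-1)
    f = ad.sigmoid(ad.add(ad.matmul(hx, params["W_f"]), params["b_f"]))
    i = ad.sigmoid(ad.add(ad.matmul(hx, params["W_i"]), params["b_i"]))
    c_tilde = ad.tanh(ad.add(ad.matmul(hx, params["W_c"]), params["b_c"]))
    c = ad.add(ad.mul(f, c_prev), ad.mul(i, c_tilde))
    o = ad.sigmoid(ad.add(ad.matmul(hx, params["W_o"]), params["b_o"]))
    h = ad.mul(o, ad.tanh(c))
    return LSTMCellState(h=h, c=c, f=f, i=i, o=o, c_tilde=c_tilde)


# ---------------------------------------------------------------------------
# sLSTM: scalar memory, exponential gating, log-domain stabilizer
# ---------------------------------------------------------------------------

@dataclass
class SLSTMState:
    h: Tensor
    c: Tensor
    n: Tensor
    m: np.ndarray  # stabilizer, carried outside the autodiff graph


def slstm_update(c_prev: Tensor, n_prev: Tensor, m_prev: np.ndarray,
                 f_pre: Tensor, i_pre: Tensor, z_pre: Tensor,
                 o_pre: Tensor) -> SLSTMState:
    """Stabilized exponential-gate update from raw gate pre-activations.

    f = exp(f_pre), i = exp(i_pre); the applied gates are rescaled by
    m = max(f_pre + m_prev, i_pre) so both stay <= 1 numerically while the
    output h = o * c / n is unchanged (c and n share the rescaling).
    """
    m_new = np.maximum(f_pre.data + m_prev, i_pre.data)
    f_eff = ad.exp(ad.add(f_pre, m_prev - m_new))
    i_eff = ad.exp(ad.add(i_pre, -m_new))
    z = ad.tanh(z_pre)
    c = ad.add(ad.mul(f_eff, c_prev), ad.mul(i_eff, z))
    n = ad.add(ad.mul(f_eff, n_prev), i_eff)
    o = ad.sigmoid(o_pre)
    h = ad.mul(o, ad.mul(c, ad.power(ad.maximum(n, Tensor(np.full_like(n.data,
               NORMALIZER_FLOOR))), -1.0)))
    return SLSTMState(h=h, c=c, n=n, m=m_new)


def make_slstm_cell_params(rng, input_dim: int, hidden_dim: int,
                           dtype=np.float64) -> ParamDict:
    params: ParamDict = {}
    add_linear(params, "Wg", rng, input_dim + hidden_dim, 4 * hidden_dim,
               dtype=dtype)
    return params


def slstm_step(params: ParamDict, state: SLSTMState, x_t: Tensor) -> SLSTMState:
    """One sLSTM step; gate order in the fused projection is (i, f, z, o)."""
    if not np.all(np.isfinite(x_t.data)):
        raise ValueError("non-finite input to slstm_step")
    u = state.h.shape[-1]
    pre = linear(params, "Wg", ad.concat([x_t, state.h], axis=-1))
    i_pre = pre[:, 0 * u:1 * u]
    f_pre = pre[:, 1 * u:2 * u]
    z_pre = pre[:, 2 * u:3 * u]
    o_pre = pre[:, 3 * u:4 * u]
    return slstm_update(state.c, state.n, state.m, f_pre, i_pre, z_pre, o_pre)


def init_slstm_state(batch: int, hidden: int, dtype=np.float64) -> SLSTMState:
    zero = lambda: Tensor(np.zeros((batch, hidden), dtype=dtype))
    return SLSTMState(h=zero(), c=zero(), n=zero(),
                      m=np.zeros((batch, hidden), dtype=dtype))


# ---------------------------------------------------------------------------
# mLSTM: matrix memory with covariance update
# ---------------------------------------------------------------------------

@dataclass
class MLSTMState:
    h: Tensor          # (B, H, d_h, 1) readout
    C: Tensor          # (B, H, d_h, d_h) matrix memory
    n: Tensor          # (B, H, d_h, 1) normalizer
    m: np.ndarray      # (B, H, 1, 1) stabilizer


def mlstm_update(C_prev: Tensor, n_prev: Tensor, m_prev: np.ndarray,
                 log_f: Tensor, log_i: Tensor, v: Tensor, k: Tensor,
                 q: Tensor) -> MLSTMState:
    """Covariance update C = f*C + i*(v k^T) with stabilized gates, then a
    query readout h = C q / max(|n^T q|, floor)."""
    m_new = np.maximum(log_f.data + m_prev, log_i.data)
    f_eff = ad.exp(ad.add(log_f, m_prev - m_new))
    i_eff = ad.exp(ad.add(log_i, -m_new))
    outer = ad.matmul(v, ad.transpose(k, (0, 1, 3, 2)))  # (B,H,dh,dh)
    C = ad.add(ad.mul(f_eff, C_prev), ad.mul(i_eff, outer))
    n = ad.add(ad.mul(f_eff, n_prev), ad.mul(i_eff, k))
    num = ad.matmul(C, q)                                # (B,H,dh,1)
    dot = ad.matmul(ad.transpose(n, (0, 1, 3, 2)), q)    # (B,H,1,1)
    denom = ad.maximum(ad.abs_(dot),
                       Tensor(np.full_like(dot.data, MLSTM_DENOM_FLOOR)))
    h = ad.mul(num, ad.power(denom, -1.0))
    return MLSTMState(h=h, C=C, n=n, m=m_new)


def make_mlstm_cell_params(rng, input_dim: int, inner_dim: int, heads: int,
                           dtype=np.float64) -> ParamDict:
    params: ParamDict = {}
    for name in ("Wq", "Wk", "Wv"):
        add_linear(params, name, rng, input_dim, inner_dim, dtype=dtype)
    add_linear(params, "Wif", rng, input_dim, 2 * heads, dtype=dtype)
    return params


def _mlstm_heads(x: Tensor, heads: int) -> Tensor:
    b, u = x.shape
    return ad.transpose(ad.reshape(x, (b, heads, u // heads, 1)), (0, 1, 2, 3))


def mlstm_step(params: ParamDict, state: MLSTMState, x_t: Tensor,
               heads: int) -> MLSTMState:
    """One mLSTM step; gates depend on the input only (no hidden feedback)."""
    if not np.all(np.isfinite(x_t.data)):
        raise ValueError("non-finite input to mlstm_step")
    d_h = state.C.shape[-1]
    q = _mlstm_heads(linear(params, "Wq", x_t), heads)
    k = ad.mul(_mlstm_heads(linear(params, "Wk", x_t), heads), d_h ** -0.5)
    v = _mlstm_heads(linear(params, "Wv", x_t), heads)
    gates = linear(params, "Wif", x_t)                   # (B, 2H)
    b = x_t.shape[0]
    log_i = ad.reshape(gates[:, :heads], (b, heads, 1, 1))
    log_f = ad.reshape(ad.logsigmoid(gates[:, heads:]), (b, heads, 1, 1))
    return mlstm_update(state.C, state.n, state.m, log_f, log_i, v, k, q)


def init_mlstm_state(batch: int, heads: int, head_dim: int,
                     dtype=np.float64) -> MLSTMState:
    return MLSTMState(
        h=Tensor(np.zeros((batch, heads, head_dim, 1), dtype=dtype)),
        C=Tensor(np.zeros((batch, heads, head_dim, head_dim), dtype=dtype)),
        n=Tensor(np.zeros((batch, heads, head_dim, 1), dtype=dtype)),
        m=np.full((batch, heads, 1, 1), -np.inf, dtype=dtype))


# ---------------------------------------------------------------------------
# stacked encoder
# ---------------------------------------------------------------------------

def init_sequence_params(config: XLSTMConfig, seed_rng,
                         dtype=np.float64) -> ParamDict:
    """All trainable tensors of the encoder, in a flat named dict."""
    d = config.model_dim
    params: ParamDict = {}
    params["embed.E"] = uniform_init(seed_rng, (N_TOKENS, d), scale=0.1,
                                     dtype=dtype)
    for b, kind in enumerate(config.block_pattern):
        prefix = f"block{b}"
        add_layer_norm(params, f"{prefix}.norm", d, dtype=dtype)
        if kind == "mlstm":
            u = config.mlstm_inner
            cell = make_mlstm_cell_params(seed_rng, d, u, config.heads,
                                          dtype=dtype)
            add_linear(params, f"{prefix}.Wo", seed_rng, d, u, dtype=dtype)
            add_linear(params, f"{prefix}.Wdown", seed_rng, u, d, dtype=dtype)
        elif kind == "slstm":
            u = config.slstm_hidden
            cell = make_slstm_cell_params(seed_rng, d, u, dtype=dtype)
            add_linear(params, f"{prefix}.Wdown", seed_rng, u, d, dtype=dtype)
        else:
            raise ValueError(f"unknown block kind {kind!r}")
        for k, v in cell.items():
            params[f"{prefix}.{k}"] = v
    return params


def _block_params(params: ParamDict, prefix: str) -> ParamDict:
    plen = len(prefix) + 1
    return {k[plen:]: v for k, v in params.items() if k.startswith(prefix + ".")}


def _split_heads_time(x: Tensor, heads: int) -> Tensor:
    """(B, T, u) -> (B, heads, T, u // heads)."""
    b, t, u = x.shape
    return ad.transpose(ad.reshape(x, (b, t, heads, u // heads)), (0, 2, 1, 3))


def _run_mlstm_block(bp: ParamDict, config: XLSTMConfig, x: Tensor) -> Tensor:
    """mLSTM block in its parallel form.

    Because the gates depend on the input only, unrolling the stabilized
    covariance recurrence gives the closed form

        h_t = sum_{s<=t} D_{ts} (q_t . k_s) v_s / max(|sum_s D_{ts} q_t . k_s|, eps)
        D_{ts} = exp(log i_s + cumlogf_t - cumlogf_s - m_t),

    with m_t the running maximum that keeps every weight <= 1.  This is
    algebraically identical to iterating :func:`mlstm_step` over time.
    """
    b, t, d = x.shape
    heads = config.heads
    d_h = config.mlstm_inner // heads
    dtype = x.dtype
    xn = layer_norm(bp, "norm", x)
    q = _split_heads_time(linear(bp, "Wq", xn), heads)
    k = ad.mul(_split_heads_time(linear(bp, "Wk", xn), heads), d_h ** -0.5)
    v = _split_heads_time(linear(bp, "Wv", xn), heads)
    gates = linear(bp, "Wif", xn)                       # (B, T, 2H)
    log_i = ad.transpose(ad.reshape(gates[:, :, :heads], (b, t, heads, 1)),
                         (0, 2, 1, 3))                  # (B, H, T, 1)
    log_f = ad.transpose(ad.reshape(ad.logsigmoid(gates[:, :, heads:]),
                                    (b, t, heads, 1)), (0, 2, 1, 3))
    lower = np.tril(np.ones((t, t), dtype=dtype))
    cum_f = ad.matmul(Tensor(lower), log_f)             # inclusive cumsum over time
    bias = ad.add(log_i, ad.mul(cum_f, -1.0))           # b_s = log i_s - cumlogf_s
    m_run = np.maximum.accumulate(bias.data, axis=2)    # stabilizer, detached
    decay_log = ad.add(ad.transpose(bias, (0, 1, 3, 2)), -m_run)  # (B,H,T,T)
    mask = lower[None, None]
    decay = ad.mul(ad.exp(ad.add(ad.mul(decay_log, mask), -60.0 * (1.0 - mask))),
                   mask)
    scores = ad.mul(ad.matmul(q, ad.transpose(k, (0, 1, 3, 2))), decay)
    num = ad.matmul(scores, v)                          # (B, H, T, d_h)
    den = ad.sum_(scores, axis=-1, keepdims=True)
    denom = ad.maximum(ad.abs_(den),
                       Tensor(np.full_like(den.data, MLSTM_DENOM_FLOOR)))
    h = ad.mul(num, ad.power(denom, -1.0))
    h_flat = ad.reshape(ad.transpose(h, (0, 2, 1, 3)), (b, t, config.mlstm_inner))
    o = ad.sigmoid(linear(bp, "Wo", xn))
    return ad.add(x, linear(bp, "Wdown", ad.mul(o, h_flat)))


def _run_slstm_block(bp: ParamDict, config: XLSTMConfig, x: Tensor) -> Tensor:
    b, t, d = x.shape
    u = config.slstm_hidden
    dtype = x.dtype
    xn = layer_norm(bp, "norm", x)
    # split the fused gate weight into input- and recurrent-acting halves so
    # the input part is one big matmul over all positions
    w = bp["Wg.W"]
    pre_x = ad.add(ad.matmul(xn, w[:d, :]), bp["Wg.b"])  # (B, T, 4u)
    w_h = w[d:, :]
    state = init_slstm_state(b, u, dtype=dtype)
    outs = []
    for step in range(t):
        pre = ad.add(pre_x[:, step, :], ad.matmul(state.h, w_h))
        state = slstm_update(state.c, state.n, state.m,
                             pre[:, u:2 * u], pre[:, :u],
                             pre[:, 2 * u:3 * u], pre[:, 3 * u:])
        outs.append(state.h)
    h = ad.stack(outs, axis=1)                           # (B, T, u)
    return ad.add(x, linear(bp, "Wdown", h))


def forward_sequence_batch(params: ParamDict, config: XLSTMConfig,
                           tokens: np.ndarray, lengths: np.ndarray) -> Tensor:
    """Embed, run the block stack, and mean-pool over unmasked positions.

    ``tokens``: (B, 50) int array, ``lengths``: (B,).  Returns (B, 128).
    """
    if np.any(lengths < 1):
        raise ValueError("true_length must be >= 1")
    t_max = int(lengths.max())
    x = ad.gather_rows(params["embed.E"], tokens[:, :t_max])  # (B, T, d)
    for b, kind in enumerate(config.block_pattern):
        bp = _block_params(params, f"block{b}")
        runner = _run_mlstm_block if kind == "mlstm" else _run_slstm_block
        x = runner(bp, config, x)
    dtype = x.dtype
    mask = (np.arange(t_max)[None, :] < lengths[:, None]).astype(dtype)
    pooled = ad.sum_(ad.mul(x, mask[:, :, None]), axis=1)
    return ad.mul(pooled, (1.0 / lengths)[:, None].astype(dtype))


def encode_sequence(config: XLSTMConfig, params: ParamDict,
                    tokens: TokenVector) -> np.ndarray:
    """128-dim embedding of a single tokenized peptide (inference mode)."""
    if tokens.true_length == 0:
        raise ValueError("cannot encode an empty sequence")
    out = forward_sequence_batch(params, config,
                                 tokens.values[None, :],
                                 np.array([tokens.true_length]))
    return out.data[0]


def count_sequence_params(config: XLSTMConfig, params: ParamDict) -> int:
    return count_params(params)
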