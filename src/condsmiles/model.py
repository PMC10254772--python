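"""Conditional decoder-only Transformer for autoregressive SMILES generation.

The decoder is a GPT-style stack in which every layer carries three
sublayers, each wrapped in a residual connection followed by layer
normalization (post-LN):

1. masked multi-head self-attention over the token prefix,
2. multi-head attention whose keys and values are a learned per-condition
   memory ``e_c`` (the "condition memory"); in base/unconditional mode the
   memory is the zero tensor, which makes this sublayer contribute exactly
   zero, so the conditional machinery is removable by construction,
3. a position-wise feed-forward network.

Next-token logits come from a separate output projection. Positions enter
through parameter-free sinusoidal encodings added to the token embeddings.

All attention projections are bias-free; this is what makes zero condition
memory yield an exactly-zero sublayer output rather than a learned offset.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, asdict, field
from functools import lru_cache
from typing import Optional

import numpy as np

from ._autodiff import (Tensor, softmax, layer_norm, relu,
                        embedding_lookup, dropout)

__all__ = ["ModelConfig", "DecoderParams", "causal_mask",
           "multi_head_attention", "decoder_forward", "init_params",
           "save_checkpoint", "load_checkpoint"]


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters of the conditional decoder.

    ``n_conditions == 0`` declares a base-only (unconditional) model.
    ``cond_memory_len`` is the number of memory slots per condition; with
    the default of 1 the condition-attention softmax is degenerate (the
    single key receives weight 1) and the sublayer acts as an additive,
    LN-gated injection of the condition embedding.
    """

    vocab_size: int
    n_layers: int = 8
    n_heads: int = 8
    d_model: int = 256
    d_k: int = 32
    d_v: int = 32
    d_ff: int = 1024
    max_len: int = 100
    n_conditions: int = 0
    cond_memory_len: int = 1
    dropout: float = 0.1

    def __post_init__(self):
        for name in ("vocab_size", "n_layers", "n_heads", "d_model",
                     "d_k", "d_v", "d_ff", "max_len", "cond_memory_len"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive integer")
        if self.n_conditions < 0:
            raise ValueError("n_conditions must be non-negative")
        if not (0.0 <= self.dropout < 1.0):
            raise ValueError("dropout must lie in [0, 1)")

    @classmethod
    def tiny(cls, vocab_size: int, n_conditions: int = 0, **kw) -> "ModelConfig":
        """Desk-scale preset: 2 layers, d_model=64, trains in minutes on CPU."""
        defaults = dict(n_layers=2, n_heads=4, d_model=64, d_k=16, d_v=16,
                        d_ff=256, max_len=48, dropout=0.1)
        defaults.update(kw)
        return cls(vocab_size=vocab_size, n_conditions=n_conditions, **defaults)


class DecoderParams:
    """All learnable tensors of the decoder, keyed by name.

    Layer ``i`` owns ``li.self.*`` and ``li.cond.*`` attention projections
    (stacked per head: ``Wq``/``Wk`` of shape (h, d_model, d_k), ``Wv`` of
    shape (h, d_model, d_v), ``Wo`` of shape (h*d_v, d_model)), layer-norm
    affines ``li.ln{1,2,3}.{g,b}`` and feed-forward weights ``li.ffn.*``.
    Global tensors: ``tok_emb``, ``cond_emb`` (n_conditions, m, d_model),
    output projection ``out.W``/``out.b``.
    """

    def __init__(self, tensors: dict[str, Tensor], config: ModelConfig):
        self.tensors = tensors
        self.config = config

    def __getitem__(self, name: str) -> Tensor:
        return self.tensors[name]

    def named(self):
        return self.tensors.items()

    def zero_grad(self) -> None:
        for t in self.tensors.values():
            t.grad = None

    def copy(self) -> "DecoderParams":
        return DecoderParams(
            {k: Tensor(v.data.copy(), requires_grad=True)
             for k, v in self.tensors.items()},
            self.config,
        )

    def allclose(self, other: "DecoderParams") -> bool:
        return (set(self.tensors) == set(other.tensors)
                and all(np.array_equal(v.data, other.tensors[k].data)
                        for k, v in self.tensors.items()))


def init_params(config: ModelConfig, seed: int) -> DecoderParams:
    """Deterministic scaled-normal initialization (std 0.02, GPT-style).

    Biases and LN offsets start at zero, LN scales at one.
    """
    rng = np.random.default_rng(seed)

    def w(*shape):
        return Tensor(rng.normal(0.0, 0.02, size=shape), requires_grad=True)

    def zeros(*shape):
        return Tensor(np.zeros(shape), requires_grad=True)

    def ones(*shape):
        return Tensor(np.ones(shape), requires_grad=True)

    c = config
    t: dict[str, Tensor] = {"tok_emb": w(c.vocab_size, c.d_model)}
    if c.n_conditions > 0:
        t["cond_emb"] = w(c.n_conditions, c.cond_memory_len, c.d_model)
    for i in range(c.n_layers):
        for sub in ("self", "cond"):
            t[f"l{i}.{sub}.Wq"] = w(c.n_heads, c.d_model, c.d_k)
            t[f"l{i}.{sub}.Wk"] = w(c.n_heads, c.d_model, c.d_k)
            t[f"l{i}.{sub}.Wv"] = w(c.n_heads, c.d_model, c.d_v)
            t[f"l{i}.{sub}.Wo"] = w(c.n_heads * c.d_v, c.d_model)
        for j in (1, 2, 3):
            t[f"l{i}.ln{j}.g"] = ones(c.d_model)
            t[f"l{i}.ln{j}.b"] = zeros(c.d_model)
        t[f"l{i}.ffn.W1"] = w(c.d_model, c.d_ff)
        t[f"l{i}.ffn.b1"] = zeros(c.d_ff)
        t[f"l{i}.ffn.W2"] = w(c.d_ff, c.d_model)
        t[f"l{i}.ffn.b2"] = zeros(c.d_model)
    t["out.W"] = w(c.d_model, c.vocab_size)
    t["out.b"] = zeros(c.vocab_size)
    return DecoderParams(t, config)


def causal_mask(n: int) -> np.ndarray:
    """Boolean (n, n) mask: entry (i, j) is True iff position i may attend to j ≤ i."""
    if n < 1:
        raise ValueError("mask size must be a positive integer")
    return np.tril(np.ones((n, n), dtype=bool))


@lru_cache(maxsize=8)
def _positional_encoding(max_len: int, d_model: int) -> np.ndarray:
    """Sinusoidal positional encodings, shape (max_len, d_model)."""
    pos = np.arange(max_len)[:, None]
    i = np.arange(d_model)[None, :]
    angle = pos / np.power(10000.0, (2 * (i // 2)) / d_model)
    pe = np.where(i % 2 == 0, np.sin(angle), np.cos(angle))
    return pe


def _mha(q: Tensor, k: Tensor, v: Tensor, Wq: Tensor, Wk: Tensor, Wv: Tensor,
         Wo: Tensor, mask: Optional[np.ndarray], d_k: int,
         attn_dropout: float = 0.0, rng: Optional[np.random.Generator] = None
         ) -> Tensor:
    """Scaled dot-product multi-head attention on (..., n, d_model) tensors.

    ``q``/``k``/``v`` have shape (B, n, d) / (B, m, d) / (B, m, d); head
    projections are stacked as (h, d, d_k). A boolean mask (n, m) marks
    positions each query may attend to; masked scores are set to -inf so
    their softmax weight is exactly zero.
    """
    B = q.shape[0]
    n_heads = Wq.shape[0]
    # (B, 1, n, d) @ (h, d, dk) -> (B, h, n, dk)
    qh = q.reshape(B, 1, q.shape[1], q.shape[2]) @ Wq
    kh = k.reshape(B, 1, k.shape[1], k.shape[2]) @ Wk
    vh = v.reshape(B, 1, v.shape[1], v.shape[2]) @ Wv
    scores = (qh @ kh.swapaxes(-1, -2)) * (1.0 / np.sqrt(d_k))
    if mask is not None:
        bias = np.where(mask, 0.0, -np.inf)
        scores = scores + Tensor(bias)
    attn = softmax(scores, axis=-1)
    if attn_dropout > 0.0 and rng is not None:
        attn = dropout(attn, attn_dropout, rng)
    out = attn @ vh                            # (B, h, n, dv)
    out = out.swapaxes(1, 2)                   # (B, n, h, dv)
    out = out.reshape(B, out.shape[1], n_heads * vh.shape[-1])
    return out @ Wo


def multi_head_attention(queries: np.ndarray, keys: np.ndarray,
                         values: np.ndarray, layer_weights: dict,
                         mask: Optional[np.ndarray] = None) -> np.ndarray:
    """Multi-head attention as a plain numpy operation.

    ``layer_weights`` maps ``Wq``/``Wk`` -> (h, d_q, d_k), ``Wv`` ->
    (h, d_v_in, d_v), ``Wo`` -> (h*d_v, d_out). Each head computes
    softmax(Q_i K_i^T / sqrt(d_k)) V_i; head outputs are concatenated and
    projected by ``Wo``. ``mask[i, j]`` True means query i may attend to
    key j; a fully masked query row is an error (its softmax is undefined).
    """
    q = np.asarray(queries, dtype=float)
    k = np.asarray(keys, dtype=float)
    v = np.asarray(values, dtype=float)
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != (q.shape[0], k.shape[0]):
            raise ValueError("mask must have shape (n_queries, n_keys)")
        if not mask.any(axis=1).all():
            raise ValueError("some query has every key masked; softmax undefined")
    Wq = Tensor(layer_weights["Wq"])
    Wk = Tensor(layer_weights["Wk"])
    Wv = Tensor(layer_weights["Wv"])
    Wo = Tensor(layer_weights["Wo"])
    d_k = Wq.shape[-1]
    out = _mha(Tensor(q[None]), Tensor(k[None]), Tensor(v[None]),
               Wq, Wk, Wv, Wo, mask, d_k)
    return out.data[0]


def forward_batch(params: DecoderParams, idx: np.ndarray,
                  cond_ids: Optional[np.ndarray], *, train: bool = False,
                  rng: Optional[np.random.Generator] = None,
                  use_condition_sublayer: bool = True) -> Tensor:
    """Batched decoder forward pass.

    Parameters
    ----------
    idx
        Integer token indices, shape (B, n); PAD (0) allowed as trailing fill.
    cond_ids
        Per-sequence condition indices shape (B,), or None for base mode
        (zero condition memory for the whole batch).
    train
        Enables dropout (requires ``rng``).
    use_condition_sublayer
        When False the condition-attention output is replaced by an exact
        zero, producing the reduced stack LN(z̄ + 0); used to verify that
        base mode and the reduced stack coincide.

    Returns next-token logits as a Tensor of shape (B, n, vocab_size).
    """
    c = params.config
    idx = np.asarray(idx)
    B, n = idx.shape
    if n > c.max_len:
        raise ValueError(f"sequence length {n} exceeds max_len {c.max_len}")
    if idx.min() < 0 or idx.max() >= c.vocab_size:
        raise ValueError("token index out of vocabulary range")
    p = c.dropout if train else 0.0
    if p > 0.0 and rng is None:
        raise ValueError("training-mode forward needs an rng for dropout")

    x = embedding_lookup(params["tok_emb"], idx)
    x = x + Tensor(_positional_encoding(c.max_len, c.d_model)[:n])
    if p > 0.0:
        x = dropout(x, p, rng)

    # self-attention mask: causal AND key-not-PAD (position 0 is always BOS)
    causal = causal_mask(n)
    key_ok = idx != 0
    self_mask = causal[None, None] & key_ok[:, None, None, :]
    self_mask = self_mask | np.eye(n, dtype=bool)[None, None]  # self always visible

    # condition memory (B, m, d): gathered embeddings or exact zeros
    if cond_ids is not None and c.n_conditions == 0:
        raise ValueError("model was built with n_conditions=0; no conditions exist")
    if cond_ids is not None:
        cond_ids = np.asarray(cond_ids)
        if cond_ids.min() < 0 or cond_ids.max() >= c.n_conditions:
            raise ValueError("condition index out of range")
        memory = embedding_lookup(params["cond_emb"], cond_ids)  # (B, m, d)
    else:
        memory = Tensor(np.zeros((B, c.cond_memory_len, c.d_model)))

    def ln(t: Tensor, i: int, j: int) -> Tensor:
        return layer_norm(t) * params[f"l{i}.ln{j}.g"] + params[f"l{i}.ln{j}.b"]

    z = x
    for i in range(c.n_layers):
        a = _mha(z, z, z, params[f"l{i}.self.Wq"], params[f"l{i}.self.Wk"],
                 params[f"l{i}.self.Wv"], params[f"l{i}.self.Wo"],
                 self_mask, c.d_k, attn_dropout=p, rng=rng)
        zbar = ln(z + a, i, 1)
        if use_condition_sublayer:
            cond_out = _mha(zbar, memory, memory, params[f"l{i}.cond.Wq"],
                            params[f"l{i}.cond.Wk"], params[f"l{i}.cond.Wv"],
                            params[f"l{i}.cond.Wo"], None, c.d_k,
                            attn_dropout=p, rng=rng)
        else:
            cond_out = Tensor(np.zeros(zbar.shape))
        zbar2 = ln(zbar + cond_out, i, 2)
        h = relu(zbar2 @ params[f"l{i}.ffn.W1"] + params[f"l{i}.ffn.b1"])
        ffn = h @ params[f"l{i}.ffn.W2"] + params[f"l{i}.ffn.b2"]
        if p > 0.0:
            ffn = dropout(ffn, p, rng)
        z = ln(zbar2 + ffn, i, 3)
    return z @ params["out.W"] + params["out.b"]


def decoder_forward(token_indices, condition_id: Optional[int],
                    params: DecoderParams, config: Optional[ModelConfig] = None,
                    use_condition_sublayer: bool = True) -> np.ndarray:
    """Next-token logits for one sequence; shape (n, vocab_size).

    ``condition_id=None`` runs base mode (zero condition memory). Logits at
    position i depend only on tokens at positions <= i and on the condition
    memory (causality contract).
    """
    if config is not None and config != params.config:
        raise ValueError("config disagrees with the one the params were built for")
    idx = np.asarray(token_indices, dtype=int)[None, :]
    cond = None if condition_id is None else np.array([condition_id])
    logits = forward_batch(params, idx, cond,
                           use_condition_sublayer=use_condition_sublayer)
    return logits.data[0]


# -- checkpoint I/O -----------------------------------------------------------

def save_checkpoint(path, params: DecoderParams, meta: Optional[dict] = None
                    ) -> None:
    """Single-archive checkpoint: config + metadata JSON and named tensors."""
    header = {"config": asdict(params.config), "meta": meta or {}}
    arrays = {f"param/{k}": v.data for k, v in params.named()}
    arrays["__header__"] = np.frombuffer(
        json.dumps(header).encode("utf-8"), dtype=np.uint8)
    with open(path, "wb") as fh:
        np.savez(fh, **arrays)


def load_checkpoint(path) -> tuple[DecoderParams, dict]:
    """Load a checkpoint; validates the shape table against the config."""
    with np.load(path) as z:
        header = json.loads(bytes(z["__header__"]).decode("utf-8"))
        config = ModelConfig(**header["config"])
        tensors = {k[len("param/"):]: Tensor(z[k], requires_grad=True)
                   for k in z.files if k.startswith("param/")}
    expected = {k: v.data.shape for k, v in init_params(config, 0).named()}
    got = {k: v.data.shape for k, v in tensors.items()}
    if expected != got:
        raise ValueError("checkpoint parameter shapes do not match its config")
    return DecoderParams(tensors, config), header["meta"]
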