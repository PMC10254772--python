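"""Autoregressive stochastic sampling of SMILES from a trained decoder.

Generation starts every sequence at BOS and draws the next token from the
temperature-scaled softmax of the model's logits (multinomial sampling;
optional top-k truncation) until EOS or the length cap. Sequences that hit
the cap are kept and validity-checked like any other draw. One random
vector is consumed per step for the whole batch regardless of which
sequences have already finished, so the draw stream — and therefore every
shared prefix — is invariant to the length cap.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .model import DecoderParams, forward_batch
from .smiles_io import BOS_IDX, EOS_IDX, PAD_IDX, canonicalize, INVALID

__all__ = ["GenerationBatch", "sample_next_token", "generate"]

_ARGMAX_TEMPERATURE = 1e-6  # below this, sampling degenerates to argmax


@dataclass
class GenerationBatch:
    """Sampled sequences with decoded SMILES, validity and provenance."""

    raw_smiles: list[str]
    canonical: list[str]
    valid_flags: list[bool]
    condition_id: Optional[int]
    seed: int
    temperature: float

    def __post_init__(self):
        n = len(self.raw_smiles)
        if not (len(self.canonical) == len(self.valid_flags) == n):
            raise ValueError("batch fields must have equal lengths")

    def __len__(self) -> int:
        return len(self.raw_smiles)

    @property
    def valid_smiles(self) -> list[str]:
        """Canonical SMILES of the valid draws, in generation order."""
        return [c for c, ok in zip(self.canonical, self.valid_flags) if ok]

    @property
    def validity(self) -> float:
        return float(np.mean(self.valid_flags)) if self.valid_flags else 0.0


def _softmax(x: np.ndarray) -> np.ndarray:
    e = np.exp(x - x.max(axis=-1, keepdims=True))
    return e / e.sum(axis=-1, keepdims=True)


def sample_next_token(logits: np.ndarray, temperature: float,
                      rng: np.random.Generator, top_k: Optional[int] = None
                      ) -> int:
    """Draw one token index from softmax(logits / temperature).

    Temperatures below 1e-6 select the argmax. ``top_k`` restricts the
    distribution to the k highest logits before renormalization.
    """
    logits = np.asarray(logits, dtype=float)
    if not np.all(np.isfinite(logits)):
        raise ValueError("logits must be finite")
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    if temperature < _ARGMAX_TEMPERATURE:
        return int(np.argmax(logits))
    z = logits / temperature
    if top_k is not None and 0 < top_k < z.size:
        cutoff = np.partition(z, -top_k)[-top_k]
        z = np.where(z >= cutoff, z, -np.inf)
        z = np.where(np.isneginf(z), -1e30, z)
    p = _softmax(z)
    return int(rng.choice(len(p), p=p))


def generate(params: DecoderParams, condition_id: Optional[int], n: int,
             max_len: Optional[int] = None, temperature: float = 1.0,
             seed: int = 0, vocab=None, top_k: Optional[int] = None,
             batch_size: int = 512) -> GenerationBatch:
    """Sample ``n`` SMILES from the decoder under one condition (or base mode).

    Reproducible given (seed, params, condition). ``vocab`` maps indices
    back to tokens and is required to decode the draws.
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    if vocab is None:
        raise ValueError("a Vocabulary is required to decode samples")
    cfg = params.config
    if condition_id is not None and not (0 <= condition_id < cfg.n_conditions):
        raise ValueError(f"condition {condition_id} out of range "
                         f"[0, {cfg.n_conditions})")
    cap = cfg.max_len - 1 if max_len is None else min(max_len, cfg.max_len - 1)
    rng = np.random.default_rng(seed)
    raw: list[str] = []
    for start in range(0, n, batch_size):
        b = min(batch_size, n - start)
        raw.extend(_generate_block(params, condition_id, b, cap,
                                   temperature, rng, vocab, top_k))
    canonical = [canonicalize(s) if s else INVALID for s in raw]
    flags = [c != INVALID for c in canonical]
    return GenerationBatch(raw, canonical, flags, condition_id, seed, temperature)


def _generate_block(params, condition_id, b, cap, temperature, rng, vocab,
                    top_k) -> list[str]:
    cfg = params.config
    seqs = np.full((b, 1), BOS_IDX, dtype=int)
    done = np.zeros(b, dtype=bool)
    cond = None if condition_id is None else np.full(b, condition_id)
    argmax = temperature < _ARGMAX_TEMPERATURE
    for _ in range(cap):
        logits = forward_batch(params, seqs, cond).data[:, -1, :]  # (b, V)
        # never emit PAD or a second BOS
        logits[:, PAD_IDX] = -np.inf
        logits[:, BOS_IDX] = -np.inf
        if argmax:
            nxt = logits.argmax(axis=-1)
        else:
            z = logits / temperature
            if top_k is not None and 0 < top_k < z.shape[1]:
                cutoff = np.partition(z, -top_k, axis=1)[:, -top_k][:, None]
                z = np.where(z >= cutoff, z, -np.inf)
            p = _softmax(np.where(np.isneginf(z), -1e30, z))
            # one uniform per sequence per step, consumed even when finished,
            # so the stream does not depend on the length cap
            u = rng.random(b)
            nxt = (p.cumsum(axis=1) > u[:, None]).argmax(axis=1)
        nxt = np.where(done, PAD_IDX, nxt)
        seqs = np.concatenate([seqs, nxt[:, None]], axis=1)
        done |= nxt == EOS_IDX
        if done.all():
            break
    out = []
    for row in seqs:
        toks = []
        for i in row[1:]:  # skip BOS
            if i in (EOS_IDX, PAD_IDX):
                break
            toks.append(vocab.index_to_token[i])
        out.append("".join(toks))
    return out
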