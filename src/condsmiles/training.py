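"""Next-token pre-training and conditional fine-tuning.

Both stages minimize the sequence negative log-likelihood
``NLL(S | c) = -sum_i ln P(t_i | t_{1:i-1}, c)`` under teacher forcing:
position i of the logits is scored against token i+1 of the BOS...EOS
framed sequence. Pre-training runs in base mode (zero condition memory);
fine-tuning feeds each sequence's target embedding as the condition memory
and, by default, updates all weights (optionally only the condition
embeddings).

The optimizer is Adam with linear learning-rate warmup and global
gradient-norm clipping. Loss reduction within a batch is the mean over
non-PAD token positions, which makes reported NLLs batch-size invariant.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from ._autodiff import Tensor, log_softmax
from .model import DecoderParams, ModelConfig, forward_batch, init_params
from .smiles_io import (MoleculeRecord, Vocabulary, build_vocabulary,
                        tokenize_smiles, PAD_IDX)

__all__ = ["TrainingConfig", "TrainingLog", "sequence_nll", "pretrain",
           "finetune", "mean_corpus_nll", "encode_records"]


@dataclass
class TrainingConfig:
    """Optimization settings (the standard small-GPT recipe by default)."""

    n_epochs: int = 10
    batch_size: int = 64
    learning_rate: float = 3e-4
    warmup_steps: int = 500
    grad_clip: float = 1.0
    beta1: float = 0.9
    beta2: float = 0.999
    adam_eps: float = 1e-8
    valid_fraction: float = 0.1
    seed: int = 0
    embeddings_only: bool = False  # fine-tune only the condition embeddings

    def __post_init__(self):
        if self.n_epochs < 0 or self.batch_size < 1 or self.learning_rate <= 0:
            raise ValueError("invalid training configuration")
        if not (0.0 <= self.valid_fraction < 1.0):
            raise ValueError("valid_fraction must lie in [0, 1)")


@dataclass
class TrainingLog:
    """Per-epoch mean NLL (nats/token) on the train and held-out splits."""

    train_nll: list[float] = field(default_factory=list)
    valid_nll: list[float] = field(default_factory=list)
    epoch_seconds: list[float] = field(default_factory=list)

    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("epoch,train_nll,valid_nll,seconds\n")
            for e, (t, v, s) in enumerate(
                    zip(self.train_nll, self.valid_nll, self.epoch_seconds)):
                fh.write(f"{e},{t:.6f},{v:.6f},{s:.3f}\n")


def sequence_nll(logits: np.ndarray, target_indices: Sequence[int]) -> float:
    """NLL (nats) of one target sequence under per-position logits.

    ``logits[i]`` scores the token that follows position i; PAD targets are
    excluded from the sum. Equals the negative log of the chain-rule
    product of the per-step softmax probabilities.
    """
    logits = np.asarray(logits, dtype=float)
    targets = np.asarray(target_indices, dtype=int)
    if logits.ndim != 2 or logits.shape[0] != targets.shape[0]:
        raise ValueError("logits must be (n, V) aligned with n targets")
    m = logits.max(axis=-1, keepdims=True)
    logp = logits - m - np.log(np.exp(logits - m).sum(axis=-1, keepdims=True))
    keep = targets != PAD_IDX
    return float(-logp[np.arange(len(targets)), targets][keep].sum())


def encode_records(records: Sequence[MoleculeRecord | str], vocab: Vocabulary
                   ) -> list[list[int]]:
    """Tokenize and index each record's SMILES, framed as [BOS, ..., EOS]."""
    out = []
    for r in records:
        s = r if isinstance(r, str) else r.smiles
        try:
            out.append(vocab.encode(tokenize_smiles(s)))
        except KeyError as e:
            raise ValueError(f"vocabulary mismatch for {s!r}: {e}") from None
    return out


def _pad_batch(seqs: list[list[int]], max_len: int
               ) -> tuple[np.ndarray, np.ndarray]:
    """Teacher-forcing batch: inputs seq[:-1], targets seq[1:], PAD-filled."""
    n = min(max(len(s) for s in seqs) - 1, max_len)
    inp = np.full((len(seqs), n), PAD_IDX, dtype=int)
    tgt = np.full((len(seqs), n), PAD_IDX, dtype=int)
    for b, s in enumerate(seqs):
        s = s[:max_len + 1]
        inp[b, :len(s) - 1] = s[:-1]
        tgt[b, :len(s) - 1] = s[1:]
    return inp, tgt


def _batch_loss(params: DecoderParams, inp: np.ndarray, tgt: np.ndarray,
                cond_ids: Optional[np.ndarray], train: bool,
                rng: Optional[np.random.Generator]) -> Tensor:
    logits = forward_batch(params, inp, cond_ids, train=train, rng=rng)
    logp = log_softmax(logits, axis=-1)
    B, n = tgt.shape
    picked = logp[np.arange(B)[:, None], np.arange(n)[None, :], tgt]
    keep = (tgt != PAD_IDX).astype(float)
    return -(picked * Tensor(keep)).sum() / keep.sum()


class _Adam:
    def __init__(self, params: DecoderParams, tcfg: TrainingConfig,
                 trainable: Optional[set[str]] = None):
        self.tcfg = tcfg
        self.trainable = trainable
        self.t = 0
        self.m = {k: np.zeros_like(v.data) for k, v in params.named()}
        self.v = {k: np.zeros_like(v.data) for k, v in params.named()}

    def step(self, params: DecoderParams) -> None:
        c = self.tcfg
        self.t += 1
        lr = c.learning_rate * min(1.0, self.t / max(1, c.warmup_steps))
        # global gradient-norm clip over trainable tensors
        grads = {k: t.grad for k, t in params.named()
                 if t.grad is not None
                 and (self.trainable is None or k in self.trainable)}
        norm = np.sqrt(sum(float((g ** 2).sum()) for g in grads.values()))
        scale = min(1.0, c.grad_clip / (norm + 1e-12))
        for k, g in grads.items():
            g = g * scale
            self.m[k] = c.beta1 * self.m[k] + (1 - c.beta1) * g
            self.v[k] = c.beta2 * self.v[k] + (1 - c.beta2) * g ** 2
            mhat = self.m[k] / (1 - c.beta1 ** self.t)
            vhat = self.v[k] / (1 - c.beta2 ** self.t)
            params[k].data -= lr * mhat / (np.sqrt(vhat) + c.adam_eps)


def mean_corpus_nll(params: DecoderParams, records: Sequence[MoleculeRecord | str],
                    vocab: Vocabulary,
                    cond_ids: Optional[np.ndarray] = None,
                    batch_size: int = 256) -> float:
    """Mean NLL in nats per (non-PAD) token over a corpus, dropout off."""
    seqs = encode_records(records, vocab)
    total, count = 0.0, 0
    for i in range(0, len(seqs), batch_size):
        chunk = seqs[i:i + batch_size]
        inp, tgt = _pad_batch(chunk, params.config.max_len)
        cc = None if cond_ids is None else cond_ids[i:i + batch_size]
        logits = forward_batch(params, inp, cc)
        for b in range(len(chunk)):
            total += sequence_nll(logits.data[b], tgt[b])
        count += int((tgt != PAD_IDX).sum())
    return total / max(count, 1)


def _run_epochs(params: DecoderParams, seqs: list[list[int]],
                cond_ids: Optional[np.ndarray], tcfg: TrainingConfig,
                trainable: Optional[set[str]]) -> TrainingLog:
    rng = np.random.default_rng(tcfg.seed)
    n_valid = int(round(len(seqs) * tcfg.valid_fraction))
    order = rng.permutation(len(seqs))
    valid_idx, train_idx = order[:n_valid], order[n_valid:]
    opt = _Adam(params, tcfg, trainable)
    log = TrainingLog()
    max_len = params.config.max_len

    def eval_split(idx) -> float:
        if len(idx) == 0:
            return float("nan")
        total, count = 0.0, 0
        for i in range(0, len(idx), 256):
            sel = idx[i:i + 256]
            inp, tgt = _pad_batch([seqs[j] for j in sel], max_len)
            cc = None if cond_ids is None else cond_ids[sel]
            logits = forward_batch(params, inp, cc)
            logp = logits.data - logits.data.max(-1, keepdims=True)
            logp = logp - np.log(np.exp(logp).sum(-1, keepdims=True))
            keep = tgt != PAD_IDX
            total += float(-logp[np.arange(tgt.shape[0])[:, None],
                                 np.arange(tgt.shape[1])[None, :], tgt][keep].sum())
            count += int(keep.sum())
        return total / max(count, 1)

    for _ in range(tcfg.n_epochs):
        t0 = time.perf_counter()
        perm = rng.permutation(train_idx)
        losses = []
        for i in range(0, len(perm), tcfg.batch_size):
            sel = perm[i:i + tcfg.batch_size]
            inp, tgt = _pad_batch([seqs[j] for j in sel], max_len)
            cc = None if cond_ids is None else cond_ids[sel]
            params.zero_grad()
            loss = _batch_loss(params, inp, tgt, cc, train=True, rng=rng)
            loss.backward()
            opt.step(params)
            losses.append(float(loss.data))
        log.train_nll.append(float(np.mean(losses)) if losses else float("nan"))
        log.valid_nll.append(eval_split(valid_idx))
        log.epoch_seconds.append(time.perf_counter() - t0)
    return log


def pretrain(corpus: Sequence[MoleculeRecord | str], config: ModelConfig,
             tcfg: TrainingConfig, vocab: Optional[Vocabulary] = None,
             params: Optional[DecoderParams] = None
             ) -> tuple[DecoderParams, TrainingLog]:
    """Unsupervised next-token pre-training in base mode (zero memory).

    Builds the vocabulary from the corpus when not supplied; the config's
    vocab_size must match. Deterministic given ``tcfg.seed``.
    """
    corpus = list(corpus)
    if not corpus:
        raise ValueError("cannot pretrain on an empty corpus")
    if vocab is None:
        vocab = build_vocabulary(
            [r if isinstance(r, str) else r.smiles for r in corpus])
    if config.vocab_size != len(vocab):
        raise ValueError(
            f"config.vocab_size={config.vocab_size} but vocabulary has "
            f"{len(vocab)} tokens")
    seqs = encode_records(corpus, vocab)
    if params is None:
        params = init_params(config, tcfg.seed)
    log = _run_epochs(params, seqs, None, tcfg, trainable=None)
    return params, log


def finetune(base: DecoderParams,
             pairs: Sequence[MoleculeRecord], tcfg: TrainingConfig,
             vocab: Vocabulary,
             condition_labels: Optional[Sequence[str]] = None
             ) -> tuple[DecoderParams, TrainingLog, list[str]]:
    """Conditional fine-tuning on <compound, target> pairs.

    Starts from a copy of ``base``; each sequence is trained with its
    target's embedding as the condition memory. ``condition_labels`` fixes
    the label -> condition-index mapping (sorted unique labels when
    omitted); every pair's target_id must be a known label. Returns the
    tuned parameters, the log, and the label order used.
    """
    pairs = list(pairs)
    if not pairs:
        raise ValueError("cannot fine-tune on an empty pair set")
    if any(r.target_id is None for r in pairs):
        raise ValueError("every fine-tuning record needs a target_id")
    if condition_labels is None:
        condition_labels = sorted({r.target_id for r in pairs})
    label_to_idx = {lab: i for i, lab in enumerate(condition_labels)}
    unknown = {r.target_id for r in pairs} - set(label_to_idx)
    if unknown:
        raise ValueError(f"unknown target_id(s): {sorted(unknown)}")
    cfg = base.config
    if cfg.n_conditions < len(condition_labels):
        raise ValueError(
            f"model supports {cfg.n_conditions} conditions but "
            f"{len(condition_labels)} labels were given")
    params = base.copy()
    cond_ids = np.array([label_to_idx[r.target_id] for r in pairs])
    seqs = encode_records(pairs, vocab)
    trainable = {"cond_emb"} if tcfg.embeddings_only else None
    log = _run_epochs(params, seqs, cond_ids, tcfg, trainable)
    return params, log, list(condition_labels)
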