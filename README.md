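# condsmiles

Target-conditioned de novo molecular design with a conditional decoder-only
Transformer.

Early-stage drug discovery needs generators that propose molecules which are
(a) valid, drug-like SMILES and (b) biased toward activity against a chosen
protein target. `condsmiles` implements this as conditional language
modeling: a GPT-style decoder is pre-trained on an unlabeled SMILES corpus
to learn chemical grammar, then fine-tuned on `<compound, target>` pairs so
that a learned per-target embedding `e_c` — injected as the keys and values
of a dedicated attention sublayer in every decoder block — steers
autoregressive sampling toward that target's chemical space. The package is
for computational / medicinal chemists who want a self-contained,
CPU-trainable reference implementation of this architecture together with
the standard generative-chemistry evaluation stack.

## The model

Each decoder layer applies three sublayers, each in a residual wrapped by
layer normalization (post-LN):

```
z̄    = LN(z + MHA(z, z, z))        # causally masked self-attention
z̄'   = LN(z̄ + MHA(z̄, e_c, e_c))   # condition memory as keys/values
z_out = LN(z̄' + FFN(z̄'))
```

with `MHA(Q,K,V) = concat_i(softmax(Q W_i^Q (K W_i^K)^T / √d_k) V W_i^V) W^O`.
Masked positions receive −∞ scores, hence exactly zero attention weight.
In base (unconditional) mode `e_c` is the zero tensor; because the attention
projections carry no bias, the condition sublayer then contributes exactly
zero and the model degenerates to a plain GPT decoder — the conditional
machinery is removable by construction. Training minimizes the conditional
negative log-likelihood `NLL(S|c) = −Σ_i ln P(t_i | t_{1:i−1}, c)` under
teacher forcing; generation samples tokens from the temperature-scaled
softmax until EOS.

The model, including reverse-mode differentiation and the Adam training
loop, is implemented directly on numpy; there is no deep-learning framework
dependency.

Also included, behind the same API and CLI:

- **Metrics**: validity, Unique@k, novelty, BRICS fragment-frequency cosine
  (Frag), nearest-neighbor Tanimoto similarity (SNN), property
  Wasserstein-1 distances, and a physico-chemical drug-likeness profile
  (MW, TPSA, LogP, HBD, HBA, QED, SA).
- **QSAR activity scoring**: FCFP6(2048) + MACCS(166) + RDKit-descriptor
  features, LightGBM pXC50 regression with grouped held-out Pearson/RMSE,
  and deterministic top-k ranking of generated libraries.
- **Synthetic data**: a seeded toy grammar that emits valid SMILES whose
  fluorinated/chlorinated motifs depend on a condition label, plus a
  synthetic pXC50 generator with a known feature→activity map, so the whole
  pipeline trains and evaluates in minutes on one CPU with no downloads.

## Worked example

Pre-train on 5,000 toy-grammar molecules, fine-tune on their target labels,
then sample 1,000 molecules per condition (~5 minutes on one CPU):

```python
import numpy as np
import condsmiles as cs

spec = cs.default_toy_spec(seed=0)
rng = np.random.default_rng(0)
records = (cs.sample_toy_molecules(spec, 0, 2500, seed=int(rng.integers(2**31)))
           + cs.sample_toy_molecules(spec, 1, 2500, seed=int(rng.integers(2**31))))
vocab = cs.build_vocabulary(spec.vocabulary_smiles())

config = cs.ModelConfig.tiny(len(vocab), n_conditions=2)
base, log = cs.pretrain(records, config,
                        cs.TrainingConfig(n_epochs=15, learning_rate=1e-3,
                                          warmup_steps=200, seed=0),
                        vocab=vocab)
print("pretrain NLL", log.valid_nll[0], "->", log.valid_nll[-1])

tuned, flog, labels = cs.finetune(base, records,
                                  cs.TrainingConfig(n_epochs=8, learning_rate=3e-4,
                                                    warmup_steps=100, seed=1),
                                  vocab)
for c in (0, 1):
    b = cs.generate(tuned, c, 1000, seed=100 + c, vocab=vocab)
    print(f"cond {c}: validity {b.validity:.3f} "
          f"match {cs.condition_consistency(b.valid_smiles, spec, c):.3f} "
          f"mismatch {cs.condition_consistency(b.valid_smiles, spec, 1 - c):.3f}")
```

Output:

```
pretrain NLL 2.0292060709472874 -> 0.4676368343324125
cond 0: validity 0.953 match 0.981 mismatch 0.038
cond 1: validity 0.954 match 0.981 mismatch 0.027
```

Held-out NLL falling from 2.03 to 0.47 nats/token shows the decoder learned
the grammar; after fine-tuning, ~95% of samples are valid molecules and 98%
of the valid samples under condition c carry condition c's motif (vs ~3%
carrying the other condition's motif) — the condition embedding, not chance,
is steering generation.

The same workflow is available from the shell via the `condsmiles` CLI
(`make-toy`, `pretrain`, `finetune`, `sample`, `evaluate`, `qsar-train`,
`qsar-score`); see `condsmiles --help`.

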