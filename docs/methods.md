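# Methods

## Model

The generator is a decoder-only Transformer over SMILES tokens. A sequence
is framed as `[BOS, t_1, …, t_N, EOS]`; the model outputs next-token logits
at every position, and the training objective is the conditional negative
log-likelihood `NLL(S|c) = −Σ_i ln P(t_i | t_{1:i−1}, c)` (nats), where the
condition `c` is a protein-target label. Reported NLLs are means over
non-PAD token positions, which makes them invariant to batch size and
padding.

Each of the `n_layers` blocks applies, in order and each wrapped as
`LN(x + sublayer(x))` (post-LN, i.e. normalization applied to the residual
sum):

1. **Masked self-attention** — scaled dot-product multi-head attention with
   a causal mask; masked scores are set to −∞ before the softmax, so
   excluded positions receive exactly zero weight rather than a small one.
   Keys at PAD positions are masked as well during batched training.
2. **Condition attention** — the same attention operation with the keys and
   values replaced by the condition memory `e_c`, a learned
   `(cond_memory_len, d_model)` tensor per target. The default memory
   length is 1: the softmax over a single key is degenerate (weight 1), so
   the sublayer acts as an additive, LN-gated injection of a projected
   condition vector. The memory length is exposed as a config knob because
   longer memories give the softmax something to do; 1 is the minimal
   faithful reading of "a per-target embedding as keys and values".
3. **Feed-forward** — position-wise `ReLU(xW₁+b₁)W₂+b₂`.

All attention projections (`W^Q, W^K, W^V, W^O`) are bias-free. This is a
deliberate invariant, not an omission: in base (unconditional) mode the
condition memory is the zero tensor, and with bias-free projections the
condition sublayer's output is *exactly* zero, so base mode coincides
bitwise with a stack that has no condition sublayer at all. The test suite
asserts this equality exactly, not approximately.

Positions enter through parameter-free sinusoidal encodings added to the
token embeddings. The output projection is a separate weight matrix (not
tied to the token embedding); untied weights are the simplest variant to
verify. Initialization is scaled normal (σ = 0.02) for weights, zeros for
biases and LN offsets, ones for LN scales, deterministic given a seed.

On the NLL sign convention: the loss is the negative sum of *all* per-token
log-probabilities, including the first. Any formulation that adds (rather
than subtracts) the later terms is not a loss function and is treated here
as a typographical artifact.

## Numerical implementation

The model runs on float64 numpy throughout, with a small tape-based
reverse-mode autodiff engine (`condsmiles._autodiff`) providing exactly the
operations the decoder needs. Every backward rule is validated against
central finite differences in the tests. Optimization is Adam
(β₁ = 0.9, β₂ = 0.999, ε = 1e-8) with linear learning-rate warmup and
global gradient-norm clipping at 1.0. Training is deterministic given the
config seed: one `numpy` generator drives the train/validation split, batch
order and dropout masks.

Sampling draws from `softmax(logits / T)`; temperatures below 1e-6 are
treated as the argmax limit to avoid overflow. PAD and BOS are never
emitted (their logits are set to −∞). One uniform variate per sequence per
step is consumed whether or not the sequence has finished, so the random
stream — and therefore every shared prefix — does not depend on the length
cap. Sequences that hit the cap are kept and validity-checked; most parse
as invalid, which is the honest accounting.

Degenerate inputs are errors, not silent defaults: empty corpora, fully
masked attention rows, out-of-range tokens or conditions, non-finite logits
at the sampler, and constant activity targets (Pearson undefined → reported
as a flag, never NaN).

## Default configurations

| parameter | default | note |
|---|---|---|
| n_layers / n_heads | 8 / 8 | standard small-GPT scale |
| d_model / d_k / d_v / d_ff | 256 / 32 / 32 / 1024 | |
| max_len | 100 tokens | covers drug-like SMILES |
| dropout | 0.1 | |
| tiny preset | 2 layers, 4 heads, d_model 64, d_ff 256 | trains in minutes on CPU |
| Adam lr | 3e-4 (TrainingConfig default) | desk-scale runs use 1e-3: the post-LN tiny model converges too slowly at 3e-4 on a small corpus |
| warmup | 500 steps (desk runs: 100–200) | scaled to the run length |
| sampling temperature | 1.0, no top-k | top-k available but off |

The desk-scale recipe used by the acceptance script and the end-to-end
tests is: pre-train 15 epochs (lr 1e-3) on 5,000 toy molecules, fine-tune 8
epochs (lr 3e-4), sample 1,000 molecules per condition. These sizes are the
package's reference study conditions; they were chosen so a full run
finishes in a few minutes on one CPU core while leaving clear margins on
the behavioural checks.

## Synthetic data: what it emulates and what it does not

`synthetic.default_toy_spec` is a combinatorial grammar: prefix chain ×
scaffold template × optional neutral decoration × condition-specific
substituent, with fluorinated substituents for condition 0 and chlorinated
for condition 1. Every combination is canonicalized at spec construction
(an invalid-capable grammar is rejected immediately), and the motifs are
verified mutually exclusive by substructure search. It emulates the
*structure* of the real task — a corpus of valid molecules whose
substructure statistics depend on a target label, learnable by a small
model — and deliberately not the scale or diversity of a real lead-like
corpus: a few thousand distinct molecules, no stereochemistry, no charges,
no macrocycles, property distributions far narrower than real screening
collections. Consequently, passing the desk-scale tests demonstrates that
the architecture, objective, conditioning mechanism and metrics are
implemented correctly and that conditional information flows end-to-end; it
does not demonstrate generation quality on real chemistry, and set-level
scores like Unique@1k or novelty are structurally low on the toy corpus
because the grammar's support is small.

Synthetic activity is `pXC50 = 6 + Σ_j w_j b_j + N(0, σ²)` over 20 FCFP6
bits chosen (deterministically) as those with occurrence frequency nearest
1/2; weights are standard-normal draws. The mapping is returned alongside
the labels so recovery tests can compare against ground truth. σ defaults
to 0.3 pXC50 units.

## Metrics

Validity is the fraction of strings RDKit parses. All other metrics use
canonical SMILES of the valid molecules only: Unique@k (distinct among the
first k), novelty (distinct generated forms absent from the training set),
Frag (cosine between BRICS fragment-frequency vectors), SNN (mean
nearest-neighbor Tanimoto over Morgan fingerprints, radius 2, 1024 bits),
and 1-Wasserstein distances between property samples
(`scipy.stats.wasserstein_distance`). The drug-likeness profile reports
min/max and the percentage inside MW [200, 500], TPSA [20, 130],
LogP [−1, 6], HBD ≤ 5, HBA ≤ 10, QED ≥ 0.4, SA ≤ 5. QED and the synthetic
accessibility score are taken from RDKit (including its contributed SA
implementation) as fixed external definitions.

## QSAR model

Features are the concatenation of a 2048-bit FCFP6 fingerprint (Morgan
radius 3 with feature-based atom invariants), the 166 MACCS keys, and the
full alphabetized RDKit descriptor block (210 descriptors in the pinned
RDKit version; the block size is recorded in every fitted bundle as part of
the feature-spec version). Molecules are re-parsed from canonical SMILES
before featurization because a few descriptors are floating-point sensitive
to atom ordering and the featurizer promises byte-identical vectors across
spellings of the same molecule. Non-finite descriptor values are imputed to
0 with a warning.

The regressor is LightGBM with library defaults plus early stopping on a
validation fold. The held-out split (default 80/20, seeded) is grouped by
canonical SMILES, so duplicated structures never straddle the split and the
recorded Pearson/RMSE are genuinely out-of-sample. Ranking of generated
libraries is by predicted pXC50 descending, with ties broken by
lexicographic canonical SMILES so top-k selections are reproducible.

## Known limitations

- The condition-memory length of 1 makes the condition-attention softmax a
  constant; richer conditioning (longer memories, multiple targets per
  molecule) is configurable but untested at scale.
- numpy training is single-core; the default (8-layer) preset is practical
  only for corpora far smaller than the millions-of-molecules scale the
  architecture is designed for. The code supports such runs; nothing in the
  test suite requires them.
- The toy grammar's small support makes uniqueness/novelty numbers
  uninformative about real-corpus behaviour (see above).
- The QSAR descriptor block tracks the installed RDKit's descriptor list;
  refitting with a different RDKit version changes the feature space (the
  bundle records the spec so mismatches are detectable).
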