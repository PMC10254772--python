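import numpy as np
import pytest

import condsmiles as cs


@pytest.fixture(scope="session")
def toy_spec():
    return cs.default_toy_spec(seed=0)


@pytest.fixture(scope="session")
def toy_vocab(toy_spec):
    # built from everything the grammar can emit, so any sample is encodable
    return cs.build_vocabulary(toy_spec.vocabulary_smiles())


@pytest.fixture(scope="session")
def toy_records(toy_spec):
    return cs.sample_toy_molecules(toy_spec, None, 300, seed=13)


@pytest.fixture(scope="session")
def tiny_config(toy_vocab):
    return cs.ModelConfig.tiny(len(toy_vocab), n_conditions=2, dropout=0.0)


@pytest.fixture(scope="session")
def tiny_params(tiny_config):
    return cs.init_params(tiny_config, seed=0)


def rand_layer_weights(rng, h, d_model, d_k, d_v, d_out=None):
    """Random stacked attention projections for oracle comparisons."""
    return {
        "Wq": rng.normal(size=(h, d_model, d_k)),
        "Wk": rng.normal(size=(h, d_model, d_k)),
        "Wv": rng.normal(size=(h, d_model, d_v)),
        "Wo": rng.normal(size=(h * d_v, d_out or d_model)),
    }


def naive_multi_head_attention(q, k, v, w, mask=None):
    """Per-head, per-position double-loop attention oracle."""
    h = w["Wq"].shape[0]
    outs = []
    for i in range(h):
        qi, ki, vi = q @ w["Wq"][i], k @ w["Wk"][i], v @ w["Wv"][i]
        d_k = qi.shape[1]
        rows = []
        for a in range(qi.shape[0]):
            scores = np.array([qi[a] @ ki[b] / np.sqrt(d_k)
                               for b in range(ki.shape[0])])
            if mask is not None:
                scores = np.where(mask[a], scores, -np.inf)
            e = np.exp(scores - scores[np.isfinite(scores)].max())
            wts = e / e.sum()
            rows.append(sum(wts[b] * vi[b] for b in range(ki.shape[0])))
        outs.append(np.array(rows))
    return np.concatenate(outs, axis=1) @ w["Wo"]
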