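"""QSAR activity model: featurization, LightGBM regression, ranking.

Each molecule is represented by the concatenation of a 2048-bit FCFP6
fingerprint (hashed circular fingerprint, radius 3, feature-based atom
invariants), the 166 MACCS structural keys, and the full alphabetized
RDKit descriptor block. pXC50 is regressed with gradient-boosted trees;
the held-out Pearson correlation and RMSE are recorded in the fitted
bundle. The train/test split is grouped by canonical SMILES so that no
molecule present in training is ever counted as held-out.
"""

from __future__ import annotations

import pickle
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from lightgbm import LGBMRegressor, early_stopping
from scipy.stats import pearsonr

from rdkit import Chem
from rdkit.Chem import Descriptors, MACCSkeys, rdFingerprintGenerator

from .smiles_io import MoleculeRecord, canonicalize, INVALID

__all__ = ["FEATURE_NAMES", "featurize", "featurize_many", "train_qsar",
           "QSARModelBundle", "predict_activity", "select_top_k"]

_FCFP_BITS = 2048
_MACCS_BITS = 166
#: Alphabetized RDKit descriptor names; the block's size is part of the
#: feature-spec version recorded in every fitted bundle.
DESCRIPTOR_NAMES: tuple[str, ...] = tuple(sorted(n for n, _ in Descriptors.descList))
_DESCRIPTOR_FUNCS = dict(Descriptors.descList)

FEATURE_NAMES: tuple[str, ...] = (
    tuple(f"fcfp6_{i}" for i in range(_FCFP_BITS))
    + tuple(f"maccs_{i}" for i in range(1, _MACCS_BITS + 1))
    + tuple(f"desc_{n}" for n in DESCRIPTOR_NAMES)
)
N_FEATURES = len(FEATURE_NAMES)
FEATURE_SPEC_VERSION = f"fcfp6-2048+maccs-166+rdkit-desc-{len(DESCRIPTOR_NAMES)}"

_FCFP = rdFingerprintGenerator.GetMorganGenerator(
    radius=3, fpSize=_FCFP_BITS,
    atomInvariantsGenerator=rdFingerprintGenerator.GetMorganFeatureAtomInvGen())


def featurize(smiles: str) -> np.ndarray:
    """Feature vector (fingerprint block, MACCS block, descriptor block).

    Deterministic for a given molecular graph, hence identical across
    SMILES spellings of the same molecule. Non-finite descriptor values
    are imputed to 0 with a warning.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"cannot featurize invalid SMILES {smiles!r}")
    # reparse from the canonical form: a few descriptors (e.g. BCUT2D) are
    # float-order sensitive to atom numbering, and byte-identical vectors
    # across SMILES spellings are part of the contract
    mol = Chem.MolFromSmiles(Chem.MolToSmiles(mol))
    fp = np.zeros(_FCFP_BITS)
    fp[list(_FCFP.GetFingerprint(mol).GetOnBits())] = 1.0
    maccs = np.array(MACCSkeys.GenMACCSKeys(mol))[1:]  # bit 0 is unused
    desc = np.empty(len(DESCRIPTOR_NAMES))
    for i, name in enumerate(DESCRIPTOR_NAMES):
        try:
            desc[i] = _DESCRIPTOR_FUNCS[name](mol)
        except Exception:
            desc[i] = np.nan
    bad = ~np.isfinite(desc)
    if bad.any():
        warnings.warn(f"{int(bad.sum())} non-finite descriptor value(s) for "
                      f"{smiles!r} imputed to 0")
        desc[bad] = 0.0
    return np.concatenate([fp, maccs.astype(float), desc])


def featurize_many(smiles_list: Sequence[str]) -> np.ndarray:
    return np.vstack([featurize(s) for s in smiles_list]) if len(smiles_list) \
        else np.empty((0, N_FEATURES))


@dataclass
class QSARModelBundle:
    """A fitted activity regressor plus its held-out evaluation."""

    model: LGBMRegressor
    feature_spec: str
    test_pearson: Optional[float]
    test_rmse: float
    split_seed: int
    n_train: int
    n_test: int
    flags: list[str] = field(default_factory=list)

    def save(self, path) -> None:
        with open(path, "wb") as fh:
            pickle.dump(self, fh)

    @staticmethod
    def load(path) -> "QSARModelBundle":
        with open(path, "rb") as fh:
            return pickle.load(fh)


def _grouped_split(groups: np.ndarray, test_fraction: float, seed: int
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Boolean train/test row masks with no canonical SMILES in both sides."""
    rng = np.random.default_rng(seed)
    uniq = np.unique(groups)
    n_test = max(1, int(round(len(uniq) * test_fraction)))
    test_groups = set(rng.permutation(uniq)[:n_test])
    test = np.array([g in test_groups for g in groups])
    return ~test, test


def train_qsar(records: Sequence[MoleculeRecord], split_seed: int = 0,
               test_fraction: float = 0.2, min_records: int = 50,
               **lgbm_params) -> QSARModelBundle:
    """Fit a gradient-boosted pXC50 regressor with a held-out evaluation.

    Uses LightGBM defaults plus early stopping on a validation fold split
    off the training side. A constant-activity input yields an undefined
    Pearson correlation, reported as None with an explanatory flag.
    """
    records = [r for r in records if r.pxc50 is not None]
    if len(records) < min_records:
        raise ValueError(f"need at least {min_records} records with pxc50, "
                         f"got {len(records)}")
    smiles = [r.smiles for r in records]
    y = np.array([r.pxc50 for r in records], dtype=float)
    groups = np.array([canonicalize(s) for s in smiles])
    if INVALID in groups:
        raise ValueError("activity table contains invalid SMILES")
    X = featurize_many(smiles)
    train_mask, test_mask = _grouped_split(groups, test_fraction, split_seed)

    # carve an early-stopping fold out of the training side, again by group
    tr_idx = np.flatnonzero(train_mask)
    es_tr, es_val = _grouped_split(groups[tr_idx], 0.1, split_seed + 1)
    params = dict(n_estimators=500, random_state=split_seed, verbose=-1)
    params.update(lgbm_params)
    model = LGBMRegressor(**params)
    model.fit(X[tr_idx[es_tr]], y[tr_idx[es_tr]],
              eval_set=[(X[tr_idx[es_val]], y[tr_idx[es_val]])],
              callbacks=[early_stopping(50, verbose=False)])

    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*valid feature names.*")
        pred = model.predict(X[test_mask])
    rmse = float(np.sqrt(np.mean((pred - y[test_mask]) ** 2)))
    flags: list[str] = []
    if np.ptp(y[test_mask]) == 0 or np.ptp(pred) == 0:
        pearson: Optional[float] = None
        flags.append("constant activity or prediction; Pearson undefined")
    else:
        pearson = float(pearsonr(pred, y[test_mask]).statistic)
    return QSARModelBundle(model=model, feature_spec=FEATURE_SPEC_VERSION,
                           test_pearson=pearson, test_rmse=rmse,
                           split_seed=split_seed,
                           n_train=int(train_mask.sum()),
                           n_test=int(test_mask.sum()), flags=flags)


def predict_activity(bundle: QSARModelBundle, smiles_list: Sequence[str]
                     ) -> list[float]:
    """Predicted pXC50 per input SMILES, order-preserving."""
    if len(smiles_list) == 0:
        return []
    for i, s in enumerate(smiles_list):
        if Chem.MolFromSmiles(s) is None:
            raise ValueError(f"invalid SMILES at index {i}: {s!r}")
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*valid feature names.*")
        preds = bundle.model.predict(featurize_many(smiles_list))
    return [float(v) for v in preds]


def select_top_k(smiles_list: Sequence[str], predictions: Sequence[float],
                 k: int) -> list[tuple[str, float]]:
    """The k molecules with the highest predictions, descending.

    Ties are broken by lexicographic order of the canonical SMILES, making
    the ranking fully deterministic.
    """
    if len(smiles_list) != len(predictions):
        raise ValueError("smiles and predictions must be aligned")
    if k > len(smiles_list):
        raise ValueError(f"k={k} exceeds list length {len(smiles_list)}")
    keyed = sorted(zip(smiles_list, predictions),
                   key=lambda sp: (-sp[1], canonicalize(sp[0])))
    return [(s, float(p)) for s, p in keyed[:k]]
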