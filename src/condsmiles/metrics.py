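"""Generative-chemistry evaluation metrics.

The suite follows the de facto standard distribution-learning benchmarks
for SMILES generators: validity, Unique@k, novelty against the training
set, fragment-frequency cosine similarity (Frag, BRICS fragments),
similarity to the nearest neighbor (SNN, Morgan fingerprints radius 2 /
1024 bits, Tanimoto), 1-Wasserstein distances between property
distributions, and a physico-chemical profile with drug-likeness ranges
(MW 200-500 Da, TPSA 20-130 A^2, LogP -1..6, HBD <= 5, HBA <= 10,
QED >= 0.4, SA <= 5).

All set-level comparisons operate on canonical SMILES so that trivially
rewritten strings never count as distinct or novel molecules.
"""

from __future__ import annotations

import json
import os
import sys
import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.stats import wasserstein_distance

from rdkit import Chem, RDConfig
from rdkit.Chem import BRICS, Crippen, Descriptors, QED, rdMolDescriptors
from rdkit.Chem import rdFingerprintGenerator
from rdkit.DataStructs import BulkTanimotoSimilarity

from .smiles_io import canonicalize, INVALID

sys.path.append(os.path.join(RDConfig.RDContribDir, "SA_Score"))
import sascorer  # noqa: E402  (RDKit contrib synthetic-accessibility score)

__all__ = ["MetricsReport", "validity_fraction", "unique_at_k", "novelty",
           "fragment_similarity", "snn", "wasserstein1", "property_profile",
           "evaluate", "PROPERTY_RANGES"]

#: Drug-likeness "good" ranges; None bound means unbounded on that side.
PROPERTY_RANGES: dict[str, tuple[Optional[float], Optional[float]]] = {
    "MW": (200.0, 500.0),
    "TPSA": (20.0, 130.0),
    "LogP": (-1.0, 6.0),
    "HBD": (None, 5.0),
    "HBA": (None, 10.0),
    "QED": (0.4, None),
    "SA": (None, 5.0),
}


def _mols(smiles: Sequence[str], where: str) -> list[Chem.Mol]:
    mols = [Chem.MolFromSmiles(s) for s in smiles]
    bad = [i for i, m in enumerate(mols) if m is None]
    if bad:
        raise ValueError(f"{where}: invalid SMILES at index {bad[0]} "
                         f"({smiles[bad[0]]!r}); pre-filter to valid molecules")
    return mols


def validity_fraction(smiles: Sequence[str]) -> float:
    """Fraction of the list that parses to a chemically sensible molecule."""
    if not smiles:
        raise ValueError("validity of an empty list is undefined")
    return sum(canonicalize(s) != INVALID for s in smiles) / len(smiles)


def unique_at_k(valid_smiles: Sequence[str], k: int) -> float:
    """Distinct canonical forms among the first k valid molecules, over k."""
    if len(valid_smiles) < k:
        raise ValueError(f"need at least k={k} molecules, got {len(valid_smiles)}")
    head = [canonicalize(s) for s in valid_smiles[:k]]
    if INVALID in head:
        raise ValueError("unique_at_k expects valid molecules only")
    return len(set(head)) / k


def novelty(generated_valid: Sequence[str], training_set: Sequence[str]) -> float:
    """Fraction of distinct generated molecules absent from the training set."""
    if not generated_valid or not training_set:
        raise ValueError("novelty needs non-empty generated and training sets")
    gen = {canonicalize(s) for s in generated_valid} - {INVALID}
    train = {canonicalize(s) for s in training_set} - {INVALID}
    if not gen:
        raise ValueError("no valid generated molecules")
    return len(gen - train) / len(gen)


def _fragment_counts(mols: Sequence[Chem.Mol]) -> Counter:
    counts: Counter = Counter()
    for m in mols:
        counts.update(BRICS.BRICSDecompose(m))
    return counts


def fragment_similarity(gen_set: Sequence[str], ref_set: Sequence[str]) -> float:
    """Cosine similarity of BRICS fragment-frequency vectors of two sets."""
    ga = _fragment_counts(_mols(gen_set, "gen_set"))
    gb = _fragment_counts(_mols(ref_set, "ref_set"))
    if not ga or not gb:
        warnings.warn("a set has no BRICS-fragmentable molecule; Frag := 0")
        return 0.0
    keys = sorted(set(ga) | set(gb))
    a = np.array([ga.get(k, 0) for k in keys], dtype=float)
    b = np.array([gb.get(k, 0) for k in keys], dtype=float)
    return float(a @ b / (np.linalg.norm(a) * np.linalg.norm(b)))


_MORGAN = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=1024)


def snn(gen_set: Sequence[str], ref_set: Sequence[str]) -> float:
    """Mean over generated molecules of the max Tanimoto to the reference set.

    Fingerprints are binary Morgan (circular substructure), radius 2,
    1024 bits.
    """
    if not gen_set or not ref_set:
        raise ValueError("snn needs two non-empty sets")
    gen_fps = [_MORGAN.GetFingerprint(m) for m in _mols(gen_set, "gen_set")]
    ref_fps = [_MORGAN.GetFingerprint(m) for m in _mols(ref_set, "ref_set")]
    best = [max(BulkTanimotoSimilarity(fp, ref_fps)) for fp in gen_fps]
    return float(np.mean(best))


def wasserstein1(sample_a: Sequence[float], sample_b: Sequence[float]) -> float:
    """Empirical 1-Wasserstein distance (area between sorted empirical CDFs)."""
    if len(sample_a) == 0 or len(sample_b) == 0:
        raise ValueError("wasserstein1 needs two non-empty samples")
    return float(wasserstein_distance(sample_a, sample_b))


_PROPERTY_FUNCS = {
    "MW": Descriptors.MolWt,
    "TPSA": rdMolDescriptors.CalcTPSA,
    "LogP": Crippen.MolLogP,
    "HBD": rdMolDescriptors.CalcNumHBD,
    "HBA": rdMolDescriptors.CalcNumHBA,
    "QED": QED.qed,
    "SA": sascorer.calculateScore,
}


def compute_properties(smiles: Sequence[str]) -> dict[str, np.ndarray]:
    """Per-molecule MW/TPSA/LogP/HBD/HBA/QED/SA arrays (valid input only)."""
    mols = _mols(smiles, "property input")
    return {name: np.array([fn(m) for m in mols], dtype=float)
            for name, fn in _PROPERTY_FUNCS.items()}


def property_profile(smiles: Sequence[str]) -> dict:
    """Min/max per property plus percentage inside each drug-likeness range."""
    if not smiles:
        raise ValueError("property_profile needs at least one valid molecule")
    values = compute_properties(smiles)
    profile = {}
    for name, arr in values.items():
        lo, hi = PROPERTY_RANGES[name]
        ok = np.ones(arr.shape, dtype=bool)
        if lo is not None:
            ok &= arr >= lo
        if hi is not None:
            ok &= arr <= hi
        profile[name] = {
            "min": float(arr.min()),
            "max": float(arr.max()),
            "pct_in_range": float(100.0 * ok.mean()),
        }
    return profile


@dataclass
class MetricsReport:
    """The full metric bundle for one generated set against references."""

    valid: float
    unique_at_1k: Optional[float] = None
    unique_at_10k: Optional[float] = None
    novelty: Optional[float] = None
    frag_test: Optional[float] = None
    snn_test: Optional[float] = None
    frag_test_sf: Optional[float] = None
    snn_test_sf: Optional[float] = None
    w1_by_property: dict[str, float] = field(default_factory=dict)
    property_profile: dict = field(default_factory=dict)
    flags: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items()}

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def evaluate(generated: Sequence[str],
             ref_test: Optional[Sequence[str]] = None,
             ref_test_sf: Optional[Sequence[str]] = None,
             training_set: Optional[Sequence[str]] = None,
             w1_properties: Sequence[str] = ("MW", "LogP", "QED", "SA")
             ) -> MetricsReport:
    """Assemble the full report for a generated SMILES list.

    Validity is computed on everything; every other metric only on the
    valid molecules, each compared against whichever reference splits are
    provided. When no generated molecule is valid the report carries
    ``valid=0`` and explanatory flags instead of metric values.
    ``generated`` may be a plain SMILES list or a sampler GenerationBatch.
    """
    if hasattr(generated, "raw_smiles"):  # a GenerationBatch
        generated = generated.raw_smiles
    generated = list(generated)
    report = MetricsReport(valid=validity_fraction(generated))
    valid = [c for c in (canonicalize(s) for s in generated) if c != INVALID]
    if not valid:
        report.flags.append("no valid molecules; set-level metrics skipped")
        return report
    for k, attr in ((1000, "unique_at_1k"), (10000, "unique_at_10k")):
        if len(valid) >= k:
            setattr(report, attr, unique_at_k(valid, k))
        else:
            report.flags.append(f"fewer than {k} valid molecules; {attr} skipped")
    if training_set is not None:
        report.novelty = novelty(valid, training_set)
    for refs, suffix in ((ref_test, "test"), (ref_test_sf, "test_sf")):
        if refs is None:
            continue
        setattr(report, f"frag_{suffix}", fragment_similarity(valid, refs))
        setattr(report, f"snn_{suffix}", snn(valid, refs))
    if ref_test is not None and w1_properties:
        gen_props = compute_properties(valid)
        ref_props = compute_properties(list(ref_test))
        report.w1_by_property = {
            p: wasserstein1(gen_props[p], ref_props[p]) for p in w1_properties}
    report.property_profile = property_profile(valid)
    return report
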