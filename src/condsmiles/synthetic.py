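"""Seeded toy molecular grammar and synthetic activity labels.

Real training data for this kind of generator is a large drug-like SMILES
corpus plus small per-target activity sets. This module stands in for both
at desk scale: a combinatorial grammar (prefix chain x scaffold template x
neutral decoration x condition-specific substituent) emits molecules that
are valid by construction, with a tokenizer-visible, mutually exclusive
substructure motif per condition (fluorinated vs chlorinated substituents
by default). A linear map from chosen fingerprint bits plus Gaussian noise
provides activity labels with a known ground truth for QSAR recovery
tests.

Every scaffold/substituent combination is canonicalized once at spec
construction; a grammar that can emit an unparseable string is rejected
there and then.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from rdkit import Chem

from .smiles_io import MoleculeRecord, canonicalize, INVALID
from .qsar import _FCFP, _FCFP_BITS

__all__ = ["ToyGrammarSpec", "default_toy_spec", "sample_toy_molecules",
           "condition_consistency", "synth_activity", "ActivityMapping"]


@dataclass(frozen=True)
class ToyGrammarSpec:
    """A toy SMILES grammar with condition-dependent substituent pools.

    ``templates`` are format strings over the fields ``pre`` (prefix
    chain), ``mid`` (condition-neutral decoration; only used by templates
    that reference it) and ``sub`` (condition-specific substituent).
    ``substituents[c]`` and ``motifs[c]`` (a SMARTS) belong to condition c;
    motifs must be mutually exclusive substructures across conditions.
    """

    templates: tuple[str, ...]
    prefixes: tuple[str, ...]
    mids: tuple[str, ...]
    substituents: tuple[tuple[str, ...], ...]
    motifs: tuple[str, ...]
    seed: int = 0

    @property
    def n_conditions(self) -> int:
        return len(self.substituents)

    def __post_init__(self):
        if len(self.motifs) != len(self.substituents):
            raise ValueError("need one motif per condition")
        for c in range(self.n_conditions):
            for s in self._combos(c):
                if canonicalize(s) == INVALID:
                    raise ValueError(f"grammar emits invalid SMILES {s!r}")
        # motif exclusivity: no combo of condition c matches another motif
        patt = [Chem.MolFromSmarts(m) for m in self.motifs]
        for c in range(self.n_conditions):
            for s in self._combos(c):
                mol = Chem.MolFromSmiles(s)
                for c2, p in enumerate(patt):
                    if (c2 != c) == mol.HasSubstructMatch(p):
                        raise ValueError(
                            f"motif exclusivity violated by {s!r} "
                            f"(condition {c} vs motif {c2})")

    def _combos(self, condition_id: int) -> list[str]:
        out = []
        for t in self.templates:
            needs_mid = "{mid}" in t
            mids = self.mids if needs_mid else ("",)
            for pre, mid, sub in itertools.product(
                    self.prefixes, mids, self.substituents[condition_id]):
                out.append(t.format(pre=pre, mid=mid, sub=sub))
        return out

    def vocabulary_smiles(self) -> list[str]:
        """Every string the grammar can emit (all conditions)."""
        return [s for c in range(self.n_conditions) for s in self._combos(c)]


def default_toy_spec(seed: int = 0) -> ToyGrammarSpec:
    """Two-condition default: fluorinated (0) vs chlorinated (1) substituents."""
    return ToyGrammarSpec(
        templates=(
            "{pre}c1ccccc1{sub}",
            "{pre}C1CCCCC1{sub}",
            "{pre}c1ccc({mid})cc1{sub}",
            "{pre}C1CCN(C{sub})CC1",
            "{pre}CC(=O)N{sub}",
            "{pre}c1cccnc1{sub}",
        ),
        prefixes=("", "C", "CC", "CCC", "CO", "CN", "CCO", "C(C)", "CCN", "OC"),
        mids=("C", "O", "N", "CC", "CO", "CCC"),
        substituents=(
            ("CF", "C(F)F", "CCF", "F", "C(F)(F)F"),
            ("CCl", "C(Cl)Cl", "CCCl", "Cl", "C(Cl)(Cl)Cl"),
        ),
        motifs=("[F]", "[Cl]"),
        seed=seed,
    )


def sample_toy_molecules(spec: ToyGrammarSpec, condition_id: Optional[int],
                         n: int, seed: Optional[int] = None
                         ) -> list[MoleculeRecord]:
    """Draw n grammar molecules; ``condition_id=None`` mixes pools uniformly.

    Deterministic given the seed (``spec.seed`` unless overridden). Labeled
    records carry ``target_id`` ("T0", "T1", ...).
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    if condition_id is not None and not (0 <= condition_id < spec.n_conditions):
        raise ValueError(f"unknown condition {condition_id}")
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    records = []
    for _ in range(n):
        c = (int(rng.integers(spec.n_conditions)) if condition_id is None
             else condition_id)
        t = spec.templates[rng.integers(len(spec.templates))]
        pre = spec.prefixes[rng.integers(len(spec.prefixes))]
        mid = spec.mids[rng.integers(len(spec.mids))] if "{mid}" in t else ""
        sub = spec.substituents[c][rng.integers(len(spec.substituents[c]))]
        s = t.format(pre=pre, mid=mid, sub=sub)
        records.append(MoleculeRecord(
            smiles=s, canonical=canonicalize(s),
            target_id=f"T{c}" if condition_id is not None else None))
    return records


def condition_consistency(smiles_list: Sequence[str], spec: ToyGrammarSpec,
                          condition_id: int) -> float:
    """Fraction of molecules containing the condition's motif substructure.

    Unparseable SMILES count as non-matching.
    """
    if not (0 <= condition_id < spec.n_conditions):
        raise ValueError(f"unknown condition {condition_id}")
    if not smiles_list:
        return 0.0
    patt = Chem.MolFromSmarts(spec.motifs[condition_id])
    hits = 0
    for s in smiles_list:
        mol = Chem.MolFromSmiles(s)
        hits += mol is not None and mol.HasSubstructMatch(patt)
    return hits / len(smiles_list)


@dataclass(frozen=True)
class ActivityMapping:
    """The ground-truth feature -> activity map used by synth_activity."""

    bit_indices: tuple[int, ...]
    weights: tuple[float, ...]
    intercept: float
    noise_sd: float
    seed: int

    def signal(self, smiles: str) -> float:
        """Noise-free activity of one molecule under the mapping."""
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            raise ValueError(f"invalid SMILES {smiles!r}")
        on = set(_FCFP.GetFingerprint(mol).GetOnBits())
        return self.intercept + sum(
            w for b, w in zip(self.bit_indices, self.weights) if b in on)


def synth_activity(records: Sequence[MoleculeRecord], noise_sd: float = 0.3,
                   seed: int = 0, n_bits: int = 20, intercept: float = 6.0
                   ) -> tuple[list[MoleculeRecord], ActivityMapping]:
    """Label records with pXC50 = linear(fingerprint bits) + Gaussian noise.

    The ``n_bits`` informative FCFP6 bits are the ones whose occurrence
    frequency over the records is closest to 1/2 (ties to the lower bit
    index), so the signal varies across the set; weights are standard
    normal draws. Returns labeled copies plus the mapping, which is kept
    for recovery tests.
    """
    rng = np.random.default_rng(seed)
    fps = []
    for r in records:
        mol = Chem.MolFromSmiles(r.smiles)
        if mol is None:
            raise ValueError(f"invalid SMILES {r.smiles!r}")
        row = np.zeros(_FCFP_BITS)
        row[list(_FCFP.GetFingerprint(mol).GetOnBits())] = 1.0
        fps.append(row)
    X = np.vstack(fps)
    freq = X.mean(axis=0)
    order = np.lexsort((np.arange(_FCFP_BITS), np.abs(freq - 0.5)))
    informative = np.sort(order[:n_bits])
    weights = rng.normal(0.0, 1.0, size=n_bits)
    signal = intercept + X[:, informative] @ weights
    labels = signal + rng.normal(0.0, noise_sd, size=len(records))
    mapping = ActivityMapping(
        bit_indices=tuple(int(b) for b in informative),
        weights=tuple(float(w) for w in weights),
        intercept=intercept, noise_sd=noise_sd, seed=seed)
    labeled = [MoleculeRecord(smiles=r.smiles, canonical=r.canonical,
                              target_id=r.target_id, pxc50=float(y))
               for r, y in zip(records, labels)]
    return labeled, mapping
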