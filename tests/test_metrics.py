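"""Metric identities, independent oracles, and bound/symmetry properties."""

import itertools
from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import condsmiles as cs
from condsmiles.metrics import compute_properties


class TestValidityAndUniqueness:
    def test_validity_fractions(self):
        assert cs.validity_fraction(["CCO", "c1ccccc1"]) == 1.0
        assert cs.validity_fraction(["C(", "CCO"]) == 0.5
        with pytest.raises(ValueError):
            cs.validity_fraction([])

    def test_unique_at_k_counts_canonical_forms(self):
        # OCC is the same molecule as CCO, so only 3 of 4 are distinct
        assert cs.unique_at_k(["CCO", "OCC", "CCN", "CCC"], 4) == 0.75
        assert cs.unique_at_k(["CCO"] * 10, 10) == 0.1

    def test_unique_at_k_requires_enough_molecules(self):
        with pytest.raises(ValueError, match="2"):
            cs.unique_at_k(["CCO", "CCN"], 3)


class TestNovelty:
    def test_subset_and_disjoint(self):
        assert cs.novelty(["CCO", "OCC"], ["CCO", "CCN"]) == 0.0
        assert cs.novelty(["CCC"], ["CCO"]) == 1.0

    def test_novelty_plus_overlap_is_one(self, toy_spec):
        gen = [r.smiles for r in cs.sample_toy_molecules(toy_spec, None, 80,
                                                         seed=1)]
        train = [r.smiles for r in cs.sample_toy_molecules(toy_spec, None, 80,
                                                           seed=2)]
        nov = cs.novelty(gen, train)
        distinct = {cs.canonicalize(s) for s in gen}
        overlap = len(distinct & {cs.canonicalize(s) for s in train})
        assert nov + overlap / len(distinct) == pytest.approx(1.0)

    def test_empty_inputs_rejected(self):
        with pytest.raises(ValueError):
            cs.novelty([], ["CCO"])


class TestFragAndSNN:
    def test_identical_sets_score_one(self):
        mols = ["CCOC(=O)c1ccccc1", "CCNc1ccccc1", "CCO"]
        assert cs.fragment_similarity(mols, list(mols)) == pytest.approx(1.0)
        assert cs.snn(mols, list(mols)) == pytest.approx(1.0)

    def test_disjoint_fragment_supports_score_zero(self):
        assert cs.fragment_similarity(["CCO"], ["c1ccncc1"]) == 0.0

    def test_frag_matches_hand_built_cosine(self):
        # unfragmentable molecules: each is its own single BRICS fragment,
        # so the count vectors are (1,1,0) and (1,0,1) -> cosine 1/2
        a, b = ["CCO", "CCN"], ["CCO", "CCC"]
        assert cs.fragment_similarity(a, b) == pytest.approx(0.5)

    def test_snn_matches_naive_bitset_tanimoto(self):
        from rdkit import Chem
        from rdkit.Chem import rdFingerprintGenerator
        gen = ["CCOc1ccccc1", "CCNC(=O)C"]
        ref = ["CCOc1ccccc1C", "CCC", "c1ccncc1"]
        fpgen = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=1024)

        def bits(s):
            return set(fpgen.GetFingerprint(Chem.MolFromSmiles(s)).GetOnBits())

        def tanimoto(x, y):
            return len(x & y) / len(x | y)

        expected = np.mean([max(tanimoto(bits(g), bits(r)) for r in ref)
                            for g in gen])
        assert cs.snn(gen, ref) == pytest.approx(expected, abs=1e-12)

    def test_invalid_input_rejected(self):
        with pytest.raises(ValueError, match="index"):
            cs.snn(["C("], ["CCO"])


class TestWasserstein1:
    def test_identical_and_shifted(self):
        assert cs.wasserstein1([1.0, 2.0, 5.0], [1.0, 2.0, 5.0]) == 0.0
        assert cs.wasserstein1([1, 2, 3], [2, 3, 4]) == pytest.approx(1.0)

    def test_matches_brute_force_optimal_matching(self):
        # in 1-D the optimal transport plan is the sorted pairing; verify
        # against exhaustive search over all permutations at n=6
        rng = np.random.default_rng(4)
        a, b = rng.normal(size=6), rng.normal(size=6)
        brute = min(np.mean(np.abs(a - b[list(p)]))
                    for p in itertools.permutations(range(6)))
        assert cs.wasserstein1(a, b) == pytest.approx(brute, abs=1e-12)

    @given(st.lists(st.floats(-50, 50), min_size=1, max_size=12),
           st.lists(st.floats(-50, 50), min_size=1, max_size=12),
           st.lists(st.floats(-50, 50), min_size=1, max_size=12))
    @settings(max_examples=40, derandomize=True, deadline=None)
    def test_symmetry_and_triangle_inequality(self, a, b, c):
        dab = cs.wasserstein1(a, b)
        assert dab >= 0
        assert dab == pytest.approx(cs.wasserstein1(b, a))
        assert dab <= cs.wasserstein1(a, c) + cs.wasserstein1(c, b) + 1e-9

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            cs.wasserstein1([], [1.0])


class TestPropertyProfile:
    def test_ethanol_descriptors(self):
        props = compute_properties(["CCO"])
        assert props["HBD"][0] == 1
        assert props["HBA"][0] == 1
        prof = cs.property_profile(["CCO"])
        assert prof["HBD"]["pct_in_range"] == 100.0
        assert prof["HBA"]["pct_in_range"] == 100.0

    def test_midrange_molecule_fully_in_mw_range(self):
        # diethyl terephthalate, MW ~222, inside [200, 500]
        prof = cs.property_profile(["CCOC(=O)c1ccc(cc1)C(=O)OCC"])
        assert 200 <= prof["MW"]["min"] == prof["MW"]["max"] <= 500
        assert prof["MW"]["pct_in_range"] == 100.0

    def test_invalid_input_is_an_error(self):
        with pytest.raises(ValueError):
            cs.property_profile(["C("])
        with pytest.raises(ValueError):
            cs.property_profile([])


class TestEvaluate:
    def test_all_invalid_generated(self):
        report = cs.evaluate(["C(", ")("], ref_test=["CCO"],
                             training_set=["CCO"])
        assert report.valid == 0.0
        assert report.novelty is None and report.frag_test is None
        assert report.flags

    def test_identity_configuration(self, toy_spec):
        mols = sorted({r.smiles for r in
                       cs.sample_toy_molecules(toy_spec, None, 40, seed=8)})
        report = cs.evaluate(mols, ref_test=mols, training_set=mols)
        assert report.valid == 1.0
        assert report.novelty == 0.0
        assert report.frag_test == pytest.approx(1.0)
        assert report.snn_test == pytest.approx(1.0)
        assert all(v == pytest.approx(0.0) for v in
                   report.w1_by_property.values())

    def test_accepts_generation_batch(self):
        batch = cs.GenerationBatch(["CCO", "C("], [cs.canonicalize("CCO"), ""],
                                   [True, False], None, 0, 1.0)
        report = cs.evaluate(batch, training_set=["CCO"])
        assert report.valid == 0.5
        assert report.novelty == 0.0

    def test_report_serializes(self, toy_spec, tmp_path):
        mols = [r.smiles for r in cs.sample_toy_molecules(toy_spec, 0, 25,
                                                          seed=9)]
        report = cs.evaluate(mols, ref_test=mols[:10], training_set=mols[:10])
        out = tmp_path / "report.json"
        report.to_json(out)
        import json
        loaded = json.loads(out.read_text())
        assert loaded["valid"] == 1.0
        assert set(loaded["w1_by_property"]) == {"MW", "LogP", "QED", "SA"}
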