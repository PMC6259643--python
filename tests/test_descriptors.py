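import numpy as np
import pandas as pd
import pytest

from qsarpls.descriptors import (
    DescriptorMatrix,
    broto_moreau_autocorrelation,
    burden_eigenvalues,
    burden_matrix,
    compute_matrix,
    geary_autocorrelation,
    moran_autocorrelation,
    parse_descriptor_name,
    prefilter,
)
from qsarpls.molgraph import MolecularGraph, parse_smiles

from conftest import random_graph
from oracles import ats_brute, geary_brute, moran_brute

PATH3 = MolecularGraph(atoms=(("C", 0),) * 3, bonds=((0, 1, 1.0), (1, 2, 1.0)))
PAIR = MolecularGraph(atoms=(("C", 0),) * 2, bonds=((0, 1, 1.0),))


class TestAutocorrelationKernels:
    def test_uniform_weights_give_zero(self):
        w = np.ones(3)
        assert moran_autocorrelation(PATH3, w, 1) == 0.0
        assert geary_autocorrelation(PATH3, w, 1) == 0.0

    def test_moran_path_hand_value(self):
        # deviations (-1, 0, 1): both adjacent products are (+-1)*0 = 0
        assert moran_autocorrelation(PATH3, np.array([1.0, 2.0, 3.0]), 1) == 0.0

    def test_geary_two_atom_hand_value(self):
        # ordered pairs at lag 1: 2, each squared difference 4 -> num 8/(2*2)=2;
        # sample variance 2 -> c = 1
        assert geary_autocorrelation(PAIR, np.array([1.0, 3.0]), 1) == pytest.approx(1.0)

    def test_ats_adjacent_pairs(self):
        assert broto_moreau_autocorrelation(PATH3, np.ones(3), 1) == pytest.approx(2.0)

    def test_lag_beyond_diameter_is_zero(self):
        w = np.array([1.0, 2.0, 3.0])
        for fn in (moran_autocorrelation, geary_autocorrelation, broto_moreau_autocorrelation):
            assert fn(PATH3, w, 9) == 0.0

    @pytest.mark.parametrize("lag", [0, -3])
    def test_nonpositive_lag_rejected(self, lag):
        with pytest.raises(ValueError):
            moran_autocorrelation(PATH3, np.ones(3), lag)

    def test_kernels_match_brute_force_oracle(self, rng):
        for _ in range(200):
            g = random_graph(rng)
            w = rng.uniform(0.5, 3.0, size=g.n_atoms)
            lag = int(rng.integers(1, 6))
            assert moran_autocorrelation(g, w, lag) == pytest.approx(
                moran_brute(g, list(w), lag), abs=1e-12
            )
            assert geary_autocorrelation(g, w, lag) == pytest.approx(
                geary_brute(g, list(w), lag), abs=1e-12
            )
            assert broto_moreau_autocorrelation(g, w, lag) == pytest.approx(
                ats_brute(g, list(w), lag), abs=1e-12
            )

    def test_relabelling_invariance(self, rng):
        for _ in range(20):
            g = random_graph(rng, max_atoms=10)
            if g.n_atoms < 3:
                continue
            perm = rng.permutation(g.n_atoms)
            inv = np.argsort(perm)
            atoms = tuple(g.atoms[inv[k]] for k in range(g.n_atoms))
            bonds = tuple(
                (min(perm[i], perm[j]), max(perm[i], perm[j]), o) for i, j, o in g.bonds
            )
            g2 = MolecularGraph(atoms=atoms, bonds=bonds)
            w = rng.uniform(0.5, 3.0, size=g.n_atoms)
            w2 = w[inv]
            for fn in (moran_autocorrelation, geary_autocorrelation, broto_moreau_autocorrelation):
                assert fn(g, w, 2) == pytest.approx(fn(g2, w2, 2), abs=1e-10)


class TestBurdenEigenvalues:
    def test_single_atom_eigenvalue_is_weight(self):
        g = MolecularGraph(atoms=(("C", 0),), bonds=())
        assert burden_eigenvalues(g, np.array([2.5]), 1) == pytest.approx(2.5)

    def test_two_carbon_closed_form(self):
        w = np.ones(2)
        assert burden_eigenvalues(PAIR, w, 1, "highest") == pytest.approx(1.1)
        assert burden_eigenvalues(PAIR, w, 2, "highest") == pytest.approx(0.9)
        assert burden_eigenvalues(PAIR, w, 1, "lowest") == pytest.approx(0.9)

    def test_trace_identity_and_monotonicity(self, rng):
        for _ in range(30):
            g = random_graph(rng)
            w = rng.uniform(0.5, 3.0, size=g.n_atoms)
            eigs = [burden_eigenvalues(g, w, k, "highest") for k in range(1, g.n_atoms + 1)]
            assert sum(eigs) == pytest.approx(w.sum(), abs=1e-9)
            assert all(a >= b - 1e-12 for a, b in zip(eigs, eigs[1:]))

    def test_aromatic_bond_order_enters_matrix(self):
        g = parse_smiles("c1ccccc1")
        B = burden_matrix(g, np.ones(6))
        assert B[0, 1] == pytest.approx(0.15)  # 0.1 * 1.5
        assert B[0, 3] == pytest.approx(0.001)  # non-bonded para pair

    def test_rank_out_of_range(self):
        with pytest.raises(ValueError, match="out of range"):
            burden_eigenvalues(PAIR, np.ones(2), 3)


class TestNameGrammarAndMatrix:
    @pytest.mark.parametrize(
        "name, family",
        [("MATS5v", "MATS"), ("GATS8p", "GATS"), ("ATS1u", "ATS"), ("BEHp2", "BEH"), ("BELm1", "BEL")],
    )
    def test_name_grammar(self, name, family):
        assert parse_descriptor_name(name)["family"] == family

    def test_unknown_family_advises_import(self):
        with pytest.raises(ValueError, match="imported from a descriptor CSV"):
            parse_descriptor_name("RDF035m")

    def test_final_model_descriptor_set_column_order(self):
        mols = [parse_smiles(s, id=f"m{i}") for i, s in enumerate(["CCO", "c1ccccc1", "CC(N)C(=O)O"])]
        X = compute_matrix(mols, ["MATS2m", "GATS8p", "MATS5v", "BEHp2"])
        assert X.names == ["MATS2m", "GATS8p", "MATS5v", "BEHp2"]
        assert X.provenance == "computed"
        assert np.isfinite(X.values).all()

    def test_empty_molecule_list_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            compute_matrix([], ["MATS2m"])

    def test_duplicate_names_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            compute_matrix([parse_smiles("CCO")], ["MATS2m", "MATS2m"])


def _dm(arrays: dict) -> DescriptorMatrix:
    frame = pd.DataFrame(arrays)
    frame.index = [f"c{k}" for k in range(len(frame))]
    return DescriptorMatrix(frame=frame)


class TestPrefilter:
    def test_constant_column_removed(self):
        X = _dm({"a": [1.0, 2, 3, 4], "b": [5.0, 5, 5, 5]})
        out, log = prefilter(X)
        assert out.names == ["a"]
        assert log[0][0] == "b" and "near-constant" in log[0][1]

    def test_identical_columns_later_one_dropped(self):
        X = _dm({"a": [1.0, 2, 3, 4], "b": [1.0, 2, 3, 4]})
        out, log = prefilter(X)
        assert out.names == ["a"]
        assert log[0][0] == "b"

    def test_correlation_cutoff_controls_removal(self, rng):
        # Cholesky mixing: corr(a, b) = 0.96 by construction
        z1, z2 = rng.standard_normal((2, 4000))
        r = 0.96
        a = z1
        b = r * z1 + np.sqrt(1 - r**2) * z2
        got = np.corrcoef(a, b)[0, 1]
        assert got == pytest.approx(0.96, abs=0.02)
        X = _dm({"a": a, "b": b})
        kept_95, _ = prefilter(X, corr_cutoff=0.95)
        kept_99, _ = prefilter(X, corr_cutoff=0.99)
        assert kept_95.names == ["a"]
        assert kept_99.names == ["a", "b"]

    def test_idempotence(self, rng):
        X = _dm({f"c{k}": rng.standard_normal(30) for k in range(8)})
        once, _ = prefilter(X)
        twice, log = prefilter(once)
        assert twice.names == once.names and log == []

    def test_all_columns_removed_is_an_error(self):
        X = _dm({"a": [1.0, 1, 1], "b": [2.0, 2, 2]})
        with pytest.raises(ValueError, match="every column"):
            prefilter(X)
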