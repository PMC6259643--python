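import numpy as np
import pytest

from qsarpls.molgraph import MolecularGraph

ELEMENTS = ["C", "C", "C", "N", "O", "S", "F", "Cl", "Br"]  # C over-weighted


def random_graph(rng: np.random.Generator, max_atoms: int = 12) -> MolecularGraph:
    """Random connected labelled graph: spanning tree + a few extra edges.

    Bond orders are drawn from {1, 2, 3, 1.5}; element labels from a small
    organic alphabet.  Valences are NOT enforced — these graphs exercise the
    descriptor kernels, which are defined on arbitrary labelled graphs.
    """
    n = int(rng.integers(1, max_atoms + 1))
    atoms = tuple((ELEMENTS[rng.integers(len(ELEMENTS))], 0) for _ in range(n))
    orders = [1.0, 1.0, 2.0, 3.0, 1.5]
    bonds = []
    present = set()
    for j in range(1, n):
        i = int(rng.integers(j))
        bonds.append((i, j, orders[rng.integers(len(orders))]))
        present.add((i, j))
    n_extra = int(rng.integers(0, max(1, n // 3) + 1))
    for _ in range(n_extra):
        i, j = sorted(rng.choice(n, size=2, replace=False)) if n > 1 else (0, 0)
        i, j = int(i), int(j)
        if i != j and (i, j) not in present:
            bonds.append((i, j, orders[rng.integers(len(orders))]))
            present.add((i, j))
    return MolecularGraph(atoms=atoms, bonds=tuple(bonds), id=f"rg{n}")


def floyd_warshall(g: MolecularGraph) -> np.ndarray:
    """Independent all-pairs shortest-path oracle (unit edge weights)."""
    n = g.n_atoms
    D = np.full((n, n), np.inf)
    np.fill_diagonal(D, 0.0)
    for i, j, _ in g.bonds:
        D[i, j] = D[j, i] = 1.0
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if D[i, k] + D[k, j] < D[i, j]:
                    D[i, j] = D[i, k] + D[k, j]
    return D


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)


@pytest.fixture(scope="session")
def planted():
    """Default planted-model benchmark shared across regression/GA tests."""
    from qsarpls.synthetic import SyntheticSpec, gen_descriptor_data

    return gen_descriptor_data(SyntheticSpec(seed=42))
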