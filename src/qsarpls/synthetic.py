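"""Synthetic data generators and packaged literature fixtures.

The original descriptor values behind the published CXCR2 models are not
available, so every pipeline stage is exercised on synthetic inputs that have
the statistical structure the analysis assumes:

* ``gen_descriptor_data`` draws a descriptor matrix with controllable
  inter-column correlation (latent-factor mixing, emulating the strong
  collinearity that motivates PLS and GA selection) and an activity that is a
  sparse linear function of a known descriptor subset plus Gaussian noise.
  The generating truth is returned so recovery can be scored.
* ``gen_molecules`` draws random valence-respecting molecular graphs (trees
  with optional ring closures) over organic elements, for exercising the
  SMILES → descriptor path end to end.

The packaged fixtures transcribe published activity tables (IC50/pIC50 by
chemical series) and the published external test-set predictions; their SHA256
checksums are verified at load time.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .dataset import ActivityVector, ic50_to_pic50
from .descriptors import DescriptorMatrix
from .molgraph import MolecularGraph, parse_smiles

__all__ = [
    "SyntheticSpec",
    "gen_descriptor_data",
    "gen_molecules",
    "load_activity_table",
    "load_prediction_table",
]

# maximum heavy-atom valence used by the random molecule generator
_VALENCE = {"C": 4, "N": 3, "O": 2, "S": 2, "F": 1, "Cl": 1, "Br": 1}
_DEFAULT_ELEMENT_WEIGHTS = {"C": 0.7, "N": 0.1, "O": 0.1, "S": 0.04, "F": 0.02, "Cl": 0.02, "Br": 0.02}


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions for the planted-model benchmark."""

    n_compounds: int = 120
    n_descriptors: int = 50
    n_informative: int = 5
    beta: float = 2.0
    noise_sd: float = 0.3
    correlation: float = 0.5  # latent-factor mixing strength in [0, 1)
    size_range: tuple[int, int] = (5, 30)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_informative > self.n_descriptors:
            raise ValueError("n_informative cannot exceed n_descriptors")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0 <= self.correlation < 1:
            raise ValueError("correlation must lie in [0, 1)")


def gen_descriptor_data(
    spec: SyntheticSpec,
) -> tuple[DescriptorMatrix, ActivityVector, dict]:
    """Planted sparse linear model with collinear descriptors.

    X columns mix independent noise with shared latent factors
    (X_j = sqrt(1-c²)·ε_j + c·F·m_j), y = X[:, support] @ beta + noise.
    Returns (X, y, truth) where truth holds the support indices/names and
    coefficients.
    """
    rng = np.random.default_rng(spec.seed)
    n, p = spec.n_compounds, spec.n_descriptors
    n_factors = max(2, p // 10)
    F = rng.standard_normal((n, n_factors))
    mix = rng.standard_normal((n_factors, p)) / np.sqrt(n_factors)
    eps = rng.standard_normal((n, p))
    c = spec.correlation
    X = np.sqrt(1 - c**2) * eps + c * (F @ mix)
    support = np.sort(rng.choice(p, size=spec.n_informative, replace=False))
    beta = np.full(spec.n_informative, spec.beta)
    y = X[:, support] @ beta + rng.normal(0.0, spec.noise_sd, size=n)
    ids = [f"S{k + 1:03d}" for k in range(n)]
    names = [f"D{j + 1:03d}" for j in range(p)]
    frame = pd.DataFrame(X, index=ids, columns=names)
    truth = {
        "support": support,
        "support_names": [names[j] for j in support],
        "beta": beta,
    }
    return (
        DescriptorMatrix(frame=frame, provenance="computed"),
        ActivityVector(ids=ids, values=y),
        truth,
    )


def gen_molecules(spec: SyntheticSpec, element_weights=None) -> list[MolecularGraph]:
    """Random connected valence-respecting molecules (trees + ring closures).

    Built atom by atom as a random spanning tree, then extra ring-closure
    bonds are added where both endpoints have spare valence.  Graphs are
    emitted through SMILES so that RDKit is the arbiter of validity.
    """
    from rdkit import Chem

    lo, hi = spec.size_range
    if lo < 2:
        raise ValueError("molecules need at least 2 heavy atoms")
    weights = dict(_DEFAULT_ELEMENT_WEIGHTS if element_weights is None else element_weights)
    elems = list(weights)
    probs = np.array([weights[e] for e in elems], dtype=float)
    probs /= probs.sum()
    rng = np.random.default_rng(spec.seed)
    molecules = []
    for k in range(spec.n_compounds):
        size = int(rng.integers(lo, hi + 1))
        rw = Chem.RWMol()
        free: list[int] = []  # remaining valence per atom index
        symbols: list[str] = []
        while rw.GetNumAtoms() < size:
            # univalent halogens cannot host further growth; force a branching
            # element while the skeleton still has to grow
            need_branch = rw.GetNumAtoms() < size - 1
            while True:
                sym = str(rng.choice(elems, p=probs))
                if not need_branch or _VALENCE[sym] >= 2:
                    break
            idx = rw.AddAtom(Chem.Atom(sym))
            symbols.append(sym)
            free.append(_VALENCE[sym])
            if idx > 0:
                hosts = [a for a in range(idx) if free[a] > 0]
                host = int(rng.choice(hosts))
                rw.AddBond(host, idx, Chem.BondType.SINGLE)
                free[host] -= 1
                free[idx] -= 1
        # optional ring closures between non-adjacent atoms with spare valence
        n_rings = int(rng.integers(0, 3))
        for _ in range(n_rings):
            cands = [a for a in range(size) if free[a] > 0]
            rng.shuffle(cands)
            done = False
            for a in cands:
                for b in cands:
                    if b <= a or rw.GetBondBetweenAtoms(a, b) is not None:
                        continue
                    rw.AddBond(a, b, Chem.BondType.SINGLE)
                    free[a] -= 1
                    free[b] -= 1
                    done = True
                    break
                if done:
                    break
        mol = rw.GetMol()
        Chem.SanitizeMol(mol)
        smiles = Chem.MolToSmiles(mol)
        molecules.append(parse_smiles(smiles, id=f"M{k + 1:03d}"))
    return molecules


def write_smiles_file(molecules: list[MolecularGraph], activities, path) -> None:
    """Write an ``id SMILES activity`` fixture file for the CLI workflow."""
    from rdkit import Chem

    with open(path, "w") as fh:
        fh.write("# id SMILES activity\n")
        for g, act in zip(molecules, activities):
            mol = Chem.RWMol()
            for sym, charge in g.atoms:
                a = Chem.Atom(sym)
                a.SetFormalCharge(charge)
                mol.AddAtom(a)
            order_map = {1.0: Chem.BondType.SINGLE, 2.0: Chem.BondType.DOUBLE,
                         3.0: Chem.BondType.TRIPLE, 1.5: Chem.BondType.AROMATIC}
            for i, j, order in g.bonds:
                mol.AddBond(i, j, order_map[order])
            m = mol.GetMol()
            Chem.SanitizeMol(m)
            fh.write(f"{g.id} {Chem.MolToSmiles(m)} {act}\n")


# ---------------------------------------------------------------------------
# Packaged literature fixtures
# ---------------------------------------------------------------------------

def _fixture_bytes(name: str) -> bytes:
    path = resources.files("qsarpls.data.fixtures").joinpath(name)
    data = path.read_bytes()
    checks = json.loads(
        resources.files("qsarpls.data.fixtures").joinpath("checksums.json").read_text()
    )
    digest = hashlib.sha256(data).hexdigest()
    if checks[name] != digest:
        raise RuntimeError(f"fixture {name} checksum mismatch: {digest}")
    return data


def load_activity_table() -> pd.DataFrame:
    """Transcribed IC50/pIC50 table with a recomputed ``self_consistent`` flag.

    ``pic50_computed`` is -log10(IC50 in mol/L) under the *printed* unit;
    ``self_consistent`` is true when it matches the printed pIC50 within ±0.01
    at 2-dp rounding.  See the fixture NOTES for the known discrepancies.
    """
    import io

    df = pd.read_csv(io.BytesIO(_fixture_bytes("cxcr2_activities.csv")), comment="#")
    df["compound_id"] = df["compound_id"].astype(str)
    df["pic50_computed"] = [
        ic50_to_pic50(v, u) for v, u in zip(df["ic50"], df["ic50_unit"])
    ]
    df["self_consistent"] = (
        (df["pic50_computed"].round(2) - df["pic50_printed"]).abs() <= 0.01 + 1e-9
    )
    return df.set_index("compound_id")


def load_prediction_table() -> pd.DataFrame:
    """Transcribed external test-set predictions of the three published models."""
    import io

    df = pd.read_csv(io.BytesIO(_fixture_bytes("test_set_predictions.csv")), comment="#")
    df["compound_id"] = df["compound_id"].astype(str)
    return df.set_index("compound_id")
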