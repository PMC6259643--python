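"""Hydrogen-depleted molecular graphs and the primitives the descriptor kernels need.

A molecule is represented as a labelled graph over its heavy atoms: element
symbols with formal charges on the vertices, bond orders (1, 2, 3 or 1.5 for
aromatic) on the edges.  Topological distances are shortest-path bond counts,
which is what the 2D-autocorrelation lags refer to.  Atomic property weights
(mass, van der Waals volume, Sanderson electronegativity, polarizability) are
read from a packaged table and, by default, scaled so that carbon equals 1 —
the convention the Dragon descriptor family documents.
"""

from __future__ import annotations

import csv
from collections import deque
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

__all__ = [
    "MolecularGraph",
    "AtomPropertyTable",
    "DistanceMatrix",
    "SmilesError",
    "parse_smiles",
    "read_smiles_file",
    "topological_distances",
    "atom_weights",
    "PROPERTIES",
]

#: bond order used for aromatic bonds in the Burden matrix
AROMATIC_ORDER = 1.5

PROPERTIES = ("mass", "volume", "electronegativity", "polarizability")


class SmilesError(ValueError):
    """Raised when a SMILES string cannot be turned into a connected heavy-atom graph."""


@dataclass(frozen=True)
class MolecularGraph:
    """Hydrogen-depleted labelled molecular graph.

    atoms: (element symbol, formal charge) per heavy atom, 0-indexed.
    bonds: (i, j, order) with i < j; order in {1.0, 2.0, 3.0, 1.5 (aromatic)}.
    """

    atoms: tuple[tuple[str, int], ...]
    bonds: tuple[tuple[int, int, float], ...]
    id: str = ""

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def n_bonds(self) -> int:
        return len(self.bonds)

    def adjacency(self) -> list[list[int]]:
        adj: list[list[int]] = [[] for _ in range(self.n_atoms)]
        for i, j, _ in self.bonds:
            adj[i].append(j)
            adj[j].append(i)
        return adj

    def __post_init__(self) -> None:
        n = len(self.atoms)
        seen = set()
        for i, j, order in self.bonds:
            if not (0 <= i < n and 0 <= j < n):
                raise ValueError(f"bond ({i},{j}) out of range for {n} atoms")
            if i == j:
                raise ValueError(f"self-loop on atom {i}")
            key = (min(i, j), max(i, j))
            if key in seen:
                raise ValueError(f"duplicate bond {key}")
            seen.add(key)


@dataclass(frozen=True)
class DistanceMatrix:
    """All-pairs shortest-path bond counts of a connected graph."""

    values: np.ndarray  # (n, n) int array
    diameter: int

    def __getitem__(self, idx):
        return self.values[idx]


@dataclass
class AtomPropertyTable:
    """Per-element atomic properties used as autocorrelation / Burden weights.

    When ``carbon_scaled`` is set (the default), every lookup returns the raw
    value divided by the carbon value, so any pure-carbon skeleton has unit
    weights for every property.
    """

    entries: dict[str, dict[str, float]] = field(default_factory=dict)
    carbon_scaled: bool = True

    @classmethod
    def default(cls, carbon_scaled: bool = True) -> "AtomPropertyTable":
        path = resources.files("qsarpls.data").joinpath("atom_properties.csv")
        entries: dict[str, dict[str, float]] = {}
        with path.open("r") as fh:
            rows = [r for r in csv.reader(fh) if r and not r[0].startswith("#")]
        header = rows[0]
        for row in rows[1:]:
            rec = dict(zip(header, row))
            entries[rec["element"]] = {p: float(rec[p]) for p in PROPERTIES}
        return cls(entries=entries, carbon_scaled=carbon_scaled)

    def value(self, element: str, prop: str) -> float:
        if prop not in PROPERTIES:
            raise KeyError(f"unknown property {prop!r}; expected one of {PROPERTIES}")
        if element not in self.entries:
            raise KeyError(
                f"element {element!r} not in property table; available: "
                f"{sorted(self.entries)}"
            )
        raw = self.entries[element][prop]
        if self.carbon_scaled:
            return raw / self.entries["C"][prop]
        return raw


def _mol_from_smiles(text: str):
    from rdkit import Chem

    mol = Chem.MolFromSmiles(text)
    if mol is None:
        # RDKit logs the offending position; re-derive a coarse pointer here.
        raise SmilesError(f"invalid SMILES: could not parse {text!r}")
    return mol


def parse_smiles(text: str, id: str = "") -> MolecularGraph:
    """Parse a SMILES string into a hydrogen-depleted :class:`MolecularGraph`.

    Aromaticity perception is delegated to RDKit; aromatic bonds carry order
    1.5.  Disconnected (dot-separated) inputs are rejected.
    """
    from rdkit import Chem

    if "." in text:
        raise SmilesError(
            f"disconnected molecule (dot-separated SMILES) not supported: {text!r}"
        )
    mol = _mol_from_smiles(text)
    mol = Chem.RemoveHs(mol)
    frags = Chem.GetMolFrags(mol)
    if len(frags) > 1:
        raise SmilesError(f"molecule has {len(frags)} fragments; expected 1: {text!r}")
    atoms = tuple(
        (a.GetSymbol(), a.GetFormalCharge())
        for a in mol.GetAtoms()
        if a.GetAtomicNum() > 1
    )
    if len(atoms) != mol.GetNumAtoms():
        raise SmilesError(f"unexpected explicit hydrogens survive in {text!r}")
    order_map = {
        Chem.BondType.SINGLE: 1.0,
        Chem.BondType.DOUBLE: 2.0,
        Chem.BondType.TRIPLE: 3.0,
        Chem.BondType.AROMATIC: AROMATIC_ORDER,
    }
    bonds = []
    for b in mol.GetBonds():
        if b.GetBondType() not in order_map:
            raise SmilesError(f"unsupported bond type {b.GetBondType()} in {text!r}")
        i, j = b.GetBeginAtomIdx(), b.GetEndAtomIdx()
        bonds.append((min(i, j), max(i, j), order_map[b.GetBondType()]))
    return MolecularGraph(atoms=atoms, bonds=tuple(sorted(bonds)), id=id)


def read_smiles_file(path) -> list[tuple[MolecularGraph, float | None]]:
    """Read a whitespace-separated SMILES file: ``id SMILES [activity]`` per line.

    Lines starting with ``#`` are skipped.  Returns (graph, activity-or-None)
    pairs in file order.
    """
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected 'id SMILES [activity]'")
            cid, smi = parts[0], parts[1]
            activity = float(parts[2]) if len(parts) > 2 else None
            out.append((parse_smiles(smi, id=cid), activity))
    return out


def topological_distances(g: MolecularGraph) -> DistanceMatrix:
    """Breadth-first all-pairs shortest paths; every bond counts as one edge."""
    n = g.n_atoms
    adj = g.adjacency()
    D = np.full((n, n), -1, dtype=int)
    for src in range(n):
        D[src, src] = 0
        q = deque([src])
        while q:
            u = q.popleft()
            for v in adj[u]:
                if D[src, v] < 0:
                    D[src, v] = D[src, u] + 1
                    q.append(v)
    if (D < 0).any():
        raise ValueError(f"graph {g.id!r} is disconnected: unreachable atom pair")
    return DistanceMatrix(values=D, diameter=int(D.max()))


def atom_weights(
    g: MolecularGraph,
    prop: str,
    table: AtomPropertyTable | None = None,
) -> np.ndarray:
    """Per-atom weight vector for one atomic property (carbon-scaled if the table says so)."""
    if table is None:
        table = AtomPropertyTable.default()
    return np.array([table.value(sym, prop) for sym, _charge in g.atoms], dtype=float)
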