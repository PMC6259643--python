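"""2D-autocorrelation (ATS/MATS/GATS) and Burden-eigenvalue (BEH/BEL) descriptors.

The descriptor families computed here are exactly the ones appearing in the
final stepwise-MLR model of the workflow (Moran and Geary topological
autocorrelations, Broto-Moreau sums, Burden eigenvalues), plus a handful of
constitutional counts.  Conventions, frozen here and documented in
``docs/methods.md``:

* Autocorrelation sums run over ordered atom pairs at topological distance
  equal to the lag; Moran normalizes by the ordered pair count and the
  population variance, Geary by twice the ordered pair count and the sample
  variance (the standard Moran/Geary spatial-statistics forms).
* Zero weight variance or an empty lag returns 0, never NaN, so matrix
  assembly is total; the prefilter later removes the resulting constant
  columns.
* Burden matrix: diagonal = atomic weights; bonded off-diagonal = 0.1 x bond
  order (aromatic = 1.5); non-bonded off-diagonal = 0.001.  BEHwk is the k-th
  largest eigenvalue, BELwk the k-th smallest.

Descriptor names follow the Dragon grammar: ``MATS5v`` = Moran, lag 5,
van-der-Waals-volume weighted; ``BEHp2`` = Burden highest eigenvalue rank 2,
polarizability weighted; suffix ``u`` means unit (unweighted).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .molgraph import (
    AtomPropertyTable,
    MolecularGraph,
    atom_weights,
    topological_distances,
)

__all__ = [
    "DescriptorMatrix",
    "moran_autocorrelation",
    "geary_autocorrelation",
    "broto_moreau_autocorrelation",
    "burden_eigenvalues",
    "compute_matrix",
    "prefilter",
    "parse_descriptor_name",
    "read_descriptor_csv",
    "write_descriptor_csv",
]

_WEIGHT_LETTERS = {
    "m": "mass",
    "v": "volume",
    "e": "electronegativity",
    "p": "polarizability",
    "u": None,  # unweighted: all weights 1
}

_AUTOCORR_RE = re.compile(r"^(ATS|MATS|GATS)(\d+)([mvepu])$")
_BURDEN_RE = re.compile(r"^(BEH|BEL)([mvepu])(\d+)$")
_CONSTITUTIONAL = ("nAT", "nBT", "nCIC")


@dataclass
class DescriptorMatrix:
    """Compounds x descriptors table with provenance and optional scaling state."""

    frame: pd.DataFrame  # index = compound ids, columns = descriptor names
    provenance: str = "computed"  # "computed" | "imported"
    means: pd.Series | None = None  # set once autoscaled (training statistics)
    sds: pd.Series | None = None

    @property
    def names(self) -> list[str]:
        return list(self.frame.columns)

    @property
    def ids(self) -> list[str]:
        return list(self.frame.index)

    @property
    def values(self) -> np.ndarray:
        return self.frame.to_numpy(dtype=float)

    def subset(self, names: list[str]) -> "DescriptorMatrix":
        missing = [n for n in names if n not in self.frame.columns]
        if missing:
            raise KeyError(f"descriptors not present: {missing}")
        return DescriptorMatrix(
            frame=self.frame[names].copy(),
            provenance=self.provenance,
            means=None if self.means is None else self.means[names],
            sds=None if self.sds is None else self.sds[names],
        )


def parse_descriptor_name(name: str) -> dict:
    """Decode a descriptor name into family / lag-or-rank / weight property."""
    m = _AUTOCORR_RE.match(name)
    if m:
        family, lag, wl = m.groups()
        if int(lag) < 1:
            raise ValueError(f"{name}: lag must be >= 1")
        return {"family": family, "lag": int(lag), "weight": _WEIGHT_LETTERS[wl]}
    m = _BURDEN_RE.match(name)
    if m:
        family, wl, rank = m.groups()
        if int(rank) < 1:
            raise ValueError(f"{name}: rank must be >= 1")
        return {"family": family, "rank": int(rank), "weight": _WEIGHT_LETTERS[wl]}
    if name in _CONSTITUTIONAL:
        return {"family": name}
    raise ValueError(
        f"unknown descriptor name {name!r}; native families are ATS/MATS/GATS "
        f"(+lag+weight), BEH/BEL (+weight+rank) and {_CONSTITUTIONAL}; other "
        "families (3D, RDF, WHIM, ...) must be imported from a descriptor CSV"
    )


def _lag_pairs(D: np.ndarray, lag: int) -> tuple[np.ndarray, np.ndarray]:
    """Ordered (i, j) index arrays of atom pairs at topological distance lag."""
    ii, jj = np.nonzero(D == lag)
    return ii, jj


def moran_autocorrelation(g: MolecularGraph, w: np.ndarray, lag: int) -> float:
    """Moran coefficient I(d) of the weight vector at topological lag d (MATS)."""
    if lag < 1:
        raise ValueError(f"lag must be >= 1, got {lag}")
    w = np.asarray(w, dtype=float)
    if w.shape != (g.n_atoms,):
        raise ValueError("weight vector length must equal atom count")
    D = topological_distances(g).values
    ii, jj = _lag_pairs(D, lag)
    if ii.size == 0:
        return 0.0
    dev = w - w.mean()
    denom = float(np.sum(dev**2)) / g.n_atoms
    if denom == 0.0:
        return 0.0
    num = float(np.sum(dev[ii] * dev[jj])) / ii.size
    return num / denom


def geary_autocorrelation(g: MolecularGraph, w: np.ndarray, lag: int) -> float:
    """Geary coefficient c(d) at topological lag d (GATS)."""
    if lag < 1:
        raise ValueError(f"lag must be >= 1, got {lag}")
    w = np.asarray(w, dtype=float)
    if w.shape != (g.n_atoms,):
        raise ValueError("weight vector length must equal atom count")
    if g.n_atoms < 2:
        return 0.0
    D = topological_distances(g).values
    ii, jj = _lag_pairs(D, lag)
    if ii.size == 0:
        return 0.0
    dev = w - w.mean()
    denom = float(np.sum(dev**2)) / (g.n_atoms - 1)
    if denom == 0.0:
        return 0.0
    num = float(np.sum((w[ii] - w[jj]) ** 2)) / (2 * ii.size)
    return num / denom


def broto_moreau_autocorrelation(g: MolecularGraph, w: np.ndarray, lag: int) -> float:
    """Broto-Moreau sum ATS(d) = sum over unordered pairs at lag d of w_i * w_j."""
    if lag < 1:
        raise ValueError(f"lag must be >= 1, got {lag}")
    w = np.asarray(w, dtype=float)
    if w.shape != (g.n_atoms,):
        raise ValueError("weight vector length must equal atom count")
    D = topological_distances(g).values
    ii, jj = _lag_pairs(D, lag)
    # ordered pairs counted twice -> halve
    return float(np.sum(w[ii] * w[jj])) / 2.0


def burden_matrix(g: MolecularGraph, w: np.ndarray) -> np.ndarray:
    """Burden (modified connectivity) matrix: weights on the diagonal, 0.1 x bond
    order for bonded pairs, 0.001 for non-bonded pairs."""
    n = g.n_atoms
    B = np.full((n, n), 0.001, dtype=float)
    np.fill_diagonal(B, np.asarray(w, dtype=float))
    for i, j, order in g.bonds:
        B[i, j] = B[j, i] = 0.1 * order
    return B


def burden_eigenvalues(
    g: MolecularGraph, w: np.ndarray, k: int, which: str = "highest"
) -> float:
    """k-th largest (BEH) or k-th smallest (BEL) eigenvalue of the Burden matrix."""
    if which not in ("highest", "lowest"):
        raise ValueError("which must be 'highest' or 'lowest'")
    if not 1 <= k <= g.n_atoms:
        raise ValueError(f"rank {k} out of range for {g.n_atoms} atoms")
    eig = np.linalg.eigvalsh(burden_matrix(g, w))  # ascending
    return float(eig[-k] if which == "highest" else eig[k - 1])


def _descriptor_value(g: MolecularGraph, name: str, table: AtomPropertyTable) -> float:
    info = parse_descriptor_name(name)
    fam = info["family"]
    if fam in _CONSTITUTIONAL:
        if fam == "nAT":
            return float(g.n_atoms)
        if fam == "nBT":
            return float(g.n_bonds)
        return float(g.n_bonds - g.n_atoms + 1)  # cyclomatic number, connected graph
    if info["weight"] is None:
        w = np.ones(g.n_atoms)
    else:
        w = atom_weights(g, info["weight"], table)
    if fam == "ATS":
        return broto_moreau_autocorrelation(g, w, info["lag"])
    if fam == "MATS":
        return moran_autocorrelation(g, w, info["lag"])
    if fam == "GATS":
        return geary_autocorrelation(g, w, info["lag"])
    if fam == "BEH":
        return burden_eigenvalues(g, w, info["rank"], "highest")
    return burden_eigenvalues(g, w, info["rank"], "lowest")


def compute_matrix(
    molecules: list[MolecularGraph],
    spec: list[str],
    table: AtomPropertyTable | None = None,
) -> DescriptorMatrix:
    """Compute the named descriptors for every molecule; columns follow ``spec`` order."""
    if not molecules:
        raise ValueError("empty molecule list")
    if len(set(spec)) != len(spec):
        dupes = sorted({n for n in spec if spec.count(n) > 1})
        raise ValueError(f"duplicate descriptor names in spec: {dupes}")
    for name in spec:
        parse_descriptor_name(name)  # fail fast on unknown families
    if table is None:
        table = AtomPropertyTable.default()
    rows = {
        (g.id or str(idx)): [_descriptor_value(g, name, table) for name in spec]
        for idx, g in enumerate(molecules)
    }
    frame = pd.DataFrame.from_dict(rows, orient="index", columns=spec)
    return DescriptorMatrix(frame=frame, provenance="computed")


def default_descriptor_names(max_lag: int = 8, max_rank: int = 4) -> list[str]:
    """A compact native descriptor catalogue: all autocorrelation lags up to
    ``max_lag`` and Burden ranks up to ``max_rank`` for each weighting, plus counts."""
    names = list(_CONSTITUTIONAL)
    for fam in ("ATS", "MATS", "GATS"):
        for lag in range(1, max_lag + 1):
            for wl in "mvep":
                names.append(f"{fam}{lag}{wl}")
    for fam in ("BEH", "BEL"):
        for wl in "mvep":
            for rank in range(1, max_rank + 1):
                names.append(f"{fam}{wl}{rank}")
    return names


def prefilter(
    X: DescriptorMatrix,
    near_constant_tol: float = 1e-8,
    corr_cutoff: float = 0.95,
) -> tuple[DescriptorMatrix, list[tuple[str, str]]]:
    """Drop near-constant columns, then one of each highly inter-correlated pair.

    Column pairs are scanned in fixed name order; when |r| exceeds the cutoff
    the later column is dropped (deterministic tie-break).  Returns the reduced
    matrix and a removal log of (name, reason) entries.
    """
    if not 0 < corr_cutoff <= 1:
        raise ValueError("corr_cutoff must lie in (0, 1]")
    log: list[tuple[str, str]] = []
    frame = X.frame.copy()
    sds = frame.std(ddof=1)
    for name in frame.columns[sds.to_numpy() <= near_constant_tol]:
        log.append((name, f"near-constant (sd={sds[name]:.3g})"))
    frame = frame.drop(columns=[n for n, _ in log])
    names = list(frame.columns)
    if not names:
        raise ValueError("prefilter removed every column")
    corr = frame.corr().abs().to_numpy()
    keep = np.ones(len(names), dtype=bool)
    for a in range(len(names)):
        if not keep[a]:
            continue
        for b in range(a + 1, len(names)):
            if keep[b] and corr[a, b] > corr_cutoff:
                keep[b] = False
                log.append(
                    (names[b], f"|r|={corr[a, b]:.4f}>{corr_cutoff} with {names[a]}")
                )
    frame = frame[[n for n, k in zip(names, keep) if k]]
    if frame.shape[1] == 0:
        raise ValueError("prefilter removed every column")
    return DescriptorMatrix(frame=frame, provenance=X.provenance), log


def read_descriptor_csv(path) -> DescriptorMatrix:
    """Import a descriptor CSV (``compound_id`` first column), e.g. for families
    not computed natively."""
    frame = pd.read_csv(path, index_col="compound_id")
    frame.index = frame.index.astype(str)
    return DescriptorMatrix(frame=frame, provenance="imported")


def write_descriptor_csv(X: DescriptorMatrix, path) -> None:
    # default float formatting is the shortest round-trip repr -> full precision
    X.frame.to_csv(path, index_label="compound_id")
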