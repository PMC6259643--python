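"""Activity handling, Kennard-Stone splitting, autoscaling and the PCA check.

Potencies arrive as IC50 values in molar units (M, mM, uM, nM) and are
modelled as pIC50 = -log10(IC50 in mol/L).  The training/prediction split uses
the Kennard-Stone maximin procedure on Euclidean distances over autoscaled
descriptors, which deterministically picks a training subset that covers the
occupied descriptor space.  Autoscaling uses the sample standard deviation
(n - 1 denominator) throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .descriptors import DescriptorMatrix

__all__ = [
    "ActivityVector",
    "SplitResult",
    "ic50_to_pic50",
    "pic50_to_ic50",
    "kennard_stone",
    "autoscale",
    "apply_scaling",
    "pca_check",
]

_UNIT_FACTORS = {"M": 1.0, "mM": 1e-3, "uM": 1e-6, "µM": 1e-6, "nM": 1e-9}


@dataclass
class ActivityVector:
    """pIC50 values aligned (by id and order) with descriptor-matrix rows."""

    ids: list[str]
    values: np.ndarray  # pIC50, log10 units
    source_units: str = "pIC50"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.ids) != self.values.size:
            raise ValueError("ids and values length mismatch")
        if not np.isfinite(self.values).all():
            raise ValueError("activities must be finite")

    def subset(self, ids: list[str]) -> "ActivityVector":
        pos = {cid: k for k, cid in enumerate(self.ids)}
        idx = [pos[cid] for cid in ids]
        return ActivityVector(list(ids), self.values[idx], self.source_units)


def ic50_to_pic50(value: float, unit: str = "M") -> float:
    """pIC50 = -log10(IC50 converted to mol/L).  Exact; round only for display."""
    if unit not in _UNIT_FACTORS:
        raise ValueError(f"unknown unit {unit!r}; expected one of {sorted(_UNIT_FACTORS)}")
    if not value > 0:
        raise ValueError(f"IC50 must be positive, got {value}")
    return -math.log10(value * _UNIT_FACTORS[unit])


def pic50_to_ic50(pic50: float) -> float:
    """Inverse transform; returns IC50 in mol/L."""
    return 10.0 ** (-pic50)


@dataclass
class SplitResult:
    train_ids: list[str]
    test_ids: list[str]
    selection_order: list[str]  # training compounds in the order selected


def kennard_stone(X: DescriptorMatrix, n_train: int) -> SplitResult:
    """Classic Kennard-Stone maximin selection on Euclidean distances.

    Seeds with the two mutually farthest points, then repeatedly adds the
    candidate whose minimum distance to the selected set is largest.  Ties are
    broken by the lowest row index, so the split is fully deterministic.
    """
    ids = X.ids
    n = len(ids)
    if not 2 <= n_train <= n:
        raise ValueError(f"n_train must lie in [2, {n}], got {n_train}")
    V = X.values
    # pairwise squared Euclidean distances
    sq = np.sum(V**2, axis=1)
    d2 = sq[:, None] + sq[None, :] - 2 * V @ V.T
    np.fill_diagonal(d2, -np.inf)
    # farthest pair, lowest indices on ties
    flat = np.argmax(d2)
    i, j = divmod(flat, n)
    first, second = min(i, j), max(i, j)
    selected = [first, second]
    in_set = np.zeros(n, dtype=bool)
    in_set[[first, second]] = True
    np.fill_diagonal(d2, np.inf)
    min_d2 = np.minimum(d2[first], d2[second])
    while len(selected) < n_train:
        min_d2[in_set] = -np.inf
        nxt = int(np.argmax(min_d2))  # argmax takes the first (lowest index) on ties
        selected.append(nxt)
        in_set[nxt] = True
        min_d2 = np.minimum(min_d2, d2[nxt])
    train = sorted(selected)
    test = [k for k in range(n) if not in_set[k]]
    return SplitResult(
        train_ids=[ids[k] for k in train],
        test_ids=[ids[k] for k in test],
        selection_order=[ids[k] for k in selected],
    )


def autoscale(X: DescriptorMatrix) -> DescriptorMatrix:
    """Center each column to mean 0 and scale to sample SD 1; statistics stored."""
    means = X.frame.mean()
    sds = X.frame.std(ddof=1)
    if (sds == 0).any():
        bad = list(sds.index[sds == 0])
        raise ValueError(f"zero-variance columns (run prefilter first): {bad}")
    return DescriptorMatrix(
        frame=(X.frame - means) / sds,
        provenance=X.provenance,
        means=means,
        sds=sds,
    )


def apply_scaling(X_new: DescriptorMatrix, reference: DescriptorMatrix) -> DescriptorMatrix:
    """Scale new rows with the training means/SDs stored on ``reference``."""
    if reference.means is None or reference.sds is None:
        raise ValueError("reference matrix carries no scaling parameters")
    if list(X_new.frame.columns) != list(reference.means.index):
        raise ValueError(
            "column names do not match the stored scaling parameters: "
            f"{list(X_new.frame.columns)} vs {list(reference.means.index)}"
        )
    return DescriptorMatrix(
        frame=(X_new.frame - reference.means) / reference.sds,
        provenance=X_new.provenance,
        means=reference.means,
        sds=reference.sds,
    )


def pca_check(X: DescriptorMatrix, n_components: int = 2):
    """PCA scores and explained-variance percentages for a homogeneity score plot."""
    from sklearn.decomposition import PCA

    V = X.values
    rank = int(np.linalg.matrix_rank(V - V.mean(axis=0)))
    if n_components > rank:
        raise ValueError(f"n_components={n_components} exceeds matrix rank {rank}")
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(V)
    pct = 100.0 * pca.explained_variance_ratio_
    return pd.DataFrame(
        scores, index=X.ids, columns=[f"PC{k + 1}" for k in range(n_components)]
    ), pct
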