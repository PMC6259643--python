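"""Ordinary / stepwise multiple linear regression and NIPALS partial least squares.

Both model kinds are exposed through one :class:`RegressionModel` container
whose coefficients live on the *original* descriptor scale, so prediction is a
plain affine map regardless of how the model was fitted.  PLS is a
single-response NIPALS with internal autoscaling of X and y; the nested
structure of NIPALS (component a+1 refines component a) is exploited to return
whole coefficient paths cheaply, which is what the cross-validation curve and
the genetic-algorithm fitness evaluation run on.

Conventions: residual = predicted - experimental; sample SD (n-1) everywhere;
latent-variable selection is the argmin of RMSECV with ties resolved toward
fewer components.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .dataset import ActivityVector
from .descriptors import DescriptorMatrix

__all__ = [
    "RegressionModel",
    "fit_mlr",
    "stepwise_select",
    "fit_pls",
    "select_lv",
    "predict",
    "nipals_coefficient_path",
    "cv_predictions",
]


@dataclass
class RegressionModel:
    """A fitted MLR or PLS model, affine in the raw descriptor values."""

    kind: str  # "MLR" | "PLS"
    names: list[str]
    coef: np.ndarray  # original descriptor scale
    intercept: float
    n_lv: int | None = None
    stats: dict = field(default_factory=dict)  # r2, F, se, training metadata

    def to_json(self) -> str:
        return json.dumps(
            {
                "kind": self.kind,
                "names": self.names,
                "coef": [float(c) for c in self.coef],
                "intercept": float(self.intercept),
                "n_lv": self.n_lv,
                "stats": {
                    k: (v.tolist() if isinstance(v, np.ndarray) else v)
                    for k, v in self.stats.items()
                },
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "RegressionModel":
        d = json.loads(text)
        return cls(
            kind=d["kind"],
            names=list(d["names"]),
            coef=np.asarray(d["coef"], dtype=float),
            intercept=float(d["intercept"]),
            n_lv=d.get("n_lv"),
            stats=d.get("stats", {}),
        )


def _design(X: DescriptorMatrix, names: list[str] | None = None) -> tuple[np.ndarray, list[str]]:
    names = list(X.frame.columns) if names is None else names
    return X.frame[names].to_numpy(dtype=float), names


def fit_mlr(X: DescriptorMatrix, y: ActivityVector, names: list[str] | None = None) -> RegressionModel:
    """Least-squares fit with intercept; reports coefficient SEs, R2 and the F-ratio."""
    A, names = _design(X, names)
    n, p = A.shape
    if n <= p + 1:
        raise ValueError(f"need n > p + 1 (n={n}, p={p})")
    M = np.column_stack([np.ones(n), A])
    rank = np.linalg.matrix_rank(M)
    if rank < p + 1:
        # point at the most collinear columns via correlation with earlier ones
        corr = np.corrcoef(A, rowvar=False)
        np.fill_diagonal(corr, 0.0)
        worst = [names[k] for k in np.argwhere(np.abs(corr) > 0.999999)[:, 1]]
        raise ValueError(f"design matrix is rank deficient; collinear columns: {sorted(set(worst)) or names}")
    beta, _, _, _ = np.linalg.lstsq(M, y.values, rcond=None)
    fitted = M @ beta
    resid = fitted - y.values
    sse = float(resid @ resid)
    sst = float(np.sum((y.values - y.values.mean()) ** 2))
    dof = n - p - 1
    sigma2 = sse / dof
    cov = sigma2 * np.linalg.inv(M.T @ M)
    se = np.sqrt(np.diag(cov))
    r2 = 1.0 - sse / sst
    f_ratio = ((sst - sse) / p) / sigma2 if p > 0 else float("nan")
    return RegressionModel(
        kind="MLR",
        names=names,
        coef=beta[1:],
        intercept=float(beta[0]),
        stats={
            "r2": r2,
            "F": f_ratio,
            "se_intercept": float(se[0]),
            "se": se[1:],
            "n": n,
            "sigma2": sigma2,
        },
    )


def stepwise_select(
    X: DescriptorMatrix,
    y: ActivityVector,
    alpha_enter: float = 0.05,
    alpha_remove: float = 0.10,
    max_terms: int | None = None,
) -> tuple[list[str], RegressionModel | None, list[str]]:
    """Forward selection with backward elimination on partial-F p-values.

    Returns (selected names, fitted model or None, selection trace).  An empty
    selection (nothing passes ``alpha_enter`` at step 1) yields model None.
    """
    if alpha_enter > alpha_remove:
        raise ValueError("alpha_enter must be <= alpha_remove")
    pool = list(X.frame.columns)
    if max_terms is None:
        max_terms = len(pool)
    selected: list[str] = []
    trace: list[str] = []

    def _pvalue_of_last(cols: list[str]) -> float:
        m = fit_mlr(X, y, cols)
        t = m.coef[-1] / m.stats["se"][-1]
        dof = m.stats["n"] - len(cols) - 1
        return 2.0 * stats.t.sf(abs(t), dof)

    changed = True
    while changed and len(selected) < max_terms:
        changed = False
        # forward step
        best_name, best_p = None, None
        for cand in pool:
            if cand in selected:
                continue
            try:
                p = _pvalue_of_last(selected + [cand])
            except (ValueError, np.linalg.LinAlgError):
                continue
            if best_p is None or p < best_p:
                best_name, best_p = cand, p
        if best_name is not None and best_p < alpha_enter:
            selected.append(best_name)
            trace.append(f"+{best_name} (p={best_p:.3g})")
            changed = True
        # backward step: drop any included term whose p-value exceeds alpha_remove
        dropped = True
        while dropped and len(selected) > 1:
            dropped = False
            worst_name, worst_p = None, None
            for name in selected:
                reordered = [c for c in selected if c != name] + [name]
                p = _pvalue_of_last(reordered)
                if worst_p is None or p > worst_p:
                    worst_name, worst_p = name, p
            if worst_p is not None and worst_p > alpha_remove:
                selected.remove(worst_name)
                trace.append(f"-{worst_name} (p={worst_p:.3g})")
                dropped = True
                changed = True
    if not selected:
        return [], None, trace + ["no candidate passed alpha_enter"]
    return selected, fit_mlr(X, y, selected), trace


# ---------------------------------------------------------------------------
# NIPALS PLS
# ---------------------------------------------------------------------------

def nipals_coefficient_path(
    A: np.ndarray, yv: np.ndarray, max_lv: int
) -> tuple[np.ndarray, np.ndarray, float, np.ndarray, np.ndarray]:
    """Single-response NIPALS on raw arrays.

    Autoscales internally and returns ``(paths, x_mean, y_mean, x_sd, scores)``
    where ``paths[a]`` is the original-scale coefficient vector using ``a+1``
    latent variables.  Deterministic; components are capped at the effective
    rank (a component with negligible score variance terminates the loop).
    """
    A = np.asarray(A, dtype=float)
    yv = np.asarray(yv, dtype=float)
    n, p = A.shape
    x_mean = A.mean(axis=0)
    x_sd = A.std(axis=0, ddof=1)
    x_sd[x_sd == 0] = 1.0  # constant columns carry no information; keep finite
    y_mean = float(yv.mean())
    y_sd = float(yv.std(ddof=1)) or 1.0
    Xc = (A - x_mean) / x_sd
    yc = (yv - y_mean) / y_sd
    W = np.zeros((p, max_lv))
    P = np.zeros((p, max_lv))
    Q = np.zeros(max_lv)
    T = np.zeros((n, max_lv))
    Xd, yd = Xc.copy(), yc.copy()
    used = 0
    for a in range(max_lv):
        w = Xd.T @ yd
        nw = np.linalg.norm(w)
        if nw < 1e-12:
            break
        w /= nw
        t = Xd @ w
        tt = float(t @ t)
        if tt < 1e-12:
            break
        pvec = Xd.T @ t / tt
        q = float(yd @ t) / tt
        Xd = Xd - np.outer(t, pvec)
        yd = yd - q * t
        W[:, a], P[:, a], Q[a], T[:, a] = w, pvec, q, t
        used = a + 1
    paths = np.zeros((max_lv, p))
    for a in range(used):
        Wa, Pa, Qa = W[:, : a + 1], P[:, : a + 1], Q[: a + 1]
        # B_scaled = W (P'W)^-1 q
        b_scaled = Wa @ np.linalg.solve(Pa.T @ Wa, Qa)
        paths[a] = b_scaled * y_sd / x_sd
    for a in range(used, max_lv):  # rank exhausted: path flat beyond `used`
        paths[a] = paths[used - 1] if used else 0.0
    return paths, x_mean, y_mean, x_sd, T[:, :used]


def fit_pls(
    X: DescriptorMatrix, y: ActivityVector, n_lv: int, names: list[str] | None = None
) -> RegressionModel:
    """NIPALS PLS with ``n_lv`` latent variables; coefficients on the raw scale."""
    A, names = _design(X, names)
    rank = int(np.linalg.matrix_rank(A - A.mean(axis=0)))
    if not 1 <= n_lv <= rank:
        raise ValueError(f"n_lv must lie in [1, rank={rank}], got {n_lv}")
    paths, x_mean, y_mean, x_sd, T = nipals_coefficient_path(A, y.values, n_lv)
    coef = paths[n_lv - 1]
    intercept = y_mean - float(x_mean @ coef)
    fitted = A @ coef + intercept
    sse = float(np.sum((fitted - y.values) ** 2))
    sst = float(np.sum((y.values - y.values.mean()) ** 2))
    return RegressionModel(
        kind="PLS",
        names=names,
        coef=coef,
        intercept=intercept,
        n_lv=n_lv,
        stats={"r2": 1.0 - sse / sst, "n": len(y.values), "scores": T},
    )


def _fold_indices(n: int, cv, rng: np.random.Generator | None = None):
    """CV folds: "loo", an integer k (contiguous balanced folds, deterministic),
    or an explicit list of index arrays."""
    if cv == "loo":
        return [np.array([i]) for i in range(n)]
    if isinstance(cv, int):
        if cv > n:
            raise ValueError(f"{cv} folds exceed {n} samples")
        idx = np.arange(n)
        if rng is not None:
            idx = rng.permutation(n)
        return [fold for fold in np.array_split(idx, cv)]
    return [np.asarray(f) for f in cv]


def cv_predictions(
    A: np.ndarray, yv: np.ndarray, max_lv: int, folds
) -> np.ndarray:
    """Cross-validated predictions for every LV count: returns (max_lv, n) array."""
    n = len(yv)
    preds = np.zeros((max_lv, n))
    for fold in folds:
        mask = np.ones(n, dtype=bool)
        mask[fold] = False
        paths, x_mean, y_mean, _, _ = nipals_coefficient_path(A[mask], yv[mask], max_lv)
        for a in range(max_lv):
            coef = paths[a]
            intercept = y_mean - float(x_mean @ coef)
            preds[a, fold] = A[fold] @ coef + intercept
    return preds


def select_lv(
    X: DescriptorMatrix,
    y: ActivityVector,
    max_lv: int,
    cv="loo",
    rng: np.random.Generator | None = None,
) -> tuple[int, np.ndarray]:
    """Pick the LV count minimizing RMSECV (ties -> fewer LVs); returns the curve too."""
    if max_lv < 1:
        raise ValueError("max_lv must be >= 1")
    A, _ = _design(X)
    folds = _fold_indices(len(y.values), cv, rng)
    preds = cv_predictions(A, y.values, max_lv, folds)
    curve = np.sqrt(np.mean((preds - y.values) ** 2, axis=1))
    best = int(np.argmin(curve)) + 1  # argmin takes the first minimum -> fewest LVs
    return best, curve


def predict(model: RegressionModel, X: DescriptorMatrix) -> np.ndarray:
    """Affine evaluation on named columns; raises if any model descriptor is missing."""
    missing = [n for n in model.names if n not in X.frame.columns]
    if missing:
        raise KeyError(f"descriptor columns missing from input: {missing}")
    A = X.frame[model.names].to_numpy(dtype=float)
    return A @ model.coef + model.intercept
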