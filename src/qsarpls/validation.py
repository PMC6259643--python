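"""Model validation battery: error metrics, external Q², Tropsha criteria,
Y-randomization and mean effects.

Metric definitions (y = experimental, ŷ = predicted, n = set size):

* REP% = (100 / ȳ) * RMSE — relative error of prediction.
* RMSE = sqrt(Σ(ŷ - y)² / n); reported as RMSEC on training fits, RMSECV on
  cross-validated predictions, RMSEP on the external prediction set.
* external Q² = 1 - Σ(y - ŷ)² / Σ(y - ȳ_train)², centred on the *training*
  mean.  A leave-one-out Q² on the training set is exposed separately as
  :func:`q2_loo`; the two are often conflated in the QSAR literature.
* Tropsha battery: through-origin slopes k = Σyŷ/Σŷ², k' = Σyŷ/Σy²,
  through-origin determination coefficients R₀² and R₀'², and the relative
  gaps (R² - R₀²)/R².  Predictive-model thresholds: Q² > 0.5, R² > 0.6,
  0.85 < k < 1.15 (or k'), min gap <= 0.1.
* mean effect MF_j = β_j Σ_i d_ij / Σ_j β_j Σ_i d_ij on raw descriptor values;
  the MF column sums to 1 by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .descriptors import DescriptorMatrix
from .regression import RegressionModel

__all__ = [
    "rep_percent",
    "rmse",
    "q2_external",
    "q2_loo",
    "r_squared",
    "TropshaReport",
    "tropsha",
    "y_randomization",
    "mean_effect",
]


def _pair(y, yhat):
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape or y.ndim != 1 or y.size == 0:
        raise ValueError("y and yhat must be equal-length 1-D vectors")
    return y, yhat


def rmse(y, yhat) -> float:
    y, yhat = _pair(y, yhat)
    return float(np.sqrt(np.mean((yhat - y) ** 2)))


def rep_percent(y, yhat) -> float:
    y, yhat = _pair(y, yhat)
    ybar = float(y.mean())
    if ybar == 0:
        raise ValueError("REP% undefined: mean of experimental values is zero")
    return 100.0 / ybar * rmse(y, yhat)


def q2_external(y, yhat, y_train_mean: float) -> float:
    y, yhat = _pair(y, yhat)
    denom = float(np.sum((y - y_train_mean) ** 2))
    if denom == 0:
        raise ValueError("Q2 undefined: zero deviation from the training mean")
    return 1.0 - float(np.sum((y - yhat) ** 2)) / denom


def q2_loo(y, yhat_cv) -> float:
    """Leave-one-out (or any CV) Q² on the set itself: centred on its own mean."""
    y, yhat_cv = _pair(y, yhat_cv)
    denom = float(np.sum((y - y.mean()) ** 2))
    if denom == 0:
        raise ValueError("Q2 undefined: constant activity vector")
    return 1.0 - float(np.sum((y - yhat_cv) ** 2)) / denom


def r_squared(y, yhat) -> float:
    """Squared Pearson correlation between experimental and predicted values."""
    y, yhat = _pair(y, yhat)
    if np.std(y) == 0 or np.std(yhat) == 0:
        raise ValueError("R2 undefined for constant vectors")
    return float(np.corrcoef(y, yhat)[0, 1] ** 2)


@dataclass
class TropshaReport:
    r2: float
    k: float
    k_prime: float
    r0_sq: float
    r0_prime_sq: float
    gap: float  # (r2 - r0_sq) / r2
    gap_prime: float
    q2: float | None
    passes: dict[str, bool]

    @property
    def overall_pass(self) -> bool:
        return all(self.passes.values())


def tropsha(y, yhat, q2: float | None = None, r0_denominator: str = "predicted") -> TropshaReport:
    """Through-origin external-validation battery.

    ``r0_denominator`` selects the normalisation of R₀²: "predicted" uses
    deviations of ŷ from its mean (the form adopted here); "experimental" uses
    deviations of y (a widely used variant).
    """
    y, yhat = _pair(y, yhat)
    sum_yy = float(np.sum(y * yhat))
    sum_yhat2 = float(np.sum(yhat**2))
    sum_y2 = float(np.sum(y**2))
    if sum_yhat2 == 0 or sum_y2 == 0:
        raise ValueError("through-origin slopes undefined: zero sum of squares")
    k = sum_yy / sum_yhat2
    k_prime = sum_yy / sum_y2
    r2 = r_squared(y, yhat)
    if r0_denominator == "predicted":
        denom0 = float(np.sum((yhat - yhat.mean()) ** 2))
    elif r0_denominator == "experimental":
        denom0 = float(np.sum((y - y.mean()) ** 2))
    else:
        raise ValueError("r0_denominator must be 'predicted' or 'experimental'")
    r0_sq = 1.0 - float(np.sum((yhat - k * yhat) ** 2)) / denom0
    r0_prime_sq = 1.0 - float(np.sum((y - k_prime * y) ** 2)) / float(
        np.sum((y - y.mean()) ** 2)
    )
    gap = (r2 - r0_sq) / r2
    gap_prime = (r2 - r0_prime_sq) / r2
    passes = {
        "r2_gt_0.6": r2 > 0.6,
        "slope_near_unity": (0.85 < k < 1.15) or (0.85 < k_prime < 1.15),
        "r0_gap_le_0.1": min(gap, gap_prime) <= 0.1,
    }
    if q2 is not None:
        passes["q2_gt_0.5"] = q2 > 0.5
    return TropshaReport(
        r2=r2,
        k=k,
        k_prime=k_prime,
        r0_sq=r0_sq,
        r0_prime_sq=r0_prime_sq,
        gap=gap,
        gap_prime=gap_prime,
        q2=q2,
        passes=passes,
    )


def y_randomization(
    X: DescriptorMatrix,
    y,
    model_builder,
    n_iter: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Refit the full modelling procedure on randomly shuffled activities.

    ``model_builder(X, y_shuffled, rng)`` must return a ``(r2, q2)`` pair under
    whatever definition the surrounding workflow reports (training, CV or
    external); the same builder applied to the unshuffled y gives the
    reference.  Returns one row per shuffle.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    yv = np.asarray(y, dtype=float)
    rng = np.random.default_rng(seed)
    rows = []
    for it in range(n_iter):
        y_shuf = rng.permutation(yv)
        r2, q2 = model_builder(X, y_shuf, rng)
        rows.append({"iteration": it + 1, "r2": r2, "q2": q2})
    return pd.DataFrame(rows).set_index("iteration")


def mean_effect(model: RegressionModel, X_train: DescriptorMatrix) -> pd.Series:
    """Normalized descriptor contributions MF_j of an MLR model (sum to 1)."""
    col_sums = X_train.frame[model.names].sum(axis=0).to_numpy(dtype=float)
    terms = model.coef * col_sums
    denom = terms.sum()
    if denom == 0:
        raise ValueError("mean effect undefined: coefficients x column sums cancel")
    return pd.Series(terms / denom, index=model.names, name="MF")
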