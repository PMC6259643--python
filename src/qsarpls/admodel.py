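"""Leverage-based applicability domain (Williams plot analysis).

Leverage of a probe x against a training design X is the hat-matrix quadratic
form h = x'(X'X)⁻¹x; training leverages sum to the model-space dimension p.
The warning leverage h* = 3(p + 1)/n marks structurally influential compounds,
and |standardized residual| > 3 marks response outliers; a compound is inside
the applicability domain when it violates neither rule.  For a PLS model the
natural model space is the latent-variable score space (p = number of LVs);
for MLR it is the selected, scaled descriptor space (p = number of
descriptors).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .descriptors import DescriptorMatrix
from .regression import RegressionModel, predict

__all__ = ["ADResult", "leverage", "warning_leverage", "williams"]

RESIDUAL_CUTOFF = 3.0


@dataclass
class ADResult:
    table: pd.DataFrame  # per compound: leverage, std_residual, flags
    h_star: float
    n_train: int
    p: int


def _xtx_inverse(X_train: np.ndarray) -> np.ndarray:
    XtX = X_train.T @ X_train
    cond = np.linalg.cond(XtX)
    if cond > 1e12:
        warnings.warn(
            f"X'X is ill-conditioned (cond={cond:.2e}); using the pseudo-inverse",
            RuntimeWarning,
            stacklevel=3,
        )
        return np.linalg.pinv(XtX)
    return np.linalg.inv(XtX)


def leverage(X_train: np.ndarray, x) -> float | np.ndarray:
    """h = x'(X'X)⁻¹x for one probe row or a matrix of probe rows."""
    X_train = np.asarray(X_train, dtype=float)
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    probes = x[None, :] if single else x
    if probes.shape[1] != X_train.shape[1]:
        raise ValueError(
            f"probe dimension {probes.shape[1]} != training dimension {X_train.shape[1]}"
        )
    inv = _xtx_inverse(X_train)
    h = np.einsum("ij,jk,ik->i", probes, inv, probes)
    return float(h[0]) if single else h


def warning_leverage(n: int, p: int) -> float:
    """h* = 3(p + 1) / n."""
    if n <= 0:
        raise ValueError("n must be positive")
    if p < 1:
        raise ValueError("p must be >= 1")
    return 3.0 * (p + 1) / n


def _model_space(model: RegressionModel, X: DescriptorMatrix, X_train: DescriptorMatrix):
    """Map compounds into the AD model space.

    PLS: latent-variable scores t = (x - x̄)/s · W(P'W)⁻¹ are equivalent, for
    leverage purposes, to the span of the training scores; the scores of the
    training matrix are stored on the model.  MLR: the autoscaled selected
    descriptor columns.  Both are computed via the stored descriptor columns,
    centred/scaled on the training statistics.
    """
    A_tr = X_train.frame[model.names].to_numpy(dtype=float)
    mean = A_tr.mean(axis=0)
    sd = A_tr.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    A = (X.frame[model.names].to_numpy(dtype=float) - mean) / sd
    A_tr_s = (A_tr - mean) / sd
    if model.kind == "PLS" and "scores" in model.stats:
        T_tr = np.asarray(model.stats["scores"], dtype=float)
        # projection: rotate descriptor space onto the training score basis
        R, *_ = np.linalg.lstsq(A_tr_s, T_tr, rcond=None)
        return A_tr_s @ R, A @ R
    return A_tr_s, A


def williams(
    model: RegressionModel,
    X_train: DescriptorMatrix,
    y_train,
    X_probe: DescriptorMatrix,
    y_probe=None,
) -> ADResult:
    """Classify probe compounds by leverage and standardized residual.

    Probes without experimental activity (``y_probe`` None or NaN entries) are
    classified on leverage alone.  Standardized residual = (predicted -
    experimental) / SD of the training residuals.
    """
    y_train = np.asarray(y_train, dtype=float)
    T_train, T_probe = _model_space(model, X_probe, X_train)
    p = T_train.shape[1]
    n = T_train.shape[0]
    h_star = warning_leverage(n, p)
    h = leverage(T_train, T_probe)

    resid_train = predict(model, X_train) - y_train
    resid_sd = float(np.std(resid_train, ddof=1))
    if resid_sd <= 1e-12 * max(1.0, float(np.abs(y_train).max())):
        raise ValueError("training residual SD is zero; standardized residuals undefined")

    preds = predict(model, X_probe)
    if y_probe is None:
        std_resid = np.full(len(preds), np.nan)
    else:
        y_probe = np.asarray(y_probe, dtype=float)
        std_resid = (preds - y_probe) / resid_sd

    high_lev = h > h_star
    with np.errstate(invalid="ignore"):
        outlier = np.abs(std_resid) > RESIDUAL_CUTOFF
    outlier = np.where(np.isnan(std_resid), False, outlier)
    in_domain = ~high_lev & ~outlier
    table = pd.DataFrame(
        {
            "predicted": preds,
            "leverage": h,
            "std_residual": std_resid,
            "high_leverage": high_lev,
            "residual_outlier": outlier,
            "in_domain": in_domain,
        },
        index=X_probe.ids,
    )
    return ADResult(table=table, h_star=h_star, n_train=n, p=p)
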