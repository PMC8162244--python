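"""Structure coefficients, inclusive R2 and beta weights.

Structure coefficients are the Pearson correlations between each
(non-intercept) design column and the linear predictor eta of the full
model; they measure a predictor's total association with the model's
prediction, shared variance included, and are unaffected by collinearity
among predictors.  Squaring them and scaling by the marginal R2 yields the
inclusive R2 — the total (unique + shared) share of response variance a
predictor accounts for.  Beta weights are standardized slopes.

All three are reported per model-matrix column (each dummy or interaction
column separately): correlations are defined for columns, and no canonical
term-level aggregate exists for multilevel factors.
"""

from __future__ import annotations

import warnings as _warnings

import numpy as np

from .glmm import FittedGLMM
from .variance import VarianceDecomposition

__all__ = [
    "structure_coefficients",
    "inclusive_r2",
    "beta_weights",
    "effect_labels",
]


def effect_labels(fit: FittedGLMM) -> list[str]:
    """Labels of the non-intercept design columns, in design order."""
    return [lab for lab in fit.design.column_labels if lab != "Intercept"]


def structure_coefficients(fit: FittedGLMM) -> np.ndarray:
    """cor(eta, x_j) for every non-intercept design column x_j.

    With a single predictor in the model the structure coefficient is 1 by
    construction (eta is a linear function of that predictor).  A constant
    eta leaves the correlation undefined: NaNs are returned with a warning.
    """
    eta = fit.eta
    cols = fit.design.noninterceptcolumns
    sd_eta = np.std(eta)
    if sd_eta == 0.0 or not cols:
        _warnings.warn(
            "linear predictor is constant; structure coefficients are undefined",
            stacklevel=2,
        )
        return np.full(len(cols), np.nan)
    X = fit.design.matrix[:, cols]
    xc = X - X.mean(axis=0)
    ec = eta - eta.mean()
    sd_x = np.sqrt(np.mean(xc**2, axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        sc = (xc.T @ ec) / len(eta) / (sd_x * np.std(eta))
    return np.clip(sc, -1.0, 1.0)


def inclusive_r2(sc: np.ndarray, total_r2: float) -> np.ndarray:
    """Inclusive R2 per column: SC^2 times the marginal R2 of the full model."""
    return np.asarray(sc) ** 2 * total_r2


def beta_weights(fit: FittedGLMM, vd: VarianceDecomposition | None = None) -> np.ndarray:
    """Standardized slopes: beta_j * sd(x_j) / sd_response.

    For Gaussian models the response sd is taken from the data; for
    non-Gaussian models the observed sd would mix the data and link scales,
    so the latent-scale sd sqrt(Y_X + Y_RE + Y_D + Y_R) is used instead
    (requires ``vd``).
    """
    cols = fit.design.noninterceptcolumns
    labels = effect_labels(fit)
    X = fit.design.matrix[:, cols]
    sd_x = np.std(X, axis=0)
    if fit.family.name == "gaussian":
        sd_resp = float(np.std(fit.y))
    else:
        if vd is None:
            raise ValueError("non-Gaussian beta weights need the variance decomposition")
        sd_resp = float(np.sqrt(vd.Y_Total))
    beta = np.array([fit.beta[fit.design.column_labels.index(lab)] for lab in labels])
    with np.errstate(invalid="ignore", divide="ignore"):
        bw = beta * sd_x / sd_resp
    if np.any(sd_x == 0):
        _warnings.warn("zero-variance design column: beta weight undefined", stacklevel=2)
        bw = np.where(sd_x == 0, np.nan, bw)
    return bw
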