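"""Parametric-bootstrap uncertainty for every reported statistic.

Each iteration simulates a fresh response from the fitted full model
(new random intercepts, new residual/overdispersion noise, new family
sampling), refits the full model on the simulated data, reruns the
partition and the effect statistics, and stores every value.  Percentile
intervals are computed from the per-iteration draws with the
median-unbiased quantile definition.

Reproducibility contract: iteration ``i`` uses the dedicated random
substream ``default_rng([seed, i])``, so results are bit-identical for a
given master seed no matter how iterations are scheduled across workers.
Failed refits are dropped from the draws and counted, never imputed, and
the point estimate is never forced inside the interval — an estimate
outside its own bootstrap CI usually flags a problem with the data or the
model and is worth seeing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import PartitionSpec
from .effects import beta_weights, effect_labels, inclusive_r2, structure_coefficients
from .glmm import FittedGLMM, fit_mixed_model, simulate_response
from .partition import FULL_LABEL, PartitionResult, run_partition
from .variance import decompose, total_r2

__all__ = ["BootstrapSummary", "bootstrap_all", "percentile_ci"]


@dataclass
class BootstrapSummary:
    """Point estimate plus percentile CI and raw draws for one statistic."""

    estimate: float
    ci_lower: float
    ci_upper: float
    draws: np.ndarray
    n_failed: int = 0
    warnings: list[str] = field(default_factory=list)


def percentile_ci(draws: np.ndarray, ci_level: float) -> tuple[float, float]:
    """Empirical percentile interval (median-unbiased quantiles).

    Missing draws are excluded; ``ci_level=0`` degenerates to the median.
    """
    draws = np.asarray(draws, dtype=float)
    draws = draws[np.isfinite(draws)]
    if draws.size == 0:
        return (np.nan, np.nan)
    alpha = (1.0 - ci_level) / 2.0
    lo, hi = np.quantile(draws, [alpha, 1.0 - alpha], method="median_unbiased")
    return float(lo), float(hi)


def _all_statistics(
    fit: FittedGLMM,
    pspec: PartitionSpec,
    data: pd.DataFrame,
    lambda_method: str,
    y_override: np.ndarray | None = None,
    part: PartitionResult | None = None,
) -> tuple[dict[str, float], list[str]]:
    """Every statistic of one (re)fitted model, as a flat name->value map."""
    vd = decompose(fit, lambda_method=lambda_method)
    if part is None:
        part = run_partition(
            fit, pspec, data, y_override=y_override, vd_full=vd,
            lambda_method=lambda_method,
        )
    values: dict[str, float] = {f"R2:{FULL_LABEL}": total_r2(vd)}
    for row in part.rows:
        values[f"R2:{row.label}"] = row.part_r2
    sc = structure_coefficients(fit)
    ir2 = inclusive_r2(sc, total_r2(vd))
    bw = beta_weights(fit, vd)
    for lab, s, i2, b in zip(effect_labels(fit), sc, ir2, bw):
        values[f"SC:{lab}"] = float(s)
        values[f"IR2:{lab}"] = float(i2)
        values[f"BW:{lab}"] = float(b)
    warnings_ = list(fit.warnings) + list(part.warnings)
    return values, warnings_


def _one_iteration(full_fit, pspec, data, lambda_method, seed, i):
    rng = np.random.default_rng([seed, i])
    try:
        ysim = simulate_response(full_fit, rng)
        refit = fit_mixed_model(
            full_fit.spec,
            data,
            y_override=ysim,
            random=full_fit.random,
            olre_group=full_fit.olre_group,
        )
        values, warns = _all_statistics(
            refit, pspec, data, lambda_method, y_override=ysim
        )
        return values, [f"iteration {i}: {w}" for w in warns]
    except Exception as exc:  # noqa: BLE001 - counted as a failed refit
        return None, [f"iteration {i}: refit failed: {exc}"]


def bootstrap_all(
    full_fit: FittedGLMM,
    pspec: PartitionSpec,
    data: pd.DataFrame,
    lambda_method: str = "latent",
    max_workers: int = 1,
    part: PartitionResult | None = None,
) -> dict[str, BootstrapSummary]:
    """Bootstrap every statistic; keys are ``"R2:<set>"``, ``"SC:<col>"``, etc.

    ``pspec.nboot == 0`` returns point estimates with empty draws and
    missing CI bounds.  With ``max_workers > 1`` iterations run in parallel
    processes (joblib); the per-iteration substreams make the draws
    independent of scheduling.
    """
    pspec = pspec.validate_against(full_fit.spec.fixed_terms, list(data.columns))
    seed = pspec.seed if pspec.seed is not None else 0
    estimates, base_warnings = _all_statistics(
        full_fit, pspec, data, lambda_method, part=part
    )

    nboot = pspec.nboot
    if nboot > 0:
        if max_workers > 1:
            from joblib import Parallel, delayed

            results = Parallel(n_jobs=max_workers)(
                delayed(_one_iteration)(full_fit, pspec, data, lambda_method, seed, i)
                for i in range(1, nboot + 1)
            )
        else:
            results = [
                _one_iteration(full_fit, pspec, data, lambda_method, seed, i)
                for i in range(1, nboot + 1)
            ]
    else:
        results = []

    draws: dict[str, list[float]] = {name: [] for name in estimates}
    warnings_: list[str] = list(base_warnings)
    n_failed = 0
    for values, warns in results:
        warnings_.extend(warns)
        if values is None:
            n_failed += 1
            continue
        for name in draws:
            draws[name].append(values.get(name, np.nan))

    out: dict[str, BootstrapSummary] = {}
    all_failed = nboot > 0 and n_failed == nboot
    if all_failed:
        warnings_.append("all bootstrap iterations failed; intervals unavailable")
    for name, est in estimates.items():
        dr = np.asarray(draws[name], dtype=float)
        if dr.size:
            lo, hi = percentile_ci(dr, pspec.ci_level)
        else:
            lo = hi = np.nan
        out[name] = BootstrapSummary(
            estimate=float(est),
            ci_lower=lo,
            ci_upper=hi,
            draws=dr,
            n_failed=n_failed,
            warnings=warnings_ if name == f"R2:{FULL_LABEL}" else [],
        )
    return out
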