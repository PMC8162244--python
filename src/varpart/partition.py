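"""Part (semi-partial) R2 by reduced-model refits.

For every enumerated set of partition units the corresponding fixed-effect
terms are removed, the reduced model is refitted from scratch (same random
structure, family and link; all parameters re-estimated), and the unique
contribution of the removed set is the drop in linear-predictor variance
relative to the full model's total variance:

    R2_part = (Y_X - Y_X_reduced) / Y_Total(full).

The denominator always comes from the FULL model, so part R2 values are
comparable across sets and additive for orthogonal predictors.  Because the
random-effect and residual variances are re-estimated in the reduced model,
sampling noise can push the numerator slightly negative; such values are
clamped to 0 by default (``allow_neg_r2`` lets them through).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .design import PartitionSpec, enumerate_units
from .glmm import FittedGLMM, fit_mixed_model
from .variance import VarianceDecomposition, decompose, total_r2, var_linear_predictor

__all__ = ["PartitionRow", "PartitionResult", "part_r2_for_set", "run_partition", "merge_runs"]

FULL_LABEL = "Full"


@dataclass
class PartitionRow:
    label: str
    term_set: frozenset[str]
    part_r2: float          # NaN when the reduced fit failed
    Y_X_reduced: float
    ndf: int
    clamped: bool = False


@dataclass
class PartitionResult:
    """Part R2 per term-combination for one fitted model."""

    full_r2: float
    rows: list[PartitionRow]
    decomposition: VarianceDecomposition
    options: PartitionSpec
    family: str
    link: str
    response: str | tuple[str, str]
    warnings: list[str] = field(default_factory=list)

    def as_frame(self) -> pd.DataFrame:
        recs = [
            {
                "term_set": row.label,
                "part_r2": row.part_r2,
                "Y_X_reduced": row.Y_X_reduced,
                "ndf": row.ndf,
            }
            for row in self.rows
        ]
        return pd.DataFrame(recs)


def part_r2_for_set(
    full_fit: FittedGLMM,
    vd_full: VarianceDecomposition,
    drop_set: frozenset[str],
    data: pd.DataFrame,
    label: str | None = None,
    allow_neg_r2: bool = False,
    y_override: np.ndarray | None = None,
    cache: dict | None = None,
    warnings_out: list[str] | None = None,
) -> PartitionRow:
    """Part R2 for one dropped term set, via a reduced-model refit.

    When the drop set covers ALL fixed terms of the full model the full fit
    is reused: at that limit Y_X_reduced is the variance of the
    intercept-only linear predictor, which is 0, so part R2 equals the total
    R2 exactly for the complement reading; here the reduced model is the
    intercept-only model and is still refit-free only in the sense of
    Y_X_reduced = 0 requiring no estimation beyond the intercept.
    """
    spec = full_fit.spec
    label = label or "+".join(sorted(drop_set))
    keep = [t for t in spec.fixed_terms if t not in drop_set]
    key = frozenset(keep)
    if set(drop_set) == set(spec.fixed_terms):
        # limit case: removing every fixed effect leaves a constant linear
        # predictor, so Y_X_reduced = 0 and part R2 = total R2 exactly
        return PartitionRow(
            label=label,
            term_set=frozenset(drop_set),
            part_r2=total_r2(vd_full),
            Y_X_reduced=0.0,
            ndf=1,
        )
    reduced = None
    if cache is not None and key in cache:
        reduced = cache[key]
    if reduced is None:
        try:
            reduced = fit_mixed_model(
                spec,
                data,
                terms=keep,
                y_override=y_override,
                random=full_fit.random,
                olre_group=full_fit.olre_group,
            )
        except Exception as exc:  # noqa: BLE001 - surfaced as a flagged row
            if warnings_out is not None:
                warnings_out.append(f"reduced fit for {label!r} failed: {exc}")
            return PartitionRow(label, frozenset(drop_set), np.nan, np.nan, 0)
        if cache is not None:
            cache[key] = reduced
    if not reduced.converged and warnings_out is not None:
        warnings_out.append(f"reduced fit for {label!r} did not converge")
    y_x_red = var_linear_predictor(reduced)
    value = (vd_full.Y_X - y_x_red) / vd_full.Y_Total
    clamped = False
    if value < 0 and not allow_neg_r2:
        value, clamped = 0.0, True
        if warnings_out is not None:
            warnings_out.append(f"negative part R2 for {label!r} clamped to 0")
    return PartitionRow(
        label=label,
        term_set=frozenset(drop_set),
        part_r2=float(value),
        Y_X_reduced=float(y_x_red),
        ndf=reduced.design.ndf,
        clamped=clamped,
    )


def run_partition(
    full_fit: FittedGLMM,
    pspec: PartitionSpec,
    data: pd.DataFrame,
    y_override: np.ndarray | None = None,
    vd_full: VarianceDecomposition | None = None,
    lambda_method: str = "latent",
) -> PartitionResult:
    """Part R2 for every enumerated combination of partition units.

    Reduced fits are cached by the surviving term set, so drop sets that
    reparametrize to the same design are fitted once.
    """
    if vd_full is None:
        vd_full = decompose(full_fit, lambda_method=lambda_method)
    pspec = pspec.validate_against(full_fit.spec.fixed_terms, list(data.columns))
    warnings_: list[str] = []
    cache: dict = {}
    rows = [
        part_r2_for_set(
            full_fit,
            vd_full,
            term_set,
            data,
            label=label,
            allow_neg_r2=pspec.allow_neg_r2,
            y_override=y_override,
            cache=cache,
            warnings_out=warnings_,
        )
        for label, term_set in enumerate_units(pspec)
    ]
    return PartitionResult(
        full_r2=total_r2(vd_full),
        rows=rows,
        decomposition=vd_full,
        options=pspec,
        family=full_fit.spec.family,
        link=full_fit.spec.link,
        response=full_fit.spec.response,
        warnings=warnings_,
    )


def merge_runs(run_a: PartitionResult, run_b: PartitionResult) -> PartitionResult:
    """Concatenate two partition runs (interaction handling, option C).

    Typical use: run A partitions the interaction term from the model that
    contains it; run B partitions the main effects from the model without
    the interaction, so each main effect keeps the variance it shares with
    its own interaction.  Row order is run A first; on term-set collisions
    run A's row wins and a warning is recorded.  The headline full R2 is run
    A's.
    """
    if (run_a.family, run_a.link) != (run_b.family, run_b.link):
        raise ValueError(
            f"cannot merge partitions of different families/links: "
            f"{run_a.family}+{run_a.link} vs {run_b.family}+{run_b.link}"
        )
    if run_a.response != run_b.response:
        raise ValueError("cannot merge partitions of different responses")
    warnings_ = list(run_a.warnings) + list(run_b.warnings)
    seen = {row.term_set for row in run_a.rows}
    rows = list(run_a.rows)
    for row in run_b.rows:
        if row.term_set in seen:
            warnings_.append(
                f"duplicate term set {row.label!r} in merged run; keeping the first"
            )
            continue
        rows.append(row)
    return replace(run_a, rows=rows, warnings=warnings_)
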