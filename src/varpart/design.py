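"""Fixed-effect design matrices and partition-unit enumeration.

Design construction is delegated to patsy, which implements the standard
marginality rules: categorical predictors get treatment contrasts (first
level in sorted order as reference), and when a main effect involved in an
interaction is removed, the interaction block is re-expanded with the full
set of dummies.  This reparametrization is exactly what a reduced-model
refit in the mixed-model ecosystem does, so the reported ndf (number of
fixed-effect columns) matches the reduced model actually fitted.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import patsy

from .formula import ModelSpec, canonicalize_term

__all__ = [
    "DesignMatrix",
    "PartitionSpec",
    "build_design",
    "reduce_design",
    "dummy_center",
    "enumerate_units",
]


@dataclass
class DesignMatrix:
    """A realized fixed-effect design: values plus column/term bookkeeping."""

    matrix: np.ndarray                 # n_obs x ndf
    column_labels: list[str]
    term_of_column: dict[str, str]     # column label -> term label
    ndf: int                           # fixed-effect columns incl. intercept
    terms: list[str]                   # term labels this design was built from

    def __post_init__(self) -> None:
        if self.ndf != self.matrix.shape[1]:
            raise ValueError("ndf must equal the number of design columns")

    @property
    def noninterceptcolumns(self) -> list[int]:
        return [j for j, lab in enumerate(self.column_labels) if lab != "Intercept"]


def _validate_data(spec: ModelSpec, data: pd.DataFrame, terms: list[str]) -> None:
    spec.validate_against(data)
    cols = set()
    for t in terms:
        cols.update(t.split(":"))
    cols.update(spec.response_columns)
    cols.update(spec.random_groups)
    for c in cols:
        if data[c].isna().any():
            raise ValueError(
                f"column {c!r} contains missing values; remove incomplete rows "
                "before the analysis"
            )
    for t in terms:
        for c in t.split(":"):
            s = data[c]
            if not pd.api.types.is_numeric_dtype(s) and s.nunique() < 2:
                raise ValueError(
                    f"categorical column {c!r} has a single level; it cannot "
                    "enter the model"
                )


def _patsy_design(terms: list[str], data: pd.DataFrame) -> patsy.DesignMatrix:
    rhs = " + ".join(terms) if terms else "1"
    return patsy.dmatrix(rhs, data, NA_action=patsy.NAAction(NA_types=[]))


def build_design(spec: ModelSpec, data: pd.DataFrame, terms: list[str] | None = None) -> DesignMatrix:
    """Build the treatment-contrast design matrix for ``terms``.

    ``terms`` defaults to the spec's full fixed part.  Interaction labels are
    canonicalized to the data's column order, so ``b:a`` and ``a:b`` produce
    identical designs.
    """
    col_order = list(data.columns)
    if terms is None:
        terms = list(spec.fixed_terms)
    terms = [canonicalize_term(t, col_order) for t in terms]
    _validate_data(spec, data, terms)
    dm = _patsy_design(terms, data)
    info = dm.design_info
    labels = list(info.column_names)
    term_of_column: dict[str, str] = {}
    for term_name, sl in info.term_name_slices.items():
        canon = (
            "Intercept"
            if term_name == "Intercept"
            else canonicalize_term(term_name, col_order)
        )
        for lab in labels[sl]:
            term_of_column[lab] = canon
    mat = np.asarray(dm, dtype=float)
    if mat.shape[0] and np.any(np.all(mat == 0.0, axis=0)):
        bad = [labels[j] for j in np.flatnonzero(np.all(mat == 0.0, axis=0))]
        raise ValueError(f"design columns are identically zero: {bad}")
    return DesignMatrix(
        matrix=mat,
        column_labels=labels,
        term_of_column=term_of_column,
        ndf=mat.shape[1],
        terms=terms,
    )


def reduce_design(
    spec: ModelSpec, data: pd.DataFrame, drop_terms: set[str] | frozenset[str]
) -> DesignMatrix:
    """Design for the model with ``drop_terms`` removed from the fixed part.

    The surviving terms are re-expanded from scratch, so removing a main
    effect that participates in an interaction regenerates the interaction
    block with the full dummy set (ndf can stay constant or even grow
    relative to naive column deletion).  The random structure is untouched.
    """
    col_order = list(data.columns)
    full = [canonicalize_term(t, col_order) for t in spec.fixed_terms]
    drop = {canonicalize_term(t, col_order) for t in drop_terms}
    unknown = drop - set(full)
    if unknown:
        raise KeyError(
            f"unknown term(s) {sorted(unknown)}; valid fixed terms: {full}"
        )
    keep = [t for t in full if t not in drop]
    return build_design(spec, data, terms=keep)


def dummy_center(data: pd.DataFrame, factor_column: str) -> pd.DataFrame:
    """Append mean-centered one-hot columns for a factor; original columns untouched.

    With centered dummies in hand, an interaction like ``x:f`` can be recoded
    as ``x + x:f_dummy...`` so that the plain ``x`` column estimates the
    average effect of ``x`` across factor levels — the coding that gives fine
    control over which interaction contrasts a reduced model drops.
    """
    s = data[factor_column]
    if pd.api.types.is_float_dtype(s):
        raise TypeError(
            f"column {factor_column!r} is continuous; dummy coding applies to "
            "categorical columns"
        )
    levels = sorted(s.unique(), key=str)
    if len(levels) < 2:
        raise TypeError(f"factor {factor_column!r} must have at least 2 levels")
    out = data.copy()
    for lev in levels:
        col = f"{factor_column}_{lev}"
        d = (s == lev).astype(float)
        out[col] = d - d.mean()
    return out


@dataclass
class PartitionSpec:
    """What to partition and how: units, combination depth, bootstrap controls.

    ``partvars`` lists fixed-effect terms to treat as individual units;
    ``partbatch`` maps a batch name to a list of terms always removed
    together.  All non-empty unions of units up to ``max_level`` are
    evaluated.
    """

    partvars: list[str] = field(default_factory=list)
    partbatch: dict[str, list[str]] = field(default_factory=dict)
    max_level: int | None = None
    nboot: int = 0
    seed: int | None = None
    ci_level: float = 0.95
    allow_neg_r2: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.ci_level < 1.0:
            raise ValueError("ci_level must lie in (0, 1)")
        if self.nboot < 0:
            raise ValueError("nboot must be >= 0")

    @property
    def units(self) -> list[tuple[str, tuple[str, ...]]]:
        """Partition units as (label, terms) pairs, partvars first."""
        out: list[tuple[str, tuple[str, ...]]] = [(v, (v,)) for v in self.partvars]
        for name, terms in self.partbatch.items():
            out.append((name, tuple(terms)))
        return out

    def validate_against(self, fixed_terms: list[str], column_order: list[str] | None = None) -> "PartitionSpec":
        """String-exact matching of every unit term against the model's terms."""
        canon_full = [canonicalize_term(t, column_order) for t in fixed_terms]
        partvars = [canonicalize_term(v, column_order) for v in self.partvars]
        partbatch = {
            name: [canonicalize_term(t, column_order) for t in terms]
            for name, terms in self.partbatch.items()
        }
        for label, terms in [(v, [v]) for v in partvars] + list(partbatch.items()):
            for t in terms:
                if t not in canon_full:
                    raise KeyError(
                        f"partition term {t!r} (unit {label!r}) does not match any "
                        f"fixed-effect term of the model; terms are matched "
                        f"string-exactly against {canon_full}"
                    )
        n_units = len(partvars) + len(partbatch)
        max_level = self.max_level
        if max_level is None:
            max_level = max(n_units, 1)
        if n_units and not 1 <= max_level <= n_units:
            raise ValueError(
                f"max_level must be between 1 and the number of partition "
                f"units ({n_units}); got {self.max_level}"
            )
        return PartitionSpec(
            partvars=partvars,
            partbatch=partbatch,
            max_level=max_level,
            nboot=self.nboot,
            seed=self.seed,
            ci_level=self.ci_level,
            allow_neg_r2=self.allow_neg_r2,
        )


def enumerate_units(pspec: PartitionSpec) -> list[tuple[str, frozenset[str]]]:
    """All non-empty unions of partition units of size <= max_level.

    Returns (label, term-set) pairs ordered by combination size then input
    order; labels of multi-unit combinations join unit names with ``+``.
    """
    units = pspec.units
    max_level = pspec.max_level if pspec.max_level is not None else len(units)
    out: list[tuple[str, frozenset[str]]] = []
    seen: set[frozenset[str]] = set()
    for k in range(1, min(max_level, len(units)) + 1):
        for combo in itertools.combinations(units, k):
            terms = frozenset(t for _, ts in combo for t in ts)
            if terms in seen:
                continue
            seen.add(terms)
            out.append(("+".join(lab for lab, _ in combo), terms))
    return out
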