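"""Model/Results front door for variance partitioning of mixed models.

``VariancePartition`` holds the data and model declaration; ``fit`` runs
the full pipeline — mixed-model estimation, latent-scale variance
decomposition, reduced-model part R2, structure coefficients / inclusive
R2 / beta weights, and the parametric bootstrap — and returns a
``VariancePartitionResults`` carrying estimates, intervals and a
``summary()`` table.

Example
-------
>>> import varpart
>>> data, truth = varpart.simulate_dataset(varpart.SimScenario(seed=1))
>>> model = varpart.VariancePartition.from_formula(
...     "y ~ x1 + x2 + (1|group)", data)
>>> res = model.fit(partvars=["x1", "x2"], nboot=100, seed=1)
>>> print(res.summary(round_to=3))          # doctest: +SKIP
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .bootstrap import BootstrapSummary, bootstrap_all
from .design import PartitionSpec, build_design
from .effects import beta_weights, effect_labels, inclusive_r2, structure_coefficients
from .formula import ModelSpec, parse_formula
from .glmm import FittedGLMM, ensure_olre, fit_mixed_model
from .partition import PartitionResult, run_partition
from .reporting import ResultBundle, build_bundle, forestplot_data, render_forestplot, render_summary
from .variance import VarianceDecomposition, decompose, total_r2

__all__ = ["VariancePartition", "VariancePartitionResults"]


class VariancePartition:
    """A mixed model declared for variance partitioning.

    Parameters
    ----------
    formula : str
        Wilkinson-style formula with at least one ``(1|group)`` random
        intercept, e.g. ``"y ~ Rank * Time + (1|MaleID)"`` or
        ``"cbind(succ, fail) ~ x1 + x2 + (1|pop)"``.
    data : pandas.DataFrame
        Complete-case data table; rows with missing values in referenced
        columns are an error.
    family : {"gaussian", "poisson", "binomial"}
    link : str, optional
        Defaults to the family's canonical link (identity / log / logit).
    """

    def __init__(self, formula: str, data: pd.DataFrame, family: str = "gaussian", link: str | None = None):
        spec = parse_formula(formula)
        self.spec = ModelSpec(
            response=spec.response,
            fixed_terms=spec.fixed_terms,
            random_groups=spec.random_groups,
            family=family,
            link=link,
        )
        self.spec.validate_against(data)
        # overdispersion: Poisson and proportion-binomial models get an
        # observation-level random effect unless one is already present
        self.spec, self.data, self.olre_added = ensure_olre(self.spec, data)
        self.formula = formula

    @classmethod
    def from_formula(cls, formula: str, data: pd.DataFrame, family: str = "gaussian", link: str | None = None):
        return cls(formula, data, family=family, link=link)

    def fit(
        self,
        partvars: list[str] | None = None,
        partbatch: dict[str, list[str]] | None = None,
        max_level: int | None = None,
        nboot: int = 0,
        seed: int | None = None,
        ci_level: float = 0.95,
        allow_neg_r2: bool = False,
        lambda_method: str = "latent",
        max_workers: int = 1,
    ) -> "VariancePartitionResults":
        """Fit the full model and partition its explained variance.

        ``partvars``/``partbatch`` name the fixed-effect terms (or named
        term batches) whose unique contributions are wanted; all non-empty
        combinations up to ``max_level`` are evaluated.  ``nboot``
        parametric-bootstrap iterations produce percentile intervals at
        ``ci_level``; negative part R2 draws are clamped to zero unless
        ``allow_neg_r2``.
        """
        pspec = PartitionSpec(
            partvars=list(partvars or []),
            partbatch=dict(partbatch or {}),
            max_level=max_level,
            nboot=nboot,
            seed=seed,
            ci_level=ci_level,
            allow_neg_r2=allow_neg_r2,
        ).validate_against(self.spec.fixed_terms, list(self.data.columns))

        full_fit = fit_mixed_model(self.spec, self.data)
        vd = decompose(full_fit, lambda_method=lambda_method)
        part = run_partition(
            full_fit, pspec, self.data, vd_full=vd, lambda_method=lambda_method
        )
        boot = bootstrap_all(
            full_fit, pspec, self.data, lambda_method=lambda_method,
            max_workers=max_workers, part=part,
        )
        metadata = {
            "formula": self.formula,
            "family": self.spec.family,
            "link": self.spec.link,
            "n_obs": full_fit.n_obs,
            "ndf_full": full_fit.design.ndf,
            "nboot": nboot,
            "seed": seed,
            "ci_level": ci_level,
            "allow_neg_r2": allow_neg_r2,
            "lambda_method": lambda_method,
            "quantile_rule": "median_unbiased percentile",
            "olre_added": self.olre_added,
            "converged": full_fit.converged,
        }
        bundle = build_bundle(part, boot, effect_labels(full_fit), metadata)
        return VariancePartitionResults(self, full_fit, vd, part, boot, bundle)


class VariancePartitionResults:
    """Estimates, uncertainties and diagnostics of one partition analysis."""

    def __init__(
        self,
        model: VariancePartition,
        fitted: FittedGLMM,
        decomposition: VarianceDecomposition,
        partition: PartitionResult,
        bootstraps: dict[str, BootstrapSummary],
        bundle: ResultBundle,
    ):
        self.model = model
        self.fitted = fitted
        self.decomposition = decomposition
        self.partition = partition
        self.bootstraps = bootstraps
        self.bundle = bundle

    # --- tables -----------------------------------------------------------
    @property
    def r2(self) -> pd.DataFrame:
        """Full and part R2 rows with CIs and reduced-model ndf."""
        return self.bundle.R2

    @property
    def sc(self) -> pd.DataFrame:
        return self.bundle.SC

    @property
    def ir2(self) -> pd.DataFrame:
        return self.bundle.IR2

    @property
    def bw(self) -> pd.DataFrame:
        return self.bundle.BW

    @property
    def total_r2(self) -> float:
        return total_r2(self.decomposition)

    @property
    def warnings(self) -> list[str]:
        return self.bundle.warnings

    # --- presentation -----------------------------------------------------
    def summary(self, round_to: int = 4) -> str:
        return render_summary(self.bundle, round_to=round_to)

    def forestplot_data(self, which: str = "R2") -> pd.DataFrame:
        return forestplot_data(self.bundle, which)

    def forestplot(self, which: str = "R2", path=None, ax=None):
        return render_forestplot(
            self.forestplot_data(which), path=path, ax=ax, title=which
        )

    def to_json(self, path=None) -> str:
        return self.bundle.to_json(path)

    def __repr__(self) -> str:
        return (
            f"<VariancePartitionResults: R2={self.total_r2:.4f}, "
            f"{len(self.partition.rows)} part-R2 rows, "
            f"nboot={self.bundle.metadata.get('nboot')}>"
        )
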