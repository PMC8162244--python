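"""Synthetic GLMM datasets with analytically known variance structure.

Every dataset comes with a *truth record*: the generating parameters imply
closed forms for all variance components and for every statistic the
package estimates, so simulations double as oracles.

Under multivariate-normal predictors x ~ N(0, Sigma) (unit variances) with
latent effects beta, the fixed-effect variance is Y_X = beta' Sigma beta.
The best linear approximation of eta from a subset S of predictors has
variance c' Sigma_SS^{-1} c with c = Cov(x_S, eta) = (Sigma beta)_S, which
is exactly what a refitted reduced model estimates at large n; the unique
(part) variance of the complement is Y_X minus that projection.  Structure
coefficients are cor(x_j, eta) = (Sigma beta)_j / sqrt(Y_X).  These linear
algebra identities are the brute-force oracle for the refit-based
estimator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .families import get_family

__all__ = ["SimScenario", "simulate_dataset", "guinea_pig_like", "truth_part_r2"]


@dataclass
class SimScenario:
    """Generating parameters for one synthetic mixed-model dataset.

    ``beta`` holds (intercept, slopes...) on the latent/link scale;
    ``predictor_cov`` is the correlation matrix of the standardized
    continuous predictors.  ``factor_spec`` optionally adds a balanced
    k-level factor with the given per-level latent effects, independent of
    the continuous predictors.  ``n_trials`` sets the binomial trial count
    per observation (1 = binary).
    """

    n_groups: int = 25
    group_size: int = 20
    beta: tuple = (0.0, 1.0, 0.5)
    predictor_cov: np.ndarray | None = None
    factor_spec: dict | None = None   # {"levels": k, "effects": [..k values..]}
    sigma2_group: float = 0.5
    sigma2_olre: float = 0.0
    sigma2_resid: float = 0.5
    family: str = "gaussian"
    link: str | None = None
    n_trials: int = 1
    seed: int = 0

    def __post_init__(self):
        n_pred = len(self.beta) - 1
        if self.predictor_cov is None:
            self.predictor_cov = np.eye(n_pred)
        self.predictor_cov = np.asarray(self.predictor_cov, dtype=float)
        if self.predictor_cov.shape != (n_pred, n_pred):
            raise ValueError("predictor_cov must be (len(beta)-1) square")
        if not np.allclose(self.predictor_cov, self.predictor_cov.T):
            raise ValueError("predictor_cov must be symmetric")
        if not np.allclose(np.diag(self.predictor_cov), 1.0):
            raise ValueError("predictor_cov must have unit diagonal")
        if n_pred and np.linalg.eigvalsh(self.predictor_cov)[0] <= 1e-10:
            raise ValueError("predictor_cov must be positive definite")
        for v in (self.sigma2_group, self.sigma2_olre, self.sigma2_resid):
            if v < 0:
                raise ValueError("variances must be non-negative")
        if self.link is None:
            self.link = {"gaussian": "identity", "poisson": "log", "binomial": "logit"}[
                self.family
            ]

    @property
    def n_obs(self) -> int:
        return self.n_groups * self.group_size

    @property
    def predictor_names(self) -> list[str]:
        return [f"x{j + 1}" for j in range(len(self.beta) - 1)]


def _factor_variance(factor_spec: dict) -> float:
    e = np.asarray(factor_spec["effects"], dtype=float)
    return float(np.mean(e**2) - np.mean(e) ** 2)


def _distribution_variance_truth(sc: SimScenario, y_x: float) -> float:
    if sc.family == "gaussian":
        return 0.0
    if sc.family == "binomial":
        return np.pi**2 / 3.0 if sc.link == "logit" else 1.0
    if sc.link == "sqrt":
        return 0.25
    lam = np.exp(
        sc.beta[0] + 0.5 * (y_x + sc.sigma2_group + sc.sigma2_olre)
    )
    return float(np.log1p(1.0 / lam))


def _components(sc: SimScenario) -> dict:
    beta = np.asarray(sc.beta[1:], dtype=float)
    y_x = float(beta @ sc.predictor_cov @ beta)
    if sc.factor_spec is not None:
        y_x += _factor_variance(sc.factor_spec)
    y_re = sc.sigma2_group
    y_r = sc.sigma2_resid if sc.family == "gaussian" else sc.sigma2_olre
    y_d = _distribution_variance_truth(sc, y_x)
    return {
        "Y_X": y_x,
        "Y_RE": y_re,
        "Y_D": y_d,
        "Y_R": y_r,
        "Y_Total": y_x + y_re + y_d + y_r,
    }


def truth_part_r2(sc: SimScenario, drop: list[str]) -> float:
    """Closed-form part R2 for dropping a set of continuous predictors.

    Computed by covariance algebra on the generating parameters: the
    reduced model's linear-predictor variance is the projection of eta onto
    the retained predictors (plus any factor block, which is independent of
    the continuous predictors and therefore retained in full).
    """
    t = _components(sc)
    names = sc.predictor_names
    beta = np.asarray(sc.beta[1:], dtype=float)
    Sigma = sc.predictor_cov
    keep = [j for j, nm in enumerate(names) if nm not in drop]
    bad = [d for d in drop if d not in names]
    if bad:
        raise KeyError(f"unknown predictors {bad}")
    cov_eta = Sigma @ beta
    if keep:
        S = Sigma[np.ix_(keep, keep)]
        c = cov_eta[keep]
        y_x_reduced = float(c @ np.linalg.solve(S, c))
    else:
        y_x_reduced = 0.0
    if sc.factor_spec is not None:
        y_x_reduced += _factor_variance(sc.factor_spec)
    return (t["Y_X"] - y_x_reduced) / t["Y_Total"]


def simulate_truth(sc: SimScenario) -> dict:
    """Analytic variance components and statistics implied by the scenario."""
    beta = np.asarray(sc.beta[1:], dtype=float)
    comp = _components(sc)
    y_x, y_total = comp["Y_X"], comp["Y_Total"]
    cov_eta = sc.predictor_cov @ beta
    sc_vec = cov_eta / np.sqrt(y_x) if y_x > 0 else np.zeros_like(cov_eta)
    r2 = y_x / y_total
    truth = {
        **comp,
        "total_r2": r2,
        "sc": dict(zip(sc.predictor_names, sc_vec)),
        "ir2": dict(zip(sc.predictor_names, sc_vec**2 * r2)),
        "beta_weights": dict(
            zip(sc.predictor_names, beta / np.sqrt(y_total))
        ),
    }
    truth["part_r2"] = {
        nm: truth_part_r2(sc, [nm]) if y_x > 0 else 0.0
        for nm in sc.predictor_names
    }
    return truth


def simulate_dataset(sc: SimScenario) -> tuple[pd.DataFrame, dict]:
    """Draw one dataset from the scenario; returns (table, truth record)."""
    rng = np.random.default_rng(sc.seed)
    n = sc.n_obs
    n_pred = len(sc.beta) - 1
    L = np.linalg.cholesky(sc.predictor_cov)
    X = rng.standard_normal((n, n_pred)) @ L.T

    eta = sc.beta[0] + X @ np.asarray(sc.beta[1:], dtype=float)
    group = np.repeat(np.arange(sc.n_groups), sc.group_size)
    if sc.sigma2_group > 0:
        eta = eta + rng.normal(0, np.sqrt(sc.sigma2_group), sc.n_groups)[group]
    data = pd.DataFrame(X, columns=sc.predictor_names)
    if sc.factor_spec is not None:
        k = sc.factor_spec["levels"]
        eff = np.asarray(sc.factor_spec["effects"], dtype=float)
        lev = np.arange(n) % k
        rng.shuffle(lev)
        data["f"] = pd.Categorical([f"lev{i + 1}" for i in lev])
        eta = eta + eff[lev]
    data["group"] = [f"g{i + 1:03d}" for i in group]

    if sc.sigma2_olre > 0 and sc.family != "gaussian":
        eta = eta + rng.normal(0, np.sqrt(sc.sigma2_olre), n)

    fam = get_family(sc.family, sc.link)
    if sc.family == "gaussian":
        data["y"] = eta + rng.normal(0, np.sqrt(sc.sigma2_resid), n)
    elif sc.family == "poisson":
        data["y"] = rng.poisson(fam.linkinv(eta)).astype(float)
    else:
        p = fam.linkinv(eta)
        succ = rng.binomial(sc.n_trials, p)
        if sc.n_trials == 1:
            data["y"] = succ.astype(float)
        else:
            data["succ"] = succ
            data["fail"] = sc.n_trials - succ
    return data, simulate_truth(sc)


def guinea_pig_like(
    seed: int = 0,
    n_subjects: int = 31,
    n_timepoints: int = 3,
    interaction_strength: float = 0.0,
    rank_effect: float = 0.4,
    time_effects: tuple = (0.0, 0.5, 1.0),
    sigma2_subject: float = 0.4,
    sigma2_resid: float = 0.3,
) -> pd.DataFrame:
    """A repeated-measures Gaussian table shaped like a hormonal study.

    Each subject is measured once per time point; the response depends on a
    time factor, a continuous (standardized) social-rank index, their
    interaction (slope of rank changing over time), and a subject-level
    random intercept.  ``interaction_strength`` is the increment of the rank
    slope per successive time point; 0 makes the model purely additive.
    """
    rng = np.random.default_rng(seed)
    subj = np.repeat(np.arange(n_subjects), n_timepoints)
    time_idx = np.tile(np.arange(n_timepoints), n_subjects)
    rank = rng.standard_normal(n_subjects * n_timepoints)
    rank = (rank - rank.mean()) / rank.std()
    te = np.asarray(time_effects[:n_timepoints], dtype=float)
    slope = rank_effect + interaction_strength * time_idx
    eta = te[time_idx] + slope * rank
    eta = eta + rng.normal(0, np.sqrt(sigma2_subject), n_subjects)[subj]
    y = eta + rng.normal(0, np.sqrt(sigma2_resid), len(eta))
    return pd.DataFrame(
        {
            "Testo": y,
            "Rank": rank,
            "Time": pd.Categorical([f"t{i + 1}" for i in time_idx]),
            "MaleID": [f"m{i + 1:02d}" for i in subj],
        }
    )
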