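"""Random-intercept mixed-model engine.

Gaussian models are fitted by REML with the variance ratios profiled out:
for ``y = X beta + sum_k Z_k a_k + e`` the covariance is
``V = sigma2_e (I + Z Lambda Lambda' Z')`` with ``Lambda`` block-diagonal in
the per-group standard-deviation ratios ``s_k = sigma_k / sigma_e``.  All
linear algebra runs on the sufficient statistics (Z'Z, Z'X, Z'y, X'X, ...),
so a single objective evaluation costs O(q^3) in the total number of random
levels q, never O(n^3).

Poisson and binomial models are fitted by Laplace-approximate maximum
likelihood: for fixed variance parameters, the joint mode of (beta, u) is
found by penalized IRLS on the working response, and the Laplace objective

    -2 l = -2 log f(y | mu_hat) + u_hat' u_hat + log det(Lambda Z'WZ Lambda + I)

is minimized over the standard deviations by a bounded quasi-Newton outer
loop.  Variance parameters live on the standard-deviation scale with a lower
bound at exactly zero, so boundary fits are representable and flagged rather
than failing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize, sparse

from .design import DesignMatrix, build_design
from .families import Family, get_family
from .formula import ModelSpec

__all__ = [
    "FittedGLMM",
    "RandomStructure",
    "RankDeficiencyError",
    "DegenerateResponseError",
    "fit_gaussian",
    "fit_glmm",
    "fit_mixed_model",
    "ensure_olre",
    "simulate_response",
    "OLRE_COLUMN",
]

OLRE_COLUMN = "OLRE"

_INNER_TOL = 1e-8   # PIRLS convergence on the linear predictor
_OUTER_TOL = 1e-6   # outer optimization tolerance on the objective
_RATIO_UPPER = 50.0  # Gaussian: bound on the sd ratio sigma_k / sigma_e
_SD_UPPER = 10.0     # GLMM: bound on latent-scale random-effect sds
_BOUNDARY_TOL = 1e-5


class RankDeficiencyError(np.linalg.LinAlgError):
    pass


class DegenerateResponseError(ValueError):
    pass


class RandomStructure:
    """Sparse indicator matrices for a set of random-intercept groupings."""

    def __init__(self, data: pd.DataFrame, groups: list[str]):
        self.groups = list(groups)
        n = len(data)
        self.n = n
        blocks = []
        self.slices: dict[str, slice] = {}
        self.levels: dict[str, np.ndarray] = {}
        start = 0
        for g in groups:
            codes, levels = pd.factorize(data[g], sort=True)
            q = len(levels)
            Zg = sparse.csr_matrix(
                (np.ones(n), (np.arange(n), codes)), shape=(n, q)
            )
            blocks.append(Zg)
            self.slices[g] = slice(start, start + q)
            self.levels[g] = np.asarray(levels)
            start += q
        self.q = start
        self.Z = sparse.hstack(blocks, format="csr") if blocks else None

    def sd_vector(self, s_by_group: dict[str, float]) -> np.ndarray:
        d = np.empty(self.q)
        for g in self.groups:
            d[self.slices[g]] = s_by_group[g]
        return d


@dataclass
class FittedGLMM:
    """A fitted random-intercept (G)LMM.

    ``resid_variance`` is the residual variance for Gaussian models and the
    observation-level random-effect (overdispersion) variance for
    non-Gaussian models (0 when no OLRE is present).  ``eta`` is the linear
    predictor ``X beta`` on the link scale, without random effects.
    """

    beta: np.ndarray
    re_variances: dict[str, float]
    resid_variance: float
    eta: np.ndarray
    design: DesignMatrix
    spec: ModelSpec
    random: RandomStructure
    family: Family
    y: np.ndarray
    weights: np.ndarray          # binomial trial counts; ones otherwise
    converged: bool
    loglik: float
    olre_added: bool = False
    olre_group: str | None = None
    warnings: list[str] = field(default_factory=list)

    @property
    def n_obs(self) -> int:
        return len(self.y)

    @property
    def sum_re_variance(self) -> float:
        """Total random-intercept variance excluding any OLRE."""
        return float(
            sum(v for g, v in self.re_variances.items() if g != self.olre_group)
        )


def _check_rank(X: np.ndarray) -> None:
    XtX = X.T @ X
    ev = np.linalg.eigvalsh(XtX)
    if ev[0] <= max(ev[-1], 1.0) * 1e-10:
        raise RankDeficiencyError(
            "design matrix is rank-deficient (collinear or empty columns)"
        )


def fit_gaussian(
    design: DesignMatrix,
    random: RandomStructure,
    y: np.ndarray,
    spec: ModelSpec | None = None,
) -> FittedGLMM:
    """REML fit of a Gaussian random-intercept model."""
    X = design.matrix
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    K = len(random.groups)
    if n <= p + K:
        raise ValueError(f"too few observations (n={n}) for {p} fixed and {K} variance parameters")
    if not np.all(np.isfinite(y)):
        raise ValueError("response contains non-finite values")
    _check_rank(X)

    Z = random.Z
    A = np.asarray((Z.T @ Z).todense())
    B = np.asarray(Z.T @ X)
    c = np.asarray(Z.T @ y).ravel()
    XtX = X.T @ X
    Xty = X.T @ y
    yty = float(y @ y)
    q = random.q

    def profile(s: np.ndarray):
        d = random.sd_vector(dict(zip(random.groups, s)))
        M = d[:, None] * A * d[None, :]
        M[np.diag_indices(q)] += 1.0
        cf = linalg.cho_factor(M, lower=True, check_finite=False)
        DB = d[:, None] * B
        Dc = d * c
        MiDB = linalg.cho_solve(cf, DB, check_finite=False)
        MiDc = linalg.cho_solve(cf, Dc, check_finite=False)
        XtVX = XtX - DB.T @ MiDB
        XtVy = Xty - DB.T @ MiDc
        ytVy = yty - Dc @ MiDc
        beta = linalg.solve(XtVX, XtVy, assume_a="pos")
        rss = max(ytVy - beta @ XtVy, 1e-300)
        sigma2 = rss / (n - p)
        logdet_M = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
        sign, logdet_XtVX = np.linalg.slogdet(XtVX)
        neg2reml = (
            logdet_M + logdet_XtVX + (n - p) * (1.0 + np.log(2.0 * np.pi * sigma2))
        )
        return neg2reml, beta, sigma2

    def objective(s: np.ndarray) -> float:
        return profile(np.asarray(s))[0]

    s0 = np.full(K, 1.0)
    res = optimize.minimize(
        objective,
        s0,
        method="L-BFGS-B",
        bounds=[(0.0, _RATIO_UPPER)] * K,
        options={"ftol": _OUTER_TOL * 1e-2, "gtol": 1e-7},
    )
    s_hat = np.asarray(res.x)
    neg2reml, beta, sigma2 = profile(s_hat)

    warnings_: list[str] = []
    if not res.success:
        warnings_.append(f"REML optimizer did not report convergence: {res.message}")
    re_variances: dict[str, float] = {}
    for g, s in zip(random.groups, s_hat):
        v = float(s * s * sigma2)
        if s < _BOUNDARY_TOL:
            v = 0.0
            warnings_.append(f"variance of random intercept {g!r} estimated at the zero boundary")
        re_variances[g] = v

    eta = X @ beta
    return FittedGLMM(
        beta=beta,
        re_variances=re_variances,
        resid_variance=float(sigma2),
        eta=eta,
        design=design,
        spec=spec,
        random=random,
        family=get_family("gaussian", "identity"),
        y=y,
        weights=np.ones(n),
        converged=bool(res.success),
        loglik=-0.5 * float(neg2reml),
        warnings=warnings_,
    )


def _pirls(X, Z, y, weights, family, d, beta0, u0):
    """Penalized IRLS for the joint mode of (beta, u) at fixed sd vector d.

    Returns (beta, u, eta, mu, neg2ll_cond, logdet, n_iter, converged).
    """
    n, p = X.shape
    q = Z.shape[1]
    beta = beta0.copy()
    u = u0.copy()
    Zd = Z.multiply(d[None, :]).tocsr()  # Z Lambda
    eta = X @ beta + Zd @ u
    eta = family.clip_eta(eta)
    converged = False
    logdet = np.nan
    for it in range(200):
        mu = family.linkinv(eta)
        gprime = np.maximum(family.mu_eta(eta), 1e-10)
        var = np.maximum(family.variance(mu), 1e-10)
        w = np.clip(weights * gprime**2 / var, 1e-12, 1e12)
        z = eta + (y - mu) / gprime

        wX = w[:, None] * X
        XtWX = X.T @ wX
        ZtWX = np.asarray(Zd.T @ wX)
        ZtWZ = np.asarray((Zd.T @ Zd.multiply(w[:, None])).todense())
        ZtWZ[np.diag_indices(q)] += 1.0
        XtWz = X.T @ (w * z)
        ZtWz = np.asarray(Zd.T @ (w * z)).ravel()

        H = np.block([[XtWX, ZtWX.T], [ZtWX, ZtWZ]])
        rhs = np.concatenate([XtWz, ZtWz])
        try:
            cf = linalg.cho_factor(H, lower=True, check_finite=False)
            sol = linalg.cho_solve(cf, rhs, check_finite=False)
        except np.linalg.LinAlgError:
            # near-singular system at extreme variance trials: ridge + lstsq
            H[np.diag_indices_from(H)] += 1e-6 * (1.0 + np.abs(np.diag(H)))
            sol = np.linalg.lstsq(H, rhs, rcond=None)[0]
        beta_new, u_new = sol[:p], sol[p:]

        eta_new = family.clip_eta(X @ beta_new + Zd @ u_new)
        step = 1.0
        # step-halving on the penalized deviance for robustness
        pdev_old = -2.0 * family.loglik(y, family.linkinv(eta), weights) + u @ u
        for _ in range(12):
            b_try = beta + step * (beta_new - beta)
            u_try = u + step * (u_new - u)
            eta_try = family.clip_eta(X @ b_try + Zd @ u_try)
            pdev_try = (
                -2.0 * family.loglik(y, family.linkinv(eta_try), weights)
                + u_try @ u_try
            )
            if np.isfinite(pdev_try) and pdev_try <= pdev_old + 1e-10:
                break
            step *= 0.5
        beta = beta + step * (beta_new - beta)
        u = u + step * (u_new - u)
        eta_prev, eta = eta, family.clip_eta(X @ beta + Zd @ u)
        if np.max(np.abs(eta - eta_prev)) < _INNER_TOL * (1.0 + np.max(np.abs(eta))):
            converged = True
            break
    mu = family.linkinv(eta)
    # log det of the u-block Hessian (Lambda Z'WZ Lambda + I) at the mode
    gprime = np.maximum(family.mu_eta(eta), 1e-10)
    var = np.maximum(family.variance(mu), 1e-10)
    w = np.clip(weights * gprime**2 / var, 1e-12, 1e12)
    Mu = np.asarray((Zd.T @ Zd.multiply(w[:, None])).todense())
    Mu[np.diag_indices(q)] += 1.0
    cfu = linalg.cho_factor(Mu, lower=True, check_finite=False)
    logdet = 2.0 * float(np.sum(np.log(np.diag(cfu[0]))))
    neg2ll_cond = -2.0 * family.loglik(y, mu, weights)
    return beta, u, eta, mu, neg2ll_cond, logdet, it + 1, converged


def fit_glmm(
    design: DesignMatrix,
    random: RandomStructure,
    y: np.ndarray,
    family: str,
    link: str,
    weights: np.ndarray | None = None,
    spec: ModelSpec | None = None,
    olre_group: str | None = None,
) -> FittedGLMM:
    """Laplace-approximate ML fit of a Poisson or binomial random-intercept model.

    For binomial proportion data, ``y`` holds proportions and ``weights`` the
    trial counts.
    """
    fam = get_family(family, link)
    X = design.matrix
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if weights is None:
        weights = np.ones(n)
    weights = np.asarray(weights, dtype=float)
    if family == "poisson" and not np.any(y > 0):
        raise DegenerateResponseError("all counts are zero; the response is degenerate")
    _check_rank(X)

    K = len(random.groups)
    Z = random.Z

    # starting values on the mean scale, nudged away from the boundary
    if family == "binomial":
        mu0 = (y * weights + 0.5) / (weights + 1.0)
        eta0 = np.log(mu0 / (1 - mu0)) if link == "logit" else np.clip(mu0, 1e-4, 1 - 1e-4)
        if link == "probit":
            from scipy.stats import norm as _norm

            eta0 = _norm.ppf(mu0)
    else:
        mu0 = y + 0.1
        eta0 = np.log(mu0) if link == "log" else np.sqrt(mu0)
    beta_start = np.linalg.lstsq(X, eta0, rcond=None)[0]

    state = {"beta": beta_start, "u": np.zeros(random.q), "pirls_ok": True}

    def objective(s: np.ndarray) -> float:
        d = random.sd_vector(dict(zip(random.groups, np.asarray(s))))
        try:
            beta, u, eta, mu, neg2ll, logdet, _, ok = _pirls(
                X, Z, y, weights, fam, d, state["beta"], state["u"]
            )
        except np.linalg.LinAlgError:
            return 1e10  # infeasible variance trial; steer the optimizer back
        state["beta"], state["u"], state["pirls_ok"] = beta, u, ok
        val = neg2ll + float(u @ u) + logdet
        return val if np.isfinite(val) else 1e10

    s0 = np.full(K, 0.5)
    res = optimize.minimize(
        objective,
        s0,
        method="L-BFGS-B",
        bounds=[(0.0, _SD_UPPER)] * K,
        options={"ftol": _OUTER_TOL * 1e-3, "gtol": 1e-7},
    )
    s_hat = np.asarray(res.x)
    neg2lap = objective(s_hat)
    beta, u = state["beta"], state["u"]

    warnings_: list[str] = []
    converged = bool(res.success) and state["pirls_ok"]
    if not res.success:
        warnings_.append(f"Laplace optimizer did not report convergence: {res.message}")
    if not state["pirls_ok"]:
        warnings_.append(
            "penalized IRLS did not converge at the optimum "
            "(possible complete separation or degenerate response)"
        )

    re_variances: dict[str, float] = {}
    for g, s in zip(random.groups, s_hat):
        v = float(s * s)
        if s < _BOUNDARY_TOL:
            v = 0.0
            warnings_.append(f"variance of random intercept {g!r} estimated at the zero boundary")
        re_variances[g] = v

    resid_variance = 0.0
    if olre_group is not None and olre_group in re_variances:
        resid_variance = re_variances.pop(olre_group)

    eta_fixed = X @ beta
    return FittedGLMM(
        beta=beta,
        re_variances=re_variances,
        resid_variance=resid_variance,
        eta=eta_fixed,
        design=design,
        spec=spec,
        random=random,
        family=fam,
        y=y,
        weights=weights,
        converged=converged,
        loglik=-0.5 * float(neg2lap),
        olre_added=olre_group is not None,
        olre_group=olre_group,
        warnings=warnings_,
    )


def ensure_olre(spec: ModelSpec, data: pd.DataFrame):
    """Add an observation-level random effect for overdispersed families.

    Poisson responses and binomial proportion responses (trials > 1) get a
    row-index grouping column appended to ``random_groups`` unless some
    grouping factor already has one level per observation.  Binary binomial
    responses are left unchanged (a Bernoulli variable cannot express
    overdispersion this way).

    Returns ``(spec, data, added)``.
    """
    if spec.family == "gaussian":
        return spec, data, False
    if spec.family == "binomial":
        if not isinstance(spec.response, tuple):
            return spec, data, False
        trials = (
            data[spec.response[0]].to_numpy() + data[spec.response[1]].to_numpy()
        )
        if np.all(trials <= 1):
            return spec, data, False
    for g in spec.random_groups:
        if data[g].nunique() == len(data):
            return spec, data, False
    data2 = data.copy()
    data2[OLRE_COLUMN] = np.arange(len(data2))
    spec2 = ModelSpec(
        response=spec.response,
        fixed_terms=list(spec.fixed_terms),
        random_groups=list(spec.random_groups) + [OLRE_COLUMN],
        family=spec.family,
        link=spec.link,
    )
    return spec2, data2, True


def extract_response(spec: ModelSpec, data: pd.DataFrame):
    """Return (y, weights): proportions + trial counts for binomial pairs."""
    if isinstance(spec.response, tuple):
        succ = data[spec.response[0]].to_numpy(dtype=float)
        fail = data[spec.response[1]].to_numpy(dtype=float)
        trials = succ + fail
        if np.any(trials <= 0):
            raise ValueError("each row needs at least one binomial trial")
        return succ / trials, trials
    y = data[spec.response].to_numpy(dtype=float)
    if spec.family == "binomial" and not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError(
            "single-column binomial response must be binary 0/1; use a "
            "(successes, failures) column pair for proportion data"
        )
    return y, np.ones(len(y))


def fit_mixed_model(
    spec: ModelSpec,
    data: pd.DataFrame,
    terms: list[str] | None = None,
    y_override: np.ndarray | None = None,
    random: RandomStructure | None = None,
    olre_group: str | None = None,
) -> FittedGLMM:
    """Fit the model described by ``spec`` (optionally with a reduced term set).

    ``y_override`` substitutes a simulated response (same scale as the
    extracted one: proportions for binomial pairs); the design, random
    structure and trial counts come from ``data``.
    """
    design = build_design(spec, data, terms=terms)
    y, weights = extract_response(spec, data)
    if y_override is not None:
        y = np.asarray(y_override, dtype=float)
    if random is None:
        random = RandomStructure(data, spec.random_groups)
    if olre_group is None and OLRE_COLUMN in spec.random_groups:
        olre_group = OLRE_COLUMN
    if spec.family == "gaussian":
        return fit_gaussian(design, random, y, spec=spec)
    return fit_glmm(
        design,
        random,
        y,
        spec.family,
        spec.link,
        weights=weights,
        spec=spec,
        olre_group=olre_group,
    )


def simulate_response(fit: FittedGLMM, rng: np.random.Generator) -> np.ndarray:
    """Draw a parametric-bootstrap response from the fitted model.

    Fresh random intercepts are drawn for every group level (including the
    OLRE, whose variance lives in ``resid_variance``), added to ``X beta``,
    and the response is sampled from the fitted family.  Binomial responses
    come back as proportions of the original trial counts.
    """
    latent = fit.eta.copy()
    rs = fit.random
    variances = dict(fit.re_variances)
    if fit.olre_group is not None:
        variances[fit.olre_group] = fit.resid_variance
    for g in rs.groups:
        v = variances.get(g, 0.0)
        sl = rs.slices[g]
        if v > 0:
            alpha = rng.normal(0.0, np.sqrt(v), sl.stop - sl.start)
            latent += rs.Z[:, sl] @ alpha
    fam = fit.family
    if fam.name == "gaussian":
        if fit.resid_variance > 0:
            return latent + rng.normal(0.0, np.sqrt(fit.resid_variance), fit.n_obs)
        return latent
    mu = fam.linkinv(latent)
    if fam.name == "poisson":
        return rng.poisson(mu).astype(float)
    k = rng.binomial(fit.weights.astype(int), mu)
    return k / fit.weights
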