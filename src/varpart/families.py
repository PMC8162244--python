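"""Exponential-family response distributions and link functions.

Only the combinations with a known latent-scale (distribution-specific)
variance are supported: Gaussian/identity, Poisson/log, Poisson/sqrt,
binomial/logit, binomial/probit.  Binomial proportion data are handled as
(successes, trials) with the response stored as a proportion and the trial
counts acting as prior weights.
"""

from __future__ import annotations

import numpy as np
from scipy import special, stats

__all__ = ["Family", "get_family", "ETA_CLIP"]

# linear predictors are clipped to this range for binomial/poisson-log to
# keep the IRLS weights finite under (near-)separation
ETA_CLIP = 30.0


class Family:
    name: str
    link: str

    def linkinv(self, eta: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def mu_eta(self, eta: np.ndarray) -> np.ndarray:
        """d mu / d eta."""
        raise NotImplementedError

    def variance(self, mu: np.ndarray) -> np.ndarray:
        """Conditional variance of a single trial given mu."""
        raise NotImplementedError

    def loglik(self, y: np.ndarray, mu: np.ndarray, weights: np.ndarray) -> float:
        raise NotImplementedError

    def clip_eta(self, eta: np.ndarray) -> np.ndarray:
        return eta


class Gaussian(Family):
    name, link = "gaussian", "identity"

    def linkinv(self, eta):
        return eta

    def mu_eta(self, eta):
        return np.ones_like(eta)

    def variance(self, mu):
        return np.ones_like(mu)


class PoissonLog(Family):
    name, link = "poisson", "log"

    def clip_eta(self, eta):
        return np.clip(eta, -ETA_CLIP, ETA_CLIP)

    def linkinv(self, eta):
        return np.exp(self.clip_eta(eta))

    def mu_eta(self, eta):
        return np.exp(self.clip_eta(eta))

    def variance(self, mu):
        return mu

    def loglik(self, y, mu, weights):
        return float(np.sum(stats.poisson.logpmf(np.round(y).astype(int), mu)))


class PoissonSqrt(PoissonLog):
    name, link = "poisson", "sqrt"

    def clip_eta(self, eta):
        # sqrt link: eta must stay positive for mu = eta^2 to be invertible
        return np.clip(eta, 1e-6, None)

    def linkinv(self, eta):
        return self.clip_eta(eta) ** 2

    def mu_eta(self, eta):
        return 2.0 * self.clip_eta(eta)


class BinomialLogit(Family):
    name, link = "binomial", "logit"

    def clip_eta(self, eta):
        return np.clip(eta, -ETA_CLIP, ETA_CLIP)

    def linkinv(self, eta):
        return special.expit(self.clip_eta(eta))

    def mu_eta(self, eta):
        p = self.linkinv(eta)
        return p * (1.0 - p)

    def variance(self, mu):
        return mu * (1.0 - mu)

    def loglik(self, y, mu, weights):
        k = np.round(y * weights).astype(int)
        n = np.round(weights).astype(int)
        return float(np.sum(stats.binom.logpmf(k, n, mu)))


class BinomialProbit(BinomialLogit):
    name, link = "binomial", "probit"

    def linkinv(self, eta):
        return stats.norm.cdf(self.clip_eta(eta))

    def mu_eta(self, eta):
        return stats.norm.pdf(self.clip_eta(eta))


_FAMILIES = {
    ("gaussian", "identity"): Gaussian,
    ("poisson", "log"): PoissonLog,
    ("poisson", "sqrt"): PoissonSqrt,
    ("binomial", "logit"): BinomialLogit,
    ("binomial", "probit"): BinomialProbit,
}


def get_family(family: str, link: str) -> Family:
    try:
        return _FAMILIES[(family, link)]()
    except KeyError:
        raise ValueError(
            f"unsupported family/link {family}+{link}; supported: "
            f"{sorted(_FAMILIES)}"
        ) from None
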