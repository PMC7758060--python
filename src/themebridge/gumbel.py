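"""Gumbel (extreme value) fitting for alignment-score nulls.

Optimal local alignment scores against random sequences follow an extreme
value (Gumbel) distribution; both the database-scan E-value and the
segment-pair p-value rest on fitting its location mu and scale beta to
empirical null scores.  Fitting is method-of-moments initialisation
(beta = s*sqrt(6)/pi, mu = mean - gamma*beta, gamma the Euler–Mascheroni
constant) followed by maximum-likelihood refinement.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

EULER_GAMMA = float(np.euler_gamma)


@dataclass(frozen=True)
class GumbelFit:
    """Location/scale of a fitted Gumbel null."""

    mu: float
    beta: float
    n_samples: int

    def __post_init__(self):
        if not self.beta > 0:
            raise ValueError("beta must be positive")
        if self.n_samples < 100:
            raise ValueError("need >= 100 samples for a usable fit")

    def cdf(self, s: float) -> float:
        return float(np.exp(-np.exp(-(s - self.mu) / self.beta)))

    def sf(self, s: float) -> float:
        """P(S >= s) = 1 - exp(-exp(-(s - mu)/beta))."""
        with np.errstate(over="ignore"):  # exp overflow -> sf saturates at 1
            return float(-np.expm1(-np.exp(-(np.asarray(s, float) - self.mu)
                                           / self.beta)))


def fit_gumbel(scores: np.ndarray) -> GumbelFit:
    """Fit by method of moments, then ML refinement."""
    scores = np.asarray(scores, dtype=float)
    if scores.size < 100:
        raise ValueError("need >= 100 scores")
    sd = scores.std(ddof=1)
    if sd == 0:
        raise ValueError("zero-variance scores: null is degenerate")
    beta0 = sd * np.sqrt(6.0) / np.pi
    mu0 = scores.mean() - EULER_GAMMA * beta0
    mu, beta = stats.gumbel_r.fit(scores, loc=mu0, scale=beta0)
    return GumbelFit(float(mu), float(beta), int(scores.size))
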