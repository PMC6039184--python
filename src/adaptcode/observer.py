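"""Optimal Bayesian observer for the two-state environment.

The observer's belief is the posterior probability ``p_low`` that the
environment currently occupies the low state.  One update step consists of

1. hazard propagation: ``p <- p (1 - h) + (1 - p) h``,
2. Bayesian combination with the stimulus likelihood (done in log space), and
3. optionally, marginalization over a decoding distribution when the observer
   receives an encoded response instead of the raw stimulus (Monte-Carlo:
   draw samples from the decoding distribution, update with each, average
   the resulting posteriors).

Point estimate and prediction are posterior-mean convex combinations of the
two state values.  For small hazard rates the prediction is approximated by
the current estimate, which is what is fed back to the encoders.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.special import xlogy

from .environment import EnvironmentConfig, state_params

__all__ = [
    "Belief",
    "DecodingDistribution",
    "hazard_propagate",
    "likelihood_update",
    "marginal_update",
    "point_estimate",
    "estimate_to_p_low",
    "uncertainty",
    "one_step_estimate",
    "predicted_params",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Belief:
    """Posterior summary: P(low state), posterior-mean estimate, and the
    hazard-propagated one-step prediction."""

    p_low: float
    estimate: float
    prediction: float

    @classmethod
    def from_p_low(cls, p_low: float, config: EnvironmentConfig) -> "Belief":
        p_next = hazard_propagate(p_low, config.hazard)
        return cls(
            p_low=float(p_low),
            estimate=point_estimate(p_low, config),
            prediction=point_estimate(p_next, config),
        )


@dataclass(frozen=True)
class DecodingDistribution:
    """The observer's model p(x_t | y_t) of the stimulus given the response.

    kind
        ``"delta"`` — the response pins the stimulus exactly (scale must be 0).
        ``"gaussian"`` — closed-form Gaussian decoder (temporal filter).
        ``"prior_marginal"`` — no information in the response; fall back on
        the predicted stimulus law (gating null symbol).  ``location`` and
        ``scale`` then carry the predicted mean and SD.
    """

    kind: str
    location: float
    scale: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("delta", "gaussian", "prior_marginal"):
            raise ValueError(f"unknown decoding kind {self.kind!r}")
        if self.kind == "delta" and self.scale != 0.0:
            raise ValueError("delta decoding must have scale 0")
        if self.kind in ("gaussian", "prior_marginal") and self.scale <= 0.0:
            raise ValueError(f"{self.kind} decoding requires scale > 0")

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.kind == "delta":
            return np.full(n, self.location)
        return rng.normal(self.location, self.scale, size=n)


def hazard_propagate(p_low, h: float):
    """One step of the state dynamics applied to the belief."""
    p_low = np.asarray(p_low, dtype=float)
    out = p_low * (1.0 - h) + (1.0 - p_low) * h
    return out if out.ndim else float(out)


def _log_normal_pdf(x, mu, sigma):
    z = (x - mu) / sigma
    return -0.5 * z * z - np.log(sigma) - 0.5 * np.log(2.0 * np.pi)


def likelihood_update(p_prior, x, config: EnvironmentConfig):
    """Combine a hazard-propagated prior with the likelihood of stimulus x.

    Returns the posterior P(low).  Vectorized over ``x`` and/or ``p_prior``.
    Computed in log space with log-sum-exp normalization; if the result is
    not finite (e.g. non-finite stimulus) the prior is returned unchanged.
    """
    p_prior = np.asarray(p_prior, dtype=float)
    x = np.asarray(x, dtype=float)
    mu_lo, sd_lo = state_params(config.theta_low, config)
    mu_hi, sd_hi = state_params(config.theta_high, config)
    with np.errstate(divide="ignore", invalid="ignore"):
        log_lo = _log_normal_pdf(x, mu_lo, sd_lo) + np.log(p_prior)
        log_hi = _log_normal_pdf(x, mu_hi, sd_hi) + np.log(1.0 - p_prior)
        norm = np.logaddexp(log_lo, log_hi)
        post = np.exp(log_lo - norm)
    # degenerate priors: log 0 - log 0; restore the absorbing belief
    post = np.where(p_prior == 0.0, 0.0, post)
    post = np.where(p_prior == 1.0, 1.0, post)
    bad = ~np.isfinite(post)
    if np.any(bad):
        logger.warning("likelihood_update: non-finite posterior for %d value(s); "
                       "returning prior unchanged", int(np.sum(bad)))
        post = np.where(bad, p_prior, post)
    return post if post.ndim else float(post)


def marginal_update(p_prev, decode: DecodingDistribution, config: EnvironmentConfig,
                    n_samples: int = 200, rng: np.random.Generator | None = None) -> float:
    """Belief update marginalized over the decoding distribution.

    Draws ``n_samples`` stimulus hypotheses from ``decode``, performs a full
    hazard + likelihood update with each, and averages the resulting
    posteriors.  For delta decoding this reduces exactly to a single update.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    p_prior = hazard_propagate(p_prev, config.hazard)
    if decode.kind == "delta":
        return float(likelihood_update(p_prior, decode.location, config))
    if rng is None:
        raise ValueError("marginal_update with a non-delta decoder needs an rng")
    xs = decode.sample(n_samples, rng)
    posts = likelihood_update(p_prior, xs, config)
    return float(np.mean(posts))


def point_estimate(p_low, config: EnvironmentConfig):
    """Posterior-mean state estimate: p θ_L + (1 - p) θ_H."""
    p_low = np.asarray(p_low, dtype=float)
    out = p_low * config.theta_low + (1.0 - p_low) * config.theta_high
    return out if out.ndim else float(out)


def estimate_to_p_low(estimate, config: EnvironmentConfig):
    """Invert the point estimate back to P(low)."""
    estimate = np.asarray(estimate, dtype=float)
    out = (config.theta_high - estimate) / (config.theta_high - config.theta_low)
    return out if out.ndim else float(out)


def uncertainty(p_low):
    """Binary entropy of the belief, in nats (0 log 0 := 0)."""
    p = np.asarray(p_low, dtype=float)
    out = -(xlogy(p, p) + xlogy(1.0 - p, 1.0 - p))
    return out if out.ndim else float(out)


def one_step_estimate(p_prev, x, config: EnvironmentConfig):
    """State estimate after one full Bayesian step (hazard + likelihood)
    starting from belief ``p_prev`` and observing raw stimulus ``x``.

    This is the ideal-observer estimate used inside the inference distortion
    of the encoders.  Vectorized over ``x``.
    """
    p_prior = hazard_propagate(p_prev, config.hazard)
    post = likelihood_update(p_prior, x, config)
    return point_estimate(post, config)


def predicted_params(estimate: float, config: EnvironmentConfig) -> tuple[float, float]:
    """(mean, sd) of the predicted stimulus distribution p(x | theta_hat)."""
    if config.mode == "mean":
        return float(estimate), config.fixed_sigma
    return config.fixed_mu, float(estimate)
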