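"""Stationary surprise/uncertainty analysis for generalized Gaussian stimuli.

A single stimulus is observed by a Bayesian estimator of the location or
scale of a stationary generalized Gaussian stimulus distribution

    p(x; mu, alpha, beta) = beta / (2 alpha Gamma(1/beta))
                            * exp(-(|x - mu| / alpha)^beta).

The *impact* of the stimulus — the squared change of the posterior-mean
estimate — is mapped over a grid of prior uncertainties (prior entropies)
and stimulus surprises.  Location estimation uses a Gaussian prior (conjugate
in closed form when the shape is 2, numeric otherwise); scale estimation
uses an inverse-gamma prior over the scale parameter and sweeps *centered*
surprise, the deviation of a stimulus's surprise from the predicted entropy.

The companion encoding-error map measures the estimate distortion induced by
reporting a response y in place of the stimulus x.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq
from scipy.special import digamma, gammaln
from scipy.stats import gennorm, invgamma

__all__ = [
    "GenGaussParams",
    "MapGrid",
    "gengauss_density",
    "gengauss_entropy",
    "entropy_to_prior",
    "surprise_to_stimulus",
    "impact_map",
    "encoding_error_map",
    "tolerance_set",
]

# nuisance parameters: unit-variance Gaussian corresponds to scale sqrt(2)
LOCATION_SCALE = float(np.sqrt(2.0))
SCALE_PRIOR_MEAN = float(np.sqrt(2.0))  # alpha_hat with alpha_hat^2 / 2 = 1


@dataclass(frozen=True)
class GenGaussParams:
    """Generalized Gaussian parameters: location mu, scale alpha > 0,
    shape beta > 0 (shape 2 = Gaussian with variance alpha^2/2, shape 1 =
    Laplace, large shape -> flat/boxy)."""

    location: float = 0.0
    scale: float = LOCATION_SCALE
    shape: float = 2.0

    def __post_init__(self) -> None:
        if self.scale <= 0 or self.shape <= 0:
            raise ValueError("scale and shape must be positive")


@dataclass(frozen=True)
class MapGrid:
    """Evaluation grid: prior entropies in [0, 0.7] crossed with (centered)
    surprises in [1, 10], 100 values each by default."""

    uncertainty_values: np.ndarray
    surprise_values: np.ndarray
    estimated_parameter: str = "location"

    @classmethod
    def default(cls, estimated_parameter: str = "location",
                n_uncertainty: int = 100, n_surprise: int = 100) -> "MapGrid":
        return cls(
            uncertainty_values=np.linspace(0.0, 0.7, n_uncertainty),
            surprise_values=np.linspace(1.0, 10.0, n_surprise),
            estimated_parameter=estimated_parameter,
        )


def gengauss_density(x, params: GenGaussParams):
    out = gennorm.pdf(np.asarray(x, dtype=float), params.shape,
                      loc=params.location, scale=params.scale)
    return out if np.ndim(out) else float(out)


def gengauss_entropy(params: GenGaussParams) -> float:
    """Closed-form differential entropy: 1/beta + log(2 alpha Gamma(1/beta) / beta)."""
    b = params.shape
    return float(1.0 / b + np.log(2.0 * params.scale / b) + gammaln(1.0 / b))


def _min_surprise(params: GenGaussParams) -> float:
    """Surprise at the density mode (the smallest attainable surprise)."""
    b = params.shape
    return float(np.log(2.0 * params.scale / b) + gammaln(1.0 / b))


def _invgamma_entropy(a0: float, b0: float) -> float:
    return float(a0 + np.log(b0) + gammaln(a0) - (1.0 + a0) * digamma(a0))


def entropy_to_prior(entropy: float, estimated_parameter: str):
    """Prior parameters whose entropy equals the requested value.

    location: zero-mean Gaussian prior with variance exp(2H)/(2 pi e).
    scale: inverse-gamma (a0, b0) over the scale parameter, with the mean
    pinned to sqrt(2) (so the estimated variance-like quantity alpha^2/2 is
    1) via b0 = sqrt(2) (a0 - 1), and a0 > 2 found by root-finding on the
    entropy formula (the regime where mean and variance exist and the
    entropy is monotonic).
    """
    if estimated_parameter == "location":
        var = float(np.exp(2.0 * entropy) / (2.0 * np.pi * np.e))
        return {"mean": 0.0, "variance": var}
    if estimated_parameter != "scale":
        raise ValueError("estimated_parameter must be 'location' or 'scale'")

    def f(a0: float) -> float:
        return _invgamma_entropy(a0, SCALE_PRIOR_MEAN * (a0 - 1.0)) - entropy

    lo, hi = 2.0 + 1e-9, 1e8
    if f(lo) < 0.0:
        raise ValueError(f"no inverse-gamma prior with a0 > 2 attains entropy {entropy}")
    a0 = brentq(f, lo, hi, xtol=1e-12)
    return {"a0": float(a0), "b0": float(SCALE_PRIOR_MEAN * (a0 - 1.0))}


def surprise_to_stimulus(surprise: float, params: GenGaussParams) -> float:
    """Positive-side stimulus whose negative log density equals ``surprise``."""
    c = _min_surprise(params)
    if surprise < c - 1e-12:
        raise ValueError(f"surprise {surprise} is below the minimum attainable {c:.4f}")
    excess = max(surprise - c, 0.0)
    return float(params.location + params.scale * excess ** (1.0 / params.shape))


def _posterior_mean_location(x_star: float, prior_var: float,
                             shape: float, *, numeric: bool = False) -> float:
    """Posterior-mean location after one observation.

    Conjugate closed form for the Gaussian case (shape 2, likelihood
    variance 1); numeric grid posterior (trapezoid, +/- 6 prior SDs, 2001
    points) otherwise, or on request via ``numeric=True``.
    """
    if shape == 2.0 and not numeric:
        return prior_var * x_star / (prior_var + 1.0)
    sd = np.sqrt(prior_var)
    mu_grid = np.linspace(-6.0 * sd, 6.0 * sd, 2001)
    log_prior = -0.5 * (mu_grid / sd) ** 2
    log_like = gennorm.logpdf(x_star, shape, loc=mu_grid, scale=LOCATION_SCALE)
    w = np.exp(log_prior + log_like - np.max(log_prior + log_like))
    z = np.trapezoid(w, mu_grid)
    return float(np.trapezoid(w * mu_grid, mu_grid) / z)


def _posterior_mean_scale(x_star: float, a0: float, b0: float,
                          shape: float) -> float:
    """Posterior-mean scale parameter after one observation (numeric grid)."""
    prior = invgamma(a0, scale=b0)
    hi = prior.mean() + 6.0 * prior.std()
    alpha_grid = np.linspace(1e-3, hi, 2001)
    log_prior = prior.logpdf(alpha_grid)
    log_like = gennorm.logpdf(x_star, shape, loc=0.0, scale=alpha_grid)
    log_post = log_prior + log_like
    w = np.exp(log_post - np.max(log_post))
    z = np.trapezoid(w, alpha_grid)
    return float(np.trapezoid(w * alpha_grid, alpha_grid) / z)


def impact_map(grid: MapGrid, shape: float = 2.0) -> np.ndarray:
    """Squared change of the estimate caused by a single stimulus, over the
    (uncertainty, surprise) grid.  Rows index uncertainty, columns surprise.

    Location estimation: prior mean 0, likelihood scale sqrt(2); the surprise
    axis is raw surprise.  Scale estimation: prior mean scale sqrt(2),
    stimulus location 0; the surprise axis is centered surprise (deviation
    above the predicted entropy), and the estimate is reported as alpha^2/2.
    """
    est = grid.estimated_parameter
    out = np.empty((len(grid.uncertainty_values), len(grid.surprise_values)))
    if est == "location":
        pred = GenGaussParams(location=0.0, scale=LOCATION_SCALE, shape=shape)
        # surprises below the density's attainable minimum clamp to the mode
        s_min = _min_surprise(pred)
        xs = [surprise_to_stimulus(max(s, s_min), pred) for s in grid.surprise_values]
        for i, H in enumerate(grid.uncertainty_values):
            prior_var = entropy_to_prior(H, "location")["variance"]
            for j, x_star in enumerate(xs):
                m = _posterior_mean_location(x_star, prior_var, shape)
                out[i, j] = m ** 2  # prior mean is 0
        return out
    if est != "scale":
        raise ValueError("estimated_parameter must be 'location' or 'scale'")
    pred = GenGaussParams(location=0.0, scale=SCALE_PRIOR_MEAN, shape=shape)
    h_pred = gengauss_entropy(pred)
    xs = [surprise_to_stimulus(h_pred + s, pred) for s in grid.surprise_values]
    prior_scale_sq = SCALE_PRIOR_MEAN ** 2 / 2.0  # = 1
    for i, H in enumerate(grid.uncertainty_values):
        pr = entropy_to_prior(H, "scale")
        for j, x_star in enumerate(xs):
            m = _posterior_mean_scale(x_star, pr["a0"], pr["b0"], shape)
            out[i, j] = (prior_scale_sq - m ** 2 / 2.0) ** 2
    return out


def encoding_error_map(uncertainty: float, stimulus, response):
    """Estimate error from reporting response y in place of stimulus x
    (Gaussian location case): squared difference of the two posterior means."""
    prior_var = entropy_to_prior(uncertainty, "location")["variance"]
    w = prior_var / (prior_var + 1.0)
    err = (w * (np.asarray(stimulus, dtype=float) - np.asarray(response, dtype=float))) ** 2
    return err if np.ndim(err) else float(err)


def tolerance_set(uncertainty: float, response: float,
                  e_tol: float) -> tuple[float, float]:
    """Interval of stimuli that the response can stand in for with encoding
    error below ``e_tol`` (Gaussian location case)."""
    if e_tol < 0:
        raise ValueError("e_tol must be nonnegative")
    prior_var = entropy_to_prior(uncertainty, "location")["variance"]
    w = prior_var / (prior_var + 1.0)
    half = np.sqrt(e_tol) / w
    return (response - half, response + half)
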