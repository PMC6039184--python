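"""Two-tap temporal-filter encoder with entropy-constrained fidelity.

The response is the filtered stimulus ``y_t = a x_t + (1 - a) x_{t-1}`` with
coefficient ``a in [0.5, 1]``: ``a = 1`` transmits the current stimulus
verbatim, ``a = 0.5`` the average of the last two stimuli.  Decoding is
closed-form Gaussian (marginalizing the unseen previous stimulus under the
predicted stimulus law), and the coding cost is the analytic joint entropy
of two consecutive responses.  The per-belief optimal coefficient minimizes

    <error> + beta * H(y_t, y_{t+1})

where the error is inference error (squared difference of one-step
ideal-observer estimates from x versus from the decoded y) or reconstruction
error ``(x - y)^2``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .environment import EnvironmentConfig
from .observer import (DecodingDistribution, hazard_propagate, likelihood_update,
                       one_step_estimate, point_estimate, predicted_params)

__all__ = [
    "FilterPolicy",
    "filter_response",
    "decode_filter",
    "joint_entropy",
    "fit_policy",
]

DEFAULT_N_PAIRS = 50_000
DEFAULT_N_ALPHA = 50
DEFAULT_N_BINS = 100


def filter_response(x_now, x_prev, alpha: float):
    """y = alpha * x_now + (1 - alpha) * x_prev."""
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha must lie in [0, 1], got {alpha}")
    return alpha * np.asarray(x_now) + (1.0 - alpha) * np.asarray(x_prev)


def _decode_moments(y, alpha: float, mu_hat: float, sigma_hat: float):
    """Mean and SD of the Gaussian decoding distribution p(x_t | y_t)."""
    denom = 1.0 - 2.0 * alpha + 2.0 * alpha * alpha  # >= 1/2 for all alpha
    mean = (alpha * np.asarray(y, dtype=float)
            - (1.0 - alpha) * (2.0 * alpha - 1.0) * mu_hat) / denom
    var = ((1.0 - alpha) ** 2 / denom) * sigma_hat ** 2
    return mean, np.sqrt(var)


def decode_filter(y: float, alpha: float, mu_hat: float,
                  sigma_hat: float) -> DecodingDistribution:
    """Gaussian decoder for the filtered response.

    Inverts the filter given the predicted stimulus law N(mu_hat,
    sigma_hat^2) for the unobserved previous stimulus.  At ``alpha = 1`` the
    decoder collapses to a delta at ``y``.
    """
    if sigma_hat <= 0:
        raise ValueError("sigma_hat must be positive")
    mean, sd = _decode_moments(y, alpha, mu_hat, sigma_hat)
    if sd == 0.0:
        return DecodingDistribution(kind="delta", location=float(mean))
    return DecodingDistribution(kind="gaussian", location=float(mean), scale=float(sd))


def joint_entropy(alpha: float, sigma_hat: float) -> float:
    """Analytic joint entropy H(y_t, y_{t+1}) of two consecutive responses
    under the predicted stimulus law (nats).

    Chain rule of the bivariate Gaussian: H(y_t) + H(y_{t+1} | y_t), where
    var(y_t) = (a^2 + (1-a)^2) s^2 and the conditional variance removes the
    share explained by the overlapping stimulus sample.
    """
    if sigma_hat <= 0:
        raise ValueError("sigma_hat must be positive")
    a = alpha
    s2 = sigma_hat ** 2
    denom = 1.0 - 2.0 * a + 2.0 * a * a
    cond_var = a * a * s2 + (1.0 - a) ** 4 * s2 / denom
    marg_var = a * a * s2 + (1.0 - a) ** 2 * s2
    return float(0.5 * np.log(4.0 * np.pi ** 2 * np.e ** 2 * cond_var * marg_var))


@dataclass
class FilterPolicy:
    """Optimal filter coefficient per belief bin."""

    config: EnvironmentConfig
    goal: str
    entropy_weight: float
    belief_grid: np.ndarray
    alpha_grid: np.ndarray
    alpha_star: np.ndarray
    objective: np.ndarray

    def alpha_for(self, p_low: float) -> float:
        """Coefficient of the nearest belief bin."""
        b = int(np.argmin(np.abs(self.belief_grid - p_low)))
        return float(self.alpha_star[b])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "bin": np.arange(len(self.belief_grid)),
            "p_low": self.belief_grid,
            "alpha_star": self.alpha_star,
            "objective": self.objective,
        })


def _marginal_estimates(y, p_low: float, alpha: float, mu_hat: float,
                        sigma_hat: float, config: EnvironmentConfig,
                        mc_samples: int, rng: np.random.Generator,
                        n_grid: int = 257) -> np.ndarray:
    """Observer estimates from decoded responses, marginalized by Monte Carlo.

    The decoded posterior depends on y only through the decoder mean, so the
    marginalized belief is evaluated on a grid of decoder means (shared noise
    draws) and interpolated at the actual responses.
    """
    mean, sd = _decode_moments(y, alpha, mu_hat, sigma_hat)
    p_prior = hazard_propagate(p_low, config.hazard)
    if sd == 0.0:
        post = likelihood_update(p_prior, mean, config)
        return point_estimate(post, config)
    grid = np.linspace(mean.min(), mean.max(), n_grid)
    z = rng.standard_normal(mc_samples)
    samples = grid[:, None] + sd * z[None, :]
    post = likelihood_update(p_prior, samples, config).mean(axis=1)
    est_grid = point_estimate(post, config)
    return np.interp(mean, grid, est_grid)


def fit_policy(
    config: EnvironmentConfig,
    goal: str,
    entropy_weight: float,
    rng: np.random.Generator,
    *,
    n_pairs: int = DEFAULT_N_PAIRS,
    n_bins: int = DEFAULT_N_BINS,
    n_alpha: int = DEFAULT_N_ALPHA,
    alpha_range: tuple[float, float] = (0.5, 1.0),
    mc_samples: int = 200,
    error_method: str = "marginal",
) -> FilterPolicy:
    """Optimize the filter coefficient for every belief bin.

    For each (belief bin, candidate alpha) the error term is a Monte-Carlo
    average over ``n_pairs`` stimulus pairs drawn from the bin's predicted
    stimulus law; the entropy term is analytic.  Ties in the objective go to
    the larger (higher-fidelity) alpha.

    ``error_method="marginal"`` marginalizes the observer update over the
    Gaussian decoding distribution (``mc_samples`` draws per response);
    ``"plugin"`` conditions on the decoder mean instead, which is faster.
    """
    if goal not in ("inference", "reconstruction"):
        raise ValueError(f"goal must be 'inference' or 'reconstruction', got {goal!r}")
    if error_method not in ("marginal", "plugin"):
        raise ValueError(f"unknown error_method {error_method!r}")
    if entropy_weight < 0:
        raise ValueError("entropy_weight must be nonnegative")
    belief_grid = np.linspace(0.0, 1.0, n_bins)
    alpha_grid = np.linspace(alpha_range[0], alpha_range[1], n_alpha)
    alpha_star = np.empty(n_bins)
    best_obj = np.empty(n_bins)
    for b, p in enumerate(belief_grid):
        est = point_estimate(p, config)
        mu_hat, sigma_hat = predicted_params(est, config)
        objs = np.empty(n_alpha)
        for k, a in enumerate(alpha_grid):
            x_prev = rng.normal(mu_hat, sigma_hat, size=n_pairs)
            x_now = rng.normal(mu_hat, sigma_hat, size=n_pairs)
            y = filter_response(x_now, x_prev, a)
            if goal == "reconstruction":
                err = float(np.mean((x_now - y) ** 2))
            else:
                est_x = one_step_estimate(p, x_now, config)
                if error_method == "plugin":
                    dec_mean, _ = _decode_moments(y, a, mu_hat, sigma_hat)
                    est_y = one_step_estimate(p, dec_mean, config)
                else:
                    est_y = _marginal_estimates(y, p, a, mu_hat, sigma_hat,
                                                config, mc_samples, rng)
                err = float(np.mean((est_x - est_y) ** 2))
            objs[k] = err + entropy_weight * joint_entropy(a, sigma_hat)
        # argmin with ties broken toward the larger alpha
        k_star = n_alpha - 1 - int(np.argmin(objs[::-1]))
        alpha_star[b] = alpha_grid[k_star]
        best_obj[b] = objs[k_star]
    return FilterPolicy(config=config, goal=goal, entropy_weight=entropy_weight,
                        belief_grid=belief_grid, alpha_grid=alpha_grid,
                        alpha_star=alpha_star, objective=best_obj)
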