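"""Stimulus-selection encoder gated by a running misalignment signal.

The encoder tracks the surprise, ``-log p(x | theta_hat)``, of the last T
stimuli under the observer's predicted stimulus law.  Its running average
minus the predicted entropy is the *misalignment* M: in expectation it
equals the KL divergence penalty of predicting with the wrong state (plus
the entropy difference), so it deviates from zero exactly when the
observer's estimate is inaccurate.  When |M| exceeds a threshold — expressed
as a fraction of the maximum analytic misalignment attainable between the
two environment states — the stimulus is transmitted verbatim; otherwise a
null symbol is sent and the observer marginalizes over its own prediction.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import numpy as np

from .environment import EnvironmentConfig, state_params
from .observer import (DecodingDistribution, marginal_update, point_estimate,
                       predicted_params)

__all__ = [
    "Response",
    "GatingState",
    "analytic_misalignment",
    "max_analytic_misalignment",
    "running_misalignment",
    "select_encode",
    "null_observer_update",
]

DEFAULT_WINDOW = 10


@dataclass(frozen=True)
class Response:
    """Encoded response: either a transmitted stimulus value or the null
    symbol.  The null symbol is an explicit flag rather than the value 0, so
    it can never collide with a genuine stimulus."""

    value: float | None
    null: bool

    @classmethod
    def transmit(cls, x: float) -> "Response":
        return cls(value=float(x), null=False)

    @classmethod
    def null_symbol(cls) -> "Response":
        return cls(value=None, null=True)


@dataclass
class GatingState:
    """Rolling buffer of recent stimuli plus the gating parameters."""

    window: int = DEFAULT_WINDOW
    threshold_fraction: float = 0.5
    stimuli: deque = field(default_factory=deque)
    steps_seen: int = 0

    def __post_init__(self) -> None:
        if self.window < 1:
            raise ValueError("window must be >= 1")
        if self.threshold_fraction < 0:
            raise ValueError("threshold_fraction must be nonnegative")
        self.stimuli = deque(self.stimuli, maxlen=self.window)

    def observe(self, x: float) -> None:
        self.stimuli.append(float(x))
        self.steps_seen += 1

    @property
    def warming_up(self) -> bool:
        """True during the first `window` steps, when the buffer is still
        filling and stimuli are transmitted unconditionally."""
        return self.steps_seen <= self.window


def analytic_misalignment(mu_true: float, sigma_true: float,
                          mu_hat: float, sigma_hat: float) -> float:
    """Expected misalignment between true and predicted Gaussian stimulus laws.

    Cross-entropy minus predicted entropy, written as
    H(true) + KL(true || predicted) - H(predicted); zero when the prediction
    matches the environment.
    """
    if sigma_true <= 0 or sigma_hat <= 0:
        raise ValueError("standard deviations must be positive")
    h_true = 0.5 * np.log(2.0 * np.pi * np.e * sigma_true ** 2)
    h_hat = 0.5 * np.log(2.0 * np.pi * np.e * sigma_hat ** 2)
    kl = (np.log(sigma_hat / sigma_true)
          + (sigma_true ** 2 + (mu_true - mu_hat) ** 2) / (2.0 * sigma_hat ** 2)
          - 0.5)
    return float(h_true + kl - h_hat)


def max_analytic_misalignment(config: EnvironmentConfig) -> float:
    """Largest |misalignment| over ordered (true, predicted) state pairs.

    This is the reference scale for the gating threshold: thresholds are
    specified as fractions of this value.
    """
    best = 0.0
    for true in config.states:
        for est in config.states:
            if true == est:
                continue
            mu_t, sd_t = state_params(true, config)
            mu_e, sd_e = state_params(est, config)
            best = max(best, abs(analytic_misalignment(mu_t, sd_t, mu_e, sd_e)))
    return best


def _surprise(x: np.ndarray, mu_hat: float, sigma_hat: float) -> np.ndarray:
    z = (x - mu_hat) / sigma_hat
    return 0.5 * z * z + np.log(sigma_hat) + 0.5 * np.log(2.0 * np.pi)


def running_misalignment(state: GatingState, mu_hat: float, sigma_hat: float) -> float:
    """Sample estimate of the misalignment from the stimulus buffer.

    All buffered stimuli are scored against the observer's *current*
    prediction; the mean surprise minus the predicted entropy estimates the
    analytic misalignment.  An empty buffer carries no evidence and returns 0.
    """
    if len(state.stimuli) == 0:
        return 0.0
    x = np.asarray(state.stimuli, dtype=float)
    mean_surprise = float(np.mean(_surprise(x, mu_hat, sigma_hat)))
    h_hat = 0.5 * np.log(2.0 * np.pi * np.e * sigma_hat ** 2)
    return mean_surprise - float(h_hat)


def select_encode(x: float, state: GatingState, max_analytic_M: float,
                  mu_hat: float, sigma_hat: float) -> tuple[Response, float]:
    """Gate one stimulus: buffer it, evaluate |M|, and transmit it verbatim
    if the threshold is exceeded (always during buffer warm-up).

    Returns the response together with the misalignment value used.
    """
    if max_analytic_M <= 0:
        raise ValueError("max_analytic_M must be positive")
    state.observe(x)
    m = running_misalignment(state, mu_hat, sigma_hat)
    if state.warming_up or abs(m) > state.threshold_fraction * max_analytic_M:
        return Response.transmit(x), m
    return Response.null_symbol(), m


def null_observer_update(p_prev: float, config: EnvironmentConfig,
                         n_samples: int = 200,
                         rng: np.random.Generator | None = None) -> float:
    """Observer update on receiving the null symbol: marginalize over the
    predicted stimulus law conditioned on the current estimate."""
    est = point_estimate(p_prev, config)
    mu_hat, sigma_hat = predicted_params(est, config)
    decode = DecodingDistribution(kind="prior_marginal", location=mu_hat,
                                  scale=sigma_hat)
    return marginal_update(p_prev, decode, config, n_samples=n_samples, rng=rng)
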