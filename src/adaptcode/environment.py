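"""Two-state switching Gaussian environment.

A latent state ``theta_t`` switches between two values ``theta_low`` and
``theta_high`` with a fixed per-step hazard rate ``h``.  The state sets either
the mean ("mean-switching") or the standard deviation ("variance-switching")
of a Gaussian stimulus distribution from which one sample is drawn per step.

A deterministic "probe" environment — blocks of exactly ``1/h`` steps in each
state — is used for all trial-averaged results.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "EnvironmentConfig",
    "StateSequence",
    "step_state",
    "probe_sequence",
    "sample_stimulus",
    "state_params",
]


@dataclass(frozen=True)
class EnvironmentConfig:
    """Parameters of the two-state switching environment.

    Parameters
    ----------
    mode
        ``"mean"`` — the state is the mean of the stimulus distribution,
        with fixed standard deviation ``fixed_sigma``.
        ``"variance"`` — the state is the standard deviation, with fixed
        mean ``fixed_mu``.
    theta_low, theta_high
        The two values the state can take.  Must differ; in variance mode
        both must be positive (they are standard deviations).
    hazard
        Per-timestep probability of a state switch.
    """

    mode: str = "mean"
    theta_low: float = -1.0
    theta_high: float = 1.0
    hazard: float = 0.01
    fixed_sigma: float = 1.0
    fixed_mu: float = 0.0

    def __post_init__(self) -> None:
        if self.mode not in ("mean", "variance"):
            raise ValueError(f"mode must be 'mean' or 'variance', got {self.mode!r}")
        if not 0.0 <= self.hazard <= 1.0:
            raise ValueError(f"hazard must lie in [0, 1], got {self.hazard}")
        if self.theta_low == self.theta_high:
            raise ValueError("theta_low and theta_high must differ")
        if self.mode == "variance" and (self.theta_low <= 0 or self.theta_high <= 0):
            raise ValueError("variance mode requires positive states (standard deviations)")
        if self.mode == "mean" and self.fixed_sigma <= 0:
            raise ValueError("fixed_sigma must be positive")

    @property
    def states(self) -> tuple[float, float]:
        return (self.theta_low, self.theta_high)


def variance_default() -> EnvironmentConfig:
    """Variance-switching environment with the standard parameters
    (sigma switching between 1 and 2, mean fixed at 0, h = 0.01)."""
    return EnvironmentConfig(mode="variance", theta_low=1.0, theta_high=2.0,
                             hazard=0.01, fixed_mu=0.0)


@dataclass(frozen=True)
class StateSequence:
    """A realized sequence of environmental states."""

    states: np.ndarray
    is_probe: bool = False

    def __len__(self) -> int:
        return len(self.states)


def state_params(theta: float, config: EnvironmentConfig) -> tuple[float, float]:
    """(mean, sd) of the stimulus distribution when the state is ``theta``."""
    if config.mode == "mean":
        return float(theta), config.fixed_sigma
    return config.fixed_mu, float(theta)


def step_state(theta_prev: float, config: EnvironmentConfig,
               rng: np.random.Generator) -> float:
    """Advance the latent state one step: stay with probability ``1 - h``,
    otherwise jump to the other state."""
    lo, hi = config.states
    if theta_prev != lo and theta_prev != hi:
        raise ValueError(f"theta_prev={theta_prev} is not a valid state of {config.states}")
    if rng.random() < config.hazard:
        return lo + hi - theta_prev
    return theta_prev


def probe_sequence(config: EnvironmentConfig, n_cycles: int) -> StateSequence:
    """Deterministic probe: ``n_cycles`` cycles, each 1/h steps in the low
    state followed by 1/h steps in the high state.

    Requires an integer 1/h so cycles tile exactly for trial averaging.
    """
    if n_cycles < 0:
        raise ValueError("n_cycles must be nonnegative")
    if config.hazard <= 0:
        raise ValueError("probe sequence requires hazard > 0")
    period = 1.0 / config.hazard
    block = round(period)
    if abs(period - block) > 1e-9:
        raise ValueError(f"1/h = {period} is not an integer; probe blocks would not align")
    cycle = np.concatenate([
        np.full(block, config.theta_low),
        np.full(block, config.theta_high),
    ])
    return StateSequence(states=np.tile(cycle, n_cycles), is_probe=True)


def sample_stimulus(theta, config: EnvironmentConfig, rng: np.random.Generator):
    """Draw one stimulus per state value: x ~ N(theta, sigma^2) in mean mode,
    x ~ N(mu, theta^2) in variance mode.  Vectorized over ``theta``."""
    theta = np.asarray(theta, dtype=float)
    if config.mode == "mean":
        out = np.asarray(rng.normal(theta, config.fixed_sigma))
    else:
        out = np.asarray(rng.normal(config.fixed_mu, theta))
    return out if out.ndim else float(out)
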