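"""Closed-loop simulation and the diagnostic battery.

``run_experiment`` drives the full encode → decode → update → feed-back loop
in the deterministic probe environment and returns a time-indexed trace,
alongside a parallel ideal observer that sees the raw stimuli.  The per-step
*inference error* is the squared difference between the coded and ideal
state estimates; *reconstruction error* is the squared stimulus error.

On top of the trace:

* ``speed_accuracy`` — stabilization time and adapted accuracy of the
  posterior around upward/downward switches;
* ``spike_raster`` — entropy-coded two-bit spike patterns for a four-level
  quantizer, and the cycle-averaged spike rate;
* ``metamer_probability`` — probability that two stimuli land on the same
  response level, as a function of prediction/environment alignment;
* ``noisy_transmission`` — the discretization loop with additive Gaussian
  transmission noise on the response.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .environment import EnvironmentConfig, probe_sequence, sample_stimulus
from .gating import (GatingState, max_analytic_misalignment, null_observer_update,
                     select_encode)
from .observer import (estimate_to_p_low, hazard_propagate, likelihood_update,
                       marginal_update, point_estimate, predicted_params,
                       uncertainty)
from .quantizer import QuantizerBank, cell_probabilities, entropy_rate
from .temporal_filter import FilterPolicy, decode_filter, filter_response

__all__ = [
    "SimulationTrace",
    "run_experiment",
    "speed_accuracy",
    "spike_raster",
    "metamer_probability",
    "noisy_transmission",
]

# two-bit spike patterns in order of increasing spike count; entropy coding
# assigns them to response levels by decreasing usage probability
SPIKE_PATTERNS = ((0, 0), (1, 0), (0, 1), (1, 1))
SPIKE_COUNTS = np.array([0, 1, 1, 2])


@dataclass
class SimulationTrace:
    """Per-timestep record of a probe-environment run."""

    df: pd.DataFrame
    config: EnvironmentConfig
    n_cycles: int
    period: int
    encoder: str

    def cycle_average(self) -> pd.DataFrame:
        """Average every column across cycles at fixed phase within the cycle."""
        phase = self.df.index.to_numpy() % self.period
        return self.df.groupby(phase).mean(numeric_only=True)

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index_label="t")


def _update_ideal(p: float, x: float, config: EnvironmentConfig) -> float:
    return float(likelihood_update(hazard_propagate(p, config.hazard), x, config))


def run_experiment(
    config: EnvironmentConfig,
    encoder=None,
    n_cycles: int = 500,
    rng: np.random.Generator | None = None,
    *,
    mc_samples: int = 200,
    noise_variance: float = 0.0,
    p_init: float = 0.5,
) -> SimulationTrace:
    """Simulate the full coding/inference loop in the probe environment.

    ``encoder`` selects the scheme: ``None`` or ``"identity"`` (raw stimuli),
    a :class:`QuantizerBank`, a :class:`FilterPolicy`, or a
    :class:`GatingState` (used as a parameter template; the run gets a fresh
    buffer).  ``noise_variance`` adds Gaussian transmission noise to the
    response of the discretization encoder.
    """
    if rng is None:
        rng = np.random.default_rng()
    if noise_variance < 0:
        raise ValueError("noise_variance must be nonnegative")
    states = probe_sequence(config, n_cycles).states
    n = len(states)
    period = 2 * round(1.0 / config.hazard)

    if encoder is None or (isinstance(encoder, str) and encoder == "identity"):
        kind = "identity"
    elif isinstance(encoder, QuantizerBank):
        kind = "discretize"
    elif isinstance(encoder, FilterPolicy):
        kind = "filter"
    elif isinstance(encoder, GatingState):
        kind = "select"
        gstate = replace(encoder, stimuli=(), steps_seen=0)
        max_m = max_analytic_misalignment(config)
    else:
        raise TypeError(f"unrecognized encoder {encoder!r}")
    if noise_variance > 0 and kind != "discretize":
        raise ValueError("transmission noise is defined for the discretization encoder")

    noise_sd = float(np.sqrt(noise_variance))
    p_y = float(p_init)   # coded observer
    p_x = float(p_init)   # ideal observer on raw stimuli
    x_prev = None

    cols = {name: np.full(n, np.nan) for name in (
        "theta", "x", "y", "null", "level", "bin", "misalignment",
        "p_low", "estimate", "prediction", "uncertainty",
        "p_low_ideal", "estimate_ideal",
        "inference_error", "reconstruction_error", "entropy_rate", "spikes")}

    for t in range(n):
        theta = float(states[t])
        x = float(sample_stimulus(theta, config, rng))
        est_prev = point_estimate(p_y, config)
        mu_hat, sigma_hat = predicted_params(est_prev, config)
        is_null = False

        if kind == "identity":
            y = x
            p_y = _update_ideal(p_y, x, config)
        elif kind == "discretize":
            b = encoder.bin_index(p_y)
            u = abs(x - config.fixed_mu) if config.mode == "variance" else x
            inner = encoder.boundaries[b, 1:-1]
            level = int(np.searchsorted(inner, u, side="left"))
            y = float(encoder.levels[b, level])
            if noise_sd > 0:
                y += rng.normal(0.0, noise_sd)
                if config.mode == "variance":
                    y = abs(y)
            p_y = _update_ideal(p_y, y, config)
            cols["level"][t] = level
            cols["bin"][t] = b
            cols["entropy_rate"][t] = entropy_rate(
                encoder.levels[b], encoder.boundaries[b], theta, config)
        elif kind == "filter":
            if x_prev is None:
                x_prev = x
            alpha = encoder.alpha_for(p_y)
            y = float(filter_response(x, x_prev, alpha))
            decode = decode_filter(y, alpha, mu_hat, sigma_hat)
            p_y = marginal_update(p_y, decode, config,
                                  n_samples=mc_samples, rng=rng)
            x_prev = x
        else:  # gating
            resp, m = select_encode(x, gstate, max_m, mu_hat, sigma_hat)
            cols["misalignment"][t] = m
            if resp.null:
                is_null = True
                y = 0.0  # null symbol carries no stimulus value
                p_y = null_observer_update(p_y, config,
                                           n_samples=mc_samples, rng=rng)
            else:
                y = resp.value
                p_y = _update_ideal(p_y, y, config)

        p_x = _update_ideal(p_x, x, config)
        est_y = point_estimate(p_y, config)
        est_x = point_estimate(p_x, config)

        cols["theta"][t] = theta
        cols["x"][t] = x
        cols["y"][t] = np.nan if is_null else y
        cols["null"][t] = float(is_null)
        cols["p_low"][t] = p_y
        cols["estimate"][t] = est_y
        cols["prediction"][t] = point_estimate(
            hazard_propagate(p_y, config.hazard), config)
        cols["uncertainty"][t] = uncertainty(p_y)
        cols["p_low_ideal"][t] = p_x
        cols["estimate_ideal"][t] = est_x
        cols["inference_error"][t] = (est_x - est_y) ** 2
        cols["reconstruction_error"][t] = (x - y) ** 2

    df = pd.DataFrame(cols)
    return SimulationTrace(df=df, config=config, n_cycles=n_cycles,
                           period=period, encoder=kind)


def speed_accuracy(avg_p_low: np.ndarray, *, window: int = 10,
                   band: float = 0.05) -> dict[str, float]:
    """Speed and accuracy of inference from a cycle-averaged posterior trace.

    The trace covers one probe cycle: the low-state phase followed by the
    high-state phase.  Accuracy is the time-averaged posterior mass on the
    true state over the final ``window`` steps of each phase.  Speed is the
    reciprocal of the number of steps after a switch until the averaged
    posterior first comes within ``band`` of its adapted (final-window)
    value; if it never does, speed is 1/(phase length).
    """
    p = np.asarray(avg_p_low, dtype=float)
    half = len(p) // 2
    low, high = p[:half], p[half:]
    final_low = float(np.mean(low[-window:]))
    final_high = float(np.mean(high[-window:]))

    def _speed(phase: np.ndarray, target: float) -> float:
        inside = np.abs(phase - target) <= band
        if not inside.any():
            return 1.0 / len(phase)
        return 1.0 / (int(np.argmax(inside)) + 1)

    return {
        "accuracy_low": final_low,
        "accuracy_high": 1.0 - final_high,
        "speed_down": _speed(low, final_low),    # switch into the low state
        "speed_up": _speed(high, final_high),    # switch into the high state
    }


def spike_raster(bank: QuantizerBank, trace: SimulationTrace,
                 rng: np.random.Generator | None = None):
    """Entropy-coded spike trains for a four-level discretization run.

    Each timestep's four levels are ranked by their usage probability under
    the true stimulus distribution; the fewest-spike pattern goes to the
    most probable level.  Returns (patterns, spike_counts, rate) where
    ``rate`` is the cycle-averaged spike count per timestep.
    """
    if bank.n_levels != 4:
        raise ValueError("spike rasters are defined for a 4-level encoder")
    df = trace.df
    if df["level"].isna().any():
        raise ValueError("trace does not come from a discretization run")
    n = len(df)
    counts = np.empty(n)
    patterns = []
    levels = df["level"].to_numpy().astype(int)
    bins = df["bin"].to_numpy().astype(int)
    thetas = df["theta"].to_numpy()
    for t in range(n):
        probs = cell_probabilities(bank.boundaries[bins[t]], thetas[t], bank.config)
        order = np.argsort(-probs, kind="stable")  # most probable first
        pattern_of_level = np.empty(4, dtype=int)
        pattern_of_level[order] = np.arange(4)
        k = pattern_of_level[levels[t]]
        counts[t] = SPIKE_COUNTS[k]
        patterns.append(SPIKE_PATTERNS[k])
    phase = np.arange(n) % trace.period
    rate = pd.Series(counts).groupby(phase).mean().to_numpy()
    return patterns, counts, rate


def metamer_probability(
    config: EnvironmentConfig,
    bank: QuantizerBank,
    rng: np.random.Generator,
    *,
    n_pairs: int = 100_000,
    n_grid: int = 100,
) -> tuple[np.ndarray, np.ndarray]:
    """Probability that two stimuli are coded to the same level (a metamer).

    The environment sits in the low state; the observer's estimate sweeps a
    grid between the two states.  Returns (theta_hat_grid, probability).
    """
    if config.mode != "mean":
        raise ValueError("metamer analysis is defined for the mean-switching environment")
    grid = np.linspace(config.theta_low, config.theta_high, n_grid)
    probs = np.empty(n_grid)
    for i, theta_hat in enumerate(grid):
        b = bank.bin_index(estimate_to_p_low(theta_hat, config))
        inner = bank.boundaries[b, 1:-1]
        x1 = rng.normal(config.theta_low, config.fixed_sigma, size=n_pairs)
        x2 = rng.normal(config.theta_low, config.fixed_sigma, size=n_pairs)
        i1 = np.searchsorted(inner, x1, side="left")
        i2 = np.searchsorted(inner, x2, side="left")
        probs[i] = np.mean(i1 == i2)
    return grid, probs


def noisy_transmission(
    config: EnvironmentConfig,
    bank: QuantizerBank,
    noise_variance: float,
    n_cycles: int,
    rng: np.random.Generator,
    *,
    mc_samples: int = 200,
) -> SimulationTrace:
    """Discretization run with Gaussian noise of variance ``noise_variance``
    added to the transmitted response."""
    return run_experiment(config, bank, n_cycles, rng,
                          mc_samples=mc_samples, noise_variance=noise_variance)
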