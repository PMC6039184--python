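"""Discretization encoder: belief-conditional Lloyd-Max quantization.

For each of 100 discretized belief values the stimulus axis is partitioned
into ``N`` cells, each represented by one response level.  Levels are fit by
Lloyd's algorithm on 50,000 samples from the predicted stimulus distribution,
under one of two distortions:

* reconstruction — squared stimulus error ``(x - y)^2``;
* inference — squared error between the one-step ideal-observer state
  estimates produced by the raw stimulus and by the representative level,
  ``(theta_hat(x) - theta_hat(y))^2``.

In the variance-switching environment levels are defined on the absolute
deviation from the (fixed, zero) mean, ``|x|``.

Both distortions are squared differences of a monotone transform of the
stimulus (the identity, or the one-step posterior-mean estimate), which keeps
the Lloyd assignment step a sorted 1-D search.  The update step replaces each
level by the mean of the stimuli assigned to it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy.special import ndtr

from .environment import EnvironmentConfig
from .observer import one_step_estimate, point_estimate, predicted_params

__all__ = [
    "QuantizerBank",
    "lloyd_fit",
    "build_bank",
    "encode_discrete",
    "entropy_rate",
    "cell_probabilities",
]

DEFAULT_TRAIN_SIZE = 50_000
DEFAULT_MAX_ITER = 200
DEFAULT_N_BINS = 100


def lloyd_fit(
    training: np.ndarray,
    n_levels: int,
    distortion: Callable | None = None,
    rng: np.random.Generator | None = None,
    *,
    transform: Callable | None = None,
    max_iter: int = DEFAULT_MAX_ITER,
    return_history: bool = False,
):
    """Fit a scalar quantizer by Lloyd's algorithm.

    Alternates (i) assignment of every training point to the level with the
    smallest distortion and (ii) replacement of every level by the mean of
    its assigned points, until assignments stabilize or ``max_iter`` passes.
    An emptied level is reseeded at a random training point.

    Parameters
    ----------
    training
        Stimulus samples (>= ``n_levels`` of them).
    distortion
        Vectorized ``d(x, y) -> nonnegative`` (broadcasting).  Ignored when
        ``transform`` is given.
    transform
        Monotone map ``f`` such that the distortion is ``(f(x) - f(y))^2``;
        enables the fast sorted assignment.  Defaults to the identity
        (squared reconstruction error) when ``distortion`` is also None.

    Returns
    -------
    (levels, boundaries) — sorted level values and the N-1 interior decision
    boundaries (midpoints between the extreme assigned points of adjacent
    cells).  With ``return_history=True`` a third element gives the mean
    distortion after each iteration.
    """
    x = np.sort(np.asarray(training, dtype=float))
    if len(x) < n_levels:
        raise ValueError(f"need at least {n_levels} training points, got {len(x)}")
    if rng is None:
        rng = np.random.default_rng()
    if transform is None and distortion is None:
        transform = lambda v: v  # noqa: E731 - reconstruction default

    levels = np.sort(rng.choice(x, size=n_levels, replace=False))
    assign = np.full(len(x), -1)
    history: list[float] = []
    fx = transform(x) if transform is not None else None

    for _ in range(max_iter):
        if transform is not None:
            fl = transform(levels)
            order = np.argsort(fl)
            levels = levels[order]
            fl = fl[order]
            mids = 0.5 * (fl[:-1] + fl[1:])
            new_assign = np.searchsorted(mids, fx, side="left")
            d_per_point = (fx - fl[new_assign]) ** 2
        else:
            d_mat = distortion(x[:, None], levels[None, :])
            new_assign = np.argmin(d_mat, axis=1)  # ties -> lower index
            d_per_point = d_mat[np.arange(len(x)), new_assign]
        history.append(float(np.mean(d_per_point)))
        converged = np.array_equal(new_assign, assign)
        assign = new_assign
        if converged:
            break
        for i in range(n_levels):
            members = x[assign == i]
            if len(members) == 0:
                levels[i] = rng.choice(x)
            else:
                levels[i] = members.mean()
        levels = np.sort(levels)

    # empirical decision boundaries between adjacent occupied cells
    boundaries = np.empty(n_levels - 1)
    for i in range(n_levels - 1):
        left = x[assign == i]
        right = x[assign == i + 1]
        hi = left.max() if len(left) else levels[i]
        lo = right.min() if len(right) else levels[i + 1]
        boundaries[i] = 0.5 * (hi + lo)
    if return_history:
        return levels, boundaries, np.asarray(history)
    return levels, boundaries


@dataclass
class QuantizerBank:
    """Per-belief-bin response levels and cell edges.

    ``levels[b]`` are the N sorted representative values for belief bin ``b``
    and ``boundaries[b]`` the N+1 cell edges (outermost edges are -inf/+inf
    in mean mode, 0/+inf in variance mode, where the axis is ``|x|``).
    """

    config: EnvironmentConfig
    goal: str
    n_levels: int
    belief_grid: np.ndarray
    levels: np.ndarray       # (n_bins, N)
    boundaries: np.ndarray   # (n_bins, N + 1)
    histories: list = field(default_factory=list, repr=False)

    def bin_index(self, p_low: float) -> int:
        """Nearest belief bin for a posterior value."""
        return int(np.argmin(np.abs(self.belief_grid - p_low)))

    def to_frame(self) -> pd.DataFrame:
        """Flat table (bin, level index, level value, lower edge, upper edge)."""
        rows = []
        for b in range(len(self.belief_grid)):
            for i in range(self.n_levels):
                rows.append({
                    "bin": b,
                    "p_low": self.belief_grid[b],
                    "level": i,
                    "value": self.levels[b, i],
                    "lower": self.boundaries[b, i],
                    "upper": self.boundaries[b, i + 1],
                })
        return pd.DataFrame(rows)


def _bin_transform(p_low: float, goal: str, config: EnvironmentConfig):
    """Monotone transform whose squared difference is the distortion for one bin."""
    if goal == "reconstruction":
        return lambda v: v
    # inference: one ideal-observer step (hazard + likelihood) from this bin's belief
    return lambda v: one_step_estimate(p_low, v, config)


def build_bank(
    config: EnvironmentConfig,
    goal: str,
    n_levels: int,
    rng: np.random.Generator,
    *,
    n_train: int = DEFAULT_TRAIN_SIZE,
    n_bins: int = DEFAULT_N_BINS,
    max_iter: int = DEFAULT_MAX_ITER,
    keep_histories: bool = False,
) -> QuantizerBank:
    """Fit levels for every belief bin against its predicted stimulus law.

    For belief bin ``p`` the predicted stimulus distribution is the Gaussian
    conditioned on the point estimate ``theta_hat(p)``.  Training samples are
    drawn from it (their absolute values in variance mode) and quantized
    under the bin's distortion.
    """
    if goal not in ("inference", "reconstruction"):
        raise ValueError(f"goal must be 'inference' or 'reconstruction', got {goal!r}")
    grid = np.linspace(0.0, 1.0, n_bins)
    all_levels = np.empty((n_bins, n_levels))
    all_bounds = np.empty((n_bins, n_levels + 1))
    histories = []
    lo_edge = 0.0 if config.mode == "variance" else -np.inf
    for b, p in enumerate(grid):
        est = point_estimate(p, config)
        mu, sd = predicted_params(est, config)
        x = rng.normal(mu, sd, size=n_train)
        if config.mode == "variance":
            x = np.abs(x)
        levels, inner, hist = lloyd_fit(
            x, n_levels, rng=rng,
            transform=_bin_transform(p, goal, config),
            max_iter=max_iter, return_history=True,
        )
        all_levels[b] = levels
        all_bounds[b] = np.concatenate([[lo_edge], inner, [np.inf]])
        if keep_histories:
            histories.append(hist)
    return QuantizerBank(config=config, goal=goal, n_levels=n_levels,
                         belief_grid=grid, levels=all_levels,
                         boundaries=all_bounds, histories=histories)


def encode_discrete(x: float, bank: QuantizerBank, belief: float) -> int:
    """Map a stimulus to a level index using the nearest belief bin's cells.

    A stimulus exactly on a cell boundary goes to the lower-index level.  In
    variance mode the stimulus enters as its absolute deviation from the mean.
    """
    b = bank.bin_index(belief)
    u = abs(x - bank.config.fixed_mu) if bank.config.mode == "variance" else x
    inner = bank.boundaries[b, 1:-1]
    return int(np.searchsorted(inner, u, side="left"))


def cell_probabilities(boundaries: np.ndarray, true_theta: float,
                       config: EnvironmentConfig) -> np.ndarray:
    """Probability of each quantizer cell under the true stimulus law.

    Gaussian CDF differences; in variance mode the cells partition ``|x|``
    and the folded (half-normal) CDF is used.
    """
    b = np.asarray(boundaries, dtype=float)
    if config.mode == "mean":
        cdf = ndtr((b - true_theta) / config.fixed_sigma)
    else:
        # |x - mu| with x ~ N(mu, theta^2): P(|x-mu| <= u) = 2 Phi(u/theta) - 1
        cdf = np.clip(2.0 * ndtr(np.maximum(b, 0.0) / true_theta) - 1.0, 0.0, 1.0)
    p = np.diff(cdf)
    p = np.clip(p, 0.0, 1.0)
    s = p.sum()
    return p / s if s > 0 else p


def entropy_rate(levels: np.ndarray, boundaries: np.ndarray, true_theta: float,
                 config: EnvironmentConfig) -> float:
    """Shannon entropy (bits) of level usage under the true stimulus law."""
    p = cell_probabilities(boundaries, true_theta, config)
    nz = p[p > 0]
    return float(-np.sum(nz * np.log2(nz)))
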