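# Methods

## Model overview

`adaptcode` implements a closed sensory loop with three components:

1. **Environment** — a two-state telegraph process θ_t ∈ {θ_L, θ_H} with
   per-step switch probability (hazard) *h*, emitting one Gaussian stimulus
   per step. In the *mean-switching* environment θ is the mean
   (defaults θ_L = −1, θ_H = 1, σ = 1); in the *variance-switching*
   environment θ is the standard deviation (defaults θ_L = 1, θ_H = 2,
   μ = 0). Default *h* = 0.01. All averaged analyses use the deterministic
   *probe* environment: blocks of exactly 1/h steps per state, so cycles
   tile exactly and trial averaging is aligned.
2. **Encoder** — one of three capacity-limited maps from stimulus x_t to
   response y_t (discretization, two-tap temporal filter, surprise-gated
   selection), whose parameters are re-chosen each step from the observer's
   fed-back estimate.
3. **Observer** — the exact two-state Bayesian filter. The belief is the
   scalar P_t^L; updates are hazard propagation followed by a likelihood
   step, performed in log space with log-sum-exp normalization so that
   beliefs remain valid probabilities over arbitrarily long runs. When the
   response is lossy, the update is marginalized over the decoding
   distribution by Monte Carlo: draw `mc_samples` stimulus hypotheses,
   update with each, average the posteriors. The default of 200 samples sits
   comfortably above the ~50 needed for stable results in our experience.

The observer's one-step prediction differs from its estimate only through
one hazard step; at *h* = 0.01 the difference is at most h·|θ_H − θ_L|, so
the estimate θ̂_t is used as the prediction that parameterizes the encoders.
Both quantities are computed and recorded.

## Encoders and their parameters

### Discretization (`quantizer`)

For each of 100 equally spaced belief values, N response levels are fitted
by Lloyd's algorithm on 50,000 samples drawn from that belief's predicted
stimulus law. Distortions:

* reconstruction: d(x, y) = (x − y)²;
* inference: d(x, y) = (θ̂(x) − θ̂(y))², where θ̂(·) is the estimate after a
  single Bayesian step (hazard + likelihood) from the bin's belief.

Both are squared differences of a monotone transform of the stimulus (the
identity, or the one-step posterior-mean map), so the assignment step is a
sorted 1-D search; the update step replaces each level with the mean of its
assigned stimuli, and iteration stops when assignments stabilize or after
200 passes. Empty levels are reseeded at a random training point. Decision
boundaries are empirical (midpoints between the extreme assigned points of
adjacent cells); outer edges are ±∞, or [0, ∞) in the variance environment,
where levels are defined on |x − μ|. Decoding uses the delta approximation
at the level value, and the belief update for this encoder skips the
Monte-Carlo marginalization (the response is already a point value); both
shortcuts were found not to change results in this regime. The per-level
distortion trace is non-increasing by construction for the reconstruction
distortion; for the inference distortion the mean-update is not exactly the
distortion minimizer, but monotonicity holds in practice and convergence is
to a local optimum, as expected for a non-convex distortion.

Coding cost is the entropy (bits) of level usage under the *true* stimulus
law, computed from Gaussian (or folded-Gaussian) CDF differences across the
cell boundaries.

### Temporal filter (`temporal_filter`)

y_t = α x_t + (1 − α) x_{t−1}, with α on a 50-point grid over [0.5, 1]
(α = 1: verbatim transmission; α = 0.5: two-sample average). The decoder is
the closed-form Gaussian inversion of the filter under the predicted
stimulus law; at α = 1 it degenerates to a delta. The coding cost is the
analytic joint entropy H(y_t, y_{t+1}) of two consecutive responses. Per
belief bin, the optimal α minimizes the Monte-Carlo error average over
50,000 stimulus pairs plus β times the joint entropy. The error term for the
inference goal marginalizes the observer update over the Gaussian decoder
(a faster plug-in variant that conditions on the decoder mean is available
via `error_method="plugin"`); because the decoded posterior depends on the
response only through the decoder mean, the marginalized update is evaluated
on a 257-point grid of decoder means with shared noise draws and
interpolated, which makes the full optimization tractable without changing
the estimator. Ties in the objective go to the larger (higher-fidelity) α.
Entropies are in nats internally; conversion to bits happens only at
reporting. The α domain [0.5, 1] is adopted because the joint-entropy
interpretation and the "minimal fidelity = averaging" semantics assume it;
a wider grid can be requested via `alpha_range`. Default β values of
interest: {0.02, 0.1, 1} (mean environment) and {0.01, 0.1, 1} (variance).

### Stimulus selection (`gating`)

The encoder buffers the last T = 10 stimuli and computes the running
misalignment M_t: their mean surprise under the *current* prediction minus
the predicted entropy. In expectation M_t equals the analytic misalignment
H(true) + KL(true‖predicted) − H(predicted), which is zero exactly when the
prediction matches the environment. All buffered stimuli are scored against
the current prediction (not the historical estimates at their original
times). If |M_t| exceeds V × (maximum analytic |M| over ordered state
pairs), the stimulus is transmitted verbatim; otherwise an explicit null
symbol — a flag, never the numeric 0, to avoid collision with genuine
stimulus values — is sent, and the observer marginalizes over its
point-conditioned predictive law. The first T steps transmit
unconditionally so the observer can initialize.

A property worth knowing: the point-conditioned null update is
*self-confirming*. Predictive samples cluster near the current estimate and
therefore re-endorse it, outweighing the hazard leak toward 0.5. Confidence
is consequently maintained (even sharpened) through long non-transmitting
periods, which is what keeps the estimate stable between switches. The
gating scheme as a whole is a deliberate heuristic; no claim of optimality
for the thresholded channel is made.

## Stationary impact and encoding-error maps (`stationary_maps`)

One-shot Bayesian estimation of the location or scale of a generalized
Gaussian stimulus law p(x; μ, α, β_shape) ∝ exp(−(|x − μ|/α)^β). The grid
crosses 100 prior entropies in [0, 0.7] nats with 100 surprises in [1, 10]
nats. For location, the prior is a zero-mean Gaussian with variance
exp(2H)/(2πe) and the likelihood scale is √2 (unit variance at shape 2); the
posterior mean is conjugate in closed form at shape 2 and otherwise computed
on a 2001-point grid spanning ±6 prior SDs with trapezoidal normalization.
For scale, the prior is inverse-gamma with mean pinned to √2 (so the
reported quantity α²/2 has prior mean 1) and shape a₀ > 2 root-found from
the entropy formula; the surprise axis is *centered* surprise (excess over
the predicted entropy), inverted on the positive side; the posterior over α
is numeric on a grid to 6 prior SDs. Surprises below a density's attainable
minimum (e.g. 1.04 nats for the Laplace case) clamp to the mode. Impact is
the squared change of the posterior-mean estimate; at the H = 0 boundary
the prior variance is 1/(2πe) ≈ 0.059, so the boundary row is small
relative to the map but not identically zero. The encoding-error map and
error-tolerance intervals use the conjugate Gaussian-location case, where
the error is (w(x − y))² with shrinkage w = σ₀²/(σ₀² + 1).

## Diagnostics (`metrics`)

* **Speed/accuracy**: accuracy is the cycle-averaged posterior mass on the
  true state over the final 10 steps of each phase; speed is the reciprocal
  of the number of post-switch steps until the averaged posterior enters a
  0.05 band around its adapted value (floor: 1/phase-length if it never
  does). The 10-step window is configurable for hazards other than 0.01.
* **Spike rasters**: for a 4-level quantizer, each step's levels are ranked
  by usage probability under the true stimulus law and assigned the two-bit
  patterns [00], [10], [01], [11] in that order (entropy coding: fewest
  spikes to the most probable level); the rate is the cycle-averaged spike
  count per step, unsmoothed (an optional boxcar can be applied downstream).
* **Metamers**: with the environment pinned to the low state, pairs of
  stimuli are encoded with an 8-level bank while the assumed estimate sweeps
  a 100-point grid between the states; the metamer probability is the
  fraction of pairs mapped to the same level.
* **Transmission noise**: Gaussian noise of variance σ_n² is added to the
  quantizer response before the observer's (delta) update.

## Problem sizes and seeds

Published-style traces average 500–800 probe cycles; the test suite and the
acceptance script use 100–200 cycles (and 10⁴ metamer pairs per grid point),
which we found sufficient for all qualitative signatures and for the
quantitative values at the tolerances asserted. All randomness flows from
explicit `numpy.random.Generator` objects; the experiment-level seed spawns
independent substreams via `SeedSequence`, so adding a diagnostic that
consumes randomness does not perturb the main trajectory, and a manifest
(config + seed) reproduces a run bit-for-bit.

## What the synthetic environment does and does not capture

The generator realizes exactly the two-state Gaussian world the observer
assumes: binary states, constant hazard, i.i.d. Gaussian emissions, and a
deterministic probe schedule for averaging. Passing tests therefore
demonstrate the internal consistency and the predicted dynamical signatures
of the coding schemes under matched model assumptions. They do not
demonstrate robustness to model mismatch: multi-state or continuous-state
worlds, multiple timescales, non-Gaussian emissions, or encoder noise other
than the additive transmission noise studied. The fully general
continuous-state observer, longer filters, output nonlinearities, and
natural-stimulus tasks are out of scope.

## Numerical choices, tie-breaks, degenerate inputs

* Beliefs of exactly 0 or 1 are absorbing under the likelihood update (the
  log-space computation restores them explicitly); non-finite posteriors
  (e.g. from non-finite stimuli) fall back to the prior with a logged
  warning.
* Quantizer ties: a stimulus exactly on a cell boundary goes to the
  lower-index level; filter-objective ties go to the larger α.
* An empty gating buffer reports zero misalignment (no evidence).
* Probe construction requires 1/h to be an integer and raises otherwise —
  rounding would silently misalign trial averaging.
* `n_cycles = 0` yields an empty trace; N = 1 quantizers, σ → 0 stimuli,
  and h ∈ {0, 1} dynamics are all well-defined edge cases covered by tests.
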