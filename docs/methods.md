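# Methods

This document records the model underlying `crossembed`, the assumptions it
makes, the meaning of every user-facing parameter, the scope of the bundled
synthetic generators, and the numerical choices and limitations of the
implementation.

## 1. Random-coordinate cross-embedding

### Delay reconstruction and random projection

For a scalar series `x(t)`, the delay matrix with delay `tau` and maximal
dimension `d_max` has rows

```
(x(t), x(t - tau), ..., x(t - (d_max - 1) * tau))
```

for every `t` with a full history, newest coordinate first.  Takens-style
embedding theory guarantees that, for generic observables of a deterministic
system, such delay vectors of sufficient dimension are diffeomorphic to the
underlying attractor — and that this remains true after a generic linear
projection.

The package projects every delay vector through a fixed square matrix `R`
(`d_max × d_max`) with i.i.d. standard-normal entries drawn once per
analysis from a seeded generator.  A `d`-dimensional reconstruction uses the
first `d` components of the projected vectors.  Two properties matter:

- every projected coordinate mixes all `d_max` delays, so even a
  low-dimensional reconstruction spans the full observation window;
- sub-reconstructions are nested (dimension `d` is a prefix of dimension
  `d + 1`), so skill-versus-dimension profiles are monotone in information.

`R` is generated at `d_max` and never truncated or regrown: requesting a
different `d_max` is a different analysis with a different `R`.

### Cross-map forecasting

Embeddedness of channel `y` in channel `x` is measured by forecasting `y(t)`
from the `k = 4` nearest neighbours of the reconstruction of `x` at time
`t`.  Neighbour weights are `exp(-(D_i^2 - D_min^2))` normalised over the
`k` neighbours, where `D_i` are Euclidean distances in reconstruction space;
the forecast is the weight-convex combination of the neighbours' `y` values.
Distance ties break toward the lower library index.  Skill is the Pearson
correlation `rho` between forecasts and held-out true values.

Cross-validation is two-fold: reconstruction rows are split in half by time;
queries (1000 by default) are sampled from one fold and forecast from the
library fold, then the roles swap and the two `rho` values are averaged
(`folds="both"`; `folds="printed"` keeps the first fold only).

### Derived quantities

- **Embeddedness profile** `rho(d)` for `d = 1 .. d_max`.
- **Optimal embeddedness** `max_d rho(d)`.
- **Complexity** `d*`: the smallest `d` with `rho(d) >= 0.95 * max_d
  rho(d)` — the number of projected coordinates needed for skill to
  saturate.  If the whole profile is non-positive the pair is uninformative
  and `d* = 1` is returned with a warning.
- **Directionality** `dir(source -> target) = embed(source by target) -
  embed(target by source)`.  The driven channel's dynamics contain the
  driver (not vice versa), so a positive value indicates that the source
  drives the target.  The operation is exactly antisymmetric under argument
  exchange.
- **Relative embeddedness** `rho(d*) - rho(1)`: the part of the coupling
  not already captured by a one-dimensional (correlation-like)
  reconstruction.
- **Convergence profile**: optimal embeddedness as the library is truncated
  to its first `L` rows with a fixed query set.  Rising skill with `L` is
  the hallmark of deterministic coupling; independent noise stays flat.

### Assumptions

- The observed channels are generic scalar observables of (approximately)
  deterministic dynamics; stochastic series yield flat, near-zero profiles.
- Stationarity over the analysed window: the two cross-validation folds must
  sample the same attractor.
- Sampling is uniform; `tau` is expressed in samples.
- Series are variance-normalised internally before forecasting, so results
  are invariant to affine rescaling of either channel.

## 2. Synthetic validation systems

### Coupled Rössler pair

Two Rössler oscillators with slightly detuned parameters (`a = 0.2/0.22`,
`c = 5.7/5.6`), where system 2 drives system 1 through a multiplicative
coupling factor on the first equation; the uncoupled control replaces that
factor by 1, recovering the standard form.  A global timescale `T`
multiplies all derivatives.  Integration is fourth-order Runge-Kutta at step
0.01, subsampled to 0.1 time units per sample, with a transient (default
100 time units) discarded.  The analysed observables are the two first
coordinates (`xi1` downstream, `xi2` upstream).

The flag `verbatim_equations=True` selects an uncorrected variant in
which the third equation of system 2 references system-1 variables; that
form contradicts unidirectional coupling and is numerically unstable, and
exists only for audit.  The default corrects it to the self-contained form (`zeta2' = zeta2 (xi2 - 5.6) + 0.2`).

System noise (`add_system_noise`) injects zero-mean Gaussian perturbations
into every state variable after each integration step, scaled by
`sqrt(step)` so the parameter is a standard deviation per unit time.  Noise
above 0.05 per unit time destabilises the attractor and is rejected.
Observation noise (`add_observation_noise`) adds i.i.d. Gaussian noise to
the observables only.

### Three-cluster network

Fifteen nodes (configurable) in three clusters — frontoparietal (FP),
visual (V), subcortical (SC) — iterate

```
x_i(t) = f( max(0, sum_j J_ij x_j(t-1)) ) + b_i(t)
```

with the Ricker-type activation `f(u) = u * exp(3 (1 - u))`.  The
rectification `max(0, .)` is this package's own stabilisation: without it
the raw map diverges almost surely at these coupling statistics,
because `f` amplifies negative inputs by `e^3` per step.  Rectification is
the minimal change that preserves the architecture and produces stable
fluctuating dynamics.

Connectivity: `J_ii = 1`; within-cluster off-diagonal entries are
`N(0, (0.1/N)^2)` with `N` the total node count; between-cluster entries
are zero in the baseline.  Model variants add blocks drawn
`N(0, (0.5/N)^2)`: model 1 adds V -> FP coupling, model 2 adds SC -> FP
coupling, and model 3 instead doubles the within-FP off-diagonal entries.
By construction, the added between-cluster entries are *stronger* per entry
than within-cluster ones.  The bias `b_i(t) = A_i sin(2 pi t / 20 + phi_i)`
has per-node amplitude `U(0, 0.1)` and phase `U(0, 2 pi)` drawn from a
dedicated `bias_seed` so one bias realisation can be shared across models.
Runs start from `x_i(0) ~ U(0.5, 1.5)`, discard a 100-step burn-in, and
retry with an advanced seed if the state diverges.

## 3. Comparison measures

- **Standard embedding dimension**: the identical cross-embedding pipeline
  with the random projection disabled (plain delay coordinates).  With unit
  delay on smooth or oversampled signals it systematically overestimates,
  which is the motivating failure mode.
- **Correlation dimension** (Grassberger–Procaccia): slope of
  `log C(r)` vs `log r`.  The scaling region defaults to the 1st–10th
  percentile of pairwise inter-point distances; the mid-range saturates
  `C(r)` and biases the slope down (circle: 1.22 instead of 1.00), which is
  why a small-scale region is used.
- **PCA dimension**: number of leading principal components of the delay
  cloud explaining 90% of variance.
- **Permutation entropy** (order 3 by default), natural-log units; ties
  rank by position.
- **Lempel–Ziv complexity**: exhaustive-production phrase count of the
  median-binarised series, normalised by `n / log2(n)` so i.i.d. coin flips
  score ~1.

## 4. Numerical choices

- Squared distances in the forecaster are accumulated coordinate by
  coordinate and neighbour sums run left to right, making every operation
  reproducible bit for bit by a scalar reference implementation (used as a
  test oracle).
- The incremental profile evaluator reuses distance accumulations across
  nested dimensions, so a full `rho(d)` profile costs the same as a single
  forecast at `d_max`.
- All randomness (projection, query sampling, simulators, biases) flows
  through seeded `numpy` generators; every public operation is a pure
  function of its arguments and seeds.
- Rössler validation analyses use 16000-sample series (order 10^4), delay
  `tau = 4` samples, `d_max = 20`; network analyses use `tau = 1` and
  `d_max = 30`.  Shorter series leave the spurious reverse-direction skill
  unconverged and make downstream complexity estimates erratic.
- Integrators and the forecasting kernel are `numba`-compiled.

## 5. Limitations

- Cross-map skill between *independent but near-resonant* oscillators is
  spuriously non-zero at single-realisation level; only its polarity
  averages out.  Directionality values for individual pairs should be
  interpreted against surrogate or ensemble baselines.
- Strong synchrony defeats directionality inference: if two channels are
  effectively diffeomorphic copies, both cross-maps succeed equally.
- Complexity `d*` is a relative saturation index, not an attractor
  dimension; it is bounded by `d_max` and depends on the 0.95 threshold
  convention.
- The network generator is a minimal architectural model, not a biophysical
  one, and its stabilising rectification is a modelling choice made for
  stability; results can depend on it.
- Statistical significance of pairwise links (`significant_only`) uses a
  t-test of the forecast correlation, which assumes approximately
  independent queries; autocorrelated data make it optimistic.
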