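"""Synthetic validation systems for the cross-embedding analysis.

Two generators are provided:

* :func:`simulate_coupled_rossler` -- a pair of Roessler oscillators with a
  unidirectional multiplicative coupling from the upstream system ``y`` to
  the downstream system ``x``.  The observables are the first coordinates
  ``(xi_1, xi_2)``.  Because the drive is one-way, ``x``'s history carries
  information about ``y`` while ``y`` evolves autonomously; the downstream
  state space is six-dimensional, which upper-bounds any correct complexity
  estimate of the downstream attractor.

* :func:`simulate_cluster_network` -- a three-cluster (frontoparietal,
  visual, subcortical) linear-nonlinear map network used to discriminate
  mechanisms that raise downstream complexity: enhanced bottom-up coupling
  (model 1), subcortical input (model 2), or doubled intra-cluster
  connectivity (model 3) on top of an uncoupled-cluster baseline.

Both are pure functions of their parameters and seeds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from numba import njit

logger = logging.getLogger(__name__)


class DivergenceError(RuntimeError):
    """A simulated trajectory left the admissible state region."""


class InstabilityError(ValueError):
    """Requested parameters lie outside the documented stability domain."""


@dataclass
class Trajectory:
    """Simulator output: full state plus the scalar observables analysed."""

    states: np.ndarray        # (time, n_state)
    observables: np.ndarray   # (time, n_obs)
    time_step: float
    observable_labels: list[str]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.states)):
            raise ValueError("trajectory states contain non-finite values")


# ---------------------------------------------------------------------------
# coupled Roessler oscillators
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RosslerParams:
    """Parameters of the unidirectionally coupled Roessler pair.

    The integrated equations (state ``(xi1, eta1, zeta1, xi2, eta2, zeta2)``,
    all time derivatives scaled by the timescale ``T``):

        T xi1'   = -(eta1 + zeta1) * (xi2 + 11)/2     [coupling y -> x]
        T eta1'  = xi1 + a1 * eta1
        T zeta1' = zeta1 * (xi1 - c1) + b
        T xi2'   = -(eta2 + zeta2)
        T eta2'  = xi2 + a2 * eta2
        T zeta2' = zeta2 * (xi2 - c2) + b

    ``uncoupled`` mode replaces the coupling factor ``(xi2 + 11)/2`` by 1,
    recovering an autonomous standard Roessler for system 1.  With
    ``verbatim_equations`` the zeta2 equation instead reads
    ``zeta1 * (xi1 - c2) + b``, an (apparently erroneous) variant that makes
    system 2 depend on system 1; it is retained for auditability only.
    """

    T: float = 1.0
    a1: float = 0.2
    a2: float = 0.22
    c1: float = 5.7
    c2: float = 5.6
    b: float = 0.2
    coupled: bool = True
    integration_step: float = 0.01
    subsample_step: float = 0.1
    duration: float = 1700.0
    transient: float = 100.0
    seed: int = 0
    initial_state: tuple | None = None
    verbatim_equations: bool = False

    def __post_init__(self) -> None:
        if self.integration_step >= self.subsample_step:
            raise ValueError("integration_step must be < subsample_step")
        ratio = self.subsample_step / self.integration_step
        if abs(ratio - round(ratio)) > 1e-9:
            raise ValueError(
                "subsample_step must be an integer multiple of integration_step"
            )
        if self.transient < 0:
            raise ValueError("transient must be >= 0")
        if self.duration <= self.transient:
            raise ValueError("duration must exceed transient")


@njit(cache=True)
def _rossler_deriv(s, T, a1, a2, c1, c2, b, coupled, verbatim):
    d = np.empty(6)
    fac = (s[3] + 11.0) / 2.0 if coupled else 1.0
    d[0] = -(s[1] + s[2]) * fac
    d[1] = s[0] + a1 * s[1]
    d[2] = s[2] * (s[0] - c1) + b
    d[3] = -(s[4] + s[5])
    d[4] = s[3] + a2 * s[4]
    if verbatim:
        d[5] = s[2] * (s[0] - c2) + b
    else:
        d[5] = s[5] * (s[3] - c2) + b
    for j in range(6):
        d[j] /= T
    return d


@njit(cache=True)
def _rossler_integrate(
    s0, T, a1, a2, c1, c2, b, coupled, verbatim,
    h, n_steps, keep_every, first_keep, noise_step_sd, noise_seed,
):
    """Fixed-step RK4, optional additive Gaussian state noise per step.

    Returns (subsampled states, diverged-at-step or -1).
    """
    if noise_step_sd > 0.0:
        np.random.seed(noise_seed)
    s = s0.copy()
    n_keep = (n_steps - first_keep) // keep_every + 1
    out = np.empty((n_keep, 6))
    m = 0
    if first_keep == 0:
        out[0] = s
        m = 1
    for i in range(1, n_steps + 1):
        k1 = _rossler_deriv(s, T, a1, a2, c1, c2, b, coupled, verbatim)
        k2 = _rossler_deriv(s + 0.5 * h * k1, T, a1, a2, c1, c2, b, coupled, verbatim)
        k3 = _rossler_deriv(s + 0.5 * h * k2, T, a1, a2, c1, c2, b, coupled, verbatim)
        k4 = _rossler_deriv(s + h * k3, T, a1, a2, c1, c2, b, coupled, verbatim)
        s = s + (h / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
        if noise_step_sd > 0.0:
            for j in range(6):
                s[j] += noise_step_sd * np.random.randn()
        for j in range(6):
            if not np.isfinite(s[j]) or abs(s[j]) > 1e6:
                return out[:m], i
        if i >= first_keep and (i - first_keep) % keep_every == 0:
            out[m] = s
            m += 1
    return out[:m], -1


def _run_rossler(params: RosslerParams, noise_step_sd: float) -> Trajectory:
    if params.initial_state is not None:
        s0 = np.asarray(params.initial_state, dtype=float)
        if s0.shape != (6,):
            raise ValueError("initial_state must have six components")
    else:
        s0 = np.random.default_rng(params.seed).uniform(-1.0, 1.0, 6)
    h = params.integration_step
    n_steps = int(round(params.duration / h))
    keep_every = int(round(params.subsample_step / h))
    first_keep = int(round(params.transient / h))
    states, diverged = _rossler_integrate(
        s0, params.T, params.a1, params.a2, params.c1, params.c2, params.b,
        params.coupled, params.verbatim_equations,
        h, n_steps, keep_every, first_keep,
        noise_step_sd, params.seed & 0x7FFFFFFF,
    )
    if diverged >= 0:
        raise DivergenceError(
            f"trajectory diverged (|state| > 1e6) at integration step "
            f"{diverged} (t = {diverged * h:.2f})"
        )
    return Trajectory(
        states=states,
        observables=states[:, [0, 3]].copy(),
        time_step=params.subsample_step,
        observable_labels=["xi1", "xi2"],
        metadata={
            "system": "coupled_rossler",
            "params": params,
            "system_noise_sd": noise_step_sd / np.sqrt(h) if noise_step_sd else 0.0,
        },
    )


def simulate_coupled_rossler(params: RosslerParams = RosslerParams()) -> Trajectory:
    """Integrate the coupled Roessler pair with fixed-step RK4.

    The state is integrated at ``integration_step``, the trailing transient
    is discarded and the remainder subsampled at ``subsample_step``.  The
    observables are ``(xi1, xi2)`` -- downstream and upstream first
    coordinates.  Raises :class:`DivergenceError` if the state exceeds 1e6.
    """
    return _run_rossler(params, 0.0)


#: largest system-noise standard deviation (per unit time) for which the
#: coupled Roessler attractor remains stable
SYSTEM_NOISE_STABILITY_LIMIT = 0.05


def add_system_noise(params: RosslerParams, sd_per_unit_time: float) -> Trajectory:
    """Coupled Roessler trajectory with additive dynamical (system) noise.

    Zero-mean Gaussian noise is injected into every state variable after
    each RK4 step, scaled by ``sqrt(integration_step)`` so that
    ``sd_per_unit_time`` is the standard deviation accumulated per unit of
    integrated time.  Noise levels above ``SYSTEM_NOISE_STABILITY_LIMIT``
    (0.05 per unit time) destabilise the attractor dynamics and are rejected
    with :class:`InstabilityError`.
    """
    if sd_per_unit_time < 0:
        raise ValueError("sd_per_unit_time must be >= 0")
    if sd_per_unit_time > SYSTEM_NOISE_STABILITY_LIMIT:
        raise InstabilityError(
            f"system noise sd {sd_per_unit_time} per unit time exceeds the "
            f"stability limit {SYSTEM_NOISE_STABILITY_LIMIT}; the attractor "
            "dynamics become unstable"
        )
    if sd_per_unit_time == 0.0:
        return _run_rossler(params, 0.0)
    step_sd = sd_per_unit_time * np.sqrt(params.integration_step)
    return _run_rossler(params, step_sd)


def add_observation_noise(traj: Trajectory, sd: float, seed: int) -> Trajectory:
    """Add i.i.d. zero-mean Gaussian noise to the observables only.

    The underlying states are untouched; ``sd = 0`` is the identity.
    """
    if sd < 0:
        raise ValueError("sd must be >= 0")
    if sd == 0.0:
        return traj
    rng = np.random.default_rng(seed)
    noisy = traj.observables + rng.normal(0.0, sd, traj.observables.shape)
    meta = dict(traj.metadata)
    meta["observation_noise_sd"] = sd
    meta["observation_noise_seed"] = seed
    return Trajectory(
        states=traj.states,
        observables=noisy,
        time_step=traj.time_step,
        observable_labels=list(traj.observable_labels),
        metadata=meta,
    )


# ---------------------------------------------------------------------------
# three-cluster linear-nonlinear network
# ---------------------------------------------------------------------------

NETWORK_MODELS = ("baseline", "model1", "model2", "model3")
CLUSTER_NAMES = ("frontoparietal", "visual", "subcortical")


@dataclass(frozen=True)
class NetworkParams:
    """Parameters of the three-cluster linear-nonlinear network.

    Node activities evolve as ``x_i(t) = f(sum_j J_ij x_j(t-1)) + b_i(t)``
    with the Ricker-type activation ``f(u) = u * exp(3 (1 - u))`` applied to
    the nonnegative part of the summed input (activities are rates; without
    the rectification any negative input is amplified by ``e^3`` per step
    and the map diverges almost surely).  ``J_ii = 1``; within-cluster
    off-diagonal entries are drawn N(0, 0.1/N); between-cluster coupling is
    zero in the baseline.  Models add, on top of the same baseline draw:

    * ``model1`` -- visual -> frontoparietal block drawn N(0, 0.5/N),
    * ``model2`` -- subcortical -> frontoparietal block drawn N(0, 0.5/N),
    * ``model3`` -- within-frontoparietal off-diagonal entries doubled.

    The sinusoidal bias ``b_i(t) = A_i sin(2 pi t / period + phi_i)`` models
    state-independent baseline correlation; fixing ``bias_seed`` reuses one
    bias realisation across the models of a comparison.
    """

    cluster_sizes: tuple[int, int, int] = (5, 5, 5)
    model: str = "baseline"
    self_coupling: float = 1.0
    sd_within: float | None = None     # default 0.1 / N
    sd_between: float | None = None    # default 0.5 / N
    sd_between_baseline: float = 0.0
    steps: int = 1000
    burn_in: int = 100
    bias_amplitude_range: tuple[float, float] = (0.0, 0.1)
    bias_period: float = 20.0
    bias_phase_range: tuple[float, float] = (0.0, 2.0 * np.pi)
    seed: int = 0
    bias_seed: int | None = None
    initial_state: tuple | None = None
    max_retries: int = 10

    def __post_init__(self) -> None:
        if self.model not in NETWORK_MODELS:
            raise ValueError(f"model must be one of {NETWORK_MODELS}")
        if any(s < 1 for s in self.cluster_sizes):
            raise ValueError("all cluster sizes must be >= 1")
        if self.steps < 1 or self.burn_in < 0:
            raise ValueError("steps must be >= 1 and burn_in >= 0")

    @property
    def n_nodes(self) -> int:
        return int(sum(self.cluster_sizes))

    def cluster_slices(self) -> dict[str, slice]:
        bounds = np.cumsum((0,) + tuple(self.cluster_sizes))
        return {
            name: slice(int(bounds[i]), int(bounds[i + 1]))
            for i, name in enumerate(CLUSTER_NAMES)
        }

    def node_labels(self) -> list[str]:
        short = {"frontoparietal": "FP", "visual": "V", "subcortical": "SC"}
        labels = []
        for name, size in zip(CLUSTER_NAMES, self.cluster_sizes):
            labels += [f"{short[name]}{i + 1}" for i in range(size)]
        return labels

    def area_labels(self) -> list[str]:
        short = {"frontoparietal": "FP", "visual": "V", "subcortical": "SC"}
        out = []
        for name, size in zip(CLUSTER_NAMES, self.cluster_sizes):
            out += [short[name]] * size
        return out


def build_connectivity(params: NetworkParams, seed: int) -> np.ndarray:
    """Connectivity matrix ``J`` (rows = receiving node) for one model.

    The within-cluster baseline draw depends only on ``seed`` and the
    cluster sizes, so all four models built from the same seed share it.
    """
    n = params.n_nodes
    sd_w = params.sd_within if params.sd_within is not None else 0.1 / n
    sd_b = params.sd_between if params.sd_between is not None else 0.5 / n
    ss = np.random.SeedSequence(seed)
    rng_within, rng_between, rng_extra = [
        np.random.default_rng(s) for s in ss.spawn(3)
    ]
    sl = params.cluster_slices()
    J = np.zeros((n, n))
    for name in CLUSTER_NAMES:
        s = sl[name]
        size = s.stop - s.start
        J[s, s] = rng_within.normal(0.0, sd_w, (size, size))
    if params.sd_between_baseline > 0:
        mask = np.ones((n, n), bool)
        for name in CLUSTER_NAMES:
            s = sl[name]
            mask[s, s] = False
        J[mask] = rng_between.normal(
            0.0, params.sd_between_baseline, int(mask.sum())
        )
    if params.model == "model3":
        fp = sl["frontoparietal"]
        J[fp, fp] *= 2.0
    np.fill_diagonal(J, params.self_coupling)
    if params.model == "model1":
        fp, v = sl["frontoparietal"], sl["visual"]
        J[fp, v] = rng_extra.normal(
            0.0, sd_b, (fp.stop - fp.start, v.stop - v.start)
        )
    elif params.model == "model2":
        fp, sc = sl["frontoparietal"], sl["subcortical"]
        J[fp, sc] = rng_extra.normal(
            0.0, sd_b, (fp.stop - fp.start, sc.stop - sc.start)
        )
    return J


def _ricker(u: np.ndarray) -> np.ndarray:
    u = np.maximum(u, 0.0)
    return u * np.exp(3.0 * (1.0 - u))


def simulate_cluster_network(params: NetworkParams = NetworkParams()) -> Trajectory:
    """Iterate the three-cluster map for ``steps`` steps after ``burn_in``.

    All node activities are returned as observables.  A run whose activity
    exceeds 1e3 is rejected, the seed advanced and the event logged, up to
    ``max_retries`` attempts.
    """
    bias_seed = params.bias_seed if params.bias_seed is not None else params.seed
    b_ss = np.random.SeedSequence((bias_seed, 17))
    rng_bias = np.random.default_rng(b_ss)
    n = params.n_nodes
    lo, hi = params.bias_amplitude_range
    A = rng_bias.uniform(lo, hi, n)
    phi = rng_bias.uniform(*params.bias_phase_range, n)

    seed = params.seed
    for attempt in range(params.max_retries + 1):
        J = build_connectivity(params, seed)
        if params.initial_state is not None:
            x = np.asarray(params.initial_state, dtype=float)
            if x.shape != (n,):
                raise ValueError(f"initial_state must have {n} components")
            x = x.copy()
        else:
            rng_init = np.random.default_rng(np.random.SeedSequence((seed, 23)))
            x = rng_init.uniform(0.5, 1.5, n)
        X = np.empty((params.steps, n))
        diverged = False
        for t in range(params.burn_in + params.steps):
            b = A * np.sin(2.0 * np.pi * t / params.bias_period + phi)
            x = _ricker(J @ x) + b
            if not np.all(np.isfinite(x)) or np.abs(x).max() > 1e3:
                diverged = True
                break
            if t >= params.burn_in:
                X[t - params.burn_in] = x
        if not diverged:
            return Trajectory(
                states=X,
                observables=X,
                time_step=1.0,
                observable_labels=params.node_labels(),
                metadata={
                    "system": "cluster_network",
                    "params": params,
                    "connectivity_seed": seed,
                    "area_labels": params.area_labels(),
                    "connectivity": J,
                },
            )
        logger.warning(
            "network run diverged (model=%s, seed=%d); advancing seed",
            params.model, seed,
        )
        seed += 1_000_003
    raise DivergenceError(
        f"network simulation diverged in {params.max_retries + 1} attempts "
        f"(model={params.model}, base seed={params.seed})"
    )
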