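"""k-nearest-neighbour cross-mapping and the pairwise statistics built on it.

Cross-mapping forecasts one channel's values from nearest neighbours located
in another channel's reconstructed state space.  For an ordered pair the
*embeddedness profile* is the Pearson correlation between true and forecast
target values as a function of reconstruction dimension ``d``; from it derive

* ``complexity``             -- min ``d`` reaching >= ``threshold`` (default
                                95 %) of the optimal embeddedness,
* ``directionality``         -- difference of optimal embeddedness between
                                the two orientations (antisymmetric exactly),
* ``relative_embeddedness``  -- embeddedness at ``d*`` minus that at
                                ``d = 1`` (coupling beyond plain correlation).

Forecast weights follow ``w_i = exp(-D_i) / sum_j exp(-D_j)`` where ``D`` is
the **squared** Euclidean distance to each of the ``k`` neighbours (shifted
by the smallest neighbour distance before exponentiation; the shift cancels
in the normalisation and keeps the exponentials in range).  Neighbour ties
break toward the lower library time index, so a forecast is a deterministic
function of its inputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .embedding import EmbeddingConfig, ProjectionMatrix, reconstruct

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ForecastSpec:
    """Settings of the cross-map forecaster and its cross-validation.

    ``n_queries`` points are subsampled uniformly without replacement from
    the query fold and shared across all dimensions of a profile.  With
    ``folds="printed"`` the library is the former half of the data and the
    queries come from the latter half; ``folds="both"`` (default) averages
    the two fold assignments.
    """

    k: int = 4
    n_queries: int = 1000
    folds: str = "both"
    threshold: float = 0.95
    query_seed: int = 0
    d_fixed: int | None = None
    normalize: bool = True

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError(f"k must be >= 1, got {self.k}")
        if not 0 < self.threshold <= 1:
            raise ValueError(f"threshold must be in (0, 1], got {self.threshold}")
        if self.n_queries < self.k + 1:
            raise ValueError("n_queries must be at least k + 1")
        if self.folds not in ("both", "printed"):
            raise ValueError("folds must be 'both' or 'printed'")
        if self.d_fixed is not None and self.d_fixed < 1:
            raise ValueError("d_fixed must be >= 1")


@dataclass
class ForecastDiagnostics:
    """Per-query neighbour sets, weights and forecasts."""

    neighbor_indices: np.ndarray   # (n_queries, k) library row indices
    squared_distances: np.ndarray  # (n_queries, k), ascending per row
    weights: np.ndarray            # (n_queries, k), each row sums to 1
    forecasts: np.ndarray          # (n_queries,)


@dataclass
class EmbeddednessProfile:
    """Cross-mapping accuracy per reconstruction dimension, one ordered pair.

    ``direction`` is ``(embedding_channel, embedded_channel)``: the first
    channel's reconstruction forecasts the second channel's values.
    """

    rho: np.ndarray
    dims: np.ndarray
    direction: tuple[str, str] = ("x", "y")
    n_effective: int = 0

    @property
    def optimal(self) -> float:
        """Optimal embeddedness, ``max_d rho(d)``."""
        return float(np.max(self.rho))

    def at(self, d: int) -> float:
        pos = np.nonzero(self.dims == d)[0]
        if pos.size == 0:
            raise ValueError(f"profile does not contain d={d}")
        return float(self.rho[pos[0]])


@dataclass
class PairResult:
    """Summary statistics for one ordered pair (source -> target)."""

    source: str
    target: str
    complexity: int
    optimal_embeddedness: float
    directionality: float
    relative_embeddedness: float


# ---------------------------------------------------------------------------
# neighbour search and forecasting core
#
# Squared distances are accumulated coordinate by coordinate and sums over
# the k neighbours run left to right, so the arithmetic is reproducible
# operation for operation by a scalar reimplementation of the formulas.
# ---------------------------------------------------------------------------


def _select_neighbors(acc: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Indices and squared distances of the k nearest library rows per query.

    Ties break toward the lower library index.  Returns ``(order, sq)`` each
    of shape ``(n_queries, k)``, sorted by ascending distance.
    """
    n_lib = acc.shape[1]
    if k > n_lib:
        raise ValueError(f"k={k} must not exceed library size {n_lib}")
    if k == n_lib:  # every library row is a neighbour; order by (distance, index)
        o = np.argsort(acc, axis=1, kind="stable")
        return o, np.take_along_axis(acc, o, 1)
    # fast path: partition to k+1 candidates, order candidates by index so the
    # subsequent stable sort breaks distance ties toward lower indices
    cand = np.argpartition(acc, k, axis=1)[:, : k + 1]
    cand = np.sort(cand, axis=1)
    csq = np.take_along_axis(acc, cand, 1)
    o = np.argsort(csq, axis=1, kind="stable")
    cand = np.take_along_axis(cand, o, 1)
    csq = np.take_along_axis(csq, o, 1)
    order, sq = cand[:, :k], csq[:, :k]
    # a tie across the selection boundary requires the exact rule on the full
    # row; rare for continuous-valued data
    boundary = csq[:, k - 1] == csq[:, k]
    if np.any(boundary):
        for row in np.nonzero(boundary)[0]:
            full = np.argsort(acc[row], kind="stable")[:k]
            order[row] = full
            sq[row] = acc[row][full]
    return order, sq


def _forecast_from_neighbors(
    sq: np.ndarray, order: np.ndarray, library_targets: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Exponential-of-squared-distance weights and the convex forecast."""
    e = np.exp(-(sq - sq[:, :1]))
    den = e[:, 0].copy()
    for j in range(1, e.shape[1]):
        den += e[:, j]
    w = e / den[:, None]
    targets = library_targets[order]
    fc = w[:, 0] * targets[:, 0]
    for j in range(1, w.shape[1]):
        fc = fc + w[:, j] * targets[:, j]
    return w, fc


def knn_forecast(
    library: np.ndarray,
    library_targets: np.ndarray,
    queries: np.ndarray,
    spec: ForecastSpec = ForecastSpec(),
) -> ForecastDiagnostics:
    """Cross-map forecast of query targets from a library of reconstructions.

    For each query row the ``k`` nearest library rows (Euclidean distance)
    are found; weights are ``exp(-squared distance)`` normalised over the
    ``k`` neighbours and the forecast is the weight-convex combination of the
    neighbours' target values, so it always lies within the neighbour target
    extremes.
    """
    L = np.atleast_2d(np.asarray(library, dtype=float))
    Q = np.atleast_2d(np.asarray(queries, dtype=float))
    y = np.asarray(library_targets, dtype=float)
    if L.shape[0] != y.shape[0]:
        raise ValueError("library and library_targets length mismatch")
    if L.shape[1] != Q.shape[1]:
        raise ValueError("library and query dimensionality mismatch")
    if spec.k > L.shape[0]:
        raise ValueError(
            f"k={spec.k} requires a library of at least k rows, "
            f"got {L.shape[0]}"
        )
    if not np.all(np.isfinite(Q)):
        raise ValueError("queries contain non-finite values")
    acc = np.zeros((Q.shape[0], L.shape[0]))
    for j in range(L.shape[1]):
        diff = Q[:, j][:, None] - L[None, :, j]
        acc += diff * diff
    order, sq = _select_neighbors(acc, spec.k)
    w, fc = _forecast_from_neighbors(sq, order, y)
    return ForecastDiagnostics(
        neighbor_indices=order, squared_distances=sq, weights=w, forecasts=fc
    )


def _pearson_or_zero(a: np.ndarray, b: np.ndarray) -> tuple[float, bool]:
    sa, sb = a.std(), b.std()
    if sa == 0.0 or sb == 0.0 or not np.isfinite(sa) or not np.isfinite(sb):
        return 0.0, True
    r = float(np.corrcoef(a, b)[0, 1])
    if not np.isfinite(r):
        return 0.0, True
    return r, False


def _profile_rhos(
    E_lib: np.ndarray,
    y_lib: np.ndarray,
    E_q: np.ndarray,
    y_q: np.ndarray,
    k: int,
    eval_dims: np.ndarray,
) -> tuple[np.ndarray, bool]:
    """rho(d) for each d in ``eval_dims`` via incremental squared distances."""
    rhos = np.empty(eval_dims.size)
    degenerate = False
    acc = np.zeros((E_q.shape[0], E_lib.shape[0]))
    pos = 0
    d_needed = int(eval_dims.max())
    for j in range(d_needed):
        diff = E_q[:, j][:, None] - E_lib[None, :, j]
        acc += diff * diff
        if pos < eval_dims.size and eval_dims[pos] == j + 1:
            order, sq = _select_neighbors(acc, k)
            _, fc = _forecast_from_neighbors(sq, order, y_lib)
            r, degen = _pearson_or_zero(fc, y_q)
            rhos[pos] = r
            degenerate = degenerate or degen
            pos += 1
    return rhos, degenerate


def _fold_slices(n: int, folds: str) -> list[tuple[slice, slice]]:
    half = n // 2
    out = [(slice(0, half), slice(half, n))]
    if folds == "both":
        out.append((slice(half, n), slice(0, half)))
    return out


def embeddedness_profile(
    x: np.ndarray,
    y: np.ndarray,
    emb: EmbeddingConfig,
    spec: ForecastSpec = ForecastSpec(),
    projection: ProjectionMatrix | None = None,
    direction: tuple[str, str] = ("x", "y"),
) -> EmbeddednessProfile:
    """Embeddedness of ``y`` by ``x``: rho(d) for d = 1..d_max.

    ``x`` is the embedding channel (its reconstruction hosts the neighbour
    search); ``y`` is the embedded channel whose contemporaneous values are
    forecast.  Cross-validation uses one data half as library and forecasts
    ``spec.n_queries`` subsampled points of the other half; with
    ``folds="both"`` the two assignments are averaged.  A degenerate fold
    (constant forecast or target) contributes rho = 0 with a logged warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have the same length")
    if spec.normalize:
        sx, sy = x.std(), y.std()
        x = x / sx if sx > 0 else x
        y = y / sy if sy > 0 else y
    rec = reconstruct(x, emb, projection=projection)
    yv = y[rec.t_offset:]
    if spec.d_fixed is not None:
        if spec.d_fixed > emb.d_max:
            raise ValueError("d_fixed exceeds d_max")
        eval_dims = np.array([spec.d_fixed])
    else:
        eval_dims = np.arange(1, emb.d_max + 1)
    rng = np.random.default_rng(spec.query_seed)
    rho_sum = np.zeros(eval_dims.size)
    n_eff = 0
    any_degen = False
    fold_list = _fold_slices(rec.n, spec.folds)
    for li, qi in fold_list:
        E_lib, y_lib = rec.vectors[li], yv[li]
        E_q, y_q = rec.vectors[qi], yv[qi]
        n_take = min(spec.n_queries, E_q.shape[0])
        qs = rng.choice(E_q.shape[0], size=n_take, replace=False)
        rhos, degen = _profile_rhos(
            E_lib, y_lib, E_q[qs], y_q[qs], spec.k, eval_dims
        )
        rho_sum += rhos
        n_eff += n_take
        any_degen = any_degen or degen
    if any_degen:
        logger.warning(
            "degenerate forecast/target for pair %s; rho set to 0", direction
        )
    return EmbeddednessProfile(
        rho=rho_sum / len(fold_list),
        dims=eval_dims,
        direction=direction,
        n_effective=n_eff,
    )


def complexity_from_profile(
    profile: EmbeddednessProfile, threshold: float = 0.95
) -> int:
    """Minimum dimension reaching ``threshold`` of the optimal embeddedness.

    Returns ``min { d : rho(d) >= threshold * max_d rho(d) }``.  When the
    profile has no positive value the pair is uninformative and the estimate
    degenerates to 1 (with a logged warning); when a finite-data profile
    peaks and then declines, the rule unchanged picks approximately the
    accuracy-maximising dimension.
    """
    if profile.rho.size == 0:
        raise ValueError("empty profile")
    m = float(np.max(profile.rho))
    if m <= 0:
        logger.warning(
            "uninformative pair %s (max rho <= 0); complexity set to 1",
            profile.direction,
        )
        return 1
    hit = np.nonzero(profile.rho >= threshold * m)[0][0]
    return int(profile.dims[hit])


def directionality(
    profile_s_by_t: EmbeddednessProfile,
    profile_t_by_s: EmbeddednessProfile,
) -> float:
    """Directionality of the interaction source -> target.

    Defined as optimal embeddedness of the source by the target minus that
    of the target by the source; positive when the source causally drives
    the target (the driven channel embeds its driver, not vice versa).
    Swapping the arguments negates the value exactly.
    """
    return profile_s_by_t.optimal - profile_t_by_s.optimal


def relative_embeddedness(profile: EmbeddednessProfile, d_star: int) -> float:
    """Embeddedness at ``d*`` minus embeddedness at ``d = 1``.

    Isolates the coupling of complex temporal structure that plain zero-lag
    correlation (captured already at one dimension) does not reflect.
    """
    return profile.at(d_star) - profile.at(1)


def convergence_profile(
    x: np.ndarray,
    y: np.ndarray,
    emb: EmbeddingConfig,
    spec: ForecastSpec,
    lengths: list[int],
    projection: ProjectionMatrix | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Optimal embeddedness of ``y`` by ``x`` versus library length.

    The library is truncated to the first ``L`` rows of the library fold for
    each requested length while the query points stay fixed, so increasing
    skill with length -- the convergence hallmark of deterministic causal
    coupling -- is measured on a common footing.  Returns
    ``(lengths_used, values)``; lengths below the neighbour minimum are
    skipped with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if spec.normalize:
        sx, sy = x.std(), y.std()
        x = x / sx if sx > 0 else x
        y = y / sy if sy > 0 else y
    rec = reconstruct(x, emb, projection=projection)
    yv = y[rec.t_offset:]
    half = rec.n // 2
    max_len = max(lengths)
    if max_len > half:
        raise ValueError(
            f"library length {max_len} exceeds available fold size {half}"
        )
    eval_dims = (
        np.array([spec.d_fixed]) if spec.d_fixed else np.arange(1, emb.d_max + 1)
    )
    rng = np.random.default_rng(spec.query_seed)
    E_q, y_q = rec.vectors[half:], yv[half:]
    n_take = min(spec.n_queries, E_q.shape[0])
    qs = rng.choice(E_q.shape[0], size=n_take, replace=False)
    E_q, y_q = E_q[qs], y_q[qs]
    used, vals = [], []
    for L in sorted(lengths):
        if L <= spec.k:
            logger.warning("library length %d below k + 1; skipped", L)
            continue
        rhos, _ = _profile_rhos(
            rec.vectors[:L], yv[:L], E_q, y_q, spec.k, eval_dims
        )
        used.append(L)
        vals.append(float(np.max(rhos)))
    return np.array(used), np.array(vals)


def analyze_pair(
    source: np.ndarray,
    target: np.ndarray,
    emb: EmbeddingConfig,
    spec: ForecastSpec = ForecastSpec(),
    projection: ProjectionMatrix | None = None,
    labels: tuple[str, str] = ("source", "target"),
) -> PairResult:
    """Full cross-embedding summary for one ordered pair source -> target.

    The main profile embeds the source by the target (the driven channel's
    reconstruction forecasting its driver); complexity, optimal embeddedness
    and relative embeddedness derive from it, directionality contrasts it
    with the reverse orientation.
    """
    p_main = embeddedness_profile(
        target, source, emb, spec, projection, direction=(labels[1], labels[0])
    )
    p_rev = embeddedness_profile(
        source, target, emb, spec, projection, direction=(labels[0], labels[1])
    )
    d_star = complexity_from_profile(p_main, spec.threshold)
    return PairResult(
        source=labels[0],
        target=labels[1],
        complexity=d_star,
        optimal_embeddedness=p_main.optimal,
        directionality=directionality(p_main, p_rev),
        relative_embeddedness=relative_embeddedness(p_main, d_star),
    )
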