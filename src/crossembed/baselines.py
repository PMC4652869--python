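"""Baseline complexity estimators used to benchmark the cross-embedding one.

Five comparators: Grassberger-Procaccia correlation dimension, PCA
dimension (axes explaining 90 % of variance), permutation entropy,
Lempel-Ziv (algorithmic) complexity of the binarised series, and the
optimal embedding dimension on standard (non-randomised) delay coordinates.
The first two are applied to a reconstructed attractor point cloud, the
next two to the raw scalar series; the last runs the identical
cross-embedding pipeline without the random projection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist

from .crossmap import (
    ForecastSpec,
    complexity_from_profile,
    embeddedness_profile,
)
from .embedding import EmbeddingConfig


@dataclass
class ComplexityEstimate:
    """One complexity value together with the settings that produced it."""

    method: str
    value: float
    settings: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not np.isfinite(self.value) or self.value < 0:
            raise ValueError(
                f"complexity estimate must be finite and >= 0, got {self.value}"
            )


def correlation_dimension(
    points: np.ndarray,
    radius_range: tuple[float, float] | None = None,
    n_radii: int = 12,
    max_points: int = 2000,
    seed: int = 0,
) -> float:
    """Grassberger-Procaccia correlation dimension of a point cloud.

    The correlation sum ``C(r)`` (fraction of point pairs closer than ``r``)
    scales as ``r**D`` on a self-similar set; ``D`` is estimated as the
    least-squares slope of ``log C(r)`` against ``log r`` over the supplied
    radius range.  By default the range spans the 1st to 10th percentile of
    the inter-point distances: a small-scale region below the attractor
    diameter, where the correlation sum has not yet saturated but every
    radius still captures enough pairs to be stable.  Clouds with
    more than ``max_points`` rows are subsampled for the O(n^2) distance
    computation.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.shape[0] < 100:
        raise ValueError("need at least 100 points")
    if pts.shape[0] > max_points:
        rng = np.random.default_rng(seed)
        pts = pts[rng.choice(pts.shape[0], max_points, replace=False)]
    dists = pdist(pts)
    positive = dists[dists > 0]
    if positive.size == 0:
        raise ValueError("degenerate point cloud: all points identical")
    logd = np.log(positive)
    if radius_range is None:
        lo, hi = np.quantile(logd, [0.01, 0.10])
    else:
        lo, hi = np.log(radius_range[0]), np.log(radius_range[1])
        if not lo < hi:
            raise ValueError("radius_range must be increasing and positive")
    radii = np.exp(np.linspace(lo, hi, n_radii))
    n_pairs = dists.size
    log_c = np.empty(n_radii)
    for i, r in enumerate(radii):
        c = np.count_nonzero(dists < r) / n_pairs
        if c == 0:
            c = 0.5 / n_pairs  # keep the log finite below the smallest pair
        log_c[i] = np.log(c)
    slope = np.polyfit(np.log(radii), log_c, 1)[0]
    return float(slope)


def dimension_from_spectrum(eigenvalues: np.ndarray, variance_fraction: float = 0.9) -> int:
    """Number of leading eigenvalues whose cumulative share reaches the cut."""
    lam = np.sort(np.asarray(eigenvalues, dtype=float))[::-1]
    if np.any(lam < 0) or lam.sum() <= 0:
        raise ValueError("eigenvalues must be nonnegative with positive sum")
    frac = np.cumsum(lam) / lam.sum()
    return int(np.searchsorted(frac, variance_fraction - 1e-12) + 1)


def pca_dimension(points: np.ndarray, variance_fraction: float = 0.9) -> int:
    """Smallest number of principal axes explaining ``variance_fraction``."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.shape[0] < 2:
        raise ValueError("need at least 2 points")
    centered = pts - pts.mean(axis=0)
    s = np.linalg.svd(centered, compute_uv=False)
    lam = s**2
    lam = lam[lam > lam[0] * 1e-12] if lam.size and lam[0] > 0 else lam
    return dimension_from_spectrum(lam, variance_fraction)


def permutation_entropy(series: np.ndarray, order: int = 3, delay: int = 1) -> float:
    """Shannon entropy (nats) of the ordinal-pattern distribution.

    Windows of ``order`` samples spaced by ``delay`` are ranked; the entropy
    of the resulting pattern frequencies measures the diversity of local
    temporal orderings, from 0 for a monotone series to ``log(order!)`` for
    i.i.d. noise.  Equal values rank by position (first occurrence lower).
    """
    if order < 2:
        raise ValueError("order must be >= 2")
    if order > 8:
        raise ValueError("order > 8 rejected: pattern count grows as order!")
    if delay < 1:
        raise ValueError("delay must be >= 1")
    x = np.asarray(series, dtype=float)
    n_win = x.size - (order - 1) * delay
    if n_win < 1:
        raise ValueError(
            f"series of length {x.size} too short for order={order}, "
            f"delay={delay}; need > {(order - 1) * delay}"
        )
    idx = np.arange(n_win)[:, None] + np.arange(order)[None, :] * delay
    windows = x[idx]
    # stable double argsort = rank with ties broken by position
    patterns = np.argsort(np.argsort(windows, axis=1, kind="stable"),
                          axis=1, kind="stable")
    codes = (patterns * (order ** np.arange(order))).sum(axis=1)
    _, counts = np.unique(codes, return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log(p)).sum())


def lz_phrase_count(bits: np.ndarray) -> int:
    """Lempel-Ziv (1976) phrase count of a binary sequence.

    Exhaustive-production parsing: a new phrase is registered whenever the
    running substring cannot be copied from the previous history.  A
    constant sequence parses into 2 phrases, a long alternation into 3, and
    an incompressible sequence of length n into ~ n / log2 n.
    """
    s = np.asarray(bits).astype(np.uint8)
    if s.size < 2:
        raise ValueError("sequence must have length >= 2")
    s = s.tolist()
    n = len(s)
    c = 1       # phrases counted (the first symbol starts phrase 1)
    u = 1       # start of the current phrase (0-based: s[u:])
    v = 1       # length of the candidate extension
    vmax = 1    # longest reproducible extension found for this phrase
    i = 0       # candidate copy start within the history s[:u]
    while u + v <= n:
        if s[i + v - 1] == s[u + v - 1]:
            v += 1
        else:
            vmax = max(v, vmax)
            i += 1
            if i == u:  # no history position reproduces the extension
                c += 1
                u += vmax
                v = 1
                vmax = 1
                i = 0
            else:
                v = 1
    if v != 1:
        c += 1
    return c


def lz_complexity(
    series: np.ndarray,
    binarization: str = "median",
    normalized: bool = True,
) -> float:
    """Lempel-Ziv complexity of a real series after threshold binarisation.

    The series is binarised at its median (the conventional choice for this
    estimator family); optionally the phrase count is normalised by
    ``n / log2 n``, the expected count of an incompressible sequence, so a
    fair-coin sequence scores about 1.
    """
    x = np.asarray(series, dtype=float)
    if x.size < 2:
        raise ValueError("series must have length >= 2")
    if binarization != "median":
        raise ValueError("only median binarisation is implemented")
    bits = (x > np.median(x)).astype(np.uint8)
    c = lz_phrase_count(bits)
    if not normalized:
        return float(c)
    n = x.size
    return float(c * math.log2(n) / n)


def standard_embedding_dimension(
    x: np.ndarray,
    y: np.ndarray,
    emb: EmbeddingConfig,
    spec: ForecastSpec = ForecastSpec(),
) -> int:
    """Optimal embedding dimension on standard (non-projected) coordinates.

    Runs the identical cross-embedding pipeline (embed ``y`` by ``x``) with
    the random projection disabled; exists to expose the overestimation
    this incurs for slow or oversampled signals.
    """
    emb_std = EmbeddingConfig(
        tau=emb.tau,
        d_max=emb.d_max,
        randomize=False,
        orthogonalize=False,
        seed=emb.seed,
        projection_sharing=emb.projection_sharing,
    )
    profile = embeddedness_profile(x, y, emb_std, spec)
    return complexity_from_profile(profile, spec.threshold)


def complexity_suite(
    x: np.ndarray,
    y: np.ndarray,
    emb: EmbeddingConfig,
    spec: ForecastSpec = ForecastSpec(),
    pe_order: int = 3,
    pe_delay: int = 1,
) -> list[ComplexityEstimate]:
    """All six complexity estimates for the ordered pair ``y`` embedded by ``x``.

    The correlation and PCA dimensions are computed on the random-coordinate
    reconstruction of the embedding channel ``x``; permutation entropy and
    Lempel-Ziv complexity on the raw ``x`` series; the last two estimates
    run the cross-embedding pipeline with and without the projection.
    """
    from .embedding import reconstruct  # local import to avoid cycle noise

    xs = np.asarray(x, dtype=float)
    sx = xs.std()
    xn = xs / sx if sx > 0 else xs
    cloud = reconstruct(xn, emb).vectors
    profile = embeddedness_profile(x, y, emb, spec)
    results = [
        ComplexityEstimate(
            "random_coordinate_complexity",
            complexity_from_profile(profile, spec.threshold),
            {"tau": emb.tau, "d_max": emb.d_max, "k": spec.k,
             "threshold": spec.threshold},
        ),
        ComplexityEstimate(
            "standard_embedding_dimension",
            standard_embedding_dimension(x, y, emb, spec),
            {"tau": emb.tau, "d_max": emb.d_max, "k": spec.k},
        ),
        ComplexityEstimate(
            "correlation_dimension",
            max(correlation_dimension(cloud, seed=emb.seed), 0.0),
            {"radius_range": "interquartile"},
        ),
        ComplexityEstimate(
            "pca_dimension",
            pca_dimension(cloud),
            {"variance_fraction": 0.9},
        ),
        ComplexityEstimate(
            "permutation_entropy",
            permutation_entropy(xs, pe_order, pe_delay),
            {"order": pe_order, "delay": pe_delay},
        ),
        ComplexityEstimate(
            "lz_complexity",
            lz_complexity(xs),
            {"binarization": "median", "normalized": True},
        ),
    ]
    return results
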