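"""Delay-coordinate reconstruction with optional random-coordinate projection.

A scalar series ``x`` is lifted to delay vectors

    x_t = (x_t, x_{t-tau}, ..., x_{t-(d_max-1) tau}),

one row per admissible time index ``t`` (0-based; the row for ``t`` holds the
newest sample first).  Random-coordinate reconstruction left-multiplies each
delay vector by a fixed square random matrix ``R`` before neighbour search,
which preserves the attractor topology while decorrelating adjacent delay
coordinates; a ``d``-dimensional reconstruction is the first ``d`` components
of the projected ``d_max``-vector.  ``R`` is always generated at size
``d_max`` and never truncated or regrown, so the sub-dimension contract holds
only within one ``d_max``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class SeriesTooShortError(ValueError):
    """The input series cannot accommodate the requested delay structure."""


@dataclass(frozen=True)
class EmbeddingConfig:
    """Settings for delay-coordinate reconstruction.

    Parameters
    ----------
    tau : int
        Unit delay, in samples (callers convert from physical time using the
        recording's sampling interval).
    d_max : int
        Maximum reconstruction dimension; sub-dimensions use the first ``d``
        projected coordinates.
    randomize : bool
        Apply the random-coordinate projection.
    orthogonalize : bool
        Replace the raw Gaussian draw by an orthonormal basis derived from it
        (rows mutually orthonormal).
    seed : int
        Seed of the projection draw; identical ``(seed, d_max, randomize,
        orthogonalize)`` reproduce the identical matrix.
    projection_sharing : {"shared-per-run", "per-channel"}
        Whether one projection is shared by all channels of a run (default;
        keeps reconstructions comparable) or redrawn per channel.
    """

    tau: int = 1
    d_max: int = 30
    randomize: bool = True
    orthogonalize: bool = False
    seed: int = 0
    projection_sharing: str = "shared-per-run"

    def __post_init__(self) -> None:
        if self.tau < 1:
            raise ValueError(f"tau must be >= 1, got {self.tau}")
        if self.d_max < 1:
            raise ValueError(f"d_max must be >= 1, got {self.d_max}")
        if self.projection_sharing not in ("shared-per-run", "per-channel"):
            raise ValueError(
                "projection_sharing must be 'shared-per-run' or 'per-channel'"
            )

    @property
    def min_length(self) -> int:
        """Shortest admissible series length."""
        return (self.d_max - 1) * self.tau + 1


@dataclass(frozen=True)
class ProjectionMatrix:
    """A fixed square random projection ``R`` applied from the left."""

    entries: np.ndarray
    seed: int
    distribution: str = "standard_normal"
    orthogonalized: bool = False

    def __post_init__(self) -> None:
        e = np.asarray(self.entries, dtype=float)
        if e.ndim != 2 or e.shape[0] != e.shape[1]:
            raise ValueError("projection matrix must be square")
        if not np.all(np.isfinite(e)):
            raise ValueError("projection matrix must be finite")
        object.__setattr__(self, "entries", e)

    @property
    def d_max(self) -> int:
        return self.entries.shape[0]


@dataclass(frozen=True)
class Reconstruction:
    """Matrix of (optionally projected) delay vectors.

    ``vectors[i]`` corresponds to time index ``t_offset + i`` of the source
    series; ``t_offset = (d_max - 1) * tau``.
    """

    vectors: np.ndarray
    t_offset: int
    tau: int
    source_channel: str | None = None
    projected: bool = False

    @property
    def d_max(self) -> int:
        return self.vectors.shape[1]

    @property
    def n(self) -> int:
        return self.vectors.shape[0]

    def dims(self, d: int) -> np.ndarray:
        """The dimension-``d`` sub-reconstruction (first ``d`` columns)."""
        if not 1 <= d <= self.d_max:
            raise ValueError(f"d must be in [1, {self.d_max}], got {d}")
        return self.vectors[:, :d]


def _validate_series(series: np.ndarray, tau: int, d_max: int) -> np.ndarray:
    x = np.asarray(series, dtype=float)
    if x.ndim != 1:
        raise ValueError(f"series must be one-dimensional, got shape {x.shape}")
    if not np.all(np.isfinite(x)):
        raise ValueError("series contains non-finite values")
    min_len = (d_max - 1) * tau + 1
    if x.size < min_len:
        raise SeriesTooShortError(
            f"series of length {x.size} too short for tau={tau}, "
            f"d_max={d_max}; need at least {min_len} samples"
        )
    return x


def build_delay_matrix(
    series: np.ndarray,
    tau: int,
    d_max: int,
    source_channel: str | None = None,
) -> Reconstruction:
    """Standard (non-projected) delay-coordinate matrix of a scalar series.

    Row ``i`` equals ``(x_t, x_{t-tau}, ..., x_{t-(d_max-1) tau})`` with
    ``t = (d_max - 1) * tau + i``; the row count is
    ``len(series) - (d_max - 1) * tau``.
    """
    if tau < 1 or d_max < 1:
        raise ValueError("tau and d_max must be >= 1")
    x = _validate_series(series, tau, d_max)
    offset = (d_max - 1) * tau
    n_rows = x.size - offset
    idx = np.arange(n_rows)[:, None] + offset - np.arange(d_max)[None, :] * tau
    return Reconstruction(
        vectors=x[idx],
        t_offset=offset,
        tau=tau,
        source_channel=source_channel,
        projected=False,
    )


def make_projection(config: EmbeddingConfig) -> ProjectionMatrix:
    """Draw the square random projection specified by ``config``.

    Entries are standard normal.  With ``orthogonalize`` the draw is
    decomposed into an orthonormal basis (QR with a deterministic sign fix),
    so the rows satisfy ``M @ M.T == I`` to within 1e-10.
    """
    rng = np.random.default_rng(config.seed)
    draw = rng.standard_normal((config.d_max, config.d_max))
    if config.orthogonalize:
        q, r = np.linalg.qr(draw)
        # fix the sign ambiguity of QR so the basis is a pure function of
        # the draw
        signs = np.sign(np.diag(r))
        signs[signs == 0] = 1.0
        entries = (q * signs).T
    else:
        entries = draw
    return ProjectionMatrix(
        entries=entries,
        seed=config.seed,
        orthogonalized=config.orthogonalize,
    )


def reconstruct(
    series: np.ndarray,
    config: EmbeddingConfig,
    projection: ProjectionMatrix | None = None,
    source_channel: str | None = None,
) -> Reconstruction:
    """Delay-coordinate reconstruction, randomly projected when configured.

    With ``config.randomize`` each delay vector ``x_t`` is replaced by
    ``R @ x_t``; otherwise the output equals :func:`build_delay_matrix`.
    An explicit ``projection`` (e.g. one shared across the channels of a
    multichannel run) overrides the config-seeded draw.
    """
    rec = build_delay_matrix(series, config.tau, config.d_max, source_channel)
    if not config.randomize:
        return rec
    if projection is None:
        projection = make_projection(config)
    if projection.d_max != config.d_max:
        raise ValueError(
            f"projection size {projection.d_max} does not match "
            f"d_max={config.d_max}"
        )
    return Reconstruction(
        vectors=rec.vectors @ projection.entries.T,
        t_offset=rec.t_offset,
        tau=rec.tau,
        source_channel=source_channel,
        projected=True,
    )
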