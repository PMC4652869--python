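"""Multichannel orchestration: I/O, preprocessing, all-pairs analysis.

Matrix orientation is fixed throughout: **columns index the source channel,
rows the target channel**, so entry ``(i, j)`` describes the interaction
from channel ``j`` to channel ``i``.  The complexity at ``(i, j)`` is the
dimension the *target* reconstruction needs to embed the source, the
directionality at ``(i, j)`` is positive when ``j`` drives ``i``, and the
directionality matrix is exactly antisymmetric.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as sp_signal
from scipy import stats as sp_stats

from .baselines import complexity_suite
from .crossmap import (
    EmbeddednessProfile,
    ForecastSpec,
    complexity_from_profile,
    embeddedness_profile,
    relative_embeddedness,
)
from .embedding import EmbeddingConfig, ProjectionMatrix, make_projection
from .simulators import (
    DivergenceError,
    RosslerParams,
    Trajectory,
    add_observation_noise,
    simulate_coupled_rossler,
)

logger = logging.getLogger(__name__)


@dataclass
class TimeSeriesSet:
    """A time x channel recording with sampling interval and channel labels."""

    data: np.ndarray
    sampling_interval: float = 1.0
    channel_labels: list[str] = field(default_factory=list)
    area_labels: list[str] | None = None
    positions: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D time x channel matrix")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("data contains non-finite entries")
        if not self.channel_labels:
            self.channel_labels = [f"ch{i}" for i in range(self.data.shape[1])]
        if len(self.channel_labels) != self.data.shape[1]:
            raise ValueError("channel_labels length does not match data columns")
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel labels must be unique")
        if self.area_labels is not None and len(self.area_labels) != self.n_channels:
            raise ValueError("area_labels length does not match channel count")

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    def channel(self, label: str) -> np.ndarray:
        return self.data[:, self.channel_labels.index(label)]

    @classmethod
    def from_trajectory(cls, traj: Trajectory) -> "TimeSeriesSet":
        """Wrap a simulator trajectory's observables as a channel set."""
        return cls(
            data=traj.observables,
            sampling_interval=traj.time_step,
            channel_labels=list(traj.observable_labels),
            area_labels=traj.metadata.get("area_labels"),
        )


def load_timeseries(
    path: str | Path,
    metadata_path: str | Path | None = None,
    delimiter: str = "\t",
    header: bool = True,
    sampling_interval: float = 1.0,
) -> TimeSeriesSet:
    """Load a delimited-text (or ``.npy``) time x channel matrix.

    The optional metadata table (columns ``channel``, ``area``, ``pos_x``,
    ``pos_y``) is joined on the channel label; a row-count mismatch or an
    unknown channel is rejected.
    """
    path = Path(path)
    if path.suffix == ".npy":
        data = np.load(path)
        labels = None
    else:
        df = pd.read_csv(path, sep=delimiter, header=0 if header else None)
        try:
            data = df.to_numpy(dtype=float)
        except (TypeError, ValueError) as exc:
            raise ValueError(f"unparseable numeric data in {path}: {exc}") from exc
        labels = [str(c) for c in df.columns] if header else None
    ts = TimeSeriesSet(
        data=data,
        sampling_interval=sampling_interval,
        channel_labels=labels or [],
    )
    if metadata_path is not None:
        meta = pd.read_csv(metadata_path, sep=delimiter)
        if "channel" not in meta.columns:
            raise ValueError("metadata must have a 'channel' column")
        meta = meta.astype({"channel": str}).set_index("channel")
        if len(meta) != ts.n_channels:
            raise ValueError(
                f"metadata rows ({len(meta)}) do not match data channels "
                f"({ts.n_channels})"
            )
        missing = [c for c in ts.channel_labels if c not in meta.index]
        if missing:
            raise ValueError(f"metadata missing channels: {missing}")
        meta = meta.loc[ts.channel_labels]
        if "area" in meta.columns:
            ts.area_labels = meta["area"].astype(str).tolist()
        if {"pos_x", "pos_y"}.issubset(meta.columns):
            ts.positions = meta[["pos_x", "pos_y"]].to_numpy(dtype=float)
    return ts


def write_timeseries(ts: TimeSeriesSet, path: str | Path, delimiter: str = "\t") -> None:
    """Write the data matrix as delimited text with a channel-label header."""
    pd.DataFrame(ts.data, columns=ts.channel_labels).to_csv(
        path, sep=delimiter, index=False, float_format="%.10g"
    )


@dataclass(frozen=True)
class PreprocessOptions:
    """Which preprocessing stages to run, in their fixed order.

    1. artifact rejection: inside caller-declared post-event windows, drop
       samples where the channel-averaged signal exceeds the whole-record
       percentile threshold;
    2. band-stop filtering of the line-noise band (default 47.5-52.5 Hz);
    3. bipolar re-referencing over a declared neighbour-pair list;
    4. per-channel variance normalisation to one.
    """

    artifact_windows: tuple[tuple[float, float], ...] | None = None
    artifact_percentile: float = 75.0
    notch: bool = False
    notch_band: tuple[float, float] = (47.5, 52.5)
    notch_order: int = 4
    bipolar_pairs: tuple[tuple[str, str], ...] | None = None
    normalize_variance: bool = True


def preprocess(ts: TimeSeriesSet, options: PreprocessOptions = PreprocessOptions()) -> TimeSeriesSet:
    """Apply the enabled preprocessing stages and return a new channel set."""
    data = ts.data.copy()
    labels = list(ts.channel_labels)
    areas = list(ts.area_labels) if ts.area_labels is not None else None
    positions = ts.positions.copy() if ts.positions is not None else None

    if options.artifact_windows is not None:
        mean_sig = data.mean(axis=1)
        thresh = np.percentile(mean_sig, options.artifact_percentile)
        t = np.arange(data.shape[0]) * ts.sampling_interval
        in_window = np.zeros(data.shape[0], bool)
        for t0, t1 in options.artifact_windows:
            in_window |= (t >= t0) & (t < t1)
        keep = ~(in_window & (mean_sig > thresh))
        data = data[keep]

    if options.notch:
        nyq = 0.5 / ts.sampling_interval
        lo, hi = options.notch_band
        if hi >= nyq:
            raise ValueError(
                f"notch band {options.notch_band} exceeds Nyquist {nyq:.3g} Hz"
            )
        sos = sp_signal.butter(
            options.notch_order, [lo / nyq, hi / nyq], btype="bandstop", output="sos"
        )
        data = sp_signal.sosfiltfilt(sos, data, axis=0)

    if options.bipolar_pairs is not None:
        cols = []
        new_labels = []
        new_areas = [] if areas is not None else None
        for a, b in options.bipolar_pairs:
            if a not in labels or b not in labels:
                raise ValueError(f"bipolar pair ({a}, {b}) references unknown channel")
            ia, ib = labels.index(a), labels.index(b)
            cols.append(data[:, ia] - data[:, ib])
            new_labels.append(f"{a}-{b}")
            if new_areas is not None:
                new_areas.append(areas[ia])
        data = np.column_stack(cols)
        labels = new_labels
        areas = new_areas
        positions = None

    if options.normalize_variance:
        sd = data.std(axis=0)
        if np.any(sd == 0):
            zero = [labels[i] for i in np.nonzero(sd == 0)[0]]
            raise ValueError(f"cannot variance-normalize constant channels: {zero}")
        data = data / sd

    return TimeSeriesSet(
        data=data,
        sampling_interval=ts.sampling_interval,
        channel_labels=labels,
        area_labels=areas,
        positions=positions,
    )


@dataclass
class PairwiseMatrices:
    """All-pairs cross-embedding output; columns = source, rows = target.

    Diagonal entries are NaN (complexity, embeddedness) or 0
    (directionality, correlation diagonal is 1).  Missing per-pair results
    are NaN, never silently zero.
    """

    complexity: np.ndarray
    directionality: np.ndarray
    optimal_embeddedness: np.ndarray
    relative_embeddedness: np.ndarray
    correlation: np.ndarray
    channel_labels: list[str]
    area_labels: list[str] | None = None
    profiles: dict[tuple[str, str], EmbeddednessProfile] | None = None

    def to_frame(self, which: str) -> pd.DataFrame:
        m = getattr(self, which)
        return pd.DataFrame(m, index=self.channel_labels, columns=self.channel_labels)

    def pair_table(self) -> pd.DataFrame:
        """Long-format per-pair table (source, target, statistics)."""
        rows = []
        labels = self.channel_labels
        for i, tgt in enumerate(labels):
            for j, src in enumerate(labels):
                if i == j:
                    continue
                rows.append({
                    "source": src,
                    "target": tgt,
                    "complexity": self.complexity[i, j],
                    "optimal_embeddedness": self.optimal_embeddedness[i, j],
                    "directionality": self.directionality[i, j],
                    "relative_embeddedness": self.relative_embeddedness[i, j],
                    "correlation": self.correlation[i, j],
                })
        return pd.DataFrame(rows)


def pairwise_analysis(
    ts: TimeSeriesSet,
    emb: EmbeddingConfig,
    spec: ForecastSpec = ForecastSpec(),
    pairs: list[tuple[str, str]] | None = None,
    significant_only: bool = False,
    alpha: float = 0.01,
    keep_profiles: bool = False,
) -> PairwiseMatrices:
    """Cross-embedding statistics for every ordered channel pair.

    One projection matrix is shared across all channels of the run (unless
    the embedding config requests per-channel draws), so reconstructions
    are mutually comparable.  ``pairs`` optionally restricts computation to
    a subset of ordered ``(source, target)`` pairs; entries not computed
    are NaN.  With ``significant_only`` a pair's statistics are kept only
    if its forecast skill passes a Pearson correlation test at ``alpha``.
    """
    n = ts.n_channels
    if n < 2:
        raise ValueError("need at least 2 channels")
    labels = ts.channel_labels
    idx = {lab: i for i, lab in enumerate(labels)}

    shared = emb.projection_sharing == "shared-per-run"
    proj_shared = make_projection(emb) if (emb.randomize and shared) else None

    def channel_projection(i: int) -> ProjectionMatrix | None:
        if not emb.randomize:
            return None
        if shared:
            return proj_shared
        return make_projection(replace(emb, seed=emb.seed + i))

    wanted: set[tuple[int, int]] = set()
    if pairs is None:
        wanted = {(i, j) for i in range(n) for j in range(n) if i != j}
    else:
        for src, tgt in pairs:
            wanted.add((idx[src], idx[tgt]))
            wanted.add((idx[tgt], idx[src]))  # reverse needed for directionality

    # profile of (source j embedded by target i), keyed (i, j)
    prof: dict[tuple[int, int], EmbeddednessProfile | None] = {}
    for (j, i) in sorted(wanted):  # wanted holds (source, target)
        x = ts.data[:, i]  # embedding channel = target
        y = ts.data[:, j]
        try:
            prof[(i, j)] = embeddedness_profile(
                x, y, emb, spec,
                projection=channel_projection(i),
                direction=(labels[i], labels[j]),
            )
        except Exception as exc:  # pragma: no cover - defensive
            logger.warning("pair (%s -> %s) failed: %s", labels[j], labels[i], exc)
            prof[(i, j)] = None

    def significant(p: EmbeddednessProfile) -> bool:
        if not significant_only:
            return True
        # Pearson test on the optimal forecasting correlation
        r = p.optimal
        n_eff = max(p.n_effective, 3)
        t = r * np.sqrt((n_eff - 2) / max(1e-12, 1 - r * r))
        pval = 2 * sp_stats.t.sf(abs(t), n_eff - 2)
        return pval < alpha

    cmx = np.full((n, n), np.nan)
    dirm = np.full((n, n), np.nan)
    opt = np.full((n, n), np.nan)
    rel = np.full((n, n), np.nan)
    np.fill_diagonal(dirm, 0.0)
    for (i, j), p in prof.items():
        if p is None:
            continue
        if not significant(p):
            continue
        cmx[i, j] = complexity_from_profile(p, spec.threshold)
        opt[i, j] = p.optimal
        rel[i, j] = relative_embeddedness(p, int(cmx[i, j]))
        rev = prof.get((j, i))
        if rev is not None:
            dirm[i, j] = p.optimal - rev.optimal

    corr = np.corrcoef(ts.data.T)
    return PairwiseMatrices(
        complexity=cmx,
        directionality=dirm,
        optimal_embeddedness=opt,
        relative_embeddedness=rel,
        correlation=corr,
        channel_labels=list(labels),
        area_labels=list(ts.area_labels) if ts.area_labels is not None else None,
        profiles=(
            {(labels[i], labels[j]): p for (i, j), p in prof.items() if p is not None}
            if keep_profiles else None
        ),
    )


@dataclass
class AreaSummary:
    """Area-level aggregation of the pairwise matrices.

    ``complexity`` / ``directionality`` are area x area block means
    (columns = source area, rows = target area); ``per_channel`` holds each
    channel's mean over its partner channels.  Averaging is electrode-first:
    area means are means over member channels.
    """

    areas: list[str]
    complexity: pd.DataFrame
    directionality: pd.DataFrame
    per_channel: pd.DataFrame
    area_means: pd.DataFrame  # per-area mean +/- sem of per-channel values


def aggregate_by_area(
    matrices: PairwiseMatrices,
    exclude_within_area: bool = False,
) -> AreaSummary:
    """Average pairwise statistics within and between labelled areas."""
    if matrices.area_labels is None:
        raise ValueError("all channels must carry an area label")
    areas_per_ch = matrices.area_labels
    unlabeled = [
        matrices.channel_labels[i]
        for i, a in enumerate(areas_per_ch)
        if a is None or (isinstance(a, float) and np.isnan(a)) or str(a) == ""
    ]
    if unlabeled:
        raise ValueError(f"channels without area label: {unlabeled}")
    areas = sorted(set(areas_per_ch))
    n = len(matrices.channel_labels)
    a_idx = {a: [i for i, x in enumerate(areas_per_ch) if x == a] for a in areas}

    def block_mean(M: np.ndarray, tgt: str, src: str) -> float:
        rows, cols = a_idx[tgt], a_idx[src]
        sub = M[np.ix_(rows, cols)]
        mask = ~np.isnan(sub)
        if tgt == src:
            off = ~np.eye(len(rows), dtype=bool)
            mask &= off
        if exclude_within_area and tgt == src:
            return np.nan
        return float(sub[mask].mean()) if mask.any() else np.nan

    cm = pd.DataFrame(
        [[block_mean(matrices.complexity, t, s) for s in areas] for t in areas],
        index=areas, columns=areas,
    )
    dm = pd.DataFrame(
        [[block_mean(matrices.directionality, t, s) for s in areas] for t in areas],
        index=areas, columns=areas,
    )

    # per-channel values averaged over partner ("cause"/source) channels
    rows = []
    for i, ch in enumerate(matrices.channel_labels):
        partner = np.ones(n, bool)
        partner[i] = False
        if exclude_within_area:
            partner &= np.array([areas_per_ch[j] != areas_per_ch[i] for j in range(n)])
        c_row = matrices.complexity[i, partner]
        d_row = matrices.directionality[i, partner]
        rows.append({
            "channel": ch,
            "area": areas_per_ch[i],
            "complexity": np.nanmean(c_row) if np.any(~np.isnan(c_row)) else np.nan,
            "directionality": np.nanmean(d_row) if np.any(~np.isnan(d_row)) else np.nan,
        })
    per_channel = pd.DataFrame(rows)

    g = per_channel.groupby("area")[["complexity", "directionality"]]
    area_means = g.agg(["mean", "sem"])
    return AreaSummary(
        areas=areas,
        complexity=cm,
        directionality=dm,
        per_channel=per_channel,
        area_means=area_means,
    )


def robustness_benchmark(
    timescales: tuple[float, ...] = (0.25, 0.5, 1.0),
    noise_levels: tuple[float, ...] = (0.0, 0.1, 0.3),
    reps: int = 5,
    seed: int = 0,
    reference: tuple[float, float] = (0.5, 0.0),
    emb: EmbeddingConfig | None = None,
    spec: ForecastSpec | None = None,
    n_points: int = 4000,
) -> pd.DataFrame:
    """Complexity-measure robustness sweep over timescale and noise grids.

    For every grid cell and repetition a coupled Roessler pair is simulated,
    the six complexity estimates are computed for the downstream channel,
    and each estimate is reported both raw and relative to its value in the
    reference cell (same repetition).  Sweeps vary one factor at a time:
    timescales at zero noise, noise levels at the reference timescale.
    """
    if emb is None:
        emb = EmbeddingConfig(tau=4, d_max=20, randomize=True, seed=seed)
    if spec is None:
        spec = ForecastSpec(query_seed=seed)
    t_ref, nz_ref = reference
    cells = [(t, 0.0) for t in timescales]
    cells += [(t_ref, nz) for nz in noise_levels if (t_ref, nz) not in cells]

    records = []
    for rep in range(reps):
        rep_seed = seed + 1000 * rep
        base = RosslerParams(
            duration=100.0 + n_points * 0.1,
            transient=100.0,
            seed=rep_seed,
        )
        for T, nz in cells:
            params = replace(base, T=T)
            for attempt in range(5):
                try:
                    traj = simulate_coupled_rossler(
                        replace(params, seed=rep_seed + 37 * attempt)
                    )
                    break
                except DivergenceError:
                    logger.warning("benchmark rep %d cell (%g, %g) diverged; "
                                   "resampling", rep, T, nz)
            else:  # pragma: no cover
                continue
            if nz > 0:
                std = traj.observables.std(axis=0)
                traj = Trajectory(
                    states=traj.states,
                    observables=traj.observables / std,
                    time_step=traj.time_step,
                    observable_labels=traj.observable_labels,
                    metadata=traj.metadata,
                )
                traj = add_observation_noise(traj, nz, seed=rep_seed + 7)
            x, y = traj.observables[:, 0], traj.observables[:, 1]
            emb_cell = replace(emb, seed=seed + rep)
            spec_cell = replace(spec, query_seed=seed + rep)
            for est in complexity_suite(x, y, emb_cell, spec_cell):
                records.append({
                    "rep": rep,
                    "timescale": T,
                    "noise_sd": nz,
                    "method": est.method,
                    "value": est.value,
                })
    df = pd.DataFrame(records)
    ref = df[(df.timescale == t_ref) & (df.noise_sd == nz_ref)]
    ref = ref.set_index(["rep", "method"])["value"]
    df["relative"] = [
        row.value / ref.loc[(row.rep, row.method)]
        if ref.loc[(row.rep, row.method)] != 0 else np.nan
        for row in df.itertuples()
    ]
    return df
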