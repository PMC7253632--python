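"""Temporal features and topographic map rendering.

Per-channel temporal statistics of the trial epoch — dHbO value at fixed
time points, interval means, least-squares slopes, skewness and kurtosis —
are interpolated across the 48-channel prefrontal montage to form 200x200
scalar images, the inputs of the CNN classifier.  The interpolation is
barycentric (linear) on a Delaunay triangulation of the channel positions
with nearest-neighbour fill outside the convex hull; both steps use
nonnegative weights, so rendering is monotone in every channel value.

Time-to-index convention: trial-relative time with t = 0 at task onset;
the sample index for time t is ``round(t * fs)`` (0-based), and interval
endpoints are inclusive on both ends.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import sparse, stats
from scipy.spatial import Delaunay, cKDTree

__all__ = [
    "ChannelLayout",
    "FeatureMapImage",
    "FeatureCatalog",
    "FeatureSet",
    "MapRenderer",
    "value_at_timepoint",
    "interval_mean",
    "interval_slope",
    "interval_skewness",
    "interval_kurtosis",
    "render_map",
    "temporal_raw_image",
    "build_feature_set",
]


@dataclass(frozen=True)
class ChannelLayout:
    """Normalized 2D montage of the prefrontal channel grid.

    Positions live in the unit square (x right, y up); row 0 of a rendered
    map corresponds to y = 1 (top).  The montage is anchored at the
    midline frontopolar reference (FpZ) at the top-centre of the grid.
    """

    channel_ids: tuple[str, ...]
    positions: np.ndarray  # (n, 2)
    reference: str = "FpZ"

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        object.__setattr__(self, "positions", pos)
        if pos.ndim != 2 or pos.shape[1] != 2 or pos.shape[0] != len(self.channel_ids):
            raise ValueError("positions must be (n_channels, 2)")
        if len(set(self.channel_ids)) != len(self.channel_ids):
            raise ValueError("channel ids must be unique")
        if np.any(pos < 0) or np.any(pos > 1):
            raise ValueError("positions must lie inside the unit square")
        if len(np.unique(pos, axis=0)) != pos.shape[0]:
            raise ValueError("positions must be pairwise distinct")

    @property
    def n_channels(self) -> int:
        return len(self.channel_ids)

    @classmethod
    def default_48(cls) -> "ChannelLayout":
        """Canonical 48-channel layout: 6 rows x 8 columns spanning the
        prefrontal band, with a small fixed jitter so channel positions are
        in general position for triangulation."""
        rng = np.random.default_rng(1820)  # fixed: part of the layout definition
        cols, rows = 8, 6
        xs = np.linspace(0.06, 0.94, cols)
        ys = np.linspace(0.88, 0.12, rows)  # row 0 at the top (y up)
        pos = np.array([(x, y) for y in ys for x in xs])
        pos += rng.uniform(-0.012, 0.012, size=pos.shape)
        pos = np.clip(pos, 0.0, 1.0)
        ids = tuple(f"CH{i + 1:02d}" for i in range(cols * rows))
        return cls(channel_ids=ids, positions=pos)

    @classmethod
    def from_csv(cls, path: str | Path) -> "ChannelLayout":
        """Load a layout file with columns ``channel,x,y``."""
        frame = pd.read_csv(path)
        return cls(channel_ids=tuple(frame["channel"].astype(str)),
                   positions=frame[["x", "y"]].to_numpy(float))

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"channel": self.channel_ids,
                      "x": self.positions[:, 0],
                      "y": self.positions[:, 1]}).to_csv(path, index=False)


def _index(t_s: float, fs: float) -> int:
    return int(round(t_s * fs))


def _window(epoch: np.ndarray, a_s: float, b_s: float, fs: float) -> np.ndarray:
    if not a_s < b_s:
        raise ValueError("need a < b")
    i0, i1 = _index(a_s, fs), _index(b_s, fs)
    n = epoch.shape[-1]
    if i0 < 0 or i1 >= n:
        raise ValueError(f"interval [{a_s}, {b_s}] s exceeds the epoch")
    return epoch[..., i0 : i1 + 1]


def value_at_timepoint(epoch: np.ndarray, t_s: float, fs: float) -> np.ndarray:
    """dHbO at sample index round(t * fs), per channel."""
    i = _index(t_s, fs)
    if i < 0 or i >= epoch.shape[-1]:
        raise ValueError(f"time point {t_s} s lies outside the epoch")
    return np.asarray(epoch, float)[..., i]


def interval_mean(epoch: np.ndarray, a_s: float, b_s: float, fs: float) -> np.ndarray:
    """Arithmetic mean over the inclusive sample window [a, b] seconds."""
    return _window(np.asarray(epoch, float), a_s, b_s, fs).mean(axis=-1)


def interval_slope(epoch: np.ndarray, a_s: float, b_s: float, fs: float) -> np.ndarray:
    """Degree-1 least-squares slope of dHbO against time (uM/s)."""
    win = _window(np.asarray(epoch, float), a_s, b_s, fs)
    if win.shape[-1] < 2:
        raise ValueError("slope window must contain at least 2 samples")
    t = (np.arange(win.shape[-1]) + _index(a_s, fs)) / fs
    tc = t - t.mean()
    return (win * tc).sum(axis=-1) / (tc @ tc)


def interval_skewness(epoch: np.ndarray, a_s: float, b_s: float, fs: float) -> np.ndarray:
    """Population-moment skewness m3 / m2^(3/2) over the window."""
    win = _window(np.asarray(epoch, float), a_s, b_s, fs)
    _check_moments(win)
    return stats.skew(win, axis=-1, bias=True)


def interval_kurtosis(epoch: np.ndarray, a_s: float, b_s: float, fs: float) -> np.ndarray:
    """Fourth standardized moment m4 / m2^2 (normal => 3, not excess)."""
    win = _window(np.asarray(epoch, float), a_s, b_s, fs)
    _check_moments(win)
    return stats.kurtosis(win, axis=-1, bias=True, fisher=False)


def _check_moments(win: np.ndarray) -> None:
    if win.shape[-1] < 3:
        raise ValueError("moment window must contain at least 3 samples")
    if np.any(win.std(axis=-1) == 0):
        raise ValueError("zero variance in window: statistic undefined")


class MapRenderer:
    """Precomputed interpolation operator from channel values to a grid.

    Builds a sparse (out_size^2, n_channels) matrix of barycentric weights
    (nearest-neighbour weight 1 outside the hull) once per layout, so a map
    render is a single sparse mat-vec.
    """

    def __init__(self, layout: ChannelLayout, out_size: int = 200):
        self.layout = layout
        self.out_size = out_size
        pts = layout.positions
        tri = Delaunay(pts)
        xs = np.linspace(0.0, 1.0, out_size)
        ys = np.linspace(1.0, 0.0, out_size)  # row 0 = top of the map
        gx, gy = np.meshgrid(xs, ys)
        grid = np.column_stack([gx.ravel(), gy.ravel()])
        simplex = tri.find_simplex(grid)
        inside = simplex >= 0

        rows, cols, vals = [], [], []
        if inside.any():
            T = tri.transform[simplex[inside]]
            delta = grid[inside] - T[:, 2]
            bary = np.einsum("nij,nj->ni", T[:, :2], delta)
            w = np.column_stack([bary, 1.0 - bary.sum(axis=1)])
            verts = tri.simplices[simplex[inside]]
            idx = np.flatnonzero(inside)
            rows.append(np.repeat(idx, 3))
            cols.append(verts.ravel())
            vals.append(np.clip(w, 0.0, 1.0).ravel())
        if (~inside).any():
            nearest = cKDTree(pts).query(grid[~inside])[1]
            idx = np.flatnonzero(~inside)
            rows.append(idx)
            cols.append(nearest)
            vals.append(np.ones(idx.size))
        self.weights = sparse.csr_matrix(
            (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
            shape=(out_size * out_size, layout.n_channels),
        )

    def render(self, channel_values: np.ndarray,
               scale: tuple[float, float] | None = None) -> np.ndarray:
        """Interpolate one value per channel to the grid.

        With ``scale=(lo, hi)`` the grid is affinely mapped so
        ``[lo, hi] -> [0, 1]`` and clipped; without it raw values are
        returned.
        """
        v = np.asarray(channel_values, dtype=float)
        if v.shape != (self.layout.n_channels,):
            raise ValueError(
                f"expected {self.layout.n_channels} channel values, got {v.shape}")
        if not np.all(np.isfinite(v)):
            raise ValueError("channel values must be finite")
        grid = (self.weights @ v).reshape(self.out_size, self.out_size)
        if scale is not None:
            lo, hi = scale
            if not lo < hi:
                raise ValueError("scale.min must be below scale.max")
            grid = np.clip((grid - lo) / (hi - lo), 0.0, 1.0)
        return grid


_RENDERER_CACHE: dict[tuple[int, int], MapRenderer] = {}


def render_map(channel_values: np.ndarray, layout: ChannelLayout,
               out_size: int = 200,
               scale: tuple[float, float] | None = None) -> np.ndarray:
    """Render one topographic map (see :class:`MapRenderer`)."""
    key = (id(layout), out_size)
    renderer = _RENDERER_CACHE.get(key)
    if renderer is None or renderer.layout is not layout:
        renderer = MapRenderer(layout, out_size)
        _RENDERER_CACHE[key] = renderer
    return renderer.render(channel_values, scale=scale)


@dataclass(frozen=True)
class FeatureMapImage:
    """One rendered map with its provenance."""

    grid: np.ndarray
    feature: str
    task: str
    subject: str
    trial: int
    scale: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        g = np.asarray(self.grid)
        if g.ndim != 2 or g.shape[0] != g.shape[1]:
            raise ValueError("grid must be square")
        if not np.all(np.isfinite(g)):
            raise ValueError("grid must be finite")


@dataclass(frozen=True)
class FeatureCatalog:
    """The configured feature set.

    Defaults: 13 time points (5..65 s step 5), interval means over 5-65 s
    and 5-25 s, slopes over 5-15 s, 20-60 s and 60-70 s, and skewness and
    kurtosis over 5-65 s.  (The 60-70 s slope window deliberately extends
    past the 65 s analysis bound; it stays inside the 90 s epoch.)
    """

    timepoints_s: tuple[float, ...] = tuple(float(t) for t in range(5, 70, 5))
    mean_windows: tuple[tuple[float, float], ...] = ((5.0, 65.0), (5.0, 25.0))
    slope_windows: tuple[tuple[float, float], ...] = ((5.0, 15.0), (20.0, 60.0), (60.0, 70.0))
    skewness_window: tuple[float, float] = (5.0, 65.0)
    kurtosis_window: tuple[float, float] = (5.0, 65.0)

    def names(self) -> list[str]:
        names = [f"timepoint_{int(t)}" for t in self.timepoints_s]
        names += [f"mean_{int(a)}_{int(b)}" for a, b in self.mean_windows]
        names += [f"slope_{int(a)}_{int(b)}" for a, b in self.slope_windows]
        a, b = self.skewness_window
        names.append(f"skewness_{int(a)}_{int(b)}")
        a, b = self.kurtosis_window
        names.append(f"kurtosis_{int(a)}_{int(b)}")
        return names

    def compute(self, name: str, epoch: np.ndarray, fs: float) -> np.ndarray:
        """Per-channel scalar values of the named feature for one epoch."""
        kind, *rest = name.split("_")
        if kind == "timepoint":
            return value_at_timepoint(epoch, float(rest[0]), fs)
        a, b = float(rest[0]), float(rest[1])
        fn = {"mean": interval_mean, "slope": interval_slope,
              "skewness": interval_skewness, "kurtosis": interval_kurtosis}.get(kind)
        if fn is None:
            raise KeyError(f"unknown feature {name!r}; valid: {', '.join(self.names())}")
        return fn(epoch, a, b, fs)


def temporal_raw_image(series: np.ndarray, out_size: int = 200) -> np.ndarray:
    """Resample one channel's 90 s series to ``out_size`` points and
    broadcast it down the rows to form a square grid."""
    x = np.asarray(series, dtype=float)
    pos = np.linspace(0, x.size - 1, out_size)
    row = np.interp(pos, np.arange(x.size), x)
    return np.tile(row, (out_size, 1))


@dataclass
class FeatureSet:
    """Labeled image collections for one task.

    ``images[name]`` is an (n_samples, size, size) raw-valued array with
    one row of ``meta`` per sample; ``temporal`` holds the per-ROI-channel
    raw time-series grids with their own ``temporal_meta``.
    """

    task: str
    images: dict[str, np.ndarray]
    meta: pd.DataFrame
    temporal: np.ndarray | None = None
    temporal_meta: pd.DataFrame | None = None

    @property
    def labels(self) -> np.ndarray:
        return self.meta["label"].to_numpy()

    @property
    def temporal_labels(self) -> np.ndarray:
        if self.temporal_meta is None:
            return np.array([], dtype=int)
        return self.temporal_meta["label"].to_numpy()


def build_feature_set(
    epochs: Mapping[tuple[str, str, int], np.ndarray],
    groups: Mapping[str, str],
    fs: float,
    task: str,
    layout: ChannelLayout,
    catalog: FeatureCatalog = FeatureCatalog(),
    feature_names: Sequence[str] | None = None,
    roi_channels: Mapping[tuple[str, str, int], np.ndarray] | None = None,
    out_size: int = 200,
    include_temporal: bool = True,
    zero_non_roi: bool = False,
) -> FeatureSet:
    """Render per-trial feature maps (and temporal-raw samples) for a task.

    Map features use all channels by default (``zero_non_roi`` zeroes the
    non-ROI channels first); temporal-raw samples are emitted one per ROI
    channel per trial and are produced only when ``roi_channels`` is given.
    Every sample carries its subject's group label (impaired = 1).
    """
    names = list(feature_names) if feature_names is not None else catalog.names()
    renderer = MapRenderer(layout, out_size)
    keys = sorted(k for k in epochs if k[1] == task)
    if not keys:
        raise ValueError(f"no epochs for task {task!r}")

    images = {name: np.empty((len(keys), out_size, out_size), dtype=np.float32)
              for name in names}
    rows = []
    for i, key in enumerate(keys):
        subject, _, trial = key
        epoch = np.asarray(epochs[key], dtype=float)
        label = 1 if groups[subject] == "impaired" else 0
        rows.append({"subject": subject, "task": task, "trial": trial, "label": label})
        for name in names:
            values = catalog.compute(name, epoch, fs)
            if zero_non_roi and roi_channels is not None:
                mask = np.zeros(values.size, dtype=bool)
                mask[np.asarray(roi_channels.get(key, []), dtype=int)] = True
                values = np.where(mask, values, 0.0)
            images[name][i] = renderer.render(values)
    meta = pd.DataFrame(rows)

    temporal = None
    temporal_meta = None
    if include_temporal and roi_channels is not None:
        t_imgs, t_rows = [], []
        for key in keys:
            subject, _, trial = key
            label = 1 if groups[subject] == "impaired" else 0
            for ci in np.asarray(roi_channels.get(key, []), dtype=int):
                t_imgs.append(temporal_raw_image(epochs[key][ci], out_size))
                t_rows.append({"subject": subject, "task": task, "trial": trial,
                               "channel": int(ci), "label": label})
        if t_imgs:
            temporal = np.stack(t_imgs).astype(np.float32)
            temporal_meta = pd.DataFrame(t_rows)
        else:
            temporal = np.empty((0, out_size, out_size), dtype=np.float32)
            temporal_meta = pd.DataFrame(
                columns=["subject", "task", "trial", "channel", "label"])

    return FeatureSet(task=task, images=images, meta=meta,
                      temporal=temporal, temporal_meta=temporal_meta)
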