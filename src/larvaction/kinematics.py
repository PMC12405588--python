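"""Midline-track kinematics: preprocessing, per-frame features, and
stride/run/pause annotation for larval crawling.

Tracks are 11-point midlines (head = point 1, tail = point 11) sampled at an
irregular framerate.  Preprocessing interpolates them onto a regular 10 Hz
grid and low-pass filters at 2 Hz — comfortably above the dominant ~1.4 Hz
peristaltic crawling frequency.  All speed-like features are scaled by the
larva's body length (the median midline length over the track), giving
dimensionless body-lengths per second.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import signal

logger = logging.getLogger(__name__)

__all__ = [
    "SpineTrack",
    "EpochAnnotation",
    "preprocess",
    "body_length",
    "centroid",
    "scaled_speeds",
    "nematic_order",
    "shape_factor",
    "axis_ratio",
    "velocity_alignment",
    "compute_features",
    "feature_window",
    "path_metrics",
    "straightness_index",
    "crawl_frequency",
    "detect_strides",
    "annotate_runs_pauses",
]

#: regular resampling grid step (s); all downstream rules count in these steps
DT = 0.1
#: low-pass cutoff (Hz) applied after resampling
LOWPASS_HZ = 2.0
#: scaled-speed threshold (body-lengths/s) a stride's peak must reach; also
#: the ceiling a pause must stay under
STRIDE_SPEED_THRESHOLD = 0.3


@dataclass
class SpineTrack:
    """One larva's 11-point midline time series.

    ``midline`` has shape (n_samples, 11, 2), in mm; point 0 is the head and
    point 10 the tail.  ``times`` are seconds from recording start and may
    be irregular before :func:`preprocess`.
    """

    larva_id: str
    times: np.ndarray
    midline: np.ndarray
    stimulus_onset: float = 60.0
    stimulus_duration: float = 30.0
    regular: bool = False

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.midline = np.asarray(self.midline, dtype=float)
        if self.midline.ndim != 3 or self.midline.shape[1:] != (11, 2):
            raise ValueError(
                f"midline must have shape (n, 11, 2), got {self.midline.shape}"
            )
        if self.midline.shape[0] != self.times.size:
            raise ValueError("times and midline lengths differ")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError(f"times must be strictly increasing (larva {self.larva_id})")

    @property
    def n_samples(self) -> int:
        return self.times.size

    @property
    def span(self) -> float:
        return float(self.times[-1] - self.times[0])

    @property
    def head(self) -> np.ndarray:
        return self.midline[:, 0, :]

    @property
    def tail(self) -> np.ndarray:
        return self.midline[:, 10, :]


@dataclass
class EpochAnnotation:
    """Stride/run/pause intervals for one track, in seconds."""

    strides: list[tuple[float, float]]
    runs: list[tuple[float, float]]
    pauses: list[tuple[float, float]]
    crawl_frequency: float
    cycle_duration: float


def preprocess(track: SpineTrack) -> SpineTrack:
    """Resample to a regular 10 Hz grid and low-pass filter at 2 Hz.

    Coordinates are linearly interpolated at a 0.1 s timestep covering the
    original span only, then filtered with a zero-phase second-order
    Butterworth (zero phase so event times are not shifted).
    """
    if track.n_samples < 2:
        raise ValueError("track must have at least 2 samples")
    if track.span < 1.0:
        raise ValueError(f"track span {track.span:.3f} s too short (need >= 1 s)")
    t0, t1 = track.times[0], track.times[-1]
    grid = t0 + DT * np.arange(int(np.floor((t1 - t0) / DT + 1e-9)) + 1)
    flat = track.midline.reshape(track.n_samples, 22)
    interp = np.column_stack([np.interp(grid, track.times, flat[:, j]) for j in range(22)])
    if grid.size > 15:  # sosfiltfilt needs padding room; very short tracks pass through
        sos = signal.butter(2, LOWPASS_HZ, btype="low", fs=1.0 / DT, output="sos")
        interp = signal.sosfiltfilt(sos, interp, axis=0)
    return replace(track, times=grid, midline=interp.reshape(-1, 11, 2), regular=True)


def _require_regular(track: SpineTrack):
    if not track.regular:
        raise ValueError("track must be preprocessed to the regular 10 Hz grid first")


def _midline_length(track: SpineTrack) -> np.ndarray:
    seg = np.diff(track.midline, axis=1)
    return np.linalg.norm(seg, axis=2).sum(axis=1)


def body_length(track: SpineTrack) -> float:
    """Median over time of the 11-point polyline length (mm)."""
    return float(np.median(_midline_length(track)))


def centroid(track: SpineTrack) -> np.ndarray:
    """Midline centroid G: the mean of the 11 points, per timestep."""
    return track.midline.mean(axis=1)


def _velocity(pos: np.ndarray, times: np.ndarray) -> np.ndarray:
    return np.gradient(pos, times, axis=0)


def scaled_speeds(track: SpineTrack) -> pd.DataFrame:
    """Head, centroid and tail speeds in body-lengths/s."""
    _require_regular(track)
    bl = body_length(track)
    out = {}
    for name, pos in (("head", track.head), ("center", centroid(track)), ("tail", track.tail)):
        out[f"speed_{name}"] = np.linalg.norm(_velocity(pos, track.times), axis=1) / bl
    return pd.DataFrame(out, index=pd.Index(track.times, name="t"))


def nematic_order(track: SpineTrack) -> np.ndarray:
    """Alignment of the 10 spine segments with the tail-to-head body axis.

    S = (3 <cos^2 theta> - 1) / 2, in [-0.5, 1]: 1 for a straight larva,
    -0.5 when every segment lies perpendicular to the axis.  Zero-length
    segments are skipped.
    """
    _require_regular(track)
    # segments pointing tail -> head, matching the body-axis direction
    seg = track.midline[:, :-1, :] - track.midline[:, 1:, :]
    axis = track.head - track.tail
    axis_norm = np.linalg.norm(axis, axis=1, keepdims=True)
    axis_unit = np.divide(axis, axis_norm, out=np.zeros_like(axis), where=axis_norm > 0)
    seg_norm = np.linalg.norm(seg, axis=2)
    dot = np.einsum("tsx,tx->ts", seg, axis_unit)
    cos2 = np.where(seg_norm > 0, (dot / np.where(seg_norm > 0, seg_norm, 1.0)) ** 2, np.nan)
    n_skipped = int(np.sum(seg_norm == 0))
    if n_skipped:
        logger.info("nematic_order: skipped %d zero-length segments", n_skipped)
    mean_cos2 = np.nanmean(cos2, axis=1)
    return 0.5 * (3.0 * mean_cos2 - 1.0)


def shape_factor(track: SpineTrack, half_window: int = 3) -> np.ndarray:
    """Elongation of the midline point cloud: (l1 - l2) / (l1 + l2).

    l1 >= l2 are the eigenvalues of the 2x2 covariance of the 11 midline
    points, averaged over a +-3-step window.  1 for a straight spine, 0 for
    an isotropic (e.g. circular) arrangement; NaN where the covariance is
    degenerate (all points coincident).
    """
    _require_regular(track)
    n = track.n_samples
    covs = np.empty((n, 2, 2))
    for t in range(n):
        covs[t] = np.cov(track.midline[t].T, bias=True)
    out = np.empty(n)
    for t in range(n):
        lo, hi = max(0, t - half_window), min(n, t + half_window + 1)
        c = covs[lo:hi].mean(axis=0)
        ev = np.linalg.eigvalsh(c)
        l2, l1 = max(ev[0], 0.0), max(ev[1], 0.0)
        tot = l1 + l2
        out[t] = np.nan if tot <= 1e-15 else (l1 - l2) / tot
    return out


def axis_ratio(track: SpineTrack, eps: float = 1e-9) -> np.ndarray:
    """||head - G|| / ||tail - G|| per timestep; NaN where the tail sits on G."""
    _require_regular(track)
    g = centroid(track)
    hg = np.linalg.norm(track.head - g, axis=1)
    tg = np.linalg.norm(track.tail - g, axis=1)
    out = np.full_like(hg, np.nan)
    ok = tg >= eps
    out[ok] = hg[ok] / tg[ok]
    if not ok.all():
        logger.info("axis_ratio: %d degenerate frames flagged NaN", int((~ok).sum()))
    return out


def velocity_alignment(track: SpineTrack, eps: float = 1e-12) -> pd.DataFrame:
    """Head/tail velocity projected on the first/last spine segment.

    The first segment points out of the head (point 2 -> point 1), the last
    out of the tail (point 10 -> point 11), so forward head motion projects
    positively.  Projections are scaled by body length (BL/s); cosines are
    NaN on zero-velocity frames.
    """
    _require_regular(track)
    bl = body_length(track)
    out = {}
    for end, pos, seg_vec in (
        ("head", track.head, track.midline[:, 0, :] - track.midline[:, 1, :]),
        ("tail", track.tail, track.midline[:, 10, :] - track.midline[:, 9, :]),
    ):
        v = _velocity(pos, track.times)
        seg_norm = np.linalg.norm(seg_vec, axis=1)
        seg_unit = np.divide(seg_vec, seg_norm[:, None],
                             out=np.zeros_like(seg_vec), where=seg_norm[:, None] > eps)
        dot = np.einsum("tx,tx->t", v, seg_unit)
        vnorm = np.linalg.norm(v, axis=1)
        cos = np.full(v.shape[0], np.nan)
        ok = (vnorm > eps) & (seg_norm > eps)
        cos[ok] = dot[ok] / vnorm[ok]
        out[f"proj_{end}"] = dot / bl
        out[f"cos_{end}"] = np.clip(cos, -1.0, 1.0)
    return pd.DataFrame(out, index=pd.Index(track.times, name="t"))


def compute_features(track: SpineTrack) -> pd.DataFrame:
    """All per-frame features as one DataFrame indexed by time."""
    _require_regular(track)
    bl = body_length(track)
    df = scaled_speeds(track)
    df["nematic_order"] = nematic_order(track)
    df["shape_factor"] = shape_factor(track)
    df["axis_ratio"] = axis_ratio(track)
    df = df.join(velocity_alignment(track))
    df["length"] = _midline_length(track)
    df["scaled_length"] = df["length"] / bl
    return df


def feature_window(features: pd.DataFrame, half_window: int = 3) -> np.ndarray:
    """Stack each feature over the 7-step window (t-3 .. t+3).

    Boundary timesteps replicate the edge frame so every timestep gets a
    vector.  Returns an (n, 7 * n_features) array; NaNs (undefined cosines
    etc.) are replaced by 0 so the vectors are classifier-ready.
    """
    n = len(features)
    if n < 2 * half_window + 1:
        raise ValueError(f"track too short for windowing: {n} < {2 * half_window + 1} steps")
    vals = np.nan_to_num(np.asarray(features, dtype=float), nan=0.0)
    blocks = []
    for off in range(-half_window, half_window + 1):
        idx = np.clip(np.arange(n) + off, 0, n - 1)
        blocks.append(vals[idx])
    return np.hstack(blocks)


#: 1-based index of the midline point used as the larva's position proxy —
#: a stable rear point insensitive to head sweeps
POSITION_POINT = 9


def _position_proxy(track: SpineTrack) -> np.ndarray:
    return track.midline[:, POSITION_POINT - 1, :]


def path_metrics(track: SpineTrack, scale_to_bl: bool = False) -> pd.DataFrame:
    """Cumulative pathlength and dispersal from the start position.

    Both follow the 9th midline point.  Dispersal is the straight-line
    distance to the initial position, so dispersal <= pathlength pointwise.
    """
    _require_regular(track)
    pos = _position_proxy(track)
    steps = np.linalg.norm(np.diff(pos, axis=0), axis=1)
    pathlength = np.concatenate([[0.0], np.cumsum(steps)])
    dispersal = np.linalg.norm(pos - pos[0], axis=1)
    if scale_to_bl:
        bl = body_length(track)
        pathlength, dispersal = pathlength / bl, dispersal / bl
    return pd.DataFrame(
        {"pathlength": pathlength, "dispersal": dispersal},
        index=pd.Index(track.times, name="t"),
    )


def straightness_index(track: SpineTrack, window: float = 20.0) -> pd.Series:
    """Windowed dispersal-to-pathlength ratio in [0, 1].

    A ``window``-second window advances along the track; each window
    reports |end - start| / distance traveled within it, assigned to the
    window center.  1 means straight-line motion, 0 no movement.
    """
    _require_regular(track)
    if track.span < window:
        raise ValueError(f"track span {track.span:.1f} s shorter than window {window} s")
    pos = _position_proxy(track)
    steps = np.linalg.norm(np.diff(pos, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(steps)])
    k = int(round(window / DT))
    n = track.n_samples
    centers, vals = [], []
    for start in range(0, n - k):
        end = start + k
        path = cum[end] - cum[start]
        disp = np.linalg.norm(pos[end] - pos[start])
        vals.append(0.0 if path <= 1e-12 else min(disp / path, 1.0))
        centers.append(track.times[(start + end) // 2])
    return pd.Series(vals, index=pd.Index(centers, name="t"), name="straightness_index")


def crawl_frequency(
    track: SpineTrack, band: tuple[float, float] = (0.5, 2.5)
) -> tuple[float, float]:
    """Dominant crawling frequency (Hz) and expected cycle duration (s).

    The spectral peak of the scaled centroid speed within the physiological
    band.  Raises on a flat spectrum (no crawling signal).
    """
    _require_regular(track)
    if track.span < 10.0 - 2 * DT:
        raise ValueError("need >= 10 s of signal for spectral estimation")
    speed = scaled_speeds(track)["speed_center"].to_numpy()
    freqs, power = signal.periodogram(speed - speed.mean(), fs=1.0 / DT)
    in_band = (freqs >= band[0]) & (freqs <= band[1])
    peak = np.max(power[in_band]) if np.any(in_band) else 0.0
    # absolute floor: constant-speed tracks only carry float rounding noise
    if peak <= 1e-12:
        raise ValueError("flat speed spectrum: no dominant crawl frequency")
    f = float(freqs[in_band][np.argmax(power[in_band])])
    return f, 1.0 / f


def _local_minima(x: np.ndarray) -> np.ndarray:
    """Strict local minima; plateaus break at the leftmost sample."""
    n = x.size
    idx = []
    i = 1
    while i < n - 1:
        if x[i] < x[i - 1]:
            j = i
            while j + 1 < n and x[j + 1] == x[j]:
                j += 1
            if j + 1 < n and x[j + 1] > x[j]:
                idx.append(i)
            i = j + 1
        else:
            i += 1
    return np.array(idx, dtype=int)


def detect_strides(
    track: SpineTrack, annotation_freq: tuple[float, float] | None = None
) -> list[tuple[float, float]]:
    """Peristaltic strides: epochs between consecutive local speed minima
    whose contained maximum reaches 0.3 BL/s and whose duration lies in
    [0.7, 1.5] x the expected cycle.
    """
    _require_regular(track)
    f, cycle = annotation_freq or crawl_frequency(track)
    speed = scaled_speeds(track)["speed_center"].to_numpy()
    minima = _local_minima(speed)
    # the track edges delimit strides too: a rising start / falling end is
    # a boundary speed minimum
    if speed.size >= 2 and speed[0] < speed[1] and (minima.size == 0 or minima[0] != 0):
        minima = np.concatenate([[0], minima])
    last = speed.size - 1
    if speed.size >= 2 and speed[last] < speed[last - 1] and (
        minima.size == 0 or minima[-1] != last
    ):
        minima = np.concatenate([minima, [last]])
    strides = []
    for a, b in zip(minima[:-1], minima[1:]):
        dur = (b - a) * DT
        if not (0.7 * cycle - 1e-9 <= dur <= 1.5 * cycle + 1e-9):
            continue
        if np.max(speed[a : b + 1]) < STRIDE_SPEED_THRESHOLD:
            continue
        strides.append((float(track.times[a]), float(track.times[b])))
    return strides


def annotate_runs_pauses(
    track: SpineTrack, strides: list[tuple[float, float]] | None = None
) -> EpochAnnotation:
    """Merge consecutive strides into runs; find sub-threshold pauses.

    Runs join strides whose boundaries touch within one timestep.  Pauses
    are maximal stride-free epochs with scaled speed < 0.3 BL/s throughout.
    """
    _require_regular(track)
    f, cycle = crawl_frequency(track)
    if strides is None:
        strides = detect_strides(track, (f, cycle))
    runs: list[tuple[float, float]] = []
    for s in strides:
        if runs and s[0] - runs[-1][1] <= DT + 1e-9:
            runs[-1] = (runs[-1][0], s[1])
        else:
            runs.append(s)
    speed = scaled_speeds(track)["speed_center"].to_numpy()
    in_stride = np.zeros(track.n_samples, dtype=bool)
    for a, b in strides:
        in_stride[(track.times >= a - 1e-9) & (track.times <= b + 1e-9)] = True
    free = (~in_stride) & (speed < STRIDE_SPEED_THRESHOLD)
    pauses: list[tuple[float, float]] = []
    start = None
    for i, ok in enumerate(free):
        if ok and start is None:
            start = i
        elif not ok and start is not None:
            if i - start >= 2:
                pauses.append((float(track.times[start]), float(track.times[i - 1])))
            start = None
    if start is not None and track.n_samples - start >= 2:
        pauses.append((float(track.times[start]), float(track.times[-1])))
    return EpochAnnotation(
        strides=strides, runs=runs, pauses=pauses,
        crawl_frequency=f, cycle_duration=cycle,
    )
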