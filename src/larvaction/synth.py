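"""Synthetic larval tracking data with known ground truth.

Everything downstream of the tracker can be exercised without recordings:
11-point midline tracks animated from parameterized action templates
(peristaltic crawl, lateral head casts, static bends, hunch contraction,
stops, back-ups), cohorts whose action scripts are drawn from pre/post
stimulus probability tables, binomial group counts for the resampling
statistics, Gaussian point clouds standing in for low-dimensional behavior
embeddings, and fluorescence traces with a controlled failure fraction.

The templates are kinematic caricatures, not biomechanics: amplitudes are
chosen so that the pipeline's defined thresholds (0.3 BL/s stride/pause
speed, the 0.3–0.6 hunch length-change band, the 10% ΔF/F failure bar) are
meaningfully straddled.  Every generator is deterministic given its seed,
and every dataset carries its ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .actions import ACTIONS, ActionSequence
from .kinematics import DT, SpineTrack

__all__ = [
    "GenerationConfig",
    "gen_track",
    "gen_cohort",
    "gen_group_counts",
    "gen_point_clouds",
    "gen_fluorescence_traces",
]

#: fine internal timebase (s) from which observations are sampled
_FINE_DT = 0.02

#: startle-type actions: drawn once at stimulus onset, never re-entered,
#: so a cohort's cumulative post-stimulus probabilities equal the table
STARTLE_ACTIONS = ("hunch", "stop", "back_up")


def _default_pre_probs():
    return {"crawl": 0.70, "head_cast": 0.20, "static_bend": 0.10}


def _default_post_probs():
    return {"hunch": 0.35, "stop": 0.20, "back_up": 0.05, "head_cast": 0.25, "crawl": 0.15}


def _default_dwell():
    # mean bout durations (s) per action
    return {"crawl": 6.0, "head_cast": 2.0, "static_bend": 2.5,
            "hunch": 1.0, "stop": 2.0, "back_up": 1.5, "small": 1.0}


@dataclass
class GenerationConfig:
    """Study-design parameters of the synthetic tracking experiment.

    Defaults mirror the in-vivo protocol: 95 s tracks, air-puff at the 60th
    second for 30 s, ~4 mm third-instar larvae crawling at the dominant
    1.4 Hz peristaltic frequency, tracked at a jittery ~10 Hz.
    """

    seed: int
    n_larvae: int = 30
    duration: float = 95.0
    stimulus_onset: float = 60.0
    stimulus_duration: float = 30.0
    body_length_mean: float = 4.0  # mm
    body_length_sd: float = 0.3
    crawl_freq: float = 1.4  # Hz
    crawl_speed_amp: float = 0.4  # BL/s; peak speed = 2*amp
    peristalsis_amp: float = 0.10  # fractional length modulation while crawling
    cast_amp: float = 1.1  # rad, lateral head-sweep amplitude
    cast_freq: float = 0.8  # Hz
    bend_angle: float = 0.9  # rad, static-bend posture
    hunch_contraction: float = 0.45  # fractional length loss of a true hunch
    small_contraction: float = 0.10  # a "small" twitch fails the hunch bar
    backup_speed_amp: float = 0.25  # BL/s
    heading_drift_sd: float = 0.05  # rad/sqrt(s) random heading walk while crawling
    frame_interval_jitter: float = 0.20  # fractional jitter around 0.1 s sampling
    coord_noise_sd: float = 0.01  # mm additive tracking noise
    pre_probs: dict = field(default_factory=_default_pre_probs)
    post_probs: dict = field(default_factory=_default_post_probs)
    dwell_means: dict = field(default_factory=_default_dwell)

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for name, tab in (("pre_probs", self.pre_probs), ("post_probs", self.post_probs)):
            vals = np.array(list(tab.values()), dtype=float)
            if np.any(vals < 0) or not np.isclose(vals.sum(), 1.0):
                raise ValueError(f"{name} must be nonnegative and sum to 1, got {tab}")
            unknown = set(tab) - set(ACTIONS)
            if unknown:
                raise ValueError(f"{name} references unknown actions {unknown}")


def _anterior_weights():
    # how strongly each of the 10 segments (tail->head order) follows a bend
    w = np.zeros(10)
    w[6:] = [0.25, 0.5, 0.75, 1.0]
    return w


def _build_spine(base, heading, length, bend, retract):
    """Chain 10 segments tail->head; returns points head-first (11, 2).

    ``bend`` rotates anterior segments laterally; ``retract`` shortens the
    anterior four segments (head retraction during a hunch).
    """
    seg_len = np.full(10, length / 10.0)
    seg_len[6:] *= 1.0 - retract
    angles = heading + bend * _anterior_weights()
    pts = np.empty((11, 2))
    pts[0] = base
    for k in range(10):
        pts[k + 1] = pts[k] + seg_len[k] * np.array([np.cos(angles[k]), np.sin(angles[k])])
    return pts[::-1]  # head first


def _validate_script(script, duration):
    if not script:
        raise ValueError("empty script")
    script = sorted(script, key=lambda e: e[1])
    prev_end = 0.0
    for label, a, b in script:
        if label not in ACTIONS:
            raise ValueError(f"unknown action {label!r}")
        if a < prev_end - 1e-9:
            raise ValueError(f"overlapping script entries at t={a:.2f}")
        if b <= a:
            raise ValueError("script entries must have positive duration")
        prev_end = b
    if script[-1][2] < duration - 1e-9:
        raise ValueError("script does not cover the track duration")
    return script


def gen_track(
    config: GenerationConfig,
    script: list[tuple[str, float, float]],
    larva_id: str = "synthetic",
    rng: np.random.Generator | None = None,
) -> tuple[SpineTrack, ActionSequence]:
    """Animate one larva from a timed action script.

    Returns the irregularly sampled noisy :class:`SpineTrack` together with
    the ground-truth :class:`ActionSequence` on the regular 10 Hz grid.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    script = _validate_script(script, config.duration)
    L0 = max(float(rng.normal(config.body_length_mean, config.body_length_sd)), 1.0)

    t_fine = np.arange(0.0, config.duration + _FINE_DT / 2, _FINE_DT)
    n = t_fine.size
    coords = np.empty((n, 11, 2))
    heading = float(rng.uniform(0, 2 * np.pi))
    bend = 0.0
    prev_pts = None
    k_script = 0
    # translating actions anchor the centroid (so the commanded speed IS the
    # centroid speed); stationary actions anchor the stable rear point 9
    rear_idx = 8  # head-first index of the 9th midline point
    for i, t in enumerate(t_fine):
        while k_script + 1 < len(script) and t >= script[k_script][2] - 1e-9:
            k_script += 1
        label, a, _b = script[k_script]
        ph = t - a
        length, retract, v = L0, 0.0, 0.0
        translating = label in ("crawl", "back_up")
        if label == "crawl":
            v = config.crawl_speed_amp * (1 - np.cos(2 * np.pi * config.crawl_freq * ph))
            length = L0 * (1 + config.peristalsis_amp * np.sin(2 * np.pi * config.crawl_freq * ph))
            bend *= 0.9
            heading += config.heading_drift_sd * np.sqrt(_FINE_DT) * rng.standard_normal()
        elif label == "back_up":
            v = -config.backup_speed_amp * (1 - np.cos(2 * np.pi * config.crawl_freq * ph))
            length = L0 * (1 + 0.5 * config.peristalsis_amp * np.sin(2 * np.pi * config.crawl_freq * ph))
            bend *= 0.9
        elif label == "head_cast":
            bend = config.cast_amp * np.sin(2 * np.pi * config.cast_freq * ph)
        elif label == "static_bend":
            bend = config.bend_angle
        elif label == "hunch":
            dur = _b - a
            c = config.hunch_contraction * np.sin(np.pi * min(ph / dur, 1.0))
            length = L0 * (1 - c)
            retract = c  # the head pulls in harder than the rest of the body
        elif label == "small":
            dur = _b - a
            c = config.small_contraction * np.sin(np.pi * min(ph / dur, 1.0))
            length = L0 * (1 - c)
            retract = c
        elif label == "stop":
            bend *= 0.98
        pts = _build_spine(np.zeros(2), heading, length, bend, retract)
        anchor_now = pts.mean(axis=0) if translating else pts[rear_idx]
        if prev_pts is None:
            anchor_prev = anchor_now  # first frame: place at the origin
        else:
            anchor_prev = prev_pts.mean(axis=0) if translating else prev_pts[rear_idx]
        step = v * L0 * _FINE_DT * np.array([np.cos(heading), np.sin(heading)])
        pts = pts + (anchor_prev + step - anchor_now)
        coords[i] = pts
        prev_pts = pts

    # irregular observation times at ~10 Hz with fractional jitter
    intervals = rng.uniform(
        DT * (1 - config.frame_interval_jitter),
        DT * (1 + config.frame_interval_jitter),
        size=int(np.ceil(config.duration / (DT * (1 - config.frame_interval_jitter)))) + 2,
    )
    t_obs = np.concatenate([[0.0], np.cumsum(intervals)])
    t_obs = t_obs[t_obs <= config.duration]
    obs = np.empty((t_obs.size, 11, 2))
    for pt in range(11):
        for xy in range(2):
            obs[:, pt, xy] = np.interp(t_obs, t_fine, coords[:, pt, xy])
    obs += rng.normal(0.0, config.coord_noise_sd, size=obs.shape)
    track = SpineTrack(
        larva_id=larva_id, times=t_obs, midline=obs,
        stimulus_onset=config.stimulus_onset,
        stimulus_duration=config.stimulus_duration,
    )
    grid = np.round(np.arange(0.0, config.duration + DT / 2, DT), 6)
    labels = np.empty(grid.size, dtype=object)
    for label, a, b in script:
        labels[(grid >= a - 1e-9) & (grid < b - 1e-9)] = label
    labels[grid >= script[-1][1]] = script[-1][0]
    truth = ActionSequence(times=grid, labels=labels, larva_id=larva_id,
                           stimulus_onset=config.stimulus_onset)
    return track, truth


def _draw_script(config: GenerationConfig, rng) -> list[tuple[str, float, float]]:
    """Pre-stimulus repertoire until onset; one startle-table draw at onset;
    then the baseline repertoire again (startle actions excluded)."""
    def draw(table):
        names = list(table)
        probs = np.array([table[a] for a in names])
        return names[rng.choice(len(names), p=probs / probs.sum())]

    def dwell(action):
        m = config.dwell_means.get(action, 2.0)
        return float(np.clip(rng.exponential(m), 0.6, 3 * m))

    script = []
    t = 0.0
    while t < config.stimulus_onset:
        a = draw(config.pre_probs)
        d = min(dwell(a), config.stimulus_onset - t)
        script.append((a, t, t + d))
        t += d
    first = draw(config.post_probs)
    d = dwell(first)
    script.append((first, t, t + d))
    t += d
    sustained = {k: v for k, v in config.pre_probs.items() if k not in STARTLE_ACTIONS}
    while t < config.duration:
        a = draw(sustained)
        d = min(dwell(a), config.duration - t)
        script.append((a, t, t + d))
        t += d
    return script


def gen_cohort(
    config: GenerationConfig,
) -> tuple[list[SpineTrack], list[ActionSequence]]:
    """A cohort of larvae with scripts drawn from the probability tables.

    The action performed at stimulus onset is a single draw from
    ``post_probs`` and startle actions are never re-entered afterwards, so
    the ground-truth cumulative probability of e.g. a Hunch in the response
    window equals ``post_probs["hunch"]`` exactly.
    """
    rng = np.random.default_rng(config.seed)
    tracks, truths = [], []
    for i in range(config.n_larvae):
        script = _draw_script(config, rng)
        track, truth = gen_track(config, script, larva_id=f"larva_{i:03d}", rng=rng)
        tracks.append(track)
        truths.append(truth)
    return tracks, truths


def gen_group_counts(
    rates: dict[str, tuple[float, float]],
    n_per_group: int | dict[str, int],
    seed: int,
):
    """Binomial responder counts per group for the Θ/GLR test harnesses.

    ``rates`` maps group name to (post-window rate, baseline-window rate).
    Returns a dict of group -> GroupWindowCounts.
    """
    from .stats import GroupWindowCounts

    rng = np.random.default_rng(seed)
    out = {}
    for group, (r_post, r_base) in rates.items():
        if not (0 <= r_post <= 1 and 0 <= r_base <= 1):
            raise ValueError(f"rates for {group} must be in [0, 1]")
        n = n_per_group[group] if isinstance(n_per_group, dict) else n_per_group
        if n <= 0:
            raise ValueError("group size must be positive")
        out[group] = GroupWindowCounts(
            n_post=int(rng.binomial(n, r_post)), N_post=n,
            n_base=int(rng.binomial(n, r_base)), N_base=n,
        )
    return out


def gen_point_clouds(
    n: int, d: int = 25, shift: float = 0.0, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Paired isotropic Gaussian samples in d dimensions; the second cloud's
    mean is displaced by ``shift`` along the first coordinate."""
    if n < 1 or d < 1:
        raise ValueError("n and d must be >= 1")
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, d))
    Y = rng.standard_normal((n, d))
    Y[:, 0] += shift
    return X, Y


def gen_fluorescence_traces(
    n_trials: int,
    failure_fraction: float = 0.0,
    response_mean: float = 0.30,
    response_sd: float = 0.10,
    noise_sd: float = 0.01,
    fs: float = 10.0,
    seed: int = 0,
):
    """Stimulus-locked fluorescence traces: 5 s baseline, 5 s stimulus,
    5 s recovery, baseline fluorescence 1.0.

    A ``failure_fraction`` of trials get a sub-10% response amplitude and
    therefore count as failed by the ΔF/F rule; the rest draw their
    amplitude from a truncated normal comfortably above the bar.
    """
    from .stats import FluorescenceTrace

    if not 0 <= failure_fraction <= 1:
        raise ValueError("failure_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, 15.0, 1.0 / fs)
    stim = (t >= 5.0) & (t < 10.0)
    traces = []
    for _ in range(n_trials):
        if rng.uniform() < failure_fraction:
            amp = rng.uniform(0.0, 0.08)
        else:
            amp = max(float(rng.normal(response_mean, response_sd)), 0.13)
        F = 1.0 + rng.normal(0.0, noise_sd, size=t.size)
        F[stim] += amp
        traces.append(FluorescenceTrace(
            times=t, F=F, baseline_window=(0.0, 5.0), stimulus_window=(5.0, 10.0),
        ))
    return traces
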