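"""Behavioral statistics: action probabilities, the Θ resampling test, GLR
transition tests, MMD permutation tests, ΔF/F metrics and the preference
index.

The Θ estimator targets population-scale emergence of an action: for each
group, χ = p_post − p_base is the change in the fraction of larvae
performing the action after versus before the stimulus, and
Θ = χ(test) − χ(control) contrasts a test line against its control.
Because Θ accumulates events over a window it detects responses whose onset
is widely distributed in time.  Significance comes from resampling the four
counts under a pooled null.  Transition-probability changes use a
generalized likelihood-ratio (GLR) z statistic referred to χ²(1).
Distributional comparisons between groups of embedded behavior segments use
the unbiased maximum mean discrepancy (MMD) with a Gaussian kernel and a
permutation test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .actions import ACTIONS, ActionSequence
from .kinematics import DT, SpineTrack

logger = logging.getLogger(__name__)

__all__ = [
    "GroupWindowCounts",
    "TransitionCounts",
    "FluorescenceTrace",
    "ActionProbability",
    "action_probabilities",
    "chi_estimator",
    "theta_statistic",
    "theta_test",
    "transition_matrix",
    "glr_transition_test",
    "segment_window_vectors",
    "mmd_statistic",
    "mmd_permutation_test",
    "dff_metrics",
    "cohort_failure_rate",
    "preference_index",
]


@dataclass(frozen=True)
class GroupWindowCounts:
    """Responder/total counts for one group in the post and baseline windows."""

    n_post: int
    N_post: int
    n_base: int
    N_base: int

    def __post_init__(self):
        for n, N in ((self.n_post, self.N_post), (self.n_base, self.N_base)):
            if not 0 <= n <= N:
                raise ValueError(f"need 0 <= n <= N, got n={n}, N={N}")

    @property
    def p_post(self) -> float:
        if self.N_post == 0:
            raise ZeroDivisionError("empty post window")
        return self.n_post / self.N_post

    @property
    def p_base(self) -> float:
        if self.N_base == 0:
            raise ZeroDivisionError("empty baseline window")
        return self.n_base / self.N_base


@dataclass
class TransitionCounts:
    """Action-to-action transition counts over a post-onset window."""

    counts: pd.DataFrame
    window: float
    n_transitions: int
    fallback_used: bool


@dataclass
class FluorescenceTrace:
    """Raw fluorescence with its baseline and stimulus windows (s)."""

    times: np.ndarray
    F: np.ndarray
    baseline_window: tuple[float, float]
    stimulus_window: tuple[float, float]


@dataclass
class ActionProbability:
    value: float
    n_responders: int
    n_qualifying: int
    mode: str
    window: tuple[float, float]


def _covers(seq: ActionSequence, window: tuple[float, float]) -> bool:
    a, b = window
    return seq.times[0] <= a + 1e-9 and seq.times[-1] >= b - DT - 1e-9


def _occupancy(seq: ActionSequence, action: str, window: tuple[float, float]) -> float:
    a, b = window
    m = (seq.times >= a - 1e-9) & (seq.times < b - 1e-9)
    return float(np.mean(seq.labels[m] == action))


def action_probabilities(
    sequences: list[ActionSequence],
    action: str,
    mode: str = "cumulative",
    post_window: tuple[float, float] | None = None,
    baseline_window: tuple[float, float] | None = None,
) -> ActionProbability:
    """Population probability of an action around stimulus onset.

    ``cumulative``: fraction of larvae showing the action at least once in
    the post window (default [onset, onset+5) s) — used for the startle
    actions Stop, Hunch, Back-up.  ``corrected_mean``: mean instantaneous
    occupancy over the post window minus the mean over the 30–50 s
    pre-stimulus baseline — used for ongoing actions (Crawl, Head Cast).
    Only larvae tracked through the entire window enter the denominator.
    """
    if action not in ACTIONS:
        raise ValueError(f"unknown action {action!r}")
    if mode not in ("cumulative", "corrected_mean"):
        raise ValueError(f"unknown mode {mode!r}")
    if not sequences:
        raise ValueError("no sequences given")
    onset = sequences[0].stimulus_onset
    post = post_window or (onset, onset + 5.0)
    base = baseline_window or (onset - 30.0, onset - 10.0)
    qualifying = [s for s in sequences if _covers(s, post)]
    if mode == "corrected_mean":
        qualifying = [s for s in qualifying if _covers(s, base)]
    if not qualifying:
        raise ValueError(
            f"no larvae tracked through the whole window {post}; denominator empty"
        )
    if mode == "cumulative":
        hits = sum(
            bool(np.any(s.labels[(s.times >= post[0] - 1e-9) & (s.times < post[1] - 1e-9)]
                        == action))
            for s in qualifying
        )
        return ActionProbability(hits / len(qualifying), hits, len(qualifying),
                                 mode, post)
    vals = [_occupancy(s, action, post) - _occupancy(s, action, base) for s in qualifying]
    return ActionProbability(float(np.mean(vals)), -1, len(qualifying), mode, post)


def chi_estimator(counts: GroupWindowCounts) -> float:
    """χ = p_post − p_base, the stimulus-induced probability change, in [−1, 1]."""
    return counts.p_post - counts.p_base


def theta_statistic(test: GroupWindowCounts, control: GroupWindowCounts) -> float:
    """Θ = χ(test) − χ(control), in [−2, 2] in principle but [−1, 1] for the
    startle actions the estimator is designed for; antisymmetric in its
    arguments."""
    return chi_estimator(test) - chi_estimator(control)


def theta_test(
    test: GroupWindowCounts,
    control: GroupWindowCounts,
    n_sim: int = 1000,
    seed: int = 0,
    scheme: str = "pooled",
    alternative: str = "two-sided",
) -> dict:
    """Resampling test of H0: Θ = 0.

    Under ``scheme="pooled"`` the four counts are redrawn as binomials with
    the per-window proportions pooled across test and control (the null of
    no group difference), Θ* is recomputed per replicate, and the add-one
    p-value is the exceedance fraction.  ``scheme="literal"`` instead
    resamples each proportion with a single hypergeometric draw per group
    and window — the scheme as printed in the original description, kept
    for comparison; with one draw it reduces to Bernoulli sampling of the
    observed proportions and is far noisier.
    """
    if n_sim < 100:
        raise ValueError("n_sim must be >= 100")
    rng = np.random.default_rng(seed)
    theta_obs = theta_statistic(test, control)
    thetas = np.empty(n_sim)
    if scheme == "pooled":
        p_post = (test.n_post + control.n_post) / (test.N_post + control.N_post)
        p_base = (test.n_base + control.n_base) / (test.N_base + control.N_base)
        chi_t = (rng.binomial(test.N_post, p_post, n_sim) / test.N_post
                 - rng.binomial(test.N_base, p_base, n_sim) / test.N_base)
        chi_c = (rng.binomial(control.N_post, p_post, n_sim) / control.N_post
                 - rng.binomial(control.N_base, p_base, n_sim) / control.N_base)
        thetas = chi_t - chi_c
    elif scheme == "literal":
        for k in range(n_sim):
            def one(n, N):
                return float(rng.hypergeometric(max(n, 0), N - n, 1))
            chi_t = one(test.n_post, test.N_post) - one(test.n_base, test.N_base)
            chi_c = one(control.n_post, control.N_post) - one(control.n_base, control.N_base)
            thetas[k] = chi_t - chi_c
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    if alternative == "two-sided":
        exceed = np.abs(thetas) >= abs(theta_obs) - 1e-12
    elif alternative == "greater":
        exceed = thetas >= theta_obs - 1e-12
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    p = (1 + int(exceed.sum())) / (1 + n_sim)
    return {
        "theta": theta_obs, "p_value": p, "null_sample": thetas,
        "n_sim": n_sim, "seed": seed, "scheme": scheme, "alternative": alternative,
    }


def transition_matrix(
    sequences: list[ActionSequence],
    window: float = 2.0,
    fallback_window: float = 10.0,
    min_transitions: int = 100,
) -> TransitionCounts:
    """Action→action transition counts just after stimulus onset.

    Uses a short window to capture the immediate response; if fewer than
    ``min_transitions`` transitions land in it the longer fallback window
    is used instead (recorded in the result).
    """

    def count(win: float) -> pd.DataFrame:
        mat = pd.DataFrame(0, index=list(ACTIONS), columns=list(ACTIONS), dtype=int)
        for s in sequences:
            if not _covers(s, (s.stimulus_onset, s.stimulus_onset + win)):
                continue
            m = (s.times >= s.stimulus_onset - 1e-9) & (s.times < s.stimulus_onset + win - 1e-9)
            idx = np.flatnonzero(m)
            # transitions INTO the window count: the switch from the
            # baseline action to the onset response is the key event
            for i in idx:
                if i == 0:
                    continue
                prev, nxt = s.labels[i - 1], s.labels[i]
                if prev != nxt:
                    mat.loc[str(prev), str(nxt)] += 1
        return mat

    mat = count(window)
    total = int(mat.to_numpy().sum())
    fallback = total < min_transitions
    if fallback:
        logger.info("only %d transitions in %.0f s window; falling back to %.0f s",
                    total, window, fallback_window)
        mat = count(fallback_window)
        total = int(mat.to_numpy().sum())
        window = fallback_window
    return TransitionCounts(counts=mat, window=window, n_transitions=total,
                            fallback_used=fallback)


def glr_transition_test(n_m: int, N_m: int, n_0: int, N_0: int) -> tuple[float, float]:
    """Generalized likelihood-ratio test for two binomial proportions.

    z = −2 log [ B(π, N_m, n_m) B(π, N_0, n_0) / (B(π_m, N_m, n_m) B(π_0, N_0, n_0)) ]
    with the pooled proportion π = (n_m + n_0)/(N_m + N_0) and the unpooled
    MLEs π_m, π_0; computed in log space.  p comes from χ² with 1 df.
    """
    for n, N in ((n_m, N_m), (n_0, N_0)):
        if N <= 0:
            raise ValueError("both groups must be non-empty")
        if not 0 <= n <= N:
            raise ValueError(f"need 0 <= n <= N, got n={n}, N={N}")
    pi = (n_m + n_0) / (N_m + N_0)
    lp_pooled = sps.binom.logpmf(n_m, N_m, pi) + sps.binom.logpmf(n_0, N_0, pi)
    lp_free = (sps.binom.logpmf(n_m, N_m, n_m / N_m)
               + sps.binom.logpmf(n_0, N_0, n_0 / N_0))
    z = float(-2.0 * (lp_pooled - lp_free))
    z = 0.0 if z <= 0.0 else z  # avoid -0.0 from rounding at equality
    p = float(sps.chi2.sf(z, df=1))
    return z, p


#: 1-based midline indices of the reduced 5-point spine used for embeddings
REDUCED_SPINE = (1, 3, 6, 9, 11)


def segment_window_vectors(
    track: SpineTrack,
    centers: np.ndarray | None = None,
    window: float = 2.0,
) -> list[np.ndarray]:
    """2-second spine segments vectorized for embedding comparisons.

    For each center time a ``window``-long clip of the 5-point reduced
    spine at 10 Hz is flattened to 5 points × 2 coords × 20 frames = 200
    values.  Default centers: 5 evenly spaced points in the 60–65 s window
    just after stimulus onset.  Centers whose window falls outside the
    track are skipped with a log message.
    """
    if not track.regular:
        raise ValueError("track must be preprocessed to the regular 10 Hz grid")
    if centers is None:
        centers = np.linspace(track.stimulus_onset, track.stimulus_onset + 5.0, 5)
    n_frames = int(round(window / DT))
    idx_pts = [i - 1 for i in REDUCED_SPINE]
    out = []
    for c in np.asarray(centers, float):
        start = c - window / 2.0
        i0 = int(round((start - track.times[0]) / DT))
        if i0 < 0 or i0 + n_frames > track.n_samples:
            logger.info("segment at %.2f s outside track %s; skipped", c, track.larva_id)
            continue
        clip = track.midline[i0 : i0 + n_frames][:, idx_pts, :]  # (20, 5, 2)
        out.append(clip.reshape(-1).copy())
    return out


def _gaussian_gram(A: np.ndarray, B: np.ndarray, sigma: float, convention: str) -> np.ndarray:
    d2 = np.sum(A**2, 1)[:, None] + np.sum(B**2, 1)[None, :] - 2 * A @ B.T
    d2 = np.maximum(d2, 0.0)
    denom = 2.0 * sigma**2 if convention == "two_sigma_sq" else sigma
    return np.exp(-d2 / denom)


def mmd_statistic(
    X: np.ndarray, Y: np.ndarray, sigma: float = 2.0, convention: str = "two_sigma_sq"
) -> float:
    """Unbiased squared-MMD U-statistic with a Gaussian kernel of width σ.

    k(x, y) = exp(−‖x−y‖² / (2σ²)) by default; ``convention="width"``
    puts the width directly in the denominator.  The unbiased estimate can
    be slightly negative for identical samples.
    """
    X, Y = np.asarray(X, float), np.asarray(Y, float)
    if X.ndim != 2 or Y.ndim != 2 or X.shape[1] != Y.shape[1]:
        raise ValueError("X and Y must be 2-D with a shared dimension")
    n, m = X.shape[0], Y.shape[0]
    if n < 2 or m < 2:
        raise ValueError("need at least 2 points per sample")
    Kxx = _gaussian_gram(X, X, sigma, convention)
    Kyy = _gaussian_gram(Y, Y, sigma, convention)
    Kxy = _gaussian_gram(X, Y, sigma, convention)
    sx = (Kxx.sum() - np.trace(Kxx)) / (n * (n - 1))
    sy = (Kyy.sum() - np.trace(Kyy)) / (m * (m - 1))
    return float(sx + sy - 2.0 * Kxy.mean())


def mmd_permutation_test(
    X: np.ndarray,
    Y: np.ndarray,
    sigma: float = 2.0,
    B: int = 1000,
    seed: int = 0,
    bonferroni_m: int = 1,
    convention: str = "two_sigma_sq",
) -> dict:
    """Permutation test on the MMD with optional Bonferroni adjustment.

    Group labels are permuted over the pooled sample ``B`` times; the
    add-one p-value is the exceedance fraction, and the adjusted p-value is
    min(1, m·p) for ``bonferroni_m`` planned comparisons.
    """
    if B < 100:
        raise ValueError("B must be >= 100")
    X, Y = np.asarray(X, float), np.asarray(Y, float)
    obs = mmd_statistic(X, Y, sigma, convention)
    pooled = np.vstack([X, Y])
    n = X.shape[0]
    rng = np.random.default_rng(seed)
    null = np.empty(B)
    for b in range(B):
        perm = rng.permutation(pooled.shape[0])
        null[b] = mmd_statistic(pooled[perm[:n]], pooled[perm[n:]], sigma, convention)
    p = (1 + int(np.sum(null >= obs - 1e-15))) / (1 + B)
    return {
        "mmd": obs, "p_value": p, "p_adjusted": min(1.0, bonferroni_m * p),
        "null_sample": null, "B": B, "seed": seed, "sigma": sigma,
        "bonferroni_m": bonferroni_m,
    }


def dff_metrics(trace: FluorescenceTrace, failure_bar: float = 0.10) -> dict:
    """ΔF/F₀ series and the stimulus-window response for one trial.

    F₀ is the mean fluorescence in the baseline window; the trial fails
    when the stimulus-averaged ΔF/F₀ does not exceed ``failure_bar``.
    """
    t, F = np.asarray(trace.times, float), np.asarray(trace.F, float)
    a0, b0 = trace.baseline_window
    a1, b1 = trace.stimulus_window
    if not (t[0] <= a0 < b0 <= t[-1] + 1e-9 and t[0] <= a1 < b1 <= t[-1] + 1e-9):
        raise ValueError("windows must lie within the trace")
    F0 = float(np.mean(F[(t >= a0) & (t < b0)]))
    if F0 <= 0:
        raise ValueError(f"baseline fluorescence must be positive, got F0={F0:g}")
    dff = (F - F0) / F0
    stim_mean = float(np.mean(dff[(t >= a1) & (t < b1)]))
    return {"dff": dff, "stimulus_mean": stim_mean, "failed": stim_mean <= failure_bar,
            "F0": F0}


def cohort_failure_rate(traces: list[FluorescenceTrace], failure_bar: float = 0.10) -> float:
    """Fraction of trials whose stimulus-averaged ΔF/F₀ fails the bar."""
    if not traces:
        raise ValueError("no traces")
    return float(np.mean([dff_metrics(tr, failure_bar)["failed"] for tr in traces]))


def preference_index(Ns: int, Na: int, Ntot: int) -> float:
    """Place-preference index PI = (Ns − Na)/Ntot ∈ [−1, 1]; larvae on the
    boundary are excluded from Ns and Na but still count in Ntot."""
    if Ntot <= 0:
        raise ValueError("Ntot must be positive")
    if Ns < 0 or Na < 0 or Ns + Na > Ntot:
        raise ValueError("need Ns + Na <= Ntot with nonnegative counts")
    return (Ns - Na) / Ntot
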