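"""Frame classification and rule-based cleanup of larval action labels.

Actions are mutually exclusive per timestep: crawl, head_cast, static_bend,
hunch, stop, back_up, small.  A bank of ten random forests votes on
windowed kinematic features; the raw label stream is then regularized
(implausibly short bouts removed), and domain rules enforce at most one
post-stimulus Hunch, reject weak Hunches by their length contraction, and
split Bends into Static Bends versus Head Casts by how much the body
actually translates.
"""

from __future__ import annotations

import hashlib
import logging
import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import train_test_split

logger = logging.getLogger(__name__)

__all__ = [
    "ACTIONS",
    "VOTE_PRIORITY",
    "ActionSequence",
    "ClassifierBundle",
    "train_frame_classifier",
    "classify_frames",
    "regularize",
    "apply_hunch_rules",
    "split_bend_types",
]

ACTIONS = ("crawl", "head_cast", "static_bend", "hunch", "stop", "back_up", "small")

#: tie-break order for classifier votes: rarer, more stereotyped classes win
VOTE_PRIORITY = ("hunch", "back_up", "stop", "static_bend", "head_cast", "crawl", "small", "bend")


@dataclass
class ActionSequence:
    """Per-timestep action labels on the regular 10 Hz grid.

    ``provenance`` tracks, per timestep, whether the label is the raw
    classifier output or was produced by a cleanup rule
    (raw / reassigned / expanded).
    """

    times: np.ndarray
    labels: np.ndarray
    larva_id: str = ""
    stimulus_onset: float = 60.0
    provenance: np.ndarray | None = None

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.labels = np.asarray(self.labels, dtype=object)
        if self.times.shape != self.labels.shape:
            raise ValueError("times and labels must align")
        if self.provenance is None:
            self.provenance = np.full(self.times.shape, "raw", dtype=object)

    def intervals(self) -> list[tuple[str, float, float, str]]:
        """Maximal constant-label intervals as (label, t_start, t_end, provenance)."""
        out = []
        for a, b in _runs(self.labels):
            prov = "raw"
            seg = set(self.provenance[a:b])
            if "expanded" in seg:
                prov = "expanded"
            elif "reassigned" in seg:
                prov = "reassigned"
            out.append((str(self.labels[a]), float(self.times[a]), float(self.times[b - 1]), prov))
        return out

    def copy(self) -> "ActionSequence":
        return ActionSequence(
            times=self.times.copy(), labels=self.labels.copy(),
            larva_id=self.larva_id, stimulus_onset=self.stimulus_onset,
            provenance=self.provenance.copy(),
        )


def _runs(labels: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, stop) index ranges of constant label."""
    out = []
    n = labels.size
    a = 0
    for i in range(1, n + 1):
        if i == n or labels[i] != labels[a]:
            out.append((a, i))
            a = i
    return out


@dataclass
class ClassifierBundle:
    """Ensemble of ten frame classifiers with majority-vote prediction."""

    members: list
    classes: tuple[str, ...]
    per_class_accuracy: dict[str, float]
    feature_dim: int
    seed: int
    fingerprint: str


def _fingerprint(X: np.ndarray, y: np.ndarray) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(X).tobytes())
    h.update("|".join(map(str, y)).encode())
    return h.hexdigest()[:16]


def train_frame_classifier(
    windows: np.ndarray,
    labels,
    seed: int = 0,
    n_members: int = 10,
    n_estimators: int = 40,
    holdout: float = 0.25,
) -> ClassifierBundle:
    """Train the ten-forest voting ensemble on windowed feature vectors.

    Each member is a random forest with balanced class weights fitted to a
    bootstrap resample of the training split; per-class accuracy (recall) is
    measured on a stratified held-out split.  Deterministic given ``seed``.
    """
    X = np.asarray(windows, dtype=float)
    y = np.asarray(labels, dtype=object)
    if X.ndim != 2 or X.shape[0] != y.size:
        raise ValueError("windows must be (n, d) aligned with labels")
    classes = tuple(sorted(set(map(str, y))))
    if len(classes) < 2:
        raise ValueError("need at least 2 classes to train")
    counts = {c: int(np.sum(y == c)) for c in classes}
    if min(counts.values()) < 4:
        warnings.warn(f"very few examples for some classes: {counts}")
    rng = np.random.default_rng(seed)
    X_tr, X_te, y_tr, y_te = train_test_split(
        X, y, test_size=holdout, stratify=y, random_state=seed
    )
    members = []
    for _ in range(n_members):
        idx = rng.integers(0, len(X_tr), size=len(X_tr))
        clf = RandomForestClassifier(
            n_estimators=n_estimators,
            class_weight="balanced",
            random_state=int(rng.integers(0, 2**31 - 1)),
            n_jobs=1,
        )
        clf.fit(X_tr[idx], y_tr[idx])
        members.append(clf)
    bundle = ClassifierBundle(
        members=members,
        classes=classes,
        per_class_accuracy={},
        feature_dim=X.shape[1],
        seed=seed,
        fingerprint=_fingerprint(X, y),
    )
    pred = _vote(bundle, X_te)
    acc = {}
    for c in classes:
        mask = y_te == c
        if mask.any():
            acc[c] = float(np.mean(pred[mask] == c))
    bundle.per_class_accuracy = acc
    logger.info("per-class held-out accuracy: %s", acc)
    return bundle


def _vote(bundle: ClassifierBundle, X: np.ndarray) -> np.ndarray:
    votes = np.stack([m.predict(X) for m in bundle.members])  # (members, n)
    prio = {c: i for i, c in enumerate(VOTE_PRIORITY)}
    out = np.empty(X.shape[0], dtype=object)
    for j in range(X.shape[0]):
        vals, cnt = np.unique(votes[:, j].astype(str), return_counts=True)
        best = cnt.max()
        tied = [v for v, c in zip(vals, cnt) if c == best]
        out[j] = min(tied, key=lambda v: prio.get(v, len(prio)))
    return out


def classify_frames(
    bundle: ClassifierBundle,
    windows: np.ndarray,
    times: np.ndarray,
    larva_id: str = "",
    stimulus_onset: float = 60.0,
) -> ActionSequence:
    """Majority vote of the ensemble per timestep; ties break by the fixed
    class priority (rarer classes win)."""
    X = np.asarray(windows, dtype=float)
    if X.ndim != 2 or X.shape[1] != bundle.feature_dim:
        raise ValueError(
            f"feature layout mismatch: got {X.shape[1]} dims, bundle expects {bundle.feature_dim}"
        )
    labels = _vote(bundle, X)
    return ActionSequence(times=np.asarray(times, float), labels=labels,
                          larva_id=larva_id, stimulus_onset=stimulus_onset)


def windowed_features(track):
    """Per-frame feature table and its stacked window vectors for a
    preprocessed track."""
    from .kinematics import compute_features, feature_window

    feats = compute_features(track)
    return feats, feature_window(feats)


def build_training_set(tracks, truths, pure_only: bool = True, half_window: int = 3):
    """Align ground-truth labels with windowed feature vectors.

    Both the feature grid and the truth grid start at t=0 with the same
    0.1 s step, so alignment is positional.  With ``pure_only`` (the
    default) frames whose 7-step window straddles a bout boundary are
    dropped: their window mixes two actions, so no single frame label
    describes them — the same reason hand-curated tags come from bout
    interiors.  Returns (X, y) ready for :func:`train_frame_classifier`.
    """
    X, y = [], []
    for track, truth in zip(tracks, truths):
        feats, W = windowed_features(track)
        n = min(len(feats), truth.labels.size)
        labels = truth.labels[:n]
        keep = np.ones(n, dtype=bool)
        if pure_only:
            for i in range(n):
                lo, hi = max(0, i - half_window), min(n, i + half_window + 1)
                keep[i] = all(l == labels[i] for l in labels[lo:hi])
        X.append(W[:n][keep])
        y.append(labels[keep])
    return np.vstack(X), np.concatenate(y)


def _reassign_label(labels, runs, k) -> str:
    """Label adopted by a too-short bout: the flanking label if both sides
    agree, else the label of the longer neighboring bout."""
    a, _ = runs[k]
    left = runs[k - 1] if k > 0 else None
    right = runs[k + 1] if k + 1 < len(runs) else None
    if left is None and right is None:
        return str(labels[a])
    if left is None:
        return str(labels[right[0]])
    if right is None:
        return str(labels[left[0]])
    l_lab, r_lab = str(labels[left[0]]), str(labels[right[0]])
    if l_lab == r_lab:
        return l_lab
    l_len, r_len = left[1] - left[0], right[1] - right[0]
    return l_lab if l_len >= r_len else r_lab


def regularize(seq: ActionSequence, min_steps: int = 3, expand_steps: int = 5) -> ActionSequence:
    """Remove biologically implausible sub-0.3 s bouts.

    Bouts of exactly 2 steps are expanded by 5 steps on each side
    (overwriting their neighbors); remaining bouts shorter than 3 steps are
    absorbed into a neighbor chosen by the flanking-context rule.  The
    output is idempotent under a second application.
    """
    out = seq.copy()
    labels, prov = out.labels, out.provenance
    n = labels.size
    # pass 1: expand 2-step bouts
    for a, b in _runs(labels):
        if b - a == 2 and prov[a] != "expanded":
            lo, hi = max(0, a - expand_steps), min(n, b + expand_steps)
            lab = labels[a]
            labels[lo:hi] = lab
            prov[lo:hi] = "expanded"
    # pass 2: absorb remaining short bouts
    for _ in range(n):
        runs = _runs(labels)
        short = [k for k, (a, b) in enumerate(runs)
                 if b - a < min_steps and not np.all(prov[a:b] == "expanded")]
        if not short or len(runs) == 1:
            break
        k = short[0]
        a, b = runs[k]
        labels[a:b] = _reassign_label(labels, runs, k)
        prov[a:b] = "reassigned"
    return out


def effective_length_change(length: np.ndarray, interval: slice, baseline: float) -> float:
    """Fractional body contraction during a bout:
    (baseline median length - minimum length in the bout) / baseline."""
    return float((baseline - np.min(length[interval])) / baseline)


def apply_hunch_rules(
    seq: ActionSequence,
    length: np.ndarray,
    line_threshold: float = 0.3,
) -> ActionSequence:
    """Enforce the post-stimulus Hunch rules.

    Larvae hunch at most once, at stimulus onset: any later post-stimulus
    Hunch bout is relabeled head_cast.  The surviving Hunch must contract
    the body by at least the line-specific threshold of its pre-stimulus
    median length, else it is relabeled small.
    """
    if not 0.3 <= line_threshold <= 0.6:
        warnings.warn(
            f"line_threshold {line_threshold} outside the usual [0.3, 0.6] range"
        )
    length = np.asarray(length, dtype=float)
    if length.shape != seq.times.shape:
        raise ValueError("length series must align with the label grid")
    out = seq.copy()
    labels, prov = out.labels, out.provenance
    pre = seq.times < seq.stimulus_onset
    if not pre.any():
        raise ValueError("no pre-stimulus data to compute the baseline length")
    baseline = float(np.median(length[pre]))
    seen_hunch = False
    for a, b in _runs(labels):
        if labels[a] != "hunch" or seq.times[a] < seq.stimulus_onset:
            continue
        if seen_hunch:
            labels[a:b] = "head_cast"
            prov[a:b] = "reassigned"
            continue
        seen_hunch = True
        if effective_length_change(length, slice(a, b), baseline) < line_threshold:
            labels[a:b] = "small"
            prov[a:b] = "reassigned"
    return out


def split_bend_types(
    seq: ActionSequence,
    motion_speed: np.ndarray,
    head_speed: np.ndarray,
    P: float = 0.75,
    p: float = 0.5,
    baseline_window: tuple[float, float] | None = None,
) -> ActionSequence:
    """Split generic Bend bouts into Static Bend versus Head Cast.

    A bout labeled ``bend`` becomes static_bend iff at least a fraction P of
    its timesteps have scaled motion (centroid) speed below p times the
    larva's mean pre-stimulus head speed (boundary inclusive); otherwise it
    is a head_cast.  P and p are line-specific calibration constants.
    """
    motion_speed = np.asarray(motion_speed, float)
    head_speed = np.asarray(head_speed, float)
    if motion_speed.shape != seq.times.shape or head_speed.shape != seq.times.shape:
        raise ValueError("speed series must align with the label grid")
    if baseline_window is None:
        baseline_window = (seq.times[0], seq.stimulus_onset)
    base_mask = (seq.times >= baseline_window[0]) & (seq.times < baseline_window[1])
    if not base_mask.any():
        raise ValueError("no pre-stimulus data to compute the baseline head speed")
    baseline_head = float(np.nanmean(head_speed[base_mask]))
    out = seq.copy()
    labels, prov = out.labels, out.provenance
    for a, b in _runs(labels):
        if labels[a] != "bend":
            continue
        frac = float(np.mean(motion_speed[a:b] < p * baseline_head))
        new = "static_bend" if frac >= P else "head_cast"
        labels[a:b] = new
        prov[a:b] = "reassigned"
    return out
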