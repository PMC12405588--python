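"""End-to-end model and pipeline studies.

Each function runs one self-contained computational experiment — a phase
scan of the circuit, a silencing comparison, a statistical calibration, or
a synthetic-cohort annotation benchmark — and returns a plain dict of the
quantities it measured.  These are the studies behind the package's
headline claims; the problem sizes default to desk-scale settings that a
single CPU handles in minutes.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as sps

from . import circuit as circ
from . import kinematics as kin
from . import actions as act
from . import stats as lst
from . import synth

__all__ = [
    "bistability_scan",
    "sucrose_threshold_shift",
    "threshold_monotonicity",
    "silencing_study",
    "solver_oracle_check",
    "theta_calibration",
    "glr_null_uniformity",
    "mmd_calibration",
    "kinematics_benchmarks",
    "annotation_benchmark",
]

#: w_iLNa neighborhood containing the coactive/monoactive transition for all
#: studied neuromodulation settings (the full scanned range is [0.5, 1.5];
#: outside this window every cell is far from the boundary)
TRANSITION_WINDOW = (0.78, 0.90)


def bistability_scan(seed: int = 0, n_w: int = 21, variant: str = "fed") -> dict:
    """Scan w_iLNa over [0.5, 1.5] and classify steady states two ways.

    Returns the k-means labels, the scalar-ratio labels, their agreement
    fraction, and the cluster centers (coactive first).
    """
    w_grid = np.linspace(0.5, 1.5, n_w)
    spec = circ.build_circuit(variant)
    ensemble = [circ.steady_state(spec.with_params(w_ilna=float(w))) for w in w_grid]
    km_labels, centers = circ.label_outcomes(ensemble, seed=seed)
    ratio_labels = [r.label for r in ensemble]
    agree = float(np.mean([a == b for a, b in zip(km_labels, ratio_labels)]))
    return {
        "w_grid": w_grid,
        "kmeans_labels": km_labels,
        "ratio_labels": ratio_labels,
        "agreement": agree,
        "centers": centers,
        "n_clusters_seen": len(set(km_labels)),
        "b1b2": np.array([[r.b1, r.b2] for r in ensemble]),
    }


def _threshold(variant_or_spec, mod_param: str, mod_value: float, dw: float = 0.01) -> float:
    base = (circ.build_circuit(variant_or_spec)
            if isinstance(variant_or_spec, str) else variant_or_spec)
    w = np.round(np.arange(TRANSITION_WINDOW[0], TRANSITION_WINDOW[1] + dw / 2, dw), 6)
    pd_ = circ.phase_diagram(base, w, mod_param, [mod_value])
    return float(pd_.thresholds[0])


def sucrose_threshold_shift(dw: float = 0.01) -> dict:
    """Transition threshold in w_iLNa: fed versus the combined sucrose model."""
    fed = _threshold("fed", "i_Hb", 0.0, dw)
    sucrose = _threshold(circ.build_circuit("sucrose_combined"), "rmax_iLNa", 18.0, dw)
    return {"fed_threshold": fed, "sucrose_threshold": sucrose,
            "shift": sucrose - fed}


def threshold_monotonicity(
    rmax_values=(17.0, 18.0, 19.0, 20.0), ihb_values=(0.0, 5.0, 10.0), dw: float = 0.01
) -> dict:
    """Thresholds across the two neuromodulation axes (fed backbone)."""
    base = circ.build_circuit("fed")
    w = np.round(np.arange(TRANSITION_WINDOW[0], TRANSITION_WINDOW[1] + dw / 2, dw), 6)
    pd_rmax = circ.phase_diagram(base, w, "rmax_iLNa", list(rmax_values))
    pd_ihb = circ.phase_diagram(base, w, "i_Hb", list(ihb_values))
    return {
        "rmax_values": np.asarray(rmax_values),
        "rmax_thresholds": pd_rmax.thresholds,
        "ihb_values": np.asarray(ihb_values),
        "ihb_thresholds": pd_ihb.thresholds,
    }


def silencing_study(
    w_grid=None, duration: float = 500.0
) -> dict:
    """Silencing predictions aggregated over the transition neighborhood.

    For each variant, sums the readout's stimulated-epoch integral excess
    (silenced minus baseline) across the w grid, for Hb->iLNa and
    iLNa->Hb silencing.
    """
    if w_grid is None:
        w_grid = np.round(np.arange(0.75, 0.901, 0.01), 6)
    out = {}
    for variant in ("fed", "sucrose_combined"):
        spec0 = circ.build_circuit(variant)
        for target, readout in (("Hb", "iLNa"), ("iLNa", "Hb")):
            excesses = []
            for w in w_grid:
                res = circ.silencing_effect(
                    spec0.with_params(w_ilna=float(w)), target, readout, duration
                )
                excesses.append(res.excess)
            out[f"{variant}:{target}->{readout}"] = {
                "w_grid": np.asarray(w_grid),
                "excess": np.asarray(excesses),
                "total_excess": float(np.sum(excesses)),
            }
    return out


def _random_spec(rng) -> circ.CircuitSpec:
    """A random valid parameterization around the published one."""
    return circ.build_circuit("fed").with_params(
        tau=np.concatenate([[1.0], rng.uniform(20, 50, 6)]),
        V0=np.concatenate([[0.0], rng.uniform(10, 30, 6)]),
        rmax=rng.uniform(15, 25, 7),
        tonic_input=rng.uniform(0, 5, 7) * rng.integers(0, 2, 7),
        k_ex=float(rng.uniform(1.5, 3.5)),
        w_ilna=float(rng.uniform(0.5, 1.5)),
        w_ilnb=float(rng.uniform(1.5, 2.5)),
        stimulus_amplitude=float(rng.uniform(30, 80)),
    )


def solver_oracle_check(seed: int = 0, n_specs: int = 5, duration: float = 50.0) -> dict:
    """Adaptive LSODA versus fixed-step explicit Euler (dt=1e-3) at t_end.

    Relative error is measured on the full 7-rate vector at the end time;
    positivity is checked over the whole adaptive trajectory.
    """
    rng = np.random.default_rng(seed)
    max_rel = 0.0
    min_rate = np.inf
    for _ in range(n_specs):
        spec = _random_spec(rng)
        a = circ.integrate(spec, duration, stimulus_on=True, n_eval=51)
        e = circ.integrate(spec, duration, stimulus_on=True, n_eval=51,
                           method="euler", euler_dt=1e-3)
        ref = np.linalg.norm(e.rates[:, -1])
        err = np.linalg.norm(a.rates[:, -1] - e.rates[:, -1]) / max(ref, 1e-12)
        max_rel = max(max_rel, float(err))
        min_rate = min(min_rate, float(a.rates.min()))
    return {"max_relative_error": max_rel, "min_rate": min_rate, "n_specs": n_specs}


def theta_calibration(
    seed: int = 0,
    n_replicates: int = 500,
    n_sim: int = 1000,
    n_per_group: int = 100,
    alpha: float = 0.05,
    effect: float = 0.3,
) -> dict:
    """Type-I error and power of the Θ resampling test on binomial cohorts.

    Null: both groups share rates (post 0.4, baseline 0.2).  Alternative:
    the test group's post-window rate is raised by ``effect``.
    """
    rng = np.random.default_rng(seed)
    rej_null = 0
    for r in range(n_replicates):
        counts = synth.gen_group_counts(
            {"test": (0.4, 0.2), "control": (0.4, 0.2)}, n_per_group,
            seed=int(rng.integers(2**31 - 1)),
        )
        res = lst.theta_test(counts["test"], counts["control"], n_sim=n_sim,
                             seed=int(rng.integers(2**31 - 1)))
        rej_null += res["p_value"] <= alpha
    rej_alt = 0
    n_alt = max(n_replicates // 2, 100)
    for r in range(n_alt):
        counts = synth.gen_group_counts(
            {"test": (0.4 + effect, 0.2), "control": (0.4, 0.2)}, n_per_group,
            seed=int(rng.integers(2**31 - 1)),
        )
        res = lst.theta_test(counts["test"], counts["control"], n_sim=n_sim,
                             seed=int(rng.integers(2**31 - 1)))
        rej_alt += res["p_value"] <= alpha
    lo, hi = sps.binom.interval(0.95, n_replicates, alpha)
    return {
        "null_rejection_rate": rej_null / n_replicates,
        "ci_low": lo / n_replicates,
        "ci_high": hi / n_replicates,
        "power": rej_alt / n_alt,
        "n_replicates": n_replicates,
    }


def glr_null_uniformity(seed: int = 0, n_sims: int = 1000, N: int = 2000,
                        rate: float = 0.3) -> dict:
    """KS check that GLR p-values are ~Uniform(0,1) under the null.

    Uses large per-group counts so binomial discreteness does not dominate
    the p-value distribution.
    """
    rng = np.random.default_rng(seed)
    ps = np.empty(n_sims)
    for i in range(n_sims):
        n1, n2 = rng.binomial(N, rate, 2)
        ps[i] = lst.glr_transition_test(int(n1), N, int(n2), N)[1]
    ks = sps.kstest(ps, "uniform")
    return {"ks_pvalue": float(ks.pvalue), "n_sims": n_sims, "N": N}


def mmd_calibration(
    seed: int = 0,
    n_runs: int = 200,
    n_points: int = 100,
    d: int = 25,
    B: int = 200,
    shift: float = 1.0,
    alpha: float = 0.05,
) -> dict:
    """Type-I error and power of the MMD permutation test on 25-D Gaussians."""
    rng = np.random.default_rng(seed)
    rej = 0
    for _ in range(n_runs):
        X, Y = synth.gen_point_clouds(n_points, d, 0.0, seed=int(rng.integers(2**31 - 1)))
        rej += lst.mmd_permutation_test(X, Y, B=B, seed=int(rng.integers(2**31 - 1)))[
            "p_value"] <= alpha
    pw = 0
    n_pw = max(n_runs // 2, 50)
    for _ in range(n_pw):
        X, Y = synth.gen_point_clouds(n_points, d, shift, seed=int(rng.integers(2**31 - 1)))
        pw += lst.mmd_permutation_test(X, Y, B=B, seed=int(rng.integers(2**31 - 1)))[
            "p_value"] <= alpha
    lo, hi = sps.binom.interval(0.95, n_runs, alpha)
    return {
        "null_rejection_rate": rej / n_runs,
        "ci_low": lo / n_runs,
        "ci_high": hi / n_runs,
        "power": pw / n_pw,
    }


def kinematics_benchmarks(seed: int = 0) -> dict:
    """Closed-form kinematics checks on constructed tracks.

    A straight constant-speed run (straightness index, dispersal equals
    pathlength), 10 s of 1.4 Hz peristalsis (stride count), a straight
    spine (nematic order) and a circular point set (shape factor).
    """
    # straight constant-speed synthetic track, no peristalsis, no noise
    n = 301
    t = np.arange(n) * kin.DT
    spine = np.zeros((n, 11, 2))
    for i in range(11):
        spine[:, i, 0] = -0.4 * i
    spine[:, :, 0] += (1.0 * t)[:, None]  # 1 mm/s along x
    straight = kin.SpineTrack("straight", t, spine, regular=True)
    si = kin.straightness_index(straight, window=20.0)
    pm = kin.path_metrics(straight)
    # peristaltic crawl
    cfg = synth.GenerationConfig(seed=seed, duration=10.0, coord_noise_sd=0.005)
    tr, _ = synth.gen_track(cfg, [("crawl", 0.0, 10.0)])
    n_strides = len(kin.detect_strides(kin.preprocess(tr)))
    # straight spine -> S = 1
    s_straight = float(kin.nematic_order(straight)[0])
    # circular point set -> shape factor 0
    ang = np.linspace(0, 2 * np.pi, 11, endpoint=False)
    circle = np.stack([np.cos(ang), np.sin(ang)], axis=-1)[None].repeat(11, axis=0)
    circ_track = kin.SpineTrack("circle", np.arange(11) * kin.DT, circle, regular=True)
    lam_circle = float(kin.shape_factor(circ_track)[5])
    return {
        "straightness_index_min": float(si.min()),
        "straightness_index_max": float(si.max()),
        "dispersal_minus_pathlength_max": float(
            np.max(np.abs(pm["dispersal"] - pm["pathlength"]))),
        "n_strides_10s": n_strides,
        "nematic_straight": s_straight,
        "shape_factor_circle": lam_circle,
    }


def annotation_benchmark(seed: int = 0, n_larvae: int = 40) -> dict:
    """Synthetic-cohort annotation: train the voting ensemble on ground
    truth, classify, regularize, apply the Hunch rules, and compare the
    recovered cumulative action probabilities with the generator's tables.
    """
    cfg = synth.GenerationConfig(seed=seed, n_larvae=n_larvae)
    tracks, truths = synth.gen_cohort(cfg)
    tracks = [kin.preprocess(t) for t in tracks]
    X, y = act.build_training_set(tracks, truths)
    bundle = act.train_frame_classifier(X, y, seed=seed, n_estimators=30)

    sequences = []
    short_violations = 0
    multi_hunch = 0
    for track in tracks:
        feats, W = act.windowed_features(track)
        seq = act.classify_frames(bundle, W, feats.index.to_numpy(),
                                  larva_id=track.larva_id,
                                  stimulus_onset=track.stimulus_onset)
        seq = act.regularize(seq)
        seq = act.apply_hunch_rules(seq, feats["length"].to_numpy())
        for label, a, b, prov in seq.intervals():
            steps = int(round((b - a) / kin.DT)) + 1
            if steps < 3 and prov != "expanded":
                short_violations += 1
        n_hunch = sum(1 for label, a, b, _ in seq.intervals()
                      if label == "hunch" and a >= seq.stimulus_onset)
        multi_hunch += n_hunch > 1
        sequences.append(seq)

    truth_p = cfg.post_probs.get("hunch", 0.0)
    rec = lst.action_probabilities(sequences, "hunch", mode="cumulative")
    tru = lst.action_probabilities(truths, "hunch", mode="cumulative")
    # binomial sampling band around the configured rate
    lo, hi = sps.binom.interval(0.999, n_larvae, truth_p) if truth_p > 0 else (0, 0)
    return {
        "per_class_accuracy": bundle.per_class_accuracy,
        "min_class_accuracy": min(bundle.per_class_accuracy.values()),
        "short_interval_violations": short_violations,
        "larvae_with_multiple_hunches": multi_hunch,
        "recovered_hunch_probability": rec.value,
        "truth_hunch_probability": tru.value,
        "configured_hunch_probability": truth_p,
        "binomial_band": (lo / n_larvae, hi / n_larvae),
        "n_larvae": n_larvae,
    }
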