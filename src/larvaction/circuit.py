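"""Connectome-constrained rate model of the larval Hunch/Head-Cast selection circuit.

Seven interacting populations — chordotonal mechanosensory input (MCh), the
two projection-neuron outputs Basin-1 and Basin-2 (B1, B2), the reciprocally
connected feedforward inhibitory interneurons iLNa/iLNb, and the feedback
inhibitory interneurons Handle-a/Handle-b (Ha, Hb) — evolve as firing rates

    tau dr/dt = -V0 - r + s + i + k_ex * (rmax - r) ⊙ (A_ex r - A_in r)

where s is the air-puff stimulus (applied to MCh only), i a tonic input from
other brain regions, V0 an activation threshold, and the shunting factor
(rmax - r) saturates rates at rmax.  Coupling weights come from synaptic
counts in the larval connectome.  The steady state of (B1, B2) under
sustained stimulation falls into one of two attractors: a *coactive* state
(both high; predicts Head Cast) or a *monoactive* state (B1 high, B2 near
zero; predicts Hunch).  Feeding-state neuromodulation is modeled either as a
tonic input current to Hb, as a reduced maximum rate of iLNa, or both.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.integrate import solve_ivp
from sklearn.cluster import KMeans

__all__ = [
    "POPULATIONS",
    "CircuitSpec",
    "RateTrajectory",
    "SteadyStateResult",
    "PhaseDiagram",
    "SilencingResult",
    "build_circuit",
    "rate_derivative",
    "integrate",
    "steady_state",
    "label_outcomes",
    "phase_diagram",
    "silencing_effect",
]

POPULATIONS = ("MCh", "B1", "B2", "iLNb", "iLNa", "Ha", "Hb")
_IDX = {name: i for i, name in enumerate(POPULATIONS)}

#: rates below this are treated as "at the positivity boundary": the
#: derivative is clamped nonnegative there so trajectories never go negative
_POSITIVITY_EPS = 1e-9

#: B1 rates below this make the B2/B1 ratio meaningless (both populations
#: silent); the ratio guard returns inf and the outcome is undetermined
_RATIO_GUARD = 1e-6

#: scalar alternative to k-means labeling: steady ratios in the fed scan
#: separate by ~2 orders of magnitude (monoactive < 0.02, coactive > 0.4),
#: so any cut in the gap works; 0.1 sits comfortably inside it
RATIO_THRESHOLD = 0.1

# Inhibitory coupling matrix from connectome synaptic counts,
# rows = postsynaptic, cols = presynaptic, population order as above.
_A_IN = np.array(
    [
        [0, 0, 0, 0, 0, 0, 0],
        [0, 0, 0, 1.7648, 1.3841, 0, 0],
        [0, 0, 0, 1.0, 5.9167, 0, 0],
        [0, 0, 0, 0, 3.3744, 1.6659, 2.191],
        [0, 0, 0, 2.7133, 0, 1.1010, 3.3031],
        [0, 0, 0, 1.8411, 1.1158, 0, 0],
        [0, 0, 0, 1.7331, 2.2145, 0, 0],
    ]
)


def _a_ex(w_ilna: float, w_ilnb: float) -> np.ndarray:
    """Excitatory couplings; the MCh->iLNa weight is the scanned parameter."""
    return np.array(
        [
            [0, 0, 0, 0, 0, 0, 0],
            [1.5, 0, 0, 0, 0, 0, 0],
            [0.75, 0, 0, 0, 0, 0, 0],
            [w_ilnb, 0, 0, 0, 0, 0, 0],
            [w_ilna, 0, 0, 0, 0, 0, 0],
            [0, 0.2, 0.2, 0, 0, 0, 0],
            [0.4, 0, 0.5, 0, 0, 0, 0],
        ]
    )


@dataclass(frozen=True)
class CircuitSpec:
    """Full parameterization of the 7-population rate model.

    All quantities are in the model's arbitrary units (rates and thresholds
    share one scale; time constants share another).
    """

    tau: np.ndarray
    V0: np.ndarray
    rmax: np.ndarray
    tonic_input: np.ndarray
    k_ex: float
    w_ilna: float
    w_ilnb: float
    stimulus_amplitude: float = 68.0
    #: if True use the literally printed shunting factor (r - rmax) instead
    #: of the corrected (rmax - r); retained for comparison only
    literal_sign: bool = False

    def __post_init__(self):
        for name in ("tau", "V0", "rmax", "tonic_input"):
            v = np.asarray(getattr(self, name), dtype=float)
            if v.shape != (7,):
                raise ValueError(f"{name} must have length 7, got shape {v.shape}")
            object.__setattr__(self, name, v)
        if np.any(self.tau <= 0):
            raise ValueError("tau must be strictly positive")
        if self.w_ilna < 0:
            raise ValueError("w_ilna must be nonnegative")

    @property
    def A_ex(self) -> np.ndarray:
        return _a_ex(self.w_ilna, self.w_ilnb)

    @property
    def A_in(self) -> np.ndarray:
        return _A_IN.copy()

    def with_params(self, **kw) -> "CircuitSpec":
        return replace(self, **kw)


@dataclass
class RateTrajectory:
    """Time course of all 7 population rates from one integration."""

    times: np.ndarray
    rates: np.ndarray  # (7, T), nonnegative
    spec: CircuitSpec
    silenced: frozenset = frozenset()

    def rate_of(self, population: str) -> np.ndarray:
        return self.rates[_IDX[population]]


@dataclass
class SteadyStateResult:
    rates: np.ndarray
    converged: bool
    b2_b1_ratio: float
    label: str  # coactive | monoactive | undetermined

    @property
    def b1(self) -> float:
        return float(self.rates[_IDX["B1"]])

    @property
    def b2(self) -> float:
        return float(self.rates[_IDX["B2"]])


@dataclass
class PhaseDiagram:
    """Steady-state outcome over a (w_iLNa, modulation) grid."""

    w_grid: np.ndarray
    mod_param: str
    mod_grid: np.ndarray
    ratio: np.ndarray  # (n_mod, n_w)
    labels: np.ndarray  # (n_mod, n_w) of str
    converged: np.ndarray  # (n_mod, n_w) of bool
    thresholds: np.ndarray  # (n_mod,) transition w per mod value; NaN if no flip


@dataclass
class SilencingResult:
    target: str
    readout: str
    baseline: RateTrajectory
    silenced: RateTrajectory
    baseline_integral: float
    silenced_integral: float

    @property
    def excess(self) -> float:
        """Readout integral gained by silencing the target."""
        return self.silenced_integral - self.baseline_integral


_VARIANTS = {
    "fed": dict(rmax_ilna=20.0, i_hb=0.0),
    "sucrose_model1": dict(rmax_ilna=20.0, i_hb=10.0),
    "sucrose_model2": dict(rmax_ilna=18.0, i_hb=0.0),
    "sucrose_combined": dict(rmax_ilna=18.0, i_hb=10.0),
}

_OVERRIDABLE = {
    "tau", "V0", "rmax", "tonic_input", "k_ex", "w_ilna", "w_ilnb",
    "stimulus_amplitude", "literal_sign", "rmax_ilna", "i_hb",
}


def build_circuit(variant: str = "fed", overrides: dict | None = None) -> CircuitSpec:
    """Build the published parameterization of the circuit.

    Parameters
    ----------
    variant
        ``fed``, ``sucrose_model1`` (tonic input i=10 a.u. to Hb),
        ``sucrose_model2`` (iLNa rmax lowered 20->18 a.u.), or
        ``sucrose_combined`` (both modulations).
    overrides
        Optional map of field names to replacement values; the shorthand
        keys ``rmax_ilna`` and ``i_hb`` patch the single modulated entry.
    """
    if variant not in _VARIANTS:
        raise ValueError(
            f"unknown variant {variant!r}; expected one of {sorted(_VARIANTS)}"
        )
    mod = dict(_VARIANTS[variant])
    overrides = dict(overrides or {})
    unknown = set(overrides) - _OVERRIDABLE
    if unknown:
        raise ValueError(f"unknown override(s): {sorted(unknown)}")
    mod["rmax_ilna"] = overrides.pop("rmax_ilna", mod["rmax_ilna"])
    mod["i_hb"] = overrides.pop("i_hb", mod["i_hb"])

    rmax = np.full(7, 20.0)
    rmax[_IDX["iLNa"]] = mod["rmax_ilna"]
    tonic = np.zeros(7)
    tonic[_IDX["Hb"]] = mod["i_hb"]
    spec = CircuitSpec(
        tau=np.array([1.0, 35, 35, 35, 35, 35, 35]),
        V0=np.array([0.0, 20, 20, 20, 20, 20, 20]),
        rmax=rmax,
        tonic_input=tonic,
        k_ex=2.5,
        w_ilna=1.0,
        w_ilnb=2.0,
    )
    if overrides:
        spec = spec.with_params(**overrides)
    return spec


def _silence_indices(silenced) -> np.ndarray:
    idx = []
    for name in silenced or ():
        if name not in _IDX:
            raise ValueError(f"unknown population {name!r}")
        idx.append(_IDX[name])
    return np.array(sorted(idx), dtype=int)


def rate_derivative(
    spec: CircuitSpec,
    r: np.ndarray,
    stimulus_on: bool,
    silenced=frozenset(),
) -> np.ndarray:
    """Right-hand side of the rate equation, with positivity clamping.

    The derivative is clamped nonnegative wherever the rate sits at the
    positivity boundary (r < 1e-9), and zeroed for silenced populations.
    """
    r = np.asarray(r, dtype=float)
    if r.shape != (7,):
        raise ValueError(f"rate vector must have shape (7,), got {r.shape}")
    s = np.zeros(7)
    if stimulus_on:
        s[_IDX["MCh"]] = spec.stimulus_amplitude
    shunt = (r - spec.rmax) if spec.literal_sign else (spec.rmax - r)
    coupling = spec.A_ex @ r - spec.A_in @ r
    d = (-spec.V0 - r + s + spec.tonic_input + spec.k_ex * shunt * coupling) / spec.tau
    boundary = r < _POSITIVITY_EPS
    d[boundary] = np.maximum(d[boundary], 0.0)
    sil = _silence_indices(silenced)
    if sil.size:
        d[sil] = 0.0
    return d


class IntegrationError(RuntimeError):
    """Solver failure; carries the last valid state and time."""

    def __init__(self, message, last_time, last_state):
        super().__init__(message)
        self.last_time = last_time
        self.last_state = last_state


class _BudgetExceeded(Exception):
    pass


def _euler(spec, duration, y0, silenced, stimulus_on, t_eval, dt):
    """Fixed-step explicit Euler with the same positivity clamping.

    Used as the independent solver oracle and as a fallback when the
    adaptive solver stalls on the non-smooth positivity boundary (which
    happens for parameters very close to the attractor bifurcation).
    """
    sil = _silence_indices(silenced)
    n_steps = int(np.ceil(duration / dt))
    y = y0.copy()
    out = np.empty((7, t_eval.size))
    k = 0
    t = 0.0
    for step in range(n_steps + 1):
        while k < t_eval.size and t_eval[k] <= t + 1e-12:
            out[:, k] = y
            k += 1
        if step == n_steps:
            break
        h = min(dt, duration - t)
        y = y + h * rate_derivative(spec, np.maximum(y, 0.0), stimulus_on, silenced)
        y = np.maximum(y, 0.0)
        if sil.size:
            y[sil] = 0.0
        t += h
    while k < t_eval.size:
        out[:, k] = y
        k += 1
    return out


def integrate(
    spec: CircuitSpec,
    duration: float,
    r0: np.ndarray | None = None,
    silenced=frozenset(),
    stimulus_on: bool = True,
    n_eval: int = 201,
    rtol: float = 1e-3,
    atol: float = 1e-3,
    method: str = "adaptive",
    euler_dt: float = 1e-2,
    max_rhs_evals: int = 100_000,
) -> RateTrajectory:
    """Integrate the rate equations.

    The default method is LSODA (adaptive, stiffness-switching) at relative
    and absolute tolerance 1e-3.  The state is constrained nonnegative:
    inside the RHS the rate vector is replaced by max(r, 0) and derivative
    components are clamped nonnegative wherever the corresponding rate is
    below 1e-9; the stored trajectory is clipped the same way.  Silenced
    populations are held at exactly 0.

    The clamping makes the vector field non-smooth, and for parameters
    sitting essentially on the coactive/monoactive bifurcation LSODA can
    stall in vanishing steps against the positivity boundary; if it spends
    more than ``max_rhs_evals`` derivative evaluations the run is redone
    with fixed-step explicit Euler (``euler_dt``), which handles the
    switching surface robustly.  ``method="euler"`` forces that integrator
    (it doubles as the independent solver oracle in the tests).
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    r0 = np.zeros(7) if r0 is None else np.asarray(r0, dtype=float)
    if np.any(r0 < 0):
        raise ValueError("initial rates must be nonnegative")
    sil = _silence_indices(silenced)
    y0 = r0.copy()
    if sil.size:
        y0[sil] = 0.0
    t_eval = np.linspace(0.0, duration, n_eval)

    if method == "euler":
        rates = _euler(spec, duration, y0, silenced, stimulus_on, t_eval, euler_dt)
        return RateTrajectory(times=t_eval, rates=np.maximum(rates, 0.0), spec=spec,
                              silenced=frozenset(silenced))
    if method != "adaptive":
        raise ValueError(f"unknown method {method!r}")

    n_evals = 0

    def rhs(_t, y):
        nonlocal n_evals
        n_evals += 1
        if n_evals > max_rhs_evals:
            raise _BudgetExceeded
        return rate_derivative(spec, np.maximum(y, 0.0), stimulus_on, silenced)

    try:
        sol = solve_ivp(
            rhs, (0.0, duration), y0, method="LSODA", t_eval=t_eval,
            rtol=rtol, atol=atol,
        )
    except _BudgetExceeded:
        rates = _euler(spec, duration, y0, silenced, stimulus_on, t_eval, euler_dt)
        return RateTrajectory(times=t_eval, rates=np.maximum(rates, 0.0), spec=spec,
                              silenced=frozenset(silenced))
    if not sol.success:
        raise IntegrationError(sol.message, sol.t[-1] if sol.t.size else 0.0,
                               sol.y[:, -1] if sol.t.size else y0)
    rates = np.maximum(sol.y, 0.0)
    if sil.size:
        rates[sil] = 0.0
    return RateTrajectory(times=sol.t, rates=rates, spec=spec, silenced=frozenset(silenced))


def _label_from_ratio(b1: float, b2: float) -> tuple[float, str]:
    if b1 < _RATIO_GUARD:
        return float("inf") if b2 >= _RATIO_GUARD else float("nan"), "undetermined"
    ratio = b2 / b1
    return ratio, ("coactive" if ratio >= RATIO_THRESHOLD else "monoactive")


def steady_state(
    spec: CircuitSpec,
    silenced=frozenset(),
    deriv_tol: float = 1e-6,
    time_cap: float | None = None,
    chunk: float = 250.0,
) -> SteadyStateResult:
    """Relax to steady state under sustained stimulation from rest.

    Integrates from r0=0 with the stimulus held on until the clamped
    derivative satisfies max|dr/dt| < ``deriv_tol`` or the time cap
    (default 50 * max(tau)) is hit.
    """
    if time_cap is None:
        time_cap = 50.0 * float(np.max(spec.tau))
    t = 0.0
    r = np.zeros(7)
    converged = False
    while t < time_cap:
        step = min(chunk, time_cap - t)
        traj = integrate(spec, step, r0=r, silenced=silenced, stimulus_on=True, n_eval=2)
        r = traj.rates[:, -1]
        t += step
        d = rate_derivative(spec, r, stimulus_on=True, silenced=silenced)
        if np.max(np.abs(d)) < deriv_tol:
            converged = True
            break
    b1, b2 = r[_IDX["B1"]], r[_IDX["B2"]]
    if converged:
        ratio, label = _label_from_ratio(b1, b2)
    else:
        ratio, label = float("nan"), "undetermined"
    # all-zero steady state (e.g. no stimulus path in): nothing to classify
    if converged and b1 < _RATIO_GUARD and b2 < _RATIO_GUARD:
        ratio, label = float("nan"), "undetermined"
    return SteadyStateResult(rates=r, converged=converged, b2_b1_ratio=ratio, label=label)


def label_outcomes(
    ensemble: list[SteadyStateResult], seed: int = 0
) -> tuple[list[str], np.ndarray]:
    """Classify steady states as coactive vs monoactive by k-means (k=2).

    Clusters the (B1, B2) steady rates; the cluster with the larger mean B2
    is *coactive* (Head Cast), the other *monoactive* (Hunch).  The
    scalar-ratio labels are available per item via
    ``SteadyStateResult.label``.

    Returns per-item labels and the (2, 2) cluster centers, coactive first.
    """
    pts = np.array([[res.b1, res.b2] for res in ensemble if res.converged])
    if len(pts) < 2:
        raise ValueError("need at least 2 converged steady states")
    if np.allclose(pts, pts[0], atol=1e-9):
        raise ValueError("degenerate ensemble: all (B1, B2) points identical")
    km = KMeans(n_clusters=2, n_init=10, random_state=seed).fit(pts)
    mean_b2 = [pts[km.labels_ == k, 1].mean() for k in (0, 1)]
    coactive_k = int(np.argmax(mean_b2))
    names = {coactive_k: "coactive", 1 - coactive_k: "monoactive"}
    labels, j = [], 0
    for res in ensemble:
        if res.converged:
            labels.append(names[km.labels_[j]])
            j += 1
        else:
            labels.append("undetermined")
    centers = km.cluster_centers_[[coactive_k, 1 - coactive_k]]
    return labels, centers


def _threshold_from_labels(w_grid: np.ndarray, labels: np.ndarray,
                           converged: np.ndarray) -> float:
    """First w (ascending) at which coactive flips to monoactive.

    Reported as the midpoint of the bracketing grid interval; NaN when the
    scan never becomes monoactive.  Non-converged cells are ignored.
    """
    prev_w = None
    for w, lab, ok in zip(w_grid, labels, converged):
        if not ok:
            continue
        if lab == "monoactive":
            return float(w) if prev_w is None else float((prev_w + w) / 2.0)
        prev_w = w
    return float("nan")


def phase_diagram(
    base: CircuitSpec,
    w_grid,
    mod_param: str,
    mod_grid,
    silenced=frozenset(),
) -> PhaseDiagram:
    """Map steady-state outcomes over the (w_iLNa, modulation) plane.

    ``mod_param`` is ``rmax_iLNa`` (maximum rate of the iLNa population) or
    ``i_Hb`` (tonic input current to Hb).  Each cell is an independent
    relaxation to steady state; per modulation value the Hunch/Head-Cast
    transition threshold in w_iLNa is extracted from the label sequence.
    """
    w_grid = np.asarray(w_grid, dtype=float)
    mod_grid = np.asarray(mod_grid, dtype=float)
    if w_grid.size == 0 or mod_grid.size == 0:
        raise ValueError("grids must be nonempty")
    if np.any(np.diff(w_grid) <= 0) or (mod_grid.size > 1 and np.any(np.diff(mod_grid) <= 0)):
        raise ValueError("grids must be sorted strictly ascending")
    if mod_param not in ("rmax_iLNa", "i_Hb"):
        raise ValueError(f"unknown mod_param {mod_param!r}")

    shape = (mod_grid.size, w_grid.size)
    ratio = np.full(shape, np.nan)
    labels = np.full(shape, "undetermined", dtype=object)
    ok = np.zeros(shape, dtype=bool)
    for i, m in enumerate(mod_grid):
        for j, w in enumerate(w_grid):
            if mod_param == "rmax_iLNa":
                rmax = base.rmax.copy()
                rmax[_IDX["iLNa"]] = m
                spec = base.with_params(rmax=rmax, w_ilna=float(w))
            else:
                tonic = base.tonic_input.copy()
                tonic[_IDX["Hb"]] = m
                spec = base.with_params(tonic_input=tonic, w_ilna=float(w))
            res = steady_state(spec, silenced=silenced)
            ratio[i, j] = res.b2_b1_ratio
            labels[i, j] = res.label
            ok[i, j] = res.converged
            if not res.converged:
                warnings.warn(
                    f"cell (w={w:g}, {mod_param}={m:g}) did not converge", stacklevel=2
                )
    thresholds = np.array(
        [_threshold_from_labels(w_grid, labels[i], ok[i]) for i in range(mod_grid.size)]
    )
    return PhaseDiagram(
        w_grid=w_grid, mod_param=mod_param, mod_grid=mod_grid,
        ratio=ratio, labels=labels, converged=ok, thresholds=thresholds,
    )


def silencing_effect(
    spec: CircuitSpec, target: str, readout: str, duration: float = 500.0
) -> SilencingResult:
    """Compare a readout population's stimulated activity with and without
    clamping a target population to zero.

    The silenced population is removed from the dynamics entirely (rate and
    derivative clamped to zero), mimicking chronic inactivation.
    """
    for name in (target, readout):
        if name not in _IDX:
            raise ValueError(f"unknown population {name!r}")
    if target == readout:
        raise ValueError("target and readout must differ")
    base = integrate(spec, duration, stimulus_on=True)
    sil = integrate(spec, duration, stimulus_on=True, silenced={target})
    y0 = base.rate_of(readout)
    y1 = sil.rate_of(readout)
    return SilencingResult(
        target=target,
        readout=readout,
        baseline=base,
        silenced=sil,
        baseline_integral=float(np.trapezoid(y0, base.times)),
        silenced_integral=float(np.trapezoid(y1, sil.times)),
    )
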