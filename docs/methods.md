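# Methods

## The circuit model

The Hunch/Head-Cast selection circuit is modeled as seven interacting
populations — chordotonal mechanosensory input (MCh), the projection-neuron
outputs Basin-1 and Basin-2 (B1, B2), the feedforward inhibitory
interneurons iLNb and iLNa, and the feedback inhibitory interneurons
Handle-a and Handle-b (Ha, Hb) — each reduced to a single firing rate.  The
rates evolve as

    tau dr/dt = -V0 - r + s + i + k_ex (rmax - r) ⊙ (A_ex r - A_in r)

with elementwise (Hadamard) products.  `V0` is an activation threshold,
`s` the air-puff stimulus applied to MCh only, `i` a tonic input from other
brain regions, and the shunting factor `(rmax - r)` saturates each rate at
its ceiling.  The coupling matrices come from synaptic counts in the larval
connectome; the MCh→iLNa weight `w_iLNa` is the scanned stimulus-intensity
parameter (MCh→iLNb is fixed at 2), and all quantities are in the model's
arbitrary units.

Two sign conventions for the shunting factor are circulating; written as
`(r - rmax)` the term makes excitatory input *suppress* sub-maximal rates
and no selective attractor structure exists.  We therefore use
`(rmax - r)` as the default and keep the other form behind the
`literal_sign` switch for comparison.

**Integration.**  `solve_ivp`/LSODA with relative and absolute tolerances
of 1e-3.  The state is constrained nonnegative by replacing `r` with
`max(r, 0)` inside the right-hand side and clamping derivative components
to be nonnegative wherever the corresponding rate is below 1e-9.  This
clamping makes the vector field non-smooth, and for parameters that sit
essentially on the attractor bifurcation LSODA can stall in vanishing
steps against the positivity boundary; `integrate` therefore carries an
RHS-evaluation budget (default 100 000) after which the run is redone with
fixed-step clamped explicit Euler at dt = 0.01.  Explicit Euler at
dt = 1e-3 also serves as the independent cross-check of the adaptive
solver (they agree to well under 1% at end time on random
parameterizations).

**Steady states and labels.**  Relaxation starts from rest (r = 0) with
the stimulus held on and stops when max|dr/dt| < 1e-6 or after
50·max(tau) time units.  The outcome is classified from the steady (B1,
B2) rates, either by k-means with k = 2 over an ensemble of scans (the
cluster with the larger mean B2 is the *coactive* / Head-Cast state, the
other *monoactive* / Hunch) or by the scalar ratio rate(B2)/rate(B1),
which separates by two orders of magnitude between the states; the ratio
cut is 0.1, comfortably inside the gap.  Both labelers agree on every grid
point of the default scan.

**Stimulus amplitude.**  The drive `s` to MCh is not fixed by the
published parameter set, yet it controls which network states exist.  For
small drive (s ≲ 40) the feedforward interneurons alone absorb the input
and both output populations stay silent; for s ≈ 45–60 the circuit is
bistable in `w_iLNa` but Hb never activates, so tonic input to Hb would be
inert; from s ≈ 65 Hb participates in the coactive attractor and both
neuromodulation axes act.  We set s = 68 a.u. as the default: it is the
smallest round value at which every studied mechanism is engaged — B1 high
in both outcomes, the coactive→monoactive transition inside the scanned
w ∈ [0.5, 1.5], and both the iLNa-saturation and the Hb-input modulations
shifting the transition in the observed directions.

**Phase diagrams and thresholds.**  Every (w, modulation) cell is an
independent relaxation from rest.  The transition threshold per modulation
value is the midpoint of the first grid interval (ascending w) across
which the label flips coactive→monoactive; a scan that never flips
reports NaN.  Under the from-rest protocol the modulation effects act
through the transient race between iLNa and the iLNb/Hb coalition, and the
resulting threshold shifts are of order 0.01–0.05 in w; the threshold
studies therefore use a 0.01-step w grid over the transition neighborhood
[0.78, 0.90] (every cell outside it is far from the boundary under all
studied modulations).

**Silencing.**  A silenced population is removed from the dynamics
entirely — rate and derivative clamped to zero — mimicking chronic
inactivation, not merely muting its outputs.  Silencing effects on a
readout are summarized as the time-integral of the readout rate over a
500-unit stimulated epoch, with and without the clamp.  Because removing
Hb moves the transition threshold, the effect of Hb silencing on iLNa is
concentrated in the band of w values between the silenced and intact
thresholds; the studies aggregate the integral excess across a w grid
spanning that band (0.75–0.90), which is also where the tonic Hb input of
the sucrose state widens the band and yields the larger sucrose effect.

## Kinematics

Tracks are 11-point midlines (point 1 = head) at an irregular ~10 Hz.
Preprocessing linearly interpolates all coordinates onto a regular 0.1 s
grid covering the original span and applies a zero-phase second-order
Butterworth low-pass at 2 Hz (zero-phase so event times are not shifted).
The zero-phase second-order response passes the dominant 1.4 Hz
peristaltic band with a gain of ~0.81 and suppresses 5 Hz jitter by more
than an order of magnitude; the residual passband droop is accounted for
in the generator amplitudes.

Body length is the median over time of the midline polyline length; all
speeds are scaled by it.  The centroid G is the mean of the 11 midline
points.  Per-frame features: head/centroid/tail scaled speeds; the
nematic order S = (3⟨cos²θ⟩ − 1)/2 of the 10 spine segments against the
tail→head axis; the shape factor λ = (λ1 − λ2)/(λ1 + λ2) of the midline
covariance averaged over a ±3-step window; the head/tail-to-centroid
distance ratio; and head/tail velocity projections and cosines against
the first/last spine segment (oriented outward, so forward head motion
projects positively).  Classifier inputs stack every feature over the
7-step window t−3…t+3 with edge replication.

Trajectory metrics follow the 9th midline point (a stable rear point):
cumulative pathlength, dispersal from the start position, and the
straightness index — the per-window (20 s) dispersal-to-pathlength ratio,
0 for no movement and 1 for straight-line motion.  The dominant crawl
frequency is the periodogram peak of the scaled centroid speed within
0.5–2.5 Hz; its inverse is the expected cycle duration.  Strides are
epochs between consecutive local speed minima (plateaus break leftmost;
a rising track start / falling track end counts as a boundary minimum)
whose peak reaches 0.3 BL/s and whose duration lies within [0.7, 1.5]
cycles; runs merge strictly consecutive strides and pauses are maximal
stride-free epochs below 0.3 BL/s throughout.

## Action annotation

Seven mutually exclusive actions: crawl, head_cast, static_bend, hunch,
stop, back_up, small.  Ten random forests with balanced class weights are
trained on bootstrap resamples of windowed feature vectors; prediction is
the majority vote, with ties broken by a fixed priority in which rarer,
more stereotyped classes win (hunch > back_up > stop > static_bend >
head_cast > crawl > small).  Training vectors come from bout interiors
only: a frame whose 7-step window straddles a bout boundary mixes two
actions and has no well-defined frame label.  Per-class held-out accuracy
(recall on a stratified 25% split) is recorded in the bundle.

Cleanup rules, in order: bouts of exactly 2 steps are expanded by 5 steps
on each side; remaining bouts shorter than 3 steps (0.3 s) are absorbed
into a neighbor — the flanking label if both sides agree, else the longer
neighbor.  Post-stimulus, at most one Hunch is kept per larva (later ones
become head_cast), and a Hunch whose effective length change — (baseline
median length − minimum length in the bout)/baseline — falls short of the
line-specific threshold (0.3–0.6; default 0.3) is relabeled small.
Generic Bend bouts split into static_bend versus head_cast: static iff at
least P = 0.75 of the bout's steps have scaled centroid speed below
p = 0.5 times the larva's mean pre-stimulus head speed (boundary
inclusive).  P and p are line-specific; the defaults were chosen to sit
between the generator's static-bend (centroid speed ≈ 0) and head-cast
regimes, and the calibration recipe is to maximize agreement with labeled
ground truth.

## Behavioral statistics

For a group of larvae, χ = p_post − p_base is the change in the fraction
performing an action in the 5 s after stimulus onset relative to the
30–50 s baseline window, counting only larvae tracked through the whole
window.  Θ = χ(test) − χ(control) contrasts a test line with its control;
it accumulates events over the window, so it detects responses whose
onsets are dispersed in time.  Significance: the four counts are redrawn
as binomials with the per-window proportions pooled across groups (the
null of no group difference), Θ* is recomputed for each of n_sim = 1000
replicates, and the two-sided add-one p-value is the exceedance fraction.
The single-draw hypergeometric scheme that the estimator's original
description prints reduces to Bernoulli sampling of the observed
proportions; it is retained behind `scheme="literal"` for comparison but
the pooled scheme is the default because it is an actual null.

Transition tests: counts of action changes in the 2 s after onset
(transitions into the window count, so the baseline→response switch at
onset is included), falling back to 10 s when fewer than 100 transitions
accrue.  The GLR statistic z = −2 log LR compares the pooled-proportion
binomial likelihood to the unpooled one in log space and is referred to
χ²(1).  Calibration note: p-values inherit the discreteness of the
counts, so the uniformity check runs at large per-group totals (N = 2000)
where the discrete lattice is fine.

MMD: unbiased U-statistic with Gaussian kernel
k(x,y) = exp(−‖x−y‖²/(2σ²)), σ = 2 ("width 2"; the convention with the
width directly in the denominator is an option).  The unbiased form can
be slightly negative on identical samples.  The permutation test relabels
the pooled sample B times with the add-one p-value and optional
Bonferroni factor.  Embedding inputs are 200-element vectors: 2 s clips
of the 5-point reduced spine (midline points 1, 3, 6, 9, 11) at 10 Hz,
taken at 5 evenly spaced centers in the 60–65 s window.

ΔF/F₀ uses the baseline-window mean as F₀; a trial fails when the
stimulus-averaged ΔF/F₀ does not exceed 10%.  The sucrose preference
index is PI = (Ns − Na)/Ntot with boundary larvae excluded from the side
counts.

## The synthetic generator

The generator emulates the tracking experiment: 95 s tracks, stimulus at
the 60th second for 30 s, ~4 mm larvae, 1.4 Hz peristalsis, ~10 Hz
sampling with 20% frame-interval jitter and 0.01 mm coordinate noise.
Action templates are kinematic caricatures — a centroid-anchored crawl
whose commanded speed is exactly the centroid speed (peak 0.8 BL/s,
minima at 0), lateral head sweeps and static bends anchored at the stable
rear point, a half-sine hunch contraction (45% of body length for true
hunches, 10% for "small" twitches, straddling the 0.3–0.6 relabeling
band), and immobility for stops.  Cohort scripts draw the pre-stimulus
repertoire from a dwell-time Markov process, draw the action at onset
once from the post-stimulus table, and never re-enter startle actions
afterwards — so the ground-truth cumulative probability of, e.g., a Hunch
in the response window equals the configured table entry exactly.

What passing tests on this data do and do not show: they demonstrate that
the features, rules, statistics and their couplings are implemented
correctly and that the pipeline recovers known ground truth through
realistic sampling noise; they do not certify classifier accuracy on real
larvae, whose postures, collisions, tracking dropouts and behavioral
idiosyncrasies the caricatures do not model.

## Problem sizes and numerical choices

The default studies run on one CPU in a few minutes: 21-point bistability
scans; 0.01-step threshold grids over w ∈ [0.78, 0.90]; 16-point
silencing grids at 500-unit integrations; 500 outer replicates × 1000
resamples for the Θ calibration; 200 runs × 200 permutations for the MMD
calibration; 40-larva cohorts for the annotation benchmark.  Seeds are
explicit everywhere; identical seeds give byte-identical outputs.

## Known limitations

- The from-rest relaxation protocol makes neuromodulation thresholds
  transient-race quantities; continuation from an established attractor
  would give larger (basin-boundary) shifts.  The protocol here matches
  the from-zero convention throughout.
- The stimulus amplitude is a calibrated, not measured, quantity; the
  qualitative claims hold over a band (≈ 65–72 a.u.) but the printed
  thresholds move with s.
- The classifier is trained and benchmarked on synthetic fixtures; its
  published counterpart was trained on curated annotations of real
  larvae, and transfer to real data is out of scope.
- The 2 Hz second-order zero-phase filter passes the 1.4 Hz band with
  gain ~0.81, not unity; amplitude-sensitive consumers see filtered
  amplitudes.
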