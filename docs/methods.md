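# Methods

This note records the models implemented in `sleepswitch`, the parameters
that matter, and the design decisions taken where the procedure left genuine
freedom. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## EEG state space and NRt scoring

**Spectral reduction.** The EEG is analysed in consecutive 5-s epochs. Each
epoch gets a single rectangular-window periodogram; band power is the sum of
periodogram density over each 2-Hz band from 1 to 33 Hz (16 bands). Powers
are absolute (arbitrary units); only ratios and within-recording comparisons
are meaningful, and a `low_fraction`-style relative normalisation is not
applied by default. Epochs with non-finite samples or all-zero power are
flagged invalid and logged, never silently dropped or interpolated.

**State space.** `x = log10 P(7–9)/P(1–9)` and `y = log10 P(1–19)`. Because
the 7–9 Hz band is a subset of 1–9 Hz, `x ≤ 0` always — this is asserted in
tests. Both coordinates are smoothed with a centered 5-epoch moving average
whose window shrinks symmetrically (1, 3, 5…) at the recording edges, so no
epochs are lost and nothing is padded. The axis orientation question (which
direction is "toward REM") is resolved internally from the fitted cluster
centroids rather than a configuration flag: movement toward REM is movement
of `x` toward the REM centroid's side. REM sits at a higher theta ratio
than NREM, so with these axes that is rightward.

**Boundaries.** Within a bounded state the trajectory reverses and crosses
itself; along a directed transition it does not. All proper crossings of
non-adjacent trajectory segments within a 5-epoch moving window are found
(each crossing segment pair reported once across overlapping windows;
degenerate zero-length segments skipped with a log entry). The four epochs
bounding each crossing join the NREM or REM cluster according to their
manual 3-stage label (wake-labelled points are discarded; each epoch counts
once). Per cluster, points beyond mean + 5 SD of the centroid distance are
removed in a single, non-iterated pass, and the convex hull of the
survivors is the state boundary. A point exactly on the hull counts as
inside. Note a small-sample caveat of the 5-SD rule: with fewer than ~26
points a single extreme outlier inflates the SD enough to retain itself;
with realistic cluster sizes (hundreds of crossing points per 2-h control
period) the rule behaves as intended.

**NRt space.** The convex envelope of all between-boundary points on
complete NREM→REM transitions (exit the NREM hull, enter the REM hull, no
intervening wake and no return), minus the state-polygon interiors. At
least one complete transition must exist in the control period or scoring
aborts with guidance to extend the control period.

**Scoring rules.** Sleep epochs outside both polygons form candidate
excursions; an excursion is continued across 1-epoch polygon dips (a
transition requires two consecutive in-polygon epochs) and across manual
arousals of ≤ 3 epochs (the wake epochs themselves are never relabelled).
An excursion's epochs are scored `t` when (1) it is preceded by two
consecutive epochs inside one state polygon — the origin; (2) polygon
landings terminate it only after two consecutive in-polygon epochs; (3) if
it ends in arousal or returns to its origin it lasts ≥ 2 epochs; (4)
arousal-split segments form one bout; (5) NREM-origin excursions move
toward the REM polygon (the mean `x` of the first two excursion epochs lies
strictly REM-ward of the last in-NREM epoch's `x`); and (6) each relabelled
point lies inside the NRt space. Rule 6 is applied per point: the bout is
gated by rules 1–5, and within a qualifying bout exactly those epochs whose
points fall inside the demarcated region are relabelled, which keeps the
invariant that every `t` epoch lies in NRt space and outside both
polygons. Excursions truncated by the end of the recording are treated
like arousal-terminated ones. Control-period boundaries are reused
unchanged for later (e.g. drug) periods.

**Bout statistics.** Bouts are maximal label runs; t-bouts separated only by
≤ 3 wake epochs merge (the wake runs remain wake bouts; a merged bout's
length counts t epochs only, so per-state epoch totals stay exact). A
t-bout's origin is the preceding state. Summary metrics: NRt bouts per
minute of origin-state time (reported as NaN, never infinity, when the
origin state has zero time), NRt amount as % of total sleep time
(N + R + t epochs), mean NRt bout duration by origin, and REM bouts split
at 15 epochs into short/long, NRt bouts at 3 epochs into long.

## Synthetic recordings

The generator emits epoch-level band powers whose state-space embedding has
the structure the scorer assumes; it does not synthesise biophysical EEG
(the analysis consumes band powers, so fidelity is only needed there).
`generate_raw_eeg` can additionally render any band-power table as
band-limited noise whose periodogram reproduces the band powers nearly
exactly, for testing the spectral front end.

* **Clusters.** Wake, NREM and REM are isotropic Gaussian clusters
  (SD 0.035 state-space units) around means chosen to mimic rodent data:
  NREM high-power/low-theta (−0.65, 3.0), REM high-theta (−0.15, 2.55),
  wake low-power off the N–R axis (−0.40, 2.10). N and R means sit ~18
  pooled SDs apart (≥ 6 required), so the clusters are visibly disjoint.
  Epoch-to-epoch scatter is independent (the memoryless limit of a bounded
  random walk); together with the 5-epoch smoothing this produces the
  within-cluster trajectory reversals and self-intersections the boundary
  method requires.
* **Dwells.** Geometric with means 50 (NREM), 30 (REM) and 20 (wake)
  epochs — minutes-scale bouts, the standard short-timescale Markov
  description of rodent sleep. 80% of NREM bouts end in a complete
  transition to REM (5–9 epochs through the corridor), the rest in wake;
  REM bouts end in wake.
* **Corridor.** A straight path between the cluster means, traversed over
  `u ∈ [0.3, 0.75]` of the N→R axis. Corridor bouts keep one coherent
  lateral offset (uniform, half-width 0.014) with a strictly monotone
  lateral drift, so out-and-back excursions are simple loops that do not
  self-intersect — transition space stays largely free of trajectory
  crossings, the empirical premise of the boundary method. Complete
  transitions sample the full tube width; failed excursions its core, so
  the region demarcated by the transitions covers the excursions. Each
  corridor bout is flanked by two "shoulder" epochs part-way toward the
  corridor but still labelled with the flanking state: real transitions
  begin with gradual spectral drift, and the shoulders keep the ground
  truth aligned with the smoothed observable. Corridor bouts are separated
  by at least one smoothing window.
* **Failed excursions** occur at 0.012 per NREM epoch and 0.008 per REM
  epoch (REM-origin NRt is rare at baseline), with geometric lengths
  (mean 5, minimum 2); 5% are interrupted by a 1–3 epoch wake arousal.
* **Drug condition** multiplies the REM-origin excursion rate by 6, NRt
  bout duration by 1.5, and wake dwell by 0.7 — the direction of a focal
  GABAergic inactivation of the midbrain switch region. Because excursions
  cannot overlap, the realised pooled density ratio is ~5, inside the
  (4, 8) band asserted in tests.
* **Ground-truth labels.** t epochs carry their origin's label in the
  manual 3-stage hypnogram (a complete N→R transition is manually scored N
  until REM onset), mirroring how transitionary sleep is conventionally
  staged by eye.

What passing the closed loop shows — and does not. On these recordings the
scorer reaches epoch-level t sensitivity/specificity ≥ 0.9 (checked across
ten unselected seeds during calibration; the suite pins seed 7). Real EEG
adds artifacts, non-stationary cluster drift, EMG contamination and
corridor shapes the generator does not model, so the closed loop validates
the pipeline's logic, not its field performance.

## Flip-flop simulations

**Model.** Non-dimensionalised LIF neurons (rest 0, threshold 1, time in
membrane time constants): `dv/dt = −v + I_applied + Σ_j W_ji s_j`, Euler
integration with fixed step `dt`; a spike resets v to 0 and feeds
downstream neurons the alpha-kernel current `α² τ e^{−ατ}` (unit integral)
scaled by `W_ji`. The kernel is integrated exactly in state-space form (two
auxiliary variables per neuron), which is linear-time and avoids history
truncation. Pools: 10 input, 25 R, 25 N; cross-pool inhibitory connections
with probability 0.5 and magnitudes uniform on [0, 1] divided by d = 2.1
(N→R, max 0.48) and d = 2.5 (R→N, max 0.40); no within-pool connections;
input connections are all-to-one-pool with constant weight (+ to R or − to
N depending on the drive scenario). Bias current 2.0 per N/R neuron; the
ramp is 0 for 2000 iterations then +0.06/iteration for 6000 more; output
epochs average spikes over 20 iterations (400 epochs), smoothed with a
3-epoch window.

**Noise.** "Gaussian noise current of amplitude 1.5" is implemented as a
Wiener increment — each Euler step adds `1.5·sqrt(dt)·ξ` to v — making the
stochastic dynamics invariant to the (non-canonical) choice of dt. A
per-step current of fixed SD would tie the effective noise to dt and, at
any dt, yields either negligible voltage noise or no bistable structure.

**Membrane floor.** v is bounded below at the resting potential
(`v_floor = 0`, configurable, `None` disables). This is a shunting-limit
reading of GABAergic inhibition (chloride reversal near rest). With the
unbounded linear membrane the suppressed pool sits several noise SDs below
rest and the switch never leaves its initial state spontaneously at any
dt/α; with the floor the circuit shows the expected noisy-asymmetric-switch
regime: N-dominant bimodal rate-difference histograms with intermittent
spontaneous REM-state entries and failed transitions.

**Free parameters.** The published configuration does not include dt, the
synapse speed, the input weight, the inhibition delta or the scoring
thresholds. Defaults — dt = 0.02 (runs span 160 membrane time constants),
α = 5.0, input weight ±0.0015, inhibition delta −0.4 from the 2.0 operating
bias — were calibrated once, before the directional experiments were
evaluated, to the qualitative operating point the procedure describes:
bistable and N-dominant at the (2.1, 2.5)/(2.0, 2.0) cell, spontaneously
switching under noise, transitioning mid-ramp. All are config keys. At
smaller dt the runs are short relative to the membrane time constant and an
N-inhibited switch flips before the ramp can stabilise the R pool, which
distorts REM-origin NRt measures; dt = 0.02 removes this artifact in both
drive scenarios.

**Scoring and thresholds.** The pooled baseline rate-difference histogram
per drive scenario is reduced to its two modes and intervening trough
(60 bins, 5-bin smoothing); a genuine second mode must carry real mass
(≥ 0.5% of the main peak and ≥ 3 smoothed counts) and be separated by a
trough dipping below half the smaller peak, else a `BistabilityError` is
raised. Flat valleys take their centre bin. Thresholds are the
trough↔mode midpoints; epochs below thr_N are N, above thr_R are R, else
NRt, and runs shorter than 2 epochs merge into the preceding run. Spontaneous
full flips at the no-ramp operating cell are intermittent, so 5-rep pooled
histograms are near the detection margin; 25-rep pools behave the same way.

**Experiments.** Per network, each scenario's baseline run fixes the
thresholds (pooled across networks); networks whose baseline is R-dominant
from onset (first scored epoch R) are excluded; each retained network then
runs the four conditions (baseline, R-inhibited, N-inhibited, both; the
inhibited pool's bias is reduced by the delta) with the same per-network
noise seed, so conditions are paired. Metrics: NRt bouts per R (or N)
epoch by origin, and latency-to-R in epochs (censored at 400 when no R
occurs). Connectivity is resampled per repetition in the tuning grids
(sub-seeds from a single `SeedSequence`).

## Drug-spread simulation

One iteration applies the source reset (when scheduled) and one separable
3-D convolution with the normalised 3-tap Gaussian kernel (SD 1.2),
replicate-edge padding, on a 250³ grid whose central voxel is the source —
the source sits ≥ 124 voxels from every face, so the 1%-radius is
edge-insensitive (asserted via symmetry/monotonicity tests on smaller
grids). Microinjection: 20 µg over 30 one-minute iterations into the 19-nl
source volume is 0.667 µg/iteration ≈ 307 mM/iteration, reset for
iterations 1–30 of 150. Microdialysis: 0.085 mM (the perfusate
concentration) reset every iteration. With SD 1.2 the post-smoothing
concentration at the source coordinate — physically, tissue just outside
the probe membrane, since the reset value models the probe interior —
plateaus at 20.4% of the reset value, matching phantom measurements of
small-molecule concentrations adjacent to a microdialysis membrane; the
literal neighbouring voxel plateaus at 16.7%, so the 20% calibration is
read as the source-coordinate value. The order of operations
(reset-then-smooth vs smooth-then-reset) changes the radius ratio by
< 0.1%.

PSI thresholds: the 1%-PSI concentration is the smallest positive root of
the cubic (≈ 2.23 nM) rather than the rounded ~2.5 nM; both are available
(`threshold_nm` override) and the radius ratio is insensitive to the
choice. Note the cubic gives PSI(10 nM) ≈ 4.4%, although the dose–response
is usually described as negligible near 10 nM — the printed polynomial is
implemented as-is. The inhibition radius is measured along a grid axis
(the field is isotropic) with linear interpolation between voxels; the
voxel scale is calibrated by pinning the microinjection radius to the
empirically observed 2-mm suppression radius.

## Estimation statistics

Paired mean differences resample pairs (never pooled values) with a
bias-corrected-and-accelerated bootstrap (5000 resamples, jackknife
acceleration, via `scipy.stats.bootstrap`); identical inputs give a zero,
degenerate-flagged interval. Cohen's d for paired data divides by the SD
of the differences (the variant name is always reported alongside the
value); identical samples give d = 0, a nonzero constant shift with zero
spread is undefined (NaN, flagged). CI coverage at nominal 95% is verified
by simulation to fall in [93%, 97%] at n = 30.

## Problem sizes

The default test run uses: 3000-epoch synthetic recordings, 20 networks per
experiment grid (the directional effects are stable from 15 up), 5-rep
tuning cells, 500-replicate bootstrap coverage, and the full 250³ × 150
diffusion comparison. The full 11×11×25 tuning sweeps (3025 runs) are
reserved for the CLI.

## Known limitations

* The scorer's accuracy claims are against the generator's own ground
  truth, not against expert-scored animal data.
* The flip-flop's quantitative effect sizes depend on the non-canonical
  defaults above; only directions of effect are meaningful.
* The diffusion model ignores tissue anisotropy, bulk flow, uptake and
  receptor kinetics; it is a calibrated smoothing cascade, not a transport
  model.
* EDF input requires the optional `mne` dependency and a single EEG
  channel selected by label; no artifact rejection beyond non-finite and
  zero-power flags is provided.
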