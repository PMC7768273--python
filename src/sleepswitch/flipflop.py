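"""Mutually inhibitory LIF pool ("flip-flop") simulations of sleep switching.

Two pools of 25 leaky integrate-and-fire neurons (an NREM-representative
N-pool and a REM-representative R-pool) inhibit each other through random
connectivity (probability 0.5 per direction, no within-pool connections).
Every N/R neuron receives a tonic excitatory bias current plus Gaussian
current noise; a 10-neuron input pool delivers a linearly ramping REM drive,
either exciting the R-pool or inhibiting the N-pool. Membrane potential is
non-dimensionalised (rest 0, threshold 1, time in membrane time constants)
and integrated with fixed-step Euler; each spike feeds downstream neurons an
alpha-function synaptic current ``alpha^2 * tau * exp(-alpha*tau)`` (unit
integral) scaled by the connection weight.

Numerical notes:

* The alpha kernel is integrated exactly in state-space form (two auxiliary
  first-order variables per neuron) rather than by summing a truncated spike
  history; both are linear-time, the state-space form is exact.
* The noise current is a Wiener increment: each Euler step adds
  ``noise_amp * sqrt(dt) * xi`` to the membrane potential, which makes the
  stochastic dynamics invariant to the choice of dt.
* Membrane potential is bounded below at the resting potential by default
  (``v_floor = 0``), a shunting-inhibition limit: GABAergic inhibition drives
  the membrane toward its reversal near rest rather than arbitrarily
  negative. Without this bound the suppressed pool sits several noise SDs
  below rest and the switch never leaves its initial state spontaneously;
  with it, the circuit shows the N-dominant bimodality with occasional
  spontaneous R entries that characterises a noisy asymmetric switch.
  Set ``v_floor=None`` for the unbounded linear membrane.

The simulation output is reduced to pooled mean spike rates per 20-iteration
epoch, smoothed (window 3), and the R-minus-N rate difference is scored into
N / NRt / R states by two thresholds derived from the baseline rate-difference
histogram (N-mode / trough / R-mode midpoints).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .smoothing import moving_average


@dataclass
class FlipFlopParams:
    """Parameters of the flip-flop circuit and its integration.

    The published configuration pins the pool sizes, connection probability,
    weight divisors (d = 2.1 for N→R, 2.5 for R→N), bias 2.0, noise amplitude
    1.5, the ramp (hold 2000 iterations, +0.06/iteration for 6000 more) and
    the 20-iteration output epoch. The integration step, synapse speed, input
    connection weight and the inhibition bias delta are not published; the
    defaults below are this package's calibration of the same qualitative
    operating point (bistable, N-dominant, spontaneously switching) and are
    all configurable.
    """

    n_input: int = 10
    n_r: int = 25
    n_n: int = 25
    conn_p: float = 0.5
    d_n_to_r: float = 2.1
    d_r_to_n: float = 2.5
    input_weight: float = 0.0015
    bias_r: float = 2.0
    bias_n: float = 2.0
    noise_amp: float = 1.5
    alpha: float = 5.0
    dt: float = 0.02
    total_iterations: int = 8000
    hold_iterations: int = 2000
    ramp_rate: float = 0.06
    epoch_iterations: int = 20
    smooth_window: int = 3
    v_floor: float | None = 0.0
    inhibition_delta: float = -0.4
    persistence_epochs: int = 2

    def __post_init__(self) -> None:
        if min(self.n_input, self.n_r, self.n_n) < 0 or self.n_r + self.n_n == 0:
            raise ValueError("invalid pool sizes")
        if not (0.0 <= self.conn_p <= 1.0):
            raise ValueError("connection probability must be in [0, 1]")
        if self.dt <= 0 or self.total_iterations <= 0:
            raise ValueError("dt and total_iterations must be positive")

    @property
    def n_total(self) -> int:
        return self.n_input + self.n_r + self.n_n

    @property
    def sl_input(self) -> slice:
        return slice(0, self.n_input)

    @property
    def sl_r(self) -> slice:
        return slice(self.n_input, self.n_input + self.n_r)

    @property
    def sl_n(self) -> slice:
        return slice(self.n_input + self.n_r, self.n_total)

    @property
    def n_epochs(self) -> int:
        return self.total_iterations // self.epoch_iterations


@dataclass
class FlipFlopNetwork:
    """A realised connectivity matrix W (W[j, i]: weight from j to i)."""

    W: np.ndarray
    params: FlipFlopParams
    seed: int
    scenario: str  # "ramp_to_r" (excite R) or "ramp_to_n" (inhibit N)


def build_network(
    seed: int,
    params: FlipFlopParams | None = None,
    scenario: str = "ramp_to_n",
) -> FlipFlopNetwork:
    """Draw a random flip-flop connectivity matrix.

    Cross-pool inhibitory weights are independent per ordered pair: with
    probability ``conn_p`` a connection exists with magnitude uniform in
    [0, 1] divided by the direction's divisor d (so N→R magnitudes are
    uniform on [0, 1/2.1] ≈ [0, 0.48] and R→N on [0, 0.4] at the defaults).
    Within-pool weights are exactly zero. Input connections target one pool
    with probability 1 and constant weight: positive to the R-pool
    (``ramp_to_r``) or negative to the N-pool (``ramp_to_n``).
    """
    p = params or FlipFlopParams()
    if scenario not in ("ramp_to_r", "ramp_to_n"):
        raise ValueError("scenario must be 'ramp_to_r' or 'ramp_to_n'")
    rng = np.random.default_rng(seed)
    W = np.zeros((p.n_total, p.n_total))
    conn = rng.random((p.n_n, p.n_r)) < p.conn_p
    W[p.sl_n, p.sl_r] = -np.where(conn, rng.random((p.n_n, p.n_r)), 0.0) / p.d_n_to_r
    conn = rng.random((p.n_r, p.n_n)) < p.conn_p
    W[p.sl_r, p.sl_n] = -np.where(conn, rng.random((p.n_r, p.n_n)), 0.0) / p.d_r_to_n
    if scenario == "ramp_to_r":
        W[p.sl_input, p.sl_r] = abs(p.input_weight)
    else:
        W[p.sl_input, p.sl_n] = -abs(p.input_weight)
    return FlipFlopNetwork(W=W, params=p, seed=seed, scenario=scenario)


@dataclass
class SimOutput:
    """Spike raster and pooled, smoothed epoch rates of one simulation."""

    spikes: np.ndarray  # (iterations, neurons) bool
    rate_r: np.ndarray  # mean spikes/neuron per epoch, smoothed
    rate_n: np.ndarray
    rate_diff: np.ndarray  # rate_r - rate_n
    params: FlipFlopParams

    @property
    def n_epochs(self) -> int:
        return self.rate_diff.size


def simulate(
    net: FlipFlopNetwork,
    sim_seed: int,
    bias_delta_r: float = 0.0,
    bias_delta_n: float = 0.0,
    ramp: bool = True,
    noise_amp: float | None = None,
) -> SimOutput:
    """Euler-integrate the network and return pooled epoch rates.

    N-pool neurons start with uniform-random membrane potentials in [0, 1)
    (everything else at rest) so every run begins in an N-state. The ramp
    current is applied to input-pool neurons only: zero during the hold, then
    strictly linear at ``ramp_rate`` per iteration. Noise is drawn fresh per
    step per N/R neuron. Raises if any membrane potential goes non-finite.
    """
    p = net.params
    rng = np.random.default_rng(sim_seed)
    sigma = p.noise_amp if noise_amp is None else noise_amp

    v = np.zeros(p.n_total)
    v[p.sl_n] = rng.random(p.n_n)
    s = np.zeros(p.n_total)
    z = np.zeros(p.n_total)
    bias = np.zeros(p.n_total)
    bias[p.sl_r] = p.bias_r + bias_delta_r
    bias[p.sl_n] = p.bias_n + bias_delta_n

    WT = np.ascontiguousarray(net.W.T)
    dt = p.dt
    sqdt = np.sqrt(dt)
    a = p.alpha
    n_noisy = p.n_r + p.n_n
    spikes = np.zeros((p.total_iterations, p.n_total), dtype=bool)

    for it in range(p.total_iterations):
        I = bias
        if ramp and it >= p.hold_iterations:
            I = bias.copy()
            I[p.sl_input] += p.ramp_rate * (it - p.hold_iterations)
        dv = dt * (-v + I + WT @ s)
        if sigma > 0.0:
            noise = np.zeros(p.n_total)
            noise[p.n_input:] = sigma * sqdt * rng.standard_normal(n_noisy)
            dv = dv + noise
        v += dv
        if p.v_floor is not None:
            np.maximum(v, p.v_floor, out=v)
        sp = v >= 1.0
        v[sp] = 0.0
        spikes[it] = sp
        z += dt * (-a * z) + a * a * sp
        s += dt * (-a * s + z)
        if not np.isfinite(v).all():
            raise FloatingPointError(
                f"non-finite membrane potential at iteration {it}"
            )

    nep = p.n_epochs
    per_epoch = spikes[: nep * p.epoch_iterations].reshape(
        nep, p.epoch_iterations, p.n_total
    ).sum(axis=1)
    rate_r = per_epoch[:, p.sl_r].mean(axis=1) if p.n_r else np.zeros(nep)
    rate_n = per_epoch[:, p.sl_n].mean(axis=1) if p.n_n else np.zeros(nep)
    rate_r = moving_average(rate_r, p.smooth_window)
    rate_n = moving_average(rate_n, p.smooth_window)
    return SimOutput(
        spikes=spikes, rate_r=rate_r, rate_n=rate_n,
        rate_diff=rate_r - rate_n, params=p,
    )


# ---------------------------------------------------------------------------
# scoring the switch output


class BistabilityError(RuntimeError):
    """Raised when the pooled rate-difference histogram is not bimodal."""


@dataclass
class SwitchThresholds:
    thr_n: float
    thr_r: float
    mode_n: float
    trough: float
    mode_r: float


def derive_thresholds(
    baseline_diffs: np.ndarray,
    bins: int = 60,
    smooth_bins: int = 5,
    min_mode_separation: float = 0.15,
    mode_fraction: float = 0.5,
    trough_depth: float = 0.5,
) -> SwitchThresholds:
    """Locate the two modes and trough of the pooled rate-difference histogram.

    Each threshold sits ``mode_fraction`` of the way from the trough toward
    its mode (the default is the midpoint). A genuine second mode must be
    separated from the first by at least ``min_mode_separation`` and by a
    trough that dips below ``trough_depth`` times the smaller peak — a bump
    on the shoulder of a single mode does not qualify. Raises
    :class:`BistabilityError` otherwise: the switch is not bistable at these
    parameters.
    """
    d = np.asarray(baseline_diffs, dtype=float).ravel()
    d = d[np.isfinite(d)]
    if d.size < 10:
        raise ValueError("too few rate-difference samples")
    h, edges = np.histogram(d, bins=bins)
    centers = (edges[:-1] + edges[1:]) / 2
    hs = moving_average(h.astype(float), smooth_bins)
    peaks = [
        i for i in range(len(hs))
        if hs[i] > 0
        and (i == 0 or hs[i] >= hs[i - 1])
        and (i == len(hs) - 1 or hs[i] >= hs[i + 1])
    ]
    peaks.sort(key=lambda i: hs[i], reverse=True)
    if not peaks:
        raise BistabilityError("empty histogram")
    p1 = peaks[0]
    min_height = max(0.005 * hs[p1], 3.0)
    p2 = None
    for q in peaks[1:]:
        if abs(centers[q] - centers[p1]) < min_mode_separation:
            continue
        if hs[q] < min_height:
            continue
        lo_, hi_ = sorted((p1, q))
        dip = hs[lo_ : hi_ + 1].min()
        if dip <= trough_depth * hs[q]:
            p2 = q
            break
    if p2 is None:
        raise BistabilityError(
            "rate-difference histogram is unimodal: switch not bistable at "
            "these parameters"
        )
    lo, hi = sorted((p1, p2))
    # centre of the minimal-value run, so a wide flat valley puts the trough
    # mid-way between the modes rather than at its first bin
    valley = hs[lo : hi + 1]
    vmin = valley.min()
    flat = np.where(valley <= vmin + 1e-12)[0]
    trough_i = lo + int(flat[len(flat) // 2])
    mode_n, mode_r = centers[lo], centers[hi]
    trough = centers[trough_i]
    return SwitchThresholds(
        thr_n=trough + mode_fraction * (mode_n - trough),
        thr_r=trough + mode_fraction * (mode_r - trough),
        mode_n=mode_n,
        trough=trough,
        mode_r=mode_r,
    )


def score_switch(
    rate_diff: np.ndarray,
    thr_n: float,
    thr_r: float,
    persistence: int = 2,
) -> np.ndarray:
    """Score each epoch N / t / R from the rate difference.

    Below thr_N is N, above thr_R is R, in between is NRt ("t"). State runs
    shorter than ``persistence`` epochs are merged into the preceding run's
    state (the leading run merges forward), so no scored state change
    persists for fewer than ``persistence`` epochs.
    """
    if thr_n >= thr_r:
        raise ValueError("thr_n must be below thr_r")
    d = np.asarray(rate_diff, dtype=float)
    lab = np.where(d < thr_n, "N", np.where(d > thr_r, "R", "t")).astype(object)

    def runs_of(seq):
        out = []
        i = 0
        while i < len(seq):
            j = i
            while j < len(seq) and seq[j] == seq[i]:
                j += 1
            out.append([i, j, seq[i]])
            i = j
        return out

    runs = runs_of(lab)
    changed = True
    while changed and len(runs) > 1:
        changed = False
        for k, (s, e, st) in enumerate(runs):
            if e - s < persistence:
                tgt = runs[k - 1][2] if k > 0 else runs[k + 1][2]
                if tgt != st:
                    runs[k][2] = tgt
                    changed = True
        merged = [runs[0]]
        for r in runs[1:]:
            if r[2] == merged[-1][2]:
                merged[-1][1] = r[1]
            else:
                merged.append(r)
        runs = merged
    out = np.empty(len(lab), dtype="U1")
    for s, e, st in runs:
        out[s:e] = st
    return out


# ---------------------------------------------------------------------------
# per-run metrics and the experiment grid


@dataclass
class RunMetrics:
    nrt_density_from_r: float  # NRt bouts originating in R per R epoch
    nrt_density_from_n: float
    latency_to_r: int  # epochs; censored at n_epochs when no R occurs
    latency_censored: bool
    n_r_epochs: int
    n_n_epochs: int


def run_metrics(scored: np.ndarray) -> RunMetrics:
    """NRt densities by origin and latency-to-R for one scored run."""
    n = len(scored)
    n_r = int((scored == "R").sum())
    n_n = int((scored == "N").sum())
    t_from = {"N": 0, "R": 0}
    prev = None
    i = 0
    while i < n:
        j = i
        while j < n and scored[j] == scored[i]:
            j += 1
        if scored[i] == "t" and prev in t_from:
            t_from[prev] += 1
        prev = scored[i]
        i = j
    has_r = (scored == "R").any()
    latency = int(np.argmax(scored == "R")) if has_r else n
    return RunMetrics(
        nrt_density_from_r=t_from["R"] / n_r if n_r else np.nan,
        nrt_density_from_n=t_from["N"] / n_n if n_n else np.nan,
        latency_to_r=latency,
        latency_censored=not has_r,
        n_r_epochs=n_r,
        n_n_epochs=n_n,
    )


CONDITIONS = ("baseline", "R-inhibited", "N-inhibited", "both-inhibited")
SCENARIOS = ("ramp_to_n", "ramp_to_r")


def _condition_deltas(condition: str, delta: float) -> tuple[float, float]:
    return {
        "baseline": (0.0, 0.0),
        "R-inhibited": (delta, 0.0),
        "N-inhibited": (0.0, delta),
        "both-inhibited": (delta, delta),
    }[condition]


def run_experiments(
    seed: int,
    n_networks: int = 60,
    params: FlipFlopParams | None = None,
    scenarios: tuple[str, ...] = SCENARIOS,
    conditions: tuple[str, ...] = CONDITIONS,
) -> tuple[pd.DataFrame, dict]:
    """Run the full inhibition-experiment grid.

    For every network, each scenario's baseline run is simulated first; the
    per-scenario pooled baseline rate differences set the scoring thresholds.
    Networks whose baseline run is R-dominant from onset (first scored epoch
    is R, in any scenario) are excluded. Each retained network then runs one
    simulation per scenario x condition with the same per-network noise seed,
    so conditions are paired within network.

    Returns a metrics table (one row per run) and an info dict with the
    thresholds and exclusion bookkeeping.
    """
    p = params or FlipFlopParams()
    ss = np.random.SeedSequence(seed)
    net_seeds = ss.spawn(n_networks)
    seeds = [
        {
            "build": int(s.generate_state(2)[0] % (2**31)),
            "sim": int(s.generate_state(2)[1] % (2**31)),
        }
        for s in net_seeds
    ]

    base: dict[str, list[SimOutput]] = {sc: [] for sc in scenarios}
    for k in range(n_networks):
        for sc in scenarios:
            net = build_network(seeds[k]["build"], p, scenario=sc)
            base[sc].append(simulate(net, seeds[k]["sim"]))

    thresholds = {
        sc: derive_thresholds(np.concatenate([o.rate_diff for o in base[sc]]))
        for sc in scenarios
    }

    excluded = []
    for k in range(n_networks):
        for sc in scenarios:
            scored = score_switch(
                base[sc][k].rate_diff,
                thresholds[sc].thr_n,
                thresholds[sc].thr_r,
                p.persistence_epochs,
            )
            if scored[0] == "R":
                excluded.append(k)
                break
    kept = [k for k in range(n_networks) if k not in excluded]

    rows = []
    for k in kept:
        for sc in scenarios:
            net = build_network(seeds[k]["build"], p, scenario=sc)
            thr = thresholds[sc]
            for cond in conditions:
                d_r, d_n = _condition_deltas(cond, p.inhibition_delta)
                if cond == "baseline":
                    out = base[sc][k]
                else:
                    out = simulate(
                        net, seeds[k]["sim"], bias_delta_r=d_r, bias_delta_n=d_n
                    )
                scored = score_switch(
                    out.rate_diff, thr.thr_n, thr.thr_r, p.persistence_epochs
                )
                m = run_metrics(scored)
                rows.append(
                    {
                        "network": k,
                        "scenario": sc,
                        "condition": cond,
                        "nrt_density_from_r": m.nrt_density_from_r,
                        "nrt_density_from_n": m.nrt_density_from_n,
                        "latency_to_r": m.latency_to_r,
                        "latency_censored": m.latency_censored,
                        "n_r_epochs": m.n_r_epochs,
                        "n_n_epochs": m.n_n_epochs,
                    }
                )
    info = {
        "n_networks": n_networks,
        "n_excluded": len(excluded),
        "excluded_networks": excluded,
        "n_retained": len(kept),
        "n_runs": len(rows),
        "thresholds": {
            sc: {"thr_n": thresholds[sc].thr_n, "thr_r": thresholds[sc].thr_r}
            for sc in scenarios
        },
    }
    return pd.DataFrame(rows), info


# ---------------------------------------------------------------------------
# tuning grids


D_VALUES = tuple(np.round(np.arange(1.8, 2.81, 0.1), 1))
BIAS_VALUES = tuple(np.round(np.arange(1.5, 2.51, 0.1), 1))


def grid_runs(
    values_a: tuple[float, ...] = D_VALUES,
    values_b: tuple[float, ...] = D_VALUES,
    reps: int = 25,
) -> list[tuple[float, float, int]]:
    """Enumerate every (cell value a, cell value b, rep) run of a tuning grid."""
    return [(a, b, r) for a in values_a for b in values_b for r in range(reps)]


@dataclass
class GridCell:
    value_a: float
    value_b: float
    n_peak: float
    trough: float
    r_peak: float
    bimodal: bool


def _cell_summary(diffs: np.ndarray, a: float, b: float) -> GridCell:
    """Histogram-shape summary of one tuning cell (heights as fractions)."""
    try:
        thr = derive_thresholds(diffs)
    except BistabilityError:
        h, edges = np.histogram(diffs, bins=60, density=True)
        return GridCell(a, b, n_peak=float(h.max()), trough=0.0, r_peak=0.0,
                        bimodal=False)
    h, edges = np.histogram(diffs, bins=60, density=True)
    centers = (edges[:-1] + edges[1:]) / 2

    def height(v):
        return float(h[np.argmin(np.abs(centers - v))])

    return GridCell(
        a, b,
        n_peak=height(thr.mode_n),
        trough=height(thr.trough),
        r_peak=height(thr.mode_r),
        bimodal=True,
    )


def _run_cell(
    params: FlipFlopParams, reps: int, seed: int
) -> np.ndarray:
    ss = np.random.SeedSequence(seed)
    diffs = []
    for child in ss.spawn(reps):
        st = child.generate_state(2)
        net = build_network(int(st[0] % 2**31), params, scenario="ramp_to_n")
        out = simulate(net, int(st[1] % 2**31), ramp=False)
        diffs.append(out.rate_diff)
    return np.concatenate(diffs)


def tune_weights(
    seed: int,
    reps: int = 25,
    d_values: tuple[float, ...] = D_VALUES,
    params: FlipFlopParams | None = None,
) -> list[GridCell]:
    """Sweep the 11x11 grid of weight divisors (ramp omitted, noise on).

    Each cell pools ``reps`` simulations with fresh connectivity and noise
    and summarises the rate-difference histogram by its N-peak, trough and
    R-peak heights.
    """
    p = params or FlipFlopParams()
    children = np.random.SeedSequence(seed).spawn(len(d_values) ** 2)
    cells = []
    for i, d_nr in enumerate(d_values):
        for j, d_rn in enumerate(d_values):
            cp = replace(p, d_n_to_r=d_nr, d_r_to_n=d_rn)
            cell_seed = int(children[i * len(d_values) + j].generate_state(1)[0] % 2**31)
            diffs = _run_cell(cp, reps, cell_seed)
            cells.append(_cell_summary(diffs, d_nr, d_rn))
    return cells


def tune_bias(
    seed: int,
    reps: int = 25,
    bias_values: tuple[float, ...] = BIAS_VALUES,
    params: FlipFlopParams | None = None,
) -> list[GridCell]:
    """Sweep the 11x11 grid of bias currents with weights fixed (d=2.1, 2.5)."""
    p = params or FlipFlopParams()
    children = np.random.SeedSequence(seed).spawn(len(bias_values) ** 2)
    cells = []
    for i, b_r in enumerate(bias_values):
        for j, b_n in enumerate(bias_values):
            cp = replace(p, bias_r=b_r, bias_n=b_n)
            cell_seed = int(
                children[i * len(bias_values) + j].generate_state(1)[0] % 2**31
            )
            diffs = _run_cell(cp, reps, cell_seed)
            cells.append(_cell_summary(diffs, b_r, b_n))
    return cells


def grid_frame(cells: list[GridCell]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "value_a": c.value_a, "value_b": c.value_b, "n_peak": c.n_peak,
                "trough": c.trough, "r_peak": c.r_peak, "bimodal": c.bimodal,
            }
            for c in cells
        ]
    )
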