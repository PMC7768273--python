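"""Synthetic labelled recordings with the structure the NRt analysis assumes.

No public dataset accompanies this kind of chronic rodent sleep recording, so
the generator emits epoch-level band-power sequences whose 2-D state-space
embedding has the features the scoring pipeline relies on:

* three clusters (wake, NREM, REM) with bounded random-walk dynamics inside
  each cluster (producing the trajectory reversals and self-intersections
  that demarcate state boundaries);
* a transition corridor between the NREM and REM clusters traversed by
  complete N→R transitions and by "failed" excursions that return to their
  state of origin — the ground-truth NRt epochs;
* a drug condition that scales the rate and duration of NRt bouts
  originating in REM sleep and reduces wake propensity, the direction of the
  focal-inactivation effect the analysis is designed to detect.

Emission happens at the state-space/band-power level (band powers are
constructed to invert exactly to the target coordinates), not as biophysical
EEG synthesis: the analysis consumes band powers, so fidelity is needed only
there. ``generate_raw_eeg`` additionally renders any band-power table as a
band-limited-noise EEG trace for testing the spectral front end.

Dwell times are geometric (memoryless epoch-to-epoch dynamics, the standard
short-timescale Markov description of sleep-stage sequences).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .spectral import BAND_EDGES, N_BANDS, EpochBandPowers, StateTrajectory


@dataclass
class SyntheticConfig:
    """Cluster geometry, dwell structure and condition multipliers.

    Coordinates are state-space units (x = log10 theta ratio, y = log10
    total 1-19 Hz power). Dwell means are in 5-s epochs.
    """

    mean_n: tuple[float, float] = (-0.65, 3.0)
    mean_r: tuple[float, float] = (-0.15, 2.55)
    mean_w: tuple[float, float] = (-0.40, 2.10)
    cluster_sd: float = 0.035
    walk_rho: float = 0.0  # AR(1) pull toward the cluster mean (0 = iid scatter)

    dwell_n: float = 50.0
    dwell_r: float = 30.0
    dwell_w: float = 20.0
    p_complete_transition: float = 0.8  # N bout ends in N→R rather than wake
    transition_len: tuple[int, int] = (5, 9)  # complete-transition duration

    fail_rate_n: float = 0.012  # failed excursions per N epoch
    fail_rate_r: float = 0.008  # per R epoch
    fail_len_mean: float = 5.0  # geometric, minimum 2
    arousal_split_p: float = 0.05  # brief wake interrupting an NRt bout

    corridor_lo: float = 0.3  # corridor span as fraction of the N→R axis
    corridor_hi: float = 0.75
    corridor_jitter: float = 0.014  # lateral half-width (per-bout offset)
    corridor_bulge: float = 0.0  # lateral arc height of the corridor curve

    # drug-condition multipliers (REM-origin NRt rate & duration up, wake down)
    drug_r_rate_mult: float = 6.0
    drug_t_duration_mult: float = 1.5
    drug_wake_mult: float = 0.7

    low_fraction: float = 0.8  # share of 1-19 Hz power in 1-9 Hz
    seed: int = 0

    def validate(self) -> None:
        d = np.hypot(
            self.mean_r[0] - self.mean_n[0], self.mean_r[1] - self.mean_n[1]
        )
        if d < 6 * self.cluster_sd:
            raise ValueError(
                "N and R cluster means closer than 6 pooled SDs; clusters "
                "would not be visibly disjoint"
            )
        for u in (self.corridor_lo, self.corridor_hi):
            if not (0.0 < u < 1.0):
                raise ValueError("corridor span must be inside (0, 1)")
            if min(u, 1.0 - u) * d < 2 * self.cluster_sd:
                raise ValueError(
                    "transition corridor enters a cluster's 2-SD core"
                )
        if self.corridor_lo >= self.corridor_hi:
            raise ValueError("corridor_lo must be below corridor_hi")


@dataclass
class SyntheticRecording:
    """A generated recording with its ground truth."""

    band_powers: EpochBandPowers
    trajectory: StateTrajectory  # noise-free ground-truth coordinates
    labels3: np.ndarray
    labels4: np.ndarray  # ground truth, includes t epochs
    origins: np.ndarray  # origin state of each t epoch ('' elsewhere)
    config: SyntheticConfig


def _geom(rng: np.random.Generator, mean: float, minimum: int) -> int:
    extra = mean - minimum
    if extra <= 0:
        return minimum
    return minimum + rng.geometric(1.0 / (extra + 1.0)) - 1


def _state_sequence(
    cfg: SyntheticConfig, n_epochs: int, rng: np.random.Generator, drug: bool
):
    """Epoch-level (label3, label4, origin, corridor position u) records."""
    w_dwell = cfg.dwell_w * (cfg.drug_wake_mult if drug else 1.0)
    rate_r = cfg.fail_rate_r * (cfg.drug_r_rate_mult if drug else 1.0)
    dur_mult = cfg.drug_t_duration_mult if drug else 1.0

    recs: list[tuple[str, str, str, float]] = []  # (label3, label4, origin, u)

    def emit_state(state: str, length: int) -> None:
        for _ in range(length):
            recs.append((state, state, "", np.nan))

    def corridor_path(origin: str, length: int, kind: str) -> np.ndarray:
        lo, hi = cfg.corridor_lo, cfg.corridor_hi
        if kind == "complete":
            return lo + (hi - lo) * (np.arange(length) + 1) / (length + 1)
        # failed: out toward the far side and back
        if origin == "N":
            peak = rng.uniform((lo + hi) / 2, hi)
            half = np.linspace(lo, peak, (length + 1) // 2 + 1)[1:]
        else:
            peak = rng.uniform(lo, (lo + hi) / 2)
            half = np.linspace(hi, peak, (length + 1) // 2 + 1)[1:]
        path = np.concatenate([half, half[::-1][1:]])
        return path[:length] if len(path) >= length else np.resize(path, length)

    def shoulder_us(side: str) -> tuple[float, float]:
        # gradual approach positions between a cluster core and the corridor
        lo, hi = cfg.corridor_lo, cfg.corridor_hi
        if side == "N":
            return (0.25 * lo, 0.55 * lo)
        return (1.0 - 0.25 * (1.0 - hi), 1.0 - 0.55 * (1.0 - hi))

    def emit_excursion(origin: str, length: int, kind: str) -> None:
        """A corridor bout with 2-epoch spectral-drift shoulders.

        The shoulders are positioned part-way toward the corridor but still
        belong to the flanking state (real transitions begin with gradual
        spectral drift before the intermediate state proper); they keep the
        ground-truth t epochs aligned with the smoothed observable.
        """
        us = corridor_path(origin, length, kind)
        label3 = "N" if (origin == "N" or kind == "complete") else "R"
        rows = [(label3, "t", origin, u) for u in us]
        if length >= 3 and rng.random() < cfg.arousal_split_p:
            # a 1-3 epoch manual arousal inside the bout (wake stays wake)
            cut = rng.integers(1, length)
            n_w = int(rng.integers(1, 4))
            rows = rows[:cut] + [("W", "W", "", np.nan)] * n_w + rows[cut:]
        u1, u2 = shoulder_us(origin)
        entry = [(origin, origin, "", u1), (origin, origin, "", u2)]
        dest = "R" if kind == "complete" else origin
        v1, v2 = shoulder_us(dest)
        exit_ = [(dest, dest, "", v2), (dest, dest, "", v1)]
        recs.extend(entry + rows + exit_)

    def emit_sleep_bout(state: str, length: int, rate: float) -> None:
        """In-state epochs with failed excursions injected mid-bout."""
        done = 0
        since_excursion = 99  # corridor bouts never share a 5-epoch window
        while done < length:
            if (done >= 2 and since_excursion >= 5 and length - done > 5
                    and rng.random() < rate):
                ex_len = _geom(rng, cfg.fail_len_mean * dur_mult, 2)
                emit_excursion(state, ex_len, "failed")
                since_excursion = 0
            recs.append((state, state, "", np.nan))
            done += 1
            since_excursion += 1

    cur = "N"
    while len(recs) < n_epochs:
        if cur == "W":
            emit_state("W", _geom(rng, w_dwell, 2))
            cur = "N"
        elif cur == "N":
            emit_sleep_bout("N", _geom(rng, cfg.dwell_n, 4), cfg.fail_rate_n)
            if rng.random() < cfg.p_complete_transition:
                t_len = int(rng.integers(cfg.transition_len[0],
                                         cfg.transition_len[1] + 1))
                emit_excursion("N", t_len, "complete")
                cur = "R"
            else:
                cur = "W"
        else:  # R
            emit_sleep_bout("R", _geom(rng, cfg.dwell_r, 4), rate_r)
            cur = "W"
    recs = recs[:n_epochs]
    labels3 = np.array([r[0] for r in recs])
    labels4 = np.array([r[1] for r in recs])
    origins = np.array([r[2] for r in recs])
    us = np.array([r[3] for r in recs])
    return labels3, labels4, origins, us


def _coordinates(
    cfg: SyntheticConfig,
    labels4: np.ndarray,
    us: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    means = {"W": cfg.mean_w, "N": cfg.mean_n, "R": cfg.mean_r}
    n_mean = np.array(cfg.mean_n)
    r_mean = np.array(cfg.mean_r)
    axis = r_mean - n_mean
    perp = np.array([-axis[1], axis[0]])
    perp /= np.linalg.norm(perp)
    step = cfg.cluster_sd * np.sqrt(1.0 - cfg.walk_rho**2)

    n = len(labels4)
    pts = np.empty((n, 2))
    walk = {s: np.zeros(2) for s in means}
    # Corridor trajectories are directed: each excursion follows one coherent
    # lateral offset with a strictly monotone drift (a simple loop), rather
    # than epoch-wise jitter. Out-and-back paths therefore do not cross
    # themselves, and transition space stays largely free of trajectory
    # intersections — the empirical premise of the boundary-demarcation
    # method.
    on_corridor = np.isfinite(us)  # t epochs plus their shoulders
    lateral = np.zeros(n)
    i = 0
    while i < n:
        if not on_corridor[i]:
            i += 1
            continue
        j = i
        while j < n and on_corridor[j]:
            j += 1
        # Bounded offsets keep every bout inside the corridor tube that the
        # complete transitions themselves span: transitions sample the full
        # tube width, failed excursions its core.
        run_is_complete = labels4[j - 1] == "R" and labels4[i] != "R"
        width = 1.0 if run_is_complete else 0.5
        base = rng.uniform(-width, width) * cfg.corridor_jitter
        drift = rng.choice([-1.0, 1.0]) * cfg.corridor_jitter * 1.5
        lateral[i:j] = base + np.linspace(-drift, drift, j - i)
        i = j
    lo, hi = cfg.corridor_lo, cfg.corridor_hi
    for i, lab in enumerate(labels4):
        if on_corridor[i]:
            # the corridor is one characteristic curved path through state
            # space; bouts deviate from it only by their lateral offset
            arc = cfg.corridor_bulge * np.sin(
                np.pi * np.clip((us[i] - lo) / (hi - lo), 0.0, 1.0)
            )
            pts[i] = n_mean + us[i] * axis + perp * (arc + lateral[i])
        else:
            w = walk[lab]
            w = cfg.walk_rho * w + rng.normal(0, step, 2)
            walk[lab] = w
            pts[i] = np.asarray(means[lab]) + w
    return pts


def _invert_to_band_powers(
    pts: np.ndarray, cfg: SyntheticConfig, rng: np.random.Generator
) -> np.ndarray:
    """Band powers whose trajectory coordinates equal the targets exactly.

    Degrees of freedom not pinned by (x, y) — the split of delta power
    across 1-7 Hz, of 9-19 Hz power, and the 19-33 Hz tail — are filled with
    Dirichlet/lognormal noise.
    """
    n = len(pts)
    powers = np.zeros((n, N_BANDS))
    total = 10.0 ** pts[:, 1]  # power 1-19 Hz
    ratio = 10.0 ** pts[:, 0]  # power(7-9)/power(1-9)
    low = cfg.low_fraction * total  # power 1-9 Hz
    theta = ratio * low
    rest_low = low - theta  # bands 1-3, 3-5, 5-7
    mid = total - low  # bands 9-19 (5 bands)

    w_low = rng.dirichlet([3.0, 2.0, 1.0], size=n)
    w_mid = rng.dirichlet([1.0] * 5, size=n)
    powers[:, 0:3] = rest_low[:, None] * w_low
    powers[:, 3] = theta
    powers[:, 4:9] = mid[:, None] * w_mid
    # small high-frequency tail, irrelevant to the state space
    powers[:, 9:] = 0.01 * total[:, None] * rng.lognormal(
        0.0, 0.3, size=(n, N_BANDS - 9)
    ) / (N_BANDS - 9)
    return powers


def generate_recording(
    cfg: SyntheticConfig | None = None,
    n_epochs: int = 2000,
    seed: int | None = None,
    drug: bool = False,
) -> SyntheticRecording:
    """Generate a labelled synthetic recording.

    Returns band powers, the noise-free ground-truth trajectory, the manual
    3-stage hypnogram (t epochs carry their origin state's label: a complete
    N→R transition is manually scored N until REM onset, mirroring how
    transitionary sleep is conventionally staged), the ground-truth 4-stage
    hypnogram, and per-epoch origins of t epochs.
    """
    cfg = cfg or SyntheticConfig()
    cfg.validate()
    if n_epochs < 200:
        raise ValueError("n_epochs must be at least 200")
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    labels3, labels4, origins, us = _state_sequence(cfg, n_epochs, rng, drug)
    pts = _coordinates(cfg, labels4, us, rng)
    powers = _invert_to_band_powers(pts, cfg, rng)
    bp = EpochBandPowers(
        powers=powers, valid=np.ones(n_epochs, dtype=bool), epoch_s=5.0
    )
    traj = StateTrajectory(
        x=pts[:, 0].copy(),
        y=pts[:, 1].copy(),
        valid=np.ones(n_epochs, dtype=bool),
        smoothed=False,
    )
    return SyntheticRecording(
        band_powers=bp,
        trajectory=traj,
        labels3=labels3,
        labels4=labels4,
        origins=origins,
        config=cfg,
    )


def generate_raw_eeg(
    powers: EpochBandPowers,
    fs: float = 500.0,
    seed: int = 0,
) -> np.ndarray:
    """Render band powers as a band-limited-noise EEG trace.

    Each epoch is synthesised in the frequency domain: within every 2-Hz
    band the rFFT bins get random phases and equal magnitudes scaled so the
    one-sided periodogram band power matches the target; bins outside
    1-33 Hz stay zero. Round-tripping through ``compute_band_powers``
    therefore recovers the band powers up to floating-point error.
    """
    if fs < 100.0:
        raise ValueError("fs must be at least 100 Hz")
    rng = np.random.default_rng(seed)
    n_per = int(round(fs * powers.epoch_s))
    freqs = np.fft.rfftfreq(n_per, d=1.0 / fs)
    masks = [(freqs >= lo) & (freqs < hi) for lo, hi in BAND_EDGES]
    out = np.empty(powers.n_epochs * n_per)
    for e in range(powers.n_epochs):
        spec = np.zeros(freqs.size, dtype=complex)
        for b, mask in enumerate(masks):
            p = powers.powers[e, b]
            nb = int(mask.sum())
            if nb == 0 or not np.isfinite(p) or p <= 0:
                continue
            mag = np.sqrt(p * fs * n_per / (2.0 * nb))
            phases = rng.uniform(0, 2 * np.pi, nb)
            spec[mask] = mag * np.exp(1j * phases)
        out[e * n_per : (e + 1) * n_per] = np.fft.irfft(spec, n=n_per)
    return out
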