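"""EEG spectral preprocessing: epoch band powers and the 2-D state-space trajectory.

The sleep-state analysis operates on 5-s epochs. For each epoch the EEG is
reduced to power in sixteen contiguous 2-Hz bands spanning 1-33 Hz, and from
those to two state-space coordinates:

* ``x`` — log10 of the theta ratio, power(7-9 Hz) / power(1-9 Hz). Since the
  7-9 Hz band is a subset of the 1-9 Hz range, x <= 0 always.
* ``y`` — log10 of total power in 1-19 Hz.

Both coordinates are smoothed with a centered 5-epoch moving average before
any geometric analysis. REM epochs sit at high theta ratio (x near 0) and
moderate total power; NREM epochs at low theta ratio and high delta-driven
total power; the corridor between the two clusters is where NREM/REM
transitionary (NRt) sleep lives.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import periodogram

from .smoothing import moving_average

#: 2-Hz band edges covering [1, 33) Hz: (1,3), (3,5), ..., (31,33).
BAND_EDGES: list[tuple[float, float]] = [(1.0 + 2 * b, 3.0 + 2 * b) for b in range(16)]
N_BANDS = 16

#: Band indices making up the composite ranges used by the state space.
THETA_BAND = 3          # 7-9 Hz
LOW_BANDS = slice(0, 4)   # 1-9 Hz
TOTAL_BANDS = slice(0, 9)  # 1-19 Hz

BAND_COLUMNS = [f"band_{int(lo)}_{int(hi)}" for lo, hi in BAND_EDGES]


@dataclass
class EpochBandPowers:
    """Per-epoch spectral power in sixteen 2-Hz bands (1-33 Hz).

    ``powers`` has shape (n_epochs, 16); all entries are non-negative.
    ``valid`` flags epochs that are usable (finite, not all-zero). ``qc_log``
    records why an epoch was rejected rather than dropping it silently.
    """

    powers: np.ndarray
    valid: np.ndarray
    epoch_s: float = 5.0
    sampling_rate_hz: float | None = None
    qc_log: list[tuple[int, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.powers = np.asarray(self.powers, dtype=float)
        if self.powers.ndim != 2 or self.powers.shape[1] != N_BANDS:
            raise ValueError(f"powers must be (n_epochs, {N_BANDS})")
        finite = np.isfinite(self.powers).all(axis=1)
        if (self.powers[finite] < 0).any():
            raise ValueError("band powers must be non-negative")
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.valid.shape != (self.powers.shape[0],):
            raise ValueError("valid mask must have one entry per epoch")

    @property
    def n_epochs(self) -> int:
        return self.powers.shape[0]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.powers, columns=BAND_COLUMNS)
        df.insert(0, "epoch_index", np.arange(self.n_epochs))
        df["valid"] = self.valid
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "EpochBandPowers":
        missing = [c for c in BAND_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"band-power table is missing columns: {missing}")
        powers = df[BAND_COLUMNS].to_numpy(float)
        if "valid" in df.columns:
            valid = df["valid"].to_numpy(bool)
        else:
            valid = np.isfinite(powers).all(axis=1) & (powers.sum(axis=1) > 0)
        return cls(powers=powers, valid=valid)

    @classmethod
    def from_csv(cls, path) -> "EpochBandPowers":
        return cls.from_frame(pd.read_csv(path))


@dataclass
class StateTrajectory:
    """Smoothed 2-D state-space coordinates per epoch.

    ``x`` is the log10 theta ratio (always <= 0 for valid epochs), ``y`` the
    log10 total 1-19 Hz power. Invalid epochs carry NaN coordinates and stay
    NaN after smoothing — gaps are explicit, never interpolated.
    """

    x: np.ndarray
    y: np.ndarray
    valid: np.ndarray
    smoothed: bool = True

    @property
    def n_epochs(self) -> int:
        return self.x.size

    def points(self) -> np.ndarray:
        """(n, 2) array of coordinates; invalid epochs are NaN rows."""
        return np.column_stack([self.x, self.y])

    def slice(self, start: int, stop: int) -> "StateTrajectory":
        """Sub-trajectory over epoch range [start, stop)."""
        return StateTrajectory(
            x=self.x[start:stop],
            y=self.y[start:stop],
            valid=self.valid[start:stop],
            smoothed=self.smoothed,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "epoch_index": np.arange(self.n_epochs),
                "x": self.x,
                "y": self.y,
                "valid": self.valid,
            }
        )


def compute_band_powers(
    signal: np.ndarray,
    fs: float,
    epoch_s: float = 5.0,
) -> EpochBandPowers:
    """Reduce a raw EEG trace to per-epoch 2-Hz band powers.

    The signal is cut into consecutive ``epoch_s`` windows (a trailing
    partial epoch is discarded); each window gets a single rectangular-window
    periodogram and band power is the sum of periodogram power over the
    band's frequency bins. Epochs containing non-finite samples are rejected
    (flagged invalid, recorded in the QC log); an all-zero epoch is flagged
    invalid as well.
    """
    signal = np.asarray(signal, dtype=float).ravel()
    if fs < 100.0:
        raise ValueError(
            f"sampling rate {fs} Hz is too low to resolve the 1-33 Hz analysis "
            "range reliably (need >= 100 Hz)"
        )
    n_per = int(round(fs * epoch_s))
    if signal.size < n_per:
        raise ValueError("signal shorter than one epoch")
    n_epochs = signal.size // n_per

    powers = np.zeros((n_epochs, N_BANDS))
    valid = np.ones(n_epochs, dtype=bool)
    qc: list[tuple[int, str]] = []

    # Frequency-bin masks are identical for every epoch.
    freqs = np.fft.rfftfreq(n_per, d=1.0 / fs)
    band_masks = [(freqs >= lo) & (freqs < hi) for lo, hi in BAND_EDGES]

    for e in range(n_epochs):
        seg = signal[e * n_per : (e + 1) * n_per]
        if not np.isfinite(seg).all():
            valid[e] = False
            qc.append((e, "non-finite samples"))
            powers[e] = np.nan
            continue
        _, pxx = periodogram(seg, fs=fs, window="boxcar", detrend=False)
        for b, mask in enumerate(band_masks):
            powers[e, b] = pxx[mask].sum()
        if powers[e].sum() == 0.0:
            valid[e] = False
            qc.append((e, "all-zero power"))

    return EpochBandPowers(
        powers=powers, valid=valid, epoch_s=epoch_s, sampling_rate_hz=fs, qc_log=qc
    )


def compute_trajectory(
    powers: EpochBandPowers,
    smooth_window: int = 5,
) -> StateTrajectory:
    """Map band powers to the smoothed 2-D state-space trajectory.

    The theta ratio is computed from band sums *before* the log transform.
    Each coordinate is smoothed with a centered moving average of width
    ``smooth_window`` (shrinking symmetric windows at the recording edges).
    Epochs with zero 1-9 Hz power (ratio undefined) are marked invalid.
    """
    if int(powers.valid.sum()) < smooth_window:
        raise ValueError("need at least `smooth_window` valid epochs")
    p = powers.powers
    valid = powers.valid.copy()

    with np.errstate(divide="ignore", invalid="ignore"):
        low = p[:, LOW_BANDS].sum(axis=1)
        total = p[:, TOTAL_BANDS].sum(axis=1)
        ratio = p[:, THETA_BAND] / low
        x_raw = np.log10(ratio)
        y_raw = np.log10(total)

    bad_den = valid & ~(np.isfinite(x_raw) & np.isfinite(y_raw))
    valid[bad_den] = False
    x_raw[~valid] = np.nan
    y_raw[~valid] = np.nan

    x = moving_average(x_raw, smooth_window)
    y = moving_average(y_raw, smooth_window)
    # Gaps stay gaps: an invalid epoch has no coordinate of its own.
    x[~valid] = np.nan
    y[~valid] = np.nan
    return StateTrajectory(x=x, y=y, valid=valid, smoothed=True)
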