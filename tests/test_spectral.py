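import numpy as np
import pytest

from sleepswitch.smoothing import moving_average
from sleepswitch.spectral import (
    BAND_EDGES,
    EpochBandPowers,
    compute_band_powers,
    compute_trajectory,
)


class TestComputeBandPowers:
    def test_zero_signal_gives_zero_invalid_epochs(self):
        bp = compute_band_powers(np.zeros(5000), fs=500.0)
        assert bp.n_epochs == 2
        assert np.allclose(bp.powers, 0.0)
        assert not bp.valid.any()
        assert all(reason == "all-zero power" for _, reason in bp.qc_log)

    def test_sinusoid_power_concentrates_in_its_band(self):
        fs, f0 = 500.0, 8.0
        t = np.arange(int(fs * 5)) / fs
        bp = compute_band_powers(np.sin(2 * np.pi * f0 * t), fs=fs)
        total = bp.powers[0].sum()
        theta = bp.powers[0, 3]  # 7-9 Hz band
        assert theta / total >= 0.99

    def test_white_noise_is_flat_across_bands(self, rng):
        n_epochs = 100
        sig = rng.standard_normal(int(500 * 5) * n_epochs)
        bp = compute_band_powers(sig, fs=500.0)
        means = bp.powers.mean(axis=0)
        sems = bp.powers.std(axis=0, ddof=1) / np.sqrt(n_epochs)
        grand = means.mean()
        assert np.all(np.abs(means - grand) < 3 * sems + 3 * sems.mean())

    def test_nonfinite_epoch_rejected_and_logged(self):
        sig = np.random.default_rng(0).standard_normal(7500)
        sig[3000] = np.nan
        bp = compute_band_powers(sig, fs=500.0)
        assert bp.valid.tolist() == [True, False, True]
        assert bp.qc_log == [(1, "non-finite samples")]

    def test_trailing_partial_epoch_discarded(self):
        bp = compute_band_powers(np.ones(2600), fs=500.0)
        assert bp.n_epochs == 1

    def test_low_sampling_rate_rejected(self):
        with pytest.raises(ValueError, match="too low"):
            compute_band_powers(np.zeros(1000), fs=50.0)

    def test_band_layout(self):
        assert len(BAND_EDGES) == 16
        assert BAND_EDGES[0] == (1.0, 3.0)
        assert BAND_EDGES[-1] == (31.0, 33.0)
        # contiguous
        for (_, hi), (lo, _) in zip(BAND_EDGES[:-1], BAND_EDGES[1:]):
            assert hi == lo


def _powers(rows):
    rows = np.asarray(rows, dtype=float)
    return EpochBandPowers(powers=rows, valid=np.ones(len(rows), bool))


class TestComputeTrajectory:
    def test_constant_powers_give_constant_coordinates(self):
        row = np.linspace(1, 2, 16)
        bp = _powers(np.tile(row, (10, 1)))
        traj = compute_trajectory(bp)
        assert np.allclose(traj.x, traj.x[0])
        assert np.allclose(traj.y, traj.y[0])

    def test_all_low_power_in_theta_gives_x_zero(self):
        row = np.zeros(16)
        row[3] = 5.0  # all 1-9 Hz power in 7-9 Hz
        row[8] = 1.0  # some 17-19 Hz power so y is finite
        bp = _powers(np.tile(row, (8, 1)))
        traj = compute_trajectory(bp)
        assert np.allclose(traj.x, 0.0)

    def test_x_never_positive(self, rng):
        bp = _powers(rng.uniform(0.1, 5.0, size=(50, 16)))
        traj = compute_trajectory(bp)
        assert np.all(traj.x[traj.valid] <= 1e-12)

    def test_step_in_y_ramps_linearly_over_window(self):
        row_lo = np.full(16, 1.0)
        row_hi = np.full(16, 10.0)
        k = 10
        bp = _powers(np.vstack([np.tile(row_lo, (k, 1)), np.tile(row_hi, (k, 1))]))
        traj = compute_trajectory(bp, smooth_window=5)
        y_lo, y_hi = np.log10(9.0 * 1.0), np.log10(9.0 * 10.0)
        # closed-form response of a width-5 centered moving average to a step
        expected = np.array([y_lo, (4 * y_lo + y_hi) / 5, (3 * y_lo + 2 * y_hi) / 5,
                             (2 * y_lo + 3 * y_hi) / 5, (y_lo + 4 * y_hi) / 5, y_hi])
        assert np.allclose(traj.y[k - 3 : k + 3], expected)

    def test_zero_denominator_marks_epoch_invalid(self):
        rows = np.tile(np.linspace(1, 2, 16), (8, 1))
        rows[4, :4] = 0.0  # no 1-9 Hz power
        bp = _powers(rows)
        traj = compute_trajectory(bp)
        assert not traj.valid[4]
        assert np.isnan(traj.x[4])


class TestMovingAverage:
    def test_shrinking_edges(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        out = moving_average(x, 3)
        assert out[0] == 1.0 and out[-1] == 5.0
        assert np.allclose(out[1:-1], [2.0, 3.0, 4.0])

    def test_commutes_with_affine_transform(self, rng):
        x = rng.standard_normal(40)
        a, b = 2.5, -1.0
        assert np.allclose(moving_average(a * x + b, 5),
                           a * moving_average(x, 5) + b)

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            moving_average(np.arange(5.0), 4)
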