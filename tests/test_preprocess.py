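import numpy as np
import pytest
from scipy import signal

from conftest import make_recording
from ecogseg.preprocess import (
    POWER_EPS,
    bin_power,
    car_per_grid,
    extract_epochs,
    gamma_log_power,
    highpass,
    notch,
    preprocess_chain,
)

FS = 1200.0


def sine(freq, seconds=4.0, amp=1.0, fs=FS):
    t = np.arange(int(seconds * fs)) / fs
    return amp * np.sin(2 * np.pi * freq * t)


def zero_phase_gain(b, a, freq, fs=FS):
    """Magnitude response of the forward-backward filter at one frequency."""
    _, h = signal.freqz(b, a, worN=[freq], fs=fs)
    return np.abs(h[0]) ** 2  # filtfilt applies the filter twice


def zero_phase_gain_sos(sos, freq, fs=FS):
    _, h = signal.sosfreqz(sos, worN=[freq], fs=fs)
    return np.abs(h[0]) ** 2


class TestHighpass:
    def test_dc_removed(self):
        rec = make_recording(np.full((2, 4800), 5.0))
        out = highpass(rec)
        assert np.max(np.abs(out.data)) < 1e-6 * 5.0

    def test_passband_sinusoid_preserved(self):
        # oracle: squared magnitude response of the order-4 Butterworth at 10 Hz
        sos = signal.butter(4, 0.5, btype="highpass", fs=FS, output="sos")
        expected = zero_phase_gain_sos(sos, 10.0)
        rec = make_recording(sine(10.0, seconds=8.0))
        out = highpass(rec)
        mid = out.data[0, 2400:-2400]
        measured = mid.std() / sine(10.0, seconds=8.0)[2400:-2400].std()
        assert expected > 0.99  # the filter itself barely touches 10 Hz
        assert abs(measured - expected) < 0.01

    def test_white_noise_mean_removed(self, rng):
        rec = make_recording(rng.standard_normal((1, 9600)) + 3.0)
        out = highpass(rec)
        assert abs(out.data.mean()) < 0.02

    def test_short_signal_rejected(self):
        rec = make_recording(np.zeros((1, 10)))
        with pytest.raises(ValueError, match="pad"):
            highpass(rec)


class TestNotch:
    def test_120hz_attenuated_40db(self):
        rec = make_recording(sine(120.0, seconds=8.0))
        out = notch(rec)
        mid = out.data[0, 2400:-2400]
        power_ratio = (mid**2).mean() / 0.5  # input power of unit sinusoid
        assert 10 * np.log10(power_ratio) < -40

    def test_100hz_nearly_untouched(self):
        b, a = signal.iirnotch(120.0, 35.0, fs=FS)
        expected = zero_phase_gain(b, a, 100.0)
        rec = make_recording(sine(100.0, seconds=8.0))
        out = notch(rec)
        mid = out.data[0, 2400:-2400]
        measured = mid.std() / sine(100.0, seconds=8.0)[2400:-2400].std()
        assert abs(measured - 1.0) < 0.05
        assert abs(measured - expected) < 0.01

    def test_zero_signal_stays_zero(self):
        rec = make_recording(np.zeros((2, 4800)))
        out = notch(rec)
        assert np.all(out.data == 0)


class TestCAR:
    def test_common_signal_removed(self):
        common = sine(7.0, seconds=1.0)
        rec = make_recording(np.tile(common, (4, 1)))
        out = car_per_grid(rec)
        assert np.max(np.abs(out.data)) < 1e-12

    def test_grids_independent(self, rng):
        base = rng.standard_normal((4, 1200))
        data = base.copy()
        data[:2] += 10.0  # common-mode only on grid 0
        rec = make_recording(data, n_grids=2)
        out = car_per_grid(rec)
        ref = car_per_grid(make_recording(base, n_grids=2))
        np.testing.assert_allclose(out.data[2:], ref.data[2:], atol=1e-12)

    def test_per_grid_mean_zero(self, rng):
        rec = make_recording(rng.standard_normal((6, 600)), n_grids=2)
        out = car_per_grid(rec)
        for g in (0, 1):
            sel = rec.grid_of == g
            assert np.max(np.abs(out.data[sel].mean(axis=0))) < 1e-10


class TestGammaLogPower:
    def test_amplitude_doubling_shifts_log_power_by_log4(self):
        # 101.3 Hz is incommensurate with fs=1200, so no sample lands on an
        # exact zero crossing where the eps floor would blunt the log shift
        rec1 = make_recording(sine(101.3, seconds=8.0, amp=1.0))
        rec2 = make_recording(sine(101.3, seconds=8.0, amp=2.0))
        p1 = gamma_log_power(rec1).data[0, 2400:-2400]
        p2 = gamma_log_power(rec2).data[0, 2400:-2400]
        assert abs((p2.mean() - p1.mean()) - np.log(4.0)) < 0.01
        # and the linear-power ratio is the analytic 4x
        ratio = np.exp(p2).mean() / np.exp(p1).mean()
        assert ratio == pytest.approx(4.0, rel=0.01)

    def test_out_of_band_suppressed(self):
        in_band = gamma_log_power(make_recording(sine(100.0, seconds=8.0)))
        out_band = gamma_log_power(make_recording(sine(30.0, seconds=8.0)))
        p_in = np.exp(in_band.data[0, 2400:-2400]).mean()
        p_out = np.exp(out_band.data[0, 2400:-2400]).mean()
        assert p_out <= 0.01 * p_in

    def test_zero_signal_gives_log_eps(self):
        rec = make_recording(np.zeros((1, 4800)))
        out = gamma_log_power(rec)
        np.testing.assert_allclose(out.data, np.log(POWER_EPS))


class TestEpochs:
    def test_epoch_length_840_samples(self, rng):
        rec = make_recording(rng.standard_normal((2, 2400)))
        epochs, kept, dropped = extract_epochs(rec, np.array([1.0]))
        assert epochs.shape == (1, 2, 840)
        assert dropped == 0

    def test_edge_epoch_dropped_and_counted(self, rng):
        rec = make_recording(rng.standard_normal((1, 600)))  # 0.5 s
        epochs, kept, dropped = extract_epochs(rec, np.array([0.1]))
        assert epochs.shape[0] == 0
        assert dropped == 1

    def test_overlapping_epochs_both_kept(self, rng):
        rec = make_recording(rng.standard_normal((1, 4800)))
        epochs, kept, dropped = extract_epochs(rec, np.array([2.0, 2.08]))
        assert epochs.shape[0] == 2
        assert dropped == 0
        # 80 ms apart = 96 samples: shared content is shifted, not copied
        np.testing.assert_allclose(epochs[0, 0, 96:], epochs[1, 0, :-96])


class TestBinning:
    def test_spatial_grid_gives_27_bins(self, rng):
        epochs = rng.standard_normal((3, 2, 840))
        binned, centers = bin_power(epochs, FS, bin_ms=50, step_ms=25)
        assert binned.shape == (3, 2, 27)
        assert centers[0] == -325.0 and centers[-1] == 325.0

    def test_temporal_grid_gives_66_bins(self, rng):
        epochs = rng.standard_normal((1, 1, 840))
        binned, centers = bin_power(epochs, FS, bin_ms=50, step_ms=10)
        assert binned.shape[-1] == 66
        np.testing.assert_allclose(np.diff(centers), 10.0)

    def test_constant_power_preserved(self):
        epochs = np.full((2, 3, 840), 1.7)
        binned, _ = bin_power(epochs, FS)
        np.testing.assert_allclose(binned, 1.7)

    def test_bin_longer_than_window_rejected(self):
        with pytest.raises(ValueError, match="bin"):
            bin_power(np.zeros((1, 1, 100)), FS, bin_ms=200, step_ms=25)


class TestChain:
    def test_chain_preserves_channels_and_grids(self, rng):
        rec = make_recording(rng.standard_normal((4, 4800)), n_grids=2)
        out = preprocess_chain(rec)
        assert out.data.shape == rec.data.shape
        np.testing.assert_array_equal(out.grid_of, rec.grid_of)

    def test_epochs_stable_under_concatenation(self, rng):
        """The same event, embedded at two positions in a longer recording,
        yields the same binned epoch values (away from filter edges)."""
        x = rng.standard_normal((2, 12000))  # 10 s
        doubled = np.concatenate([x, x], axis=1)
        out = preprocess_chain(make_recording(doubled))
        e1, _, _ = extract_epochs(out, np.array([5.0]))
        e2, _, _ = extract_epochs(out, np.array([15.0]))
        b1, _ = bin_power(e1, FS)
        b2, _ = bin_power(e2, FS)
        np.testing.assert_allclose(b1, b2, atol=0.05)
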