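"""ECoG signal chain: high-pass, 120 Hz notch, per-grid CAR, gamma log power.

The chain mirrors a standard event-related high-gamma analysis:

1. zero-phase (forward-backward) Butterworth high-pass at 0.5 Hz, order 4,
   to remove DC and drift;
2. zero-phase IIR notch at 120 Hz with Q = 35 — the only power-line
   component inside the analysis band (60 and 180 Hz fall outside 70-170 Hz
   and are deliberately left in);
3. common-average re-referencing, separately for each electrode grid;
4. gamma band power: order-4 zero-phase Butterworth band-pass 70-170 Hz,
   squared, natural-log transformed (with a tiny floor so exact zeros do
   not map to -inf).

Epochs are 700 ms windows centered on phoneme onsets (350 ms pre, 350 ms
post, half-open on the right), then reduced to per-bin mean log power on an
overlapping time-bin grid (50 ms bins / 25 ms steps -> 27 bins for the
spatial analysis; 50 ms / 10 ms steps -> 66 bins for the temporal one).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import h5py
import numpy as np
from scipy import signal

__all__ = [
    "Recording",
    "EpochSet",
    "highpass",
    "notch",
    "car_per_grid",
    "gamma_log_power",
    "preprocess_chain",
    "extract_epochs",
    "bin_power",
    "read_recording",
    "write_recording",
]

#: Floor added to the squared band-passed signal before the log transform,
#: in squared signal units; far below any physiological gamma power.
POWER_EPS = 1e-12

GAMMA_BAND = (70.0, 170.0)


@dataclass
class Recording:
    """Multi-channel recording: ``data`` is channels x samples."""

    data: np.ndarray
    fs: float
    grid_of: np.ndarray  # per-channel grid identifier (int)
    coords: np.ndarray | None = None  # channels x 2 (or 3), template units

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.grid_of = np.asarray(self.grid_of)
        if self.data.ndim != 2:
            raise ValueError("data must be channels x samples")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if len(self.grid_of) != self.n_channels:
            raise ValueError("grid_of length must equal channel count")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("recording contains NaN/Inf samples")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass
class EpochSet:
    """Binned epoch power with +/- labels.

    ``power`` is epochs x channels x bins of mean log gamma power;
    ``labels`` is boolean with True = "+"; ``bin_centers`` are bin-midpoint
    latencies in ms relative to phoneme onset.
    """

    power: np.ndarray
    labels: np.ndarray
    bin_centers: np.ndarray
    window_ms: tuple[float, float] = (350.0, 350.0)
    onsets: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=bool)
        if self.power.shape[0] != len(self.labels):
            raise ValueError("one label per epoch required")
        if np.any(np.diff(self.bin_centers) <= 0):
            raise ValueError("bin centers must be strictly increasing")

    @property
    def label_chars(self) -> np.ndarray:
        return np.where(self.labels, "+", "-")


def _filtfilt(b, a, rec: Recording) -> Recording:
    pad = 3 * (max(len(a), len(b)) - 1)
    if rec.n_samples <= pad:
        raise ValueError(
            f"signal of {rec.n_samples} samples is shorter than the filter "
            f"pad length ({pad})"
        )
    return replace(rec, data=signal.filtfilt(b, a, rec.data, axis=1))


def _sosfiltfilt(sos, rec: Recording) -> Recording:
    pad = 3 * (2 * sos.shape[0] + 1)
    if rec.n_samples <= pad:
        raise ValueError(
            f"signal of {rec.n_samples} samples is shorter than the filter "
            f"pad length ({pad})"
        )
    return replace(rec, data=signal.sosfiltfilt(sos, rec.data, axis=1))


def highpass(rec: Recording, cutoff_hz: float = 0.5, order: int = 4) -> Recording:
    """Zero-phase Butterworth high-pass (removes DC/drift).

    Second-order sections keep the order-4 filter numerically exact at the
    extreme normalized cutoff (0.5 Hz of a 1200 Hz rate).
    """
    if rec.fs <= 2 * cutoff_hz:
        raise ValueError("sampling rate too low for the requested cutoff")
    sos = signal.butter(order, cutoff_hz, btype="highpass", fs=rec.fs,
                        output="sos")
    return _sosfiltfilt(sos, rec)


def notch(rec: Recording, f0_hz: float = 120.0, q: float = 35.0) -> Recording:
    """Zero-phase IIR notch at ``f0_hz`` with quality factor ``q`` = f0/bw."""
    if rec.fs <= 2 * f0_hz:
        raise ValueError("sampling rate too low for the requested notch")
    b, a = signal.iirnotch(f0_hz, q, fs=rec.fs)
    return _filtfilt(b, a, rec)


def car_per_grid(rec: Recording) -> Recording:
    """Common average reference, computed separately within each grid."""
    data = rec.data.copy()
    for g in np.unique(rec.grid_of):
        sel = rec.grid_of == g
        data[sel] -= data[sel].mean(axis=0, keepdims=True)
    return replace(rec, data=data)


def gamma_log_power(
    rec: Recording,
    band: tuple[float, float] = GAMMA_BAND,
    order: int = 4,
    eps: float = POWER_EPS,
) -> Recording:
    """Per-sample log gamma power: band-pass, square, natural log."""
    if rec.fs <= 2 * band[1]:
        raise ValueError("sampling rate too low for the requested band")
    sos = signal.butter(order, band, btype="bandpass", fs=rec.fs, output="sos")
    bp = _sosfiltfilt(sos, rec)
    return replace(bp, data=np.log(bp.data**2 + eps))


def preprocess_chain(rec: Recording) -> Recording:
    """Full chain: high-pass -> 120 Hz notch -> per-grid CAR -> log gamma power."""
    return gamma_log_power(car_per_grid(notch(highpass(rec))))


def extract_epochs(
    rec: Recording,
    onsets: np.ndarray,
    pre_ms: float = 350.0,
    post_ms: float = 350.0,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Cut per-event windows ``[onset - pre, onset + post)`` from a recording.

    Events whose window would run past either edge of the recording are
    dropped (never padded).

    Returns
    -------
    epochs : (n_kept, channels, samples) array
    kept : indices into ``onsets`` of the retained events
    n_dropped : number of events dropped at the recording edges
    """
    onsets = np.asarray(onsets, dtype=float)
    pre = int(round(pre_ms * rec.fs / 1000.0))
    post = int(round(post_ms * rec.fs / 1000.0))
    starts = np.round(onsets * rec.fs).astype(int) - pre
    ok = (starts >= 0) & (starts + pre + post <= rec.n_samples)
    kept = np.flatnonzero(ok)
    n = pre + post
    out = np.empty((len(kept), rec.n_channels, n), dtype=float)
    for i, s in enumerate(starts[kept]):
        out[i] = rec.data[:, s : s + n]
    return out, kept, int(len(onsets) - len(kept))


def bin_power(
    epochs: np.ndarray,
    fs: float,
    bin_ms: float = 50.0,
    step_ms: float = 25.0,
    pre_ms: float = 350.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Average epoch samples into overlapping time bins.

    Returns ``(binned, bin_centers_ms)`` where ``binned`` is
    epochs x channels x bins and centers are the bins' temporal midpoints
    relative to event onset.  A 700 ms window at 50 ms bins / 25 ms steps
    yields 27 bins; at 10 ms steps, 66 bins.
    """
    n_samp = epochs.shape[-1]
    blen = int(round(bin_ms * fs / 1000.0))
    step = int(round(step_ms * fs / 1000.0))
    if blen > n_samp:
        raise ValueError("bin longer than epoch window")
    if step <= 0:
        raise ValueError("step must be positive")
    n_bins = (n_samp - blen) // step + 1
    starts = np.arange(n_bins) * step
    binned = np.empty(epochs.shape[:-1] + (n_bins,), dtype=float)
    for k, s in enumerate(starts):
        binned[..., k] = epochs[..., s : s + blen].mean(axis=-1)
    centers = -pre_ms + starts * 1000.0 / fs + bin_ms / 2.0
    return binned, centers


# ---------------------------------------------------------------------------
# Recording container: single HDF5 file with datasets data / fs / grid_of
# and optionally coords.  Written by the simulator, validated on read.


def write_recording(path, rec: Recording) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=rec.data)
        f.create_dataset("fs", data=float(rec.fs))
        f.create_dataset("grid_of", data=np.asarray(rec.grid_of, dtype=np.int64))
        if rec.coords is not None:
            f.create_dataset("coords", data=np.asarray(rec.coords, dtype=float))


def read_recording(path) -> Recording:
    with h5py.File(path, "r") as f:
        coords = f["coords"][()] if "coords" in f else None
        return Recording(
            data=f["data"][()],
            fs=float(f["fs"][()]),
            grid_of=f["grid_of"][()],
            coords=coords,
        )
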