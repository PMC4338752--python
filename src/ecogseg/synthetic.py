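"""Ground-truth simulator for phoneme-locked gamma-band ECoG.

Generates (a) phoneme alignment + word-boundary tables with class
frequencies matching continuous English speech, and (b) a multi-channel
recording with the noise structure the analysis chain assumes:

* per-channel 1/f background (FFT-shaped Gaussian noise),
* a shared common-mode component within each electrode grid (removed by
  per-grid CAR),
* power-line sinusoids at 60 / 120 / 180 Hz (only 120 Hz lies inside the
  70-170 Hz analysis band and is notched by the chain),
* for each configured effect: band-limited (70-170 Hz) Gaussian noise
  bursts added at designated electrodes, time-locked to the onsets of
  phonemes that are "+" on the effect's feature dimension.  The burst is
  multiplicative in amplitude terms: its standard deviation is
  ``gain`` times the electrode's baseline gamma-band noise SD, and the
  burst window is *centered* at onset + latency.

Everything is reproducible from ``SimConfig.seed``; the ground truth
(which electrodes carry which feature effect, at what latency and gain)
is returned alongside the recording so recovery can be scored.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal

from . import phonology
from .preprocess import GAMMA_BAND, Recording, write_recording

__all__ = [
    "Effect",
    "SimConfig",
    "sample_alignments",
    "synthesize_recording",
    "write_fixture",
    "study_effects",
    "CONSONANT_P",
    "VOWEL_FRACTION",
]

#: Fraction of generated phonemes that are vowels.
VOWEL_FRACTION = 0.392

# Per-consonant sampling probabilities (conditional on drawing a consonant),
# chosen to match observed per-consonant place frequencies as closely as the
# feature geometry allows: labial 0.229 (exact), dorsal 0.124 (exact),
# coronal 0.761 (0.780 is infeasible jointly with the other two because only
# /w/ carries two place features).
CONSONANT_P: dict[str, float] = {}
for _ph in ("B", "P", "F", "V", "M"):
    CONSONANT_P[_ph] = 0.109 / 5
CONSONANT_P["W"] = 0.120
for _ph in ("K", "G", "NG"):
    CONSONANT_P[_ph] = 0.004 / 3
CONSONANT_P["HH"] = 0.006
for _ph in ("T", "D", "TH", "DH", "S", "Z", "SH", "ZH", "N", "CH", "JH",
            "R", "L", "Y"):
    CONSONANT_P[_ph] = 0.761 / 14


@dataclass(frozen=True)
class Effect:
    """A feature-locked gamma burst at a set of electrodes.

    ``gain`` scales the burst SD relative to the electrode's baseline
    gamma-band SD (gain 1.5 means the burst roughly triples gamma power).
    The burst occupies ``[onset + latency - duration/2,
    onset + latency + duration/2)``.
    """

    dimension: str
    electrodes: tuple[int, ...]
    gain: float = 1.5
    latency_ms: float = 50.0
    duration_ms: float = 100.0


@dataclass
class SimConfig:
    n_electrodes: int = 48
    n_grids: int = 1
    fs: float = 1200.0
    duration_s: float = 120.0
    phoneme_rate: float = 10.0  # phonemes per second within words
    background_exponent: float = 1.0  # 1/f^exponent PSD slope
    background_amplitude: float = 15.0  # SD, arbitrary microvolt-scale units
    common_mode_amplitude: float = 10.0
    line_amplitudes: dict = field(
        default_factory=lambda: {60.0: 4.0, 120.0: 1.5, 180.0: 0.8}
    )
    effects: tuple[Effect, ...] = ()
    seed: int = 0

    def __post_init__(self):
        if self.fs <= 2 * GAMMA_BAND[1]:
            raise ValueError("fs must exceed twice the gamma-band upper edge")
        for eff in self.effects:
            if eff.gain < 0:
                raise ValueError("effect gains must be non-negative")
            if eff.dimension not in phonology.LABEL_DIMENSIONS:
                raise ValueError(f"unknown dimension {eff.dimension!r}")
            if not set(eff.electrodes) <= set(range(self.n_electrodes)):
                raise ValueError("effect electrodes outside the montage")


def _grid_assignment(cfg: SimConfig) -> np.ndarray:
    return np.minimum(
        np.arange(cfg.n_electrodes) * cfg.n_grids // cfg.n_electrodes,
        cfg.n_grids - 1,
    )


def _grid_coords(cfg: SimConfig) -> np.ndarray:
    # 8-column grid, 10 mm pitch.
    idx = np.arange(cfg.n_electrodes)
    return np.column_stack((idx % 8, idx // 8)) * 10.0


def sample_alignments(cfg: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw a phoneme alignment table and its word boundaries.

    Words are 2-8 phonemes; phoneme durations jitter around
    1/phoneme_rate.  Half the inter-word pauses are long (1.5-2.5 s) so the
    recording contains enough 700 ms silence windows for the
    speech-vs-silence screening; the rest are short (150-350 ms).
    """
    if cfg.phoneme_rate <= 0:
        raise ValueError("phoneme_rate must be positive")
    if cfg.phoneme_rate * cfg.duration_s < 50:
        raise ValueError("config too short to generate a usable alignment")
    rng = np.random.default_rng([cfg.seed, 0])
    cons = list(CONSONANT_P)
    cons_p = np.array([CONSONANT_P[c] for c in cons])
    cons_p = cons_p / cons_p.sum()
    vowels = list(phonology.VOWELS)

    rows = []
    words = []
    t = 2.0  # lead-in silence covers the 350 ms pre-window
    margin = cfg.duration_s - 2.0
    widx = 0
    while True:
        n_ph = int(rng.integers(2, 9))
        durs = (1.0 / cfg.phoneme_rate) * rng.uniform(0.8, 1.2, size=n_ph)
        if t + durs.sum() > margin:
            break
        onset_word = t
        syms = []
        for d in durs:
            if rng.uniform() < VOWEL_FRACTION:
                ph = vowels[rng.integers(len(vowels))]
            else:
                ph = cons[rng.choice(len(cons), p=cons_p)]
            syms.append(ph)
            rows.append((ph, t, t + d, widx))
            t += d
        words.append(("".join(syms).lower(), onset_word, t))
        widx += 1
        if rng.uniform() < 0.5:
            t += rng.uniform(1.5, 2.5)
        else:
            t += rng.uniform(0.15, 0.35)
    alignments = pd.DataFrame(
        rows, columns=["phoneme", "onset", "offset", "word_index"]
    )
    word_df = pd.DataFrame(words, columns=["word", "onset", "offset"])
    return alignments, word_df


def _colored_noise(rng: np.random.Generator, n: int, exponent: float) -> np.ndarray:
    """Unit-SD Gaussian noise with a 1/f^exponent power spectrum."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    scale = np.zeros_like(f)
    scale[1:] = f[1:] ** (-exponent / 2.0)
    x = np.fft.irfft(spec * scale, n=n)
    return x / x.std()


def _band_noise(rng: np.random.Generator, n: int, fs: float) -> np.ndarray:
    """Unit-SD band-limited (gamma band) Gaussian noise."""
    b, a = signal.butter(4, GAMMA_BAND, btype="bandpass", fs=fs)
    x = signal.filtfilt(b, a, rng.standard_normal(n))
    return x / x.std()


def synthesize_recording(
    cfg: SimConfig, alignments: pd.DataFrame
) -> tuple[Recording, pd.DataFrame]:
    """Render the recording for an alignment table.

    Returns the :class:`Recording` and a ground-truth table with one row
    per (effect, electrode): dimension, electrode, gain, latency_ms,
    duration_ms.
    """
    rng = np.random.default_rng([cfg.seed, 1])
    n = int(round(cfg.duration_s * cfg.fs))
    tvec = np.arange(n) / cfg.fs
    data = np.empty((cfg.n_electrodes, n))
    background = np.empty_like(data)
    for ch in range(cfg.n_electrodes):
        background[ch] = cfg.background_amplitude * _colored_noise(
            rng, n, cfg.background_exponent
        )
    grid_of = _grid_assignment(cfg)
    data[:] = background
    for g in np.unique(grid_of):
        cm = cfg.common_mode_amplitude * _colored_noise(
            rng, n, cfg.background_exponent
        )
        data[grid_of == g] += cm
    for f0, amp in cfg.line_amplitudes.items():
        phases = rng.uniform(0, 2 * np.pi, size=cfg.n_electrodes)
        amps = amp * rng.uniform(0.8, 1.2, size=cfg.n_electrodes)
        data += amps[:, None] * np.sin(2 * np.pi * f0 * tvec + phases[:, None])

    # Baseline gamma-band SD per channel sets the burst scale.
    b, a = signal.butter(4, GAMMA_BAND, btype="bandpass", fs=cfg.fs)
    sigma_gamma = signal.filtfilt(b, a, background, axis=1).std(axis=1)

    table = phonology.build_feature_table()
    truth_rows = []
    for eff in cfg.effects:
        labels = phonology.label_for_feature(alignments, table, eff.dimension)
        pos_onsets = labels.loc[labels["label"] == "+", "onset"].to_numpy()
        half = eff.duration_ms / 2000.0
        envelope = np.zeros(n)
        blen = int(round(eff.duration_ms / 1000.0 * cfg.fs))
        taper = signal.windows.tukey(max(blen, 2), alpha=0.25)
        for onset in pos_onsets:
            c = onset + eff.latency_ms / 1000.0
            s = int(round((c - half) * cfg.fs))
            e = s + blen
            if s < 0 or e > n:
                continue
            # overlapping bursts merge rather than stack
            envelope[s:e] = np.maximum(envelope[s:e], taper[: e - s])
        for ch in eff.electrodes:
            burst = _band_noise(rng, n, cfg.fs)
            data[ch] += eff.gain * sigma_gamma[ch] * envelope * burst
            truth_rows.append(
                (eff.dimension, ch, eff.gain, eff.latency_ms, eff.duration_ms)
            )
    truth = pd.DataFrame(
        truth_rows,
        columns=["dimension", "electrode", "gain", "latency_ms", "duration_ms"],
    )
    rec = Recording(data=data, fs=cfg.fs, grid_of=grid_of, coords=_grid_coords(cfg))
    return rec, truth


def write_fixture(cfg: SimConfig, outdir) -> dict[str, Path]:
    """Write a complete fixture: recording container, alignment, word and
    ground-truth tables.  Seed-reproducible."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    alignments, words = sample_alignments(cfg)
    rec, truth = synthesize_recording(cfg, alignments)
    paths = {
        "recording": outdir / "recording.h5",
        "alignments": outdir / "alignments.tsv",
        "words": outdir / "words.tsv",
        "ground_truth": outdir / "ground_truth.tsv",
    }
    write_recording(paths["recording"], rec)
    phonology.write_alignments(paths["alignments"], alignments)
    phonology.write_words(paths["words"], words)
    truth.to_csv(paths["ground_truth"], sep="\t", index=False)
    return paths


def study_effects(n_electrodes: int = 48) -> tuple[Effect, ...]:
    """A realistic multi-dimension effect layout for the analysis scripts.

    Electrode counts per dimension scale the reported topography of
    segmental-feature discrimination (coronal most widespread, dorsal most
    focal) to a 48-channel montage; latencies follow the reported peak
    order (place peaks just after onset, manner/voicing/phonological later).
    """
    rng = np.random.default_rng(2015)
    layout = {
        "labial": (4, 25.0),
        "coronal": (9, 35.0),
        "dorsal": (2, 45.0),
        "obstruent": (5, 85.0),
        "voiced": (6, 95.0),
        "vowel": (4, 95.0),
    }
    effects = []
    for dim, (count, latency) in layout.items():
        electrodes = tuple(
            int(e) for e in rng.choice(n_electrodes, size=count, replace=False)
        )
        effects.append(
            Effect(dimension=dim, electrodes=electrodes, latency_ms=latency)
        )
    return tuple(effects)
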