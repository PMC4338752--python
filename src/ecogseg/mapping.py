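"""Study-level analyses: screening, spatial topography, temporal dynamics.

Three orchestrated analyses sit on top of the signal chain and the
mRMR + shrinkage-LDA engine:

* **Screening** — can spoken words be discriminated from silence at all?
  700 ms epochs centered on words and on silence windows, 27 time-bin
  features per electrode pooled over the montage, mRMR down to 50
  features, 5-fold CV; a subject passes when the AUC exceeds 0.8.
* **Spatial topography** — per electrode, 27 time-bin features, mRMR to
  10, 5-fold CV per binary feature contrast; the CV AUC maps through the
  Hanley-McNeil normal test and BH-FDR to an activation index per
  electrode.  Place runs three one-vs-rest contrasts (labial, coronal,
  dorsal); manner, voicing and the phonological class are single binary
  contrasts.
* **Temporal dynamics** — restricted to electrodes significant in the
  spatial analysis; gamma power re-binned at 50 ms / 10 ms steps (66
  bins); a single-feature LDA per (electrode, bin) gives an AUC -> AI
  series whose mean over electrodes is the temporal activation profile
  (peak and local maxima reported on the 10 ms latency grid).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from . import phonology
from .classify import cross_validate
from .preprocess import EpochSet, Recording, bin_power, extract_epochs, preprocess_chain
from .stats import AI_ALPHA, activation_index, auc_stat, fdr_adjust

__all__ = [
    "ScreeningResult",
    "TemporalProfile",
    "screening_pass",
    "phoneme_epoch_set",
    "screen_subject",
    "spatial_analysis",
    "temporal_analysis",
    "accumulate_across_subjects",
    "significant_electrodes",
    "render_map",
    "SCREEN_AUC_THRESHOLD",
]

SCREEN_AUC_THRESHOLD = 0.8


@dataclass
class ScreeningResult:
    auc: float
    passed: bool
    n_word_epochs: int
    n_silence_epochs: int
    threshold: float = SCREEN_AUC_THRESHOLD


@dataclass
class TemporalProfile:
    dimension: str
    bin_centers: np.ndarray  # latency in ms, 10 ms grid
    ai_series: np.ndarray  # mean AI over electrodes per bin
    peak_ai: float
    peak_latency_ms: float
    local_maxima_ms: np.ndarray
    electrodes: np.ndarray
    ai_matrix: np.ndarray = field(repr=False, default=None)  # type: ignore


def screening_pass(aucs: dict, threshold: float = SCREEN_AUC_THRESHOLD) -> dict:
    """Apply the inclusion rule AUC > threshold to a table of subject AUCs."""
    return {subject: float(a) > threshold for subject, a in aucs.items()}


def phoneme_epoch_set(
    power_rec: Recording,
    alignments: pd.DataFrame,
    dimension: str,
    feature_table: pd.DataFrame | None = None,
    bin_ms: float = 50.0,
    step_ms: float = 25.0,
) -> EpochSet:
    """Phoneme-locked binned epochs labeled along one feature dimension.

    ``power_rec`` must already hold log gamma power (see
    :func:`ecogseg.preprocess.preprocess_chain`).  Epochs that overrun the
    recording edges are dropped.
    """
    if feature_table is None:
        feature_table = phonology.build_feature_table()
    labels = phonology.label_for_feature(alignments, feature_table, dimension)
    epochs, kept, _ = extract_epochs(power_rec, labels["onset"].to_numpy())
    binned, centers = bin_power(epochs, power_rec.fs, bin_ms=bin_ms, step_ms=step_ms)
    y = (labels["label"].to_numpy() == "+")[kept]
    return EpochSet(
        power=binned,
        labels=y,
        bin_centers=centers,
        onsets=labels["onset"].to_numpy()[kept],
    )


def _silence_centers(
    words: pd.DataFrame,
    duration_s: float,
    window_s: float = 0.7,
    guard_s: float = 0.15,
) -> np.ndarray:
    """Centers of non-overlapping 700 ms windows tiled into silent gaps.

    Gaps are the intervals between consecutive word offsets and onsets
    (plus the recording lead-in/out), shrunk by a guard so speech-locked
    activity cannot bleed into "silence" epochs.
    """
    w = words.sort_values("onset")
    edges = [(0.0, float(w["onset"].iloc[0]))]
    edges += list(
        zip(w["offset"].to_numpy()[:-1], w["onset"].to_numpy()[1:], strict=True)
    )
    edges.append((float(w["offset"].iloc[-1]), duration_s))
    centers = []
    for lo, hi in edges:
        lo, hi = lo + guard_s, hi - guard_s
        n_fit = int((hi - lo) // window_s)
        for k in range(n_fit):
            centers.append(lo + (k + 0.5) * window_s)
    return np.array(centers)


def screen_subject(
    rec: Recording,
    words: pd.DataFrame,
    seed: int = 0,
    threshold: float = SCREEN_AUC_THRESHOLD,
    k_select: int = 50,
    n_folds: int = 5,
) -> ScreeningResult:
    """Speech-vs-silence discrimination screening for one subject.

    Word epochs (700 ms centered on each word's midpoint) and an equal
    number of silence epochs are classified from the pooled
    27-bins-per-electrode feature set with mRMR (50 features) and
    shrinkage LDA under 5-fold CV.  A subject passes at AUC > 0.8.
    """
    if len(words) < 10:
        raise ValueError("need at least 10 words to screen a subject")
    power = preprocess_chain(rec)
    duration_s = rec.n_samples / rec.fs
    word_centers = ((words["onset"] + words["offset"]) / 2.0).to_numpy()
    sil_centers = _silence_centers(words, duration_s)
    if len(sil_centers) < 10:
        raise ValueError(
            f"only {len(sil_centers)} non-overlapping 700 ms silence windows "
            "available; need at least 10"
        )
    w_epochs, w_kept, _ = extract_epochs(power, word_centers)
    s_epochs, s_kept, _ = extract_epochs(power, sil_centers)
    rng = np.random.default_rng(seed)
    n = min(len(w_kept), len(s_kept))
    wi = rng.choice(len(w_kept), size=n, replace=False) if len(w_kept) > n else np.arange(n)
    si = rng.choice(len(s_kept), size=n, replace=False) if len(s_kept) > n else np.arange(n)
    epochs = np.concatenate([w_epochs[wi], s_epochs[si]], axis=0)
    binned, _ = bin_power(epochs, power.fs, bin_ms=50.0, step_ms=25.0)
    X = binned.reshape(binned.shape[0], -1)
    y = np.concatenate([np.ones(n, bool), np.zeros(n, bool)])
    cv = cross_validate(X, y, k_select=k_select, n_folds=n_folds, seed=seed)
    return ScreeningResult(
        auc=cv.auc_mean,
        passed=cv.auc_mean > threshold,
        n_word_epochs=n,
        n_silence_epochs=n,
        threshold=threshold,
    )


def spatial_analysis(
    epochs: EpochSet,
    seed: int = 0,
    k_select: int = 10,
    n_folds: int = 5,
    family_m: int | None = None,
    adjust: bool = True,
    coords: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-electrode discrimination of one feature contrast.

    For each electrode the 27 binned-power features go through in-fold
    mRMR (10 features) + shrinkage-LDA 5-fold CV; the mean test AUC is
    tested against 0.5 (Hanley-McNeil) and, if ``adjust``, BH-corrected
    over the electrode family and mapped to an activation index.

    Returns a DataFrame with one row per electrode: ``electrode, auc, se,
    p`` (+ ``p_adj, ai`` when adjusted, + ``x, y`` when coords are given).
    """
    y = epochs.labels
    if y.all() or not y.any():
        raise ValueError("both +/- classes must be present")
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    rows = []
    for e in range(epochs.power.shape[1]):
        cv = cross_validate(
            epochs.power[:, e, :], y, k_select=k_select, n_folds=n_folds,
            seed=seed,
        )
        st = auc_stat(cv.auc_mean, n_pos, n_neg)
        rows.append((e, st.auc, st.se, st.p))
    df = pd.DataFrame(rows, columns=["electrode", "auc", "se", "p"])
    if adjust:
        df["p_adj"] = fdr_adjust(df["p"].to_numpy(), m=family_m)
        df["ai"] = activation_index(df["p_adj"].to_numpy())
    if coords is not None:
        df["x"] = coords[df["electrode"], 0]
        df["y"] = coords[df["electrode"], 1]
    return df


def significant_electrodes(spatial_map: pd.DataFrame) -> np.ndarray:
    """Electrodes with a positive activation index."""
    return spatial_map.loc[spatial_map["ai"] > 0, "electrode"].to_numpy()


def temporal_analysis(
    epochs: EpochSet,
    electrodes: np.ndarray,
    dimension: str = "",
    seed: int = 0,
    n_folds: int = 5,
    family_m: int | None = None,
    smooth_bins: int = 3,
    prominence: float = 0.5,
) -> TemporalProfile:
    """Activation-index time course over the spatially significant electrodes.

    ``epochs`` must be binned on the fine 10 ms grid (66 bins).  Each
    (electrode, bin) runs a single-feature LDA 5-fold CV — no feature
    selection or shrinkage is needed with one feature — and the pooled
    BH family spans electrodes x bins.  The profile is the AI mean across
    electrodes; local maxima are strict peaks of the 3-bin moving-average
    series with the given minimum prominence.
    """
    electrodes = np.asarray(electrodes, dtype=int)
    if len(electrodes) == 0:
        raise ValueError("temporal analysis requires >= 1 significant electrode")
    y = epochs.labels
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    n_bins = epochs.power.shape[2]
    pvals = np.empty((len(electrodes), n_bins))
    for i, e in enumerate(electrodes):
        for b in range(n_bins):
            cv = cross_validate(
                epochs.power[:, e, b : b + 1], y, k_select=None,
                n_folds=n_folds, seed=seed, shrinkage=0.0,
            )
            pvals[i, b] = auc_stat(cv.auc_mean, n_pos, n_neg).p
    p_adj = fdr_adjust(pvals.ravel(), m=family_m).reshape(pvals.shape)
    ai = activation_index(p_adj)
    series = ai.mean(axis=0)
    peak_idx = int(np.argmax(series))
    # moving-average smoothing with edge replication before peak picking
    pad = smooth_bins // 2
    padded = np.concatenate([series[:1].repeat(pad), series, series[-1:].repeat(pad)])
    smoothed = np.convolve(padded, np.ones(smooth_bins) / smooth_bins, mode="valid")
    peaks, _ = find_peaks(smoothed, prominence=prominence)
    return TemporalProfile(
        dimension=dimension,
        bin_centers=epochs.bin_centers,
        ai_series=series,
        peak_ai=float(series[peak_idx]),
        peak_latency_ms=float(epochs.bin_centers[peak_idx]),
        local_maxima_ms=np.asarray(epochs.bin_centers)[peaks],
        electrodes=electrodes,
        ai_matrix=ai,
    )


def accumulate_across_subjects(
    maps: list[pd.DataFrame],
    subjects: list | None = None,
    family_m: int | None = None,
) -> pd.DataFrame:
    """Pool per-subject spatial maps into one family and one scatter map.

    Raw p-values from every (subject, electrode) are re-adjusted as a
    single BH family (subjects x electrodes) and mapped to activation
    indices; electrode coordinates are carried through for rendering.
    """
    if subjects is None:
        subjects = list(range(len(maps)))
    frames = []
    for subj, m in zip(subjects, maps, strict=True):
        f = m.copy()
        f.insert(0, "subject", subj)
        frames.append(f)
    pooled = pd.concat(frames, ignore_index=True)
    pooled["p_adj"] = fdr_adjust(pooled["p"].to_numpy(), m=family_m)
    pooled["ai"] = activation_index(pooled["p_adj"].to_numpy())
    return pooled


def render_map(pooled: pd.DataFrame, ax=None, alpha: float = AI_ALPHA):
    """Scatter the pooled activation map (marker intensity = AI)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    sig = pooled["ai"] > 0
    ax.scatter(pooled.loc[~sig, "x"], pooled.loc[~sig, "y"], s=15,
               c="lightgray", label="n.s.")
    if sig.any():
        sc = ax.scatter(pooled.loc[sig, "x"], pooled.loc[sig, "y"],
                        s=45, c=pooled.loc[sig, "ai"], cmap="viridis",
                        label=f"p_adj < {alpha}")
        plt.colorbar(sc, ax=ax, label="activation index")
    ax.set_xlabel("x (mm)")
    ax.set_ylabel("y (mm)")
    ax.legend(loc="best", fontsize=8)
    return ax
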