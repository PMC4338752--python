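"""Cohort report: recovery of the simulated ground truth and figures.

Joins the spatial and temporal results against the simulator's ground
truth, reports per-dimension recovery (significant electrodes vs injected
effect electrodes, recovered vs injected peak latency), and renders the
pooled activation maps and temporal profiles under scratch/figures/.
"""

import sys
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from config import DIMENSIONS, FIGURE_DIR, RESULTS, SUBJECT_DIR

from ecogseg.mapping import render_map


def load_truth(subjects):
    frames = []
    for subject in subjects:
        path = SUBJECT_DIR / subject / "ground_truth.tsv"
        t = pd.read_csv(path, sep="\t")
        t.insert(0, "subject", subject)
        frames.append(t)
    return pd.concat(frames, ignore_index=True)


def main() -> None:
    FIGURE_DIR.mkdir(parents=True, exist_ok=True)
    activation = pd.read_csv(RESULTS / "spatial_activation.csv")
    peaks = pd.read_csv(RESULTS / "temporal_peaks.csv")
    profiles = pd.read_csv(RESULTS / "temporal_profiles.csv")
    subjects = sorted(activation["subject"].unique())
    truth = load_truth(subjects)

    # The feature dimensions overlap phonologically (every vowel is voiced
    # and sonorant), so an electrode injected for one dimension can
    # legitimately discriminate another.  Recall is scored per dimension;
    # false positives only count electrodes outside EVERY injected effect.
    union_true = set(map(tuple, truth[["subject", "electrode"]].values))
    rows = []
    for dim in DIMENSIONS:
        act = activation[activation["dimension"] == dim]
        sig = set(map(tuple, act.loc[act["ai"] > 0, ["subject", "electrode"]].values))
        true = set(
            map(tuple, truth.loc[truth["dimension"] == dim,
                                 ["subject", "electrode"]].values)
        )
        n_true = len(true)
        recovered = len(sig & true)
        pk = peaks[peaks["dimension"] == dim]
        true_latency = truth.loc[truth["dimension"] == dim, "latency_ms"]
        rows.append(
            {
                "dimension": dim,
                "true_electrodes": n_true,
                "significant": len(sig),
                "recovered": recovered,
                "cross_dimension": len((sig - true) & union_true),
                "false_positives": len(sig - union_true),
                "recall": round(recovered / n_true, 3) if n_true else float("nan"),
                "true_latency_ms": float(true_latency.iloc[0]) if len(true_latency) else float("nan"),
                "peak_latency_ms": float(pk["peak_latency_ms"].iloc[0]) if len(pk) else float("nan"),
                "peak_ai": float(pk["peak_ai"].iloc[0]) if len(pk) else float("nan"),
            }
        )

    summary = pd.DataFrame(rows)
    summary.to_csv(RESULTS / "summary.csv", index=False)
    print(summary.to_string(index=False))

    # figures: pooled activation map per dimension + profile overlay
    for dim in DIMENSIONS:
        act = activation[activation["dimension"] == dim]
        if act.empty:
            continue
        ax = render_map(act)
        ax.set_title(f"{dim}: pooled activation map ({len(subjects)} subjects)")
        ax.figure.savefig(FIGURE_DIR / f"map_{dim}.png", dpi=120,
                          bbox_inches="tight")
        plt.close(ax.figure)

    fig, ax = plt.subplots(figsize=(7, 4))
    for dim, grp in profiles.groupby("dimension"):
        ax.plot(grp["latency_ms"], grp["ai"], label=dim)
    ax.axvline(0.0, color="k", lw=0.5)
    ax.set_xlabel("latency relative to phoneme onset (ms)")
    ax.set_ylabel("mean activation index")
    ax.legend(fontsize=8)
    fig.savefig(FIGURE_DIR / "temporal_profiles.png", dpi=120, bbox_inches="tight")
    plt.close(fig)
    print(f"\nwrote {RESULTS / 'summary.csv'} and figures under {FIGURE_DIR}")


if __name__ == "__main__":
    main()
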