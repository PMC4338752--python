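"""Spatial topography of segmental-feature discrimination.

For every screened-in subject and every feature contrast, each electrode's
27 binned gamma-power features run through in-fold mRMR (10 features) +
shrinkage-LDA 5-fold CV; the CV AUC maps to a Hanley-McNeil p-value.  Raw
p-values are then pooled across subjects per dimension into one
Benjamini-Hochberg family (subjects x electrodes) and converted to
activation indices.  Electrodes with AI > 0 form the significant set that
the temporal analysis (04) is restricted to.
"""

import sys
import zlib
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from config import DIMENSIONS, RESULTS, SUBJECT_DIR

from ecogseg.mapping import accumulate_across_subjects, phoneme_epoch_set, spatial_analysis
from ecogseg.phonology import read_alignments
from ecogseg.preprocess import preprocess_chain, read_recording


def main() -> None:
    screening = pd.read_csv(RESULTS / "screening.csv")
    included = screening.loc[screening["passed"], "subject"].tolist()
    print(f"spatial analysis over subjects: {', '.join(included)}\n")

    powers = {}
    for subject in included:
        fixture = SUBJECT_DIR / subject
        rec = read_recording(fixture / "recording.h5")
        powers[subject] = (
            preprocess_chain(rec),
            read_alignments(fixture / "alignments.tsv"),
            rec.coords,
        )

    pooled_frames = []
    count_rows = []
    for dim in DIMENSIONS:
        per_subject = []
        for subject in included:
            power, alignments, coords = powers[subject]
            epochs = phoneme_epoch_set(power, alignments, dim)
            seed = zlib.crc32(f"{dim}:{subject}".encode()) % 2**31
            per_subject.append(
                spatial_analysis(epochs, seed=seed, adjust=False, coords=coords)
            )
        pooled = accumulate_across_subjects(per_subject, subjects=included)
        pooled.insert(0, "dimension", dim)
        pooled_frames.append(pooled)
        n_sig = int((pooled["ai"] > 0).sum())
        count_rows.append(
            {
                "dimension": dim,
                "n_significant": n_sig,
                "n_tested": len(pooled),
                "max_ai": round(float(pooled["ai"].max()), 2),
            }
        )
        print(
            f"{dim:>10}: {n_sig} significant (subject, electrode) pairs "
            f"of {len(pooled)}, max AI {pooled['ai'].max():.1f}"
        )

    activation = pd.concat(pooled_frames, ignore_index=True)
    activation.to_csv(RESULTS / "spatial_activation.csv", index=False)
    pd.DataFrame(count_rows).to_csv(RESULTS / "spatial_counts.csv", index=False)
    print(f"\nwrote {RESULTS / 'spatial_activation.csv'}")
    print(f"wrote {RESULTS / 'spatial_counts.csv'}")


if __name__ == "__main__":
    main()
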