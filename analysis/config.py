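"""Shared layout for the numbered analysis drivers.

Seven synthetic subjects mirror a typical cohort: four carry
feature-locked gamma effects over a shared electrode layout (and are
expected to pass the speech-vs-silence screening), three are
effect-free controls (expected to fail it).
"""

from pathlib import Path

from ecogseg.synthetic import SimConfig, study_effects

ROOT = Path(__file__).resolve().parent.parent
SCRATCH = ROOT / "scratch"
RESULTS = ROOT / "results"
SUBJECT_DIR = SCRATCH / "subjects"
FIGURE_DIR = SCRATCH / "figures"

#: Feature dimensions analyzed (three place contrasts, manner, voicing,
#: phonological class with "+" = vowel).
DIMENSIONS = ("labial", "coronal", "dorsal", "obstruent", "voiced", "vowel")

#: subject -> (seed, carries_effects)
SUBJECTS = {
    "A": (101, False),
    "B": (102, True),
    "C": (103, False),
    "D": (104, False),
    "E": (105, True),
    "F": (106, True),
    "G": (107, True),
}

N_ELECTRODES = 48
DURATION_S = 120.0


def subject_config(subject: str) -> SimConfig:
    seed, has_effects = SUBJECTS[subject]
    effects = study_effects(N_ELECTRODES) if has_effects else ()
    return SimConfig(
        n_electrodes=N_ELECTRODES,
        duration_s=DURATION_S,
        effects=effects,
        seed=seed,
    )
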