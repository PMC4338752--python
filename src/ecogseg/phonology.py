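"""Phoneme inventory, segmental-feature coding, and alignment tables.

The analysis discriminates neural activity along binary segmental-feature
dimensions of General American English phonemes: place of articulation
(labial / coronal / dorsal), manner (obstruent / sonorant), voicing
(voiced / voiceless) and phonological class (consonant / vowel).  Each
phoneme carries a "+" or "-" for every dimension, and a single phoneme may
be "+" on several dimensions at once (e.g. "B" is labial+, obstruent+,
voiced+, consonant+).

The inventory is the standard ARPAbet set: 24 consonants and 15 vowels.
Feature assignments follow standard English phonology.  Notes on two
conventions adopted here:

* /h/ (HH) is coded obstruent and voiceless with no oral place feature
  (it is glottal), and /ng/ (NG) is coded dorsal — top-level feature
  charts sometimes omit both symbols from their place lists.
* All vowels are sonorant and voiced, and carry no place feature.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "CONSONANTS",
    "VOWELS",
    "INVENTORY",
    "DIMENSIONS",
    "LABEL_DIMENSIONS",
    "IPA",
    "build_feature_table",
    "label_for_feature",
    "read_alignments",
    "write_alignments",
    "read_words",
    "write_words",
    "AlignmentError",
]

# ARPAbet, General American English.
CONSONANTS: tuple[str, ...] = (
    "P", "B", "T", "D", "K", "G", "CH", "JH", "F", "V", "TH", "DH",
    "S", "Z", "SH", "ZH", "HH", "M", "N", "NG", "L", "R", "W", "Y",
)
VOWELS: tuple[str, ...] = (
    "IY", "IH", "EH", "AE", "AA", "AH", "AO", "UW", "UH", "ER",
    "AY", "EY", "AW", "OW", "OY",
)
INVENTORY: tuple[str, ...] = CONSONANTS + VOWELS

#: The seven stored feature dimensions.
DIMENSIONS: tuple[str, ...] = (
    "labial", "coronal", "dorsal", "obstruent", "sonorant", "voiced",
    "consonant",
)

#: Dimensions accepted by :func:`label_for_feature`; "vowel" is the
#: complement of "consonant" and is the positive class used for the
#: phonological contrast in the mapping analyses.
LABEL_DIMENSIONS: tuple[str, ...] = DIMENSIONS + ("vowel",)

# Display forms for figures/reports.
IPA: dict[str, str] = {
    "P": "p", "B": "b", "T": "t", "D": "d", "K": "k", "G": "g",
    "CH": "tʃ", "JH": "dʒ", "F": "f", "V": "v", "TH": "θ", "DH": "ð",
    "S": "s", "Z": "z", "SH": "ʃ", "ZH": "ʒ", "HH": "h", "M": "m",
    "N": "n", "NG": "ŋ", "L": "l", "R": "r", "W": "w", "Y": "j",
    "IY": "i", "IH": "ɪ", "EH": "ɛ", "AE": "æ", "AA": "ɑ", "AH": "ə",
    "AO": "ɔ", "UW": "u", "UH": "ʊ", "ER": "ɝ", "AY": "aɪ", "EY": "eɪ",
    "AW": "aʊ", "OW": "oʊ", "OY": "ɔɪ",
}

_LABIAL = frozenset({"B", "P", "F", "V", "M", "W"})
_CORONAL = frozenset(
    {"T", "D", "TH", "DH", "S", "Z", "SH", "ZH", "N", "CH", "JH", "R", "L", "Y"}
)
_DORSAL = frozenset({"K", "G", "W", "NG"})
_SONORANT_CONS = frozenset({"M", "N", "NG", "L", "R", "W", "Y"})
_VOICELESS = frozenset({"P", "T", "K", "F", "TH", "S", "SH", "CH", "HH"})


class AlignmentError(ValueError):
    """Raised for malformed or invalid alignment / word-boundary files."""


def build_feature_table() -> pd.DataFrame:
    """Compile the per-phoneme binary feature table.

    Returns
    -------
    DataFrame indexed by ARPAbet symbol with boolean columns
    ``labial, coronal, dorsal, obstruent, sonorant, voiced, consonant``.
    """
    rows = {}
    for ph in INVENTORY:
        cons = ph in CONSONANTS
        son = (not cons) or ph in _SONORANT_CONS
        rows[ph] = dict(
            labial=ph in _LABIAL,
            coronal=ph in _CORONAL,
            dorsal=ph in _DORSAL,
            obstruent=cons and not son,
            sonorant=son,
            voiced=ph not in _VOICELESS,
            consonant=cons,
        )
    table = pd.DataFrame.from_dict(rows, orient="index", dtype=bool)
    table = table.loc[list(INVENTORY), list(DIMENSIONS)]
    table.index.name = "phoneme"
    return table


def label_for_feature(
    alignments: pd.DataFrame, table: pd.DataFrame, dimension: str
) -> pd.DataFrame:
    """Assign a +/- label to every alignment row for one feature dimension.

    ``dimension`` may be any of :data:`LABEL_DIMENSIONS`; ``"vowel"`` labels
    "+" exactly where ``"consonant"`` labels "-".

    Returns a DataFrame with columns ``onset`` and ``label`` (strings "+"
    and "-"), one row per alignment row, in alignment order.
    """
    if dimension not in LABEL_DIMENSIONS:
        raise ValueError(f"unknown feature dimension {dimension!r}")
    unknown = set(alignments["phoneme"]) - set(table.index)
    if unknown:
        raise ValueError(f"phonemes missing from feature table: {sorted(unknown)}")
    if dimension == "vowel":
        positive = ~table["consonant"]
    else:
        positive = table[dimension]
    pos = positive.reindex(alignments["phoneme"]).to_numpy()
    return pd.DataFrame(
        {
            "onset": alignments["onset"].to_numpy(),
            "label": np.where(pos, "+", "-"),
        }
    )


# ---------------------------------------------------------------------------
# Alignment and word-boundary files: UTF-8, tab-delimited, header row,
# times in seconds.


def _read_tsv(path, columns: tuple[str, ...]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise AlignmentError(f"{path}: cannot parse: {exc}") from exc
    missing = set(columns) - set(df.columns)
    if missing:
        raise AlignmentError(f"{path}: missing columns {sorted(missing)}")
    return df


def read_alignments(path, inventory: tuple[str, ...] = INVENTORY) -> pd.DataFrame:
    """Read and validate a phoneme alignment table.

    Columns: ``phoneme`` (inventory symbol), ``onset``/``offset`` (seconds),
    ``word`` (integer word index).  Rows must be onset-sorted with
    onset < offset; unknown symbols are reported with their row numbers.
    """
    raw = _read_tsv(path, ("phoneme", "onset", "offset", "word"))
    try:
        df = pd.DataFrame(
            {
                "phoneme": raw["phoneme"].astype(str),
                "onset": raw["onset"].astype(float),
                "offset": raw["offset"].astype(float),
                "word_index": raw["word"].astype(int),
            }
        )
    except ValueError as exc:
        raise AlignmentError(f"{path}: malformed numeric field: {exc}") from exc
    bad = df.index[df["onset"] >= df["offset"]]
    if len(bad):
        # +2: header line plus 1-based numbering.
        raise AlignmentError(
            f"{path}: onset >= offset at line(s) {[int(i) + 2 for i in bad]}"
        )
    unknown = df.index[~df["phoneme"].isin(inventory)]
    if len(unknown):
        syms = df.loc[unknown, "phoneme"].unique().tolist()
        raise AlignmentError(
            f"{path}: unknown phoneme symbols {syms} at line(s) "
            f"{[int(i) + 2 for i in unknown]}"
        )
    if not df["onset"].is_monotonic_increasing:
        raise AlignmentError(f"{path}: rows not sorted by onset")
    return df


def write_alignments(path, alignments: pd.DataFrame) -> None:
    out = pd.DataFrame(
        {
            "phoneme": alignments["phoneme"],
            "onset": alignments["onset"].map(lambda t: f"{t:.4f}"),
            "offset": alignments["offset"].map(lambda t: f"{t:.4f}"),
            "word": alignments["word_index"].astype(int),
        }
    )
    out.to_csv(path, sep="\t", index=False)


def read_words(path) -> pd.DataFrame:
    """Read a word-boundary table with columns ``word, onset, offset``."""
    raw = _read_tsv(path, ("word", "onset", "offset"))
    df = pd.DataFrame(
        {
            "word": raw["word"].astype(str),
            "onset": raw["onset"].astype(float),
            "offset": raw["offset"].astype(float),
        }
    )
    bad = df.index[df["onset"] >= df["offset"]]
    if len(bad):
        raise AlignmentError(
            f"{path}: onset >= offset at line(s) {[int(i) + 2 for i in bad]}"
        )
    return df


def write_words(path, words: pd.DataFrame) -> None:
    out = pd.DataFrame(
        {
            "word": words["word"],
            "onset": words["onset"].map(lambda t: f"{t:.4f}"),
            "offset": words["offset"].map(lambda t: f"{t:.4f}"),
        }
    )
    out.to_csv(path, sep="\t", index=False)
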