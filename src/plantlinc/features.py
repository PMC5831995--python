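"""Per-transcript coding-potential and composition features.

Two feature families characterise the low coding capacity of long
intergenic non-coding RNAs (lincRNAs) against protein-coding transcripts
(PCTs):

* the longest open reading frame (ORF) — its length in nucleotides and its
  proportion of the transcript length; a transcript whose longest ORF is
  shorter than 100 amino acids is the classical lincRNA landmark;
* overlapping k-mer frequencies for k in {2, 3, 4}, normalised per k over
  the windows free of ambiguous bases.
"""

from __future__ import annotations

from dataclasses import dataclass
from collections import Counter
from itertools import product
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import Transcript

__all__ = [
    "OrfResult",
    "STOP_CODONS",
    "find_longest_orf",
    "orf_features",
    "kmer_frequencies",
    "kmer_frequency_matrix",
    "build_feature_matrix",
    "validate_patterns",
    "FEATURE_PREFIX_COLUMNS",
]

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
START_CODON = "ATG"
VALID_KS = (2, 3, 4)

#: fixed leading columns of every feature matrix
FEATURE_PREFIX_COLUMNS = ("orf_length", "orf_proportion")

_PATTERNS_BY_K: dict[int, tuple[str, ...]] = {
    k: tuple("".join(p) for p in product("ACGT", repeat=k)) for k in VALID_KS
}


@dataclass(frozen=True)
class OrfResult:
    """Longest ORF of a transcript: ATG through the first in-frame stop.

    ``nt_length`` includes the stop codon; ``aa_length`` counts translated
    residues (start codon included, stop excluded).
    """

    start: int
    end: int  # exclusive, one past the last base of the stop codon
    frame: int

    @property
    def nt_length(self) -> int:
        return self.end - self.start

    @property
    def aa_length(self) -> int:
        return self.nt_length // 3 - 1


def find_longest_orf(t: Transcript | str) -> OrfResult | None:
    """Return the longest complete ORF on the given strand, or None.

    All three reading frames are scanned; an ORF runs from an ATG to the
    first downstream in-frame stop codon (TAA/TAG/TGA), stop included.
    Ties are broken by smallest start, then smallest frame. Sequences
    without a complete ORF (no ATG, or no in-frame stop after one) give
    None.
    """
    seq = t.seq if isinstance(t, Transcript) else t
    n = len(seq)
    best: OrfResult | None = None
    for frame in range(3):
        open_start = -1  # leftmost unclosed ATG in this frame
        for i in range(frame, n - 2, 3):
            codon = seq[i : i + 3]
            if codon in STOP_CODONS:
                if open_start >= 0:
                    cand = OrfResult(start=open_start, end=i + 3, frame=frame)
                    if _orf_better(cand, best):
                        best = cand
                    open_start = -1
            elif codon == START_CODON and open_start < 0:
                open_start = i
    return best


def _orf_better(cand: OrfResult, best: OrfResult | None) -> bool:
    if best is None:
        return True
    return (cand.nt_length, -cand.start, -cand.frame) > (
        best.nt_length,
        -best.start,
        -best.frame,
    )


def orf_features(t: Transcript | str) -> tuple[int, float]:
    """(longest ORF length in nt, ORF length / transcript length)."""
    seq = t.seq if isinstance(t, Transcript) else t
    orf = find_longest_orf(seq)
    if orf is None:
        return 0, 0.0
    return orf.nt_length, orf.nt_length / len(seq)


def kmer_frequencies(t: Transcript | str, k: int) -> dict[str, float]:
    """Overlapping k-mer frequencies over the 4**k patterns, for k in {2,3,4}.

    Windows containing any character outside ACGT are excluded from both
    the numerator and the denominator, so ambiguous bases do not deflate
    the frequencies of clean patterns. When no valid window exists, every
    frequency is 0.
    """
    if k not in VALID_KS:
        raise ValueError(f"k must be one of {VALID_KS}, got {k}")
    seq = t.seq if isinstance(t, Transcript) else t
    patterns = _PATTERNS_BY_K[k]
    counts = Counter(seq[i : i + k] for i in range(len(seq) - k + 1))
    valid = {p: counts[p] for p in patterns if p in counts}
    total = sum(valid.values())
    if total == 0:
        return {p: 0.0 for p in patterns}
    return {p: valid.get(p, 0) / total for p in patterns}


def kmer_frequency_matrix(
    transcripts: Sequence[Transcript], ks: Iterable[int] = VALID_KS
) -> pd.DataFrame:
    """Frequencies of every k-mer pattern (k ascending, lexicographic within
    k) for each transcript; rows indexed by transcript id, input order kept."""
    ks = tuple(ks)
    for k in ks:
        if k not in VALID_KS:
            raise ValueError(f"k must be one of {VALID_KS}, got {k}")
    cols = [p for k in ks for p in _PATTERNS_BY_K[k]]
    data = np.zeros((len(transcripts), len(cols)))
    for i, t in enumerate(transcripts):
        j = 0
        for k in ks:
            freqs = kmer_frequencies(t, k)
            for p in _PATTERNS_BY_K[k]:
                data[i, j] = freqs[p]
                j += 1
    return pd.DataFrame(data, index=[t.id for t in transcripts], columns=cols)


def validate_patterns(patterns: Sequence[str]) -> None:
    if not patterns:
        raise ValueError("pattern list must be non-empty")
    for p in patterns:
        if len(p) not in VALID_KS or any(c not in "ACGT" for c in p):
            raise ValueError(
                f"invalid pattern {p!r}: must be a 2-, 3- or 4-mer over ACGT"
            )


def build_feature_matrix(
    transcripts: Sequence[Transcript], patterns: Sequence[str]
) -> pd.DataFrame:
    """Assemble the classifier's feature matrix.

    Columns are fixed as [orf_length, orf_proportion] followed by the
    supplied patterns in their given order; rows follow the input order and
    are indexed by transcript id.
    """
    validate_patterns(patterns)
    cols = list(FEATURE_PREFIX_COLUMNS) + list(patterns)
    data = np.zeros((len(transcripts), len(cols)))
    ks_needed = sorted({len(p) for p in patterns})
    for i, t in enumerate(transcripts):
        length, prop = orf_features(t)
        data[i, 0] = length
        data[i, 1] = prop
        freqs: Mapping[str, float] = {}
        for k in ks_needed:
            freqs = {**freqs, **kmer_frequencies(t, k)}
        for j, p in enumerate(patterns, start=2):
            data[i, j] = freqs[p]
    return pd.DataFrame(data, index=[t.id for t in transcripts], columns=cols)
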