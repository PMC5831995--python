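"""Presence/absence differential expression across sequencing libraries.

Predicted lincRNAs from all libraries are pooled (rows keep their
library-qualified id ``library:transcript``); a similarity search of the
pool against itself yields a boolean presence matrix (rows = pooled
lincRNAs, columns = libraries): a sequence is "present" in a library when
it is similar (e-value <= 1e-12 by default) to some sequence predicted
there, and always present in its home library. A row is differentially
expressed when it is present in at least one library of one condition
(treated or control) and absent from every library of the other.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .io import BlastHit, Transcript

__all__ = [
    "LibrarySet",
    "qualified_id",
    "build_presence_matrix",
    "call_differential",
    "naive_similarity_hits",
]

TREATED = "treated"
CONTROL = "control"
DEFAULT_EVALUE_MAX = 1e-12


def qualified_id(library_id: str, transcript_id: str) -> str:
    return f"{library_id}:{transcript_id}"


@dataclass(frozen=True)
class LibrarySet:
    """Predicted lincRNAs per library plus each library's condition."""

    libraries: tuple[tuple[str, tuple[Transcript, ...]], ...]
    condition: Mapping[str, str]

    def __post_init__(self) -> None:
        ids = [lib for lib, _ in self.libraries]
        if len(set(ids)) != len(ids):
            raise ValueError("library ids must be unique")
        missing = set(ids) - set(self.condition)
        if missing:
            raise ValueError(f"libraries without a condition: {sorted(missing)}")
        values = {self.condition[lib] for lib in ids}
        bad = values - {TREATED, CONTROL}
        if bad:
            raise ValueError(f"conditions must be treated/control, got {sorted(bad)}")
        if values != {TREATED, CONTROL}:
            raise ValueError("need at least one treated and one control library")

    @classmethod
    def from_lists(
        cls,
        libraries: Sequence[tuple[str, Sequence[Transcript]]],
        condition: Mapping[str, str],
    ) -> "LibrarySet":
        return cls(
            libraries=tuple((lib, tuple(ts)) for lib, ts in libraries),
            condition=dict(condition),
        )

    @property
    def library_ids(self) -> list[str]:
        return [lib for lib, _ in self.libraries]

    def pooled_rows(self) -> list[tuple[str, str, Transcript]]:
        """(row id, home library, transcript) for every pooled lincRNA."""
        return [
            (qualified_id(lib, t.id), lib, t)
            for lib, ts in self.libraries
            for t in ts
        ]


def build_presence_matrix(
    ls: LibrarySet,
    hits: Iterable[BlastHit],
    evalue_max: float = DEFAULT_EVALUE_MAX,
) -> pd.DataFrame:
    """Boolean presence matrix (pooled lincRNAs x libraries).

    Hit query/subject ids must use the library-qualified convention.
    A cell (r, L) is True iff r's home library is L, or r has a hit with
    e-value <= ``evalue_max`` (inclusive) to a sequence whose home library
    is L. Hits naming unknown ids are ignored with a warning.
    """
    rows = ls.pooled_rows()
    row_ids = [rid for rid, _, _ in rows]
    home = {rid: lib for rid, lib, _ in rows}
    matrix = pd.DataFrame(False, index=row_ids, columns=ls.library_ids)
    for rid, lib, _ in rows:
        matrix.loc[rid, lib] = True

    n_unknown = 0
    for h in hits:
        if h.evalue > evalue_max:
            continue
        if h.query_id not in home or h.subject_id not in home:
            n_unknown += 1
            continue
        matrix.loc[h.query_id, home[h.subject_id]] = True
    if n_unknown:
        warnings.warn(
            f"{n_unknown} hits reference ids absent from every library; ignored"
        )
    return matrix


def call_differential(
    matrix: pd.DataFrame, condition: Mapping[str, str]
) -> tuple[set[str], int]:
    """Differentially expressed rows of a presence matrix.

    A row qualifies when it has at least one True among the libraries of
    one condition and all False among the other — in either direction.
    Returns the id set and its cardinality.
    """
    missing = set(matrix.columns) - set(condition)
    if missing:
        raise ValueError(f"columns without a condition: {sorted(missing)}")
    treated_cols = [c for c in matrix.columns if condition[c] == TREATED]
    control_cols = [c for c in matrix.columns if condition[c] == CONTROL]
    in_treated = matrix[treated_cols].any(axis=1)
    in_control = matrix[control_cols].any(axis=1)
    differential = in_treated ^ in_control  # exactly one side occupied
    ids = set(matrix.index[differential])
    return ids, len(ids)


def naive_similarity_hits(ls: LibrarySet, min_shared_kmer_len: int) -> list[BlastHit]:
    """Synthetic all-vs-all hit table based on exact shared substrings.

    Test plumbing standing in for an external similarity search: an
    (ordered) hit with e-value 1e-30 is emitted for every pair of pooled
    sequences sharing an exact substring of length >= ``min_shared_kmer_len``
    (self-pairs included). Two sequences share a substring of length >= L
    iff they share one of length exactly L, so L-mer sets suffice.
    """
    rows = ls.pooled_rows()
    L = min_shared_kmer_len
    kmer_sets = {
        rid: {t.seq[i : i + L] for i in range(t.length - L + 1)}
        for rid, _, t in rows
    }
    hits = []
    for qid, _, _ in rows:
        for sid, _, _ in rows:
            if kmer_sets[qid] & kmer_sets[sid]:
                hits.append(
                    BlastHit(
                        query_id=qid,
                        subject_id=sid,
                        percent_identity=100.0,
                        align_length=L,
                        mismatches=0,
                        gap_opens=0,
                        qstart=1,
                        qend=L,
                        sstart=1,
                        send=L,
                        evalue=1e-30,
                        bitscore=2 * L,
                    )
                )
    return hits
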