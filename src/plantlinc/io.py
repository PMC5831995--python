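"""Readers and writers for the external formats the workflow touches.

All coordinates are 0-based half-open internally; conversions to and from
1-based closed (GFF3) happen only at the parse/write boundary. Downstream
modules consume only the domain types defined here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import joblib
from Bio import SeqIO
from intervaltree import IntervalTree

__all__ = [
    "Transcript",
    "BlastHit",
    "GenomicInterval",
    "GeneAnnotation",
    "ParseError",
    "ModelIOError",
    "read_fasta",
    "write_fasta",
    "read_blast_tab",
    "write_blast_tab",
    "read_gff3_genes",
    "write_gff3_genes",
    "read_bed_intervals",
    "write_bed_intervals",
    "save_model",
    "load_model",
]

MODEL_FORMAT = "plantlinc-model"
MODEL_FORMAT_VERSION = 1


class ParseError(ValueError):
    """Malformed content in an input file; message carries the line number."""


class ModelIOError(ValueError):
    """Model archive cannot be loaded (truncated, wrong format, wrong version)."""


@dataclass(frozen=True)
class Transcript:
    """A transcript: an id and an uppercase nucleotide sequence."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("transcript id must be non-empty")
        if not self.seq:
            raise ValueError(f"transcript {self.id!r} has an empty sequence")

    @property
    def length(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class BlastHit:
    """One row of a 12-column tabular similarity-search result (outfmt 6)."""

    query_id: str
    subject_id: str
    percent_identity: float
    align_length: int
    mismatches: int
    gap_opens: int
    qstart: int
    qend: int
    sstart: int
    send: int
    evalue: float
    bitscore: float

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValueError(f"negative e-value {self.evalue} for {self.query_id}")


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open genomic span; ``name`` carries a transcript or gene id."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str = ""

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0 or self.end <= self.start:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                f"(need 0 <= start < end)"
            )
        if self.strand not in {"+", "-", "."}:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


class GeneAnnotation:
    """Protein-coding gene bodies indexed per chromosome for overlap queries."""

    def __init__(self, intervals: Iterable[GenomicInterval]):
        self.intervals: list[GenomicInterval] = list(intervals)
        self._trees: dict[str, IntervalTree] = {}
        for iv in self.intervals:
            self._trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, iv.name)

    def __len__(self) -> int:
        return len(self.intervals)

    def overlaps(self, iv: GenomicInterval, min_distance: int = 0) -> bool:
        """True iff ``iv``, padded by ``min_distance``, overlaps any gene body.

        Half-open semantics: an interval that merely touches a gene boundary
        does not overlap it (when ``min_distance`` is 0).
        """
        tree = self._trees.get(iv.chrom)
        if tree is None:
            return False
        start = max(0, iv.start - min_distance)
        return bool(tree.overlap(start, iv.end + min_distance))


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> list[Transcript]:
    """Read transcripts from a FASTA file (wrapped or single-line).

    The header token before the first whitespace is the id; sequences are
    uppercased. Duplicate ids and empty-sequence records are rejected.
    """
    path = Path(path)
    _check_fasta_leader(path)
    out: list[Transcript] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ParseError(f"{path}: duplicate transcript id {rec.id!r}")
        seq = str(rec.seq).upper()
        if not seq:
            raise ParseError(f"{path}: record {rec.id!r} has an empty sequence")
        seen.add(rec.id)
        out.append(Transcript(id=rec.id, seq=seq))
    return out


def _check_fasta_leader(path: Path) -> None:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            if not line.startswith(">"):
                raise ParseError(
                    f"{path}: line {lineno}: expected a FASTA header ('>'), "
                    f"got {line.strip()[:40]!r}"
                )
            return


def write_fasta(transcripts: Iterable[Transcript], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for t in transcripts:
            fh.write(f">{t.id}\n")
            for i in range(0, t.length, width):
                fh.write(t.seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# BLAST tabular (outfmt 6)

_BLAST_FIELDS = (
    ("query_id", str),
    ("subject_id", str),
    ("percent_identity", float),
    ("align_length", int),
    ("mismatches", int),
    ("gap_opens", int),
    ("qstart", int),
    ("qend", int),
    ("sstart", int),
    ("send", int),
    ("evalue", float),
    ("bitscore", float),
)


def read_blast_tab(path: str | Path) -> list[BlastHit]:
    """Parse a 12-column tabular hit file; '#' comment lines are skipped.

    Extra columns beyond the standard twelve are tolerated and ignored.
    """
    path = Path(path)
    hits: list[BlastHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            cols = line.split()
            if len(cols) < len(_BLAST_FIELDS):
                raise ParseError(
                    f"{path}: line {lineno}: expected >=12 columns, got {len(cols)}"
                )
            kwargs = {}
            for (name, cast), raw in zip(_BLAST_FIELDS, cols):
                try:
                    kwargs[name] = cast(raw)
                except ValueError as exc:
                    raise ParseError(
                        f"{path}: line {lineno}: cannot parse field {name!r} "
                        f"from {raw!r}"
                    ) from exc
            hits.append(BlastHit(**kwargs))
    return hits


def write_blast_tab(hits: Iterable[BlastHit], path: str | Path) -> None:
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                "\t".join(
                    str(v)
                    for v in (
                        h.query_id,
                        h.subject_id,
                        h.percent_identity,
                        h.align_length,
                        h.mismatches,
                        h.gap_opens,
                        h.qstart,
                        h.qend,
                        h.sstart,
                        h.send,
                        repr(h.evalue),
                        h.bitscore,
                    )
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# GFF3 / BED


def read_gff3_genes(path: str | Path) -> GeneAnnotation:
    """Extract gene bodies from a GFF3 file as 0-based half-open intervals.

    Only records with feature type ``gene`` are kept. When the attributes
    column carries a biotype, non-protein-coding genes are dropped; files
    without biotype tags keep every ``gene`` record. Non-gene features
    (mRNA, exon, ...) are ignored.
    """
    path = Path(path)
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 8:
                raise ParseError(
                    f"{path}: line {lineno}: expected >=8 tab-separated GFF3 "
                    f"columns, got {len(cols)}"
                )
            chrom, _source, ftype, start_s, end_s = cols[0], cols[1], cols[2], cols[3], cols[4]
            if ftype != "gene":
                continue
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError as exc:
                raise ParseError(
                    f"{path}: line {lineno}: non-integer coordinates "
                    f"{start_s!r}/{end_s!r}"
                ) from exc
            if end1 < start1:
                raise ParseError(
                    f"{path}: line {lineno}: end {end1} < start {start1}"
                )
            attrs = _parse_gff3_attributes(cols[8]) if len(cols) > 8 else {}
            biotype = attrs.get("biotype") or attrs.get("gene_biotype")
            if biotype is not None and biotype != "protein_coding":
                continue
            strand = cols[6] if len(cols) > 6 and cols[6] in {"+", "-"} else "."
            name = attrs.get("ID", f"gene_{lineno}")
            intervals.append(
                GenomicInterval(chrom=chrom, start=start1 - 1, end=end1, strand=strand, name=name)
            )
    if not intervals:
        warnings.warn(f"{path}: no 'gene' records found; annotation is empty")
    return GeneAnnotation(intervals)


def _parse_gff3_attributes(col9: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for part in col9.strip().split(";"):
        part = part.strip()
        if not part or "=" not in part:
            continue
        key, _, value = part.partition("=")
        out[key] = value
    return out


def read_bed_intervals(path: str | Path) -> list[GenomicInterval]:
    """Read transcript-to-genome alignments from a BED4+/BED6 file.

    Column 4 must carry the transcript id; strand (column 6) defaults to '.'.
    """
    path = Path(path)
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 4:
                raise ParseError(
                    f"{path}: line {lineno}: BED input needs >=4 columns "
                    f"(chrom, start, end, transcript id), got {len(cols)}"
                )
            try:
                start, end = int(cols[1]), int(cols[2])
            except ValueError as exc:
                raise ParseError(
                    f"{path}: line {lineno}: non-integer coordinates"
                ) from exc
            if start >= end:
                raise ParseError(
                    f"{path}: line {lineno}: empty or inverted interval "
                    f"[{start}, {end})"
                )
            strand = cols[5] if len(cols) >= 6 and cols[5] in {"+", "-"} else "."
            try:
                out.append(
                    GenomicInterval(
                        chrom=cols[0], start=start, end=end, strand=strand, name=cols[3]
                    )
                )
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from exc
    return out


def write_gff3_genes(genes: GeneAnnotation, path: str | Path) -> None:
    """Write gene bodies back out as GFF3 (1-based closed at the boundary)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for iv in genes.intervals:
            fh.write(
                "\t".join(
                    [
                        iv.chrom,
                        "plantlinc",
                        "gene",
                        str(iv.start + 1),
                        str(iv.end),
                        ".",
                        iv.strand if iv.strand != "." else "+",
                        ".",
                        f"ID={iv.name};biotype=protein_coding",
                    ]
                )
                + "\n"
            )


def write_bed_intervals(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\t0\t{iv.strand}\n"
            )


# ---------------------------------------------------------------------------
# Model archive


def save_model(spec, path: str | Path) -> None:
    """Serialize a trained model spec as a self-describing versioned archive.

    The archive embeds the selected pattern list and the per-feature scaling
    statistics, so predict-time feature extraction cannot diverge from the
    statistics frozen at training time.
    """
    payload = {
        "format": MODEL_FORMAT,
        "version": MODEL_FORMAT_VERSION,
        "spec": spec,
    }
    joblib.dump(payload, path)


def load_model(path: str | Path):
    path = Path(path)
    if path.stat().st_size == 0:
        raise ModelIOError(f"{path}: empty file is not a model archive")
    try:
        payload = joblib.load(path)
    except Exception as exc:  # truncated pickle, wrong format, ...
        raise ModelIOError(f"{path}: cannot read model archive: {exc}") from exc
    if not isinstance(payload, dict) or payload.get("format") != MODEL_FORMAT:
        raise ModelIOError(f"{path}: not a {MODEL_FORMAT} archive")
    if payload.get("version") != MODEL_FORMAT_VERSION:
        raise ModelIOError(
            f"{path}: model format version {payload.get('version')} != "
            f"supported version {MODEL_FORMAT_VERSION}"
        )
    spec = payload["spec"]
    _validate_model_spec(path, spec)
    return spec


def _validate_model_spec(path: Path, spec) -> None:
    clf = getattr(spec, "classifier", None)
    if clf is None or getattr(clf, "mean_", None) is None or getattr(clf, "scale_", None) is None:
        raise ModelIOError(f"{path}: archive is missing feature scaling parameters")
    if not getattr(spec, "patterns", None):
        raise ModelIOError(f"{path}: archive is missing the k-mer pattern list")
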