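"""The lincRNA prediction cascade.

Candidate transcripts pass, in order: removal of transcripts with strong
similarity to protein-coding sequence, the >= 200 bp length rule, an
intergenic filter against annotated gene bodies, and finally the
intersection of two parallel calls — the SVM prediction and annotation by
similarity to a known lncRNA database. Per-stage survivor counts are
recorded in a StageReport whose counts are non-increasing by construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Protocol, Sequence

from .classifier import LABEL_POSITIVE
from .io import BlastHit, GeneAnnotation, GenomicInterval, Transcript

__all__ = [
    "PipelineConfig",
    "StageReport",
    "filter_coding",
    "filter_length",
    "filter_intergenic",
    "annotate_lnc",
    "intersect_calls",
    "run_pipeline",
]

LAYOUTS = ("generic", "sugarcane", "maize")


class TranscriptPredictor(Protocol):
    def predict_transcripts(self, transcripts: Sequence[Transcript]) -> dict[str, str]: ...


@dataclass(frozen=True)
class PipelineConfig:
    """Thresholds and layout of one cascade run.

    ``layout`` selects between the published case-study orderings:
    generic/sugarcane apply the coding filter to the raw input first;
    maize consumes already-assembled consensus transcripts and enters at
    the length filter (coding removal happened upstream).
    """

    min_length: int = 200
    coding_evalue_max: float = 1e-10
    lnc_evalue_max: float = 1e-12
    min_gene_distance: int = 0
    layout: str = "generic"

    def __post_init__(self) -> None:
        if self.min_length < 1:
            raise ValueError("min_length must be >= 1")
        if self.coding_evalue_max <= 0 or self.lnc_evalue_max <= 0:
            raise ValueError("e-value thresholds must be > 0")
        if self.layout not in LAYOUTS:
            raise ValueError(f"layout must be one of {LAYOUTS}")


@dataclass
class StageReport:
    """Ordered (stage, input count, output count) rows plus the final id set.

    The two parallel calls feeding the intersection are reported separately
    in ``svm_positive_count`` / ``lnc_annotated_count`` so that the linear
    stage chain keeps its input==previous-output invariant.
    """

    stages: list[tuple[str, int, int]] = field(default_factory=list)
    final_ids: set[str] = field(default_factory=set)
    svm_positive_count: int = 0
    lnc_annotated_count: int = 0

    def add(self, name: str, n_in: int, n_out: int) -> None:
        if n_out > n_in:
            raise ValueError(f"stage {name}: output {n_out} exceeds input {n_in}")
        if self.stages and self.stages[-1][2] != n_in:
            raise ValueError(
                f"stage {name}: input {n_in} != previous output {self.stages[-1][2]}"
            )
        self.stages.append((name, n_in, n_out))

    def to_tsv(self) -> str:
        lines = ["stage\tinput\toutput"]
        for name, n_in, n_out in self.stages:
            lines.append(f"{name}\t{n_in}\t{n_out}")
        lines.append(f"# svm_positive\t{self.svm_positive_count}")
        lines.append(f"# lnc_annotated\t{self.lnc_annotated_count}")
        return "\n".join(lines) + "\n"


def _ids_with_hit(hits: Iterable[BlastHit], evalue_max: float) -> set[str]:
    return {h.query_id for h in hits if h.evalue <= evalue_max}


def filter_coding(
    transcripts: Sequence[Transcript],
    hits: Iterable[BlastHit],
    evalue_max: float,
) -> list[Transcript]:
    """Drop transcripts with any protein-coding hit at e-value <= threshold."""
    hits = list(hits)
    known = {t.id for t in transcripts}
    unknown = {h.query_id for h in hits} - known
    if unknown:
        warnings.warn(
            f"{len(unknown)} hit query ids do not match any transcript; ignored"
        )
    coding = _ids_with_hit(hits, evalue_max)
    return [t for t in transcripts if t.id not in coding]


def filter_length(transcripts: Sequence[Transcript], min_length: int = 200) -> list[Transcript]:
    """Keep transcripts of length >= min_length (boundary inclusive)."""
    return [t for t in transcripts if t.length >= min_length]


def filter_intergenic(
    transcripts: Sequence[Transcript],
    alignments: Iterable[GenomicInterval],
    genes: GeneAnnotation,
    min_gene_distance: int = 0,
) -> list[Transcript]:
    """Keep transcripts mapped entirely outside annotated gene bodies.

    A transcript survives iff it has at least one genome alignment and
    none of its alignments overlaps any gene body by >= 1 bp (half-open,
    strand-agnostic). Unmapped transcripts are dropped; multi-mapping
    transcripts must be gene-free at every placement.
    """
    known = {t.id for t in transcripts}
    by_tid: dict[str, list[GenomicInterval]] = {}
    n_unknown = 0
    for iv in alignments:
        if iv.name not in known:
            n_unknown += 1
            continue
        by_tid.setdefault(iv.name, []).append(iv)
    if n_unknown:
        warnings.warn(
            f"{n_unknown} alignments reference unknown transcript ids; ignored"
        )
    out = []
    for t in transcripts:
        ivs = by_tid.get(t.id)
        if not ivs:
            continue
        if any(genes.overlaps(iv, min_distance=min_gene_distance) for iv in ivs):
            continue
        out.append(t)
    return out


def annotate_lnc(
    transcripts: Sequence[Transcript],
    hits: Iterable[BlastHit],
    evalue_max: float,
) -> set[str]:
    """Ids of transcripts with any lncRNA-database hit at e-value <= threshold."""
    annotated = _ids_with_hit(hits, evalue_max)
    return {t.id for t in transcripts if t.id in annotated}


def intersect_calls(svm_positive: set[str], lnc_annotated: set[str]) -> set[str]:
    """Final call: transcripts both SVM-positive and lncRNA-annotated."""
    return set(svm_positive) & set(lnc_annotated)


def run_pipeline(
    cfg: PipelineConfig,
    transcripts: Sequence[Transcript],
    model: TranscriptPredictor,
    coding_hits: Iterable[BlastHit] = (),
    lnc_hits: Iterable[BlastHit] = (),
    alignments: Iterable[GenomicInterval] = (),
    genes: GeneAnnotation | None = None,
) -> StageReport:
    """Run the full cascade and return its StageReport.

    A stage that leaves zero survivors completes the run with an empty
    final set and a warning rather than an error.
    """
    if genes is None:
        genes = GeneAnnotation([])
    report = StageReport()
    current = list(transcripts)

    report.add("raw_input", len(current), len(current))

    if cfg.layout != "maize":
        survivors = filter_coding(current, coding_hits, cfg.coding_evalue_max)
        report.add("coding_filter", len(current), len(survivors))
        current = survivors

    survivors = filter_length(current, cfg.min_length)
    report.add("length_filter", len(current), len(survivors))
    current = survivors

    # alignments of transcripts already dropped upstream are irrelevant here
    current_ids = {t.id for t in current}
    survivors = filter_intergenic(
        current,
        [iv for iv in alignments if iv.name in current_ids],
        genes,
        min_gene_distance=cfg.min_gene_distance,
    )
    report.add("intergenic_filter", len(current), len(survivors))
    current = survivors

    labels = model.predict_transcripts(current) if current else {}
    svm_positive = {tid for tid, lab in labels.items() if lab == LABEL_POSITIVE}
    lnc_annotated = annotate_lnc(current, lnc_hits, cfg.lnc_evalue_max)
    final = intersect_calls(svm_positive, lnc_annotated)

    report.svm_positive_count = len(svm_positive)
    report.lnc_annotated_count = len(lnc_annotated)
    report.add("svm_blast_intersection", len(current), len(final))
    report.final_ids = final

    if not final:
        warnings.warn("pipeline finished with an empty final lincRNA set")
    return report
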