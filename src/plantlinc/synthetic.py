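"""Seeded generators for every input the workflow consumes.

The generators emulate the statistical structure the features assume:

* protein-coding-like negatives carry a sampled-codon ORF of at least 100
  amino acids spanning most of the transcript;
* lincRNA-like positives are uniform background sequence with planted
  class-specific k-mer composition biases, post-edited with
  in-frame stops so the longest ORF stays below the 100-amino-acid
  landmark;
* a toy genome provides non-overlapping genes and genic/intergenic
  transcript placements for the intergenic filter;
* synthetic similarity-hit tables carry controllable e-values.

Every generator is a pure function of its configuration (seed included).

Composition biases are planted by selection re-weighting, a finite-pool
approximation to exponential tilting: for each output sequence, K uniform
candidate sequences are drawn and one is sampled with probability
proportional to exp(score), where the score is the sum of standardised
planted-pattern counts weighted by log multiplier. Enrichment arises
purely by selection, so non-planted patterns shift only through their
natural overlap covariance with the planted ones, and the tilt strength
grows with both the multipliers and K. This design matters: constructive
mechanisms (re-weighted transition probabilities, or
overwriting/concatenating pattern copies into a background) conserve
window counts locally and therefore concentrate a compensating depletion
or junction disruption on specific non-planted patterns, at a magnitude
comparable to the planted signal itself — those patterns then rival the
planted ones on any discrimination ranking, and no rescaling of the
effect size changes the ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from typing import Sequence

import numpy as np
import pandas as pd

from .classifier import LABEL_NEGATIVE, LABEL_POSITIVE, LABEL_TOO_SHORT
from .features import STOP_CODONS, find_longest_orf
from .io import BlastHit, GeneAnnotation, GenomicInterval, Transcript

__all__ = [
    "GeneratorConfig",
    "DEFAULT_PLANTED_PATTERNS",
    "gen_labeled_transcripts",
    "gen_composition_classes",
    "gen_toy_genome",
    "gen_hit_table",
    "gen_cascade_fixture",
    "CascadeFixture",
    "DesignatedPositivePredictor",
]

_BASES = "ACGT"
_B2I = {b: i for i, b in enumerate(_BASES)}
_NONSTOP_CODONS = tuple(
    "".join(c) for c in product(_BASES, repeat=3) if "".join(c) not in STOP_CODONS
)
_STOPS = tuple(sorted(STOP_CODONS))

#: default planted composition biases of the positive class: four dimers
#: and six trimers with spread start/end bases. No planted trimer contains
#: a planted dimer and no two planted trimers share a constituent dimer,
#: which keeps the overlap covariance between planted features small so
#: each carries its own share of the selection tilt.
#: candidate sequences drawn per output sequence; caps the attainable
#: selection tilt (K = 1 disables planting entirely)
DEFAULT_TILT_CANDIDATES = 12

#: default planted composition biases of the positive class: two dimers
#: and eight trimers. Because k-mer counts of overlapping patterns are
#: strongly correlated (corr of a k-mer with a contained (k+1)-mer is
#: exactly sqrt(E_{k+1}/E_k) = 0.5 in uniform sequence), a naive planted
#: set lets non-planted neighbours inherit tilt shifts as large as the
#: planted ones. This set and its multiplier ratios were chosen against
#: the empirical 336 x 336 count-correlation matrix of uniform sequences
#: so that every planted pattern receives an equal unit tilt shift while
#: the worst non-planted pattern receives at most 0.70 of it.
DEFAULT_PLANTED_PATTERNS: tuple[tuple[str, float], ...] = (
    ("CC", 1.33),
    ("TT", 1.20),
    ("ACC", 1.44),
    ("AGC", 1.76),
    ("ATT", 1.60),
    ("CCA", 1.30),
    ("CTC", 1.71),
    ("GAA", 1.78),
    ("GTT", 1.59),
    ("TTG", 1.24),
)


@dataclass(frozen=True)
class GeneratorConfig:
    """Conditions for labeled transcript generation.

    The 100-amino-acid ORF landmark is the class boundary: negatives carry
    an ORF of at least ``pct_orf_min_aa`` residues, positives stay at or
    below ``linc_orf_max_aa``. ``relax_orf_ceiling`` drops the positive-side
    ceiling, emulating a looser lncRNA (rather than strictly lincRNA-like)
    positive set.
    """

    seed: int
    n_pos: int = 1000
    n_neg: int = 1000
    length_range: tuple[int, int] = (400, 1200)
    planted_patterns: tuple[tuple[str, float], ...] = DEFAULT_PLANTED_PATTERNS
    pct_orf_min_aa: int = 100
    linc_orf_max_aa: int = 99
    relax_orf_ceiling: bool = False
    tilt_candidates: int = DEFAULT_TILT_CANDIDATES

    def __post_init__(self) -> None:
        if self.tilt_candidates < 1:
            raise ValueError("tilt_candidates must be >= 1")
        lo, hi = self.length_range
        if lo < 200:
            raise ValueError("minimum length must be >= 200")
        if hi < lo:
            raise ValueError("length_range must be (min, max) with min <= max")
        if self.pct_orf_min_aa <= self.linc_orf_max_aa:
            raise ValueError("pct_orf_min_aa must exceed linc_orf_max_aa")
        for p, m in self.planted_patterns:
            if len(p) not in (2, 3, 4) or any(c not in _BASES for c in p):
                raise ValueError(f"invalid planted pattern {p!r}")
            if m <= 0:
                raise ValueError(f"multiplier for {p!r} must be > 0")
        min_orf_nt = 3 * (self.pct_orf_min_aa + 1)
        if min_orf_nt > hi:
            raise ValueError(
                f"length_range too short for a {self.pct_orf_min_aa}-aa ORF "
                f"({min_orf_nt} nt needed)"
            )


def _pattern_counts(cands: np.ndarray, pattern: str) -> np.ndarray:
    """Overlapping occurrence counts of ``pattern`` in each candidate row."""
    L = cands.shape[1]
    k = len(pattern)
    hit = np.ones((cands.shape[0], L - k + 1), dtype=bool)
    for off, ch in enumerate(pattern):
        hit &= cands[:, off : L - k + 1 + off] == _B2I[ch]
    return hit.sum(axis=1)


def _tilted_sequence(
    rng: np.random.Generator,
    length: int,
    planted: Sequence[tuple[str, float]],
    n_candidates: int,
) -> str:
    """Softmax selection among K candidates toward the planted biases."""
    cands = rng.integers(0, 4, size=(n_candidates, length)).astype(np.int8)
    if planted and n_candidates > 1:
        score = np.zeros(n_candidates)
        for p, m in planted:
            k = len(p)
            expected = (length - k + 1) / 4**k
            sd = np.sqrt(expected * (1 - 4.0**-k))
            score += np.log(m) * (_pattern_counts(cands, p) - expected) / sd
        probs = np.exp(score - score.max())
        probs /= probs.sum()
        pick = int(rng.choice(n_candidates, p=probs))
    else:
        pick = 0
    return "".join(_BASES[b] for b in cands[pick])


def _cap_orf(rng: np.random.Generator, seq: str, max_aa: int, max_rounds: int = 200) -> str:
    """Insert in-frame stops until the longest ORF is <= max_aa residues."""
    for _ in range(max_rounds):
        orf = find_longest_orf(seq)
        if orf is None or orf.aa_length <= max_aa:
            return seq
        # replace a codon near the middle of the ORF (never ATG or the stop)
        n_codons = orf.nt_length // 3
        j = n_codons // 2
        pos = orf.start + 3 * j
        stop = _STOPS[rng.integers(len(_STOPS))]
        seq = seq[:pos] + stop + seq[pos + 3 :]
    raise RuntimeError("could not cap ORF length")  # pragma: no cover


def _background_transcripts(
    rng: np.random.Generator,
    n: int,
    length_range: tuple[int, int],
    planted: Sequence[tuple[str, float]],
    id_prefix: str,
    n_candidates: int = DEFAULT_TILT_CANDIDATES,
) -> list[Transcript]:
    out = []
    for i in range(n):
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        seq = _tilted_sequence(rng, length, planted, n_candidates)
        out.append(Transcript(id=f"{id_prefix}{i:05d}", seq=seq))
    return out


def _coding_transcript(
    rng: np.random.Generator, cfg: GeneratorConfig, idx: int
) -> Transcript:
    lo, hi = cfg.length_range
    min_orf_nt = 3 * (cfg.pct_orf_min_aa + 1)
    total = int(rng.integers(max(lo, min_orf_nt), hi + 1))
    prop = rng.uniform(0.65, 0.9)
    orf_nt = max(min_orf_nt, 3 * int(prop * total / 3))
    orf_nt = min(orf_nt, 3 * (total // 3))
    n_codons = orf_nt // 3 - 2  # interior codons between ATG and stop
    codons = rng.integers(0, len(_NONSTOP_CODONS), size=n_codons)
    orf = "ATG" + "".join(_NONSTOP_CODONS[c] for c in codons) + _STOPS[rng.integers(3)]
    flank = total - len(orf)
    pre = int(rng.integers(0, flank + 1))
    bases = rng.integers(0, 4, size=flank)
    utr = "".join(_BASES[b] for b in bases)
    return Transcript(id=f"pct_{idx:05d}", seq=utr[:pre] + orf + utr[pre:])


def gen_labeled_transcripts(
    cfg: GeneratorConfig,
) -> tuple[list[Transcript], list[Transcript], pd.DataFrame]:
    """Labeled positive/negative transcript sets plus a truth manifest.

    Positives and negatives are guaranteed separable by the ORF features
    alone at the 100-amino-acid boundary; the manifest records the longest
    ORF and planted properties of every sequence.
    """
    rng = np.random.default_rng(cfg.seed)
    pos = _background_transcripts(
        rng, cfg.n_pos, cfg.length_range, cfg.planted_patterns, "linc_",
        n_candidates=cfg.tilt_candidates,
    )
    if not cfg.relax_orf_ceiling:
        pos = [
            Transcript(id=t.id, seq=_cap_orf(rng, t.seq, cfg.linc_orf_max_aa))
            for t in pos
        ]
    neg = [_coding_transcript(rng, cfg, i) for i in range(cfg.n_neg)]

    records = []
    for label, ts in ((LABEL_POSITIVE, pos), (LABEL_NEGATIVE, neg)):
        for t in ts:
            orf = find_longest_orf(t)
            aa = orf.aa_length if orf else 0
            records.append(
                {
                    "id": t.id,
                    "label": label,
                    "length": t.length,
                    "orf_nt": orf.nt_length if orf else 0,
                    "orf_aa": aa,
                }
            )
            if label == LABEL_NEGATIVE and aa < cfg.pct_orf_min_aa:
                raise RuntimeError(f"generator violated ORF floor for {t.id}")
            if (
                label == LABEL_POSITIVE
                and not cfg.relax_orf_ceiling
                and aa > cfg.linc_orf_max_aa
            ):
                raise RuntimeError(f"generator violated ORF ceiling for {t.id}")
    return pos, neg, pd.DataFrame(records)


def gen_composition_classes(
    cfg: GeneratorConfig,
) -> tuple[list[Transcript], list[Transcript]]:
    """Two classes differing only in the planted k-mer composition biases.

    Both classes are uniform background sequence of the same length
    distribution; the positive class additionally carries
    ``cfg.planted_patterns``. No ORF structure is imposed, so the planted
    biases are the only systematic class difference — the setting in which
    pattern selection is benchmarked.
    """
    rng = np.random.default_rng(cfg.seed)
    pos = _background_transcripts(
        rng, cfg.n_pos, cfg.length_range, cfg.planted_patterns, "pos_",
        n_candidates=cfg.tilt_candidates,
    )
    neg = _background_transcripts(rng, cfg.n_neg, cfg.length_range, (), "neg_")
    return pos, neg


# ---------------------------------------------------------------------------
# Toy genome


def gen_toy_genome(
    seed: int,
    n_genes: int = 20,
    n_transcripts: int = 100,
    genic_fraction: float = 0.35,
) -> tuple[Transcript, GeneAnnotation, list[Transcript], list[GenomicInterval], pd.DataFrame]:
    """One-chromosome toy genome with genic/intergenic transcript placements.

    Genes are placed non-overlapping with generous gaps; each transcript is
    placed either overlapping a gene body or strictly inside a gap,
    according to ``genic_fraction`` (exact counts, rounded). Returns the
    genome, the annotation, transcript sequences extracted from the genome,
    their BED-style alignments, and a manifest labeling each transcript.
    """
    if not 0 <= genic_fraction <= 1:
        raise ValueError("genic_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)

    genes: list[GenomicInterval] = []
    pos = int(rng.integers(500, 1500))
    for g in range(n_genes):
        glen = int(rng.integers(300, 800))
        genes.append(
            GenomicInterval(
                chrom="chr1",
                start=pos,
                end=pos + glen,
                strand="+" if rng.random() < 0.5 else "-",
                name=f"g{g:03d}",
            )
        )
        pos += glen + int(rng.integers(900, 2000))
    chrom_len = pos + 1500
    gaps = []
    prev_end = 0
    for g in genes:
        if g.start - prev_end > 0:
            gaps.append((prev_end, g.start))
        prev_end = g.end
    gaps.append((prev_end, chrom_len))

    genome_seq = "".join(_BASES[b] for b in rng.integers(0, 4, size=chrom_len))

    n_genic = round(genic_fraction * n_transcripts)
    transcripts, alignments, rows = [], [], []
    for i in range(n_transcripts):
        tlen = int(rng.integers(200, 501))
        genic = i < n_genic
        if genic:
            if not genes:
                raise ValueError("cannot place genic transcripts without genes")
            g = genes[int(rng.integers(len(genes)))]
            start = int(rng.integers(max(0, g.start - tlen + 1), g.end))
        else:
            fitting = [(a, b) for a, b in gaps if b - a >= tlen + 2]
            if not fitting:
                raise ValueError("chromosome too small for requested placements")
            a, b = fitting[int(rng.integers(len(fitting)))]
            start = int(rng.integers(a + 1, b - tlen))
        end = start + tlen
        tid = f"t{i:04d}"
        strand = "+" if rng.random() < 0.5 else "-"
        transcripts.append(Transcript(id=tid, seq=genome_seq[start:end]))
        alignments.append(
            GenomicInterval(chrom="chr1", start=start, end=end, strand=strand, name=tid)
        )
        rows.append(
            {"id": tid, "genic": genic, "chrom": "chr1", "start": start, "end": end}
        )
    manifest = pd.DataFrame(rows)
    return (
        Transcript(id="chr1", seq=genome_seq),
        GeneAnnotation(genes),
        transcripts,
        alignments,
        manifest,
    )


# ---------------------------------------------------------------------------
# Hit tables


def gen_hit_table(pairs: Sequence[tuple[str, str, float]]) -> list[BlastHit]:
    """Synthetic 12-column hits with plausible filler fields.

    The (query, subject, e-value) triples round-trip exactly through the
    tabular writer/reader.
    """
    hits = []
    for q, s, e in pairs:
        if e <= 0:
            raise ValueError(f"e-value must be > 0, got {e} for ({q}, {s})")
        hits.append(
            BlastHit(
                query_id=q,
                subject_id=s,
                percent_identity=98.0,
                align_length=100,
                mismatches=2,
                gap_opens=0,
                qstart=1,
                qend=100,
                sstart=1,
                send=100,
                evalue=e,
                bitscore=180.0,
            )
        )
    return hits


# ---------------------------------------------------------------------------
# End-to-end cascade fixture


class DesignatedPositivePredictor:
    """Deterministic stand-in predictor for cascade fixtures (test plumbing).

    Labels a transcript lincRNA-like iff its id is in the designated set, so
    a fixture can force the SVM-branch count exactly.
    """

    def __init__(self, positive_ids: set[str]):
        self.positive_ids = set(positive_ids)

    def predict_transcripts(self, transcripts: Sequence[Transcript]) -> dict[str, str]:
        out = {}
        for t in transcripts:
            if t.length < 4:
                out[t.id] = LABEL_TOO_SHORT
            else:
                out[t.id] = (
                    LABEL_POSITIVE if t.id in self.positive_ids else LABEL_NEGATIVE
                )
        return out


@dataclass
class CascadeFixture:
    """All inputs of one synthetic end-to-end cascade run plus its truth."""

    transcripts: list[Transcript]
    coding_hits: list[BlastHit]
    lnc_hits: list[BlastHit]
    alignments: list[GenomicInterval]
    genes: GeneAnnotation
    model: DesignatedPositivePredictor
    expected: dict = field(default_factory=dict)


def gen_cascade_fixture(
    seed: int,
    n_coding: int = 40,
    n_short: int = 10,
    n_genic: int = 20,
    n_clean: int = 30,
    n_svm_pos: int = 18,
    n_lnc: int = 12,
    n_overlap: int = 9,
) -> CascadeFixture:
    """Construct a cascade input where every stage count is forced.

    Transcript groups are built so each one is removed at exactly its
    designated stage: ``n_coding`` carry a strong protein hit, ``n_short``
    are under 200 nt, ``n_genic`` map inside a gene body, and the
    ``n_clean`` remainder survive to the parallel calls, of which
    ``n_svm_pos`` are designated SVM-positive, ``n_lnc`` are
    lncRNA-annotated, and exactly ``n_overlap`` are both (the forced final
    count). The construction is asserted before returning.
    """
    if n_overlap > min(n_svm_pos, n_lnc) or max(n_svm_pos, n_lnc) > n_clean:
        raise ValueError("inconsistent designated counts")
    if n_svm_pos - n_overlap + n_lnc > n_clean:
        raise ValueError("clean pool too small for the requested overlap layout")
    rng = np.random.default_rng(seed)
    gene = GenomicInterval(chrom="chr1", start=10_000, end=20_000, strand="+", name="g001")
    genes = GeneAnnotation([gene])

    def random_seq(length: int) -> str:
        return "".join(_BASES[b] for b in rng.integers(0, 4, size=length))

    transcripts, alignments = [], []
    coding_pairs, lnc_pairs = [], []
    groups = (
        [("coding", 250)] * n_coding
        + [("short", 150)] * n_short
        + [("genic", 250)] * n_genic
        + [("clean", 250)] * n_clean
    )
    clean_ids = []
    intergenic_cursor = 30_000
    for i, (group, length) in enumerate(groups):
        tid = f"t{i:04d}"
        transcripts.append(Transcript(id=tid, seq=random_seq(length)))
        if group == "genic":
            start = int(rng.integers(gene.start, gene.end - 50))
        else:
            start = intergenic_cursor
            intergenic_cursor += length + 100
        alignments.append(
            GenomicInterval(chrom="chr1", start=start, end=start + length, name=tid)
        )
        if group == "coding":
            coding_pairs.append((tid, "pct_db_hit", 1e-40))
        if group == "clean":
            clean_ids.append(tid)

    svm_pos = set(clean_ids[:n_svm_pos])
    lnc_ids = set(clean_ids[n_svm_pos - n_overlap : n_svm_pos - n_overlap + n_lnc])
    lnc_pairs = [(tid, "lnc_db_hit", 1e-30) for tid in sorted(lnc_ids)]

    assert len(svm_pos & lnc_ids) == n_overlap
    assert len(svm_pos) == n_svm_pos and len(lnc_ids) == n_lnc

    n_total = n_coding + n_short + n_genic + n_clean
    expected = {
        "raw_input": n_total,
        "after_coding": n_total - n_coding,
        "after_length": n_total - n_coding - n_short,
        "after_intergenic": n_clean,
        "svm_positive": n_svm_pos,
        "lnc_annotated": n_lnc,
        "final": n_overlap,
        "final_ids": svm_pos & lnc_ids,
    }
    return CascadeFixture(
        transcripts=transcripts,
        coding_hits=gen_hit_table(coding_pairs),
        lnc_hits=gen_hit_table(lnc_pairs),
        alignments=alignments,
        genes=genes,
        model=DesignatedPositivePredictor(svm_pos),
        expected=expected,
    )
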