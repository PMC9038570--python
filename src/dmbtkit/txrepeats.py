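"""Count complete tandem-repeat units in long-read transcript exon chains.

A transcript's exon chain is intersected with a genomic annotation of repeat
units; a unit covered to at least ``coverage_frac`` of its length counts as
complete, a unit covered below the threshold but above zero counts as
partial.  A transcript is full-length when both its 5' and 3' ends are
mappable, in which case its complete-unit count is comparable with the
genomic allele's unit count.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Sequence


@dataclass
class RepeatAnnotation:
    """Ordered, disjoint repeat-unit intervals (0-based half-open) on a contig."""

    contig: str
    units: list[tuple[int, int]]
    strand: str = "+"

    def __post_init__(self) -> None:
        if not self.units:
            raise ValueError("annotation needs at least one unit")
        self.units = sorted((int(s), int(e)) for s, e in self.units)
        prev_end = None
        for s, e in self.units:
            if e <= s:
                raise ValueError(f"empty unit interval ({s}, {e})")
            if prev_end is not None and s < prev_end:
                raise ValueError("unit intervals overlap")
            prev_end = e


@dataclass
class TranscriptAlignment:
    """Exon chain of one aligned transcript read."""

    transcript_id: str
    contig: str
    exons: list[tuple[int, int]]
    five_prime_mappable: bool = True
    three_prime_mappable: bool = True

    def __post_init__(self) -> None:
        self.exons = sorted((int(s), int(e)) for s, e in self.exons)
        prev_end = None
        for s, e in self.exons:
            if e <= s:
                raise ValueError(f"empty exon interval ({s}, {e})")
            if prev_end is not None and s < prev_end:
                raise ValueError("exon intervals overlap")
            prev_end = e


@dataclass
class RepeatCount:
    transcript_id: str
    complete_units: int
    partial_units: int
    full_length: bool


@dataclass
class TranscriptSummary:
    """Aggregate over full-length transcripts."""

    n_transcripts: int
    n_full_length: int
    histogram: dict[int, int] = field(default_factory=dict)
    mode: int | None = None
    genomic_allele: int | None = None
    concordant_with_genome: bool | None = None


def _overlap(exons: Sequence[tuple[int, int]], start: int, end: int) -> int:
    return sum(max(0, min(e, end) - max(s, start)) for s, e in exons)


def count_repeat_units(aln: TranscriptAlignment, ann: RepeatAnnotation,
                       coverage_frac: float = 0.95) -> RepeatCount:
    """Classify each annotated unit as complete, partial or absent for a read."""
    if aln.contig != ann.contig:
        raise ValueError(
            f"contig mismatch: read on {aln.contig}, units on {ann.contig}")
    if not 0 < coverage_frac <= 1:
        raise ValueError("coverage_frac must lie in (0, 1]")
    complete = partial = 0
    for s, e in ann.units:
        cov = _overlap(aln.exons, s, e) / (e - s)
        if cov >= coverage_frac:
            complete += 1
        elif cov > 0:
            partial += 1
    return RepeatCount(aln.transcript_id, complete, partial,
                       aln.five_prime_mappable and aln.three_prime_mappable)


def summarize_transcripts(counts: Sequence[RepeatCount],
                          genomic_allele: int | None = None) -> TranscriptSummary:
    """Histogram complete-unit counts of full-length transcripts.

    The histogram mode (ties broken toward the larger count) is compared with
    ``genomic_allele`` when supplied, reporting concordance between the
    transcript repeat length and the genetically encoded repeat length.
    """
    full = [c for c in counts if c.full_length]
    hist = dict(Counter(c.complete_units for c in full))
    mode = None
    if hist:
        top = max(hist.values())
        mode = max(k for k, v in hist.items() if v == top)
    concord = (mode == genomic_allele) if (mode is not None
                                           and genomic_allele is not None) else None
    return TranscriptSummary(
        n_transcripts=len(counts), n_full_length=len(full),
        histogram=dict(sorted(hist.items())), mode=mode,
        genomic_allele=genomic_allele, concordant_with_genome=concord)
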