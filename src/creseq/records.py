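"""Canonical in-memory records shared by every pipeline stage.

All coordinates are 0-based half-open, matching BED. WIG is the only
1-based representation and exists on disk only (see :mod:`creseq.io`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional


class DataError(ValueError):
    """Raised when an input file or record violates a format invariant."""


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open interval [start, end) on a named chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise DataError("chromosome name must be non-empty")
        if not (0 <= self.start < self.end):
            raise DataError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class Peak:
    """A called binding site: interval, single-base summit and read support.

    ``summit`` is the base of maximal evidence and is the anchor for every
    downstream step (annotation, motif windows, co-occupancy matrices); the
    interval itself is carried as metadata. ``n_reads`` is the number of
    clustered sequencing tags supporting the peak.
    """

    interval: GenomicInterval
    summit: int
    n_reads: Optional[int] = None
    p_value: Optional[float] = None
    fold_enrichment: Optional[float] = None
    dataset_label: str = ""

    def __post_init__(self) -> None:
        if not (self.interval.start <= self.summit < self.interval.end):
            raise DataError(
                f"summit {self.summit} outside interval "
                f"{self.interval.chrom}:{self.interval.start}-{self.interval.end}"
            )
        if self.n_reads is not None and self.n_reads < 0:
            raise DataError("n_reads must be >= 0")

    @property
    def chrom(self) -> str:
        return self.interval.chrom


@dataclass(frozen=True)
class TranscriptRecord:
    """A strand-aware gene model reduced to what annotation needs.

    ``tss`` is the 0-based position of the first transcribed base:
    ``tx_start`` on the + strand and ``tx_end - 1`` on the - strand.
    """

    transcript_id: str
    gene_symbol: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise DataError(f"unknown strand {self.strand!r} for {self.transcript_id}")
        if not self.tx_start < self.tx_end:
            raise DataError(
                f"transcript {self.transcript_id}: require tx_start < tx_end"
            )

    @property
    def tss(self) -> int:
        return self.tx_start if self.strand == "+" else self.tx_end - 1

    @property
    def tes(self) -> int:
        """Position of the last transcribed base (transcription end site)."""
        return self.tx_end - 1 if self.strand == "+" else self.tx_start


@dataclass(frozen=True)
class Read:
    """A sequencing tag reduced to its 5'-most aligned base."""

    chrom: str
    pos5: int
    strand: str = "+"
    length: int = 36

    def __post_init__(self) -> None:
        if self.pos5 < 0:
            raise DataError("read pos5 must be >= 0")
        if self.length <= 0:
            raise DataError("read length must be > 0")
        if self.strand not in ("+", "-"):
            raise DataError(f"unknown strand {self.strand!r}")


@dataclass
class PeakAnnotation:
    """Assignment of one peak to a transcript and a genomic category.

    ``signed_distance`` is strand-aware: negative means the summit lies
    upstream of the matched transcript's TSS. It is defined only when a
    transcript within 5 kb was found (``no_match`` is False).
    """

    peak: Peak
    category: str  # promoter | intragenic | intergenic
    matched_transcript: Optional[TranscriptRecord] = None
    signed_distance: Optional[int] = None
    no_match: bool = False
    motif_class: Optional[str] = None
    h3k4me3: Optional[bool] = None

    def __post_init__(self) -> None:
        if self.category not in ("promoter", "intragenic", "intergenic"):
            raise DataError(f"unknown category {self.category!r}")
        if self.no_match and self.matched_transcript is not None:
            raise DataError("no_match annotation cannot carry a transcript")
        if self.category == "promoter":
            if self.matched_transcript is None or self.signed_distance is None:
                raise DataError("promoter annotation requires a matched transcript")
            if not (-5000 <= self.signed_distance <= 2000):
                raise DataError(
                    f"promoter distance {self.signed_distance} outside [-5000, +2000]"
                )


@dataclass
class PromoterStatus:
    """Per-transcript summary used by the occupancy/activity association."""

    transcript_id: str
    gene_symbol: str
    occupied: bool
    k4_positive: bool
    expression_value: float
    expression_class: int = field(init=False)
    expressed: bool = field(init=False)

    def __post_init__(self) -> None:
        from .association import expression_class, is_expressed  # cycle-free

        self.expression_class = expression_class(self.expression_value)
        self.expressed = is_expressed(self.expression_value)
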