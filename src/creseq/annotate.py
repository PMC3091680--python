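"""Peak-to-transcript annotation, strand-aware TSS distances, the
high-confidence read filter, and the TSS-distance histogram.

A peak is anchored at its summit. The summit is matched to the transcript
whose TSS minimizes the absolute signed distance, searching within 5 kb;
the peak is a promoter peak if that distance lies in [-5000, +2000]
(upstream negative), otherwise intragenic if the summit falls inside any
gene body, otherwise intergenic. Peaks with no transcript within 5 kb are
flagged ``no_match``. These categories are exclusive and partition every
peak list; promoter takes precedence over intragenic when both apply.
"""

from __future__ import annotations

from bisect import bisect_left
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .records import DataError, Peak, PeakAnnotation, TranscriptRecord

MATCH_RADIUS = 5000
PROMOTER_WINDOW = (-5000, 2000)
HIGH_CONFIDENCE_MIN_READS = 40


def signed_tss_distance(summit: int, transcript: TranscriptRecord) -> int:
    """Strand-aware summit-to-TSS distance; negative = upstream of the TSS."""
    if transcript.strand == "+":
        return summit - transcript.tss
    return transcript.tss - summit


class TranscriptIndex:
    """TSS-sorted and gene-body interval lookups over a transcript set."""

    def __init__(self, transcripts: Sequence[TranscriptRecord]):
        if not transcripts:
            raise DataError("cannot build an index over zero transcripts")
        self.transcripts = list(transcripts)
        self._tss: Dict[str, Tuple[List[int], List[TranscriptRecord]]] = {}
        self._bodies: Dict[str, IntervalTree] = {}
        by_chrom: Dict[str, List[TranscriptRecord]] = {}
        for t in transcripts:
            by_chrom.setdefault(t.chrom, []).append(t)
        for chrom, ts in by_chrom.items():
            # sort by (tss, transcript_id) so equidistant ties resolve to the
            # lexicographically smallest id deterministically
            ts_sorted = sorted(ts, key=lambda t: (t.tss, t.transcript_id))
            self._tss[chrom] = ([t.tss for t in ts_sorted], ts_sorted)
            tree = IntervalTree()
            for t in ts:
                tree[t.tx_start : t.tx_end] = t
            self._bodies[chrom] = tree

    def nearest_tss(self, chrom: str, summit: int, radius: int = MATCH_RADIUS):
        """Transcript with minimal |summit - tss| within radius, or None.

        Ties on distance are broken by lexicographically smallest
        transcript_id.
        """
        if chrom not in self._tss:
            return None
        positions, ts = self._tss[chrom]
        i = bisect_left(positions, summit - radius)
        best = None
        best_key = None
        while i < len(positions) and positions[i] <= summit + radius:
            t = ts[i]
            key = (abs(summit - t.tss), t.transcript_id)
            if best_key is None or key < best_key:
                best, best_key = t, key
            i += 1
        return best

    def overlapping_bodies(self, chrom: str, pos: int) -> List[TranscriptRecord]:
        tree = self._bodies.get(chrom)
        if tree is None:
            return []
        return [iv.data for iv in tree[pos]]


def annotate_peak(peak: Peak, index: TranscriptIndex) -> PeakAnnotation:
    """Assign one peak to a category and (when possible) a transcript."""
    best = index.nearest_tss(peak.chrom, peak.summit)
    if best is not None:
        dist = signed_tss_distance(peak.summit, best)
        if PROMOTER_WINDOW[0] <= dist <= PROMOTER_WINDOW[1]:
            return PeakAnnotation(
                peak=peak,
                category="promoter",
                matched_transcript=best,
                signed_distance=dist,
            )
        category = (
            "intragenic"
            if index.overlapping_bodies(peak.chrom, peak.summit)
            else "intergenic"
        )
        return PeakAnnotation(
            peak=peak,
            category=category,
            matched_transcript=best,
            signed_distance=dist,
        )
    category = (
        "intragenic"
        if index.overlapping_bodies(peak.chrom, peak.summit)
        else "intergenic"
    )
    return PeakAnnotation(peak=peak, category=category, no_match=True)


def annotate_peaks(
    peaks: Sequence[Peak], transcripts: Sequence[TranscriptRecord]
) -> List[PeakAnnotation]:
    index = TranscriptIndex(transcripts)
    return [annotate_peak(p, index) for p in peaks]


def high_confidence_filter(
    peaks: Sequence[Peak], min_reads: int = HIGH_CONFIDENCE_MIN_READS
) -> List[Peak]:
    """Retain peaks supported by strictly more than ``min_reads`` tags."""
    for p in peaks:
        if p.n_reads is None:
            raise DataError(
                f"peak at {p.chrom}:{p.interval.start} has no read count; "
                "cannot apply the high-confidence filter"
            )
    return [p for p in peaks if p.n_reads > min_reads]


def tss_distance_histogram(
    annotations: Sequence[PeakAnnotation],
    bin_width: int = 100,
    distance_range: int = 5000,
) -> pd.DataFrame:
    """Histogram of signed summit-to-TSS distances over +/- distance_range.

    Bins are half-open [lo, hi); peaks without a matched transcript are
    excluded. Returns a DataFrame with columns bin_lo, bin_hi, count.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    edges = np.arange(-distance_range, distance_range + bin_width, bin_width)
    dists = [
        a.signed_distance
        for a in annotations
        if a.matched_transcript is not None and a.signed_distance is not None
    ]
    counts, _ = np.histogram(dists, bins=edges)
    # np.histogram closes the last bin; drop values exactly at +range from it
    # to keep every bin half-open
    if dists:
        at_top = sum(1 for d in dists if d == edges[-1])
        counts[-1] -= at_top
    return pd.DataFrame(
        {"bin_lo": edges[:-1], "bin_hi": edges[1:], "count": counts}
    )


def category_counts(annotations: Sequence[PeakAnnotation]) -> Dict[str, int]:
    out = {"promoter": 0, "intragenic": 0, "intergenic": 0}
    for a in annotations:
        out[a.category] += 1
    return out
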