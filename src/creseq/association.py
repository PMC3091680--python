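"""Promoter H3K4me3 status, expression-class association, false-negative
detection, and intersection with a deregulated-gene list.

Expression values (RMA-normalised array units) are binned into the four
classes <=10, 11-50, 51-500 and >=501; a gene counts as expressed from
class 3 up. Non-integer values are assigned by the half-open real
intervals [0, 10.5), [10.5, 50.5), [50.5, 500.5), [500.5, inf) so that
integers land exactly on the printed class bounds and the expressed flag
stays consistent with the class on every input.
"""

from __future__ import annotations

import warnings
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import pandas as pd

from .cooccupancy import DensityTrack
from .records import DataError, Peak, PeakAnnotation, PromoterStatus, TranscriptRecord

OCCUPANCY_WINDOW = (-1000, 500)
EXPRESSION_BOUNDS = (10.5, 50.5, 500.5)
EXPRESSED_MIN = 50.5  # equals "value >= 51" on integer inputs
CLASS_LABELS = {1: "<=10", 2: "11-50", 3: "51-500", 4: ">=501"}


def expression_class(value: float) -> int:
    """Map a non-negative expression value to class 1-4."""
    if value < 0:
        raise DataError(f"negative expression value {value}")
    for cls, bound in enumerate(EXPRESSION_BOUNDS, start=1):
        if value < bound:
            return cls
    return 4


def is_expressed(value: float) -> bool:
    if value < 0:
        raise DataError(f"negative expression value {value}")
    return value >= EXPRESSED_MIN


def promoter_occupancy(
    annotations: Sequence[PeakAnnotation],
    window: Tuple[int, int] = OCCUPANCY_WINDOW,
) -> Set[str]:
    """Transcripts with a peak summit in [window_lo, window_hi] of the TSS.

    Both bounds are inclusive. This proximal window is deliberately
    tighter than the promoter-category window used for annotation.
    """
    lo, hi = window
    occupied = set()
    for a in annotations:
        if a.matched_transcript is None or a.signed_distance is None:
            continue
        if lo <= a.signed_distance <= hi:
            occupied.add(a.matched_transcript.transcript_id)
    return occupied


def k4_status(
    transcript: TranscriptRecord,
    k4_peaks: Optional[Sequence[Peak]] = None,
    k4_track: Optional[DensityTrack] = None,
    window: Tuple[int, int] = OCCUPANCY_WINDOW,
    min_reads: int = 10,
) -> bool:
    """H3K4me3 positivity of one promoter.

    Peak evidence (preferred): positive iff any H3K4me3 peak summit falls
    in the strand-aware window around the TSS. Track evidence: positive
    iff the summed tag density over the window is >= min_reads.
    """
    if k4_peaks is None and k4_track is None:
        raise DataError("k4_status needs peak or track evidence")
    lo, hi = window
    tss = transcript.tss
    if transcript.strand == "+":
        g_lo, g_hi = tss + lo, tss + hi
    else:
        g_lo, g_hi = tss - hi, tss - lo
    if k4_peaks is not None:
        for p in k4_peaks:
            if p.chrom == transcript.chrom and g_lo <= p.summit <= g_hi:
                return True
        return False
    assert k4_track is not None
    bins = k4_track.bins_by_chrom.get(transcript.chrom)
    if bins is None:
        return False
    w = k4_track.bin_width
    b_lo = max(0, g_lo // w)
    b_hi = min(len(bins), g_hi // w + 1)
    return int(bins[b_lo:b_hi].sum()) >= min_reads


def build_promoter_statuses(
    transcripts: Sequence[TranscriptRecord],
    occupied: Set[str],
    expression: Dict[str, float],
    k4_peaks: Optional[Sequence[Peak]] = None,
    k4_track: Optional[DensityTrack] = None,
    window: Tuple[int, int] = OCCUPANCY_WINDOW,
    min_reads: int = 10,
) -> List[PromoterStatus]:
    """Assemble the per-transcript occupancy/activity/expression table.

    Transcripts without an expression value are skipped.
    """
    statuses = []
    for t in transcripts:
        if t.gene_symbol not in expression:
            continue
        statuses.append(
            PromoterStatus(
                transcript_id=t.transcript_id,
                gene_symbol=t.gene_symbol,
                occupied=t.transcript_id in occupied,
                k4_positive=k4_status(
                    t, k4_peaks=k4_peaks, k4_track=k4_track,
                    window=window, min_reads=min_reads,
                ),
                expression_value=expression[t.gene_symbol],
            )
        )
    return statuses


def association_table(statuses: Sequence[PromoterStatus]) -> pd.DataFrame:
    """Expression-class distributions: all genes vs occupied+K4 genes.

    Returns one row per group ("all", "occupied_k4") with the proportion
    of genes in each of the four classes and the expressed fraction.
    """
    if not statuses:
        raise DataError("cannot build an association table from zero statuses")
    rows = []
    groups = {
        "all": list(statuses),
        "occupied_k4": [s for s in statuses if s.occupied and s.k4_positive],
    }
    for name, members in groups.items():
        n = len(members)
        row = {"group": name, "n": n}
        for cls in (1, 2, 3, 4):
            row[f"class_{CLASS_LABELS[cls]}"] = (
                sum(s.expression_class == cls for s in members) / n if n else 0.0
            )
        row["expressed_fraction"] = (
            sum(s.expressed for s in members) / n if n else 0.0
        )
        rows.append(row)
    return pd.DataFrame(rows)


def false_negatives(statuses: Sequence[PromoterStatus]) -> Set[str]:
    """Occupied promoters scored H3K4me3-negative yet clearly expressed.

    These are candidate detection failures of the H3K4me3 assay: the
    factor is bound and the gene is expressed (>= class 3) but no
    trimethylation signal was called.
    """
    return {
        s.transcript_id
        for s in statuses
        if s.occupied and not s.k4_positive and s.expressed
    }


def direct_targets(
    occupied_symbols: Iterable[str], deregulated_symbols: Iterable[str]
) -> Tuple[Set[str], Dict[str, int]]:
    """Intersect occupied genes with a deregulated list (case-insensitive).

    Returns the overlap (direct targets, in the deregulated list's casing)
    and Venn counts (occupied_only, overlap, deregulated_only).
    """
    occ = _fold_unique(occupied_symbols, "occupied")
    dereg = _fold_unique(deregulated_symbols, "deregulated")
    overlap_keys = set(occ) & set(dereg)
    venn = {
        "occupied_only": len(set(occ) - overlap_keys),
        "overlap": len(overlap_keys),
        "deregulated_only": len(set(dereg) - overlap_keys),
    }
    return {dereg[k] for k in overlap_keys}, venn


def _fold_unique(symbols: Iterable[str], label: str) -> Dict[str, str]:
    folded: Dict[str, str] = {}
    dupes = 0
    for s in symbols:
        key = s.casefold()
        if key in folded:
            dupes += 1
        folded[key] = s
    if dupes:
        warnings.warn(
            f"collapsed {dupes} duplicate symbols in the {label} list",
            stacklevel=3,
        )
    return folded
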