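"""Hierarchical CRE classification of summit windows and TATA detection.

The cyclic-AMP response element (CRE) is the palindromic 8-mer TGACGTCA;
its two halves TGACG and CGTCA are mutual reverse complements. A
summit-centered window is assigned exactly one class with precedence
FULL_CRE > CRE_1MM > HALF_CRE > NONE: a window holding both a one-mismatch
full site and a half site is CRE_1MM. Because the full consensus is its own
reverse complement, classification is invariant under reverse complement of
the window; N bases never match any pattern.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Dict, List, Sequence, Tuple

FULL_CRE_SEQ = "TGACGTCA"
HALF_CRE_SEQS = ("TGACG", "CGTCA")
TATA_PATTERN = re.compile("TATA[AT]A[AT]")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


class MotifClass(str, Enum):
    FULL_CRE = "full"
    CRE_1MM = "one_mismatch"
    HALF_CRE = "half"
    NONE = "none"


#: precedence order, strongest first
CLASS_PRECEDENCE: Tuple[MotifClass, ...] = (
    MotifClass.FULL_CRE,
    MotifClass.CRE_1MM,
    MotifClass.HALF_CRE,
    MotifClass.NONE,
)


@dataclass
class MotifResult:
    """Class call for one window plus the matches that produced it."""

    motif_class: MotifClass
    positions: List[int] = field(default_factory=list)
    strands: List[str] = field(default_factory=list)


def _hamming_no_n(a: str, b: str) -> int:
    """Hamming distance; any N makes the k-mer unmatchable (+inf-ish)."""
    if "N" in a:
        return len(a) + 1
    return sum(x != y for x, y in zip(a, b))


def extract_summit_window(
    genome: Dict[str, str], chrom: str, summit: int, width: int = 500
) -> str:
    """Uppercase sequence [summit - width/2, summit + width/2), edge-clipped."""
    if chrom not in genome:
        raise KeyError(f"chromosome {chrom!r} not in genome")
    seq = genome[chrom]
    if not (0 <= summit < len(seq)):
        raise ValueError(f"summit {summit} outside chromosome {chrom}")
    half = width // 2
    lo = max(0, summit - half)
    hi = min(len(seq), summit + (width - half))
    return seq[lo:hi].upper()


def classify_cre(window: str) -> MotifResult:
    """Classify one window into the 4-class CRE scheme with precedence.

    FULL_CRE if the consensus TGACGTCA occurs anywhere (a forward scan
    covers both strands: the site is palindromic); else CRE_1MM if any
    8-mer on either strand is within Hamming distance 1 of the consensus;
    else HALF_CRE if TGACG or CGTCA occurs on the forward strand (this
    also covers the reverse strand since the two halves are mutual
    reverse complements); else NONE.
    """
    window = window.upper()
    if not window:
        warnings.warn("empty window classified as NONE", stacklevel=2)
        return MotifResult(MotifClass.NONE)

    full_pos = [
        i for i in range(len(window) - 7) if window[i : i + 8] == FULL_CRE_SEQ
    ]
    if full_pos:
        return MotifResult(MotifClass.FULL_CRE, full_pos, ["+"] * len(full_pos))

    mm_pos: List[int] = []
    mm_strand: List[str] = []
    rc = reverse_complement(window)
    n = len(window)
    for i in range(n - 7):
        if _hamming_no_n(window[i : i + 8], FULL_CRE_SEQ) == 1:
            mm_pos.append(i)
            mm_strand.append("+")
        # the same 8 bases read on the reverse strand; position reported
        # in forward-window coordinates
        if _hamming_no_n(rc[n - 8 - i : n - i], FULL_CRE_SEQ) == 1:
            mm_pos.append(i)
            mm_strand.append("-")
    if mm_pos:
        return MotifResult(MotifClass.CRE_1MM, mm_pos, mm_strand)

    half_pos: List[int] = []
    half_strand: List[str] = []
    for pat in HALF_CRE_SEQS:
        start = 0
        while True:
            i = window.find(pat, start)
            if i < 0:
                break
            half_pos.append(i)
            half_strand.append("+")
            start = i + 1
    if half_pos:
        order = sorted(range(len(half_pos)), key=lambda j: half_pos[j])
        return MotifResult(
            MotifClass.HALF_CRE,
            [half_pos[j] for j in order],
            [half_strand[j] for j in order],
        )

    return MotifResult(MotifClass.NONE)


def class_frequencies(
    classes: Sequence[MotifClass],
) -> Tuple[Dict[MotifClass, float], Dict[MotifClass, int]]:
    """Proportions and raw counts of each class, in precedence order."""
    if len(classes) == 0:
        raise ValueError("cannot compute frequencies of an empty class list")
    counts = {c: 0 for c in CLASS_PRECEDENCE}
    for c in classes:
        counts[MotifClass(c)] += 1
    total = len(classes)
    props = {c: counts[c] / total for c in CLASS_PRECEDENCE}
    return props, counts


def has_tata(
    genome: Dict[str, str],
    transcript,
    search_window: Tuple[int, int] = (-100, -10),
) -> bool:
    """True iff a consensus TATA element (TATAWAW) lies in the promoter.

    The search window is strand-aware and given in bp relative to the TSS
    (negative = upstream); the pattern is matched on the sense strand.
    Windows running off the chromosome are clipped, not errors.
    """
    lo_rel, hi_rel = search_window
    if lo_rel > hi_rel:
        raise ValueError("search window must satisfy lo <= hi")
    seq = genome[transcript.chrom]
    tss = transcript.tss
    if transcript.strand == "+":
        lo = tss + lo_rel
        hi = tss + hi_rel + 1  # inclusive relative bound
        region = seq[max(0, lo) : max(0, hi)].upper()
    else:
        lo = tss - hi_rel
        hi = tss - lo_rel + 1
        region = reverse_complement(seq[max(0, lo) : max(0, hi)])
    return TATA_PATTERN.search(region) is not None
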