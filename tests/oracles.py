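"""Independent brute-force oracles the fast implementations are checked
against. Deliberately naive: enumerate everything, no shared code paths
with the package internals."""

from itertools import product

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

FULL = "TGACGTCA"
HALVES = ("TGACG", "CGTCA")


def rc(seq):
    return "".join(_COMP[b] for b in reversed(seq.upper()))


def oracle_classify(window):
    """Enumerate every k-mer of both strands and apply class precedence."""
    window = window.upper()
    strands = [window, rc(window)]
    eights = [s[i : i + 8] for s in strands for i in range(len(s) - 7)]
    fives = [s[i : i + 5] for s in strands for i in range(len(s) - 4)]
    if any(k == FULL for k in eights):
        return "full"
    for k in eights:
        if "N" in k:
            continue
        if sum(a != b for a, b in zip(k, FULL)) == 1:
            return "one_mismatch"
    if any(k in HALVES for k in fives):
        return "half"
    return "none"


def oracle_annotate(peak, transcripts):
    """All-pairs scan reproducing the annotation rules from scratch."""
    candidates = []
    for t in transcripts:
        if t.chrom != peak.chrom:
            continue
        if abs(peak.summit - t.tss) <= 5000:
            sd = peak.summit - t.tss if t.strand == "+" else t.tss - peak.summit
            candidates.append((abs(sd), t.transcript_id, sd, t))
    inside_body = any(
        t.chrom == peak.chrom and t.tx_start <= peak.summit < t.tx_end
        for t in transcripts
    )
    if not candidates:
        return ("intragenic" if inside_body else "intergenic", None, None, True)
    _, _, sd, t = min(candidates)
    if -5000 <= sd <= 2000:
        return ("promoter", t, sd, False)
    return ("intragenic" if inside_body else "intergenic", t, sd, False)


def oracle_density(reads, chrom, n_bins, width):
    """Per-bin recount of read 5' ends by direct enumeration."""
    counts = [0] * n_bins
    for r in reads:
        if r.chrom == chrom and r.pos5 // width < n_bins:
            counts[r.pos5 // width] += 1
    return counts


def oracle_kmeans_sse(X, k=2):
    """Minimal SSE over every assignment of rows to k clusters."""
    import numpy as np

    n = X.shape[0]
    best = float("inf")
    best_labels = None
    for labels in product(range(k), repeat=n):
        sse = 0.0
        for j in range(k):
            members = X[[i for i in range(n) if labels[i] == j]]
            if len(members):
                sse += float(((members - members.mean(axis=0)) ** 2).sum())
        if sse < best:
            best = sse
            best_labels = labels
    return best, best_labels
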