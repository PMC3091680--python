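"""Tag-density tracks, locus-by-position matrices, K-means clustering,
cross-dataset occupancy calls, and the merged union of binding loci.

The density model follows the ChIP-seq convention of counting read 5'
ends in consecutive 25-bp tiles (a tiling, so the track round-trips
through fixedStep WIG). Co-occupancy between two datasets is scored by
extracting dataset-B density in a +/- 5 kb window around every dataset-A
summit, normalising to reads-per-million, compressing with log2(1+x),
and clustering the rows with K-means (k = 2): loci in the B-occupied
cluster are shared, the rest are A-specific.

K-means is Lloyd's algorithm with k-means++ seeding and best-of-n_init
restarts. It is implemented here (rather than delegated) because the
pipeline asserts the per-iteration SSE trace is non-increasing and uses
deterministic farthest-point repair for empty clusters; scikit-learn is
used as an independent cross-check in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .records import DataError, GenomicInterval, Peak, Read

BIN_WIDTH = 25
MATRIX_FLANK = 5000
CENTRAL_FLANK = 500  # central window used to label occupied clusters


# ---------------------------------------------------------------------------
# density tracks


@dataclass
class DensityTrack:
    """Per-chromosome tag counts in consecutive fixed-width bins."""

    bins_by_chrom: Dict[str, np.ndarray]
    bin_width: int = BIN_WIDTH
    name: str = ""

    def __post_init__(self) -> None:
        if self.bin_width <= 0:
            raise DataError("bin_width must be > 0")
        self.bins_by_chrom = {
            c: np.asarray(v, dtype=np.int64) for c, v in self.bins_by_chrom.items()
        }

    def chroms(self) -> List[str]:
        return sorted(self.bins_by_chrom)

    def bins(self, chrom: str) -> np.ndarray:
        return self.bins_by_chrom[chrom]

    @property
    def library_size(self) -> int:
        return int(sum(v.sum() for v in self.bins_by_chrom.values()))

    def __eq__(self, other) -> bool:
        if not isinstance(other, DensityTrack):
            return NotImplemented
        return (
            self.bin_width == other.bin_width
            and self.chroms() == other.chroms()
            and all(
                np.array_equal(self.bins(c), other.bins(c)) for c in self.chroms()
            )
        )


def compute_density(
    reads: Sequence[Read],
    genome_sizes: Dict[str, int],
    bin_width: int = BIN_WIDTH,
    name: str = "",
) -> DensityTrack:
    """Count read 5' ends per bin: bin i covers [i*w, (i+1)*w)."""
    bins = {
        chrom: np.zeros((size + bin_width - 1) // bin_width, dtype=np.int64)
        for chrom, size in genome_sizes.items()
    }
    for r in reads:
        if r.chrom not in bins:
            raise DataError(f"read on unknown chromosome {r.chrom!r}")
        if r.pos5 >= genome_sizes[r.chrom]:
            raise DataError(
                f"read at {r.chrom}:{r.pos5} lies beyond the chromosome end "
                f"({genome_sizes[r.chrom]} bp)"
            )
        bins[r.chrom][r.pos5 // bin_width] += 1
    return DensityTrack(bins_by_chrom=bins, bin_width=bin_width, name=name)


# ---------------------------------------------------------------------------
# locus-by-position matrices


@dataclass
class DensityMatrix:
    """Rows = loci, columns = positional bins spanning center +/- flank."""

    loci: List[Tuple[str, int]]  # (chrom, center)
    values: np.ndarray  # float matrix, possibly transformed
    raw_counts: np.ndarray  # untransformed integer counts
    bin_width: int
    flank: int
    transform_label: str = "counts"

    @property
    def n_columns(self) -> int:
        return self.values.shape[1]

    def central_columns(self, half_width: int = CENTRAL_FLANK) -> slice:
        n = self.n_columns
        k = half_width // self.bin_width
        return slice(n // 2 - k, n // 2 + k)


def extract_matrix(
    track: DensityTrack,
    loci: Sequence[Tuple[str, int]],
    flank: int = MATRIX_FLANK,
    rpm: bool = False,
    log2: bool = False,
) -> DensityMatrix:
    """Per-locus density profile over [center - flank, center + flank).

    Column c holds the track bin covering position center - flank + c*w.
    Loci near a chromosome edge are zero-padded. Optional reads-per-million
    scaling (x * 1e6 / library_size) and log2(1 + x) compression are applied
    in that order.
    """
    w = track.bin_width
    if flank % w != 0:
        raise ValueError("flank must be a multiple of the bin width")
    n_cols = 2 * flank // w
    raw = np.zeros((len(loci), n_cols), dtype=np.int64)
    offsets = np.arange(n_cols)
    for r, (chrom, center) in enumerate(loci):
        if chrom not in track.bins_by_chrom:
            raise DataError(f"locus on unknown chromosome {chrom!r}")
        bins = track.bins(chrom)
        # floor((center - flank + c*w) / w) = floor((center - flank)/w) + c
        idx = (center - flank) // w + offsets
        valid = (idx >= 0) & (idx < len(bins))
        raw[r, valid] = bins[idx[valid]]
    values = raw.astype(float)
    label = "counts"
    if rpm:
        lib = track.library_size
        if lib > 0:
            values = values * 1e6 / lib
        label = "rpm"
    if log2:
        values = np.log2(1.0 + values)
        label += "+log2"
    return DensityMatrix(
        loci=list(loci),
        values=values,
        raw_counts=raw,
        bin_width=w,
        flank=flank,
        transform_label=label,
    )


# ---------------------------------------------------------------------------
# K-means


@dataclass
class ClusterResult:
    k: int
    labels: np.ndarray
    centroids: np.ndarray
    sse: float
    sse_trace: List[float] = field(default_factory=list)
    occupied: Optional[np.ndarray] = None  # bool per cluster


def _kmeans_pp_init(X: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    n = X.shape[0]
    centroids = np.empty((k, X.shape[1]))
    first = rng.integers(n)
    centroids[0] = X[first]
    d2 = np.sum((X - centroids[0]) ** 2, axis=1)
    for j in range(1, k):
        total = d2.sum()
        if total <= 0:
            idx = rng.integers(n)
        else:
            idx = rng.choice(n, p=d2 / total)
        centroids[j] = X[idx]
        d2 = np.minimum(d2, np.sum((X - centroids[j]) ** 2, axis=1))
    return centroids


def _lloyd(
    X: np.ndarray, centroids: np.ndarray, max_iter: int
) -> Tuple[np.ndarray, np.ndarray, float, List[float]]:
    k = centroids.shape[0]
    trace: List[float] = []
    labels = np.zeros(X.shape[0], dtype=int)
    for _ in range(max_iter):
        d2 = ((X[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
        labels = d2.argmin(axis=1)
        sse = float(d2[np.arange(X.shape[0]), labels].sum())
        if trace and sse > trace[-1] + 1e-9:
            raise AssertionError("K-means SSE increased between iterations")
        converged = bool(trace) and trace[-1] - sse <= 1e-12
        trace.append(sse)
        new_centroids = centroids.copy()
        for j in range(k):
            members = X[labels == j]
            if len(members) == 0:
                # deterministic repair: move the empty centroid to the point
                # farthest from its current assigned centroid
                far = int(
                    np.argmax(((X - centroids[labels]) ** 2).sum(axis=1))
                )
                new_centroids[j] = X[far]
            else:
                new_centroids[j] = members.mean(axis=0)
        if converged:
            break
        centroids = new_centroids
    d2 = ((X[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
    labels = d2.argmin(axis=1)
    sse = float(d2[np.arange(X.shape[0]), labels].sum())
    return labels, centroids, sse, trace


def kmeans_cluster(
    matrix: DensityMatrix,
    k: int = 2,
    seed: int = 0,
    n_init: int = 10,
    max_iter: int = 300,
) -> ClusterResult:
    """Euclidean K-means over matrix rows; best of n_init restarts by SSE.

    Clusters are labelled occupied by the mean transformed signal in the
    central +/- 500 bp columns; for k = 2 exactly the higher-signal cluster
    is occupied.
    """
    X = matrix.values
    if k < 2:
        raise ValueError("k must be >= 2")
    if X.shape[0] < k:
        raise DataError(f"cannot form {k} clusters from {X.shape[0]} rows")
    rng = np.random.default_rng(seed)
    best: Optional[ClusterResult] = None
    for _ in range(n_init):
        init = _kmeans_pp_init(X, k, rng)
        labels, centroids, sse, trace = _lloyd(X, init, max_iter)
        if best is None or sse < best.sse - 1e-12:
            best = ClusterResult(k=k, labels=labels, centroids=centroids,
                                 sse=sse, sse_trace=trace)
    assert best is not None
    central = matrix.central_columns()
    central_means = best.centroids[:, central].mean(axis=1)
    occupied = np.zeros(k, dtype=bool)
    occupied[int(np.argmax(central_means))] = True
    best.occupied = occupied
    return best


# ---------------------------------------------------------------------------
# cross-dataset specificity


def call_specific_loci(
    loci_A: Sequence[Peak],
    track_B: DensityTrack,
    k: int = 2,
    seed: int = 0,
    flank: int = MATRIX_FLANK,
    fold_threshold: float = 2.0,
) -> Tuple[List[str], ClusterResult, DensityMatrix]:
    """Label every dataset-A locus shared vs A_specific using dataset-B reads.

    Builds the B-density matrix around A summits (rpm + log2), clusters
    rows with K-means, then labels each *cluster* occupied-in-B iff the
    mean raw central (+/- 500 bp) count of its member rows exceeds
    ``fold_threshold`` times their mean flanking count. The absolute
    enrichment test (rather than a purely relative highest-cluster rule)
    makes the degenerate regimes come out right: B identical to A yields
    all shared, background-only B yields all A-specific.
    """
    if len(loci_A) < k:
        raise DataError(f"need at least {k} loci, got {len(loci_A)}")
    centers = [(p.chrom, p.summit) for p in loci_A]
    matrix = extract_matrix(track_B, centers, flank=flank, rpm=True, log2=True)
    result = kmeans_cluster(matrix, k=k, seed=seed)

    central = matrix.central_columns()
    n_cols = matrix.n_columns
    flank_cols = np.r_[0 : central.start, central.stop : n_cols]
    occupied = np.zeros(k, dtype=bool)
    for j in range(k):
        rows = matrix.raw_counts[result.labels == j]
        if len(rows) == 0:
            continue
        central_mean = rows[:, central].mean()
        flank_mean = rows[:, flank_cols].mean()
        occupied[j] = central_mean > fold_threshold * flank_mean and central_mean > 0
    result.occupied = occupied
    calls = ["shared" if occupied[lab] else "A_specific" for lab in result.labels]
    return calls, result, matrix


# ---------------------------------------------------------------------------
# merged union of loci


def merge_union(
    peaks_A: Sequence[Peak], peaks_B: Sequence[Peak]
) -> List[Tuple[GenomicInterval, str]]:
    """Single-linkage merge of the two peak sets (>= 1 bp overlap joins).

    Each merged locus is labelled by its contributing datasets: A_only,
    B_only or both. The operation is idempotent and order-invariant.
    """
    tagged = [(p.interval, "A") for p in peaks_A] + [
        (p.interval, "B") for p in peaks_B
    ]
    tagged.sort(key=lambda t: (t[0].chrom, t[0].start, t[0].end, t[1]))
    merged: List[Tuple[GenomicInterval, str]] = []
    cur: Optional[Tuple[str, int, int, set]] = None
    for iv, tag in tagged:
        if cur is not None and iv.chrom == cur[0] and iv.start < cur[2]:
            cur = (cur[0], cur[1], max(cur[2], iv.end), cur[3] | {tag})
        else:
            if cur is not None:
                merged.append(_finish_locus(cur))
            cur = (iv.chrom, iv.start, iv.end, {tag})
    if cur is not None:
        merged.append(_finish_locus(cur))
    return merged


def _finish_locus(cur: Tuple[str, int, int, set]) -> Tuple[GenomicInterval, str]:
    chrom, start, end, tags = cur
    label = "both" if tags == {"A", "B"} else ("A_only" if tags == {"A"} else "B_only")
    return GenomicInterval(chrom, start, end), label


def venn_counts(merged: Sequence[Tuple[GenomicInterval, str]]) -> Dict[str, int]:
    out = {"A_only": 0, "both": 0, "B_only": 0}
    for _, label in merged:
        out[label] += 1
    return out
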