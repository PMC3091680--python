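# Methods

## Coordinate conventions

All internal coordinates are 0-based half-open, identical to BED, so
BED ↔ internal conversion is the identity. WIG is the single 1-based
representation and exists only on disk: the writer shifts starts by
exactly +1 and the reader shifts them back, and the pair round-trips
integer tracks bit-exactly. A transcript's TSS is `tx_start` on the +
strand and `tx_end − 1` on the − strand; signed summit-to-TSS distances
are `summit − tss` on + and `tss − summit` on −, so negative always
means upstream.

## Annotation model

A peak is represented by its summit, the single base of maximal
evidence; the interval is metadata. The matched transcript minimizes
the absolute signed distance to the TSS among transcripts within 5 kb,
with distance ties broken by lexicographically smallest transcript id
(a deterministic rule; any tie-break is defensible and this one is
reproducible across platforms). Categories are exclusive: *promoter*
when the best match's distance falls in [−5000, +2000]; otherwise
*intragenic* when the summit lies inside any gene body; otherwise
*intergenic*. Promoter deliberately takes precedence over intragenic —
a summit at +1500 inside the gene is a promoter peak, since the window
defines the category and the three classes must partition the peak
list. `no_match` (no TSS within 5 kb) is a flag orthogonal to the
category: an intragenic summit 30 kb from any TSS is both intragenic
and no-match. The high-confidence filter keeps peaks with strictly
more than 40 supporting reads.

The proximal *occupancy* window used by the association stage,
[−1000, +500] with both bounds inclusive, is intentionally tighter than
the promoter-category window; the two windows answer different
questions (annotation vs functional occupancy) and are configured
independently.

## Motif classification

Windows of 500 nt centered on the summit (edge-clipped, uppercased) are
classified hierarchically: FULL_CRE > CRE_1MM > HALF_CRE > NONE, so a
window holding both a one-mismatch site and a half site is CRE_1MM and
the four classes are mutually exclusive. Because TGACGTCA is its own
reverse complement, a forward scan finds full sites on both strands,
and Hamming-1 neighbourhoods are likewise strand-symmetric; the
implementation still scans both strands for the 1-mismatch class and
reports match positions and strands. The half sites TGACG and CGTCA
are mutual reverse complements, so scanning the forward strand for both
covers both strands. N bases never match: any 8-mer containing an N is
treated as unmatchable rather than as a wildcard (conservative, and it
makes the classifier total on ACGTN input). The test suite proves exact
agreement with a brute-force both-strand k-mer enumeration and
invariance under reverse complement.

TATA detection uses the consensus TATAWAW searched on the sense strand
in [−100, −10] relative to the TSS. Neither the pattern nor the window
is universal in the literature; both are configurable arguments, and
the defaults follow the common core-promoter convention.

## Density and co-occupancy

Tag density is the count of read 5′ ends in consecutive 25-bp tiles
(step = width). Tiles rather than overlapping sliding windows were
chosen because the track must round-trip through fixedStep WIG, which
is a tiling; an overlapping-window density has no faithful WIG
serialization.

The co-occupancy matrix has one row per reference locus and 400
columns spanning ±5 kb in 25-bp bins. Before clustering, values are
scaled to reads per million (libraries of different depth would
otherwise bias occupancy calls) and compressed with log2(1+x) (pileup
heights span two orders of magnitude and untransformed Euclidean
distance would be dominated by the tallest loci). Both transforms are
optional flags.

K-means is Lloyd's algorithm with k-means++ initialization, best of 10
restarts by SSE, deterministic under a mandatory seed. It is
implemented in the package rather than delegated because two
behaviours are asserted as invariants: the per-iteration SSE trace is
non-increasing (checked on every run), and empty clusters are repaired
deterministically by re-seeding the empty centroid at the point
farthest from its assigned centroid. scikit-learn's KMeans serves as an
independent cross-check in the tests, never as the implementation.
k defaults to 2 for cross-dataset specificity (occupied vs not); k = 3
is the conventional choice when clustering promoter-machinery signal
that separates sense/antisense structure, and k is always an explicit
argument, never inferred.

Cluster-level occupancy labelling: `kmeans_cluster` labels the cluster
with the highest mean central (±500 bp) signal occupied — a relative
rule, exactly one occupied cluster for k = 2. `call_specific_loci`
instead applies an absolute enrichment test per cluster: occupied iff
the mean raw central count of its member rows exceeds 2× their mean
flanking count. The absolute rule is what makes the degenerate regimes
correct — when dataset B is dataset A every locus is shared (both
clusters pass), and when B is pure background every locus is A-specific
(neither passes) — while agreeing with the relative rule in the mixed
regime. The 2× fold threshold sits far below the ≳ 50× central
enrichment of a real pileup and far above the ~1× of background, so the
call is insensitive to its exact value; the central window uses raw
counts so the threshold has a Poisson interpretation independent of the
rpm/log transforms.

Locus merging is single-linkage over ≥ 1 bp overlaps (half-open, so
abutting intervals do not merge), labelling each merged locus by its
contributing datasets. The operation is idempotent and invariant to
input order and to pre-merging either input.

## Association

Expression classes ≤10, 11–50, 51–500, ≥501 are stated on integers; real
values are assigned by the half-open intervals [0, 10.5), [10.5, 50.5),
[50.5, 500.5), [500.5, ∞), which reproduce the integer bounds exactly
and leave no gaps. The *expressed* flag is class ≥ 3 (i.e. value ≥ 50.5,
equal to ≥ 51 on integers), keeping flag and class consistent on every
input. H3K4me3 positivity accepts either peak evidence (a K4 summit in
the occupancy window) or track evidence (windowed density above a read
threshold, default 20 reads — chosen so that, at the generator's default
depths, an active promoter's expected ~37 in-window reads are detected
while the ~7 background reads are not). False negatives are the
occupied ∧ K4-negative ∧ expressed set. Gene-symbol matching for the
deregulated-list intersection is exact after case-folding; alias
resolution is out of scope.

## The synthetic study

The generator emulates the statistical structure the analysis assumes,
with an exact truth table for every planted feature:

- **Genome**: i.i.d. uniform ACGT, default 2 chromosomes × 2 Mb.
- **Genes**: 100 transcripts on a jittered grid with TSSs ≥ 12 kb apart,
  so promoter windows never collide and every planted site has a unique
  nearest TSS. Lengths uniform 4–10 kb, strands random.
- **Sites**: 60% of genes receive a promoter site at TSS + offset,
  offset ~ Normal(−150, 60) bp truncated to [−2000, +500] — the
  empirical concentration of CRE-factor binding just upstream of the
  TSS; 15 intergenic sites sit ≥ 5 kb from every TSS and outside gene
  bodies. Each site draws a motif class from the mixture
  full 13% / one-mismatch 29% / half 41% / none 17% and an occupancy
  pattern from shared 40% / A-only 30% / B-only 30%.
- **Rejection rule**: each 500-nt site window is resampled until the
  classifier returns exactly the planted class. Without this, a random
  500-nt window contains a spurious half-CRE with probability ≈ 0.6 and
  a "none" site would be nearly impossible to plant, making truth labels
  meaningless. With it, truth class = classifier class by construction,
  and the planted-recovery test verifies that generator and classifier
  implement the same definition.
- **Reads**: point 5′ ends only — background Poisson(0.005 reads/bp)
  uniform, plus Poisson(60) reads per occupied site scattered
  Normal(site, 80 bp). No fragment-length model, sequencing errors,
  mappability structure or duplicates: the pipeline consumes only 5′
  positions, so modelling more would add realism the analysis cannot
  see. Enrichment and depth are not derived from any published library
  (none is available); they were chosen once for clear signal/background
  separability at desk scale and are ordinary config fields.
- **Peaks**: the generator also emits per-condition peak calls (interval
  = site ± 250 bp, summit = planted position, n_reads = tags within the
  interval), standing in for the upstream peak caller, which is outside
  this package's scope.
- **H3K4me3 and expression**: promoters occupied in condition A are
  K4-positive with probability 0.95 (the concordance observed in this
  assay class; the 5% complement creates the false-negative stratum),
  unoccupied promoters with probability 0.5. K4-positive promoters get
  Poisson(60) reads uniform over the first 1 kb downstream of the TSS.
  Expression is log-normal per stratum with medians 300 (occupied+K4),
  80 (K4-only) and 5 (K4-negative), σ = 1.0 — ordered so occupied+K4
  genes are over-represented in the top expression classes, as the
  association stage should detect. `couple_expression=False` collapses
  all strata to one distribution, the negative control under which the
  association table must show no shift.
- **Deregulated list**: 10 occupied genes (direct targets) plus 12
  unoccupied genes, mirroring the roughly half-direct composition of a
  knockout-deregulation experiment at this scale.

Every stage draws from an independent child stream of
`SeedSequence([seed, stage])`, so outputs are byte-identical across
reruns and regenerating one stage never perturbs another.

What passing on synthetic data does *not* show: robustness to mappability
artifacts, GC bias, fragment-size effects, imprecise summits (planted
summits are exact), overlapping promoters of real gene annotations, or
probe-to-gene mapping noise in expression data. The synthetic design
isolates the logic of the pipeline; conclusions about a real dataset
still depend on the quality of its peak calls and annotation.

## Problem sizes

The default design (4 Mb genome, ~23k reads/condition, 75 sites) runs
the full pipeline in a few seconds and is used by the end-to-end and
acceptance checks. Statistical checks that need more power use dedicated
designs: ~2000 planted sites (6 Mb genome) for motif-mix recovery, and
500 promoter sites (10 Mb genome) for the TSS-distance histogram. These
sizes give standard errors small enough for 3·SE assertions while
keeping the whole suite fast.

## Known limitations

- The annotation nearest-match rule (summit to TSS, |distance|) is one
  reasonable reading of promoter-annotation tools whose internal rules
  are unpublished; alternatives (distance to gene body) would differ for
  long genes.
- `call_specific_loci`'s fold threshold is a heuristic; datasets with
  genuinely intermediate occupancy would need a calibrated cutoff or a
  mixture model.
- WIG support is fixedStep only; variableStep and bigWig are not read.
- Expression is keyed by gene symbol; probe-level normalisation and
  alias resolution are upstream of this package.
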