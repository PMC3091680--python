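# creseq

A tested, reusable re-implementation of the ChIP-seq analysis chain used to
map genome-wide occupancy of CRE-binding transcription factors (CREB/CREM)
in male germ cells: tag-density tracks, peak-to-TSS annotation, hierarchical
CRE motif classification, cross-dataset co-occupancy clustering, and
promoter H3K4me3/expression association. A synthetic-study generator with an
exact ground-truth table drives the whole pipeline, so every stage is
exercisable and verifiable without any external data download.

## Who it is for

Computational biologists who have peak calls (e.g. from MACS), aligned reads
(BED), a genome (FASTA) and a transcript annotation, and want the classic
CREB/CREM-style occupancy analysis: which promoters are bound, where binding
sits relative to the TSS, which sites carry a CRE, which loci are shared
between two cell states, and how occupancy relates to promoter activity and
expression.

## The analysis

- **Density tracks.** Read 5′ ends are counted in consecutive 25-bp bins per
  chromosome and serialized as fixedStep WIG.
- **Annotation.** Each peak is anchored at its summit and matched to the
  transcript with the nearest TSS within 5 kb (strand-aware signed distance
  d = summit − TSS on +, TSS − summit on −; negative = upstream). Category:
  *promoter* if d ∈ [−5000, +2000], else *intragenic* if the summit lies in a
  gene body, else *intergenic*; peaks with no TSS within 5 kb are flagged
  `no_match`. Peaks supported by > 40 clustered reads form the
  high-confidence set.
- **Motif classification.** The 500-nt window centered on each summit is
  assigned one class with precedence FULL_CRE (TGACGTCA, a palindrome) >
  CRE_1MM (any 8-mer within Hamming distance 1, either strand) > HALF_CRE
  (TGACG or CGTCA) > NONE. A consensus TATA element (TATAWAW, W = A/T) is
  searched in [−100, −10] of the TSS on the sense strand.
- **Co-occupancy.** For dataset-A summits, dataset-B density is extracted in
  ±5 kb windows (400 bins of 25 bp), scaled to reads per million,
  log2(1+x)-compressed, and clustered with K-means (k = 2, k-means++ seeding,
  best of 10 restarts). A cluster is called B-occupied when its central
  ±500 bp signal exceeds twice its flanking signal; member loci are *shared*,
  the rest *A-specific*. The union of both peak sets is single-linkage merged
  (≥ 1 bp overlap) into distinct loci labelled A-only / B-only / both.
- **Association.** A promoter is *occupied* if a summit lies in
  [−1000, +500] of its TSS and *active* if H3K4me3 evidence covers the same
  window. Expression values are binned into the classes ≤10, 11–50, 51–500,
  ≥501 (expressed ⇔ class ≥ 3), and the class distribution of occupied+K4
  genes is compared with all genes. Occupied, K4-negative but expressed
  promoters are reported as false negatives; occupied genes are intersected
  with a knockout-deregulated list to call direct targets.

## Worked example

Run the full pipeline on a self-generated synthetic study:

```bash
creseq run-all --seed 7 --simulate --out report/
```

which logs one line per stage and ends with

```
report written to report/ (75 merged loci)
```

`report/summary.json` then contains (seed 7, default design: 2 × 2 Mb
genome, 100 genes, 75 planted sites, 40/30/30% shared/A-only/B-only,
enrichment 60 reads per site over 0.005 reads/bp background):

```
"n_high_confidence_A": 47     peaks in condition A passing the > 40-read filter
"merged_loci": 75             distinct loci after merging both conditions
"venn": {"A_only": 21, "both": 26, "B_only": 28}
"expressed_fraction_all": 0.55
"expressed_fraction_occupied_k4": 0.9117...
"n_direct_targets": 10        occupied ∩ deregulated (all 10 planted targets)
```

The occupied+K4 genes are strongly over-represented among expressed genes
(91% vs 55%), the planted direct-target overlap is recovered exactly, and
every shared/specific label matches the simulation's truth table. Individual
stages are available as `creseq simulate | density | annotate |
classify-motifs | cooccupy | associate`.

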