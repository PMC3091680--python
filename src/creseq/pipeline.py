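"""End-to-end pipeline: simulate (optional) -> density -> annotate ->
classify motifs -> co-occupancy -> association, with one report directory
and a replayable run manifest.

Every stochastic step draws from the single mandatory seed, so a rerun
with the same manifest reproduces every output byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass
from typing import Dict, Optional, Tuple

import pandas as pd

from . import io as cio
from .annotate import (
    annotate_peaks,
    category_counts,
    high_confidence_filter,
    tss_distance_histogram,
)
from .association import (
    association_table,
    build_promoter_statuses,
    direct_targets,
    false_negatives,
    promoter_occupancy,
)
from .cooccupancy import (
    call_specific_loci,
    compute_density,
    merge_union,
    venn_counts,
)
from .motif import classify_cre, extract_summit_window
from .records import DataError
from .simulate import SimulationConfig, simulate_study, write_study

log = logging.getLogger("creseq")


@dataclass
class PipelineConfig:
    """Paths and parameters for one pipeline run. Seed is mandatory."""

    seed: int
    outdir: str
    genome: Optional[str] = None
    transcripts: Optional[str] = None
    peaks_a: Optional[str] = None
    peaks_b: Optional[str] = None
    reads_a: Optional[str] = None
    reads_b: Optional[str] = None
    reads_k4: Optional[str] = None
    expression: Optional[str] = None
    deregulated: Optional[str] = None
    simulate: bool = False
    bin_width: int = 25
    matrix_flank: int = 5000
    summit_window: int = 500
    promoter_window: Tuple[int, int] = (-5000, 2000)
    occupancy_window: Tuple[int, int] = (-1000, 500)
    min_reads: int = 40
    k4_min_reads: int = 20
    k: int = 2

    def validate(self) -> None:
        if self.seed is None:
            raise DataError("a seed is mandatory for every pipeline run")
        if not self.simulate:
            for name in ("genome", "transcripts", "peaks_a", "peaks_b",
                         "reads_a", "reads_b", "reads_k4", "expression",
                         "deregulated"):
                path = getattr(self, name)
                if path is None:
                    raise DataError(f"input {name!r} missing and --simulate not set")
                if not os.path.exists(path):
                    raise DataError(f"input {name!r} not found: {path}")


def run_all(config: PipelineConfig) -> Dict[str, object]:
    """Execute the whole chain and write the report directory.

    Returns the summary dict (also written as report/summary.json).
    """
    config.validate()
    outdir = cio.ensure_dir(config.outdir)

    if config.simulate:
        log.info("stage=simulate seed=%d", config.seed)
        sim = simulate_study(SimulationConfig(seed=config.seed))
        simdir = os.path.join(outdir, "simulated")
        paths = write_study(sim, simdir)
        genome = sim.genome
        transcripts = sim.transcripts
        peaks_a, peaks_b = sim.peaks_A, sim.peaks_B
        reads_a, reads_b, reads_k4 = sim.reads_A, sim.reads_B, sim.reads_K4
        expression = sim.expression
        deregulated = sim.deregulated
    else:
        genome = cio.read_genome(config.genome)
        transcripts = cio.read_transcripts(config.transcripts)
        peaks_a = cio.read_peaks(config.peaks_a, dialect="table_s1")
        peaks_b = cio.read_peaks(config.peaks_b, dialect="table_s1")
        reads_a = cio.read_reads_bed(config.reads_a)
        reads_b = cio.read_reads_bed(config.reads_b)
        reads_k4 = cio.read_reads_bed(config.reads_k4)
        expression = cio.read_expression(config.expression)
        deregulated = cio.read_gene_list(config.deregulated)

    sizes = {c: len(s) for c, s in genome.items()}

    # --- density tracks -> WIG
    tracks = {}
    for name, reads in (("A", reads_a), ("B", reads_b), ("K4", reads_k4)):
        tracks[name] = compute_density(reads, sizes, config.bin_width,
                                       name=f"density_{name}")
        cio.write_wig(tracks[name], os.path.join(outdir, f"density_{name}.wig"))
        log.info("stage=density dataset=%s reads=%d", name, len(reads))

    # --- high-confidence filter + annotation (condition A)
    hc_peaks = high_confidence_filter(peaks_a, config.min_reads)
    log.info("stage=filter in=%d out=%d min_reads=%d",
             len(peaks_a), len(hc_peaks), config.min_reads)
    annotations = annotate_peaks(hc_peaks, transcripts)
    for a in annotations:
        window = extract_summit_window(genome, a.peak.chrom, a.peak.summit,
                                       config.summit_window)
        a.motif_class = classify_cre(window).motif_class.value
    cats = category_counts(annotations)
    hist = tss_distance_histogram(annotations, bin_width=100,
                                  distance_range=5000)
    hist.to_csv(os.path.join(outdir, "tss_distance_histogram.tsv"),
                sep="\t", index=False)
    log.info("stage=annotate peaks=%d categories=%s", len(annotations), cats)

    # --- motif class frequencies over the high-confidence peaks
    from .motif import class_frequencies

    props, counts = class_frequencies(
        [a.motif_class for a in annotations]
    )
    motif_df = pd.DataFrame({
        "motif_class": [c.value for c in props],
        "count": [counts[c] for c in props],
        "proportion": [props[c] for c in props],
    })
    motif_df.to_csv(os.path.join(outdir, "motif_class_frequencies.tsv"),
                    sep="\t", index=False, float_format="%.6g")

    # --- co-occupancy: B density around A summits, and the swap
    calls_a, _, _ = call_specific_loci(hc_peaks, tracks["B"], k=config.k,
                                       seed=config.seed,
                                       flank=config.matrix_flank)
    hc_peaks_b = high_confidence_filter(peaks_b, config.min_reads)
    calls_b, _, _ = call_specific_loci(hc_peaks_b, tracks["A"], k=config.k,
                                       seed=config.seed,
                                       flank=config.matrix_flank)
    spec_df = pd.DataFrame(
        [{"dataset": "A", "chrom": p.chrom, "summit": p.summit, "call": c}
         for p, c in zip(hc_peaks, calls_a)]
        + [{"dataset": "B", "chrom": p.chrom, "summit": p.summit,
            "call": c.replace("A_specific", "B_specific")}
           for p, c in zip(hc_peaks_b, calls_b)]
    )
    spec_df.to_csv(os.path.join(outdir, "specificity_calls.tsv"),
                   sep="\t", index=False)
    merged = merge_union(peaks_a, peaks_b)
    venn = venn_counts(merged)
    with open(os.path.join(outdir, "merged_loci_venn.txt"), "w") as fh:
        for key in ("A_only", "both", "B_only"):
            fh.write(f"{key}\t{venn[key]}\n")
    log.info("stage=cooccupy merged_loci=%d venn=%s", len(merged), venn)

    # --- association with H3K4me3 and expression
    occupied = promoter_occupancy(annotations, config.occupancy_window)
    statuses = build_promoter_statuses(
        transcripts, occupied, expression, k4_track=tracks["K4"],
        window=config.occupancy_window, min_reads=config.k4_min_reads,
    )
    assoc = association_table(statuses)
    assoc.to_csv(os.path.join(outdir, "association_table.tsv"),
                 sep="\t", index=False, float_format="%.6g")
    fns = false_negatives(statuses)
    pd.DataFrame({"transcript_id": sorted(fns)}).to_csv(
        os.path.join(outdir, "false_negatives.tsv"), sep="\t", index=False)
    tid_to_symbol = {t.transcript_id: t.gene_symbol for t in transcripts}
    occupied_symbols = sorted({tid_to_symbol[t] for t in occupied})
    overlap, dt_venn = direct_targets(occupied_symbols, deregulated)
    pd.DataFrame({"gene_symbol": sorted(overlap)}).to_csv(
        os.path.join(outdir, "direct_targets.tsv"), sep="\t", index=False)
    log.info("stage=associate occupied=%d k4_pos=%d direct_targets=%d",
             len(occupied), sum(s.k4_positive for s in statuses),
             len(overlap))

    # --- annotation table last so it can carry K4 status
    k4_by_tid = {s.transcript_id: s.k4_positive for s in statuses}
    for a in annotations:
        if a.matched_transcript is not None:
            a.h3k4me3 = k4_by_tid.get(a.matched_transcript.transcript_id)
    cio.write_annotation_table(
        annotations, os.path.join(outdir, "annotations.tsv"))

    summary = {
        "n_peaks_A": len(peaks_a),
        "n_peaks_B": len(peaks_b),
        "n_high_confidence_A": len(hc_peaks),
        "category_counts": cats,
        "motif_class_proportions": {c.value: props[c] for c in props},
        "n_shared_A": sum(c == "shared" for c in calls_a),
        "n_A_specific": sum(c == "A_specific" for c in calls_a),
        "n_shared_B": sum(c == "shared" for c in calls_b),
        "n_B_specific": sum(c == "A_specific" for c in calls_b),
        "merged_loci": len(merged),
        "venn": venn,
        "n_occupied_promoters": len(occupied),
        "expressed_fraction_all": float(
            assoc.loc[assoc.group == "all", "expressed_fraction"].iloc[0]),
        "expressed_fraction_occupied_k4": float(
            assoc.loc[assoc.group == "occupied_k4",
                      "expressed_fraction"].iloc[0]),
        "n_false_negatives": len(fns),
        "n_direct_targets": len(overlap),
        "direct_target_venn": dt_venn,
    }
    with open(os.path.join(outdir, "summary.json"), "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")

    # paths are deliberately excluded so a report is byte-identical across
    # reruns regardless of where it is written
    path_fields = {"outdir", "genome", "transcripts", "peaks_a", "peaks_b",
                   "reads_a", "reads_b", "reads_k4", "expression",
                   "deregulated"}
    manifest = {
        "parameters": {
            k: v for k, v in dataclasses.asdict(config).items()
            if k not in path_fields
        },
    }
    with open(os.path.join(outdir, "run_manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
    return summary
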