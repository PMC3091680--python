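"""Synthetic ChIP-seq study generator with exact ground truth.

Emulates the statistical structure the analysis assumes: a random genome
with well-spaced gene models; binding sites planted upstream of TSSs with
offsets drawn Normal(-150, 60) bp (truncated to [-2000, +500]) plus
intergenic sites far from any TSS; a CRE motif-class mixture at the sites;
two-condition (A/B) shared/specific occupancy; H3K4me3 reads at active
promoters; and log-normal expression strata coupled to occupancy so that
occupied+H3K4me3 genes are over-represented among highly expressed genes.

Every planted site's 500-nt window is rejection-resampled until the
hierarchical CRE classifier returns exactly the planted class, so truth
labels equal classifier labels by construction — without this, random
windows contain spurious half-sites with probability near 1 and the
"none" class would be untestable.

All outputs are deterministic functions of the seed: each stage draws
from an independent child stream of ``numpy.random.SeedSequence([seed,
stage])``, so regenerating any stage reproduces it bit-for-bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .motif import MotifClass, classify_cre
from .records import DataError, GenomicInterval, Peak, Read, TranscriptRecord

_STREAMS = {"genome": 0, "genes": 1, "sites": 2, "A": 3, "B": 4, "K4": 5,
            "expression": 6, "deregulated": 7}

FULL = "TGACGTCA"
HALVES = ("TGACG", "CGTCA")
BASES = np.array(list("ACGT"))

OCCUPANCY_PATTERNS = ("shared", "A_only", "B_only")


@dataclass
class SimulationConfig:
    """Knobs of the synthetic study; defaults define the standard design."""

    seed: int
    n_chroms: int = 2
    chrom_length: int = 2_000_000
    n_genes: int = 100
    read_length: int = 36
    background_rate: float = 0.005  # reads per bp per condition
    site_enrichment: float = 60.0  # mean signal reads per occupied site
    read_scatter_sd: float = 80.0  # sd of signal-read 5' ends around a site
    site_offset_mean: float = -150.0
    site_offset_sd: float = 60.0
    offset_bounds: Tuple[int, int] = (-2000, 500)
    motif_class_mix: Dict[str, float] = field(
        default_factory=lambda: {
            "full": 0.13, "one_mismatch": 0.29, "half": 0.41, "none": 0.17,
        }
    )
    shared_fraction: float = 0.4
    a_specific_fraction: float = 0.3
    b_specific_fraction: float = 0.3
    occupied_gene_fraction: float = 0.6
    n_intergenic_sites: int = 15
    k4_concordance: float = 0.95  # P(K4+ | promoter occupied in A)
    k4_active_fraction: float = 0.5  # P(K4+ | promoter not occupied in A)
    k4_enrichment: float = 60.0
    expr_lognormal_params: Dict[str, Tuple[float, float]] = field(
        default_factory=lambda: {
            "occupied_k4": (math.log(300.0), 1.0),
            "k4_only": (math.log(80.0), 1.0),
            "inactive": (math.log(5.0), 1.0),
        }
    )
    n_direct_targets: int = 10
    n_nondirect_deregulated: int = 12
    min_gene_spacing: int = 12_000

    def __post_init__(self) -> None:
        mix_total = sum(self.motif_class_mix.values())
        if abs(mix_total - 1.0) > 1e-9:
            raise DataError(f"motif_class_mix sums to {mix_total}, not 1")
        occ_total = (
            self.shared_fraction + self.a_specific_fraction + self.b_specific_fraction
        )
        if abs(occ_total - 1.0) > 1e-9:
            raise DataError(f"occupancy fractions sum to {occ_total}, not 1")
        for name in ("occupied_gene_fraction", "k4_concordance",
                     "k4_active_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise DataError(f"{name} must be in [0, 1]")
        if self.background_rate <= 0 or self.site_enrichment <= 0:
            raise DataError("rates must be > 0")

    def rng(self, stage: str) -> np.random.Generator:
        return np.random.default_rng(
            np.random.SeedSequence([self.seed, _STREAMS[stage]])
        )


@dataclass
class SimulationResult:
    """Everything one simulated study comprises, in memory."""

    config: SimulationConfig
    genome: Dict[str, str]
    transcripts: List[TranscriptRecord]
    truth_sites: pd.DataFrame
    truth_genes: pd.DataFrame
    reads_A: List[Read]
    reads_B: List[Read]
    reads_K4: List[Read]
    peaks_A: List[Peak]
    peaks_B: List[Peak]
    expression: Dict[str, float]
    deregulated: List[str]


# ---------------------------------------------------------------------------
# genome and gene models


def generate_genome(config: SimulationConfig) -> Dict[str, str]:
    """I.i.d. uniform-ACGT chromosomes, deterministic under the seed."""
    rng = config.rng("genome")
    genome = {}
    for c in range(config.n_chroms):
        seq = rng.integers(0, 4, size=config.chrom_length)
        genome[f"chr{c + 1}"] = "".join(BASES[seq])
    return genome


def generate_transcripts(config: SimulationConfig) -> List[TranscriptRecord]:
    """Gene models on a jittered grid so promoter windows never collide."""
    rng = config.rng("genes")
    per_chrom = [config.n_genes // config.n_chroms] * config.n_chroms
    for i in range(config.n_genes % config.n_chroms):
        per_chrom[i] += 1
    records: List[TranscriptRecord] = []
    gene_no = 0
    for c, n in enumerate(per_chrom):
        if n == 0:
            continue
        slot = config.chrom_length // n
        if slot < config.min_gene_spacing + 8_000:
            raise DataError(
                f"cannot space {n} genes >= {config.min_gene_spacing} bp apart "
                f"on a {config.chrom_length} bp chromosome; "
                "increase chrom_length or reduce n_genes"
            )
        chrom = f"chr{c + 1}"
        for i in range(n):
            margin = 4_000
            lo = i * slot + margin
            hi = (i + 1) * slot - config.min_gene_spacing
            tss = int(rng.integers(lo, hi))
            length = int(rng.integers(4_000, 10_000))
            strand = "+" if rng.random() < 0.5 else "-"
            if strand == "+":
                tx_start, tx_end = tss, tss + length
            else:
                tx_start, tx_end = tss + 1 - length, tss + 1
            gene_no += 1
            records.append(
                TranscriptRecord(
                    transcript_id=f"NM_{gene_no:06d}",
                    gene_symbol=f"Gene{gene_no}",
                    chrom=chrom,
                    strand=strand,
                    tx_start=max(0, tx_start),
                    tx_end=min(config.chrom_length, tx_end),
                )
            )
    return records


# ---------------------------------------------------------------------------
# site planting


def _truncated_normal_offset(rng: np.random.Generator,
                             config: SimulationConfig) -> int:
    lo, hi = config.offset_bounds
    while True:
        x = rng.normal(config.site_offset_mean, config.site_offset_sd)
        if lo <= x <= hi:
            return int(round(x))


def _mutate_one(rng: np.random.Generator, motif: str) -> str:
    i = int(rng.integers(len(motif)))
    alternatives = [b for b in "ACGT" if b != motif[i]]
    return motif[:i] + alternatives[int(rng.integers(3))] + motif[i + 1 :]


def _random_window(rng: np.random.Generator, length: int) -> str:
    return "".join(BASES[rng.integers(0, 4, size=length)])


def _build_window(rng: np.random.Generator, truth_class: str,
                  length: int = 500, max_tries: int = 2_000) -> str:
    """Draw a window whose classifier call equals the planted class."""
    half = length // 2
    for _ in range(max_tries):
        window = _random_window(rng, length)
        if truth_class == "full":
            motif = FULL
        elif truth_class == "one_mismatch":
            motif = _mutate_one(rng, FULL)
        elif truth_class == "half":
            motif = HALVES[int(rng.integers(2))]
        else:
            motif = None
        if motif is not None:
            start = half - len(motif) // 2
            window = window[:start] + motif + window[start + len(motif) :]
        if classify_cre(window).motif_class == MotifClass(truth_class):
            return window
    raise DataError(
        f"could not construct a clean window for class {truth_class!r}"
    )


def plant_sites(
    genome: Dict[str, str],
    transcripts: Sequence[TranscriptRecord],
    config: SimulationConfig,
) -> Tuple[Dict[str, str], pd.DataFrame]:
    """Edit motif windows into the genome; return (genome, truth table).

    Promoter sites go at TSS + offset (strand-aware, offset ~ truncated
    Normal); intergenic sites sit >= 5 kb from every TSS and outside gene
    bodies. The returned truth table has one row per planted site.
    """
    rng = config.rng("sites")
    seqs = {c: list(s) for c, s in genome.items()}
    rows = []

    n_occ = int(round(config.occupied_gene_fraction * len(transcripts)))
    order = rng.permutation(len(transcripts))
    chosen = [transcripts[i] for i in sorted(order[:n_occ])]

    mix_names = list(config.motif_class_mix)
    mix_p = np.array([config.motif_class_mix[k] for k in mix_names])
    occ_p = np.array([config.shared_fraction, config.a_specific_fraction,
                      config.b_specific_fraction])

    site_id = 0
    for t in chosen:
        offset = _truncated_normal_offset(rng, config)
        pos = t.tss + offset if t.strand == "+" else t.tss - offset
        chrom_len = len(seqs[t.chrom])
        pos = int(np.clip(pos, 250, chrom_len - 251))
        truth_class = mix_names[int(rng.choice(len(mix_names), p=mix_p))]
        occupancy = OCCUPANCY_PATTERNS[int(rng.choice(3, p=occ_p))]
        window = _build_window(rng, truth_class)
        seqs[t.chrom][pos - 250 : pos + 250] = list(window)
        site_id += 1
        rows.append({
            "site_id": f"site{site_id:05d}",
            "chrom": t.chrom,
            "pos": pos,
            "site_type": "promoter",
            "transcript_id": t.transcript_id,
            "gene_symbol": t.gene_symbol,
            "offset": offset,
            "motif_class": truth_class,
            "occupancy": occupancy,
        })

    # intergenic candidates: jittered 1-kb grid, >= 5 kb from every TSS and
    # outside gene bodies, so planted windows never overlap
    if config.n_intergenic_sites > 0:
        tss_by_chrom: Dict[str, np.ndarray] = {}
        bodies: Dict[str, List[Tuple[int, int]]] = {}
        for t in transcripts:
            tss_by_chrom.setdefault(t.chrom, [])
            bodies.setdefault(t.chrom, []).append((t.tx_start, t.tx_end))
        for t in transcripts:
            tss_by_chrom[t.chrom] = np.append(
                np.asarray(tss_by_chrom[t.chrom]), t.tss
            )
        candidates: List[Tuple[str, int]] = []
        for chrom in sorted(seqs):
            length = len(seqs[chrom])
            grid = np.arange(1_000, length - 1_000, 1_000)
            jitter = rng.integers(-200, 201, size=len(grid))
            positions = grid + jitter
            tss = np.sort(tss_by_chrom.get(chrom, np.array([])))
            for p in positions:
                p = int(p)
                if len(tss) and np.min(np.abs(tss - p)) < 5_000:
                    continue
                if any(s <= p < e for s, e in bodies.get(chrom, [])):
                    continue
                candidates.append((chrom, p))
        if len(candidates) < config.n_intergenic_sites:
            raise DataError(
                "not enough intergenic space for "
                f"{config.n_intergenic_sites} sites; increase chrom_length"
            )
        pick = rng.choice(len(candidates), size=config.n_intergenic_sites,
                          replace=False)
        for idx in sorted(pick):
            chrom, pos = candidates[int(idx)]
            truth_class = mix_names[int(rng.choice(len(mix_names), p=mix_p))]
            occupancy = OCCUPANCY_PATTERNS[int(rng.choice(3, p=occ_p))]
            window = _build_window(rng, truth_class)
            seqs[chrom][pos - 250 : pos + 250] = list(window)
            site_id += 1
            rows.append({
                "site_id": f"site{site_id:05d}",
                "chrom": chrom,
                "pos": pos,
                "site_type": "intergenic",
                "transcript_id": "",
                "gene_symbol": "",
                "offset": np.nan,
                "motif_class": truth_class,
                "occupancy": occupancy,
            })

    edited = {c: "".join(s) for c, s in seqs.items()}
    return edited, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# reads


def _occupied_in(occupancy: str, condition: str) -> bool:
    return occupancy == "shared" or occupancy == f"{condition}_only"


def simulate_reads(
    truth_sites: pd.DataFrame,
    genome_sizes: Dict[str, int],
    config: SimulationConfig,
    condition: str,
) -> List[Read]:
    """Background Poisson reads plus Gaussian pileups at occupied sites."""
    if condition not in ("A", "B"):
        raise ValueError("condition must be 'A' or 'B'")
    rng = config.rng(condition)
    reads: List[Read] = []
    for chrom in sorted(genome_sizes):
        size = genome_sizes[chrom]
        n_bg = rng.poisson(config.background_rate * size)
        positions = np.sort(rng.integers(0, size, size=n_bg))
        strands = rng.random(n_bg) < 0.5
        for p, s in zip(positions, strands):
            reads.append(Read(chrom=chrom, pos5=int(p),
                              strand="+" if s else "-",
                              length=config.read_length))
    for row in truth_sites.itertuples(index=False):
        if not _occupied_in(row.occupancy, condition):
            continue
        n = rng.poisson(config.site_enrichment)
        pos = np.round(rng.normal(row.pos, config.read_scatter_sd, size=n))
        pos = np.clip(pos, 0, genome_sizes[row.chrom] - 1).astype(int)
        strands = rng.random(n) < 0.5
        for p, s in zip(pos, strands):
            reads.append(Read(chrom=row.chrom, pos5=int(p),
                              strand="+" if s else "-",
                              length=config.read_length))
    return reads


def make_peaks(
    truth_sites: pd.DataFrame,
    reads: Sequence[Read],
    genome_sizes: Dict[str, int],
    condition: str,
) -> List[Peak]:
    """Peak calls for one condition, standing in for the upstream caller.

    One peak per site occupied in the condition: interval = site +/- 250 bp,
    summit = the planted position, n_reads = tags with 5' end inside the
    interval.
    """
    pos_by_chrom: Dict[str, np.ndarray] = {}
    for chrom in sorted(genome_sizes):
        pos_by_chrom[chrom] = np.sort(
            np.array([r.pos5 for r in reads if r.chrom == chrom])
        )
    peaks = []
    for row in truth_sites.itertuples(index=False):
        if not _occupied_in(row.occupancy, condition):
            continue
        start = max(0, row.pos - 250)
        end = min(genome_sizes[row.chrom], row.pos + 250)
        positions = pos_by_chrom[row.chrom]
        n = int(np.searchsorted(positions, end) - np.searchsorted(positions, start))
        peaks.append(Peak(
            interval=GenomicInterval(row.chrom, start, end),
            summit=int(row.pos),
            n_reads=n,
            dataset_label=condition,
        ))
    return peaks


# ---------------------------------------------------------------------------
# H3K4me3 and expression


def simulate_k4_and_expression(
    truth_sites: pd.DataFrame,
    transcripts: Sequence[TranscriptRecord],
    genome_sizes: Dict[str, int],
    config: SimulationConfig,
    couple_expression: bool = True,
) -> Tuple[List[Read], Dict[str, float], pd.DataFrame]:
    """H3K4me3 reads, an expression table, and the per-gene truth table.

    Promoters occupied in condition A are K4-positive with probability
    ``k4_concordance``; unoccupied promoters with ``k4_active_fraction``.
    Expression is log-normal per stratum with medians ordered
    occupied+K4 > K4-only > inactive. With ``couple_expression=False``
    every gene draws from one common distribution regardless of stratum
    (the negative control: occupancy independent of expression).
    """
    rng = config.rng("K4")
    occupied_tids = set(
        truth_sites.loc[
            (truth_sites.site_type == "promoter")
            & truth_sites.occupancy.isin(["shared", "A_only"]),
            "transcript_id",
        ]
    )
    reads: List[Read] = []
    for chrom in sorted(genome_sizes):
        size = genome_sizes[chrom]
        n_bg = rng.poisson(config.background_rate * size)
        positions = np.sort(rng.integers(0, size, size=n_bg))
        strands = rng.random(n_bg) < 0.5
        for p, s in zip(positions, strands):
            reads.append(Read(chrom=chrom, pos5=int(p),
                              strand="+" if s else "-",
                              length=config.read_length))

    gene_rows = []
    for t in transcripts:
        occupied = t.transcript_id in occupied_tids
        p_k4 = config.k4_concordance if occupied else config.k4_active_fraction
        k4 = bool(rng.random() < p_k4)
        if k4:
            n = rng.poisson(config.k4_enrichment)
            offsets = rng.integers(0, 1_000, size=n)
            if t.strand == "+":
                pos = t.tss + offsets
            else:
                pos = t.tss - offsets
            pos = np.clip(pos, 0, genome_sizes[t.chrom] - 1)
            strands = rng.random(n) < 0.5
            for p, s in zip(pos, strands):
                reads.append(Read(chrom=t.chrom, pos5=int(p),
                                  strand="+" if s else "-",
                                  length=config.read_length))
        if occupied and k4:
            stratum = "occupied_k4"
        elif k4:
            stratum = "k4_only"
        else:
            stratum = "inactive"
        gene_rows.append({
            "transcript_id": t.transcript_id,
            "gene_symbol": t.gene_symbol,
            "occupied_A": occupied,
            "k4": k4,
            "stratum": stratum,
        })

    expr_rng = config.rng("expression")
    expression: Dict[str, float] = {}
    for row in gene_rows:
        if couple_expression:
            mu, sigma = config.expr_lognormal_params[row["stratum"]]
        else:
            mu, sigma = config.expr_lognormal_params["k4_only"]
        expression[row["gene_symbol"]] = float(expr_rng.lognormal(mu, sigma))
    truth_genes = pd.DataFrame(gene_rows)
    truth_genes["expression"] = truth_genes.gene_symbol.map(expression)
    return reads, expression, truth_genes


def make_deregulated_list(
    truth_genes: pd.DataFrame,
    config: SimulationConfig,
) -> Tuple[List[str], pd.DataFrame]:
    """A knockout-deregulated gene list mixing direct targets and bystanders.

    Direct targets are drawn from occupied promoters, the rest from
    unoccupied genes; the returned truth table marks which is which.
    """
    rng = config.rng("deregulated")
    occ = truth_genes.loc[truth_genes.occupied_A, "gene_symbol"].tolist()
    non = truth_genes.loc[~truth_genes.occupied_A, "gene_symbol"].tolist()
    if config.n_direct_targets > len(occ):
        raise DataError(
            f"requested {config.n_direct_targets} direct targets but only "
            f"{len(occ)} occupied genes exist"
        )
    if config.n_nondirect_deregulated > len(non):
        raise DataError(
            f"requested {config.n_nondirect_deregulated} non-direct genes "
            f"but only {len(non)} unoccupied genes exist"
        )
    direct = [occ[i] for i in sorted(rng.choice(len(occ),
              size=config.n_direct_targets, replace=False))]
    indirect = [non[i] for i in sorted(rng.choice(len(non),
                size=config.n_nondirect_deregulated, replace=False))]
    genes = direct + indirect
    truth = pd.DataFrame({
        "gene_symbol": genes,
        "direct_target": [True] * len(direct) + [False] * len(indirect),
    })
    return genes, truth


# ---------------------------------------------------------------------------
# full study


def simulate_study(
    config: SimulationConfig, couple_expression: bool = True
) -> SimulationResult:
    """Run every generator stage and return the complete in-memory study."""
    genome = generate_genome(config)
    transcripts = generate_transcripts(config)
    genome, truth_sites = plant_sites(genome, transcripts, config)
    sizes = {c: len(s) for c, s in genome.items()}
    reads_A = simulate_reads(truth_sites, sizes, config, "A")
    reads_B = simulate_reads(truth_sites, sizes, config, "B")
    peaks_A = make_peaks(truth_sites, reads_A, sizes, "A")
    peaks_B = make_peaks(truth_sites, reads_B, sizes, "B")
    reads_K4, expression, truth_genes = simulate_k4_and_expression(
        truth_sites, transcripts, sizes, config,
        couple_expression=couple_expression,
    )
    deregulated, dereg_truth = make_deregulated_list(truth_genes, config)
    truth_genes = truth_genes.merge(dereg_truth, on="gene_symbol", how="left")
    truth_genes["direct_target"] = (
        truth_genes.direct_target.astype("boolean").fillna(False).astype(bool)
    )
    truth_genes["deregulated"] = truth_genes.gene_symbol.isin(deregulated)
    return SimulationResult(
        config=config,
        genome=genome,
        transcripts=transcripts,
        truth_sites=truth_sites,
        truth_genes=truth_genes,
        reads_A=reads_A,
        reads_B=reads_B,
        reads_K4=reads_K4,
        peaks_A=peaks_A,
        peaks_B=peaks_B,
        expression=expression,
        deregulated=deregulated,
    )


def write_study(result: SimulationResult, outdir: str) -> Dict[str, str]:
    """Serialize a simulated study to its standard file set."""
    import os

    from . import io as cio

    os.makedirs(outdir, exist_ok=True)
    paths = {
        "genome": os.path.join(outdir, "genome.fa"),
        "transcripts": os.path.join(outdir, "transcripts.tsv"),
        "reads_A": os.path.join(outdir, "reads_A.bed"),
        "reads_B": os.path.join(outdir, "reads_B.bed"),
        "reads_K4": os.path.join(outdir, "reads_K4.bed"),
        "peaks_A": os.path.join(outdir, "peaks_A.tsv"),
        "peaks_B": os.path.join(outdir, "peaks_B.tsv"),
        "expression": os.path.join(outdir, "expression.tsv"),
        "deregulated": os.path.join(outdir, "deregulated.tsv"),
        "truth_sites": os.path.join(outdir, "truth_sites.tsv"),
        "truth_genes": os.path.join(outdir, "truth_genes.tsv"),
    }
    cio.write_fasta(result.genome, paths["genome"])
    cio.write_transcripts(result.transcripts, paths["transcripts"])
    cio.write_reads_bed(result.reads_A, paths["reads_A"])
    cio.write_reads_bed(result.reads_B, paths["reads_B"])
    cio.write_reads_bed(result.reads_K4, paths["reads_K4"])
    cio.write_peaks_table(result.peaks_A, paths["peaks_A"])
    cio.write_peaks_table(result.peaks_B, paths["peaks_B"])
    cio.write_expression(result.expression, paths["expression"])
    cio.write_gene_list(result.deregulated, paths["deregulated"])
    result.truth_sites.to_csv(paths["truth_sites"], sep="\t", index=False,
                              float_format="%.0f")
    result.truth_genes.to_csv(paths["truth_genes"], sep="\t", index=False,
                              float_format="%.6g")
    return paths
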