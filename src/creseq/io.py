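"""Readers and writers for every external format the pipeline touches.

Formats: FASTA (genome, via pyfaidx on read), BED3/BED6 (reads and peaks),
fixedStep WIG (density tracks), and headered TSVs (peaks in the annotated
table dialect, transcripts, expression, gene lists, annotations).

Internal coordinates are 0-based half-open throughout; BED round-trips as
the identity and WIG shifts start positions by exactly +1 on disk.
"""

from __future__ import annotations

import os
from typing import Dict, Iterable, List, Optional, Sequence

import pandas as pd
from pyfaidx import Fasta

from .records import DataError, GenomicInterval, Peak, Read, TranscriptRecord

TABLE_S1_COLUMNS = [
    "chrom",
    "start",
    "end",
    "summit",
    "n_reads",
    "p_value",
    "fold_enrichment",
]

ANNOTATION_COLUMNS = [
    "chrom",
    "start",
    "end",
    "summit",
    "n_reads",
    "category",
    "transcript_id",
    "gene_symbol",
    "tss",
    "signed_distance",
    "motif_class",
    "h3k4me3_status",
]

NO_MATCH = "no_match"


# ---------------------------------------------------------------------------
# genome FASTA


def read_genome(path: str) -> Dict[str, str]:
    """Load a genome FASTA into an uppercase chrom -> sequence dict."""
    fa = Fasta(path, as_raw=True, read_ahead=None, rebuild=True)
    return {name: str(fa[name][:]).upper() for name in fa.keys()}


def write_fasta(sequences: Dict[str, str], path: str, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def genome_sizes(sequences: Dict[str, str]) -> Dict[str, int]:
    return {name: len(seq) for name, seq in sequences.items()}


# ---------------------------------------------------------------------------
# peaks


def read_peaks(path: str, dialect: str = "bed") -> List[Peak]:
    """Parse peak calls.

    ``dialect="bed"``: BED3+ with no header; summit = floor midpoint.
    ``dialect="table_s1"``: headered TSV with columns chrom, start, end,
    summit, n_reads and optional p_value / fold_enrichment.
    """
    if dialect == "bed":
        return _read_peaks_bed(path)
    if dialect == "table_s1":
        return _read_peaks_table(path)
    raise ValueError(f"unknown peak dialect {dialect!r}")


def _read_peaks_bed(path: str) -> List[Peak]:
    peaks: List[Peak] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise DataError(f"{path}:{lineno}: expected >= 3 BED columns")
            try:
                chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise DataError(f"{path}:{lineno}: malformed coordinates") from exc
            try:
                interval = GenomicInterval(chrom, start, end)
            except DataError as exc:
                raise DataError(f"{path}:{lineno}: {exc}") from exc
            score = None
            if len(fields) >= 5 and fields[4] not in ("", "."):
                score = int(float(fields[4]))
            peaks.append(
                Peak(interval=interval, summit=(start + end) // 2, n_reads=score)
            )
    return peaks


def _read_peaks_table(path: str) -> List[Peak]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = {"chrom", "start", "end"}
    missing = required - set(df.columns)
    if missing:
        raise DataError(f"{path}: missing columns {sorted(missing)}")
    peaks: List[Peak] = []
    for lineno, row in enumerate(df.itertuples(index=False), start=2):
        try:
            interval = GenomicInterval(str(row.chrom), int(row.start), int(row.end))
        except DataError as exc:
            raise DataError(f"{path}:{lineno}: {exc}") from exc
        summit = (
            int(row.summit)
            if "summit" in df.columns and pd.notna(row.summit)
            else (interval.start + interval.end) // 2
        )
        def _opt(name, cast):
            if name in df.columns:
                v = getattr(row, name)
                if pd.notna(v):
                    return cast(v)
            return None

        try:
            peaks.append(
                Peak(
                    interval=interval,
                    summit=summit,
                    n_reads=_opt("n_reads", int),
                    p_value=_opt("p_value", float),
                    fold_enrichment=_opt("fold_enrichment", float),
                )
            )
        except DataError as exc:
            raise DataError(f"{path}:{lineno}: {exc}") from exc
    return peaks


def write_peaks_table(peaks: Sequence[Peak], path: str) -> None:
    """Write peaks in the table_s1 dialect (round-trips with read_peaks)."""
    rows = [
        {
            "chrom": p.chrom,
            "start": p.interval.start,
            "end": p.interval.end,
            "summit": p.summit,
            "n_reads": p.n_reads,
            "p_value": p.p_value,
            "fold_enrichment": p.fold_enrichment,
        }
        for p in peaks
    ]
    df = pd.DataFrame(rows, columns=TABLE_S1_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# transcripts


def read_transcripts(path: str) -> List[TranscriptRecord]:
    """Parse the transcript TSV (id, symbol, chrom, strand, start, end)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "id": str, "symbol": str})
    required = {"id", "symbol", "chrom", "strand", "start", "end"}
    missing = required - set(df.columns)
    if missing:
        raise DataError(f"{path}: missing columns {sorted(missing)}")
    if df["id"].duplicated().any():
        dupes = df.loc[df["id"].duplicated(), "id"].tolist()
        raise DataError(f"{path}: duplicate transcript ids {dupes[:5]}")
    records = []
    for row in df.itertuples(index=False):
        records.append(
            TranscriptRecord(
                transcript_id=str(row.id),
                gene_symbol=str(row.symbol),
                chrom=str(row.chrom),
                strand=str(row.strand),
                tx_start=int(row.start),
                tx_end=int(row.end),
            )
        )
    return records


def write_transcripts(transcripts: Sequence[TranscriptRecord], path: str) -> None:
    df = pd.DataFrame(
        [
            {
                "id": t.transcript_id,
                "symbol": t.gene_symbol,
                "chrom": t.chrom,
                "strand": t.strand,
                "start": t.tx_start,
                "end": t.tx_end,
            }
            for t in transcripts
        ],
        columns=["id", "symbol", "chrom", "strand", "start", "end"],
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# reads (BED6)


def read_reads_bed(path: str) -> List[Read]:
    reads: List[Read] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise DataError(f"{path}:{lineno}: expected BED6 for reads")
            chrom, start, end, strand = (
                fields[0],
                int(fields[1]),
                int(fields[2]),
                fields[5],
            )
            if start >= end:
                raise DataError(f"{path}:{lineno}: start >= end")
            # 5' end is the left edge on +, the right edge on -
            pos5 = start if strand == "+" else end - 1
            reads.append(Read(chrom=chrom, pos5=pos5, strand=strand, length=end - start))
    return reads


def write_reads_bed(reads: Iterable[Read], path: str) -> None:
    with open(path, "w") as fh:
        for i, r in enumerate(reads):
            if r.strand == "+":
                start, end = r.pos5, r.pos5 + r.length
            else:
                start, end = r.pos5 - r.length + 1, r.pos5 + 1
            start = max(start, 0)
            fh.write(f"{r.chrom}\t{start}\t{end}\tread{i}\t0\t{r.strand}\n")


# ---------------------------------------------------------------------------
# WIG density tracks


def write_wig(track, path: str) -> None:
    """Serialize a density track as fixedStep WIG (1-based starts on disk)."""
    with open(path, "w") as fh:
        fh.write(f'track type=wiggle_0 name="{track.name}"\n')
        for chrom in track.chroms():
            bins = track.bins(chrom)
            if len(bins) == 0:
                continue
            fh.write(
                f"fixedStep chrom={chrom} start=1 "
                f"step={track.bin_width} span={track.bin_width}\n"
            )
            fh.write("\n".join(str(int(v)) for v in bins) + "\n")


def read_wig(path: str):
    """Parse fixedStep WIG back into a density track (bit-exact round trip)."""
    from .cooccupancy import DensityTrack  # avoid import cycle

    name = ""
    bin_width = None
    data: Dict[str, List[int]] = {}
    current: Optional[List[int]] = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("track"):
                if 'name="' in line:
                    name = line.split('name="', 1)[1].rstrip('"')
                continue
            if line.startswith("fixedStep"):
                kv = dict(tok.split("=", 1) for tok in line.split()[1:])
                if int(kv.get("start", "1")) != 1:
                    raise DataError(f"{path}:{lineno}: only start=1 blocks supported")
                step = int(kv["step"])
                if bin_width is None:
                    bin_width = step
                elif step != bin_width:
                    raise DataError(f"{path}:{lineno}: inconsistent step")
                current = data.setdefault(kv["chrom"], [])
                continue
            if current is None:
                raise DataError(f"{path}:{lineno}: data line before fixedStep header")
            current.append(int(line))
    if bin_width is None:
        bin_width = 25
    return DensityTrack(
        bins_by_chrom={c: v for c, v in data.items()},
        bin_width=bin_width,
        name=name,
    )


# ---------------------------------------------------------------------------
# annotations


def write_annotation_table(annotations: Sequence, path: str) -> None:
    """Write per-peak annotations; unmatched rows carry the no_match marker."""
    rows = []
    for a in annotations:
        t = a.matched_transcript
        rows.append(
            {
                "chrom": a.peak.chrom,
                "start": a.peak.interval.start,
                "end": a.peak.interval.end,
                "summit": a.peak.summit,
                "n_reads": a.peak.n_reads,
                "category": a.category,
                "transcript_id": t.transcript_id if t else NO_MATCH,
                "gene_symbol": t.gene_symbol if t else "",
                "tss": t.tss if t else "",
                "signed_distance": a.signed_distance if t else "",
                "motif_class": a.motif_class or "",
                "h3k4me3_status": (
                    "" if a.h3k4me3 is None else ("positive" if a.h3k4me3 else "negative")
                ),
            }
        )
    df = pd.DataFrame(rows, columns=ANNOTATION_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def read_annotation_table(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", keep_default_na=False, dtype={"chrom": str})


# ---------------------------------------------------------------------------
# expression + gene lists


def read_expression(path: str) -> Dict[str, float]:
    """Read a gene_symbol -> expression-value table."""
    df = pd.read_csv(path, sep="\t", dtype={"symbol": str})
    if not {"symbol", "value"} <= set(df.columns):
        raise DataError(f"{path}: expected columns symbol, value")
    if df["symbol"].duplicated().any():
        raise DataError(f"{path}: duplicate gene symbols")
    if (df["value"] < 0).any():
        raise DataError(f"{path}: negative expression values")
    return dict(zip(df["symbol"], df["value"].astype(float)))


def write_expression(table: Dict[str, float], path: str) -> None:
    df = pd.DataFrame(
        {"symbol": list(table.keys()), "value": list(table.values())}
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_gene_list(path: str) -> List[str]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "symbol" not in df.columns:
        raise DataError(f"{path}: expected a 'symbol' column")
    return df["symbol"].tolist()


def write_gene_list(symbols: Iterable[str], path: str) -> None:
    pd.DataFrame({"symbol": list(symbols)}).to_csv(path, sep="\t", index=False)


def ensure_dir(path: str) -> str:
    os.makedirs(path, exist_ok=True)
    return path
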