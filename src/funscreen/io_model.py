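"""Shared domain types, coordinate conventions and readers/writers.

All coordinates are 0-based half-open (BED convention) everywhere inside the
package.  GTF input (1-based inclusive) is converted at the boundary by
:func:`read_gtf`.  Bulk data (alignments, intervals, quantifications) travels
as :class:`pandas.DataFrame` objects with the column schemas declared below;
single intervals are :class:`GenomicInterval` instances.

Experimental groups follow the screen's design: a genomic restriction digest,
the cloned library, cells harvested immediately after transduction (d0),
after 47 days of continuous culture, and after continuous culture followed by
a cytotoxic anti-FAS challenge.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

# --------------------------------------------------------------------------
# Group labels (screen conditions).  Conventional shorthand codes for these
# samples in parentheses: GENOME_DIGEST = raw restriction digest, LIBRARY =
# cloned library, D0 = harvested after transduction (JCPZ), CULTURE47 = 47 d
# continuous culture (MFZ), CULTURE47_FAS = 47 d culture + anti-FAS
# challenge (MF) -- hence the MF:MFZ name of the challenge:culture ratio.
GROUP_GENOME_DIGEST = "GENOME_DIGEST"
GROUP_LIBRARY = "LIBRARY"
GROUP_D0 = "D0"
GROUP_CULTURE47 = "CULTURE47"
GROUP_CULTURE47_FAS = "CULTURE47_FAS"
GROUPS = (
    GROUP_GENOME_DIGEST,
    GROUP_LIBRARY,
    GROUP_D0,
    GROUP_CULTURE47,
    GROUP_CULTURE47_FAS,
)
#: groups that undergo selection relative to D0
SELECTED_GROUPS = (GROUP_CULTURE47, GROUP_CULTURE47_FAS)

#: column schema of the alignment table (simulator truth TSV and SAM import)
ALIGNMENT_COLUMNS = [
    "seqid", "start", "end", "strand",
    "group", "replicate", "mate", "directional", "read_id",
]

#: column schema of interval tables (BED-like)
INTERVAL_COLUMNS = ["seqid", "start", "end", "id", "strand"]


class FormatError(ValueError):
    """Raised for malformed or contract-violating input files."""


@dataclasses.dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open interval on a named sequence."""

    seqid: str
    start: int
    end: int
    id: str | None = None
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise ValueError(
                f"invalid interval {self.seqid}:{self.start}-{self.end}: "
                "require end > start >= 0"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.seqid == other.seqid
            and self.start < other.end
            and other.start < self.end
        )


class GenomeSequence:
    """An ordered collection of named nucleotide sequences.

    A synthetic stand-in for a reference genome assembly: sequences are held
    uppercase in memory and a sequence dictionary (seqid -> length) is exposed.
    """

    def __init__(self, records: Mapping[str, str]):
        if not records:
            raise FormatError("genome contains no sequences")
        self.records: dict[str, str] = {}
        for seqid, seq in records.items():
            if not seq:
                raise FormatError(f"empty sequence for record {seqid!r}")
            self.records[seqid] = seq.upper()

    @property
    def lengths(self) -> dict[str, int]:
        return {k: len(v) for k, v in self.records.items()}

    def __contains__(self, seqid: str) -> bool:
        return seqid in self.records

    def __getitem__(self, seqid: str) -> str:
        return self.records[seqid]

    def __iter__(self):
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def total_length(self) -> int:
        return sum(self.lengths.values())


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


# --------------------------------------------------------------------------
# FASTA

def load_genome(path: str | Path) -> GenomeSequence:
    """Read a FASTA file into a :class:`GenomeSequence`.

    Order is preserved; sequences are uppercased.  Duplicate sequence ids and
    empty records are hard errors naming the offending record.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"genome FASTA not found: {path}")
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise FormatError(f"duplicate seqid in FASTA: {rec.id!r}")
        seq = str(rec.seq).upper()
        if not seq:
            raise FormatError(f"empty FASTA record: {rec.id!r}")
        records[rec.id] = seq
    if not records:
        raise FormatError(f"no FASTA records found in {path}")
    return GenomeSequence(records)


def write_fasta(genome: GenomeSequence, path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for seqid, seq in genome.records.items():
            fh.write(f">{seqid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# --------------------------------------------------------------------------
# BED

def intervals_to_frame(intervals: Iterable[GenomicInterval]) -> pd.DataFrame:
    rows = [
        (iv.seqid, iv.start, iv.end, iv.id if iv.id is not None else ".", iv.strand)
        for iv in intervals
    ]
    return pd.DataFrame(rows, columns=INTERVAL_COLUMNS)


def frame_to_intervals(df: pd.DataFrame) -> list[GenomicInterval]:
    out = []
    for row in df.itertuples(index=False):
        name = getattr(row, "id", ".")
        out.append(
            GenomicInterval(
                seqid=row.seqid,
                start=int(row.start),
                end=int(row.end),
                id=None if name in (".", None) else str(name),
                strand=getattr(row, "strand", "."),
            )
        )
    return out


def write_bed(intervals, path: str | Path) -> None:
    """Write intervals (DataFrame or iterable of GenomicInterval) as BED.

    BED6 is written when any interval carries an id or strand; BED3 otherwise.
    Invalid intervals (end <= start) are refused before anything is written.
    """
    if not isinstance(intervals, pd.DataFrame):
        intervals = intervals_to_frame(intervals)
    df = intervals.copy()
    if "id" not in df.columns:
        df["id"] = "."
    if "strand" not in df.columns:
        df["strand"] = "."
    bad = df[(df["end"] <= df["start"]) | (df["start"] < 0)]
    if len(bad):
        r = bad.iloc[0]
        raise ValueError(
            f"refusing to write invalid interval {r['seqid']}:{r['start']}-{r['end']}"
        )
    bed6 = bool(((df["id"] != ".") | (df["strand"] != ".")).any())
    with open(path, "w") as fh:
        for row in df.itertuples(index=False):
            if bed6:
                fh.write(
                    f"{row.seqid}\t{row.start}\t{row.end}\t{row.id}\t0\t{row.strand}\n"
                )
            else:
                fh.write(f"{row.seqid}\t{row.start}\t{row.end}\n")


def read_bed(path: str | Path) -> pd.DataFrame:
    """Read BED3/BED6 into the interval schema."""
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 3:
                raise FormatError(f"{path}:{ln}: BED line has <3 fields")
            name = f[3] if len(f) > 3 else "."
            strand = f[5] if len(f) > 5 else "."
            rows.append((f[0], int(f[1]), int(f[2]), name, strand))
    return pd.DataFrame(rows, columns=INTERVAL_COLUMNS)


# --------------------------------------------------------------------------
# Alignments

def _check_alignment_frame(df: pd.DataFrame, genome: GenomeSequence | None) -> None:
    if genome is not None:
        lengths = genome.lengths
        unknown = set(df["seqid"].unique()) - set(lengths)
        if unknown:
            raise FormatError(
                f"alignment seqid(s) not in genome sequence dictionary: "
                f"{sorted(unknown)}"
            )
        for seqid, sub in df.groupby("seqid", observed=True):
            if (sub["start"] < 0).any() or (sub["end"] > lengths[seqid]).any():
                raise FormatError(f"alignment span outside sequence {seqid!r}")


def read_alignments_tsv(
    path: str | Path, genome: GenomeSequence | None = None
) -> pd.DataFrame:
    """Read the simulator's truth-alignment TSV.

    Columns: seqid, start, end, strand, group, replicate, mate, directional,
    read_id.  Spans are validated against the genome dictionary when given.
    """
    df = pd.read_csv(path, sep="\t", dtype={"seqid": str, "replicate": str})
    missing = set(ALIGNMENT_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing alignment columns {sorted(missing)}")
    df = df[ALIGNMENT_COLUMNS].copy()
    df["directional"] = df["directional"].astype(bool)
    _check_alignment_frame(df, genome)
    return df


def write_alignments_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df[ALIGNMENT_COLUMNS].to_csv(path, sep="\t", index=False)


def read_alignments_sam(
    path: str | Path,
    group: str,
    replicate: str,
    genome: GenomeSequence | None = None,
    directional_tag: str = "XD",
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Import mapped reads from a SAM/BAM file.

    Unmapped, secondary and supplementary records are skipped and counted
    (one read, one vote: only primary alignments contribute).  The optional
    integer tag ``XD`` marks directional (forward-primer-bearing) reads, as
    emitted by the readprep stage; absent tags mean non-directional.

    Returns the alignment frame plus a skip counter.
    """
    import pysam

    if group is None or replicate is None:
        raise FormatError("sample group and replicate labels are required")
    skipped = {"unmapped": 0, "secondary": 0, "supplementary": 0}
    rows = []
    mode = "rb" if str(path).endswith(".bam") else "r"
    with pysam.AlignmentFile(str(path), mode, check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped:
                skipped["unmapped"] += 1
                continue
            if rec.is_secondary:
                skipped["secondary"] += 1
                continue
            if rec.is_supplementary:
                skipped["supplementary"] += 1
                continue
            mate = "R2" if rec.is_read2 else "R1"
            directional = False
            if rec.has_tag(directional_tag):
                directional = bool(rec.get_tag(directional_tag))
            rows.append(
                (
                    rec.reference_name,
                    rec.reference_start,
                    rec.reference_end,
                    "-" if rec.is_reverse else "+",
                    group,
                    replicate,
                    mate,
                    directional,
                    rec.query_name,
                )
            )
    df = pd.DataFrame(rows, columns=ALIGNMENT_COLUMNS)
    _check_alignment_frame(df, genome)
    return df, skipped


def read_samplesheet(path: str | Path) -> pd.DataFrame:
    """Read the samplesheet TSV (columns: file, group, replicate).

    The group structure of the screen (conditions x replicates) must be
    explicit rather than inferred from file names.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = {"file", "group", "replicate"} - set(df.columns)
    if missing:
        raise FormatError(f"samplesheet missing columns: {sorted(missing)}")
    bad = set(df["group"]) - set(GROUPS)
    if bad:
        raise FormatError(f"unknown group label(s) in samplesheet: {sorted(bad)}")
    return df


def load_alignments(
    samplesheet: pd.DataFrame,
    genome: GenomeSequence | None = None,
    base_dir: str | Path | None = None,
) -> pd.DataFrame:
    """Load and concatenate alignments for every samplesheet row.

    Files ending in .sam/.bam are read as alignments with the row's labels;
    anything else is treated as a simulator truth TSV (whose group/replicate
    columns are filtered to the row's labels).
    """
    frames = []
    for row in samplesheet.itertuples(index=False):
        fp = Path(row.file)
        if base_dir is not None and not fp.is_absolute():
            fp = Path(base_dir) / fp
        if fp.suffix in (".sam", ".bam"):
            df, _ = read_alignments_sam(fp, row.group, row.replicate, genome)
        else:
            df = read_alignments_tsv(fp, genome)
            df = df[(df["group"] == row.group) & (df["replicate"] == row.replicate)]
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


# --------------------------------------------------------------------------
# GTF (GENCODE dialect)

def read_gtf(path: str | Path) -> pd.DataFrame:
    """Read a GENCODE-dialect GTF into 0-based half-open feature intervals.

    Returns a frame with columns seqid, start, end, feature, strand, gene_id,
    gene_type, gene_name (attribute columns empty-string when absent).
    """
    import pyranges as pr

    gr = pr.read_gtf(str(path))  # converts to 0-based half-open
    df = gr.df if hasattr(gr, "df") else pd.DataFrame(gr)
    if df.empty:
        raise FormatError(f"no features parsed from GTF {path}")
    out = pd.DataFrame(
        {
            "seqid": df["Chromosome"].astype(str),
            "start": df["Start"].astype(int),
            "end": df["End"].astype(int),
            "feature": df["Feature"].astype(str),
            "strand": df["Strand"].astype(str) if "Strand" in df else ".",
        }
    )
    for attr in ("gene_id", "gene_type", "gene_name"):
        out[attr] = df[attr].fillna("").astype(str) if attr in df else ""
    if (out["gene_id"] == "").all():
        raise FormatError(f"GTF {path} carries no gene_id attributes")
    return out


def write_gtf(features: pd.DataFrame, path: str | Path, source: str = "funscreen") -> None:
    """Write feature intervals as GTF (converting back to 1-based inclusive)."""
    with open(path, "w") as fh:
        for row in features.itertuples(index=False):
            attrs = (
                f'gene_id "{row.gene_id}"; gene_type "{row.gene_type}"; '
                f'gene_name "{row.gene_name}";'
            )
            fh.write(
                f"{row.seqid}\t{source}\t{row.feature}\t{row.start + 1}\t{row.end}\t"
                f".\t{row.strand}\t.\t{attrs}\n"
            )


# --------------------------------------------------------------------------
# FASTQ

def write_fastq(reads: Iterable[tuple[str, str, str]], path: str | Path) -> None:
    """Write (read_id, sequence, quality) triples as FASTQ (phred+33)."""
    with open(path, "w") as fh:
        for rid, seq, qual in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")


def iter_fastq(path: str | Path):
    """Yield (read_id, sequence, quality) from a FASTQ file."""
    import pysam

    with pysam.FastxFile(str(path)) as fh:
        for rec in fh:
            yield rec.name, rec.sequence, rec.quality


def total_mapped_per_sample(alignments: pd.DataFrame) -> pd.Series:
    """Total mapped-read count per (group, replicate), for RPM normalisation."""
    return alignments.groupby(["group", "replicate"], observed=True).size()
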