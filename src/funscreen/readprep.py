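"""Read validation, vector/primer trimming and insert orientation.

A read is validated as library-derived when its prefix matches one of the
two vector flanks (the library is genomic DNA cloned into a vector and
transfected back into cells of the same species, so vector sequence is the
only reliable provenance signal).  Reads matching the forward flank -- which
begins with the forward PCR primer -- are "directional": they fix the
insert's orientation of insertion, and thus of transcription.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .io_model import FormatError, iter_fastq, reverse_complement
from .simulate import FLANK_FWD, FLANK_REV


@dataclasses.dataclass
class ReadValidation:
    read_id: str
    library_derived: bool
    flank_found: str  # "fwd" | "rev" | "none"
    trim_start: int
    trim_end: int
    directional: bool

    def __post_init__(self) -> None:
        if self.directional and self.flank_found != "fwd":
            raise ValueError("directional reads must carry the forward flank")


def hamming_prefix(read: str, pattern: str) -> int:
    """Mismatch count between the read prefix and pattern (len(pattern))."""
    if len(read) < len(pattern):
        return len(pattern)  # cannot match
    a = np.frombuffer(read[: len(pattern)].encode(), dtype=np.uint8)
    b = np.frombuffer(pattern.encode(), dtype=np.uint8)
    return int((a != b).sum())


def detect_flank(
    read_sequence: str,
    flank_fwd: str = FLANK_FWD,
    flank_rev: str = FLANK_REV,
    max_mismatches: int = 2,
) -> ReadValidation:
    """Mismatch-tolerant anchored flank detection on a read prefix.

    R1 reads start at the forward primer, so the forward flank is matched
    against the read prefix; R2 reads start from the amplicon's other end,
    so their prefix is the reverse complement of the reverse flank.  Up to
    ``max_mismatches`` substitutions are allowed (default 2 over the
    flank length; exact matching would discard true library reads carrying
    sequencing errors).  Degenerate reads shorter than the flank never
    validate.
    """
    if not flank_fwd or not flank_rev:
        raise ValueError("flanks must be non-empty")
    if max_mismatches < 0:
        raise ValueError("max_mismatches must be >= 0")
    d_fwd = hamming_prefix(read_sequence, flank_fwd)
    rev_probe = reverse_complement(flank_rev)
    d_rev = hamming_prefix(read_sequence, rev_probe)
    if d_fwd <= max_mismatches and d_fwd <= d_rev:
        return ReadValidation(
            read_id="", library_derived=True, flank_found="fwd",
            trim_start=len(flank_fwd), trim_end=len(read_sequence),
            directional=True,
        )
    if d_rev <= max_mismatches:
        return ReadValidation(
            read_id="", library_derived=True, flank_found="rev",
            trim_start=len(rev_probe), trim_end=len(read_sequence),
            directional=False,
        )
    return ReadValidation(
        read_id="", library_derived=False, flank_found="none",
        trim_start=0, trim_end=len(read_sequence), directional=False,
    )


def quality_trim_end(qual: str, window: int = 4, min_q: float = 20.0) -> int:
    """3'-end sliding-window quality trim; returns the kept length.

    Scans windows from the 5' end and cuts at the first window whose mean
    phred quality falls below ``min_q``.
    """
    q = np.frombuffer(qual.encode(), dtype=np.uint8).astype(float) - 33.0
    n = len(q)
    if n < window:
        return n if (n and q.mean() >= min_q) else 0
    means = np.convolve(q, np.ones(window) / window, mode="valid")
    bad = np.flatnonzero(means < min_q)
    return n if len(bad) == 0 else int(bad[0])


def trim_and_tag(
    fastq_r1: str | Path,
    fastq_r2: str | Path,
    out_dir: str | Path,
    flank_fwd: str = FLANK_FWD,
    flank_rev: str = FLANK_REV,
    max_mismatches: int = 2,
    min_length: int = 30,
    window: int = 4,
    min_q: float = 20.0,
) -> tuple[pd.DataFrame, dict]:
    """Quality-trim, validate and flank-trim a read pair file set.

    Writes trimmed FASTQ files (vector bases removed, discarded reads
    dropped) plus a per-read validation TSV into ``out_dir``; returns the
    validation frame and a summary counter dict.  Mates must be paired by
    id, in order.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    summary = {"pairs": 0, "validated": 0, "directional": 0, "discarded_short": 0}
    out1 = open(out_dir / (Path(fastq_r1).stem + ".trimmed.fastq"), "w")
    out2 = open(out_dir / (Path(fastq_r2).stem + ".trimmed.fastq"), "w")
    try:
        for (id1, s1, q1), (id2, s2, q2) in zip(
            iter_fastq(fastq_r1), iter_fastq(fastq_r2), strict=True
        ):
            if id1 != id2:
                raise FormatError(f"unpaired read: {id1!r} vs {id2!r}")
            summary["pairs"] += 1
            for mate, (rid, seq, qual, out) in {
                "R1": (id1, s1, q1, out1),
                "R2": (id2, s2, q2, out2),
            }.items():
                keep = quality_trim_end(qual, window=window, min_q=min_q)
                seq_t, qual_t = seq[:keep], qual[:keep]
                v = detect_flank(seq_t, flank_fwd, flank_rev, max_mismatches)
                v.read_id = f"{rid}/{mate}"
                genomic = seq_t[v.trim_start :]
                if v.library_derived:
                    summary["validated"] += 1
                if v.directional:
                    summary["directional"] += 1
                if len(genomic) < min_length:
                    summary["discarded_short"] += 1
                elif v.library_derived:
                    out.write(
                        f"@{rid}\n{genomic}\n+\n{qual_t[v.trim_start:]}\n"
                    )
                rows.append(
                    (v.read_id, v.library_derived, v.flank_found,
                     v.trim_start, v.trim_end, v.directional)
                )
    finally:
        out1.close()
        out2.close()
    validations = pd.DataFrame(
        rows,
        columns=["read_id", "library_derived", "flank_found",
                 "trim_start", "trim_end", "directional"],
    )
    validations.to_csv(out_dir / "validations.tsv", sep="\t", index=False)
    with open(out_dir / "readprep_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    return validations, summary


def orient_inserts(
    alignments: pd.DataFrame,
    catalogue: pd.DataFrame,
    margin: float = 2.0,
) -> pd.DataFrame:
    """Call each catalogue insert's orientation from directional reads.

    Directional reads mapping on "+" vote sense, on "-" antisense; the call
    is the majority orientation when it beats the minority by at least
    ``margin``-fold (default 2:1), otherwise "ambiguous".  Inserts with no
    directional reads are "ambiguous".
    """
    from .quantify import assign_reads_to_inserts

    dirs = alignments[alignments["directional"]]
    votes = pd.DataFrame(
        {"insert_id": catalogue["id"].to_numpy(), "n_sense": 0, "n_antisense": 0}
    ).set_index("insert_id")
    if len(dirs):
        hits = assign_reads_to_inserts(dirs, catalogue)
        tab = (
            hits.groupby(["insert_id", "strand"], observed=True)
            .size()
            .unstack(fill_value=0)
        )
        if "+" in tab:
            votes.loc[tab.index, "n_sense"] = tab["+"]
        if "-" in tab:
            votes.loc[tab.index, "n_antisense"] = tab["-"]
    votes = votes.reset_index()
    s, a = votes["n_sense"].to_numpy(), votes["n_antisense"].to_numpy()
    call = np.full(len(votes), "ambiguous", dtype=object)
    for i, (ns, na) in enumerate(zip(s, a)):
        if ns == 0 and na == 0:
            continue
        if na == 0 and ns > 0:
            call[i] = "sense"
        elif ns == 0 and na > 0:
            call[i] = "antisense"
        elif ns >= margin * na:
            call[i] = "sense"
        elif na >= margin * ns:
            call[i] = "antisense"
    votes["orientation"] = call
    return votes
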