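"""Per-insert read counting, normalisation, and coverage-diversity statistics.

Counting semantics follow multi-coverage counting over a disjoint interval
catalogue: a read contributes one count to every insert whose interval its
mapped span overlaps by at least one base (a read straddling the gap between
two catalogue inserts therefore counts toward both).  Counts are normalised
to reads per million mapped reads (RPM); an insert is "present" in a sample
when at least ``presence_min`` raw reads map to it (default 10).

Two diversity statistics summarise selection breadth:

* bin fill -- the genome is tiled in fixed bins (default 1 kb, final partial
  bin included); a bin is filled when any counted read overlaps it.
* fingerprint -- per-bin read counts (each read assigned to the bin holding
  its start) sorted ascending; the cumulative read fraction as a function of
  cumulative bin fraction.  Selection concentrates reads into few bins and
  pushes the curve down; the statistic reported is the read fraction reached
  within the lowest 97% of bins.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

DEFAULT_PRESENCE_MIN = 10
DEFAULT_BIN_SIZE = 1000
DEFAULT_PROBE_BIN_FRACTION = 0.97


def _catalogue_arrays(catalogue: pd.DataFrame, seqid: str):
    cat = catalogue[catalogue["seqid"] == seqid]
    return (
        cat["start"].to_numpy(dtype=np.int64),
        cat["end"].to_numpy(dtype=np.int64),
        cat["id"].to_numpy(),
        cat.index.to_numpy(),
    )


def assign_reads_to_inserts(
    alignments: pd.DataFrame,
    catalogue: pd.DataFrame,
    columns: tuple[str, ...] = ("group", "replicate", "strand"),
) -> pd.DataFrame:
    """Expand alignments to one row per (read, overlapped catalogue insert).

    Requires the catalogue to be sorted and non-overlapping per seqid.  Only
    ``columns`` of the alignment frame are carried over (plus ``insert_id``).
    """
    frames = []
    for seqid, sub in alignments.groupby("seqid", observed=True):
        starts, ends, ids, _ = _catalogue_arrays(catalogue, seqid)
        if len(starts) == 0:
            continue
        s = sub["start"].to_numpy(dtype=np.int64)
        e = sub["end"].to_numpy(dtype=np.int64)
        lo = np.searchsorted(ends, s, side="right")
        hi = np.searchsorted(starts, e, side="left")
        n_over = hi - lo
        keep = n_over > 0
        if not keep.any():
            continue
        reps = n_over[keep]
        lo_k = lo[keep]
        total = int(reps.sum())
        # insert indices lo_k[i] .. lo_k[i]+reps[i]-1 per read, flattened
        # without per-read arange (runs encoded as cumsum steps)
        step = np.ones(total, dtype=np.int64)
        bounds = np.zeros(len(reps), dtype=np.int64)
        bounds[1:] = np.cumsum(reps)[:-1]
        prev_last = np.concatenate(([0], lo_k[:-1] + reps[:-1] - 1))
        step[bounds] = lo_k - prev_last
        insert_idx = np.cumsum(step)
        row_pos = np.repeat(np.flatnonzero(keep), reps)
        data = {"insert_id": ids[insert_idx]}
        for c in columns:
            data[c] = sub[c].to_numpy()[row_pos]
        frames.append(pd.DataFrame(data))
    if not frames:
        return pd.DataFrame(columns=["insert_id", *columns])
    return pd.concat(frames, ignore_index=True)


def count_reads(alignments: pd.DataFrame, catalogue: pd.DataFrame) -> pd.DataFrame:
    """Raw read counts per catalogue insert per (group, replicate) sample.

    Returns a long frame (insert_id, group, replicate, raw_count) covering
    every insert x sample combination (zeros included).
    """
    samples = (
        alignments[["group", "replicate"]].drop_duplicates().itertuples(index=False)
    )
    sample_keys = [(s.group, s.replicate) for s in samples]
    hits = assign_reads_to_inserts(alignments, catalogue)
    if len(hits):
        counted = (
            hits.groupby(["insert_id", "group", "replicate"], observed=True)
            .size()
            .rename("raw_count")
            .reset_index()
        )
    else:
        counted = pd.DataFrame(columns=["insert_id", "group", "replicate", "raw_count"])
    full = pd.DataFrame(
        [(i, g, r) for i in catalogue["id"] for (g, r) in sample_keys],
        columns=["insert_id", "group", "replicate"],
    )
    out = full.merge(counted, on=["insert_id", "group", "replicate"], how="left")
    out["raw_count"] = (
        pd.to_numeric(out["raw_count"], errors="coerce").fillna(0).astype(int)
    )
    return out


def normalize_and_flag(
    raw_counts: pd.DataFrame,
    totals: pd.Series,
    presence_min: int = DEFAULT_PRESENCE_MIN,
) -> pd.DataFrame:
    """Attach RPM values and presence flags to a raw count table.

    ``totals`` indexes total mapped reads by (group, replicate); a zero
    total is an error.  rpm = raw * 1e6 / total; present <=> raw >=
    presence_min (the presence rule applies to raw counts, not RPM).
    """
    if (totals <= 0).any():
        bad = totals[totals <= 0].index.tolist()
        raise ValueError(f"zero total mapped reads for sample(s): {bad}")
    out = raw_counts.copy()
    t = out.set_index(["group", "replicate"]).index.map(totals)
    if pd.isna(t).any():
        missing = out.loc[pd.isna(t), ["group", "replicate"]].drop_duplicates()
        raise ValueError(f"no mapped-read total for samples:\n{missing}")
    out["rpm"] = out["raw_count"] * 1e6 / np.asarray(t, dtype=float)
    out["present"] = out["raw_count"] >= presence_min
    return out


def distinct_insert_counts(quant: pd.DataFrame) -> pd.DataFrame:
    """Number of present inserts per sample (the insert-diversity table)."""
    return (
        quant.groupby(["group", "replicate"], observed=True)["present"]
        .sum()
        .astype(int)
        .rename("distinct_inserts")
        .reset_index()
    )


# --------------------------------------------------------------------------
# Genome-bin statistics

@dataclasses.dataclass
class BinCoverageSummary:
    bin_size: int
    n_bins: int
    n_filled: int

    @property
    def fraction_filled(self) -> float:
        return self.n_filled / self.n_bins if self.n_bins else 0.0


def _bin_layout(genome_lengths: dict[str, int], bin_size: int):
    """Per-seqid (offset, n_bins) with a genome-wide flat bin indexing."""
    layout = {}
    off = 0
    for seqid, L in genome_lengths.items():
        n = int(np.ceil(L / bin_size))  # final partial bin counts as a bin
        layout[seqid] = (off, n)
        off += n
    return layout, off


def bin_fill(
    alignments: pd.DataFrame,
    genome_lengths: dict[str, int],
    bin_size: int = DEFAULT_BIN_SIZE,
) -> BinCoverageSummary:
    """Fraction of fixed-width genome bins touched by at least one read."""
    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")
    layout, total_bins = _bin_layout(genome_lengths, bin_size)
    filled = np.zeros(total_bins, dtype=bool)
    for seqid, sub in alignments.groupby("seqid", observed=True):
        off, n = layout[seqid]
        s = sub["start"].to_numpy(dtype=np.int64)
        e = sub["end"].to_numpy(dtype=np.int64)
        first = s // bin_size
        last = (e - 1) // bin_size
        filled[off + first] = True
        filled[off + last] = True
        # reads spanning >2 bins (longer than bin_size) need the middles too
        wide = np.flatnonzero(last - first > 1)
        for i in wide:
            filled[off + first[i] : off + last[i] + 1] = True
    return BinCoverageSummary(bin_size, total_bins, int(filled.sum()))


@dataclasses.dataclass
class FingerprintCurve:
    """Cumulative read fraction vs cumulative (ascending) bin fraction."""

    bin_fraction: np.ndarray  # increasing from 0 to 1
    read_fraction: np.ndarray  # non-decreasing from 0 to 1
    bin_size: int
    n_bins: int
    total_reads: int

    def read_fraction_at(self, bin_fraction: float) -> float:
        """Read fraction within the lowest floor(f * n_bins) bins."""
        if not (0.0 < bin_fraction <= 1.0):
            raise ValueError("bin_fraction must lie in (0, 1]")
        k = int(np.floor(bin_fraction * self.n_bins))
        return float(self.read_fraction[k])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"bin_fraction": self.bin_fraction, "read_fraction": self.read_fraction}
        )


def fingerprint(
    alignments: pd.DataFrame,
    genome_lengths: dict[str, int],
    bin_size: int = DEFAULT_BIN_SIZE,
) -> FingerprintCurve:
    """Build the coverage fingerprint curve for one sample.

    Each read is assigned to the single bin containing its start (the curve
    needs a partition of reads so fractions sum to one); bins are sorted
    ascending by count and read counts accumulated.
    """
    layout, total_bins = _bin_layout(genome_lengths, bin_size)
    counts = np.zeros(total_bins, dtype=np.int64)
    for seqid, sub in alignments.groupby("seqid", observed=True):
        off, n = layout[seqid]
        b = off + sub["start"].to_numpy(dtype=np.int64) // bin_size
        counts += np.bincount(b, minlength=total_bins)
    total = int(counts.sum())
    order = np.sort(counts)
    cum = np.concatenate(([0], np.cumsum(order)))
    read_frac = cum / total if total else cum.astype(float)
    bin_frac = np.arange(total_bins + 1) / total_bins
    return FingerprintCurve(bin_frac, read_frac, bin_size, total_bins, total)
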