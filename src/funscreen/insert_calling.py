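"""Coverage computation, enrichment-interval calling and the insert catalogue.

The peak-calling step is a documented threshold caller rather than a
ChIP-seq model: amplicon coverage of clonal inserts is block-like with sharp
edges, so an interval is any maximal run of bases whose coverage reaches
both an absolute floor and a fold over the global background rate
(lambda = total counted bases / genome length).

Nearby intervals are merged transitively when their gap is at most
``merge_distance`` (default 25 bp: sequences within 25 bp of each other are
considered to originate from the same cloned fragment).  The catalogue is
the merged union of every sample's called intervals, with stable
coordinate-derived insert ids.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io_model import GenomeSequence

DEFAULT_MERGE_DISTANCE = 25
DEFAULT_MIN_COVERAGE = 5
DEFAULT_FOLD = 5.0
DEFAULT_MIN_LENGTH = 50


class CoverageTrack:
    """Per-base read coverage over a genome plus counting totals."""

    def __init__(self, genome_lengths: dict[str, int]):
        self.arrays: dict[str, np.ndarray] = {
            s: np.zeros(L, dtype=np.int32) for s, L in genome_lengths.items()
        }
        self.total_mapped = 0
        self.total_bases = 0

    @property
    def genome_length(self) -> int:
        return sum(len(a) for a in self.arrays.values())

    @property
    def background(self) -> float:
        """Global mean coverage: total counted bases / genome length."""
        return self.total_bases / self.genome_length if self.genome_length else 0.0


def compute_coverage(
    alignments: pd.DataFrame, genome_lengths: dict[str, int]
) -> CoverageTrack:
    """Increment coverage over each counted read's mapped span."""
    track = CoverageTrack(genome_lengths)
    for seqid, sub in alignments.groupby("seqid", observed=True):
        if seqid not in track.arrays:
            raise KeyError(f"alignment seqid {seqid!r} not in genome dictionary")
        L = genome_lengths[seqid]
        diff = np.zeros(L + 1, dtype=np.int64)
        starts = sub["start"].to_numpy(dtype=np.int64)
        ends = sub["end"].to_numpy(dtype=np.int64)
        np.add.at(diff, starts, 1)
        np.add.at(diff, ends, -1)
        track.arrays[seqid] = np.cumsum(diff[:-1]).astype(np.int32)
        track.total_mapped += len(sub)
        track.total_bases += int((ends - starts).sum())
    return track


def call_enriched_intervals(
    track: CoverageTrack,
    min_coverage: int = DEFAULT_MIN_COVERAGE,
    fold_over_background: float = DEFAULT_FOLD,
    min_length: int = DEFAULT_MIN_LENGTH,
) -> pd.DataFrame:
    """Call read-enriched intervals against the global background.

    Threshold = max(min_coverage, fold_over_background * lambda); intervals
    are maximal runs of bases at or above it, dropping runs shorter than
    ``min_length``.  An empty result is legitimate (e.g. an all-zero track).
    """
    if min_coverage <= 0 or fold_over_background <= 0 or min_length <= 0:
        raise ValueError("thresholds must be positive")
    thr = max(float(min_coverage), fold_over_background * track.background)
    rows = []
    for seqid, cov in track.arrays.items():
        above = np.concatenate(([0], (cov >= thr).astype(np.int8), [0]))
        d = np.diff(above)
        starts = np.flatnonzero(d == 1)
        ends = np.flatnonzero(d == -1)
        for s, e in zip(starts, ends):
            if e - s >= min_length:
                rows.append((seqid, int(s), int(e)))
    return pd.DataFrame(rows, columns=["seqid", "start", "end"])


def merge_intervals(
    intervals: pd.DataFrame, merge_distance: int = DEFAULT_MERGE_DISTANCE
) -> pd.DataFrame:
    """Transitively merge intervals whose gap is <= merge_distance.

    Gap is start2 - end1 for same-seqid sorted intervals; the output is
    sorted with pairwise gaps strictly greater than ``merge_distance``
    (touching/overlapping intervals always merge).
    """
    if merge_distance < 0:
        raise ValueError("merge_distance must be >= 0")
    if intervals.empty:
        return intervals.copy().reset_index(drop=True)[["seqid", "start", "end"]]
    df = intervals.sort_values(["seqid", "start", "end"]).reset_index(drop=True)
    rows = []
    cur = None
    for row in df.itertuples(index=False):
        if cur is not None and row.seqid == cur[0] and row.start - cur[2] <= merge_distance:
            cur[2] = max(cur[2], row.end)
        else:
            if cur is not None:
                rows.append(tuple(cur))
            cur = [row.seqid, int(row.start), int(row.end)]
    rows.append(tuple(cur))
    return pd.DataFrame(rows, columns=["seqid", "start", "end"])


def build_catalogue(
    per_sample_intervals: dict[str, pd.DataFrame],
    merge_distance: int = DEFAULT_MERGE_DISTANCE,
) -> pd.DataFrame:
    """Merged union of all samples' intervals with stable insert ids.

    Ids are coordinate-derived (assigned after sorting by seqid, start), so
    a rebuilt catalogue is identical regardless of sample input order.
    Provenance records which samples contributed an overlapping interval.
    """
    if not per_sample_intervals:
        raise ValueError("at least one sample interval set is required")
    pooled = pd.concat(per_sample_intervals.values(), ignore_index=True)
    if pooled.empty:
        return pd.DataFrame(columns=["seqid", "start", "end", "id", "provenance"])
    merged = merge_intervals(pooled, merge_distance)
    merged = merged.sort_values(["seqid", "start"]).reset_index(drop=True)
    merged["id"] = [f"INS{i:06d}" for i in range(len(merged))]
    prov: list[list[str]] = [[] for _ in range(len(merged))]
    for sample in sorted(per_sample_intervals):
        ivs = per_sample_intervals[sample]
        for seqid, sub in ivs.groupby("seqid", observed=True):
            cat = merged[merged["seqid"] == seqid]
            if cat.empty:
                continue
            cs = cat["start"].to_numpy()
            ce = cat["end"].to_numpy()
            lo = np.searchsorted(ce, sub["start"].to_numpy(), side="right")
            hi = np.searchsorted(cs, sub["end"].to_numpy(), side="left")
            for l, h in zip(lo, hi):
                for j in range(l, h):
                    prov[cat.index[j]].append(sample)
    merged["provenance"] = [",".join(sorted(set(p))) for p in prov]
    return merged
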