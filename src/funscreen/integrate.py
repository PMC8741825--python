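"""Replicate intersection, hit criteria and enrichment scores.

The prioritisation rule of the screen: an insert is *selected* in a
condition when it is present (>= 10 reads) in at least ``min_replicates``
independent replicates of that condition AND is supported by at least one
directional (forward-primer-bearing) read anywhere in the dataset.  An
insert is *high-confidence* when a DraI/AanI cut site lies within
``restriction_max`` (100 bp) of its interval and it has directional support.

Enrichment scores:

* potentiation -- mean RPM in the selected condition divided by mean RPM at
  day 0, as a percentage.  A zero baseline yields NaN (an explicit
  "undefined" sentinel, excluded from summaries; a pseudocount would
  fabricate enrichment for inserts absent at transduction).
* MF:MFZ ratio -- mean RPM after the cytotoxic challenge over mean RPM in
  continuous culture alone: how much better an insert fares under the
  challenge than culture alone.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io_model import GROUP_CULTURE47, GROUP_CULTURE47_FAS, GROUP_D0
from .insert_calling import merge_intervals

DEFAULT_MIN_REPLICATES = 3
DEFAULT_RESTRICTION_MAX = 100


def replicate_support(quant: pd.DataFrame, group: str) -> pd.Series:
    """Number of replicates of ``group`` in which each insert is present.

    Quantifications are computed against the shared catalogue, so the
    multi-replicate interval intersection reduces to presence counting per
    insert id; the result is invariant to replicate ordering.
    """
    sub = quant[quant["group"] == group]
    if sub.empty:
        raise ValueError(f"no replicates quantified for group {group!r}")
    return sub.groupby("insert_id", observed=True)["present"].sum().astype(int)


def multiintersect_depth(replicate_intervals: list[pd.DataFrame]) -> pd.DataFrame:
    """BED-space multi-intersection: partition the genome by coverage depth.

    For arbitrary per-replicate interval sets, returns the sub-intervals
    delimited by all interval boundaries with the number of replicate sets
    covering each (sets are internally merged first, so depth counts sets,
    not intervals).  Depth-0 sub-intervals are omitted.
    """
    merged_sets = [merge_intervals(df, 0) for df in replicate_intervals if len(df)]
    if not merged_sets:
        return pd.DataFrame(columns=["seqid", "start", "end", "depth"])
    events: dict[str, list[tuple[int, int]]] = {}
    for df in merged_sets:
        for row in df.itertuples(index=False):
            events.setdefault(row.seqid, []).append((int(row.start), +1))
            events[row.seqid].append((int(row.end), -1))
    rows = []
    for seqid in sorted(events):
        evs = sorted(events[seqid])
        depth = 0
        prev = None
        for pos, delta in evs:
            if prev is not None and pos > prev and depth > 0:
                rows.append((seqid, prev, pos, depth))
            depth += delta
            prev = pos
    out = pd.DataFrame(rows, columns=["seqid", "start", "end", "depth"])
    # coalesce adjacent sub-intervals at equal depth
    coalesced = []
    for row in out.itertuples(index=False):
        if (
            coalesced
            and coalesced[-1][0] == row.seqid
            and coalesced[-1][2] == row.start
            and coalesced[-1][3] == row.depth
        ):
            coalesced[-1][2] = row.end
        else:
            coalesced.append([row.seqid, row.start, row.end, row.depth])
    return pd.DataFrame(coalesced, columns=["seqid", "start", "end", "depth"])


def directional_support(alignments: pd.DataFrame, catalogue: pd.DataFrame) -> pd.Series:
    """True for catalogue inserts overlapped by >= 1 directional read."""
    from .quantify import assign_reads_to_inserts

    dirs = alignments[alignments["directional"]]
    supported = (
        set(assign_reads_to_inserts(dirs, catalogue)["insert_id"].unique())
        if len(dirs)
        else set()
    )
    return pd.Series(
        catalogue["id"].isin(supported).to_numpy(),
        index=catalogue["id"],
        name="directional_support",
    )


def call_hits(
    quant: pd.DataFrame,
    catalogue: pd.DataFrame,
    directional: pd.Series,
    restriction_distance: pd.Series,
    min_replicates: int = DEFAULT_MIN_REPLICATES,
    restriction_max: int = DEFAULT_RESTRICTION_MAX,
    groups: tuple[str, ...] = (GROUP_CULTURE47, GROUP_CULTURE47_FAS),
) -> pd.DataFrame:
    """Evaluate all hit criteria for every catalogue insert.

    Returns one record per insert with per-group replicate support, the
    directional flag, restriction-site distance, the high-confidence flag
    and ``selected_in`` (comma-joined groups meeting the selection rule).
    """
    out = catalogue[["id", "seqid", "start", "end"]].rename(columns={"id": "insert_id"}).copy()
    out = out.set_index("insert_id")
    out["directional_support"] = directional.reindex(out.index).fillna(False).astype(bool)
    rd = restriction_distance.reindex(out.index)
    out["restriction_distance"] = rd
    out["high_confidence"] = (
        (rd <= restriction_max).fillna(False) & out["directional_support"]
    )
    available = [g for g in groups if (quant["group"] == g).any()]
    sel_sets: dict[str, pd.Series] = {}
    for g in available:
        sup = replicate_support(quant, g).reindex(out.index).fillna(0).astype(int)
        out[f"support_{g}"] = sup
        sel_sets[g] = (sup >= min_replicates) & out["directional_support"]
    out["selected_in"] = [
        ",".join(g for g in available if sel_sets[g].loc[i]) for i in out.index
    ]
    return out.reset_index()


def selected_counts(hits: pd.DataFrame) -> dict[str, int]:
    """Number of selected inserts per group."""
    counts: dict[str, int] = {}
    for sel in hits["selected_in"]:
        for g in filter(None, sel.split(",")):
            counts[g] = counts.get(g, 0) + 1
    return counts


def _group_mean_rpm(
    quant: pd.DataFrame, group: str, exclude_replicate: str | None = None
) -> pd.Series:
    sub = quant[quant["group"] == group]
    if exclude_replicate is not None:
        sub = sub[sub["replicate"] != exclude_replicate]
    if sub.empty:
        raise ValueError(f"no quantified replicates for group {group!r}")
    return sub.groupby("insert_id", observed=True)["rpm"].mean()


def potentiation(
    quant: pd.DataFrame,
    group_selected: str,
    group_baseline: str = GROUP_D0,
    exclude_replicate: str | None = None,
) -> pd.Series:
    """Per-insert potentiation score (%).

    100 * mean(RPM in the selected group) / mean(RPM at baseline).  The
    ``exclude_replicate`` variant recomputes the selected-group mean without
    one replicate (leave-one-out outlier handling, generalised to any
    replicate).  Zero-baseline inserts score NaN.
    """
    num = _group_mean_rpm(quant, group_selected, exclude_replicate)
    den = _group_mean_rpm(quant, group_baseline)
    idx = num.index.union(den.index)
    num = num.reindex(idx).fillna(0.0)
    den = den.reindex(idx).fillna(0.0)
    score = pd.Series(np.where(den > 0, 100.0 * num / den, np.nan), index=idx)
    return score.rename(f"potentiation_{group_selected}")


def mf_mfz_ratio(
    quant: pd.DataFrame,
    exclude_replicate: str | None = None,
) -> pd.Series:
    """Per-insert challenge:culture abundance ratio.

    mean(RPM in CULTURE47_FAS) / mean(RPM in CULTURE47); NaN when the
    culture-alone mean is zero.
    """
    num = _group_mean_rpm(quant, GROUP_CULTURE47_FAS, exclude_replicate)
    den = _group_mean_rpm(quant, GROUP_CULTURE47)
    idx = num.index.union(den.index)
    num = num.reindex(idx).fillna(0.0)
    den = den.reindex(idx).fillna(0.0)
    return pd.Series(
        np.where(den > 0, num / den, np.nan), index=idx, name="mf_mfz_ratio"
    )


def ratio_cohort_means(
    quant: pd.DataFrame, hits: pd.DataFrame, exclude_replicate: str | None = None
) -> dict[str, float]:
    """Cohort means of the challenge:culture ratio.

    Cohort "present_culture": inserts present in >= 1 continuous-culture
    replicate.  Cohort "selected_both": inserts selected in both the culture
    and challenge conditions.  NaN ratios are excluded from both means.
    """
    ratio = mf_mfz_ratio(quant, exclude_replicate)
    present_c47 = (
        quant[(quant["group"] == GROUP_CULTURE47) & quant["present"]]["insert_id"]
        .unique()
    )
    # exact membership test (CULTURE47 is a prefix of CULTURE47_FAS)
    def _has(sel: str, g: str) -> bool:
        return g in sel.split(",")

    both = hits[
        hits["selected_in"].map(lambda s: _has(s, GROUP_CULTURE47) and _has(s, GROUP_CULTURE47_FAS))
    ]["insert_id"]
    m_present = float(ratio.reindex(present_c47).dropna().mean())
    m_both = float(ratio.reindex(both).dropna().mean())
    return {"present_culture": m_present, "selected_both": m_both}
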