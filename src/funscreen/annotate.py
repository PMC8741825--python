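"""Restriction-site distances, feature-context classification and tallies.

Distance semantics follow closest-feature conventions: overlap counts as
distance 0, otherwise the gap between nearest edges; restriction cut points
are zero-width boundaries between bases.  Classification rules:

* ``gene_100bp`` / ``exon_100bp`` / ``intron_100bp`` -- the insert lies
  within ``proximity_gene`` (default 100 bp) of the feature class; intron
  space is gene space minus exon space.
* ``promoter_1000bp`` -- within ``proximity_promoter`` (default 1000 bp) of
  a gene but *not* within ``proximity_gene`` (the "additional inserts near
  genes" class).  A strand-aware TSS-only mode is available.
* ``intergenic`` -- by elimination: not ``gene_100bp``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io_model import FormatError, GenomeSequence
from .insert_calling import merge_intervals
from .simulate import DEFAULT_ENZYMES, RestrictionEnzyme, find_motif_cuts

DEFAULT_PROXIMITY_GENE = 100
DEFAULT_PROXIMITY_PROMOTER = 1000


def find_restriction_sites(
    genome: GenomeSequence,
    enzymes: tuple[RestrictionEnzyme, ...] = DEFAULT_ENZYMES,
) -> dict[str, np.ndarray]:
    """Sorted, de-duplicated blunt cut positions per seqid (all enzymes)."""
    out = {}
    for seqid, seq in genome.records.items():
        pos = np.concatenate([find_motif_cuts(seq, e) for e in enzymes])
        out[seqid] = np.unique(pos)
    return out


def distance_to_positions(
    seqid: str, start: int, end: int, positions: dict[str, np.ndarray]
) -> float:
    """Distance from an interval to the nearest cut position.

    Cut positions are inter-base boundaries: a position p inside [start, end]
    gives distance 0; otherwise the gap to the nearer of start/end.  Returns
    inf when the seqid has no positions.
    """
    pos = positions.get(seqid)
    if pos is None or len(pos) == 0:
        return float("inf")
    iL = np.searchsorted(pos, start, side="left") - 1
    iR = np.searchsorted(pos, end, side="right")
    if iR - 1 >= iL + 1:  # some position within [start, end]
        return 0.0
    best = np.inf
    if iL >= 0:
        best = min(best, start - pos[iL])
    if iR < len(pos):
        best = min(best, pos[iR] - end)
    return float(best)


def distances_to_positions(
    intervals: pd.DataFrame, positions: dict[str, np.ndarray]
) -> pd.Series:
    """Vector form of :func:`distance_to_positions` over an interval frame."""
    vals = [
        distance_to_positions(r.seqid, int(r.start), int(r.end), positions)
        for r in intervals.itertuples(index=False)
    ]
    idx = intervals["id"] if "id" in intervals.columns else intervals.index
    return pd.Series(vals, index=idx, name="restriction_distance")


def distance_to_nearest(
    seqid: str,
    start: int,
    end: int,
    features: pd.DataFrame,
) -> tuple[str | None, float]:
    """Nearest feature interval and its edge distance (0 on overlap).

    Ties are broken toward the lower coordinate.  Returns (None, inf) when
    the seqid carries no features.
    """
    sub = features[features["seqid"] == seqid]
    if sub.empty:
        return None, float("inf")
    starts = sub["start"].to_numpy()
    ends = sub["end"].to_numpy()
    gaps = np.maximum(0, np.maximum(start - ends, starts - end))
    # edge distance: touching intervals ([a,b) then [b,c)) are 0 apart under
    # the overlap rule only if they share a base, so use gap = s2 - e1
    best = int(np.argmin(gaps))
    name_col = "id" if "id" in sub.columns else None
    name = str(sub.iloc[best][name_col]) if name_col else str(sub.index[best])
    return name, float(gaps[best])


def _nearest_gap_vector(queries: pd.DataFrame, features: pd.DataFrame) -> np.ndarray:
    """Per-query edge distance to the nearest feature (inf if none).

    Sort-based: for features sorted by start, the nearest non-overlapping
    left neighbour is found through a running maximum of ends, the right
    neighbour through searchsorted on starts; anything in between overlaps.
    """
    out = np.full(len(queries), np.inf)
    for seqid, qsub in queries.groupby("seqid", observed=True):
        fsub = features[features["seqid"] == seqid].sort_values("start")
        if fsub.empty:
            continue
        fs = fsub["start"].to_numpy(dtype=np.int64)
        fe = fsub["end"].to_numpy(dtype=np.int64)
        max_end = np.maximum.accumulate(fe)
        qs = qsub["start"].to_numpy(dtype=np.int64)
        qe = qsub["end"].to_numpy(dtype=np.int64)
        res = np.full(len(qsub), np.inf)
        # right neighbour: first feature starting at/after the query end
        k = np.searchsorted(fs, qe, side="left")
        has_r = k < len(fs)
        res[has_r] = fs[k[has_r]] - qe[has_r]
        # left/overlap side: features starting before the query end
        j = np.searchsorted(fs, qe, side="left") - 1
        has_l = j >= 0
        lme = np.where(has_l, max_end[np.clip(j, 0, None)], -1)
        left_gap = np.where(has_l, np.maximum(qs - lme, 0), np.inf)
        res = np.minimum(res, left_gap)
        out[queries.index.get_indexer(qsub.index)] = res
    return out


def gene_features(gtf: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Split a GTF frame into merged gene, exon and derived intron space.

    Introns are gene space minus exon space (computed globally over merged
    intervals).
    """
    genes = gtf[gtf["feature"] == "gene"]
    exons = gtf[gtf["feature"] == "exon"]
    if genes.empty:
        raise FormatError("GTF contains no gene features")
    gene_space = merge_intervals(genes[["seqid", "start", "end"]], 0)
    exon_space = merge_intervals(exons[["seqid", "start", "end"]], 0) if len(exons) else exons[["seqid", "start", "end"]]
    intron_space = subtract_intervals(gene_space, exon_space)
    return {
        "gene": genes[["seqid", "start", "end", "gene_id", "gene_type", "gene_name", "strand"]].reset_index(drop=True),
        "gene_space": gene_space,
        "exon_space": exon_space,
        "intron_space": intron_space,
    }


def subtract_intervals(a: pd.DataFrame, b: pd.DataFrame) -> pd.DataFrame:
    """Interval-space subtraction a \\ b (both merged internally)."""
    a = merge_intervals(a, 0) if len(a) else a
    b = merge_intervals(b, 0) if len(b) else b
    rows = []
    for seqid, asub in (a.groupby("seqid", observed=True) if len(a) else []):
        bsub = b[b["seqid"] == seqid] if len(b) else b
        cuts = (
            list(zip(bsub["start"].to_numpy(), bsub["end"].to_numpy()))
            if len(bsub)
            else []
        )
        for row in asub.itertuples(index=False):
            cur = row.start
            for bs, be in cuts:
                if be <= cur or bs >= row.end:
                    continue
                if bs > cur:
                    rows.append((seqid, int(cur), int(bs)))
                cur = max(cur, be)
            if cur < row.end:
                rows.append((seqid, int(cur), int(row.end)))
    return pd.DataFrame(rows, columns=["seqid", "start", "end"])


def classify_inserts(
    inserts: pd.DataFrame,
    gtf: pd.DataFrame,
    proximity_gene: int = DEFAULT_PROXIMITY_GENE,
    proximity_promoter: int = DEFAULT_PROXIMITY_PROMOTER,
    tss_only: bool = False,
) -> pd.DataFrame:
    """Annotate catalogue inserts against gene/exon/intron space.

    Returns one record per insert with distance-based class flags, the
    nearest gene (id, distance) and its biotype when within
    ``proximity_gene``.  ``tss_only`` measures promoter proximity to the
    strand-aware gene start rather than either gene edge.
    """
    feats = gene_features(gtf)
    ins = inserts.rename(columns={"id": "insert_id"}).reset_index(drop=True)
    d_gene = _nearest_gap_vector(ins, feats["gene_space"])
    d_exon = _nearest_gap_vector(ins, feats["exon_space"])
    d_intron = _nearest_gap_vector(ins, feats["intron_space"])
    if tss_only:
        g = feats["gene"]
        tss = np.where(g["strand"] == "-", g["end"] - 1, g["start"])
        prom_space = pd.DataFrame(
            {"seqid": g["seqid"], "start": tss, "end": tss + 1}
        )
        d_prom = _nearest_gap_vector(ins, prom_space)
    else:
        d_prom = d_gene
    nearest_gene_id = []
    nearest_gene_dist = []
    biotype = []
    gene_tbl = feats["gene"].rename(columns={"gene_id": "id"})
    for row in ins.itertuples(index=False):
        gid, dist = distance_to_nearest(row.seqid, int(row.start), int(row.end), gene_tbl)
        nearest_gene_id.append(gid if gid is not None else "")
        nearest_gene_dist.append(dist)
        if gid is not None and dist <= proximity_gene:
            bt = gene_tbl.loc[gene_tbl["id"] == gid, "gene_type"]
            biotype.append(bt.iloc[0] if len(bt) else "")
        else:
            biotype.append("")
    out = pd.DataFrame(
        {
            "insert_id": ins["insert_id"],
            "seqid": ins["seqid"],
            "start": ins["start"],
            "end": ins["end"],
            "nearest_gene": nearest_gene_id,
            "nearest_gene_distance": nearest_gene_dist,
            "gene_100bp": d_gene <= proximity_gene,
            "exon_100bp": d_exon <= proximity_gene,
            "intron_100bp": d_intron <= proximity_gene,
            "biotype": biotype,
        }
    )
    out["promoter_1000bp"] = (d_prom <= proximity_promoter) & ~out["gene_100bp"]
    out["intergenic"] = ~out["gene_100bp"]
    return out


def tally_classes(annotation: pd.DataFrame) -> pd.DataFrame:
    """Counts and percentages of inserts per annotation class."""
    n = len(annotation)
    rows = []
    for cls in ("gene_100bp", "exon_100bp", "intron_100bp", "promoter_1000bp", "intergenic"):
        c = int(annotation[cls].sum())
        rows.append((cls, c, 100.0 * c / n if n else 0.0))
    return pd.DataFrame(rows, columns=["class", "count", "percent"])


def tally_by_catalogue(
    hit_sets: dict[str, pd.DataFrame],
    feature_sets: dict[str, pd.DataFrame],
    proximity: int = DEFAULT_PROXIMITY_GENE,
    annotation: pd.DataFrame | None = None,
    gene_level: bool = False,
) -> pd.DataFrame:
    """Cross-tabulate hit sets against named feature sets.

    Rows are feature sets (plus an ``undescribed`` row for hits within
    ``proximity`` of no feature set at all); columns are hit sets.  With
    ``gene_level`` and an annotation table, hits are first grouped by their
    nearest gene so different fragments of the same gene count once.
    """
    cols = {}
    for hname, hits in hit_sets.items():
        h = hits.rename(columns={"id": "insert_id"})
        counts = {}
        near_any = np.zeros(len(h), dtype=bool)
        for fname, feats in feature_sets.items():
            d = _nearest_gap_vector(h.reset_index(drop=True), feats)
            within = d <= proximity
            near_any |= within
            if gene_level and annotation is not None:
                ann = annotation.set_index("insert_id")
                genes = ann.reindex(h["insert_id"])["nearest_gene"]
                counts[fname] = int(genes[within].replace("", np.nan).dropna().nunique())
            else:
                counts[fname] = int(within.sum())
        counts["undescribed"] = int((~near_any).sum())
        counts["total"] = len(h)
        cols[hname] = counts
    return pd.DataFrame(cols)


def intersect_hit_sets(hit_sets: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Pairwise intersection sizes of hit sets (by insert id)."""
    names = list(hit_sets)
    mat = pd.DataFrame(index=names, columns=names, dtype=int)
    ids = {n: set(hit_sets[n].rename(columns={"id": "insert_id"})["insert_id"]) for n in names}
    for a in names:
        for b in names:
            mat.loc[a, b] = len(ids[a] & ids[b])
    return mat
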