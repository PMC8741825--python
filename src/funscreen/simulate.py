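"""Synthetic screen generator with known ground truth.

Emulates the wet-lab workflow end to end: blunt restriction digestion of a
genome with DraI and AanI in separate reactions, cloning of size-selected
fragments between fixed vector flanks in both orientations, transduction at a
given multiplicity of infection, weeks of continuous competitive culture with
per-insert growth effects, a cytotoxic-challenge bottleneck with per-insert
survival probabilities, and vector-anchored 300 bp paired-end amplicon
sequencing.  Every stage is seeded and reproducible; truth tables (insert
coordinates, fitness classes, per-read genomic spans) are emitted so that the
analysis pipeline can be validated against known answers.

Model summary
-------------
* Growth: deterministic exponential growth at per-insert rate
  ``ln(2) / doubling_time * (1 + fitness_growth)`` between subcultures,
  followed by multinomial dilution back to the subculture census.
* Challenge: per-cell death under the cytotoxic agent is a constant-hazard
  process.  A measured survival fraction ``p`` over ``reference_h`` hours
  becomes ``p ** (duration_h / reference_h)`` over the challenge duration;
  survivors are drawn per insert from a binomial and then resume growth for
  the challenge duration.
* Sequencing: each amplicon is flank_fwd + insert (oriented) + flank_rev;
  R1 reads the amplicon 5' end (and therefore carries forward-primer-derived
  vector sequence: the "directional" read), R2 the reverse-complemented 3'
  end.  Substitution errors only, so truth spans stay exact.
"""

from __future__ import annotations

import dataclasses
import re
from pathlib import Path

import numpy as np
import pandas as pd

from .io_model import (
    GROUP_CULTURE47,
    GROUP_CULTURE47_FAS,
    GROUP_D0,
    ALIGNMENT_COLUMNS,
    GenomeSequence,
    reverse_complement,
)

# --------------------------------------------------------------------------
# Defaults: enzymes, primers, vector flanks, selection regime

@dataclasses.dataclass(frozen=True)
class RestrictionEnzyme:
    """A blunt-cutting restriction enzyme (palindromic recognition motif)."""

    name: str
    recognition: str
    cut_offset: int  # bases from motif start to the blunt cut point

    def __post_init__(self) -> None:
        if not (0 < self.cut_offset < len(self.recognition)):
            raise ValueError("cut_offset must fall strictly inside the motif")
        if reverse_complement(self.recognition) != self.recognition:
            raise ValueError(f"{self.name}: recognition motif must be palindromic")


# REBASE definitions; both cut centrally leaving blunt ends.
DRAI = RestrictionEnzyme("DraI", "TTTAAA", 3)
AANI = RestrictionEnzyme("AanI", "TTATAA", 3)
DEFAULT_ENZYMES = (DRAI, AANI)

#: the two vector-anchored PCR primers (20-mers)
PRIMER_FWD = "CCATCCACGCTGTTTTGACC"
PRIMER_REV = "CGCCGGTACCTTTAAGACCA"

# Synthetic 60-mer vector flanks whose primer-derived prefixes are fixed.
# FLANK_FWD begins with the forward primer; the reverse complement of
# FLANK_REV begins with the reverse primer (as a reverse primer anneals to
# the amplicon's bottom strand).
_FWD_EXT = "GATCGTACCAGTTGGCTAAGCCTAGGATCCAATGGCTACG"
_REV_EXT = "CTAGGCATTGACCGGTTCAAGGCATCCGATTGGCCATAGC"
FLANK_FWD = PRIMER_FWD + _FWD_EXT
FLANK_REV = reverse_complement(PRIMER_REV + _REV_EXT)

#: observed insert size range of the screen library (bp); simulator default
DEFAULT_SIZE_MIN = 132
DEFAULT_SIZE_MAX = 8293

#: growth effect reproducing the selected-culture doubling time of 19.1 h
#: against the neutral 26.3 h: rate factor 26.3/19.1 - 1
DEFAULT_GROWTH_EFFECT = 26.3 / 19.1 - 1.0
#: per-challenge survival of resistant vs control cells
DEFAULT_SURVIVAL_EFFECT = 0.628
DEFAULT_SURVIVAL_NEUTRAL = 0.025


@dataclasses.dataclass
class Challenge:
    """Cytotoxic challenge bottleneck parameters."""

    survival_neutral: float = DEFAULT_SURVIVAL_NEUTRAL
    duration_h: float = 96.0
    #: exposure time over which the survival fractions were measured
    reference_h: float = 22.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.survival_neutral <= 1.0):
            raise ValueError("survival_neutral must lie in [0, 1]")
        if self.duration_h <= 0 or self.reference_h <= 0:
            raise ValueError("challenge durations must be positive")


@dataclasses.dataclass
class SelectionRegime:
    """Transduction + culture + optional challenge schedule.

    Defaults follow the screen design: MOI 3.7, 47 days of continuous
    culture subcultured every 2-3 days to a 2e5-cell census, neutral
    doubling time 26.3 h, 96 h cytotoxic challenge.
    """

    moi: float = 3.7
    n_cells: int = 200_000
    days: float = 47.0
    subculture_interval_days: float = 2.5
    doubling_time_neutral_h: float = 26.3
    challenge: Challenge | None = dataclasses.field(default_factory=Challenge)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.moi <= 0 or self.n_cells <= 0 or self.days <= 0:
            raise ValueError("moi, n_cells and days must be positive")
        if self.subculture_interval_days <= 0 or self.doubling_time_neutral_h <= 0:
            raise ValueError("culture intervals and doubling time must be positive")


class ExtinctionError(RuntimeError):
    """Population went extinct under the challenge bottleneck."""


# --------------------------------------------------------------------------
# Digestion

def find_motif_cuts(sequence: str, enzyme: RestrictionEnzyme) -> np.ndarray:
    """All blunt cut positions of `enzyme` in `sequence` (sorted).

    A cut position is a 0-based boundary: cutting at position p splits the
    sequence into [0, p) and [p, L).  Overlapping motif occurrences are all
    cut (step-1 scan via a lookahead regex).
    """
    pat = re.compile(f"(?=({enzyme.recognition}))")
    cuts = [m.start() + enzyme.cut_offset for m in pat.finditer(sequence)]
    return np.asarray(sorted(set(cuts)), dtype=np.int64)


def digest_genome(
    genome: GenomeSequence,
    enzymes: tuple[RestrictionEnzyme, ...] = DEFAULT_ENZYMES,
) -> dict[str, pd.DataFrame]:
    """Digest the genome with each enzyme independently.

    Returns a mapping of enzyme name -> fragment frame (seqid, start, end,
    enzyme), plus a ``"combined"`` entry pooling the separate digests at
    equal representation.  Fragments of one digest tile each sequence
    exactly; a motif-free sequence yields one whole-sequence fragment.
    """
    out: dict[str, pd.DataFrame] = {}
    for enz in enzymes:
        rows = []
        for seqid, seq in genome.records.items():
            cuts = find_motif_cuts(seq, enz)
            bounds = np.concatenate(([0], cuts, [len(seq)]))
            bounds = np.unique(bounds)
            for s, e in zip(bounds[:-1], bounds[1:]):
                rows.append((seqid, int(s), int(e), enz.name))
        out[enz.name] = pd.DataFrame(rows, columns=["seqid", "start", "end", "enzyme"])
    out["combined"] = pd.concat(
        [out[e.name] for e in enzymes], ignore_index=True
    )
    return out


def reassemble_digest(genome: GenomeSequence, fragments: pd.DataFrame) -> dict[str, str]:
    """Concatenate one digest's fragments in order per seqid (oracle helper)."""
    rebuilt = {}
    for seqid, sub in fragments.groupby("seqid"):
        sub = sub.sort_values("start")
        rebuilt[seqid] = "".join(
            genome[seqid][r.start : r.end] for r in sub.itertuples(index=False)
        )
    return rebuilt


# --------------------------------------------------------------------------
# Library construction

LIBRARY_COLUMNS = [
    "insert_id", "seqid", "start", "end", "enzyme", "orientation",
    "fitness_growth", "fitness_survival",
]


def build_library(
    fragments: pd.DataFrame,
    size_min: int = DEFAULT_SIZE_MIN,
    size_max: int = DEFAULT_SIZE_MAX,
    seed: int = 0,
    orientations: str = "both",
    survival_neutral: float = DEFAULT_SURVIVAL_NEUTRAL,
) -> pd.DataFrame:
    """Clone size-selected fragments into the vector.

    Fragments with length inside [size_min, size_max] are retained; each
    yields a sense and an antisense insert (``orientations="both"``), or a
    single random orientation (``orientations="single"``).  Fitness fields
    start neutral (growth 0, survival = survival_neutral).
    """
    if size_min >= size_max:
        raise ValueError("size_min must be < size_max")
    if orientations not in ("both", "single"):
        raise ValueError("orientations must be 'both' or 'single'")
    lens = fragments["end"] - fragments["start"]
    kept = fragments[(lens >= size_min) & (lens <= size_max)].reset_index(drop=True)
    if kept.empty:
        raise ValueError(
            "no fragments fall inside the size window; use a genome with a "
            "higher motif density or widen [size_min, size_max]"
        )
    kept = kept.sort_values(["seqid", "start", "end", "enzyme"]).reset_index(drop=True)
    rng = np.random.default_rng(seed)
    rows = []
    for row in kept.itertuples(index=False):
        if orientations == "both":
            orients = ("sense", "antisense")
        else:
            orients = (rng.choice(["sense", "antisense"]),)
        for o in orients:
            iid = f"{row.seqid}:{row.start}-{row.end}:{o[0]}"
            rows.append(
                (iid, row.seqid, row.start, row.end, row.enzyme, o, 0.0,
                 survival_neutral)
            )
    return pd.DataFrame(rows, columns=LIBRARY_COLUMNS)


def assign_fitness(
    inserts: pd.DataFrame,
    n_growth_hits: int,
    n_survival_hits: int,
    growth_effect: float = DEFAULT_GROWTH_EFFECT,
    survival_effect: float = DEFAULT_SURVIVAL_EFFECT,
    seed: int = 0,
    mode: str = "nested",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Plant growth and survival hits into a neutral library.

    Hits are drawn on distinct fragments (so two hit classes never collide on
    the same genomic interval); one orientation of the chosen fragment is the
    functional insert.

    ``mode="nested"`` (default): survival hits also receive the growth
    effect.  The screen is serial -- the challenge is applied to the day-47
    culture -- so only inserts that persist through competitive growth are
    observable at the challenge; survival-capable inserts are modelled as
    culture-fit.  ``mode="disjoint"`` keeps survival hits growth-neutral.

    Returns the updated insert frame and a truth table
    (insert_id, seqid, start, end, orientation, class).
    """
    if mode not in ("nested", "disjoint"):
        raise ValueError("mode must be 'nested' or 'disjoint'")
    frag_key = inserts["seqid"].astype(str) + ":" + inserts["start"].astype(str) + "-" + inserts["end"].astype(str)
    frags = frag_key.unique()
    n_hits = n_growth_hits + n_survival_hits
    if n_hits > len(frags):
        raise ValueError(
            f"requested {n_hits} hits but only {len(frags)} distinct fragments"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(frags, size=n_hits, replace=False)
    growth_frags = set(chosen[:n_growth_hits])
    survival_frags = set(chosen[n_growth_hits:])

    out = inserts.copy()
    out["class"] = "neutral"
    truth_rows = []
    for frag in chosen:
        sub_idx = out.index[frag_key == frag]
        pick = rng.choice(sub_idx)  # one orientation is the functional insert
        if frag in growth_frags:
            cls = "growth"
            out.loc[pick, "fitness_growth"] = growth_effect
        else:
            cls = "survival"
            out.loc[pick, "fitness_survival"] = survival_effect
            if mode == "nested":
                out.loc[pick, "fitness_growth"] = growth_effect
        out.loc[pick, "class"] = cls
        r = out.loc[pick]
        truth_rows.append(
            (r["insert_id"], r["seqid"], int(r["start"]), int(r["end"]),
             r["orientation"], cls)
        )
    truth = pd.DataFrame(
        truth_rows,
        columns=["insert_id", "seqid", "start", "end", "orientation", "class"],
    ).sort_values(["seqid", "start"]).reset_index(drop=True)
    return out, truth


# --------------------------------------------------------------------------
# Selection dynamics

def _growth_factors(inserts: pd.DataFrame, regime: SelectionRegime, hours: float) -> np.ndarray:
    rate = np.log(2.0) / regime.doubling_time_neutral_h
    g = inserts["fitness_growth"].to_numpy(dtype=float)
    return np.exp(rate * (1.0 + g) * hours)


def apply_challenge(
    counts: np.ndarray,
    survival: np.ndarray,
    challenge: Challenge,
    rng: np.random.Generator,
) -> np.ndarray:
    """Binomial survival bottleneck under constant-hazard death.

    ``survival`` holds each insert's measured survival fraction over
    ``challenge.reference_h`` hours; the per-cell survival probability over
    the full challenge is ``survival ** (duration_h / reference_h)``.
    """
    expo = challenge.duration_h / challenge.reference_h
    p = np.clip(survival, 0.0, 1.0) ** expo
    return rng.binomial(counts.astype(np.int64), p)


def simulate_selection(
    inserts: pd.DataFrame,
    regime: SelectionRegime,
    n_replicates: int = 4,
    cotransduction: bool = False,
) -> pd.DataFrame:
    """Run the screen's selection dynamics for each replicate.

    Returns a long frame (insert_id, group, replicate, cells) covering D0,
    CULTURE47 and CULTURE47_FAS.  All randomness flows from ``regime.seed``
    through per-replicate substreams, so replicates are independent but the
    whole simulation is reproducible.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    n = len(inserts)
    if n == 0:
        raise ValueError("empty insert library")
    survival = inserts["fitness_survival"].to_numpy(dtype=float)
    weights = np.full(n, 1.0 / n)  # equimolar library composition
    ss = np.random.SeedSequence(regime.seed)
    children = ss.spawn(n_replicates)
    frames = []
    rep_ids = [chr(ord("A") + i) if n_replicates <= 26 else f"R{i+1}" for i in range(n_replicates)]
    for rep, child in zip(rep_ids, children):
        rng = np.random.default_rng(child)
        # transduction: one integration per transduced cell by default; with
        # cotransduction, the number of integration events is Poisson(moi)
        # per cell and every event is an independent library draw.
        n_events = (
            int(rng.poisson(regime.moi * regime.n_cells))
            if cotransduction
            else regime.n_cells
        )
        counts = rng.multinomial(n_events, weights).astype(np.int64)
        d0 = counts.copy()
        # continuous culture: exponential growth then dilution to census
        t = 0.0
        while t < regime.days - 1e-9:
            dt = min(regime.subculture_interval_days, regime.days - t)
            mass = counts * _growth_factors(inserts, regime, dt * 24.0)
            total = mass.sum()
            if total <= 0:
                raise ExtinctionError("culture extinct; increase n_cells")
            counts = rng.multinomial(regime.n_cells, mass / total)
            t += dt
        d47 = counts.copy()
        # cytotoxic challenge + regrowth for the challenge duration
        if regime.challenge is not None:
            surv = apply_challenge(d47, survival, regime.challenge, rng)
            if surv.sum() == 0:
                raise ExtinctionError(
                    "no cells survived the challenge; increase n_cells"
                )
            mass = surv * _growth_factors(inserts, regime, regime.challenge.duration_h)
            fas = np.rint(mass).astype(np.int64)
        else:
            fas = None
        for group, vec in ((GROUP_D0, d0), (GROUP_CULTURE47, d47),
                           (GROUP_CULTURE47_FAS, fas)):
            if vec is None:
                continue
            frames.append(
                pd.DataFrame(
                    {
                        "insert_id": inserts["insert_id"].to_numpy(),
                        "group": group,
                        "replicate": rep,
                        "cells": vec,
                    }
                )
            )
    return pd.concat(frames, ignore_index=True)


# --------------------------------------------------------------------------
# Amplicon sequencing

_BASE_TO_CODE = {65: 0, 67: 1, 71: 2, 84: 3}  # A C G T
_CODE_TO_BASE = np.frombuffer(b"ACGT", dtype=np.uint8)


def _read_templates(
    inserts: pd.DataFrame,
    genome: GenomeSequence,
    read_length: int,
    flank_fwd: str,
    flank_rev: str,
) -> pd.DataFrame:
    """Per-insert R1/R2 sequences and truth genomic spans (error-free).

    Amplicon sequencing from fixed vector primers means every read pair of a
    given insert is identical before sequencing error; templates are built
    once per insert.  Truth spans cover the insert-overlapping portion of
    each read only (vector bases are not genomic).
    """
    lf, lr = len(flank_fwd), len(flank_rev)
    rows = []
    for row in inserts.itertuples(index=False):
        frag = genome[row.seqid][row.start : row.end]
        ins = frag if row.orientation == "sense" else reverse_complement(frag)
        amplicon = flank_fwd + ins + flank_rev
        alen = len(amplicon)
        r1 = amplicon[: min(read_length, alen)]
        r2 = reverse_complement(amplicon[max(0, alen - read_length) :])
        L = len(ins)
        g1 = max(0, min(read_length - lf, L))  # genomic bases in R1
        g2 = max(0, min(read_length - lr, L))  # genomic bases in R2
        if row.orientation == "sense":
            s1, e1, st1 = row.start, row.start + g1, "+"
            s2, e2, st2 = row.end - g2, row.end, "-"
        else:
            s1, e1, st1 = row.end - g1, row.end, "-"
            s2, e2, st2 = row.start, row.start + g2, "+"
        rows.append(
            (row.insert_id, row.seqid, r1, r2, s1, e1, st1, s2, e2, st2, g1, g2)
        )
    return pd.DataFrame(
        rows,
        columns=[
            "insert_id", "seqid", "r1", "r2",
            "r1_start", "r1_end", "r1_strand",
            "r2_start", "r2_end", "r2_strand",
            "g1", "g2",
        ],
    )


def _inject_errors(seqs: list[str], error_rate: float, rng: np.random.Generator) -> list[str]:
    """Apply iid substitution errors to equal-purpose read sequences."""
    if error_rate <= 0 or not seqs:
        return seqs
    out = []
    for s in seqs:
        arr = np.frombuffer(s.encode(), dtype=np.uint8).copy()
        k = rng.binomial(len(arr), error_rate)
        if k:
            pos = rng.choice(len(arr), size=k, replace=False)
            codes = np.array([_BASE_TO_CODE.get(b, 0) for b in arr[pos]])
            arr[pos] = _CODE_TO_BASE[(codes + rng.integers(1, 4, size=k)) % 4]
        out.append(arr.tobytes().decode())
    return out


def simulate_reads(
    inserts: pd.DataFrame,
    abundances: pd.DataFrame,
    genome: GenomeSequence,
    read_length: int = 300,
    flank_fwd: str = FLANK_FWD,
    flank_rev: str = FLANK_REV,
    error_rate: float = 0.0,
    reads_per_cell: float = 0.125,
    seed: int = 0,
    fastq_dir: str | Path | None = None,
) -> pd.DataFrame:
    """Generate paired-end amplicon reads for every sample.

    For each (group, replicate) sample, ``round(reads_per_cell * total
    cells)`` read pairs are drawn multinomially over inserts by cell
    abundance.  Returns the truth alignment frame (one row per read, R1 and
    R2); when ``fastq_dir`` is given, writes ``<group>_<replicate>_R[12]
    .fastq`` files with matching read ids.

    R1 always carries the forward-primer flank and is flagged directional.
    """
    if read_length < len(PRIMER_FWD):
        raise ValueError("read_length shorter than the primer")
    if not flank_fwd.startswith(PRIMER_FWD[: min(len(PRIMER_FWD), len(flank_fwd))]):
        raise ValueError("flank_fwd must begin with the forward primer")
    templates = _read_templates(inserts, genome, read_length, flank_fwd, flank_rev)
    tmpl = templates.set_index("insert_id")
    order = inserts["insert_id"].to_numpy()
    tmpl = tmpl.loc[order]
    rng_root = np.random.SeedSequence(seed)
    frames = []
    fastq_dir = Path(fastq_dir) if fastq_dir is not None else None
    if fastq_dir is not None:
        fastq_dir.mkdir(parents=True, exist_ok=True)
    sample_keys = sorted(abundances.groupby(["group", "replicate"], observed=True).groups)
    streams = {k: np.random.default_rng(c) for k, c in
               zip(sample_keys, rng_root.spawn(len(sample_keys)))}
    for (group, rep), sub in abundances.groupby(["group", "replicate"], observed=True):
        rng = streams[(group, rep)]
        cells = (
            sub.set_index("insert_id")["cells"].reindex(order).fillna(0).to_numpy()
        )
        total = cells.sum()
        n_pairs = int(round(reads_per_cell * total))
        if n_pairs == 0 or total == 0:
            continue
        counts = rng.multinomial(n_pairs, cells / total)
        idx = np.repeat(np.arange(len(order)), counts)
        pair_ids = np.array(
            [f"{group}_{rep}_{i:07d}" for i in range(len(idx))]
        )
        t = tmpl.iloc[idx]
        half = pd.DataFrame(
            {
                "seqid": t["seqid"].to_numpy(),
                "group": group,
                "replicate": rep,
                "read_id": pair_ids,
            }
        )
        r1 = half.copy()
        r1["start"], r1["end"], r1["strand"] = (
            t["r1_start"].to_numpy(), t["r1_end"].to_numpy(), t["r1_strand"].to_numpy()
        )
        r1["mate"], r1["directional"] = "R1", True
        r2 = half.copy()
        r2["start"], r2["end"], r2["strand"] = (
            t["r2_start"].to_numpy(), t["r2_end"].to_numpy(), t["r2_strand"].to_numpy()
        )
        r2["mate"], r2["directional"] = "R2", False
        truth = pd.concat([r1, r2], ignore_index=True)[ALIGNMENT_COLUMNS]
        # zero-length genomic portions (read entirely in vector) cannot map
        truth = truth[truth["end"] > truth["start"]].reset_index(drop=True)
        frames.append(truth)
        if fastq_dir is not None:
            seqs1 = _inject_errors(list(t["r1"].to_numpy()), error_rate, rng)
            seqs2 = _inject_errors(list(t["r2"].to_numpy()), error_rate, rng)
            for mate, seqs in (("R1", seqs1), ("R2", seqs2)):
                fp = fastq_dir / f"{group}_{rep}_{mate}.fastq"
                with open(fp, "w") as fh:
                    for rid, s in zip(pair_ids, seqs):
                        fh.write(f"@{rid}\n{s}\n+\nI" + "I" * (len(s) - 1) + "\n")
    if not frames:
        return pd.DataFrame(columns=ALIGNMENT_COLUMNS)
    return pd.concat(frames, ignore_index=True)


# --------------------------------------------------------------------------
# Genome synthesis (for fixtures and tests)

def random_genome(
    lengths: dict[str, int],
    seed: int = 0,
    motif_spacing: float | None = None,
    enzymes: tuple[RestrictionEnzyme, ...] = DEFAULT_ENZYMES,
) -> GenomeSequence:
    """Generate a random genome, optionally enriched in restriction motifs.

    With ``motif_spacing`` set, each enzyme's motif is additionally planted
    at Poisson-spaced positions (mean spacing in bp), so small genomes can
    carry a screen-sized restriction-fragment library.
    """
    rng = np.random.default_rng(seed)
    records = {}
    for seqid, L in lengths.items():
        arr = _CODE_TO_BASE[rng.integers(0, 4, size=L)].copy()
        if motif_spacing is not None:
            for enz in enzymes:
                n = rng.poisson(L / motif_spacing)
                pos = rng.integers(0, max(1, L - len(enz.recognition)), size=n)
                motif = np.frombuffer(enz.recognition.encode(), dtype=np.uint8)
                for p in pos:
                    arr[p : p + len(motif)] = motif
        records[seqid] = arr.tobytes().decode()
    return GenomeSequence(records)
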