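"""End-to-end orchestration: config, fixtures, the full analysis, reporting.

The pipeline runs the stages in method order: read preparation (when raw
reads are given), per-sample enrichment-interval calling, catalogue
construction, per-insert quantification and presence, replicate-intersection
hit calling with enrichment scores, feature annotation, and coverage
diversity statistics.  Every tunable is a named config field defaulting to
the screen's standard constants (merge distance 25 bp, presence >= 10
reads, >= 3 replicates, restriction site within 100 bp, gene proximity
100 bp, promoter window 1000 bp, 1 kb bins, 97% bin probe).

``make_fixture`` builds seeded synthetic screens with planted ground truth;
they power the test-suite and the worked examples.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field, field_validator

from . import annotate as ann
from . import insert_calling as ic
from . import integrate as intg
from . import io_model as io
from . import quantify as qt
from . import readprep as rp
from . import simulate as sim
from .io_model import (
    GROUP_CULTURE47,
    GROUP_CULTURE47_FAS,
    GROUP_D0,
    GenomeSequence,
)


# --------------------------------------------------------------------------
# Configuration

class SimulatorConfig(BaseModel):
    size_min: int = sim.DEFAULT_SIZE_MIN
    size_max: int = sim.DEFAULT_SIZE_MAX
    orientations: str = "both"
    n_growth_hits: int = 0
    n_survival_hits: int = 0
    growth_effect: float = sim.DEFAULT_GROWTH_EFFECT
    survival_effect: float = sim.DEFAULT_SURVIVAL_EFFECT
    fitness_mode: str = "nested"
    moi: float = 3.7
    n_cells: int = 200_000
    days: float = 47.0
    subculture_interval_days: float = 2.5
    doubling_time_neutral_h: float = 26.3
    survival_neutral: float = sim.DEFAULT_SURVIVAL_NEUTRAL
    challenge_duration_h: float = 96.0
    challenge_reference_h: float = 22.0
    n_replicates: int = 4
    read_length: int = 300
    error_rate: float = 0.0
    reads_per_cell: float = 0.125
    write_fastq: bool = False


class PipelineConfig(BaseModel):
    """Validated pipeline configuration (YAML-loadable)."""

    genome: str
    samplesheet: str | None = None
    gtf: str | None = None
    extra_beds: dict[str, str] = Field(default_factory=dict)
    seed: int = 0
    merge_distance: int = ic.DEFAULT_MERGE_DISTANCE
    presence_min: int = qt.DEFAULT_PRESENCE_MIN
    min_replicates: int = intg.DEFAULT_MIN_REPLICATES
    restriction_max: int = intg.DEFAULT_RESTRICTION_MAX
    proximity_gene: int = ann.DEFAULT_PROXIMITY_GENE
    proximity_promoter: int = ann.DEFAULT_PROXIMITY_PROMOTER
    bin_size: int = qt.DEFAULT_BIN_SIZE
    probe_bin_fraction: float = qt.DEFAULT_PROBE_BIN_FRACTION
    min_coverage: int = ic.DEFAULT_MIN_COVERAGE
    fold_over_background: float = ic.DEFAULT_FOLD
    min_length: int = ic.DEFAULT_MIN_LENGTH
    simulator: SimulatorConfig = Field(default_factory=SimulatorConfig)

    @field_validator(
        "merge_distance", "presence_min", "min_replicates", "restriction_max",
        "proximity_gene", "proximity_promoter", "bin_size", "min_coverage",
        "min_length",
    )
    @classmethod
    def _non_negative(cls, v, info):
        if v < 0:
            raise ValueError(f"{info.field_name} must be >= 0, got {v}")
        return v

    @field_validator("probe_bin_fraction")
    @classmethod
    def _probe(cls, v):
        if not (0.0 < v <= 1.0):
            raise ValueError("probe_bin_fraction must lie in (0, 1]")
        return v

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


# --------------------------------------------------------------------------
# Fixtures

#: fixture profiles: desk-scale synthetic screens.  "tiny" is a smoke-test
#: scale; "screen" is the screen-scale benchmark (two-chromosome 3 Mb
#: genome, ~1000 inserts, 20 growth + 20 survival hits at the standard
#: effect sizes, 4 replicates, 47-day regime).
FIXTURE_PROFILES: dict[str, dict] = {
    "tiny": dict(
        lengths={"chrA": 120_000, "chrB": 80_000},
        motif_spacing=1500.0,
        size_min=132, size_max=505,
        n_growth_hits=3, n_survival_hits=3,
        n_cells=20_000, n_replicates=4,
        reads_per_cell=0.5,
    ),
    "screen": dict(
        lengths={"chr1": 1_800_000, "chr2": 1_200_000},
        motif_spacing=None,
        size_min=132, size_max=2000,
        n_growth_hits=20, n_survival_hits=20,
        n_cells=200_000, n_replicates=4,
        reads_per_cell=0.125,
    ),
}
FIXTURE_PROFILES["small"] = FIXTURE_PROFILES["screen"]


@dataclasses.dataclass
class Fixture:
    """A complete synthetic screen with ground truth."""

    genome: GenomeSequence
    inserts: pd.DataFrame
    truth: pd.DataFrame
    abundances: pd.DataFrame
    alignments: pd.DataFrame
    gtf: pd.DataFrame
    regime: sim.SelectionRegime
    profile: str
    seed: int
    fastq_dir: Path | None = None


def _toy_gtf(genome: GenomeSequence, seed: int, n_genes_per_mb: float = 60.0) -> pd.DataFrame:
    """A toy gene annotation: random genes with two exons each."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xA11]))
    rows = []
    gi = 0
    for seqid, L in genome.lengths.items():
        n = max(2, int(L / 1e6 * n_genes_per_mb))
        starts = np.sort(rng.integers(0, max(1, L - 4000), size=n))
        for s in starts:
            glen = int(rng.integers(1500, 4000))
            e = min(L, s + glen)
            strand = rng.choice(["+", "-"])
            gtype = "protein_coding" if gi % 3 else "lncRNA"
            gid = f"GENE{gi:04d}"
            rows.append((seqid, int(s), int(e), "gene", strand, gid, gtype, gid))
            ex1 = (int(s), int(min(e, s + 300)))
            ex2 = (int(max(s, e - 300)), int(e))
            rows.append((seqid, ex1[0], ex1[1], "exon", strand, gid, gtype, gid))
            if ex2[0] > ex1[1]:
                rows.append((seqid, ex2[0], ex2[1], "exon", strand, gid, gtype, gid))
            gi += 1
    return pd.DataFrame(
        rows,
        columns=["seqid", "start", "end", "feature", "strand",
                 "gene_id", "gene_type", "gene_name"],
    )


def make_fixture(
    profile: str = "tiny",
    seed: int = 0,
    outdir: str | Path | None = None,
    write_fastq: bool = False,
    error_rate: float = 0.0,
    orientations: str = "both",
    fitness_mode: str = "nested",
    enzymes: tuple[sim.RestrictionEnzyme, ...] = sim.DEFAULT_ENZYMES,
) -> Fixture:
    """Generate a seeded synthetic screen with planted hits.

    All randomness derives from ``seed``; two calls with the same arguments
    produce identical truth tables, abundances and reads.  With ``outdir``
    the whole bundle (genome FASTA, truth BED/TSV, abundances, alignment
    TSV, toy GTF, samplesheet, config echo) is written to disk.
    """
    if profile not in FIXTURE_PROFILES:
        raise ValueError(f"unknown fixture profile {profile!r}")
    p = FIXTURE_PROFILES[profile]
    genome = sim.random_genome(
        p["lengths"], seed=seed, motif_spacing=p["motif_spacing"], enzymes=enzymes
    )
    digests = sim.digest_genome(genome, enzymes)
    library = sim.build_library(
        digests["combined"], p["size_min"], p["size_max"], seed=seed,
        orientations=orientations,
    )
    inserts, truth = sim.assign_fitness(
        library, p["n_growth_hits"], p["n_survival_hits"], seed=seed,
        mode=fitness_mode,
    )
    regime = sim.SelectionRegime(n_cells=p["n_cells"], seed=seed)
    abundances = sim.simulate_selection(inserts, regime, n_replicates=p["n_replicates"])
    fastq_dir = None
    if write_fastq:
        fastq_dir = Path(outdir or ".") / "fastq"
    alignments = sim.simulate_reads(
        inserts, abundances, genome,
        error_rate=error_rate,
        reads_per_cell=p["reads_per_cell"],
        seed=seed,
        fastq_dir=fastq_dir,
    )
    gtf = _toy_gtf(genome, seed)
    fx = Fixture(genome, inserts, truth, abundances, alignments, gtf, regime,
                 profile, seed, fastq_dir)
    if outdir is not None:
        write_fixture(fx, outdir)
    return fx


def write_fixture(fx: Fixture, outdir: str | Path) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    io.write_fasta(fx.genome, outdir / "genome.fa")
    fx.inserts.to_csv(outdir / "library.tsv", sep="\t", index=False)
    fx.truth.to_csv(outdir / "truth_hits.tsv", sep="\t", index=False)
    io.write_bed(
        fx.truth.assign(id=fx.truth["insert_id"], strand=".")[
            ["seqid", "start", "end", "id", "strand"]
        ],
        outdir / "truth_hits.bed",
    )
    fx.abundances.to_csv(outdir / "abundances.tsv", sep="\t", index=False)
    io.write_alignments_tsv(fx.alignments, outdir / "alignments.tsv")
    io.write_gtf(fx.gtf, outdir / "annotation.gtf")
    sheet = (
        fx.alignments[["group", "replicate"]]
        .drop_duplicates()
        .assign(file="alignments.tsv")[["file", "group", "replicate"]]
    )
    sheet.to_csv(outdir / "samplesheet.tsv", sep="\t", index=False)
    cfg = {
        "genome": "genome.fa",
        "samplesheet": "samplesheet.tsv",
        "gtf": "annotation.gtf",
        "seed": fx.seed,
    }
    with open(outdir / "config.yaml", "w") as fh:
        yaml.safe_dump(cfg, fh)
    return outdir


# --------------------------------------------------------------------------
# The analysis proper

@dataclasses.dataclass
class ScreenResult:
    """All pipeline outputs for one run."""

    per_sample_intervals: dict[str, pd.DataFrame]
    catalogue: pd.DataFrame
    quant: pd.DataFrame
    diversity: pd.DataFrame
    hits: pd.DataFrame
    orientation: pd.DataFrame
    covstats: pd.DataFrame
    fingerprints: dict[str, qt.FingerprintCurve]
    potentiation_culture: pd.Series
    potentiation_fas: pd.Series
    ratio: pd.Series
    ratio_cohorts: dict[str, float]
    annotation: pd.DataFrame | None
    tally: pd.DataFrame | None
    totals: pd.Series


def analyze(
    alignments: pd.DataFrame,
    genome: GenomeSequence,
    config: PipelineConfig | None = None,
    gtf: pd.DataFrame | None = None,
) -> ScreenResult:
    """Run calling, quantification, integration and annotation in memory."""
    cfg = config or PipelineConfig(genome="")
    lengths = genome.lengths
    totals = io.total_mapped_per_sample(alignments)

    per_sample: dict[str, pd.DataFrame] = {}
    covrows = []
    fingerprints: dict[str, qt.FingerprintCurve] = {}
    for (group, rep), sub in alignments.groupby(["group", "replicate"], observed=True):
        name = f"{group}_{rep}"
        track = ic.compute_coverage(sub, lengths)
        called = ic.call_enriched_intervals(
            track, cfg.min_coverage, cfg.fold_over_background, cfg.min_length
        )
        per_sample[name] = ic.merge_intervals(called, cfg.merge_distance)
        fill = qt.bin_fill(sub, lengths, cfg.bin_size)
        curve = qt.fingerprint(sub, lengths, cfg.bin_size)
        fingerprints[name] = curve
        covrows.append(
            (
                group, rep, len(sub),
                fill.n_bins, fill.n_filled, 100.0 * fill.fraction_filled,
                100.0 * curve.read_fraction_at(cfg.probe_bin_fraction),
            )
        )
    covstats = pd.DataFrame(
        covrows,
        columns=["group", "replicate", "mapped_reads", "n_bins", "bins_filled",
                 "bins_filled_pct", "read_fraction_at_probe_pct"],
    )

    catalogue = ic.build_catalogue(per_sample, cfg.merge_distance)
    raw = qt.count_reads(alignments, catalogue)
    quant = qt.normalize_and_flag(raw, totals, cfg.presence_min)
    diversity = qt.distinct_insert_counts(quant)

    dirsupp = intg.directional_support(alignments, catalogue)
    sites = ann.find_restriction_sites(genome)
    rdist = ann.distances_to_positions(catalogue, sites)
    hits = intg.call_hits(
        quant, catalogue, dirsupp, rdist,
        cfg.min_replicates, cfg.restriction_max,
    )
    orientation = rp.orient_inserts(alignments, catalogue)

    pot_c = pot_f = pd.Series(dtype=float)
    ratio = pd.Series(dtype=float)
    cohorts: dict[str, float] = {}
    if (alignments["group"] == GROUP_CULTURE47).any():
        pot_c = intg.potentiation(quant, GROUP_CULTURE47)
    if (alignments["group"] == GROUP_CULTURE47_FAS).any():
        pot_f = intg.potentiation(quant, GROUP_CULTURE47_FAS)
        if (alignments["group"] == GROUP_CULTURE47).any():
            ratio = intg.mf_mfz_ratio(quant)
            cohorts = intg.ratio_cohort_means(quant, hits)

    annotation = tally = None
    if gtf is not None:
        annotation = ann.classify_inserts(
            catalogue, gtf, cfg.proximity_gene, cfg.proximity_promoter
        )
        tally = ann.tally_classes(annotation)

    return ScreenResult(
        per_sample, catalogue, quant, diversity, hits, orientation, covstats,
        fingerprints, pot_c, pot_f, ratio, cohorts, annotation, tally, totals,
    )


# --------------------------------------------------------------------------
# Truth comparison

def _any_overlap(selected: pd.DataFrame, truth: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """(per-truth recovered flags, per-selected matched flags) by overlap."""
    rec = np.zeros(len(truth), dtype=bool)
    matched = np.zeros(len(selected), dtype=bool)
    for i, t in enumerate(truth.itertuples(index=False)):
        m = (
            (selected["seqid"] == t.seqid)
            & (selected["start"] < t.end)
            & (selected["end"] > t.start)
        ).to_numpy()
        rec[i] = m.any()
        matched |= m
    return rec, matched


def evaluate_against_truth(
    hits: pd.DataFrame,
    truth: pd.DataFrame,
    group: str = GROUP_CULTURE47_FAS,
    classes: tuple[str, ...] = ("survival",),
) -> dict:
    """Planted-vs-recovered confusion summary for one selected group.

    A planted hit is recovered when any selected interval overlaps its
    fragment; a selected interval is a false positive when it overlaps no
    planted hit of the given classes.
    """
    sel_col = hits["selected_in"].fillna("").astype(str)
    selected = hits[sel_col.map(lambda s: group in s.split(","))]
    truth_c = truth[truth["class"].isin(classes)].drop_duplicates(
        subset=["seqid", "start", "end"]
    )
    rec, matched = _any_overlap(selected, truth_c)
    n_true = len(truth_c)
    return {
        "group": group,
        "n_planted": n_true,
        "n_selected": int(len(selected)),
        "n_recovered": int(rec.sum()),
        "recall": float(rec.sum() / n_true) if n_true else float("nan"),
        "false_positives": int((~matched).sum()),
    }


# --------------------------------------------------------------------------
# Run directory + report

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig, outdir: str | Path, base_dir: str | Path | None = None) -> Path:
    """Execute the full pipeline from config to a run directory.

    Re-running with the same config and inputs reproduces byte-identical
    tables; the manifest records the config echo, the seed and input
    checksums.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    base = Path(base_dir) if base_dir is not None else Path(".")

    def _p(rel: str) -> Path:
        q = Path(rel)
        return q if q.is_absolute() else base / q

    genome = io.load_genome(_p(config.genome))
    if config.samplesheet is None:
        raise ValueError("config.samplesheet is required to run the pipeline")
    sheet = io.read_samplesheet(_p(config.samplesheet))
    alignments = io.load_alignments(sheet, genome, base_dir=base)
    gtf = io.read_gtf(_p(config.gtf)) if config.gtf else None

    res = analyze(alignments, genome, config, gtf)
    write_result(res, outdir)

    manifest = {
        "config": json.loads(config.model_dump_json()),
        "inputs": {
            str(config.genome): _sha256(_p(config.genome)),
            str(config.samplesheet): _sha256(_p(config.samplesheet)),
        },
        "seed": config.seed,
    }
    with open(outdir / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh)
    return outdir


def write_result(res: ScreenResult, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    io.write_bed(
        res.catalogue.assign(strand=".")[["seqid", "start", "end", "id", "strand"]],
        outdir / "catalogue.bed",
    )
    beddir = outdir / "per_sample_beds"
    beddir.mkdir(exist_ok=True)
    for name, df in res.per_sample_intervals.items():
        io.write_bed(df, beddir / f"{name}.bed")
    res.quant.to_csv(outdir / "quant.tsv", sep="\t", index=False)
    res.diversity.to_csv(outdir / "diversity.tsv", sep="\t", index=False)
    hits = res.hits.copy()
    hits["potentiation_culture"] = res.potentiation_culture.reindex(hits["insert_id"]).to_numpy()
    hits["potentiation_fas"] = res.potentiation_fas.reindex(hits["insert_id"]).to_numpy()
    hits["mf_mfz_ratio"] = res.ratio.reindex(hits["insert_id"]).to_numpy()
    hits.to_csv(outdir / "hits.tsv", sep="\t", index=False)
    for g in (GROUP_CULTURE47, GROUP_CULTURE47_FAS):
        sel = res.hits[res.hits["selected_in"].map(lambda s: g in s.split(","))]
        if len(sel):
            io.write_bed(
                sel.assign(id=sel["insert_id"], strand=".")[
                    ["seqid", "start", "end", "id", "strand"]
                ],
                outdir / f"selected_{g}.bed",
            )
    res.orientation.to_csv(outdir / "orientation.tsv", sep="\t", index=False)
    res.covstats.to_csv(outdir / "covstats.tsv", sep="\t", index=False)
    curves = pd.concat(
        [c.to_frame().assign(sample=name) for name, c in res.fingerprints.items()],
        ignore_index=True,
    )
    curves.to_csv(outdir / "fingerprint_curves.tsv", sep="\t", index=False)
    if res.annotation is not None:
        res.annotation.to_csv(outdir / "annotation.tsv", sep="\t", index=False)
        res.tally.to_csv(outdir / "annotation_tally.tsv", sep="\t", index=False)
    summary = {
        "n_catalogue_inserts": int(len(res.catalogue)),
        "selected_counts": intg.selected_counts(res.hits),
        "ratio_cohorts": res.ratio_cohorts,
        "samples": {
            f"{r.group}_{r.replicate}": int(r.mapped_reads)
            for r in res.covstats.itertuples(index=False)
        },
    }
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=float)


def report(run_dir: str | Path, truth_path: str | Path | None = None) -> str:
    """Render a human-readable run summary from a completed run directory."""
    run_dir = Path(run_dir)
    required = ["summary.json", "covstats.tsv", "diversity.tsv", "hits.tsv"]
    missing = [f for f in required if not (run_dir / f).exists()]
    if missing:
        return "INCOMPLETE RUN; missing outputs:\n" + "\n".join(f"  - {m}" for m in missing)
    with open(run_dir / "summary.json") as fh:
        summary = json.load(fh)
    covstats = pd.read_csv(run_dir / "covstats.tsv", sep="\t")
    diversity = pd.read_csv(run_dir / "diversity.tsv", sep="\t")
    hits = pd.read_csv(run_dir / "hits.tsv", sep="\t")
    lines = ["# Screen run report", ""]
    lines.append(f"Catalogue inserts: {summary['n_catalogue_inserts']}")
    lines.append(f"Selected inserts per group: {summary['selected_counts']}")
    if summary.get("ratio_cohorts"):
        rc = summary["ratio_cohorts"]
        lines.append(
            "Challenge:culture ratio -- present-in-culture cohort "
            f"{rc.get('present_culture', float('nan')):.2f}, selected-in-both cohort "
            f"{rc.get('selected_both', float('nan')):.2f}"
        )
    lines.append("")
    lines.append("## Coverage diversity (per sample)")
    lines.append(
        covstats[["group", "replicate", "mapped_reads", "bins_filled_pct",
                  "read_fraction_at_probe_pct"]].to_string(index=False)
    )
    lines.append("")
    lines.append("## Distinct present inserts (per sample)")
    piv = diversity.pivot(index="replicate", columns="group", values="distinct_inserts")
    lines.append(piv.to_string())
    lines.append("")
    lines.append("## Hit table head")
    lines.append(hits.head(10).to_string(index=False))
    if truth_path is not None and Path(truth_path).exists():
        truth = pd.read_csv(truth_path, sep="\t")
        ev = evaluate_against_truth(hits, truth)
        lines.append("")
        lines.append("## Planted-vs-recovered (survival hits, challenge condition)")
        lines.append(json.dumps(ev, indent=2))
    return "\n".join(lines)
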