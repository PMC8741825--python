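# Methods

## The screen being modelled

funscreen analyses a functional forward-genetics screen in which a whole
genome is digested with the blunt-cutting restriction enzymes DraI
(TTT^AAA) and AanI (TTA^TAA) in two separate reactions, the pooled
fragments are cloned in both orientations into an expression vector, and
the resulting library is transduced into cultured cells.  Selection (weeks
of continuous culture, optionally followed by a cytotoxic anti-FAS
challenge) enriches cells whose insert confers a proliferation or survival
advantage.  The inserts still present after selection are identified by
vector-anchored PCR amplification and 300 bp paired-end sequencing: each
amplicon begins with vector sequence whose first 20 bases are the PCR
primer, followed by the genomic insert.  Read counts over an insert's
genomic interval serve as a surrogate for the number of cells carrying that
insert.

The analysis pipeline turns mapped reads into hit calls in method order:

1. **readprep** — a read is *library-derived* when its prefix matches a
   vector flank within a mismatch budget; reads matching the forward-primer
   flank are *directional* and orient the insert.
2. **insert_calling** — per-sample read-enriched intervals are called
   against a global background, merged within 25 bp, and unioned across all
   samples into an insert catalogue with stable coordinate-derived ids.
3. **quantify** — reads are counted per catalogue insert per sample
   (any-overlap semantics), normalised to reads per million mapped (RPM),
   and an insert is *present* when ≥ 10 raw reads map to it.
4. **integrate** — an insert is *selected* in a condition when present in
   ≥ 3 independent replicates and supported by ≥ 1 directional read;
   *high-confidence* when a DraI/AanI cut site lies within 100 bp and it
   has directional support.  Enrichment is scored by potentiation (mean
   RPM in the selected condition over mean RPM at day 0, as a percent) and
   by the challenge:culture abundance ratio.
5. **annotate** — nearest-feature distances against a gene annotation
   (gene/exon/derived-intron space), promoter windows, intergenic by
   elimination, biotype of the nearest gene, and tallies against arbitrary
   user feature sets.
6. **covstats** — diversity statistics: the fraction of fixed 1 kb genome
   bins containing ≥ 1 read (*bin fill*), and the *fingerprint curve*
   (cumulative read fraction over ascending-sorted bins), summarised as the
   read fraction contained in the lowest 97% of bins.  Selection
   concentrates reads into few bins and drives this fraction toward zero.

## Simulator model and assumptions

The simulator emulates the wet-lab workflow with a deliberately transparent
population model so that every pipeline stage can be validated against
known truth.

**Digestion.**  Cut points are every motif occurrence's start plus the
blunt-cut offset (3 for both enzymes), scanned with step 1 so overlapping
occurrences all cut.  Each enzyme digests separately (fragments of one
digest tile the genome exactly) and the two digests are pooled at equal
representation.  Hybrid fragments with mixed DraI/AanI ends do not exist,
matching separate-reaction digestion.

**Library.**  Fragments inside a size window are retained; each yields a
sense and an antisense insert (`orientations="both"`, the cloning default)
with equimolar composition.  The default window [132, 8293] bp is the
observed insert size range of screens of this design.

**Selection dynamics.**  Transduction draws one integration per cell,
multinomially over the library (a Poisson co-occupancy switch exists for
MOI > 1 co-transduction, default off so per-insert effects stay clean).
Growth between subcultures is deterministic exponential at per-insert rate
`ln(2)/doubling_time · (1 + fitness_growth)`; each subculture dilutes the
population multinomially back to the census.  This bulk
growth-plus-dilution model matches a subculture-every-2–3-days regime and
keeps runtimes at desk scale while preserving the stochastic lineage loss
that drives diversity reduction.

**Challenge bottleneck.**  Per-cell death under the cytotoxic agent is
modelled as a constant-hazard process.  Measured survival fractions
(defaults 0.628 for resistant inserts vs 0.025 for neutral cells) refer to
a 22 h reference exposure; over a challenge of duration `d` the per-cell
survival probability is `p ** (d / 22 h)`.  Survivors are drawn per insert
from a binomial, then regrow for the challenge duration.  With the default
96 h challenge this reproduces the observed endpoint that unprotected
cultures do not survive selection while resistant inserts dominate; a
single application of the 22 h figure would understate a 96 h exposure by
orders of magnitude.

**Fitness truth model.**  `assign_fitness` plants growth hits (default
effect `26.3/19.1 − 1 ≈ 0.377`, i.e. doubling time 19.1 h vs the neutral
26.3 h) and survival hits on distinct fragments.  The default mode is
*nested*: survival hits also receive the growth effect.  The screen is
serial — the challenge is applied to the day-47 culture — so an insert can
only be observable at the challenge if it persisted through weeks of
competitive growth; under strictly disjoint effects, growth hits sweep by
`exp(ln2·24·47·(1/19.1 − 1/26.3)) ≈ 7×10^4`-fold and growth-neutral
survival hits are diluted to extinction before the challenge is ever
applied.  Nesting also reflects the screen's own working hypothesis that
challenge resistance contributes to selection by continuous culture.  A
`disjoint` mode is available for studying exactly that failure mode.

**Sequencing.**  Every amplicon is `flank_fwd + insert + flank_rev`; R1
reads the 5′ end (so it carries forward-primer-derived vector sequence and
is flagged directional), R2 the reverse-complemented 3′ end.  The vector
flanks are synthetic 60-mers whose first 20 bases are the two PCR primers —
only the primer-derived prefix matters for validation logic.  Per-sample
depth is `reads_per_cell ×` harvested cells, drawn multinomially over
inserts by abundance.  Errors are iid substitutions only, keeping truth
alignment spans exact; indels, chimeras and PCR amplification bias are not
modelled.  Reads are emitted as truth alignments (and optionally FASTQ);
short-read mapping itself is an external step.

## What the fixtures emulate — and what they do not

`make_fixture` builds complete seeded screens.  The `screen` profile is the
benchmark: a two-chromosome 3 Mb random genome at natural motif density
(~520 retained fragments → ~1000 inserts), insert window [132, 2000] bp,
4 replicates, 200 000-cell census, the 47-day regime, 20 growth + 20
survival hits at the default effect sizes, and 0.125 read pairs per
harvested cell (~25 000 pairs per sample, ~48 reads per insert at day 0 —
comfortably above the 10-read presence rule).  The 2 kb insert cap keeps
most inserts fully covered by 300 bp paired-end reads from both amplicon
ends; larger inserts are represented in real data but their interiors are
invisible to end-anchored amplicon sequencing, so their called intervals
are end blocks rather than full spans.  The `tiny` profile (200 kb,
motif-enriched) is a smoke-test scale used for FASTQ-level tests.

Consequences for interpretation: passing tests demonstrate the pipeline's
interval arithmetic, counting, intersection and scoring logic, and recovery
of planted effects under this population model.  They do not demonstrate
robustness to mapping artefacts, repeat sequence, PCR bias, indel errors,
co-occupancy deconvolution, or effect-size continua — none of which the
generator emulates.

## Parameters that matter

| parameter | default | units | role |
|---|---|---|---|
| `merge_distance` | 25 | bp | intervals closer than this derive from one cloned fragment |
| `presence_min` | 10 | reads | raw-count presence rule (applies to raw counts, not RPM) |
| `min_replicates` | 3 | replicates | selection requires presence in this many independent replicates |
| `restriction_max` | 100 | bp | max cut-site distance for high confidence |
| `proximity_gene` | 100 | bp | gene/exon/intron proximity window |
| `proximity_promoter` | 1000 | bp | promoter window (outside the gene window) |
| `bin_size` | 1000 | bp | diversity-statistic bin width |
| `probe_bin_fraction` | 0.97 | — | fingerprint probe (read fraction in the lowest 97% of bins) |
| `min_coverage`, `fold_over_background`, `min_length` | 5, 5, 50 | reads, ×, bp | enrichment-interval caller thresholds |
| `moi` | 3.7 | constructs/cell | transduction multiplicity |
| `days`, `subculture_interval_days` | 47, 2.5 | days | culture schedule |
| `doubling_time_neutral_h` | 26.3 | h | neutral growth rate |
| `growth_effect` | 0.377 | — | rate multiplier − 1 (hit doubling 19.1 h) |
| `survival_effect` / `survival_neutral` | 0.628 / 0.025 | per 22 h | challenge survival fractions |
| `challenge_duration_h` / `reference_h` | 96 / 22 | h | challenge exposure vs measurement window |

## Numerical and design choices

* **Coordinates** are 0-based half-open everywhere; GTF input is converted
  at the boundary (a verified bijection).  Restriction cut points are
  inter-base boundaries: a cut inside an interval has distance 0, otherwise
  the gap to the nearer interval edge.
* **Enrichment calling** replaces a ChIP-seq-style peak model with a
  threshold caller (`max(min_coverage, fold × λ)` against the global
  background λ = counted bases / genome length): amplicon coverage of
  clonal inserts is block-like with sharp edges, and the thresholds are
  explicit config rather than model internals.  Empty output is legal.
* **Catalogue semantics**: per-sample interval sets are unioned (not
  intersected) and merged; presence per sample is decided downstream by
  counting.  Replicate intersection then reduces to exact, order-free
  presence counting per insert id; a BED-space multi-intersection
  (depth-partition) mode exists for externally supplied interval sets.
* **Counting** is strand-blind and any-overlap; because catalogue intervals
  are disjoint, a read straddling a gap may count toward two inserts.
* **Fingerprint** assigns each read to the bin containing its start (a
  partition, so fractions sum to 1); bin fill uses any-overlap (an
  occupancy question).  The final partial bin of each sequence counts as a
  bin.
* **Orientation calling** requires a 2:1 majority of directional-read
  votes; ties and vote-free inserts are `ambiguous`.  Directional support
  for hit calling is a separate, weaker criterion (≥ 1 directional read).
* **Undefined scores** (zero baseline) are NaN sentinels, excluded from
  summaries — a pseudocount would fabricate enrichment for inserts absent
  at transduction, which genuinely occur under multinomial sampling.
* **Leave-one-replicate-out** recomputation of group means is generalised
  to any replicate, for symmetric, auditable outlier handling.
* **Flank matching** is prefix-anchored Hamming comparison with a
  2-mismatch budget over the 60-mer flank (exact matching would discard
  true library reads carrying sequencing errors); indel-tolerant matching
  is out of scope.  Quality trimming: sliding window of 4, mean Q ≥ 20,
  minimum kept genomic length 30.
* **Secondary/supplementary/unmapped** SAM records are skipped and counted;
  reads vote once.
* **Determinism**: all simulator randomness flows from one seed through
  per-replicate/per-sample substreams; fixed seed + config ⇒ byte-identical
  outputs (tested).

## Known limitations

* End-anchored amplicon reads cannot resolve the interiors of inserts
  longer than twice the usable read length; interval recovery is exact only
  below ~500 bp inserts (see fixture design above).
* When both orientations of a fragment are present in comparable abundance
  (e.g. pre-selection samples), orientation calls for that interval are
  legitimately ambiguous; orientation accuracy is asserted on
  single-orientation libraries.
* At fixture scale the day-0 samples saturate the small genome, so called
  intervals there can span several adjacent fragments; hit-level
  conclusions are unaffected because selected intervals are matched to
  truth by overlap.
* No statistical significance testing of enrichment is performed; the
  selection rule is the replicate-support criterion.
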