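# Methods

## Model

An M2 plant from EMS-mutagenised seed of a homozygous inbred carries a
private set of heterozygous transition SNPs (G>A / C>T). After selfing,
an M3 offspring inherits two independent gametes from that plant. Writing
the homolog label of gamete *g* at position *x* as a binary function that
toggles at each of the gamete's crossovers, marker zygosity in the
offspring is the XOR of the two labels: heterozygous exactly where the
gametes disagree. Consequently **every crossover in either gamete toggles
zygosity**, and crossovers are countable as het ↔ hom switches along each
chromosome. Two crossovers falling in the same inter-marker interval
(one per gamete, or a close double) cancel and are invisible at marker
resolution; the phase of the EMS mutations never enters, because only
label *equality* matters.

## Marker-map construction

Stage order is fixed: confidence filter → EMS-transition filter →
background subtraction → informative selection → introgression mask →
thinning; each stage's output is a subset of its input and per-stage counts
are logged.

- Confidence: QUAL ≥ 30; total depth < 100 (strict); alt reads ≥ 3;
  depth ≥ 10 for heterozygous calls, ≥ 3 for homozygous. All lower bounds
  inclusive. Missing DP/AD with the corresponding filter active is a
  configuration error, not a silent pass.
- EMS transitions: (ref, alt) ∈ {(G,A), (C,T)} exactly as called against
  the reference; the two pairs already cover both strands, so no further
  complementing.
- Background subtraction removes sites whose (chrom, pos, ref, alt) occurs
  in the untreated line (pre-existing variation). The background stream is
  confidence-filtered with the same thresholds first, treating both variant
  files symmetrically.
- Informative selection keeps sites heterozygous in the M2 whose
  background genotype is homozygous-reference or absent. Absence is read
  as reference: the background is a homozygous inbred sequenced at ~15×,
  so no call means no variant. Homozygous-alternative M2 sites are routed
  to the mutation-frequency statistics, never to the marker map.
- Masking uses BED (0-based half-open) intervals, merged and sorted;
  internally all coordinates are 1-based and conversion happens only at
  the format boundary.
- Thinning stage 1 is a greedy left-to-right scan per chromosome keeping a
  site only when ≥ `bp_space` (default 10 kb) past the last kept site,
  anchored at the leftmost marker — deterministic, PLINK `--bp-space`
  behaviour. Stage 2, when survivors exceed `thin_count` (default 20 000),
  is a uniform random subsample without replacement, genome-wide rather
  than per chromosome, matching PLINK `--thin-count` semantics; seeded and
  reproducible.

## Window plan

Chromosomes are tiled with tumbling (non-overlapping) windows whose size
depends on relative position, because recombination and hence the signal
density is strongly distal in barley-like genomes. Default scheme: zones
covering fractions 0.15 / 0.15 / 0.40 / 0.15 / 0.15 of the chromosome with
nominal window sizes 14.3 / 28 / 42 / 28 / 14.3 Mbp. Only the distal and
core *averages* (≈ 14.3 and ≈ 42.0 Mbp) are externally constrained; the
five-zone layout with a 28 Mbp intermediate band is this package's
reconstruction, and the zone table is exposed in configuration. Within a
zone, windows are laid left to right; a remainder shorter than half the
nominal size merges into the previous window, otherwise it stands as the
final window. A chromosome shorter than the smallest window becomes a
single window with a warning. The realised zone means over the bundled
barley-scale chromosome lengths are 14.33 Mbp (distal) and 42.64 Mbp
(core).

## Crossover calling

- Collapse: HOM_REF and HOM_ALT both become HOM — a crossover toggles
  zygosity, not allele identity. Calls below the per-coverage-class
  minimum depth (2 for 2× samples, 4 for 4×; interpreted as a minimum
  total depth and exposed in config) and missing calls are dropped.
- Window vote: the weighted median of the binary-coded states, computed in
  closed form as HET iff w_het·n_het ≥ w_hom·n_hom. Defaults w_het = 1.5,
  w_hom = 1. Ties resolve to HET: heterozygosity needs two informative
  reads where homozygosity needs one, so residual doubt should favour the
  under-observed state. Raising w_het can only turn windows HOM → HET
  (monotone), and a per-sample override (w_het = 3) handles unusually
  noisy libraries.
- Empty windows inherit the preceding non-empty state (leading empties
  take the first non-empty state): a marker-poor pericentromeric window
  with no data is not evidence of a switch. A chromosome with zero
  retained calls yields a NO_CALL segment excluded from counting.
- Boundary refinement: merged segments are window-granular, but crossover
  resolution should be bounded by marker spacing, not window size. Each
  boundary is therefore moved to the split minimising observed-state
  mismatches against the two segment states, over the raw calls in the two
  windows abutting the boundary; ties resolve to the split nearest the
  original window edge, then leftmost; the boundary lands midway between
  the two flanking calls. Refinement never creates or destroys segments.
- Double-CO filter: an internal segment with fewer than `min_support`
  (default 4) raw calls of its own state is deleted and its two same-state
  neighbours merged, removing two putative crossovers. Applied
  iteratively, lowest support first, ties leftmost, until stable —
  deterministic and always removing the weakest evidence first. Support
  counts raw calls, not windows. Terminal segments are exempt: they imply
  a single crossover, not a double.
- Events: one per remaining het ↔ hom boundary, reported as the two
  retained markers flanking the refined boundary (no retained marker lies
  strictly inside) plus the interval midpoint. A widened *support*
  interval — from the last call matching the left segment's state to the
  first call matching the right's — is also reported; with asymmetric
  noise (observed HET implies true HET when the read error is negligible)
  it is the tightest interval the evidence can actually guarantee to
  bracket the switch.
- Adjusted fraction: the share of raw calls whose state the smoothing
  overrode; undefined (reported missing) with zero calls. At realistic
  read error it is substantially higher at 2× than 4× coverage, which is
  the practical argument that 2× plus smoothing suffices.

## Summaries

Per-individual totals (mean, sample SD, median), per-chromosome totals,
and the distribution of per-chromosome counts, whose invariants (Σ k·n_k =
total events; Σ n_k = individuals × chromosomes) are enforced in tests.
The landscape profile bins event midpoints into 50 equal fractions (2%) of
physical chromosome length, clamping a midpoint exactly at the end into
the last bin; the midpoint is the unbiased anchor for an interval-valued
call. Mutation spacing is genome length / (SNP count × class fraction)
over a 4.3 Gb genome, reported both exactly and rounded to integer kb/Mb.
GECN segregation for g effective cells: per induced SNP the homozygous
mutant frequency is 1/(4g), heterozygous 1/(2g), wild type (4g−3)/(4g) —
reduced ratios (4g−3):2:1 and (4g−1):1, recovering 1:2:1 at g = 1 and
21:2:1 / 23:1 at g = 6.

## Simulator

What it emulates: a ~20 000-marker map uniform per bp over seven
barley-scale chromosomes (Morex-V2-like lengths, ~4.6 Gb total); per
gamete per chromosome a Poisson(1.4) crossover count, clamped to ≥ 1 when
the obligate-crossover flag is set (wild-type preset; the mutant preset
halves the mean and drops the obligation, emulating a mismatch-repair
mutant); crossover positions i.i.d. from 0.45·Beta(2,8) + 0.45·Beta(8,2) +
0.10·Uniform over relative position, reproducing distal enrichment and a
depleted pericentromere (the mixture parameters are simulator choices, not
measured values); observation at Poisson(λ) depth with Binomial(d, ½) alt
reads at true-het sites and each read flipped with probability ε (default
0.002) — errors flip the sampled allele rather than introducing third
alleles, because the pipeline is biallelic and call-level noise is what
matters. Depth 0 is MISSING; 0 or d alt reads read as homozygous, anything
else heterozygous, so a single read can never reveal heterozygosity.

What it does not model: crossover interference, chromatid-level (tetrad)
structure, segregation distortion, mismapping hotspots, or read sequences.
Passing end-to-end tests therefore demonstrates correct recovery of the
zygosity-switch signal under idealised independent noise, not performance
on real libraries.

A structural limit worth stating plainly: a window-median smoother cannot
see a true segment much shorter than the local window (28–42 Mbp in mid-
chromosome zones). Under the wild-type preset, whose obligate crossovers
cluster distally, a noticeable minority of chromosomes contain such short
segments, so simulated per-chromosome recovery plateaus around 70–90%
rather than approaching 100%; the misses are always under-calls of close
double crossovers. Shrinking windows would raise resolution but admit the
low-coverage noise the windows exist to suppress.

## Numerical and interface choices

- Problem sizes in the test suite: cohorts of 12–25 individuals at 20 000
  markers for end-to-end checks, smaller cohorts for CLI round trips —
  the full pipeline on a 25-individual cohort runs in seconds.
- Determinism: every stochastic step takes a NumPy `Generator` or integer
  seed; identical seeds give byte-identical marker maps, cohorts and
  thinning output. CLI runs write a manifest (config hash, seed, input
  checksums).
- Multi-allelic records and indels are skipped with logged counts (the
  marker set is biallelic EMS SNPs by construction); unsorted inputs are
  fatal rather than silently reordered.
- Weighted-median correctness is pinned to an independent oracle (integer
  copy expansion + upper median) over all call counts ≤ 20 under both
  weight sets, including the tie rule.
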