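# selfco

Counting and locating meiotic crossovers in the selfed progeny of a
homozygous inbred line, using low-level EMS-induced heterozygous mutations
as genetic markers and shallow (2–4×) whole-genome sequencing as the
readout.

## The problem

Comparing recombination between near-identical lines — a mutant and its
wild-type parent, or a treatment and a control — is awkward with classical
genetic mapping, which needs a polymorphic F1 hybrid. An alternative:
mutagenise seed with EMS, which scatters thousands of heterozygous G>A /
C>T transitions through an otherwise homozygous genome of a single M2
plant. When that plant selfs, every crossover carried by either gamete
toggles marker zygosity (heterozygous ↔ homozygous) along the chromosome of
an M3 offspring, so crossovers can be counted directly as zygosity
switches — no cross, no hybrid, no genetic map.

The catch is coverage: at 2× depth a heterozygous call needs at least two
reads, one per allele, so heterozygosity is systematically under-observed
and the raw zygosity track is noisy. `selfco` implements the full analysis:

1. **Marker map** (`m2_reference`): from the deep-sequenced M2 and an
   untreated background line, keep high-confidence SNPs (QUAL ≥ 30, depth
   ≥ 3 hom / ≥ 10 het, alt reads ≥ 3, total depth < 100), restrict to EMS
   transitions heterozygous in the M2 and absent/homozygous-reference in
   the background, drop introgression-masked intervals, then thin to one
   marker per 10 kb and at most 20 000 markers genome-wide (PLINK
   `--bp-space` / `--thin-count` semantics).
2. **Window plan** (`window_plan`): tile each chromosome with tumbling
   windows sized by position — ~14.3 Mbp in the recombinogenic distal 15%,
   ~28 Mbp intermediate, ~42 Mbp in the crossover-poor pericentromeric
   core.
3. **Crossover calling** (`co_caller`): per window the smoothed state is
   the *weighted median* of the collapsed HOM/HET calls, with w_het = 1.5
   (w_hom = 1; ties → HET) to offset het under-detection, raisable to 3 for
   noisy samples. Same-state windows merge into segments, each boundary is
   refined to marker resolution by a minimum-mismatch changepoint search,
   internal segments with < 4 supporting calls are deleted (unsupported
   double crossovers), and one crossover event is emitted per remaining
   het ↔ hom boundary as a flanking-marker interval with midpoint.
4. **Summaries** (`summaries`): per-individual and per-chromosome counts,
   the count distribution over chromosomes, crossover landscape in 2%
   physical-length bins, mean mutation spacing, and the segregation ratios
   expected from the genetically effective cell number (GECN) of the
   mutagenised embryo: with g cells, per induced SNP the M2 population
   segregates (4g−3) WT : 2 het : 1 homozygous mutant — for barley's g = 6
   that is 21:2:1, i.e. 23:1 non-mutant : mutant.
5. **Simulator** (`simulator`): synthetic meiosis (Poisson crossover counts
   per gamete, telomere-skewed position mixture, obligate-CO option),
   selfing of two independent gametes into a zygosity mosaic with known
   truth, and shallow-read observation (Poisson depth, binomial allele
   sampling, optional per-read error), so the whole pipeline is testable
   without any sequencing data.

## Worked example

A small synthetic cohort (5 individuals, 5 000 markers, error-free 4×),
called and summarised entirely from the command line:

```
$ selfco simulate --n-individuals 5 --n-markers 5000 --depth 4 --error 0 \
      --seed 42 --out-dir sim
simulated 5 individuals at 4.0x -> sim

$ selfco call --vcf sim/progeny.vcf --markers sim/markers.tsv \
      --chrom-table sim/chromosomes.tsv --sample-sheet sim/samples.tsv \
      --out-dir calls
called 98 crossover events over 5 samples -> calls

$ selfco summarize --events calls/events.tsv \
      --chrom-table sim/chromosomes.tsv --out-dir summary
mean CO per individual: 19.60 ± 2.3 (median 18)
```

The wild-type preset draws max(Poisson(1.4), 1) crossovers per gamete per
chromosome; over 7 chromosomes and two gametes that is ≈ 20–23 expected
zygosity switches per plant, and the pipeline calls 19.6 ± 2.3 here — the
small deficit is real: switches flanking segments shorter than one smoothing
window are invisible to a window-median smoother. `calls/events.tsv` lists
each crossover as sample, chromosome, flanking-marker interval and
midpoint; `calls/adjusted_fraction.tsv` reports the fraction of raw calls
the smoothing overrode (higher at 2× than at 4×); `summary/` holds the
count distribution, per-2%-bin landscape and plots.

The marker-map stage runs the same way from VCFs:

```
$ selfco build-markers --m2-vcf m2.vcf --m2-sample M2 \
      --background-vcf wt.vcf --background-sample WT \
      --mask-bed introgressions.bed --out markers.tsv
```

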