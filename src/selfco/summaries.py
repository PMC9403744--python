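"""Descriptive summaries of called crossovers and mutagenesis arithmetic.

Covers per-individual and per-chromosome crossover counts, the distribution
of counts over chromosomes, the recombination landscape binned into 2%
intervals of physical chromosome length, mean spacing between induced
mutations, and the segregation ratios expected from the genetically
effective cell number (GECN) of the mutagenised embryo.
"""
from __future__ import annotations

import json
import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .co_caller import COEvent
from .variant_io import ChromTable

BARLEY_GENOME_BP = 4_300_000_000


@dataclass
class COSummary:
    """Crossover count summaries over individuals and chromosomes."""

    per_individual: dict[str, int]
    per_chromosome: dict[str, int]
    distribution: dict[int, int]  # k -> number of chromosomes with exactly k COs
    mean: float
    sd: float
    median: float

    @property
    def total(self) -> int:
        return sum(self.per_individual.values())

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump({
                "per_individual": self.per_individual,
                "per_chromosome": self.per_chromosome,
                "distribution": {str(k): v for k, v in sorted(self.distribution.items())},
                "mean": self.mean, "sd": self.sd, "median": self.median,
                "total": self.total,
            }, fh, indent=2)


def summarize(events: Iterable[COEvent], n_individuals: int,
              chroms: ChromTable,
              samples: Sequence[str] | None = None) -> COSummary:
    """Aggregate events into a :class:`COSummary`.

    ``n_individuals`` must be supplied (individuals with zero events still
    count).  ``samples`` optionally fixes the individual labels; otherwise
    they are taken from the events plus anonymous zero-count entries.
    The sd is the sample standard deviation of per-individual totals.
    """
    events = list(events)
    per_ind: Counter[str] = Counter()
    per_chrom_ind: Counter[tuple[str, str]] = Counter()
    for e in events:
        per_ind[e.sample] += 1
        per_chrom_ind[(e.sample, e.chrom)] += 1
    if samples is None:
        samples = sorted(per_ind)
        samples += [f"_zero_{i}" for i in range(n_individuals - len(samples))]
    if len(samples) != n_individuals:
        raise ValueError("sample list does not match n_individuals")
    totals = np.array([per_ind.get(s, 0) for s in samples], dtype=float)
    per_chrom = {c: sum(per_chrom_ind.get((s, c), 0) for s in samples)
                 for c in chroms.names}
    dist: Counter[int] = Counter()
    for s in samples:
        for c in chroms.names:
            dist[per_chrom_ind.get((s, c), 0)] += 1
    sd = float(totals.std(ddof=1)) if len(totals) > 1 else 0.0
    return COSummary(
        per_individual={s: int(per_ind.get(s, 0)) for s in samples},
        per_chromosome=per_chrom,
        distribution=dict(dist),
        mean=float(totals.mean()),
        sd=sd,
        median=float(np.median(totals)),
    )


def summary_from_distribution(distribution: Mapping[int, int],
                              n_individuals: int) -> dict[str, float]:
    """Arithmetic on a printed per-chromosome CO-count distribution.

    Returns the total chromosome count, total crossovers, and the mean
    number of crossovers per individual.
    """
    n_chrom = sum(distribution.values())
    total = sum(k * v for k, v in distribution.items())
    return {
        "n_chromosomes": float(n_chrom),
        "total_co": float(total),
        "mean_per_individual": total / n_individuals,
    }


@dataclass
class BinProfile:
    """Mean crossover count per 2%-of-length bin along each chromosome."""

    n_bins: int
    counts: dict[str, np.ndarray] = field(default_factory=dict)  # chrom -> bin counts
    n_individuals: int = 1

    @property
    def total(self) -> int:
        return int(sum(c.sum() for c in self.counts.values()))

    def mean_per_individual(self, chrom: str | None = None) -> np.ndarray:
        """Per-bin mean count per individual; averaged over chromosomes when
        ``chrom`` is None."""
        if chrom is not None:
            return self.counts[chrom] / self.n_individuals
        stacked = np.stack(list(self.counts.values()))
        return stacked.mean(axis=0) / self.n_individuals

    def to_frame(self) -> pd.DataFrame:
        rows = [(c, i, int(n)) for c, arr in self.counts.items()
                for i, n in enumerate(arr)]
        return pd.DataFrame(rows, columns=["chrom", "bin", "count"])


def bin_events(events: Iterable[COEvent], chroms: ChromTable,
               n_bins: int = 50, n_individuals: int = 1) -> BinProfile:
    """Bin event midpoints into ``n_bins`` equal fractions of chromosome
    length (bin = floor(n_bins * midpoint / length), clamped to the last
    bin).  Each event lands in exactly one bin."""
    profile = BinProfile(n_bins=n_bins,
                         counts={c: np.zeros(n_bins, dtype=np.int64) for c in chroms.names},
                         n_individuals=n_individuals)
    for e in events:
        length = chroms.length(e.chrom)
        b = min(int(n_bins * e.midpoint / length), n_bins - 1)
        profile.counts[e.chrom][b] += 1
    return profile


def mutation_spacing(n_snps: int, class_fraction: float,
                     genome_len: int = BARLEY_GENOME_BP) -> dict[str, float | str]:
    """Mean spacing between mutations of one zygosity class.

    ``class_fraction`` is the fraction of the ``n_snps`` belonging to the
    class (e.g. 0.989 heterozygous).  Returns the exact spacing in bp plus
    a human-readable value rounded to integer kb (or Mb when >= 1 Mb),
    matching the reporting precision of mutagenesis studies.
    """
    if not 0 < class_fraction <= 1:
        raise ValueError("class_fraction must be in (0, 1]")
    spacing = genome_len / (n_snps * class_fraction)
    if spacing >= 1_000_000:
        label, rounded = "Mb", round(spacing / 1_000_000)
    else:
        label, rounded = "kb", round(spacing / 1_000)
    return {"spacing_bp": spacing, "rounded": rounded, "unit": label,
            "text": f"1 every {rounded} {label}"}


@dataclass(frozen=True)
class GECNModel:
    """Genetically effective cell number of the mutagenised embryo.

    ``g`` independent meristem cells found the germ line; an EMS hit occurs
    in one of them, so only 1/g of the M2 seed descends from the mutated
    lineage and segregates 1:2:1 within it.
    """

    g: int = 6

    def __post_init__(self) -> None:
        if self.g < 1 or int(self.g) != self.g:
            raise ValueError("g must be a positive integer")


def gecn_segregation(model: GECNModel | int = GECNModel()) -> dict[str, tuple[int, ...]]:
    """Expected M2 segregation per induced SNP under the GECN model.

    Frequencies: homozygous mutant 1/(4g), heterozygous 1/(2g), wild type
    (4g-3)/(4g).  Returned as reduced integer ratios: ``wt_het_hom`` (e.g.
    21:2:1 for g=6) and ``non_mut_vs_mut`` ((4g-1):1, e.g. 23:1).
    """
    g = model.g if isinstance(model, GECNModel) else GECNModel(model).g
    # scale frequencies by 4g: wt 4g-3, het 2, hom 1
    terms = (4 * g - 3, 2, 1)
    d = math.gcd(math.gcd(terms[0], terms[1]), terms[2])
    wt_het_hom = tuple(t // d for t in terms)
    nm = (4 * g - 1, 1)
    d2 = math.gcd(*nm)
    return {
        "frequencies": (terms[0] / (4 * g), 2 / (4 * g), 1 / (4 * g)),
        "wt_het_hom": wt_het_hom,
        "non_mut_vs_mut": (nm[0] // d2, nm[1] // d2),
    }


def events_to_frame(events: Iterable[COEvent]) -> pd.DataFrame:
    rows = [(e.sample, e.chrom, e.left, e.right, e.midpoint,
             e.left_support, e.right_support) for e in events]
    return pd.DataFrame(rows, columns=["sample", "chrom", "left", "right",
                                       "midpoint", "left_support", "right_support"])
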