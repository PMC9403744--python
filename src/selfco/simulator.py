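"""Synthetic meiosis and low-coverage sequencing generator.

Emulates the structure of the real experiment so the whole pipeline is
testable without any download: ~20,000 heterozygous EMS markers spread over
seven barley-scale chromosomes (~4.3-4.6 Gb), selfed M3 progeny whose
zygosity mosaics derive from two independently simulated gametes with known
crossover positions, and shallow (2x / 4x) read sampling with optional
per-read error.

Marker zygosity in an M3 individual depends only on whether its two gametes
carry the same homolog label at that position — each crossover in either
gamete toggles the label, hence the zygosity.  The phase of the EMS
mutations across markers therefore never needs to be modelled.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

from .co_caller import SegState, ZygosityCall
from .variant_io import ChromTable, GenotypeState, MarkerMap

#: Barley Morex-V2-like chromosome lengths (bp), 7 chromosomes, ~4.6 Gb.
BARLEY_CHROMOSOMES: tuple[tuple[str, int], ...] = (
    ("chr1H", 558_535_432),
    ("chr2H", 768_075_024),
    ("chr3H", 699_711_114),
    ("chr4H", 647_060_158),
    ("chr5H", 670_030_160),
    ("chr6H", 583_380_513),
    ("chr7H", 657_224_461),
)


def default_chrom_table() -> ChromTable:
    return ChromTable(BARLEY_CHROMOSOMES)


@dataclass(frozen=True)
class COModel:
    """Crossover process per gamete per chromosome.

    ``mean_co`` is the Poisson mean; with ``obligate_co`` the draw is
    clamped to at least one (chiasmata ensure proper disjunction).
    Positions follow a telomere-skewed mixture over relative position:
    ``pi_tel`` * Beta(2,8) + ``pi_tel`` * Beta(8,2) + ``pi_uni`` * U(0,1),
    reproducing distal CO enrichment and a depleted pericentromere.
    """

    mean_co: float = 1.4
    obligate_co: bool = True
    pi_tel: float = 0.45
    pi_uni: float = 0.10
    beta_a: float = 2.0
    beta_b: float = 8.0

    def __post_init__(self) -> None:
        if self.mean_co < 0:
            raise ValueError("mean_co must be >= 0")
        if abs(2 * self.pi_tel + self.pi_uni - 1.0) > 1e-9:
            raise ValueError("mixture weights must sum to 1")

    def position_cdf(self, x: np.ndarray) -> np.ndarray:
        """CDF of the relative-position mixture (for distribution checks)."""
        from scipy.stats import beta as beta_dist
        return (self.pi_tel * beta_dist.cdf(x, self.beta_a, self.beta_b)
                + self.pi_tel * beta_dist.cdf(x, self.beta_b, self.beta_a)
                + self.pi_uni * np.clip(x, 0, 1))


#: Presets: wild type (~20 COs per plant over 7 chromosomes x 2 gametes) and
#: a CO-reduced mutant emulating a mismatch-repair (*mlh3*-like) background.
PRESETS: dict[str, COModel] = {
    "wt": COModel(mean_co=1.4, obligate_co=True),
    "mutant": COModel(mean_co=0.7, obligate_co=False),
}


@dataclass(frozen=True)
class SeqModel:
    """Shallow sequencing: depth ~ Poisson(lambda), per-read error epsilon."""

    depth: float = 2.0
    error: float = 0.002

    def __post_init__(self) -> None:
        if self.depth <= 0:
            raise ValueError("depth must be > 0")
        if not 0 <= self.error < 0.5:
            raise ValueError("error must be in [0, 0.5)")


@dataclass
class ChromTruth:
    """Ground truth for one chromosome of one individual."""

    gamete_cos: tuple[list[int], list[int]]
    switch_positions: list[int]  # bp positions where net zygosity flips
    zygosity: np.ndarray  # bool, HET at each marker

    def marker_switch_count(self) -> int:
        """Switches observable at marker resolution (colliding crossovers in
        one inter-marker interval cancel pairwise)."""
        z = self.zygosity
        return int(np.sum(z[1:] != z[:-1])) if len(z) > 1 else 0


@dataclass
class SimTruth:
    """Per-individual, per-chromosome crossover truth."""

    individuals: dict[str, dict[str, ChromTruth]] = field(default_factory=dict)

    def switch_count(self, sample: str, chrom: str) -> int:
        return self.individuals[sample][chrom].marker_switch_count()


def simulate_markers(n: int, chroms: ChromTable, rng: np.random.Generator,
                     ) -> MarkerMap:
    """Draw ``n`` unique marker positions uniformly per bp across the genome
    (counts per chromosome proportional to length), alleles G>A or C>T."""
    if n < 1:
        raise ValueError("n must be >= 1")
    lengths = np.array([l for _, l in chroms.items()], dtype=np.float64)
    names = [c for c, _ in chroms.items()]
    probs = lengths / lengths.sum()
    records: list[tuple[str, int, str, str]] = []
    counts = rng.multinomial(n, probs)
    for name, length, k in zip(names, lengths.astype(np.int64), counts):
        positions: set[int] = set()
        while len(positions) < k:
            draw = rng.integers(1, length + 1, size=k - len(positions))
            positions.update(int(p) for p in draw)
        for p in sorted(positions):
            if rng.random() < 0.5:
                records.append((name, p, "G", "A"))
            else:
                records.append((name, p, "C", "T"))
    return MarkerMap.from_records(records)


def simulate_gamete(chrom_length: int, model: COModel, rng: np.random.Generator,
                    ) -> tuple[int, list[int]]:
    """One gamete's chromosome: (starting homolog label, sorted CO positions).

    The label toggles after each crossover position.
    """
    k = int(rng.poisson(model.mean_co))
    if model.obligate_co:
        k = max(k, 1)
    rel = _mixture_positions(k, model, rng)
    positions = sorted(int(np.clip(round(x * chrom_length), 1, chrom_length - 1))
                       for x in rel)
    start_label = int(rng.integers(0, 2))
    return start_label, positions


def _mixture_positions(k: int, model: COModel, rng: np.random.Generator) -> np.ndarray:
    if k == 0:
        return np.empty(0)
    comp = rng.choice(3, size=k, p=[model.pi_tel, model.pi_tel, model.pi_uni])
    out = np.empty(k)
    for i, c in enumerate(comp):
        if c == 0:
            out[i] = rng.beta(model.beta_a, model.beta_b)
        elif c == 1:
            out[i] = rng.beta(model.beta_b, model.beta_a)
        else:
            out[i] = rng.random()
    return out


def _labels_at(start: int, cos: Sequence[int], pos: np.ndarray) -> np.ndarray:
    """Homolog label at each marker: start XOR parity of crossovers left of it."""
    toggles = np.searchsorted(np.asarray(cos, dtype=np.int64), pos, side="left")
    return (start + toggles) % 2


def simulate_individual(markers: MarkerMap, model: COModel,
                        rng: np.random.Generator,
                        chroms: ChromTable | None = None) -> dict[str, ChromTruth]:
    """Self the M2: draw two independent gametes per chromosome and derive
    marker zygosity (HET where the gametes' homolog labels differ)."""
    truth: dict[str, ChromTruth] = {}
    for chrom in markers.chroms:
        pos = markers.positions(chrom)
        length = chroms.length(chrom) if chroms is not None else int(pos[-1]) + 1
        s1, co1 = simulate_gamete(length, model, rng)
        s2, co2 = simulate_gamete(length, model, rng)
        zyg = _labels_at(s1, co1, pos) != _labels_at(s2, co2, pos)
        switches = sorted(co1 + co2)  # every CO in either gamete flips zygosity
        truth[chrom] = ChromTruth((list(co1), list(co2)), switches, zyg)
    return truth


def simulate_reads(zygosity: np.ndarray, model: SeqModel,
                   rng: np.random.Generator
                   ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Observe each marker at Poisson depth.

    True HET sites yield Binomial(d, 1/2) alt reads, true HOM sites zero
    (labelled HOM_REF w.l.o.g.); each read then flips allele with
    probability ``error``.  Returns (depth, alt_count, state) arrays with
    state coded 0=HOM_REF, 1=HET, 2=HOM_ALT, 3=MISSING.
    """
    n = len(zygosity)
    depth = rng.poisson(model.depth, size=n)
    alt = np.zeros(n, dtype=np.int64)
    het = np.asarray(zygosity, dtype=bool)
    alt[het] = rng.binomial(depth[het], 0.5)
    if model.error > 0:
        kept = rng.binomial(alt, 1.0 - model.error)
        flipped_in = rng.binomial(depth - alt, model.error)
        alt = kept + flipped_in
    state = np.full(n, 1, dtype=np.int64)
    state[alt == 0] = 0
    state[(alt == depth) & (depth > 0)] = 2
    state[depth == 0] = 3
    return depth, alt, state

_STATE_CODE = {0: GenotypeState.HOM_REF, 1: GenotypeState.HET,
               2: GenotypeState.HOM_ALT, 3: GenotypeState.MISSING}


def observed_calls(markers: MarkerMap, truth: dict[str, ChromTruth],
                   model: SeqModel, rng: np.random.Generator,
                   min_depth: int | None = None,
                   ) -> dict[str, list[ZygosityCall]]:
    """Simulate reads for one individual and return collapsed zygosity calls
    (optionally depth-filtered), ready for the crossover caller."""
    out: dict[str, list[ZygosityCall]] = {}
    for chrom in markers.chroms:
        pos = markers.positions(chrom)
        depth, _alt, state = simulate_reads(truth[chrom].zygosity, model, rng)
        calls = []
        for p, d, s in zip(pos, depth, state):
            if s == 3:
                continue
            if min_depth is not None and d < min_depth:
                continue
            st = SegState.HET if s == 1 else SegState.HOM
            calls.append(ZygosityCall(chrom, int(p), st, int(d)))
        out[chrom] = calls
    return out


@dataclass
class SimulatedDataset:
    markers: MarkerMap
    chroms: ChromTable
    truth: SimTruth
    #: sample -> chrom -> (depth, alt_count, state-code) arrays over markers
    observations: dict[str, dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]]

    @property
    def samples(self) -> list[str]:
        return list(self.observations)

    def calls(self, sample: str, min_depth: int) -> dict[str, list[ZygosityCall]]:
        out: dict[str, list[ZygosityCall]] = {}
        for chrom in self.markers.chroms:
            pos = self.markers.positions(chrom)
            depth, _alt, state = self.observations[sample][chrom]
            calls = []
            for p, d, s in zip(pos, depth, state):
                if s == 3 or d < min_depth:
                    continue
                st = SegState.HET if s == 1 else SegState.HOM
                calls.append(ZygosityCall(chrom, int(p), st, int(d)))
            out[chrom] = calls
        return out


def simulate_dataset(n_individuals: int, chroms: ChromTable | None = None,
                     n_markers: int = 20_000,
                     co_model: COModel | str = "wt",
                     seq_model: SeqModel = SeqModel(),
                     seed: int = 0,
                     sample_prefix: str = "M3") -> SimulatedDataset:
    """Simulate a full progeny cohort: markers, truth and observations."""
    if isinstance(co_model, str):
        co_model = PRESETS[co_model]
    if chroms is None:
        chroms = default_chrom_table()
    rng = np.random.default_rng(seed)
    markers = simulate_markers(n_markers, chroms, rng)
    truth = SimTruth()
    observations: dict[str, dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]] = {}
    for i in range(n_individuals):
        sample = f"{sample_prefix}_{i + 1}"
        ind_truth = simulate_individual(markers, co_model, rng, chroms)
        truth.individuals[sample] = ind_truth
        obs: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom in markers.chroms:
            obs[chrom] = simulate_reads(ind_truth[chrom].zygosity, seq_model, rng)
        observations[sample] = obs
    return SimulatedDataset(markers, chroms, truth, observations)


def write_vcf(dataset: SimulatedDataset, path: str) -> None:
    """Write the observations as an uncompressed multi-sample VCF with
    GT/DP/AD fields at every marker position."""
    header = pysam.VariantHeader()
    for chrom, length in dataset.chroms.items():
        header.contigs.add(chrom, length=length)
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    header.add_line('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">')
    header.add_line('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele depths">')
    samples = dataset.samples
    for s in samples:
        header.add_sample(s)
    gt_map = {0: (0, 0), 1: (0, 1), 2: (1, 1), 3: (None, None)}
    marker_df = dataset.markers.df
    with pysam.VariantFile(path, "w", header=header) as out:
        for chrom in dataset.markers.chroms:
            sub = marker_df[marker_df["chrom"] == chrom]
            obs = {s: dataset.observations[s][chrom] for s in samples}
            for row_i, (_, row) in enumerate(sub.iterrows()):
                rec = out.new_record(contig=chrom, start=int(row["pos"]) - 1,
                                     alleles=(row["ref"], row["alt"]))
                rec.qual = 100
                for s in samples:
                    depth, alt, state = obs[s]
                    d, a, st = int(depth[row_i]), int(alt[row_i]), int(state[row_i])
                    rec.samples[s]["GT"] = gt_map[st]
                    rec.samples[s]["DP"] = d
                    rec.samples[s]["AD"] = (d - a, a)
                out.write(rec)


def write_truth(truth: SimTruth, co_path: str, switch_path: str) -> None:
    """Write gamete crossover positions (TSV) and derived switch positions
    (TSV); both round-trip losslessly via :func:`read_truth`."""
    co_rows = []
    sw_rows = []
    for sample, per_chrom in truth.individuals.items():
        for chrom, t in per_chrom.items():
            for g, cos in enumerate(t.gamete_cos, start=1):
                for p in cos:
                    co_rows.append((sample, chrom, g, p))
            for p in t.switch_positions:
                sw_rows.append((sample, chrom, p))
    pd.DataFrame(co_rows, columns=["sample", "chrom", "gamete", "pos"]).to_csv(
        co_path, sep="\t", index=False)
    pd.DataFrame(sw_rows, columns=["sample", "chrom", "pos"]).to_csv(
        switch_path, sep="\t", index=False)


def read_truth(co_path: str, markers: MarkerMap | None = None) -> SimTruth:
    """Rebuild a :class:`SimTruth` from the gamete crossover TSV.

    Marker-level zygosity is re-derived when ``markers`` is given (labels
    start at 0; only switch structure, not absolute labels, is recoverable,
    which is all downstream checks use).
    """
    df = pd.read_csv(co_path, sep="\t", dtype={"sample": str, "chrom": str})
    truth = SimTruth()
    for (sample, chrom), grp in df.groupby(["sample", "chrom"], sort=False):
        co1 = sorted(int(p) for p in grp.loc[grp["gamete"] == 1, "pos"])
        co2 = sorted(int(p) for p in grp.loc[grp["gamete"] == 2, "pos"])
        if markers is not None:
            pos = markers.positions(chrom)
            zyg = _labels_at(0, co1, pos) != _labels_at(0, co2, pos)
        else:
            zyg = np.empty(0, dtype=bool)
        truth.individuals.setdefault(sample, {})[chrom] = ChromTruth(
            (co1, co2), sorted(co1 + co2), zyg)
    return truth
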