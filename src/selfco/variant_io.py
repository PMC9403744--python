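"""Readers and writers for the standard formats the pipeline touches.

Defines the genotype data model shared by every stage: a :class:`VariantSite`
is one biallelic SNP call with per-sample genotype state, depth and
alt-supporting read count; an :class:`IntervalMask` holds BED regions to
exclude (introgressions); a :class:`ChromTable` is the physical axis; a
:class:`MarkerMap` is the ordered set of heterozygous marker positions the
crossover caller genotypes progeny against.

Coordinate conventions: VCF positions are 1-based inclusive, BED masks are
0-based half-open; every internal coordinate in this package is 1-based bp.
Conversion happens here, at the boundary, and nowhere else.
"""
from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from bisect import bisect_right
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd
import pysam

log = logging.getLogger(__name__)

MARKER_COLUMNS = ["chrom", "pos", "ref", "alt"]


class GenotypeState(enum.Enum):
    """Diploid genotype state of one sample at one biallelic site."""

    HOM_REF = "hom_ref"
    HET = "het"
    HOM_ALT = "hom_alt"
    MISSING = "missing"


@dataclass(frozen=True)
class SampleCall:
    """Per-sample record at a site: genotype state, total depth, alt reads."""

    state: GenotypeState
    depth: int | None = None
    alt_count: int | None = None


@dataclass(frozen=True)
class VariantSite:
    """One biallelic SNP call site.

    ``pos`` is 1-based. ``samples`` maps sample name to its call.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    qual: float | None
    samples: dict[str, SampleCall] = field(default_factory=dict)

    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


def _classify_gt(gt: tuple | None) -> GenotypeState:
    if gt is None or all(a is None for a in gt):
        return GenotypeState.MISSING
    alleles = set(gt)
    if alleles == {0}:
        return GenotypeState.HOM_REF
    if alleles == {1}:
        return GenotypeState.HOM_ALT
    if alleles == {0, 1}:
        return GenotypeState.HET
    return GenotypeState.MISSING  # non-biallelic genotype; caller skips site


def read_variants(path: str, sample_names: Sequence[str] | None = None) -> Iterator[VariantSite]:
    """Stream biallelic SNP sites from a VCF in (chrom, pos) order.

    Multi-allelic records and indels are skipped (counts logged once the
    stream is exhausted).  GT ``0/1``/``1/0`` map to HET, ``0/0`` to HOM_REF,
    ``1/1`` to HOM_ALT, ``./.`` to MISSING.  Alt read counts come from AD
    (index 1) or AO when present.

    Raises ``ValueError`` on an unknown sample name or an unsorted file.
    """
    try:
        vcf = pysam.VariantFile(path)
    except (OSError, ValueError) as exc:
        raise ValueError(f"cannot parse VCF {path!r}: {exc}") from exc
    file_samples = list(vcf.header.samples)
    if sample_names is None:
        sample_names = file_samples
    else:
        missing = [s for s in sample_names if s not in file_samples]
        if missing:
            raise ValueError(f"sample(s) {missing} not present in {path!r}")

    n_multi = 0
    n_indel = 0
    last: tuple[str, int] | None = None
    seen_chroms: set[str] = set()
    for rec in vcf:
        if rec.alts is None or len(rec.alts) != 1:
            n_multi += 1
            continue
        ref, alt = rec.ref, rec.alts[0]
        if len(ref) != 1 or len(alt) != 1:
            n_indel += 1
            continue
        if last is not None:
            if rec.chrom == last[0] and rec.pos < last[1]:
                raise ValueError(f"VCF {path!r} not sorted at {rec.chrom}:{rec.pos}")
            if rec.chrom != last[0] and rec.chrom in seen_chroms:
                raise ValueError(f"VCF {path!r}: chromosome {rec.chrom} interleaved")
        seen_chroms.add(rec.chrom)
        last = (rec.chrom, rec.pos)

        calls: dict[str, SampleCall] = {}
        for name in sample_names:
            samp = rec.samples[name]
            state = _classify_gt(samp.get("GT"))
            depth = samp.get("DP")
            alt_count = None
            ad = samp.get("AD")
            if ad is not None and len(ad) >= 2 and ad[1] is not None:
                alt_count = ad[1]
            else:
                ao = samp.get("AO")
                if ao is not None:
                    alt_count = ao[0] if isinstance(ao, tuple) else ao
            if state is GenotypeState.MISSING and depth is None:
                depth = 0
            calls[name] = SampleCall(state=state, depth=depth, alt_count=alt_count)
        yield VariantSite(rec.chrom, rec.pos, ref, alt, rec.qual, calls)

    if n_multi or n_indel:
        log.info("read_variants(%s): skipped %d multi-allelic and %d indel records",
                 path, n_multi, n_indel)


class IntervalMask:
    """Sorted, merged genomic intervals in 0-based half-open coordinates."""

    def __init__(self, intervals: Iterable[tuple[str, int, int]] = ()):
        per_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, end in intervals:
            if start >= end:
                raise ValueError(f"invalid interval {chrom}:{start}-{end} (start >= end)")
            per_chrom.setdefault(chrom, []).append((int(start), int(end)))
        self._ivals: dict[str, list[tuple[int, int]]] = {
            c: _merge(sorted(v)) for c, v in per_chrom.items()
        }

    @property
    def intervals(self) -> list[tuple[str, int, int]]:
        return [(c, s, e) for c in sorted(self._ivals) for s, e in self._ivals[c]]

    def __len__(self) -> int:
        return sum(len(v) for v in self._ivals.values())

    def contains(self, chrom: str, pos: int) -> bool:
        """True if the 1-based position falls inside a masked interval."""
        ivals = self._ivals.get(chrom)
        if not ivals:
            return False
        zero = pos - 1
        i = bisect_right(ivals, (zero, float("inf"))) - 1
        return i >= 0 and ivals[i][0] <= zero < ivals[i][1]


def _merge(sorted_ivals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[tuple[int, int]] = []
    for s, e in sorted_ivals:
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def read_mask(path: str) -> IntervalMask:
    """Read a BED3 file into an :class:`IntervalMask` (merged, sorted)."""
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: BED line has fewer than 3 columns")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start >= end:
                raise ValueError(f"{path}:{lineno}: start {start} >= end {end}")
            intervals.append((parts[0], start, end))
    return IntervalMask(intervals)


class ChromTable:
    """Ordered chromosome names and physical lengths (bp)."""

    def __init__(self, entries: Iterable[tuple[str, int]]):
        self._names: list[str] = []
        self._lengths: dict[str, int] = {}
        for name, length in entries:
            if name in self._lengths:
                raise ValueError(f"duplicate chromosome name {name!r}")
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length {length}")
            self._names.append(name)
            self._lengths[name] = int(length)

    @property
    def names(self) -> list[str]:
        return list(self._names)

    def length(self, chrom: str) -> int:
        return self._lengths[chrom]

    def items(self) -> list[tuple[str, int]]:
        return [(n, self._lengths[n]) for n in self._names]

    def __len__(self) -> int:
        return len(self._names)

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._lengths

    @classmethod
    def from_tsv(cls, path: str) -> "ChromTable":
        df = pd.read_csv(path, sep="\t")
        if not {"chrom", "length"}.issubset(df.columns):
            raise ValueError(f"{path}: expected columns 'chrom' and 'length'")
        return cls(zip(df["chrom"].astype(str), df["length"].astype(int)))

    def to_tsv(self, path: str) -> None:
        pd.DataFrame(self.items(), columns=["chrom", "length"]).to_csv(
            path, sep="\t", index=False)


class MarkerMap:
    """Ordered, per-chromosome heterozygous marker positions with alleles."""

    def __init__(self, df: pd.DataFrame):
        missing = set(MARKER_COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"marker table missing columns {sorted(missing)}")
        df = df[MARKER_COLUMNS].copy()
        df["pos"] = df["pos"].astype(np.int64)
        # preserve first-appearance chromosome order, sort positions within
        order = {c: i for i, c in enumerate(pd.unique(df["chrom"]))}
        df = df.sort_values(["chrom", "pos"], key=lambda s: s.map(order) if s.name == "chrom" else s)
        df = df.reset_index(drop=True)
        dup = df.duplicated(subset=["chrom", "pos"])
        if dup.any():
            first = df.loc[dup.idxmax()]
            raise ValueError(f"duplicate marker position {first['chrom']}:{first['pos']}")
        self._df = df

    @classmethod
    def from_records(cls, records: Iterable[tuple[str, int, str, str]]) -> "MarkerMap":
        return cls(pd.DataFrame(list(records), columns=MARKER_COLUMNS))

    @property
    def df(self) -> pd.DataFrame:
        return self._df.copy()

    @property
    def chroms(self) -> list[str]:
        return list(pd.unique(self._df["chrom"]))

    def positions(self, chrom: str) -> np.ndarray:
        return self._df.loc[self._df["chrom"] == chrom, "pos"].to_numpy()

    def __len__(self) -> int:
        return len(self._df)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MarkerMap):
            return NotImplemented
        return self._df.equals(other._df)

    def __iter__(self) -> Iterator[tuple[str, int, str, str]]:
        return iter(self._df.itertuples(index=False, name=None))


def write_markers(markers: MarkerMap, path: str) -> None:
    """Write a marker map as TSV with header chrom/pos/ref/alt."""
    markers.df.to_csv(path, sep="\t", index=False)


def read_markers(path: str) -> MarkerMap:
    """Read a marker-map TSV; duplicate (chrom, pos) rows are fatal."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return MarkerMap(df)
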