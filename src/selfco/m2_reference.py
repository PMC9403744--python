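"""Construction of the heterozygous EMS marker map from the M2 parent.

The M2 plant carries EMS-induced mutations, heterozygous at most sites
because only one of several genetically effective embryo cells acquired each
hit.  After stringent confidence filtering, the candidate marker set is the
EMS transition SNPs (G>A / C>T) that are heterozygous in the M2 but absent
or homozygous-reference in the untreated background line, outside any
introgression mask, thinned to an even genome-wide spacing and a fixed
marker count (PLINK ``--bp-space`` / ``--thin-count`` semantics).

Fixed stage order: confidence -> EMS transition -> background subtraction ->
informative selection -> mask -> thinning.  Each stage's output is a subset
of its input.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .variant_io import (GenotypeState, IntervalMask, MarkerMap, VariantSite)

log = logging.getLogger(__name__)

EMS_TRANSITIONS = {("G", "A"), ("C", "T")}


@dataclass(frozen=True)
class FilterThresholds:
    """High-confidence SNP thresholds.

    Retained sites need quality >= ``min_qual``, total depth strictly below
    ``max_total_depth``, alt-supporting reads >= ``min_alt_count``, and depth
    >= ``min_depth_het`` (heterozygous) or >= ``min_depth_hom`` (homozygous).
    """

    min_qual: float = 30.0
    min_depth_hom: int = 3
    min_depth_het: int = 10
    min_alt_count: int = 3
    max_total_depth: int = 100

    def __post_init__(self) -> None:
        if min(self.min_qual, self.min_depth_hom, self.min_depth_het,
               self.min_alt_count, self.max_total_depth) < 0:
            raise ValueError("thresholds must be non-negative")
        if self.min_depth_hom > self.min_depth_het:
            raise ValueError("min_depth_hom must not exceed min_depth_het")


@dataclass(frozen=True)
class ThinningParams:
    """Marker thinning: greedy ``bp_space`` scan, then uniform subsample."""

    bp_space: int = 10_000
    thin_count: int = 20_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.bp_space < 0:
            raise ValueError("bp_space must be >= 0")
        if self.thin_count < 1:
            raise ValueError("thin_count must be >= 1")


def filter_ems_transitions(sites: Iterable[VariantSite]) -> list[VariantSite]:
    """Keep only the canonical EMS transition SNPs G>A and C>T.

    The two pairs already cover both strands of a G:C -> A:T transition as
    called against the reference, so no further complementing is applied.
    """
    return [s for s in sites if (s.ref, s.alt) in EMS_TRANSITIONS]


def filter_confidence(sites: Iterable[VariantSite], sample: str,
                      thresholds: FilterThresholds = FilterThresholds()) -> list[VariantSite]:
    """Keep high-confidence calls for ``sample`` per :class:`FilterThresholds`.

    MISSING calls are dropped.  Sites lacking depth or alt-count annotations
    while the corresponding filter is active are a configuration error.
    """
    t = thresholds
    kept = []
    for site in sites:
        call = site.samples[sample]
        if call.state is GenotypeState.MISSING:
            continue
        if call.depth is None:
            raise ValueError(
                f"site {site.chrom}:{site.pos} has no depth for sample {sample!r}; "
                "depth filters require DP")
        if call.alt_count is None and t.min_alt_count > 0:
            raise ValueError(
                f"site {site.chrom}:{site.pos} has no alt count for sample {sample!r}; "
                "set min_alt_count=0 or provide AD/AO")
        qual = site.qual if site.qual is not None else 0.0
        if qual < t.min_qual:
            continue
        if call.depth >= t.max_total_depth:
            continue
        if call.alt_count is not None and call.alt_count < t.min_alt_count:
            continue
        min_depth = (t.min_depth_het if call.state is GenotypeState.HET
                     else t.min_depth_hom)
        if call.depth < min_depth:
            continue
        kept.append(site)
    return kept


def _check_sorted(sites: Sequence[VariantSite], label: str) -> None:
    last: tuple[str, int] | None = None
    seen: set[str] = set()
    for s in sites:
        if last is not None:
            if s.chrom == last[0] and s.pos < last[1]:
                raise ValueError(f"{label} input not sorted at {s.chrom}:{s.pos}")
            if s.chrom != last[0] and s.chrom in seen:
                raise ValueError(f"{label} input has interleaved chromosome {s.chrom}")
        seen.add(s.chrom)
        last = (s.chrom, s.pos)


def subtract_background(m2_sites: Sequence[VariantSite],
                        background_sites: Iterable[VariantSite]) -> list[VariantSite]:
    """Remove M2 sites whose (chrom, pos, ref, alt) also appears in the background.

    Shared variants are pre-existing differences from the reference genome,
    not EMS hits.  Both inputs must be coordinate-sorted.
    """
    bg = list(background_sites)
    _check_sorted(m2_sites, "subtract_background m2")
    _check_sorted(bg, "subtract_background background")
    bg_keys = {s.key() for s in bg}
    return [s for s in m2_sites if s.key() not in bg_keys]


def select_informative(m2_sites: Iterable[VariantSite], m2_sample: str,
                       background_states: Mapping[tuple[str, int], GenotypeState],
                       ) -> list[VariantSite]:
    """Keep sites heterozygous in the M2 and homozygous-reference (or absent)
    in the background line.

    Absence of a background call is read as homozygous reference: the
    background is a homozygous inbred sequenced deep enough that no call
    means no variant.
    """
    kept = []
    for site in m2_sites:
        if site.samples[m2_sample].state is not GenotypeState.HET:
            continue
        bg = background_states.get((site.chrom, site.pos))
        if bg is None or bg is GenotypeState.HOM_REF:
            kept.append(site)
    return kept


def select_hom_mutations(m2_sites: Iterable[VariantSite], m2_sample: str,
                         background_states: Mapping[tuple[str, int], GenotypeState],
                         ) -> list[VariantSite]:
    """Homozygous-alternative EMS sites in the M2 (background wild type).

    Not markers — these feed the mutation-frequency statistics only.
    """
    kept = []
    for site in m2_sites:
        if site.samples[m2_sample].state is not GenotypeState.HOM_ALT:
            continue
        bg = background_states.get((site.chrom, site.pos))
        if bg is None or bg is GenotypeState.HOM_REF:
            kept.append(site)
    return kept


def apply_mask(sites: Iterable[VariantSite], mask: IntervalMask) -> list[VariantSite]:
    """Drop sites inside masked (introgressed) intervals."""
    return [s for s in sites if not mask.contains(s.chrom, s.pos)]


def thin_markers(sites: Sequence[VariantSite],
                 params: ThinningParams = ThinningParams()) -> MarkerMap:
    """Thin markers to an even spacing and a fixed count.

    Stage 1: greedy left-to-right scan per chromosome, keeping a site only if
    it lies at least ``bp_space`` bp beyond the last kept site (anchored at
    the leftmost marker).  Stage 2: if more than ``thin_count`` survive,
    a uniform random subsample without replacement, genome-wide, using
    ``seed``.  Output sorted.
    """
    _check_sorted(sites, "thin_markers")
    survivors: list[VariantSite] = []
    last_kept: dict[str, int] = {}
    for s in sites:
        prev = last_kept.get(s.chrom)
        if prev is None or s.pos - prev >= params.bp_space:
            survivors.append(s)
            last_kept[s.chrom] = s.pos
    if len(survivors) > params.thin_count:
        rng = np.random.default_rng(params.seed)
        idx = rng.choice(len(survivors), size=params.thin_count, replace=False)
        survivors = [survivors[i] for i in sorted(idx)]
    return MarkerMap.from_records((s.chrom, s.pos, s.ref, s.alt) for s in survivors)


def build_marker_map(m2_sites: Sequence[VariantSite], m2_sample: str,
                     background_sites: Sequence[VariantSite], background_sample: str,
                     mask: IntervalMask | None = None,
                     thresholds: FilterThresholds = FilterThresholds(),
                     thinning: ThinningParams = ThinningParams(),
                     ) -> tuple[MarkerMap, dict[str, int]]:
    """Run the full marker-map pipeline; returns the map and a per-stage
    attrition report.

    The background stream is confidence-filtered with the same thresholds
    before the comparison steps, mirroring symmetric treatment of the two
    variant files.
    """
    report: dict[str, int] = {"input": len(m2_sites)}
    sites = filter_confidence(m2_sites, m2_sample, thresholds)
    report["confidence"] = len(sites)
    sites = filter_ems_transitions(sites)
    report["ems_transition"] = len(sites)

    bg = filter_confidence(background_sites, background_sample, thresholds)
    bg = filter_ems_transitions(bg)
    sites = subtract_background(sites, bg)
    report["background_subtracted"] = len(sites)

    bg_states = {(s.chrom, s.pos): s.samples[background_sample].state
                 for s in background_sites}
    sites = select_informative(sites, m2_sample, bg_states)
    report["informative_het"] = len(sites)

    if mask is not None:
        sites = apply_mask(sites, mask)
    report["masked"] = len(sites)

    markers = thin_markers(sites, thinning)
    report["thinned"] = len(markers)
    for stage, n in report.items():
        log.info("build_marker_map: %s -> %d sites", stage, n)
    return markers, report
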