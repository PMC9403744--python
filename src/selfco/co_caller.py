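"""Zygosity smoothing and crossover calling.

In M3 progeny of a selfed, partially heterozygous M2 plant, each crossover
carried by either gamete toggles marker zygosity (heterozygous <->
homozygous) along the chromosome.  At 2-4x sequencing depth the raw
zygosity track is noisy — a heterozygous call needs at least two reads, one
per allele, so heterozygosity is systematically under-observed.  The caller
therefore:

1. collapses raw genotypes to HOM/HET and applies a per-sample minimum
   depth (2 for 2x samples, 4 for 4x samples);
2. assigns each window of the position-dependent plan the *weighted median*
   state, giving heterozygous calls extra weight (default 1.5, raised to 3
   for unusually noisy samples) to offset their under-detection;
3. merges same-state windows into segments, refines each segment boundary
   to marker resolution with a minimum-mismatch changepoint search;
4. deletes internal segments supported by fewer than ``min_support`` raw
   calls (a putative double crossover on too little evidence) and merges
   their neighbours;
5. emits one crossover event per remaining het<->hom boundary, located as
   the flanking-marker interval and its midpoint.
"""
from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .variant_io import GenotypeState, VariantSite
from .window_plan import WindowPlan

log = logging.getLogger(__name__)


class SegState(enum.Enum):
    HOM = "hom"
    HET = "het"
    NO_CALL = "no_call"


@dataclass(frozen=True)
class ZygosityCall:
    """Collapsed zygosity of one sample at one marker position."""

    chrom: str
    pos: int
    state: SegState  # HOM or HET
    depth: int


@dataclass(frozen=True)
class SmoothingWeights:
    """Weighted-median weights; ``overrides`` maps sample name to w_het."""

    w_het: float = 1.5
    w_hom: float = 1.0
    overrides: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.w_het <= 0 or self.w_hom <= 0 or any(v <= 0 for v in self.overrides.values()):
            raise ValueError("weights must be positive")

    def resolve(self, sample: str) -> tuple[float, float]:
        return (self.overrides.get(sample, self.w_het), self.w_hom)


@dataclass(frozen=True)
class DepthFilterParams:
    """Minimum retained depth per coverage class (2 for 2x, 4 for 4x)."""

    min_depth: Mapping[str, int] = field(
        default_factory=lambda: {"2x": 2, "4x": 4})

    def min_depth_for(self, depth_class: str) -> int:
        try:
            d = self.min_depth[depth_class]
        except KeyError:
            raise ValueError(f"no depth filter configured for class {depth_class!r}")
        if d < 1:
            raise ValueError("minimum depth must be >= 1")
        return d


@dataclass
class ZygositySegment:
    """Maximal run of uniform smoothed zygosity (1-based inclusive span)."""

    chrom: str
    start: int
    end: int
    state: SegState
    n_support: int = 0
    window_span: tuple[int, int] = (0, 0)  # first/last window index pre-refinement


@dataclass(frozen=True)
class COEvent:
    """One called crossover: the het<->hom boundary between two segments.

    ``left`` / ``right`` are the retained marker positions immediately
    flanking the refined boundary (no retained marker lies strictly
    between them).  ``left_support`` / ``right_support`` widen the interval
    to the nearest flanking markers whose observed state matches their
    segment — the tightest interval the raw evidence can actually vouch for.
    """

    sample: str
    chrom: str
    left: int
    right: int
    left_support: int
    right_support: int

    @property
    def midpoint(self) -> float:
        return (self.left + self.right) / 2


def collapse_and_depth_filter(variants: Iterable[VariantSite], sample: str,
                              min_depth: int) -> dict[str, list[ZygosityCall]]:
    """Collapse genotypes to HOM/HET and drop shallow or missing calls.

    HOM_REF and HOM_ALT both become HOM: zygosity, not allele identity, is
    what a crossover toggles.
    """
    out: dict[str, list[ZygosityCall]] = {}
    for site in variants:
        call = site.samples[sample]
        if call.state is GenotypeState.MISSING:
            continue
        depth = call.depth
        if depth is None:
            raise ValueError(
                f"site {site.chrom}:{site.pos} lacks DP for sample {sample!r}; "
                "the depth filter requires it")
        if depth < min_depth:
            continue
        state = SegState.HET if call.state is GenotypeState.HET else SegState.HOM
        out.setdefault(site.chrom, []).append(
            ZygosityCall(site.chrom, site.pos, state, depth))
    return out


def window_state(n_het: int, n_hom: int, w_het: float = 1.5, w_hom: float = 1.0
                 ) -> SegState | None:
    """Weighted-median state of one window; ``None`` means empty.

    Equivalent to the (upper) weighted median of the binary-coded states
    with HET = 1, HOM = 0: HET iff w_het*n_het >= w_hom*n_hom (ties go to
    HET, since heterozygosity is the under-observed state).
    """
    if n_het == 0 and n_hom == 0:
        return None
    return SegState.HET if w_het * n_het >= w_hom * n_hom else SegState.HOM


def _tracks(calls: Sequence[ZygosityCall]) -> tuple[np.ndarray, np.ndarray]:
    pos = np.array([c.pos for c in calls], dtype=np.int64)
    het = np.array([c.state is SegState.HET for c in calls], dtype=bool)
    return pos, het


def smooth_chromosome(chrom: str, calls: Sequence[ZygosityCall],
                      windows: Sequence[tuple[int, int]],
                      w_het: float = 1.5, w_hom: float = 1.0,
                      ) -> list[ZygositySegment]:
    """Assign each window its weighted-median state and merge into segments.

    Empty windows inherit the preceding non-empty state (leading empties
    inherit the first non-empty state): a window with no data is not
    evidence of a switch.  A chromosome with no calls at all yields a single
    NO_CALL segment, excluded from crossover counting.
    """
    start0, end_last = windows[0][0], windows[-1][1]
    if not calls:
        log.warning("chromosome %s has no retained calls; emitting NO_CALL", chrom)
        return [ZygositySegment(chrom, start0, end_last, SegState.NO_CALL, 0,
                                (0, len(windows) - 1))]
    pos, het = _tracks(calls)
    win_starts = np.array([w[0] for w in windows], dtype=np.int64)
    idx = np.searchsorted(win_starts, pos, side="right") - 1
    n_win = len(windows)
    n_het = np.bincount(idx[het], minlength=n_win)
    n_hom = np.bincount(idx[~het], minlength=n_win)

    states: list[SegState | None] = [
        window_state(int(n_het[i]), int(n_hom[i]), w_het, w_hom) for i in range(n_win)
    ]
    # forward fill, then back-fill the leading run of empties
    first_state = next(s for s in states if s is not None)
    filled: list[SegState] = []
    prev = first_state
    for s in states:
        if s is not None:
            prev = s
        filled.append(prev)

    segments: list[ZygositySegment] = []
    run_start = 0
    for i in range(1, n_win + 1):
        if i == n_win or filled[i] is not filled[run_start]:
            segments.append(ZygositySegment(
                chrom, windows[run_start][0], windows[i - 1][1], filled[run_start],
                window_span=(run_start, i - 1)))
            run_start = i
    _recompute_support(segments, pos, het)
    return segments


def _recompute_support(segments: list[ZygositySegment],
                       pos: np.ndarray, het: np.ndarray) -> None:
    for seg in segments:
        lo = np.searchsorted(pos, seg.start, side="left")
        hi = np.searchsorted(pos, seg.end, side="right")
        inside = het[lo:hi]
        seg.n_support = int(inside.sum() if seg.state is SegState.HET
                            else (~inside).sum())


def refine_boundaries(segments: list[ZygositySegment],
                      calls: Sequence[ZygosityCall],
                      windows: Sequence[tuple[int, int]]) -> list[ZygositySegment]:
    """Sharpen window-granular segment boundaries to marker resolution.

    For each boundary, raw calls in the two abutting windows are scanned for
    the split minimising observed-state mismatches against the two segment
    states; ties resolve to the split nearest the original window edge, then
    leftmost.  The boundary moves to the midpoint between the two calls
    around the chosen split, so crossover resolution is bounded by marker
    spacing rather than window size.  Segments still tile the chromosome.
    """
    if len(segments) < 2 or not calls:
        return segments
    pos, het = _tracks(calls)
    win_ends = [w[1] for w in windows]
    win_starts = [w[0] for w in windows]
    for i in range(len(segments) - 1):
        left, right = segments[i], segments[i + 1]
        if SegState.NO_CALL in (left.state, right.state):
            continue
        k = left.window_span[1]  # last window of the left segment
        orig_edge = win_ends[k] + 0.5
        region_lo = max(win_starts[k], left.start)
        region_hi = min(win_ends[min(k + 1, len(windows) - 1)], right.end)
        a = int(np.searchsorted(pos, region_lo, side="left"))
        b = int(np.searchsorted(pos, region_hi, side="right"))
        m = b - a
        if m == 0:
            continue
        h = het[a:b]
        left_is_het = left.state is SegState.HET
        mismatch_left = (h != left_is_het).astype(np.int64)
        mismatch_right = (h == left_is_het).astype(np.int64)
        cost = np.concatenate(([0], np.cumsum(mismatch_left))) + \
            np.concatenate((np.cumsum(mismatch_right[::-1])[::-1], [0]))
        split_pos = np.empty(m + 1)
        split_pos[0] = region_lo - 0.5
        split_pos[m] = region_hi + 0.5
        if m > 1:
            split_pos[1:m] = (pos[a:b - 1] + pos[a + 1:b]) / 2
        best = np.flatnonzero(cost == cost.min())
        j = int(best[np.lexsort((best, np.abs(split_pos[best] - orig_edge)))[0]])
        nb = int(np.floor(split_pos[j]))
        nb = max(nb, left.start)
        nb = min(nb, right.end - 1)
        left.end = nb
        right.start = nb + 1
    _recompute_support(segments, pos, het)
    return segments


def filter_double_co(segments: list[ZygositySegment],
                     calls: Sequence[ZygosityCall],
                     min_support: int = 4) -> list[ZygositySegment]:
    """Delete weakly supported internal segments (putative double crossovers).

    An internal segment with fewer than ``min_support`` matching raw calls
    is removed and its two (same-state) neighbours merged, erasing two
    putative crossovers.  Applied iteratively, weakest first, ties leftmost,
    until stable.  Terminal segments — a single crossover, not a double —
    are exempt.
    """
    segs = [ZygositySegment(s.chrom, s.start, s.end, s.state, s.n_support,
                            s.window_span) for s in segments]
    pos, het = _tracks(calls) if calls else (np.empty(0, np.int64), np.empty(0, bool))
    while len(segs) >= 3:
        internal = [(segs[i].n_support, i) for i in range(1, len(segs) - 1)
                    if segs[i].n_support < min_support]
        if not internal:
            break
        _, i = min(internal)
        merged = ZygositySegment(
            segs[i].chrom, segs[i - 1].start, segs[i + 1].end, segs[i - 1].state,
            window_span=(segs[i - 1].window_span[0], segs[i + 1].window_span[1]))
        segs[i - 1:i + 2] = [merged]
        _recompute_support([merged], pos, het)
    return segs


def call_crossovers(segments: Sequence[ZygositySegment],
                    calls: Sequence[ZygosityCall],
                    sample: str = "sample") -> list[COEvent]:
    """Emit one crossover event per adjacent segment pair of differing state.

    The event interval is the pair of retained markers flanking the
    boundary; the support interval widens each flank to the nearest call
    matching its segment's state.
    """
    events: list[COEvent] = []
    if not calls:
        return events
    pos, het = _tracks(calls)
    for left, right in zip(segments[:-1], segments[1:]):
        if SegState.NO_CALL in (left.state, right.state) or left.state is right.state:
            continue
        li = int(np.searchsorted(pos, left.end, side="right")) - 1
        ri = int(np.searchsorted(pos, right.start, side="left"))
        if li < 0 or ri >= len(pos):
            continue
        left_is_het = left.state is SegState.HET
        lm = li
        while lm >= 0 and het[lm] != left_is_het:
            lm -= 1
        rm = ri
        while rm < len(pos) and het[rm] == left_is_het:
            rm += 1
        events.append(COEvent(
            sample, left.chrom, int(pos[li]), int(pos[ri]),
            int(pos[lm]) if lm >= 0 else int(pos[li]),
            int(pos[rm]) if rm < len(pos) else int(pos[ri])))
    return events


def adjusted_fraction(calls: Sequence[ZygosityCall],
                      segments: Sequence[ZygositySegment]) -> float | None:
    """Fraction of raw calls whose state the smoothing overrode.

    ``None`` when there are no calls (undefined).
    """
    if not calls:
        return None
    pos, het = _tracks(calls)
    seg_starts = np.array([s.start for s in segments], dtype=np.int64)
    idx = np.searchsorted(seg_starts, pos, side="right") - 1
    seg_het = np.array([s.state is SegState.HET for s in segments], dtype=bool)
    keep = np.array([s.state is not SegState.NO_CALL for s in segments], dtype=bool)[idx]
    if not keep.any():
        return None
    mismatch = het[keep] != seg_het[idx][keep]
    return float(mismatch.mean())


@dataclass
class ChromCallResult:
    chrom: str
    segments: list[ZygositySegment]
    events: list[COEvent]
    n_calls: int
    n_adjusted: int


@dataclass
class SampleCallResult:
    """All per-chromosome results for one sample."""

    sample: str
    chroms: dict[str, ChromCallResult]

    @property
    def events(self) -> list[COEvent]:
        return [e for r in self.chroms.values() for e in r.events]

    @property
    def adjusted_fraction(self) -> float | None:
        n = sum(r.n_calls for r in self.chroms.values())
        if n == 0:
            return None
        return sum(r.n_adjusted for r in self.chroms.values()) / n


def call_sample(calls_by_chrom: Mapping[str, Sequence[ZygosityCall]],
                plan: WindowPlan, sample: str,
                w_het: float = 1.5, w_hom: float = 1.0,
                min_support: int = 4, refine: bool = True) -> SampleCallResult:
    """Run smoothing, refinement, double-CO filtering and event calling for
    one sample across every chromosome of the window plan."""
    results: dict[str, ChromCallResult] = {}
    for chrom in plan.chroms:
        calls = list(calls_by_chrom.get(chrom, ()))
        windows = plan.windows(chrom)
        segments = smooth_chromosome(chrom, calls, windows, w_het, w_hom)
        if refine:
            segments = refine_boundaries(segments, calls, windows)
        segments = filter_double_co(segments, calls, min_support)
        events = call_crossovers(segments, calls, sample)
        frac = adjusted_fraction(calls, segments)
        n_adj = 0 if frac is None else round(frac * len(calls))
        results[chrom] = ChromCallResult(chrom, segments, events, len(calls), n_adj)
    return SampleCallResult(sample, results)
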