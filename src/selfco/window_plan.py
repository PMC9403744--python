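"""Position-dependent window tiling of chromosomes.

Barley recombination is concentrated in the distal ends of each chromosome
while the huge pericentromeric core almost never recombines, and marker
density follows suit.  Windows for zygosity smoothing are therefore small
near the telomeres (high resolution where crossovers happen) and large in
the core (enough markers per window where they are sparse).

Each chromosome is split into zones given as fractions of its physical
length; each zone is tiled left to right with windows of the zone's nominal
size, the remainder merging into the last window when it is shorter than
half the nominal size.  Windows are tumbling (non-overlapping) and tile the
chromosome exactly.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from .variant_io import ChromTable

log = logging.getLogger(__name__)

#: Five-zone default: distal 15% ends at 14.3 Mbp, intermediate 15% zones at
#: 28 Mbp, central 40% at 42 Mbp.  Zone averages over barley-scale
#: chromosomes land near the 14.3 / 42.0 Mbp distal/core means.
DEFAULT_ZONES: tuple[tuple[float, int], ...] = (
    (0.15, 14_300_000),
    (0.15, 28_000_000),
    (0.40, 42_000_000),
    (0.15, 28_000_000),
    (0.15, 14_300_000),
)


@dataclass(frozen=True)
class WindowScheme:
    """Ordered (fraction_of_chromosome, window_size_bp) zones covering [0, 1]."""

    zones: tuple[tuple[float, int], ...] = DEFAULT_ZONES

    def __post_init__(self) -> None:
        fracs = [f for f, _ in self.zones]
        if abs(sum(fracs) - 1.0) > 1e-9:
            raise ValueError(f"zone fractions must sum to 1, got {sum(fracs)}")
        if any(f <= 0 for f in fracs):
            raise ValueError("zone fractions must be positive")
        if any(s <= 0 for _, s in self.zones):
            raise ValueError("window sizes must be positive")

    @property
    def min_size(self) -> int:
        return min(s for _, s in self.zones)


class WindowPlan:
    """Per-chromosome ordered windows, 1-based inclusive, exact tiling."""

    def __init__(self, windows: dict[str, list[tuple[int, int]]], lengths: dict[str, int]):
        self._starts: dict[str, np.ndarray] = {}
        self._ends: dict[str, np.ndarray] = {}
        self._lengths = dict(lengths)
        for chrom, wins in windows.items():
            starts = np.array([w[0] for w in wins], dtype=np.int64)
            ends = np.array([w[1] for w in wins], dtype=np.int64)
            if starts[0] != 1 or ends[-1] != lengths[chrom] or \
                    (len(wins) > 1 and not np.all(starts[1:] == ends[:-1] + 1)):
                raise ValueError(f"windows do not tile chromosome {chrom}")
            self._starts[chrom] = starts
            self._ends[chrom] = ends

    @property
    def chroms(self) -> list[str]:
        return list(self._starts)

    def windows(self, chrom: str) -> list[tuple[int, int]]:
        return list(zip(self._starts[chrom].tolist(), self._ends[chrom].tolist()))

    def starts(self, chrom: str) -> np.ndarray:
        return self._starts[chrom]

    def ends(self, chrom: str) -> np.ndarray:
        return self._ends[chrom]

    def n_windows(self, chrom: str) -> int:
        return len(self._starts[chrom])

    def window_of(self, chrom: str, pos: int) -> int:
        """Index of the window containing 1-based ``pos``; out of range is fatal."""
        if pos < 1 or pos > self._lengths[chrom]:
            raise ValueError(f"position {chrom}:{pos} outside [1, {self._lengths[chrom]}]")
        return int(np.searchsorted(self._starts[chrom], pos, side="right")) - 1

    def window_index(self, chrom: str, pos: np.ndarray) -> np.ndarray:
        """Vectorised :meth:`window_of` (positions assumed in range)."""
        return np.searchsorted(self._starts[chrom], pos, side="right") - 1

    def to_bed(self, path: str) -> None:
        rows = [(c, s - 1, e) for c in self.chroms for s, e in self.windows(c)]
        pd.DataFrame(rows, columns=["chrom", "start", "end"]).to_csv(
            path, sep="\t", index=False, header=False)


def _tile_zone(start: int, end: int, size: int) -> list[tuple[int, int]]:
    """Tile [start, end] with windows of ``size``; short remainder merges left."""
    length = end - start + 1
    n_full = length // size
    windows = []
    for i in range(n_full):
        windows.append((start + i * size, start + (i + 1) * size - 1))
    rem = length - n_full * size
    if rem > 0:
        if windows and rem < size / 2:
            windows[-1] = (windows[-1][0], end)
        else:
            windows.append((end - rem + 1, end))
    return windows


def build_plan(chroms: ChromTable, scheme: WindowScheme = WindowScheme()) -> WindowPlan:
    """Tile every chromosome of ``chroms`` according to ``scheme``."""
    plan: dict[str, list[tuple[int, int]]] = {}
    for chrom, length in chroms.items():
        if length < scheme.min_size:
            log.warning("chromosome %s (%d bp) shorter than smallest window; "
                        "using a single whole-chromosome window", chrom, length)
            plan[chrom] = [(1, length)]
            continue
        windows: list[tuple[int, int]] = []
        cum = 0.0
        bound_prev = 0
        for i, (frac, size) in enumerate(scheme.zones):
            cum += frac
            bound = length if i == len(scheme.zones) - 1 else int(round(cum * length))
            if bound <= bound_prev:
                continue
            zone = _tile_zone(bound_prev + 1, bound, size)
            if len(zone) == 1 and windows and (zone[0][1] - zone[0][0] + 1) < size / 2:
                # zone too short for even one half-window: absorb into neighbour
                windows[-1] = (windows[-1][0], zone[0][1])
            else:
                windows.extend(zone)
            bound_prev = bound
        plan[chrom] = windows
    return WindowPlan(plan, dict(chroms.items()))


def zone_mean_sizes(chroms: ChromTable, scheme: WindowScheme = WindowScheme()
                    ) -> dict[int, float]:
    """Mean realised window size per zone index, across chromosomes.

    Windows are attributed to the zone containing their midpoint.
    """
    plan = build_plan(chroms, scheme)
    sums: dict[int, list[int]] = {}
    for chrom, length in chroms.items():
        bounds = np.cumsum([f for f, _ in scheme.zones]) * length
        for s, e in plan.windows(chrom):
            mid = (s + e) / 2
            zone = int(np.searchsorted(bounds, mid, side="left"))
            zone = min(zone, len(scheme.zones) - 1)
            sums.setdefault(zone, []).append(e - s + 1)
        # noqa: chromosome loop
    return {z: float(np.mean(v)) for z, v in sums.items()}
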