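"""Zygosity smoothing, double-CO filtering and crossover event extraction."""
import numpy as np
import pytest

from selfco.co_caller import (COEvent, SegState, ZygosityCall, ZygositySegment,
                              adjusted_fraction, call_crossovers, call_sample,
                              collapse_and_depth_filter, filter_double_co,
                              refine_boundaries, smooth_chromosome,
                              window_state)
from selfco.variant_io import ChromTable, GenotypeState
from selfco.window_plan import WindowScheme, build_plan

from conftest import site

HET, HOM = SegState.HET, SegState.HOM


def oracle_weighted_median(n_het: int, n_hom: int, w_het: float, w_hom: float):
    """Independent oracle: expand each call into weight-many copies (weights
    scaled to integers) of its binary code and take the upper median."""
    scale = 2  # makes 1.5 integral; exact for the weight sets in use
    values = [1] * int(round(w_het * scale)) * n_het + \
             [0] * int(round(w_hom * scale)) * n_hom
    if not values:
        return None
    arr = np.sort(np.array(values))
    return HET if arr[len(arr) // 2] == 1 else HOM


class TestWindowState:
    @pytest.mark.parametrize("n_het,n_hom,w_het,expected", [
        (2, 3, 1.5, HET),   # 3.0 vs 3.0: tie resolves heterozygous
        (1, 2, 1.5, HOM),   # 1.5 vs 2.0
        (1, 2, 3.0, HET),   # raised weight lets sparse het evidence dominate
        (0, 0, 1.5, None),  # empty window
    ])
    def test_reference_cases(self, n_het, n_hom, w_het, expected):
        assert window_state(n_het, n_hom, w_het=w_het) is expected

    @pytest.mark.parametrize("w_het", [1.5, 3.0])
    def test_equals_expanded_copy_median_oracle(self, w_het):
        for n_het in range(21):
            for n_hom in range(21):
                assert window_state(n_het, n_hom, w_het=w_het) is \
                    oracle_weighted_median(n_het, n_hom, w_het, 1.0), \
                    (n_het, n_hom, w_het)

    def test_raising_het_weight_is_monotone(self, rng):
        """More heterozygous weight never turns a HET window HOM."""
        for _ in range(200):
            n_het, n_hom = int(rng.integers(0, 30)), int(rng.integers(1, 30))
            w1, w2 = sorted(rng.uniform(0.5, 5.0, size=2))
            if window_state(n_het, n_hom, w_het=w1) is HET:
                assert window_state(n_het, n_hom, w_het=w2) is HET


def calls_for(chrom, specs):
    """specs: list of (pos, state)."""
    return [ZygosityCall(chrom, p, s, 4) for p, s in specs]


WINDOWS_10 = [(1 + 10 * i, 10 * (i + 1)) for i in range(6)]  # six 10-bp windows


def window_calls(states_per_window):
    """Place three calls of the given state in each non-empty window."""
    specs = []
    for i, st in enumerate(states_per_window):
        if st is None:
            continue
        base = 1 + 10 * i
        specs += [(base + j, st) for j in range(3)]
    return calls_for("c", specs)


class TestSmoothing:
    def test_run_length_merge(self):
        calls = window_calls([HET, HET, HOM, HOM, HOM, HET])
        segs = smooth_chromosome("c", calls, WINDOWS_10)
        assert [s.state for s in segs] == [HET, HOM, HET]
        assert (segs[0].start, segs[0].end) == (1, 20)
        assert (segs[1].start, segs[1].end) == (21, 50)
        assert (segs[2].start, segs[2].end) == (51, 60)

    def test_empty_windows_inherit(self):
        calls = window_calls([None, HET, None, HOM, HOM, HOM])
        segs = smooth_chromosome("c", calls, WINDOWS_10)
        # leading empty takes the first non-empty state; mid empty extends HET
        assert [(s.state, s.start, s.end) for s in segs] == \
            [(HET, 1, 30), (HOM, 31, 60)]

    def test_all_het_single_segment(self):
        calls = window_calls([HET] * 6)
        segs = smooth_chromosome("c", calls, WINDOWS_10)
        assert len(segs) == 1 and segs[0].state is HET
        assert call_crossovers(segs, calls) == []

    def test_no_calls_yields_no_call_segment(self):
        segs = smooth_chromosome("c", [], WINDOWS_10)
        assert len(segs) == 1 and segs[0].state is SegState.NO_CALL
        assert call_crossovers(segs, []) == []

    def test_support_counts_matching_raw_calls(self):
        calls = window_calls([HET, HET, HOM, HOM, HOM, HET])
        # add one contrarian call inside the HOM stretch
        calls += calls_for("c", [(35, HET)])
        calls.sort(key=lambda c: c.pos)
        segs = smooth_chromosome("c", calls, WINDOWS_10)
        assert segs[1].state is HOM and segs[1].n_support == 9
        assert segs[0].n_support == 6


class TestCollapse:
    def test_depth_filter_and_collapse(self):
        sites = [
            site(pos=10, state=GenotypeState.HOM_ALT, depth=2, sample="S"),
            site(pos=20, state=GenotypeState.HET, depth=3, sample="S"),
            site(pos=30, state=GenotypeState.MISSING, depth=0, sample="S"),
            site(pos=40, state=GenotypeState.HOM_REF, depth=9, sample="S"),
        ]
        by_2x = collapse_and_depth_filter(sites, "S", min_depth=2)["chr1"]
        assert [(c.pos, c.state) for c in by_2x] == \
            [(10, HOM), (20, HET), (40, HOM)]
        by_4x = collapse_and_depth_filter(sites, "S", min_depth=4)["chr1"]
        assert [(c.pos, c.state) for c in by_4x] == [(40, HOM)]


def segment(state, start, end, n_support, chrom="c"):
    return ZygositySegment(chrom, start, end, state, n_support)


def support_calls(segments):
    """Raw calls realising each segment's n_support, evenly spaced."""
    calls = []
    for seg in segments:
        span = seg.end - seg.start
        for j in range(seg.n_support):
            pos = seg.start + (j * span) // max(seg.n_support, 1)
            calls.append(ZygosityCall(seg.chrom, pos, seg.state, 4))
    calls.sort(key=lambda c: c.pos)
    return calls


class TestDoubleCOFilter:
    def test_weak_internal_segment_removed(self):
        segs = [segment(HET, 1, 400, 40), segment(HOM, 401, 430, 3),
                segment(HET, 431, 1000, 55)]
        calls = support_calls(segs)
        out = filter_double_co(segs, calls, min_support=4)
        assert len(out) == 1 and out[0].state is HET
        assert (out[0].start, out[0].end) == (1, 1000)
        assert call_crossovers(out, calls) == []

    def test_boundary_support_four_kept(self):
        segs = [segment(HET, 1, 400, 40), segment(HOM, 401, 430, 4),
                segment(HET, 431, 1000, 55)]
        calls = support_calls(segs)
        out = filter_double_co(segs, calls, min_support=4)
        assert [s.state for s in out] == [HET, HOM, HET]
        assert len(call_crossovers(out, calls)) == 2

    def test_terminal_segments_exempt(self):
        segs = [segment(HET, 1, 20, 2), segment(HOM, 21, 1000, 90)]
        calls = support_calls(segs)
        out = filter_double_co(segs, calls, min_support=4)
        assert [s.state for s in out] == [HET, HOM]

    def test_iterative_lowest_first(self):
        # two weak internal segments; removing the weaker merges neighbours
        # whose combined support then protects the structure
        segs = [segment(HET, 1, 100, 30), segment(HOM, 101, 120, 2),
                segment(HET, 121, 200, 3), segment(HOM, 201, 400, 50)]
        calls = support_calls(segs)
        out = filter_double_co(segs, calls, min_support=4)
        # HOM(2) removed first -> HET(30+3+...) merged; remaining HET/HOM
        assert [s.state for s in out] == [HET, HOM]


class TestCallCrossovers:
    def test_single_segment_no_events(self):
        segs = [segment(HET, 1, 100, 10)]
        assert call_crossovers(segs, support_calls(segs)) == []

    def test_het_hom_het_two_events(self):
        segs = [segment(HET, 1, 100, 10), segment(HOM, 101, 200, 10),
                segment(HET, 201, 300, 10)]
        calls = support_calls(segs)
        events = call_crossovers(segs, calls, sample="s1")
        assert len(events) == 2
        for e in events:
            assert e.left < e.right
            assert e.midpoint == (e.left + e.right) / 2

    def test_no_retained_marker_strictly_inside(self, rng):
        """Scan oracle: the event interval is a gap between adjacent calls."""
        chroms = ChromTable([("c", 2_000_000)])
        plan = build_plan(chroms, WindowScheme(((1.0, 100_000),)))
        pos = np.sort(rng.choice(2_000_000, size=400, replace=False) + 1)
        switch = 1_000_000
        calls = [ZygosityCall("c", int(p), HET if p < switch else HOM, 4)
                 for p in pos]
        res = call_sample({"c": calls}, plan, "s")
        events = res.events
        assert len(events) >= 1
        all_pos = set(int(p) for p in pos)
        for e in events:
            assert e.left < e.right
            strictly_inside = [p for p in all_pos if e.left < p < e.right]
            assert strictly_inside == []


class TestRefinement:
    def test_boundary_moves_to_marker_resolution(self):
        """A switch in the middle of a window is located between the flanking
        raw calls, not at the window edge."""
        chroms = ChromTable([("c", 1_000_000)])
        plan = build_plan(chroms, WindowScheme(((1.0, 100_000),)))
        switch = 450_000  # mid-window
        pos = list(range(10_000, 1_000_000, 10_000))
        calls = [ZygosityCall("c", p, HET if p < switch else HOM, 4) for p in pos]
        res = call_sample({"c": calls}, plan, "s")
        [event] = res.events
        assert event.left == 440_000 and event.right == 450_000

    def test_clean_data_unchanged_by_refinement(self):
        calls = window_calls([HET, HET, HET, HOM, HOM, HOM])
        segs = smooth_chromosome("c", calls, WINDOWS_10)
        refined = refine_boundaries(segs, calls, WINDOWS_10)
        assert [s.state for s in refined] == [HET, HOM]
        assert refined[0].end < refined[1].start


class TestAdjustedFraction:
    def test_all_match_zero(self):
        segs = [segment(HET, 1, 100, 10)]
        calls = support_calls(segs)
        assert adjusted_fraction(calls, segs) == 0.0

    def test_mismatch_fraction_and_complement(self):
        segs = [segment(HET, 1, 1000, 82)]
        calls = [ZygosityCall("c", 10 * (i + 1), HET if i >= 18 else HOM, 4)
                 for i in range(100)]
        frac = adjusted_fraction(calls, segs)
        assert frac == pytest.approx(0.18)
        matching = sum(1 for c in calls if c.state is HET)
        assert frac == pytest.approx(1 - matching / len(calls))

    def test_no_calls_undefined(self):
        assert adjusted_fraction([], [segment(HET, 1, 10, 0)]) is None


class TestConservation:
    def test_events_equal_state_alternations(self, rng):
        """Per chromosome, event count equals adjacent-segment state changes."""
        chroms = ChromTable([("c", 5_000_000)])
        plan = build_plan(chroms, WindowScheme(((1.0, 250_000),)))
        pos = np.sort(rng.choice(5_000_000, size=800, replace=False) + 1)
        breaks = [1_200_000, 2_400_000, 3_900_000]
        state_of = lambda p: HET if sum(p > b for b in breaks) % 2 == 0 else HOM
        calls = [ZygosityCall("c", int(p), state_of(p), 4) for p in pos]
        res = call_sample({"c": calls}, plan, "s")
        segs = res.chroms["c"].segments
        alternations = sum(1 for a, b in zip(segs[:-1], segs[1:])
                           if a.state is not b.state)
        assert len(res.events) == alternations == 3
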