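"""Stitching, super/typical split against an exhaustive oracle, distances."""

import itertools

import numpy as np
import pytest

from thyromics.enhancers import (
    EnhancerParams,
    StitchedEnhancer,
    Tss,
    enhancer_gene_distance,
    nearest_target,
    split_super,
    stitch,
)
from thyromics.io import PeakInterval


def peak(start, end, signal=1.0, chrom="c"):
    return PeakInterval(chrom, start, end, signal)


class TestStitch:
    def test_gap_within_stitch_distance_merges(self):
        out = stitch([peak(0, 100), peak(12_500, 12_600)])
        assert len(out) == 1 and out[0].constituent_count == 2

    def test_gap_beyond_stitch_distance_stays_split(self):
        out = stitch([peak(0, 100), peak(12_701, 12_800)])
        assert len(out) == 2

    def test_promoter_contained_peak_excluded(self):
        tss = [Tss("g", "c", 10_000)]
        contained = peak(9_500, 10_800)  # within TSS +- 2000
        straddling = peak(8_500, 12_500)  # not fully contained
        out = stitch([contained, straddling], tss)
        assert len(out) == 1 and out[0].start == 8_500

    def test_idempotent_and_order_invariant(self):
        rng = np.random.default_rng(8)
        peaks = []
        pos = 0
        for _ in range(30):
            w = int(rng.integers(100, 2000))
            peaks.append(peak(pos, pos + w, float(rng.lognormal(1, 1))))
            pos += w + int(rng.integers(1000, 30_000))
        out = stitch(peaks)
        shuffled = list(peaks)
        rng.shuffle(shuffled)
        assert stitch(shuffled) == out
        # re-stitching the stitched intervals changes nothing
        as_peaks = [peak(e.start, e.end, e.signal) for e in out]
        out2 = stitch(as_peaks)
        assert [(e.start, e.end, e.signal) for e in out2] == [
            (e.start, e.end, e.signal) for e in out
        ]

    def test_total_signal_conserved(self):
        rng = np.random.default_rng(9)
        peaks = [peak(i * 3000, i * 3000 + 1000, float(rng.random() * 10))
                 for i in range(20)]
        out = stitch(peaks)
        assert sum(e.signal for e in out) == pytest.approx(
            sum(p.signal for p in peaks)
        )


def split_super_oracle(signals):
    """Independent re-derivation of the scaled-tangent cutoff by explicit
    scanning; returns the boolean is_super vector in input order."""
    n = len(signals)
    order = sorted(range(n), key=lambda i: signals[i])
    s = [signals[i] for i in order]
    if s[0] == s[-1]:
        return [False] * n
    x = [i / (n - 1) for i in range(n)]
    y = [(v - s[0]) / (s[-1] - s[0]) for v in s]
    slopes = []
    for i in range(n):
        lo, hi = max(0, i - 1), min(n - 1, i + 1)
        slopes.append((y[hi] - y[lo]) / (x[hi] - x[lo]))
    first = next((i for i, sl in enumerate(slopes) if sl >= 1.0), None)
    if first is None:
        return [False] * n
    # rightmost index at/after `first` minimizing |slope - 1|
    devs = [abs(slopes[i] - 1.0) for i in range(first, n)]
    mn = min(devs)
    best = first + max(i for i, d in enumerate(devs) if d <= mn + 1e-12)
    cutoff = s[best]
    return [signals[i] > cutoff for i in range(n)]


def enhancers_from(signals):
    return [
        StitchedEnhancer("c", i * 10, i * 10 + 5, 1, float(v))
        for i, v in enumerate(signals)
    ]


class TestSplitSuper:
    def test_single_outlier_is_the_only_super(self):
        out = split_super(enhancers_from([1, 1, 1, 1, 10]))
        assert [e.is_super for e in out] == split_super_oracle([1, 1, 1, 1, 10])
        assert sum(e.is_super for e in out) == 1
        assert out[-1].is_super and out[-1].rank == 1

    def test_linear_ramp_no_supers(self):
        out = split_super(enhancers_from([1, 2, 3, 4, 5, 6]))
        assert sum(e.is_super for e in out) == 0

    def test_appending_extreme_peak_adds_exactly_it(self):
        base = [1.0, 2.0, 2.5, 3.0, 40.0]
        with_extreme = base + [40.0 * 100]
        out = split_super(enhancers_from(with_extreme))
        oracle = split_super_oracle(with_extreme)
        assert [e.is_super for e in out] == oracle
        assert out[-1].is_super

    def test_all_equal_warns_zero_supers(self):
        with pytest.warns(UserWarning, match="all enhancer signals equal"):
            out = split_super(enhancers_from([2, 2, 2]))
        assert not any(e.is_super for e in out)

    def test_scaling_signals_preserves_flags(self):
        signals = [1.0, 1.5, 2.0, 3.0, 25.0, 30.0]
        out1 = split_super(enhancers_from(signals))
        out2 = split_super(enhancers_from([s * 7.5 for s in signals]))
        assert [e.is_super for e in out1] == [e.is_super for e in out2]

    def test_exhaustive_oracle_agreement_up_to_length_8(self):
        """Implementation matches the explicit cutoff-scan oracle on every
        signal vector over {1, 4, 16} of length 3..8."""
        for n in range(3, 9):
            for combo in itertools.product((1.0, 4.0, 16.0), repeat=n):
                out = split_super(enhancers_from(list(combo)))
                assert [e.is_super for e in out] == split_super_oracle(list(combo)), combo

    def test_too_few_enhancers(self):
        with pytest.raises(ValueError, match="at least 3"):
            split_super(enhancers_from([1, 2]))

    def test_ranks_unique(self):
        out = split_super(enhancers_from([5, 1, 3, 3, 2]))
        assert sorted(e.rank for e in out) == [1, 2, 3, 4, 5]


class TestDistances:
    enh = StitchedEnhancer("chr5", 1000, 2000, 1, 10.0)

    def test_tss_inside_enhancer(self):
        assert enhancer_gene_distance(self.enh, Tss("g", "chr5", 1500)) == 0

    def test_gap_to_nearest_edge(self):
        assert enhancer_gene_distance(self.enh, Tss("g", "chr5", 5000)) == 3000
        assert enhancer_gene_distance(self.enh, Tss("g", "chr5", 400)) == 600

    def test_cross_chromosome_requires_junction(self):
        with pytest.raises(ValueError, match="junction"):
            enhancer_gene_distance(self.enh, Tss("TERT", "chr2", 500))

    def test_through_junction_distance(self):
        # enhancer 100 kb from breakpoint A; gene 79 kb from breakpoint B
        enh = StitchedEnhancer("chr2", 1_000_000, 1_010_000, 1, 5.0)
        junction = (("chr2", 1_110_000), ("chr5", 2_000_000))
        tss = Tss("TERT", "chr5", 2_079_000)
        assert enhancer_gene_distance(enh, tss, junction) == 179_000

    def test_nearest_target_tie_broken_leftmost(self):
        tss = [Tss("right", "chr5", 2500), Tss("left", "chr5", 500)]
        assert nearest_target(self.enh, tss).gene == "left"
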