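"""ROSE-style super-enhancer identification and enhancer-gene distances.

H3K27ac peaks fully contained in a promoter window (TSS +- 2000 bp) are
excluded; the remainder are stitched transitively when separated by at most
12,500 bp, with the stitched signal equal to the sum of constituent signals.
Super-enhancers are separated from typical enhancers at the inflection point
of the signal-versus-rank curve: with rank and signal each min-max scaled to
[0, 1], the cutoff is the point on the upper tail whose local tangent slope
is closest to 1; enhancers with signal above the cutoff are super.

For translocation (enhancer-hijacking) analysis, enhancer-gene distance can
be measured through a rearrangement junction: the sum of the distance from
the enhancer to its breakpoint and from the gene TSS to the partner
breakpoint.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np

from .io import PeakInterval

__all__ = [
    "EnhancerParams",
    "StitchedEnhancer",
    "Tss",
    "stitch",
    "split_super",
    "enhancer_gene_distance",
    "nearest_target",
]


@dataclass(frozen=True)
class EnhancerParams:
    stitch_distance: int = 12_500
    promoter_window: int = 2_000

    def __post_init__(self) -> None:
        if self.stitch_distance <= 0 or self.promoter_window <= 0:
            raise ValueError("stitch_distance and promoter_window must be positive")


@dataclass(frozen=True)
class Tss:
    gene: str
    chrom: str
    pos: int


@dataclass(frozen=True)
class StitchedEnhancer:
    chrom: str
    start: int
    end: int
    constituent_count: int
    signal: float
    rank: Optional[int] = None  # 1 = highest signal, unique within a run
    is_super: Optional[bool] = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("enhancer start >= end")
        if self.signal < 0:
            raise ValueError("negative enhancer signal")


def _in_promoter(peak: PeakInterval, tss_list: Sequence[Tss], window: int) -> bool:
    # exclusion applies only to peaks *fully contained* in a promoter window
    return any(
        t.chrom == peak.chrom
        and peak.start >= t.pos - window
        and peak.end <= t.pos + window
        for t in tss_list
    )


def stitch(
    peaks: Sequence[PeakInterval],
    tss_list: Sequence[Tss] = (),
    params: EnhancerParams = EnhancerParams(),
) -> list[StitchedEnhancer]:
    """Promoter exclusion, then transitive merging of nearby peaks.

    Idempotent (stitching stitched output changes nothing) and invariant to
    peak input order; total signal over the output equals total signal over
    the retained peaks.
    """
    retained = [p for p in peaks if not _in_promoter(p, tss_list, params.promoter_window)]
    retained.sort(key=lambda p: (p.chrom, p.start, p.end))
    out: list[StitchedEnhancer] = []
    cur: list[PeakInterval] = []

    def flush() -> None:
        if cur:
            out.append(
                StitchedEnhancer(
                    chrom=cur[0].chrom,
                    start=cur[0].start,
                    end=max(p.end for p in cur),
                    constituent_count=len(cur),
                    signal=float(sum(p.signal for p in cur)),
                )
            )

    for p in retained:
        if cur and p.chrom == cur[-1].chrom and p.start - max(q.end for q in cur) <= params.stitch_distance:
            cur.append(p)
        else:
            flush()
            cur = [p]
    flush()
    return out


def split_super(
    enhancers: Sequence[StitchedEnhancer], mode: str = "scaled_tangent"
) -> list[StitchedEnhancer]:
    """Set ``is_super`` and ``rank`` by the scaled-tangent inflection rule.

    Signals are sorted ascending; rank index and signal are each min-max
    scaled to [0, 1]; local slopes come from a 3-point window (one-sided at
    the edges).  The cutoff is the point, among those at or beyond the first
    slope >= 1, minimizing |slope - 1| (ties resolved to the rightmost);
    enhancers with signal strictly above the cutoff signal are super.  An
    all-equal signal vector yields zero supers with a warning.
    """
    if mode != "scaled_tangent":
        raise ValueError(f"unknown mode {mode!r}")
    n = len(enhancers)
    if n < 3:
        raise ValueError("need at least 3 enhancers to place an inflection point")
    order = sorted(range(n), key=lambda i: enhancers[i].signal)
    signals = np.array([enhancers[i].signal for i in order], dtype=float)

    if signals[0] == signals[-1]:
        warnings.warn("all enhancer signals equal; no super-enhancers")
        cutoff = np.inf
    else:
        x = np.arange(n, dtype=float) / (n - 1)
        y = (signals - signals[0]) / (signals[-1] - signals[0])
        slopes = np.empty(n)
        slopes[0] = (y[1] - y[0]) / (x[1] - x[0])
        slopes[-1] = (y[-1] - y[-2]) / (x[-1] - x[-2])
        for i in range(1, n - 1):
            slopes[i] = (y[i + 1] - y[i - 1]) / (x[i + 1] - x[i - 1])
        at_least_one = np.nonzero(slopes >= 1.0)[0]
        if at_least_one.size == 0:
            cutoff = np.inf  # no elbow (e.g. concave curve)
        else:
            cand = np.arange(at_least_one[0], n)
            dev = np.abs(slopes[cand] - 1.0)
            best = cand[dev <= dev.min() + 1e-12][-1]  # rightmost minimizer
            cutoff = signals[best]

    # ranks: 1 = highest signal; ties broken by position in the sorted order
    ranked = sorted(range(n), key=lambda i: -enhancers[i].signal)
    rank_of = {i: r + 1 for r, i in enumerate(ranked)}
    return [
        replace(e, rank=rank_of[i], is_super=bool(e.signal > cutoff))
        for i, e in enumerate(enhancers)
    ]


Junction = tuple[tuple[str, int], tuple[str, int]]  # ((chromA, posA), (chromB, posB))


def _point_distance(enhancer: StitchedEnhancer, pos: int) -> int:
    if enhancer.start <= pos < enhancer.end:
        return 0
    return pos - enhancer.end if pos >= enhancer.end else enhancer.start - pos


def enhancer_gene_distance(
    enhancer: StitchedEnhancer,
    tss: Tss,
    junction: Optional[Junction] = None,
) -> int:
    """bp distance between an enhancer and a gene TSS.

    Zero when the TSS lies inside the enhancer; otherwise the gap to the
    nearest enhancer edge.  Across chromosomes a rearrangement junction must
    be supplied, and the distance is measured through it: enhancer-to-
    breakpoint plus TSS-to-partner-breakpoint.
    """
    if tss.chrom == enhancer.chrom:
        return _point_distance(enhancer, tss.pos)
    if junction is None:
        raise ValueError(
            f"enhancer on {enhancer.chrom} and TSS on {tss.chrom}: "
            "a rearrangement junction is required"
        )
    (chrom_a, pos_a), (chrom_b, pos_b) = junction
    if enhancer.chrom == chrom_a and tss.chrom == chrom_b:
        return _point_distance(enhancer, pos_a) + abs(tss.pos - pos_b)
    if enhancer.chrom == chrom_b and tss.chrom == chrom_a:
        return _point_distance(enhancer, pos_b) + abs(tss.pos - pos_a)
    raise ValueError("junction does not connect the enhancer and TSS chromosomes")


def nearest_target(
    enhancer: StitchedEnhancer,
    tss_list: Sequence[Tss],
    junction: Optional[Junction] = None,
) -> Tss:
    """The TSS nearest the enhancer; ties broken by leftmost TSS position."""
    if not tss_list:
        raise ValueError("empty TSS list")
    candidates = []
    for t in tss_list:
        try:
            d = enhancer_gene_distance(enhancer, t, junction)
        except ValueError:
            continue  # unreachable chromosome without a junction
        candidates.append((d, t.pos, t.gene, t))
    if not candidates:
        raise ValueError("no TSS reachable from the enhancer")
    candidates.sort(key=lambda c: (c[0], c[1], c[2]))
    return candidates[0][3]
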