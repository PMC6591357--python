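"""Copy-number calls from segment tables.

Gene-level homozygous deletion uses the rule: any segment overlapping the
gene locus with log2 copy ratio <= -0.6 (inclusive) calls the gene deleted.
Arm-level burden follows a GISTIC-like convention: an arm is counted altered
when segments cover at least half of it and their length-weighted mean log2
ratio exceeds +0.2 (gain) or falls below -0.2 (loss).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import Segment

__all__ = ["CnaParams", "call_gene_deletion", "gene_deletion_table", "arm_level_burden"]

Interval = tuple[str, int, int]  # chrom, start, end -- 0-based half-open

#: Approximate CDKN2A locus (GRCh37, 0-based half-open).
DEFAULT_GENE_LOCI: dict[str, Interval] = {
    "CDKN2A": ("9", 21_967_751, 21_995_300),
}


@dataclass(frozen=True)
class CnaParams:
    homdel_log2_threshold: float = -0.6
    arm_amp_threshold: float = 0.2
    arm_del_threshold: float = -0.2
    arm_coverage_fraction: float = 0.5
    gene_loci: Mapping[str, Interval] = field(
        default_factory=lambda: dict(DEFAULT_GENE_LOCI)
    )
    arm_definitions: Mapping[str, Interval] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.homdel_log2_threshold >= 0:
            raise ValueError("homdel threshold must be negative")
        if not 0 < self.arm_coverage_fraction <= 1:
            raise ValueError("arm_coverage_fraction must be in (0,1]")
        if self.arm_amp_threshold <= 0 or self.arm_del_threshold >= 0:
            raise ValueError("arm thresholds must be +/- of zero")


def _overlap(seg: Segment, iv: Interval) -> int:
    chrom, start, end = iv
    if seg.chrom != chrom:
        return 0
    return max(0, min(seg.end, end) - max(seg.start, start))


def call_gene_deletion(
    segments: Sequence[Segment], gene: str, params: CnaParams = CnaParams()
) -> str:
    """``"del"`` iff any segment overlapping the gene locus has log2 ratio
    <= the homozygous-deletion threshold (inclusive), else ``"2n"``.

    No overlapping segment at all yields ``"2n"`` with a coverage warning.
    """
    if gene not in params.gene_loci:
        raise ValueError(f"no locus defined for gene {gene!r}")
    locus = params.gene_loci[gene]
    overlapping = [s for s in segments if _overlap(s, locus) > 0]
    if not overlapping:
        warnings.warn(f"no segment covers the {gene} locus; calling 2n")
        return "2n"
    if any(s.log2ratio <= params.homdel_log2_threshold for s in overlapping):
        return "del"
    return "2n"


def gene_deletion_table(
    segments: Sequence[Segment], gene: str, params: CnaParams = CnaParams()
) -> pd.DataFrame:
    """Per-sample deletion status and the minimum overlapping log2 ratio."""
    by_sample: dict[str, list[Segment]] = {}
    for s in segments:
        by_sample.setdefault(s.sample, []).append(s)
    rows = []
    for sample in sorted(by_sample):
        segs = by_sample[sample]
        status = call_gene_deletion(segs, gene, params)
        locus = params.gene_loci[gene]
        ratios = [s.log2ratio for s in segs if _overlap(s, locus) > 0]
        rows.append(
            {
                "sample": sample,
                "gene": gene,
                "status": status,
                "min_log2ratio": min(ratios) if ratios else np.nan,
            }
        )
    return pd.DataFrame(rows).set_index("sample")


def arm_level_burden(
    segments_by_sample: Mapping[str, Sequence[Segment]],
    params: CnaParams,
) -> pd.Series:
    """Per-sample count of chromosome arms with a coherent gain or loss.

    An arm is assessable when overlapping segments cover at least
    ``arm_coverage_fraction`` of it; it counts as altered when the
    length-weighted mean log2 ratio of the overlap exceeds the gain threshold
    or falls below the loss threshold.  Splitting a segment into adjacent
    pieces with the same ratio leaves the burden unchanged.
    """
    if not params.arm_definitions:
        raise ValueError("arm_definitions required for arm-level burden")
    out = {}
    for sample, segs in segments_by_sample.items():
        if not segs:
            warnings.warn(f"sample {sample!r} has an empty segment table; burden 0")
            out[sample] = 0
            continue
        n_altered = 0
        for arm, iv in params.arm_definitions.items():
            arm_len = iv[2] - iv[1]
            weights, values = [], []
            for s in segs:
                ov = _overlap(s, iv)
                if ov > 0:
                    weights.append(ov)
                    values.append(s.log2ratio)
            if not weights or sum(weights) < params.arm_coverage_fraction * arm_len:
                continue  # not assessable
            mean = float(np.average(values, weights=weights))
            if mean > params.arm_amp_threshold or mean < params.arm_del_threshold:
                n_altered += 1
        out[sample] = n_altered
    return pd.Series(out, name="arm_level_burden").sort_index()
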