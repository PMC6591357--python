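"""Per-CCGG-site methylation from HpaII-digested WGS alignments.

HpaII cuts C^CGG, but only when the internal (second) cytosine is
unmethylated.  Digesting genomic DNA with HpaII before library preparation
therefore encodes the methylation state of every CCGG site in the *fragment
boundaries* of the sequenced library: an unmethylated site produces fragments
whose ends fall exactly at the cut position, while a methylated site is
spanned intact.  Random shearing produces boundaries everywhere else.

Spanning-fragment pattern taxonomy
----------------------------------
Let ``m`` be the 0-based start of a CCGG motif, so the motif occupies
``[m, m+4)`` and the HpaII cut coordinate is ``c = m + 1`` (between the two
cytosines).  A sequenced fragment ``[fs, fe)`` that overlaps the motif falls
into exactly one of ten classes:

====  =============================================  ===========  ============
 id    boundary configuration                         informative  evidence
====  =============================================  ===========  ============
  1    fs < m and fe > m+4 (spans, flanked)           yes          methylated
  2    spans motif, a boundary at a motif edge        yes          methylated
  3    fe == c, fs < m (upstream cut product)         yes          unmethylated
  4    fe == c, fs == m (bare upstream cut product)   yes          unmethylated
  5    fs == c, fe > m+4 (downstream cut product)     yes          unmethylated
  6    fs == c, fe <= m+4 (truncated cut product)     yes          unmethylated
  7    fs < m, fe inside motif (not at cut)           no           --
  8    fs == m, fe inside motif (not at cut)          no           --
  9    fs inside motif past cut, fe >= m+4            no           --
 10    fragment wholly inside the motif               no           --
====  =============================================  ===========  ============

A fully covered motif proves the molecule was not cut there (methylated
evidence); a boundary exactly at the cut coordinate on either end is cut
evidence (unmethylated) and takes precedence over an interior boundary on the
other end; any other boundary inside the motif is indistinguishable shear and
contributes nothing.  Classes 7-10 are the four uninformative patterns that
overlap the site but are excluded from the level calculation.

The methylation level of the second cytosine is the fraction of informative
fragments carrying methylated evidence, reported only when the site has at
least ``min_informative_reads`` informative fragments.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .io import AlignedReadTable

__all__ = [
    "MethylationParams",
    "PatternClass",
    "CcggSiteCall",
    "PATTERN_TAXONOMY",
    "classify_spanning_read",
    "enumerate_pattern_classes",
    "scan_ccgg",
    "site_methylation_level",
    "call_sample",
    "cohort_methylation_profile",
]

MOTIF = "CCGG"
CUT_OFFSET = 1  # HpaII cuts C^CGG: between motif offsets 0 and 1 (1-based: 1 and 2)


@dataclass(frozen=True)
class MethylationParams:
    min_mapq: int = 20
    min_informative_reads: int = 5

    def __post_init__(self) -> None:
        if not 0 <= self.min_mapq <= 255:
            raise ValueError(f"min_mapq outside [0,255]: {self.min_mapq}")
        if self.min_informative_reads < 1:
            raise ValueError("min_informative_reads must be >= 1")


@dataclass(frozen=True)
class PatternClass:
    id: int
    name: str
    informative: bool
    evidence: str  # methylated / unmethylated / none


PATTERN_TAXONOMY: tuple[PatternClass, ...] = (
    PatternClass(1, "span_flanked", True, "methylated"),
    PatternClass(2, "span_edge", True, "methylated"),
    PatternClass(3, "upstream_cut_flanked", True, "unmethylated"),
    PatternClass(4, "upstream_cut_bare", True, "unmethylated"),
    PatternClass(5, "downstream_cut_flanked", True, "unmethylated"),
    PatternClass(6, "downstream_cut_truncated", True, "unmethylated"),
    PatternClass(7, "left_flank_shear_inside", False, "none"),
    PatternClass(8, "edge_start_shear_inside", False, "none"),
    PatternClass(9, "internal_start_runs_right", False, "none"),
    PatternClass(10, "wholly_internal", False, "none"),
)
_BY_ID = {p.id: p for p in PATTERN_TAXONOMY}


@dataclass(frozen=True)
class CcggSiteCall:
    chrom: str
    motif_start: int
    n_methylated_evidence: int
    n_unmethylated_evidence: int
    level: Optional[float]

    @property
    def n_informative(self) -> int:
        return self.n_methylated_evidence + self.n_unmethylated_evidence


def classify_spanning_read(
    fragment_start: int,
    fragment_end: int,
    mapq: int,
    motif_start: int,
    params: MethylationParams = MethylationParams(),
) -> Optional[PatternClass]:
    """Classify one fragment against one CCGG site.

    Returns ``None`` when the fragment fails the MAPQ threshold (rejected, not
    classified).  Raises if the fragment does not overlap the motif.
    """
    m = motif_start
    c = m + CUT_OFFSET
    motif_end = m + 4
    fs, fe = fragment_start, fragment_end
    if not (fs < motif_end and fe > m):
        raise ValueError(
            f"fragment [{fs},{fe}) does not overlap motif [{m},{motif_end})"
        )
    if mapq < params.min_mapq:
        return None

    if fe == c:  # upstream cut product: molecule cut at this site
        return _BY_ID[3] if fs < m else _BY_ID[4]
    if fs == c:  # downstream cut product
        return _BY_ID[5] if fe > motif_end else _BY_ID[6]
    if fs <= m and fe >= motif_end:  # motif intact within one molecule
        return _BY_ID[1] if (fs < m and fe > motif_end) else _BY_ID[2]
    if fs <= m:  # enters motif from the left, shears inside (not at cut)
        return _BY_ID[7] if fs < m else _BY_ID[8]
    # fs strictly inside the motif, past the cut
    return _BY_ID[9] if fe >= motif_end else _BY_ID[10]


def enumerate_pattern_classes(
    flank: int = 10, params: MethylationParams | None = None
) -> list[PatternClass]:
    """Exhaustively sweep fragment boundaries within ``+-flank`` bp of a motif
    and return the distinct classes the classifier emits.

    Used to verify the taxonomy is a partition: every motif-overlapping
    fragment maps to exactly one class, and the sweep hits all ten.
    """
    params = params or MethylationParams()
    m = flank  # motif on a toy contig at [flank, flank+4)
    seen: dict[int, PatternClass] = {}
    lo, hi = 0, 2 * flank + 4
    for fs in range(lo, hi):
        for fe in range(fs + 1, hi + 1):
            if not (fs < m + 4 and fe > m):
                continue
            cls = classify_spanning_read(fs, fe, 60, m, params)
            assert cls is not None
            seen[cls.id] = cls
    return [seen[i] for i in sorted(seen)]


def scan_ccgg(sequence: str) -> list[int]:
    """Return 0-based start positions of every CCGG occurrence."""
    seq = sequence.upper()
    out = []
    i = seq.find(MOTIF)
    while i != -1:
        out.append(i)
        i = seq.find(MOTIF, i + 1)
    return out


def site_methylation_level(
    fragments: pd.DataFrame,
    chrom: str,
    motif_start: int,
    params: MethylationParams = MethylationParams(),
) -> CcggSiteCall:
    """Aggregate fragment evidence into a site-level methylation call.

    ``fragments`` is the output of :meth:`AlignedReadTable.fragments`.  The
    level is missing (``None``) when informative coverage is below
    ``min_informative_reads``.
    """
    m = motif_start
    sel = fragments[
        (fragments["chrom"] == chrom)
        & (fragments["start"] < m + 4)
        & (fragments["end"] > m)
    ]
    n_meth = n_unmeth = 0
    for fs, fe, mapq in zip(sel["start"], sel["end"], sel["mapq"]):
        cls = classify_spanning_read(int(fs), int(fe), int(mapq), m, params)
        if cls is None or not cls.informative:
            continue
        if cls.evidence == "methylated":
            n_meth += 1
        else:
            n_unmeth += 1
    total = n_meth + n_unmeth
    level = n_meth / total if total >= params.min_informative_reads else None
    return CcggSiteCall(chrom, m, n_meth, n_unmeth, level)


def call_sample(
    table: AlignedReadTable,
    sites: Mapping[str, Sequence[int]] | Sequence[tuple[str, int]],
    params: MethylationParams = MethylationParams(),
) -> list[CcggSiteCall]:
    """Call every CCGG site for one sample.

    ``sites`` is either a mapping chrom -> motif starts (e.g. from
    :func:`scan_ccgg` per contig) or a flat sequence of (chrom, start) pairs.
    """
    if isinstance(sites, Mapping):
        flat = [(c, int(p)) for c, ps in sites.items() for p in ps]
    else:
        flat = [(c, int(p)) for c, p in sites]
    frags = table.fragments()
    return [site_methylation_level(frags, c, p, params) for c, p in flat]


def cohort_methylation_profile(
    calls_by_sample: Mapping[str, Sequence[CcggSiteCall]],
) -> pd.DataFrame:
    """Site x sample matrix of levels, restricted to sites callable in *all*
    samples (joint-coverage rule).  Empty intersection yields an empty frame
    with a warning."""
    import warnings

    if not calls_by_sample:
        raise ValueError("no samples provided")
    per_sample = {}
    callable_sets = []
    for sample, calls in calls_by_sample.items():
        levels = {
            (c.chrom, c.motif_start): c.level for c in calls if c.level is not None
        }
        per_sample[sample] = levels
        callable_sets.append(set(levels))
    shared = sorted(set.intersection(*callable_sets)) if callable_sets else []
    if not shared:
        warnings.warn("no CCGG site callable across all samples")
        return pd.DataFrame(index=pd.MultiIndex.from_tuples([], names=["chrom", "motif_start"]))
    index = pd.MultiIndex.from_tuples(shared, names=["chrom", "motif_start"])
    data = {s: [per_sample[s][k] for k in shared] for s in per_sample}
    return pd.DataFrame(data, index=index)


def write_site_calls(calls: Iterable[CcggSiteCall], path) -> None:
    """BED-like TSV: chrom, motif_start, motif_end, level, n_meth, n_unmeth."""
    with open(path, "w") as fh:
        fh.write("chrom\tmotif_start\tmotif_end\tlevel\tn_meth\tn_unmeth\n")
        for c in calls:
            lv = "" if c.level is None else f"{c.level:.6g}"
            fh.write(
                f"{c.chrom}\t{c.motif_start}\t{c.motif_start + 4}\t{lv}"
                f"\t{c.n_methylated_evidence}\t{c.n_unmethylated_evidence}\n"
            )
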