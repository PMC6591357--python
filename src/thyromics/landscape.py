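"""Variant-retention rules, the alteration matrix, and landscape statistics.

The retention filter keeps rare, functionally relevant variants: population
allele frequency below 0.1% (or absent from the reference database), combined
with either an unconditional loss-of-function effect (nonsense, splice,
frameshift), a missense call judged deleterious by PolyPhen2 *or* SIFT, or a
promoter variant in a telomere-maintenance gene (TERT).  Synonymous variants
are always dropped.

The alteration matrix is the oncoprint-style samples x genes table of
categorical alteration classes on which frequencies, co-mutation tests, TMB
and platform concordance are computed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import FormatError, VariantRecord

__all__ = [
    "FilterParams",
    "AlterationMatrix",
    "TmbRecord",
    "HISTOLOGIES",
    "ALTERATION_CLASSES",
    "LOF_EFFECTS",
    "filter_variants",
    "split_somatic_germline",
    "build_alteration_matrix",
    "alteration_frequency",
    "cooccurrence",
    "platform_concordance",
    "tmb_records",
]

HISTOLOGIES = ("ATC", "PDTC", "focal ATC/PDTC", "wiFTC", "metastatic PTC")
ALTERATION_CLASSES = ("missense", "LoF", "promoter", "fusion", "CN_loss")
LOF_EFFECTS = frozenset({"nonsense", "splice", "frameshift"})
GENE_ROLES = ("oncogene", "TSG", "telomere", "splicing", "fusion")


@dataclass(frozen=True)
class FilterParams:
    max_popmax_af: float = 0.001
    keep_effects_unconditional: frozenset = LOF_EFFECTS
    telomere_genes: frozenset = frozenset({"TERT"})

    def __post_init__(self) -> None:
        if not 0.0 <= self.max_popmax_af <= 1.0:
            raise ValueError(f"max_popmax_af outside [0,1]: {self.max_popmax_af}")


def filter_variants(
    records: Sequence[VariantRecord], params: FilterParams = FilterParams()
) -> list[VariantRecord]:
    """Apply the retention rules.  Pure, idempotent; output is a sublist."""
    out = []
    for r in records:
        if r.popmax_af is not None and r.popmax_af >= params.max_popmax_af:
            continue
        if r.effect in params.keep_effects_unconditional:
            out.append(r)
        elif r.effect == "missense" and (
            r.polyphen_call == "deleterious" or r.sift_call == "deleterious"
        ):
            out.append(r)
        elif r.effect == "promoter" and r.gene in params.telomere_genes:
            out.append(r)
    return out


def split_somatic_germline(
    records: Sequence[VariantRecord],
) -> tuple[set[str], set[str]]:
    """Split mutated genes into two groups.

    Group 1: genes with at least one confirmed-somatic record from a
    WGS/WES-profiled tumor.  Group 2: remaining mutated genes, flagged as
    possibly germline (targeted panels here lack matched normals).
    """
    confirmed: set[str] = set()
    mutated: set[str] = set()
    for r in records:
        mutated.add(r.gene)
        if r.somatic_status == "somatic" and (r.platform or "").upper() in (
            "WGS",
            "WES",
        ):
            confirmed.add(r.gene)
    return confirmed, mutated - confirmed


class AlterationMatrix:
    """Samples x genes categorical alteration calls plus histology labels.

    Cells hold a (possibly empty) set of alteration classes.  Genes carry a
    functional role used to define gene sets (e.g. the TSG set).
    """

    def __init__(
        self,
        samples: Sequence[str],
        histology: Mapping[str, str],
        genes: Sequence[str],
        gene_roles: Mapping[str, str] | None = None,
    ):
        if len(set(samples)) != len(samples):
            raise ValueError("duplicate sample ids")
        if len(set(genes)) != len(genes):
            raise ValueError("duplicate gene symbols")
        for s in samples:
            if s not in histology:
                raise ValueError(f"sample {s!r} lacks a histology label")
            if histology[s] not in HISTOLOGIES:
                raise ValueError(f"unknown histology {histology[s]!r} for {s!r}")
        self.samples = list(samples)
        self.histology = {s: histology[s] for s in samples}
        self.genes = list(genes)
        self.gene_roles = dict(gene_roles or {})
        for g, role in self.gene_roles.items():
            if role not in GENE_ROLES:
                raise ValueError(f"unknown gene role {role!r} for {g!r}")
        self._cells: dict[tuple[str, str], set[str]] = {}

    def add(self, sample: str, gene: str, alteration_class: str) -> None:
        if sample not in self.histology:
            raise ValueError(f"unknown sample {sample!r}")
        if gene not in self.genes:
            raise ValueError(f"unknown gene {gene!r}")
        if alteration_class not in ALTERATION_CLASSES:
            raise ValueError(f"unknown alteration class {alteration_class!r}")
        self._cells.setdefault((sample, gene), set()).add(alteration_class)

    def classes(self, sample: str, gene: str) -> frozenset[str]:
        return frozenset(self._cells.get((sample, gene), ()))

    def has_alteration(self, sample: str, gene: str) -> bool:
        return bool(self._cells.get((sample, gene)))

    def genes_with_role(self, role: str) -> list[str]:
        return [g for g in self.genes if self.gene_roles.get(g) == role]

    def samples_of(self, histology: str) -> list[str]:
        return [s for s in self.samples if self.histology[s] == histology]

    # -- serialization ------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        data = {
            g: [";".join(sorted(self.classes(s, g))) for s in self.samples]
            for g in self.genes
        }
        df = pd.DataFrame(data, index=self.samples)
        df.insert(0, "histology", [self.histology[s] for s in self.samples])
        df.index.name = "sample"
        return df

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t")

    @classmethod
    def read(
        cls, path: str | Path, gene_roles: Mapping[str, str] | None = None
    ) -> "AlterationMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0, keep_default_na=False)
        if "histology" not in df.columns:
            raise FormatError(f"{path}: missing histology column")
        genes = [c for c in df.columns if c != "histology"]
        mat = cls(df.index.tolist(), df["histology"].to_dict(), genes, gene_roles)
        for s in df.index:
            for g in genes:
                cell = df.at[s, g]
                if cell:
                    for klass in str(cell).split(";"):
                        mat.add(s, g, klass)
        return mat


def build_alteration_matrix(
    records: Sequence[VariantRecord],
    histology: Mapping[str, str],
    gene_roles: Mapping[str, str] | None = None,
    extra_calls: Sequence[tuple[str, str, str]] = (),
) -> AlterationMatrix:
    """Build the matrix from retained variants plus non-variant calls.

    ``extra_calls`` carries (sample, gene, class) triples for alterations that
    do not arrive as small variants: copy-number loss and fusions.
    """
    genes = sorted({r.gene for r in records} | {g for _, g, _ in extra_calls})
    mat = AlterationMatrix(sorted(histology), histology, genes, gene_roles)
    for r in records:
        if r.sample is None:
            raise ValueError(f"variant at {r.chrom}:{r.pos} lacks a sample id")
        if r.effect in LOF_EFFECTS:
            klass = "LoF"
        elif r.effect == "promoter":
            klass = "promoter"
        else:
            klass = "missense"
        mat.add(r.sample, r.gene, klass)
    for sample, gene, klass in extra_calls:
        mat.add(sample, gene, klass)
    return mat


def alteration_frequency(
    matrix: AlterationMatrix,
    gene_or_geneset: str | Iterable[str],
    histology: str,
) -> float:
    """Percent of samples of a histology altered in any of the queried genes.

    Reported rounded to two decimals (e.g. 15/27 -> 55.56).
    """
    genes = [gene_or_geneset] if isinstance(gene_or_geneset, str) else list(gene_or_geneset)
    for g in genes:
        if g not in matrix.genes:
            raise ValueError(f"unknown gene {g!r}")
    stratum = matrix.samples_of(histology)
    if not stratum:
        raise ValueError(f"no samples with histology {histology!r}")
    hits = sum(any(matrix.has_alteration(s, g) for g in genes) for s in stratum)
    return round(100.0 * hits / len(stratum), 2)


def cooccurrence(
    matrix: AlterationMatrix,
    gene_set_a: Iterable[str],
    gene_set_b: Iterable[str],
    histology: str,
) -> tuple[np.ndarray, float, float]:
    """2x2 contingency of alteration status in two disjoint gene sets, with
    the two-sided Fisher exact probability (sum over tables with probability
    <= the observed one, at fixed margins).

    Returns (table, odds_ratio, p).  Table rows: altered/not in set A;
    columns: altered/not in set B.
    """
    a, b = set(gene_set_a), set(gene_set_b)
    if a & b:
        raise ValueError(f"gene sets overlap: {sorted(a & b)}")
    stratum = matrix.samples_of(histology)
    if not stratum:
        raise ValueError(f"no samples with histology {histology!r}")
    in_a = np.array([any(matrix.has_alteration(s, g) for g in a) for s in stratum])
    in_b = np.array([any(matrix.has_alteration(s, g) for g in b) for s in stratum])
    table = np.array(
        [
            [int((in_a & in_b).sum()), int((in_a & ~in_b).sum())],
            [int((~in_a & in_b).sum()), int((~in_a & ~in_b).sum())],
        ]
    )
    odds, p = stats.fisher_exact(table, alternative="two-sided")
    return table, float(odds), float(p)


def _variant_key(r: VariantRecord) -> tuple:
    return (r.sample, r.gene, r.chrom, r.pos, r.ref, r.alt)


def _in_region(r: VariantRecord, region: Sequence[tuple[str, int, int]]) -> bool:
    p = r.pos - 1  # region intervals are 0-based half-open
    return any(c == r.chrom and s <= p < e for c, s, e in region)


def platform_concordance(
    calls_a: Sequence[VariantRecord],
    calls_b: Sequence[VariantRecord],
    assessable_region: Sequence[tuple[str, int, int]] | None = None,
    denominator: str = "union",
) -> float:
    """Percent of assessable calls matched between two platforms.

    A match requires the same sample, gene and normalized variant key
    (chrom, pos, ref, alt).  Calls outside ``assessable_region`` (0-based
    half-open intervals, e.g. panel targets) are excluded.  ``denominator``
    chooses the assessable-call set: the union of both platforms' keys
    (default, symmetric) or ``"first"`` (platform A's keys only).
    """
    samples_a = {r.sample for r in calls_a}
    samples_b = {r.sample for r in calls_b}
    shared = samples_a & samples_b
    if not shared:
        raise ValueError("no shared samples between call sets")

    def keys(calls):
        return {
            _variant_key(r)
            for r in calls
            if r.sample in shared
            and (assessable_region is None or _in_region(r, assessable_region))
        }

    ka, kb = keys(calls_a), keys(calls_b)
    assessable = ka | kb if denominator == "union" else ka
    if denominator not in ("union", "first"):
        raise ValueError(f"unknown denominator mode {denominator!r}")
    if not assessable:
        raise ValueError("no assessable calls")
    matched = len(ka & kb)
    return round(100.0 * matched / len(assessable), 2)


@dataclass(frozen=True)
class TmbRecord:
    sample: str
    n_retained_nonsyn: int
    target_size_mb: float

    @property
    def tmb(self) -> float:
        return self.n_retained_nonsyn / self.target_size_mb


def tmb_records(
    retained: Sequence[VariantRecord], target_size_mb: float
) -> list[TmbRecord]:
    """Tumor mutational burden: retained nonsynonymous variants per megabase
    of assayed territory.  The denominator is supplied in config (captured
    target size)."""
    if target_size_mb <= 0:
        raise ValueError("target_size_mb must be positive")
    counts: dict[str, int] = {}
    for r in retained:
        if r.effect == "synonymous" or r.sample is None:
            continue
        counts[r.sample] = counts.get(r.sample, 0) + 1
    return [TmbRecord(s, n, target_size_mb) for s, n in sorted(counts.items())]
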