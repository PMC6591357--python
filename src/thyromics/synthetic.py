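"""Synthetic-cohort generators for every input the pipeline consumes.

The generators emulate the statistical structure of a 113-sample advanced
thyroid cancer cohort: five histologies with their published sample counts,
per-gene alteration prevalences, exponential proportional-hazards survival
with a CDKN2A-loss hazard effect, expression matrices with four separable
molecular subtypes, HpaII-cut fragment reads over a toy genome with known
per-CCGG methylation, and 96-motif mutation catalogs sampled from reference
signatures.  All randomness flows through a single seeded
``numpy.random.Generator`` per call; identical spec + seed gives bitwise
identical serialized output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .io import AlignedReadTable
from .landscape import HISTOLOGIES, AlterationMatrix
from .signatures import MutationCatalog, SignatureReference

__all__ = [
    "CohortSpec",
    "ExpressionSpec",
    "DigestSpec",
    "HpaiiSimulation",
    "DEFAULT_COHORT_SIZES",
    "DEFAULT_PREVALENCE",
    "DEFAULT_MEDIAN_DSS_MONTHS",
    "calibrate_baseline_hazard",
    "generate_cohort",
    "generate_expression",
    "generate_hpaii_reads",
    "generate_signature_catalogs",
]

#: Cohort sizes per histology (published clinicopathological table).
DEFAULT_COHORT_SIZES: dict[str, int] = {
    "ATC": 27,
    "PDTC": 15,
    "focal ATC/PDTC": 28,
    "wiFTC": 12,
    "metastatic PTC": 31,
}

#: Median disease-specific survival in months per histology (published).
DEFAULT_MEDIAN_DSS_MONTHS: dict[str, float] = {
    "ATC": 6.9,
    "PDTC": 60.3,
    "focal ATC/PDTC": 109.2,
    "wiFTC": 25.7,
    "metastatic PTC": 44.0,
}

#: Death-of-disease fractions per histology (published); censoring = 1 - DOD.
_DOD_FRACTION: dict[str, float] = {
    "ATC": 0.741,
    "PDTC": 0.133,
    "focal ATC/PDTC": 0.179,
    "wiFTC": 0.083,
    "metastatic PTC": 0.387,
}

#: Per-gene alteration prevalence by histology (published frequencies / 100).
DEFAULT_PREVALENCE: dict[tuple[str, str], float] = {
    ("ATC", "BRAF"): 0.4074, ("ATC", "RAS"): 0.4444, ("ATC", "TERT"): 0.5556,
    ("ATC", "TP53"): 0.4815, ("ATC", "CDKN2A"): 0.2222, ("ATC", "PTEN"): 0.15,
    ("ATC", "EIF1AX"): 0.15, ("ATC", "AKT1"): 0.07, ("ATC", "PIK3CA"): 0.11,
    ("PDTC", "BRAF"): 0.2667, ("PDTC", "RAS"): 0.2667, ("PDTC", "TERT"): 0.4667,
    ("PDTC", "TP53"): 0.13, ("PDTC", "CDKN2A"): 0.0667, ("PDTC", "PTEN"): 0.05,
    ("PDTC", "EIF1AX"): 0.07, ("PDTC", "AKT1"): 0.03, ("PDTC", "PIK3CA"): 0.05,
    ("focal ATC/PDTC", "BRAF"): 0.8214, ("focal ATC/PDTC", "RAS"): 0.07,
    ("focal ATC/PDTC", "TERT"): 0.3929, ("focal ATC/PDTC", "TP53"): 0.11,
    ("focal ATC/PDTC", "CDKN2A"): 0.0356, ("focal ATC/PDTC", "PTEN"): 0.04,
    ("focal ATC/PDTC", "EIF1AX"): 0.04, ("focal ATC/PDTC", "AKT1"): 0.04,
    ("focal ATC/PDTC", "PIK3CA"): 0.04,
    ("wiFTC", "BRAF"): 0.0, ("wiFTC", "RAS"): 0.6667, ("wiFTC", "TERT"): 0.9167,
    ("wiFTC", "TP53"): 0.0833, ("wiFTC", "CDKN2A"): 0.0, ("wiFTC", "PTEN"): 0.08,
    ("wiFTC", "EIF1AX"): 0.08, ("wiFTC", "AKT1"): 0.0, ("wiFTC", "PIK3CA"): 0.0,
    ("metastatic PTC", "BRAF"): 0.6452, ("metastatic PTC", "RAS"): 0.2258,
    ("metastatic PTC", "TERT"): 0.4739, ("metastatic PTC", "TP53"): 0.13,
    ("metastatic PTC", "CDKN2A"): 0.0645, ("metastatic PTC", "PTEN"): 0.06,
    ("metastatic PTC", "EIF1AX"): 0.06, ("metastatic PTC", "AKT1"): 0.03,
    ("metastatic PTC", "PIK3CA"): 0.06,
}

_GENE_ROLES = {
    "BRAF": "oncogene", "RAS": "oncogene", "AKT1": "oncogene",
    "PIK3CA": "oncogene", "EIF1AX": "oncogene",
    "TP53": "TSG", "CDKN2A": "TSG", "PTEN": "TSG",
    "TERT": "telomere",
}
_GENE_CLASS = {
    "BRAF": "missense", "RAS": "missense", "AKT1": "missense",
    "PIK3CA": "missense", "EIF1AX": "missense",
    "TP53": "LoF", "PTEN": "LoF",
    "CDKN2A": "CN_loss", "TERT": "promoter",
}

# Demographics per histology: (age mean, age sd, male fraction,
# distant-metastasis fraction, (PTC, FTC, unknown) origin fractions).
_DEMOGRAPHICS = {
    "ATC": (64.7, 12.4, 0.370, 0.741, (0.593, 0.296, 0.111)),
    "PDTC": (55.8, 20.1, 0.267, 0.400, (0.400, 0.400, 0.200)),
    "focal ATC/PDTC": (57.9, 16.5, 0.286, 0.250, (0.964, 0.036, 0.0)),
    "wiFTC": (65.4, 12.7, 0.500, 0.833, (0.0, 1.0, 0.0)),
    "metastatic PTC": (60.4, 8.2, 0.290, 1.000, (1.0, 0.0, 0.0)),
}


def calibrate_baseline_hazard(
    target_median_months: float, cdkn2a_prevalence: float, hazard_ratio: float
) -> float:
    """Baseline exponential hazard (per month) such that the *mixture* of the
    CDKN2A-neutral and CDKN2A-deleted sub-populations has the target median.

    Solves q*exp(-h*lam*M) + (1-q)*exp(-lam*M) = 1/2 for lam.
    """
    if target_median_months <= 0:
        raise ValueError("target median must be positive")
    q, h, M = cdkn2a_prevalence, hazard_ratio, target_median_months

    def f(lam: float) -> float:
        return q * math.exp(-h * lam * M) + (1 - q) * math.exp(-lam * M) - 0.5

    return brentq(f, 1e-9, 100.0 / M)


def _per_histology(value, histologies, name: str) -> dict[str, float]:
    if isinstance(value, Mapping):
        missing = [h for h in histologies if h not in value]
        if missing:
            raise ValueError(f"{name} missing histologies {missing}")
        return {h: float(value[h]) for h in histologies}
    return {h: float(value) for h in histologies}


@dataclass(frozen=True)
class CohortSpec:
    """Conditions for the alteration/clinical cohort generator.

    ``baseline_hazard`` and ``censoring_rate`` accept a scalar or a
    per-histology mapping; the defaults reproduce the published per-histology
    median disease-specific survival (the baseline hazard of each stratum is
    calibrated against it, accounting for the CDKN2A-loss mixture) and
    death-of-disease fractions.
    """

    n_per_histology: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_COHORT_SIZES)
    )
    alteration_prevalence: Mapping[tuple[str, str], float] = field(
        default_factory=lambda: dict(DEFAULT_PREVALENCE)
    )
    hazard_ratio_cdkn2a: float = 6.67
    baseline_hazard: float | Mapping[str, float] | None = None
    censoring_rate: float | Mapping[str, float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        for h, n in self.n_per_histology.items():
            if h not in HISTOLOGIES:
                raise ValueError(f"unknown histology {h!r}")
            if n < 0:
                raise ValueError(f"negative count for {h!r}")
        for (h, g), p in self.alteration_prevalence.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"prevalence outside [0,1] for ({h},{g}): {p}")
        if self.hazard_ratio_cdkn2a <= 0:
            raise ValueError("hazard_ratio_cdkn2a must be positive")

    def resolved_hazards(self) -> dict[str, float]:
        hists = list(self.n_per_histology)
        if self.baseline_hazard is None:
            out = {}
            for h in hists:
                q = self.alteration_prevalence.get((h, "CDKN2A"), 0.0)
                out[h] = calibrate_baseline_hazard(
                    DEFAULT_MEDIAN_DSS_MONTHS[h], q, self.hazard_ratio_cdkn2a
                )
            return out
        out = _per_histology(self.baseline_hazard, hists, "baseline_hazard")
        if any(v <= 0 for v in out.values()):
            raise ValueError("baseline hazard must be positive")
        return out

    def resolved_censoring(self) -> dict[str, float]:
        hists = list(self.n_per_histology)
        if self.censoring_rate is None:
            return {h: 1.0 - _DOD_FRACTION[h] for h in hists}
        out = _per_histology(self.censoring_rate, hists, "censoring_rate")
        if any(not 0.0 <= v < 1.0 for v in out.values()):
            raise ValueError("censoring_rate must be in [0,1)")
        return out


def _censoring_window(baseline_hazard: float, censor_rate: float) -> float:
    """Follow-up window W such that uniform censoring on (0, W) censors the
    requested fraction of an Exp(baseline_hazard) population:
    P(censor) = (1 - exp(-lam*W)) / (lam*W), decreasing in W."""
    lam = baseline_hazard

    def f(w: float) -> float:
        return (1.0 - math.exp(-lam * w)) / (lam * w) - censor_rate

    return brentq(f, 1e-9 / lam, 1e9 / lam)


def generate_cohort(spec: CohortSpec) -> tuple[AlterationMatrix, pd.DataFrame]:
    """Draw an alteration matrix and a clinical table under the spec.

    Per-gene alteration indicators are independent Bernoulli draws at the
    configured prevalence.  Survival is exponential proportional-hazards with
    the stratum baseline hazard multiplied by ``hazard_ratio_cdkn2a`` for
    CDKN2A-deleted samples; censoring is uniform over a follow-up window
    sized to the configured censoring rate (non-informative).
    """
    rng = np.random.default_rng(spec.seed)
    genes = sorted({g for _, g in spec.alteration_prevalence})
    hazards = spec.resolved_hazards()
    censoring = spec.resolved_censoring()

    samples, histology = [], {}
    for h in spec.n_per_histology:  # mapping order is part of the spec
        for i in range(spec.n_per_histology[h]):
            sid = f"{h.replace(' ', '_').replace('/', '-')}_{i + 1:03d}"
            samples.append(sid)
            histology[sid] = h

    matrix = AlterationMatrix(samples, histology, genes, _GENE_ROLES)
    clin_rows = []
    for s in samples:
        h = histology[s]
        for g in genes:
            p = spec.alteration_prevalence.get((h, g), 0.0)
            if rng.random() < p:
                matrix.add(s, g, _GENE_CLASS.get(g, "missense"))
        cdkn2a_del = matrix.has_alteration(s, "CDKN2A") if "CDKN2A" in genes else False
        lam = hazards[h] * (spec.hazard_ratio_cdkn2a if cdkn2a_del else 1.0)
        event_time = rng.exponential(1.0 / lam)
        rate = censoring[h]
        if rate > 0:
            w = _censoring_window(hazards[h], rate)
            censor_time = rng.uniform(0.0, w)
        else:
            censor_time = math.inf
        time = min(event_time, censor_time)
        event = int(event_time <= censor_time)

        age_mu, age_sd, male_frac, met_frac, origin_fracs = _DEMOGRAPHICS[h]
        origin = rng.choice(["PTC", "FTC", "unknown"], p=np.asarray(origin_fracs))
        clin_rows.append(
            {
                "sample": s,
                "histology": h,
                "age_at_surgery": round(float(rng.normal(age_mu, age_sd)), 1),
                "sex": "M" if rng.random() < male_frac else "F",
                "distant_metastasis": int(rng.random() < met_frac),
                "tumor_origin": origin,
                "cdkn2a_status": "del" if cdkn2a_del else "2n",
                "time_months": max(float(time), 1e-3),
                "event": event,
            }
        )
    clinical = pd.DataFrame(clin_rows).set_index("sample")
    return matrix, clinical


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------

DEFAULT_SUBTYPES = ("BRAFV600E-like", "RAS-like", "NBNR", "ATC-like")


@dataclass(frozen=True)
class ExpressionSpec:
    """Conditions for the four-subtype expression generator.

    Each subtype owns a disjoint block of ``n_markers_per_subtype`` marker
    genes shifted by ``marker_shift`` standard deviations (default 2, chosen
    so subtype recovery is reliable but not trivial); ``subtype_means``
    overrides the shift per subtype when supplied.
    """

    n_genes: int = 1000
    subtypes: tuple[str, ...] = DEFAULT_SUBTYPES
    n_per_subtype: int | Mapping[str, int] = 30
    n_markers_per_subtype: int = 50
    marker_shift: float = 2.0
    subtype_means: Optional[Mapping[str, float]] = None
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.subtypes) != 4:
            raise ValueError("exactly 4 subtypes required")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.n_genes < len(self.subtypes) * self.n_markers_per_subtype:
            raise ValueError(
                "n_genes smaller than the total number of marker genes"
            )

    def counts(self) -> dict[str, int]:
        if isinstance(self.n_per_subtype, Mapping):
            return {s: int(self.n_per_subtype[s]) for s in self.subtypes}
        return {s: int(self.n_per_subtype) for s in self.subtypes}


def generate_expression(
    spec: ExpressionSpec,
) -> tuple[pd.DataFrame, pd.Series, dict[str, list[str]]]:
    """Returns (genes x samples log2-scale matrix, sample -> subtype truth,
    subtype -> marker genes)."""
    rng = np.random.default_rng(spec.seed)
    genes = [f"G{i + 1:05d}" for i in range(spec.n_genes)]
    counts = spec.counts()
    samples, labels = [], []
    for sub in spec.subtypes:
        for i in range(counts[sub]):
            samples.append(f"{sub.replace(' ', '_')}_{i + 1:03d}")
            labels.append(sub)

    baseline = rng.normal(5.0, 1.0, size=spec.n_genes)  # per-gene log2 baseline
    markers: dict[str, list[str]] = {}
    shift_of: dict[str, float] = {}
    for k, sub in enumerate(spec.subtypes):
        lo = k * spec.n_markers_per_subtype
        markers[sub] = genes[lo : lo + spec.n_markers_per_subtype]
        shift_of[sub] = (
            float(spec.subtype_means[sub])
            if spec.subtype_means is not None
            else spec.marker_shift
        )

    data = np.empty((spec.n_genes, len(samples)))
    for j, sub in enumerate(labels):
        mean = baseline.copy()
        k = spec.subtypes.index(sub)
        lo = k * spec.n_markers_per_subtype
        mean[lo : lo + spec.n_markers_per_subtype] += shift_of[sub]
        noise = rng.normal(0.0, spec.noise_sd, size=spec.n_genes) if spec.noise_sd > 0 else 0.0
        data[:, j] = mean + noise

    matrix = pd.DataFrame(data, index=genes, columns=samples)
    truth = pd.Series(labels, index=samples, name="subtype")
    return matrix, truth, markers


# ---------------------------------------------------------------------------
# HpaII digest reads
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DigestSpec:
    """Conditions for the HpaII-digested WGS read generator over a toy genome.

    ``depth`` is the number of site-overlapping fragments simulated per CCGG
    site; one fragment is emitted per sampled molecule (an intact spanning
    fragment with probability = methylation level, otherwise one of the two
    cut products chosen at random), so informative evidence counts are
    Binomial(depth, level) and the level estimator is unbiased.
    """

    genome_length: int = 50_000
    ccgg_positions: Optional[Sequence[int]] = None
    methylation_truth: Optional[Mapping[int, float]] = None
    read_length: int = 100
    fragment_length_mean: float = 300.0
    fragment_length_sd: float = 50.0
    depth: int = 30
    low_mapq_fraction: float = 0.05
    n_background_fragments: int = 0
    chrom: str = "toy1"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.read_length > self.fragment_length_mean:
            raise ValueError("read_length exceeds mean fragment length")
        if self.ccgg_positions is not None:
            pos = sorted(self.ccgg_positions)
            if pos and (pos[0] < 0 or pos[-1] > self.genome_length - 4):
                raise ValueError("ccgg_positions outside [0, genome_length-4]")
        if self.methylation_truth is not None:
            if any(not 0.0 <= v <= 1.0 for v in self.methylation_truth.values()):
                raise ValueError("methylation_truth values must be in [0,1]")
        if not 0.0 <= self.low_mapq_fraction <= 1.0:
            raise ValueError("low_mapq_fraction must be in [0,1]")
        if self.depth < 1:
            raise ValueError("depth must be >= 1")


@dataclass(frozen=True)
class HpaiiSimulation:
    reads: AlignedReadTable
    truth: pd.DataFrame  # chrom, motif_start, methylation_truth
    sequence: str
    chrom: str


def _default_sites(spec: DigestSpec, rng: np.random.Generator) -> list[int]:
    margin = int(spec.fragment_length_mean + 5 * spec.fragment_length_sd)
    step = 1000
    return list(range(margin, spec.genome_length - 4 - margin, step))


def generate_hpaii_reads(spec: DigestSpec) -> HpaiiSimulation:
    """Simulate HpaII-digested paired-end reads over a toy genome.

    The returned sequence has CCGG planted exactly at the simulated sites (and
    nowhere else), so motif scanning over it recovers the truth table's
    coordinates.
    """
    rng = np.random.default_rng(spec.seed)
    sites = (
        sorted(spec.ccgg_positions)
        if spec.ccgg_positions is not None
        else _default_sites(spec, rng)
    )
    if spec.methylation_truth is not None:
        truth_of = {int(p): float(spec.methylation_truth.get(p, 0.5)) for p in sites}
    else:
        # bimodal, like real methylomes: mostly high or low
        levels = np.where(
            rng.random(len(sites)) < 0.7,
            rng.beta(5, 1, len(sites)),
            rng.beta(1, 5, len(sites)),
        )
        truth_of = {int(p): float(v) for p, v in zip(sites, levels)}

    # toy genome without accidental CCGG: alternate A/T background, then plant
    bg = np.frombuffer((b"AT" * (spec.genome_length // 2 + 1)), dtype="S1")[
        : spec.genome_length
    ].copy()
    for p in sites:
        bg[p : p + 4] = [b"C", b"C", b"G", b"G"]
    sequence = b"".join(bg).decode()

    qnames, chroms, starts, ends, mapqs, mates = [], [], [], [], [], []
    frag_id = 0

    def emit_fragment(fs: int, fe: int, mapq: int) -> None:
        nonlocal frag_id
        frag_id += 1
        base = f"frag{frag_id:07d}"
        fs = max(0, fs)
        fe = min(spec.genome_length, fe)
        if fe - fs <= spec.read_length:  # fragment shorter than one read
            qnames.append(base + "/1")
            chroms.append(spec.chrom)
            starts.append(fs)
            ends.append(fe)
            mapqs.append(mapq)
            mates.append("")
            return
        for suffix, s, e, mate in (
            ("/1", fs, fs + spec.read_length, base + "/2"),
            ("/2", fe - spec.read_length, fe, base + "/1"),
        ):
            qnames.append(base + suffix)
            chroms.append(spec.chrom)
            starts.append(s)
            ends.append(e)
            mapqs.append(mapq)
            mates.append(mate)

    def frag_len() -> int:
        return max(
            spec.read_length + 10,
            int(round(rng.normal(spec.fragment_length_mean, spec.fragment_length_sd))),
        )

    for m in sites:
        c = m + 1  # HpaII cut coordinate (C^CGG)
        p_meth = truth_of[m]
        for _ in range(spec.depth):
            mapq = 10 if rng.random() < spec.low_mapq_fraction else 60
            L = frag_len()
            if rng.random() < p_meth:
                # intact molecule: fragment spans the motif with flanks
                off = int(rng.integers(5, max(6, L - 9)))
                emit_fragment(m - off, m - off + L, mapq)
            elif rng.random() < 0.5:
                emit_fragment(c - L, c, mapq)  # upstream cut product
            else:
                emit_fragment(c, c + L, mapq)  # downstream cut product

    for _ in range(spec.n_background_fragments):
        L = frag_len()
        fs = int(rng.integers(0, max(1, spec.genome_length - L)))
        mapq = 10 if rng.random() < spec.low_mapq_fraction else 60
        emit_fragment(fs, fs + L, mapq)

    frame = pd.DataFrame(
        {
            "qname": qnames,
            "chrom": chroms,
            "start": starts,
            "end": ends,
            "mapq": mapqs,
            "mate_qname": mates,
        }
    )
    truth = pd.DataFrame(
        {
            "chrom": spec.chrom,
            "motif_start": sites,
            "methylation_truth": [truth_of[p] for p in sites],
        }
    )
    return HpaiiSimulation(AlignedReadTable(frame), truth, sequence, spec.chrom)


# ---------------------------------------------------------------------------
# Enhancer peak clusters
# ---------------------------------------------------------------------------

def generate_peaks(
    n_loci: int = 100,
    seed: int = 0,
    chrom: str = "toy1",
    n_promoter_tss: int = 10,
) -> tuple[list, list]:
    """Clusters of H3K27ac-like peaks with a heavy-tailed signal distribution.

    Each locus holds 1-4 peaks within stitching range of one another; loci are
    separated by more than the default 12.5 kb stitch distance.  Per-peak
    signals are lognormal (sigma = 1.5), so a small minority of loci carry
    most of the signal, as super-enhancer rank curves assume.  Also returns a
    TSS list whose first ``n_promoter_tss`` promoters contain one small peak
    each (exercising promoter exclusion).
    """
    from .enhancers import Tss
    from .io import PeakInterval

    rng = np.random.default_rng(seed)
    peaks: list[PeakInterval] = []
    tss: list[Tss] = []
    pos = 10_000
    for i in range(n_loci):
        n_peaks = int(rng.integers(1, 5))
        for _ in range(n_peaks):
            width = int(rng.integers(500, 2_500))
            signal = float(rng.lognormal(mean=2.0, sigma=1.5))
            peaks.append(PeakInterval(chrom, pos, pos + width, signal))
            pos += width + int(rng.integers(500, 12_000))  # within stitch range
        pos += 20_000  # break the cluster
    for i in range(n_promoter_tss):
        t = pos + 10_000
        tss.append(Tss(f"PROM{i + 1}", chrom, t))
        peaks.append(
            PeakInterval(chrom, t - 500, t + int(rng.integers(200, 800)),
                         float(rng.lognormal(1.0, 0.5)))
        )
        pos = t + 10_000
    tss.append(Tss("TERT", chrom, pos + 50_000))
    return peaks, tss


# ---------------------------------------------------------------------------
# Mutation catalogs from reference signatures
# ---------------------------------------------------------------------------

def generate_signature_catalogs(
    reference: SignatureReference,
    mixture: Mapping[str, float],
    n_mutations: int,
    seed: int = 0,
    sample: str = "synthetic",
) -> MutationCatalog:
    """Multinomial draw over the 96 motifs from a mixture of reference rows."""
    if n_mutations <= 0:
        raise ValueError("n_mutations must be positive")
    weights = np.array(list(mixture.values()), dtype=float)
    if not math.isclose(weights.sum(), 1.0, abs_tol=1e-9):
        raise ValueError(f"mixture weights sum to {weights.sum()}, expected 1")
    probs = np.zeros(96)
    for name, w in mixture.items():
        probs += w * reference.row(name)  # KeyError on unknown signature
    probs /= probs.sum()
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(n_mutations, probs)
    return MutationCatalog(sample, counts)
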