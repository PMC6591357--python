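"""End-to-end orchestration of the pipeline stages on synthetic data.

``run_pipeline`` executes the stages in dependency order under one YAML-style
config (validated against known keys), writes every stage's outputs under the
output directory, and records a manifest with the effective config, the seed
and a sha256 per output file.  Deterministic stages reproduce identical
hashes on rerun with the same config.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd

from . import cna, enhancers, io, landscape, methylation, outcome, scores, signatures
from .subtypes import ClusterParams, subtype_pipeline
from .synthetic import (
    CohortSpec,
    DigestSpec,
    ExpressionSpec,
    generate_cohort,
    generate_expression,
    generate_hpaii_reads,
    generate_peaks,
    generate_signature_catalogs,
)

__all__ = ["PipelineConfig", "run_pipeline"]

_KNOWN_KEYS = {
    "seed",
    "outdir",
    "cohort",
    "expression",
    "digest",
    "enhancers",
    "signatures",
    "survival",
}
_KNOWN_SUBKEYS = {
    "cohort": {"hazard_ratio_cdkn2a", "censoring_rate", "n_per_histology"},
    "expression": {"n_genes", "n_per_subtype", "n_markers_per_subtype",
                   "marker_shift", "noise_sd"},
    "digest": {"genome_length", "depth", "read_length"},
    "enhancers": {"n_loci", "stitch_distance", "promoter_window"},
    "signatures": {"n_mutations", "n_flat", "n_apobec"},
    "survival": {"covariates"},
}


@dataclass(frozen=True)
class PipelineConfig:
    seed: int = 0
    outdir: Path = Path("thyromics_run")
    options: Mapping[str, Mapping[str, Any]] = field(default_factory=dict)

    @classmethod
    def from_mapping(cls, raw: Mapping[str, Any]) -> "PipelineConfig":
        unknown = set(raw) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        options = {}
        for section, sub in raw.items():
            if section in ("seed", "outdir"):
                continue
            bad = set(sub) - _KNOWN_SUBKEYS[section]
            if bad:
                raise ValueError(f"unknown key(s) in {section!r}: {sorted(bad)}")
            options[section] = dict(sub)
        return cls(
            seed=int(raw.get("seed", 0)),
            outdir=Path(raw.get("outdir", "thyromics_run")),
            options=options,
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_mapping(raw)

    def opt(self, section: str) -> dict:
        return dict(self.options.get(section, {}))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage on a freshly simulated cohort; returns the manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = config.seed
    written: list[Path] = []

    def save_frame(df: pd.DataFrame, name: str, **kwargs) -> None:
        path = outdir / name
        df.to_csv(path, sep="\t", **kwargs)
        written.append(path)

    # --- simulate -----------------------------------------------------------
    cohort_spec = CohortSpec(seed=seed, **config.opt("cohort"))
    matrix, clinical = generate_cohort(cohort_spec)
    matrix.write(outdir / "alterations.tsv")
    written.append(outdir / "alterations.tsv")
    save_frame(clinical, "clinical.tsv")

    expr_spec = ExpressionSpec(seed=seed + 1, **config.opt("expression"))
    expr, truth, markers = generate_expression(expr_spec)
    io.write_expression(expr, outdir / "expression.tsv")
    written.append(outdir / "expression.tsv")
    save_frame(truth.to_frame(), "subtype_truth.tsv")

    digest_spec = DigestSpec(seed=seed + 2, **config.opt("digest"))
    sim = generate_hpaii_reads(digest_spec)
    io.write_alignments(sim.reads, outdir / "hpaii_reads.tsv")
    written.append(outdir / "hpaii_reads.tsv")
    save_frame(sim.truth, "methylation_truth.tsv", index=False)

    # --- landscape ----------------------------------------------------------
    freq_rows = []
    for hist, n in cohort_spec.n_per_histology.items():
        if n == 0:
            continue
        for gene in matrix.genes:
            freq_rows.append(
                {
                    "histology": hist,
                    "gene": gene,
                    "frequency_pct": landscape.alteration_frequency(matrix, gene, hist),
                }
            )
        tsgs = matrix.genes_with_role("TSG")
        freq_rows.append(
            {
                "histology": hist,
                "gene": "TSG_set",
                "frequency_pct": landscape.alteration_frequency(matrix, tsgs, hist),
            }
        )
    save_frame(pd.DataFrame(freq_rows), "landscape_frequencies.tsv", index=False)

    # --- cna: segments consistent with the simulated CDKN2A status ----------
    params = cna.CnaParams()
    chrom, lo, hi = params.gene_loci["CDKN2A"]
    segs = []
    for s in matrix.samples:
        deleted = matrix.has_alteration(s, "CDKN2A")
        segs.append(io.Segment(s, chrom, lo - 50_000, hi + 50_000,
                               -1.2 if deleted else 0.0))
    io.write_segments(segs, outdir / "segments.seg")
    written.append(outdir / "segments.seg")
    save_frame(cna.gene_deletion_table(segs, "CDKN2A", params), "cdkn2a_calls.tsv")

    # --- scores + subtype on the marker-defined signatures -------------------
    sub_names = list(expr_spec.subtypes)
    braf_markers, ras_markers = markers[sub_names[0]], markers[sub_names[1]]
    brs_sig = scores.GeneSignature(
        "BRS-demo",
        tuple(braf_markers + ras_markers),
        class_labels={**{g: "BRAF-like" for g in braf_markers},
                      **{g: "RAS-like" for g in ras_markers}},
    )
    tds_sig = scores.GeneSignature("TDS-demo", tuple(markers[sub_names[2]]))
    table = pd.DataFrame(
        {
            "tds": scores.centered_set_score(expr, tds_sig),
            "brs": scores.brs(expr, brs_sig),
        }
    )
    save_frame(table, "scores.tsv")

    reference = {
        s: sub for s, sub in truth.items() if sub != "ATC-like"
    }  # DTC reference cohort; the fourth cluster must emerge unaided
    histology = {s: ("ATC" if sub == "ATC-like" else "wiFTC")
                 for s, sub in truth.items()}
    assignment = subtype_pipeline(
        expr, histology, reference,
        ClusterParams(seed=seed, n_components=3),  # k-1 components resolve k=4
    )
    save_frame(assignment, "subtypes.tsv")

    # --- methylation ---------------------------------------------------------
    sites = [(r.chrom, int(r.motif_start)) for r in sim.truth.itertuples()]
    calls = methylation.call_sample(sim.reads, sites)
    methylation.write_site_calls(calls, outdir / "methylation_calls.tsv")
    written.append(outdir / "methylation_calls.tsv")

    # --- enhancers -----------------------------------------------------------
    enh_opt = config.opt("enhancers")
    peaks, tss = generate_peaks(n_loci=enh_opt.pop("n_loci", 100), seed=seed + 3)
    eparams = enhancers.EnhancerParams(**enh_opt) if enh_opt else enhancers.EnhancerParams()
    stitched = enhancers.split_super(enhancers.stitch(peaks, tss, eparams))
    save_frame(
        pd.DataFrame(
            [
                {"chrom": e.chrom, "start": e.start, "end": e.end,
                 "signal": e.signal, "rank": e.rank, "is_super": e.is_super}
                for e in stitched
            ]
        ),
        "enhancers.tsv",
        index=False,
    )

    # --- mutational signatures: 16 WGS-like tumors (15 flat-type, 1 APOBEC) --
    sig_opt = config.opt("signatures")
    n_mut = sig_opt.get("n_mutations", 10_000)
    ref = signatures.synthetic_reference_signatures()
    catalogs = [
        generate_signature_catalogs(
            ref, {"Signature 5": 1.0}, n_mut, seed=seed + 10 + i, sample=f"WGS{i + 1:02d}"
        )
        for i in range(sig_opt.get("n_flat", 15))
    ] + [
        generate_signature_catalogs(
            ref, {"Signature 2": 1.0}, n_mut, seed=seed + 99, sample="WGS16"
        )
        for _ in range(sig_opt.get("n_apobec", 1))
    ]
    save_frame(signatures.assign_signatures(catalogs, ref), "signature_assignments.tsv")

    # --- survival ------------------------------------------------------------
    covariates = config.opt("survival").get(
        "covariates", list(outcome.DEFAULT_COVARIATES)
    )
    if clinical["cdkn2a_status"].nunique() >= 2:
        medians, logrank_p = outcome.km_median_and_logrank(clinical, "cdkn2a_status")
        try:
            cox = outcome.cox_ph(clinical, "cdkn2a_status", covariates)
        except (ValueError, RuntimeError) as exc:
            cox = {"error": str(exc)}
        survival_summary = {
            "km_median_months": medians,
            "logrank_p": logrank_p,
            "cox_cdkn2a": cox,
        }
    else:
        survival_summary = {"note": "single CDKN2A stratum; no comparison possible"}
    with open(outdir / "survival_summary.json", "w") as fh:
        json.dump(survival_summary, fh, indent=2)
    written.append(outdir / "survival_summary.json")

    manifest = {
        "seed": seed,
        "config": {k: dict(v) for k, v in config.options.items()},
        "outputs": {p.name: _sha256(p) for p in sorted(written)},
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
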