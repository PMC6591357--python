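# thyromics

Genomic and transcriptomic analysis of **advanced thyroid cancer** cohorts:
anaplastic thyroid cancer (ATC) and advanced differentiated thyroid cancers
(poorly differentiated, widely invasive follicular, metastatic papillary).
These tumors are rare and fatal — ATC has a median disease-specific survival
of months — and their molecular characterization combines several analyses
that this package implements as one tested, scriptable pipeline for
bioinformaticians working with variant tables, copy-number segments,
expression matrices, H3K27ac peaks and HpaII-digested WGS alignments.

## What it computes

* **Alteration landscape** — variant retention (population MAF < 0.1%;
  loss-of-function kept unconditionally; missense kept when PolyPhen2 *or*
  SIFT calls it deleterious; TERT promoter variants kept), somatic/germline
  gene grouping, oncoprint-style alteration matrix, per-histology alteration
  frequencies, Fisher-exact co-mutation/exclusivity, tumor mutational burden,
  and cross-platform call concordance.
* **Copy number** — homozygous-deletion calls (segment log2 ratio ≤ −0.6
  over the gene locus, e.g. *CDKN2A*) and GISTIC-like arm-level SCNA burden.
* **Transcriptome scores** — thyroid differentiation score (TDS, 16 genes)
  and ERK score (52 genes) as means of median-centered log2 expression, and
  the BRAF^V600E–RAS score (BRS, 71 genes) as a signed single-sample
  enrichment (ssGSEA) contrast: negative = BRAF-like, positive = RAS-like.
* **Molecular subtyping** — PCA + k-means (k = 4) with reference-majority
  cluster naming, recovering BRAF^V600E-like, RAS-like, NBNR and the
  ATC-dominated fourth cluster, **ATC-like**.
* **DNA methylation from HpaII-digested WGS** — HpaII cuts C^CGG only at
  unmethylated sites, so fragment boundaries encode methylation; a
  10-class spanning-fragment taxonomy (4 classes uninformative, MAPQ ≥ 20,
  ≥ 5 informative fragments) yields per-CCGG methylation levels.
* **Super-enhancers** — ROSE-style stitching (12.5 kb, TSS ± 2 kb promoter
  exclusion) and the super/typical split at the rank–signal inflection
  point, plus through-junction enhancer–gene distances for
  enhancer-hijacking rearrangements.
* **Mutational signatures** — 96-motif pyrimidine-strand catalogs and
  per-sample signature assignment by average-linkage/cosine clustering
  against a 30-signature reference panel.
* **Outcome statistics** — Kaplan–Meier medians, log-rank tests, Cox
  proportional hazards with clinical covariates, DEG thresholds
  (adjusted P < 0.05, |log2FC| ≥ 1) and hypergeometric pathway
  over-representation with BH control.
* **Synthetic cohort generator** — produces every input above with the
  published cohort's structure (113 samples across five histologies,
  published alteration prevalences, survival calibrated to the published
  medians with a CDKN2A-loss hazard ratio of 6.67), so the full pipeline
  runs end to end with no external data.

See `docs/methods.md` for the models, parameter defaults and numerical
choices.

## Worked example

```python
from thyromics.synthetic import CohortSpec, generate_cohort
from thyromics.landscape import alteration_frequency
from thyromics.outcome import km_median_and_logrank, cox_ph

matrix, clinical = generate_cohort(CohortSpec(seed=1))   # 113 samples
print(alteration_frequency(matrix, "TERT", "wiFTC"))     # 91.67
print(alteration_frequency(matrix, "TERT", "ATC"))       # 59.26
med, p = km_median_and_logrank(clinical, "cdkn2a_status")
print({k: round(v, 1) for k, v in med.items()})          # {'del': 4.4, '2n': 44.5}
fit = cox_ph(clinical, "cdkn2a_status",
             ["age_at_surgery", "sex", "distant_metastasis", "tumor_origin"])
print(round(fit["hr"], 2), round(fit["ci_low"], 2), round(fit["ci_high"], 2))
# 9.85 4.42 21.95
```

The wiFTC TERT frequency is 91.67% (11/12 — at prevalence 0.9167 every draw
hit in this seed); the ATC frequency 59.26% is the sampling realization of
the configured 55.56% prevalence at n = 27. CDKN2A-deleted samples die of
disease far earlier (median 4.4 vs 44.5 months across the pooled cohort),
and the covariate-adjusted Cox hazard ratio estimate of 9.85
(95% CI 4.42–21.95) covers the generating hazard ratio of 6.67 — at 113
samples the estimate is noisy, which is exactly what the generator lets you
quantify.

The same run from the shell:

```bash
thyromics pipeline demo --outdir demo --seed 1
```

writes the alteration matrix, clinical table, expression matrix, HpaII reads
and truth tables, per-stage outputs (frequencies, CDKN2A calls, scores,
subtypes, methylation levels, enhancers, signature assignments, survival
summary) and a `manifest.json` with a sha256 per output; rerunning with the
same seed reproduces the hashes.

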