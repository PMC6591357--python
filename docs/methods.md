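# Methods

`thyromics` re-implements, as one tested pipeline, the analyses used to
characterize a 113-tumor cohort of advanced thyroid cancers (27 anaplastic
[ATC], 15 poorly differentiated [PDTC], 28 focal ATC/PDTC, 12 widely invasive
follicular [wiFTC], 31 metastatic papillary [PTC]). A synthetic-cohort module
generates every input the pipeline consumes, so the whole analysis runs with
no external or controlled-access data. This note records the models, the
parameters that matter, the numerical choices, and what the synthetic data do
and do not establish.

## Variant retention and the alteration landscape

A variant is retained when its population allele frequency is below 0.1% (or
it is absent from the reference database) **and** it is either an
unconditional loss-of-function effect (nonsense, splice-site, frameshift), a
missense call judged deleterious by PolyPhen2 *or* SIFT, or a promoter
variant in a telomere-maintenance gene (TERT). Synonymous variants are always
dropped. Deleteriousness is consumed as pre-computed annotation columns and
never recomputed. Mutated genes are split into a confirmed-somatic group
(at least one somatic call from a WGS/WES tumor with a matched normal) and a
possibly-germline group (seen only on matched-normal-free targeted panels).

Alteration frequencies are reported as percentages rounded to two decimals
(15/27 → 55.56), matching the cohort's reporting style. Mutual exclusivity
uses the two-sided Fisher exact test — the sum of hypergeometric
probabilities, at fixed margins, of all tables no more probable than the
observed one (`scipy.stats.fisher_exact`; a brute-force enumeration oracle
checks it in the tests). Platform concordance counts matched
(sample, gene, chrom, pos, ref, alt) keys over the assessable calls; because
it is not published whether the denominator is one platform's calls within
the panel regions or the union of both, both modes are exposed
(`denominator="union"` is the default, which is symmetric). Tumor mutational
burden is retained nonsynonymous variants per megabase; the denominator
(captured target size) is supplied in config because no standard exists.

## Copy number

A gene is called homozygously deleted when any segment overlapping its locus
has log2 copy ratio ≤ −0.6, inclusive ("any overlap" rather than containment,
since focal deletions straddle segment boundaries). The threshold is taken as
given; it was calibrated upstream against WGS and the calibration data are
not available. Arm-level burden is a GISTIC-like convention: an arm counts as
altered when segments cover ≥ 50% of it and their length-weighted mean log2
ratio exceeds +0.2 or falls below −0.2. All three thresholds are
config-exposed (`CnaParams`).

## Transcriptome scores

* **TDS** (thyroid differentiation score) and the **ERK score** are
  centered-set scores: each signature gene's log2 expression is
  median-centered across all samples of the supplied matrix, and the score is
  the mean of centered values over the signature genes present (missing genes
  are skipped with a warning). Whether the original centering cohort included
  the DTC reference samples is ambiguous; the module centers over whatever
  matrix it is given, so both modes are available by construction.
* **ssGSEA**: per sample, genes are ordered by descending expression (stable
  sort; ties broken by input order); the gene at position *i* (0-based, *N*
  genes) carries rank statistic *N − i* and weight *(N − i)^α*, α = 0.25 by
  default (the common single-sample enrichment default; the original tool's
  parameters are not published, so α is config-exposed). The score is the sum
  over the ordering of (weighted in-set ECDF − uniform out-of-set ECDF) — the
  integrated form. All-constant samples are an error (ranks undefined).
* **BRS** = ssGSEA(RAS-like half) − ssGSEA(BRAF-like half) of a 71-gene
  labelled signature, divided by the cohort's maximum absolute contrast so
  values lie in [−1, 1] with the sign preserved: negative = BRAF-like
  (the TCGA sign convention; a min-max rescale would not preserve the sign,
  so scaling is by max |raw| instead).

The shipped signature files (`data/tds16.synthetic.tsv`,
`erk52.synthetic.tsv`, `brs71.synthetic.tsv`) carry 16/52/71 genes. The exact
published gene identities live in a supplement that cannot be redistributed
here, so the files are curated stand-ins (well-known thyroid differentiation
markers for TDS; MAPK transcriptional-output genes for ERK; plausible
BRAF-like vs RAS-like markers for BRS), flagged `synthetic` in their names.
The set sizes and the file format are the tested contract; every scoring
operation accepts any user-supplied signature file.

## Subtype clustering

Expression is embedded by PCA over the top variance-ranked genes (default
2000; per-gene centering; SVD), with each component's sign fixed by making
its largest-magnitude loading positive so embeddings are reproducible.
k-means (k-means++ seeding, 25 restarts, fixed seed) with k = 4 assigns
clusters, which are then named by the strict-majority reference subtype they
contain; a cluster with no reference majority whose ATC fraction is ≥ 0.5 is
named **ATC-like**. Name clashes go to the cluster with the higher reference
fraction; the loser is flagged with `*`.

The default embedding uses 2 components, mirroring the 2-D subtype plots.
For *recovery* analyses (and in the end-to-end pipeline) 3 components are
used: four balanced clusters whose centroids form a regular simplex span a
3-D subspace, and a 2-D projection can collapse two of them — k clusters
need k − 1 components in the worst case. The component count is a
`ClusterParams` field.

## HpaII-digest methylation

HpaII cuts C^CGG only when the internal cytosine is unmethylated, so
digesting DNA before WGS encodes per-CCGG methylation in fragment
boundaries. The classifier works on *fragments* (joined mate pairs), because
a cut manifests as a fragment boundary, and reads with MAPQ < 20 are
rejected before classification. The published description states that 10
spanning-read patterns exist and 4 are excluded, without enumerating them;
the taxonomy here (documented in full in `methylation.py`) is constructed
from boundary logic so that it is a partition of all motif-overlapping
fragments with exactly that structure:

* methylated evidence (2 classes): the motif is fully covered inside one
  fragment — flanked on both sides, or with a boundary exactly at a motif
  edge;
* unmethylated evidence (4 classes): a boundary exactly at the cut
  coordinate (motif offset 1) — upstream products (flanked or bare) and
  downstream products (flanked or truncated). A cut boundary takes
  precedence over an interior boundary on the other end;
* uninformative (4 classes): a boundary inside the motif that is not at the
  cut — indistinguishable from shear.

This realization is faithful but not unique; the classification *rule*, not
the class identities, is the tested contract. The site's methylation level is
methylated evidence / informative evidence, reported only at ≥ 5 informative
fragments, for the second cytosine only (reverse-strand CpGs are not scored
separately). Cohort profiles keep only sites callable in **all** samples.

## Super-enhancers

Peaks fully contained in a promoter window (TSS ± 2000 bp) are removed
before stitching (per constituent peak, in that order); survivors merge
transitively at gaps ≤ 12,500 bp, and the stitched signal is the sum of
constituent signals (background subtraction happens upstream and is out of
scope). The super/typical split scales rank and signal each to [0, 1] on the
ascending curve and places the cutoff at the point whose local tangent slope
(3-point discrete window; one-sided at the edges — a discrete scan is
deterministic and oracle-checkable, unlike spline fits) is closest to 1,
restricted to the upper tail (at or beyond the first slope ≥ 1, rightmost on
ties); enhancers with signal strictly above the cutoff are super. Raw
(unsmoothed) curves are the default. Enhancer–gene distance is 0 when the
TSS lies inside the enhancer, else the gap to the nearest edge; across
chromosomes a rearrangement junction must be supplied and the distance is
measured through it (enhancer→breakpoint + partner breakpoint→TSS), which is
how hijacked-enhancer distances are evaluated.

## Mutational signatures

Single-base substitutions are mapped to the pyrimidine strand (purine refs
reverse-complemented with their flanks) and accumulated into the standard
96-motif catalog. Samples are assigned a reference signature by clustering
their probability vectors *jointly* with the reference rows (average
linkage, cosine distance) and taking the reference their cluster first
co-merges with; when several references join at once the most
cosine-similar one wins, and the nearest-reference cosine similarity is
always reported as a sanity fallback. Distance metric and assignment rule
are not published beyond "average hierarchical clustering"; cosine with
first-co-merge is this package's documented choice. De novo extraction
(NMF) is deliberately out of scope.

The published 30-signature reference panel is distributed by COSMIC and is
not redistributable, so the package ships a deterministic **synthetic**
stand-in (`synthetic_reference_signatures()`): "Signature 1" concentrates
C>T at NpCpG, "Signature 2" concentrates C>T/C>G at TpCpA/TpCpT
(APOBEC-like), "Signature 5" is near-flat, and the rest are sparse, mutually
well-separated profiles (pairwise cosine < 0.9, asserted in tests).
`load_signature_reference()` accepts the real COSMIC TSV when available.

## Survival and enrichment

Kaplan–Meier estimates use lifelines; the median is the first time with
S(t) ≤ 0.5. Two-group comparisons use the log-rank statistic against
χ²(1). Cox proportional-hazards fits use Efron tie handling (the common
default; the original tie method is not published) with the clinical
covariates age at surgery, sex, distant metastasis and tumor origin;
categorical covariates are dummy-coded against the first sorted level (the
reference coding is config-visible because the published coding is not
stated). DEGs pass adjusted P strictly < 0.05 and |log2FC| ≥ 1 (inclusive).
Pathway enrichment is a hypergeometric over-representation test with
Benjamini–Hochberg adjustment and ranked top-k reporting — a re-implementation
choice standing in for the original web tool.

## The synthetic cohort: what it emulates, and what it does not

`CohortSpec` defaults reproduce the published study conditions: the five
histology sample counts (27/15/28/12/31), per-gene alteration prevalences
taken from the published frequencies, a CDKN2A-loss hazard ratio of 6.67,
and per-histology exponential baseline hazards *calibrated* so that the
mixture of CDKN2A-neutral and deleted sub-populations reproduces the
published median disease-specific survival (6.9 / 60.3 / 109.2 / 25.7 / 44.0
months). No generative survival model is published — only fitted hazard
ratios — so exponential proportional hazards is this package's choice.
Censoring is per-subject uniform on (0, W), with W solved so the expected
censored fraction matches the configured rate (defaults: one minus the
published death-of-disease fractions); uniform-window censoring is
non-informative, so Cox recovery is unbiased. Both hazard and censoring
accept a scalar or a per-histology map.

`ExpressionSpec` gives each of the four subtypes a disjoint block of 50
marker genes shifted by 2 standard deviations over a per-gene baseline —
separation the published effect sizes do not quantify; 2 SD was chosen once
so that recovery is reliable but not trivial. `DigestSpec` emits one
fragment per sampled molecule per CCGG site (an intact spanning fragment
with probability equal to the methylation level, otherwise one of the two
cut products at random), so informative evidence counts are
Binomial(depth, level) and the site estimator is unbiased; emitting both cut
products would double-count unmethylated evidence. Fragment lengths are
Normal(300, 50) bp, echoing the 300-bp shearing target; a configurable
fraction of reads carries MAPQ 10 to exercise the quality filter.

What passing tests on these data show: the estimators recover their
generating parameters (hazard ratios, methylation levels, subtype labels,
signature identities) at the study's sample sizes. What they do not show:
robustness to real-data features the generators omit — sequencing error,
alignment artifacts, correlated genes, batch effects, subclonality,
informative censoring, or linked multi-omic structure beyond the subtype
labels.

## Problem sizes used in the checks

Recovery analyses run at sizes chosen to make the binomial/Wald noise small
relative to the tolerances: Cox recovery at 1000 samples (≈500 per arm) over
20 seeds; signature recovery at 10,000 mutations × 30 references × 20
replicates; subtype recovery at 120 samples × 1000 genes over 20 seeds;
methylation recovery at depth 500 over 20 sites spanning levels 0–1; the
ssGSEA and super-enhancer implementations are checked against independent
brute-force oracles (500 random instances; all signal vectors over
{1, 4, 16} up to length 8).

## Known limitations

* The 10-pattern taxonomy is one faithful realization of an unpublished
  classification; class *identities* may differ from the original.
* Shipped signature gene lists and the reference signature panel are
  synthetic/curated stand-ins (sizes and shapes are contractual, identities
  are not); supply the real files where licensing allows.
* The alteration generator draws genes independently, so co-mutation and
  exclusivity structure (e.g. AKT1/PIK3CA vs EIF1AX) is not emulated unless
  configured explicitly.
* Arm-level burden needs arm definitions supplied by the user; none are
  bundled.
* No FASTQ emission, sequencing-error model, or fusion-detection stage.
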