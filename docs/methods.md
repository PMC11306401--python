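# Methods

`magicrv` implements the post-calling stages of a rare-variant
case-control exome study and the single-cell polygenic burden score
(scPBS) that projects case-control burden onto individual cells of an
scRNA-seq dataset. This note records the models, the defaults and their
rationale, the numerical choices, and what the synthetic validation does
and does not establish.

## Qualifying variants and cohort QC

Coding variants are classified into four mutually exclusive classes:

* **PTV** — consequence in {frameshift, splice acceptor, splice donor,
  stop gained, start lost};
* **D-mis** — missense-family consequence with PolyPhen-2
  "probably damaging" **and** SIFT "deleterious" **and** CADD (PHRED) > 20;
* **B-mis** — concordant benign PolyPhen-2/SIFT calls **or** CADD < 15 on
  a missense-family consequence;
* **synonymous** — the negative-control class;

everything else is OTHER. The conjunction for D-mis is strict: a missing
predictor can never yield D-mis, while the CADD < 15 route to B-mis stands
on its own. A variant is *qualifying* when its folded minor-allele
frequency is below 0.5% both in the cohort and in every reference panel
attached to its annotation (a panel without a recorded frequency counts
as zero). MAF is computed on non-missing alleles.

QC proceeds call → site → sample. Calls with depth < 10, genotype quality
< 20, or a heterozygous allele balance outside [0.2, 0.8] are set to
missing; sites in low-complexity regions, failing the upstream VQSR flag
(consumed, never recomputed), with call rate < 90%, or with an exact
Hardy–Weinberg p < 1e-6 on the combined cohort are dropped, the first
matching reason being reported. The HWE test is the exact conditional
test: given the allele counts, the heterozygote count has a known
discrete distribution and the two-sided p sums the probabilities of all
configurations no more probable than the observed one (no mid-p). Sample
QC applies hard thresholds (call rate ≥ 0.9, mean depth ≥ 10, mean GQ
≥ 65) and then a single-pass 4-SD outlier exclusion on the Ti/Tv, het/hom
and ins/del ratios, computed among the samples that survive the hard
thresholds. Sex is inferred from the X-chromosome inbreeding coefficient
F = 1 − observed/expected heterozygosity (strict thresholds: male above
0.8, female below 0.4, excluded otherwise — boundary values excluded).
Ancestry PCs come from common variants (MAF > 1%) centered at 2p and
scaled by sqrt(2p(1−p)); signs are fixed so each component's
largest-magnitude loading is positive, making outputs reproducible.
Case-control matching is greedy nearest-neighbor without replacement in
the top-3 PC space, cases in input order, ties to the lowest control id —
deterministic by construction.

## Burden testing

Carrier coding is the field's collapsing convention: an indicator of at
least one qualifying allele in the unit (gene or gene set); allele-count
coding is available behind `mode="count"`. Missing genotypes count as
non-carrier — the 90% site call-rate floor bounds the information loss,
and the number of affected calls is logged. The per-sample *total exome
count* (qualifying alleles summed over all four classes) is the
sequencing-intensity covariate.

Two tests are provided. The Fisher exact test uses the two-sided
minimum-likelihood convention; the reported odds ratio is the sample OR
(ad)/(bc), with a Haldane 0.5 correction applied — and flagged — only
when a cell is zero, and a log-OR normal-approximation 95% CI. The
Firth-penalized logistic regression maximizes l(β) + ½ log|I(β)|
(Jeffreys prior), which keeps estimates finite under the complete or
quasi-complete separation that sparse carrier tables produce. Newton
iterations use the Firth-adjusted score with step-halving so the
penalized likelihood never decreases; convergence requires max |score| <
1e-6 and max |Δβ| < 1e-8 within 100 iterations. Inference on the burden
coefficient is the penalized likelihood-ratio test: the null maximizes
the same penalized likelihood with that coefficient pinned at zero while
retaining the full design's information matrix in the penalty, so the
two log-likelihoods are on a common scale (dropping the column and
re-penalizing in the smaller dimension mis-calibrates the test — an
exactly balanced null predictor then gets p ≈ 0.1 instead of ≈ 1). Wald
standard errors are reported for CIs. The most conservative model uses
sex, PC1–PC10 and the total exome count as covariates.

The gene-set scan applies Benjamini–Hochberg FDR across the scanned
collection; the per-gene collapsing scan uses Bonferroni (α divided by
the number of genes carrying at least one qualifying variant) and builds
the expected p-value curve for QQ plots by permuting case-control labels
(1000 by default), sorting each permutation's p-values and averaging
rank by rank. The length-matched resampling null draws gene sets
reproducing the target set's composition across coding-length deciles
(deciles are our binning choice; sampling is without replacement within
a decile, with replacement — warned — when a decile is too small), with
empirical p = (1 + #{resampled ≥ observed}) / (B + 1), which can never
be zero. Genomic control uses λ = median(χ²)/0.456 and divides the
statistics by λ only when λ > 1. All resampling requires an explicit
seed; there is no global RNG state.

## scPBS

Expression lives in an `AnnData` (counts in `X`, log1p library-normalized
values in `layers["lognorm"]`, cell types in `obs["cell_type"]`).
Specificity of gene g in type c is the per-type mean expression scaled to
TPM, divided by the gene's maximum TPM across types — in [0, 1], with
every expressed gene attaining 1 in its most specific type. The pipeline
is:

1. **Per-cell gene sets.** Each cell's expressed genes are scored by
   (cell-level log-normalized expression) × (specificity of the cell's
   type); the top 10% (ceiling of the cell's expressed-gene count) form
   its set, ties broken lexicographically. The published description
   ("highly expressed genes specific to each cell") admits several
   formalizations; this one uses both quoted ingredients and is exposed
   as a parameter. Cells with < 10 expressed genes are skipped.
2. **Per-cell burden.** A sample is a carrier for a cell if it carries a
   qualifying PTV in any gene of the cell's set. The cell's score (scPBS)
   is the Firth log-odds coefficient of that indicator with the full
   covariate set; cells whose set has no carriers score 0 and are
   null-flagged (excluded downstream rather than imputed). We work on the
   log-OR scale rather than the OR so the null is 0 and correlations are
   symmetric. Identical carrier patterns across cells are fitted once
   (a cache keyed on the indicator bytes; results are bit-identical).
3. **Trait-relevant genes and rvTRS.** Each gene's Pearson correlation
   with scPBS across non-flagged cells ranks the genes (zero-variance
   genes excluded); the top decile are the trait-relevant genes. The
   rvTRS of a cell is the mean log-normalized expression of the trait
   genes minus that of a control pool — 100 control genes per trait gene
   drawn (seeded) from the trait gene's bin among 25 equal-frequency bins
   of average expression, the standard module-score construction. Its
   expectation under random trait-gene draws is 0.

Cell-type-level enrichment tests the union of each type's top-10% marker
genes for PTV carrier burden, with the synonymous class as a negative
control. Marker ranking is one-vs-rest with a tie-corrected Wilcoxon
rank-sum z statistic under Seurat-style filters (positive ln fold change
≥ 0.25 computed on un-logged normalized means with pseudocount 1,
detection fraction ≥ 0.1); the published analysis used a mixed-model DE
test at this step, which is out of scope here — the filters and the
top-10% convention are preserved. Upstream clustering, batch correction
and embeddings are consumed as inputs, never computed.

## Synthetic data

The generator creates the coupled ground truth the pipeline assumes.
Cohort: per gene, controls carry a qualifying PTV with probability equal
to the baseline carrier rate; for causal genes the case probability is
the baseline odds multiplied by the target OR, so the planted OR is
exactly the estimand of a carrier test. Each carrier is materialized as
one of the gene's 3 synthetic frameshift variants (echoing a three-PTV
top gene), with sub-0.5% reference frequencies, HC loss-of-function
flags, Bernoulli(0.5) sex, standard-normal PCs, and a Poisson(100)
background plus carried alleles as the total exome count. Expression:
negative-binomial counts (over-dispersion α = 0.3; α → 0 degenerates to
Poisson) around log-normal gene means modulated by per-(gene, type)
lognormal effects of scale 0.35 — without such pervasive between-type
variation almost no non-marker gene passes the log-FC filter and
top-fraction marker lists degenerate — plus an exp(2) mean shift for
each type's 15 planted marker genes. The linked fixture sets the causal
gene set to one designated type's markers.

Default study conditions: 500 cases / 500 controls, 1000 genes, baseline
carrier rate 0.01, planted OR 5, 5 cell types × 200 cells. At these
sizes the causal-gene case carrier rate is ≈ 4.8% versus 1% in controls;
aggregated over the 15-gene causal set the case/control carrier split is
roughly 52% vs 14%, ample for rank-1 recovery while keeping a full
20-replicate recovery run to a few minutes on one CPU.

What the simulation does *not* emulate: linkage disequilibrium, realistic
site-frequency spectra, population structure correlated with carriage,
batch effects, doublets or ambient RNA. Passing recovery therefore shows
the pipeline correctly extracts the signal it defines, not that the
signal is identifiable in any real cohort.

## Numerical and degenerate-input choices

* Exact tests tolerate ties with a 1e-12 relative slack when summing
  "no more probable" configurations; monomorphic HWE tables return 1.
* Degenerate 2×2 margins (an empty row/column) return p = 1 with an
  undefined OR rather than erroring, and zero-carrier units are
  null-flagged.
* PCA returns fewer components (warned) on degenerate input; identical
  samples yield all-zero scores.
* Firth non-convergence raises an error carrying the last iterate.
* All writers are deterministic given config + seeds and record a JSON
  manifest (config hash, seeds, input checksums); output directories are
  not overwritten without `force`.

## Validation problem sizes

The test suite checks exact-test implementations against exact-fraction
enumeration oracles on seeded samples of margins up to 200 (the full
cross-product of all such margins is ~1e8 tables; a sampled grid of
~150 margin configurations with every table enumerated within each
sampled configuration gives the same coverage of the tie and edge cases
at desk scale), the Firth solver against a zooming grid maximizer of the
penalized likelihood on 2-parameter designs, type-I error over 2000
seeded null cohorts of 200/200, and ground-truth recovery over 20 seeded
replicates at the default study conditions.

## Known limitations

* SKAT/SKAT-O/ACAT and mixed-model association are not reimplemented; a
  hook accepts externally computed per-gene p-values for joint reporting.
* The marker-gene test is a rank-sum approximation to mixed-model DE.
* The per-cell gene-set rule is one of several defensible readings of
  the published description; results for real data may be sensitive to
  it (it is a parameter, not a constant).
* Firth CIs are Wald-based; profile-likelihood CIs are not implemented.
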