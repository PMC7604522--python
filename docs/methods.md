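# Methods

This note documents the statistical model behind `lncqtl`, the choices
made where the design was genuinely open, and what the synthetic-cohort
tests do and do not establish about behaviour on real data.

## Association model

Expression of each lncRNA, after quantile normalisation and a rank-based
inverse normal transform (INT), is regressed on additive SNP dosage with
age, sex and K latent expression factors as covariates. The scan uses the
Frisch–Waugh–Lovell fast path: expression and dosage are residualised on
the covariate block once (via QR), and each pair's slope, t statistic
(n − p − 1 degrees of freedom) and p-value follow from cross-products.
This is algebraically identical to per-pair OLS; the test suite asserts
agreement to |Δβ| < 10⁻¹⁰.

Missing dosages are mean-imputed per SNP for the scan (the matrix-scan
convention); the multivariate refit instead drops incomplete samples.
Constant covariates (e.g. sex in a single-sex cohort) are dropped from the
design rather than producing a singular fit.

**Cis/trans definition.** The cis window is anchored to the full feature
interval — [start − 1 Mb, end + 1 Mb] — not the TSS, and "trans" is the
complement of that window (including other chromosomes). Strand is
carried in the annotation but ignored for windowing.

**Multiple testing.** Cis pairs: Benjamini–Hochberg FDR, computed per
mode across all tested cis pairs of a cohort. Trans pairs: fixed p < 10⁻⁷
gate. With the generator's defaults the trans yield is sparse — a trans
effect of 0.5 at n = 300 rarely clears 10⁻⁷ after INT — which mirrors the
deliberate stringency of the gate.

**Scales.** INT is the scan's default response scale; it makes the t test
exact under the null but attenuates slopes by the total latent standard
deviation, so generative effect sizes are recovered in their own units on
the log2(RPKM + 1) scale (which equals the generator's latent scale
whenever expression is above the flooring point). Parameter-recovery
tests therefore scan the log2 scale; calibration tests use INT.

## Latent expression factors

PEER-style latent covariates are computed as the top-K left singular
vectors of the expression matrix after residualising on the known
covariates, standardised, with a deterministic sign convention
(largest-magnitude loading positive). K defaults to 5. This surrogate is
validated behaviourally: a planted batch shift is recovered by factor 1
with point-biserial |r| > 0.9, pure-noise factors explain roughly the
Marchenko–Pastur top-edge share, and including the factors restores
power on batch-confounded data. The surrogate lacks PEER's automatic
relevance determination, so K is a fixed choice rather than inferred.

## QC rules and boundary conventions

* Purity: samples with purity ≥ 0.6 are kept (boundary kept).
* Genotype QC order: INFO ≥ 0.5 → posterior masking (calls with
  posterior < 0.7 set missing; skipped when no posteriors are supplied,
  since nothing in the inputs supports the rule then) → missing rate
  < 5% → MAF ≥ 5% on non-missing calls → exact HWE p > 10⁻⁶. A QC report
  row per filter satisfies removed + retained = input.
* HWE: exact conditional test (enumeration of heterozygote counts given
  allele counts, summing probabilities ≤ the observed table's, with a
  10⁻¹² relative tolerance on the equality). An exact test rather than
  chi-square because the 10⁻⁶ cutoff lives deep in the tail.
* lncRNA detection: keep iff q10(RPKM) > 0 **and** q90(RPKM) > 0.1,
  with linear-interpolation quantiles. The two published rules are
  combined with AND — the only reading under which both have effect.
* Methylation: per-sample median beta over a feature's TSS200/TSS1500
  probes, binned at 0.2 and 0.6; medians exactly at a cutoff fall in the
  middle level (1). Features without probes get a missing level and are
  fitted without the methylation term.
* Inverse normal transform: Blom offset, Φ⁻¹((r − 3/8)/(n + 1/4)),
  average ranks for ties; no offset is canonical and Blom is the common
  default in eQTL practice.
* Quantile normalisation reference: the across-sample mean of sorted
  per-sample vectors; ties within a sample receive the mean of the
  reference values they span.

## Clumping and validation

Clumping is greedy: repeatedly take the lowest-p unassigned SNP as tag
and absorb every unassigned SNP within 500 kb with genotypic r² ≥ 0.2
(squared Pearson correlation of dosages, pairwise-complete — the
phase-free composite r²). Ties on p break deterministically by
(chrom, pos, snp_id), a documented convention where reference
implementations leave the order to floating-point sorting. Clumps
partition the input; the suite checks this against an independent greedy
oracle.

The multivariate validation refits each feature's most significant cis
tag (plus its most significant trans tag, when one exists — the choice
among several trans tags is an interpretation, flagged as such) together
with age, sex, latent factors, SCNA and the ordinal methylation level,
dropping incomplete samples and raising a named error on collinear
designs.

## Variance partition

Nested plain-R² increments in the fixed order age, sex, latent factors,
cis tag, trans tag, SCNA, methylation (configurable; sequential R² is
order-dependent and the order is part of the definition). Plain rather
than adjusted R² so increments are non-negative up to rounding; tiny
negative numerical increments are floored at zero and counted. The
telescoping identity Σ increments = full-model R² is asserted to 10⁻⁹,
and per-feature increments are averaged after flooring.

## Enrichment statistics

All enrichments are 2×2 Fisher exact tests (two-sided by default) with
the Woolf log-interval 95% CI; the Haldane 0.5 correction is applied to
the odds ratio and CI only when a zero cell occurs. A "fold" statistic —
the ratio of flagged proportions — is emitted alongside the OR because
both conventions appear in the enrichment literature; a zero background
proportion yields an infinite fold with the Haldane-corrected OR as the
finite summary. The fold-enrichment background defaults to QC-passing,
tested-but-not-significant SNPs and is configurable, since "non-eQTL" is
not otherwise pinned down. Peak membership is point-in-interval on the
0-based half-open BED convention (a 1-based position p is inside
[start, end) iff start ≤ p − 1 < end).

Meta-analysis pools per-stratum log-ORs by inverse variance: the
fixed-effect estimate, Cochran's Q, I², the DerSimonian–Laird τ², and
the random-effects estimate (reported by default). Implemented directly
— the estimator is closed-form arithmetic — and verified against a
hand-computed two-stratum example.

## Instrumental-variable estimation

One instrument per exposure (the cis clump tag). Stage 1 regresses the
lncRNA on instrument plus covariates; stage 2 regresses the outcome on
the fitted exposure plus covariates. Standard errors are homoskedastic
2SLS errors computed from the **structural** residuals y − βx − Cδ, not
the stage-2 residuals; with a single instrument and no covariates the
estimator reduces exactly to the Wald ratio (asserted to 10⁻¹⁰). The
reported adjusted R² is that of the structural fit. First-stage partial
F < 10 flags a weak instrument; flagged rows are reported, never
silently dropped, because filtering on F would itself induce selection.

mRNA outcomes are log2(count + 1); candidate genes must pass CV > 0.5,
q30(log2(count+1)) > 0, q90 > 5, and |Spearman ρ| > 0.3 against the
exposure. Axes are BH-FDR-controlled across all tested axes of a run and
reported at FDR < 0.1 with adjusted R² > 0.1. Immune-cell fractions are
log2(fraction + 1)-transformed and tested per cell type at p < 0.05 with
model R² > 0; treating compositional fractions independently follows the
analysis convention and is a documented limitation (a positive effect on
one cell type mechanically depresses others).

**Known small-sample behaviour.** The 2SLS t-test is conservative at
small n with a moderate instrument (null rejection ≈ 0.02–0.03 at
n = 100, first-stage F ≈ 20); it is well calibrated by n ≈ 400. The
calibration suite therefore evaluates uniformity of null p-values at
cohort-scale n = 400, and the weak-instrument flag exists precisely
because inference degrades as F falls.

## Synthetic cohorts

The generator emulates exactly the structure the method assumes:

* **Genotypes.** Per LD block, haplotypes come from a latent AR(1)
  Gaussian thresholded at the MAF quantile; the latent autocorrelation is
  solved numerically (bivariate-normal orthant probability, Brent's
  method) so adjacent-haplotype r² hits its target. Two independent
  haplotypes per sample are summed, so HWE holds by construction —
  verified by null calibration of the exact test. Defaults: ten 50-SNP
  blocks, MAF 0.3, adjacent r² 0.5, one block per chromosome. INFO
  scores are drawn Uniform(0.4, 1) (so the INFO filter has work to do;
  planted-effect SNPs get INFO 1), and 1% of calls are set missing.
* **Expression.** Latent log2-scale expression is the additive model
  itself: intercept 3 + cis effect 0.5 + trans effect 0.5 + age/sex
  effects (0.1) + five latent factors (loading sd 0.3) + SCNA (0.3) +
  methylation (0.2) + N(0, 1) noise; RPKM = 2^latent − 1 floored at 0.
  10% of non-effect lncRNAs get a deeply negative intercept so the
  detection filter has true positives to remove. Setting
  `scna_geno_corr` > 0 loads SCNA on the cis genotype, creating exactly
  the confounding the multivariate refit is meant to remove.
* **Downstream.** Five of 100 mRNAs are true mediation targets:
  latent = 6 + 1.5·(x − x̄) + 0.8·u + noise, where u is the standardised
  residual of the lncRNA on its cis SNP — a shared confounder that biases
  OLS of y on x upward while leaving the SNP a valid instrument (it is
  orthogonal to the genotype by construction). Counts are
  round(2^latent − 1). Immune fractions are the row-softmax of five
  per-cell-type linear predictors, one driven by the first cis lncRNA
  (γ = 0.5); rows sum to 1 exactly.
* Cohort defaults (300 samples, 500 SNPs, 50 lncRNAs, 100 mRNAs, 5 cell
  types) sit inside the range of the tumour cohorts this design targets
  (tens to a few hundred samples) while keeping the full test suite and
  the acceptance script to seconds of runtime; recovery and calibration
  checks use the sizes stated with each check (n = 500 single-SNP
  replicates for effect coverage, n = 400 for IV calibration, a
  150 × 100 × 100 null cohort for the 10,000-pair type-I check). The
  single-SNP recovery replicates use intercept 5 so the RPKM link stays
  in its linear regime and the generative β is recovered in its own
  units.

What the synthetic tests do **not** show: the generator makes no attempt
to mimic real allele-frequency spectra, gene lengths, realistic LD maps,
RNA-seq count overdispersion beyond the lognormal link, or the
complicated missingness of tumour covariates. Passing tests demonstrate
that each estimator recovers the quantity it defines under its own
assumptions and that the pipeline's plumbing is correct — not that those
assumptions hold in any particular cancer cohort.

## Determinism and degenerate inputs

Every simulation consumes an explicit integer seed through NumPy
Generators (`[seed, stage]` seed sequences), and all analysis stages are
deterministic functions of their inputs, so a full file-based run is
byte-reproducible. Degenerate inputs have defined behaviour: features
with no admissible cis SNP yield an empty record set; monomorphic SNPs
are skipped with a log entry; constant expression vectors, empty
universes, inverted BED intervals, out-of-range thresholds and
collinear designs raise errors that name the offending item.
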