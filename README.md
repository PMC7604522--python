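# lncqtl

Mapping the germline genetic determinants of long non-coding RNA (lncRNA)
expression in tumour cohorts, and estimating what those determinants do
downstream.

Tumour transcriptomes are shaped simultaneously by germline variants,
somatic copy-number alterations (SCNA), promoter CpG methylation, tumour
purity and latent technical structure. `lncqtl` implements, as a tested and
reusable pipeline, the full chain of analyses needed to isolate the
germline signal for lncRNAs and trace it forward:

1. **QC** — sample filtering by tumour purity (≥ 0.6); genotype filtering by
   imputation INFO ≥ 0.5, best-guess call posterior ≥ 0.7, missing rate
   < 5%, MAF ≥ 5%, and an exact Hardy–Weinberg test (p > 10⁻⁶); lncRNA
   detection filtering (10th-percentile RPKM > 0 and 90th-percentile
   RPKM > 0.1).
2. **Normalisation** — quantile normalisation across samples, then a
   rank-based inverse normal transform per lncRNA; log2(RPKM + 1) is kept
   as an alternative reportable scale.
3. **cis/trans eQTL scan** — for each SNP *g* and lncRNA *y*,

   &nbsp;&nbsp;&nbsp;&nbsp;*yᵢ = β₀ + β₁ gᵢ + β₂ ageᵢ + β₃ sexᵢ + Σₖ γₖ Fₖᵢ + εᵢ*

   by OLS, where *Fₖ* are latent expression factors (a residual-SVD
   surrogate for PEER, K = 5). Cis means the SNP lies within 1 Mb of the
   feature; everything beyond that 2-Mb interval, or on another chromosome,
   is trans. Cis pairs are controlled at Benjamini–Hochberg FDR < 0.1,
   trans pairs at p < 10⁻⁷.
4. **LD clumping** — greedy collapse of significant SNPs into haplotype
   blocks (r² ≥ 0.2 within 500 kb), each represented by its most
   significant tag eSNP.
5. **Multivariate validation** — tag SNPs are re-fitted jointly with age,
   sex, latent factors, per-gene SCNA and the discretised promoter
   methylation level (cutoffs 0.2/0.6 on the TSS200/TSS1500 median beta).
6. **Variance partition** — sequential R² increments in the fixed order
   age → sex → latent factors → cis tag → trans tag → SCNA → methylation.
7. **Enrichment** — LD interception with GWAS risk loci (proxies at
   r² ≥ 0.5 within 500 kb), Fisher-exact set and ChIP-seq peak-overlap
   enrichment with odds ratios and fold statistics, and inverse-variance
   (fixed and DerSimonian–Laird random-effects) meta-analysis across
   epigenetic markers.
8. **Mendelian randomization** — each clump tag serves as the genetic
   instrument for its lncRNA; two-stage least squares (2SLS) estimates the
   causal effect of the lncRNA on mRNA expression (regulatory axes at
   FDR < 0.1 with adjusted R² > 0.1) and on log2-transformed immune-cell
   fractions, with first-stage-F weak-instrument diagnostics. With a
   single instrument the estimator equals the Wald ratio
   cov(y, g)/cov(x, g).

Because the cohorts this kind of study uses are access-controlled, the
package ships a first-class synthetic-cohort generator
(`lncqtl.synthetic_data`) that reproduces the statistical structure every
stage assumes — Hardy–Weinberg genotypes in LD blocks, the additive
expression model above, lncRNA-mediated mRNA, softmax immune fractions —
together with ground-truth effect tables, so every stage is verified by
parameter recovery rather than by fixture files.

## Worked example

```python
from lncqtl import *

cfg = SimulationConfig(seed=1)          # 300 samples, 500 SNPs, 50 lncRNAs
geno, lnc, cov, mrna, immune, truth = simulate_cohort(cfg)

lnc_f, _ = filter_lncrna_expression(lnc)
E = inverse_normal(quantile_normalize(lnc_f))
cov.latent_factors = estimate_latent_factors(E, k=5, covariates=cov)

cis = scan_eqtl(geno, E, cov, mode="cis")
cis["fdr"] = bh_fdr(cis["p"].to_numpy())
sig = cis[cis["fdr"] < 0.1]
clumped = clump_all(sig, geno)
print(f"{len(cis)} cis pairs tested, {len(sig)} significant (FDR<0.1), "
      f"{clumped['is_tag'].sum()} clump tags, "
      f"{sig['feature_id'].nunique()} cis-elncRNAs")

axes = run_axes(clumped, geno, log2_rpkm(lnc_f), mrna, cov)
hit = axes[axes["passes"]].iloc[0]
print(f"top axis: {hit['instrument']} -> {hit['exposure']} -> {hit['outcome']}  "
      f"beta={hit['beta']:.2f}  fdr={hit['fdr']:.2e}  F={hit['first_stage_f']:.1f}")
```

prints

```
1250 cis pairs tested, 214 significant (FDR<0.1), 60 clump tags, 25 cis-elncRNAs
top axis: snp_chr2_25 -> ln_001 -> mr_001  beta=1.36  fdr=8.49e-16  F=31.1
```

All 25 lncRNAs with a planted cis effect (β = 0.5) are detected, and the
top regulatory axis recovers the planted mediation effect (α = 1.5; the
2SLS estimate 1.36 is within two standard errors) through a strong
instrument (first-stage F = 31).

The same pipeline runs from files via the CLI:

```bash
lncqtl --seed 1 --outdir cohort/ simulate        # write a synthetic cohort
lncqtl --config cfg.yaml --outdir results/ all   # QC -> ... -> MR, all stages
```

where `cfg.yaml` names the input paths and overrides any thresholds
(all defaults are the analysis settings listed above).

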