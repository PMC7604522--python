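"""Synthetic cohort generator with known ground truth.

Generates genotype, expression, covariate, mRNA and immune-fraction data
with exactly the statistical structure the analysis assumes, so every
pipeline stage has a parameter-recovery test:

* Haplotypes come from a Gaussian copula: a latent AR(1) normal per LD
  block, thresholded at the quantile giving the target minor-allele
  frequency, with the latent autocorrelation solved numerically so the
  *haplotype* allele correlation hits the target r^2.  Two independent
  haplotypes per sample are summed, so Hardy-Weinberg equilibrium holds by
  construction.
* lncRNA expression follows the additive model on a latent log2 scale:
  intercept + cis/trans genotype effects + age + sex + latent-factor
  loadings + SCNA + methylation + Gaussian noise; RPKM = 2^latent - 1
  floored at zero, so log2(RPKM + 1) returns the latent scale and the
  detection filters have real work to do.
* mRNA is mediated by a designated lncRNA (optionally with a confounder
  shared between lncRNA and mRNA, constructed from the lncRNA's
  non-genetic residual so the cis SNP stays a valid instrument), and
  immune-cell fractions are a softmax of per-cell-type linear predictors,
  one of them driven by a designated lncRNA.

Every quantity with a nonzero planted effect is recorded in a
:class:`TruthTable`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .core_io import (
    CovariateTable,
    ExpressionMatrix,
    FEATURE_META_COLUMNS,
    GenotypeMatrix,
    ImmuneFractionTable,
    SNP_META_COLUMNS,
    get_logger,
)

logger = get_logger("synthetic_data")


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic cohort.

    Defaults describe a mid-sized tumour cohort: 300 samples (the study's
    cohorts range from 42 to 459), ten 50-SNP LD blocks at MAF 0.3 with
    adjacent-haplotype r^2 0.5, 50 lncRNAs (half with a planted cis eQTL of
    effect 0.5, ten with an additional trans eQTL), 100 mRNAs of which five
    are true mediation targets with alpha = 1.5, and five immune cell types
    with one lncRNA-driven fraction.
    """

    n_samples: int = 300
    blocks: list = field(default_factory=lambda: [(50, 0.3, 0.5)] * 10)
    n_lncrna: int = 50
    n_mrna: int = 100
    n_cis: int = 25          # lncRNAs with a planted cis eQTL
    n_trans: int = 10        # of those, how many also get a trans eQTL
    n_axes: int = 5          # mRNAs truly mediated by a cis lncRNA
    n_cell_types: int = 5
    # effect grid
    cis_beta: float = 0.5
    trans_beta: float = 0.5
    mediation_alpha: float = 1.5
    immune_gamma: float = 0.5
    # confounder scales
    sd_latent: float = 0.3
    beta_scna: float = 0.3
    beta_meth: float = 0.2
    beta_age: float = 0.1
    beta_sex: float = 0.1
    scna_geno_corr: float = 0.0   # SCNA loading on the cis genotype (confounding)
    confound_share: float = 0.8   # shared lncRNA->mRNA confounder scale
    noise_sd: float = 1.0
    mrna_noise_sd: float = 0.5
    mrna_null_sd: float = 1.5
    immune_noise_sd: float = 0.5
    n_latent_true: int = 5
    # nuisance structure
    lnc_intercept: float = 3.0
    mrna_intercept: float = 6.0
    low_expr_fraction: float = 0.1
    miss_rate: float = 0.01
    purity_alpha: float = 8.0
    purity_beta: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 20:
            raise ValueError("n_samples must be >= 20")
        for n_snps, maf, r2 in self.blocks:
            if not (0 < maf <= 0.5):
                raise ValueError(f"target_maf {maf} outside (0, 0.5]")
            if not (0 <= r2 < 1):
                raise ValueError(f"target_r2 {r2} outside [0, 1) (r2=1 is degenerate)")
            if n_snps < 1:
                raise ValueError("block must contain at least one SNP")
        if self.n_cis > self.n_lncrna or self.n_trans > self.n_cis:
            raise ValueError("n_trans <= n_cis <= n_lncrna required")
        if self.n_axes > min(self.n_cis, self.n_mrna):
            raise ValueError("n_axes must not exceed n_cis or n_mrna")


@dataclass
class TruthTable:
    """Ground-truth effects of one simulated cohort."""

    eqtl: pd.DataFrame        # snp_id, feature_id, mode, true_beta
    mediation: pd.DataFrame   # lncrna_id, mrna_id, true_alpha
    immune: pd.DataFrame      # lncrna_id, cell_type, true_gamma

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.eqtl.to_csv(outdir / "truth_eqtl.tsv", sep="\t", index=False)
        self.mediation.to_csv(outdir / "truth_mediation.tsv", sep="\t", index=False)
        self.immune.to_csv(outdir / "truth_immune.tsv", sep="\t", index=False)

    @classmethod
    def read(cls, outdir: str | Path) -> "TruthTable":
        outdir = Path(outdir)
        return cls(
            eqtl=pd.read_csv(outdir / "truth_eqtl.tsv", sep="\t"),
            mediation=pd.read_csv(outdir / "truth_mediation.tsv", sep="\t"),
            immune=pd.read_csv(outdir / "truth_immune.tsv", sep="\t"),
        )


# ---------------------------------------------------------------------------
# Genotypes
# ---------------------------------------------------------------------------


def latent_autocorrelation(maf: float, target_r2: float) -> float:
    """Latent-normal correlation giving adjacent-allele r^2 = ``target_r2``.

    For alleles defined by thresholding standard normals at the MAF
    quantile, the allele (phi) correlation is
    ``(Phi2(t, t; rho) - maf^2) / (maf (1 - maf))``; this inverts that
    relation numerically so the achieved haplotype correlation is
    ``sqrt(target_r2)``.
    """
    if target_r2 == 0:
        return 0.0
    t = stats.norm.ppf(maf)
    target_r = np.sqrt(target_r2)

    def gap(rho: float) -> float:
        p11 = stats.multivariate_normal(cov=[[1.0, rho], [rho, 1.0]]).cdf([t, t])
        return (p11 - maf * maf) / (maf * (1.0 - maf)) - target_r

    return float(optimize.brentq(gap, 0.0, 0.999999, xtol=1e-10))


def simulate_genotypes(config: SimulationConfig) -> GenotypeMatrix:
    """Draw HWE genotypes in AR(1) LD blocks (one block per chromosome)."""
    rng = np.random.default_rng([config.seed, 1])
    n = config.n_samples
    meta_rows, dos_cols = [], []
    for b, (m, maf, r2) in enumerate(config.blocks):
        rho = latent_autocorrelation(maf, r2)
        t = stats.norm.ppf(maf)
        z = np.empty((2 * n, m))
        z[:, 0] = rng.standard_normal(2 * n)
        innov = rng.standard_normal((2 * n, max(m - 1, 0)))
        for j in range(1, m):
            z[:, j] = rho * z[:, j - 1] + np.sqrt(1 - rho * rho) * innov[:, j - 1]
        alleles = (z < t).astype(float)  # alt allele is the minor allele
        dosage = alleles[0::2] + alleles[1::2]
        if config.miss_rate > 0:
            dosage[rng.random((n, m)) < config.miss_rate] = np.nan
        info = rng.uniform(0.4, 1.0, size=m)
        chrom = f"chr{b + 1}"
        for j in range(m):
            meta_rows.append(
                dict(
                    snp_id=f"snp_{chrom}_{j}",
                    chrom=chrom,
                    pos=1_000_000 + j * 5_000,
                    ref_allele="A",
                    alt_allele="G",
                    info_score=info[j],
                    maf=np.nan,
                )
            )
        dos_cols.append(dosage)
    snps = pd.DataFrame(meta_rows, columns=SNP_META_COLUMNS)
    dosage = np.concatenate(dos_cols, axis=1)
    samples = [f"S{i:04d}" for i in range(n)]
    return GenotypeMatrix(samples=samples, snps=snps, dosage=dosage)


def _effect_snp_indices(geno: GenotypeMatrix, config: SimulationConfig) -> tuple[list[int], list[int]]:
    """Pick one cis SNP per cis lncRNA and one trans SNP per trans lncRNA.

    Cis SNPs cycle over blocks (middle of each block, stepping within the
    block on reuse); trans SNPs are taken from the *next* chromosome so
    they are guaranteed off-chromosome for their feature.
    """
    chroms = geno.snps["chrom"].unique()
    by_chrom = {c: np.flatnonzero((geno.snps["chrom"] == c).to_numpy()) for c in chroms}
    cis_idx, trans_idx = [], []
    used: set[int] = set()
    for i in range(config.n_cis):
        c = chroms[i % len(chroms)]
        pool = [j for j in by_chrom[c] if j not in used]
        if not pool:
            raise ValueError("not enough SNPs to place cis effects")
        j = pool[len(pool) // 2]
        used.add(j)
        cis_idx.append(j)
    for i in range(config.n_trans):
        c_cis = geno.snps["chrom"].iloc[cis_idx[i]]
        c = chroms[(list(chroms).index(c_cis) + 1) % len(chroms)]
        pool = [j for j in by_chrom[c] if j not in used]
        if not pool:
            raise ValueError("not enough SNPs to place trans effects")
        j = pool[len(pool) // 3]
        used.add(j)
        trans_idx.append(j)
    return cis_idx, trans_idx


def _impute_mean(dosage: np.ndarray) -> np.ndarray:
    d = dosage.copy()
    mu = np.nanmean(d, axis=0)
    miss = np.isnan(d)
    if miss.any():
        d[miss] = np.take(mu, np.nonzero(miss)[1])
    return d


def simulate_expression(
    genotypes: GenotypeMatrix, config: SimulationConfig
) -> tuple[ExpressionMatrix, CovariateTable, TruthTable]:
    """Generate lncRNA RPKM, covariates and ground truth from genotypes.

    The latent log2-scale expression of feature f is

        intercept_f + beta_cis g_cis + beta_trans g_trans
        + beta_age (age-60)/10 + beta_sex sex + L @ loadings_f
        + beta_scna SCNA_f + beta_meth (M_f - 1) + N(0, noise_sd^2)

    and RPKM = 2^latent - 1 floored at 0.  A ``low_expr_fraction`` of
    non-effect lncRNAs gets a deeply negative intercept so their
    10th-percentile RPKM is 0 and the detection filter removes them.
    """
    rng = np.random.default_rng([config.seed, 2])
    n, p = config.n_samples, config.n_lncrna
    cis_idx, trans_idx = _effect_snp_indices(genotypes, config)
    D = _impute_mean(genotypes.dosage)

    age = rng.normal(60.0, 10.0, size=n)
    sex = rng.integers(0, 2, size=n).astype(float)
    purity = rng.beta(config.purity_alpha, config.purity_beta, size=n)
    L = rng.standard_normal((n, config.n_latent_true))
    loadings = rng.normal(0.0, config.sd_latent, size=(config.n_latent_true, p))

    # feature geometry: cis features sit 50 kb from their SNP; the rest are
    # placed far along the same chromosomes
    feat_rows = []
    chroms = genotypes.snps["chrom"].unique()
    for f in range(p):
        if f < config.n_cis:
            snp = genotypes.snps.iloc[cis_idx[f]]
            chrom, start = snp["chrom"], int(snp["pos"]) + 50_000
            if not (start - 1_000_000 <= snp["pos"] <= start + 1_000 + 1_000_000):
                raise ValueError(f"cis SNP for feature ln_{f} falls outside the 1 Mb window")
        else:
            chrom = chroms[f % len(chroms)]
            start = 30_000_000 + f * 10_000
        feat_rows.append(
            dict(feature_id=f"ln_{f:03d}", chrom=chrom, start=start, end=start + 1_000,
                 strand="+", biotype="lncRNA")
        )
    features = pd.DataFrame(feat_rows, columns=FEATURE_META_COLUMNS)

    meth = rng.choice([0.0, 1.0, 2.0], size=(n, p), p=[0.25, 0.5, 0.25])
    scna = rng.normal(0.0, 0.5, size=(n, p))
    truth_rows = []
    latent = np.full((n, p), config.lnc_intercept)
    n_low = int(round(config.low_expr_fraction * p))
    low_feats = list(range(p - n_low, p))  # only non-effect features
    for f in low_feats:
        latent[:, f] = -3.0

    age_c = (age - 60.0) / 10.0
    latent += config.beta_age * age_c[:, None] + config.beta_sex * sex[:, None]
    latent += L @ loadings
    for f in range(p):
        g_cis = None
        if f < config.n_cis:
            j = cis_idx[f]
            g_cis = D[:, j]
            latent[:, f] += config.cis_beta * g_cis
            truth_rows.append(
                dict(snp_id=genotypes.snps["snp_id"].iloc[j], feature_id=f"ln_{f:03d}",
                     mode="cis", true_beta=config.cis_beta)
            )
        if f < config.n_trans:
            j = trans_idx[f]
            latent[:, f] += config.trans_beta * D[:, j]
            truth_rows.append(
                dict(snp_id=genotypes.snps["snp_id"].iloc[j], feature_id=f"ln_{f:03d}",
                     mode="trans", true_beta=config.trans_beta)
            )
        if config.scna_geno_corr != 0.0 and g_cis is not None:
            gz = (g_cis - g_cis.mean()) / max(g_cis.std(), 1e-12)
            scna[:, f] = config.scna_geno_corr * gz + rng.normal(0.0, 0.5, size=n)
    latent += config.beta_scna * scna + config.beta_meth * (meth - 1.0)
    latent += rng.normal(0.0, config.noise_sd, size=(n, p))

    rpkm = np.maximum(np.exp2(latent) - 1.0, 0.0)
    samples = list(genotypes.samples)
    expr = ExpressionMatrix(samples=samples, features=features, values=rpkm, stage="raw_rpkm")
    feat_ids = features["feature_id"].tolist()
    cov = CovariateTable(
        samples=samples,
        age=age,
        sex=sex,
        purity=purity,
        latent_factors=None,
        scna=pd.DataFrame(scna, index=samples, columns=feat_ids),
        methylation_level=pd.DataFrame(meth, index=samples, columns=feat_ids),
    )
    truth = TruthTable(
        eqtl=pd.DataFrame(truth_rows, columns=["snp_id", "feature_id", "mode", "true_beta"]),
        mediation=pd.DataFrame(columns=["lncrna_id", "mrna_id", "true_alpha"]),
        immune=pd.DataFrame(columns=["lncrna_id", "cell_type", "true_gamma"]),
    )
    # planted-effect SNPs must survive genotype QC
    for j in set(cis_idx) | set(trans_idx):
        genotypes.snps.loc[j, "info_score"] = 1.0
    return expr, cov, truth


def simulate_downstream(
    lncrna: ExpressionMatrix,
    genotypes: GenotypeMatrix,
    truth: TruthTable,
    config: SimulationConfig,
) -> tuple[ExpressionMatrix, ImmuneFractionTable, TruthTable]:
    """Generate mediated mRNA counts and lncRNA-driven immune fractions.

    For each of the ``n_axes`` true axes the mRNA's latent log2 expression is
    ``intercept + alpha * (x - mean(x)) + kappa * u + noise`` where ``x`` is
    the mediating lncRNA on the log2 scale and ``u`` is the standardised
    residual of ``x`` on its cis genotype — a confounder shared between
    exposure and outcome that biases ordinary regression of y on x but not
    the instrumental-variable estimate.  Counts are ``round(2^latent - 1)``.
    Immune fractions are the row-softmax of per-cell-type linear predictors,
    with ``immune_gamma * x`` added to the first cell type.
    """
    rng = np.random.default_rng([config.seed, 3])
    n = lncrna.n_samples
    x_all = np.log2(lncrna.values + 1.0) if lncrna.stage == "raw_rpkm" else lncrna.values
    cis_truth = truth.eqtl[truth.eqtl["mode"] == "cis"].reset_index(drop=True)
    snp_pos = {s: i for i, s in enumerate(genotypes.snp_ids)}
    feat_pos = {f: i for i, f in enumerate(lncrna.feature_ids)}
    D = _impute_mean(genotypes.dosage)

    def genetic_residual(x: np.ndarray, snp_id: str) -> np.ndarray:
        g = D[:, snp_pos[snp_id]]
        X = np.column_stack([np.ones(n), g])
        coef, *_ = np.linalg.lstsq(X, x, rcond=None)
        r = x - X @ coef
        sd = r.std()
        return r / sd if sd > 0 else r

    med_rows = []
    latent = np.full((n, config.n_mrna), config.mrna_intercept)
    for k in range(config.n_mrna):
        if k < config.n_axes and len(cis_truth) > k:
            row = cis_truth.iloc[k]
            x = x_all[:, feat_pos[row["feature_id"]]]
            u = genetic_residual(x, row["snp_id"])
            latent[:, k] += config.mediation_alpha * (x - x.mean())
            latent[:, k] += config.confound_share * u
            latent[:, k] += rng.normal(0.0, config.mrna_noise_sd, size=n)
            med_rows.append(
                dict(lncrna_id=row["feature_id"], mrna_id=f"mr_{k:03d}",
                     true_alpha=config.mediation_alpha)
            )
        else:
            latent[:, k] += rng.normal(0.0, config.mrna_null_sd, size=n)
    counts = np.maximum(np.round(np.exp2(latent) - 1.0), 0.0)
    # mRNAs live on a separate chromosome so every axis outcome is trans
    mrna_features = pd.DataFrame(
        [
            dict(feature_id=f"mr_{k:03d}", chrom="chr_m", start=1_000_000 + k * 10_000,
                 end=1_001_000 + k * 10_000, strand="+", biotype="mRNA")
            for k in range(config.n_mrna)
        ],
        columns=FEATURE_META_COLUMNS,
    )
    mrna = ExpressionMatrix(
        samples=list(lncrna.samples), features=mrna_features, values=counts, stage="raw_count"
    )

    cell_types = [f"cell_{c}" for c in range(config.n_cell_types)]
    base = np.linspace(1.0, -1.0, config.n_cell_types)
    eta = np.tile(base, (n, 1)) + rng.normal(0.0, config.immune_noise_sd, (n, config.n_cell_types))
    imm_rows = []
    if len(cis_truth) and config.immune_gamma != 0.0:
        row = cis_truth.iloc[0]
        x = x_all[:, feat_pos[row["feature_id"]]]
        xz = (x - x.mean()) / max(x.std(), 1e-12)
        eta[:, 0] += config.immune_gamma * xz
        imm_rows.append(
            dict(lncrna_id=row["feature_id"], cell_type=cell_types[0],
                 true_gamma=config.immune_gamma)
        )
    ex = np.exp(eta - eta.max(axis=1, keepdims=True))
    fractions = ex / ex.sum(axis=1, keepdims=True)
    immune = ImmuneFractionTable(samples=list(lncrna.samples), cell_types=cell_types,
                                 fraction=fractions)
    out_truth = TruthTable(
        eqtl=truth.eqtl.copy(),
        mediation=pd.DataFrame(med_rows, columns=["lncrna_id", "mrna_id", "true_alpha"]),
        immune=pd.DataFrame(imm_rows, columns=["lncrna_id", "cell_type", "true_gamma"]),
    )
    return mrna, immune, out_truth


def simulate_cohort(config: SimulationConfig):
    """Convenience wrapper: genotypes, lncRNA, covariates, mRNA, immune, truth."""
    geno = simulate_genotypes(config)
    lnc, cov, truth = simulate_expression(geno, config)
    mrna, immune, truth = simulate_downstream(lnc, geno, truth, config)
    return geno, lnc, cov, mrna, immune, truth


def write_cohort(config: SimulationConfig, outdir: str | Path) -> dict:
    """Simulate a cohort and write every fixture in the formats the readers
    accept; returns the ``inputs`` mapping for :class:`PipelineConfig`."""
    from .core_io import write_covariates, write_expression, write_genotypes, write_immune_fractions

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    geno, lnc, cov, mrna, immune, truth = simulate_cohort(config)
    write_genotypes(geno, outdir / "genotypes.tsv")
    write_expression(lnc, outdir / "lncrna.tsv", outdir / "lncrna_annotation.tsv")
    write_expression(mrna, outdir / "mrna.tsv", outdir / "mrna_annotation.tsv")
    write_covariates(cov, outdir / "covariates.tsv")
    cov.scna.to_csv(outdir / "scna.tsv", sep="\t", index_label="sample_id", float_format="%.10g")
    cov.methylation_level.to_csv(
        outdir / "methylation_level.tsv", sep="\t", index_label="sample_id", float_format="%.10g"
    )
    write_immune_fractions(immune, outdir / "immune_fractions.tsv")
    truth.write(outdir)
    return {
        "genotypes": str(outdir / "genotypes.tsv"),
        "genotype_format": "tsv",
        "lncrna": str(outdir / "lncrna.tsv"),
        "lncrna_annotation": str(outdir / "lncrna_annotation.tsv"),
        "mrna": str(outdir / "mrna.tsv"),
        "mrna_annotation": str(outdir / "mrna_annotation.tsv"),
        "covariates": str(outdir / "covariates.tsv"),
        "scna": str(outdir / "scna.tsv"),
        "methylation_level": str(outdir / "methylation_level.tsv"),
        "immune_fractions": str(outdir / "immune_fractions.tsv"),
    }
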