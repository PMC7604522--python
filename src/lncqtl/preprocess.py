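"""Sample, genotype and expression QC plus normalisation transforms.

Implements the tumour-cohort preprocessing stack: purity-based sample
filtering, genotype QC (INFO, call posterior, missingness, MAF, exact HWE),
the two-rule RPKM detection filter, quantile normalisation, the rank-based
inverse normal transform, log2(RPKM+1), residual-SVD latent expression
factors (a surrogate for PEER), promoter-methylation discretisation, and the
count-based mRNA prefilter used before instrumental-variable analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats

from .core_io import CovariateTable, ExpressionMatrix, GenotypeMatrix, get_logger

logger = get_logger("preprocess")


@dataclass
class QcReport:
    """Per-filter bookkeeping: removed + retained = input for every filter."""

    rows: list = field(default_factory=list)

    def add(self, filter_name: str, item_type: str, n_input: int, n_removed: int) -> None:
        if n_removed < 0 or n_removed > n_input:
            raise ValueError(f"{filter_name}: removed {n_removed} of {n_input}")
        self.rows.append(
            dict(
                filter=filter_name,
                item_type=item_type,
                n_input=n_input,
                n_removed=n_removed,
                n_retained=n_input - n_removed,
            )
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.rows, columns=["filter", "item_type", "n_input", "n_removed", "n_retained"]
        )


# ---------------------------------------------------------------------------
# Sample QC
# ---------------------------------------------------------------------------


def filter_samples_by_purity(covariates: CovariateTable, threshold: float = 0.6) -> list[str]:
    """Retain samples with tumour purity >= ``threshold`` (boundary kept).

    Raises if any purity is missing (naming the sample) or if no sample
    survives.
    """
    purity = covariates.purity
    if np.isnan(purity).any():
        bad = covariates.samples[int(np.argmax(np.isnan(purity)))]
        raise ValueError(f"purity missing for sample {bad}")
    keep = [s for s, p in zip(covariates.samples, purity) if p >= threshold]
    if not keep:
        raise ValueError(f"all {len(purity)} samples removed by purity >= {threshold}")
    logger.info("purity filter: kept %d of %d samples", len(keep), len(purity))
    return keep


# ---------------------------------------------------------------------------
# Genotype QC
# ---------------------------------------------------------------------------


def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact Hardy-Weinberg test p-value for one biallelic SNP.

    Conditions on the observed allele counts and sums the probabilities of
    all heterozygote counts whose conditional probability does not exceed
    that of the observed count (the standard exact-test convention).
    """
    for c in (n_AA, n_Aa, n_aa):
        if c < 0 or int(c) != c:
            raise ValueError(f"genotype counts must be non-negative integers, got {c}")
    n_AA, n_Aa, n_aa = int(n_AA), int(n_Aa), int(n_aa)
    n = n_AA + n_Aa + n_aa
    if n < 1:
        raise ValueError("total genotype count must be >= 1")
    rare = min(2 * n_AA + n_Aa, 2 * n_aa + n_Aa)  # minor-allele copies
    if rare == 0:
        return 1.0
    # heterozygote counts share the parity of the minor-allele count
    hets = np.arange(rare % 2, rare + 1, 2)
    hom_r = (rare - hets) // 2
    hom_c = n - hets - hom_r
    # log P(het = h | n, rare): multinomial over genotypes / binomial over alleles
    logp = (
        special.gammaln(n + 1)
        - special.gammaln(hom_r + 1)
        - special.gammaln(hets + 1)
        - special.gammaln(hom_c + 1)
        + hets * np.log(2.0)
        + special.gammaln(rare + 1)
        + special.gammaln(2 * n - rare + 1)
        - special.gammaln(2 * n + 1)
    )
    p_h = np.exp(logp - special.logsumexp(logp))
    p_obs = p_h[np.searchsorted(hets, n_Aa)]
    return float(min(1.0, p_h[p_h <= p_obs * (1 + 1e-12)].sum()))


def qc_genotypes(
    G: GenotypeMatrix,
    info_min: float = 0.5,
    maf_min: float = 0.05,
    miss_max: float = 0.05,
    hwe_min: float = 1e-6,
    posterior_min: float = 0.7,
) -> tuple[GenotypeMatrix, QcReport]:
    """Apply the genotype QC cascade: INFO -> posterior masking -> missingness
    -> MAF -> exact HWE.

    Calls with posterior below ``posterior_min`` are set missing before the
    missing rate is computed (only when per-call posteriors are available —
    without them the rule is skipped).  MAF is computed on non-missing calls.
    SNPs with INFO absent (NaN) pass the INFO filter.
    """
    report = QcReport()
    dosage = G.dosage.copy()

    info = G.snps["info_score"].to_numpy(float)
    keep_info = np.isnan(info) | (info >= info_min)
    report.add("info_score", "snp", G.n_snps, int((~keep_info).sum()))

    if G.call_posterior is not None:
        masked = (G.call_posterior < posterior_min) & ~np.isnan(dosage)
        dosage[masked] = np.nan
        logger.info("qc_genotypes: masked %d calls with posterior < %g", int(masked.sum()), posterior_min)
    else:
        logger.info("qc_genotypes: no call posteriors available; posterior rule skipped")

    miss_rate = np.isnan(dosage).mean(axis=0)
    keep_miss = miss_rate < miss_max
    report.add("missing_rate", "snp", int(keep_info.sum()), int((keep_info & ~keep_miss).sum()))

    with np.errstate(invalid="ignore"):
        af = np.nanmean(dosage, axis=0) / 2.0
    maf = np.minimum(af, 1.0 - af)
    maf = np.where(np.isnan(maf), 0.0, maf)
    keep_maf = maf >= maf_min
    prev = keep_info & keep_miss
    report.add("maf", "snp", int(prev.sum()), int((prev & ~keep_maf).sum()))

    prev = prev & keep_maf
    keep_hwe = np.ones(G.n_snps, dtype=bool)
    for j in np.flatnonzero(prev):
        col = dosage[:, j]
        col = col[~np.isnan(col)]
        n_aa = int((col == 2).sum())
        n_Aa = int((col == 1).sum())
        n_AA = int((col == 0).sum())
        keep_hwe[j] = hwe_exact_test(n_AA, n_Aa, n_aa) > hwe_min
    report.add("hwe", "snp", int(prev.sum()), int((prev & ~keep_hwe).sum()))

    keep = prev & keep_hwe
    if not keep.any():
        logger.warning("qc_genotypes: no SNPs survived QC")
    out = GenotypeMatrix(
        samples=list(G.samples),
        snps=G.snps.loc[keep].reset_index(drop=True),
        dosage=dosage[:, keep],
        call_posterior=None,
    )
    out.snps["maf"] = maf[keep]
    return out, report


# ---------------------------------------------------------------------------
# Expression filtering and transforms
# ---------------------------------------------------------------------------


def filter_lncrna_expression(E: ExpressionMatrix) -> tuple[ExpressionMatrix, QcReport]:
    """Detection filter on RPKM: keep features with 10th-percentile RPKM > 0
    and 90th-percentile RPKM > 0.1 (linear-interpolation sample quantiles)."""
    if E.stage != "raw_rpkm":
        raise ValueError(f"expected stage raw_rpkm, got {E.stage}")
    q10 = np.quantile(E.values, 0.10, axis=0)
    q90 = np.quantile(E.values, 0.90, axis=0)
    keep = (q10 > 0) & (q90 > 0.1)
    report = QcReport()
    report.add("rpkm_percentile", "feature", E.n_features, int((~keep).sum()))
    out = E.subset_features(keep)
    out.stage = "filtered"
    logger.info("lncRNA filter: kept %d of %d features", int(keep.sum()), E.n_features)
    return out, report


def quantile_normalize(E: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample's expression distribution to the mean of the
    per-sample order statistics; ties within a sample get the mean of the
    reference values they span."""
    if E.n_features < 2:
        raise ValueError("quantile normalisation needs >= 2 features")
    V = E.values
    ref = np.sort(V, axis=1).mean(axis=0)  # mean of order statistics
    out = np.empty_like(V)
    for i in range(V.shape[0]):
        v = V[i]
        order = np.argsort(v, kind="stable")
        row = np.empty_like(v)
        row[order] = ref
        uniq, inv = np.unique(v, return_inverse=True)
        if len(uniq) < len(v):  # average reference values over tie groups
            sums = np.bincount(inv, weights=row)
            row = (sums / np.bincount(inv))[inv]
        out[i] = row
    return ExpressionMatrix(list(E.samples), E.features.copy(), out, stage="quantile_normalized")


def inverse_normal_transform(x: np.ndarray) -> np.ndarray:
    """Rank-based inverse normal transform with the Blom offset:
    ``Phi^-1((rank - 3/8) / (n + 1/4))``, average ranks for ties."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or len(x) < 3:
        raise ValueError("inverse normal transform needs a 1-D vector of length >= 3")
    if np.ptp(x) == 0:
        raise ValueError("constant vector: all ranks tied")
    ranks = stats.rankdata(x, method="average")
    return stats.norm.ppf((ranks - 3.0 / 8.0) / (len(x) + 0.25))


def inverse_normal(E: ExpressionMatrix) -> ExpressionMatrix:
    """Apply the inverse normal transform feature-wise across samples."""
    out = np.column_stack([inverse_normal_transform(E.values[:, j]) for j in range(E.n_features)])
    return ExpressionMatrix(list(E.samples), E.features.copy(), out, stage="inverse_normal")


def log2_rpkm(E: ExpressionMatrix) -> ExpressionMatrix:
    """Elementwise log2(x + 1); input must be non-negative."""
    if (E.values < 0).any():
        raise ValueError("negative expression value in log2 transform")
    return ExpressionMatrix(list(E.samples), E.features.copy(), np.log2(E.values + 1.0), stage="log2")


def estimate_latent_factors(
    E: ExpressionMatrix, k: int = 5, covariates: CovariateTable | None = None
) -> np.ndarray:
    """Residual-SVD latent expression factors.

    Residualises the (inverse-normal) expression matrix on the known
    covariates (intercept, age, sex), then returns the top-``k`` left
    singular vectors of the residual matrix, standardised to zero mean and
    unit variance.  These play the role PEER factors play in the association
    model: they absorb broad latent structure (batches, cell-composition
    shifts) shared across many features.
    """
    V = E.values
    n, p = V.shape
    if k >= min(n, p):
        raise ValueError(f"k={k} must be < min(n_samples, n_features)={min(n, p)}")
    if k == 0:
        return np.zeros((n, 0))
    if covariates is not None:
        X = np.column_stack([np.ones(n), covariates.age, covariates.sex])
    else:
        X = np.ones((n, 1))
    Q, _ = np.linalg.qr(X)
    R = V - Q @ (Q.T @ V)
    U, s, _ = np.linalg.svd(R, full_matrices=False)
    F = U[:, :k]
    F = (F - F.mean(axis=0)) / F.std(axis=0)
    # sign convention for determinism: largest-magnitude loading positive
    for j in range(k):
        i = np.argmax(np.abs(F[:, j]))
        if F[i, j] < 0:
            F[:, j] = -F[:, j]
    return F


# ---------------------------------------------------------------------------
# Methylation and mRNA prefilters
# ---------------------------------------------------------------------------


def discretize_methylation(beta: pd.DataFrame, probe_map: pd.DataFrame) -> pd.DataFrame:
    """Collapse promoter-probe beta values to an ordinal level per feature.

    ``beta`` is samples x probe_id with values in [0, 1]; ``probe_map`` has
    columns ``probe_id`` and ``feature_id`` restricted to TSS200/TSS1500
    probes.  The per-sample median beta over a feature's probes is binned at
    0.2 and 0.6: level 0 below 0.2, level 1 in [0.2, 0.6] (boundaries
    inclusive), level 2 above 0.6.  Features with no mapped probes get NaN
    and a warning.
    """
    vals = beta.to_numpy(float)
    if np.nanmin(vals) < 0 or np.nanmax(vals) > 1:
        raise ValueError("methylation beta values must lie in [0, 1]")
    features = probe_map["feature_id"].unique()
    out = pd.DataFrame(index=beta.index, columns=features, dtype=float)
    for feat, grp in probe_map.groupby("feature_id"):
        probes = [p for p in grp["probe_id"] if p in beta.columns]
        if not probes:
            logger.warning("discretize_methylation: feature %s has no probes", feat)
            continue
        med = beta[probes].median(axis=1)
        out[feat] = np.where(med < 0.2, 0.0, np.where(med <= 0.6, 1.0, 2.0))
    return out


def filter_mrna_for_iv(counts: ExpressionMatrix, cv_min: float = 0.5) -> np.ndarray:
    """Boolean keep-mask for mRNAs entering the instrumental-variable stage.

    Keeps a gene iff its coefficient of variation on the count scale exceeds
    ``cv_min``, the 30th percentile of log2(count+1) exceeds 0, and the 90th
    percentile of log2(count+1) exceeds 5.  Genes with zero mean count (CV
    undefined) are dropped and logged.
    """
    if counts.stage not in ("raw_count", "raw_rpkm"):
        raise ValueError(f"expected raw counts, got stage {counts.stage}")
    V = counts.values
    mean = V.mean(axis=0)
    zero_mean = mean == 0
    if zero_mean.any():
        logger.info("filter_mrna_for_iv: dropped %d genes with zero mean count", int(zero_mean.sum()))
    with np.errstate(invalid="ignore", divide="ignore"):
        cv = np.where(zero_mean, np.nan, V.std(axis=0, ddof=1) / mean)
    logv = np.log2(V + 1.0)
    q30 = np.quantile(logv, 0.30, axis=0)
    q90 = np.quantile(logv, 0.90, axis=0)
    keep = ~zero_mean & (cv > cv_min) & (q30 > 0) & (q90 > 5)
    logger.info("filter_mrna_for_iv: kept %d of %d genes", int(keep.sum()), len(keep))
    return keep
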