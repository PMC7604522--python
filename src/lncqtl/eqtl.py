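"""Cis/trans eQTL association scanning, multiple-testing control, LD
clumping, and multivariate revalidation.

The scan fits, for every admissible SNP-feature pair, the additive linear
model

    expression_i = b0 + b1 * G_i + b2 * age_i + b3 * sex_i + latent factors + e_i

by ordinary least squares and reports the per-alt-allele effect b1 with its
t-test.  The implementation uses the residualise-then-correlate fast path
(Frisch-Waugh-Lovell), which is algebraically identical to per-pair OLS.
Significant SNPs are collapsed into LD clumps (greedy, most significant SNP
as tag, r^2 and distance gates), and each feature's tag SNPs are re-fitted
in one multivariate model that additionally adjusts for somatic copy number
and discretised promoter methylation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core_io import CovariateTable, ExpressionMatrix, FeatureMeta, GenotypeMatrix, SnpMeta, get_logger

logger = get_logger("eqtl")

EQTL_COLUMNS = [
    "snp_id", "chrom", "pos", "feature_id", "mode",
    "beta", "se", "t", "p", "fdr", "distance_bp", "n_samples",
]


def classify_pair(snp: SnpMeta, feature: FeatureMeta, cis_window: int = 1_000_000) -> str:
    """Classify a SNP-feature pair as ``cis`` or ``trans``.

    Cis means same chromosome with the SNP inside
    ``[feature.start - cis_window, feature.end + cis_window]`` (the 1 Mb
    upstream / 1 Mb downstream window); anything beyond that interval, or on
    a different chromosome, is trans.  Strand is ignored.
    """
    for c in (snp.chrom, feature.chrom):
        if not isinstance(c, str) or not c:
            raise ValueError(f"unknown chromosome name: {c!r}")
    if snp.chrom != feature.chrom:
        return "trans"
    if feature.start - cis_window <= snp.pos <= feature.end + cis_window:
        return "cis"
    return "trans"


def _cis_mask(geno: GenotypeMatrix, expr: ExpressionMatrix, cis_window: int) -> np.ndarray:
    """(n_snps, n_features) boolean: True where the pair is cis."""
    s_chrom = geno.snps["chrom"].to_numpy()
    s_pos = geno.snps["pos"].to_numpy()
    f_chrom = expr.features["chrom"].to_numpy()
    f_start = expr.features["start"].to_numpy()
    f_end = expr.features["end"].to_numpy()
    same = s_chrom[:, None] == f_chrom[None, :]
    inside = (s_pos[:, None] >= f_start[None, :] - cis_window) & (
        s_pos[:, None] <= f_end[None, :] + cis_window
    )
    return same & inside


def scan_eqtl(
    G: GenotypeMatrix,
    E: ExpressionMatrix,
    covariates: CovariateTable,
    mode: str = "cis",
    cis_window: int = 1_000_000,
) -> pd.DataFrame:
    """Association scan over all admissible SNP-feature pairs of one mode.

    Expression must be at the ``inverse_normal`` stage.  Missing dosages are
    mean-imputed per SNP for the scan; SNPs left with zero variance are
    skipped and logged.  Returns one row per pair with columns
    ``EQTL_COLUMNS`` (``fdr`` is left NaN — apply :func:`bh_fdr` afterwards).
    """
    if mode not in ("cis", "trans"):
        raise ValueError(f"mode must be cis or trans, got {mode!r}")
    if E.stage not in ("inverse_normal", "log2"):
        # inverse_normal is the pipeline default; log2 is the alternative
        # reportable scale on which generative effects stay in their own units
        raise ValueError(f"scan expects stage inverse_normal or log2, got {E.stage}")
    if G.samples != E.samples or G.samples != covariates.samples:
        raise ValueError("samples not aligned across genotypes/expression/covariates")

    n = G.n_samples
    X = covariates.design_matrix()
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("covariate design matrix is rank deficient")
    dof = n - X.shape[1] - 1
    if dof < 1:
        raise ValueError("not enough samples for the scan model")

    D = G.dosage.copy()
    col_mean = np.nanmean(D, axis=0)
    miss = np.isnan(D)
    if miss.any():
        D[miss] = np.take(col_mean, np.nonzero(miss)[1])
    ok = D.std(axis=0) > 0
    if not ok.all():
        logger.info("scan_eqtl: skipped %d zero-variance SNPs", int((~ok).sum()))

    Q, _ = np.linalg.qr(X)
    RG = D - Q @ (Q.T @ D)
    RY = E.values - Q @ (Q.T @ E.values)
    gg = (RG * RG).sum(axis=0)
    yy = (RY * RY).sum(axis=0)

    pair_ok = _cis_mask(G, E, cis_window)
    if mode == "trans":
        pair_ok = ~pair_ok
    pair_ok &= ok[:, None]
    si, fi = np.nonzero(pair_ok)
    if not len(si):
        return pd.DataFrame(columns=EQTL_COLUMNS)

    C = RG.T @ RY  # (m, f) cross products
    beta = C[si, fi] / gg[si]
    rss = yy[fi] - beta * C[si, fi]
    rss = np.maximum(rss, 0.0)
    se = np.sqrt(rss / dof / gg[si])
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta / se, np.sign(beta) * np.inf)
    p = 2.0 * stats.t.sf(np.abs(t), dof)
    p = np.clip(p, np.finfo(float).tiny, 1.0)

    s_chrom = G.snps["chrom"].to_numpy()[si]
    s_pos = G.snps["pos"].to_numpy()[si]
    f_chrom = E.features["chrom"].to_numpy()[fi]
    f_start = E.features["start"].to_numpy()[fi]
    f_end = E.features["end"].to_numpy()[fi]
    same = s_chrom == f_chrom
    # signed distance to the nearest feature edge; 0 inside the feature body
    dist = np.where(
        s_pos < f_start, s_pos - f_start, np.where(s_pos > f_end, s_pos - f_end, 0)
    ).astype(float)
    dist[~same] = np.nan

    return pd.DataFrame(
        {
            "snp_id": G.snps["snp_id"].to_numpy()[si],
            "chrom": s_chrom,
            "pos": s_pos,
            "feature_id": E.features["feature_id"].to_numpy()[fi],
            "mode": mode,
            "beta": beta,
            "se": se,
            "t": t,
            "p": p,
            "fdr": np.nan,
            "distance_bp": dist,
            "n_samples": n,
        }
    )


def bh_fdr(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone non-decreasing in p)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def ld_r2(g1: np.ndarray, g2: np.ndarray) -> float:
    """Composite genotypic r^2: squared Pearson correlation of dosage
    vectors, pairwise-complete over missing calls."""
    g1 = np.asarray(g1, dtype=float)
    g2 = np.asarray(g2, dtype=float)
    ok = ~np.isnan(g1) & ~np.isnan(g2)
    a, b = g1[ok], g2[ok]
    if a.std() == 0 or b.std() == 0:
        raise ValueError("monomorphic genotype vector in ld_r2")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


@dataclass
class ClumpedEqtl:
    """One LD clump: the tag record plus its member SNP ids."""

    tag_snp_id: str
    member_snp_ids: list[str]
    feature_id: str
    mode: str
    tag_record: dict = field(default_factory=dict)


def clump(
    records: pd.DataFrame,
    genotypes: GenotypeMatrix,
    r2_min: float = 0.2,
    window_bp: int = 500_000,
) -> list[ClumpedEqtl]:
    """Greedy LD clumping of significant records for one feature and mode.

    Repeatedly takes the lowest-p unassigned SNP as tag and assigns to it
    every unassigned SNP within ``window_bp`` on the same chromosome with
    dosage r^2 >= ``r2_min``.  Ties on p are broken by (chrom, pos, snp_id).
    """
    if records.empty:
        return []
    if records["feature_id"].nunique() != 1 or records["mode"].nunique() != 1:
        raise ValueError("clump operates on one feature and one mode at a time")
    idx_of = {s: i for i, s in enumerate(genotypes.snp_ids)}
    rec = records.sort_values(["p", "chrom", "pos", "snp_id"], kind="stable").reset_index(drop=True)
    assigned = np.zeros(len(rec), dtype=bool)
    clumps: list[ClumpedEqtl] = []
    for i in range(len(rec)):
        if assigned[i]:
            continue
        tag = rec.iloc[i]
        assigned[i] = True
        members = [tag["snp_id"]]
        g_tag = genotypes.dosage[:, idx_of[tag["snp_id"]]]
        for j in range(i + 1, len(rec)):
            if assigned[j]:
                continue
            cand = rec.iloc[j]
            if cand["chrom"] != tag["chrom"] or abs(cand["pos"] - tag["pos"]) > window_bp:
                continue
            g_cand = genotypes.dosage[:, idx_of[cand["snp_id"]]]
            try:
                r2 = ld_r2(g_tag, g_cand)
            except ValueError:
                continue
            if r2 >= r2_min:
                assigned[j] = True
                members.append(cand["snp_id"])
        clumps.append(
            ClumpedEqtl(
                tag_snp_id=tag["snp_id"],
                member_snp_ids=members,
                feature_id=tag["feature_id"],
                mode=tag["mode"],
                tag_record=tag.to_dict(),
            )
        )
    return clumps


def clump_all(
    records: pd.DataFrame,
    genotypes: GenotypeMatrix,
    r2_min: float = 0.2,
    window_bp: int = 500_000,
) -> pd.DataFrame:
    """Clump every (feature, mode) group; long table with ``clump_tag`` and
    ``is_tag`` columns appended to the input records."""
    if records.empty:
        return pd.DataFrame(columns=EQTL_COLUMNS + ["clump_tag", "is_tag"])
    out = []
    for (feat, mode), grp in records.groupby(["feature_id", "mode"], sort=True):
        for cl in clump(grp, genotypes, r2_min=r2_min, window_bp=window_bp):
            sub = grp[grp["snp_id"].isin(cl.member_snp_ids)].copy()
            sub["clump_tag"] = cl.tag_snp_id
            sub["is_tag"] = sub["snp_id"] == cl.tag_snp_id
            out.append(sub)
    return pd.concat(out, ignore_index=True).sort_values(
        ["feature_id", "mode", "clump_tag", "p"], kind="stable"
    ).reset_index(drop=True)


@dataclass
class ValidatedEqtl:
    """Multivariate refit of one feature's tag SNPs with somatic covariates."""

    feature_id: str
    cis_tag_snp: str
    trans_tag_snp: str | None
    coefficients: pd.DataFrame  # term, beta, se, t, p
    model_r2: float
    n_samples: int


def validate_multivariate(
    feature_id: str,
    cis_tag: str,
    trans_tag: str | None,
    genotypes: GenotypeMatrix,
    expression: ExpressionMatrix,
    covariates: CovariateTable,
) -> ValidatedEqtl:
    """One OLS fit of expression on cis (+ trans) tag dosage, age, sex,
    latent factors, and — when available for the feature — SCNA and the
    ordinal methylation level.  Samples with any missing term are dropped.
    """
    fidx = expression.feature_ids.index(feature_id)
    y = expression.values[:, fidx]
    sidx = {s: i for i, s in enumerate(genotypes.snp_ids)}
    terms: dict[str, np.ndarray] = {"cis_genotype": genotypes.dosage[:, sidx[cis_tag]]}
    if trans_tag is not None:
        terms["trans_genotype"] = genotypes.dosage[:, sidx[trans_tag]]
    if np.ptp(covariates.age) > 0:
        terms["age"] = covariates.age
    if np.ptp(covariates.sex) > 0:
        terms["sex"] = covariates.sex
    if covariates.latent_factors is not None:
        for j in range(covariates.latent_factors.shape[1]):
            terms[f"factor_{j + 1}"] = covariates.latent_factors[:, j]
    if covariates.scna is not None and feature_id in covariates.scna.columns:
        terms["scna"] = covariates.scna[feature_id].to_numpy(float)
    if covariates.methylation_level is not None and feature_id in covariates.methylation_level.columns:
        m = covariates.methylation_level[feature_id].to_numpy(float)
        if np.isnan(m).all():
            logger.warning("validate: feature %s has no methylation level; term dropped", feature_id)
        else:
            terms["methylation"] = m

    M = np.column_stack([np.ones(len(y))] + list(terms.values()))
    names = ["intercept"] + list(terms.keys())
    ok = ~np.isnan(M).any(axis=1) & ~np.isnan(y)
    M, yv = M[ok], y[ok]
    if np.linalg.matrix_rank(M) < M.shape[1]:
        # name the offending columns for the caller
        bad = []
        for j in range(1, M.shape[1]):
            sub = np.delete(M, j, axis=1)
            if np.linalg.matrix_rank(sub) == np.linalg.matrix_rank(M):
                bad.append(names[j])
        raise ValueError(f"collinear design for feature {feature_id}: {bad}")

    import statsmodels.api as sm

    fit = sm.OLS(yv, M).fit()
    coef = pd.DataFrame(
        {"term": names, "beta": fit.params, "se": fit.bse, "t": fit.tvalues, "p": fit.pvalues}
    )
    return ValidatedEqtl(
        feature_id=feature_id,
        cis_tag_snp=cis_tag,
        trans_tag_snp=trans_tag,
        coefficients=coef.reset_index(drop=True),
        model_r2=float(fit.rsquared),
        n_samples=int(ok.sum()),
    )


def validate_all(
    clumped: pd.DataFrame,
    genotypes: GenotypeMatrix,
    expression: ExpressionMatrix,
    covariates: CovariateTable,
) -> pd.DataFrame:
    """Multivariate revalidation for every feature with at least one cis tag.

    The most significant cis tag enters as the cis term; when the feature
    also has trans tags the most significant one enters as the trans term
    (the remaining trans tags are not refitted).
    """
    rows = []
    if clumped.empty:
        return pd.DataFrame(
            columns=["feature_id", "cis_tag_snp", "trans_tag_snp", "term", "beta", "se", "t", "p",
                     "model_r2", "n_samples"]
        )
    tags = clumped[clumped["is_tag"]]
    for feat, grp in tags.groupby("feature_id", sort=True):
        cis_grp = grp[grp["mode"] == "cis"]
        if cis_grp.empty:
            continue
        cis_tag = cis_grp.sort_values(["p", "chrom", "pos", "snp_id"]).iloc[0]["snp_id"]
        trans_grp = grp[grp["mode"] == "trans"]
        trans_tag = (
            trans_grp.sort_values(["p", "chrom", "pos", "snp_id"]).iloc[0]["snp_id"]
            if len(trans_grp)
            else None
        )
        res = validate_multivariate(feat, cis_tag, trans_tag, genotypes, expression, covariates)
        for _, c in res.coefficients.iterrows():
            rows.append(
                dict(
                    feature_id=feat,
                    cis_tag_snp=res.cis_tag_snp,
                    trans_tag_snp=res.trans_tag_snp if res.trans_tag_snp else "",
                    term=c["term"],
                    beta=c["beta"],
                    se=c["se"],
                    t=c["t"],
                    p=c["p"],
                    model_r2=res.model_r2,
                    n_samples=res.n_samples,
                )
            )
    return pd.DataFrame(rows)
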