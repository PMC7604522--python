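"""Two-stage least-squares instrumental-variable estimation of
eQTL -> elncRNA -> outcome causal axes.

A clumped cis tag SNP serves as the (single) genetic instrument for its
lncRNA, and the 2SLS estimate of the lncRNA's effect on an mRNA (or on a
log2-transformed immune-cell fraction) is consistent under confounding
shared between exposure and outcome, provided the instrument affects the
outcome only through the exposure.  With one instrument and no covariates
the estimator reduces to the Wald ratio cov(y, g) / cov(x, g).  Standard
errors are homoskedastic 2SLS errors computed from the structural
residuals y - beta*x (not y - beta*x_hat); the first-stage partial F for
the instrument is reported, and F < 10 rows are flagged as weak.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import CovariateTable, ExpressionMatrix, GenotypeMatrix, ImmuneFractionTable, get_logger
from .eqtl import bh_fdr
from .preprocess import filter_mrna_for_iv

logger = get_logger("mr")

WEAK_INSTRUMENT_F = 10.0


@dataclass
class IvResult:
    """One instrument -> exposure -> outcome 2SLS fit."""

    instrument: str
    exposure: str
    outcome: str
    beta_2sls: float
    se: float
    p: float
    r2: float
    adj_r2: float
    first_stage_f: float
    first_stage_p: float
    n: int
    weak_instrument: bool = False


def spearman_prefilter(
    lncrna: np.ndarray, mrna: np.ndarray, rho_min: float = 0.3
) -> tuple[bool, float]:
    """Spearman correlation gate: keep iff |rho| > ``rho_min``.

    Average ranks for ties; a constant vector has undefined rho and is
    dropped with a warning.
    """
    x = np.asarray(lncrna, float)
    y = np.asarray(mrna, float)
    if len(x) != len(y) or len(x) < 10:
        raise ValueError("aligned vectors of length >= 10 required")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        logger.warning("spearman_prefilter: constant vector, pair dropped")
        return False, np.nan
    rho = stats.spearmanr(x, y).statistic
    return bool(abs(rho) > rho_min), float(rho)


def two_stage_least_squares(
    g: np.ndarray,
    x: np.ndarray,
    y: np.ndarray,
    covariates: np.ndarray | None = None,
    instrument: str = "g",
    exposure: str = "x",
    outcome: str = "y",
) -> IvResult:
    """Single-instrument 2SLS of ``y`` on ``x`` instrumented by ``g``.

    ``covariates`` is an optional n x c matrix of exogenous controls (an
    intercept is always added).  Stage 1 regresses x on [g, C]; stage 2
    regresses y on [x_hat, C]; the reported SE and (adjusted) R^2 come from
    the structural residuals ``y - beta*x - C*delta``.  A first-stage F of
    zero is returned with a warning flag, never silently dropped.
    """
    g = np.asarray(g, float)
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(g)
    if len(x) != n or len(y) != n:
        raise ValueError("g, x, y must be aligned")
    if np.ptp(g[~np.isnan(g)]) == 0:
        raise ValueError("instrument is monomorphic")
    C = np.ones((n, 1))
    if covariates is not None and np.asarray(covariates).size:
        cov = np.asarray(covariates, float)
        if cov.ndim == 1:
            cov = cov[:, None]
        C = np.column_stack([C, cov])
    ok = ~(np.isnan(g) | np.isnan(x) | np.isnan(y) | np.isnan(C).any(axis=1))
    g, x, y, C = g[ok], x[ok], y[ok], C[ok]
    n = len(g)
    k = C.shape[1] + 1  # structural parameters: x plus exogenous block
    if n <= k + 1:
        raise ValueError("not enough complete samples for 2SLS")

    # first stage: x on [C, g]
    X1 = np.column_stack([C, g])
    c1, *_ = np.linalg.lstsq(X1, x, rcond=None)
    xhat = X1 @ c1
    rss1 = float(((x - xhat) ** 2).sum())
    c0, *_ = np.linalg.lstsq(C, x, rcond=None)
    rss0 = float(((x - C @ c0) ** 2).sum())
    df1 = n - X1.shape[1]
    if rss1 <= 0:
        f_stat, f_p = np.inf, 0.0
    else:
        f_stat = max(0.0, (rss0 - rss1) / (rss1 / df1))
        f_p = float(stats.f.sf(f_stat, 1, df1))

    # second stage: y on [xhat, C]
    Z_hat = np.column_stack([xhat, C])
    coef, *_ = np.linalg.lstsq(Z_hat, y, rcond=None)
    beta = float(coef[0])
    # structural residuals use the observed exposure
    Z = np.column_stack([x, C])
    resid = y - Z @ coef
    dof = n - k
    sigma2 = float(resid @ resid) / dof
    XtX_inv = np.linalg.pinv(Z_hat.T @ Z_hat)
    se = float(np.sqrt(sigma2 * XtX_inv[0, 0]))
    t = beta / se if se > 0 else np.sign(beta) * np.inf
    p = float(2.0 * stats.t.sf(abs(t), dof))
    tss = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - float(resid @ resid) / tss if tss > 0 else np.nan
    adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / dof if tss > 0 else np.nan
    if f_stat == 0.0:
        logger.warning("2SLS %s->%s->%s: first-stage F = 0", instrument, exposure, outcome)
    return IvResult(
        instrument=instrument,
        exposure=exposure,
        outcome=outcome,
        beta_2sls=beta,
        se=se,
        p=p,
        r2=r2,
        adj_r2=adj_r2,
        first_stage_f=f_stat,
        first_stage_p=f_p,
        n=n,
        weak_instrument=bool(f_stat < WEAK_INSTRUMENT_F),
    )


IV_COLUMNS = [
    "instrument", "exposure", "outcome", "beta", "se", "p", "fdr",
    "r2", "adj_r2", "first_stage_f", "n", "flag_weak_instrument", "passes",
]


def _results_frame(results: list[IvResult], fdr: np.ndarray | None = None) -> pd.DataFrame:
    df = pd.DataFrame(
        {
            "instrument": [r.instrument for r in results],
            "exposure": [r.exposure for r in results],
            "outcome": [r.outcome for r in results],
            "beta": [r.beta_2sls for r in results],
            "se": [r.se for r in results],
            "p": [r.p for r in results],
            "fdr": np.nan if fdr is None else fdr,
            "r2": [r.r2 for r in results],
            "adj_r2": [r.adj_r2 for r in results],
            "first_stage_f": [r.first_stage_f for r in results],
            "n": [r.n for r in results],
            "flag_weak_instrument": [r.weak_instrument for r in results],
        }
    )
    return df


def _cis_instruments(clumped: pd.DataFrame) -> pd.DataFrame:
    """One (instrument SNP, exposure lncRNA) pair per feature: the most
    significant cis clump tag."""
    tags = clumped[(clumped["mode"] == "cis") & clumped["is_tag"]]
    if tags.empty:
        return pd.DataFrame(columns=["snp_id", "feature_id"])
    best = tags.sort_values(["p", "chrom", "pos", "snp_id"]).groupby("feature_id", sort=True).head(1)
    return best[["snp_id", "feature_id"]].reset_index(drop=True)


def run_axes(
    clumped: pd.DataFrame,
    genotypes: GenotypeMatrix,
    lncrna: ExpressionMatrix,
    mrna_counts: ExpressionMatrix,
    covariates: CovariateTable,
    fdr_max: float = 0.1,
    adj_r2_min: float = 0.1,
    cv_min: float = 0.5,
    rho_min: float = 0.3,
) -> pd.DataFrame:
    """2SLS over every (cis instrument-lncRNA pair) x (prefiltered mRNA).

    mRNAs first pass the count-based detection filter, then the per-pair
    Spearman gate against the exposure; outcomes are log2(count + 1).
    BH-FDR is computed across all tested axes; ``passes`` marks axes with
    fdr < ``fdr_max`` and adjusted R^2 > ``adj_r2_min``.
    """
    pairs = _cis_instruments(clumped)
    if pairs.empty or mrna_counts.n_features == 0:
        return pd.DataFrame(columns=IV_COLUMNS)
    keep = filter_mrna_for_iv(mrna_counts, cv_min=cv_min)
    mr_log = np.log2(mrna_counts.values + 1.0)
    sidx = {s: i for i, s in enumerate(genotypes.snp_ids)}
    fidx = {f: i for i, f in enumerate(lncrna.feature_ids)}
    C = covariates.design_matrix()[:, 1:]  # intercept added inside 2SLS
    results: list[IvResult] = []
    for _, pr in pairs.iterrows():
        if pr["feature_id"] not in fidx:
            continue
        g = genotypes.dosage[:, sidx[pr["snp_id"]]]
        x = lncrna.values[:, fidx[pr["feature_id"]]]
        for j in np.flatnonzero(keep):
            y = mr_log[:, j]
            ok, _rho = spearman_prefilter(x, y, rho_min=rho_min)
            if not ok:
                continue
            results.append(
                two_stage_least_squares(
                    g, x, y, covariates=C,
                    instrument=pr["snp_id"], exposure=pr["feature_id"],
                    outcome=mrna_counts.feature_ids[j],
                )
            )
    if not results:
        return pd.DataFrame(columns=IV_COLUMNS)
    df = _results_frame(results, fdr=bh_fdr(np.array([r.p for r in results])))
    df["passes"] = (df["fdr"] < fdr_max) & (df["adj_r2"] > adj_r2_min)
    logger.info("run_axes: %d tested, %d significant axes", len(df), int(df["passes"].sum()))
    return df


def run_immune(
    axes: pd.DataFrame,
    genotypes: GenotypeMatrix,
    lncrna: ExpressionMatrix,
    fractions: ImmuneFractionTable,
    covariates: CovariateTable,
    p_max: float = 0.05,
    r2_min: float = 0.0,
) -> pd.DataFrame:
    """2SLS of each significant axis' instrument-lncRNA pair on every
    immune-cell fraction (outcome = log2(fraction + 1)).

    Cell types with all-zero fractions are skipped and logged.  ``passes``
    marks results with p < ``p_max`` and model R^2 > ``r2_min``.
    """
    if axes.empty:
        return pd.DataFrame(columns=IV_COLUMNS)
    sig = axes[axes["passes"]] if "passes" in axes.columns else axes
    pairs = sig[["instrument", "exposure"]].drop_duplicates()
    if pairs.empty:
        return pd.DataFrame(columns=IV_COLUMNS)
    sidx = {s: i for i, s in enumerate(genotypes.snp_ids)}
    fidx = {f: i for i, f in enumerate(lncrna.feature_ids)}
    C = covariates.design_matrix()[:, 1:]
    results: list[IvResult] = []
    for _, pr in pairs.iterrows():
        g = genotypes.dosage[:, sidx[pr["instrument"]]]
        x = lncrna.values[:, fidx[pr["exposure"]]]
        for c, cell in enumerate(fractions.cell_types):
            f = fractions.fraction[:, c]
            if (f == 0).all():
                logger.info("run_immune: cell type %s has all-zero fractions, skipped", cell)
                continue
            y = np.log2(f + 1.0)
            results.append(
                two_stage_least_squares(
                    g, x, y, covariates=C,
                    instrument=pr["instrument"], exposure=pr["exposure"], outcome=cell,
                )
            )
    if not results:
        return pd.DataFrame(columns=IV_COLUMNS)
    df = _results_frame(results)
    df["passes"] = (df["p"] < p_max) & (df["r2"] > r2_min)
    return df
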