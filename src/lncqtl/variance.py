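"""Sequential variance decomposition, allelic effect-size summaries, and
cross-cohort specificity bookkeeping.

The decomposition adds factor groups to a nested OLS model in a fixed order
(age, sex, latent factors, cis tag, trans tag, SCNA, methylation) and
reports the R^2 increment of each group; the increments telescope exactly
to the full-model R^2, and the residual share is one minus their sum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import CovariateTable, ExpressionMatrix, GenotypeMatrix, get_logger

logger = get_logger("variance")

DEFAULT_FACTOR_ORDER = [
    "age", "sex", "latent_factors", "cis_eqtl", "trans_eqtl", "scna", "methylation",
]


@dataclass
class VariancePartition:
    feature_id: str
    factors: list[str]
    increments: np.ndarray          # floored at 0
    residual: float
    full_r2: float
    n_floored: int = 0


def _r2(y: np.ndarray, X: np.ndarray) -> float:
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    tss = ((y - y.mean()) ** 2).sum()
    if tss == 0:
        raise ValueError("zero-variance response")
    return 1.0 - float((resid**2).sum() / tss)


def sequential_variance_partition(
    y: np.ndarray,
    factor_groups: list[tuple[str, np.ndarray | None]],
    feature_id: str = "",
) -> VariancePartition:
    """R^2 increments from sequentially adding factor groups to an OLS fit.

    ``factor_groups`` is an ordered list of (name, design-block) pairs;
    ``None`` or zero-column blocks are skipped (increment 0).  Negative
    numerical increments (nested plain R^2 is non-decreasing, so these can
    only be rounding noise) are floored at 0 and counted.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    blocks = []
    for name, block in factor_groups:
        if block is None:
            blocks.append((name, np.empty((n, 0))))
            continue
        block = np.asarray(block, dtype=float)
        if block.ndim == 1:
            block = block[:, None]
        blocks.append((name, block))
    total_params = 1 + sum(b.shape[1] for _, b in blocks)
    if n <= total_params:
        raise ValueError(f"n={n} samples <= {total_params} parameters")

    X = np.ones((n, 1))
    prev = 0.0  # R^2 of the intercept-only model
    raw = []
    for name, block in blocks:
        if block.shape[1] == 0:
            raw.append(0.0)
            continue
        X = np.column_stack([X, block])
        cur = _r2(y, X)
        raw.append(cur - prev)
        prev = cur
    raw = np.asarray(raw)
    n_floored = int((raw < 0).sum())
    if n_floored:
        logger.info("variance partition %s: floored %d negative increments", feature_id, n_floored)
    inc = np.maximum(raw, 0.0)
    return VariancePartition(
        feature_id=feature_id,
        factors=[name for name, _ in blocks],
        increments=inc,
        residual=1.0 - float(inc.sum()),
        full_r2=prev,
        n_floored=n_floored,
    )


def partition_all(
    clumped: pd.DataFrame,
    genotypes: GenotypeMatrix,
    expression: ExpressionMatrix,
    covariates: CovariateTable,
    order: list[str] | None = None,
) -> pd.DataFrame:
    """Variance partition for every feature with at least one clump tag.

    The cis and trans terms use only the feature's most significant tag SNP
    of each mode (the same design the multivariate validation uses).
    """
    order = order or DEFAULT_FACTOR_ORDER
    if clumped.empty:
        return pd.DataFrame(columns=["feature_id", "factor", "increment_r2"])
    sidx = {s: i for i, s in enumerate(genotypes.snp_ids)}
    D = genotypes.dosage
    rows = []
    tags = clumped[clumped["is_tag"]]
    for feat, grp in tags.groupby("feature_id", sort=True):
        fidx = expression.feature_ids.index(feat)
        y = expression.values[:, fidx]
        available: dict[str, np.ndarray | None] = {
            "age": covariates.age,
            "sex": covariates.sex,
            "latent_factors": covariates.latent_factors,
            "cis_eqtl": None,
            "trans_eqtl": None,
            "scna": None,
            "methylation": None,
        }
        for mode, key in (("cis", "cis_eqtl"), ("trans", "trans_eqtl")):
            sub = grp[grp["mode"] == mode]
            if len(sub):
                tag = sub.sort_values(["p", "chrom", "pos", "snp_id"]).iloc[0]["snp_id"]
                g = D[:, sidx[tag]]
                g = np.where(np.isnan(g), np.nanmean(g), g)
                available[key] = g
        if covariates.scna is not None and feat in covariates.scna.columns:
            available["scna"] = covariates.scna[feat].to_numpy(float)
        if covariates.methylation_level is not None and feat in covariates.methylation_level.columns:
            m = covariates.methylation_level[feat].to_numpy(float)
            if not np.isnan(m).any():
                available["methylation"] = m
        part = sequential_variance_partition(
            y, [(name, available.get(name)) for name in order], feature_id=feat
        )
        for name, inc in zip(part.factors, part.increments):
            rows.append(dict(feature_id=feat, factor=name, increment_r2=inc))
        rows.append(dict(feature_id=feat, factor="residual", increment_r2=part.residual))
    return pd.DataFrame(rows)


def allelic_effect_summary(records: pd.DataFrame) -> pd.DataFrame:
    """Distribution summary of |beta| over tag eSNPs (one per clump).

    Returns a one-row frame per mode with n, mean |beta|, and the
    0/25/50/75/100% quantiles.  An empty input yields an empty frame.
    """
    if records.empty:
        return pd.DataFrame(
            columns=["mode", "n", "mean_abs_beta", "q0", "q25", "q50", "q75", "q100"]
        )
    tags = records[records["is_tag"]] if "is_tag" in records.columns else records
    rows = []
    for mode, grp in tags.groupby("mode", sort=True):
        b = np.abs(grp["beta"].to_numpy(float))
        q = np.quantile(b, [0, 0.25, 0.5, 0.75, 1.0])
        rows.append(
            dict(mode=mode, n=len(b), mean_abs_beta=b.mean(),
                 q0=q[0], q25=q[1], q50=q[2], q75=q[3], q100=q[4])
        )
    return pd.DataFrame(rows)


@dataclass
class SpecificitySummary:
    """Cross-cohort occurrence bookkeeping for eQTLs or elncRNAs."""

    counts: pd.DataFrame            # entity, n_cohorts
    n_unique: int
    fraction_specific: float        # entities in exactly one cohort
    fraction_shared: dict = field(default_factory=dict)  # k -> fraction in > k cohorts

    def percent_specific(self) -> float:
        return round(100.0 * self.fraction_specific, 2)


def cross_cohort_specificity(
    cohort_sets: dict[str, set], shared_thresholds: tuple[int, ...] = (8,)
) -> SpecificitySummary:
    """Count, for each entity, the number of cohorts it occurs in.

    Reports the fraction occurring in exactly one cohort (cohort-specific)
    and, for each ``k`` in ``shared_thresholds``, the fraction occurring in
    more than ``k`` cohorts.
    """
    if not cohort_sets:
        raise ValueError("need at least one cohort")
    tally: dict[str, int] = {}
    for members in cohort_sets.values():
        for e in members:
            tally[e] = tally.get(e, 0) + 1
    counts = pd.DataFrame(
        sorted(tally.items()), columns=["entity", "n_cohorts"]
    )
    n_unique = len(counts)
    frac_specific = float((counts["n_cohorts"] == 1).mean()) if n_unique else 0.0
    shared = {
        k: float((counts["n_cohorts"] > k).mean()) if n_unique else 0.0
        for k in shared_thresholds
    }
    return SpecificitySummary(
        counts=counts, n_unique=n_unique, fraction_specific=frac_specific,
        fraction_shared=shared,
    )


def cohort_summary(per_cohort: pd.DataFrame) -> pd.DataFrame:
    """Per-cohort summary percentages.

    ``per_cohort`` must have columns ``cohort``, ``n_elncrna`` and
    ``n_filtered_lncrna``; adds ``percent_elncrna`` =
    100 * n_elncrna / n_filtered_lncrna rounded to 2 decimals.
    """
    out = per_cohort.copy()
    out["percent_elncrna"] = (
        100.0 * out["n_elncrna"] / out["n_filtered_lncrna"]
    ).round(2)
    return out
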