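"""GWAS risk-locus LD interception, set/peak enrichment, and meta-analysis.

Every enrichment is a 2x2 table tested with Fisher's exact test; the odds
ratio carries a Woolf log-interval 95% CI, with the Haldane 0.5 correction
applied only when a zero cell occurs.  Besides the odds ratio a "fold"
statistic (ratio of the flagged proportions in the two groups) is emitted
for every test, since both conventions are common in the enrichment
literature.  Per-stratum results are pooled by inverse-variance fixed- and
DerSimonian-Laird random-effects meta-analysis with Cochran's Q and I^2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import GenotypeMatrix, GwasCatalogTable, PeakSet, get_logger
from .eqtl import ld_r2

logger = get_logger("overlap_enrichment")

_Z95 = stats.norm.ppf(0.975)


@dataclass
class EnrichmentResult:
    """One 2x2 enrichment test: a/b = query in/out, c/d = background in/out."""

    set_name: str
    a: int
    b: int
    c: int
    d: int
    odds_ratio: float
    ci_low: float
    ci_high: float
    p: float
    fold: float


def _fisher_or(a: int, b: int, c: int, d: int, set_name: str = "",
               alternative: str = "two-sided") -> EnrichmentResult:
    for x in (a, b, c, d):
        if x < 0:
            raise ValueError("negative cell count")
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative=alternative)
    if min(a, b, c, d) == 0:  # Haldane correction only on zero cells
        aa, bb, cc, dd = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    else:
        aa, bb, cc, dd = float(a), float(b), float(c), float(d)
    odds = (aa * dd) / (bb * cc)
    se = math.sqrt(1 / aa + 1 / bb + 1 / cc + 1 / dd)
    ci_low = math.exp(math.log(odds) - _Z95 * se)
    ci_high = math.exp(math.log(odds) + _Z95 * se)
    q_frac = a / (a + b) if a + b else np.nan
    bg_frac = c / (c + d) if c + d else np.nan
    fold = np.inf if bg_frac == 0 else q_frac / bg_frac
    return EnrichmentResult(set_name, a, b, c, d, odds, ci_low, ci_high, float(p), fold)


# ---------------------------------------------------------------------------
# GWAS interception
# ---------------------------------------------------------------------------


def build_ld_proxies(
    catalog: GwasCatalogTable,
    reference: GenotypeMatrix,
    r2_min: float = 0.5,
    window_bp: int = 500_000,
) -> dict[str, set[str]]:
    """LD proxies of each catalog risk SNP in the reference panel.

    The proxy set of a tag is the tag itself plus every panel SNP on the
    same chromosome within ``window_bp`` with dosage r^2 >= ``r2_min``.
    Catalog SNPs absent from the panel are logged and skipped.
    """
    idx = {s: i for i, s in enumerate(reference.snp_ids)}
    chrom = reference.snps["chrom"].to_numpy()
    pos = reference.snps["pos"].to_numpy()
    proxies: dict[str, set[str]] = {}
    n_missing = 0
    for _, row in catalog.rows.iterrows():
        tag = row["risk_snp_id"]
        if tag not in idx:
            n_missing += 1
            continue
        ti = idx[tag]
        g_tag = reference.dosage[:, ti]
        members = {tag}
        near = np.flatnonzero((chrom == chrom[ti]) & (np.abs(pos - pos[ti]) <= window_bp))
        for j in near:
            if j == ti:
                continue
            try:
                if ld_r2(g_tag, reference.dosage[:, j]) >= r2_min:
                    members.add(reference.snp_ids[j])
            except ValueError:
                continue
        proxies[tag] = members
    if n_missing:
        logger.info("build_ld_proxies: %d catalog SNPs absent from reference panel", n_missing)
    return proxies


def gwas_intercept(snp_ids, proxy_map: dict[str, set[str]]) -> tuple[np.ndarray, float]:
    """Flag each SNP that falls in any risk-SNP proxy set; return flags and
    the flagged fraction (0.0 for an empty input or empty catalog)."""
    snp_ids = list(snp_ids)
    universe: set[str] = set()
    for members in proxy_map.values():
        universe |= members
    flags = np.array([s in universe for s in snp_ids], dtype=bool)
    frac = float(flags.mean()) if len(flags) else 0.0
    return flags, frac


def fold_enrichment(eqtl_flags: np.ndarray, non_eqtl_flags: np.ndarray) -> EnrichmentResult:
    """Fold enrichment of flagged SNPs among eQTLs versus non-eQTL background.

    fold = (flagged fraction among eQTLs) / (flagged fraction among
    background); a zero background fraction yields fold = inf (flagged by
    the one-sided Haldane-corrected CI).  p from Fisher's exact test.
    """
    eqtl_flags = np.asarray(eqtl_flags, dtype=bool)
    non_eqtl_flags = np.asarray(non_eqtl_flags, dtype=bool)
    if not len(eqtl_flags) or not len(non_eqtl_flags):
        raise ValueError("both groups must be non-empty")
    a, b = int(eqtl_flags.sum()), int((~eqtl_flags).sum())
    c, d = int(non_eqtl_flags.sum()), int((~non_eqtl_flags).sum())
    res = _fisher_or(a, b, c, d, set_name="gwas_fold")
    if c == 0:
        logger.warning("fold_enrichment: zero flagged background; fold is infinite")
    return res


# ---------------------------------------------------------------------------
# Set / peak enrichment
# ---------------------------------------------------------------------------


def set_enrichment(query: set, annotation: set, universe: set, set_name: str = "") -> EnrichmentResult:
    """Fisher-exact enrichment of ``query`` for ``annotation`` inside
    ``universe`` (both must be subsets of the universe)."""
    if not universe:
        raise ValueError("empty universe")
    query, annotation, universe = set(query), set(annotation), set(universe)
    if not query <= universe or not annotation <= universe:
        raise ValueError("query and annotation must be subsets of the universe")
    a = len(query & annotation)
    b = len(query - annotation)
    c = len(annotation - query)
    d = len(universe) - a - b - c
    return _fisher_or(a, b, c, d, set_name=set_name)


def peak_overlap_enrichment(
    positions: pd.DataFrame,
    peaks: PeakSet,
    background: pd.DataFrame,
) -> EnrichmentResult:
    """Enrichment of SNP positions inside ChIP-seq peaks versus background.

    ``positions`` and ``background`` need ``chrom`` and ``pos`` (1-based)
    columns; membership is the 1-bp point falling inside a half-open
    0-based peak interval.  An empty peak set raises (OR undefined).
    """
    if peaks.n_intervals == 0:
        raise ValueError("empty peak set: odds ratio undefined")
    q_in = peaks.contains(positions["chrom"].to_numpy(), positions["pos"].to_numpy())
    b_in = peaks.contains(background["chrom"].to_numpy(), background["pos"].to_numpy())
    return _fisher_or(
        int(q_in.sum()), int((~q_in).sum()), int(b_in.sum()), int((~b_in).sum()),
        set_name=peaks.marker_name or "peaks",
    )


# ---------------------------------------------------------------------------
# Meta-analysis
# ---------------------------------------------------------------------------


@dataclass
class MetaResult:
    """Pooled enrichment across strata (markers), on the log-OR scale."""

    k: int
    fixed_log_or: float
    fixed_se: float
    random_log_or: float
    random_se: float
    tau2: float
    q: float
    q_p: float
    i2: float

    @property
    def random_or(self) -> float:
        return math.exp(self.random_log_or)

    @property
    def random_ci(self) -> tuple[float, float]:
        return (
            math.exp(self.random_log_or - _Z95 * self.random_se),
            math.exp(self.random_log_or + _Z95 * self.random_se),
        )


def meta_enrichment(results: list[EnrichmentResult]) -> MetaResult:
    """Inverse-variance pooling of per-stratum odds ratios.

    Computes the fixed-effect pooled log-OR, the DerSimonian-Laird
    random-effects estimate (reported by default), Cochran's Q and I^2.
    Requires >= 2 strata with finite log-OR and strictly positive SE.
    """
    if len(results) < 2:
        raise ValueError("meta-analysis needs >= 2 strata")
    log_or, se = [], []
    for r in results:
        if not np.isfinite(r.odds_ratio) or r.odds_ratio <= 0:
            raise ValueError(f"stratum {r.set_name}: non-finite odds ratio")
        aa, bb, cc, dd = (x + 0.5 if min(r.a, r.b, r.c, r.d) == 0 else x for x in (r.a, r.b, r.c, r.d))
        s = math.sqrt(1 / aa + 1 / bb + 1 / cc + 1 / dd)
        if s == 0:
            raise ValueError(f"stratum {r.set_name}: zero standard error")
        log_or.append(math.log(r.odds_ratio))
        se.append(s)
    y = np.asarray(log_or)
    w = 1.0 / np.asarray(se) ** 2
    fixed = float((w * y).sum() / w.sum())
    fixed_se = float(1.0 / math.sqrt(w.sum()))
    q = float((w * (y - fixed) ** 2).sum())
    dfree = len(y) - 1
    tau2 = max(0.0, (q - dfree) / (w.sum() - (w**2).sum() / w.sum()))
    w_star = 1.0 / (np.asarray(se) ** 2 + tau2)
    random = float((w_star * y).sum() / w_star.sum())
    random_se = float(1.0 / math.sqrt(w_star.sum()))
    i2 = max(0.0, (q - dfree) / q) if q > 0 else 0.0
    return MetaResult(
        k=len(y),
        fixed_log_or=fixed,
        fixed_se=fixed_se,
        random_log_or=random,
        random_se=random_se,
        tau2=tau2,
        q=q,
        q_p=float(stats.chi2.sf(q, dfree)),
        i2=i2,
    )
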