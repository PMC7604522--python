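"""Association scan, FDR, LD and clumping against brute-force oracles."""

import numpy as np
import pandas as pd
import pytest

from lncqtl import (
    CovariateTable,
    ExpressionMatrix,
    FeatureMeta,
    SnpMeta,
    bh_fdr,
    classify_pair,
    clump,
    clump_all,
    ld_r2,
    scan_eqtl,
    validate_multivariate,
)
from lncqtl.core_io import FEATURE_META_COLUMNS, GenotypeMatrix, SNP_META_COLUMNS


def _cohort(dosage, expr_values, chrom_snp=None, pos_snp=None, features=None,
            age=None, sex=None, latent=None):
    dosage = np.asarray(dosage, float)
    n, m = dosage.shape
    p = expr_values.shape[1]
    snps = pd.DataFrame(
        [
            (f"rs{j}",
             "chr1" if chrom_snp is None else chrom_snp[j],
             100 + j if pos_snp is None else pos_snp[j],
             "A", "G", np.nan, np.nan)
            for j in range(m)
        ],
        columns=SNP_META_COLUMNS,
    )
    if features is None:
        features = pd.DataFrame(
            [(f"f{k}", "chr1", 1, 10, "+", "lncRNA") for k in range(p)],
            columns=FEATURE_META_COLUMNS,
        )
    samples = [f"s{i}" for i in range(n)]
    geno = GenotypeMatrix(samples=samples, snps=snps, dosage=dosage)
    expr = ExpressionMatrix(samples=samples, features=features, values=expr_values,
                            stage="inverse_normal")
    cov = CovariateTable(
        samples=samples,
        age=np.zeros(n) if age is None else age,
        sex=np.zeros(n) if sex is None else sex,
        purity=np.ones(n),
        latent_factors=latent,
    )
    return geno, expr, cov


# ---------------------------------------------------------------------------
# cis/trans classification
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "snp_chrom,snp_pos,expected",
    [
        ("chr1", 1_500_000, "cis"),      # inside the upstream 1 Mb window
        ("chr2", 1_500_000, "trans"),    # different chromosome
        ("chr1", 3_001_001, "trans"),    # 1 bp beyond end + 1 Mb
        ("chr1", 3_001_000, "cis"),      # exactly at end + 1 Mb
        ("chr1", 1_000_000, "cis"),      # exactly at start - 1 Mb
        ("chr1", 999_999, "trans"),
    ],
)
def test_classify_pair_boundaries(snp_chrom, snp_pos, expected):
    feature = FeatureMeta("lnc1", "chr1", 2_000_000, 2_001_000)
    snp = SnpMeta("rs1", snp_chrom, snp_pos)
    assert classify_pair(snp, feature) == expected


def test_classify_pair_rejects_bad_chromosome():
    with pytest.raises(ValueError):
        classify_pair(SnpMeta("rs1", "", 5), FeatureMeta("f", "chr1", 1, 2))


# ---------------------------------------------------------------------------
# scan: noiseless fit, fast path == per-pair OLS, null calibration
# ---------------------------------------------------------------------------


def test_scan_noiseless_fit(rng):
    g = rng.binomial(2, 0.4, 80).astype(float)
    y = 0.5 * g
    geno, expr, cov = _cohort(g[:, None], y[:, None])
    rec = scan_eqtl(geno, expr, cov, mode="cis")
    assert rec["beta"].iloc[0] == pytest.approx(0.5, abs=1e-12)
    assert rec["p"].iloc[0] < 1e-100


def brute_force_ols(y, g, X):
    """Per-pair OLS oracle via the normal equations on [X, g]."""
    M = np.column_stack([X, g])
    coef, *_ = np.linalg.lstsq(M, y, rcond=None)
    resid = y - M @ coef
    dof = len(y) - M.shape[1]
    sigma2 = resid @ resid / dof
    cov_beta = sigma2 * np.linalg.inv(M.T @ M)
    return coef[-1], np.sqrt(cov_beta[-1, -1])


def test_scan_fast_path_equals_per_pair_ols(rng):
    n, m, p = 50, 20, 10
    dosage = rng.binomial(2, 0.3, (n, m)).astype(float)
    values = rng.normal(0, 1, (n, p))
    age = rng.normal(60, 10, n)
    sex = rng.integers(0, 2, n).astype(float)
    latent = rng.normal(0, 1, (n, 3))
    geno, expr, cov = _cohort(dosage, values, age=age, sex=sex, latent=latent)
    rec = scan_eqtl(geno, expr, cov, mode="cis")
    assert len(rec) == m * p
    X = np.column_stack([np.ones(n), age, sex, latent])
    sidx = {s: j for j, s in enumerate(geno.snp_ids)}
    fidx = {f: k for k, f in enumerate(expr.feature_ids)}
    for _, row in rec.iterrows():
        b, se = brute_force_ols(values[:, fidx[row["feature_id"]]],
                                dosage[:, sidx[row["snp_id"]]], X)
        assert abs(row["beta"] - b) < 1e-10
        assert abs(row["se"] - se) < 1e-10


def test_scan_null_p_uniform(rng):
    """Independent genotype and expression give uniform p-values."""
    n = 100
    dosage = rng.binomial(2, 0.3, (n, 50)).astype(float)
    values = rng.normal(0, 1, (n, 20))
    geno, expr, cov = _cohort(dosage, values)
    rec = scan_eqtl(geno, expr, cov, mode="cis")
    from scipy import stats

    assert len(rec) == 1000
    assert stats.kstest(rec["p"], "uniform").pvalue > 0.01


def test_scan_mean_imputes_missing_and_skips_monomorphic(rng):
    n = 60
    g = rng.binomial(2, 0.4, n).astype(float)
    g[:5] = np.nan
    mono = np.ones(n)
    dosage = np.column_stack([g, mono])
    geno, expr, cov = _cohort(dosage, rng.normal(0, 1, (n, 2)))
    rec = scan_eqtl(geno, expr, cov, mode="cis")
    assert set(rec["snp_id"]) == {"rs0"}  # monomorphic SNP skipped


# ---------------------------------------------------------------------------
# BH FDR
# ---------------------------------------------------------------------------


def test_bh_hand_example():
    np.testing.assert_allclose(
        bh_fdr(np.array([0.01, 0.02, 0.03, 0.5])), [0.04, 0.04, 0.04, 0.5]
    )


def test_bh_trivial_cases():
    assert bh_fdr(np.array([0.2])) == pytest.approx([0.2])
    np.testing.assert_allclose(bh_fdr(np.full(5, 0.07)), np.full(5, 0.07))
    assert bh_fdr(np.array([])).size == 0


def test_bh_significant_set_monotone(rng):
    p = rng.uniform(0, 1, 200)
    q = bh_fdr(p)
    strict = set(np.flatnonzero(q < 0.05))
    loose = set(np.flatnonzero(q < 0.2))
    assert strict <= loose
    # q is monotone non-decreasing in p
    order = np.argsort(p)
    assert (np.diff(q[order]) >= -1e-15).all()


# ---------------------------------------------------------------------------
# LD r^2
# ---------------------------------------------------------------------------


def test_ld_r2_identity_and_flip(rng):
    g = rng.binomial(2, 0.4, 200).astype(float)
    assert ld_r2(g, g) == pytest.approx(1.0)
    assert ld_r2(g, 2 - g) == pytest.approx(1.0)
    with pytest.raises(ValueError):
        ld_r2(g, np.zeros(200))


def test_ld_r2_independent_snps(rng):
    g1 = rng.binomial(2, 0.3, 2000).astype(float)
    g2 = rng.binomial(2, 0.3, 2000).astype(float)
    assert ld_r2(g1, g2) < 0.01


# ---------------------------------------------------------------------------
# clumping vs brute-force greedy
# ---------------------------------------------------------------------------


def _records(snp_ids, chroms, poss, ps, feature="f0", mode="cis"):
    return pd.DataFrame(
        {
            "snp_id": snp_ids, "chrom": chroms, "pos": poss,
            "feature_id": feature, "mode": mode,
            "beta": 0.1, "se": 0.01, "t": 1.0, "p": ps,
            "fdr": np.nan, "distance_bp": 0, "n_samples": 100,
        }
    )


def brute_force_clump(rec, geno, r2_min, window_bp):
    """Independent greedy oracle over explicit sets."""
    idx = {s: i for i, s in enumerate(geno.snp_ids)}
    rows = rec.sort_values(["p", "chrom", "pos", "snp_id"]).to_dict("records")
    unassigned = list(range(len(rows)))
    partition = []
    while unassigned:
        t = unassigned.pop(0)
        tag = rows[t]
        members = {tag["snp_id"]}
        rest = []
        for j in unassigned:
            c = rows[j]
            same = (
                c["chrom"] == tag["chrom"]
                and abs(c["pos"] - tag["pos"]) <= window_bp
                and ld_r2(geno.dosage[:, idx[tag["snp_id"]]],
                          geno.dosage[:, idx[c["snp_id"]]]) >= r2_min
            )
            (members.add(c["snp_id"]) if same else rest.append(j))
        unassigned = rest
        partition.append((tag["snp_id"], frozenset(members)))
    return partition


def test_clump_matches_brute_force_on_random_fixtures(rng):
    n, m = 120, 30
    base = rng.binomial(1, 0.3, (2 * n, 5)).astype(float)
    # build correlated SNPs by copying base haplotype columns with flips
    hap = np.empty((2 * n, m))
    for j in range(m):
        src = base[:, j % 5]
        noise = rng.random(2 * n) < 0.15
        hap[:, j] = np.where(noise, 1 - src, src)
    dosage = hap[0::2] + hap[1::2]
    poss = rng.integers(1, 2_000_000, m)
    snps = pd.DataFrame(
        [(f"rs{j}", "chr1", int(poss[j]), "A", "G", np.nan, np.nan) for j in range(m)],
        columns=SNP_META_COLUMNS,
    )
    geno = GenotypeMatrix(samples=[f"s{i}" for i in range(n)], snps=snps, dosage=dosage)
    rec = _records([f"rs{j}" for j in range(m)], ["chr1"] * m, poss,
                   rng.uniform(1e-10, 1e-3, m))
    got = clump(rec, geno, r2_min=0.2, window_bp=500_000)
    expected = brute_force_clump(rec, geno, 0.2, 500_000)
    assert [(c.tag_snp_id, frozenset(c.member_snp_ids)) for c in got] == expected
    # partition property: members are disjoint and cover the input
    all_members = [s for c in got for s in c.member_snp_ids]
    assert sorted(all_members) == sorted(rec["snp_id"])


def test_clump_distance_gate(rng):
    g = rng.binomial(2, 0.4, 300).astype(float)
    flip = g.copy()
    flip[:10] = 2 - flip[:10]  # r^2 still ~0.9
    snps = pd.DataFrame(
        [("rs0", "chr1", 1_000_000, "A", "G", np.nan, np.nan),
         ("rs1", "chr1", 1_600_000, "A", "G", np.nan, np.nan)],
        columns=SNP_META_COLUMNS,
    )
    geno = GenotypeMatrix(samples=[f"s{i}" for i in range(300)], snps=snps,
                          dosage=np.column_stack([g, flip]))
    assert ld_r2(g, flip) > 0.2
    rec = _records(["rs0", "rs1"], ["chr1", "chr1"], [1_000_000, 1_600_000], [1e-8, 1e-6])
    got = clump(rec, geno)  # 600 kb apart -> two clumps despite high r^2
    assert len(got) == 2


def test_clump_single_record(rng):
    g = rng.binomial(2, 0.4, 50).astype(float)
    snps = pd.DataFrame([("rs0", "chr1", 10, "A", "G", np.nan, np.nan)],
                        columns=SNP_META_COLUMNS)
    geno = GenotypeMatrix(samples=[f"s{i}" for i in range(50)], snps=snps,
                          dosage=g[:, None])
    got = clump(_records(["rs0"], ["chr1"], [10], [1e-9]), geno)
    assert len(got) == 1 and got[0].tag_snp_id == "rs0"


# ---------------------------------------------------------------------------
# multivariate validation
# ---------------------------------------------------------------------------


def test_validate_nests_to_scan(rng):
    """With no extra covariates the multivariate fit equals the scan OLS."""
    n = 80
    g = rng.binomial(2, 0.4, n).astype(float)
    y = 0.4 * g + rng.normal(0, 1, n)
    geno, expr, cov = _cohort(g[:, None], y[:, None])
    rec = scan_eqtl(geno, expr, cov, mode="cis")
    res = validate_multivariate("f0", "rs0", None, geno, expr, cov)
    cis_row = res.coefficients.set_index("term").loc["cis_genotype"]
    assert cis_row["beta"] == pytest.approx(rec["beta"].iloc[0], abs=1e-10)
    assert cis_row["se"] == pytest.approx(rec["se"].iloc[0], abs=1e-10)


def test_validate_collinear_design_names_columns(rng):
    n = 60
    g = rng.binomial(2, 0.4, n).astype(float)
    y = rng.normal(0, 1, n)
    geno, expr, cov = _cohort(g[:, None], y[:, None])
    cov.scna = pd.DataFrame({"f0": g}, index=cov.samples)  # SCNA == genotype
    with pytest.raises(ValueError, match="scna"):
        validate_multivariate("f0", "rs0", None, geno, expr, cov)


def test_validate_null_scna_coefficient_centered(rng):
    n = 400
    betas = []
    for _ in range(20):
        g = rng.binomial(2, 0.4, n).astype(float)
        scna = rng.normal(0, 0.5, n)
        y = 0.5 * g + rng.normal(0, 1, n)  # SCNA truly null
        geno, expr, cov = _cohort(g[:, None], y[:, None])
        cov.scna = pd.DataFrame({"f0": scna}, index=cov.samples)
        res = validate_multivariate("f0", "rs0", None, geno, expr, cov)
        betas.append(res.coefficients.set_index("term").loc["scna", "beta"])
    assert abs(np.mean(betas)) < 0.05


def test_clump_all_partition(small_cohort, rng):
    from lncqtl import inverse_normal, quantile_normalize, filter_lncrna_expression
    from lncqtl import estimate_latent_factors

    geno, lnc, cov = small_cohort["geno"], small_cohort["lnc"], small_cohort["cov"]
    lf, _ = filter_lncrna_expression(lnc)
    E = inverse_normal(quantile_normalize(lf))
    cov = cov.subset_samples(cov.samples)
    cov.latent_factors = estimate_latent_factors(E, k=3, covariates=cov)
    rec = scan_eqtl(geno, E, cov, mode="cis")
    rec["fdr"] = bh_fdr(rec["p"].to_numpy())
    sig = rec[rec["fdr"] < 0.1]
    clumped = clump_all(sig, geno)
    if len(clumped):
        # every record appears exactly once and its tag p is minimal
        assert len(clumped) == len(sig)
        for (_, _, tag), grp in clumped.groupby(["feature_id", "mode", "clump_tag"]):
            tag_p = grp.loc[grp["snp_id"] == tag, "p"].iloc[0]
            assert (grp["p"] >= tag_p - 1e-15).all()
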