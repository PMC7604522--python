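"""QC filters and normalisation transforms against independent oracles."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from lncqtl import (
    CovariateTable,
    ExpressionMatrix,
    discretize_methylation,
    estimate_latent_factors,
    filter_lncrna_expression,
    filter_mrna_for_iv,
    filter_samples_by_purity,
    hwe_exact_test,
    inverse_normal_transform,
    log2_rpkm,
    qc_genotypes,
    quantile_normalize,
)
from lncqtl.core_io import FEATURE_META_COLUMNS, GenotypeMatrix, SNP_META_COLUMNS


def _expr(values, stage="raw_rpkm"):
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    feats = pd.DataFrame(
        [(f"f{j}", "chr1", 1000 + j, 2000 + j, "+", "lncRNA") for j in range(p)],
        columns=FEATURE_META_COLUMNS,
    )
    return ExpressionMatrix(samples=[f"s{i}" for i in range(n)], features=feats,
                            values=values, stage=stage)


def _cov(purity, age=None, sex=None):
    n = len(purity)
    return CovariateTable(
        samples=[f"s{i}" for i in range(n)],
        age=np.full(n, 60.0) if age is None else np.asarray(age, float),
        sex=np.zeros(n) if sex is None else np.asarray(sex, float),
        purity=np.asarray(purity, float),
    )


# ---------------------------------------------------------------------------
# purity filter
# ---------------------------------------------------------------------------


def test_purity_filter_keeps_boundary():
    keep = filter_samples_by_purity(_cov([0.59, 0.60, 0.9]))
    assert keep == ["s1", "s2"]


def test_purity_filter_identity_and_errors():
    assert len(filter_samples_by_purity(_cov([1.0, 1.0]))) == 2
    with pytest.raises(ValueError, match="s1"):
        filter_samples_by_purity(_cov([0.9, np.nan]))
    with pytest.raises(ValueError, match="all"):
        filter_samples_by_purity(_cov([0.1, 0.2]))


# ---------------------------------------------------------------------------
# HWE exact test vs brute-force enumeration
# ---------------------------------------------------------------------------


def brute_force_hwe(n_AA, n_Aa, n_aa):
    """Independent oracle: enumerate every genotype table with the observed
    allele counts and sum the probabilities <= that of the observed table."""
    n = n_AA + n_Aa + n_aa
    n_alt = 2 * n_aa + n_Aa
    probs = {}
    for h in range(n_alt % 2, min(n_alt, 2 * n - n_alt) + 1, 2):
        hom_alt = (n_alt - h) // 2
        hom_ref = n - h - hom_alt
        if hom_ref < 0:
            continue
        # P(table) = multinomial / C(2n, n_alt)
        probs[h] = (
            math.comb(n, hom_alt) * math.comb(n - hom_alt, h) * 2**h
            / math.comb(2 * n, n_alt)
        )
    total = sum(probs.values())
    p_obs = probs[n_Aa] / total
    return sum(v / total for v in probs.values() if v / total <= p_obs * (1 + 1e-12))


@pytest.mark.parametrize(
    "counts",
    [(25, 50, 25), (50, 0, 50), (100, 0, 0), (5, 3, 2), (0, 1, 0), (17, 6, 27), (3, 44, 3)],
)
def test_hwe_matches_enumeration(counts):
    assert hwe_exact_test(*counts) == pytest.approx(brute_force_hwe(*counts), rel=1e-9)


def test_hwe_known_values():
    assert hwe_exact_test(25, 50, 25) == pytest.approx(1.0)  # modal table
    assert hwe_exact_test(50, 0, 50) < 1e-6  # extreme heterozygote deficit
    assert hwe_exact_test(100, 0, 0) == 1.0  # monomorphic
    with pytest.raises(ValueError):
        hwe_exact_test(-1, 0, 1)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(
    n_AA=st.integers(0, 20), n_Aa=st.integers(0, 20), n_aa=st.integers(0, 10),
)
def test_hwe_matches_enumeration_property(n_AA, n_Aa, n_aa):
    if n_AA + n_Aa + n_aa == 0:
        return
    assert hwe_exact_test(n_AA, n_Aa, n_aa) == pytest.approx(
        brute_force_hwe(n_AA, n_Aa, n_aa), rel=1e-9
    )


# ---------------------------------------------------------------------------
# genotype QC cascade
# ---------------------------------------------------------------------------


def _geno(dosage, info=None):
    dosage = np.asarray(dosage, float)
    m = dosage.shape[1]
    snps = pd.DataFrame(
        [(f"rs{j}", "chr1", 100 + j, "A", "G",
          np.nan if info is None else info[j], np.nan) for j in range(m)],
        columns=SNP_META_COLUMNS,
    )
    return GenotypeMatrix(samples=[f"s{i}" for i in range(dosage.shape[0])],
                          snps=snps, dosage=dosage)


def test_qc_genotypes_examples(rng):
    n = 100
    good = rng.binomial(2, 0.3, n).astype(float)
    missing6 = good.copy()
    missing6[:6] = np.nan  # 6% missing -> removed
    maf_ok = np.array([0.0, 1.0, 2.0, 2.0] + [0.0] * (n - 4))  # MAF 5/200 = 0.025 < 0.05
    hwe_bad = np.array([0.0] * 50 + [2.0] * 50)  # no hets: exact p << 1e-6
    low_info = good.copy()
    G = _geno(np.column_stack([good, missing6, maf_ok, hwe_bad, low_info]),
              info=[0.9, 0.9, 0.9, 0.9, 0.3])
    out, report = qc_genotypes(G)
    assert out.snp_ids == ["rs0"]
    rep = report.to_frame().set_index("filter")
    assert rep.loc["info_score", "n_removed"] == 1
    assert rep.loc["missing_rate", "n_removed"] == 1
    assert rep.loc["maf", "n_removed"] == 1
    assert rep.loc["hwe", "n_removed"] == 1
    # conservation at every filter
    assert (report.to_frame()["n_removed"] + report.to_frame()["n_retained"]
            == report.to_frame()["n_input"]).all()


def test_qc_maf_computed_on_nonmissing():
    # dosages [0,1,2,2]: alt freq 5/8 -> folded MAF 3/8, retained
    G = _geno(np.array([[0.0], [1.0], [2.0], [2.0]]))
    out, _ = qc_genotypes(G, hwe_min=0.0)
    assert out.snps["maf"].iloc[0] == pytest.approx(3 / 8)


def test_qc_posterior_masking_feeds_missing_rate(rng):
    n = 100
    d = rng.binomial(2, 0.4, (n, 1)).astype(float)
    post = np.ones((n, 1))
    post[:10, 0] = 0.5  # 10% of calls masked -> missing rate 10% -> removed
    G = _geno(d)
    G.call_posterior = post
    out, report = qc_genotypes(G)
    assert out.n_snps == 0
    assert report.to_frame().set_index("filter").loc["missing_rate", "n_removed"] == 1


# ---------------------------------------------------------------------------
# expression filter and transforms
# ---------------------------------------------------------------------------


def test_lncrna_detection_filter_rules(rng):
    n = 100
    zeros30 = rng.exponential(1.0, n)
    zeros30[:30] = 0.0  # q10 = 0 -> excluded
    const_low = np.full(n, 0.05)  # q90 = 0.05 <= 0.1 -> excluded
    const_ok = np.full(n, 1.0)  # retained
    E = _expr(np.column_stack([zeros30, const_low, const_ok]))
    out, report = filter_lncrna_expression(E)
    assert out.feature_ids == ["f2"]
    assert out.stage == "filtered"
    r = report.to_frame().iloc[0]
    assert r["n_removed"] + r["n_retained"] == r["n_input"] == 3


def test_quantile_normalize_mean_of_order_statistics():
    E = _expr(np.array([[1.0, 2.0, 3.0], [10.0, 20.0, 30.0]]), stage="filtered")
    out = quantile_normalize(E)
    np.testing.assert_allclose(out.values, [[5.5, 11.0, 16.5], [5.5, 11.0, 16.5]])


def test_quantile_normalize_makes_distributions_identical(rng):
    E = _expr(rng.exponential(2.0, (15, 40)), stage="filtered")
    out = quantile_normalize(E)
    ref = np.sort(out.values[0])
    for i in range(out.n_samples):
        np.testing.assert_allclose(np.sort(out.values[i]), ref, atol=1e-12)


def test_quantile_normalize_ties_get_mean_of_span():
    E = _expr(np.array([[1.0, 1.0, 5.0], [10.0, 20.0, 30.0]]), stage="filtered")
    out = quantile_normalize(E)
    # reference = [5.5, 10.5, 17.5]; tied pair spans the first two -> mean 8.0
    np.testing.assert_allclose(out.values[0], [8.0, 8.0, 17.5])


def test_inverse_normal_blom_values():
    got = inverse_normal_transform(np.array([1.0, 2.0, 3.0]))
    np.testing.assert_allclose(got, [-0.8694, 0.0, 0.8694], atol=5e-5)


@settings(max_examples=40, deadline=None, derandomize=True)
@given(st.lists(st.floats(-50, 50), min_size=5, max_size=30, unique=True))
def test_inverse_normal_invariant_to_monotone_transform(xs):
    """The transform depends on the data only through ranks."""
    x = np.asarray(xs)
    ranks = stats.rankdata(x)  # an exact strictly monotone transform of x
    np.testing.assert_allclose(
        inverse_normal_transform(x), inverse_normal_transform(2.0 * ranks + 1.0), atol=1e-12
    )


def test_inverse_normal_errors_and_symmetry():
    with pytest.raises(ValueError):
        inverse_normal_transform(np.array([1.0, 1.0, 1.0]))
    out = inverse_normal_transform(np.arange(11.0))
    assert abs(out.mean()) < 1e-12


def test_log2_rpkm_values_and_domain():
    E = _expr(np.array([[0.0, 1.0, 3.0]]) * np.ones((3, 1)), stage="filtered")
    out = log2_rpkm(E)
    np.testing.assert_allclose(out.values[0], [0.0, 1.0, 2.0])
    with pytest.raises(ValueError):
        log2_rpkm(_expr(-np.ones((3, 3)), stage="raw_rpkm"))


# ---------------------------------------------------------------------------
# latent factors
# ---------------------------------------------------------------------------


def test_latent_factor_recovers_planted_batch(rng):
    n, p = 100, 60
    batch = np.repeat([0.0, 1.0], n // 2)
    E = _expr(rng.normal(0, 1, (n, p)) + np.outer(batch, rng.normal(2.0, 0.2, p)),
              stage="filtered")
    F = estimate_latent_factors(E, k=3)
    r = np.corrcoef(F[:, 0], batch)[0, 1]
    assert abs(r) > 0.9


def test_latent_factor_noise_share_is_small(rng):
    n, p = 200, 100
    E = _expr(rng.normal(0, 1, (n, p)), stage="filtered")
    F = estimate_latent_factors(E, k=2)
    V = E.values
    corr = (F.T @ ((V - V.mean(axis=0)) / V.std(axis=0))) / n
    share = (corr[0] ** 2).mean()  # mean variance share explained by factor 1
    # Marchenko-Pastur edge: top-eigenvalue share ~ (1 + sqrt(p/n))^2 / p
    assert 1 / p < share < 3 * (1 + np.sqrt(p / n)) ** 2 / p


def test_latent_factor_k_bounds(rng):
    E = _expr(rng.normal(0, 1, (10, 5)), stage="filtered")
    with pytest.raises(ValueError):
        estimate_latent_factors(E, k=5)


# ---------------------------------------------------------------------------
# methylation and mRNA prefilter
# ---------------------------------------------------------------------------


def test_discretize_methylation_cutoffs():
    beta = pd.DataFrame(
        {"p1": [0.1, 0.6, 0.9], "p2": [0.1, 0.6, 0.9], "p3": [0.15, 0.6, 0.9]},
        index=["s0", "s1", "s2"],
    )
    probe_map = pd.DataFrame({"probe_id": ["p1", "p2", "p3"], "feature_id": ["g"] * 3})
    out = discretize_methylation(beta, probe_map)
    # medians 0.1 / 0.6 / 0.9 -> levels 0 / 1 (boundary) / 2
    assert out["g"].tolist() == [0.0, 1.0, 2.0]


def test_discretize_methylation_missing_probes():
    beta = pd.DataFrame({"p1": [0.5]}, index=["s0"])
    probe_map = pd.DataFrame({"probe_id": ["p1", "px"], "feature_id": ["g1", "g2"]})
    out = discretize_methylation(beta, probe_map)
    assert out["g1"].tolist() == [1.0]
    assert np.isnan(out["g2"]).all()
    with pytest.raises(ValueError):
        discretize_methylation(pd.DataFrame({"p1": [1.5]}), probe_map.iloc[:1])


def test_mrna_prefilter_rules(rng):
    n = 100
    const = np.full(n, 50.0)  # CV 0 -> dropped
    q90_31 = np.full(n, 10.0)
    q90_31[:11] = 31.0  # q90 count 31 -> log2(32)=5, not > 5 -> dropped
    heavy = rng.lognormal(3.0, 1.5, n) + 1  # CV large, q30 > 0, q90 >> 32 -> kept
    zero = np.zeros(n)
    E = _expr(np.column_stack([const, q90_31, heavy, zero]), stage="raw_count")
    keep = filter_mrna_for_iv(E)
    assert keep.tolist() == [False, False, True, False]
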