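import numpy as np
import pytest

from lncqtl import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A modest seeded cohort shared by tests that only read from it."""
    cfg = SimulationConfig(
        n_samples=150,
        blocks=[(20, 0.3, 0.5)] * 4,
        n_lncrna=12,
        n_cis=6,
        n_trans=3,
        n_mrna=30,
        n_axes=3,
        seed=7,
    )
    geno, lnc, cov, mrna, immune, truth = simulate_cohort(cfg)
    return dict(cfg=cfg, geno=geno, lnc=lnc, cov=cov, mrna=mrna, immune=immune, truth=truth)


@pytest.fixture(scope="session")
def default_analysis():
    """Default-scale cohort with the cis analysis precomputed (scan -> FDR ->
    clump), shared by the planted-truth recovery tests."""
    from lncqtl import (
        bh_fdr,
        clump_all,
        estimate_latent_factors,
        filter_lncrna_expression,
        inverse_normal,
        quantile_normalize,
        scan_eqtl,
    )

    cfg = SimulationConfig(seed=3)
    geno, lnc, cov, mrna, immune, truth = simulate_cohort(cfg)
    lf, _ = filter_lncrna_expression(lnc)
    E = inverse_normal(quantile_normalize(lf))
    cov.latent_factors = estimate_latent_factors(E, k=cfg.n_latent_true, covariates=cov)
    rec = scan_eqtl(geno, E, cov, mode="cis")
    rec["fdr"] = bh_fdr(rec["p"].to_numpy())
    clumped = clump_all(rec[rec["fdr"] < 0.1], geno)
    return dict(cfg=cfg, geno=geno, lnc=lnc, cov=cov, mrna=mrna, immune=immune,
                truth=truth, expr=E, cis=rec, clumped=clumped)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
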