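"""Shared fixtures: small synthetic datasets generated at test time."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from mutvar import context as ctx
from mutvar import filters, regression, synthetic
from mutvar.genomic_io import RegionMask, VariantRecord


@pytest.fixture(scope="session")
def cpg_truth():
    """Truth table of a CpG-effect rate model (no finite-genome noise)."""
    model = synthetic.ContextRateModel(cpg_multiplier=10.0)
    return synthetic.TruthContextTable(
        model.k, model.rate_table(),
        weights=np.full(4 ** model.k, 1 / 4 ** model.k),
        base_frequencies=(0.25, 0.25, 0.25, 0.25))


@pytest.fixture(scope="session")
def small_genome_sim():
    """1 Mb CpG-effect genome with variants, shared across context tests."""
    params = synthetic.GenomeSimParams(
        length=1_000_000,
        rate_model=synthetic.ContextRateModel(cpg_multiplier=10.0),
        seed=11)
    return synthetic.simulate_genome(params)


@pytest.fixture(scope="session")
def arma_block_fit():
    """One Bayesian ARMA regression fit on simulated blocks, reused by tests."""
    series, truth = synthetic.simulate_blocks(
        synthetic.BlockSimParams(n_blocks=1000, seed=5))
    analysis = filters.apply_exclusions(series)
    post = regression.fit_bayes_arma_regression(
        analysis, (1, 1), regression.McmcConfig(seed=5),
        fallback_orders=[(2, 1)])
    return analysis, post, truth


@pytest.fixture(scope="session")
def coverage_study():
    """20-seed calibration study: Bayes-ARMA vs OLS interval coverage.

    Each replicate simulates 1,000 blocks with ARMA(1,1) noise
    (phi=0.5, theta=0.3) around intercept 0.026, slope 0.007, fits both
    models, and records whether each 95% interval covers the truth.
    """
    truth_a, truth_b = 0.026, 0.007
    rows = []
    for seed in range(20):
        series, _ = synthetic.simulate_blocks(synthetic.BlockSimParams(
            n_blocks=1000, intercept_true=truth_a, slope_true=truth_b,
            arma_order=(1, 1), ar_coeffs=(0.5,), ma_coeffs=(0.3,),
            noise_sd=0.003, seed=1000 + seed))
        analysis = filters.apply_exclusions(series)
        post = regression.fit_bayes_arma_regression(
            analysis, (1, 1), regression.McmcConfig(seed=seed),
            fallback_orders=[(2, 1), (1, 2)])
        summ = regression.summarize_recombination(post, analysis)
        ols = regression.ols_confint(analysis)
        rows.append({
            "bayes_a": summ.intercept_ci[0] <= truth_a <= summ.intercept_ci[1],
            "bayes_b": summ.slope_ci[0] <= truth_b <= summ.slope_ci[1],
            "ols_a": ols["intercept"][1][0] <= truth_a <= ols["intercept"][1][1],
            "ols_b": ols["slope"][1][0] <= truth_b <= ols["slope"][1][1],
        })
    return pd.DataFrame(rows)


def make_variant(chrom: str, pos: int, ancestral: str, derived: str,
                 extra: str | None = None) -> VariantRecord:
    alleles = (ancestral, derived) + ((extra,) if extra else ())
    return VariantRecord.build(chrom, pos, ancestral, alleles)


@pytest.fixture
def plus_mask():
    def _make(chrom: str, start: int, end: int, strand: str = "+",
              cls: str = "intronic") -> RegionMask:
        return RegionMask(pd.DataFrame(
            [(chrom, start, end, cls, strand)],
            columns=["chrom", "start", "end", "cls", "strand"]))
    return _make
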