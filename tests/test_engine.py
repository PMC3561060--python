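"""Association engine: dosage coding, transforms, binning, model fits and
the full per-study scan."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize, stats

from phewaskit.core import PhenotypeDescriptor, SnpRecord
from phewaskit.engine import (EngineConfig, FitError, bin_categorical,
                              code_additive, fit_linear, fit_logistic,
                              run_study_phewas, transform_log1p)
from phewaskit.simulate import simulate_studies
from tests.conftest import tiny_config

SNP = SnpRecord("rs1", "1", 100, "A", "G")


# --- code_additive ----------------------------------------------------------

def test_dosage_counts_coded_allele_copies():
    dose, caf = code_additive([2, 1, 0, 1], SNP)
    np.testing.assert_array_equal(dose, [2, 1, 0, 1])
    assert caf == pytest.approx(4 / 8)


def test_all_missing_column_gives_undefined_caf():
    dose, caf = code_additive([np.nan, np.nan], SNP)
    assert np.isnan(caf)


def test_dosage_outside_012_is_an_error():
    with pytest.raises(ValueError, match="outside"):
        code_additive([0, 1, 3], SNP)


def test_caf_matches_binomial_sampling_at_large_n():
    rng = np.random.default_rng(5)
    maf = 0.2
    n = 50_000
    dose, caf = code_additive(rng.binomial(2, maf, size=n), SNP)
    se = np.sqrt(maf * (1 - maf) / (2 * n))
    assert abs(caf - maf) < 3 * se


# --- log1p ------------------------------------------------------------------

def test_log1p_known_values_and_missing():
    out = transform_log1p([0.0, np.e - 1, np.nan])
    assert out[0] == 0.0
    assert out[1] == pytest.approx(1.0)
    assert np.isnan(out[2])


def test_log1p_below_minus_one_errors_negative_warns():
    with pytest.raises(ValueError):
        transform_log1p([-1.5])
    with pytest.warns(RuntimeWarning):
        out = transform_log1p([-0.5])
    assert out[0] == pytest.approx(np.log(0.5))


def test_log1p_inverse_and_rank_preservation():
    rng = np.random.default_rng(1)
    y = rng.exponential(5, size=200)
    out = transform_log1p(y)
    np.testing.assert_allclose(np.expm1(out), y, atol=1e-12)
    assert (np.argsort(out) == np.argsort(y)).all()


# --- categorical binning ----------------------------------------------------

CAT = PhenotypeDescriptor("S", "cat", "categorical")


def test_binning_counts_cases_and_controls():
    values = [0] * 5 + [1] * 3 + [2] * 2
    bins = bin_categorical(values, CAT)
    assert [b[0] for b in bins] == ["cat=0", "cat=1", "cat=2"]
    cases = [int(np.nansum(b[1])) for b in bins]
    controls = [int((b[1] == 0).sum()) for b in bins]
    assert cases == [5, 3, 2]
    assert controls == [5, 7, 8]


def test_binning_preserves_missing_and_degenerate_inputs():
    bins = bin_categorical([0, 1, np.nan], CAT)
    assert all(np.isnan(b[1][2]) for b in bins)
    assert bin_categorical([1, 1, 1], CAT) == []
    assert bin_categorical([np.nan, np.nan], CAT) == []
    with pytest.raises(ValueError, match="categorical"):
        bin_categorical([0, 1], PhenotypeDescriptor("S", "b", "binary"))


# --- linear fits ------------------------------------------------------------

def _closed_form_ols(x, y):
    """Normal-equations oracle: beta, se and two-sided t-test p."""
    X = np.column_stack([np.ones(len(x)), x])
    beta_hat = np.linalg.solve(X.T @ X, X.T @ y)
    resid = y - X @ beta_hat
    df = len(x) - 2
    sigma2 = resid @ resid / df
    cov = sigma2 * np.linalg.inv(X.T @ X)
    se = np.sqrt(cov[1, 1])
    t = beta_hat[1] / se
    p = 2 * stats.t.sf(abs(t), df)
    return beta_hat[1], se, p


def test_linear_fit_matches_normal_equations_on_worked_instance():
    x = np.array([0, 0, 1, 1, 2, 2], dtype=float)
    y = np.array([1.0, 1.4, 2.1, 2.3, 3.2, 2.8])
    fit = fit_linear(x, y, min_n=2)
    beta, se, p = _closed_form_ols(x, y)
    assert fit.beta == pytest.approx(beta, abs=1e-12)
    assert fit.se == pytest.approx(se, abs=1e-12)
    assert fit.p == pytest.approx(p, abs=1e-12)


def test_linear_fit_matches_normal_equations_on_random_instances():
    rng = np.random.default_rng(7)
    for _ in range(20):
        n = rng.integers(10, 60)
        x = rng.binomial(2, 0.4, size=n).astype(float)
        if np.ptp(x) == 0:
            continue
        y = rng.normal(size=n)
        fit = fit_linear(x, y, min_n=2)
        beta, se, p = _closed_form_ols(x, y)
        np.testing.assert_allclose([fit.beta, fit.se, fit.p],
                                   [beta, se, p], rtol=1e-10, atol=1e-12)


def test_linear_fit_recovers_strong_signal():
    rng = np.random.default_rng(2)
    x = rng.binomial(2, 0.5, size=1000).astype(float)
    y = 2.0 * x + rng.normal(0, 0.1, size=1000)
    fit = fit_linear(x, y)
    assert 1.99 <= fit.beta <= 2.01
    assert fit.n == 1000


def test_linear_fit_null_p_values_are_uniform():
    rng = np.random.default_rng(3)
    x = rng.binomial(2, 0.3, size=200).astype(float)
    ps = [fit_linear(x, rng.normal(size=200)).p for _ in range(500)]
    assert stats.kstest(ps, "uniform").pvalue > 1e-3


def test_linear_fit_skips_degenerate_inputs():
    with pytest.raises(FitError, match="constant dosage"):
        fit_linear([1, 1, 1, 1] * 5, np.arange(20.0))
    with pytest.raises(FitError, match="constant outcome"):
        fit_linear(np.arange(20.0) % 3, [5.0] * 20)
    with pytest.raises(FitError, match="below minimum"):
        fit_linear([0, 1, 2], [1.0, 2.0, 3.0], min_n=10)


def test_linear_covariate_adjustment_changes_estimate():
    rng = np.random.default_rng(8)
    n = 2000
    x = rng.binomial(2, 0.4, size=n).astype(float)
    conf = x + rng.normal(size=n)
    y = 1.0 * conf + rng.normal(size=n)   # effect only through confounder
    unadj = fit_linear(x, y)
    adj = fit_linear(x, y, covariates=conf[:, None])
    assert abs(adj.beta) < abs(unadj.beta)


# --- logistic fits ----------------------------------------------------------

def _brute_force_logistic(counts_cases, counts_controls):
    """Direct likelihood maximization oracle on a 2x3 dosage table."""
    doses = np.array([0.0, 1.0, 2.0])

    def negll(params):
        a, b = params
        eta = a + b * doses
        logp = -np.log1p(np.exp(-eta))
        log1mp = -np.log1p(np.exp(eta))
        return -(np.sum(counts_cases * logp)
                 + np.sum(counts_controls * log1mp))

    res = optimize.minimize(negll, [0.0, 0.0], method="Nelder-Mead",
                            options={"xatol": 1e-10, "fatol": 1e-12,
                                     "maxiter": 10000})
    return res.x[1]


def test_logistic_beta_matches_brute_force_mle_on_2x3_table():
    cases, controls = np.array([10, 20, 30]), np.array([30, 20, 10])
    dose = np.repeat([0.0, 1.0, 2.0], cases + controls)
    y = np.concatenate([
        np.concatenate([np.ones(c), np.zeros(k)])
        for c, k in zip(cases, controls)])
    dose = np.concatenate([np.full(c + k, d) for d, c, k
                           in zip([0.0, 1.0, 2.0], cases, controls)])
    fit = fit_logistic(dose, y)
    assert fit.beta == pytest.approx(
        _brute_force_logistic(cases, controls), abs=1e-4)


def test_logistic_null_wald_statistic_calibrated():
    """|beta| < 3·se in ≥99% of null replicates (balanced, n=2000)."""
    rng = np.random.default_rng(4)
    hits = 0
    reps = 300
    for _ in range(reps):
        d = rng.binomial(2, 0.3, size=2000).astype(float)
        y = rng.binomial(1, 0.5, size=2000).astype(float)
        fit = fit_logistic(d, y)
        hits += abs(fit.beta) < 3 * fit.se
    assert hits / reps >= 0.99


def test_logistic_perfect_separation_is_withheld():
    d = np.array([2.0] * 20 + [0.0] * 20)
    y = np.array([1.0] * 20 + [0.0] * 20)
    with pytest.raises(FitError):
        fit_logistic(d, y)


def test_logistic_one_class_outcome_is_withheld():
    d = np.arange(20.0) % 3
    with pytest.raises(FitError, match="two levels"):
        fit_logistic(d, np.ones(20))


def test_logistic_minor_allele_count_gate():
    d = np.array([1.0] + [0.0] * 99)
    y = (np.arange(100) % 2).astype(float)
    with pytest.raises(FitError, match="minor allele count"):
        fit_logistic(d, y, min_mac=5)


# --- allele-flip antisymmetry ----------------------------------------------

def test_allele_flip_antisymmetry_linear_and_logistic():
    """Recoding dosage d -> 2-d negates beta, preserves se and p, and maps
    CAF -> 1-CAF, for both models."""
    rng = np.random.default_rng(9)
    d = rng.binomial(2, 0.3, size=500).astype(float)
    y = 0.4 * d + rng.normal(size=500)
    a = fit_linear(d, y)
    b = fit_linear(2 - d, y)
    assert b.beta == pytest.approx(-a.beta, rel=1e-10)
    assert b.se == pytest.approx(a.se, rel=1e-10)
    assert b.p == pytest.approx(a.p, rel=1e-8)

    yb = rng.binomial(1, 1 / (1 + np.exp(-(-0.3 + 0.5 * d)))).astype(float)
    a = fit_logistic(d, yb)
    b = fit_logistic(2 - d, yb)
    assert b.beta == pytest.approx(-a.beta, rel=1e-6)
    assert b.se == pytest.approx(a.se, rel=1e-6)

    _, caf = code_additive(d, SNP)
    _, caf_flipped = code_additive(2 - d, SNP)
    assert caf_flipped == pytest.approx(1 - caf, abs=1e-15)


# --- full scan --------------------------------------------------------------

def test_scan_row_count_is_combinatorial():
    """1 stratum x 2 SNPs x {1 continuous, 1 binary, 1 three-level
    categorical} -> 2 x (2 + 1 + 3) = 12 result rows."""
    from phewaskit.simulate import PhenotypeSpec

    phenos = [
        PhenotypeSpec("c1", "continuous", class_id="C1", mean=100, sd=10),
        PhenotypeSpec("b1", "binary", class_id="C2", prevalence=0.4),
        PhenotypeSpec("k1", "categorical", class_id="C3", n_levels=3),
    ]
    config = tiny_config(seed=1, n=400, n_studies=1, n_snps=2,
                         phenotypes=phenos)
    sim = simulate_studies(config)
    frame, skips = run_study_phewas(sim.studies[0], EngineConfig())
    assert len(frame) == 12
    assert not skips
    # deterministic order: SNP-major, raw before log1p
    first = frame.iloc[0]
    assert (first["snp_id"], first["transform"]) == ("rs1", "none")
    assert list(frame["transform"][:2]) == ["none", "log1p"]


def test_scan_skips_monomorphic_snp_and_logs_reason():
    sim = simulate_studies(tiny_config(seed=2, n=50, n_studies=1, n_snps=2))
    ds = sim.studies[0]
    ds.dosages.iloc[:, 0] = 1.0   # monomorphic
    frame, skips = run_study_phewas(ds, EngineConfig())
    assert (frame.snp_id == "rs1").sum() == 0
    assert any(s.snp_id == "rs1" and "monomorphic" in s.reason
               for s in skips)


def test_scan_empty_phenotype_panel_gives_empty_results():
    sim = simulate_studies(tiny_config(seed=2, n=30, n_studies=1))
    ds = sim.studies[0]
    ds.phenotypes = ds.phenotypes.iloc[:, :0]
    frame, _ = run_study_phewas(ds, EngineConfig())
    assert frame.empty


def test_scan_records_per_test_caf_and_n(example_results):
    sim = simulate_studies(tiny_config(seed=6, n=300, n_studies=1,
                                       missing=0.2))
    frame, _ = run_study_phewas(sim.studies[0], EngineConfig())
    assert (frame.n <= 300).all() and (frame.n >= 10).all()
    assert frame.caf.between(0, 1).all()
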