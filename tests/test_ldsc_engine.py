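import numpy as np
import pandas as pd
import pytest

from gsem_cortex._linalg import vech
from gsem_cortex.ldsc_engine import (
    LDScores,
    OverlapModel,
    bivariate_ldsc,
    liability_multiplier,
    liability_transform,
    multivariable_ldsc,
    univariate_ldsc,
)
from gsem_cortex.sumstats_io import CleanedSumstats, TraitMeta
from gsem_cortex.synthetic_data import AnnotationDef, GenerativeSpec, make_ld_scores, \
    simulate_sumstats


def _null_trait(ld, z, name="t"):
    tab = pd.DataFrame(
        {"A1": "A", "A2": "G", "Z": z, "N": 20_000.0, "MAF": 0.3}, index=ld.table.index
    )
    return CleanedSumstats(trait=TraitMeta(name=name), table=tab)


@pytest.fixture(scope="module")
def base_ld():
    rng = np.random.default_rng(7)
    ld, ann, _ = make_ld_scores(20_000, [AnnotationDef("base", 1.0, 1.0)], rng=rng)
    return ld, rng


class TestUnivariate:
    def test_null_gives_zero_h2_unit_intercept(self, base_ld):
        ld, rng = base_ld
        ss = _null_trait(ld, rng.standard_normal(20_000))
        fit = univariate_ldsc(ss, ld, m_ref=20_000)
        assert abs(fit.slope) <= 2 * fit.slope_se
        assert abs(fit.intercept - 1.0) <= 2 * fit.intercept_se

    def test_h2_recovery(self):
        spec = GenerativeSpec(
            loadings=np.array([[0.1], [0.1]]), h2=np.array([0.2, 0.2]), seed=12
        )
        st = simulate_sumstats(spec)
        fit = univariate_ldsc(st.sumstats[0], st.ld, m_ref=spec.M)
        assert abs(fit.slope - 0.2) <= 2 * fit.slope_se

    def test_degenerate_zero_z(self, base_ld):
        ld, _ = base_ld
        ss = _null_trait(ld, np.zeros(20_000))
        fit = univariate_ldsc(ss, ld, m_ref=20_000)
        assert fit.slope <= 0
        assert abs(fit.intercept) < 1e-10

    def test_too_few_snps_errors(self, base_ld):
        ld, rng = base_ld
        short = LDScores(ld.table.iloc[:100].copy())
        ss = _null_trait(short, rng.standard_normal(100))
        with pytest.raises(ValueError, match="blocks"):
            univariate_ldsc(ss, short, n_blocks=200)


class TestBivariate:
    def test_self_covariance_equals_h2(self, small_study):
        st = small_study["study"]
        uni = univariate_ldsc(st.sumstats[0], st.ld, m_ref=small_study["spec"].M)
        biv = bivariate_ldsc(
            st.sumstats[0], st.sumstats[0], st.ld, m_ref=small_study["spec"].M
        )
        # the product regression of a trait with itself is the chi2 regression;
        # small weight differences keep this approximate rather than exact
        assert biv.slope == pytest.approx(uni.slope, rel=0.02)
        assert biv.intercept == pytest.approx(uni.intercept, abs=0.02)

    def test_overlap_intercept_matches_expectation(self):
        # rho=0.5, N_s=1000, N1=N2=2000 -> expected cross intercept 0.25
        om = OverlapModel(rho=0.5, n_shared=1000.0)
        assert om.expected_intercept(2000.0, 2000.0) == pytest.approx(0.25)
        spec = GenerativeSpec(
            loadings=np.array([[0.01], [0.01]]), h2=np.array([1e-3, 1e-3]),
            M=20_000, N=2000.0, overlap={(0, 1): (0.5, 1000.0)}, seed=0,
        )
        st = simulate_sumstats(spec)
        biv = bivariate_ldsc(st.sumstats[0], st.sumstats[1], st.ld, m_ref=20_000)
        assert abs(biv.intercept - 0.25) <= 2 * biv.intercept_se

    def test_rg_recovery_without_overlap(self):
        lam = np.full((2, 1), np.sqrt(0.6))  # implied r_g = 0.6
        spec = GenerativeSpec(loadings=lam, h2=np.array([0.3, 0.3]), seed=5)
        st = simulate_sumstats(spec)
        biv = bivariate_ldsc(st.sumstats[0], st.sumstats[1], st.ld, m_ref=spec.M)
        cov_true = 0.6 * 0.3
        assert abs(biv.slope - cov_true) <= 2 * biv.slope_se
        assert abs(biv.intercept) <= 2 * biv.intercept_se


class TestMultivariable:
    def test_duplicated_trait_gives_perfect_error_correlation(self, small_study):
        st = small_study["study"]
        pair = multivariable_ldsc(
            [st.sumstats[0], st.sumstats[0]], st.ld, m_ref=small_study["spec"].M
        )
        # vech order for k=2: (h2_1, cov_12, h2_2)
        v = pair.V
        assert v[0, 2] == pytest.approx(v[0, 0], rel=1e-6)
        assert pair.S[0, 0] == pytest.approx(pair.S[1, 1])

    def test_trait_order_permutes_s_and_v(self, small_study):
        st = small_study["study"]
        m = small_study["spec"].M
        fwd = small_study["pair"]
        rev = multivariable_ldsc(st.sumstats[::-1], st.ld, m_ref=m)
        k = 6
        perm = np.arange(k)[::-1]
        assert np.allclose(rev.S, fwd.S[np.ix_(perm, perm)], atol=1e-10)
        # V re-indexes consistently: SEs of matching elements agree
        se_f = fwd.se_matrix()
        se_r = rev.se_matrix()
        assert np.allclose(se_r, se_f[np.ix_(perm, perm)], atol=1e-10)

    def test_jackknife_block_count_stability(self, small_study):
        st = small_study["study"]
        m = small_study["spec"].M
        p200 = small_study["pair"]
        p100 = multivariable_ldsc(st.sumstats, st.ld, n_blocks=100, m_ref=m)
        assert np.allclose(p100.S, p200.S, atol=1e-10)  # estimates identical
        se_a, se_b = vech(p200.se_matrix()), vech(p100.se_matrix())
        assert np.all(np.abs(se_a - se_b) <= 0.25 * np.maximum(se_a, se_b))

    def test_parameter_recovery_against_truth(self, small_study):
        pair, spec = small_study["pair"], small_study["spec"]
        dev = np.abs(vech(pair.S) - vech(spec.S_true))
        within = dev <= 2 * vech(pair.se_matrix())
        assert within.mean() >= 0.8  # single seed; the 20-seed average is checked in acceptance


class TestLiability:
    def test_balanced_case_gives_pi_over_two(self):
        assert liability_multiplier(0.5, 0.5) == pytest.approx(np.pi / 2, rel=1e-12)

    def test_zero_maps_to_zero(self):
        assert liability_transform(0.0, 0.3, 0.01) == 0.0

    def test_frozen_numeric_oracle(self):
        # K=0.01, P=0.5, h2_obs=0.1; value computed from an independent
        # evaluation of the closed form (scipy.special.ndtri + density)
        assert liability_transform(0.1, 0.5, 0.01) == pytest.approx(
            0.0551907298063172, rel=1e-10
        )

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            liability_multiplier(0.0, 0.1)
        with pytest.raises(ValueError):
            liability_multiplier(0.5, 1.0)
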