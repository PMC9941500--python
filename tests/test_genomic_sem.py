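import numpy as np
import pandas as pd
import pytest

from gsem_cortex._linalg import vech
from gsem_cortex.genomic_sem import (
    build_model,
    cfi,
    combine_specs,
    constrain_cross_correlations,
    fit,
    fit_indices,
    general_factor_share,
    independence_model,
    joint_external_model,
    omnibus_equality_test,
    parse_model,
    residual_search,
)
from gsem_cortex.ldsc_engine import multivariable_ldsc
from gsem_cortex.synthetic_data import GenerativeSpec, simulate_sumstats


class TestBuildModel:
    def test_common_model_df_accounting(self):
        spec = build_model({n: "F1" for n in "ABCDEF"}, "common")
        # 6 loadings + 6 residual variances free, factor variance fixed: df = 21 - 12
        assert spec.n_free == 12
        assert spec.df() == 9

    def test_two_indicator_factor_gets_equality_group(self):
        spec = build_model(
            {"A": "F1", "B": "F1", "C": "F1", "D": "F2", "E": "F2"}, "correlated"
        )
        assert ["F2=~D", "F2=~E"] in spec.equality_groups
        # 5 loadings (one equality merges two) + 1 factor corr + 5 residuals
        assert spec.n_free == 4 + 1 + 5

    def test_single_indicator_bifactor_rules(self):
        spec = build_model(
            {"A": "F1", "B": "F1", "C": "F1", "D": "F2", "E": "F2", "X": "F5"},
            "bifactor",
        )
        assert spec.residual_var["X"] == 0.0
        # all factor covariances fixed to zero (orthogonal residual structure)
        for pair, v in spec.factor_cov.items():
            if pair[0] != pair[1]:
                assert v == 0.0
        assert spec.df() == 21 - 16

    def test_empty_factor_errors(self):
        with pytest.raises(ValueError):
            build_model({}, "common")


class TestFit:
    def test_exact_recovery_on_population_matrix(self, pop_model):
        spec = build_model(pop_model["assignment"], "correlated")
        res = fit(pop_model["S"], pop_model["V"], spec)
        assert res.converged
        assert res.chi2 < 1e-6
        truths = {
            **{f"F1=~{n}": t for n, t in zip("ABC", (0.7, 0.6, 0.5))},
            **{f"F2=~{n}": t for n, t in zip("DEF", (0.65, 0.55, 0.45))},
            "F1~~F2": 0.4,
        }
        for name, t in truths.items():
            assert res.estimates[name] == pytest.approx(t, abs=1e-4)

    def test_misfixed_loading_produces_misfit(self, pop_model):
        spec = build_model(pop_model["assignment"], "correlated")
        spec.loading_pattern[("F1", "A")] = 0.0
        res = fit(pop_model["S"], pop_model["V"], spec)
        fi = fit_indices(res, pop_model["S"], pop_model["V"])
        assert res.chi2 > 1.0
        assert fi.SRMR > 1e-3

    def test_relabeling_invariance(self, pop_model):
        S, V = pop_model["S"], pop_model["V"]
        spec = build_model(pop_model["assignment"], "correlated")
        res = fit(S, V, spec)
        perm = [3, 4, 5, 0, 1, 2]
        names = [pop_model["names"][i] for i in perm]
        S2 = pd.DataFrame(S[np.ix_(perm, perm)], index=names, columns=names)
        # V for the permuted order: rebuild from scratch for the diagonal case
        res2 = fit(S2, V, build_model({n: pop_model["assignment"][n] for n in names},
                                      "correlated"))
        for name, est in res.estimates.items():
            assert res2.estimates[name] == pytest.approx(est, abs=1e-6)

    def test_bifactor_never_fits_worse_than_correlated(self, pop_model):
        rng = np.random.default_rng(1)
        E = rng.standard_normal((6, 6)) * 0.02
        P = pop_model["S"] + (E + E.T) / 2
        np.fill_diagonal(P, np.diag(pop_model["S"]))
        V = pop_model["V"]
        c = fit(P, V, build_model(pop_model["assignment"], "correlated"))
        b = fit(P, V, build_model(pop_model["assignment"], "bifactor"))
        assert b.chi2 <= c.chi2 + 1e-6

    def test_recovery_from_simulated_study(self, small_study):
        pair = small_study["pair"]
        assignment = {n: ("F1" if i < 3 else "F2") for i, n in enumerate(pair.names)}
        res = fit(
            pd.DataFrame(pair.S, index=pair.names, columns=pair.names),
            pair.V, build_model(assignment, "correlated"),
        )
        assert res.converged
        # truth on the covariance metric: loading = 0.7 * sqrt(0.3)
        lam_true = 0.7 * np.sqrt(0.3)
        hits = 0
        checks = 0
        for name, est in res.estimates.items():
            if "=~" in name:
                checks += 1
                hits += abs(est - lam_true) <= 2 * res.se[name]
        assert checks == 6 and hits >= 5


class TestFitIndices:
    def test_cfi_formula_arithmetic(self):
        assert cfi(50.0, 10, 500.0, 15) == pytest.approx(1 - 40.0 / 485.0)
        assert cfi(5.0, 10, 500.0, 15) == 1.0     # better than its df: clamp
        assert cfi(500.0, 10, 20.0, 15) == 0.0    # worse than independence: clamp

    def test_perfect_fit_has_unit_cfi_zero_srmr(self, pop_model):
        spec = build_model(pop_model["assignment"], "correlated")
        res = fit(pop_model["S"], pop_model["V"], spec)
        fi = fit_indices(res, pop_model["S"], pop_model["V"])
        assert fi.CFI == 1.0
        assert fi.SRMR < 1e-6

    def test_aic_difference_identity_for_nested_specs(self, pop_model):
        S, V = pop_model["S"], pop_model["V"]
        free = build_model(pop_model["assignment"], "correlated")
        constrained = build_model(pop_model["assignment"], "correlated")
        constrained.factor_cov[("F1", "F2")] = 0.0
        a = fit(S, V, free)
        b = fit(S, V, constrained)
        fa = fit_indices(a, S, V)
        fb = fit_indices(b, S, V)
        ddf = b.df - a.df
        assert fb.AIC - fa.AIC == pytest.approx((b.chi2 - a.chi2) - 2 * ddf, abs=1e-6)


class TestResidualSearch:
    def test_planted_pair_found_then_stop(self, pop_model):
        S = pop_model["S"].copy()
        S[0, 4] = S[4, 0] = S[0, 4] + 0.15
        V = np.eye(21) * 1e-4
        spec = build_model(pop_model["assignment"], "correlated")
        final, res, trace = residual_search(S, V, spec, alpha=0.01)
        assert [s["pair"] for s in trace.steps] == [("A", "E")]
        assert trace.steps[0]["p"] < 0.01
        assert res.estimates["A~~E"] == pytest.approx(0.15, abs=0.01)
        if trace.stopped_candidate is not None:
            assert trace.stopped_candidate["p"] >= 0.01

    def test_exact_model_needs_no_steps(self, pop_model):
        spec = build_model(pop_model["assignment"], "correlated")
        _, _, trace = residual_search(pop_model["S"], np.eye(21) * 1e-4, spec)
        assert trace.steps == []


class TestGeneralFactorShare:
    def test_share_is_squared_standardized_loading(self, pop_model):
        rng = np.random.default_rng(1)
        E = rng.standard_normal((6, 6)) * 0.02
        P = pop_model["S"] + (E + E.T) / 2
        np.fill_diagonal(P, np.diag(pop_model["S"]))
        b = fit(P, pop_model["V"], build_model(pop_model["assignment"], "bifactor"))
        shares, avg = general_factor_share(b)
        lam_a = b.standardized["G=~A"]
        assert shares["A"] == pytest.approx(lam_a ** 2)
        assert avg == pytest.approx(np.mean(list(shares.values())))

    def test_requires_bifactor(self, pop_model):
        res = fit(pop_model["S"], pop_model["V"],
                  build_model(pop_model["assignment"], "correlated"))
        with pytest.raises(ValueError):
            general_factor_share(res)


def _joint_population(r_f1_g=0.3, r_f2_g=0.0):
    """9-indicator population: 6 brain (2 factors) + 3 external (g)."""
    lam = np.zeros((9, 3))
    lam[:3, 0] = 0.7
    lam[3:6, 1] = 0.7
    lam[6:, 2] = 0.6
    phi = np.eye(3)
    phi[0, 1] = phi[1, 0] = 0.4
    phi[0, 2] = phi[2, 0] = r_f1_g
    phi[1, 2] = phi[2, 1] = r_f2_g
    common = lam @ phi @ lam.T
    S = common + np.diag(1 - np.diag(common))
    names = [f"roi{i}" for i in range(1, 7)] + ["cog1", "cog2", "cog3"]
    return pd.DataFrame(S, index=names, columns=names), names


class TestJointAndOmnibus:
    def test_external_correlation_recovery(self):
        S, names = _joint_population()
        V = np.eye(45) * 1e-5
        brain = build_model({f"roi{i}": ("F1" if i <= 3 else "F2")
                             for i in range(1, 7)}, "correlated")
        ext = build_model({c: "g" for c in names[6:]}, "common")
        res = joint_external_model(brain, ext, S, V)
        tbl = res.factor_correlations.set_index(["brain_factor", "external_factor"])
        assert tbl.loc[("F1", "g"), "r_g"] == pytest.approx(0.3, abs=1e-3)
        assert tbl.loc[("F2", "g"), "r_g"] == pytest.approx(0.0, abs=1e-3)
        assert res.bonferroni_threshold == pytest.approx(0.05 / 18)

    def test_identical_specs_give_zero_difference(self, pop_model):
        spec = build_model(pop_model["assignment"], "correlated")
        res = fit(pop_model["S"], pop_model["V"], spec)
        om = omnibus_equality_test(res, res)
        assert om.dchi2 == 0.0 and om.ddf == 0

    def test_type_one_error_calibration(self):
        # equal true correlations: the chi2 difference should follow its
        # reference distribution; check rejection near alpha over replicates
        S, names = _joint_population(r_f1_g=0.2, r_f2_g=0.2)
        sigma = 0.01
        V = np.eye(45) * sigma ** 2
        brain = build_model({f"roi{i}": ("F1" if i <= 3 else "F2")
                             for i in range(1, 7)}, "correlated")
        ext = build_model({c: "g" for c in names[6:]}, "common")
        free = combine_specs(brain, ext)
        con = constrain_cross_correlations(free, ["F1", "F2"], "g")
        s_true = vech(S.to_numpy())
        rng = np.random.default_rng(42)
        rejections = 0
        n_rep = 120
        for _ in range(n_rep):
            s_draw = s_true + sigma * rng.standard_normal(45)
            S_draw = S.copy()
            S_draw.loc[:, :] = _unvech_df(s_draw, S)
            om = omnibus_equality_test(
                fit(S_draw, V, free), fit(S_draw, V, con)
            )
            rejections += om.p < 0.05
        rate = rejections / n_rep
        assert 0.005 <= rate <= 0.13  # 95% binomial band around 0.05 for n=120

    def test_power_against_heterogeneous_truth(self):
        S, names = _joint_population(r_f1_g=0.4, r_f2_g=0.0)
        V = np.eye(45) * 1e-4
        brain = build_model({f"roi{i}": ("F1" if i <= 3 else "F2")
                             for i in range(1, 7)}, "correlated")
        ext = build_model({c: "g" for c in names[6:]}, "common")
        free = combine_specs(brain, ext)
        con = constrain_cross_correlations(free, ["F1", "F2"], "g")
        om = omnibus_equality_test(fit(S, V, free), fit(S, V, con))
        assert om.p < 1e-6


def _unvech_df(v, template):
    from gsem_cortex._linalg import unvech

    return unvech(v, template.shape[0])


class TestParser:
    def test_round_trip_structure(self):
        text = """
        F1 =~ A + B + C
        F2 =~ D + E
        F1 ~~ F2
        A ~~ D
        equal("F2=~D", "F2=~E")
        """
        spec = parse_model(text)
        assert spec.indicators == ["A", "B", "C", "D", "E"]
        assert spec.factor_cov[("F1", "F2")] == "free"
        assert ("A", "D") in spec.residual_cov
        assert ["F2=~D", "F2=~E"] in spec.equality_groups

    def test_fixed_covariance(self):
        spec = parse_model("F1 =~ A + B\nF2 =~ C + D\nF1 ~~ 0*F2")
        assert spec.factor_cov[("F1", "F2")] == 0.0

    def test_parse_equivalence_with_builder(self, pop_model):
        spec_text = parse_model(
            "F1 =~ A + B + C\nF2 =~ D + E + F\nF1 ~~ F2"
        )
        built = build_model(pop_model["assignment"], "correlated")
        res_a = fit(pop_model["S"], pop_model["V"], spec_text)
        res_b = fit(pop_model["S"], pop_model["V"], built)
        assert res_a.chi2 == pytest.approx(res_b.chi2, abs=1e-8)
        assert res_a.df == res_b.df
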