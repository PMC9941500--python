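import numpy as np
import pandas as pd
import pytest

from gsem_cortex._linalg import unvech, vech
from gsem_cortex.genomic_sem import build_model, fit
from gsem_cortex.ldsc_engine import AnnotationSet, multivariable_ldsc
from gsem_cortex.stratified_enrichment import (
    TauMatrixSet,
    ZeroOrderCovariance,
    bonferroni_threshold,
    factor_enrichment,
    screen_and_smooth,
    stratified_ldsc,
    zero_order,
)
from gsem_cortex.synthetic_data import AnnotationDef, GenerativeSpec, simulate_sumstats


@pytest.fixture(scope="module")
def annotated_study():
    ann = [AnnotationDef("hot", 0.10, 0.20), AnnotationDef("cold", 0.90, 0.80)]
    spec = GenerativeSpec.two_factor(seed=2, annotations=ann)
    study = simulate_sumstats(spec)
    pair = multivariable_ldsc(study.sumstats, study.ld, m_ref=spec.M)
    taus = stratified_ldsc(study.sumstats, study.ld, study.annotations)
    return {"spec": spec, "study": study, "pair": pair, "taus": taus}


def _random_tau_set(k=3, n_ann=4, n_blocks=50, seed=0):
    rng = np.random.default_rng(seed)
    names = [f"a{i}" for i in range(n_ann)]
    n_pairs = k * (k + 1) // 2
    reps = rng.standard_normal((n_blocks, n_ann, n_pairs)) * 0.01
    taus = {c: unvech(reps[:, ci, :].mean(axis=0) * n_blocks, k)
            for ci, c in enumerate(names)}
    return TauMatrixSet(
        trait_names=[f"t{i}" for i in range(k)], annotation_names=names,
        taus=taus, intercepts=np.eye(k), replicates=reps, n_blocks=n_blocks,
    )


class TestStratifiedRegression:
    def test_single_genome_annotation_collapses_to_unstratified(self, small_study):
        st, spec = small_study["study"], small_study["spec"]
        taus = stratified_ldsc(st.sumstats, st.ld, st.annotations)
        tau_base = taus.taus["base"]
        assert np.allclose(tau_base, small_study["pair"].S, atol=5e-3)

    def test_disjoint_share_recovery(self, annotated_study):
        taus = annotated_study["taus"]
        spec = annotated_study["spec"]
        for name, share in (("hot", 0.2), ("cold", 0.8)):
            truth = share * spec.S_true
            se = np.sqrt(np.maximum(np.diag(taus.sampling_cov(name)), 1e-30))
            dev = np.abs(vech(taus.taus[name]) - vech(truth))
            assert (dev <= 2 * se).mean() >= 0.8

    def test_null_annotation_tau_near_zero(self):
        ann = [AnnotationDef("on", 0.5, 1.0), AnnotationDef("off", 0.5, 0.0)]
        spec = GenerativeSpec(
            loadings=np.full((2, 1), 0.7), h2=np.array([0.3, 0.3]),
            annotations=ann, seed=8,
        )
        st = simulate_sumstats(spec)
        taus = stratified_ldsc(st.sumstats, st.ld, st.annotations)
        se = np.sqrt(np.diag(taus.sampling_cov("off")))
        assert np.all(np.abs(vech(taus.taus["off"])) <= 2.5 * se)

    def test_collinear_design_rejected(self, annotated_study):
        st = annotated_study["study"]
        ld = st.ld
        ld2 = type(ld)(ld.table.copy())
        ld2.table["dup"] = ld2.table["hot"]
        sizes = dict(st.annotations.sizes)
        sizes["dup"] = sizes["hot"]
        overlaps = dict(st.annotations.overlaps)
        for c in list(st.annotations.sizes):
            overlaps[("dup", c)] = st.annotations.overlap("hot", c)
        overlaps[("dup", "dup")] = sizes["dup"]
        overlaps[("dup", "hot")] = sizes["dup"]
        ann2 = AnnotationSet(sizes=sizes, overlaps=overlaps,
                             total_m=st.annotations.total_m, genome_annotation="base")
        with pytest.raises(ValueError, match="rank deficient"):
            stratified_ldsc(st.sumstats, ld2, ann2)


class TestZeroOrder:
    def test_matches_brute_force_weighted_sum(self):
        tau_set = _random_tau_set(seed=4)
        names = tau_set.annotation_names
        rng = np.random.default_rng(5)
        sizes = {c: int(rng.integers(100, 1000)) for c in names}
        overlaps = {}
        for c in names:
            for t in names:
                if c == t:
                    overlaps[(c, t)] = sizes[c]
                else:
                    overlaps[(c, t)] = int(min(sizes[c], sizes[t]) * rng.random() * 0.5)
        overlaps = {k: v for k, v in overlaps.items()}
        ann = AnnotationSet(sizes=sizes, overlaps=dict(overlaps), total_m=5000)
        zo = zero_order(tau_set, ann)
        for t in names:
            brute = np.zeros_like(tau_set.taus[t])
            for c in names:
                brute = brute + (ann.overlap(c, t) / sizes[c]) * tau_set.taus[c]
            assert np.allclose(zo[t].zeta, brute, atol=1e-14)

    def test_disjoint_annotations_return_own_tau(self):
        tau_set = _random_tau_set(seed=6)
        names = tau_set.annotation_names
        sizes = {c: 100 for c in names}
        overlaps = {(c, t): (100 if c == t else 0) for c in names for t in names}
        ann = AnnotationSet(sizes=sizes, overlaps=dict(overlaps), total_m=400)
        zo = zero_order(tau_set, ann)
        for c in names:
            assert np.allclose(zo[c].zeta, tau_set.taus[c], atol=1e-15)

    def test_nested_annotation_arithmetic(self):
        tau_set = _random_tau_set(n_ann=2, seed=7)
        a, b = tau_set.annotation_names
        # b nested inside a with |M_b|/|M_a| = 0.25
        sizes = {a: 400, b: 100}
        overlaps = {(a, a): 400, (b, b): 100, (a, b): 100, (b, a): 100}
        ann = AnnotationSet(sizes=sizes, overlaps=dict(overlaps), total_m=400)
        zo = zero_order(tau_set, ann)
        expected = tau_set.taus[b] + 0.25 * tau_set.taus[a]
        assert np.allclose(zo[b].zeta, expected, atol=1e-14)

    def test_whole_genome_target_sums_all_taus(self):
        tau_set = _random_tau_set(seed=8)
        names = tau_set.annotation_names
        sizes = {c: 100 for c in names}
        sizes["genome"] = 400
        overlaps = {(c, t): (100 if c == t else 0) for c in names for t in names}
        for c in names:
            overlaps[(c, "genome")] = 100
        overlaps[("genome", "genome")] = 400
        ann = AnnotationSet(sizes=sizes, overlaps=dict(overlaps), total_m=400,
                            genome_annotation="genome")
        zo = zero_order(tau_set, ann, targets=["genome"])
        total = sum(tau_set.taus[c] for c in names)
        assert np.allclose(zo["genome"].zeta, total, atol=1e-14)

    def test_missing_overlap_errors(self):
        tau_set = _random_tau_set(n_ann=2, seed=9)
        a, b = tau_set.annotation_names
        ann = AnnotationSet(sizes={a: 100, b: 100},
                            overlaps={(a, a): 100, (b, b): 100}, total_m=200)
        with pytest.raises(KeyError, match="overlap"):
            zero_order(tau_set, ann)

    def test_partition_sums_to_total(self, annotated_study):
        zo = zero_order(annotated_study["taus"], annotated_study["study"].annotations,
                        targets=["hot", "cold"])
        total = zo["hot"].zeta + zo["cold"].zeta
        pair = annotated_study["pair"]
        se = pair.se_matrix()
        assert np.all(np.abs(total - pair.S) <= 4 * np.maximum(se, 1e-3))


class TestScreen:
    def _zo(self, zeta, se_scale):
        p = zeta.shape[0] * (zeta.shape[0] + 1) // 2
        return ZeroOrderCovariance(annotation="x", zeta=zeta, V=np.eye(p) * se_scale ** 2)

    def test_pd_matrix_unchanged_and_retained(self):
        zeta = np.array([[0.3, 0.1], [0.1, 0.3]])
        out = screen_and_smooth({"x": self._zo(zeta, 0.05)})["x"]
        assert out.retained
        assert out.max_z_discrepancy == 0.0
        assert np.allclose(out.zeta, zeta)

    def test_small_negative_eigenvalue_smoothed_and_kept(self):
        zeta = np.array([[0.1, 0.101], [0.101, 0.1]])  # min eig ~ -0.001
        out = screen_and_smooth({"x": self._zo(zeta, 0.05)})["x"]
        assert out.retained
        assert 0 < out.max_z_discrepancy <= 1.96
        assert np.linalg.eigvalsh(out.zeta).min() >= -1e-12

    def test_large_discrepancy_excluded(self):
        zeta = np.array([[0.1, 0.5], [0.5, 0.1]])  # strongly indefinite
        out = screen_and_smooth({"x": self._zo(zeta, 0.01)})["x"]
        assert not out.retained
        assert out.max_z_discrepancy > 1.96


class TestEnrichment:
    def test_planted_enrichment_recovered(self, annotated_study):
        pair = annotated_study["pair"]
        zo = zero_order(annotated_study["taus"], annotated_study["study"].annotations,
                        targets=["hot", "cold", "base"])
        screened = screen_and_smooth(zo)
        assignment = {n: ("F1" if i < 3 else "F2") for i, n in enumerate(pair.names)}
        gw = fit(pd.DataFrame(pair.S, index=pair.names, columns=pair.names),
                 pair.V, build_model(assignment, "correlated"))
        table = factor_enrichment(gw, screened, annotated_study["study"].annotations)
        hot = table[table.annotation == "hot"]
        assert np.all(np.abs(hot.enrichment - 2.0) <= 2 * hot.se)
        base = table[table.annotation == "base"]
        assert np.all(base.enrichment == 1.0)  # definitional for the whole genome

    def test_bonferroni_thresholds(self):
        assert bonferroni_threshold(152, 6) == pytest.approx(0.05 / 912)
        assert bonferroni_threshold(374, 1) == pytest.approx(0.05 / 374)
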