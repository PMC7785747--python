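"""IVW pooling, genomic control, 2-df dimorphic test, Cochran's Q, I-squared."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from sexdimorph.meta_core import (
    CHI2_1DF_MEDIAN,
    Estimate,
    GCReport,
    MetaConfig,
    apply_gc,
    cochran_q,
    genomic_control,
    i_squared,
    ivw_meta,
    meta_pipeline,
    sex_dimorphic_test,
)
from sexdimorph.synthetic_data import CohortSpec, generate_study_sumstats

est = st.builds(
    Estimate,
    beta=st.floats(-1, 1, allow_nan=False),
    se=st.floats(1e-3, 1.0),
)


class TestIVW:
    def test_single_study_identity(self):
        out = ivw_meta([Estimate(0.1, 0.05)])
        assert out.beta == pytest.approx(0.1, rel=1e-15)
        assert out.se == pytest.approx(0.05, rel=1e-15)

    def test_equal_weight_symmetry(self):
        out = ivw_meta([Estimate(0.2, 0.1), Estimate(0.0, 0.1)])
        assert out.beta == pytest.approx(0.1)
        assert out.se == pytest.approx(0.1 / np.sqrt(2))

    def test_hand_computed_weighted_mean(self):
        out = ivw_meta([Estimate(0.3, 0.1), Estimate(0.1, 0.2)])
        assert out.beta == pytest.approx(0.26)
        assert out.se == pytest.approx(1 / np.sqrt(125))

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            ivw_meta([])

    @given(ests=st.lists(est, min_size=1, max_size=6))
    @settings(max_examples=50, deadline=None)
    def test_pooled_se_never_exceeds_best_input(self, ests):
        out = ivw_meta(ests)
        assert out.se <= min(e.se for e in ests) + 1e-12


class TestCochranQ:
    def test_znf12_table_row(self):
        """Q and its p from the printed sex-specific estimates at rs7798471."""
        het = cochran_q([Estimate(0.0262, 0.0046), Estimate(0.0067, 0.0051)])
        assert het.q == pytest.approx(8.06, abs=0.01)
        assert 4.4e-3 < het.p < 4.7e-3

    def test_identical_estimates_homogeneous(self):
        het = cochran_q([Estimate(0.1, 0.05), Estimate(0.1, 0.05)])
        assert het.q == pytest.approx(0.0, abs=1e-20)
        assert het.p == pytest.approx(1.0)
        assert het.i2 == 0.0

    def test_two_group_closed_form(self):
        het = cochran_q([Estimate(0.1, 0.05), Estimate(0.0, 0.05)])
        assert het.q == pytest.approx(2.0)
        assert het.p == pytest.approx(stats.chi2.sf(2.0, 1), rel=1e-12)

    def test_requires_two(self):
        with pytest.raises(ValueError):
            cochran_q([Estimate(0.1, 0.05)])

    @given(ests=st.lists(est, min_size=2, max_size=5), scale=st.floats(0.1, 10))
    @settings(max_examples=50, deadline=None)
    def test_q_and_i2_scale_invariant(self, ests, scale):
        """Rescaling all betas and SEs by a common factor leaves Q and I2 fixed."""
        het = cochran_q(ests)
        scaled = cochran_q([Estimate(e.beta * scale, e.se * scale) for e in ests])
        assert scaled.q == pytest.approx(het.q, rel=1e-9, abs=1e-12)
        assert scaled.i2 == pytest.approx(het.i2, rel=1e-9, abs=1e-9)


class TestDimorphicTest:
    def test_znf12_inputs(self):
        res = sex_dimorphic_test(Estimate(0.0262, 0.0046), Estimate(0.0067, 0.0051))
        assert 33 < res.t2 < 35
        assert 3e-8 < res.p < 6e-8

    def test_null_inputs(self):
        res = sex_dimorphic_test(Estimate(0.0, 1.0), Estimate(0.0, 1.0))
        assert res.t2 == 0.0 and res.p == 1.0

    def test_two_df_closed_form(self):
        res = sex_dimorphic_test(Estimate(2.0, 1.0), Estimate(2.0, 1.0))
        assert res.t2 == pytest.approx(8.0)
        assert res.p == pytest.approx(np.exp(-4.0), rel=1e-12)

    @given(f=est, m=est)
    @settings(max_examples=100, deadline=None)
    def test_p_matches_generic_chi2_survival(self, f, m):
        res = sex_dimorphic_test(f, m)
        assert res.p == pytest.approx(
            max(float(stats.chi2.sf(res.t2, 2)), 1e-300), rel=1e-12
        )

    @given(f=est, m=est)
    @settings(max_examples=100, deadline=None)
    def test_decomposition_identity(self, f, m):
        """z_f^2 + z_m^2 = z_pooled^2 + Q, exactly, for any two estimates."""
        pooled = ivw_meta([f, m])
        q = cochran_q([f, m]).q
        lhs = f.z**2 + m.z**2
        assert lhs == pytest.approx(pooled.z**2 + q, abs=1e-10 * max(1.0, lhs))


class TestISquared:
    @pytest.mark.parametrize(
        "p_q, expected",
        [(0.015, 83), (0.051, 74), (0.069, 70), (0.0099, 85)],
    )
    def test_inverts_genetic_correlation_heterogeneity(self, p_q, expected):
        """Q recovered from the printed 1-df p reproduces the printed I2."""
        q = stats.chi2.isf(p_q, 1)
        assert round(i_squared(q, 1)) == expected

    def test_q_equals_df_gives_zero(self):
        assert i_squared(1.0, 1) == 0.0

    def test_hand_formula(self):
        assert i_squared(4.0, 1) == pytest.approx(75.0)

    def test_floor_at_zero(self):
        assert i_squared(0.5, 1) == 0.0
        assert i_squared(0.0, 1) == 0.0


class TestGenomicControl:
    def test_null_calibration(self):
        rep = genomic_control(np.array([CHI2_1DF_MEDIAN]))
        assert rep.lam == pytest.approx(1.0)

    def test_median_rule_by_hand(self):
        rep = genomic_control(np.array([0.5, 1.0, 2.0]))
        assert rep.lam == pytest.approx(1.0 / CHI2_1DF_MEDIAN)

    def test_no_deflation(self):
        rep = GCReport(lam=0.95, n_variants_used=100)
        ses = np.array([0.1, 0.2])
        np.testing.assert_array_equal(apply_gc(ses, rep), ses)

    def test_inflation_applied_as_sqrt_lambda(self):
        rep = GCReport(lam=1.21, n_variants_used=100)
        np.testing.assert_allclose(apply_gc(np.array([0.1]), rep), [0.11])

    def test_subset_rule_restricts_median(self):
        x = np.concatenate([np.full(50, 10.0), np.full(50, CHI2_1DF_MEDIAN)])
        subset = np.arange(100) >= 50
        rep = genomic_control(x, subset, subset_rule="qt_interval_subset")
        assert rep.lam == pytest.approx(1.0)
        assert rep.n_variants_used == 50

    def test_z_statistic_input(self):
        z = np.array([1.0, -1.0, 0.5])
        assert genomic_control(z, statistic="z").lam == pytest.approx(
            1.0 / CHI2_1DF_MEDIAN
        )


class TestMetaPipeline:
    def test_single_study_per_sex_identity(self):
        spec = CohortSpec(seed=11, n_variants=50, n_studies=1, n_f=5000, n_m=5000)
        panels, _ = generate_study_sumstats(spec)
        res = meta_pipeline(
            panels["female"] + panels["male"], MetaConfig(study_gc=False, meta_gc=False)
        )
        src = panels["female"][0].records.set_index("marker_id")
        merged = res.set_index("MARKER")
        np.testing.assert_allclose(
            merged["BETA_F"].loc[src.index], src["beta"], rtol=1e-12
        )
        np.testing.assert_allclose(merged["SE_F"].loc[src.index], src["se"], rtol=1e-12)
        # decomposition identity on the output table
        zf2 = (merged["BETA_F"] / merged["SE_F"]) ** 2
        zm2 = (merged["BETA_M"] / merged["SE_M"]) ** 2
        np.testing.assert_allclose(merged["CHI2_2DF"], zf2 + zm2, rtol=1e-12)

    def test_known_effect_recovered_from_six_studies(self):
        spec = CohortSpec(
            seed=12, n_variants=40, n_studies=6, n_f=70_000, n_m=70_000,
            fraction_causal=1.0, beta_f_sd=0.03, beta_m_sd=0.03,
        )
        panels, truth = generate_study_sumstats(spec)
        res = meta_pipeline(panels["female"] + panels["male"]).set_index("MARKER")
        t = truth.set_index("marker_id")
        within = (
            (res["BETA_F"] - t["beta_f"]).abs() <= 2 * res["SE_F"]
        )
        assert within.mean() > 0.85  # ~95% nominal

    def test_injected_inflation_corrected(self):
        spec = CohortSpec(
            seed=13, n_variants=10_000, n_studies=3, n_f=30_000, n_m=30_000, gc_lambda=1.2
        )
        panels, _ = generate_study_sumstats(spec)
        res = meta_pipeline(panels["female"] + panels["male"])
        for col in ("F", "M"):
            chi2 = (res[f"BETA_{col}"] / res[f"SE_{col}"]) ** 2
            lam = genomic_control(chi2.to_numpy()).lam
            assert 0.97 <= lam <= 1.03

    def test_variant_missing_in_one_sex_still_combined(self):
        spec = CohortSpec(seed=14, n_variants=10, n_studies=1, n_f=5000, n_m=5000)
        panels, _ = generate_study_sumstats(spec)
        male = panels["male"][0]
        male.records = male.records.iloc[:-1]  # drop last variant from men
        res = meta_pipeline(
            panels["female"] + [male], MetaConfig(study_gc=False, meta_gc=False)
        ).set_index("MARKER")
        lone = res.iloc[-1]
        assert np.isfinite(lone["BETA_ALL"])
        assert np.isnan(lone["P_DIMORPHIC"]) and np.isnan(lone["Q"])
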