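"""Wald ratios, random-effect IVW, MR-Egger, instrument selection."""

import numpy as np
import pandas as pd
import pytest

from sexdimorph.mr_causal import (
    BONFERRONI_4TESTS,
    egger,
    harmonize_instruments,
    ivw,
    ratio_estimate,
    select_instruments,
)
from sexdimorph.synthetic_data import generate_mr_system


def _table(bx, by, se_out=0.01, se_exp=0.001):
    k = len(bx)
    return pd.DataFrame(
        {
            "MARKER": [f"iv{i}" for i in range(k)],
            "EA": "A", "NEA": "G",
            "BETA_EXP": bx, "SE_EXP": se_exp,
            "BETA_OUT": by, "SE_OUT": se_out,
            "EAF": 0.3,
        }
    )


class TestRatioEstimate:
    def test_delta_method_by_hand(self):
        inst = {"BETA_EXP": 0.2, "SE_EXP": 0.01, "BETA_OUT": 0.04, "SE_OUT": 0.01}
        est = ratio_estimate(inst)
        assert est.beta == pytest.approx(0.2)
        assert est.se == pytest.approx(0.05)

    def test_zero_outcome(self):
        inst = {"BETA_EXP": 0.2, "SE_EXP": 0.01, "BETA_OUT": 0.0, "SE_OUT": 0.01}
        est = ratio_estimate(inst)
        assert est.beta == 0.0
        assert est.se == pytest.approx(0.05)

    def test_sign_flip_invariant(self):
        a = ratio_estimate({"BETA_EXP": 0.2, "SE_EXP": 0.01, "BETA_OUT": 0.04, "SE_OUT": 0.01})
        b = ratio_estimate({"BETA_EXP": -0.2, "SE_EXP": 0.01, "BETA_OUT": -0.04, "SE_OUT": 0.01})
        assert a.beta == b.beta and a.se == b.se

    def test_zero_exposure_errors(self):
        with pytest.raises(ValueError):
            ratio_estimate({"BETA_EXP": 0.0, "SE_EXP": 0.01, "BETA_OUT": 0.1, "SE_OUT": 0.01})

    def test_second_order_term_enlarges_se(self):
        inst = {"BETA_EXP": 0.2, "SE_EXP": 0.05, "BETA_OUT": 0.04, "SE_OUT": 0.01}
        assert ratio_estimate(inst, second_order=True).se > ratio_estimate(inst).se


class TestIVW:
    def test_exact_line_through_origin(self):
        res = ivw(_table([0.1, 0.2, 0.3], [0.02, 0.04, 0.06]))
        assert res.beta_iv == pytest.approx(0.2)
        assert res.q_ivw == pytest.approx(0.0, abs=1e-20)

    def test_fixed_equals_random_when_homogeneous(self):
        res = ivw(_table([0.1, 0.2, 0.3], [0.02, 0.04, 0.06]))
        w = 1 / 0.01**2
        se_fixed = 1 / np.sqrt(w * (0.01 + 0.04 + 0.09))
        assert res.se_iv == pytest.approx(se_fixed)

    def test_slope_invariant_to_common_se_scaling(self):
        a = ivw(_table([0.1, 0.2, 0.3], [0.01, 0.05, 0.05], se_out=0.01))
        b = ivw(_table([0.1, 0.2, 0.3], [0.01, 0.05, 0.05], se_out=0.03))
        assert a.beta_iv == pytest.approx(b.beta_iv)

    def test_requires_two_instruments(self):
        with pytest.raises(ValueError):
            ivw(_table([0.1], [0.02]))

    def test_parameter_recovery_over_seeds(self):
        hits = 0
        for seed in range(200):
            tab, truth = generate_mr_system(50, 1.0, seed=seed)
            res = ivw(tab)
            hits += abs(res.beta_iv - truth["true_slope"]) <= 2 * res.se_iv
        assert hits / 200 >= 0.90


class TestEgger:
    def test_exact_affine_data(self):
        bx = np.array([0.1, 0.2, 0.3, 0.4])
        res = egger(_table(bx, 0.05 + 0.2 * bx))
        assert res.intercept == pytest.approx(0.05)
        assert res.beta_iv == pytest.approx(0.2)

    def test_orientation_invariance(self):
        """Flipping the allele coding of some instruments changes nothing."""
        bx = np.array([0.1, 0.2, 0.3, 0.4])
        by = 0.05 + 0.2 * bx + np.array([0.001, -0.002, 0.0005, -0.001])
        a = egger(_table(bx, by))
        bx2, by2 = bx.copy(), by.copy()
        bx2[::2] *= -1
        by2[::2] *= -1
        b = egger(_table(bx2, by2))
        assert a.beta_iv == pytest.approx(b.beta_iv)
        assert a.intercept == pytest.approx(b.intercept)

    def test_zero_intercept_constraint_reproduces_ivw(self):
        """Egger through the origin is algebraically the IVW slope."""
        rng = np.random.default_rng(8)
        bx = rng.uniform(0.05, 0.3, 30)
        by = 1.5 * bx + rng.normal(0, 0.01, 30)
        tab = _table(bx, by)
        w = 1.0 / tab["SE_OUT"].to_numpy() ** 2
        slope0 = float(w @ (bx * by)) / float(w @ bx**2)
        assert ivw(tab).beta_iv == pytest.approx(slope0)

    def test_requires_three_instruments(self):
        with pytest.raises(ValueError):
            egger(_table([0.1, 0.2], [0.02, 0.04]))

    def test_null_intercept_calibration(self):
        hits = 0
        for seed in range(100):
            tab, _ = generate_mr_system(50, 1.0, seed=seed)
            res = egger(tab)
            hits += abs(res.intercept) <= 2 * res.se_intercept
        assert hits / 100 >= 0.90

    def test_planted_pleiotropy_recovered(self):
        """Directional pleiotropy lands in the intercept, slope stays unbiased."""
        ints, slopes = [], []
        for seed in range(50):
            tab, _ = generate_mr_system(222, 1.86, pleiotropy_mean=-0.002, seed=seed)
            res = egger(tab)
            ints.append(res.intercept)
            slopes.append(res.beta_iv)
        assert np.median(ints) == pytest.approx(-0.002, abs=0.001)
        assert abs(np.median(slopes) - 1.86) < 0.05 * 1.86

    def test_median_bias_across_slope_pleiotropy_grid(self):
        for slope in (0.0, 0.5, 1.86):
            for pleio in (0.0, 0.002, -0.002):
                ests = []
                for seed in range(30):
                    tab, _ = generate_mr_system(
                        200, slope, pleiotropy_mean=pleio, seed=1000 + seed
                    )
                    ests.append(egger(tab).beta_iv)
                bias = np.median(ests) - slope
                assert abs(bias) < max(0.05 * abs(slope), 0.02), (slope, pleio)


class TestInstrumentSelection:
    GWAS = pd.DataFrame(
        {
            "MARKER": ["rs1", "rs2", "rs3"],
            "CHR": [1, 1, 2],
            "POS": [1_000_000, 5_000_000, 1_000_000],
            "P": [1e-10, 1e-9, 1e-12],
        }
    )

    def test_independent_snps_all_retained(self):
        ld = pd.DataFrame(columns=["MARKER1", "MARKER2", "R2"])
        out = select_instruments(self.GWAS, ld=ld)
        assert len(out) == 3

    def test_pruning_keeps_lowest_p(self):
        gwas = pd.DataFrame(
            {"MARKER": ["rsA", "rsB"], "CHR": [1, 1], "POS": [1, 2], "P": [1e-10, 1e-9]}
        )
        ld = pd.DataFrame({"MARKER1": ["rsA"], "MARKER2": ["rsB"], "R2": [0.5]})
        out = select_instruments(gwas, ld=ld)
        assert list(out["MARKER"]) == ["rsA"]

    def test_planted_ld_blocks_yield_one_instrument_each(self):
        rng = np.random.default_rng(33)
        rows, ld_rows = [], []
        for block in range(10):
            members = [f"b{block}_s{j}" for j in range(5)]
            for j, m in enumerate(members):
                rows.append(
                    {"MARKER": m, "CHR": 1 + block % 5, "POS": block * 10**7 + j,
                     "P": float(10.0 ** -rng.uniform(9, 15))}
                )
            for a in members:
                for b in members:
                    if a < b:
                        ld_rows.append({"MARKER1": a, "MARKER2": b, "R2": 0.9})
        out = select_instruments(pd.DataFrame(rows), ld=pd.DataFrame(ld_rows))
        assert len(out) == 10

    def test_empty_selection_advises(self):
        with pytest.raises(ValueError, match="relax"):
            select_instruments(self.GWAS, p_threshold=1e-20, ld=pd.DataFrame(columns=["MARKER1", "MARKER2", "R2"]))

    def test_distance_fallback_flagged(self):
        out = select_instruments(self.GWAS)
        assert out.attrs["pruning"] == "distance"
        assert len(out) == 3


def _two_trait_system(seed, slope_women, slope_men, k=30):
    """GWAS tables per sex for traits A and B; A -> B causal with per-sex slope.

    Trait A has k genome-wide-significant instruments with no effect on it
    from B's instruments (so the reverse direction is null by design).
    """
    rng = np.random.default_rng(seed)
    slopes = {"female": slope_women, "male": slope_men}
    bx = rng.uniform(0.05, 0.2, k) * rng.choice([-1, 1], k)
    bz = rng.uniform(0.05, 0.2, k) * rng.choice([-1, 1], k)
    gwas_a, gwas_b = {}, {}
    for sex in ("female", "male"):
        noise_b = rng.normal(0, 0.01, k)
        noise_a = rng.normal(0, 0.005, k)
        a_rows = pd.DataFrame(
            {
                "MARKER": [f"a{i}" for i in range(k)] + [f"b{i}" for i in range(k)],
                "EA": "A", "NEA": "G", "EAF": 0.3,
                "CHR": list(range(1, k + 1)) * 2,
                "POS": [10**7 * (i + 1) for i in range(k)] + [2 * 10**9 + i for i in range(k)],
                "BETA": np.concatenate([bx, noise_a]),
                "SE": 0.005,
                "P": [1e-12] * k + [0.5] * k,
            }
        )
        b_rows = a_rows.copy()
        b_rows["BETA"] = np.concatenate([slopes[sex] * bx + noise_b, bz])
        b_rows["SE"] = 0.01
        b_rows["P"] = [0.5] * k + [1e-12] * k
        gwas_a[sex], gwas_b[sex] = a_rows, b_rows
    return gwas_a, gwas_b


class TestBidirectional:
    def test_planted_causal_direction_in_women_only(self):
        """A -> B causal in women only: exactly the forward-women IVW cell is
        significant at the four-test Bonferroni level in >= 90% of seeds."""
        from sexdimorph.mr_causal import bidirectional

        good = 0
        n_seeds = 20
        for seed in range(n_seeds):
            ga, gb = _two_trait_system(seed, slope_women=0.5, slope_men=0.0)
            res = bidirectional(ga, gb, label_a="A", label_b="B")
            iv = res[res["METHOD"] == "ivw_random"].set_index(["EXPOSURE", "SEX"])
            ok = (
                iv.loc[("A", "female"), "SIGNIFICANT"]
                and not iv.loc[("A", "male"), "SIGNIFICANT"]
                and not iv.loc[("B", "female"), "SIGNIFICANT"]
                and not iv.loc[("B", "male"), "SIGNIFICANT"]
            )
            good += ok
        assert good / n_seeds >= 0.9

    def test_swapping_trait_labels_transposes_table(self):
        from sexdimorph.mr_causal import bidirectional

        ga, gb = _two_trait_system(3, slope_women=0.5, slope_men=0.2)
        ab = bidirectional(ga, gb, label_a="A", label_b="B")
        ba = bidirectional(gb, ga, label_a="B", label_b="A")
        key = ["EXPOSURE", "OUTCOME", "SEX", "METHOD"]
        merged = ab.set_index(key)[["BETA_IV"]].join(
            ba.set_index(key)[["BETA_IV"]], rsuffix="_swapped", how="inner"
        )
        assert len(merged) == len(ab)
        np.testing.assert_allclose(merged["BETA_IV"], merged["BETA_IV_swapped"])


class TestHarmonizeInstruments:
    def test_swapped_outcome_alleles_negated(self):
        exposure = pd.DataFrame(
            {"MARKER": ["rs1"], "EA": ["A"], "NEA": ["G"], "BETA": [0.1],
             "SE": [0.01], "EAF": [0.3]}
        )
        outcome = pd.DataFrame(
            {"MARKER": ["rs1"], "EA": ["G"], "NEA": ["A"], "BETA": [0.05],
             "SE": [0.02], "EAF": [0.7]}
        )
        inst = harmonize_instruments(exposure, outcome)
        assert inst["BETA_OUT"].iloc[0] == pytest.approx(-0.05)

    def test_bonferroni_threshold_value(self):
        assert BONFERRONI_4TESTS == pytest.approx(0.0125)
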