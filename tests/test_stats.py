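"""Correlations, rank tests, the type-II GLM and condition contrasts."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from envlrtc.hmatrix import HMatrix
from envlrtc.stats import (
    bootstrap_rho_ci,
    condition_contrast,
    glm_type2,
    ranksum_test,
    spearman_rho,
    spearman_test,
    within_vs_across_correlation,
)


def _cohort(n_id=10, n_ctrl=10, seed=0):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        {
            "id": [f"S{i}" for i in range(n_id + n_ctrl)],
            "group": ["ID"] * n_id + ["CTRL"] * n_ctrl,
            "isi": np.concatenate(
                [rng.integers(8, 29, n_id), rng.integers(0, 8, n_ctrl)]
            ),
        }
    )


class TestSpearman:
    def test_monotone_relation_is_perfect(self):
        x = np.array([1.0, 2.0, 5.0, 7.0, 11.0])
        assert spearman_rho(x, np.exp(x)) == pytest.approx(1.0)
        assert spearman_rho(x, -np.exp(x)) == pytest.approx(-1.0)

    def test_hand_computed_example(self):
        # y = (2,3,1,4,5): d = (-1,-1,2,0,0), sum d^2 = 6,
        # rho = 1 - 6*6/(5*24) = 0.7
        assert spearman_rho([1, 2, 3, 4, 5], [2, 3, 1, 4, 5]) == pytest.approx(0.7)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            spearman_rho([1, 1, 1, 1], [1, 2, 3, 4])

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        seed=st.integers(0, 10_000),
        scale=st.floats(0.1, 10.0),
        offset=st.floats(-5.0, 5.0),
    )
    def test_invariance_under_monotone_transform(self, seed, scale, offset):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=12)
        y = rng.normal(size=12)
        rho = spearman_rho(x, y)
        assert spearman_rho(np.exp(scale * x + offset), y) == pytest.approx(rho)

    @pytest.mark.parametrize(
        "rho,n,expected",
        [(0.521, 52, 4.317), (0.547, 43, 4.181)],
    )
    def test_rho_to_t_reference_values(self, rho, n, expected):
        x = np.arange(n, dtype=float)
        res = spearman_test(x, x)
        assert res.df == n - 2
        from envlrtc.stats import rho_to_t

        assert rho_to_t(rho, n) == pytest.approx(expected, abs=0.005)

    def test_zero_rho_gives_unit_p(self):
        # y = (2,4,1,3): d = (-1,-2,2,1), sum d^2 = 10 = n(n^2-1)/6 -> rho = 0
        res = spearman_test([1, 2, 3, 4], [2, 4, 1, 3])
        assert res.rho == pytest.approx(0.0, abs=1e-12)
        assert res.t == 0.0
        assert res.p == pytest.approx(1.0)

    def test_perfect_relation_flagged(self):
        res = spearman_test([1, 2, 3, 4, 5], [1, 2, 3, 4, 5])
        assert np.isinf(res.t)
        assert res.p == 0.0


class TestBootstrap:
    def test_perfect_correlation_degenerate_ci(self):
        x = np.arange(10.0)
        res = bootstrap_rho_ci(x, 2 * x + 1, n_boot=100, seed=1)
        assert res.ci_low == pytest.approx(1.0)
        assert res.ci_high == pytest.approx(1.0)
        assert res.robust

    def test_seeded_reproducibility(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=30), rng.normal(size=30)
        a = bootstrap_rho_ci(x, y, n_boot=200, seed=7)
        b = bootstrap_rho_ci(x, y, n_boot=200, seed=7)
        assert (a.ci_low, a.ci_high) == (b.ci_low, b.ci_high)

    def test_ci_contains_point_estimate(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=40)
        y = 0.5 * x + rng.normal(size=40)
        res = bootstrap_rho_ci(x, y, n_boot=300, seed=2)
        assert res.ci_low <= res.rho <= res.ci_high

    def test_coverage_near_nominal(self):
        """95% percentile CI covers the population rho in ~95% of cohorts."""
        rho_true = 0.5
        cov = np.array([[1.0, rho_true], [rho_true, 1.0]])
        chol = np.linalg.cholesky(cov)
        rng = np.random.default_rng(11)
        # population Spearman rho of a bivariate normal
        rho_s = 6 / np.pi * np.arcsin(rho_true / 2)
        hits = 0
        n_rep = 200
        for rep in range(n_rep):
            xy = rng.standard_normal((50, 2)) @ chol.T
            res = bootstrap_rho_ci(xy[:, 0], xy[:, 1], n_boot=400, seed=rep)
            hits += res.ci_low <= rho_s <= res.ci_high
        assert 0.90 <= hits / n_rep <= 1.0


class TestRanksum:
    def test_identical_samples_null(self):
        a = np.arange(10.0)
        z, p = ranksum_test(a, a)
        assert abs(z) < 1e-12
        assert p == pytest.approx(1.0)

    def test_large_shift_detected(self):
        rng = np.random.default_rng(5)
        a = rng.normal(size=30)
        z, p = ranksum_test(a, a + 10.0)
        assert abs(z) > 5
        assert p < 1e-3

    def test_all_tied_degenerate(self):
        z, p = ranksum_test(np.ones(5), np.ones(7))
        assert (z, p) == (0.0, 1.0)

    def test_type_one_error_rate(self):
        rng = np.random.default_rng(17)
        rejections = 0
        n_rep = 1000
        for _ in range(n_rep):
            _, p = ranksum_test(rng.normal(size=50), rng.normal(size=50))
            rejections += p < 0.05
        assert 0.03 <= rejections / n_rep <= 0.07


class TestGlmType2:
    def test_balanced_orthogonal_equals_sequential(self):
        # balanced groups with identical centred ISI patterns: the design is
        # orthogonal, so type-II F must match sequential (type-I) F
        import statsmodels.api as sm
        import statsmodels.formula.api as smf

        isi_pattern = np.array([-2, -1, 0, 1, 2] * 2, dtype=float)
        cohort = pd.DataFrame(
            {
                "id": [f"S{i}" for i in range(20)],
                "group": ["ID"] * 10 + ["CTRL"] * 10,
                "isi": np.concatenate([isi_pattern, isi_pattern]),
            }
        )
        rng = np.random.default_rng(2)
        y = rng.normal(size=20)
        table2 = glm_type2(y, cohort)
        data = cohort.copy()
        data["_y"] = y
        table1 = sm.stats.anova_lm(smf.ols("_y ~ C(group) * isi", data=data).fit(), typ=1)
        for term, label in [("C(group)", "group"), ("isi", "isi")]:
            assert table2.loc[label, "F"] == pytest.approx(table1.loc[term, "F"])

    def test_power_at_planted_isi_slope(self):
        hits = 0
        n_rep = 100
        for rep in range(n_rep):
            rng = np.random.default_rng(1000 + rep)
            cohort = _cohort(52, 43, seed=rep)
            y = 0.7 + 0.004 * cohort["isi"].to_numpy() + rng.normal(0, 0.03, 95)
            table = glm_type2(y, cohort)
            hits += table.loc["isi", "p"] < 0.05
        assert hits >= 80

    def test_type_one_error_rate(self):
        rejections = np.zeros(3)
        n_rep = 500
        for rep in range(n_rep):
            rng = np.random.default_rng(5000 + rep)
            cohort = _cohort(25, 25, seed=rep)
            table = glm_type2(rng.normal(size=50), cohort)
            rejections += (table["p"] < 0.05).to_numpy()
        rates = rejections / n_rep
        assert np.all(rates > 0.03) and np.all(rates < 0.07)

    def test_degrees_of_freedom(self):
        cohort = _cohort(52, 43)
        table = glm_type2(np.random.default_rng(0).normal(size=95), cohort)
        assert (table["df_den"] == 91).all()  # 95 - 4 model parameters

    def test_rank_deficient_rejected(self):
        cohort = _cohort(5, 5)
        cohort["isi"] = 3  # constant: interaction collinear
        with pytest.raises(ValueError):
            glm_type2(np.random.default_rng(0).normal(size=10), cohort)


def _hm_from(h, condition="EO"):
    h = np.asarray(h, dtype=float)
    return HMatrix(
        h,
        [f"p{i}" for i in range(h.shape[0])],
        [f"e{i}" for i in range(h.shape[1])],
        [f"b{i}" for i in range(h.shape[2])],
        condition,
    )


class TestConditionContrast:
    def test_identical_conditions_null(self):
        h = 0.6 + 0.3 * np.random.default_rng(0).random((12, 5, 2))
        table = condition_contrast(_hm_from(h), _hm_from(h, "EC"))
        assert np.allclose(table["median_diff"], 0.0)
        assert (table["p_median"] == 1.0).all()

    def test_planted_offset_detected(self):
        rng = np.random.default_rng(1)
        h_ec = 0.6 + 0.05 * rng.random((20, 6, 2))
        h_eo = h_ec + 0.03 + 0.005 * rng.random((20, 6, 2))
        table = condition_contrast(_hm_from(h_eo), _hm_from(h_ec, "EC"))
        assert (table["median_diff"] > 0).all()
        assert (table["p_median"] < 0.01).all()

    def test_consistent_participant_shuffle_invariant(self):
        rng = np.random.default_rng(2)
        h_eo = 0.6 + 0.2 * rng.random((10, 4, 2))
        h_ec = 0.6 + 0.2 * rng.random((10, 4, 2))
        base = condition_contrast(_hm_from(h_eo), _hm_from(h_ec, "EC"))
        perm = rng.permutation(10)
        ids = [f"p{i}" for i in perm]
        shuffled = condition_contrast(
            HMatrix(h_eo[perm], ids, ["e0", "e1", "e2", "e3"], ["b0", "b1"], "EO"),
            HMatrix(h_ec[perm], ids, ["e0", "e1", "e2", "e3"], ["b0", "b1"], "EC"),
        )
        pd.testing.assert_frame_equal(base, shuffled)

    def test_participant_mismatch_rejected(self):
        h = np.full((3, 2, 1), 0.7)
        a = _hm_from(h)
        b = HMatrix(h, ["x0", "x1", "x2"], ["e0", "e1"], ["b0"], "EC")
        with pytest.raises(ValueError):
            condition_contrast(a, b)


class TestWithinVsAcross:
    def test_group_specific_slopes_strengthen_within(self):
        rng = np.random.default_rng(4)
        cohort = _cohort(40, 40, seed=4)
        isi = cohort["isi"].to_numpy(dtype=float)
        is_id = (cohort["group"] == "ID").to_numpy()
        # strong within-group slopes with opposite group offsets weaken the
        # pooled association
        gm = np.where(is_id, -0.1, 0.1) + 0.01 * isi + rng.normal(0, 0.02, 80)
        out = within_vs_across_correlation(cohort, gm, n_boot=300, seed=1)
        assert out["rho_within_id"] > out["rho_pooled"]
        assert out["rho_within_ctrl"] > out["rho_pooled"]
        assert out["mean_within_minus_pooled"] > 0

    def test_common_slope_no_offset_similar(self):
        rng = np.random.default_rng(5)
        cohort = _cohort(40, 40, seed=5)
        gm = 0.01 * cohort["isi"].to_numpy() + rng.normal(0, 0.05, 80)
        out = within_vs_across_correlation(cohort, gm, n_boot=300, seed=2)
        assert abs(out["mean_within_minus_pooled"]) < 0.25

    def test_seeded_reproducibility(self):
        cohort = _cohort(10, 10, seed=6)
        gm = np.random.default_rng(6).normal(size=20)
        a = within_vs_across_correlation(cohort, gm, n_boot=100, seed=3)
        b = within_vs_across_correlation(cohort, gm, n_boot=100, seed=3)
        assert a["boot_diff_ci"] == b["boot_diff_ci"]
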