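"""Quantile normalization, fold-change filtering, ddCt, correlation, t-tests."""
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cerna_scan.expression import (
    ExpressionMatrix,
    bh_adjust,
    delta_delta_ct,
    fold_change_filter,
    paired_t_test,
    pearson_r,
    quantile_normalize,
)
from cerna_scan.simulate import SimConfig, generate_ct_table, generate_expression


def make_matrix(values: np.ndarray, n_normal: int, n_model: int) -> ExpressionMatrix:
    samples = [f"n{i}" for i in range(n_normal)] + [f"m{i}" for i in range(n_model)]
    groups = pd.Series(["normal"] * n_normal + ["model"] * n_model, index=samples)
    df = pd.DataFrame(values, index=[f"p{i}" for i in range(len(values))], columns=samples)
    return ExpressionMatrix(df, groups)


class TestQuantileNormalize:
    def test_identical_columns_are_a_fixed_point(self):
        x = np.array([[1.0, 1.0], [5.0, 5.0], [3.0, 3.0]])
        assert np.allclose(quantile_normalize(x), x)

    def test_worked_two_by_two_case(self):
        x = np.array([[1.0, 2.0], [3.0, 6.0]])
        expected = np.array([[1.5, 1.5], [4.5, 4.5]])
        assert np.allclose(quantile_normalize(x), expected)

    def test_all_column_distributions_equal_after_normalization(self, rng):
        x = rng.uniform(0, 1000, size=(50, 8))
        out = quantile_normalize(x)
        sorted_cols = np.sort(out, axis=0)
        for j in range(1, 8):
            assert np.array_equal(sorted_cols[:, 0], sorted_cols[:, j])

    def test_idempotent(self, rng):
        x = rng.uniform(0, 1000, size=(40, 5))
        once = quantile_normalize(x)
        assert np.allclose(quantile_normalize(once), once, atol=1e-12)

    def test_ties_get_the_mean_of_tied_quantiles(self):
        x = np.array([[2.0, 1.0], [2.0, 5.0], [7.0, 9.0]])
        out = quantile_normalize(x)
        # column 0 has a tie for the two lowest ranks: both get the mean of
        # the two lowest reference quantiles
        assert out[0, 0] == out[1, 0]

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            quantile_normalize(np.empty((0, 0)))


class TestFoldChangeFilter:
    def test_boundary_fold_of_exactly_two_passes(self):
        values = np.array([[100.0] * 4 + [200.0] * 4])
        res = fold_change_filter(make_matrix(values, 4, 4), 2.0)
        assert res[0].fold_change == pytest.approx(2.0)
        assert res[0].passes and res[0].direction == "up"

    def test_equal_means_do_not_pass(self):
        values = np.array([[100.0] * 8])
        res = fold_change_filter(make_matrix(values, 4, 4), 2.0)
        assert res[0].fold_change == pytest.approx(1.0)
        assert not res[0].passes

    def test_downregulation_passes_symmetrically(self):
        values = np.array([[200.0] * 4 + [100.0] * 4])
        res = fold_change_filter(make_matrix(values, 4, 4), 2.0)
        assert res[0].direction == "down" and res[0].passes

    def test_zero_normal_mean_is_an_error(self):
        values = np.array([[0.0] * 4 + [100.0] * 4])
        with pytest.raises(ValueError, match="zero normal-group mean"):
            fold_change_filter(make_matrix(values, 4, 4))

    def test_raising_threshold_never_adds_probes(self, rng):
        values = rng.uniform(50, 500, size=(40, 12))
        m = make_matrix(values, 6, 6)
        passing = [
            {r.probe_id for r in fold_change_filter(m, t) if r.passes}
            for t in (1.2, 1.5, 2.0, 3.0)
        ]
        for tighter, looser in zip(passing[1:], passing):
            assert tighter <= looser

    def test_planted_folds_recovered_exactly_at_low_noise(self):
        cfg = SimConfig(
            rng_seed=5,
            noise_sd=0.05,
            n_extra_probes=490,
            fold_change_plan={f"de_{i}": 2.5 for i in range(10)},
        )
        matrix, _ = generate_expression(cfg)
        res = fold_change_filter(matrix, 2.0)
        passing = {r.probe_id for r in res if r.passes}
        assert passing == {f"de_{i}" for i in range(10)}

    def test_bh_adjustment_is_monotone_and_bounded(self, rng):
        p = list(rng.uniform(0, 1, 20))
        q = bh_adjust(p)
        assert all(qi >= pi for qi, pi in zip(q, p))
        assert all(0 <= qi <= 1 for qi in q)


class TestDeltaDeltaCt:
    def test_closed_form_fold_four(self):
        table, _ = generate_ct_table(SimConfig(), 4.0, noise_sd=0.0)
        summary, per_sample = delta_delta_ct(table)
        assert summary["Delta_delta_ct"].iloc[0] == pytest.approx(-2.0)
        assert summary["Relative_quantity"].iloc[0] == pytest.approx(4.0)
        dct = per_sample.groupby("group")["delta_ct"].mean()
        assert dct["normal"] - dct["model"] == pytest.approx(2.0)

    def test_fold_one_means_equal_delta_ct(self):
        table, _ = generate_ct_table(SimConfig(), 1.0, noise_sd=0.0)
        summary, per_sample = delta_delta_ct(table)
        assert summary["Relative_quantity"].iloc[0] == pytest.approx(1.0)
        assert per_sample["delta_ct"].nunique() == 1

    def test_mirna_targets_use_u6_reference(self):
        table, truth = generate_ct_table(SimConfig(), 2.0, target_kind="miRNA")
        assert set(table["reference_name"]) == {"U6"}
        assert truth.payload["reference"] == "U6"

    def test_constant_ct_shift_leaves_quantity_unchanged(self):
        table, _ = generate_ct_table(SimConfig(), 3.0, noise_sd=0.0)
        shifted = table.copy()
        shifted["ct_target"] += 1.7
        shifted["ct_reference"] += 1.7
        q0 = delta_delta_ct(table)[0]["Relative_quantity"].iloc[0]
        q1 = delta_delta_ct(shifted)[0]["Relative_quantity"].iloc[0]
        assert q0 == pytest.approx(q1)

    def test_noisy_estimate_tracks_true_fold(self):
        # 6 replicates per group, realistic Ct noise: the estimate stays
        # within +/-25 % of the planted fold over repeated simulations
        errors = []
        for seed in range(500):
            cfg = SimConfig(rng_seed=seed, group_sizes=(6, 6), ct_noise_sd=0.2)
            table, _ = generate_ct_table(cfg, 4.0)
            q = delta_delta_ct(table)[0]["Relative_quantity"].iloc[0]
            errors.append(abs(q - 4.0) / 4.0)
        assert np.mean(errors) < 0.25
        assert np.quantile(errors, 0.95) < 0.5

    def test_missing_group_is_an_error(self):
        table, _ = generate_ct_table(SimConfig(), 2.0)
        with pytest.raises(ValueError, match="group"):
            delta_delta_ct(table[table["group"] == "model"])


class TestPearson:
    def test_perfect_positive_and_negative(self):
        x = np.arange(10.0)
        assert pearson_r(x, x)[0] == pytest.approx(1.0)
        assert pearson_r(x, -2 * x + 7)[0] == pytest.approx(-1.0)

    def test_zero_variance_is_an_error_not_nan(self):
        with pytest.raises(ValueError, match="variance"):
            pearson_r([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        st.floats(min_value=0.1, max_value=10),
        st.floats(min_value=-100, max_value=100),
    )
    def test_invariance_under_positive_affine_maps(self, a, b):
        rng = np.random.default_rng(7)
        x = rng.normal(size=15)
        y = rng.normal(size=15) + 0.5 * x
        r0, p0 = pearson_r(x, y)
        r1, p1 = pearson_r(a * x + b, y)
        assert r0 == pytest.approx(r1, abs=1e-9)
        assert p0 == pytest.approx(p1, abs=1e-9)

    def test_small_sample_mean_r_matches_monte_carlo_expectation(self):
        # At rho=0.9, n=20, the sample correlation is biased low; the
        # Monte-Carlo mean sits near 0.885
        rng = np.random.default_rng(11)
        rho = 0.9
        rs = []
        for _ in range(2000):
            z = rng.standard_normal(20)
            x = z + rng.standard_normal(20) * math.sqrt(1 / rho - 1)
            y = z + rng.standard_normal(20) * math.sqrt(1 / rho - 1)
            rs.append(pearson_r(x, y)[0])
        assert abs(np.mean(rs) - 0.885) <= 0.03


class TestPairedT:
    def test_identical_vectors_give_t_zero_p_one(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        assert paired_t_test(x, x) == (0.0, 1.0)

    def test_constant_nonzero_difference_gives_extreme_p(self):
        t, p = paired_t_test([2.0, 3.0, 4.0], [1.0, 2.0, 3.0])
        assert math.isinf(t) and t > 0
        assert 0 < p < 1e-300

    def test_hand_computed_four_pair_table(self):
        x = np.array([10.0, 12.0, 9.0, 11.0])
        y = np.array([8.0, 11.0, 10.0, 7.0])
        d = x - y
        expected_t = d.mean() / (d.std(ddof=1) / math.sqrt(4))
        t, _ = paired_t_test(x, y)
        assert t == pytest.approx(expected_t, abs=1e-10)

    def test_null_rejection_rate_is_calibrated(self):
        rng = np.random.default_rng(3)
        rejections = 0
        n_rep = 2000
        for _ in range(n_rep):
            x = rng.standard_normal(10)
            y = rng.standard_normal(10)
            if paired_t_test(x, y)[1] < 0.05:
                rejections += 1
        assert 0.035 <= rejections / n_rep <= 0.065


class TestExpressionMatrixValidation:
    def test_single_sample_group_rejected(self):
        values = np.array([[1.0, 2.0, 3.0]])
        samples = ["a", "b", "c"]
        df = pd.DataFrame(values, index=["p0"], columns=samples)
        groups = pd.Series(["normal", "normal", "model"], index=samples)
        with pytest.raises(ValueError, match=">=2 samples"):
            ExpressionMatrix(df, groups)

    def test_unlabelled_sample_rejected(self):
        df = pd.DataFrame(np.ones((1, 4)), index=["p0"], columns=list("abcd"))
        groups = pd.Series(["normal", "normal", "model"], index=["a", "b", "c"])
        with pytest.raises(ValueError, match="without group"):
            ExpressionMatrix(df, groups)
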