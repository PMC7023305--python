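import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from metabopanel import (
    Direction,
    QScope,
    SyntheticConfig,
    bh_adjust,
    dichotomized_adjust,
    filter_features,
    fold_change,
    generate_cohort,
    global_template,
    normalize_matrix,
    rank_sum_test,
    test_all as run_panel_tests,
    volcano_select,
)
from metabopanel.univariate_stats import MetaboliteTestResult

from conftest import make_panel


def enumeration_oracle(a, b):
    """Independent exact two-sided rank-sum p: enumerate all label splits."""
    from scipy.stats import rankdata

    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)
    w_obs = ranks[: len(a)].sum()
    sums = [
        sum(ranks[list(c)])
        for c in itertools.combinations(range(len(pooled)), len(a))
    ]
    p_le = np.mean([s <= w_obs + 1e-9 for s in sums])
    p_ge = np.mean([s >= w_obs - 1e-9 for s in sums])
    return min(1.0, 2 * min(p_le, p_ge))


class TestRankSum:
    @pytest.mark.parametrize(
        "a, b, expected",
        [
            ((1, 2), (3, 4), 1 / 3),
            ((1, 2, 3), (4, 5, 6), 0.1),
        ],
    )
    def test_exact_small_samples(self, a, b, expected):
        assert rank_sum_test(a, b, method="exact") == pytest.approx(expected)
        assert enumeration_oracle(a, b) == pytest.approx(expected)

    def test_constant_samples_p_one(self):
        assert rank_sum_test([2, 2, 2], [2, 2], method="auto") == 1.0

    def test_empty_sample_raises(self):
        with pytest.raises(ValueError):
            rank_sum_test([], [1, 2])

    def test_exact_matches_enumeration_with_ties(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            a = rng.integers(0, 4, size=4).astype(float)
            b = rng.integers(0, 4, size=5).astype(float)
            if np.ptp(np.concatenate([a, b])) == 0:
                continue
            assert rank_sum_test(a, b, method="exact") == pytest.approx(
                enumeration_oracle(a, b)
            )

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(st.lists(st.floats(-50, 50), min_size=3, max_size=8, unique=True).filter(
        lambda v: len(v) >= 6))
    def test_two_sided_symmetry(self, values):
        a, b = values[:3], values[3:]
        assert rank_sum_test(a, b, "exact") == pytest.approx(rank_sum_test(b, a, "exact"))
        assert rank_sum_test(a, b, "normal_approx") == pytest.approx(
            rank_sum_test(b, a, "normal_approx")
        )

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(st.lists(st.floats(0.01, 50), min_size=6, max_size=9, unique=True))
    def test_monotone_transform_invariance(self, values):
        a, b = values[:3], values[3:]
        transformed_a = np.log(np.asarray(a)) * 2 + 1
        transformed_b = np.log(np.asarray(b)) * 2 + 1
        assert rank_sum_test(a, b, "exact") == pytest.approx(
            rank_sum_test(transformed_a, transformed_b, "exact")
        )

    def test_exact_close_to_normal_approx(self):
        rng = np.random.default_rng(12)
        for _ in range(50):
            a, b = rng.normal(size=10), rng.normal(size=10)
            assert abs(
                rank_sum_test(a, b, "exact") - rank_sum_test(a, b, "normal_approx")
            ) < 0.02


class TestBH:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.03]) == pytest.approx([0.03])

    def test_hand_computed_step_up(self):
        np.testing.assert_allclose(
            bh_adjust([0.005, 0.01, 0.03, 0.04]), [0.02, 0.02, 0.04, 0.04]
        )

    def test_order_preserving_with_input(self):
        p = [0.04, 0.005, 0.03, 0.01]
        np.testing.assert_allclose(bh_adjust(p), [0.04, 0.02, 0.04, 0.02])

    def test_out_of_range_raises(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    def test_bounds_and_monotonicity(self, p):
        q = bh_adjust(p)
        assert (q >= min(p) - 1e-12).all() and (q <= 1 + 1e-12).all()
        order = np.argsort(p, kind="stable")
        assert (np.diff(np.asarray(q)[order]) >= -1e-12).all()


class TestFoldChange:
    def test_identical_samples(self):
        assert fold_change([1, 2, 3], [1, 2, 3]) == 1.0

    def test_median_example(self):
        assert fold_change([2, 4, 6], [1, 2, 3], center="median") == 2.0

    def test_zero_patient_center_is_undefined(self):
        assert fold_change([1, 2], [0, 0]) is None

    def test_both_zero_is_flat(self):
        assert fold_change([0, 0], [0, 0]) == 1.0

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(
        st.lists(st.floats(0.1, 100), min_size=2, max_size=8),
        st.lists(st.floats(0.1, 100), min_size=2, max_size=8),
        st.sampled_from(["mean", "median"]),
    )
    def test_reciprocal_identity(self, a, b, center):
        fab, fba = fold_change(a, b, center), fold_change(b, a, center)
        assert fab * fba == pytest.approx(1.0)


def _result(mid, p, fc):
    return MetaboliteTestResult(
        metabolite_id=mid, p_value=p, q_value=p, q_scope=QScope.WHOLE_PANEL,
        fc_mean=fc, fc_median=fc,
        direction=Direction.FLAT if fc == 1 else (
            Direction.DOWN_IN_PATIENTS if (fc is None or fc > 1) else Direction.UP_IN_PATIENTS
        ),
    )


class TestVolcano:
    def test_infinite_threshold_empty(self):
        rs = [_result("a", 0.001, 10.0)]
        assert volcano_select(rs, fc_min=float("inf")) == []

    def test_toy_rule_application(self):
        rs = [_result("m1", 0.05, 2.5), _result("m2", 0.01, 1.1), _result("m3", 0.2, 0.4)]
        assert [r.metabolite_id for r in volcano_select(rs)] == ["m1"]

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(4)
        rs = [
            _result(f"m{i}", rng.uniform(), float(np.exp(rng.normal(0, 1))))
            for i in range(100)
        ]
        tight = {r.metabolite_id for r in volcano_select(rs, fc_min=2, p_max=0.05)}
        loose_p = {r.metabolite_id for r in volcano_select(rs, fc_min=2, p_max=0.2)}
        loose_fc = {r.metabolite_id for r in volcano_select(rs, fc_min=1.5, p_max=0.05)}
        assert tight <= loose_p and tight <= loose_fc


class TestDichotomized:
    def test_single_group_equals_bh(self):
        rs = [_result("a", 0.01, 2.0), _result("b", 0.04, 0.5), _result("c", 0.5, 1.0)]
        out = dichotomized_adjust(rs, ["G"] * 3)
        np.testing.assert_allclose(
            [r.q_value for r in out], bh_adjust([0.01, 0.04, 0.5])
        )
        assert all(r.q_scope is QScope.SUPER_PATHWAY for r in out)

    def test_two_groups_per_group_step_up(self):
        rs = [_result("a", 0.01, 2.0), _result("b", 0.01, 2.0), _result("c", 0.5, 1.0)]
        out = dichotomized_adjust(rs, ["G1", "G2", "G2"])
        assert [r.q_value for r in out] == pytest.approx([0.01, 0.02, 0.5])

    def test_results_in_input_order(self):
        rs = [_result(m, p, 1.0) for m, p in [("x", 0.3), ("y", 0.1), ("z", 0.2)]]
        out = dichotomized_adjust(rs, {"x": "A", "y": "B", "z": "A"})
        assert [r.metabolite_id for r in out] == ["x", "y", "z"]


class TestTestAll:
    def test_requires_imputed_dataset(self, toy_panel):
        with pytest.raises(ValueError, match="missing"):
            run_panel_tests(toy_panel)

    def test_small_cohort_raises(self):
        ds = make_panel([[1.0, 2.0]], [[False, False]], ["Sterol"], ["control", "patient"])
        with pytest.raises(ValueError, match="at least 2"):
            run_panel_tests(ds)

    def test_vectorized_matches_scalar_path(self):
        ds, _ = generate_cohort(
            SyntheticConfig(template=global_template()[:5], n_controls=8, n_patients=8,
                            lod_quantile=0.0, xenobiotic_usage_prob=1.0, seed=9)
        )
        fast = run_panel_tests(ds, method="normal_approx")
        slow = run_panel_tests(ds, method="normal_approx", allow_missing=True)
        np.testing.assert_allclose(
            [r.p_value for r in fast], [r.p_value for r in slow]
        )

    def test_null_type_one_error(self):
        fractions = []
        template = [t for t in global_template() if "Drug" not in t.sub_pathway
                    and t.sub_pathway != "Tobacco Metabolites"]
        for seed in range(5):
            ds, _ = generate_cohort(
                SyntheticConfig(template=template, lod_quantile=0.0, seed=seed)
            )
            res = run_panel_tests(ds)
            fractions.append(np.mean([r.p_value < 0.05 for r in res]))
        assert abs(np.mean(fractions) - 0.05) <= 0.02


class TestNormalize:
    def test_log10_values(self):
        out = normalize_matrix(np.array([[1.0, 10.0, 100.0]]), autoscale=False)
        np.testing.assert_allclose(out, [[0, 1, 2]])

    def test_autoscale_mean_sd(self):
        rng = np.random.default_rng(2)
        x = rng.lognormal(size=(5, 20))
        out = normalize_matrix(x)
        np.testing.assert_allclose(out.mean(axis=1), 0, atol=1e-12)
        np.testing.assert_allclose(out.std(axis=1, ddof=1), 1, atol=1e-12)

    def test_constant_row_zeroed_with_warning(self, caplog):
        x = np.array([[3.0, 3.0, 3.0], [1.0, 2.0, 4.0]])
        with caplog.at_level("WARNING", logger="metabopanel"):
            out = normalize_matrix(x, log_transform=False)
        np.testing.assert_array_equal(out[0], 0.0)
        assert any("zero-variance" in r.message for r in caplog.records)

    def test_zero_offset_half_min_positive(self):
        x = np.array([[0.0, 2.0, 8.0]])
        out = normalize_matrix(x, autoscale=False, log_base=2)
        np.testing.assert_allclose(out, [[0.0, 1.0, 3.0]])  # zero -> 1.0 (= 2/2)


class TestFilterFeatures:
    def test_zero_drop_identity(self):
        x = np.arange(12, dtype=float).reshape(3, 4)
        np.testing.assert_array_equal(filter_features(x, "iqr", 0.0), x)

    def test_rsd_drops_least_dispersed(self):
        rng = np.random.default_rng(1)
        base = rng.lognormal(0, 0.01, size=(1, 30))
        mid = rng.lognormal(0, 0.5, size=(1, 30))
        top = rng.lognormal(0, 0.9, size=(1, 30))
        x = np.vstack([base, mid, top])
        out = filter_features(x, "rsd", 1 / 3)
        assert out.shape[0] == 2
        np.testing.assert_array_equal(out, x[1:])

    def test_mad_over_median_constant_row_ranked_lowest(self):
        x = np.vstack([np.full((1, 10), 5.0), np.random.default_rng(0).normal(10, 3, (2, 10))])
        out = filter_features(x, "mad_over_median", 1 / 3)
        np.testing.assert_array_equal(out, x[1:])
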