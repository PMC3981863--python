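"""Normalization, BH adjustment, two-group screen, clustering and ddCt."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from dmrpipe.expression import (
    bh_adjust,
    hierarchical_cluster,
    percentile_shift_normalize,
    qpcr_relative_expression,
    two_group_screen,
)
from dmrpipe.simulate import simulate_expression
from oracles import brute_force_average_linkage, brute_force_bh


class TestPercentileShiftNormalize:
    def test_common_percentile_preserves_relative_differences(self, rng):
        values = pd.DataFrame(
            np.power(2.0, rng.normal(8, 2, size=(200, 4))),
            columns=list("abcd"),
        )
        norm = percentile_shift_normalize(values)
        p75 = np.percentile(norm, 75, axis=0)
        assert np.allclose(p75, p75[0], atol=1e-9)
        # per-sample shift only: within-sample differences survive
        log2 = np.log2(values)
        diffs = log2 - log2.iloc[0]
        norm_diffs = norm - norm.iloc[0]
        assert np.allclose(diffs, norm_diffs, atol=1e-9)

    def test_scaled_duplicate_sample_collapses_onto_original(self, rng):
        base = np.power(2.0, rng.normal(8, 2, size=100))
        values = pd.DataFrame({"orig": base, "x8": base * 8, "other": base[::-1]})
        norm = percentile_shift_normalize(values)
        assert np.allclose(norm["orig"], norm["x8"], atol=1e-9)

    def test_five_probe_toy_matrix_matches_hand_computation(self):
        values = pd.DataFrame({"s1": [1, 2, 4, 8, 16], "s2": [4, 8, 16, 32, 64]})
        norm = percentile_shift_normalize(values)
        # log2 percentiles (75th): s1 -> 3, s2 -> 5; median target = 4
        expected_s1 = np.log2([1, 2, 4, 8, 16]) + 1.0
        expected_s2 = np.log2([4, 8, 16, 32, 64]) - 1.0
        assert np.allclose(norm["s1"], expected_s1)
        assert np.allclose(norm["s2"], expected_s2)

    def test_idempotent_on_log2_output(self, rng):
        values = pd.DataFrame(
            np.power(2.0, rng.normal(8, 2, size=(50, 3))), columns=list("abc")
        )
        once = percentile_shift_normalize(values)
        twice = percentile_shift_normalize(once, input_scale="log2")
        assert np.allclose(once, twice, atol=1e-12)

    def test_rejects_non_positive_values(self):
        with pytest.raises(ValueError):
            percentile_shift_normalize(pd.DataFrame({"s": [1.0, 0.0]}))


class TestBHAdjust:
    @pytest.mark.parametrize(
        "p,expected",
        [
            ([0.03], [0.03]),
            ([0.2, 0.2, 0.2], [0.2, 0.2, 0.2]),
            ([0.01, 0.02, 0.03, 0.04], [0.04, 0.04, 0.04, 0.04]),
        ],
    )
    def test_examples(self, p, expected):
        assert np.allclose(bh_adjust(p), expected)

    def test_matches_brute_force_step_up_on_random_vectors(self, rng):
        for _ in range(1000):
            m = int(rng.integers(1, 40))
            p = rng.random(m)
            assert np.allclose(bh_adjust(p), brute_force_bh(p), atol=1e-12)

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=50))
    def test_q_dominates_p_and_is_monotone_along_sorted_p(self, p):
        q = bh_adjust(p)
        assert np.all(q >= np.asarray(p) - 1e-12)
        assert np.all(q <= 1.0)
        order = np.argsort(p, kind="stable")
        assert np.all(np.diff(q[order]) >= -1e-12)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    def test_agrees_with_statsmodels_implementation(self, rng):
        from statsmodels.stats.multitest import multipletests

        for _ in range(50):
            p = rng.random(int(rng.integers(1, 200)))
            _, q_sm, _, _ = multipletests(p, method="fdr_bh")
            assert np.allclose(bh_adjust(p), q_sm, atol=1e-12)


class TestTwoGroupScreen:
    def test_identical_groups_find_nothing(self, rng):
        data = rng.normal(8, 1, size=(100, 3))
        matrix = pd.DataFrame(
            np.hstack([data, data]), columns=list("abcdef")
        )
        res = two_group_screen(matrix, ["a", "b", "c"], ["d", "e", "f"])
        assert (res["status"] == "not_significant").all()

    def test_recovers_planted_probes_exactly(self):
        matrix, groups, truth = simulate_expression(seed=42)
        norm = percentile_shift_normalize(matrix)
        ga = [s for s, g in groups.items() if g == "A"]
        gb = [s for s, g in groups.items() if g == "B"]
        res = two_group_screen(norm, ga, gb)
        assert set(res.index[res["status"] == "up"]) == set(truth.up_probes)
        assert set(res.index[res["status"] == "down"]) == set(truth.down_probes)

    def test_fold_change_gate_blocks_small_effects(self, rng):
        jitter = rng.normal(0, 1e-6, size=(1, 6))
        matrix = pd.DataFrame(
            np.array([[1.0] * 3 + [0.0] * 3]) + jitter,
            index=["p1"], columns=list("abcdef"),
        )
        res = two_group_screen(matrix, ["a", "b", "c"], ["d", "e", "f"])
        assert res.loc["p1", "log2_fold_change"] == pytest.approx(1.0, abs=1e-4)
        assert res.loc["p1", "status"] == "not_significant"

    def test_zero_variance_edge_rules(self):
        matrix = pd.DataFrame(
            {
                "a": [1.0, 1.0], "b": [1.0, 1.0],
                "c": [1.0, 5.0], "d": [1.0, 5.0],
            },
            index=["equal", "different"],
        )
        res = two_group_screen(matrix, ["a", "b"], ["c", "d"])
        assert res.loc["equal", "p_value"] == 1.0
        assert res.loc["different", "p_value"] == 0.0

    def test_status_invariant_under_probe_order(self):
        matrix, groups, _ = simulate_expression(n_probes=300, seed=3)
        norm = percentile_shift_normalize(matrix)
        ga = [s for s, g in groups.items() if g == "A"]
        gb = [s for s, g in groups.items() if g == "B"]
        res = two_group_screen(norm, ga, gb)
        shuffled = norm.sample(frac=1.0, random_state=0)
        res_shuffled = two_group_screen(shuffled, ga, gb)
        assert res_shuffled["status"].sort_index().equals(res["status"].sort_index())

    def test_requires_two_samples_per_group(self):
        matrix = pd.DataFrame(np.ones((5, 3)), columns=list("abc"))
        with pytest.raises(ValueError):
            two_group_screen(matrix, ["a"], ["b", "c"])


class TestHierarchicalCluster:
    def test_identical_samples_merge_at_height_zero(self, rng):
        x = rng.normal(size=30)
        matrix = pd.DataFrame({"s1": x, "s2": x, "s3": rng.normal(size=30)})
        linkage, labels = hierarchical_cluster(matrix)
        assert labels == ["s1", "s2", "s3"]
        assert sorted(linkage[0, :2]) == [0, 1]
        assert linkage[0, 2] == pytest.approx(0.0, abs=1e-12)

    def test_shift_invariance_of_correlation(self, rng):
        x = rng.normal(size=40)
        matrix = pd.DataFrame({"x": x, "x_shift": x + 5.0, "neg": -x})
        linkage, _ = hierarchical_cluster(matrix)
        assert sorted(linkage[0, :2]) == [0, 1]
        assert linkage[0, 2] == pytest.approx(0.0, abs=1e-9)

    def test_matches_exhaustive_average_linkage(self, rng):
        matrix = pd.DataFrame(rng.normal(size=(25, 4)), columns=list("abcd"))
        linkage, _ = hierarchical_cluster(matrix)
        corr = np.corrcoef(matrix.to_numpy().T)
        merges = brute_force_average_linkage(1.0 - corr)
        assert np.allclose(
            sorted(linkage[:, 2]), sorted(h for _, _, h in merges), atol=1e-9
        )

    def test_zero_variance_sample_raises_with_name(self):
        matrix = pd.DataFrame({"ok": [1.0, 2.0, 3.0], "flat": [5.0, 5.0, 5.0]})
        with pytest.raises(ValueError, match="flat"):
            hierarchical_cluster(matrix)


class TestQpcrRelativeExpression:
    def test_self_calibrated_sample_is_one(self):
        ct = pd.Series({"s1": 20.0})
        levels = qpcr_relative_expression(ct, ct.copy(), ["s1"])
        assert levels["s1"] == pytest.approx(1.0)

    def test_one_cycle_higher_halves_the_level(self):
        ct_target = pd.Series({"cal": 20.0, "test": 21.0})
        ct_ref = pd.Series({"cal": 18.0, "test": 18.0})
        levels = qpcr_relative_expression(ct_target, ct_ref, ["cal"])
        assert levels["test"] == pytest.approx(0.5)

    def test_three_sample_toy_matches_ddct_formula(self):
        ct_target = pd.Series({"a": 22.0, "b": 24.0, "c": 21.0})
        ct_ref = pd.Series({"a": 18.0, "b": 19.0, "c": 18.0})
        levels = qpcr_relative_expression(ct_target, ct_ref, ["a", "b"])
        raw = 2.0 ** -(ct_target - ct_ref)
        expected = raw / raw[["a", "b"]].mean()
        assert np.allclose(levels, expected)
        assert levels[["a", "b"]].mean() == pytest.approx(1.0)

    def test_empty_calibrator_raises(self):
        ct = pd.Series({"s1": 20.0})
        with pytest.raises(ValueError):
            qpcr_relative_expression(ct, ct, [])
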