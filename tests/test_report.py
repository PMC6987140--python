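"""Quantile profiles, binomial median CIs, orderings, heatmap, summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from threec import (Cohort, VariableCatalog, build_heatmap_matrix,
                    build_signature_table, characterize_clusters,
                    cluster_quantile_profile, empirical_quantile_transform,
                    median_with_binomial_ci, order_variables_by_similarity)


class TestQuantileTransform:
    def test_higher_worse_endpoints(self):
        np.testing.assert_allclose(
            empirical_quantile_transform([1, 3, 5], "higher_worse"),
            [0.0, 0.5, 1.0])

    def test_higher_better_flips(self):
        np.testing.assert_allclose(
            empirical_quantile_transform([1, 3, 5], "higher_better"),
            [1.0, 0.5, 0.0])

    def test_ties_share_midrank_quantiles(self):
        # midranks (1.5, 1.5, 3) -> ((r-1)/(n-1)) = (0.25, 0.25, 1)
        np.testing.assert_allclose(
            empirical_quantile_transform([2, 2, 7], "higher_worse"),
            [0.25, 0.25, 1.0])

    def test_constant_vector_all_half_with_warning(self):
        with pytest.warns(UserWarning):
            out = empirical_quantile_transform([4.0] * 5)
        np.testing.assert_allclose(out, 0.5)

    @given(st.lists(st.floats(-1e6, 1e6), min_size=2, max_size=100,
                    unique=True))
    @settings(max_examples=60, deadline=None)
    def test_bounds_and_mean(self, values):
        q = empirical_quantile_transform(np.array(values))
        assert q.min() == 0.0 and q.max() == 1.0
        assert np.mean(q) == pytest.approx(0.5)   # exact for tie-free data


class TestMedianBinomialCI:
    def test_constant_data_zero_width(self):
        ci = median_with_binomial_ci([2.0] * 9)
        assert ci.median == ci.lower == ci.upper == 2.0

    def test_single_value_degenerate(self):
        ci = median_with_binomial_ci([3.0])
        assert ci.median == 3.0 and ci.degenerate

    def test_order_statistic_indices_match_cdf_search(self):
        n, level = 25, 0.95
        x = np.sort(np.random.default_rng(1).normal(size=n))
        ci = median_with_binomial_ci(x, level)
        cdf = sps.binom.cdf(np.arange(n), n, 0.5)
        l = max(i for i in range(1, n + 1) if cdf[i - 1] <= 0.025)
        u = min(i for i in range(1, n + 1) if cdf[i - 1] >= 0.975)
        assert ci.lower == x[l - 1] and ci.upper == x[u - 1]

    def test_median_inside_ci_and_endpoints_observed(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            x = rng.normal(size=rng.integers(3, 60))
            ci = median_with_binomial_ci(x)
            assert ci.lower <= ci.median <= ci.upper
            assert ci.lower in x and ci.upper in x

    def test_coverage_at_least_nominal(self):
        """Coverage of the true median >= 0.95 over 2000 replicates."""
        rng = np.random.default_rng(3)
        n, hits = 25, 0
        for _ in range(2000):
            x = rng.normal(size=n)      # true median 0
            ci = median_with_binomial_ci(x, 0.95)
            hits += ci.lower <= 0.0 <= ci.upper
        assert hits / 2000 >= 0.95

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            median_with_binomial_ci([])


class TestOrdering:
    def test_identical_columns_adjacent(self):
        prof = pd.DataFrame({"a": [0.1, 0.9], "b": [0.9, 0.1],
                             "c": [0.1, 0.9]}, index=[1, 2])
        order = order_variables_by_similarity(prof)
        assert abs(order.index("a") - order.index("c")) == 1

    def test_two_groups_form_contiguous_blocks(self):
        rng = np.random.default_rng(4)
        low = {f"L{i}": 0.1 + 0.01 * rng.random(3) for i in range(3)}
        high = {f"H{i}": 0.9 + 0.01 * rng.random(3) for i in range(3)}
        prof = pd.DataFrame({**low, **high}, index=[1, 2, 3])
        order = order_variables_by_similarity(prof)
        kinds = [v[0] for v in order]
        assert kinds in (["L"] * 3 + ["H"] * 3, ["H"] * 3 + ["L"] * 3)

    def test_permutation_invariant_up_to_reflection(self):
        rng = np.random.default_rng(5)
        prof = pd.DataFrame(rng.random((4, 8)),
                            columns=[f"v{i}" for i in range(8)])
        o1 = order_variables_by_similarity(prof)
        cols = list(rng.permutation(prof.columns))
        o2 = order_variables_by_similarity(prof[cols])
        assert o1 == o2 or o1 == o2[::-1]


class TestHeatmap:
    @staticmethod
    def table_for(k, shifts, n_per=60, seed=0):
        rng = np.random.default_rng(seed)
        labels = np.repeat(np.arange(1, k + 1), n_per)
        cols = {}
        for name, shifted in shifts.items():
            v = rng.normal(size=len(labels))
            for c in shifted:
                v[labels == c] += 6.0
            cols[name] = v
        for j in range(8):
            cols[f"null{j}"] = rng.normal(size=len(labels))
        return build_signature_table(pd.DataFrame(cols), labels)

    def test_fifteen_columns_for_six_clusters(self):
        table = self.table_for(6, {"s1": [1]}, n_per=40)
        hm = build_heatmap_matrix(table)
        assert hm.matrix.shape[1] == 15

    @pytest.mark.parametrize("k", [2, 3, 4, 5])
    def test_column_count_is_k_choose_2(self, k):
        table = self.table_for(k, {"s1": [1]}, n_per=40, seed=k)
        hm = build_heatmap_matrix(table)
        assert hm.matrix.shape[1] == k * (k - 1) // 2

    def test_cells_three_state_and_rows_nonzero(self):
        table = self.table_for(3, {"s1": [1], "s2": [2]}, seed=2)
        hm = build_heatmap_matrix(table)
        assert set(np.unique(hm.matrix.values)) <= {-1, 0, 1}
        assert (hm.matrix != 0).any(axis=1).all()

    def test_identical_sign_groups_separate_in_row_order(self):
        table = self.table_for(3, {"s1": [1], "s2": [1], "s3": [3],
                                   "s4": [3]}, n_per=80, seed=3)
        hm = build_heatmap_matrix(table)
        if {"s1", "s2", "s3", "s4"} <= set(hm.row_order):
            pos = {v: hm.row_order.index(v) for v in ("s1", "s2", "s3", "s4")}
            assert abs(pos["s1"] - pos["s2"]) == 1
            assert abs(pos["s3"] - pos["s4"]) == 1

    def test_no_significant_pbms_gives_empty_matrix(self):
        rng = np.random.default_rng(6)
        labels = np.repeat([1, 2], 30)
        pbm = pd.DataFrame({f"n{j}": rng.normal(size=60) for j in range(5)})
        table = build_signature_table(pbm, labels)
        hm = build_heatmap_matrix(table)
        assert hm.matrix.shape[0] == 0


def demo_cohort(age_shift=0.0, n_per=50, seed=0):
    rng = np.random.default_rng(seed)
    labels = pd.Series(np.repeat([1, 2], n_per))
    age = np.concatenate([rng.normal(70, 5, n_per),
                          rng.normal(70 + age_shift, 5, n_per)])
    sex = rng.choice(["F", "M"], size=2 * n_per)
    data = pd.DataFrame({"DX": np.where(labels == 1, "CN", "AD"),
                         "age": age, "sex": sex})
    cat = VariableCatalog.from_records([
        {"variable": "DX", "category": "DX", "vartype": "categorical",
         "direction": "none", "domain": ""},
        {"variable": "age", "category": "CM", "vartype": "continuous",
         "direction": "higher_worse", "domain": ""},
        {"variable": "sex", "category": "CM", "vartype": "categorical",
         "direction": "higher_worse", "domain": ""},
    ])
    labels.index = data.index
    return Cohort(data, cat), labels


class TestCharacterize:
    def test_single_cluster_no_pvalues(self):
        cohort, labels = demo_cohort()
        out = characterize_clusters(cohort, pd.Series(1, index=labels.index),
                                    ["age"])
        assert (out["p"] == "").all()

    def test_identical_distributions_h_zero(self):
        cohort, labels = demo_cohort()
        data = cohort.data.copy()
        data["age"] = np.tile(data["age"][:50], 2)   # same values per cluster
        out = characterize_clusters(Cohort(data, cohort.catalog), labels,
                                    ["age"])
        p = float(out.loc[out["variable"] == "age", "p"].iloc[0])
        assert p > 0.9

    def test_planted_age_shift_detected(self):
        detections = 0
        for seed in range(20):
            cohort, labels = demo_cohort(age_shift=5.0, n_per=200, seed=seed)
            out = characterize_clusters(cohort, labels, ["age"])
            p = float(out.loc[out["variable"] == "age", "p"].iloc[0])
            detections += p < 0.001
        assert detections >= 19

    def test_categorical_counts_and_chi2(self):
        cohort, labels = demo_cohort(seed=3)
        out = characterize_clusters(cohort, labels, ["sex"])
        assert (out["variable"] == "sex").sum() == 2   # F and M rows
        assert "(" in out.loc[out["variable"] == "sex",
                              "cluster_1"].iloc[0]


class TestClusterProfile:
    def test_profile_bounds_and_order(self, small_cohort):
        cohort, truth, _ = small_cohort
        prof = cluster_quantile_profile(cohort, truth.cluster_of_subject,
                                        cohort.catalog.names("CM")[:10])
        assert ((prof.medians >= 0) & (prof.medians <= 1)).all().all()
        assert ((prof.lower <= prof.medians) &
                (prof.medians <= prof.upper)).all().all()
        assert sorted(prof.order) == sorted(prof.medians.columns)

    def test_informative_cms_track_severity(self, small_cohort):
        """On informative CMs, later clusters sit at higher severity."""
        cohort, truth, _ = small_cohort
        prof = cluster_quantile_profile(cohort, truth.cluster_of_subject,
                                        sorted(truth.informative_cm_ids))
        med = prof.medians
        for v in med.columns:
            assert med.loc[1, v] < med.loc[2, v] < med.loc[3, v]
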