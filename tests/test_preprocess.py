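"""Complete-case filtering, redundancy removal, composites, transforms."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from threec import (Cohort, PreprocessConfig, VariableCatalog,
                    complete_case_filter, domain_sum_scores,
                    monotone_transform, remove_redundant)
from threec.preprocess import EmptyResultError, gini_impurity


def build_cohort(columns: dict, vartypes: dict | None = None,
                 directions: dict | None = None) -> Cohort:
    vartypes = vartypes or {}
    directions = directions or {}
    n = len(next(iter(columns.values())))
    data = {"DX": ["CN", "AD"] * (n // 2) + ["CN"] * (n % 2), **columns}
    records = [{"variable": "DX", "category": "DX", "vartype": "categorical",
                "direction": "none", "domain": ""}]
    for v in columns:
        records.append({"variable": v, "category": "CM",
                        "vartype": vartypes.get(v, "continuous"),
                        "direction": directions.get(v, "higher_worse"),
                        "domain": ""})
    idx = pd.Index([f"s{i}" for i in range(n)], name="subject_id")
    return Cohort(pd.DataFrame(data, index=idx),
                  VariableCatalog.from_records(records))


class TestCompleteCaseFilter:
    def test_complete_input_unchanged(self):
        cohort = build_cohort({"A": [1.0, 2.0, 3.0, 4.0]})
        out = complete_case_filter(cohort, PreprocessConfig())
        assert out.data.equals(cohort.data)
        assert out.meta["complete_case_report"]["variables_dropped"] == []
        assert out.meta["complete_case_report"]["subjects_dropped"] == []

    def test_fully_missing_column_dropped_subjects_kept(self):
        cohort = build_cohort({"A": [np.nan] * 4, "B": [1.0, 2.0, 3.0, 4.0]})
        out = complete_case_filter(cohort, PreprocessConfig(
            max_var_missing_frac=0.3))
        assert "A" not in out.data.columns
        assert out.n_subjects == 4

    def test_two_step_hand_trace(self, tiny_cohort):
        """A (frac 0.5 > 0.3) goes first; then subject s3 (missing B) goes."""
        out = complete_case_filter(tiny_cohort,
                                   PreprocessConfig(max_var_missing_frac=0.3))
        assert list(out.data.columns) == ["DX", "B"]
        assert list(out.data.index) == ["s1", "s2", "s4"]
        assert out.is_complete()

    def test_everything_dropped_raises_with_report(self):
        cohort = build_cohort({"A": [np.nan] * 4})
        with pytest.raises(EmptyResultError) as exc:
            # A is kept (frac <= 1.0) so every subject carries a gap
            complete_case_filter(cohort, PreprocessConfig(
                max_var_missing_frac=1.0))
        assert len(exc.value.report["subjects_dropped"]) == 4

    @given(st.integers(0, 2 ** 31 - 1), st.floats(0.0, 0.6))
    @settings(max_examples=40, deadline=None)
    def test_output_always_complete(self, seed, frac):
        rng = np.random.default_rng(seed)
        vals = rng.normal(size=(12, 4))
        vals[rng.random((12, 4)) < frac] = np.nan
        cohort = build_cohort({f"V{j}": vals[:, j] for j in range(4)})
        try:
            out = complete_case_filter(cohort, PreprocessConfig())
        except EmptyResultError:
            return
        assert out.is_complete()


class TestRemoveRedundant:
    def test_exact_duplicate_second_dropped(self):
        x = [1.0, 2.0, 3.0, 4.0]
        cohort = build_cohort({"A": x, "B": x, "C": [4.0, 1.0, 3.0, 2.0]})
        out = remove_redundant(cohort, PreprocessConfig())
        assert list(out.data.columns) == ["DX", "A", "C"]

    def test_rare_binary_dropped_by_gini(self):
        # proportions (0.99, 0.01): Gini = 1 - .99^2 - .01^2 = 0.0198 < 0.05
        vals = [0.0] * 99 + [1.0]
        assert gini_impurity(vals) == pytest.approx(0.0198)
        cohort = build_cohort({"A": vals, "B": list(np.linspace(0, 1, 100))},
                              vartypes={"A": "categorical"})
        out = remove_redundant(cohort, PreprocessConfig())
        assert "A" not in out.data.columns and "B" in out.data.columns

    def test_independent_columns_retained(self):
        rng = np.random.default_rng(0)
        cohort = build_cohort({"A": rng.normal(size=1000),
                               "B": rng.normal(size=1000)})
        out = remove_redundant(cohort, PreprocessConfig())
        assert {"A", "B"} <= set(out.data.columns)

    def test_constant_continuous_dropped(self):
        cohort = build_cohort({"A": [2.0] * 4, "B": [1.0, 2.0, 3.0, 4.0]})
        out = remove_redundant(cohort, PreprocessConfig())
        assert "A" not in out.data.columns
        reasons = {d["variable"]: d["reason"]
                   for d in out.meta["redundancy_report"]}
        assert reasons["A"] == "constant"

    def test_idempotent(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=50)
        cohort = build_cohort({"A": x, "B": x * 2.0, "C": rng.normal(size=50),
                               "D": [0.0] * 49 + [1.0]},
                              vartypes={"D": "ordinal"})
        once = remove_redundant(cohort, PreprocessConfig())
        twice = remove_redundant(once, PreprocessConfig())
        assert once.data.equals(twice.data)


class TestDomainSumScores:
    def test_composite_is_item_sum(self):
        cohort = build_cohort({"m1": [2.0, 1.0], "m2": [3.0, 4.0]})
        cfg = PreprocessConfig(domain_map={"memory": ["m1", "m2"]})
        out = domain_sum_scores(cohort, cfg)
        assert out.data["memory_sum"].tolist() == [5.0, 5.0]
        assert out.catalog.direction("memory_sum") == "higher_worse"
        assert {"m1", "m2"} <= set(out.data.columns)   # originals retained

    def test_empty_map_identity(self):
        cohort = build_cohort({"A": [1.0, 2.0]})
        out = domain_sum_scores(cohort, PreprocessConfig())
        assert out.data.equals(cohort.data)

    def test_mixed_directions_rejected(self):
        cohort = build_cohort({"m1": [1.0, 2.0], "m2": [1.0, 2.0]},
                              directions={"m2": "higher_better"})
        cfg = PreprocessConfig(domain_map={"d": ["m1", "m2"]})
        with pytest.raises(ValueError, match="direction"):
            domain_sum_scores(cohort, cfg)

    def test_uniform_items_composite_properties(self):
        rng = np.random.default_rng(8)
        items = {f"i{j}": rng.integers(0, 3, size=500).astype(float)
                 for j in range(3)}
        cohort = build_cohort(items)
        cfg = PreprocessConfig(domain_map={"dom": list(items)})
        out = domain_sum_scores(cohort, cfg)
        comp = out.data["dom_sum"]
        assert comp.between(0, 6).all()
        for j in items:
            assert np.corrcoef(comp, out.data[j])[0, 1] > 0


class TestMonotoneTransform:
    def test_symmetric_input_keeps_identity(self):
        x = np.tile([-1.0, 0.0, 1.0], 20)
        out, label = monotone_transform(x)
        assert label == "identity"
        np.testing.assert_array_equal(out, x)

    def test_lognormal_symmetrized_by_log(self):
        rng = np.random.default_rng(12)
        x = np.exp(rng.normal(size=500))
        out, label = monotone_transform(x, family=("identity", "log", "sqrt"))
        assert label == "log"
        assert abs(sps.skew(out)) < abs(sps.skew(x))

    def test_constant_flagged_degenerate(self):
        out, label = monotone_transform([3.0, 3.0, 3.0])
        assert label == "degenerate"

    @given(st.lists(st.floats(-1e4, 1e4), min_size=3, max_size=60,
                    unique=True))
    @settings(max_examples=60, deadline=None)
    def test_order_isomorphic(self, values):
        """Output is non-decreasing along the input order (monotone map)."""
        x = np.array(values)
        out, _ = monotone_transform(x)
        assert np.all(np.diff(out[np.argsort(x)]) >= 0)

    def test_rank_preservation_seeded_sample(self):
        rng = np.random.default_rng(77)
        x = rng.gamma(2.0, size=200)
        out, _ = monotone_transform(x)
        np.testing.assert_array_equal(np.argsort(out), np.argsort(x))
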