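"""Tests of percentile placement, the Tukey fence, and cohort selection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from _oracles import tukey_fence
from conftest import compendium_from_log
from panoutlier.errors import CohortSizeError, ConfigError, InputError
from panoutlier.io import FocusSample
from panoutlier.outliers import (
    OutlierParams,
    call_outliers,
    combine_lists,
    percentile_of,
    select_pan_disease_cohort,
)


def focus_from_log(log_values, gene_ids, sample_id="FOCUS") -> FocusSample:
    tpm = np.exp2(np.asarray(log_values, dtype=float)) - 1.0
    return FocusSample(sample_id, pd.Series(tpm, index=gene_ids))


class TestPercentileOf:
    def test_extremes_and_midrank(self):
        cohort = [1.0, 2.0, 3.0, 4.0, 5.0]
        assert percentile_of(0.0, cohort) == 0.0
        assert percentile_of(3.0, cohort) == 50.0  # (2 + 0.5) / 5
        assert percentile_of(9.0, cohort) == 100.0

    def test_constant_cohort_sits_at_median(self):
        assert percentile_of(2.0, [2.0] * 7) == 50.0

    def test_empty_cohort_rejected(self):
        with pytest.raises(InputError):
            percentile_of(1.0, [])

    @given(
        values=st.lists(
            st.floats(-5, 5).map(lambda x: round(x, 2)), min_size=1, max_size=30
        ),
        probe=st.floats(-5, 5).map(lambda x: round(x, 2)),
    )
    def test_invariant_under_strictly_monotone_transform(self, values, probe):
        # x^3 + 8x is strictly increasing and exact on rounded inputs:
        # equal inputs stay equal, distinct inputs stay ordered
        before = percentile_of(probe, values)
        transform = lambda x: x**3 + 8.0 * x
        after = percentile_of(transform(probe), [transform(v) for v in values])
        assert before == pytest.approx(after)


class TestCallOutliers:
    def test_fence_matches_brute_force_oracle_on_random_cohorts(self):
        rng = np.random.default_rng(123)
        for _ in range(200):
            n = int(rng.integers(20, 60))
            log_values = rng.normal(4.0, 1.5, size=(1, n)).clip(min=0)
            comp = compendium_from_log(log_values)
            focus = focus_from_log([5.0], comp.tpm.index)
            calls = call_outliers(focus, comp, OutlierParams(), "pan_cancer")
            q1, q3, fence = tukey_fence(log_values[0])
            assert calls.loc[0, "q1"] == pytest.approx(q1, abs=1e-9)
            assert calls.loc[0, "q3"] == pytest.approx(q3, abs=1e-9)
            assert calls.loc[0, "threshold"] == pytest.approx(fence, abs=1e-9)

    def test_constant_cohort_equal_focus_is_not_outlier(self):
        comp = compendium_from_log(np.full((3, 25), 4.0))
        focus = focus_from_log([4.0, 4.0, 4.0], comp.tpm.index)
        calls = call_outliers(focus, comp, OutlierParams(), "pan_cancer")
        # threshold equals the value; the fence is a strict inequality
        assert not calls["is_outlier"].any()
        assert (calls["percentile"] == 50.0).all()

    def test_fence_on_1_to_8_cohort(self):
        # oracle: sorted 1..8 -> Q1=2.75, Q3=6.25, fence=6.25+1.5*3.5=11.5
        log_values = np.array([[1, 2, 3, 4, 5, 6, 7, 8]], dtype=float)
        comp = compendium_from_log(log_values)
        params = OutlierParams(min_cohort_size=4)
        q1, q3, fence = tukey_fence(log_values[0])
        assert (q1, q3, fence) == (2.75, 6.25, 11.5)
        below = call_outliers(focus_from_log([11.0], comp.tpm.index), comp, params, "pan_cancer")
        above = call_outliers(focus_from_log([12.0], comp.tpm.index), comp, params, "pan_cancer")
        assert not below.loc[0, "is_outlier"]
        assert above.loc[0, "is_outlier"]

    def test_min_expression_floor_dominates(self):
        # focus above the fence but below the expression floor: no call
        comp = compendium_from_log(np.full((1, 30), 0.1))
        focus = focus_from_log([1.0], comp.tpm.index)
        calls = call_outliers(focus, comp, OutlierParams(min_log_expression=2.5), "pan_cancer")
        assert calls.loc[0, "sample_log_value"] > calls.loc[0, "threshold"]
        assert not calls.loc[0, "is_outlier"]

    def test_monotone_in_focus_value_and_multiplier(self):
        rng = np.random.default_rng(7)
        comp = compendium_from_log(rng.normal(4, 1, size=(20, 40)).clip(min=0))
        low = focus_from_log(rng.normal(5, 1, 20).clip(min=0), comp.tpm.index)
        high = focus_from_log(np.log2(low.tpm.to_numpy() + 1) + 1.0, comp.tpm.index)
        calls_low = call_outliers(low, comp, OutlierParams(), "pan_cancer")
        calls_high = call_outliers(high, comp, OutlierParams(), "pan_cancer")
        assert (calls_high["is_outlier"] | ~calls_low["is_outlier"]).all()
        wide = call_outliers(low, comp, OutlierParams(iqr_multiplier=3.0), "pan_cancer")
        assert (calls_low["is_outlier"] | ~wide["is_outlier"]).all()

    def test_small_cohort_error_names_track(self):
        comp = compendium_from_log(np.full((2, 5), 3.0))
        focus = focus_from_log([3.0, 3.0], comp.tpm.index)
        with pytest.raises(CohortSizeError, match="pan_disease"):
            call_outliers(focus, comp, OutlierParams(), "pan_disease")

    def test_focus_sample_excluded_from_own_cohort(self):
        log_values = np.full((1, 30), 3.0)
        comp = compendium_from_log(log_values)
        # focus shares an id with a compendium member whose value is huge
        comp.tpm.loc[:, "S000"] = 1e6
        focus = focus_from_log([3.0], comp.tpm.index, sample_id="S000")
        calls = call_outliers(focus, comp, OutlierParams(), "pan_cancer")
        # with the self column dropped the cohort is constant again
        assert calls.loc[0, "q3"] == 3.0
        assert calls.loc[0, "percentile"] == 50.0


class TestPanDiseaseCohort:
    def test_identical_sample_ranks_first_with_correlation_one(self, small_compendium):
        member = small_compendium.sample_ids[5]
        focus = FocusSample("FOCUS", small_compendium.tpm[member].copy())
        spec = select_pan_disease_cohort(focus, small_compendium, k=30, n_variable_genes=200)
        top_id, top_corr = spec.similarity[0]
        assert top_id == member
        assert top_corr == pytest.approx(1.0)

    def test_k_equal_to_compendium_returns_everyone(self, small_compendium):
        focus = FocusSample("FOCUS", small_compendium.tpm.iloc[:, 0].copy())
        spec = select_pan_disease_cohort(
            focus, small_compendium, k=small_compendium.n_samples, n_variable_genes=100
        )
        assert set(spec.member_ids) == set(small_compendium.sample_ids)
        assert sum(spec.disease_composition.values()) == small_compendium.n_samples

    def test_k_below_min_cohort_size_rejected(self, small_compendium):
        focus = FocusSample("FOCUS", small_compendium.tpm.iloc[:, 0].copy())
        with pytest.raises(ConfigError):
            select_pan_disease_cohort(focus, small_compendium, k=10, min_cohort_size=20)

    def test_similarity_sorted_nonincreasing(self, small_compendium):
        focus = FocusSample("FOCUS", small_compendium.tpm.iloc[:, 3].copy())
        spec = select_pan_disease_cohort(focus, small_compendium, k=50, n_variable_genes=150)
        correlations = [c for _, c in spec.similarity]
        assert correlations == sorted(correlations, reverse=True)


class TestCombineLists:
    def _calls(self, flags):
        return pd.DataFrame(
            {
                "gene_id": [f"G{i}" for i in range(len(flags))],
                "is_outlier": flags,
            }
        )

    def test_intersection_of_overlapping_lists(self):
        pan_cancer = self._calls([True, True, True, False])
        pan_disease = self._calls([False, True, True, True])
        lists = combine_lists(pan_cancer, pan_disease)
        assert lists.pan_cancer == frozenset({"G0", "G1", "G2"})
        assert lists.pan_disease == frozenset({"G1", "G2", "G3"})
        assert lists.intersection == frozenset({"G1", "G2"})

    def test_disjoint_and_identical_lists(self):
        a = self._calls([True, False])
        b = self._calls([False, True])
        assert combine_lists(a, b).intersection == frozenset()
        same = combine_lists(a, a)
        assert same.intersection == same.pan_cancer == same.pan_disease

    def test_symbol_translation_uppercases(self):
        calls = self._calls([True])
        lists = combine_lists(calls, calls, symbols={"G0": "flt3"})
        assert lists.pan_cancer == frozenset({"FLT3"})
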