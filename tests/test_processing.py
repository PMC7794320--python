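"""Unit and property tests for profile normalisation, filtering and transforms."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mycoconcord import FeatureTable
from mycoconcord.containers import FeatureTableError
from mycoconcord.processing import (
    aggregate_taxonomy,
    filter_blacklist,
    filter_prevalence,
    hellinger_transform,
    log10_transform,
    logit_transform,
    normalize_relative,
    parse_lineage,
)


def table(rows, units="counts", features=None):
    arr = np.asarray(rows, dtype=float)
    return FeatureTable(
        pd.DataFrame(
            arr,
            index=[f"S{i}" for i in range(arr.shape[0])],
            columns=features or [f"F{j}" for j in range(arr.shape[1])],
        ),
        units=units,
    )


class TestNormalizeRelative:
    def test_rows_divided_by_row_sum(self):
        rel = normalize_relative(table([[2, 2], [1, 3]]))
        assert rel.units == "relative"
        np.testing.assert_allclose(rel.values, [[0.5, 0.5], [0.25, 0.75]])

    def test_zeros_preserved(self):
        rel = normalize_relative(table([[1, 0, 3]]))
        np.testing.assert_allclose(rel.values, [[0.25, 0, 0.75]])

    def test_all_zero_sample_is_named(self):
        with pytest.raises(FeatureTableError, match="S1"):
            normalize_relative(table([[1, 1], [0, 0]]))

    def test_rejects_non_count_units(self):
        rel = normalize_relative(table([[1, 1]]))
        with pytest.raises(FeatureTableError):
            normalize_relative(rel)


class TestFilters:
    def test_empty_blacklist_is_identity(self, counts_table):
        out = filter_blacklist(counts_table, set())
        pd.testing.assert_frame_equal(out.data, counts_table.data)

    def test_blacklist_removes_columns_keeps_samples(self, counts_table):
        out = filter_blacklist(counts_table, {"F0", "F3"})
        assert out.feature_ids == ["F1", "F2", "F4", "F5"]
        assert out.sample_ids == counts_table.sample_ids

    def test_unknown_blacklist_ids_warn(self, counts_table):
        with pytest.warns(UserWarning):
            filter_blacklist(counts_table, {"nope"})

    def test_blacklisting_everything_errors(self, counts_table):
        with pytest.raises(FeatureTableError):
            filter_blacklist(counts_table, set(counts_table.feature_ids))

    def test_prevalence_boundary_is_strict(self):
        # 10 samples: a feature in exactly 1 sample (10%) is dropped,
        # one in 2 samples (20%) is retained.
        rows = np.zeros((10, 3))
        rows[:, 0] = 1  # everywhere
        rows[0, 1] = 1  # 1/10 == boundary -> dropped
        rows[0, 2] = rows[1, 2] = 1  # 2/10 -> kept
        out = filter_prevalence(table(rows), min_fraction=0.10)
        assert out.feature_ids == ["F0", "F2"]

    def test_prevalence_idempotent(self, counts_table):
        once = filter_prevalence(counts_table, 0.3)
        twice = filter_prevalence(once, 0.3)
        pd.testing.assert_frame_equal(once.data, twice.data)


class TestLogit:
    def test_half_maps_to_zero(self):
        out = logit_transform(table([[0.5, 0.5]], units="relative"))
        np.testing.assert_allclose(out.values, 0.0, atol=1e-12)

    def test_formula_at_point_one(self):
        out = logit_transform(table([[0.1, 0.9]], units="relative"))
        assert out.values[0, 0] == pytest.approx(np.log(1 / 9), abs=1e-5)

    def test_zero_clamped_to_epsilon_floor(self):
        out = logit_transform(table([[0.0, 1.0]], units="relative"))
        assert out.values[0, 0] == pytest.approx(np.log(1e-6 / (1 - 1e-6)), abs=1e-5)
        assert out.values[0, 0] == pytest.approx(-13.81551, abs=1e-4)

    def test_unit_mismatch_errors(self):
        with pytest.raises(FeatureTableError, match="relative"):
            logit_transform(table([[1, 2]], units="counts"))

    @given(st.floats(min_value=1e-5, max_value=1 - 1e-5))
    @settings(max_examples=50, deadline=None)
    def test_antisymmetric_about_half(self, x):
        t = table([[x, 1 - x]], units="relative")
        out = logit_transform(t).values[0]
        assert out[0] == pytest.approx(-out[1], rel=1e-9, abs=1e-9)


class TestLog10:
    def test_zero_maps_exactly_to_zero(self):
        out = log10_transform(table([[0.0, 0.5]], units="relative"))
        assert out.values[0, 0] == 0.0

    def test_formula_at_one(self):
        out = log10_transform(table([[1.0]], units="relative"))
        assert out.values[0, 0] == pytest.approx(np.log10(1 + 1e-6) + 6, abs=1e-12)

    @given(
        st.floats(min_value=0, max_value=100),
        st.floats(min_value=1e-7, max_value=100),
    )
    @settings(max_examples=50, deadline=None)
    def test_strictly_monotone(self, x, dx):
        out = log10_transform(table([[x, x + dx]], units="intensity"))
        assert out.values[0, 0] < out.values[0, 1]

    def test_negative_entries_error(self):
        t = FeatureTable(pd.DataFrame([[-0.1, 1.0]], index=["S0"], columns=["a", "b"]),
                         units="intensity")
        with pytest.raises(FeatureTableError):
            log10_transform(t)


class TestHellinger:
    def test_equal_row(self):
        out = hellinger_transform(table([[1, 1]]))
        np.testing.assert_allclose(out.values, np.sqrt(0.5))

    def test_single_support(self):
        out = hellinger_transform(table([[4, 0]]))
        np.testing.assert_allclose(out.values, [[1, 0]])

    def test_rows_have_unit_sum_of_squares(self, counts_table):
        out = hellinger_transform(counts_table)
        np.testing.assert_allclose((out.values**2).sum(axis=1), 1.0, atol=1e-12)

    def test_all_zero_row_errors(self):
        with pytest.raises(FeatureTableError, match="S1"):
            hellinger_transform(table([[1, 2], [0, 0]]))


class TestTaxonomy:
    TAX = {
        "F0": "k__Fungi;p__Ascomycota;c__;o__;f__;g__Candida;s__Candida_sp1",
        "F1": "k__Fungi;p__Ascomycota;c__;o__;f__;g__Candida;s__Candida_sp2",
        "F2": "k__Fungi;p__Basidiomycota;c__;o__;f__;g__;s__",
    }

    def test_parse_lineage_ranks(self):
        ranks = parse_lineage(self.TAX["F0"])
        assert ranks["kingdom"] == "Fungi"
        assert ranks["genus"] == "Candida"
        assert ranks["class"] == ""

    def test_same_genus_columns_sum(self):
        t = table([[1, 2, 5], [3, 4, 6]], features=["F0", "F1", "F2"])
        out = aggregate_taxonomy(t, self.TAX, "genus")
        assert set(out.feature_ids) == {"Candida", "unclassified"}
        np.testing.assert_allclose(out.data["Candida"], [3, 7])
        np.testing.assert_allclose(out.data["unclassified"], [5, 6])

    def test_per_sample_totals_conserved(self, counts_table):
        tax = {f: self.TAX["F0"] for f in counts_table.feature_ids}
        out = aggregate_taxonomy(counts_table, tax, "genus")
        np.testing.assert_allclose(
            out.values.sum(axis=1), counts_table.values.sum(axis=1)
        )

    def test_missing_feature_is_named(self, counts_table):
        tax = {f: self.TAX["F0"] for f in counts_table.feature_ids[:-1]}
        with pytest.raises(KeyError, match="F5"):
            aggregate_taxonomy(counts_table, tax, "genus")


def test_pipeline_order_recorded_in_provenance(counts_table):
    out = logit_transform(filter_prevalence(normalize_relative(counts_table)))
    steps = [s.split("(")[0] for s in out.provenance]
    assert steps == ["normalize_relative", "filter_prevalence", "logit_transform"]
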