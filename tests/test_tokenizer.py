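"""Hourly binning, forward-fill imputation and feature encoding."""

import numpy as np
import pytest
from hypothesis import HealthCheck, given, settings
from hypothesis import strategies as st

from icufusion.nn import Linear
from icufusion.schema import default_schema, drop_all_missing_items
from icufusion.tokenizer import (
    ClinicalEventStream,
    ClinicalMatrix,
    FeatureScaler,
    bin_events,
    encode,
    impute,
    project_tokens,
    streams_from_csv,
    streams_to_csv,
)


class TestBinEvents:
    def test_last_event_within_bin_wins(self, toy_schema):
        stream = ClinicalEventStream("s1", [("heart rate", 0.2, 80), ("heart rate", 0.9, 90)])
        m = bin_events(stream, toy_schema, T=48)
        assert m.values[0, 0] == 90
        assert m.observed[0, 0]

    def test_event_at_horizon_is_discarded(self, toy_schema):
        stream = ClinicalEventStream("s1", [("heart rate", 48.0, 100)])
        m = bin_events(stream, toy_schema, T=48)
        assert not m.observed[0, 47]
        assert not m.observed.any()

    def test_empty_stream_gives_all_false_mask(self, toy_schema):
        m = bin_events(ClinicalEventStream("s1", []), toy_schema, T=48)
        assert m.values.shape == (3, 48)
        assert not m.observed.any()
        assert np.isnan(m.values).all()

    def test_unsorted_events_resolve_by_time(self, toy_schema):
        stream = ClinicalEventStream(
            "s1", [("heart rate", 3.9, 70), ("heart rate", 3.1, 95)]
        )
        m = bin_events(stream, toy_schema, T=8)
        assert m.values[0, 3] == 70

    def test_non_numeric_value_errors_with_item_and_time(self, toy_schema):
        stream = ClinicalEventStream("s1", [("heart rate", 2.0, "fast")])
        with pytest.raises(ValueError, match="heart rate.*2.0"):
            bin_events(stream, toy_schema, T=8)

    def test_unknown_item_and_bad_time_error(self, toy_schema):
        with pytest.raises(KeyError):
            bin_events(ClinicalEventStream("s1", [("xx", 0.0, 1)]), toy_schema, T=8)
        with pytest.raises(ValueError):
            bin_events(ClinicalEventStream("s1", [("heart rate", -1.0, 1)]), toy_schema, T=8)

    def test_categorical_value_outside_categories_errors(self, toy_schema):
        stream = ClinicalEventStream("s1", [("gcs eye", 0.0, 7)])
        with pytest.raises(ValueError, match="gcs eye"):
            bin_events(stream, toy_schema, T=8)


class TestImpute:
    def test_unobserved_item_takes_schema_default_everywhere(self, paper_schema):
        usable = drop_all_missing_items(paper_schema)
        m = impute(bin_events(ClinicalEventStream("s", []), usable, T=48), usable)
        fio2 = usable.index("fraction inspired oxygen")
        assert np.all(m.values[fio2] == 0.21)
        assert m.observed.all()

    def test_default_before_first_observation_then_forward_fill(self, paper_schema):
        usable = drop_all_missing_items(paper_schema)
        stream = ClinicalEventStream(
            "s", [("glasgow coma scale eye opening", 5.2, 3)]
        )
        m = impute(bin_events(stream, usable, T=48), usable)
        row = usable.index("glasgow coma scale eye opening")
        assert np.all(m.values[row, :5] == 4)  # schema default
        assert np.all(m.values[row, 5:] == 3)  # carried forward

    def test_fully_observed_row_is_unchanged(self, toy_schema, rng):
        events = [("heart rate", t + 0.5, 60 + t) for t in range(8)]
        binned = bin_events(ClinicalEventStream("s", events), toy_schema, T=8)
        m = impute(binned, toy_schema)
        assert np.array_equal(m.values[0], binned.values[0])

    def test_impute_is_idempotent(self, toy_schema):
        stream = ClinicalEventStream("s", [("heart rate", 10.5, 99), ("gcs eye", 3.0, 2)])
        once = impute(bin_events(stream, toy_schema, T=48), toy_schema)
        twice = impute(once, toy_schema)
        assert np.array_equal(once.values, twice.values)

    @settings(deadline=None, max_examples=30,
              suppress_health_check=[HealthCheck.function_scoped_fixture])
    @given(st.data())
    def test_fill_never_propagates_backward(self, toy_schema, data):
        """Adding or permuting events after bin t never changes bins < t."""
        t_cut = data.draw(st.integers(min_value=1, max_value=10))
        early = [("heart rate", float(t) + 0.25, 60 + t)
                 for t in data.draw(st.lists(st.integers(0, 10), max_size=5))
                 if t < t_cut]
        late_times = data.draw(
            st.lists(st.floats(min_value=float(t_cut), max_value=47.9), max_size=5)
        )
        late = [("heart rate", t, 150.0) for t in late_times]
        base = impute(bin_events(ClinicalEventStream("s", early), toy_schema, T=48), toy_schema)
        full = impute(
            bin_events(ClinicalEventStream("s", early + late), toy_schema, T=48), toy_schema
        )
        assert np.array_equal(base.values[:, :t_cut], full.values[:, :t_cut])


class TestEncode:
    def test_onehot_groups_sum_to_one_each_hour(self, toy_schema):
        stream = ClinicalEventStream("s", [("gcs eye", 2.5, 2)])
        m = impute(bin_events(stream, toy_schema, T=8), toy_schema)
        fm = encode(m, toy_schema, FeatureScaler.identity(toy_schema))
        onehot_rows = [i for i, src in enumerate(fm.source_item) if src == "gcs eye"]
        assert np.allclose(fm.features[onehot_rows].sum(axis=0), 1.0)
        assert fm.F == 2 + 4

    def test_identity_scaler_leaves_continuous_untouched(self, toy_schema):
        stream = ClinicalEventStream("s", [("heart rate", 0.5, 90)])
        m = impute(bin_events(stream, toy_schema, T=8), toy_schema)
        fm = encode(m, toy_schema, FeatureScaler.identity(toy_schema))
        assert fm.features[0, 0] == 90.0

    def test_fitted_scaler_standardises_and_constant_rows_become_zero(self, toy_schema):
        streams = [
            ClinicalEventStream("a", [("heart rate", 0.5, 80)]),
            ClinicalEventStream("b", [("heart rate", 0.5, 92)]),
        ]
        mats = [impute(bin_events(s, toy_schema, T=8), toy_schema) for s in streams]
        scaler = FeatureScaler.fit(mats, toy_schema)
        fm = encode(mats[0], toy_schema, scaler)
        assert fm.features[0, 0] == pytest.approx(-1.0)  # (80-86)/6
        # FiO2 is constant at its default in both stays -> scale clamps, zeros out
        fio2_row = fm.feature_names.index("fraction inspired oxygen")
        assert np.allclose(fm.features[fio2_row], 0.0)

    def test_encode_requires_imputed_matrix(self, toy_schema):
        raw = bin_events(ClinicalEventStream("s", []), toy_schema, T=8)
        with pytest.raises(ValueError):
            encode(raw, toy_schema, FeatureScaler.identity(toy_schema))

    def test_unknown_category_errors(self, toy_schema):
        m = impute(bin_events(ClinicalEventStream("s", []), toy_schema, T=8), toy_schema)
        m.values[2, :] = 9.0  # not a valid gcs eye level
        with pytest.raises(ValueError, match="gcs eye"):
            encode(m, toy_schema, FeatureScaler.identity(toy_schema))


class TestProjectTokens:
    def test_token_count_equals_T_and_width_D(self, toy_schema, rng):
        m = impute(bin_events(ClinicalEventStream("s", []), toy_schema, T=48), toy_schema)
        fm = encode(m, toy_schema, FeatureScaler.identity(toy_schema))
        proj = Linear(fm.F, 8, rng)
        block = project_tokens(fm, proj)
        assert (block.count, block.D, block.modality) == (48, 8, "clinical")

    def test_zero_projection_gives_zero_tokens(self, toy_schema, rng):
        m = impute(bin_events(ClinicalEventStream("s", []), toy_schema, T=8), toy_schema)
        fm = encode(m, toy_schema, FeatureScaler.identity(toy_schema))
        proj = Linear(fm.F, 4, rng)
        proj.weight.data[:] = 0.0
        proj.bias.data[:] = 0.0
        assert np.allclose(project_tokens(fm, proj).tokens.data, 0.0)

    def test_shape_mismatch_errors(self, toy_schema, rng):
        m = impute(bin_events(ClinicalEventStream("s", []), toy_schema, T=8), toy_schema)
        fm = encode(m, toy_schema, FeatureScaler.identity(toy_schema))
        with pytest.raises(ValueError):
            project_tokens(fm, Linear(fm.F + 1, 4, rng))


def test_event_csv_round_trip(tmp_path, toy_schema):
    streams = {
        "s1": ClinicalEventStream("s1", [("heart rate", 0.5, 88.0), ("gcs eye", 1.5, 3.0)]),
        "s2": ClinicalEventStream("s2", [("fraction inspired oxygen", 2.0, 0.4)]),
    }
    path = tmp_path / "events.csv"
    streams_to_csv(streams, path)
    again = streams_from_csv(path)
    assert set(again) == {"s1", "s2"}
    m1 = bin_events(streams["s1"], toy_schema, T=8)
    m2 = bin_events(again["s1"], toy_schema, T=8)
    assert np.array_equal(m1.observed, m2.observed)
    assert np.allclose(m1.values[m1.observed], m2.values[m2.observed])


def test_clinical_matrix_rejects_inband_missing():
    with pytest.raises(ValueError):
        ClinicalMatrix(
            values=np.zeros((1, 4)),
            observed=np.array([[True, False, True, True]]),
            item_names=["x"],
        )
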