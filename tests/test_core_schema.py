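"""Container invariants and core operations (timing, ragged columns,
electrode regions, session slots)."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from _oracles import accumulated_timestamps
from hdml.containers import (
    DynamicTable,
    DynamicTableRegion,
    SessionRoot,
    TimeSeries,
    add_ragged_column,
    add_to_session,
    create_electrical_series,
    get_timestamps,
)
from hdml.errors import InvariantError, NamingError


def _session():
    return SessionRoot(
        session_description="d", identifier="id-1",
        session_start_time="2022-06-01T12:00:00+00:00",
    )


def _electrode_table(n=4):
    t = DynamicTable("electrodes", description="channels")
    t.add_column("x", np.linspace(0, 1, n), description="x")
    return t


class TestTiming:
    def test_rate_form_expands_to_uniform_grid(self):
        ts = TimeSeries("t", np.zeros(3), unit="v", rate=10.0, starting_time=0.5)
        assert np.allclose(get_timestamps(ts), [0.5, 0.6, 0.7], atol=1e-15)

    def test_explicit_timestamps_returned_as_stored(self):
        ts = TimeSeries("t", np.zeros(3), unit="v", timestamps=[0.0, 1.0, 4.0])
        assert get_timestamps(ts).tolist() == [0.0, 1.0, 4.0]

    @given(
        rate=st.floats(min_value=0.5, max_value=10_000, allow_nan=False),
        start=st.floats(min_value=-100, max_value=100, allow_nan=False),
        n=st.integers(min_value=1, max_value=2000),
    )
    @settings(derandomize=True, max_examples=60, deadline=None)
    def test_rate_form_matches_accumulation_oracle(self, rate, start, n):
        ts = TimeSeries("t", np.zeros(n), unit="v", rate=rate, starting_time=start)
        got = get_timestamps(ts)
        expected = np.array(accumulated_timestamps(rate, start, n))
        scale = np.maximum(np.abs(expected), 1.0)
        assert np.all(np.abs(got - expected) / scale <= 1e-12)

    def test_exactly_one_timing_form_enforced(self):
        with pytest.raises(InvariantError, match="exactly one"):
            TimeSeries("t", np.zeros(3), unit="v")
        with pytest.raises(InvariantError, match="exactly one"):
            TimeSeries("t", np.zeros(3), unit="v", rate=1.0, timestamps=[0, 1, 2])

    def test_timestamp_length_and_order_enforced(self):
        with pytest.raises(InvariantError, match="timestamps"):
            TimeSeries("t", np.zeros(3), unit="v", timestamps=[0.0, 1.0])
        with pytest.raises(InvariantError, match="non-decreasing"):
            TimeSeries("t", np.zeros(3), unit="v", timestamps=[0.0, 2.0, 1.0])
        with pytest.raises(InvariantError, match="rate"):
            TimeSeries("t", np.zeros(3), unit="v", rate=-5.0)


class TestRaggedColumns:
    def test_cumulative_index_definition(self):
        t = DynamicTable("t", description="d")
        add_ragged_column(t, "ev", [[1.0], [2.0, 3.0], []])
        assert t.fields["ev"].data.tolist() == [1.0, 2.0, 3.0]
        assert t.fields["ev_index"].data.tolist() == [1, 3, 3]
        rows = t.ragged_rows("ev")
        assert [r.tolist() for r in rows] == [[1.0], [2.0, 3.0], []]

    def test_all_rows_empty(self):
        t = DynamicTable("t", description="d")
        add_ragged_column(t, "ev", [[], [], []])
        assert t.fields["ev"].data.size == 0
        assert t.fields["ev_index"].data.tolist() == [0, 0, 0]

    def test_random_tables_reconstruct_exactly(self):
        for seed in range(50):
            rng = np.random.default_rng(seed)
            n = int(rng.integers(0, 10))
            rows = [rng.normal(size=rng.integers(0, 6)) for _ in range(n)]
            t = DynamicTable("t", description="d")
            add_ragged_column(t, "ev", rows)
            back = t.ragged_rows("ev")
            assert len(back) == n
            for a, b in zip(back, rows):
                assert np.array_equal(a, b)

    def test_row_count_mismatch_rejected(self):
        t = DynamicTable("t", description="d")
        t.add_column("v", np.arange(3), description="d")
        with pytest.raises(InvariantError, match="rows"):
            add_ragged_column(t, "ev", [[1.0]])

    def test_duplicate_column_rejected(self):
        t = DynamicTable("t", description="d")
        t.add_column("v", np.arange(3), description="d")
        with pytest.raises(NamingError):
            t.add_column("v", np.arange(3), description="d")


class TestElectricalSeries:
    def test_consistent_channel_count_accepted(self, reg):
        from hdml.builders import build
        from hdml.validation import validate_builders

        table = _electrode_table(4)
        es = create_electrical_series(
            "es", np.zeros((10, 4)), [0, 1, 2, 3], table, rate=100.0,
            description="raw",
        )
        root = _session()
        add_to_session(root, "electrodes", table)
        add_to_session(root, "acquisition", es)
        issues = validate_builders(build(root, reg), reg)
        assert [i for i in issues if i.severity == "error"] == []

    def test_channel_count_mismatch_rejected(self):
        with pytest.raises(InvariantError, match="channels"):
            create_electrical_series(
                "es", np.zeros((10, 4)), [0, 1], _electrode_table(4), rate=100.0
            )

    def test_out_of_range_rows_rejected(self):
        with pytest.raises(InvariantError, match="rows"):
            DynamicTableRegion("electrodes", [0, 9], _electrode_table(4))


class TestSessionSlots:
    def test_acquisition_and_processing_both_reachable(self):
        root = _session()
        raw = TimeSeries("raw", np.zeros((5, 2)), unit="v", rate=10.0,
                         description="raw")
        dff = TimeSeries("dff", np.zeros(5), unit="n.a.", rate=10.0,
                         description="dff")
        add_to_session(root, "acquisition", raw)
        add_to_session(root, "processing.ophys", dff)
        members = root.all_containers()
        assert raw in members and dff in members
        # raw + dff + the implicit ophys processing module
        assert len(members) == 3

    def test_duplicate_name_in_slot_rejected(self):
        root = _session()
        ts = TimeSeries("a", np.zeros(2), unit="v", rate=1.0)
        add_to_session(root, "acquisition", ts)
        with pytest.raises(NamingError, match="duplicate"):
            add_to_session(root, "acquisition",
                           TimeSeries("a", np.zeros(2), unit="v", rate=1.0))

    def test_unknown_module_lists_allowed_labels(self):
        root = _session()
        ts = TimeSeries("a", np.zeros(2), unit="v", rate=1.0)
        with pytest.raises(NamingError, match="ecephys.*behavior"):
            add_to_session(root, "processing.astro", ts)
        with pytest.raises(NamingError, match="slot"):
            add_to_session(root, "general", ts)

    def test_random_insertions_reachable_set_equals_inserted_set(self):
        slots = ["acquisition", "stimulus", "processing.ecephys",
                 "processing.ophys", "processing.behavior"]
        for seed in range(20):
            rng = np.random.default_rng(seed)
            root = _session()
            inserted = []
            for i in range(int(rng.integers(1, 8))):
                ts = TimeSeries(f"s{i}", np.zeros(2), unit="v", rate=1.0)
                add_to_session(root, slots[rng.integers(len(slots))], ts)
                inserted.append(ts)
            reachable = root.all_containers()
            assert {id(c) for c in inserted} <= {id(c) for c in reachable}
            modules = [c for c in reachable if c.neurodata_type == "ProcessingModule"]
            assert len(reachable) == len(inserted) + len(modules)

    def test_identifier_must_be_nonempty(self):
        with pytest.raises(InvariantError):
            SessionRoot(session_description="d", identifier="",
                        session_start_time="2022-01-01T00:00:00+00:00")
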