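import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import helpers
from qcstore import connect, new_analysis
from qcstore.exceptions import ScopeError, ValidationError
from qcstore.reports import (
    PropertyFilter,
    ReportTable,
    get_average_values,
    get_per_partition_values,
    get_per_position_base_content,
    get_per_position_values,
    get_summary_values_with_comments,
    list_runs,
    list_selectable_properties,
    list_selectable_values_from_property,
    list_summary_per_scope,
)


def insert_with_props(store, values=(), **props):
    """Insert a small analysis: props + general value pairs (key, value)."""
    a = new_analysis()
    for k, v in props.items():
        a.add_property(k, v)
    for key, value in values:
        a.add_valid_type(key, "analysis")
        a.add_general_value(key, value)
    return store.insert_analysis(a)


class TestPropertyFilter:
    def test_empty_filter_legal(self):
        assert len(PropertyFilter()) == 0

    def test_only_controlled_keys(self):
        with pytest.raises(ValidationError):
            PropertyFilter(casava_version="1.8.2")

    def test_key_translation(self):
        f = PropertyFilter(sampleName="S1", softwareOnInstrument="RTA",
                           typeOfExperiment="WGS")
        assert f.to_properties() == {
            "sample_name": "S1", "software": "RTA", "type": "WGS"
        }


class TestListQueries:
    def test_list_runs_empty(self, store):
        assert list_runs(store) == []

    def test_list_runs_distinct_sorted(self, store):
        for run in ("R1", "R1", "R2"):
            insert_with_props(store, run=run)
        assert list_runs(store) == ["R1", "R2"]

    def test_list_runs_matches_brute_force(self, store):
        rng = np.random.default_rng(5)
        mirrors = helpers.populate_random_store(store, rng)
        expected = sorted({m.properties["run"] for m in mirrors})
        assert list_runs(store) == expected

    def test_selectable_properties(self, store):
        assert list_selectable_properties(store) == []
        insert_with_props(store, lane="1", run="R1", casava_version="1.8.2")
        props = list_selectable_properties(store)
        assert "lane" in props and "run" in props
        assert "casava_version" not in props

    def test_selectable_values(self, store):
        for lane in ("1", "2", "1"):
            insert_with_props(store, lane=lane)
        assert list_selectable_values_from_property(store, "lane") == ["1", "2"]

    def test_selectable_values_unmultiplexed(self, store):
        insert_with_props(store, run="R1")
        assert list_selectable_values_from_property(store, "barcode") == []

    def test_selectable_values_unknown_key(self, store):
        with pytest.raises(ValidationError):
            list_selectable_values_from_property(store, "casava_version")

    def test_summary_per_scope(self, store, worked_analysis):
        store.insert_analysis(worked_analysis)
        table = list_summary_per_scope(store, "base_partition")
        assert ["quality_mean", None] in table.rows

    def test_summary_per_scope_registered_once(self, store, worked_analysis):
        store.insert_analysis(worked_analysis)
        store.insert_analysis(worked_analysis)
        keys = [r[0] for r in list_summary_per_scope(store, "sequence_cumulative").rows]
        assert keys == ["quality_score_count"]

    def test_summary_per_scope_bad_scope(self, store):
        with pytest.raises(ScopeError):
            list_summary_per_scope(store, "per_tile")

    def test_summary_per_scope_empty(self, store):
        assert list_summary_per_scope(store, "analysis").rows == []


class TestAverageValues:
    def test_single_analysis(self, store, worked_analysis, full_filter):
        store.insert_analysis(worked_analysis)
        rows = {r[0]: r for r in get_average_values(store, full_filter).rows}
        assert rows["average_length"][1] == pytest.approx(100)
        assert rows["average_length"][2] == 1

    def test_mean_across_two_analyses(self, store):
        # two analyses sharing an instrument, distinct runs
        insert_with_props(store, values=[("general_gc_content", 40)],
                          instrument="M1", run="R1")
        insert_with_props(store, values=[("general_gc_content", 60)],
                          instrument="M1", run="R2")
        table = get_average_values(store, PropertyFilter(instrument="M1"))
        assert table.rows == [["general_gc_content", pytest.approx(50.0), 2]]
        assert table.n_analyses == 2

    def test_empty_store(self, store):
        table = get_average_values(store, PropertyFilter())
        assert table.rows == [] and table.n_analyses == 0

    def test_text_values_counted_not_averaged(self, store):
        a = new_analysis()
        a.add_property("run", "R1")
        a.add_valid_type("basic_statistics_status", "analysis")
        a.add_general_value("basic_statistics_status", "pass")
        store.insert_analysis(a)
        table = get_average_values(store)
        assert table.rows == [["basic_statistics_status", None, 1]]


class TestPerPositionValues:
    def test_worked_example(self, store, worked_analysis, full_filter):
        store.insert_analysis(worked_analysis)
        table = get_per_position_values(store, "quality_score_count", full_filter)
        assert table.rows == [[30, pytest.approx(15000), 1]]

    def test_mean_of_two_runs(self, store):
        for run, count in (("R1", 10), ("R2", 20)):
            a = new_analysis()
            a.add_property("run", run)
            a.add_property("lane", "1")
            a.add_valid_type("quality_score_count", "sequence_cumulative")
            a.add_position_value(5, "quality_score_count", count)
            store.insert_analysis(a)
        table = get_per_position_values(
            store, "quality_score_count", PropertyFilter(lane="1")
        )
        assert table.rows == [[5, pytest.approx(15.0), 2]]

    def test_scope_guard(self, store, worked_analysis):
        store.insert_analysis(worked_analysis)
        with pytest.raises(ScopeError) as exc:
            get_per_position_values(store, "quality_mean")
        assert "quality_mean" in str(exc.value)


class TestPerPartitionValues:
    def test_worked_example(self, store, worked_analysis, full_filter):
        store.insert_analysis(worked_analysis)
        table = get_per_partition_values(store, "quality_mean", full_filter)
        assert table.rows == [[10, 14, pytest.approx(38.7), 1]]

    def test_mean_over_identical_partition(self, store):
        for run, value in (("R1", 30), ("R2", 40)):
            a = new_analysis()
            a.add_property("run", run)
            a.add_valid_type("quality_mean", "base_partition")
            a.add_partition_value((1, 1), "quality_mean", value)
            store.insert_analysis(a)
        table = get_per_partition_values(store, "quality_mean")
        assert table.rows == [[1, 1, pytest.approx(35.0), 2]]

    def test_differing_partitions_not_blended(self, store):
        for run, rng in (("R1", (1, 5)), ("R2", (1, 4))):
            a = new_analysis()
            a.add_property("run", run)
            a.add_valid_type("quality_mean", "base_partition")
            a.add_partition_value(rng, "quality_mean", 10.0)
            store.insert_analysis(a)
        table = get_per_partition_values(store, "quality_mean")
        assert [(r[0], r[1], r[3]) for r in table.rows] == [(1, 4, 1), (1, 5, 1)]

    def test_empty_store(self, store):
        assert get_per_partition_values(store, "quality_mean").rows == []

    def test_scope_guard(self, store, worked_analysis):
        store.insert_analysis(worked_analysis)
        with pytest.raises(ScopeError):
            get_per_partition_values(store, "quality_score_count")


class TestSummaryWithComments:
    def test_primer_example(self, store, worked_analysis, full_filter):
        store.insert_analysis(worked_analysis)
        rows = {r[0]: r for r in
                get_summary_values_with_comments(store, "analysis", full_filter).rows}
        assert rows["ACCTGATAT"] == [
            "ACCTGATAT", pytest.approx(10), "over-represented common primer in library A", 1
        ]

    def test_value_without_description(self, store, worked_analysis, full_filter):
        store.insert_analysis(worked_analysis)
        rows = {r[0]: r for r in
                get_summary_values_with_comments(store, "analysis", full_filter).rows}
        assert rows["average_length"][2] is None

    def test_latest_wins_under_full_filter(self, store, full_filter):
        # two-insert oracle: only the second insert's value may appear
        for value in (1.0, 2.0):
            a = new_analysis()
            for k, v in zip(("run", "lane", "pair", "barcode", "sample_name"),
                            ("RUN-123", "1", "1", "ACCGTT", "SAMPLE-1")):
                a.add_property(k, v)
            a.add_valid_type("k", "analysis")
            a.add_general_value("k", value, "desc")
            store.insert_analysis(a)
        rows = get_summary_values_with_comments(store, "analysis", full_filter).rows
        assert rows == [["k", pytest.approx(2.0), "desc", 1]]

    def test_invalid_scope(self, store):
        with pytest.raises(ScopeError):
            get_summary_values_with_comments(store, "nope")


class TestBaseContent:
    def make_content_analysis(self, run, values):
        a = new_analysis()
        a.add_property("run", run)
        for base, value in values.items():
            key = f"base_content_{base.lower()}"
            a.add_valid_type(key, "base_partition")
            a.add_partition_value((1, 1), key, value)
        return a

    def test_matrix_equals_four_joined_queries(self, store):
        store.insert_analysis(
            self.make_content_analysis("R1", {"A": 25.0, "C": 24.0, "G": 26.0, "T": 25.0})
        )
        table = get_per_position_base_content(store)
        assert table.columns == ["start", "end", "A", "C", "G", "T"]
        per_base = {
            base: get_per_partition_values(store, f"base_content_{base.lower()}").rows
            for base in "ACGT"
        }
        for row in table.rows:
            start, end = row[0], row[1]
            for i, base in enumerate("ACGT"):
                match = [r for r in per_base[base] if (r[0], r[1]) == (start, end)]
                assert row[2 + i] == pytest.approx(match[0][2])

    def test_missing_base_gives_empty_cell(self, store):
        store.insert_analysis(self.make_content_analysis("R1", {"A": 25.0}))
        table = get_per_position_base_content(store)
        assert table.rows == [[1, 1, 25.0, None, None, None]]

    def test_empty_store(self, store):
        assert get_per_position_base_content(store).rows == []


class TestAggregationOracle:
    """Randomized store states checked against the brute-force scanner."""

    @pytest.mark.parametrize("seed", range(20))
    def test_random_states(self, seed):
        rng = np.random.default_rng(seed)
        with connect(":memory:") as store:
            mirrors = helpers.populate_random_store(store, rng)
            for _ in range(3):
                entries = helpers.random_filter(rng)
                flt = PropertyFilter(entries)
                latest = helpers.brute_latest(mirrors, entries)

                got = {r[0]: (r[1], r[2]) for r in get_average_values(store, flt).rows}
                expected = helpers.brute_averages(latest)
                assert got.keys() == expected.keys()
                for key, (mean, n) in expected.items():
                    if mean is None:
                        assert got[key][0] is None
                    else:
                        assert got[key][0] == pytest.approx(mean, abs=1e-9)
                    assert got[key][1] == n

                for key in helpers.POSITION_KEYS:
                    got_pos = {
                        r[0]: (r[1], r[2])
                        for r in get_per_position_values(store, key, flt).rows
                    }
                    exp_pos = helpers.brute_positions(latest, key)
                    assert got_pos.keys() == exp_pos.keys()
                    for pos, (mean, n) in exp_pos.items():
                        assert got_pos[pos][0] == pytest.approx(mean, abs=1e-9)
                        assert got_pos[pos][1] == n

                for key in helpers.PARTITION_KEYS:
                    got_part = {
                        (r[0], r[1]): (r[2], r[3])
                        for r in get_per_partition_values(store, key, flt).rows
                    }
                    exp_part = helpers.brute_partitions(latest, key)
                    assert got_part.keys() == exp_part.keys()
                    for se, (mean, n) in exp_part.items():
                        assert got_part[se][0] == pytest.approx(mean, abs=1e-9)
                        assert got_part[se][1] == n

    @pytest.mark.parametrize("seed", range(5))
    def test_filter_monotonicity(self, seed):
        """Adding a constraint never increases any row's n."""
        rng = np.random.default_rng(100 + seed)
        with connect(":memory:") as store:
            helpers.populate_random_store(store, rng)
            base = {"run": "R1"}
            tighter = {"run": "R1", "lane": "1"}
            for key in helpers.PARTITION_KEYS:
                loose = {
                    (r[0], r[1]): r[3]
                    for r in get_per_partition_values(store, key, PropertyFilter(base)).rows
                }
                tight = get_per_partition_values(store, key, PropertyFilter(tighter)).rows
                for r in tight:
                    assert r[3] <= loose[(r[0], r[1])]


# ---------------------------------------------------------------------------
# serialization

cell_strategy = st.one_of(
    st.none(),
    st.integers(-10**9, 10**9),
    # floats representable in <= 10 significant digits survive %.10g
    st.floats(-1000, 1000, allow_nan=False).map(lambda v: float(f"{v:.6f}")),
    st.text(
        alphabet=st.characters(blacklist_categories=("Cs", "Cc")), min_size=1, max_size=20
    ).filter(lambda s: s.strip() == s and s != "" and _not_numeric(s)),
)


def _not_numeric(s):
    try:
        float(s)
        return False
    except (ValueError, OverflowError):
        return True


@st.composite
def report_tables(draw):
    n_cols = draw(st.integers(1, 5))
    columns = [f"col_{i}" for i in range(n_cols)]
    rows = draw(
        st.lists(st.lists(cell_strategy, min_size=n_cols, max_size=n_cols), max_size=8)
    )
    return ReportTable(columns=columns, rows=rows, n_analyses=draw(st.integers(0, 10)))


class TestReportTable:
    def test_empty_table_csv(self):
        t = ReportTable(columns=["a", "b"])
        assert t.to_csv() == "a,b\n"

    def test_empty_table_json(self):
        t = ReportTable(columns=["a"])
        assert t.to_json() == '{"columns": ["a"], "rows": [], "n_analyses": 0}'

    def test_comma_bearing_cell_quoted(self):
        t = ReportTable(columns=["key", "description"],
                        rows=[["k", "a, b and c"]])
        assert '"a, b and c"' in t.to_csv()

    def test_ragged_row_rejected(self):
        with pytest.raises(ValidationError):
            ReportTable(columns=["a", "b"], rows=[[1]])

    @given(report_tables())
    @settings(max_examples=50)
    def test_csv_round_trip(self, table):
        parsed = ReportTable.from_csv(table.to_csv(), n_analyses=table.n_analyses)
        assert parsed == table

    @given(report_tables())
    @settings(max_examples=50)
    def test_json_round_trip(self, table):
        assert ReportTable.from_json(table.to_json()) == table
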