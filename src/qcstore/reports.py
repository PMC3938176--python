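"""Consumer-facing query layer.

All queries take a :class:`PropertyFilter` of controlled, platform-agnostic
keys; any subset (including none) may be given. When more than one analysis
matches, an unweighted arithmetic mean across analyses is returned together
with the contributing count ``n``. Re-runs of the same analysis identity are
always resolved to the newest record before aggregating, so a fully-specified
filter returns exactly the latest analysis's values.

Results come back as :class:`ReportTable` objects serializable to RFC-4180
CSV or to plot-ready JSON (``{"columns": ..., "rows": ..., "n_analyses": ...}``).
"""

from __future__ import annotations

import csv
import io
import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Union

from .datastore import Store, _in_clause
from .exceptions import ScopeError, ValidationError
from .model import SCOPES, SCOPE_ANALYSIS, SCOPE_BASE_PARTITION, SCOPE_SEQUENCE_CUMULATIVE

__all__ = [
    "CONTROLLED_KEYS",
    "PropertyFilter",
    "ReportTable",
    "list_runs",
    "list_selectable_properties",
    "list_selectable_values_from_property",
    "list_summary_per_scope",
    "get_average_values",
    "get_per_position_values",
    "get_per_partition_values",
    "get_summary_values_with_comments",
    "get_per_position_base_content",
]

#: Controlled query keys mapped to the stored property name each selects on.
CONTROLLED_KEYS: dict[str, str] = {
    "encoding": "encoding",
    "chemistry": "chemistry",
    "instrument": "instrument",
    "softwareOnInstrument": "software",
    "typeOfExperiment": "type",
    "pair": "pair",
    "sampleName": "sample_name",
    "lane": "lane",
    "barcode": "barcode",
    "run": "run",
}


class PropertyFilter(Mapping):
    """A subset of the ten controlled query keys with their required values.

    An empty filter is legal and matches every analysis.
    """

    def __init__(self, entries: Optional[Mapping[str, str]] = None, **kwargs: str):
        merged = dict(entries or {})
        merged.update(kwargs)
        for key in merged:
            if key not in CONTROLLED_KEYS:
                raise ValidationError(
                    f"unknown filter key {key!r}; allowed keys: "
                    + ", ".join(sorted(CONTROLLED_KEYS))
                )
        self._entries = {k: str(v) for k, v in merged.items() if v is not None}

    def __getitem__(self, key: str) -> str:
        return self._entries[key]

    def __iter__(self):
        return iter(self._entries)

    def __len__(self) -> int:
        return len(self._entries)

    def __repr__(self) -> str:
        return f"PropertyFilter({self._entries!r})"

    def to_properties(self) -> dict[str, str]:
        """Translate controlled keys into stored property names."""
        return {CONTROLLED_KEYS[k]: v for k, v in self._entries.items()}


def _fmt_cell(cell) -> str:
    if cell is None:
        return ""
    if isinstance(cell, float):
        if math.isnan(cell):
            return ""
        return format(cell, ".10g")
    return str(cell)


def _parse_cell(text: str):
    if text == "":
        return None
    try:
        return int(text)
    except ValueError:
        pass
    try:
        return float(text)
    except ValueError:
        return text


def _cells_equal(a, b) -> bool:
    if a is None or b is None:
        return a is None and b is None
    if isinstance(a, (int, float)) and isinstance(b, (int, float)):
        return a == b
    return str(a) == str(b)


@dataclass
class ReportTable:
    """Ordered columns plus rows of numeric-or-text cells.

    ``n_analyses`` records how many analyses were aggregated (provenance).
    """

    columns: list[str]
    rows: list[list] = field(default_factory=list)
    n_analyses: int = 0

    def __post_init__(self) -> None:
        for row in self.rows:
            if len(row) != len(self.columns):
                raise ValidationError(
                    f"row has {len(row)} cells but table has {len(self.columns)} columns"
                )

    def __eq__(self, other) -> bool:
        if not isinstance(other, ReportTable):
            return NotImplemented
        return (
            self.columns == other.columns
            and self.n_analyses == other.n_analyses
            and len(self.rows) == len(other.rows)
            and all(
                len(r1) == len(r2) and all(_cells_equal(a, b) for a, b in zip(r1, r2))
                for r1, r2 in zip(self.rows, other.rows)
            )
        )

    def to_csv(self) -> str:
        buf = io.StringIO()
        writer = csv.writer(buf, lineterminator="\n")
        writer.writerow(self.columns)
        for row in self.rows:
            writer.writerow([_fmt_cell(c) for c in row])
        return buf.getvalue()

    def to_json(self) -> str:
        return json.dumps(
            {"columns": self.columns, "rows": self.rows, "n_analyses": self.n_analyses}
        )

    @classmethod
    def from_csv(cls, text: str, n_analyses: int = 0) -> "ReportTable":
        reader = csv.reader(io.StringIO(text))
        try:
            columns = next(reader)
        except StopIteration:
            raise ValidationError("CSV text has no header line")
        rows = [[_parse_cell(c) for c in row] for row in reader]
        return cls(columns=columns, rows=rows, n_analyses=n_analyses)

    @classmethod
    def from_json(cls, text: str) -> "ReportTable":
        obj = json.loads(text)
        return cls(
            columns=list(obj["columns"]),
            rows=[list(r) for r in obj["rows"]],
            n_analyses=int(obj.get("n_analyses", 0)),
        )


# ---------------------------------------------------------------------------
# listing queries


def list_runs(store: Store) -> list[str]:
    """Distinct run names present in the store, sorted."""
    rows = store.conn.execute(
        "SELECT DISTINCT value FROM analysis_property WHERE property = 'run' "
        "AND value IS NOT NULL ORDER BY value"
    )
    return [r[0] for r in rows]


def list_selectable_properties(store: Store) -> list[str]:
    """Controlled query keys whose underlying property occurs in the store."""
    present = {
        r[0] for r in store.conn.execute("SELECT DISTINCT property FROM analysis_property")
    }
    return sorted(k for k, prop in CONTROLLED_KEYS.items() if prop in present)


def list_selectable_values_from_property(store: Store, prop: str) -> list[str]:
    """Distinct stored values of a controlled query key, sorted."""
    if prop not in CONTROLLED_KEYS:
        raise ValidationError(
            f"{prop!r} is not a selectable property; allowed: "
            + ", ".join(sorted(CONTROLLED_KEYS))
        )
    rows = store.conn.execute(
        "SELECT DISTINCT value FROM analysis_property WHERE property = ? "
        "AND value IS NOT NULL ORDER BY value",
        (CONTROLLED_KEYS[prop],),
    )
    return [r[0] for r in rows]


def list_summary_per_scope(store: Store, scope: str) -> ReportTable:
    """Registered value types of one scope with their (first) descriptions."""
    if scope not in SCOPES:
        raise ScopeError(f"unknown scope {scope!r}; valid scopes are {', '.join(SCOPES)}")
    rows = store.conn.execute(
        "SELECT vt.value_key, vt.description FROM value_type vt "
        "JOIN type_scope ts ON ts.id = vt.type_scope_id "
        "WHERE ts.scope = ? ORDER BY vt.value_key",
        (scope,),
    )
    return ReportTable(columns=["key", "description"], rows=[list(r) for r in rows])


# ---------------------------------------------------------------------------
# summary queries


def _latest_ids(store: Store, f: Optional[PropertyFilter]) -> list[int]:
    f = f if f is not None else PropertyFilter()
    return store.latest_analysis_ids(f.to_properties())


def _guard_scope(store: Store, key: str, expected: str, query_hint: str) -> None:
    scope = store.scope_of(key)
    if scope is not None and scope != expected:
        raise ScopeError(
            f"value type {key!r} has scope {scope!r}, not {expected!r}; "
            f"use the {query_hint} query instead"
        )


def get_average_values(store: Store, f: Optional[PropertyFilter] = None) -> ReportTable:
    """Summary of analysis-scope (global) values across matching analyses.

    One row per value-type key: (key, mean of numeric values, n analyses
    contributing). Non-numeric values are excluded from means and show up in
    ``n`` only.
    """
    ids = _latest_ids(store, f)
    table = ReportTable(columns=["key", "mean", "n"], n_analyses=len(ids))
    if not ids:
        return table
    rows = store.conn.execute(
        "SELECT vt.value_key, AVG(av.value), COUNT(DISTINCT av.analysis_id) "
        "FROM analysis_value av JOIN value_type vt ON vt.id = av.value_type_id "
        f"WHERE av.analysis_id IN ({_in_clause(ids)}) "
        "GROUP BY vt.value_key ORDER BY vt.value_key"
    )
    table.rows = [[key, mean, n] for key, mean, n in rows]
    return table


def get_per_position_values(
    store: Store, key: str, f: Optional[PropertyFilter] = None
) -> ReportTable:
    """Per-position summary of a sequence_cumulative metric.

    Rows are (position, mean across matching analyses, n), ordered by position.
    """
    _guard_scope(store, key, SCOPE_SEQUENCE_CUMULATIVE, "partition/global")
    ids = _latest_ids(store, f)
    table = ReportTable(columns=["position", "mean", "n"], n_analyses=len(ids))
    if not ids:
        return table
    rows = store.conn.execute(
        "SELECT pv.position, AVG(pv.value), COUNT(DISTINCT pv.analysis_id) "
        "FROM per_position_value pv JOIN value_type vt ON vt.id = pv.value_type_id "
        f"WHERE vt.value_key = ? AND pv.analysis_id IN ({_in_clause(ids)}) "
        "GROUP BY pv.position ORDER BY pv.position",
        (key,),
    )
    table.rows = [[pos, mean, n] for pos, mean, n in rows]
    return table


def get_per_partition_values(
    store: Store, key: str, f: Optional[PropertyFilter] = None
) -> ReportTable:
    """Per-partition summary of a base_partition metric.

    Rows are (start, end, mean, n) grouped by identical (start, end) pairs;
    analyses partitioned differently contribute separate rows rather than
    being blended.
    """
    _guard_scope(store, key, SCOPE_BASE_PARTITION, "position/global")
    ids = _latest_ids(store, f)
    table = ReportTable(columns=["start", "end", "mean", "n"], n_analyses=len(ids))
    if not ids:
        return table
    rows = store.conn.execute(
        "SELECT pv.position_start, pv.position_end, AVG(pv.value), "
        "COUNT(DISTINCT pv.analysis_id) "
        "FROM per_partition_value pv JOIN value_type vt ON vt.id = pv.value_type_id "
        f"WHERE vt.value_key = ? AND pv.analysis_id IN ({_in_clause(ids)}) "
        "GROUP BY pv.position_start, pv.position_end "
        "ORDER BY pv.position_start, pv.position_end",
        (key,),
    )
    table.rows = [[start, end, mean, n] for start, end, mean, n in rows]
    return table


def get_summary_values_with_comments(
    store: Store, scope: str, f: Optional[PropertyFilter] = None
) -> ReportTable:
    """Summary values of one scope with each value type's description.

    Rows are (key, value, description, n); the value is the mean of numeric
    values, or the latest text value when a key holds only text; description
    is empty when none was ever stored.
    """
    if scope not in SCOPES:
        raise ScopeError(f"unknown scope {scope!r}; valid scopes are {', '.join(SCOPES)}")
    ids = _latest_ids(store, f)
    table = ReportTable(columns=["key", "value", "description", "n"], n_analyses=len(ids))
    if not ids:
        return table
    clause = _in_clause(ids)
    if scope == SCOPE_ANALYSIS:
        sql = (
            "SELECT vt.value_key, AVG(av.value), MAX(av.text_value), vt.description, "
            "COUNT(DISTINCT av.analysis_id) "
            "FROM analysis_value av JOIN value_type vt ON vt.id = av.value_type_id "
            "JOIN type_scope ts ON ts.id = vt.type_scope_id "
            f"WHERE ts.scope = ? AND av.analysis_id IN ({clause}) "
            "GROUP BY vt.value_key ORDER BY vt.value_key"
        )
        rows = [
            [key, mean if mean is not None else text, desc, n]
            for key, mean, text, desc, n in store.conn.execute(sql, (scope,))
        ]
    else:
        value_table = (
            "per_partition_value" if scope == SCOPE_BASE_PARTITION else "per_position_value"
        )
        sql = (
            f"SELECT vt.value_key, AVG(v.value), vt.description, "
            "COUNT(DISTINCT v.analysis_id) "
            f"FROM {value_table} v JOIN value_type vt ON vt.id = v.value_type_id "
            "JOIN type_scope ts ON ts.id = vt.type_scope_id "
            f"WHERE ts.scope = ? AND v.analysis_id IN ({clause}) "
            "GROUP BY vt.value_key ORDER BY vt.value_key"
        )
        rows = [list(r) for r in store.conn.execute(sql, (scope,))]
    table.rows = rows
    return table


_BASE_CONTENT_KEYS = {
    "A": "base_content_a",
    "C": "base_content_c",
    "G": "base_content_g",
    "T": "base_content_t",
}


def get_per_position_base_content(
    store: Store, f: Optional[PropertyFilter] = None
) -> ReportTable:
    """Matrix of per-partition base content: columns (start, end, A, C, G, T).

    Equivalent to the column-wise join of four per-partition queries, one per
    base; partitions missing a base show an empty cell.
    """
    per_base = {
        base: get_per_partition_values(store, key, f)
        for base, key in _BASE_CONTENT_KEYS.items()
    }
    partitions: dict[tuple[int, int], dict[str, float]] = {}
    for base, t in per_base.items():
        for start, end, mean, _n in t.rows:
            partitions.setdefault((start, end), {})[base] = mean
    n_analyses = max((t.n_analyses for t in per_base.values()), default=0)
    rows = [
        [start, end] + [cells.get(b) for b in ("A", "C", "G", "T")]
        for (start, end), cells in sorted(partitions.items())
    ]
    return ReportTable(
        columns=["start", "end", "A", "C", "G", "T"], rows=rows, n_analyses=n_analyses
    )
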