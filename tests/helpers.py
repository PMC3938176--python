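"""Shared test utilities: a brute-force, pure-Python aggregation oracle.

The oracle keeps its own mirror of every analysis handed to the store and
recomputes latest-wins filtering and all means by exhaustive scanning, fully
independent of the SQL path it checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from qcstore.datastore import IDENTITY_KEYS, Store
from qcstore.model import QCAnalysis, Range, new_analysis
from qcstore.reports import CONTROLLED_KEYS


@dataclass
class Mirror:
    """Plain-python snapshot of one inserted analysis."""

    order: int
    properties: dict[str, str]
    general: list[tuple[str, object]] = field(default_factory=list)
    positions: list[tuple[str, int, float]] = field(default_factory=list)
    partitions: list[tuple[str, int, int, float]] = field(default_factory=list)


def snapshot(analysis: QCAnalysis, order: int) -> Mirror:
    return Mirror(
        order=order,
        properties=dict(analysis.properties),
        general=[(gv.key, gv.value) for gv in analysis.general_values],
        positions=[(pv.key, pv.position, pv.value) for pv in analysis.position_values],
        partitions=[
            (pv.key, pv.range.start, pv.range.end, pv.value)
            for pv in analysis.partition_values
        ],
    )


def brute_latest(mirrors: list[Mirror], filter_entries: dict[str, str]) -> list[Mirror]:
    """Filter by controlled keys, then keep the newest per identity tuple."""
    props = {CONTROLLED_KEYS[k]: str(v) for k, v in filter_entries.items()}
    matching = [
        m for m in mirrors
        if all(m.properties.get(k) == v for k, v in props.items())
    ]
    best: dict[tuple, Mirror] = {}
    for m in matching:  # insertion order == timestamp order; later wins
        best[tuple(m.properties.get(k) for k in IDENTITY_KEYS)] = m
    return sorted(best.values(), key=lambda m: m.order)


def brute_averages(latest: list[Mirror]) -> dict[str, tuple[float | None, int]]:
    values: dict[str, list[float]] = {}
    analyses: dict[str, set[int]] = {}
    for m in latest:
        for key, value in m.general:
            analyses.setdefault(key, set()).add(m.order)
            if isinstance(value, float):
                values.setdefault(key, []).append(value)
    return {
        key: (
            (sum(values[key]) / len(values[key])) if values.get(key) else None,
            len(orders),
        )
        for key, orders in analyses.items()
    }


def brute_positions(latest: list[Mirror], key: str) -> dict[int, tuple[float, int]]:
    acc: dict[int, list[float]] = {}
    who: dict[int, set[int]] = {}
    for m in latest:
        for k, pos, value in m.positions:
            if k == key:
                acc.setdefault(pos, []).append(value)
                who.setdefault(pos, set()).add(m.order)
    return {p: (sum(v) / len(v), len(who[p])) for p, v in acc.items()}


def brute_partitions(
    latest: list[Mirror], key: str
) -> dict[tuple[int, int], tuple[float, int]]:
    acc: dict[tuple[int, int], list[float]] = {}
    who: dict[tuple[int, int], set[int]] = {}
    for m in latest:
        for k, start, end, value in m.partitions:
            if k == key:
                acc.setdefault((start, end), []).append(value)
                who.setdefault((start, end), set()).add(m.order)
    return {se: (sum(v) / len(v), len(who[se])) for se, v in acc.items()}


# ---------------------------------------------------------------------------
# randomized store states

GENERAL_KEYS = ("g_alpha", "g_beta", "g_gamma")
TEXT_KEY = "g_status"
POSITION_KEYS = ("p_count_one", "p_count_two")
PARTITION_KEYS = ("q_mean_one", "q_mean_two")

_RUN_POOL = ("R1", "R2", "R3")
_LANE_POOL = ("1", "2")
_BARCODE_POOL = ("AAACTGA", "ACCGTT")
_SAMPLE_POOL = ("S1", "S2")


def random_analysis(rng: np.random.Generator) -> QCAnalysis:
    a = new_analysis()
    a.add_property("tool", "FastQC")
    a.add_property("run", str(rng.choice(_RUN_POOL)))
    a.add_property("lane", str(rng.choice(_LANE_POOL)))
    a.add_property("pair", "1")
    if rng.random() < 0.8:  # sometimes unmultiplexed
        a.add_property("barcode", str(rng.choice(_BARCODE_POOL)))
    a.add_property("sample_name", str(rng.choice(_SAMPLE_POOL)))
    a.add_property("instrument", "MISEQ-1")

    for key in GENERAL_KEYS:
        a.add_valid_type(key, "analysis")
        for _ in range(int(rng.integers(0, 3))):  # 0..2 values, duplicates allowed
            a.add_general_value(key, float(np.round(rng.uniform(0, 100), 6)))
    a.add_valid_type(TEXT_KEY, "analysis")
    if rng.random() < 0.5:
        a.add_general_value(TEXT_KEY, str(rng.choice(["pass", "warn", "fail"])))

    for key in POSITION_KEYS:
        a.add_valid_type(key, "sequence_cumulative")
        for pos in rng.choice(100, size=int(rng.integers(0, 20)), replace=False):
            a.add_position_value(int(pos), key, float(np.round(rng.uniform(0, 5000), 6)))

    for key in PARTITION_KEYS:
        a.add_valid_type(key, "base_partition")
        for _ in range(int(rng.integers(0, 12))):
            start = int(rng.integers(1, 95))
            end = start + int(rng.integers(0, 6))
            a.add_partition_value(Range(start, end), key, float(np.round(rng.uniform(2, 41), 6)))
    return a


def random_filter(rng: np.random.Generator) -> dict[str, str]:
    entries: dict[str, str] = {}
    if rng.random() < 0.7:
        entries["run"] = str(rng.choice(_RUN_POOL))
    if rng.random() < 0.5:
        entries["lane"] = str(rng.choice(_LANE_POOL))
    if rng.random() < 0.3:
        entries["barcode"] = str(rng.choice(_BARCODE_POOL))
    if rng.random() < 0.3:
        entries["sampleName"] = str(rng.choice(_SAMPLE_POOL))
    return entries


def populate_random_store(store: Store, rng: np.random.Generator) -> list[Mirror]:
    mirrors = []
    for i in range(int(rng.integers(1, 11))):
        analysis = random_analysis(rng)
        store.insert_analysis(analysis)
        mirrors.append(snapshot(analysis, order=i))
    return mirrors
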