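"""Synthetic FastQC reports and metadata tables with known ground truth.

The generator emits the same plain-text report dialect the parser reads
(``##FastQC`` sentinel, ``>>Module<tab>status`` ... ``>>END_MODULE`` blocks),
seeded and fully deterministic, and returns a :class:`GroundTruth` that
mirrors every number written so round-trip tests need no real sequencer data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np

from .exceptions import ValidationError
from .model import Range

__all__ = ["FixtureParams", "GroundTruth", "generate_fastqc_report",
           "write_metadata_table", "table1_entry"]

_BASES = ("A", "C", "G", "T")


@dataclass
class FixtureParams:
    """Knobs for one synthetic report."""

    read_length: int = 50
    n_reads: int = 10000
    quality_start: float = 38.0       # mean quality at position 1
    quality_decay: float = 0.15       # linear drop per position
    quality_noise: float = 0.4        # sd of per-partition jitter
    base_composition: dict[str, float] = field(
        default_factory=lambda: {"A": 0.25, "C": 0.25, "G": 0.25, "T": 0.25}
    )
    n_overrepresented: int = 2
    group_bases_from: Optional[int] = None   # FastQC-style grouping starts here
    group_width: int = 5
    filename: str = "sample.fastq"
    encoding: str = "Sanger / Illumina 1.9"
    seed: int = 42

    def __post_init__(self) -> None:
        if self.read_length < 1:
            raise ValidationError("read_length must be >= 1")
        if self.n_reads < 1:
            raise ValidationError("n_reads must be >= 1")
        total = sum(self.base_composition.get(b, 0.0) for b in _BASES)
        if abs(total - 1.0) > 1e-9:
            raise ValidationError(f"base_composition must sum to 1, got {total}")
        if self.group_bases_from is not None and self.group_bases_from < 2:
            raise ValidationError("group_bases_from must be >= 2")
        if self.group_width < 1:
            raise ValidationError("group_width must be >= 1")


@dataclass
class GroundTruth:
    """Exact copy of every numeric table the report contains.

    Values are stored post-formatting, i.e. exactly what a parser reading the
    file back will see.
    """

    properties: dict[str, str] = field(default_factory=dict)
    general_values: dict[str, float] = field(default_factory=dict)
    #: key -> [(start, end, value), ...] for base-partition metrics
    partition_values: dict[str, list[tuple[int, int, float]]] = field(default_factory=dict)
    #: key -> [(position, value), ...] for sequence-cumulative metrics
    position_values: dict[str, list[tuple[int, float]]] = field(default_factory=dict)
    #: (sequence, count, percentage, source) rows
    overrepresented: list[tuple[str, float, float, str]] = field(default_factory=list)
    statuses: dict[str, str] = field(default_factory=dict)


def _round(value: float, places: int = 4) -> float:
    """Round through the exact decimal text written to the file."""
    return float(f"{value:.{places}f}")


def _partition_ranges(params: FixtureParams) -> list[Range]:
    """Base labels used by the per-base modules, honouring grouping."""
    length = params.read_length
    if params.group_bases_from is None or params.group_bases_from > length:
        return [Range(i, i) for i in range(1, length + 1)]
    ranges = [Range(i, i) for i in range(1, params.group_bases_from)]
    pos = params.group_bases_from
    while pos <= length:
        end = min(pos + params.group_width - 1, length)
        ranges.append(Range(pos, end))
        pos = end + 1
    return ranges


def _label(r: Range) -> str:
    return str(r.start) if r.start == r.end else f"{r.start}-{r.end}"


def _quality_profile(params: FixtureParams, rng: np.random.Generator,
                     ranges: Sequence[Range]) -> list[dict[str, float]]:
    rows = []
    for r in ranges:
        positions = np.arange(r.start, r.end + 1)
        base_mean = float(np.mean(params.quality_start - params.quality_decay * (positions - 1)))
        mean = base_mean + params.quality_noise * float(rng.standard_normal())
        mean = max(2.0, mean)
        rows.append({
            "Mean": _round(mean),
            "Median": _round(max(2.0, mean + 0.3)),
            "Lower Quartile": _round(max(2.0, mean - 1.5)),
            "Upper Quartile": _round(mean + 1.2),
            "10th Percentile": _round(max(2.0, mean - 3.0)),
            "90th Percentile": _round(mean + 2.0),
        })
    return rows


def _counts_over(rng: np.random.Generator, support: np.ndarray, center: float,
                 sd: float, total: int) -> np.ndarray:
    weights = np.exp(-0.5 * ((support - center) / sd) ** 2)
    weights = weights / weights.sum()
    return rng.multinomial(total, weights)


def _random_sequence(rng: np.random.Generator, length: int = 20) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


def generate_fastqc_report(
    params: FixtureParams, out: Union[str, Path]
) -> GroundTruth:
    """Write a synthetic ``fastqc_data.txt`` and return its exact contents.

    Deterministic given ``params.seed``: the same parameters produce a
    byte-identical file. The per-sequence quality counts sum exactly to
    ``n_reads``.
    """
    params.__post_init__()  # re-validate in case fields were mutated
    rng = np.random.default_rng(params.seed)
    truth = GroundTruth()
    ranges = _partition_ranges(params)
    lines: list[str] = ["##FastQC\t0.11.9"]

    def module(name: str, status: str, header: Sequence[str],
               rows: Sequence[Sequence[str]], pre_rows: Sequence[str] = ()) -> None:
        lines.append(f">>{name}\t{status}")
        lines.append("#" + "\t".join(header))
        lines.extend(pre_rows)
        lines.extend("\t".join(r) for r in rows)
        lines.append(">>END_MODULE")
        truth.statuses[name.lower().replace(" ", "_")] = status

    # Basic Statistics
    gc_fraction = params.base_composition["G"] + params.base_composition["C"]
    gc_percent = int(round(gc_fraction * 100))
    module("Basic Statistics", "pass", ["Measure", "Value"], [
        ["Filename", params.filename],
        ["File type", "Conventional base calls"],
        ["Encoding", params.encoding],
        ["Total Sequences", str(params.n_reads)],
        ["Sequences flagged as poor quality", "0"],
        ["Sequence length", str(params.read_length)],
        ["%GC", str(gc_percent)],
    ])
    truth.properties.update({
        "filename": params.filename,
        "file_type": "Conventional base calls",
        "encoding": params.encoding,
    })
    truth.general_values.update({
        "general_total_sequences": float(params.n_reads),
        "general_filtered_sequences": 0.0,
        "general_min_length": float(params.read_length),
        "general_max_length": float(params.read_length),
        "general_gc_content": float(gc_percent),
    })

    # Per base sequence quality
    quality_rows = _quality_profile(params, rng, ranges)
    header = ["Base", "Mean", "Median", "Lower Quartile", "Upper Quartile",
              "10th Percentile", "90th Percentile"]
    key_of = {
        "Mean": "quality_mean", "Median": "quality_median",
        "Lower Quartile": "quality_lower_quartile",
        "Upper Quartile": "quality_upper_quartile",
        "10th Percentile": "quality_10th_percentile",
        "90th Percentile": "quality_90th_percentile",
    }
    module("Per base sequence quality", "pass", header, [
        [_label(r)] + [f"{row[c]:.4f}" for c in header[1:]]
        for r, row in zip(ranges, quality_rows)
    ])
    for col, key in key_of.items():
        truth.partition_values[key] = [
            (r.start, r.end, row[col]) for r, row in zip(ranges, quality_rows)
        ]

    # Per sequence quality scores (counts sum exactly to n_reads)
    scores = np.arange(2, 41)
    mean_q = params.quality_start - params.quality_decay * (params.read_length - 1) / 2
    score_counts = _counts_over(rng, scores, mean_q, 2.5, params.n_reads)
    module("Per sequence quality scores", "pass", ["Quality", "Count"], [
        [str(int(s)), f"{float(c):.1f}"] for s, c in zip(scores, score_counts)
    ])
    truth.position_values["quality_score_count"] = [
        (int(s), float(c)) for s, c in zip(scores, score_counts)
    ]

    # Per base sequence content (FastQC column order G, A, T, C)
    content_rows = []
    for r in ranges:
        pct = {
            b: _round(max(0.0, params.base_composition[b] * 100
                          + 0.8 * float(rng.standard_normal())))
            for b in _BASES
        }
        content_rows.append(pct)
    module("Per base sequence content", "pass", ["Base", "G", "A", "T", "C"], [
        [_label(r)] + [f"{row[b]:.4f}" for b in ("G", "A", "T", "C")]
        for r, row in zip(ranges, content_rows)
    ])
    for b in _BASES:
        truth.partition_values[f"base_content_{b.lower()}"] = [
            (r.start, r.end, row[b]) for r, row in zip(ranges, content_rows)
        ]

    # Per sequence GC content
    gc_bins = np.arange(0, 101)
    gc_counts = _counts_over(rng, gc_bins, gc_fraction * 100, 8.0, params.n_reads)
    module("Per sequence GC content", "pass", ["GC Content", "Count"], [
        [str(int(b)), f"{float(c):.1f}"] for b, c in zip(gc_bins, gc_counts)
    ])
    truth.position_values["gc_content_count"] = [
        (int(b), float(c)) for b, c in zip(gc_bins, gc_counts)
    ]

    # Sequence Length Distribution (uniform length)
    module("Sequence Length Distribution", "pass", ["Length", "Count"], [
        [str(params.read_length), f"{float(params.n_reads):.1f}"]
    ])
    truth.position_values["length_count"] = [(params.read_length, float(params.n_reads))]

    # Overrepresented sequences
    over_rows = []
    for i in range(params.n_overrepresented):
        seq = _random_sequence(rng)
        count = max(1, params.n_reads // (100 * (i + 1)))
        pct = _round(count / params.n_reads * 100)
        source = "No Hit"
        over_rows.append([seq, str(count), f"{pct:.4f}", source])
        truth.overrepresented.append((seq, float(count), pct, source))
    module("Overrepresented sequences",
           "warn" if over_rows else "pass",
           ["Sequence", "Count", "Percentage", "Possible Source"], over_rows)

    out = Path(out)
    out.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return truth


def write_metadata_table(entries: Sequence, out: Union[str, Path]) -> None:
    """Write entries as a tab-delimited metadata table parse_run_table reads.

    Accepts dicts or RunTableEntry objects; the header is the union of keys
    in first-seen order; missing cells are written empty.
    """
    dicts = [dict(getattr(e, "columns", e)) for e in entries]
    header: list[str] = []
    for d in dicts:
        for key in d:
            k = str(key).strip().upper()
            if k not in header:
                header.append(k)
    lines = ["\t".join(header)]
    for d in dicts:
        norm = {str(k).strip().upper(): str(v) for k, v in d.items()}
        lines.append("\t".join(norm.get(k, "") for k in header))
    Path(out).write_text("\n".join(lines) + "\n", encoding="utf-8")


def table1_entry(path: Union[str, Path], **overrides: str) -> dict[str, str]:
    """A realistic single-analysis metadata row, overridable per field."""
    entry = {
        "TYPE_OF_EXPERIMENT": "NGS",
        "PATH_TO_ANALYSIS": str(path),
        "ANALYSIS_TYPE": "FastQC",
        "INSTRUMENT": "MISEQ-1",
        "CHEMISTRY_VERSION": "TRUSEQ_SBS_V3",
        "SOFTWARE_ON_INSTRUMENT_VERSION": "MCS_2.2.0_RTA_1.17.28.0",
        "CASAVA_VERSION": "1.8.2",
        "RUN_FOLDER": "/path/to/run_folder",
        "SAMPLE_NAME": "TEST_SAMPLE",
        "LANE": "1",
        "BARCODE": "AAACTGA",
        "PAIR": "1",
        "RUN": "RUN_NAME",
    }
    entry.update({k.strip().upper(): str(v) for k, v in overrides.items()})
    return entry
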