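"""Report parsers and the batch-loading wrapper.

Three cooperating pieces mirror the usual loader architecture:

* :func:`parse_run_table` reads the tab-delimited analysis-metadata table
  (one analysis per line) into :class:`RunTableEntry` objects;
* a *specific parser* (here :class:`FastQCParser`) turns one report file
  into values on a :class:`~qcstore.model.QCAnalysis`;
* :func:`load` wires them together: it owns the store connection, dispatches
  each entry to the parser registered for its ANALYSIS_TYPE, and inserts.

Parsers never touch the store; registration is by case-insensitive name in a
:class:`ParserRegistry`, so support for a new QC tool is one class with a
``parse(path, analysis)`` method.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Protocol, Union

from . import datastore
from .exceptions import ParseError, QCStoreError
from .model import (
    Range,
    SCOPE_ANALYSIS,
    SCOPE_BASE_PARTITION,
    SCOPE_SEQUENCE_CUMULATIVE,
    QCAnalysis,
    new_analysis,
    parse_range,
)

logger = logging.getLogger(__name__)

__all__ = [
    "RunTableEntry",
    "parse_run_table",
    "entry_to_analysis",
    "COLUMN_PROPERTY_MAP",
    "SpecificParser",
    "FastQCParser",
    "ParserRegistry",
    "default_registry",
    "LoadSummary",
    "load",
]

#: Metadata-table column -> canonical property key. Unlisted columns map to
#: their lower-cased name, so the mapping is total.
COLUMN_PROPERTY_MAP = {
    "TYPE_OF_EXPERIMENT": "type",
    "PATH_TO_ANALYSIS": "path_to_analysis",
    "ANALYSIS_TYPE": "tool",
    "INSTRUMENT": "instrument",
    "CHEMISTRY_VERSION": "chemistry",
    "SOFTWARE_ON_INSTRUMENT_VERSION": "software",
    "CASAVA_VERSION": "casava_version",
    "RUN_FOLDER": "run_folder",
    "SAMPLE_NAME": "sample_name",
    "LANE": "lane",
    "BARCODE": "barcode",
    "PAIR": "pair",
    "RUN": "run",
}


class RunTableEntry:
    """One line of the metadata table: column name -> verbatim value."""

    def __init__(self, columns: dict[str, str], line: Optional[int] = None):
        self.columns = {k.strip().upper(): v for k, v in columns.items()}
        self.line = line

    def get(self, column: str, default: Optional[str] = None) -> Optional[str]:
        return self.columns.get(column.strip().upper(), default)

    def __getitem__(self, column: str) -> str:
        return self.columns[column.strip().upper()]

    def __contains__(self, column: str) -> bool:
        return column.strip().upper() in self.columns

    def __eq__(self, other) -> bool:
        if isinstance(other, RunTableEntry):
            return self.columns == other.columns
        if isinstance(other, dict):
            return self.columns == {k.strip().upper(): v for k, v in other.items()}
        return NotImplemented

    def __repr__(self) -> str:
        return f"RunTableEntry({self.columns!r})"

    @property
    def path(self) -> str:
        return self.columns.get("PATH_TO_ANALYSIS", "")


def parse_run_table(path: Union[str, Path]) -> list[RunTableEntry]:
    """Read a tab-delimited analysis-metadata table.

    The first non-comment line is the header (normalized case-insensitively);
    each following non-comment line is one analysis. ``#`` lines and blank
    lines are ignored. Ragged rows and a missing PATH_TO_ANALYSIS column are
    parse errors naming the line.
    """
    path = Path(path)
    header: Optional[list[str]] = None
    entries: list[RunTableEntry] = []
    text = path.read_text(encoding="utf-8")
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.rstrip("\r\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        cells = line.split("\t")
        if header is None:
            header = [c.strip().upper() for c in cells]
            if "PATH_TO_ANALYSIS" not in header:
                raise ParseError(
                    "metadata table header lacks a PATH_TO_ANALYSIS column",
                    path=path, line=lineno,
                )
            continue
        if len(cells) != len(header):
            raise ParseError(
                f"expected {len(header)} tab-separated fields, found {len(cells)}",
                path=path, line=lineno,
            )
        entries.append(RunTableEntry(dict(zip(header, cells)), line=lineno))
    if header is None:
        raise ParseError("metadata table has no header line", path=path)
    return entries


def entry_to_analysis(entry: RunTableEntry) -> QCAnalysis:
    """Build a QCAnalysis carrying the entry's metadata as properties.

    Every column lands in exactly one property (canonical key where mapped,
    lower-cased column name otherwise); empty cells yield no property.
    """
    analysis = new_analysis()
    for column, value in entry.columns.items():
        if value == "":
            continue
        analysis.add_property(COLUMN_PROPERTY_MAP.get(column, column.lower()), value)
    return analysis


# ---------------------------------------------------------------------------
# FastQC


class SpecificParser(Protocol):
    """Contract every report parser implements."""

    #: metadata-table column carrying the report path for this parser
    path_column: str

    def parse(self, path: Union[str, Path], analysis: QCAnalysis) -> QCAnalysis: ...


def _parse_float(cell: str, module: str, lineno: int, path) -> Optional[float]:
    cell = cell.strip()
    if cell == "" or cell.lower() == "nan":
        return None
    try:
        return float(cell)
    except ValueError:
        raise ParseError(
            f"non-numeric cell {cell!r} in module {module!r}", path=path, line=lineno
        )


def _iter_modules(path: Path):
    """Yield (name, status, header, rows) per FastQC module block.

    ``rows`` are (lineno, cells) pairs; ``header`` is the last ``#``-prefixed
    line seen before data (FastQC column names), or None.
    """
    text = path.read_text(encoding="utf-8", errors="replace")
    lines = text.splitlines()
    if not lines or not lines[0].startswith("##FastQC"):
        raise ParseError("missing ##FastQC sentinel on first line", path=path, line=1)
    name = status = header = None
    rows: list[tuple[int, list[str]]] = []
    extra_headers: list[tuple[int, str]] = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        if line.startswith(">>END_MODULE"):
            if name is None:
                raise ParseError("END_MODULE outside any module", path=path, line=lineno)
            yield name, status, header, rows, extra_headers
            name = status = header = None
            rows, extra_headers = [], []
        elif line.startswith(">>"):
            if name is not None:
                raise ParseError(
                    f"module {name!r} not terminated before a new module",
                    path=path, line=lineno,
                )
            parts = line[2:].split("\t")
            name = parts[0].strip()
            status = parts[1].strip() if len(parts) > 1 else ""
        elif line.startswith("#"):
            if name is None:
                continue
            if header is None and not rows:
                header = line[1:].split("\t")
            else:
                extra_headers.append((lineno, line))
        else:
            if name is None:
                raise ParseError("data line outside any module", path=path, line=lineno)
            rows.append((lineno, line.split("\t")))
    if name is not None:
        raise ParseError(f"module {name!r} has no >>END_MODULE", path=path)


def _module_key(name: str) -> str:
    return name.strip().lower().replace(" ", "_")


class FastQCParser:
    """Parse a ``fastqc_data.txt`` report into a QCAnalysis.

    Module-to-scope mapping: the six per-base quality quantiles, per-base
    sequence/GC/N content become base partitions (grouped base labels such as
    ``10-14`` become one partition); per-sequence quality scores, GC content,
    length distribution and duplication levels become sequence-cumulative
    counts; Basic Statistics becomes properties plus global values;
    overrepresented sequences and kmers become global values carrying their
    source text as the description. Each module's pass/warn/fail status is
    stored as the global text value ``<module_key>_status``. Unknown modules
    are skipped with a warning so newer FastQC output still loads.
    """

    path_column = "PATH_TO_ANALYSIS"

    _PER_BASE_QUALITY = {
        "mean": "quality_mean",
        "median": "quality_median",
        "lower quartile": "quality_lower_quartile",
        "upper quartile": "quality_upper_quartile",
        "10th percentile": "quality_10th_percentile",
        "90th percentile": "quality_90th_percentile",
    }
    _BASE_CONTENT = {"a": "base_content_a", "c": "base_content_c",
                     "g": "base_content_g", "t": "base_content_t"}

    def parse(self, path: Union[str, Path], analysis: QCAnalysis) -> QCAnalysis:
        path = Path(path)
        analysis.add_property("tool", "FastQC")
        handlers = {
            "basic statistics": self._basic_statistics,
            "per base sequence quality": self._per_base_quality,
            "per sequence quality scores": self._per_sequence_quality,
            "per base sequence content": self._per_base_content,
            "per base gc content": self._per_base_gc,
            "per base n content": self._per_base_n,
            "per sequence gc content": self._per_sequence_gc,
            "sequence length distribution": self._length_distribution,
            "sequence duplication levels": self._duplication_levels,
            "overrepresented sequences": self._overrepresented,
            "kmer content": self._kmer_content,
        }
        for name, status, header, rows, extra in _iter_modules(path):
            handler = handlers.get(name.lower())
            if handler is None:
                logger.warning("skipping unknown FastQC module %r in %s", name, path)
                continue
            if status:
                status_key = f"{_module_key(name)}_status"
                analysis.add_valid_type(status_key, SCOPE_ANALYSIS)
                analysis.add_general_value(status_key, status)
            handler(analysis, header, rows, extra, name, path)
        return analysis

    # -- module handlers -----------------------------------------------------

    def _basic_statistics(self, analysis, header, rows, extra, module, path):
        for lineno, cells in rows:
            if len(cells) < 2:
                raise ParseError("Basic Statistics row lacks a value", path=path, line=lineno)
            measure, value = cells[0].strip(), cells[1].strip()
            low = measure.lower()
            if low == "encoding":
                analysis.add_property("encoding", value)
            elif low == "filename":
                analysis.add_property("filename", value)
            elif low == "file type":
                analysis.add_property("file_type", value)
            elif low == "total sequences":
                self._general(analysis, "general_total_sequences", value)
            elif low in ("filtered sequences", "sequences flagged as poor quality"):
                self._general(analysis, "general_filtered_sequences", value)
            elif low == "sequence length":
                rng = parse_range(value)
                self._general(analysis, "general_min_length", float(rng.start))
                self._general(analysis, "general_max_length", float(rng.end))
            elif low == "%gc":
                self._general(analysis, "general_gc_content", value)
            else:
                self._general(analysis, "general_" + _module_key(measure), value)

    @staticmethod
    def _general(analysis, key, value, description=None):
        analysis.add_valid_type(key, SCOPE_ANALYSIS)
        analysis.add_general_value(key, value, description)

    def _partition_module(self, analysis, header, rows, module, path, column_map):
        """Generic per-base module: first column is a base label/range."""
        if header is None:
            raise ParseError(f"module {module!r} lacks a column header", path=path)
        keys = []
        for col in header[1:]:
            key = column_map.get(col.strip().lower())
            keys.append(key)
            if key is not None:
                analysis.add_valid_type(key, SCOPE_BASE_PARTITION)
        for lineno, cells in rows:
            rng = parse_range(cells[0])
            for key, cell in zip(keys, cells[1:]):
                if key is None:
                    continue
                value = _parse_float(cell, module, lineno, path)
                if value is None:
                    logger.warning(
                        "skipping empty/NaN cell for %s at %s:%d", key, path, lineno
                    )
                    continue
                analysis.add_partition_value(rng, key, value)

    def _per_base_quality(self, analysis, header, rows, extra, module, path):
        self._partition_module(analysis, header, rows, module, path, self._PER_BASE_QUALITY)

    def _per_base_content(self, analysis, header, rows, extra, module, path):
        self._partition_module(analysis, header, rows, module, path, self._BASE_CONTENT)

    def _per_base_gc(self, analysis, header, rows, extra, module, path):
        self._partition_module(
            analysis, header, rows, module, path, {"%gc": "gc_content_percentage"}
        )

    def _per_base_n(self, analysis, header, rows, extra, module, path):
        self._partition_module(
            analysis, header, rows, module, path, {"n-count": "base_content_n"}
        )

    def _position_module(self, analysis, rows, module, path, key, label_to_position):
        analysis.add_valid_type(key, SCOPE_SEQUENCE_CUMULATIVE)
        for lineno, cells in rows:
            if len(cells) < 2:
                raise ParseError(f"module {module!r} row lacks a count", path=path, line=lineno)
            position = label_to_position(cells[0].strip())
            value = _parse_float(cells[1], module, lineno, path)
            if position is None or value is None:
                logger.warning("skipping row at %s:%d in %r", path, lineno, module)
                continue
            analysis.add_position_value(position, key, value)

    def _per_sequence_quality(self, analysis, header, rows, extra, module, path):
        self._position_module(
            analysis, rows, module, path, "quality_score_count", lambda s: int(float(s))
        )

    def _per_sequence_gc(self, analysis, header, rows, extra, module, path):
        self._position_module(
            analysis, rows, module, path, "gc_content_count", lambda s: int(float(s))
        )

    def _length_distribution(self, analysis, header, rows, extra, module, path):
        # length bins may be ranges ("35-39"); counted on the bin's start
        self._position_module(
            analysis, rows, module, path, "length_count", lambda s: parse_range(s).start
        )

    def _duplication_levels(self, analysis, header, rows, extra, module, path):
        # FastQC emits "#Total Duplicate Percentage<tab>N" before the column header
        candidates = list(extra)
        if header and header[0].lower().startswith("total"):
            candidates.append((0, "#" + "\t".join(header)))
        for lineno, line in candidates:
            if line.lower().startswith("#total"):
                cells = line.split("\t")
                if len(cells) > 1:
                    value = _parse_float(cells[1], module, lineno, path)
                    if value is not None:
                        self._general(analysis, "general_duplication_percentage", value)

        def level(label: str) -> Optional[int]:
            digits = "".join(ch for ch in label if ch.isdigit())
            return int(digits) if digits else None

        self._position_module(
            analysis, rows, module, path, "duplication_level_relative_count", level
        )

    def _overrepresented(self, analysis, header, rows, extra, module, path):
        for lineno, cells in rows:
            if len(cells) < 2:
                raise ParseError(
                    "overrepresented-sequence row lacks a count", path=path, line=lineno
                )
            sequence = cells[0].strip()
            count = _parse_float(cells[1], module, lineno, path)
            if count is None:
                continue
            source = cells[3].strip() if len(cells) > 3 else None
            self._general(analysis, sequence, count, source or None)

    def _kmer_content(self, analysis, header, rows, extra, module, path):
        for lineno, cells in rows:
            if len(cells) < 2:
                continue
            count = _parse_float(cells[1], module, lineno, path)
            if count is None:
                continue
            self._general(analysis, cells[0].strip(), count, "kmer")


# ---------------------------------------------------------------------------
# registry and load wrapper


class ParserRegistry:
    """Case-insensitive name -> SpecificParser registry; fastqc is built in."""

    def __init__(self):
        self._parsers: dict[str, SpecificParser] = {}
        self.register("fastqc", FastQCParser())

    def register(self, name: str, parser: SpecificParser) -> None:
        self._parsers[name.strip().lower()] = parser

    def get(self, name: str) -> SpecificParser:
        parser = self._parsers.get(name.strip().lower())
        if parser is None:
            raise ParseError(
                f"no parser registered for analysis type {name!r}; "
                f"registered parsers: {', '.join(sorted(self._parsers))}"
            )
        return parser

    def names(self) -> list[str]:
        return sorted(self._parsers)

    def __contains__(self, name: str) -> bool:
        return name.strip().lower() in self._parsers


default_registry = ParserRegistry()


@dataclass
class LoadSummary:
    """Outcome of one batch load."""

    parsed: int = 0
    inserted: int = 0
    failed: int = 0
    test_mode: bool = False
    errors: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return self.failed == 0


def load(
    config,
    metadata_path: Union[str, Path],
    test_mode: bool = False,
    registry: Optional[ParserRegistry] = None,
) -> LoadSummary:
    """Parse every entry of a metadata table and insert it into the store.

    Per-entry failures are recorded and do not abort the remaining entries;
    a config/connection failure aborts. In test mode everything is parsed and
    validated but nothing is written.
    """
    registry = registry or default_registry
    entries = parse_run_table(metadata_path)
    store = datastore.connect(config)
    summary = LoadSummary(test_mode=test_mode)
    try:
        for entry in entries:
            try:
                tool = entry.get("ANALYSIS_TYPE")
                if not tool:
                    raise ParseError(
                        "entry has no ANALYSIS_TYPE", path=metadata_path, line=entry.line
                    )
                parser = registry.get(tool)
                report_path = entry.get(parser.path_column) or entry.path
                if not report_path:
                    raise ParseError(
                        "entry has no analysis path", path=metadata_path, line=entry.line
                    )
                analysis = entry_to_analysis(entry)
                parser.parse(report_path, analysis)
                summary.parsed += 1
                if not test_mode:
                    store.insert_analysis(analysis)
                    summary.inserted += 1
            except (QCStoreError, OSError) as exc:
                summary.failed += 1
                summary.errors.append(
                    f"line {entry.line}: {exc}" if entry.line else str(exc)
                )
                logger.error("failed to load entry at line %s: %s", entry.line, exc)
    finally:
        store.disconnect()
    return summary
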