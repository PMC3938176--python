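"""In-memory QC analysis builder.

A :class:`QCAnalysis` aggregates everything one QC run of one tool produced:
free-form string *properties* (run, lane, barcode, ...), a registry of *value
types* (each metric key bound to exactly one scope), and three containers of
values, one per scope:

``analysis``
    Global values: one number or text per analysis (e.g. total GC content,
    an overrepresented sequence with its count).
``base_partition``
    Values attached to an inclusive range of base positions (e.g. mean
    quality over positions 10-14). Width-1 ranges are legal.
``sequence_cumulative``
    Counts indexed by a score or bin across all reads (e.g. number of reads
    whose mean quality is 30).

The builder enforces scope discipline up front so that anything it accepts is
always insertable into a datastore.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Optional, Union

from .exceptions import RangeError, ScopeError, ValidationError

__all__ = [
    "SCOPE_ANALYSIS",
    "SCOPE_BASE_PARTITION",
    "SCOPE_SEQUENCE_CUMULATIVE",
    "SCOPES",
    "Range",
    "parse_range",
    "GeneralValue",
    "PositionValue",
    "PartitionValue",
    "QCAnalysis",
    "new_analysis",
]

SCOPE_ANALYSIS = "analysis"
SCOPE_BASE_PARTITION = "base_partition"
SCOPE_SEQUENCE_CUMULATIVE = "sequence_cumulative"

#: The only scope labels a value type may carry.
SCOPES = (SCOPE_ANALYSIS, SCOPE_BASE_PARTITION, SCOPE_SEQUENCE_CUMULATIVE)

_RANGE_RE = re.compile(r"^(\d+)(?:-(\d+))?$")


@dataclass(frozen=True, order=True)
class Range:
    """Inclusive 1-based base-position partition ``[start, end]``."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if not (isinstance(self.start, int) and isinstance(self.end, int)):
            raise RangeError(f"range bounds must be integers, got ({self.start!r}, {self.end!r})")
        if self.start < 1:
            raise RangeError(f"range start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise RangeError(f"reversed range: start {self.start} > end {self.end}")

    @property
    def width(self) -> int:
        """Number of base positions covered, ``end - start + 1``."""
        return self.end - self.start + 1


def parse_range(text: str) -> Range:
    """Convert a range string into a :class:`Range`.

    ``"10"`` denotes the width-1 partition ``(10, 10)``; ``"10-14"`` the
    inclusive partition ``(10, 14)``. Surrounding whitespace is trimmed; no
    other dialects are accepted.
    """
    if not isinstance(text, str):
        raise RangeError(f"range must be a string, got {type(text).__name__}")
    stripped = text.strip()
    m = _RANGE_RE.match(stripped)
    if not m:
        raise RangeError(f"malformed range string: {text!r}")
    start = int(m.group(1))
    end = int(m.group(2)) if m.group(2) is not None else start
    if start < 1:
        raise RangeError(f"range positions are 1-based: {text!r}")
    if end < start:
        raise RangeError(f"reversed range string: {text!r}")
    return Range(start, end)


def _coerce_numeric(value) -> tuple[Optional[float], Optional[str]]:
    """Split a value into (numeric, text) slots; numeric text becomes a double."""
    if isinstance(value, bool):
        return float(value), None
    if isinstance(value, (int, float)):
        return float(value), None
    if isinstance(value, str):
        try:
            return float(value), None
        except ValueError:
            return None, value
    raise ValidationError(f"unsupported value type: {type(value).__name__}")


def _require_number(value, context: str) -> float:
    num, text = _coerce_numeric(value)
    if num is None:
        raise ValidationError(f"{context} requires a numeric value, got {text!r}")
    return num


@dataclass(frozen=True)
class GeneralValue:
    key: str
    value: Union[float, str]
    description: Optional[str] = None


@dataclass(frozen=True)
class PositionValue:
    position: int
    key: str
    value: float


@dataclass(frozen=True)
class PartitionValue:
    range: Range
    key: str
    value: float


@dataclass
class QCAnalysis:
    """One QC analysis under construction.

    Values can only be added for keys previously registered with
    :meth:`add_valid_type`, and only into the container matching the key's
    scope.
    """

    properties: dict[str, str] = field(default_factory=dict)
    valid_types: dict[str, str] = field(default_factory=dict)
    general_values: list[GeneralValue] = field(default_factory=list)
    position_values: list[PositionValue] = field(default_factory=list)
    partition_values: list[PartitionValue] = field(default_factory=list)

    def add_valid_type(self, key: str, scope: str) -> None:
        """Register metric *key* under *scope*.

        Re-registering the same (key, scope) pair is a no-op; registering an
        existing key under a different scope is a conflict.
        """
        if scope not in SCOPES:
            raise ScopeError(
                f"unknown scope {scope!r}; valid scopes are {', '.join(SCOPES)}"
            )
        if not key:
            raise ValidationError("value type key must be non-empty")
        existing = self.valid_types.get(key)
        if existing is not None and existing != scope:
            raise ScopeError(
                f"key {key!r} already registered with scope {existing!r}, "
                f"cannot re-register with {scope!r}"
            )
        self.valid_types[key] = scope

    def add_property(self, key: str, value) -> None:
        """Record a property; a repeated key overwrites (last write wins)."""
        if not key:
            raise ValidationError("property key must be non-empty")
        self.properties[str(key)] = str(value)

    def get_property(self, key: str) -> Optional[str]:
        return self.properties.get(key)

    def _check_scope(self, key: str, expected: str) -> None:
        scope = self.valid_types.get(key)
        if scope is None:
            raise ScopeError(f"key {key!r} has not been registered with add_valid_type")
        if scope != expected:
            raise ScopeError(
                f"key {key!r} is registered with scope {scope!r}, "
                f"but this container requires scope {expected!r}"
            )

    def add_general_value(self, key: str, value, description: Optional[str] = None) -> None:
        """Append a global (analysis-scope) value, numeric or text."""
        self._check_scope(key, SCOPE_ANALYSIS)
        num, text = _coerce_numeric(value)
        self.general_values.append(
            GeneralValue(key, num if num is not None else text, description)
        )

    def add_position_value(self, position: int, key: str, value) -> None:
        """Append a sequence_cumulative value at a non-negative index."""
        self._check_scope(key, SCOPE_SEQUENCE_CUMULATIVE)
        if not isinstance(position, int) or isinstance(position, bool) or position < 0:
            raise ValidationError(f"position must be a non-negative integer, got {position!r}")
        self.position_values.append(
            PositionValue(position, key, _require_number(value, "add_position_value"))
        )

    def add_partition_value(self, r: Union[Range, tuple], key: str, value) -> None:
        """Append a base_partition value over an inclusive position range."""
        self._check_scope(key, SCOPE_BASE_PARTITION)
        if not isinstance(r, Range):
            try:
                start, end = r
            except (TypeError, ValueError):
                raise RangeError(f"expected a Range or (start, end) pair, got {r!r}")
            r = Range(int(start), int(end))
        self.partition_values.append(
            PartitionValue(r, key, _require_number(value, "add_partition_value"))
        )


def new_analysis() -> QCAnalysis:
    """Create an empty :class:`QCAnalysis`."""
    return QCAnalysis()
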