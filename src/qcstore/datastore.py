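"""Persistent relational store for QC analyses.

The store is an embedded sqlite database (zero-install) holding an
entity-attribute-value schema: an ``analysis`` row per recorded analysis,
``analysis_property`` rows for its free-form properties, a ``value_type``
registry (key, scope, first-wins description), and one value table per scope
(``analysis_value``, ``per_position_value``, ``per_partition_value``).

The store is append-only; re-running an analysis with the same parameters
creates a new record, and latest-wins resolution happens at query time.
"""

from __future__ import annotations

import sqlite3
from dataclasses import dataclass
from datetime import datetime, timezone
from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd

from .exceptions import ConfigError, ScopeError, StoreClosedError
from .model import SCOPES, QCAnalysis

__all__ = ["StoreConfig", "Store", "connect", "IDENTITY_KEYS"]

#: Property keys that together identify one analysis for latest-wins purposes.
IDENTITY_KEYS = ("run", "lane", "pair", "barcode", "sample_name", "tool")

_PERL_KEYS = {"db_string": "url", "db_user": "user", "db_password": "password"}
_JAVA_KEYS = {
    "statsdb.url": "url",
    "statsdb.username": "user",
    "statsdb.password": "password",
    "statsdb.driver": "driver",
}

_SCHEMA = """
CREATE TABLE IF NOT EXISTS analysis (
    id        INTEGER PRIMARY KEY AUTOINCREMENT,
    timestamp TEXT NOT NULL
);
CREATE TABLE IF NOT EXISTS analysis_property (
    id          INTEGER PRIMARY KEY AUTOINCREMENT,
    analysis_id INTEGER NOT NULL REFERENCES analysis(id),
    property    TEXT NOT NULL,
    value       TEXT
);
CREATE TABLE IF NOT EXISTS type_scope (
    id    INTEGER PRIMARY KEY AUTOINCREMENT,
    scope TEXT NOT NULL UNIQUE
);
CREATE TABLE IF NOT EXISTS value_type (
    id            INTEGER PRIMARY KEY AUTOINCREMENT,
    value_key     TEXT NOT NULL UNIQUE,
    type_scope_id INTEGER NOT NULL REFERENCES type_scope(id),
    description   TEXT
);
CREATE TABLE IF NOT EXISTS analysis_value (
    id            INTEGER PRIMARY KEY AUTOINCREMENT,
    analysis_id   INTEGER NOT NULL REFERENCES analysis(id),
    value_type_id INTEGER NOT NULL REFERENCES value_type(id),
    value         REAL,
    text_value    TEXT
);
CREATE TABLE IF NOT EXISTS per_position_value (
    id            INTEGER PRIMARY KEY AUTOINCREMENT,
    analysis_id   INTEGER NOT NULL REFERENCES analysis(id),
    value_type_id INTEGER NOT NULL REFERENCES value_type(id),
    position      INTEGER NOT NULL CHECK (position >= 0),
    value         REAL NOT NULL
);
CREATE TABLE IF NOT EXISTS per_partition_value (
    id             INTEGER PRIMARY KEY AUTOINCREMENT,
    analysis_id    INTEGER NOT NULL REFERENCES analysis(id),
    value_type_id  INTEGER NOT NULL REFERENCES value_type(id),
    position_start INTEGER NOT NULL,
    position_end   INTEGER NOT NULL,
    value          REAL NOT NULL,
    CHECK (position_start <= position_end)
);
CREATE INDEX IF NOT EXISTS idx_property_analysis ON analysis_property(analysis_id);
CREATE INDEX IF NOT EXISTS idx_property_key ON analysis_property(property, value);
CREATE INDEX IF NOT EXISTS idx_value_analysis ON analysis_value(analysis_id);
CREATE INDEX IF NOT EXISTS idx_position_analysis ON per_position_value(analysis_id);
CREATE INDEX IF NOT EXISTS idx_partition_analysis ON per_partition_value(analysis_id);
"""

_TABLES = (
    "analysis",
    "analysis_property",
    "type_scope",
    "value_type",
    "analysis_value",
    "per_position_value",
    "per_partition_value",
)


def _url_to_path(url: str) -> str:
    """Resolve the accepted connection-string dialects to a sqlite path."""
    url = url.strip()
    low = url.lower()
    for prefix in ("sqlite:///", "jdbc:sqlite:", "sqlite:"):
        if low.startswith(prefix):
            return url[len(prefix):]
    if low.startswith("dbi:sqlite:"):
        rest = url[len("dbi:sqlite:"):]
        for part in rest.split(";"):
            if part.startswith("dbname="):
                return part[len("dbname="):]
        return rest
    if low.startswith(("dbi:", "jdbc:", "mysql:", "postgresql:")):
        raise ConfigError(
            f"unsupported database engine in connection string {url!r}; "
            "only the embedded sqlite engine is available"
        )
    return url  # bare file path (or :memory:)


@dataclass
class StoreConfig:
    """Connection settings, parseable from either config-file dialect."""

    url: str
    user: Optional[str] = None
    password: Optional[str] = None
    driver: Optional[str] = None

    @property
    def path(self) -> str:
        return _url_to_path(self.url)

    @classmethod
    def from_file(cls, path: Union[str, Path]) -> "StoreConfig":
        """Parse a key-value config file.

        Accepts the ``db_string``/``db_user``/``db_password`` dialect and the
        ``statsdb.url``/``statsdb.username``/``statsdb.password``/
        ``statsdb.driver`` dialect; ``key<whitespace>value`` or ``key=value``
        lines; ``#`` starts a comment.
        """
        fields: dict[str, str] = {}
        text = Path(path).read_text(encoding="utf-8")
        for raw in text.splitlines():
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if "=" in line and (line.split("=", 1)[0].strip() in _JAVA_KEYS
                                or not any(c.isspace() for c in line.split("=", 1)[0].strip())):
                key, _, value = line.partition("=")
            else:
                parts = line.split(None, 1)
                key, value = parts[0], parts[1] if len(parts) > 1 else ""
            key = key.strip()
            value = value.strip()
            if key in _PERL_KEYS:
                fields[_PERL_KEYS[key]] = value
            elif key in _JAVA_KEYS:
                fields[_JAVA_KEYS[key]] = value
        if "url" not in fields:
            raise ConfigError(
                f"config file {path} defines neither 'db_string' nor 'statsdb.url'"
            )
        return cls(**fields)

    @classmethod
    def coerce(cls, source: Union["StoreConfig", str, Path]) -> "StoreConfig":
        """Accept a StoreConfig, a config-file path, or a bare database path."""
        if isinstance(source, StoreConfig):
            return source
        p = Path(source)
        if p.is_file():
            head = p.read_bytes()[:512]
            if b"db_string" in head or b"statsdb.url" in head:
                return cls.from_file(p)
        return cls(url=str(source))


class Store:
    """Open handle on the relational store. Use :func:`connect` to obtain one."""

    def __init__(self, config: StoreConfig):
        self.config = config
        try:
            self._conn: Optional[sqlite3.Connection] = sqlite3.connect(config.path)
        except sqlite3.Error as exc:
            raise ConfigError(f"cannot open database at {config.path!r}: {exc}") from exc
        self._conn.execute("PRAGMA foreign_keys = ON")
        self._ensure_schema()

    # -- lifecycle ---------------------------------------------------------

    def _ensure_schema(self) -> None:
        cur = self._conn.execute(
            "SELECT name FROM sqlite_master WHERE type='table' AND name='analysis'"
        )
        if cur.fetchone() is None:
            self._conn.executescript(_SCHEMA)
            self._conn.executemany(
                "INSERT OR IGNORE INTO type_scope(scope) VALUES (?)",
                [(s,) for s in SCOPES],
            )
            self._conn.commit()

    @property
    def conn(self) -> sqlite3.Connection:
        if self._conn is None:
            raise StoreClosedError("store has been disconnected")
        return self._conn

    @property
    def closed(self) -> bool:
        return self._conn is None

    def disconnect(self) -> None:
        """Close the handle; idempotent."""
        if self._conn is not None:
            self._conn.close()
            self._conn = None

    close = disconnect

    def __enter__(self) -> "Store":
        return self

    def __exit__(self, *exc) -> None:
        self.disconnect()

    # -- insert path -------------------------------------------------------

    def _value_type_id(self, cur: sqlite3.Cursor, key: str, scope: str) -> int:
        row = cur.execute(
            "SELECT vt.id, ts.scope FROM value_type vt "
            "JOIN type_scope ts ON ts.id = vt.type_scope_id WHERE vt.value_key = ?",
            (key,),
        ).fetchone()
        if row is not None:
            vt_id, existing_scope = row
            if existing_scope != scope:
                raise ScopeError(
                    f"value type {key!r} already stored with scope {existing_scope!r}, "
                    f"conflicting scope {scope!r} rejected"
                )
            return vt_id
        cur.execute(
            "INSERT INTO value_type(value_key, type_scope_id) "
            "VALUES (?, (SELECT id FROM type_scope WHERE scope = ?))",
            (key, scope),
        )
        return cur.lastrowid

    def insert_analysis(self, analysis: QCAnalysis) -> int:
        """Persist one builder-validated analysis atomically; return its id.

        Value types not yet in the store are registered on the fly; a scope
        conflict with an existing value type aborts the whole insert.
        """
        conn = self.conn
        cur = conn.cursor()
        try:
            timestamp = datetime.now(timezone.utc).isoformat()
            cur.execute("INSERT INTO analysis(timestamp) VALUES (?)", (timestamp,))
            analysis_id = cur.lastrowid

            cur.executemany(
                "INSERT INTO analysis_property(analysis_id, property, value) VALUES (?,?,?)",
                [(analysis_id, k, v) for k, v in analysis.properties.items()],
            )

            type_ids = {
                key: self._value_type_id(cur, key, scope)
                for key, scope in analysis.valid_types.items()
            }

            for gv in analysis.general_values:
                numeric = gv.value if isinstance(gv.value, float) else None
                text = gv.value if isinstance(gv.value, str) else None
                cur.execute(
                    "INSERT INTO analysis_value(analysis_id, value_type_id, value, text_value) "
                    "VALUES (?,?,?,?)",
                    (analysis_id, type_ids[gv.key], numeric, text),
                )
                if gv.description is not None:
                    # first description wins; later ones are ignored
                    cur.execute(
                        "UPDATE value_type SET description = ? "
                        "WHERE id = ? AND description IS NULL",
                        (gv.description, type_ids[gv.key]),
                    )

            cur.executemany(
                "INSERT INTO per_position_value(analysis_id, value_type_id, position, value) "
                "VALUES (?,?,?,?)",
                [(analysis_id, type_ids[pv.key], pv.position, pv.value)
                 for pv in analysis.position_values],
            )
            cur.executemany(
                "INSERT INTO per_partition_value"
                "(analysis_id, value_type_id, position_start, position_end, value) "
                "VALUES (?,?,?,?,?)",
                [(analysis_id, type_ids[pv.key], pv.range.start, pv.range.end, pv.value)
                 for pv in analysis.partition_values],
            )
        except Exception:
            conn.rollback()
            raise
        conn.commit()
        return analysis_id

    # -- views and queries -------------------------------------------------

    def analysis_count(self) -> int:
        return self.conn.execute("SELECT COUNT(*) FROM analysis").fetchone()[0]

    def row_counts(self) -> dict[str, int]:
        """Row count per table (useful for atomicity and test-mode checks)."""
        return {
            t: self.conn.execute(f"SELECT COUNT(*) FROM {t}").fetchone()[0]
            for t in _TABLES
        }

    def properties_by_analysis(self) -> dict[int, dict[str, str]]:
        out: dict[int, dict[str, str]] = {
            row[0]: {} for row in self.conn.execute("SELECT id FROM analysis")
        }
        for aid, prop, value in self.conn.execute(
            "SELECT analysis_id, property, value FROM analysis_property"
        ):
            out[aid][prop] = value
        return out

    def property_view(self) -> pd.DataFrame:
        """Pivot of analysis properties: one row per analysis, keys as columns.

        Missing properties are empty cells (NaN); the column set is the union
        of property keys present in the store.
        """
        props = self.properties_by_analysis()
        df = pd.DataFrame.from_dict(props, orient="index")
        df.index.name = "analysis_id"
        return df.sort_index()

    def matching_ids(self, properties: dict[str, str]) -> list[int]:
        """Ids of analyses whose properties satisfy every (key, value) pair."""
        props = self.properties_by_analysis()
        return sorted(
            aid for aid, p in props.items()
            if all(p.get(k) == str(v) for k, v in properties.items())
        )

    def latest_analysis_ids(self, properties: Optional[dict[str, str]] = None) -> list[int]:
        """Matching ids reduced to the newest analysis per identity tuple.

        Identity is the property tuple over :data:`IDENTITY_KEYS`; among
        records sharing an identity, the newest timestamp wins and ties break
        to the highest id.
        """
        properties = properties or {}
        ids = self.matching_ids(properties)
        if not ids:
            return []
        props = self.properties_by_analysis()
        stamps = dict(self.conn.execute("SELECT id, timestamp FROM analysis"))
        best: dict[tuple, int] = {}
        for aid in ids:
            identity = tuple(props[aid].get(k) for k in IDENTITY_KEYS)
            cur = best.get(identity)
            if cur is None or (stamps[aid], aid) > (stamps[cur], cur):
                best[identity] = aid
        return sorted(best.values())

    def value_types(self) -> list[tuple[str, str, Optional[str]]]:
        """All registered value types as (key, scope, description)."""
        return list(self.conn.execute(
            "SELECT vt.value_key, ts.scope, vt.description FROM value_type vt "
            "JOIN type_scope ts ON ts.id = vt.type_scope_id ORDER BY vt.value_key"
        ))

    def scope_of(self, key: str) -> Optional[str]:
        row = self.conn.execute(
            "SELECT ts.scope FROM value_type vt "
            "JOIN type_scope ts ON ts.id = vt.type_scope_id WHERE vt.value_key = ?",
            (key,),
        ).fetchone()
        return row[0] if row else None


def connect(config: Union[StoreConfig, str, Path]) -> Store:
    """Open a store; creates the schema on first use of an empty database."""
    return Store(StoreConfig.coerce(config))


def _in_clause(ids: Sequence[int]) -> str:
    return ",".join(str(int(i)) for i in ids)
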