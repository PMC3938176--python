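# qcstore

Platform-agnostic, tool-independent storage and querying of sequencing-run QC
metrics. QC-tool output (FastQC reports, driven by a tab-delimited
analysis-metadata table) is parsed into an embedded relational store; granular
summary queries (per run, lane, barcode, instrument, ...) come back as CSV/JSON
report tables ready for plotting.

## Layout

| module               | role |
|----------------------|------|
| `qcstore.model`      | in-memory `QCAnalysis` builder: properties, value-type registry (scopes `analysis`, `base_partition`, `sequence_cumulative`), per-position / per-partition / global values, `parse_range` |
| `qcstore.datastore`  | sqlite-backed append-only store: atomic `insert_analysis`, property pivot view, latest-wins id resolution, both config-file dialects |
| `qcstore.parsers`    | metadata-table reader, the FastQC report parser, a case-insensitive parser registry, and the batch `load` wrapper (with test mode) |
| `qcstore.reports`    | consumer queries: run/property listings, per-scope summaries, averaged per-position / per-partition tables, base-content matrix, `ReportTable` CSV/JSON serialization |
| `qcstore.fixtures`   | seeded synthetic FastQC reports + metadata tables with exact ground truth |
| `qcstore.cli`        | `qcstore load | query | list | generate` |

## CLI

```sh
# generate a synthetic report + one-line metadata table
qcstore generate --out fastqc_data.txt --metadata-out meta.tsv --run RUN-123 --seed 7

# load it (use -t for test mode: parse/validate, write nothing)
qcstore load -m meta.tsv --db qc.db

# or load a single report directly
qcstore load -f fastqc_data.txt -r RUN-123 --db qc.db

# query (any subset of --run --lane --pair --barcode --sample --instrument
# --encoding --chemistry --software --experiment-type; full identity filters
# return only the latest analysis)
qcstore query partitions quality_mean --run RUN-123 --lane 1 --db qc.db
qcstore query positions quality_score_count --db qc.db --format json
qcstore query averages --db qc.db
qcstore query base-content --db qc.db

# listings
qcstore list runs --db qc.db
qcstore list values lane --db qc.db
qcstore list types base_partition --db qc.db
```

`--db` takes either a sqlite database path or a key-value config file
(`db_string`/`db_user`/`db_password` or `statsdb.url`/`statsdb.username`/...);
without it, `$QCSTORE_DB` and then `./qcstore.properties` /
`./statsdb.properties` are consulted. Exit codes: 0 success, 1 usage error,
2 partial load failure, 3 config/connection failure.

## Python API

```python
from qcstore import connect, new_analysis, parse_range
from qcstore.reports import PropertyFilter, get_per_partition_values

a = new_analysis()
a.add_property("tool", "FastQC")
a.add_property("run", "RUN-123")
a.add_valid_type("quality_mean", "base_partition")
a.add_partition_value(parse_range("10-14"), "quality_mean", 38.7)

store = connect("qc.db")
store.insert_analysis(a)
table = get_per_partition_values(store, "quality_mean", PropertyFilter(run="RUN-123"))
print(table.to_csv())
store.disconnect()
```

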