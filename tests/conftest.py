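import pytest

from qcstore import connect, new_analysis, parse_range
from qcstore.reports import PropertyFilter


@pytest.fixture
def store():
    """Fresh in-memory store."""
    s = connect(":memory:")
    yield s
    s.disconnect()


@pytest.fixture
def file_store(tmp_path):
    """Fresh file-backed store (for persistence/bit-identity tests)."""
    path = tmp_path / "qc.sqlite"
    s = connect(str(path))
    yield s, path
    s.disconnect()


def build_worked_analysis():
    """The worked example analysis: FastQC tool, one value per scope."""
    a = new_analysis()
    a.add_property("tool", "FastQC")
    a.add_property("run", "RUN-123")
    a.add_property("lane", "1")
    a.add_property("pair", "1")
    a.add_property("barcode", "ACCGTT")
    a.add_property("sample_name", "SAMPLE-1")
    a.add_valid_type("quality_score_count", "sequence_cumulative")
    a.add_valid_type("quality_mean", "base_partition")
    a.add_valid_type("average_length", "analysis")
    a.add_valid_type("ACCTGATAT", "analysis")
    a.add_position_value(30, "quality_score_count", 15000)
    a.add_partition_value(parse_range("10-14"), "quality_mean", 38.7)
    a.add_general_value("average_length", 100)
    a.add_general_value("ACCTGATAT", 10, "over-represented common primer in library A")
    return a


@pytest.fixture
def worked_analysis():
    return build_worked_analysis()


@pytest.fixture
def full_filter():
    """Fully-specified identity filter matching the worked analysis."""
    return PropertyFilter(
        run="RUN-123", lane="1", pair="1", barcode="ACCGTT", sampleName="SAMPLE-1"
    )
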