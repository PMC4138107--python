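import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def registry():
    from aedes_ptp.motifs import default_registry
    return default_registry()


@pytest.fixture(scope="session")
def table1():
    """Packaged per-domain motif strings and published statuses."""
    from aedes_ptp.motifs import load_table1_fixture
    return load_table1_fixture()


@pytest.fixture(scope="session")
def table1_annotations():
    """The fixture proteome scanned and classified once per session."""
    from aedes_ptp.domains import scan_proteome
    from aedes_ptp.repertoire import annotate_verdicts
    from aedes_ptp.synth import table1_proteome
    records, truth = table1_proteome(seed=0)
    return records, truth, annotate_verdicts(scan_proteome(records))
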