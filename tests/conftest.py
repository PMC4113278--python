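import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def reference_compounds():
    from netpharm.tables import load_reference_compounds

    return load_reference_compounds()


@pytest.fixture(scope="session")
def reference_metabolites():
    from netpharm.tables import load_reference_metabolites

    return load_reference_metabolites()


@pytest.fixture(scope="session")
def reference_peaks():
    from netpharm.tables import load_reference_peaks

    return load_reference_peaks()
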