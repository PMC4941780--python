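import pytest
from hypothesis import HealthCheck, settings

import protowing as pw

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def specimens():
    return pw.load_packaged_specimens()


@pytest.fixture(scope="session")
def reference_bw():
    return pw.load_packaged_reference_bw()


@pytest.fixture(scope="session")
def extant_table():
    return pw.load_packaged_extant_validation()


@pytest.fixture(scope="session")
def calibrated_models(specimens, reference_bw):
    return pw.calibrate_from_reference(specimens, reference_bw)


@pytest.fixture(scope="session")
def by_key(specimens):
    return {r.key: r for r in specimens}


@pytest.fixture(scope="session")
def microraptor_ph881(by_key):
    return by_key[("Microraptor gui", "BMNHC PH 881", "CF")]
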