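import pytest

import acatpk as ap


@pytest.fixture(scope="session")
def drug():
    return ap.gemcitabine()


@pytest.fixture(scope="session")
def subject():
    return ap.default_subject()


@pytest.fixture(scope="session")
def physiology():
    return ap.default_human_physiology()


@pytest.fixture(scope="session")
def study():
    """Calibrated six-regimen gemcitabine study (calibration runs once)."""
    return ap.run_study()
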