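import pytest

from terradose import DoseCoefficients, load_survey_table


@pytest.fixture(scope="session")
def survey():
    """The bundled 26-sample soil survey."""
    return load_survey_table()


@pytest.fixture(scope="session")
def coeff():
    return DoseCoefficients()
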