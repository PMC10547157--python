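import pytest

import apkpath as ap


@pytest.fixture(scope="session")
def registry():
    return ap.default_registry()


@pytest.fixture(scope="session")
def params():
    return ap.default_parameters()


@pytest.fixture(scope="session")
def f6p_design():
    return ap.generate("F6P", "fls")


@pytest.fixture(scope="session")
def xu5p_design():
    return ap.generate("Xu5P", "fls")


@pytest.fixture(scope="session")
def f6p_timecourse(f6p_design, params):
    return ap.simulate(f6p_design, params, {"F6P": 10.0})


@pytest.fixture(scope="session")
def xu5p_timecourse(xu5p_design, params):
    return ap.simulate(xu5p_design, params, {"Xu5P": 10.0})
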