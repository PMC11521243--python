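import pytest

from sedem_odt import datasets


@pytest.fixture(scope="session")
def api_excipient_table():
    return datasets.load_api_excipient_radii()


@pytest.fixture(scope="session")
def blend_table():
    return datasets.load_blend_radii()


@pytest.fixture(scope="session")
def design_table():
    return datasets.load_design_compositions()


@pytest.fixture(scope="session")
def quality_table():
    return datasets.load_quality_attributes()


@pytest.fixture(scope="session")
def kinetics_table():
    return datasets.load_kinetics_table()


@pytest.fixture(scope="session")
def classic_profiles():
    return {p.label: p for p in datasets.radius_profiles("classic12")}


@pytest.fixture(scope="session")
def blend_profiles():
    return {p.label: p for p in datasets.radius_profiles("odt15")}


@pytest.fixture(scope="session")
def stability_table():
    return {s.label: s for s in datasets.stability_series()}
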