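import pytest

from helixscan.simulate import GeneratorConfig, fixtures_tables_1_2


@pytest.fixture(scope="session")
def library_table():
    """The packaged 50-row MDM2 stapled-peptide library transcription."""
    return fixtures_tables_1_2()


@pytest.fixture
def noiseless_cfg():
    return GeneratorConfig(seed=0, sigma_r=0.0, sigma_response=0.0, sigma_mdeg=0.0)
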