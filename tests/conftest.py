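import pytest

from cyp2c19_cea import default_life_table, null_effect_parameters, paper_default_parameters


@pytest.fixture(scope="session")
def paper_params():
    return paper_default_parameters()


@pytest.fixture(scope="session")
def null_params():
    return null_effect_parameters()


@pytest.fixture(scope="session")
def life_table():
    return default_life_table()


@pytest.fixture(scope="session")
def base_case(paper_params, life_table):
    from cyp2c19_cea import run_base_case

    return run_base_case(paper_params, life_table)
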