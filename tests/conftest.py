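import pytest

from cawi import simulate


@pytest.fixture(scope="session")
def default_panel():
    """Default synthetic panel (94 institutions x 5 years), seed 1."""
    panel, truth = simulate.generate_panel(simulate.default_params(seed=1))
    return panel, truth


@pytest.fixture(scope="session")
def small_panel():
    """A 12-institution, 2-year panel for fast structural tests."""
    params = simulate.GeneratorParams(n_institutions=12, years=(2019, 2020), seed=7)
    panel, truth = simulate.generate_panel(params)
    return panel, truth
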