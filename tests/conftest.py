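import warnings

import pytest

from endonet import CoexpressionNetwork, SyntheticConfig, generate_expression_matrix


@pytest.fixture(scope="session")
def default_dataset():
    """One default synthetic study (matrix + planted truth)."""
    return generate_expression_matrix(config=SyntheticConfig(seed=3))


@pytest.fixture(scope="session")
def fitted_network(default_dataset):
    """Co-expression network fitted on the default synthetic study."""
    expr, _ = default_dataset
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return CoexpressionNetwork().fit(expr.values.T)
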