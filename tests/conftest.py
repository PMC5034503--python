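import pytest

from quadme.arith import ArithmeticContext
from quadme.nlp_solve import solve_me
from quadme.synthetic import (make_analytic_model, make_coupled_complex_model,
                              make_multiscale_model, make_two_pathway_model)


@pytest.fixture(scope="session")
def ctx():
    return ArithmeticContext.quad()


@pytest.fixture(scope="session")
def ctx_double():
    return ArithmeticContext.double()


@pytest.fixture()
def analytic_model():
    return make_analytic_model()


@pytest.fixture()
def coupled_model():
    return make_coupled_complex_model()


@pytest.fixture()
def two_pathway_model():
    return make_two_pathway_model()


@pytest.fixture(scope="session")
def multiscale_model():
    return make_multiscale_model(seed=42)


@pytest.fixture(scope="session")
def multiscale_solution(multiscale_model, ctx):
    return solve_me(multiscale_model, ctx=ctx)
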