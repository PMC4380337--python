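import pytest
import sympy as sp

from dsrstab.fixtures import make_classical_network


@pytest.fixture(scope="session")
def bundles():
    """All classical network bundles, built once per session."""
    names = (
        "jenkin_maxwell",
        "van_der_pol",
        "lotka_volterra",
        "brusselator",
        "selkov",
        "repressilator",
        "repressilator_positive",
    )
    return {name: make_classical_network(name) for name in names}


def instantiate_at_params(reduced, values):
    """Edge weights that realize given reduced-parameter values.

    One representative edge per parameter group carries the value, the rest
    are 1, and the temporal unit group is all-ones (beta = 1); by
    construction ``reduced.parameter_values`` recovers ``values`` exactly.
    """
    weights = {}
    for sym in reduced.base.free_symbols():
        weights[str(sym)] = sp.Integer(1)
    beta_syms = reduced.beta.free_symbols
    for name, value in values.items():
        target = sp.Symbol(str(name), positive=True)
        definition = reduced.definitions[target]
        own = sorted(definition.free_symbols - beta_syms, key=str)
        assert own, f"parameter {name} has no symbol outside the temporal unit"
        weights[str(own[0])] = sp.nsimplify(value, rational=True)
    params = reduced.parameter_values(weights)
    for name, value in values.items():
        assert params[sp.Symbol(str(name), positive=True)] == sp.nsimplify(value, rational=True)
    return weights
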