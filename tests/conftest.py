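import pytest

from pembrocea import load_bundled
from pembrocea.parameters import Parameter, ParameterSet


@pytest.fixture(scope="session")
def nonsq_params():
    return load_bundled("non_squamous")


@pytest.fixture(scope="session")
def sq_params():
    return load_bundled("squamous")


def all_fixed(ps: ParameterSet) -> ParameterSet:
    """Copy of a parameter set with every distribution degenerate."""
    frozen = {
        name: Parameter(name, p.value, p.value, p.value, "fixed", p.kind)
        for name, p in ps.parameters.items()
    }
    return ParameterSet(ps.histology, frozen, ps.regimens)


@pytest.fixture()
def nonsq_fixed(nonsq_params):
    return all_fixed(nonsq_params)
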