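import pytest

from amirnakit.scaffold_core import ViennaFold
from amirnakit.design_engine import (
    ModificationSpec,
    apply_all,
    apply_base_modification,
    embed_duplex,
)
from amirnakit.fixtures import SCREENING_GUIDE, pri_let7a1, pri_mir26b


@pytest.fixture(scope="session")
def service():
    return ViennaFold()


@pytest.fixture(scope="session")
def spec():
    return ModificationSpec()


@pytest.fixture(scope="session")
def let7a1():
    return pri_let7a1()


@pytest.fixture(scope="session")
def mir26b():
    return pri_mir26b()


@pytest.fixture(scope="session")
def base_scaffold_let7(let7a1, spec, service):
    return apply_base_modification(let7a1, spec, service, seed=0)


@pytest.fixture(scope="session")
def all_scaffold_26b(mir26b, spec, service):
    return apply_all(mir26b, spec, service, seed=0)


@pytest.fixture(scope="session")
def grafted_scaffold(all_scaffold_26b, spec, service):
    """The all-modification mir-26b scaffold carrying the 22-nt screening guide."""
    return embed_duplex(
        all_scaffold_26b, SCREENING_GUIDE, spec=spec, service=service, seed=0
    )
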