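import pytest

from adaptiveq import ConditionOrder, compile_all, load_fixture


@pytest.fixture(scope="session")
def d2d6():
    """The two formalized STOPP/START rules only."""
    return load_fixture("stoppstart_d2d6")


@pytest.fixture(scope="session")
def demo():
    """D2 + D6 plus the eight illustrative rules."""
    return load_fixture("stoppstart_demo")


@pytest.fixture(scope="session")
def decl_order(d2d6):
    """Catalogue declaration order: constipation ≺ diverticulosis ≺ ..."""
    return ConditionOrder(d2d6.clinical_ids)


@pytest.fixture(scope="session")
def d2d6_rules(d2d6, decl_order):
    return compile_all(d2d6, decl_order)
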