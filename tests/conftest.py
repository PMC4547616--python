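import pytest

from lipidforge.assembly import SlotAssignment, SlotFill, make_isomeric
from lipidforge.building_blocks import (
    FATTY_ACID,
    FATTY_ALCOHOL,
    ALKENYL,
    ESTER,
    ChainDescriptor,
    default_templates,
)


def _Z(*positions):
    return tuple((p, "Z") for p in positions)


@pytest.fixture(scope="session")
def palmitic():
    return ChainDescriptor(FATTY_ACID, 16, 0, (), "palmitic acid")


@pytest.fixture(scope="session")
def oleic():
    return ChainDescriptor(FATTY_ACID, 18, 1, _Z(9), "oleic acid")


@pytest.fixture(scope="session")
def arachidonic():
    return ChainDescriptor(FATTY_ACID, 20, 4, _Z(5, 8, 11, 14), "arachidonic acid")


@pytest.fixture(scope="session")
def hexadecanol():
    return ChainDescriptor(FATTY_ALCOHOL, 16, 0, (), "hexadecanol")


@pytest.fixture(scope="session")
def templates_by_subclass():
    return {t.subclass_name: t for t in default_templates()}


@pytest.fixture(scope="session")
def diacyl_pc(templates_by_subclass):
    return templates_by_subclass["Diacylglycerophosphocholine"]


@pytest.fixture(scope="session")
def ether_pc(templates_by_subclass):
    return templates_by_subclass["Monoalkylmonoacylglycerophosphocholine"]


@pytest.fixture(scope="session")
def lyso_pc(templates_by_subclass):
    return templates_by_subclass["Monoacylglycerophosphocholine"]


@pytest.fixture(scope="session")
def tag(templates_by_subclass):
    return templates_by_subclass["Triacylglycerol"]


@pytest.fixture(scope="session")
def pc_16_0_18_1(diacyl_pc, palmitic, oleic):
    """PC(16:0/18:1(9Z)) — the stock worked example."""
    assignment = SlotAssignment(
        diacyl_pc, {1: SlotFill(palmitic, ESTER), 2: SlotFill(oleic, ESTER)}
    )
    return make_isomeric(diacyl_pc, assignment)


@pytest.fixture(scope="session")
def plasmalogen_pc(ether_pc, hexadecanol, arachidonic):
    """PC(P-16:0/20:4(5Z,8Z,11Z,14Z)) — the published hierarchy example."""
    assignment = SlotAssignment(
        ether_pc, {1: SlotFill(hexadecanol, ALKENYL), 2: SlotFill(arachidonic, ESTER)}
    )
    return make_isomeric(ether_pc, assignment)
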