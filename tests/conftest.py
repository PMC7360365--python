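import math

import pytest

from glycompart import (
    Compartment,
    EnzymeRule,
    MonomerType,
    Oligomer,
    PromiscuityClass,
    make_alphabet,
    parse_oligomer,
)


@pytest.fixture(scope="session")
def blood_alphabet():
    """GlcNAc/Gal/Fuc alphabet used by the blood-group worked example."""
    return make_alphabet(
        MonomerType("GlcNAc", frozenset({3, 4, 6}), 1),
        MonomerType("Gal", frozenset({2, 3, 4, 6}), 1),
        MonomerType("Fuc", frozenset({2}), 1),
    )


@pytest.fixture(scope="session")
def lac(blood_alphabet):
    """The Gal-GlcNAc core the B-antigen grows from."""
    return parse_oligomer("Gal(3-1)GlcNAc", blood_alphabet)


@pytest.fixture(scope="session")
def h_antigen(blood_alphabet):
    return parse_oligomer("[Fuc(2-1)]Gal(3-1)GlcNAc", blood_alphabet)


@pytest.fixture(scope="session")
def b_antigen(blood_alphabet):
    return parse_oligomer("[Fuc(2-1)][Gal(3-1)]Gal(3-1)GlcNAc", blood_alphabet)


@pytest.fixture(scope="session")
def fut2_cf(blood_alphabet):
    """Promiscuous (context-free) fucosyltransferase: Fuc onto Gal carbon 2."""
    return EnzymeRule("Fut2CF", blood_alphabet["Fuc"], blood_alphabet["Gal"], 2)


@pytest.fixture(scope="session")
def gtb_bs(blood_alphabet):
    """Branch-sensitive galactosyltransferase: Gal onto Gal carbon 3,
    requiring a fucose branch at carbon 2."""
    return EnzymeRule(
        "GTB",
        blood_alphabet["Gal"],
        blood_alphabet["Gal"],
        3,
        promiscuity_class=PromiscuityClass.BRANCH_SENSITIVE,
        required_branches=frozenset({(2, Oligomer(blood_alphabet["Fuc"]))}),
    )


@pytest.fixture(scope="session")
def one_compartment(fut2_cf, gtb_bs):
    return Compartment(frozenset({fut2_cf, gtb_bs}), math.inf)


@pytest.fixture(scope="session")
def two_compartments(fut2_cf, gtb_bs):
    return [
        Compartment(frozenset({fut2_cf}), math.inf),
        Compartment(frozenset({gtb_bs}), math.inf),
    ]
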