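"""Random generators and named scenarios for reproducible experiments.

The named scenarios mirror the canonical observations motivating the
framework: blood-group B-antigen synthesis (two promiscuous enzymes that
fail in one compartment but succeed in two), and hypothetical enzyme
sets producing the three empirically observed variability patterns —
mucin-like (truncated), human-chorionic-gonadotropin-like (divergent,
1:1:2 inputs to the final compartment) and horse-chorionic-gonadotropin-
like (runaway tandem repeats).  The enzyme sets for the variability
scenarios are hypothetical reconstructions chosen to exhibit the stated
cause; they are not measured enzyme complements.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .diagnostics import Compartment
from .enzymes import EnzymeRule, PromiscuityClass, make_ideal_enzyme
from .oligomer import (
    Alphabet,
    MonomerType,
    Oligomer,
    add_monomer,
    free_sites,
    make_alphabet,
    parse_oligomer,
)

__all__ = [
    "FixtureSpec",
    "Scenario",
    "generate_random_oligomer",
    "generate_random_enzyme_library",
    "builtin_fixtures",
]


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of the random oligomer / enzyme-library generators.

    The defaults describe a small, chemistry-like universe: a handful of
    monomer types with acceptor carbons drawn from {2,3,4,6} and the
    anomeric carbon 1 as the donor position (kept out of the acceptor
    set, as in glycosidic chemistry).
    """

    alphabet_size: int = 3
    acceptor_carbons: frozenset[int] = frozenset({2, 3, 4, 6})
    carbons_per_type: int = 2
    max_oligomer_size: int = 5
    class_mix: tuple[tuple[str, float], ...] = (
        ("context_free", 0.5),
        ("branch_sensitive", 0.3),
        ("root_sensitive", 0.2),
    )
    library_size: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.alphabet_size, self.max_oligomer_size, self.library_size,
               self.carbons_per_type) < 1:
            raise ValueError("all fixture sizes must be positive")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    def alphabet(self) -> dict[str, MonomerType]:
        rng = np.random.default_rng(self.seed ^ 0x5F5F)
        carbons = sorted(self.acceptor_carbons)
        types = []
        for i in range(self.alphabet_size):
            k = min(self.carbons_per_type, len(carbons))
            chosen = rng.choice(carbons, size=k, replace=False)
            types.append(MonomerType(f"M{i}", frozenset(int(c) for c in chosen), 1))
        return make_alphabet(*types)


def generate_random_oligomer(
    spec: FixtureSpec,
    rng: np.random.Generator | None = None,
    alphabet: Alphabet | None = None,
) -> Oligomer:
    """A random rooted tree respecting each type's carbon constraints;
    deterministic for a given seed/generator."""
    rng = spec.rng() if rng is None else rng
    alphabet = spec.alphabet() if alphabet is None else alphabet
    types = list(alphabet.values())
    size = int(rng.integers(1, spec.max_oligomer_size + 1))
    o = Oligomer(types[rng.integers(len(types))])
    for _ in range(size - 1):
        sites = free_sites(o)
        if not sites:
            break
        s = sites[rng.integers(len(sites))]
        donor = types[rng.integers(len(types))]
        o = add_monomer(o, s, donor)
    return o


def _random_class(spec: FixtureSpec, rng: np.random.Generator) -> PromiscuityClass:
    names = [n for n, _ in spec.class_mix]
    weights = np.array([w for _, w in spec.class_mix], dtype=float)
    weights = weights / weights.sum()
    return PromiscuityClass.coerce(names[rng.choice(len(names), p=weights)])


def generate_random_enzyme_library(
    spec: FixtureSpec,
    rng: np.random.Generator | None = None,
    alphabet: Alphabet | None = None,
) -> list[EnzymeRule]:
    """Random rules with valid carbons and class-appropriate constraints,
    built through the ideal-enzyme constructor from random contexts."""
    rng = spec.rng() if rng is None else rng
    alphabet = spec.alphabet() if alphabet is None else alphabet
    types = list(alphabet.values())
    rules: list[EnzymeRule] = []
    attempts = 0
    while len(rules) < spec.library_size and attempts < 50 * spec.library_size:
        attempts += 1
        cls = _random_class(spec, rng)
        context = generate_random_oligomer(spec, rng, alphabet)
        sites = free_sites(context)
        if not sites:
            continue
        s = sites[rng.integers(len(sites))]
        donor = types[rng.integers(len(types))]
        if cls is PromiscuityClass.CONTEXT_FREE:
            # context irrelevant: keep only the bond
            from .oligomer import get_node

            node = get_node(context, s.node_path)
            rule = EnzymeRule(
                name=f"E{len(rules)}",
                donor_type=donor,
                acceptor_type=node.type,
                acceptor_carbon=s.carbon,
                promiscuity_class=cls,
            )
        else:
            rule = make_ideal_enzyme(
                cls, context, s, donor, name=f"E{len(rules)}",
            )
        rules.append(rule)
    return rules


# -- named scenarios ---------------------------------------------------------


@dataclass
class Scenario:
    """A named, self-contained experiment: alphabet, compartment series,
    input, optional target, and what the scenario illustrates."""

    name: str
    description: str
    alphabet: dict[str, MonomerType]
    series: list[Compartment]
    input: Oligomer
    target: Oligomer | None = None
    library: list[EnzymeRule] = field(default_factory=list)


def _b_antigen() -> Scenario:
    ab = make_alphabet(
        MonomerType("GlcNAc", frozenset({3, 4, 6}), 1),
        MonomerType("Gal", frozenset({2, 3, 4, 6}), 1),
        MonomerType("Fuc", frozenset({2}), 1),
    )
    fut2 = EnzymeRule("Fut2CF", ab["Fuc"], ab["Gal"], 2)
    gtb = EnzymeRule(
        "GTB",
        ab["Gal"],
        ab["Gal"],
        3,
        promiscuity_class=PromiscuityClass.BRANCH_SENSITIVE,
        required_branches=frozenset({(2, Oligomer(ab["Fuc"]))}),
    )
    return Scenario(
        name="b_antigen",
        description=(
            "Blood-group B-antigen synthesis with a context-free "
            "fucosyltransferase and a branch-sensitive "
            "galactosyltransferase: one shared compartment runs away into "
            "tandem repeats; two compartments restore specific synthesis."
        ),
        alphabet=ab,
        series=[
            Compartment(frozenset({fut2}), math.inf),
            Compartment(frozenset({gtb}), math.inf),
        ],
        input=parse_oligomer("Gal(3-1)GlcNAc", ab),
        target=parse_oligomer("[Fuc(2-1)][Gal(3-1)]Gal(3-1)GlcNAc", ab),
        library=[fut2, gtb],
    )


def _mucin_like() -> Scenario:
    """Truncated-convergent: two independent decorations of the core; at
    intermediate residence times partially grown intermediates exit."""
    ab = make_alphabet(
        MonomerType("Core", frozenset({2, 3, 6}), 1),
        MonomerType("Gal", frozenset({3}), 1),
        MonomerType("GlcNAc", frozenset({4}), 1),
    )
    e1 = EnzymeRule("add_Gal", ab["Gal"], ab["Core"], 3)
    e2 = EnzymeRule("add_GlcNAc", ab["GlcNAc"], ab["Core"], 6)
    return Scenario(
        name="mucin_like",
        description=(
            "Hypothetical truncated-convergent compartment: two "
            "context-free enzymes decorate distinct carbons of the core, "
            "so every fork reconverges and the unique terminal carries "
            "both branches; finite residence time releases intermediates "
            "(mucin-like mixtures of partial structures)."
        ),
        alphabet=ab,
        series=[Compartment(frozenset({e1, e2}), 5.0)],
        input=Oligomer(ab["Core"]),
        target=parse_oligomer("[Gal(3-1)][GlcNAc(6-1)]Core", ab),
    )


def _human_cg_like() -> Scenario:
    """Divergent upstream stage yielding a 1:1:2 input mixture (1.5 bits)
    to the probed final compartment."""
    ab = make_alphabet(
        MonomerType("Core", frozenset({2, 3, 4}), 1),
        MonomerType("Gal", frozenset({2}), 1),
        MonomerType("Sia", frozenset({2}), 1),
        MonomerType("Fuc", frozenset({2}), 1),
    )
    f1 = EnzymeRule("branch_Gal", ab["Gal"], ab["Core"], 2)
    f2 = EnzymeRule("branch_Sia", ab["Sia"], ab["Core"], 2)
    f3 = EnzymeRule(
        "cap_Gal",
        ab["Gal"],
        ab["Core"],
        3,
        promiscuity_class=PromiscuityClass.BRANCH_SENSITIVE,
        required_branches=frozenset({(2, Oligomer(ab["Gal"]))}),
    )
    f4 = EnzymeRule(
        "cap_Sia",
        ab["Sia"],
        ab["Core"],
        3,
        promiscuity_class=PromiscuityClass.BRANCH_SENSITIVE,
        required_branches=frozenset({(2, Oligomer(ab["Gal"]))}),
    )
    # final stage: one further context-free decoration of the core
    g1 = EnzymeRule("late_Fuc", ab["Fuc"], ab["Core"], 4)
    return Scenario(
        name="human_cg_like",
        description=(
            "Hypothetical divergent scenario: upstream competition for "
            "the same acceptor carbon splits the flux 1:1:2 over three "
            "oligomers (input entropy 1.5 bits to the final "
            "compartment); the final compartment's convergent decoration "
            "lets the entropy fall back toward the input entropy at "
            "long residence times."
        ),
        alphabet=ab,
        series=[
            Compartment(frozenset({f1, f2, f3, f4}), math.inf),
            Compartment(frozenset({g1}), 5.0),
        ],
        input=Oligomer(ab["Core"]),
    )


def _horse_cg_like() -> Scenario:
    ab = make_alphabet(
        MonomerType("Core", frozenset({3}), 1),
        MonomerType("LacNAc", frozenset({3}), 1),
    )
    rep = EnzymeRule("repeat", ab["LacNAc"], ab["LacNAc"], 3)
    seed = EnzymeRule("seed", ab["LacNAc"], ab["Core"], 3)
    return Scenario(
        name="horse_cg_like",
        description=(
            "Hypothetical runaway scenario: a chain-extending enzyme "
            "whose donor equals its acceptor forms a linkage-network "
            "self-loop, producing tandem repeats of every length; the "
            "output entropy stays high at long residence times."
        ),
        alphabet=ab,
        series=[Compartment(frozenset({seed, rep}), 10.0)],
        input=Oligomer(ab["Core"]),
    )


def builtin_fixtures() -> dict[str, Scenario]:
    """The named scenario set, keyed by name."""
    scenarios = [_b_antigen(), _mucin_like(), _human_cg_like(), _horse_cg_like()]
    return {s.name: s for s in scenarios}
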