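"""Planner: single-enzyme steps, stretch edges, minimal compartment counts.

The exhaustive oracle enumerates ordered tuples of enzyme subsets (each
subset a compartment at infinite residence time), propagates the exact
terminal distribution through the series, and accepts a tuple iff the
final distribution is a point mass on the target.  The planner must agree
with this oracle on both feasibility and the minimal count.
"""

import itertools
import math

import numpy as np
import pytest

from glycompart import (
    Compartment,
    EnzymeRule,
    FixtureSpec,
    Oligomer,
    OutputDistribution,
    PromiscuityClass,
    RunawayError,
    Site,
    enumerate_sub_oligomers,
    exact_output_distribution,
    feasible_single_enzyme_chain,
    free_sites,
    generate_random_oligomer,
    is_algorithmic_stretch,
    make_alphabet,
    make_ideal_enzyme,
    min_compartments,
    min_compartments_over_suboligomers,
    parse_oligomer,
    run_series,
    shannon_entropy,
    single_enzyme_step,
)
from glycompart.oligomer import MonomerType, growth_orders, missing_additions, get_node


# -- the independent oracle ---------------------------------------------------

_stage_cache: dict = {}


def _stage_map(enzymes: frozenset, o: Oligomer):
    """Terminal distribution of one compartment at T=∞, or None if a
    runaway makes it ill-defined."""
    key = (enzymes, o)
    if key not in _stage_cache:
        comp = Compartment(enzymes, math.inf)
        try:
            out = exact_output_distribution(
                comp, OutputDistribution.point(o), size_cap=o.size + 20
            )
            _stage_cache[key] = dict(out.probabilities)
        except RunawayError:
            _stage_cache[key] = None
    return _stage_cache[key]


def _apply_stage(enzymes: frozenset, dist: dict, target: Oligomer):
    """One T=∞ compartment applied to a distribution; None when a runaway
    occurs or mass lands on an oligomer that no longer embeds in the
    target (growth is irreversible, so that mass can never reach it)."""
    from glycompart import embeds

    nxt: dict = {}
    for o, p in dist.items():
        stage = _stage_map(enzymes, o)
        if stage is None:
            return None
        for q, pq in stage.items():
            if pq > 1e-12 and not embeds(q, target):
                return None
            nxt[q] = nxt.get(q, 0.0) + p * pq
    return nxt


def _series_yields(tup, input: Oligomer, target: Oligomer) -> bool:
    dist = {input: 1.0}
    for enzymes in tup:
        dist = _apply_stage(enzymes, dist, target)
        if dist is None:
            return False
    return dist.get(target, 0.0) > 1.0 - 1e-9


def brute_force_min_n(input: Oligomer, target: Oligomer, library, max_n=3):
    """Minimum series length over all ordered tuples of enzyme subsets,
    explored breadth-first over distinct reachable distributions."""
    subsets = [
        frozenset(c)
        for r in range(1, len(library) + 1)
        for c in itertools.combinations(library, r)
    ]

    def freeze(d):
        return frozenset((o.canonical, round(p, 9)) for o, p in d.items())

    level = [{input: 1.0}]
    seen = {freeze(level[0])}
    for n in range(1, max_n + 1):
        nxt_level = []
        for dist in level:
            for S in subsets:
                out = _apply_stage(S, dist, target)
                if out is None:
                    continue
                if out.get(target, 0.0) > 1.0 - 1e-9:
                    return n
                fz = freeze(out)
                if fz not in seen:
                    seen.add(fz)
                    nxt_level.append(out)
        level = nxt_level
    return None


# -- fixtures ----------------------------------------------------------------


@pytest.fixture(scope="module")
def ab_small():
    return make_alphabet(
        MonomerType("A", frozenset({2, 3}), 1),
        MonomerType("B", frozenset({2}), 1),
    )


def _random_planner_instance(seed):
    """Random (input, target, library): the library mixes ideal enzymes
    read off the target's own growth steps (all three classes) so that a
    reasonable fraction of instances is feasible."""
    rng = np.random.default_rng(seed)
    spec = FixtureSpec(
        seed=seed, alphabet_size=3, carbons_per_type=2, max_oligomer_size=5
    )
    ab = spec.alphabet()
    target = generate_random_oligomer(spec, rng, ab)
    while target.size < 2:
        target = generate_random_oligomer(spec, rng, ab)
    subs = sorted(enumerate_sub_oligomers(target), key=lambda o: (o.size, o.canonical))
    input = subs[rng.integers(len(subs) - 1)]  # proper sub-oligomer
    root = subs[0]
    order = next(growth_orders(root, target))
    library = []
    classes = ["context_free", "branch_sensitive", "root_sensitive"]
    for k, (cur, nxt) in enumerate(zip(order, order[1:])):
        path, ac, dc, donor = missing_additions(cur, nxt)[0]
        cls = classes[rng.integers(3)]
        try:
            e = make_ideal_enzyme(cls, cur, Site(path, ac), donor, dc, name=f"L{k}")
        except Exception:
            continue
        library.append(e)
    # occasionally add an unrelated enzyme
    if rng.random() < 0.5 and len(library) < 5:
        types = list(ab.values())
        t = types[rng.integers(len(types))]
        c = sorted(t.acceptor_carbons)[rng.integers(len(t.acceptor_carbons))]
        library.append(
            EnzymeRule(f"X{seed % 97}", types[rng.integers(len(types))], t, c)
        )
    return input, target, library[:5]


class TestSingleEnzymeStep:
    def test_fucosylation_step(self, blood_alphabet, fut2_cf, gtb_bs, lac, h_antigen):
        assert single_enzyme_step(lac, h_antigen, [fut2_cf, gtb_bs]) == fut2_cf

    def test_self_loop_enzyme_never_terminates(self, ab_small):
        ext = EnzymeRule("ext", ab_small["A"], ab_small["A"], 3)
        a = Oligomer(ab_small["A"])
        b = parse_oligomer("A(3-1)A", ab_small)
        assert single_enzyme_step(a, b, [ext]) is None

    def test_identity_returns_none(self, lac, fut2_cf):
        assert single_enzyme_step(lac, lac, [fut2_cf]) is None


class TestStretch:
    def test_root_sensitive_single_additions_always_work(self):
        spec = FixtureSpec(seed=2, alphabet_size=3, max_oligomer_size=6)
        rng = spec.rng()
        ab = spec.alphabet()
        for _ in range(30):
            b = generate_random_oligomer(spec, rng, ab)
            if b.size < 2:
                continue
            subs = sorted(enumerate_sub_oligomers(b), key=lambda o: o.size)
            a = [s for s in subs if s.size == b.size - 1][0]
            ok, witness = is_algorithmic_stretch(a, b, "rs")
            assert ok and witness

    def test_combined_compartment_reactivates_the_loop(
        self, fut2_cf, gtb_bs, lac, b_antigen
    ):
        ok, _ = is_algorithmic_stretch(lac, b_antigen, [fut2_cf, gtb_bs])
        assert not ok

    def test_agrees_with_subset_expansion_oracle(self):
        # verdict of the stretch search == existence of a working subset
        hits = 0
        for seed in range(40):
            input, target, lib = _random_planner_instance(seed)
            ok, witness = is_algorithmic_stretch(input, target, lib)
            oracle = any(
                _series_yields((frozenset(c),), input, target)
                for r in range(1, len(lib) + 1)
                for c in itertools.combinations(lib, r)
            )
            assert ok == oracle, f"seed {seed}"
            if ok:
                hits += 1
                assert _series_yields((witness,), input, target)
        assert hits >= 5

    def test_witness_compartment_executes(self, fut2_cf, gtb_bs, lac, h_antigen):
        ok, witness = is_algorithmic_stretch(lac, h_antigen, [fut2_cf, gtb_bs])
        assert ok
        out = run_series([Compartment(witness, math.inf)], lac, "exact")
        assert out.prob(h_antigen) == pytest.approx(1.0)


class TestMinCompartments:
    def test_b_antigen_needs_two(self, fut2_cf, gtb_bs, lac, b_antigen):
        plan = min_compartments(lac, b_antigen, [fut2_cf, gtb_bs])
        assert plan is not None and plan.n_compartments == 2
        assert [sorted(e.name for e in s[0]) for s in plan.stages] == [
            ["Fut2CF"], ["GTB"]
        ]
        out = run_series(plan.compartments(), lac, "exact")
        assert out.prob(b_antigen) == pytest.approx(1.0)
        assert shannon_entropy(out) == pytest.approx(0.0, abs=1e-12)

    def test_root_sensitive_single_compartment_everywhere(self):
        spec = FixtureSpec(seed=9, alphabet_size=3, max_oligomer_size=6)
        rng = spec.rng()
        ab = spec.alphabet()
        for _ in range(8):
            target = generate_random_oligomer(spec, rng, ab)
            if target.size < 2:
                continue
            table = min_compartments_over_suboligomers(target, "rs")
            for sub, n in table.items():
                assert n == (0 if sub == target else 1), sub.canonical

    def test_context_free_chain_of_distinct_types(self):
        ab = make_alphabet(
            MonomerType("A", frozenset({2}), 1),
            MonomerType("B", frozenset({2}), 1),
            MonomerType("C", frozenset({2}), 1),
        )
        chain = parse_oligomer("C(2-1)B(2-1)A", ab)
        table = min_compartments_over_suboligomers(chain, "cf")
        assert all(n == (0 if s == chain else 1) for s, n in table.items())

    def test_matches_brute_force_on_random_instances(self):
        feasible_seen = 0
        for seed in range(30):
            input, target, lib = _random_planner_instance(seed)
            plan = min_compartments(input, target, lib)
            planner_n = plan.n_compartments if plan else None
            oracle_n = brute_force_min_n(input, target, lib, max_n=3)
            if planner_n is not None and planner_n <= 3 or oracle_n is not None:
                assert planner_n == oracle_n, (
                    f"seed {seed}: planner={planner_n} oracle={oracle_n}"
                )
            if planner_n:
                feasible_seen += 1
                out = run_series(plan.compartments(), input, "exact")
                assert out.prob(target) == pytest.approx(1.0)
        assert feasible_seen >= 8

    def test_promiscuity_monotonicity(self):
        spec = FixtureSpec(seed=21, alphabet_size=3, max_oligomer_size=5)
        rng = spec.rng()
        ab = spec.alphabet()
        checked = 0
        for _ in range(10):
            target = generate_random_oligomer(spec, rng, ab)
            if target.size < 3:
                continue
            root = Oligomer(target.type)
            ns = {}
            for cls in ("rs", "bs", "cf"):
                plan = min_compartments(root, target, cls)
                ns[cls] = plan.n_compartments if plan else math.inf
            assert ns["rs"] <= ns["bs"] <= ns["cf"]
            assert ns["rs"] == 1
            checked += 1
        assert checked >= 5


@pytest.fixture(scope="module")
def world(ab_small):
    """Synthetic counterexample universe: every branch-sensitive rule for
    the two bonds of the target, with all depth-1 constraint options on
    the free carbon."""
    A, B = ab_small["A"], ab_small["B"]
    target = parse_oligomer("[B(2-1)][A(3-1)]A", ab_small)
    input = Oligomer(A)
    leafA, leafB = Oligomer(A), Oligomer(B)
    space = []
    for donor, acc_carbon, other_carbon in ((B, 2, 3), (A, 3, 2)):
        options = [
            {},
            {"required_branches": frozenset({(other_carbon, leafA)})},
            {"required_branches": frozenset({(other_carbon, leafB)})}
            if other_carbon == 2
            else {"required_branches": frozenset({(other_carbon, leafA)})},
            {"forbidden_branches": frozenset({(other_carbon, None)})},
        ]
        for k, kw in enumerate(options):
            space.append(
                EnzymeRule(
                    f"bs_{donor.name}{acc_carbon}_{k}",
                    donor,
                    A,
                    acc_carbon,
                    promiscuity_class="branch_sensitive",
                    **kw,
                )
            )
    return input, target, space


class TestBranchSensitiveCounterexample:
    """A target no single branch-sensitive compartment can synthesize
    byproduct-free, although two compartments can: the chain extension
    A→A must be gated by a decoration the extender's own compartment
    cannot supply, otherwise the fresh acceptor re-triggers the
    extension."""

    def test_no_single_compartment_works(self, world):
        input, target, space = world
        for r in range(1, 4):
            for combo in itertools.combinations(space, r):
                assert not _series_yields((frozenset(combo),), input, target), [
                    e.name for e in combo
                ]

    def test_two_compartments_suffice(self, world, ab_small):
        input, target, space = world
        plan = min_compartments(input, target, space)
        assert plan is not None and plan.n_compartments == 2
        out = run_series(plan.compartments(), input, "exact")
        assert out.prob(target) == pytest.approx(1.0)

    def test_class_mode_also_finds_two(self, world):
        input, target, _ = world
        plan = min_compartments(input, target, "bs")
        assert plan is not None and plan.n_compartments == 2


class TestStretchGraph:
    def test_b_antigen_lattice_edges(self, fut2_cf, gtb_bs, lac, h_antigen, b_antigen):
        from glycompart import build_stretch_graph

        g = build_stretch_graph(b_antigen, [fut2_cf, gtb_bs])
        assert (lac.canonical, h_antigen.canonical) in g.edges
        assert (h_antigen.canonical, b_antigen.canonical) in g.edges
        # the combined stretch is impossible: the loop reactivates
        assert (lac.canonical, b_antigen.canonical) not in g.edges
        assert g.reachable(lac, b_antigen)


class TestSingleEnzymeFeasibilityProtocol:
    def test_single_enzyme_feasibility_equals_general(self):
        for seed in range(25):
            input, target, lib = _random_planner_instance(seed)
            single = feasible_single_enzyme_chain(input, target, lib)
            general = min_compartments(input, target, lib) is not None
            assert single == general, f"seed {seed}"
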