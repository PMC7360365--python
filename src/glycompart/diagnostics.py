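"""Reaction/linkage networks and the three enzymatic causes of variability.

A compartment is a set of GTase rules with an average residence time
``T``.  Its *reaction network* unrolls every possible growth order from a
given input oligomer; its *linkage network* is the far smaller type-level
summary with one directed edge per enzyme, from acceptor monomer type to
donor monomer type.  Three — and only three — mechanisms make the output
of an assembly line variable:

* **truncated** reactions: intermediates exit before reaching a terminal
  oligomer (finite residence time / low enzyme concentration);
* **runaway** reactions: an infinite growth path producing tandem
  repeats, present exactly when the linkage network (restricted to active
  edges of non-root-sensitive enzymes) contains a directed loop;
* **divergent** reactions: a fork in the reaction network that never
  reconverges, which requires an *acceptor block* — one enzyme's action
  forbidding another's.

Branch-sensitive enzymes can escape a linkage loop through a *trigger*:
an acceptor motif that cannot be synthesized within the compartment from
a single monomer, leaving the enzyme's edge permanently inactive.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from functools import lru_cache

import networkx as nx

from .enzymes import EnzymeRule, PromiscuityClass, match_sites
from .oligomer import (
    MonomerType,
    Oligomer,
    Site,
    add_monomer,
    iter_nodes,
)

__all__ = [
    "Compartment",
    "ReactionNetwork",
    "LinkageNetwork",
    "VariabilityReport",
    "build_reaction_network",
    "is_trigger_disabled",
    "build_linkage_network",
    "detect_runaway",
    "detect_acceptor_blocks",
    "detect_divergence",
    "classify_variability",
    "make_algorithmic",
    "is_algorithmic_compartment",
    "DEFAULT_SIZE_CAP",
]

DEFAULT_SIZE_CAP = 30
# headroom added to the input size when expanding a network believed finite
_ALGORITHMIC_HEADROOM = 60


@dataclass(frozen=True)
class Compartment:
    """An enzyme set plus an exit process.

    ``residence_time`` is the average time an oligomer spends inside
    (``math.inf`` = react to completion); the exit time is exponentially
    distributed under the ``transport`` model and fixed under
    ``maturation``.  An empty enzyme set is permitted and acts as the
    identity map.
    """

    enzymes: frozenset[EnzymeRule]
    residence_time: float = math.inf
    exit_model: str = "transport"

    def __post_init__(self) -> None:
        object.__setattr__(self, "enzymes", frozenset(self.enzymes))
        if self.residence_time <= 0:
            raise ValueError("residence time must be positive")
        if self.exit_model not in ("transport", "maturation"):
            raise ValueError(f"unknown exit model {self.exit_model!r}")

    @property
    def sorted_enzymes(self) -> list[EnzymeRule]:
        return sorted(self.enzymes, key=lambda e: e.name)

    @property
    def alphabet_types(self) -> dict[str, MonomerType]:
        """Monomer types mentioned anywhere in the compartment's rules."""
        types: dict[str, MonomerType] = {}

        def add(t: MonomerType) -> None:
            types.setdefault(t.name, t)

        def add_tree(o: Oligomer) -> None:
            for _, node in iter_nodes(o):
                add(node.type)

        for e in self.sorted_enzymes:
            add(e.donor_type)
            add(e.acceptor_type)
            for _, p in e.required_branches:
                add_tree(p)
            for _, p in e.forbidden_branches:
                if p is not None:
                    add_tree(p)
        return types


@dataclass
class ReactionNetwork:
    """All growth orders from ``input`` under a compartment's enzymes.

    ``graph`` is a DiGraph whose nodes are canonical strings; node
    attribute ``oligomer`` holds the tree, ``clipped`` marks states whose
    expansion was suppressed by the size cap.  Edge attribute ``moves``
    lists the realizing ``(enzyme, site)`` pairs and ``rate`` their total
    propensity.
    """

    graph: nx.DiGraph
    input: Oligomer
    size_cap: int
    truncated: bool

    def oligomer(self, key: str) -> Oligomer:
        return self.graph.nodes[key]["oligomer"]

    @property
    def terminals(self) -> list[Oligomer]:
        """States with no outgoing reaction that were fully expanded."""
        return [
            self.graph.nodes[n]["oligomer"]
            for n in self.graph.nodes
            if self.graph.out_degree(n) == 0 and not self.graph.nodes[n]["clipped"]
        ]

    def is_terminal(self, key: str) -> bool:
        return self.graph.out_degree(key) == 0 and not self.graph.nodes[key]["clipped"]


def _moves(c: Compartment, o: Oligomer) -> list[tuple[EnzymeRule, Site, Oligomer]]:
    out = []
    for e in c.sorted_enzymes:
        if e.concentration == 0:
            continue
        for s in match_sites(e, o):
            out.append((e, s, add_monomer(o, s, e.donor_type, e.donor_carbon)))
    return out


def build_reaction_network(
    c: Compartment,
    input: Oligomer,
    size_cap: int = DEFAULT_SIZE_CAP,
    max_states: int = 50_000,
) -> ReactionNetwork:
    """Breadth-first closure of single-monomer additions from ``input``,
    deduplicated by canonical string, stopping at the size cap.  The
    state-count guard turns combinatorial blow-ups into an honest
    truncation instead of exhausting memory."""
    if size_cap < input.size:
        raise ValueError("size cap below the input oligomer's size")
    g = nx.DiGraph()
    g.add_node(input.canonical, oligomer=input, clipped=False)
    truncated = False
    queue = [input]
    while queue:
        o = queue.pop(0)
        key = o.canonical
        if g.nodes[key].get("expanded"):
            continue
        g.nodes[key]["expanded"] = True
        for e, s, product in _moves(c, o):
            if product.size > size_cap:
                truncated = True
                g.nodes[key]["clipped"] = True
                continue
            pkey = product.canonical
            if pkey not in g:
                if g.number_of_nodes() >= max_states:
                    truncated = True
                    g.nodes[key]["clipped"] = True
                    continue
                g.add_node(pkey, oligomer=product, clipped=False)
                queue.append(product)
            if g.has_edge(key, pkey):
                g.edges[key, pkey]["moves"].append((e, s))
                g.edges[key, pkey]["rate"] += e.concentration
            else:
                g.add_edge(key, pkey, moves=[(e, s)], rate=e.concentration)
    return ReactionNetwork(graph=g, input=input, size_cap=size_cap, truncated=truncated)


# -- triggers and the linkage network ---------------------------------------


def is_trigger_disabled(e: EnzymeRule, c: Compartment) -> bool:
    """True iff the branch-sensitive rule's acceptor motif cannot be built
    from any single monomer of the compartment's alphabet using the
    compartment's own enzymes (so the rule can never fire on material
    seeded inside the compartment).

    The reachability search is bounded: witnesses are explored up to the
    motif size plus the total required-branch mass of the compartment,
    which covers chains of mutually triggering branch-sensitive rules.
    """
    if e not in c.enzymes:
        raise ValueError(f"{e.name} is not in the compartment")
    if e.promiscuity_class is not PromiscuityClass.BRANCH_SENSITIVE:
        raise ValueError(f"{e.name}: trigger analysis applies to branch-sensitive rules")
    if not e.required_branches:
        return False
    return _trigger_disabled_cached(e, c)


@lru_cache(maxsize=100_000)
def _trigger_disabled_cached(e: EnzymeRule, c: Compartment) -> bool:
    bound = e.motif_size + sum(
        sum(p.size for _, p in other.required_branches) for other in c.enzymes
    ) + 1
    for t in c.alphabet_types.values():
        seed = Oligomer(t)
        net = build_reaction_network(c, seed, size_cap=bound)
        for key in net.graph.nodes:
            if match_sites(e, net.oligomer(key)):
                return False
    return True


@dataclass
class LinkageNetwork:
    """Type-level multigraph: one edge per enzyme, acceptor type → donor
    type, with ``active=False`` on trigger-disabled branch-sensitive
    edges."""

    graph: nx.MultiDiGraph

    def edges_for(self, enzyme_name: str) -> list[tuple[str, str, dict]]:
        return [
            (u, v, d)
            for u, v, k, d in self.graph.edges(keys=True, data=True)
            if k == enzyme_name
        ]


def build_linkage_network(c: Compartment) -> LinkageNetwork:
    g = nx.MultiDiGraph()
    for t in c.alphabet_types:
        g.add_node(t)
    for e in c.sorted_enzymes:
        active = True
        if (
            e.promiscuity_class is PromiscuityClass.BRANCH_SENSITIVE
            and e.required_branches
        ):
            active = not is_trigger_disabled(e, c)
        g.add_edge(
            e.acceptor_type.name,
            e.donor_type.name,
            key=e.name,
            enzyme=e,
            acceptor_carbon=e.acceptor_carbon,
            donor_carbon=e.donor_carbon,
            active=active,
        )
    return LinkageNetwork(graph=g)


def _cycle_is_realizable(cycle: tuple[EnzymeRule, ...]) -> bool:
    """Carbon-occupancy filter: along the repeating chain each fresh
    acceptor arrives attached through the previous enzyme's donor carbon,
    which must not collide with the carbons the next enzyme needs."""
    n = len(cycle)
    for i, e_next in enumerate(cycle):
        e_prev = cycle[i - 1] if n > 1 else e_next
        occupied = e_prev.donor_carbon
        if e_next.acceptor_carbon == occupied:
            return False
        if any(carbon == occupied for carbon, _ in e_next.required_branches):
            return False
    return True


def _availability(c: Compartment, input: Oligomer) -> set[tuple[str, int]]:
    """Fixed-point closure of ``(monomer type, free acceptor carbon)``
    pairs obtainable starting from the input oligomer.

    Seeded from a small bounded expansion of the actual input rather than
    the input alone: a trigger-disabled enzyme can still fire finitely
    often on motifs the input carries ready-made, and the types it seeds
    that way can feed a loop.  Beyond the bounded horizon only active
    edges propagate (they are the ones that can iterate)."""
    bound = input.size + sum(e.motif_size - 1 for e in c.enzymes) + 2
    seed_net = build_reaction_network(c, input, size_cap=bound)
    av: set[tuple[str, int]] = set()
    for key in seed_net.graph.nodes:
        for _, node in iter_nodes(seed_net.oligomer(key)):
            for carbon in node.free_carbons:
                av.add((node.type.name, carbon))
    ln = build_linkage_network(c)
    edges = [
        d["enzyme"]
        for _, _, d in ln.graph.edges(data=True)
        if d["active"]
    ]
    changed = True
    while changed:
        changed = False
        for e in edges:
            if (e.acceptor_type.name, e.acceptor_carbon) in av:
                for carbon in e.donor_type.acceptor_carbons:
                    if carbon != e.donor_carbon:
                        pair = (e.donor_type.name, carbon)
                        if pair not in av:
                            av.add(pair)
                            changed = True
    return av


def detect_runaway(
    c: Compartment, input: Oligomer | None = None, max_cycles: int = 1000
) -> list[tuple[EnzymeRule, ...]]:
    """Directed loops among active, non-root-sensitive linkage edges; with
    an input, only loops seedable from material reachable from it.

    Root-sensitive enzymes are excluded outright: their acceptors sit at a
    fixed depth from the root, so they can never iterate along a chain.
    An empty result certifies a finite reaction network.
    """
    return list(_runaway_cached(c, input, max_cycles))


@lru_cache(maxsize=100_000)
def _runaway_cached(
    c: Compartment, input: Oligomer | None, max_cycles: int
) -> tuple[tuple[EnzymeRule, ...], ...]:
    ln = build_linkage_network(c)
    g = nx.MultiDiGraph()
    for u, v, k, d in ln.graph.edges(keys=True, data=True):
        e = d["enzyme"]
        if not d["active"]:
            continue
        if e.promiscuity_class is PromiscuityClass.ROOT_SENSITIVE:
            continue
        g.add_edge(u, v, key=k, enzyme=e)
    # collapse to a simple digraph for cycle enumeration, then expand the
    # parallel-enzyme choices per step
    simple = nx.DiGraph()
    per_edge: dict[tuple[str, str], list[EnzymeRule]] = {}
    for u, v, d in g.edges(data=True):
        per_edge.setdefault((u, v), []).append(d["enzyme"])
        simple.add_edge(u, v)
    av = _availability(c, input) if input is not None else None
    cycles: list[tuple[EnzymeRule, ...]] = []
    for node_cycle in nx.simple_cycles(simple):
        pairs = [
            (node_cycle[i], node_cycle[(i + 1) % len(node_cycle)])
            for i in range(len(node_cycle))
        ]
        for combo in itertools.product(*(per_edge[p] for p in pairs)):
            if not _cycle_is_realizable(combo):
                continue
            if av is not None and not any(
                (e.acceptor_type.name, e.acceptor_carbon) in av for e in combo
            ):
                continue
            cycles.append(combo)
            if len(cycles) >= max_cycles:
                return tuple(cycles)
    return tuple(cycles)


# -- acceptor blocks ---------------------------------------------------------


def _motifs_cosatisfiable(e1: EnzymeRule, e2: EnzymeRule) -> bool:
    """Can a single node simultaneously satisfy both acceptor motifs?"""
    if e1.acceptor_type.name != e2.acceptor_type.name:
        return False
    c1, c2 = e1.promiscuity_class, e2.promiscuity_class
    if (
        c1 is PromiscuityClass.ROOT_SENSITIVE
        and c2 is PromiscuityClass.ROOT_SENSITIVE
        and e1.required_root_chain != e2.required_root_chain
    ):
        return False
    if c1 is PromiscuityClass.BRANCH_SENSITIVE and c2 is PromiscuityClass.BRANCH_SENSITIVE:
        req1 = dict(e1.required_branches)
        req2 = dict(e2.required_branches)
        for carbon in set(req1) & set(req2):
            if req1[carbon] != req2[carbon]:
                return False
        for forb, req in ((e1.forbidden_branches, req2), (e2.forbidden_branches, req1)):
            for carbon, pattern in forb:
                if carbon in req and (pattern is None or pattern == req[carbon]):
                    return False
    # a branch-sensitive motif also occupies its required carbons: the
    # other enzyme's target carbon must not be one of them
    for a, b in ((e1, e2), (e2, e1)):
        if any(carbon == b.acceptor_carbon for carbon, _ in a.required_branches):
            return False
    return True


def _acts_inside_pattern(e1: EnzymeRule, pattern: Oligomer) -> bool:
    """Could ``e1`` extend a node inside an exact instance of ``pattern``
    (thereby destroying the exact-subtree match)?  Root-sensitive rules
    are treated permissively since the pattern's upward context is
    unknown here."""
    for _, node in iter_nodes(pattern):
        if node.type.name != e1.acceptor_type.name:
            continue
        if node.child_at(e1.acceptor_carbon) is not None:
            continue
        if e1.acceptor_carbon not in node.type.acceptor_carbons:
            continue
        cls = e1.promiscuity_class
        if cls is PromiscuityClass.CONTEXT_FREE or cls is PromiscuityClass.ROOT_SENSITIVE:
            return True
        ok = True
        for carbon, req in e1.required_branches:
            hit = node.child_at(carbon)
            if hit is None or hit[1] != req:
                ok = False
                break
        if ok:
            for carbon, forb in e1.forbidden_branches:
                hit = node.child_at(carbon)
                if forb is None:
                    if hit is not None:
                        ok = False
                        break
                elif hit is not None and hit[1] == forb:
                    ok = False
                    break
        if ok:
            return True
    return False


def detect_acceptor_blocks(
    c: Compartment,
) -> list[tuple[EnzymeRule, EnzymeRule, str]]:
    """All enzyme pairs where one enzyme's action can forbid the other's.

    Bidirectional blocks (any class): two enzymes compete for the same
    acceptor carbon of co-satisfiable motifs.  Unidirectional blocks
    (branch-sensitive victims only): the blocker can grow inside the
    victim's required branch (destroying the exact match) or create a
    branch at one of its forbidden carbons.  Detection is symbolic on the
    motifs and intentionally generous: blocks are necessary, not
    sufficient, for divergence.
    """
    enzymes = c.sorted_enzymes
    blocks: list[tuple[EnzymeRule, EnzymeRule, str]] = []
    for i, e1 in enumerate(enzymes):
        for e2 in enzymes[i + 1:]:
            if (
                e1.acceptor_carbon == e2.acceptor_carbon
                and _motifs_cosatisfiable(e1, e2)
                and (
                    e1.donor_type.name != e2.donor_type.name
                    or e1.donor_carbon != e2.donor_carbon
                )
            ):
                blocks.append((e1, e2, "bidirectional"))
    for e1 in enzymes:
        for e2 in enzymes:
            if e2.promiscuity_class is not PromiscuityClass.BRANCH_SENSITIVE:
                continue
            uni = False
            for _, pattern in e2.required_branches:
                if _acts_inside_pattern(e1, pattern):
                    uni = True
                    break
            if not uni and e1.acceptor_type.name == e2.acceptor_type.name:
                for carbon, pattern in e2.forbidden_branches:
                    if e1.acceptor_carbon != carbon:
                        continue
                    if pattern is None or pattern.type.name == e1.donor_type.name:
                        uni = True
                        break
            if uni:
                blocks.append((e1, e2, "unidirectional"))
    return blocks


# -- divergence --------------------------------------------------------------


def detect_divergence(net: ReactionNetwork) -> list[tuple[str, str, str]]:
    """Non-reconverging forks: nodes with two successors sharing no common
    descendant.  On cap-clipped networks, forks whose descendants include
    a clipped state are skipped (their fate is unknown)."""
    g = net.graph
    desc: dict[str, frozenset[str]] = {}
    complete: dict[str, bool] = {}
    for key in reversed(list(nx.topological_sort(g))):
        ds: set[str] = {key}
        ok = not g.nodes[key]["clipped"]
        for _, child in g.out_edges(key):
            ds |= desc[child]
            ok = ok and complete[child]
        desc[key] = frozenset(ds)
        complete[key] = ok
    forks = []
    for key in g.nodes:
        succ = sorted(g.successors(key))
        for a, b in itertools.combinations(succ, 2):
            if not (complete[a] and complete[b]):
                continue
            if desc[a].isdisjoint(desc[b]):
                forks.append((key, a, b))
    return forks


# -- the taxonomy ------------------------------------------------------------


@dataclass
class VariabilityReport:
    causes: set[str]
    loops: list[tuple[EnzymeRule, ...]]
    blocks: list[tuple[EnzymeRule, EnzymeRule, str]]
    forks: list[tuple[str, str, str]]
    truncation: bool
    approximate: bool = False

    def to_dict(self) -> dict:
        return {
            "causes": sorted(self.causes),
            "loops": [[e.name for e in cyc] for cyc in self.loops],
            "blocks": [[a.name, b.name, d] for a, b, d in self.blocks],
            "forks": list(self.forks),
            "truncation": self.truncation,
            "approximate": self.approximate,
        }


def classify_variability(
    series: list[Compartment],
    input: Oligomer,
    size_cap: int = DEFAULT_SIZE_CAP,
) -> VariabilityReport:
    """Walk the series, propagating the exact output distribution stage by
    stage, and attribute every source of output variability to one of the
    three causes."""
    from .assembly import OutputDistribution, exact_output_distribution

    causes: set[str] = set()
    loops: list[tuple[EnzymeRule, ...]] = []
    blocks: list[tuple[EnzymeRule, EnzymeRule, str]] = []
    forks: list[tuple[str, str, str]] = []
    truncation = False
    approximate = False

    dist = OutputDistribution.point(input)
    for comp in series:
        stage_runaway = False
        for o in dist.support():
            cycles = detect_runaway(comp, o)
            if cycles:
                stage_runaway = True
                loops.extend(cyc for cyc in cycles if cyc not in loops)
            net = build_reaction_network(comp, o, size_cap)
            if net.truncated:
                approximate = True
            forks.extend(f for f in detect_divergence(net) if f not in forks)
        if stage_runaway:
            causes.add("runaway")
        stage_blocks = detect_acceptor_blocks(comp)
        if forks:
            causes.add("divergent")
            blocks.extend(b for b in stage_blocks if b not in blocks)
        out = exact_output_distribution(comp, dist, size_cap=size_cap, allow_clipped=True)
        if math.isfinite(comp.residence_time):
            for o, p in out.probabilities.items():
                if p <= 1e-12:
                    continue
                net = build_reaction_network(comp, o, size_cap)
                if net.graph.out_degree(o.canonical) > 0 or net.graph.nodes[o.canonical]["clipped"]:
                    truncation = True
                    causes.add("truncated")
                    break
        dist = out
    return VariabilityReport(
        causes=causes,
        loops=loops,
        blocks=blocks,
        forks=forks,
        truncation=truncation,
        approximate=approximate,
    )


# -- algorithmic compartments ------------------------------------------------


def make_algorithmic(c: Compartment) -> Compartment:
    """Greedily remove enzymes until no active loops and no blocks remain,
    then pin the residence time to infinity.

    Removal order: the enzyme appearing in the most loops plus blocks
    goes first, ties broken by name; triggers are exploited implicitly
    because loop detection re-evaluates branch-sensitive edge activity
    after every removal.
    """
    enzymes = set(c.enzymes)
    while enzymes:
        trial = Compartment(frozenset(enzymes), math.inf, c.exit_model)
        loops = detect_runaway(trial)
        blocks = detect_acceptor_blocks(trial)
        if not loops and not blocks:
            return trial
        score: dict[EnzymeRule, int] = {e: 0 for e in enzymes}
        for cyc in loops:
            for e in cyc:
                score[e] += 1
        for a, b, _ in blocks:
            score[a] += 1
            if b is not a:
                score[b] += 1
        victim = max(enzymes, key=lambda e: (score[e], e.name))
        enzymes.discard(victim)
    return Compartment(frozenset(), math.inf, c.exit_model)


def is_algorithmic_compartment(
    c: Compartment, input: Oligomer, size_cap: int | None = None
) -> tuple[bool, Oligomer | None]:
    """True, with the unique terminal, iff the compartment at infinite
    residence time maps the input to exactly one output."""
    if detect_runaway(c, input):
        return False, None
    cap = size_cap if size_cap is not None else input.size + _ALGORITHMIC_HEADROOM
    net = build_reaction_network(c, input, cap)
    if net.truncated:
        # no loop was detected yet the cap was hit: treat as non-algorithmic
        return False, None
    terms = net.terminals
    if len(terms) == 1:
        return True, terms[0]
    return False, None
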