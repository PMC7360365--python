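"""Minimal-compartment planning for byproduct-free glycan synthesis.

Two structural facts drive the planner.  First, a target oligomer can be
specifically synthesized from an input at all iff it can be synthesized
by a chain of single-enzyme, infinite-residence-time compartments.
Second, the minimum number of compartments equals the minimum number of
*algorithmic growth stretches* into which some growth order from input to
target can be decomposed — a stretch being a segment realizable
byproduct-free inside one algorithmic compartment.

Both facts are exploited on the *sub-oligomer lattice*: the set of
root-containing subtrees of the target (the only possible intermediates
of a monomer-by-monomer synthesis).  A stretch edge ``a → b`` is drawn
whenever some enzyme set maps ``a`` to the unique terminal ``b`` at
infinite residence time; the minimal plan is a shortest path from input
to target in this graph.

"Algorithmic growth stretch" is operationalized dynamically — existence
of an enzyme set whose compartment maps the stretch start to the stretch
end as unique terminal — which is exactly the property the compartment-
count equivalence uses.  For class-based planning, candidate enzymes are
constructed ideally from the growth steps themselves: root-sensitive
candidates pin each addition to its exact position (so a single
compartment always suffices); branch- sensitive candidates are read off
each growth order, optionally in the "forbid absent branches" form;
context-free candidates are the bare bond rules.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable

from .diagnostics import Compartment, is_algorithmic_compartment
from .enzymes import EnzymeRule, PromiscuityClass, make_ideal_enzyme
from .oligomer import (
    Oligomer,
    Site,
    embeds,
    enumerate_sub_oligomers,
    get_node,
    growth_orders,
    missing_additions,
)

__all__ = [
    "SynthesisPlan",
    "StretchGraph",
    "build_stretch_graph",
    "single_enzyme_step",
    "is_algorithmic_stretch",
    "min_compartments",
    "min_compartments_over_suboligomers",
    "feasible_single_enzyme_chain",
]

_MAX_GROWTH_ORDERS = 2000


@dataclass
class SynthesisPlan:
    """An ordered compartment assignment achieving specific synthesis."""

    stages: list[tuple[frozenset[EnzymeRule], float, Oligomer]]
    input: Oligomer
    target: Oligomer

    @property
    def n_compartments(self) -> int:
        return len(self.stages)

    def compartments(self) -> list[Compartment]:
        return [Compartment(enzymes, T) for enzymes, T, _ in self.stages]

    def to_dict(self) -> dict:
        return {
            "input": self.input.canonical,
            "target": self.target.canonical,
            "n_compartments": self.n_compartments,
            "stages": [
                {
                    "enzymes": sorted(e.name for e in enzymes),
                    "residence_time": "inf" if math.isinf(T) else T,
                    "output": out.canonical,
                }
                for enzymes, T, out in self.stages
            ],
        }


@dataclass
class StretchGraph:
    """Edges ``a → b`` on the sub-oligomer lattice wherever one
    algorithmic compartment maps ``a`` to ``b``; payload = witness
    enzyme set."""

    nodes: list[Oligomer]
    edges: dict[tuple[str, str], frozenset[EnzymeRule]]

    def reachable(self, input: Oligomer, target: Oligomer) -> bool:
        frontier, seen = [input.canonical], {input.canonical}
        adj: dict[str, list[str]] = {}
        for (u, v) in self.edges:
            adj.setdefault(u, []).append(v)
        while frontier:
            u = frontier.pop()
            if u == target.canonical:
                return True
            for v in adj.get(u, ()):
                if v not in seen:
                    seen.add(v)
                    frontier.append(v)
        return target.canonical in seen


def build_stretch_graph(
    target: Oligomer,
    class_or_library: "PromiscuityClass | str | Iterable[EnzymeRule]",
) -> StretchGraph:
    """The full stretch graph over the target's sub-oligomer lattice.

    ``min_compartments`` evaluates the same edges lazily; this eager
    variant supports inspection and the all-sub-oligomers table."""
    if not isinstance(class_or_library, (PromiscuityClass, str)):
        class_or_library = list(class_or_library)
    nodes = sorted(
        enumerate_sub_oligomers(target), key=lambda o: (o.size, o.canonical)
    )
    edges: dict[tuple[str, str], frozenset[EnzymeRule]] = {}
    for a in nodes:
        for b in nodes:
            if b.size <= a.size or not embeds(a, b):
                continue
            ok, witness = is_algorithmic_stretch(a, b, class_or_library)
            if ok:
                edges[(a.canonical, b.canonical)] = witness
    return StretchGraph(nodes=nodes, edges=edges)


@lru_cache(maxsize=200_000)
def _unique_terminal(enzymes: frozenset[EnzymeRule], a: Oligomer) -> Oligomer | None:
    ok, out = is_algorithmic_compartment(Compartment(enzymes, math.inf), a)
    return out if ok else None


def _compartment_maps(enzymes: frozenset[EnzymeRule], a: Oligomer, b: Oligomer) -> bool:
    return _unique_terminal(enzymes, a) == b


def single_enzyme_step(
    a: Oligomer, b: Oligomer, library: Iterable[EnzymeRule]
) -> EnzymeRule | None:
    """An enzyme whose lone compartment specifically synthesizes ``b``
    from ``a`` (possibly adding several monomers before self-
    terminating), or None."""
    if a == b or not embeds(a, b):
        return None
    for e in sorted(library, key=lambda r: r.name):
        if _compartment_maps(frozenset({e}), a, b):
            return e
    return None


def _relevant_enzymes(
    a: Oligomer, b: Oligomer, library: Iterable[EnzymeRule]
) -> list[EnzymeRule]:
    """Enzymes catalyzing at least one of the bonds present in b but not
    in a; any other enzyme either adds foreign material (a byproduct) or
    can never fire on this stretch."""
    steps = missing_additions(a, b)
    keys = set()
    for path, ac, dc, donor in steps:
        parent = get_node(b, path)
        keys.add((parent.type.name, ac, donor.name, dc))
    return [
        e
        for e in sorted(library, key=lambda r: r.name)
        if (e.acceptor_type.name, e.acceptor_carbon, e.donor_type.name, e.donor_carbon)
        in keys
    ]


def _class_candidates(
    a: Oligomer, b: Oligomer, cls: PromiscuityClass
) -> Iterable[frozenset[EnzymeRule]]:
    """Candidate ideal enzyme sets for the stretch a → b, per class."""
    if cls is PromiscuityClass.ROOT_SENSITIVE:
        enzymes = set()
        for path, ac, dc, donor in missing_additions(a, b):
            # context read off the target with the added subtree removed:
            # the acceptor's root chain is identical there and the carbon
            # is free, which is what the ideal constructor needs
            pruned = _remove_child(b, path, ac)
            enzymes.add(make_ideal_enzyme(cls, pruned, Site(path, ac), donor, dc))
        yield frozenset(enzymes)
        return
    if cls is PromiscuityClass.CONTEXT_FREE:
        enzymes = set()
        for path, ac, dc, donor in missing_additions(a, b):
            parent = get_node(b, path)
            enzymes.add(
                EnzymeRule(
                    name=f"cf_{donor.name}{dc}_to_{parent.type.name}{ac}",
                    donor_type=donor,
                    acceptor_type=parent.type,
                    acceptor_carbon=ac,
                    donor_carbon=dc,
                )
            )
        yield frozenset(enzymes)
        return
    # branch-sensitive: read the acceptor context off each growth order
    seen: set[frozenset[EnzymeRule]] = set()
    for forbid_absent in (False, True):
        for order in growth_orders(a, b, limit=_MAX_GROWTH_ORDERS):
            enzymes = set()
            for current, nxt in zip(order, order[1:]):
                (path, ac, dc, donor) = missing_additions(current, nxt)[0]
                enzymes.add(
                    make_ideal_enzyme(
                        cls, current, Site(path, ac), donor, dc,
                        forbid_absent=forbid_absent,
                    )
                )
            fs = frozenset(enzymes)
            if fs not in seen:
                seen.add(fs)
                yield fs


def _remove_child(node: Oligomer, path: tuple[int, ...], ac: int) -> Oligomer:
    if not path:
        kids = tuple(entry for entry in node.children if entry[0] != ac)
        return Oligomer(node.type, kids)
    head, rest = path[0], path[1:]
    kids = tuple(
        (c, dc, _remove_child(child, rest, ac) if c == head else child)
        for c, dc, child in node.children
    )
    return Oligomer(node.type, kids)


def is_algorithmic_stretch(
    a: Oligomer,
    b: Oligomer,
    class_or_library: PromiscuityClass | str | Iterable[EnzymeRule],
) -> tuple[bool, frozenset[EnzymeRule] | None]:
    """True, with a witness enzyme set, iff some compartment at infinite
    residence time maps ``a`` to the unique terminal ``b``."""
    if a == b or not embeds(a, b):
        return False, None
    if isinstance(class_or_library, (PromiscuityClass, str)):
        cls = PromiscuityClass.coerce(class_or_library)
        for candidate in _class_candidates(a, b, cls):
            if candidate and _compartment_maps(candidate, a, b):
                return True, candidate
        return False, None
    library = list(class_or_library)
    relevant = _relevant_enzymes(a, b, library)
    for r in range(1, len(relevant) + 1):
        for combo in itertools.combinations(relevant, r):
            fs = frozenset(combo)
            if _compartment_maps(fs, a, b):
                return True, fs
    return False, None


def _lattice_from(input: Oligomer, target: Oligomer) -> list[Oligomer]:
    subs = enumerate_sub_oligomers(target)
    return sorted(
        (s for s in subs if embeds(input, s)), key=lambda o: (o.size, o.canonical)
    )


def min_compartments(
    input: Oligomer,
    target: Oligomer,
    class_or_library: PromiscuityClass | str | Iterable[EnzymeRule],
) -> SynthesisPlan | None:
    """Shortest-path stretch decomposition on the sub-oligomer lattice;
    None when no series of compartments, of any length, can specifically
    synthesize the target from the input."""
    if not embeds(input, target):
        raise ValueError("input is not a sub-oligomer of the target")
    if input == target:
        return SynthesisPlan(stages=[], input=input, target=target)
    if not isinstance(class_or_library, (PromiscuityClass, str)):
        class_or_library = list(class_or_library)
    lattice = _lattice_from(input, target)
    # breadth-first layers with lazily evaluated stretch edges; predecessor
    # choice is lexicographic on canonical strings for reproducible plans
    frontier = [input]
    parent: dict[str, tuple[Oligomer, frozenset[EnzymeRule]] | None] = {
        input.canonical: None
    }
    while frontier:
        next_frontier: list[Oligomer] = []
        for a in sorted(frontier, key=lambda o: o.canonical):
            for b in lattice:
                if b.canonical in parent or b.size <= a.size:
                    continue
                if not embeds(a, b):
                    continue
                ok, witness = is_algorithmic_stretch(a, b, class_or_library)
                if not ok:
                    continue
                parent[b.canonical] = (a, witness)
                if b == target:
                    return _plan_from(parent, input, target)
                next_frontier.append(b)
        frontier = next_frontier
    return None


def _plan_from(
    parent: dict[str, tuple[Oligomer, frozenset[EnzymeRule]] | None],
    input: Oligomer,
    target: Oligomer,
) -> SynthesisPlan:
    stages: list[tuple[frozenset[EnzymeRule], float, Oligomer]] = []
    cursor = target
    while cursor != input:
        prev, witness = parent[cursor.canonical]  # type: ignore[misc]
        stages.append((witness, math.inf, cursor))
        cursor = prev
    stages.reverse()
    return SynthesisPlan(stages=stages, input=input, target=target)


def min_compartments_over_suboligomers(
    target: Oligomer,
    class_or_library: PromiscuityClass | str | Iterable[EnzymeRule],
) -> dict[Oligomer, int | None]:
    """Minimal compartment count from every sub-oligomer of the target
    (None = infeasible); the map's maximum over feasible entries is the
    compartment demand of the target."""
    if not isinstance(class_or_library, (PromiscuityClass, str)):
        class_or_library = list(class_or_library)
    out: dict[Oligomer, int | None] = {}
    for sub in sorted(enumerate_sub_oligomers(target), key=lambda o: (o.size, o.canonical)):
        plan = min_compartments(sub, target, class_or_library)
        out[sub] = plan.n_compartments if plan is not None else None
    return out


def feasible_single_enzyme_chain(
    input: Oligomer, target: Oligomer, library: Iterable[EnzymeRule]
) -> bool:
    """Feasibility via chains of single-enzyme compartments only (the
    efficient search protocol; equivalent to general feasibility)."""
    library = list(library)
    lattice = _lattice_from(input, target)
    reached = {input.canonical}
    frontier = [input]
    while frontier:
        a = frontier.pop()
        if a == target:
            return True
        for b in lattice:
            if b.canonical in reached or b.size <= a.size or not embeds(a, b):
                continue
            if single_enzyme_step(a, b, library) is not None:
                reached.add(b.canonical)
                frontier.append(b)
    return target.canonical in reached
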