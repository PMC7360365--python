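"""Branched glycan oligomers as rooted trees of typed monomers.

A glycan is modeled as a rooted tree: each node is a monomer of some
:class:`MonomerType`, and each edge is a glycosidic linkage recorded as a
pair of carbon numbers ``(acceptor_carbon, donor_carbon)`` — the position
on the parent where the child is attached, and the position on the child
used for the bond (typically the anomeric carbon, C1).  Growth is
monomer-by-monomer and irreversible: oligomers are never pruned, so every
reachable intermediate of a synthesis is a root-containing subtree of the
final product.

The canonical text form writes a child before its parent, either
chain-style (``Gal(3-1)GlcNAc``: Gal attached at carbon 3 of GlcNAc via
Gal's carbon 1) or as a bracketed branch (``[Fuc(2-1)]Gal``).  Branches
are emitted in ascending acceptor-carbon order so that structurally equal
oligomers serialize identically.
"""

from __future__ import annotations

import itertools
import json
import re
from dataclasses import dataclass, field
from typing import Iterator, Mapping

__all__ = [
    "MonomerType",
    "Linkage",
    "Oligomer",
    "Site",
    "OligomerError",
    "ParseError",
    "make_alphabet",
    "default_alphabet",
    "parse_oligomer",
    "serialize_canonical",
    "oligomer_equal",
    "add_monomer",
    "enumerate_sub_oligomers",
    "get_node",
    "iter_nodes",
    "free_sites",
    "embeds",
    "missing_additions",
    "growth_orders",
    "oligomer_to_json",
    "oligomer_from_json",
    "load_alphabet",
    "dump_alphabet",
]


class OligomerError(ValueError):
    """Invalid oligomer construction or growth step."""


class ParseError(OligomerError):
    """Syntax or semantic error in the canonical text grammar."""

    def __init__(self, message: str, position: int | None = None):
        self.position = position
        if position is not None:
            message = f"{message} (at position {position})"
        super().__init__(message)


@dataclass(frozen=True)
class MonomerType:
    """A monomer species: its name, attachment positions, and bond carbon.

    ``acceptor_carbons`` are the positions at which branches may be
    attached to a monomer of this type; ``donor_carbon`` is the position
    this type uses when it is itself attached as a branch.
    """

    name: str
    acceptor_carbons: frozenset[int]
    donor_carbon: int = 1

    def __post_init__(self) -> None:
        if not self.name or not re.fullmatch(r"[A-Za-z][A-Za-z0-9]*", self.name):
            raise OligomerError(f"invalid monomer type name {self.name!r}")
        object.__setattr__(self, "acceptor_carbons", frozenset(self.acceptor_carbons))
        if not self.acceptor_carbons:
            raise OligomerError(f"monomer type {self.name}: empty acceptor carbon set")
        if any(c <= 0 for c in self.acceptor_carbons) or self.donor_carbon <= 0:
            raise OligomerError(f"monomer type {self.name}: carbons must be positive")

    def __repr__(self) -> str:  # compact, stable
        carbons = ",".join(map(str, sorted(self.acceptor_carbons)))
        return f"MonomerType({self.name}; ac={{{carbons}}}; dc={self.donor_carbon})"


@dataclass(frozen=True)
class Linkage:
    """A glycosidic bond: ``acceptor_carbon`` on the parent, ``donor_carbon`` on the child."""

    acceptor_carbon: int
    donor_carbon: int

    def __post_init__(self) -> None:
        if self.acceptor_carbon <= 0 or self.donor_carbon <= 0:
            raise OligomerError("linkage carbons must be positive")

    def __str__(self) -> str:
        return f"({self.acceptor_carbon}-{self.donor_carbon})"


@dataclass(frozen=True, eq=False)
class Oligomer:
    """A rooted oligomer tree (each instance is simultaneously a node).

    ``children`` maps are stored as tuples ``(acceptor_carbon,
    donor_carbon, subtree)`` sorted by acceptor carbon, so structural
    equality coincides with equality of canonical strings.  Size and the
    canonical string are computed eagerly and bottom-up (children exist
    before their parent), keeping every operation safe on arbitrarily
    deep chains.
    """

    type: MonomerType
    children: tuple[tuple[int, int, "Oligomer"], ...] = ()

    def __post_init__(self) -> None:
        kids = tuple(sorted(self.children, key=lambda t: t[0]))
        carbons = [ac for ac, _, _ in kids]
        if len(set(carbons)) != len(carbons):
            raise OligomerError(f"duplicate acceptor carbon on a {self.type.name} node")
        for ac, dc, child in kids:
            if ac not in self.type.acceptor_carbons:
                raise OligomerError(
                    f"carbon {ac} is not an acceptor carbon of {self.type.name}"
                )
            if dc <= 0 or not isinstance(child, Oligomer):
                raise OligomerError("malformed child entry")
        object.__setattr__(self, "children", kids)
        object.__setattr__(self, "size", 1 + sum(ch.size for _, _, ch in kids))
        # non-root (branch) text form: a single *internal* child is written
        # chain-style, everything else as bracketed branches
        if len(kids) == 1 and kids[0][2].children:
            ac, dc, child = kids[0]
            inner = f"{child._inner}({ac}-{dc}){self.type.name}"
        else:
            inner = (
                "".join(f"[{ch._inner}({ac}-{dc})]" for ac, dc, ch in kids)
                + self.type.name
            )
        object.__setattr__(self, "_inner", inner)
        # root text form: a single child is always written chain-style
        if len(kids) == 1:
            ac, dc, child = kids[0]
            canon = f"{child._inner}({ac}-{dc}){self.type.name}"
        else:
            canon = inner
        object.__setattr__(self, "canonical", canon)

    size: int = field(init=False, repr=False)
    canonical: str = field(init=False, repr=False)
    _inner: str = field(init=False, repr=False)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, Oligomer) and self.canonical == other.canonical

    def __hash__(self) -> int:
        return hash(self.canonical)

    def child_at(self, carbon: int) -> tuple[int, "Oligomer"] | None:
        """Return ``(donor_carbon, subtree)`` attached at ``carbon``, or None."""
        for ac, dc, child in self.children:
            if ac == carbon:
                return dc, child
        return None

    @property
    def occupied_carbons(self) -> frozenset[int]:
        return frozenset(ac for ac, _, _ in self.children)

    @property
    def free_carbons(self) -> frozenset[int]:
        return self.type.acceptor_carbons - self.occupied_carbons

    def __str__(self) -> str:
        return self.canonical

    def __repr__(self) -> str:
        return f"Oligomer({self.canonical!r})"


@dataclass(frozen=True)
class Site:
    """A free attachment position: the node (as a path of acceptor carbons
    from the root) plus the free acceptor carbon on that node."""

    node_path: tuple[int, ...]
    carbon: int


Alphabet = Mapping[str, MonomerType]


def make_alphabet(*types: MonomerType) -> dict[str, MonomerType]:
    out: dict[str, MonomerType] = {}
    for t in types:
        if t.name in out:
            raise OligomerError(f"duplicate monomer type name {t.name!r}")
        out[t.name] = t
    return out


def default_alphabet(*names: str) -> dict[str, MonomerType]:
    """Alphabet with the default carbon model: acceptor carbons {2,3,4,6},
    donor carbon 1 (the anomeric position) for every named type."""
    return make_alphabet(
        *(MonomerType(n, frozenset({2, 3, 4, 6}), 1) for n in names)
    )


# -- serialization -----------------------------------------------------------


def serialize_canonical(o: Oligomer) -> str:
    """Deterministic canonical string; equal trees serialize identically."""
    return o.canonical


def oligomer_equal(a: Oligomer, b: Oligomer) -> bool:
    """Structural equality of rooted trees (child order irrelevant)."""
    return a == b


# -- parsing -----------------------------------------------------------------

_TOKEN = re.compile(
    r"(?P<name>[A-Za-z][A-Za-z0-9]*)|(?P<link>\((\d+)-(\d+)\))|(?P<open>\[)|(?P<close>\])"
)


class _Parser:
    def __init__(self, text: str, alphabet: Alphabet):
        self.text = text
        self.alphabet = alphabet
        self.pos = 0

    def error(self, msg: str) -> ParseError:
        return ParseError(msg, self.pos)

    def peek(self) -> str:
        return self.text[self.pos] if self.pos < len(self.text) else ""

    def parse_link(self) -> Linkage:
        m = re.compile(r"\((\d+)-(\d+)\)").match(self.text, self.pos)
        if not m:
            raise self.error("expected linkage '(ac-dc)'")
        self.pos = m.end()
        return Linkage(int(m.group(1)), int(m.group(2)))

    def parse_name(self) -> MonomerType:
        m = re.compile(r"[A-Za-z][A-Za-z0-9]*").match(self.text, self.pos)
        if not m:
            raise self.error("expected monomer type name")
        name = m.group(0)
        if name not in self.alphabet:
            raise self.error(f"unknown monomer type {name!r}")
        self.pos = m.end()
        return self.alphabet[name]

    def parse_item(self) -> Oligomer:
        """Item := Branch* TypeName."""
        branches: list[tuple[int, int, Oligomer]] = []
        while self.peek() == "[":
            self.pos += 1
            subtree, link = self.parse_chain(in_bracket=True)
            if self.peek() != "]":
                raise self.error("expected ']'")
            self.pos += 1
            branches.append((link.acceptor_carbon, link.donor_carbon, subtree))
        mtype = self.parse_name()
        seen = [ac for ac, _, _ in branches]
        if len(set(seen)) != len(seen):
            raise self.error(f"duplicate acceptor carbon on a {mtype.name} node")
        try:
            return Oligomer(mtype, tuple(branches))
        except OligomerError as exc:
            raise self.error(str(exc)) from exc

    def parse_chain(self, in_bracket: bool) -> tuple[Oligomer, Linkage | None]:
        """Chain := Item (Link Item)*; inside a bracket the final trailing
        link attaches the chain to the enclosing node."""
        current = self.parse_item()
        while self.peek() == "(":
            link = self.parse_link()
            if in_bracket and self.peek() == "]":
                return current, link
            nxt = self.parse_item()
            # current becomes a child of nxt
            entry = (link.acceptor_carbon, link.donor_carbon, current)
            if any(ac == link.acceptor_carbon for ac, _, _ in nxt.children):
                raise self.error(
                    f"duplicate acceptor carbon on a {nxt.type.name} node"
                )
            try:
                current = Oligomer(nxt.type, nxt.children + (entry,))
            except OligomerError as exc:
                raise self.error(str(exc)) from exc
        if in_bracket:
            raise self.error("branch must end with its attachment linkage")
        return current, None


def parse_oligomer(text: str, alphabet: Alphabet) -> Oligomer:
    """Parse the canonical text grammar (whitespace forbidden)."""
    if not text or any(ch.isspace() for ch in text):
        raise ParseError("empty string or whitespace in oligomer text", 0)
    p = _Parser(text, alphabet)
    tree, _ = p.parse_chain(in_bracket=False)
    if p.pos != len(text):
        raise ParseError("trailing characters after oligomer", p.pos)
    return tree


# -- growth ------------------------------------------------------------------


def get_node(o: Oligomer, path: tuple[int, ...]) -> Oligomer:
    """Resolve a node by its path of acceptor carbons from the root."""
    node = o
    for carbon in path:
        hit = node.child_at(carbon)
        if hit is None:
            raise OligomerError(f"path {path} does not resolve: no child at {carbon}")
        node = hit[1]
    return node


def iter_nodes(o: Oligomer) -> Iterator[tuple[tuple[int, ...], Oligomer]]:
    """Depth-first preorder traversal in canonical child order."""
    stack: list[tuple[tuple[int, ...], Oligomer]] = [((), o)]
    while stack:
        path, node = stack.pop()
        yield path, node
        for ac, _, child in reversed(node.children):
            stack.append((path + (ac,), child))


def free_sites(o: Oligomer) -> list[Site]:
    """All free attachment positions, depth-first, carbons ascending."""
    out = []
    for path, node in iter_nodes(o):
        for carbon in sorted(node.free_carbons):
            out.append(Site(path, carbon))
    return out


def _replace(node: Oligomer, path: tuple[int, ...], carbon: int,
             donor: MonomerType, donor_carbon: int) -> Oligomer:
    if not path:
        if node.child_at(carbon) is not None:
            raise OligomerError(f"acceptor carbon {carbon} is occupied")
        if carbon not in node.type.acceptor_carbons:
            raise OligomerError(
                f"carbon {carbon} is not an acceptor carbon of {node.type.name}"
            )
        leaf = Oligomer(donor)
        return Oligomer(node.type, node.children + ((carbon, donor_carbon, leaf),))
    head, rest = path[0], path[1:]
    new_children = []
    found = False
    for ac, dc, child in node.children:
        if ac == head:
            child = _replace(child, rest, carbon, donor, donor_carbon)
            found = True
        new_children.append((ac, dc, child))
    if not found:
        raise OligomerError(f"path does not resolve: no child at {head}")
    return Oligomer(node.type, tuple(new_children))


def add_monomer(o: Oligomer, s: Site, donor: MonomerType,
                donor_carbon: int | None = None) -> Oligomer:
    """Attach one monomer at a free site; the input is unchanged
    (single-monomer additions are irreversible — oligomers are not pruned)."""
    dc = donor.donor_carbon if donor_carbon is None else donor_carbon
    return _replace(o, s.node_path, s.carbon, donor, dc)


# -- sub-oligomer lattice ----------------------------------------------------


def _variants(node: Oligomer) -> list[Oligomer]:
    """All root-containing subtrees of ``node``'s subtree."""
    options: list[list[tuple[int, int, Oligomer] | None]] = []
    for ac, dc, child in node.children:
        opts: list[tuple[int, int, Oligomer] | None] = [None]
        opts.extend((ac, dc, v) for v in _variants(child))
        options.append(opts)
    out = []
    for combo in itertools.product(*options):
        kids = tuple(entry for entry in combo if entry is not None)
        out.append(Oligomer(node.type, kids))
    return out


def enumerate_sub_oligomers(target: Oligomer) -> set[Oligomer]:
    """All connected subtrees of ``target`` containing the root: the
    possible intermediates of a monomer-by-monomer growth from the root."""
    return set(_variants(target))


def embeds(a: Oligomer, b: Oligomer) -> bool:
    """True iff ``a`` is a sub-oligomer of ``b`` (root-aligned embedding).

    Because children are keyed by acceptor carbon, the embedding is unique
    when it exists.
    """
    if a.type.name != b.type.name:
        return False
    for ac, dc, child in a.children:
        hit = b.child_at(ac)
        if hit is None or hit[0] != dc or not embeds(child, hit[1]):
            return False
    return True


def missing_additions(a: Oligomer, b: Oligomer) -> list[tuple[tuple[int, ...], int, int, MonomerType]]:
    """The single-monomer additions present in ``b`` but not in ``a``, as
    ``(parent_path_in_b, acceptor_carbon, donor_carbon, donor_type)``."""
    if not embeds(a, b):
        raise OligomerError("first oligomer does not embed in the second")
    out = []

    def walk(path: tuple[int, ...], an: Oligomer | None, bn: Oligomer) -> None:
        for ac, dc, bchild in bn.children:
            achild = an.child_at(ac)[1] if (an is not None and an.child_at(ac)) else None
            if achild is None:
                out.append((path, ac, dc, bchild.type))
                walk(path + (ac,), None, bchild)
            else:
                walk(path + (ac,), achild, bchild)

    walk((), a, b)
    return out


def growth_orders(a: Oligomer, b: Oligomer, limit: int | None = None) -> Iterator[list[Oligomer]]:
    """Enumerate growth orders from ``a`` to ``b``: sequences of
    intermediates, each obtained from the previous by one addition present
    in ``b``.  Yields at most ``limit`` orders when given."""
    count = 0

    def recurse(current: Oligomer, trail: list[Oligomer]) -> Iterator[list[Oligomer]]:
        nonlocal count
        if current == b:
            yield trail
            return
        for path, ac, dc, donor in missing_additions(current, b):
            # addable now iff the parent path exists in current
            try:
                node = get_node(current, path)
            except OligomerError:
                continue
            if node.child_at(ac) is not None:
                continue
            nxt = add_monomer(current, Site(path, ac), donor, dc)
            if limit is not None and count >= limit:
                return
            for full in recurse(nxt, trail + [nxt]):
                count += 1
                yield full
                if limit is not None and count >= limit:
                    return

    yield from recurse(a, [a])


# -- interoperability --------------------------------------------------------


def oligomer_to_json(o: Oligomer) -> str:
    """Node/edge JSON export (ids are preorder indices)."""
    nodes, edges = [], []

    def walk(node: Oligomer, parent: int | None, link: tuple[int, int] | None) -> None:
        idx = len(nodes)
        nodes.append({"id": idx, "type": node.type.name})
        if parent is not None:
            edges.append({
                "parent": parent, "child": idx,
                "acceptor_carbon": link[0], "donor_carbon": link[1],
            })
        for ac, dc, child in node.children:
            walk(child, idx, (ac, dc))

    walk(o, None, None)
    return json.dumps({"nodes": nodes, "edges": edges}, indent=2)


def oligomer_from_json(text: str, alphabet: Alphabet) -> Oligomer:
    data = json.loads(text)
    children: dict[int, list[tuple[int, int, int]]] = {}
    for e in data["edges"]:
        children.setdefault(e["parent"], []).append(
            (e["acceptor_carbon"], e["donor_carbon"], e["child"])
        )
    types = {n["id"]: n["type"] for n in data["nodes"]}
    roots = set(types) - {e["child"] for e in data["edges"]}
    if len(roots) != 1:
        raise OligomerError("JSON tree must have exactly one root")

    def build(idx: int) -> Oligomer:
        kids = tuple(
            (ac, dc, build(cid)) for ac, dc, cid in children.get(idx, ())
        )
        name = types[idx]
        if name not in alphabet:
            raise OligomerError(f"unknown monomer type {name!r}")
        return Oligomer(alphabet[name], kids)

    return build(roots.pop())


def load_alphabet(source) -> dict[str, MonomerType]:
    """Load an alphabet from YAML: a list of
    ``{name, acceptor_carbons, donor_carbon}`` mappings (or a mapping with
    an ``alphabet`` key holding that list)."""
    import yaml

    data = yaml.safe_load(source)
    if isinstance(data, Mapping) and "alphabet" in data:
        data = data["alphabet"]
    types = [
        MonomerType(
            entry["name"],
            frozenset(entry["acceptor_carbons"]),
            int(entry.get("donor_carbon", 1)),
        )
        for entry in data
    ]
    return make_alphabet(*types)


def dump_alphabet(alphabet: Alphabet) -> str:
    import yaml

    return yaml.safe_dump(
        {
            "alphabet": [
                {
                    "name": t.name,
                    "acceptor_carbons": sorted(t.acceptor_carbons),
                    "donor_carbon": t.donor_carbon,
                }
                for t in alphabet.values()
            ]
        },
        sort_keys=False,
    )
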