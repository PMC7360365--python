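"""Glycosyltransferase (GTase) rules and the three promiscuity classes.

A GTase catalyzes one specific glycosidic bond: it attaches a specific
donor monomer type, via a specific donor carbon, to a specific acceptor
monomer type at a specific acceptor carbon.  What varies between enzymes
is how much structural context the acceptor must carry:

* ``context_free`` — the acceptor is any monomer of the right type with
  the target carbon free (maximally promiscuous; cf. β4GalNT1 acting on
  branched or un-branched galactose).
* ``branch_sensitive`` — the acceptor monomer must carry (or lack)
  specific branches; ideal enzymes read branches to arbitrary depth, so
  required branch patterns match as full subtrees (cf. GTB requiring a
  fucose branch on its galactose acceptor).
* ``root_sensitive`` — the acceptor monomer must sit on a specific chain
  of linkages running all the way down to the root; such enzymes can
  distinguish the position of every monomer (cf. Fut2 requiring its
  galactose to be linked to a GlcNAc root).

Donor (nucleotide-sugar) availability is assumed unlimited; the enzyme's
``concentration`` sets the propensity of each matching site in the
stochastic model.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping

from .oligomer import (
    Alphabet,
    MonomerType,
    Oligomer,
    ParseError,
    Site,
    add_monomer,
    get_node,
    parse_oligomer,
)

__all__ = [
    "PromiscuityClass",
    "EnzymeRule",
    "EnzymeError",
    "match_sites",
    "apply_enzyme",
    "make_ideal_enzyme",
    "load_enzyme_library",
    "dump_enzyme_library",
    "parse_root_chain",
    "format_root_chain",
]


class EnzymeError(ValueError):
    """Invalid enzyme rule or misuse of one."""


class PromiscuityClass(str, Enum):
    CONTEXT_FREE = "context_free"
    BRANCH_SENSITIVE = "branch_sensitive"
    ROOT_SENSITIVE = "root_sensitive"

    @classmethod
    def coerce(cls, value: "PromiscuityClass | str") -> "PromiscuityClass":
        if isinstance(value, cls):
            return value
        aliases = {"cf": cls.CONTEXT_FREE, "bs": cls.BRANCH_SENSITIVE,
                   "rs": cls.ROOT_SENSITIVE}
        v = str(value).lower()
        return aliases.get(v) or cls(v)


# A required branch: (carbon on the acceptor, exact subtree pattern).
# A forbidden branch: (carbon, pattern) or (carbon, None) = nothing at all
# may occupy that carbon ("lacking a branch").
# A root chain entry: (acceptor_carbon, donor_carbon, parent type name),
# listed from the acceptor's immediate parent down to the root.


@dataclass(frozen=True)
class EnzymeRule:
    name: str
    donor_type: MonomerType
    acceptor_type: MonomerType
    acceptor_carbon: int
    donor_carbon: int | None = None
    promiscuity_class: PromiscuityClass = PromiscuityClass.CONTEXT_FREE
    required_branches: frozenset[tuple[int, Oligomer]] = frozenset()
    forbidden_branches: frozenset[tuple[int, Oligomer | None]] = frozenset()
    required_root_chain: tuple[tuple[int, int, str], ...] | None = None
    concentration: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "promiscuity_class", PromiscuityClass.coerce(self.promiscuity_class)
        )
        if self.donor_carbon is None:
            object.__setattr__(self, "donor_carbon", self.donor_type.donor_carbon)
        object.__setattr__(self, "required_branches", frozenset(self.required_branches))
        object.__setattr__(self, "forbidden_branches", frozenset(self.forbidden_branches))
        if self.required_root_chain is not None:
            object.__setattr__(
                self, "required_root_chain", tuple(self.required_root_chain)
            )
        if not re.fullmatch(r"\S+", self.name or ""):
            raise EnzymeError(f"invalid enzyme name {self.name!r}")
        if self.acceptor_carbon not in self.acceptor_type.acceptor_carbons:
            raise EnzymeError(
                f"{self.name}: carbon {self.acceptor_carbon} is not an acceptor "
                f"carbon of {self.acceptor_type.name}"
            )
        if self.concentration < 0:
            raise EnzymeError(f"{self.name}: negative concentration")
        cls = self.promiscuity_class
        if cls is not PromiscuityClass.BRANCH_SENSITIVE and (
            self.required_branches or self.forbidden_branches
        ):
            raise EnzymeError(f"{self.name}: branch constraints on a {cls.value} rule")
        if cls is not PromiscuityClass.ROOT_SENSITIVE and self.required_root_chain is not None:
            raise EnzymeError(f"{self.name}: root chain on a {cls.value} rule")
        req_carbons = {c for c, _ in self.required_branches}
        forb_carbons = {c for c, _ in self.forbidden_branches}
        if req_carbons & forb_carbons:
            raise EnzymeError(f"{self.name}: required and forbidden carbons overlap")
        if self.acceptor_carbon in req_carbons:
            raise EnzymeError(
                f"{self.name}: required branch occupies the acceptor carbon itself"
            )
        bad = (req_carbons | forb_carbons) - self.acceptor_type.acceptor_carbons
        if bad:
            raise EnzymeError(
                f"{self.name}: constraint carbons {sorted(bad)} not in the "
                f"acceptor type's carbon set"
            )

    # -- descriptive helpers -------------------------------------------------

    @property
    def motif_size(self) -> int:
        """Monomer count of the minimal acceptor motif (acceptor monomer
        plus its required branch subtrees)."""
        return 1 + sum(p.size for _, p in self.required_branches)

    def __repr__(self) -> str:
        return (
            f"EnzymeRule({self.name}: {self.donor_type.name}({self.donor_carbon}) -> "
            f"{self.acceptor_type.name}@{self.acceptor_carbon}, "
            f"{self.promiscuity_class.value})"
        )


def _node_matches(e: EnzymeRule, node: Oligomer,
                  chain_up: tuple[tuple[int, int, str], ...]) -> bool:
    if node.type.name != e.acceptor_type.name:
        return False
    if node.child_at(e.acceptor_carbon) is not None:
        return False
    cls = e.promiscuity_class
    if cls is PromiscuityClass.CONTEXT_FREE:
        return True
    if cls is PromiscuityClass.BRANCH_SENSITIVE:
        for carbon, pattern in e.required_branches:
            hit = node.child_at(carbon)
            if hit is None or hit[1] != pattern:
                return False
        for carbon, pattern in e.forbidden_branches:
            hit = node.child_at(carbon)
            if pattern is None:
                if hit is not None:
                    return False
            elif hit is not None and hit[1] == pattern:
                return False
        return True
    # root-sensitive: the full path to the root must equal the rule's chain
    return e.required_root_chain == chain_up


def match_sites(e: EnzymeRule, o: Oligomer) -> list[Site]:
    """All sites where the enzyme can act: nodes of the acceptor type with
    the acceptor carbon free and the class constraints satisfied.
    Deterministic depth-first order in canonical child order."""
    out: list[Site] = []

    # chain entries read from the acceptor upward: nearest parent first,
    # root last.
    def walk(node: Oligomer, path: tuple[int, ...],
             up: tuple[tuple[int, int, str], ...]) -> None:
        if _node_matches(e, node, up):
            out.append(Site(path, e.acceptor_carbon))
        for ac, dc, child in node.children:
            walk(child, path + (ac,), ((ac, dc, node.type.name),) + up)

    walk(o, (), ())
    return out


def apply_enzyme(e: EnzymeRule, o: Oligomer, s: Site) -> Oligomer:
    """One catalytic step: attach the donor at a matched site."""
    if s not in match_sites(e, o):
        raise EnzymeError(f"{e.name}: site {s} is not matched on {o.canonical}")
    return add_monomer(o, s, e.donor_type, e.donor_carbon)


def make_ideal_enzyme(
    cls: PromiscuityClass | str,
    parent_oligomer: Oligomer,
    s: Site,
    donor: MonomerType,
    donor_carbon: int | None = None,
    *,
    name: str | None = None,
    forbid_absent: bool = False,
    concentration: float = 1.0,
) -> EnzymeRule:
    """Construct the ideal enzyme of class ``cls`` realizing the growth
    step "attach ``donor`` at site ``s`` of ``parent_oligomer``".

    For ``branch_sensitive`` the rule requires exactly the branches the
    acceptor node currently carries; with ``forbid_absent=True`` it also
    forbids any branch at the node's other free carbons (the "lacking"
    form of branch sensitivity).  For ``root_sensitive`` the rule pins the
    acceptor's full path to the root.  The returned rule always matches
    ``s`` on ``parent_oligomer``.
    """
    cls = PromiscuityClass.coerce(cls)
    node = get_node(parent_oligomer, s.node_path)
    if node.child_at(s.carbon) is not None:
        raise EnzymeError(f"site {s} is occupied")
    if s.carbon not in node.type.acceptor_carbons:
        raise EnzymeError(f"carbon {s.carbon} not available on {node.type.name}")
    kwargs: dict = {}
    if cls is PromiscuityClass.BRANCH_SENSITIVE:
        kwargs["required_branches"] = frozenset(
            (ac, child) for ac, _, child in node.children
        )
        if forbid_absent:
            kwargs["forbidden_branches"] = frozenset(
                (c, None)
                for c in node.free_carbons
                if c != s.carbon
            )
    elif cls is PromiscuityClass.ROOT_SENSITIVE:
        # rebuild the path from root to node, then reverse it so the chain
        # reads nearest-parent-first, root-last
        trail: list[tuple[int, int, str]] = []
        cursor = parent_oligomer
        for carbon in s.node_path:
            dc, child = cursor.child_at(carbon)  # type: ignore[misc]
            trail.append((carbon, dc, cursor.type.name))
            cursor = child
        kwargs["required_root_chain"] = tuple(reversed(trail))
    if name is None:
        name = (
            f"{cls.value[:2]}_{donor.name}{donor.donor_carbon if donor_carbon is None else donor_carbon}"
            f"_to_{node.type.name}{s.carbon}"
        )
    return EnzymeRule(
        name=name,
        donor_type=donor,
        acceptor_type=node.type,
        acceptor_carbon=s.carbon,
        donor_carbon=donor_carbon,
        promiscuity_class=cls,
        concentration=concentration,
        **kwargs,
    )


# -- root-chain text helpers -------------------------------------------------


def parse_root_chain(text: str, alphabet: Alphabet) -> tuple[tuple[int, int, str], ...]:
    """Parse a root chain written as repeated ``(ac-dc)Type`` segments,
    e.g. ``"(3-1)GlcNAc"``: the acceptor is linked via its carbon 1 to
    carbon 3 of a GlcNAc, which is the root."""
    chain: list[tuple[int, int, str]] = []
    pos = 0
    pat = re.compile(r"\((\d+)-(\d+)\)([A-Za-z][A-Za-z0-9]*)")
    while pos < len(text):
        m = pat.match(text, pos)
        if not m:
            raise ParseError("expected '(ac-dc)Type' segment", pos)
        ac, dc, name = int(m.group(1)), int(m.group(2)), m.group(3)
        if name not in alphabet:
            raise ParseError(f"unknown monomer type {name!r}", pos)
        chain.append((ac, dc, name))
        pos = m.end()
    if not chain:
        raise ParseError("empty root chain", 0)
    return tuple(chain)


def format_root_chain(chain: tuple[tuple[int, int, str], ...]) -> str:
    return "".join(f"({ac}-{dc}){name}" for ac, dc, name in chain)


# -- library I/O -------------------------------------------------------------


def load_enzyme_library(source, alphabet: Alphabet) -> list[EnzymeRule]:
    """Load enzyme rules from YAML/JSON.  Schema: a list (or a mapping with
    an ``enzymes`` key) of entries with fields ``name``, ``class``,
    ``donor``, ``acceptor``, ``acceptor_carbon`` and optionally
    ``donor_carbon``, ``concentration``, ``required_branches`` (list of
    ``{carbon, pattern}`` with patterns in the canonical oligomer
    grammar), ``forbidden_branches`` (``pattern`` omitted = lacking any
    branch), ``root_chain`` (``(ac-dc)Type...`` string)."""
    import yaml

    data = yaml.safe_load(source)
    if isinstance(data, Mapping) and "enzymes" in data:
        data = data["enzymes"]
    rules = []
    for entry in data:
        cls = PromiscuityClass.coerce(entry.get("class", "context_free"))
        req = frozenset(
            (int(b["carbon"]), parse_oligomer(b["pattern"], alphabet))
            for b in entry.get("required_branches", ())
        )
        forb = frozenset(
            (
                int(b["carbon"]),
                parse_oligomer(b["pattern"], alphabet) if "pattern" in b else None,
            )
            for b in entry.get("forbidden_branches", ())
        )
        chain = (
            parse_root_chain(entry["root_chain"], alphabet)
            if "root_chain" in entry
            else None
        )
        rules.append(
            EnzymeRule(
                name=entry["name"],
                donor_type=alphabet[entry["donor"]],
                acceptor_type=alphabet[entry["acceptor"]],
                acceptor_carbon=int(entry["acceptor_carbon"]),
                donor_carbon=int(entry["donor_carbon"]) if "donor_carbon" in entry else None,
                promiscuity_class=cls,
                required_branches=req,
                forbidden_branches=forb,
                required_root_chain=chain,
                concentration=float(entry.get("concentration", 1.0)),
            )
        )
    return rules


def dump_enzyme_library(rules: Iterable[EnzymeRule]) -> str:
    import yaml

    entries = []
    for e in rules:
        entry: dict = {
            "name": e.name,
            "class": e.promiscuity_class.value,
            "donor": e.donor_type.name,
            "donor_carbon": e.donor_carbon,
            "acceptor": e.acceptor_type.name,
            "acceptor_carbon": e.acceptor_carbon,
            "concentration": e.concentration,
        }
        if e.required_branches:
            entry["required_branches"] = [
                {"carbon": c, "pattern": p.canonical}
                for c, p in sorted(e.required_branches, key=lambda t: t[0])
            ]
        if e.forbidden_branches:
            entry["forbidden_branches"] = [
                ({"carbon": c} if p is None else {"carbon": c, "pattern": p.canonical})
                for c, p in sorted(
                    e.forbidden_branches, key=lambda t: (t[0], t[1].canonical if t[1] else "")
                )
            ]
        if e.required_root_chain is not None:
            entry["root_chain"] = format_root_chain(e.required_root_chain)
        entries.append(entry)
    return yaml.safe_dump({"enzymes": entries}, sort_keys=False)
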