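"""DANAI micro-interaction statements: grammar, canonical form, built-in modes.

A statement reads ``[<topology><order>]<sequence>`` where the topology letter
is ``L`` (linear chain), ``R`` (ring) or ``J`` (junction/star) and the order is
the number of participating species.  The sequence lists species codes joined
by ``:`` (a non-bonded contact).  Ring statements repeat the opening species at
the end to mark the closure.  Branch species are parenthesised: ``(X:)`` binds
to the backbone species that *follows* the group, ``(:X)`` to the one that
*precedes* it.  Letter case is semantic: an uppercase species has no contacts
beyond those shown in the statement, a lowercase species may have more.

Examples::

    [L2]C182:C180                      isolated mixed pair
    [R3]c182:c182:c182:c182            three-membered ring
    [J4]c182:c182(:c182):c182          3-star centred on the second species
    [J5]c182:(c182:)c182(:c182):c182   4-star centred on the second species
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterator, Sequence

from .contact_graph import MacroClass, SpeciesTag, macro_edge_class
from .errors import NotationSyntaxError

__all__ = [
    "PatternSpecies",
    "MicroPattern",
    "ModeSet",
    "parse_danai",
    "format_danai",
    "canonicalize",
    "builtin_modes",
    "BUILTIN_STATEMENTS",
]


@dataclass(frozen=True)
class PatternSpecies:
    """A species slot in a statement: canonical code plus case flag."""

    code: str  # canonical, letters uppercased, e.g. "C182"
    upper: bool

    @property
    def text(self) -> str:
        m = re.match(r"^([A-Za-z]+)(\d+)$", self.code)
        letters, digits = m.group(1), m.group(2)
        return (letters.upper() if self.upper else letters.lower()) + digits

    @property
    def tag(self) -> SpeciesTag:
        return SpeciesTag(self.code)

    def sort_key(self) -> tuple:
        # trihaloalkane-type codes (higher functional-group number) sort first;
        # this is the orientation Table-style statements are written in
        m = re.match(r"^([A-Za-z]+)(\d+)$", self.code)
        return (m.group(1), -int(m.group(2)), 0 if self.upper else 1)


@dataclass(frozen=True)
class MicroPattern:
    """Structured reading of a DANAI statement.

    ``backbone`` holds the chain species in order; for rings it includes the
    repeated closure species as its final entry.  ``branches`` holds
    ``(attach_index, species)`` pairs, the index pointing into the backbone.
    """

    topology: str  # "L" | "R" | "J"
    order: int
    backbone: tuple[PatternSpecies, ...]
    branches: tuple[tuple[int, PatternSpecies], ...] = ()

    def __post_init__(self):
        if self.topology not in ("L", "R", "J"):
            raise NotationSyntaxError(f"unknown topology letter {self.topology!r}")
        nb, nbr = len(self.backbone), len(self.branches)
        if self.topology == "L":
            if nbr:
                raise NotationSyntaxError("linear pattern cannot carry branches")
            if self.order != nb or nb < 2:
                raise NotationSyntaxError(
                    f"L{self.order} requires exactly {self.order} species, got {nb}"
                )
        elif self.topology == "R":
            if nbr:
                raise NotationSyntaxError("ring pattern cannot carry branches")
            if nb != self.order + 1:
                raise NotationSyntaxError(
                    f"R{self.order} requires {self.order + 1} species "
                    f"(closure repeated), got {nb}"
                )
            if self.order < 3:
                raise NotationSyntaxError("ring order must be at least 3")
            if self.backbone[0] != self.backbone[-1]:
                raise NotationSyntaxError(
                    "ring statement must close on its opening species"
                )
        else:  # J
            if self.order != nb + nbr or nbr < 1 or nb < 3:
                raise NotationSyntaxError(
                    f"J{self.order} requires backbone + branches = {self.order} "
                    f"with at least one branch on a 3+ backbone"
                )
            for idx, _ in self.branches:
                if not 0 < idx < nb - 1:
                    raise NotationSyntaxError(
                        f"branch attached at non-interior backbone position {idx}"
                    )

    # -- structural views -------------------------------------------------

    def ring_members(self) -> tuple[PatternSpecies, ...]:
        if self.topology != "R":
            raise ValueError("not a ring pattern")
        return self.backbone[:-1]

    def vertices(self) -> tuple[PatternSpecies, ...]:
        """Pattern vertices in canonical order: backbone (sans ring closure),
        then branch species."""
        base = self.ring_members() if self.topology == "R" else self.backbone
        return base + tuple(sp for _, sp in self.branches)

    def edges(self) -> tuple[tuple[int, int], ...]:
        """Edges between vertex indices as returned by :meth:`vertices`."""
        base = self.ring_members() if self.topology == "R" else self.backbone
        nb = len(base)
        out = [(i, i + 1) for i in range(nb - 1)]
        if self.topology == "R":
            out.append((nb - 1, 0))
        for k, (idx, _) in enumerate(self.branches):
            out.append((idx, nb + k))
        return tuple(out)

    def vertex_degrees(self) -> tuple[int, ...]:
        deg = [0] * len(self.vertices())
        for i, j in self.edges():
            deg[i] += 1
            deg[j] += 1
        return tuple(deg)

    @property
    def macro(self) -> MacroClass:
        numbers = {sp.tag.number for sp in self.vertices()}
        it = sorted(numbers)
        return macro_edge_class(
            SpeciesTag(f"C{it[0]}"), SpeciesTag(f"C{it[-1]}")
        )

    @property
    def statement(self) -> str:
        return format_danai(self)


# ---------------------------------------------------------------------------
# parsing
# ---------------------------------------------------------------------------

_HEAD_RE = re.compile(r"^\[([A-Za-z])(\d+)\]")
_TOKEN_RE = re.compile(r"([A-Za-z]+\d+)|(:)|(\()|(\))|(\S)")


def _species(token: str, offset: int) -> PatternSpecies:
    m = re.match(r"^([A-Za-z]+)(\d+)$", token)
    letters = m.group(1)
    if letters.isupper():
        upper = True
    elif letters.islower():
        upper = False
    else:
        raise NotationSyntaxError(f"mixed-case species token {token!r}", offset)
    return PatternSpecies(code=letters.upper() + m.group(2), upper=upper)


def parse_danai(text: str) -> MicroPattern:
    """Parse a DANAI statement into a :class:`MicroPattern`.

    Raises :class:`NotationSyntaxError` (with character offset) on any
    grammar violation; guarantees ``parse(format(p)) == p``.
    """
    text = text.strip()
    head = _HEAD_RE.match(text)
    if not head:
        raise NotationSyntaxError("statement must start with [<letter><order>]", 0)
    topology = head.group(1).upper()
    if topology not in ("L", "R", "J"):
        raise NotationSyntaxError(
            f"unknown topology letter {head.group(1)!r}", 1
        )
    order = int(head.group(2))
    body = text[head.end():]
    base = head.end()

    backbone: list[PatternSpecies] = []
    branches: list[tuple[int, PatternSpecies]] = []
    pending_forward: list[tuple[PatternSpecies, int]] = []
    expect_species = True  # a top-level colon has been consumed (or start)

    tokens = [(m, base + m.start()) for m in _TOKEN_RE.finditer(body)]
    i = 0
    while i < len(tokens):
        m, off = tokens[i]
        tok = m.group(0)
        if m.group(1):  # species
            if not expect_species:
                raise NotationSyntaxError("missing ':' between species", off)
            backbone.append(_species(tok, off))
            for sp, _ in pending_forward:
                branches.append((len(backbone) - 1, sp))
            pending_forward.clear()
            expect_species = False
            i += 1
        elif tok == ":":
            if expect_species:
                raise NotationSyntaxError("dangling ':'", off)
            expect_species = True
            i += 1
        elif tok == "(":
            # branch group: "(species:)" forward or "(:species)" backward
            group = tokens[i + 1 : i + 4]
            if len(group) < 3 or group[2][0].group(0) != ")":
                raise NotationSyntaxError("malformed branch group", off)
            g1, g2 = group[0][0].group(0), group[1][0].group(0)
            if g1 == ":" and group[1][0].group(1):
                # backward: attaches to the preceding backbone species
                if not backbone or expect_species:
                    raise NotationSyntaxError(
                        "backward branch must directly follow a backbone species",
                        off,
                    )
                branches.append((len(backbone) - 1, _species(g2, group[1][1])))
            elif group[0][0].group(1) and g2 == ":":
                if not expect_species:
                    raise NotationSyntaxError(
                        "forward branch must directly precede a backbone species",
                        off,
                    )
                pending_forward.append((_species(g1, group[0][1]), off))
            else:
                raise NotationSyntaxError(
                    "branch group must be '(species:)' or '(:species)'", off
                )
            i += 4
        elif tok == ")":
            raise NotationSyntaxError("unmatched ')'", off)
        else:
            raise NotationSyntaxError(f"unexpected character {tok!r}", off)

    if pending_forward:
        raise NotationSyntaxError(
            "forward branch never attached", pending_forward[0][1]
        )
    if expect_species:
        off = tokens[-1][1] if tokens else base
        raise NotationSyntaxError("statement ends with a dangling ':'", off)
    return MicroPattern(
        topology=topology,
        order=order,
        backbone=tuple(backbone),
        branches=tuple(branches),
    )


# ---------------------------------------------------------------------------
# formatting
# ---------------------------------------------------------------------------


def format_danai(p: MicroPattern) -> str:
    """Serialize to canonical text; inverse of :func:`parse_danai`.

    Branches attached to one backbone species are split around it: the first
    half rendered ``(X:)`` before, the rest ``(:X)`` after, reproducing the
    built-in table's writing (one branch goes after; of two, one each side).
    """
    by_index: dict[int, list[PatternSpecies]] = {}
    for idx, sp in p.branches:
        by_index.setdefault(idx, []).append(sp)
    parts: list[str] = []
    for i, sp in enumerate(p.backbone):
        piece = ""
        here = by_index.get(i, []) if p.topology == "J" else []
        before = here[: len(here) // 2]
        after = here[len(here) // 2 :]
        for b in before:
            piece += f"({b.text}:)"
        piece += sp.text
        for b in after:
            piece += f"(:{b.text})"
        parts.append(piece)
    return f"[{p.topology}{p.order}]" + ":".join(parts)


# ---------------------------------------------------------------------------
# canonical form
# ---------------------------------------------------------------------------


def canonicalize(p: MicroPattern) -> MicroPattern:
    """Collapse the symmetric textual readings of a motif onto one.

    Linear chains pick the smaller of the forward/reversed species sequence;
    rings pick, over all rotations and reflections, first a writing whose cut
    edge joins two identical species (so the closure repeats the majority
    species, as the built-in table does), then the smallest sequence;
    junctions orient the backbone minimally and sort branches.  Case flags are
    never altered.  Idempotent.
    """
    key = PatternSpecies.sort_key
    if p.topology == "L":
        fwd = p.backbone
        rev = tuple(reversed(p.backbone))
        best = min(fwd, rev, key=lambda seq: tuple(key(s) for s in seq))
        return MicroPattern("L", p.order, best)
    if p.topology == "R":
        members = p.ring_members()
        n = len(members)
        candidates = []
        for seq in (members, tuple(reversed(members))):
            for r in range(n):
                rot = seq[r:] + seq[:r]
                cut_ok = 0 if rot[0] == rot[-1] else 1
                candidates.append(((cut_ok, tuple(key(s) for s in rot)), rot))
        best = min(candidates, key=lambda c: c[0])[1]
        return MicroPattern("R", p.order, best + (best[0],))
    # J: forward vs reversed backbone, branch indices remapped, branches sorted
    nb = len(p.backbone)
    options = []
    for flip in (False, True):
        bb = tuple(reversed(p.backbone)) if flip else p.backbone
        remapped = [(((nb - 1 - idx) if flip else idx), sp) for idx, sp in p.branches]
        brs = tuple(sorted(remapped, key=lambda t: (t[0], key(t[1]))))
        options.append(
            (
                (
                    tuple(key(s) for s in bb),
                    tuple((i, key(s)) for i, s in brs),
                ),
                (bb, brs),
            )
        )
    bb, brs = min(options, key=lambda o: o[0])[1]
    return MicroPattern("J", p.order, bb, brs)


# ---------------------------------------------------------------------------
# built-in mode set
# ---------------------------------------------------------------------------

BUILTIN_STATEMENTS: dict[MacroClass, tuple[str, ...]] = {
    MacroClass.ID_182_182: (
        "[L2]C182:C182",
        "[L2]c182:c182",
        "[L3]c182:c182:c182",
        "[R3]c182:c182:c182:c182",
        "[J4]c182:c182(:c182):c182",
        "[J4]C182:C182(:C182):C182",
        "[J5]c182:(c182:)c182(:c182):c182",
    ),
    MacroClass.ID_180_180: (
        "[L2]C180:C180",
        "[L2]c180:c180",
        "[L3]c180:c180:c180",
        "[R3]c180:c180:c180:c180",
        "[J4]c180:c180(:c180):c180",
        "[J4]C180:C180(:C180):C180",
        "[J5]c180:(c180:)c180(:c180):c180",
    ),
    MacroClass.ID_180_182: (
        "[L2]C182:C180",
        "[L2]c182:c180",
        "[L3]c182:c180:c182",
        "[R3]c182:c180:c182:c182",
        "[L3]c180:c182:c180",
        "[R3]c180:c182:c180:c180",
    ),
}


class ModeSet:
    """An ordered collection of canonical micro-interaction modes."""

    def __init__(self, statements: Sequence[str]):
        self._statements: list[str] = []
        self._patterns: dict[str, MicroPattern] = {}
        for s in statements:
            pat = canonicalize(parse_danai(s))
            canon = format_danai(pat)
            if canon != s.strip():
                raise NotationSyntaxError(
                    f"statement {s!r} is not canonical (expected {canon!r})"
                )
            if canon in self._patterns:
                raise NotationSyntaxError(f"duplicate mode {canon!r}")
            self._statements.append(canon)
            self._patterns[canon] = pat

    def __len__(self) -> int:
        return len(self._statements)

    def __iter__(self) -> Iterator[tuple[str, MicroPattern]]:
        for s in self._statements:
            yield s, self._patterns[s]

    def __contains__(self, statement: str) -> bool:
        return statement in self._patterns

    @property
    def statements(self) -> list[str]:
        return list(self._statements)

    def pattern(self, statement: str) -> MicroPattern:
        return self._patterns[statement]

    def by_macro(self, macro: MacroClass) -> list[str]:
        return [s for s in self._statements if self._patterns[s].macro == macro]


def builtin_modes() -> ModeSet:
    """The 20 built-in modes (7 + 7 + 6), grouped by macro class, in table order."""
    ordered: list[str] = []
    for macro in (MacroClass.ID_182_182, MacroClass.ID_180_180, MacroClass.ID_180_182):
        ordered.extend(BUILTIN_STATEMENTS[macro])
    return ModeSet(ordered)
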