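"""Per-frame census of micro-interaction modes in a contact graph.

Counting convention: a mode's count is the number of distinct role
assignments of graph nodes to pattern vertices, up to the pattern's
automorphisms — i.e. a subgraph census, not a component classification.  A
triangle therefore also contributes three 3-chains and three pairs.  Pattern
edges are required in the graph; extra edges among the matched nodes are not
excluded (non-induced matching), except as dictated by case semantics:

* an uppercase species must have *exactly* the contacts shown in the pattern
  (its degree, in the configured scope, equals its in-pattern degree);
* a lowercase species is unconstrained under ``superset`` semantics, or must
  have at least one contact beyond the pattern under ``exclusive``.

Degree scope is the full graph by default (``global``) or the macro-class
subgraph (``macro``).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Sequence

from .contact_graph import ContactGraph, MacroClass, macro_edge_class
from .errors import UnsupportedPatternError
from .notation import MicroPattern, ModeSet, PatternSpecies

__all__ = [
    "SemanticsConfig",
    "MotifInstance",
    "ModeCounts",
    "macro_subgraph",
    "count_pattern",
    "closed_form_count",
    "count_modes",
    "pattern_automorphism_count",
]

_SUPPORTED = {("L", 2), ("L", 3), ("R", 3), ("J", 4), ("J", 5)}


@dataclass(frozen=True)
class SemanticsConfig:
    """Interpretation knobs for the case semantics (defaults match the rules)."""

    case_scope: str = "global"  # "global" | "macro"
    lowercase_mode: str = "superset"  # "superset" | "exclusive"

    def __post_init__(self):
        if self.case_scope not in ("global", "macro"):
            raise ValueError(f"unknown case_scope {self.case_scope!r}")
        if self.lowercase_mode not in ("superset", "exclusive"):
            raise ValueError(f"unknown lowercase_mode {self.lowercase_mode!r}")


@dataclass(frozen=True)
class MotifInstance:
    pattern: MicroPattern
    nodes: tuple[int, ...]
    frame_step: int = 0


@dataclass
class ModeCounts:
    frame_step: int
    time: float
    counts: dict[str, int] = field(default_factory=dict)


def macro_subgraph(g: ContactGraph, m: MacroClass) -> ContactGraph:
    """Same nodes, only the edges of macro class ``m``; the full-graph degree
    map is carried through for case-semantics scoping."""
    edges = {
        (u, v)
        for u, v in g.edges
        if macro_edge_class(g.species_of(u), g.species_of(v)) is m
    }
    return ContactGraph(
        nodes=g.nodes,
        edges=edges,
        cutoff=g.cutoff,
        full_degree=dict(g.full_degree),
    )


def pattern_automorphism_count(p: MicroPattern) -> int:
    """Label-preserving automorphisms of the pattern graph (|V| <= 5)."""
    verts = p.vertices()
    edges = {frozenset(e) for e in p.edges()}
    n = len(verts)
    count = 0
    for perm in itertools.permutations(range(n)):
        if any(verts[perm[i]] != verts[i] for i in range(n)):
            continue
        if all(frozenset((perm[i], perm[j])) in edges for i, j in edges):
            count += 1
    return count


def _scoped_degree(g: ContactGraph, p: MicroPattern, s: SemanticsConfig) -> dict[int, int]:
    if s.case_scope == "global":
        return g.full_degree
    sub = macro_subgraph(g, p.macro)
    return {v: len(nb) for v, nb in sub.adjacency.items()}


def _role_pred(g, sp: PatternSpecies, role_deg: int, scoped, s: SemanticsConfig):
    code = sp.code

    def pred(v: int) -> bool:
        if g.species_of(v).code != code:
            return False
        d = scoped[v]
        if sp.upper:
            return d == role_deg
        if s.lowercase_mode == "exclusive":
            return d >= role_deg + 1
        return True

    return pred


def _count_injective(role_masks: Sequence[int], candidates: Sequence[int]) -> int:
    """Ordered injective assignments of candidates to roles.

    ``candidates[i]`` is a bitmask of the roles node ``i`` can fill.  Counted
    by grouping nodes into mask classes and recursing over roles.
    """
    n_roles = len(role_masks)
    classes: dict[int, int] = {}
    for m in candidates:
        classes[m] = classes.get(m, 0) + 1
    masks = list(classes.keys())
    counts = [classes[m] for m in masks]

    def rec(role: int, used: tuple[int, ...]) -> int:
        if role == n_roles:
            return 1
        total = 0
        bit = 1 << role
        for ci, m in enumerate(masks):
            if m & bit and counts[ci] - used[ci] > 0:
                nu = list(used)
                nu[ci] += 1
                total += (counts[ci] - used[ci]) * rec(role + 1, tuple(nu))
        return total

    return rec(0, tuple([0] * len(masks)))


def count_pattern(g: ContactGraph, p: MicroPattern, s: SemanticsConfig = SemanticsConfig()) -> int:
    """Number of instances of ``p`` in ``g`` under semantics ``s``."""
    if (p.topology, p.order) not in _SUPPORTED:
        raise UnsupportedPatternError(
            f"unsupported pattern family {p.topology}{p.order}"
        )
    if p.topology == "J" and len(p.backbone) != 3:
        # only star-shaped junctions (all branches on the single centre)
        raise UnsupportedPatternError(
            "junction patterns are supported in star form only"
        )
    scoped = _scoped_degree(g, p, s)
    verts = p.vertices()
    degs = p.vertex_degrees()
    preds = [_role_pred(g, sp, d, scoped, s) for sp, d in zip(verts, degs)]
    adj = g.adjacency
    aut = pattern_automorphism_count(p)

    ordered = 0
    if p.topology == "L" and p.order == 2:
        for u, v in g.edges:
            if preds[0](u) and preds[1](v):
                ordered += 1
            if preds[0](v) and preds[1](u):
                ordered += 1
    elif p.topology == "R":
        p0, p1, p2 = preds
        for u, v in g.edges:
            common = adj[u] & adj[v]
            for w in common:
                # each unordered triangle reached 3 times via its edges; count
                # both orientations per reaching edge -> 6 ordered per triangle
                if p1(w):
                    if p0(u) and p2(v):
                        ordered += 1
                    if p0(v) and p2(u):
                        ordered += 1
    elif p.topology == "L":  # L3: centre is backbone[1]
        for v in adj:
            if not preds[1](v):
                continue
            nbrs = list(adj[v])
            masks = []
            for u in nbrs:
                m = (1 if preds[0](u) else 0) | (2 if preds[2](u) else 0)
                masks.append(m)
            ordered += _count_injective([1, 2], masks)
    else:  # J4 / J5: centre is backbone[1], leaves are the remaining roles
        centre_role = 1
        leaf_roles = [i for i in range(len(verts)) if i != centre_role]
        for v in adj:
            if not preds[centre_role](v):
                continue
            masks = []
            for u in adj[v]:
                m = 0
                for bit, role in enumerate(leaf_roles):
                    if preds[role](u):
                        m |= 1 << bit
                masks.append(m)
            ordered += _count_injective(leaf_roles, masks)

    if ordered % aut:
        raise AssertionError("ordered count not divisible by automorphism count")
    return ordered // aut


def closed_form_count(g: ContactGraph, p: MicroPattern) -> int:
    """Fast closed form for lowercase single-species chains/stars.

    On the macro subgraph: L2 = |E|, L3 = sum C(deg,2), J4 = sum C(deg,3),
    J5 = sum C(deg,4).
    """
    verts = p.vertices()
    codes = {sp.code for sp in verts}
    if len(codes) != 1 or any(sp.upper for sp in verts):
        raise UnsupportedPatternError(
            "closed form applies to lowercase single-species patterns only"
        )
    if (p.topology, p.order) not in {("L", 2), ("L", 3), ("J", 4), ("J", 5)}:
        raise UnsupportedPatternError(
            f"no closed form for {p.topology}{p.order}"
        )
    sub = macro_subgraph(g, p.macro)
    if p.topology == "L" and p.order == 2:
        return sub.n_edges
    k = {("L", 3): 2, ("J", 4): 3, ("J", 5): 4}[(p.topology, p.order)]
    return sum(math.comb(len(nb), k) for nb in sub.adjacency.values())


def count_modes(
    g: ContactGraph,
    modes: ModeSet,
    s: SemanticsConfig = SemanticsConfig(),
    frame_step: int = 0,
    time: float = 0.0,
) -> ModeCounts:
    """One count per mode; deterministic and independent of node ordering."""
    counts = {stmt: count_pattern(g, pat, s) for stmt, pat in modes}
    return ModeCounts(frame_step=frame_step, time=time, counts=counts)
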