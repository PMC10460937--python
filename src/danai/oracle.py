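"""Exhaustive brute-force motif census, used as ground truth in tests.

Deliberately shares no counting code with :mod:`danai.motif_count`: instances
are enumerated as subgraph monomorphisms via networkx, case constraints are
checked literally on every candidate mapping, and the result is reduced by the
pattern's label-preserving automorphism group.  Exponential in pattern size by
design; refuses graphs with more than 200 nodes.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
from networkx.algorithms import isomorphism

from .contact_graph import ContactGraph
from .errors import OracleSizeError
from .motif_count import SemanticsConfig
from .notation import MicroPattern

__all__ = ["OracleResult", "brute_force_count"]

_MAX_NODES = 200


@dataclass
class OracleResult:
    pattern: MicroPattern
    count: int
    instances: list[tuple[int, ...]]


def _pattern_graph(p: MicroPattern) -> nx.Graph:
    pg = nx.Graph()
    for i, sp in enumerate(p.vertices()):
        pg.add_node(i, code=sp.code, upper=sp.upper)
    pg.add_edges_from(p.edges())
    return pg


def _host_graph(g: ContactGraph) -> nx.Graph:
    hg = nx.Graph()
    for c in g.nodes:
        hg.add_node(c.node_id, code=c.species.code)
    hg.add_edges_from(g.edges)
    return hg


def _automorphisms(pg: nx.Graph) -> list[dict[int, int]]:
    gm = isomorphism.GraphMatcher(
        pg, pg, node_match=lambda a, b: a["code"] == b["code"] and a["upper"] == b["upper"]
    )
    return list(gm.isomorphisms_iter())


def _scoped_degrees(g: ContactGraph, p: MicroPattern, s: SemanticsConfig) -> dict[int, int]:
    if s.case_scope == "global":
        return {v: len(nb) for v, nb in g.adjacency.items()} if not g.full_degree else g.full_degree
    # macro scope: count only neighbours joined by an edge of the pattern's class
    macro = p.macro
    out: dict[int, int] = {}
    for v, nbrs in g.adjacency.items():
        d = 0
        for u in nbrs:
            pair = frozenset({g.species_of(v).number, g.species_of(u).number})
            name = (
                "ID_182_182"
                if pair == frozenset({182})
                else "ID_180_180"
                if pair == frozenset({180})
                else "ID_180_182"
            )
            if name == macro.value:
                d += 1
        out[v] = d
    return out


def brute_force_count(
    g: ContactGraph, p: MicroPattern, s: SemanticsConfig = SemanticsConfig()
) -> OracleResult:
    """Count all instances of ``p`` in ``g`` by exhaustive enumeration."""
    if g.n_nodes > _MAX_NODES:
        raise OracleSizeError(
            f"graph has {g.n_nodes} nodes; oracle contract is <= {_MAX_NODES}"
        )
    pg = _pattern_graph(p)
    hg = _host_graph(g)
    autos = _automorphisms(pg)
    scoped = _scoped_degrees(g, p, s)
    pat_deg = dict(pg.degree())

    valid: list[tuple[int, ...]] = []
    gm = isomorphism.GraphMatcher(
        hg, pg, node_match=lambda h, q: h["code"] == q["code"]
    )
    for mapping in gm.subgraph_monomorphisms_iter():
        # mapping: host node -> pattern vertex
        assignment: dict[int, int] = {pv: hv for hv, pv in mapping.items()}
        ok = True
        for pv, sp in enumerate(p.vertices()):
            hv = assignment[pv]
            d = scoped[hv]
            if sp.upper:
                if d != pat_deg[pv]:
                    ok = False
                    break
            elif s.lowercase_mode == "exclusive":
                if d < pat_deg[pv] + 1:
                    ok = False
                    break
        if ok:
            valid.append(tuple(assignment[i] for i in range(pg.number_of_nodes())))

    n_aut = len(autos)
    canonical: set[tuple[int, ...]] = set()
    for tup in valid:
        images = [tuple(tup[a[i]] for i in range(len(tup))) for a in autos]
        canonical.add(min(images))
    if len(valid) != n_aut * len(canonical):
        raise AssertionError("orbit sizes inconsistent with automorphism count")
    return OracleResult(pattern=p, count=len(canonical), instances=sorted(canonical))
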