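"""Interaction centers and the per-frame intermolecular contact graph.

Centers are atoms whose label matches a configured species tag (by default the
two tagged carbon types ``C180``/``C182``).  An edge joins two centers of
*different* molecules whose minimum-image distance is at or below the cutoff
(5 Angstrom by default).  Intramolecular pairs never form edges: the two
carbons of one molecule are covalently bonded, so molecule-level exclusion
implements the "non-bonded" criterion exactly for this chemistry.
"""

from __future__ import annotations

import itertools
import logging
import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .errors import ClassificationError, GeometryError, StructuralError
from .trajectory_io import Cell, Frame

__all__ = [
    "SpeciesTag",
    "InteractionCenter",
    "ContactGraph",
    "MacroClass",
    "DEFAULT_TAGS",
    "DEFAULT_CUTOFF",
    "minimum_image_distance",
    "extract_centers",
    "build_contact_graph",
    "macro_edge_class",
]

logger = logging.getLogger(__name__)

DEFAULT_CUTOFF = 5.0
DEFAULT_TAGS = ("C180", "C182")

# cell-list/tree acceleration kicks in above this many centers
_TREE_THRESHOLD = 500

_TAG_RE = re.compile(r"^([A-Za-z]+)(\d+)$")


@dataclass(frozen=True)
class SpeciesTag:
    """A chemically tagged species code such as ``C182``."""

    code: str
    description: str = ""

    def __post_init__(self):
        if not _TAG_RE.match(self.code):
            raise ClassificationError(f"malformed species code {self.code!r}")

    @property
    def number(self) -> int:
        return int(_TAG_RE.match(self.code).group(2))

    @property
    def element(self) -> str:
        return _TAG_RE.match(self.code).group(1)


@dataclass(frozen=True)
class InteractionCenter:
    node_id: int
    species: SpeciesTag
    molecule_id: int
    position: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "position", np.asarray(self.position, dtype=float))


class MacroClass(Enum):
    """Unordered species-pair class of a contact."""

    ID_182_182 = "ID_182_182"
    ID_180_180 = "ID_180_180"
    ID_180_182 = "ID_180_182"


_MACRO_BY_NUMBERS = {
    frozenset({182}): MacroClass.ID_182_182,
    frozenset({180}): MacroClass.ID_180_180,
    frozenset({180, 182}): MacroClass.ID_180_182,
}


def macro_edge_class(species_a: SpeciesTag | str, species_b: SpeciesTag | str) -> MacroClass:
    """Classify an edge by its two species, unordered."""

    def number(s):
        if isinstance(s, SpeciesTag):
            return s.number
        m = _TAG_RE.match(s)
        if not m:
            raise ClassificationError(f"malformed species code {s!r}")
        return int(m.group(2))

    key = frozenset({number(species_a), number(species_b)})
    try:
        return _MACRO_BY_NUMBERS[key]
    except KeyError:
        raise ClassificationError(
            f"species pair {sorted(key)} outside the configured tag set"
        ) from None


# ---------------------------------------------------------------------------
# minimum-image geometry
# ---------------------------------------------------------------------------

_SHIFTS = np.array(list(itertools.product((-1.0, 0.0, 1.0), repeat=3)))


def minimum_image_distance(a: np.ndarray, b: np.ndarray, cell: Cell) -> float:
    """Distance between ``a`` and ``b`` under the minimum-image convention.

    Exact (equal to the minimum over all lattice translations) whenever the
    separation of interest is below half the smallest cell width, which the
    graph builder enforces for its cutoff.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if not cell.periodic:
        return float(np.linalg.norm(b - a))
    if cell.volume <= 0.0:
        raise GeometryError("degenerate (zero-volume) cell")
    d = b - a
    # reduce into the central cell, then polish over the 27 surrounding images
    frac = np.linalg.solve(cell.matrix.T, d)
    frac -= np.round(frac)
    cand = (frac[None, :] + _SHIFTS) @ cell.matrix
    return float(np.sqrt(np.min(np.einsum("ij,ij->i", cand, cand))))


def _min_image_sqdist_matrix(pos: np.ndarray, cell: Cell) -> np.ndarray:
    """All-pairs squared minimum-image distances (vectorized)."""
    d = pos[:, None, :] - pos[None, :, :]
    if cell.periodic:
        if cell.periodic_flag in ("cubic", "orthorhombic"):
            box = np.diag(cell.matrix)
            d -= box * np.round(d / box)
            return np.einsum("ijk,ijk->ij", d, d)
        frac = np.einsum("ijk,kl->ijl", d, np.linalg.inv(cell.matrix))
        frac -= np.round(frac)
        best = None
        for shift in _SHIFTS:
            cart = np.einsum("ijk,kl->ijl", frac + shift, cell.matrix)
            sq = np.einsum("ijk,ijk->ij", cart, cart)
            best = sq if best is None else np.minimum(best, sq)
        return best
    return np.einsum("ijk,ijk->ij", d, d)


# ---------------------------------------------------------------------------
# contact graph
# ---------------------------------------------------------------------------


@dataclass
class ContactGraph:
    """Undirected intermolecular contact graph over interaction centers.

    ``full_degree`` is the degree of each node in the *full* (unrestricted)
    graph; macro-class subgraphs carry it through so that uppercase isolation
    semantics can be judged against all contacts, not just the restricted ones.
    """

    nodes: list[InteractionCenter]
    edges: set[tuple[int, int]]
    cutoff: float | None = None
    adjacency: dict[int, set[int]] = field(default_factory=dict)
    full_degree: dict[int, int] = field(default_factory=dict)

    def __post_init__(self):
        if not self.adjacency:
            adj: dict[int, set[int]] = {c.node_id: set() for c in self.nodes}
            for u, v in self.edges:
                adj[u].add(v)
                adj[v].add(u)
            self.adjacency = adj
        if not self.full_degree:
            self.full_degree = {v: len(nb) for v, nb in self.adjacency.items()}

    @classmethod
    def from_edges(
        cls,
        species: Sequence[str],
        edges: Iterable[tuple[int, int]],
        molecule_ids: Sequence[int] | None = None,
        cutoff: float | None = None,
    ) -> "ContactGraph":
        """Build an abstract (geometry-free) graph, one molecule per node
        unless ``molecule_ids`` says otherwise.  Intended for tests and
        programmatic fixtures."""
        if molecule_ids is None:
            molecule_ids = list(range(len(species)))
        nodes = [
            InteractionCenter(i, SpeciesTag(code), molecule_ids[i], np.zeros(3))
            for i, code in enumerate(species)
        ]
        eset = set()
        for u, v in edges:
            if u == v:
                raise StructuralError(f"self-edge on node {u}")
            if molecule_ids[u] == molecule_ids[v]:
                raise StructuralError(f"intramolecular edge {u}-{v}")
            eset.add((min(u, v), max(u, v)))
        return cls(nodes=nodes, edges=eset, cutoff=cutoff)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def degree(self, v: int) -> int:
        return len(self.adjacency[v])

    def species_of(self, v: int) -> SpeciesTag:
        return self.nodes[v].species


def extract_centers(
    frame: Frame, tag_patterns: Sequence[str] = DEFAULT_TAGS
) -> list[InteractionCenter]:
    """One interaction center per atom whose label equals a tag, in atom order."""
    if not tag_patterns:
        raise ValueError("tag_patterns must be non-empty")
    tags = {code: SpeciesTag(code) for code in tag_patterns}
    centers = []
    for atom in frame.atoms:
        tag = tags.get(atom.label)
        if tag is not None:
            centers.append(
                InteractionCenter(
                    node_id=len(centers),
                    species=tag,
                    molecule_id=atom.molecule_id,
                    position=atom.position,
                )
            )
    if not centers:
        logger.warning("no atoms matched tags %s", list(tag_patterns))
    return centers


def build_contact_graph(
    centers: Sequence[InteractionCenter],
    cell: Cell,
    cutoff: float = DEFAULT_CUTOFF,
    method: str = "auto",
) -> ContactGraph:
    """Edges join centers of different molecules within ``cutoff`` (inclusive).

    ``method`` is one of ``auto`` / ``brute`` / ``tree``; the tree accelerator
    (periodic k-d tree, orthorhombic cells only) and the brute-force all-pairs
    path produce identical edge sets.
    """
    if cutoff <= 0:
        raise GeometryError("cutoff must be positive")
    if cell.periodic and cutoff >= cell.min_width() / 2.0:
        raise GeometryError(
            f"cutoff {cutoff} >= half the smallest cell width "
            f"{cell.min_width() / 2.0:.4g}: nearest-image ambiguity"
        )
    centers = list(centers)
    n = len(centers)
    if method not in ("auto", "brute", "tree"):
        raise ValueError(f"unknown method {method!r}")
    use_tree = (
        method == "tree"
        or (method == "auto" and n > _TREE_THRESHOLD)
    ) and cell.periodic_flag in ("cubic", "orthorhombic")
    if method == "tree" and not use_tree:
        raise GeometryError("tree method requires an orthorhombic or cubic cell")

    mol = np.array([c.molecule_id for c in centers])
    edges: set[tuple[int, int]] = set()
    if n >= 2:
        pos = np.array([c.position for c in centers], dtype=float)
        if use_tree:
            box = np.diag(cell.matrix).copy()
            wrapped = np.mod(pos, box)
            wrapped[wrapped >= box[None, :]] = 0.0  # guard float round-up at the edge
            tree = cKDTree(wrapped, boxsize=box)
            for u, v in tree.query_pairs(cutoff):
                if mol[u] != mol[v]:
                    edges.add((min(u, v), max(u, v)))
        else:
            sq = _min_image_sqdist_matrix(pos, cell)
            iu, iv = np.triu_indices(n, k=1)
            mask = (sq[iu, iv] <= cutoff * cutoff) & (mol[iu] != mol[iv])
            for u, v in zip(iu[mask], iv[mask]):
                edges.add((int(u), int(v)))
    graph = ContactGraph(nodes=centers, edges=edges, cutoff=cutoff)
    return graph
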