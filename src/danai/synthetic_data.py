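"""Synthetic configurations with known structure.

Two generators:

* :func:`generate_liquid` — N randomly placed and oriented two-carbon dimers
  (one ``C180`` and one ``C182`` site a bond length apart) in a periodic cubic
  box, rejection-sampled against an intermolecular clash distance.  Frames are
  independent redraws: the target of study is counting and statistics, not
  dynamics.
* :func:`plant_pattern` — a frame whose contact graph contains *exactly* one
  planted instance of a given micro-pattern and no other intermolecular edge,
  companion (bonded-partner) sites included.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import GenerationError, UnsupportedPatternError
from .notation import MicroPattern
from .trajectory_io import AtomRecord, Cell, Frame, Trajectory

__all__ = ["LiquidSpec", "PlantedSpec", "generate_liquid", "plant_pattern"]


@dataclass(frozen=True)
class LiquidSpec:
    n_molecules: int
    box_length: float
    bond_length: float = 1.5
    min_separation: float = 2.0
    n_frames: int = 1
    seed: int = 0

    def __post_init__(self):
        if self.n_molecules < 1 or self.n_frames < 1:
            raise ValueError("n_molecules and n_frames must be positive")
        if not self.min_separation < self.box_length / 2:
            raise ValueError("min_separation must be below half the box length")


@dataclass(frozen=True)
class PlantedSpec:
    pattern: MicroPattern
    cutoff: float = 5.0
    box_length: float | None = None
    bond_length: float = 1.5
    seed: int = 0


def _random_unit(rng: np.random.Generator) -> np.ndarray:
    while True:
        v = rng.normal(size=3)
        n = np.linalg.norm(v)
        if n > 1e-12:
            return v / n


def _wrapped_min_dist_sq(existing: np.ndarray, site: np.ndarray, L: float) -> float:
    d = existing - site
    d -= L * np.round(d / L)
    return float(np.min(np.einsum("ij,ij->i", d, d)))


_MAX_TRIES = 500


def _liquid_frame(spec: LiquidSpec, rng: np.random.Generator, index: int) -> Frame:
    L = spec.box_length
    sites = np.empty((2 * spec.n_molecules, 3))
    placed = 0
    for i in range(spec.n_molecules):
        for _ in range(_MAX_TRIES):
            centre = rng.uniform(0.0, L, size=3)
            u = _random_unit(rng)
            s180 = np.mod(centre - u * spec.bond_length / 2.0, L)
            s182 = np.mod(centre + u * spec.bond_length / 2.0, L)
            if placed:
                lim = spec.min_separation**2
                if (
                    _wrapped_min_dist_sq(sites[:placed], s180, L) < lim
                    or _wrapped_min_dist_sq(sites[:placed], s182, L) < lim
                ):
                    continue
            sites[placed] = s180
            sites[placed + 1] = s182
            placed += 2
            break
        else:
            raise GenerationError(
                f"packing failed after {_MAX_TRIES} attempts for molecule {i}",
                achieved=i,
            )
    atoms = []
    for i in range(spec.n_molecules):
        for k, label in enumerate(("C180", "C182")):
            idx = 2 * i + k + 1
            atoms.append(
                AtomRecord(
                    label=label,
                    global_index=idx,
                    molecule_id=i,
                    position=sites[2 * i + k],
                )
            )
    return Frame(step=2000 * index, time=4.0 * index, cell=Cell.cubic(L), atoms=atoms)


def generate_liquid(spec: LiquidSpec) -> Trajectory:
    """Deterministic (per seed) i.i.d. dimer liquid frames."""
    frames = []
    for f in range(spec.n_frames):
        rng = np.random.default_rng(np.random.SeedSequence([spec.seed, f]))
        frames.append(_liquid_frame(spec, rng, f))
    return Trajectory(frames=frames, source=f"generate_liquid(seed={spec.seed})")


# ---------------------------------------------------------------------------
# planted motifs
# ---------------------------------------------------------------------------


def _motif_geometry(p: MicroPattern, d: float) -> tuple[np.ndarray, np.ndarray]:
    """Positions of the pattern vertices (order as ``p.vertices()``) and the
    outward unit direction along which each molecule's companion site points.

    Motif edges have length ``d``; every non-edge vertex pair is strictly
    farther than ``d / 0.96 * 1.1`` by construction.  Junction leaves sit on a
    60-degree cone about -z so the centre's companion can point up +z without
    coming within the contact cutoff of any leaf.
    """
    key = (p.topology, len(p.vertices()))
    if key == ("L", 2):
        pos = np.array([[0.0, 0.0, 0.0], [d, 0.0, 0.0]])
        comp = np.array([[-1.0, 0.0, 0.0], [1.0, 0.0, 0.0]])
    elif key == ("L", 3):
        pos = np.array([[-d, 0.0, 0.0], [0.0, 0.0, 0.0], [d, 0.0, 0.0]])
        comp = np.array([[-1.0, 0.0, 0.0], [0.0, 0.0, 1.0], [1.0, 0.0, 0.0]])
    elif key == ("R", 3):
        r = d / math.sqrt(3.0)
        dirs = np.array(
            [
                [math.cos(a), math.sin(a), 0.0]
                for a in (0.0, 2 * math.pi / 3, 4 * math.pi / 3)
            ]
        )
        pos = r * dirs
        comp = dirs
    elif key in (("J", 4), ("J", 5)):
        n_leaves = len(p.vertices()) - 1
        alpha = math.radians(60.0)
        azim = [2 * math.pi * k / n_leaves for k in range(n_leaves)]
        leaf_dirs = np.array(
            [
                [
                    math.sin(alpha) * math.cos(a),
                    math.sin(alpha) * math.sin(a),
                    -math.cos(alpha),
                ]
                for a in azim
            ]
        )
        # vertex order: backbone leaf, centre, backbone leaf, branch leaves
        pos = np.vstack([leaf_dirs[0] * d, np.zeros(3), leaf_dirs[1:] * d])
        comp = np.vstack([leaf_dirs[0], [0.0, 0.0, 1.0], leaf_dirs[1:]])
    else:
        raise UnsupportedPatternError(
            f"cannot plant pattern family {p.topology}{p.order}"
        )
    return pos, comp


def _companion_label(code: str) -> str:
    return {"C180": "C182", "C182": "C180"}.get(code, code)


def plant_pattern(spec: PlantedSpec) -> Frame:
    """A frame whose 5 A-style contact graph contains exactly the planted
    instance: motif edges at 0.96 x cutoff, every other intermolecular pair
    beyond the cutoff.  Each motif node gets a bonded companion carbon."""
    p = spec.pattern
    d = 0.96 * spec.cutoff
    pos, comp_dirs = _motif_geometry(p, d)
    verts = p.vertices()

    L = spec.box_length if spec.box_length is not None else 8.0 * spec.cutoff
    rng = np.random.default_rng(spec.seed)
    # random rigid motion: proper rotation + translation, then wrap
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    shift = rng.uniform(0.0, L, size=3)

    atoms: list[AtomRecord] = []
    for i, sp in enumerate(verts):
        node_pos = pos[i]
        comp_pos = pos[i] + comp_dirs[i] * spec.bond_length
        for k, (label, xyz) in enumerate(
            ((sp.code, node_pos), (_companion_label(sp.code), comp_pos))
        ):
            xyz = np.mod(xyz @ q.T + shift, L)
            atoms.append(
                AtomRecord(
                    label=label,
                    global_index=2 * i + k + 1,
                    molecule_id=i,
                    position=xyz,
                )
            )
    return Frame(step=0, time=0.0, cell=Cell.cubic(L), atoms=atoms)
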