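"""Built-in geometric annotator: base pairs and stacking from coordinates.

Used as a fallback when no precomputed (DSSR-style) annotation is
supplied.  A base pair is emitted when at least ``min_hbonds`` polar
heavy-atom contacts within ``hbond_distance`` exist between two bases,
with each contact vector lying roughly in both base planes (this rejects
the short vertical N/O distances of stacked bases).  The edge assigned to
each residue is the Leontis-Westhof edge whose atoms participate most in
those contacts; cis/trans comes from the sign of the glycosidic torsion
C1'-N(gly)-N(gly)'-C1'.

A stacking contact is emitted when the base-ring centroids lie within
``stack_distance``, the planes are within ``stack_angle`` degrees of
parallel and the projected rings overlap with nonzero area.

All thresholds are exposed on :class:`AnnotationConfig`; the defaults
follow common annotation practice and are deliberately permissive, since
tetrad finding — not pair detection — decides admissibility.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from typing import Optional

import numpy as np

from .model import (
    AnnotationGraph,
    BasePair,
    Edge,
    Orientation,
    Residue,
    Structure3D,
)

logger = logging.getLogger(__name__)

__all__ = [
    "AnnotationConfig",
    "EDGE_ATOMS",
    "annotate",
    "detect_base_pairs",
    "detect_stacking",
]


@dataclass
class AnnotationConfig:
    """Tunable thresholds of the geometric annotator.

    hbond_distance   maximum donor-acceptor heavy-atom distance, Angstrom
    min_hbonds       minimum number of such contacts to call a pair
    max_normal_cos   maximum |cos| between a contact vector and either
                     base normal (rejects stacked-base false positives)
    stack_distance   maximum ring-centroid distance, Angstrom
    stack_angle      maximum inter-plane angle, degrees
    """

    hbond_distance: float = 3.5
    min_hbonds: int = 2
    max_normal_cos: float = 0.5
    stack_distance: float = 4.5
    stack_angle: float = 30.0


#: Leontis-Westhof edge -> participating heavy atoms, per parent base.
#: An atom sitting on two edges (e.g. guanine O6 on both Watson-Crick and
#: Hoogsteen) counts toward both when edges are scored.
EDGE_ATOMS: dict = {
    "A": {
        Edge.WATSON_CRICK: ("N1", "N6"),
        Edge.HOOGSTEEN: ("N7", "N6"),
        Edge.SUGAR: ("N3", "C2"),
    },
    "G": {
        Edge.WATSON_CRICK: ("N1", "N2", "O6"),
        Edge.HOOGSTEEN: ("N7", "O6"),
        Edge.SUGAR: ("N3", "N2"),
    },
    "C": {
        Edge.WATSON_CRICK: ("N3", "N4", "O2"),
        Edge.HOOGSTEEN: ("N4", "C5"),
        Edge.SUGAR: ("O2",),
    },
    "U": {
        Edge.WATSON_CRICK: ("N3", "O4", "O2"),
        Edge.HOOGSTEEN: ("O4", "C5"),
        Edge.SUGAR: ("O2",),
    },
}
EDGE_ATOMS["T"] = EDGE_ATOMS["U"]

_POLAR = {
    "A": ("N1", "N3", "N6", "N7"),
    "G": ("N1", "N2", "N3", "O6", "N7"),
    "C": ("O2", "N3", "N4"),
    "U": ("O2", "N3", "O4"),
}
_POLAR["T"] = _POLAR["U"]

_RING = {
    "A": ("N9", "C8", "N7", "C5", "C6", "N1", "C2", "N3", "C4"),
    "G": ("N9", "C8", "N7", "C5", "C6", "N1", "C2", "N3", "C4"),
    "C": ("N1", "C2", "N3", "C4", "C5", "C6"),
    "U": ("N1", "C2", "N3", "C4", "C5", "C6"),
}
_RING["T"] = _RING["U"]

_GLYCOSIDIC = {"A": "N9", "G": "N9", "C": "N1", "U": "N1", "T": "N1"}

_SUGAR_PHOSPHATE = {
    "P", "OP1", "OP2", "OP3", "O5'", "C5'", "C4'", "O4'", "C3'", "O3'",
    "C2'", "O2'", "C1'",
}


def _base_atoms(base: str, atoms: dict) -> dict:
    """Base-moiety heavy atoms (name -> xyz), excluding sugar/phosphate/H."""
    out = {}
    for name, xyz in atoms.items():
        if name in _SUGAR_PHOSPHATE or name.startswith("H") or "'" in name:
            continue
        out[name] = xyz
    return out


def _polar_atoms(base: str, atoms: dict) -> dict:
    if base in _POLAR:
        return {n: atoms[n] for n in _POLAR[base] if n in atoms}
    return {
        n: x for n, x in _base_atoms(base, atoms).items() if n[:1] in ("N", "O")
    }


def _ring_coords(base: str, atoms: dict) -> Optional[np.ndarray]:
    if base in _RING:
        names = [n for n in _RING[base] if n in atoms]
        if len(names) < 5:
            return None
        return np.array([atoms[n] for n in names])
    pts = [x for n, x in _base_atoms(base, atoms).items()]
    return np.array(pts) if len(pts) >= 4 else None


def _plane_normal(points: np.ndarray) -> np.ndarray:
    centered = points - points.mean(axis=0)
    _, _, vt = np.linalg.svd(centered)
    return vt[2]


def _glycosidic_frame(base: str, atoms: dict):
    n = _GLYCOSIDIC.get(base)
    if n is None:
        n = "N9" if "N9" in atoms else "N1"
    if n in atoms and "C1'" in atoms:
        return atoms["C1'"], atoms[n]
    return None


def _torsion(p1, p2, p3, p4) -> float:
    b1, b2, b3 = p2 - p1, p3 - p2, p4 - p3
    n1, n2 = np.cross(b1, b2), np.cross(b2, b3)
    m1 = np.cross(n1, b2 / np.linalg.norm(b2))
    x, y = np.dot(n1, n2), np.dot(m1, n2)
    return float(np.degrees(np.arctan2(y, x)))


def _dominant_edge(base: str, contact_atoms: list[str]) -> Edge:
    table = EDGE_ATOMS.get(base)
    if table is None:
        return Edge.UNKNOWN
    counts = {e: sum(1 for a in contact_atoms if a in names)
              for e, names in table.items()}
    best = max(counts.values())
    if best == 0:
        return Edge.UNKNOWN
    for edge in (Edge.WATSON_CRICK, Edge.HOOGSTEEN, Edge.SUGAR):
        if counts[edge] == best:
            return edge
    return Edge.UNKNOWN  # pragma: no cover


def detect_base_pairs(
    structure: Structure3D, config: Optional[AnnotationConfig] = None
) -> list[BasePair]:
    """Detect base pairs from coordinates; deterministic 5'->3' order."""
    config = config or AnnotationConfig()
    prepared = []
    for res, atoms in zip(structure.residues, structure.coords):
        base_atoms = _base_atoms(res.base, atoms)
        polar = _polar_atoms(res.base, atoms)
        ring = _ring_coords(res.base, atoms)
        if ring is None or not polar:
            logger.warning("skipping %s: missing base atoms", res.label)
            continue
        prepared.append(
            {
                "res": res,
                "polar": polar,
                "normal": _plane_normal(ring),
                "centroid": ring.mean(axis=0),
                "frame": _glycosidic_frame(res.base, atoms),
            }
        )

    pairs: list[BasePair] = []
    for d1, d2 in combinations(prepared, 2):
        if np.linalg.norm(d1["centroid"] - d2["centroid"]) > 12.0:
            continue
        contacts = []
        for a1, x1 in d1["polar"].items():
            for a2, x2 in d2["polar"].items():
                v = x2 - x1
                dist = np.linalg.norm(v)
                if dist > config.hbond_distance or dist < 1.5:
                    continue
                u = v / dist
                if (
                    abs(np.dot(u, d1["normal"])) > config.max_normal_cos
                    or abs(np.dot(u, d2["normal"])) > config.max_normal_cos
                ):
                    continue
                contacts.append((a1, a2))
        if len(contacts) < config.min_hbonds:
            continue
        e1 = _dominant_edge(d1["res"].base, [c[0] for c in contacts])
        e2 = _dominant_edge(d2["res"].base, [c[1] for c in contacts])
        orientation = Orientation.UNKNOWN
        if d1["frame"] and d2["frame"]:
            c1p_1, n_1 = d1["frame"]
            c1p_2, n_2 = d2["frame"]
            tau = _torsion(c1p_1, n_1, n_2, c1p_2)
            orientation = Orientation.CIS if abs(tau) <= 90.0 else Orientation.TRANS
        pairs.append(
            BasePair(
                donor=d1["res"],
                acceptor=d2["res"],
                donor_edge=e1,
                acceptor_edge=e2,
                orientation=orientation,
            )
        )
    return pairs


def _projected_polygon(ring: np.ndarray, origin, u, v):
    from shapely.geometry import Polygon

    pts = [(float(np.dot(p - origin, u)), float(np.dot(p - origin, v))) for p in ring]
    poly = Polygon(pts)
    if not poly.is_valid:
        poly = poly.buffer(0)
    return poly


def detect_stacking(
    structure: Structure3D, config: Optional[AnnotationConfig] = None
) -> list[tuple[Residue, Residue]]:
    """Detect base-stacking contacts from coordinates."""
    config = config or AnnotationConfig()
    prepared = []
    for res, atoms in zip(structure.residues, structure.coords):
        ring = _ring_coords(res.base, atoms)
        if ring is None:
            logger.warning("skipping %s in stacking: missing ring atoms", res.label)
            continue
        prepared.append((res, ring, ring.mean(axis=0), _plane_normal(ring)))

    contacts = []
    for (r1, ring1, c1, n1), (r2, ring2, c2, n2) in combinations(prepared, 2):
        if np.linalg.norm(c1 - c2) > config.stack_distance:
            continue
        cosang = abs(float(np.dot(n1, n2)))
        if np.degrees(np.arccos(min(1.0, cosang))) > config.stack_angle:
            continue
        n2a = n2 if np.dot(n1, n2) >= 0 else -n2
        normal = n1 + n2a
        normal /= np.linalg.norm(normal)
        origin = (c1 + c2) / 2.0
        u = np.cross(normal, [1.0, 0.0, 0.0])
        if np.linalg.norm(u) < 1e-6:
            u = np.cross(normal, [0.0, 1.0, 0.0])
        u /= np.linalg.norm(u)
        v = np.cross(normal, u)
        p1 = _projected_polygon(ring1, origin, u, v)
        p2 = _projected_polygon(ring2, origin, u, v)
        if p1.intersection(p2).area > 1e-3:
            contacts.append((r1, r2))
    return contacts


def annotate(
    structure: Structure3D, config: Optional[AnnotationConfig] = None
) -> AnnotationGraph:
    """Run pair + stacking detection and assemble an annotation graph."""
    config = config or AnnotationConfig()
    graph = AnnotationGraph(structure.residues, chain_order=structure.chain_order)
    for pair in detect_base_pairs(structure, config):
        graph.add_pair(pair)
    for a, b in detect_stacking(structure, config):
        graph.add_stack(a, b)
    return graph
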