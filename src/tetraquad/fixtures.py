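"""Synthetic fixture generators with known ground truth.

Everything here is synthetic: annotation graphs are laid out so that the
classification rules *must* produce a requested class, and coordinate
fixtures are built by rigid placement of idealized base geometry (from
the bundled chemical-component library), so the geometric annotator can
be tested without downloading any structure.

Two families of generators exist:

* graph-level fixtures (:func:`make_tetrad_graph`,
  :func:`make_quadruplex_graph`, :func:`make_octamer_graph`,
  :func:`make_r_class_graph`) — residues, cis WC/Hoogsteen pairs and
  stacking contacts with attached ground-truth ONZ/ONZM classes;
* coordinate fixtures (:func:`make_pair_structure`,
  :func:`make_stack_structure`, :func:`make_tetrad_structure`) — small
  all-atom arrangements exercising the geometric annotator.

Ground truth for the multichain *adversarial* layouts (which chain
permutation the reordering optimizer commits, and the class it yields)
was derived by hand enumeration of the possible chain orders on 3+1 and
1+1+1+1 strand splits and is frozen in the tables below.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .model import (
    AnnotationGraph,
    BasePair,
    Edge,
    Orientation,
    Residue,
    Structure3D,
)
from .onz import ONZ_CLASSES, PATTERN_TO_CLASS

__all__ = [
    "TetradTruth",
    "QuadruplexTruth",
    "make_tetrad_graph",
    "make_quadruplex_graph",
    "make_octamer_graph",
    "make_r_class_graph",
    "make_pair_structure",
    "make_stack_structure",
    "make_tetrad_structure",
    "to_dssr_json",
    "write_mmcif",
    "write_protein_mmcif",
]

CLASS_TO_PATTERN = {v: k for k, v in PATTERN_TO_CLASS.items()}

#: cycle order over the 5'-sorted residues (w, x, y, z) realizing each class
#: (pairs run donor->acceptor along the cycle, donor on its WC edge)
_CYCLE_FOR_CLASS = {
    "O+": (0, 1, 2, 3),
    "O-": (0, 3, 2, 1),
    "N+": (0, 1, 3, 2),
    "N-": (0, 3, 1, 2),
    "Z+": (0, 2, 1, 3),
    "Z-": (0, 2, 3, 1),
}


@dataclass
class TetradTruth:
    """Ground truth attached to a tetrad fixture."""

    onz: str                      # the class the fixture realizes (see below)
    identity_onz: str             # class under the emitted (input) chain order
    reordered_onz: Optional[str]  # class after reordering, where determined
    chains: int
    adversarial: bool
    residues: dict                # role letter -> Residue


@dataclass
class QuadruplexTruth:
    """Ground truth attached to a quadruplex fixture."""

    onzm: str
    tetrad_classes: list
    tract_columns: list           # list of residue tuples, one per tract


def _add_cwh_cycle(graph: AnnotationGraph, cycle: Sequence[Residue]) -> None:
    for a, b in zip(cycle, list(cycle[1:]) + [cycle[0]]):
        graph.add_pair(
            BasePair(
                donor=a,
                acceptor=b,
                donor_edge=Edge.WATSON_CRICK,
                acceptor_edge=Edge.HOOGSTEEN,
                orientation=Orientation.CIS,
            )
        )


def _number_chain(residues: list[Residue]) -> None:
    for i, r in enumerate(residues, 1):
        r.number = i


def _spacers(rng: random.Random, chain: str, k: int) -> list[Residue]:
    return [Residue(chain, 0, None, rng.choice("ACGU")) for _ in range(k)]


# ---------------------------------------------------------------------------
# single tetrads
# ---------------------------------------------------------------------------

# chains=2 adversarial layouts on a 3+1 strand split (chain P holds p0,p1,p2
# in 5'->3' order, chain Q holds q0).  Tuples give: cycle over
# (p0,p1,p2,q0) indices, chain name of P, of Q, emitted chain order, and the
# class under that emitted order.  The target class is what the O-then-N
# maximizing reordering commits (hand-enumerated over both chain orders).
_ADVERSARIAL_2 = {
    "O+": ((0, 1, 2, 3), "A", "B", ("B", "A"), "O+"),
    "O-": ((0, 3, 2, 1), "A", "B", ("B", "A"), "O-"),
    "N+": ((0, 1, 3, 2), "A", "B", ("B", "A"), "N-"),
    "N-": ((0, 1, 3, 2), "B", "A", ("B", "A"), "N+"),
    "Z-": ((0, 2, 3, 1), "A", "B", ("B", "A"), "Z+"),
    "Z+": ((0, 2, 3, 1), "B", "A", ("B", "A"), "Z-"),
}

# chains=4 adversarial layouts (one residue per chain, cycle r1->r2->r3->r4):
# chain names per cycle position, emitted order, class under emitted order.
# Only O targets are reachable: with four single-residue strands some
# permutation always realizes an O class, so the O-maximizing reordering can
# never commit an N or Z class.
_ADVERSARIAL_4 = {
    "O+": (("A", "B", "C", "D"), ("A", "C", "B", "D"), "Z+"),
    "O-": (("A", "D", "C", "B"), ("A", "C", "D", "B"), "Z+"),
}


def make_tetrad_graph(
    onz: str, chains: int = 1, seed: int = 0, adversarial: bool = False
) -> tuple[AnnotationGraph, TetradTruth]:
    """Build a graph holding one tetrad of the requested ONZ class.

    Non-adversarial fixtures realize ``onz`` under the emitted (identity)
    chain order, for 1, 2 or 4 chains.  Adversarial multichain fixtures
    emit a scrambled chain order instead: the requested class is what the
    reordering optimizer commits (frozen ground truth), while the emitted
    order yields ``truth.identity_onz``.  Random spacer residues (seeded)
    surround the tetrad members.
    """
    if onz not in ONZ_CLASSES:
        raise ValueError(f"unknown ONZ class {onz!r}")
    if chains not in (1, 2, 4):
        raise ValueError("chains must be 1, 2 or 4")
    rng = random.Random(seed)

    if not adversarial:
        pattern = CLASS_TO_PATTERN[onz]
        seq_roles = ["A"] + list(pattern)  # roles in 5'->3' order
        chain_names = {1: ["A"], 2: ["A", "B"], 4: ["A", "B", "C", "D"]}[chains]
        split = {1: [4], 2: [2, 2], 4: [1, 1, 1, 1]}[chains]
        role_residue: dict = {}
        all_res: list[Residue] = []
        it = iter(seq_roles)
        for cname, k in zip(chain_names, split):
            members = [next(it) for _ in range(k)]
            lst: list[Residue] = []
            for role in members:
                lst.extend(_spacers(rng, cname, rng.randint(0, 2)))
                r = Residue(cname, 0, None, "G")
                role_residue[role] = r
                lst.append(r)
            lst.extend(_spacers(rng, cname, rng.randint(0, 1)))
            _number_chain(lst)
            all_res.extend(lst)
        graph = AnnotationGraph(all_res, chain_order=chain_names)
        _add_cwh_cycle(
            graph, [role_residue[x] for x in ("A", "B", "C", "D")]
        )
        truth = TetradTruth(
            onz=onz,
            identity_onz=onz,
            reordered_onz=onz if chains == 1 else None,
            chains=chains,
            adversarial=False,
            residues=role_residue,
        )
        return graph, truth

    if chains == 2:
        cycle_idx, name_p, name_q, emit_order, identity_onz = _ADVERSARIAL_2[onz]
        p_res = [Residue(name_p, 0, None, "G") for _ in range(3)]
        q_res = [Residue(name_q, 0, None, "G")]
        members = p_res + q_res  # (p0, p1, p2, q0)
        per_chain = {name_p: p_res, name_q: [q_res[0]]}
    elif chains == 4:
        if onz not in _ADVERSARIAL_4:
            raise ValueError(
                f"{onz} is unreachable after reordering with 4 single-residue "
                "strands; only O+ and O- adversarial layouts exist"
            )
        names, emit_order, identity_onz = _ADVERSARIAL_4[onz]
        members = [Residue(n, 0, None, "G") for n in names]
        per_chain = {n: [r] for n, r in zip(names, members)}
        cycle_idx = (0, 1, 2, 3)
    else:
        raise ValueError("adversarial fixtures require 2 or 4 chains")

    all_res = []
    for cname in emit_order:
        lst = list(per_chain[cname])
        _number_chain(lst)
        all_res.extend(lst)
    graph = AnnotationGraph(all_res, chain_order=list(emit_order))
    _add_cwh_cycle(graph, [members[i] for i in cycle_idx])
    roles = {
        role: members[i]
        for role, i in zip(("A", "B", "C", "D"), cycle_idx)
    }
    truth = TetradTruth(
        onz=onz,
        identity_onz=identity_onz,
        reordered_onz=onz,
        chains=chains,
        adversarial=True,
        residues=roles,
    )
    return graph, truth


# ---------------------------------------------------------------------------
# quadruplexes
# ---------------------------------------------------------------------------


def _class_schedule(letter: str, sign: str, n: int) -> list[str]:
    if letter in ("O", "N", "Z"):
        if sign in ("+", "-"):
            return [letter + sign] * n
        return [letter + "+", letter + "-"] + [letter + "+"] * (n - 2)
    if letter == "M":
        base = {"+": ["O+", "N+"], "-": ["O-", "N-"], "*": ["O+", "N-"]}[sign]
        return base + [base[0]] * (n - 2)
    raise ValueError(f"unknown quadruplex letter {letter!r}")


def make_quadruplex_graph(
    letter: str,
    direction: str,
    sign: str,
    n_tetrads: int = 3,
    seed: int = 0,
    stack_contacts: int = 4,
) -> tuple[AnnotationGraph, QuadruplexTruth]:
    """Build a single-chain quadruplex with the requested ONZM class.

    Four tract blocks of ``n_tetrads`` guanines each are laid out 5'->3';
    ``direction`` decides which blocks run antiparallel (none for p,
    blocks 2 and 4 for a, block 4 for h), and each tetrad's pair cycle is
    chosen to realize its scheduled ONZ class.  ``stack_contacts`` (< 4)
    leaves some residue columns unstacked between consecutive tetrads,
    for exercising the stacking-mismatch tolerance.
    """
    if direction not in ("p", "a", "h"):
        raise ValueError("direction must be one of p/a/h")
    if sign not in ("+", "-", "*"):
        raise ValueError("sign must be one of +/-/*")
    if n_tetrads < 2:
        raise ValueError("a quadruplex needs at least two tetrads")
    if sign == "*" and n_tetrads < 2:
        raise ValueError("a hybrid sign needs at least two tetrads")
    if letter == "M" and n_tetrads < 2:
        raise ValueError("a mixed quadruplex needs at least two tetrads")
    classes = _class_schedule(letter, sign, n_tetrads)
    rng = random.Random(seed)

    reversed_blocks = {"p": (), "a": (1, 3), "h": (3,)}[direction]
    blocks: list[list[Residue]] = []
    chain: list[Residue] = []
    for b in range(4):
        chain.extend(_spacers(rng, "A", rng.randint(0, 2)))
        block = [Residue("A", 0, None, "G") for _ in range(n_tetrads)]
        blocks.append(block)
        chain.extend(block)
    chain.extend(_spacers(rng, "A", rng.randint(0, 1)))
    _number_chain(chain)
    graph = AnnotationGraph(chain, chain_order=["A"])

    def row(block_index: int, t: int) -> int:
        return n_tetrads - 1 - t if block_index in reversed_blocks else t

    tetrad_members = []
    for t, cls in enumerate(classes):
        members = tuple(blocks[b][row(b, t)] for b in range(4))
        tetrad_members.append(members)
        cycle = [members[i] for i in _CYCLE_FOR_CLASS[cls]]
        _add_cwh_cycle(graph, cycle)
    for t in range(n_tetrads - 1):
        for b in range(min(stack_contacts, 4)):
            graph.add_stack(blocks[b][row(b, t)], blocks[b][row(b, t + 1)])

    tracts = [
        tuple(blocks[b][row(b, t)] for t in range(n_tetrads)) for b in range(4)
    ]
    truth = QuadruplexTruth(
        onzm=f"{letter}{direction}{sign}",
        tetrad_classes=classes,
        tract_columns=tracts,
    )
    return graph, truth


def make_octamer_graph(seed: int = 0) -> tuple[AnnotationGraph, dict]:
    """Synthetic eight-strand analogue of a DNA/RNA-hybrid double quadruplex.

    Two tetramolecular 5-tetrad quadruplexes (strand quartets A/C/E/G and
    B/D/F/H) are emitted with a scrambled chain order, so that without
    reordering none of the ten tetrads is classifiable, while the
    reordering optimizer commits the alphabetical order and finds two Op*
    quadruplexes: one with four O+ and one O- tetrad, the other with
    three O+ and two O-.  Ground-truth dict keys: ``n_tetrads``,
    ``quadruplexes`` (list of per-quadruplex class lists, 5' first),
    ``onzm``, ``committed_order``, ``identity_counts``.
    """
    rng = random.Random(seed)  # reserved; layout is deterministic
    quartets = [("A", "C", "E", "G"), ("B", "D", "F", "H")]
    reversed_rows = [(4,), (3, 4)]
    n_rows = 5
    chains: dict[str, list[Residue]] = {}
    for quartet in quartets:
        for c in quartet:
            chains[c] = [Residue(c, i + 1, None, "G") for i in range(n_rows)]
    emit_order = ["A", "E", "C", "G", "B", "F", "D", "H"]
    all_res = [r for c in emit_order for r in chains[c]]
    graph = AnnotationGraph(all_res, chain_order=emit_order)
    for quartet, rev in zip(quartets, reversed_rows):
        for row_i in range(n_rows):
            members = [chains[c][row_i] for c in quartet]
            if row_i in rev:
                members = [members[0]] + members[1:][::-1]
            _add_cwh_cycle(graph, members)
        for row_i in range(n_rows - 1):
            for c in quartet:
                graph.add_stack(chains[c][row_i], chains[c][row_i + 1])
    truth = {
        "n_tetrads": 10,
        "quadruplexes": [
            ["O+", "O+", "O+", "O+", "O-"],
            ["O+", "O+", "O+", "O-", "O-"],
        ],
        "onzm": ["Op*", "Op*"],
        "committed_order": ["A", "B", "C", "D", "E", "F", "G", "H"],
        # classes under the emitted (scrambled) order, hand-enumerated:
        # forward-cycle rows read Z+, reversed rows read N-
        "identity_counts": {"Z+": 7, "N-": 3},
    }
    return graph, truth


def make_r_class_graph(seed: int = 0) -> tuple[AnnotationGraph, dict]:
    """Bimolecular 2-tetrad quadruplex: R class when reordering is off.

    Both tetrads span chains A and B, so without a committed chain order
    they stay unclassified and the quadruplex falls into the R class.
    """
    a = [Residue("A", i + 1, None, "G") for i in range(4)]
    b = [Residue("B", i + 1, None, "G") for i in range(4)]
    graph = AnnotationGraph(a + b, chain_order=["A", "B"])
    t1 = (a[0], a[3], b[0], b[3])
    t2 = (a[1], a[2], b[1], b[2])
    _add_cwh_cycle(graph, list(t1))
    _add_cwh_cycle(graph, list(t2))
    for x, y in zip(t1, t2):
        graph.add_stack(x, y)
    return graph, {"n_tetrads": 2, "onzm_no_reorder": "R"}


# ---------------------------------------------------------------------------
# coordinate fixtures (rigid placement of idealized bases)
# ---------------------------------------------------------------------------

_RING_PURINE = ("N9", "C8", "N7", "C5", "C6", "N1", "C2", "N3", "C4")
_RING_PYRIMIDINE = ("N1", "C2", "N3", "C4", "C5", "C6")


def _ideal_base(letter: str) -> dict:
    """Heavy-atom ideal geometry of a ribonucleotide from the bundled CCD."""
    import biotite.structure.info as info

    arr = info.residue(letter)
    return {
        str(n): np.array(c, dtype=float)
        for n, c in zip(arr.atom_name, arr.coord)
        if not str(n).startswith("H")
    }


def _planarize(atoms: dict, ring_names: Sequence[str]) -> dict:
    ring = np.array([atoms[n] for n in ring_names if n in atoms])
    centroid = ring.mean(axis=0)
    centered = {n: c - centroid for n, c in atoms.items()}
    _, _, vt = np.linalg.svd(ring - centroid)
    normal = vt[2]
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(normal, z)
    s, c = np.linalg.norm(v), float(np.dot(normal, z))
    if s < 1e-9:
        rot = np.eye(3) if c > 0 else np.diag([1.0, -1.0, -1.0])
    else:
        vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
        rot = np.eye(3) + vx + vx @ vx * ((1 - c) / s**2)
    return {n: rot @ p for n, p in centered.items()}


def _kabsch(mobile: np.ndarray, target: np.ndarray):
    """Rigid transform (rot, trans) minimizing RMSD mobile -> target."""
    mc, tc = mobile.mean(axis=0), target.mean(axis=0)
    h = (mobile - mc).T @ (target - tc)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    return rot, tc - rot @ mc

def _apply(atoms: dict, rot: np.ndarray, trans: np.ndarray) -> dict:
    return {n: rot @ p + trans for n, p in atoms.items()}


def _outward(atoms: dict, name: str, ring_names: Sequence[str]) -> np.ndarray:
    ring = np.array([atoms[n] for n in ring_names if n in atoms])
    v = atoms[name] - ring.mean(axis=0)
    v[2] = 0.0
    return v / np.linalg.norm(v)


def _structure(residue_atoms: list[dict], bases: str) -> Structure3D:
    residues = [
        Residue("A", i + 1, None, b, global_index=i)
        for i, b in enumerate(bases)
    ]
    return Structure3D(
        residues=residues, coords=residue_atoms, chain_order=["A"]
    )


_Z = np.array([0.0, 0.0, 1.0])
_HBOND = 2.85  # target donor-acceptor distance, Angstrom


def _place_onto(
    mobile_atoms: dict,
    mobile_names: Sequence[str],
    targets: Sequence[np.ndarray],
    flip: bool = False,
) -> dict:
    """Rigidly place a planar base so the named atoms land on targets.

    ``flip`` maps the base normal to -z (the geometry of a canonical
    antiparallel-duplex pair); otherwise normals stay parallel (the
    geometry of same-plane tetrad neighbours).
    """
    nz = -_Z if flip else _Z
    mob = [mobile_atoms[n] for n in mobile_names]
    mob += [p + _Z for p in mob]
    tgt = list(targets) + [t + nz for t in targets]
    rot, trans = _kabsch(np.array(mob), np.array(tgt))
    return _apply(mobile_atoms, rot, trans)


def make_pair_structure(kind: str) -> tuple[Structure3D, dict]:
    """Two-residue coordinate fixture for base-pair detection.

    Kinds: ``"gg_cwh"`` — a G·G pair with the first G presenting its
    Watson-Crick edge to the second G's Hoogsteen edge; ``"gc_canonical"``
    — a Watson-Crick G·C pair; ``"far"`` — two guanines 30 A apart.
    Returns the structure and the expected annotation (possibly empty).
    """
    g = _planarize(_ideal_base("G"), _RING_PURINE)
    if kind == "gg_cwh":
        t_o6 = g["N1"] + _HBOND * _outward(g, "N1", _RING_PURINE)
        t_n7 = g["N2"] + _HBOND * _outward(g, "N2", _RING_PURINE)
        g2 = _place_onto(dict(g), ("O6", "N7"), (t_o6, t_n7))
        return (
            _structure([g, g2], "GG"),
            {"pairs": [(0, 1, Edge.WATSON_CRICK, Edge.HOOGSTEEN)]},
        )
    if kind == "gc_canonical":
        c = _planarize(_ideal_base("C"), _RING_PYRIMIDINE)
        targets = (
            g["O6"] + _HBOND * _outward(g, "O6", _RING_PURINE),
            g["N1"] + _HBOND * _outward(g, "N1", _RING_PURINE),
            g["N2"] + _HBOND * _outward(g, "N2", _RING_PURINE),
        )
        c2 = _place_onto(c, ("N4", "N3", "O2"), targets, flip=True)
        return (
            _structure([g, c2], "GC"),
            {"pairs": [(0, 1, Edge.WATSON_CRICK, Edge.WATSON_CRICK)],
             "canonical": True},
        )
    if kind == "far":
        g2 = {n: p + np.array([30.0, 0.0, 0.0]) for n, p in g.items()}
        return _structure([g, g2], "GG"), {"pairs": []}
    raise ValueError(f"unknown pair fixture kind {kind!r}")


def _rot_z(angle_deg: float) -> np.ndarray:
    a = np.radians(angle_deg)
    return np.array(
        [[np.cos(a), -np.sin(a), 0], [np.sin(a), np.cos(a), 0], [0, 0, 1.0]]
    )


def make_stack_structure(kind: str) -> tuple[Structure3D, dict]:
    """Two-residue coordinate fixture for stacking detection.

    Kinds: ``"stacked"`` — coaxial guanines 3.3 A apart with a 25 degree
    twist (a contact); ``"coplanar"`` — side by side in one plane (no
    contact); ``"tilted"`` — 3.3 A apart but with a 60 degree inter-plane
    angle (no contact).
    """
    g = _planarize(_ideal_base("G"), _RING_PURINE)
    if kind == "stacked":
        rot = _rot_z(25.0)
        g2 = {n: rot @ p + np.array([0.0, 0.0, 3.3]) for n, p in g.items()}
        expected = {"stacks": [(0, 1)]}
    elif kind == "coplanar":
        g2 = {n: p + np.array([8.5, 0.0, 0.0]) for n, p in g.items()}
        expected = {"stacks": []}
    elif kind == "tilted":
        a = np.radians(60.0)
        rot = np.array(
            [[1.0, 0, 0], [0, np.cos(a), -np.sin(a)], [0, np.sin(a), np.cos(a)]]
        )
        g2 = {n: rot @ p + np.array([0.0, 0.0, 3.3]) for n, p in g.items()}
        expected = {"stacks": []}
    else:
        raise ValueError(f"unknown stack fixture kind {kind!r}")
    return _structure([g, g2], "GG"), expected


def make_tetrad_structure() -> tuple[Structure3D, dict]:
    """Four guanines in one plane forming a cWH cycle (a G-tetrad).

    Successive guanines are exact 90-degree rotations about a common
    in-plane center chosen (least squares) so that each G's Watson-Crick
    donors face the next G's Hoogsteen acceptors at H-bond range; the
    four pairs then close into a cycle whose 5'->3' layout reads O+.
    """
    g = _planarize(_ideal_base("G"), _RING_PURINE)
    t_o6 = g["N1"] + _HBOND * _outward(g, "N1", _RING_PURINE)
    t_n7 = g["N2"] + _HBOND * _outward(g, "N2", _RING_PURINE)
    best = None
    for angle in (90.0, -90.0):
        rot2 = _rot_z(angle)[:2, :2]
        m = np.eye(2) - rot2
        p = np.array([g["O6"][:2], g["N7"][:2]])
        t = np.array([t_o6[:2], t_n7[:2]])
        rhs = (t - p @ rot2.T).mean(axis=0)
        center2 = np.linalg.solve(m, rhs)
        resid = float(np.abs((p - center2) @ rot2.T + center2 - t).sum())
        if best is None or resid < best[0]:
            best = (resid, angle, center2)
    _, angle, center2 = best
    center = np.array([center2[0], center2[1], 0.0])
    copies = []
    for k in range(4):
        rot = _rot_z(angle * k)
        copies.append({n: rot @ (p - center) + center for n, p in g.items()})
    expected = {
        "pairs": [(0, 1), (1, 2), (2, 3), (0, 3)],
        "tetrad_onz": "O+",
    }
    return _structure(copies, "GGGG"), expected


# ---------------------------------------------------------------------------
# file-format helpers
# ---------------------------------------------------------------------------


def to_dssr_json(graph: AnnotationGraph) -> dict:
    """Render a graph as annotator-style JSON (nts / pairs / stacks)."""
    def nt_id(r: Residue) -> str:
        ic = f"^{r.icode}" if r.icode else ""
        return f"{r.chain_id}.{r.base}{r.number}{ic}"

    index = {r: i for i, r in enumerate(graph.residues)}
    return {
        "nts": [
            {
                "index": i + 1,
                "nt_id": nt_id(r),
                "chain_name": r.chain_id,
                "nt_resnum": r.number,
                "nt_name": r.base,
                "nt_code": r.base,
            }
            for i, r in enumerate(graph.residues)
        ],
        "pairs": [
            {"nt1": nt_id(p.donor), "nt2": nt_id(p.acceptor), "LW": p.lw}
            for p in sorted(
                graph.pairs,
                key=lambda p: (index[p.donor], index[p.acceptor]),
            )
        ],
        "stacks": [
            {"nts_long": ",".join(nt_id(r) for r in sorted(s, key=index.get))}
            for s in sorted(
                graph.stacks, key=lambda s: sorted(index[r] for r in s)
            )
        ],
    }


_ELEMENT = {"N": "N", "C": "C", "O": "O", "P": "P"}


def _gemmi_structure(structure: Structure3D, rna_names: bool = True):
    import gemmi

    st = gemmi.Structure()
    st.name = "synthetic"
    model = gemmi.Model("1")
    for chain_name in structure.chain_order:
        chain = gemmi.Chain(chain_name)
        for res, atoms in zip(structure.residues, structure.coords):
            if res.chain_id != chain_name:
                continue
            r = gemmi.Residue()
            r.name = res.base if res.base in "ACGU" else "DT"
            r.seqid = gemmi.SeqId(res.number, res.icode or " ")
            for name, xyz in atoms.items():
                a = gemmi.Atom()
                a.name = name
                a.pos = gemmi.Position(*xyz)
                a.element = gemmi.Element(_ELEMENT.get(name[0], "C"))
                r.add_atom(a)
            chain.add_residue(r)
        model.add_chain(chain)
    st.add_model(model)
    return st


def write_mmcif(structure: Structure3D, path) -> None:
    """Write a coordinate fixture as a minimal mmCIF file."""
    st = _gemmi_structure(structure)
    st.setup_entities()
    st.make_mmcif_document().write_file(str(path))


def write_pdb(structure: Structure3D, path) -> None:
    """Write a coordinate fixture as a minimal PDB file."""
    st = _gemmi_structure(structure)
    st.setup_entities()
    st.write_pdb(str(path))


def write_protein_mmcif(path) -> None:
    """Write a synthetic protein-only mmCIF (no nucleotides at all)."""
    import gemmi

    st = gemmi.Structure()
    st.name = "synthetic-protein"
    model = gemmi.Model("1")
    chain = gemmi.Chain("A")
    for i in range(3):
        r = gemmi.Residue()
        r.name = "ALA"
        r.seqid = gemmi.SeqId(i + 1, " ")
        for j, name in enumerate(("N", "CA", "C", "O", "CB")):
            a = gemmi.Atom()
            a.name = name
            a.pos = gemmi.Position(float(i) * 3.8 + j * 0.5, 0.0, 0.0)
            a.element = gemmi.Element(name[0])
            r.add_atom(a)
        chain.add_residue(r)
    model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    st.make_mmcif_document().write_file(str(path))
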