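"""Grouping tetrads into quadruplexes (and N4-helices) via stacking.

Two tetrads are *stacked* when a one-to-one matching between their
residues covers at least ``4 - mismatch`` pairs present in the stacking
contact set; the optimal matching is found by exhaustive enumeration of
the 4! assignments (exact and cheap).  Connected components of the
resulting tetrad graph — optionally augmented with sequence-adjacency
edges under the relaxed stem definition — become quadruplexes when they
contain at least two tetrads; singleton components are reported as lone
tetrads.

Tract columns are built by chaining the stacking matchings from the
first tetrad's (A, B, C, D).  A component whose consecutive tetrads
chain across different strand sets is an N4-helix: it is split into
quadruplex segments at those tract breaks and reported structurally.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import permutations
from typing import Optional, Sequence

from .model import AnnotationGraph, Residue
from .tetrads import Tetrad

logger = logging.getLogger(__name__)

__all__ = [
    "StackingParams",
    "Quadruplex",
    "N4Helix",
    "tetrads_stacked",
    "best_stacking_matching",
    "build_quadruplexes",
]


@dataclass
class StackingParams:
    """Assembly tolerances.

    ``mismatch`` in {0, 1, 2}: how many of the 4 residue columns may lack
    a stacking contact between consecutive tetrads (0 enforces ideal
    geometry; 2, the default, leaves room for imperfect stacking).
    ``relaxed_stem`` additionally links sequentially neighbouring tetrads
    regardless of their mutual stacking.
    """

    mismatch: int = 2
    relaxed_stem: bool = False

    def __post_init__(self):
        if self.mismatch not in (0, 1, 2):
            raise ValueError("mismatch must be 0, 1 or 2")


@dataclass(eq=False)
class Quadruplex:
    """An ordered stack of >=2 tetrads with its four tract columns."""

    tetrads: list
    tracts: list  # 4 lists, one residue per tetrad each
    onzm: Optional[str] = None

    @property
    def min_index(self) -> int:
        return min(t.min_index for t in self.tetrads)

    @property
    def chains(self) -> set:
        return set().union(*(t.chains for t in self.tetrads))


@dataclass(eq=False)
class N4Helix:
    """A coaxial stack extending beyond one quadruplex's four tracts."""

    tetrads: list            # full component, stack order
    quadruplexes: list       # >=2-tetrad segments, classification applies here
    lone_tetrads: list       # 1-tetrad segments


def best_stacking_matching(
    t1: Tetrad, t2: Tetrad, graph: AnnotationGraph
) -> tuple[int, tuple]:
    """Exact optimal residue matching between two tetrads.

    Returns ``(score, perm)`` where ``perm[i]`` is the slot of ``t2``
    matched to slot ``i`` of ``t1`` and ``score`` counts matched residue
    pairs present in the stacking-contact set.  Ties resolve to the
    lexicographically first permutation, which prefers the slot-aligned
    identity when nothing distinguishes the assignments.
    """
    r1, r2 = t1.residues, t2.residues
    best_score, best_perm = -1, None
    for perm in permutations(range(4)):
        score = sum(1 for i in range(4) if graph.stacked(r1[i], r2[perm[i]]))
        if score > best_score:
            best_score, best_perm = score, perm
    return best_score, best_perm


def tetrads_stacked(
    t1: Tetrad, t2: Tetrad, graph: AnnotationGraph, params: StackingParams
) -> bool:
    """True iff an assignment matches >= (4 - mismatch) stacked columns."""
    score, _ = best_stacking_matching(t1, t2, graph)
    return score >= 4 - params.mismatch


def _sequence_adjacent(
    t1: Tetrad, t2: Tetrad, all_tetrads: Sequence[Tetrad]
) -> bool:
    """Relaxed-stem adjacency: on every shared chain, the combined residue
    span of the two tetrads contains no residue of a third tetrad."""
    shared = t1.chains & t2.chains
    if not shared:
        return False
    others = [t for t in all_tetrads if t is not t1 and t is not t2]
    for chain in shared:
        idx = [r.global_index for r in t1.residues + t2.residues
               if r.chain_id == chain]
        lo, hi = min(idx), max(idx)
        for other in others:
            for r in other.residues:
                if r.chain_id == chain and lo < r.global_index < hi:
                    return False
    return True


def _order_component(
    comp: list[Tetrad], adj: dict, graph: AnnotationGraph
) -> list[Tetrad]:
    """Order a component along a stacking path from the 5'-most tetrad."""
    start = min(comp, key=lambda t: t.min_index)
    ordered = [start]
    remaining = set(comp) - {start}
    while remaining:
        current = ordered[-1]
        nxt = None
        candidates = [t for t in adj[current] if t in remaining]
        if candidates:
            nxt = max(
                candidates,
                key=lambda t: (
                    best_stacking_matching(current, t, graph)[0],
                    -t.min_index,
                ),
            )
        if nxt is None:
            logger.warning(
                "tetrad component has no full stacking path; "
                "remaining tetrads appended in 5' order"
            )
            ordered.extend(sorted(remaining, key=lambda t: t.min_index))
            break
        ordered.append(nxt)
        remaining.discard(nxt)
    return ordered


def _chain_tracts(
    ordered: list[Tetrad], graph: AnnotationGraph
) -> tuple[list, list[bool]]:
    """Chain matchings into 4 tract columns; flag cross-chain breaks."""
    tracts = [[r] for r in ordered[0].residues]
    breaks = []
    for t_prev, t_next in zip(ordered, ordered[1:]):
        _, perm = best_stacking_matching(t_prev, t_next, graph)
        mapping = {t_prev.residues[i]: t_next.residues[perm[i]] for i in range(4)}
        is_break = any(a.chain_id != b.chain_id for a, b in mapping.items())
        breaks.append(is_break)
        for column in tracts:
            column.append(mapping[column[-1]])
    return tracts, breaks


def _segment(ordered: list[Tetrad], breaks: list[bool]) -> list[list[Tetrad]]:
    segments, current = [], [ordered[0]]
    for t, brk in zip(ordered[1:], breaks):
        if brk:
            segments.append(current)
            current = [t]
        else:
            current.append(t)
    segments.append(current)
    return segments


def _make_quadruplex(tetrads: list[Tetrad], graph: AnnotationGraph) -> Quadruplex:
    tracts, _ = _chain_tracts(tetrads, graph)
    return Quadruplex(tetrads=tetrads, tracts=tracts)


def build_quadruplexes(
    tetrads: Sequence[Tetrad],
    graph: AnnotationGraph,
    params: Optional[StackingParams] = None,
) -> tuple[list[Quadruplex], list[Tetrad], list[N4Helix]]:
    """Partition tetrads into quadruplexes, lone tetrads and N4-helices.

    Every input tetrad lands in exactly one quadruplex or in the lone
    list; helices additionally record which quadruplexes share a coaxial
    stack.  Output sorted by 5'-most residue.
    """
    params = params or StackingParams()
    tetrads = list(tetrads)
    adj: dict = {t: [] for t in tetrads}
    for i, t1 in enumerate(tetrads):
        for t2 in tetrads[i + 1:]:
            linked = tetrads_stacked(t1, t2, graph, params)
            if not linked and params.relaxed_stem:
                linked = _sequence_adjacent(t1, t2, tetrads)
            if linked:
                adj[t1].append(t2)
                adj[t2].append(t1)

    seen: set = set()
    quadruplexes: list[Quadruplex] = []
    lone: list[Tetrad] = []
    helices: list[N4Helix] = []
    for t in sorted(tetrads, key=lambda t: t.min_index):
        if t in seen:
            continue
        comp = []
        stack = [t]
        while stack:
            cur = stack.pop()
            if cur in seen:
                continue
            seen.add(cur)
            comp.append(cur)
            stack.extend(n for n in adj[cur] if n not in seen)
        if len(comp) == 1:
            lone.append(comp[0])
            continue
        ordered = _order_component(comp, adj, graph)
        _, breaks = _chain_tracts(ordered, graph)
        segments = _segment(ordered, breaks)
        segment_quads = [
            _make_quadruplex(seg, graph) for seg in segments if len(seg) >= 2
        ]
        segment_lone = [seg[0] for seg in segments if len(seg) == 1]
        quadruplexes.extend(segment_quads)
        lone.extend(segment_lone)
        if len(segments) > 1:
            helices.append(
                N4Helix(
                    tetrads=ordered,
                    quadruplexes=segment_quads,
                    lone_tetrads=segment_lone,
                )
            )
    quadruplexes.sort(key=lambda q: q.min_index)
    lone.sort(key=lambda t: t.min_index)
    return quadruplexes, lone, helices
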