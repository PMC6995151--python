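"""Tetrad finding: vertex-disjoint 4-cycles in the base-pair graph.

A tetrad is four residues forming a single cycle of base pairs, each
residue pairing with exactly its two cycle neighbours.  In strict mode
only cis Watson-Crick/Hoogsteen pairs are traversable; by default any
annotated pair is, which admits tetrads linked by pairs of mixed types.

When candidate cycles share residues, a maximum-cardinality disjoint
subset is selected, preferring (in order) subsets with more cis WC/H
pairs in total, then subsets whose sorted 5'-most indices are
lexicographically smallest.  The search is exact for realistic candidate
counts and falls back to a greedy selection beyond a hard cap.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import networkx as nx

from .model import AnnotationGraph, BasePair, Edge, Residue

logger = logging.getLogger(__name__)

__all__ = ["Tetrad", "find_tetrads", "orient_tetrad"]

#: beyond this many candidate cycles the disjoint-subset search turns greedy
_EXACT_SELECTION_CAP = 40


@dataclass(eq=False)
class Tetrad:
    """An oriented 4-cycle (A, B, C, D) of residues with its four pairs.

    ``residues`` lists (A, B, C, D) where A is the 5'-most of the four and
    B follows A's Watson-Crick edge (or the documented index tie-break);
    ``pairs`` holds the cycle pairs ((A,B), (B,C), (C,D), (D,A)).
    ``onz`` is filled in by the classifier, e.g. ``"O+"``; ``None`` means
    unclassified (multi-strand tetrad without a committed chain order).
    """

    residues: tuple
    pairs: tuple
    onz: Optional[str] = None

    @property
    def min_index(self) -> int:
        return min(r.global_index for r in self.residues)

    @property
    def chains(self) -> set:
        return {r.chain_id for r in self.residues}

    @property
    def is_multichain(self) -> bool:
        return len(self.chains) > 1

    @property
    def letter(self) -> Optional[str]:
        return self.onz[0] if self.onz else None

    @property
    def sign(self) -> Optional[str]:
        return self.onz[1] if self.onz else None

    @property
    def cwh_count(self) -> int:
        return sum(1 for p in self.pairs if p.is_cwh)

    def label(self) -> str:
        ids = " ".join(r.label for r in self.residues)
        return f"{self.onz or '??'} {ids}"

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tetrad({self.label()})"


def _traversable(pair: BasePair, strict: bool) -> bool:
    return pair.is_cwh if strict else True


def _cycle_pairs(graph: AnnotationGraph, nodes: Sequence[Residue]) -> list[BasePair]:
    out = []
    for i, r in enumerate(nodes):
        p = graph.pair_between(r, nodes[(i + 1) % len(nodes)])
        if p is None:
            raise ValueError("nodes do not form a cycle in the pair graph")
        out.append(p)
    return out


@dataclass(eq=False)
class _Candidate:
    nodes: tuple            # cycle order
    residue_set: frozenset
    cwh: int
    min_index: int
    edge_key: tuple


def _candidate_cycles(graph: AnnotationGraph, strict: bool) -> list[_Candidate]:
    g = nx.Graph()
    g.add_nodes_from(graph.residues)
    for p in graph.pairs:
        if _traversable(p, strict):
            g.add_edge(p.donor, p.acceptor)
    by_set: dict[frozenset, _Candidate] = {}
    for cyc in nx.simple_cycles(g, length_bound=4):
        if len(cyc) != 4:
            continue
        pairs = _cycle_pairs(graph, cyc)
        cwh = sum(1 for p in pairs if p.is_cwh)
        edge_key = tuple(
            sorted(
                tuple(sorted((p.donor.global_index, p.acceptor.global_index)))
                for p in pairs
            )
        )
        cand = _Candidate(
            nodes=tuple(cyc),
            residue_set=frozenset(cyc),
            cwh=cwh,
            min_index=min(r.global_index for r in cyc),
            edge_key=edge_key,
        )
        prev = by_set.get(cand.residue_set)
        # the same 4 residues may cycle in more than one way (extra chords);
        # keep the best single cycle per residue set
        if prev is None or (cand.cwh, [-x for x in sum(cand.edge_key, ())]) > (
            prev.cwh,
            [-x for x in sum(prev.edge_key, ())],
        ):
            by_set[cand.residue_set] = cand
    return sorted(by_set.values(), key=lambda c: (-c.cwh, c.min_index, c.edge_key))


def _selection_key(chosen: list[_Candidate]) -> tuple:
    # maximum cardinality, then most cis WC/H pairs, then lexicographically
    # smallest sorted 5'-most indices, residue sets and edge lists (the last
    # two make fully tied selections deterministic)
    mins = tuple(sorted(c.min_index for c in chosen))
    rsets = tuple(sorted(
        tuple(sorted(r.global_index for r in c.residue_set)) for c in chosen
    ))
    edges = tuple(sorted(c.edge_key for c in chosen))
    negate = lambda tup: tuple(-x for t in tup for x in (t if isinstance(t, tuple) else (t,)))
    return (
        len(chosen),
        sum(c.cwh for c in chosen),
        tuple(-m for m in mins),
        negate(rsets),
        tuple(-x for grp in edges for pair in grp for x in pair),
    )


def _select_disjoint(cands: list[_Candidate]) -> list[_Candidate]:
    if len(cands) > _EXACT_SELECTION_CAP:
        logger.warning(
            "%d candidate 4-cycles: falling back to greedy disjoint selection",
            len(cands),
        )
        chosen: list[_Candidate] = []
        used: set = set()
        for c in cands:
            if not (c.residue_set & used):
                chosen.append(c)
                used |= c.residue_set
        return chosen

    best: list[_Candidate] = []
    best_key = _selection_key(best)

    def recurse(i: int, chosen: list[_Candidate], used: set) -> None:
        nonlocal best, best_key
        if len(chosen) + (len(cands) - i) < len(best):
            return
        if i == len(cands):
            key = _selection_key(chosen)
            if key > best_key:
                best, best_key = list(chosen), key
            return
        c = cands[i]
        if not (c.residue_set & used):
            chosen.append(c)
            recurse(i + 1, chosen, used | c.residue_set)
            chosen.pop()
        recurse(i + 1, chosen, used)

    recurse(0, [], set())
    return best


def orient_tetrad(cycle: Sequence[Residue], graph: AnnotationGraph) -> Tetrad:
    """Orient a 4-cycle canonically: A 5'-most, B along A's WC edge.

    ``cycle`` lists the four residues in cycle order (consecutive members
    paired, last paired with first).  If A's edges toward both neighbours
    are symmetric or unknown, the traversal runs toward the neighbour with
    the smaller global index.  Pure function of the cycle's pairs/indices.
    """
    if len(cycle) != 4:
        raise ValueError("a tetrad cycle must have exactly 4 residues")
    nodes = list(cycle)
    pairs = _cycle_pairs(graph, nodes)  # validates the cycle
    ia = min(range(4), key=lambda i: nodes[i].global_index)
    a = nodes[ia]
    nxt, prv = nodes[(ia + 1) % 4], nodes[(ia - 1) % 4]
    opp = nodes[(ia + 2) % 4]
    e_next = graph.pair_between(a, nxt).edge_of(a)
    e_prev = graph.pair_between(a, prv).edge_of(a)
    if e_next is Edge.WATSON_CRICK and e_prev is not Edge.WATSON_CRICK:
        b, d = nxt, prv
    elif e_prev is Edge.WATSON_CRICK and e_next is not Edge.WATSON_CRICK:
        b, d = prv, nxt
    elif nxt.global_index < prv.global_index:
        b, d = nxt, prv
    else:
        b, d = prv, nxt
    ordered = (a, b, opp, d)
    return Tetrad(residues=ordered, pairs=tuple(_cycle_pairs(graph, list(ordered))))


def find_tetrads(graph: AnnotationGraph, strict: bool = False) -> list[Tetrad]:
    """Find all vertex-disjoint tetrads in the pair graph.

    Returns oriented tetrads sorted by A's global index.  ``strict``
    restricts traversable pairs to cis Watson-Crick/Hoogsteen ones.
    """
    cands = _candidate_cycles(graph, strict)
    chosen = _select_disjoint(cands)
    tetrads = [orient_tetrad(c.nodes, graph) for c in chosen]
    tetrads.sort(key=lambda t: t.residues[0].global_index)
    return tetrads
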