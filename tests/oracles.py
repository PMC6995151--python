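"""Independent reference implementations used as test oracles.

These deliberately re-derive results by exhaustive enumeration (or via a
third-party algorithm) rather than reusing the package's code paths.
"""

from __future__ import annotations

import itertools
import random

from tetraquad.model import (
    AnnotationGraph,
    BasePair,
    Edge,
    Orientation,
    Residue,
)


def brute_force_disjoint_tetrads(graph: AnnotationGraph, strict: bool = False):
    """Exhaustively enumerate vertex-disjoint 4-cycle selections.

    Returns a list of (residue_frozenset, pair_frozenset) tuples for the
    best selection under the documented preference order: maximum count,
    then maximum total cis-WC/H pairs, then lexicographically smallest
    sorted tuple of per-cycle minimum global indices.
    """
    residues = graph.residues

    def traversable(p):
        return p.is_cwh if strict else True

    def linked(a, b):
        p = graph.pair_between(a, b)
        return p is not None and traversable(p)

    # all 4-cycles, one best cycle per 4-residue set
    best_cycle: dict = {}
    for quad in itertools.combinations(residues, 4):
        first = quad[0]
        for perm in itertools.permutations(quad[1:]):
            cyc = (first,) + perm
            if not all(linked(cyc[i], cyc[(i + 1) % 4]) for i in range(4)):
                continue
            pairs = [graph.pair_between(cyc[i], cyc[(i + 1) % 4]) for i in range(4)]
            cwh = sum(1 for p in pairs if p.is_cwh)
            edge_key = tuple(sorted(
                tuple(sorted((p.donor.global_index, p.acceptor.global_index)))
                for p in pairs
            ))
            key = frozenset(quad)
            prev = best_cycle.get(key)
            rank = (cwh, [-x for pair in edge_key for x in pair])
            if prev is None or rank > prev[0]:
                best_cycle[key] = (rank, cyc, frozenset(edge_key), cwh)

    cands = [
        (rset, cyc, edges, cwh)
        for rset, (rank, cyc, edges, cwh) in best_cycle.items()
    ]
    best_sel = []
    best_score = (0, 0, ())
    for r in range(len(cands), -1, -1):
        for combo in itertools.combinations(cands, r):
            used: set = set()
            ok = True
            for rset, *_ in combo:
                if rset & used:
                    ok = False
                    break
                used |= rset
            if not ok:
                continue
            mins = tuple(sorted(
                min(x.global_index for x in rset) for rset, *_ in combo
            ))
            rsets = tuple(sorted(
                tuple(sorted(x.global_index for x in rset))
                for rset, *_ in combo
            ))
            edge_lists = tuple(sorted(
                tuple(sorted(edges)) for rset, cyc, edges, cwh in combo
            ))
            score = (
                len(combo),
                sum(c[3] for c in combo),
                tuple(-m for m in mins),
                tuple(-x for t in rsets for x in t),
                tuple(-x for grp in edge_lists for pair in grp for x in pair),
            )
            if score > best_score:
                best_score, best_sel = score, list(combo)
        if best_sel and len(best_sel) == r:
            # no larger selection can exist below this cardinality
            break
    return [(rset, edges) for rset, cyc, edges, cwh in best_sel]


def maximum_stacking_score(t1, t2, graph) -> int:
    """Max-cardinality residue matching via the Hungarian algorithm."""
    import numpy as np
    from scipy.optimize import linear_sum_assignment

    cost = np.zeros((4, 4))
    for i, a in enumerate(t1.residues):
        for j, b in enumerate(t2.residues):
            cost[i, j] = -1.0 if graph.stacked(a, b) else 0.0
    rows, cols = linear_sum_assignment(cost)
    return int(-cost[rows, cols].sum())


def random_pair_graph(seed: int) -> AnnotationGraph:
    """Small random annotation graph with planted cWH cycles + noise pairs."""
    rng = random.Random(seed)
    n = rng.randint(8, 12)
    n_chains = rng.choice([1, 1, 2])
    residues = []
    for i in range(n):
        chain = "A" if n_chains == 1 or i < n // 2 else "B"
        residues.append(Residue(chain, 0, None, rng.choice("GGAU")))
    by_chain: dict = {}
    for r in residues:
        by_chain.setdefault(r.chain_id, []).append(r)
    for lst in by_chain.values():
        for k, r in enumerate(lst, 1):
            r.number = k
    graph = AnnotationGraph(residues, chain_order=sorted(by_chain))

    def add(a, b, lw_edges, orient):
        if a is b or graph.pair_between(a, b):
            return
        graph.add_pair(BasePair(
            donor=a, acceptor=b, donor_edge=lw_edges[0],
            acceptor_edge=lw_edges[1], orientation=orient,
        ))

    for _ in range(rng.randint(1, 2)):  # planted cWH 4-cycles (may overlap)
        cyc = rng.sample(residues, 4)
        for a, b in zip(cyc, cyc[1:] + cyc[:1]):
            add(a, b, (Edge.WATSON_CRICK, Edge.HOOGSTEEN), Orientation.CIS)
    for _ in range(rng.randint(0, 4)):  # noise pairs of arbitrary type
        a, b = rng.sample(residues, 2)
        edges = rng.choice([
            (Edge.WATSON_CRICK, Edge.WATSON_CRICK),
            (Edge.WATSON_CRICK, Edge.HOOGSTEEN),
            (Edge.HOOGSTEEN, Edge.SUGAR),
            (Edge.UNKNOWN, Edge.UNKNOWN),
        ])
        add(a, b, edges, rng.choice([Orientation.CIS, Orientation.TRANS]))
    return graph
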