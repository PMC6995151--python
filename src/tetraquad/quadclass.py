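"""ONZM classification of quadruplexes and chain-reordering optimization.

A quadruplex's class combines three independent observations:

* the letter — the common ONZ letter of its tetrads (O/N/Z), or M when
  the tetrads mix letters; R when any tetrad is unclassified;
* the direction — from the monotonicity of residue indices along each
  tract across the tetrad stack: all four tracts running the same way is
  parallel (p), a 2/2 split antiparallel (a), a 3/1 split hybrid (h);
* the sign — '+' when every tetrad is positive, '-' when every tetrad is
  negative, '*' for a mixture.

For structures where several strands build the motif, the 5'->3' order
of strands is itself a degree of freedom.  The reordering optimizer
examines all permutations of the participating chains and commits the
one maximizing the number of O-class tetrads (then N-class, then the
lexicographically earliest permutation), mirroring the observed dominance
of O-type tetrads in single-stranded motifs.
"""

from __future__ import annotations

import logging
from itertools import permutations
from typing import Optional, Sequence

from .assembly import Quadruplex
from .model import AnnotationGraph, Edge, Residue
from .onz import PATTERN_TO_CLASS
from .tetrads import Tetrad

logger = logging.getLogger(__name__)

__all__ = ["classify_quadruplex", "reorder_chains", "MAX_REORDER_CHAINS"]

#: exhaustive permutation search is refused above this many participating chains
MAX_REORDER_CHAINS = 8


def _tract_direction(tract: Sequence[Residue]) -> Optional[str]:
    idx = [r.global_index for r in tract]
    if all(a < b for a, b in zip(idx, idx[1:])):
        return "asc"
    if all(a > b for a, b in zip(idx, idx[1:])):
        return "desc"
    return None


def classify_quadruplex(q: Quadruplex) -> str:
    """Assign the ONZM class string, e.g. ``"Op+"``, ``"Mh*"`` or ``"R"``.

    Requires all tetrads classified; otherwise the quadruplex goes to the
    R class.  A non-monotone tract leaves the direction undetermined
    (reported as ``'?'``) with a logged warning.
    """
    if any(t.onz is None for t in q.tetrads):
        return "R"
    letters = {t.letter for t in q.tetrads}
    letter = letters.pop() if len(letters) == 1 else "M"
    signs = {t.sign for t in q.tetrads}
    sign = signs.pop() if len(signs) == 1 else "*"
    directions = [_tract_direction(tr) for tr in q.tracts]
    if any(d is None for d in directions):
        logger.warning("non-monotone tract: quadruplex direction undetermined")
        direction = "?"
    else:
        n_asc = sum(1 for d in directions if d == "asc")
        if n_asc in (0, 4):
            direction = "p"
        elif n_asc == 2:
            direction = "a"
        else:
            direction = "h"
    return f"{letter}{direction}{sign}"


# ---------------------------------------------------------------------------
# chain reordering
# ---------------------------------------------------------------------------


def _classify_cycle_under_key(cycle, edge_toward, key) -> str:
    """Re-orient a 4-cycle and classify it under an arbitrary 5'->3' key.

    ``cycle`` is the residue 4-tuple in cycle order; ``edge_toward`` maps
    ``(residue, neighbour)`` to the residue's own LW edge in that pair.
    """
    ia = min(range(4), key=lambda i: key(cycle[i]))
    a = cycle[ia]
    nxt, prv = cycle[(ia + 1) % 4], cycle[(ia - 1) % 4]
    opp = cycle[(ia + 2) % 4]
    e_next = edge_toward[(a, nxt)]
    e_prev = edge_toward[(a, prv)]
    if e_next is Edge.WATSON_CRICK and e_prev is not Edge.WATSON_CRICK:
        b, d = nxt, prv
    elif e_prev is Edge.WATSON_CRICK and e_next is not Edge.WATSON_CRICK:
        b, d = prv, nxt
    elif key(nxt) < key(prv):
        b, d = nxt, prv
    else:
        b, d = prv, nxt
    labelled = sorted((("B", b), ("C", opp), ("D", d)), key=lambda it: key(it[1]))
    return PATTERN_TO_CLASS["".join(lab for lab, _ in labelled)]


def reorder_chains(
    graph: AnnotationGraph, tetrads: Sequence[Tetrad]
) -> tuple[list[str], dict]:
    """Find the chain order maximizing O-class tetrad allocation.

    Returns ``(chain_order, classes)`` where ``chain_order`` is the full
    committed order (winning permutation of participating chains followed
    by the remaining chains in their original relative order) and
    ``classes`` maps each tetrad to its class under that order.  With
    fewer than two participating chains the identity order is returned
    unchanged; with more than :data:`MAX_REORDER_CHAINS` the exhaustive
    search is refused and identity is kept, with a warning.
    """
    participating = sorted({r.chain_id for t in tetrads for r in t.residues})
    identity_order = list(graph.chain_order)

    def classes_under(order_of_chains: Sequence[str]) -> dict:
        rank = {c: i for i, c in enumerate(order_of_chains)}
        pos = graph.within_chain_position()
        key = lambda r: (rank[r.chain_id], pos[r])
        out = {}
        for t in tetrads:
            cycle = t.residues
            edge_toward = {}
            for i in range(4):
                for j in (1, 3):
                    r, n = cycle[i], cycle[(i + j) % 4]
                    edge_toward[(r, n)] = graph.pair_between(r, n).edge_of(r)
            out[t] = _classify_cycle_under_key(cycle, edge_toward, key)
        return out

    if len(participating) < 2:
        return identity_order, classes_under(identity_order)
    if len(participating) > MAX_REORDER_CHAINS:
        logger.warning(
            "%d chains participate in tetrads (> %d): exhaustive reordering "
            "refused, keeping input chain order",
            len(participating),
            MAX_REORDER_CHAINS,
        )
        return identity_order, classes_under(identity_order)

    pos = graph.within_chain_position()
    # precompute per-tetrad cycle + edge lookups once
    tetrad_data = []
    for t in tetrads:
        cycle = t.residues
        edge_toward = {}
        for i in range(4):
            for j in (1, 3):
                r, n = cycle[i], cycle[(i + j) % 4]
                edge_toward[(r, n)] = graph.pair_between(r, n).edge_of(r)
        tetrad_data.append((t, cycle, edge_toward))

    best_perm = None
    best_score = (-1, -1)
    best_classes: dict = {}
    for perm in permutations(participating):
        rank = {c: i for i, c in enumerate(perm)}
        key = lambda r: (rank[r.chain_id], pos[r])
        classes = {}
        n_o = n_n = 0
        for t, cycle, edge_toward in tetrad_data:
            cls = _classify_cycle_under_key(cycle, edge_toward, key)
            classes[t] = cls
            if cls[0] == "O":
                n_o += 1
            elif cls[0] == "N":
                n_n += 1
        score = (n_o, n_n)
        # permutations() of the sorted chain list is lexicographic, so the
        # first permutation reaching the best score is the lex-earliest one
        if score > best_score:
            best_score, best_perm, best_classes = score, perm, classes
    rest = [c for c in identity_order if c not in set(participating)]
    return list(best_perm) + rest, best_classes
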