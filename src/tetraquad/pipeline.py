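"""End-to-end analysis: find, orient, (re)order, classify, assemble.

The pipeline commits a chain order before classifying anything.  For a
single-stranded structure the input order is the only possible
commitment.  When several strands participate in tetrads, the reordering
optimizer picks the O-maximizing permutation — unless reordering is
disabled, in which case the input order is kept and multi-strand tetrads
remain unclassified (their quadruplexes fall into the R class).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

from .assembly import N4Helix, Quadruplex, StackingParams, build_quadruplexes
from .model import AnnotationGraph
from .onz import classify_tetrad
from .quadclass import MAX_REORDER_CHAINS, classify_quadruplex, reorder_chains
from .tetrads import Tetrad, find_tetrads, orient_tetrad

logger = logging.getLogger(__name__)

__all__ = ["AnalysisParams", "AnalysisResult", "analyse"]


@dataclass
class AnalysisParams:
    """User-facing switches of one analysis run."""

    stacking_mismatch: int = 2
    relaxed_stem: bool = False
    strict: bool = False
    no_reorder: bool = False

    def stacking(self) -> StackingParams:
        return StackingParams(
            mismatch=self.stacking_mismatch, relaxed_stem=self.relaxed_stem
        )


@dataclass
class AnalysisResult:
    graph: AnnotationGraph
    tetrads: list
    quadruplexes: list
    lone_tetrads: list
    helices: list
    reordered: bool = False

    @property
    def onz_counts(self) -> dict:
        counts: dict = {}
        for t in self.tetrads:
            counts[t.onz] = counts.get(t.onz, 0) + 1
        return counts


def analyse(
    graph: AnnotationGraph, params: Optional[AnalysisParams] = None
) -> AnalysisResult:
    """Run the full tetrad/quadruplex identification and classification."""
    params = params or AnalysisParams()
    tetrads = find_tetrads(graph, strict=params.strict)
    logger.info("found %d tetrad(s)", len(tetrads))

    participating = sorted({c for t in tetrads for c in t.chains})
    reordered = False
    if tetrads and len(participating) >= 2 and not params.no_reorder:
        order, _ = reorder_chains(graph, tetrads)
        if order != graph.chain_order:
            logger.info("committing reordered chains: %s", ", ".join(order))
            graph.reorder(order)
            reordered = True
        # re-orient under the committed indices (A may have moved)
        tetrads = [orient_tetrad(t.residues, graph) for t in tetrads]
        tetrads.sort(key=lambda t: t.residues[0].global_index)
        for t in tetrads:
            t.onz = classify_tetrad(t)
    else:
        for t in tetrads:
            if t.is_multichain and params.no_reorder:
                logger.info(
                    "tetrad %s spans chains %s: unclassified (--no-reorder)",
                    t.label(),
                    ",".join(sorted(t.chains)),
                )
                t.onz = None
            else:
                t.onz = classify_tetrad(t)

    quadruplexes, lone, helices = build_quadruplexes(
        tetrads, graph, params.stacking()
    )
    for q in quadruplexes:
        q.onzm = classify_quadruplex(q)
        logger.info("quadruplex %s with %d tetrads", q.onzm, len(q.tetrads))
    return AnalysisResult(
        graph=graph,
        tetrads=tetrads,
        quadruplexes=quadruplexes,
        lone_tetrads=lone,
        helices=helices,
        reordered=reordered,
    )
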