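"""Quadruplex assembly: stacking matching, components, tracts, helices."""

import random

import pytest

from conftest import build_graph
from oracles import maximum_stacking_score
from tetraquad import fixtures as fx
from tetraquad.assembly import (
    StackingParams,
    best_stacking_matching,
    build_quadruplexes,
    tetrads_stacked,
)
from tetraquad.pipeline import AnalysisParams, analyse
from tetraquad.tetrads import find_tetrads


def two_tetrad_graph(stack_columns):
    """Two O+ tetrads; residue column i stacked iff i in stack_columns."""
    g = build_graph(
        8,
        cwh_cycles=[(0, 2, 4, 6), (1, 3, 5, 7)],
        stacks=[(2 * i, 2 * i + 1) for i in stack_columns],
    )
    t1, t2 = find_tetrads(g)
    return g, t1, t2


@pytest.mark.parametrize(
    "columns,mismatch,expected",
    [
        ((0, 1, 2, 3), 0, True),    # ideal geometry
        ((0, 1), 2, True),          # 2 of 4 tolerated at default
        ((0, 1), 1, False),
        ((0, 1), 0, False),
        ((), 0, False),             # no stacking at all
        ((), 2, False),
    ],
)
def test_tetrads_stacked_thresholds(columns, mismatch, expected):
    g, t1, t2 = two_tetrad_graph(columns)
    params = StackingParams(mismatch=mismatch)
    assert tetrads_stacked(t1, t2, g, params) is expected


@pytest.mark.parametrize("seed", range(50))
def test_matching_score_equals_hungarian_oracle(seed):
    """The 4! assignment equals an independent maximum-matching solver."""
    rng = random.Random(seed)
    columns = []
    for i in range(4):
        for j in range(4):
            if rng.random() < 0.4:
                columns.append((i, j))
    g = build_graph(
        8,
        cwh_cycles=[(0, 2, 4, 6), (1, 3, 5, 7)],
        stacks=[(2 * i, 2 * j + 1) for i, j in columns],
    )
    t1, t2 = find_tetrads(g)
    score, _ = best_stacking_matching(t1, t2, g)
    assert score == maximum_stacking_score(t1, t2, g)


def test_monotone_in_mismatch():
    """Stacked-pair sets only grow as the mismatch tolerance grows."""
    for columns in [(), (0,), (0, 1), (0, 1, 2), (0, 1, 2, 3)]:
        g, t1, t2 = two_tetrad_graph(columns)
        verdicts = [
            tetrads_stacked(t1, t2, g, StackingParams(mismatch=m))
            for m in (0, 1, 2)
        ]
        assert verdicts == sorted(verdicts)  # False may never follow True


def test_two_stacked_tetrads_form_one_quadruplex():
    g, t1, t2 = two_tetrad_graph((0, 1, 2, 3))
    quads, lone, helices = build_quadruplexes([t1, t2], g)
    assert len(quads) == 1 and not lone and not helices
    assert quads[0].tetrads == [t1, t2]


def test_isolated_tetrad_reported_lone(simple_tetrad_graph):
    tetrads = find_tetrads(simple_tetrad_graph)
    quads, lone, helices = build_quadruplexes(tetrads, simple_tetrad_graph)
    assert not quads and lone == tetrads and not helices


def test_three_tetrad_chain_order_and_tracts():
    """Tract k chains the stacking matchings from the first tetrad."""
    graph, truth = fx.make_quadruplex_graph("O", "p", "+", n_tetrads=3, seed=0)
    result = analyse(graph)
    assert len(result.quadruplexes) == 1
    q = result.quadruplexes[0]
    got_tracts = {tuple(tr) for tr in q.tracts}
    assert got_tracts == {tuple(col) for col in truth.tract_columns}
    # tract columns reconstruct each tetrad's residue set row-wise
    for i, t in enumerate(q.tetrads):
        assert {tr[i] for tr in q.tracts} == set(t.residues)


def test_partition_property_on_octamer():
    graph, _ = fx.make_octamer_graph()
    result = analyse(graph)
    assigned = [t for q in result.quadruplexes for t in q.tetrads]
    assigned += result.lone_tetrads
    assert len(assigned) == len(set(assigned)) == len(result.tetrads)


def test_stacking_mismatch_zero_splits_imperfect_stack():
    graph, _ = fx.make_quadruplex_graph(
        "O", "p", "+", n_tetrads=2, seed=0, stack_contacts=2
    )
    tolerant = analyse(graph, AnalysisParams(stacking_mismatch=2))
    assert len(tolerant.quadruplexes) == 1
    strict = analyse(graph, AnalysisParams(stacking_mismatch=0))
    assert not strict.quadruplexes and len(strict.lone_tetrads) == 2


def test_relaxed_stem_joins_unstacked_neighbours():
    graph, _ = fx.make_quadruplex_graph(
        "O", "p", "+", n_tetrads=2, seed=0, stack_contacts=0
    )
    plain = analyse(graph)
    assert not plain.quadruplexes and len(plain.lone_tetrads) == 2
    relaxed = analyse(graph, AnalysisParams(relaxed_stem=True))
    assert len(relaxed.quadruplexes) == 1
    assert relaxed.quadruplexes[0].onzm == "Op+"


def test_cross_chain_stack_reported_as_n4_helix():
    """Two coaxially stacked quadruplexes from different strands split."""
    graph, _ = fx.make_octamer_graph()
    # join the two quadruplexes by stacking the top tetrad of the first
    # onto the bottom tetrad of the second, column by column
    chains = {c: graph.chain_residues(c) for c in "ACEGBDFH"}
    for c1, c2 in zip("ACEG", "BDFH"):
        graph.add_stack(chains[c1][4], chains[c2][0])
    result = analyse(graph)
    assert len(result.helices) == 1
    helix = result.helices[0]
    assert len(helix.tetrads) == 10
    assert len(result.quadruplexes) == 2
    assert [q.onzm for q in result.quadruplexes] == ["Op*", "Op*"]
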