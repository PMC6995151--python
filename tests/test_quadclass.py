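"""ONZM classification and the strand-reordering optimizer."""

import random

import pytest

from conftest import build_graph
from tetraquad import fixtures as fx
from tetraquad.assembly import Quadruplex
from tetraquad.model import Residue
from tetraquad.onz import classify_tetrad
from tetraquad.pipeline import AnalysisParams, analyse
from tetraquad.quadclass import classify_quadruplex, reorder_chains
from tetraquad.tetrads import Tetrad, find_tetrads


def quadruplex_from_columns(classes, columns):
    """Build a bare Quadruplex from per-tetrad classes and index columns."""
    n = len(classes)
    tetrads = []
    residues = [
        [Residue("A", idx + 1, None, "G", idx) for idx in col] for col in columns
    ]
    for i, cls in enumerate(classes):
        tetrads.append(
            Tetrad(residues=tuple(col[i] for col in residues), pairs=(), onz=cls)
        )
    return Quadruplex(tetrads=tetrads, tracts=[list(col) for col in residues])


@pytest.mark.parametrize(
    "classes,columns,expected",
    [
        # all O+, all four tracts ascending -> Op+
        (["O+"] * 3, [(0, 1, 2), (3, 4, 5), (6, 7, 8), (9, 10, 11)], "Op+"),
        # two tracts reversed -> antiparallel
        (["O+"] * 3, [(0, 1, 2), (5, 4, 3), (6, 7, 8), (11, 10, 9)], "Oa+"),
        # one tract reversed -> hybrid
        (["O+"] * 3, [(0, 1, 2), (3, 4, 5), (6, 7, 8), (11, 10, 9)], "Oh+"),
        # mixed letters -> M; mixed signs -> *
        (["O+", "Z-"], [(0, 1), (3, 4), (6, 7), (9, 10)], "Mp*"),
        # mixture of O+ and O- -> Op*
        (["O+", "O+", "O-"], [(0, 1, 2), (3, 4, 5), (6, 7, 8), (9, 10, 11)], "Op*"),
        (["O-"] * 2, [(0, 1), (3, 4), (6, 7), (9, 10)], "Op-"),
    ],
)
def test_onzm_rules(classes, columns, expected):
    assert classify_quadruplex(quadruplex_from_columns(classes, columns)) == expected


def test_unclassified_tetrad_forces_r_class():
    q = quadruplex_from_columns(["O+", None], [(0, 1), (3, 4), (6, 7), (9, 10)])
    assert classify_quadruplex(q) == "R"


def test_non_monotone_tract_reports_unknown_direction():
    q = quadruplex_from_columns(
        ["O+"] * 3, [(0, 2, 1), (3, 4, 5), (6, 7, 8), (9, 10, 11)]
    )
    assert classify_quadruplex(q) == "O?+"


def test_invariant_under_stack_reversal():
    """Reading the tetrad stack bottom-up preserves the class."""
    for classes, columns in [
        (["O+"] * 3, [(0, 1, 2), (5, 4, 3), (6, 7, 8), (11, 10, 9)]),
        (["O+", "N+", "O+"], [(0, 1, 2), (3, 4, 5), (6, 7, 8), (11, 10, 9)]),
    ]:
        q = quadruplex_from_columns(classes, columns)
        q_rev = quadruplex_from_columns(
            classes[::-1], [tuple(reversed(c)) for c in columns]
        )
        assert classify_quadruplex(q) == classify_quadruplex(q_rev)


# -- reordering -------------------------------------------------------------


def test_unimolecular_reordering_is_identity():
    graph, truth = fx.make_tetrad_graph("Z+", chains=1, seed=4)
    tetrads = find_tetrads(graph)
    order, classes = reorder_chains(graph, tetrads)
    assert order == graph.chain_order
    assert classes[tetrads[0]] == truth.onz


def test_octamer_reordering_recovers_all_o(octamer=None):
    graph, truth = fx.make_octamer_graph()
    tetrads = find_tetrads(graph)
    order, classes = reorder_chains(graph, tetrads)
    assert order == truth["committed_order"]
    assert all(cls.startswith("O") for cls in classes.values())


def test_equal_o_counts_keep_lex_earlier_order():
    """Both chain orders yield O+: the alphabetical order is committed."""
    # 2+2 split, forward cycle: O+ under either chain order (hand-checked)
    g = build_graph(
        4, cwh_cycles=[(0, 1, 2, 3)], chains={0: "B", 1: "B", 2: "A", 3: "A"}
    )
    assert g.chain_order == ["B", "A"]
    tetrads = find_tetrads(g)
    order, classes = reorder_chains(g, tetrads)
    assert order == ["A", "B"]
    assert list(classes.values()) == ["O+"]


def test_reordering_never_decreases_o_count():
    rng = random.Random(20240)
    for _ in range(60):
        onz = rng.choice(("O+", "O-", "N+", "N-", "Z+", "Z-"))
        chains = rng.choice((2, 4))
        adversarial = chains == 2 or onz in ("O+", "O-")
        graph, truth = fx.make_tetrad_graph(
            onz, chains=chains, seed=rng.randrange(10_000),
            adversarial=adversarial,
        )
        tetrads = find_tetrads(graph)
        identity_o = sum(
            1 for t in tetrads if classify_tetrad(t).startswith("O")
        )
        result = analyse(graph)
        reordered_o = sum(
            1 for t in result.tetrads if (t.onz or "").startswith("O")
        )
        assert reordered_o >= identity_o


def test_adversarial_fixtures_reach_frozen_reorder_outcomes():
    for onz in ("O+", "O-", "N+", "N-", "Z+", "Z-"):
        graph, truth = fx.make_tetrad_graph(onz, chains=2, seed=1, adversarial=True)
        result = analyse(graph)
        assert result.tetrads[0].onz == truth.reordered_onz == onz
    for onz in ("O+", "O-"):
        graph, truth = fx.make_tetrad_graph(onz, chains=4, seed=1, adversarial=True)
        result = analyse(graph)
        assert result.tetrads[0].onz == onz


def test_no_reorder_leaves_multichain_unclassified():
    graph, _ = fx.make_tetrad_graph("Z-", chains=2, seed=0, adversarial=True)
    result = analyse(graph, AnalysisParams(no_reorder=True))
    assert result.tetrads[0].onz is None
    assert not result.reordered


def test_too_many_chains_fall_back_to_identity(caplog):
    # ten single-residue strands in one cycle-of-pairs arrangement:
    # two disjoint tetrads over 8 chains plus 2 extra participating chains
    chains = {i: chr(ord("A") + i) for i in range(12)}
    g = build_graph(
        12,
        cwh_cycles=[(0, 1, 2, 3), (4, 5, 6, 7), (8, 9, 10, 11)],
        chains=chains,
    )
    tetrads = find_tetrads(g)
    with caplog.at_level("WARNING"):
        order, classes = reorder_chains(g, tetrads)
    assert order == g.chain_order
    assert "refused" in caplog.text
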