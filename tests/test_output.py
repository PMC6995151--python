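"""Two-line dot-bracket encoding, parse-back, arc-diagram SVG, reports."""

import pytest

from conftest import build_graph
from tetraquad import fixtures as fx
from tetraquad.model import BasePair, Edge, Orientation
from tetraquad.output import (
    DEFAULT_PALETTE,
    encode_dot_bracket,
    json_report,
    parse_dot_bracket,
    render_arc_diagram,
    text_report,
    _columns,
)
from tetraquad.pipeline import AnalysisParams, analyse


def reported_pairs(result):
    col, _ = _columns(result.graph)
    expected = set()
    for t in result.tetrads:
        for p in t.pairs:
            expected.add(tuple(sorted((col[p.donor], col[p.acceptor]))))
    return expected


def test_single_tetrad_round_trip(simple_tetrad_graph):
    result = analyse(simple_tetrad_graph)
    db = encode_dot_bracket(result)
    assert db.sequence == "GGGG"
    assert len(db.line1) == len(db.line2) == 4
    assert parse_dot_bracket(db) == reported_pairs(result)


def test_crossing_pairs_get_distinct_levels():
    """A Z+ tetrad crosses (A,B) with (C,D) on the first line."""
    graph, _ = fx.make_tetrad_graph("Z+", seed=99)
    result = analyse(graph)
    db = encode_dot_bracket(result)
    assert "[" in db.line1 or "[" in db.line2
    assert parse_dot_bracket(db) == reported_pairs(result)


def test_empty_structure_encodes_to_dots():
    g = build_graph(5)
    result = analyse(g)
    db = encode_dot_bracket(result)
    assert db.line1 == db.line2 == "....."


def test_chain_breaks_rendered_as_dash():
    graph, _ = fx.make_tetrad_graph("O+", chains=2, seed=0)
    result = analyse(graph, AnalysisParams(no_reorder=True))
    db = encode_dot_bracket(result)
    assert db.sequence.count("-") == 1
    i = db.sequence.index("-")
    assert db.line1[i] == db.line2[i] == "-"
    assert parse_dot_bracket(db) == reported_pairs(result)


@pytest.mark.parametrize(
    "letter,direction,sign",
    [("O", "p", "+"), ("O", "a", "*"), ("N", "h", "-"), ("M", "p", "*")],
)
def test_parse_back_on_quadruplex_fixtures(letter, direction, sign):
    graph, _ = fx.make_quadruplex_graph(letter, direction, sign, seed=7)
    result = analyse(graph)
    db = encode_dot_bracket(result)
    assert parse_dot_bracket(db) == reported_pairs(result)


def test_svg_is_deterministic_and_uses_class_colors():
    graph, _ = fx.make_quadruplex_graph("O", "p", "*", seed=3)
    result = analyse(graph)
    svg1 = render_arc_diagram(result)
    svg2 = render_arc_diagram(analyse(fx.make_quadruplex_graph("O", "p", "*", seed=3)[0]))
    assert svg1 == svg2
    assert DEFAULT_PALETTE["O+"] in svg1      # dark blue for O+
    assert DEFAULT_PALETTE["O-"] in svg1      # light blue for O-


def test_unclassified_tetrads_are_grey():
    graph, _ = fx.make_octamer_graph()
    result = analyse(graph, AnalysisParams(no_reorder=True))
    svg = render_arc_diagram(result)
    assert DEFAULT_PALETTE["unclassified"] in svg
    for cls in ("O+", "O-", "N+", "N-", "Z+", "Z-"):
        assert DEFAULT_PALETTE[cls] not in svg


def test_complete_2d_adds_black_canonical_arcs():
    g = build_graph(6, cwh_cycles=[(0, 1, 2, 3)])
    r4, r5 = g.residues[4], g.residues[5]
    r5.base = "C"
    g.add_pair(BasePair(
        donor=r4, acceptor=r5, donor_edge=Edge.WATSON_CRICK,
        acceptor_edge=Edge.WATSON_CRICK, orientation=Orientation.CIS,
    ))
    result = analyse(g)
    assert DEFAULT_PALETTE["canonical"] not in render_arc_diagram(result)
    svg = render_arc_diagram(result, complete_2d=True)
    assert DEFAULT_PALETTE["canonical"] in svg


def test_palette_override():
    graph, _ = fx.make_tetrad_graph("O+", seed=0)
    result = analyse(graph)
    svg = render_arc_diagram(result, palette={"O+": "#123456"})
    assert "#123456" in svg
    assert DEFAULT_PALETTE["O+"] not in svg


def test_text_and_json_reports_agree():
    graph, truth = fx.make_quadruplex_graph("Z", "a", "+", seed=11)
    result = analyse(graph)
    text = text_report(result)
    data = json_report(result)
    assert "Za+" in text
    assert data["quadruplexes"][0]["onzm"] == "Za+"
    assert [t["onz"] for t in data["tetrads"]] == truth.tetrad_classes
    db = data["dot_bracket"]
    assert db["sequence"] in text
    assert len(db["line1"]) == len(db["sequence"])
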