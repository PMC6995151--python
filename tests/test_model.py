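"""Domain model: LW decoding, pair symmetry, serialization, file ingestion."""

import json

import pytest

from tetraquad import fixtures as fx
from tetraquad.model import (
    AnnotationGraph,
    AnnotationParseError,
    BasePair,
    Edge,
    EmptyStructureError,
    Orientation,
    Residue,
    StructureParseError,
    TetraquadError,
    decode_lw,
    normalize_base,
    read_dssr_json,
    read_structure,
)


@pytest.mark.parametrize(
    "code,orient,e1,e2",
    [
        ("cWH", Orientation.CIS, Edge.WATSON_CRICK, Edge.HOOGSTEEN),
        ("tHW", Orientation.TRANS, Edge.HOOGSTEEN, Edge.WATSON_CRICK),
        ("cWW", Orientation.CIS, Edge.WATSON_CRICK, Edge.WATSON_CRICK),
        ("tSS", Orientation.TRANS, Edge.SUGAR, Edge.SUGAR),
        ("c--", Orientation.CIS, Edge.UNKNOWN, Edge.UNKNOWN),
        ("t--", Orientation.TRANS, Edge.UNKNOWN, Edge.UNKNOWN),
    ],
)
def test_lw_decoding(code, orient, e1, e2):
    assert decode_lw(code) == (orient, e1, e2)


def test_pair_edge_labels_swap_between_endpoints():
    """Querying a pair from either residue yields mutually swapped edges."""
    x = Residue("A", 1, None, "G", 0)
    y = Residue("A", 2, None, "G", 1)
    p = BasePair(donor=x, acceptor=y, donor_edge=Edge.WATSON_CRICK,
                 acceptor_edge=Edge.HOOGSTEEN, orientation=Orientation.TRANS)
    assert p.edge_of(x) is Edge.WATSON_CRICK
    assert p.edge_of(y) is Edge.HOOGSTEEN
    assert p.other(y) is x
    assert p.orientation is Orientation.TRANS


@pytest.mark.parametrize(
    "bases,edges,orient,expected",
    [
        (("G", "C"), (Edge.WATSON_CRICK, Edge.WATSON_CRICK), Orientation.CIS, True),
        (("A", "T"), (Edge.WATSON_CRICK, Edge.WATSON_CRICK), Orientation.CIS, True),
        (("G", "U"), (Edge.WATSON_CRICK, Edge.WATSON_CRICK), Orientation.CIS, True),
        (("G", "G"), (Edge.WATSON_CRICK, Edge.WATSON_CRICK), Orientation.CIS, False),
        (("G", "C"), (Edge.WATSON_CRICK, Edge.HOOGSTEEN), Orientation.CIS, False),
        (("G", "C"), (Edge.WATSON_CRICK, Edge.WATSON_CRICK), Orientation.TRANS, False),
    ],
)
def test_canonical_flag(bases, edges, orient, expected):
    x = Residue("A", 1, None, bases[0], 0)
    y = Residue("A", 2, None, bases[1], 1)
    p = BasePair(donor=x, acceptor=y, donor_edge=edges[0],
                 acceptor_edge=edges[1], orientation=orient)
    assert p.canonical is expected


@pytest.mark.parametrize(
    "name,one_letter,expected",
    [("G", None, "G"), ("DG", "g", "G"), ("BRU", "u", "T"),
     ("PSU", None, "U"), ("XYZ", None, "?"), ("XYZ", "a", "A")],
)
def test_modified_base_mapping(name, one_letter, expected):
    assert normalize_base(name, one_letter) == expected


def test_duplicate_residue_identity_rejected():
    residues = [Residue("A", 1, None, "G"), Residue("A", 1, None, "C")]
    with pytest.raises(TetraquadError, match="duplicate"):
        AnnotationGraph(residues)


def test_global_index_bijection_and_chain_grouping():
    residues = [
        Residue("B", 1, None, "G"), Residue("A", 5, None, "G"),
        Residue("B", 2, None, "C"), Residue("A", 7, None, "U"),
    ]
    g = AnnotationGraph(residues, chain_order=["B", "A"])
    assert [r.global_index for r in g.residues] == [0, 1, 2, 3]
    assert [r.chain_id for r in g.residues] == ["B", "B", "A", "A"]
    assert [r.number for r in g.residues] == [1, 2, 5, 7]
    g.reorder(["A", "B"])
    assert [(r.chain_id, r.number) for r in g.residues] == [
        ("A", 5), ("A", 7), ("B", 1), ("B", 2)
    ]
    assert [r.global_index for r in g.residues] == [0, 1, 2, 3]


def test_internal_json_round_trip(tmp_path):
    graph, _ = fx.make_octamer_graph()
    path = tmp_path / "graph.json"
    graph.dump_json(path)
    again = AnnotationGraph.load_json(path)
    assert again.to_dict() == graph.to_dict()


# -- DSSR-style JSON --------------------------------------------------------


def test_dssr_json_pair_decoding(tmp_path):
    graph, _ = fx.make_tetrad_graph("O+", seed=0)
    path = tmp_path / "ann.json"
    path.write_text(json.dumps(fx.to_dssr_json(graph)))
    parsed = read_dssr_json(path)
    assert len(parsed.residues) == len(graph.residues)
    assert len(parsed.pairs) == 4
    p = parsed.pairs[0]
    assert p.orientation is Orientation.CIS
    assert p.donor_edge is Edge.WATSON_CRICK
    assert p.acceptor_edge is Edge.HOOGSTEEN


def test_dssr_json_zero_pairs_ok(tmp_path):
    path = tmp_path / "empty.json"
    path.write_text(json.dumps({
        "nts": [{"nt_id": "A.G1", "chain_name": "A", "nt_resnum": 1,
                 "nt_name": "G", "nt_code": "G"}],
        "pairs": [],
    }))
    graph = read_dssr_json(path)
    assert len(graph.residues) == 1 and not graph.pairs


def test_dssr_json_missing_pairs_mentions_annotator(tmp_path):
    path = tmp_path / "bad.json"
    path.write_text(json.dumps({"nts": []}))
    with pytest.raises(AnnotationParseError, match="re-run the annotator"):
        read_dssr_json(path)


def test_dssr_json_malformed_names_line(tmp_path):
    path = tmp_path / "broken.json"
    path.write_text('{"pairs": [,]}')
    with pytest.raises(AnnotationParseError, match="line"):
        read_dssr_json(path)


def test_dssr_nt_id_with_icode_and_negative_number(tmp_path):
    path = tmp_path / "icode.json"
    path.write_text(json.dumps({
        "pairs": [{"nt1": "B.DG-1^A", "nt2": "B.DG2", "LW": "tHW"}],
    }))
    graph = read_dssr_json(path)
    r = graph.residues[0]
    assert (r.chain_id, r.number, r.icode, r.base) == ("B", -1, "A", "G")


# -- 3D structure ingestion -------------------------------------------------


def test_read_structure_minimal_mmcif(tmp_path):
    structure, _ = fx.make_tetrad_structure()
    path = tmp_path / "tetrad.cif"
    fx.write_mmcif(structure, path)
    st = read_structure(path)
    assert [r.base for r in st.residues] == ["G"] * 4
    assert st.chain_order == ["A"]
    assert "N9" in st.coords[0]


def test_read_structure_pdb_format(tmp_path):
    structure, _ = fx.make_pair_structure("gg_cwh")
    path = tmp_path / "pair.pdb"
    fx.write_pdb(structure, path)
    st = read_structure(path, format="pdb")
    assert len(st.residues) == 2


def test_read_structure_protein_only_raises(tmp_path):
    path = tmp_path / "protein.cif"
    fx.write_protein_mmcif(path)
    with pytest.raises(EmptyStructureError):
        read_structure(path)


def test_read_structure_chain_order_follows_file(tmp_path):
    import numpy as np

    base, _ = fx.make_pair_structure("far")
    from tetraquad.model import Structure3D

    shifted = {n: c + np.array([40.0, 0.0, 0.0]) for n, c in base.coords[0].items()}
    s = Structure3D(
        residues=[Residue("B", 1, None, "G"), Residue("A", 1, None, "G")],
        coords=[base.coords[0], shifted],
        chain_order=["B", "A"],
    )
    path = tmp_path / "ba.cif"
    fx.write_mmcif(s, path)
    st = read_structure(path)
    assert st.chain_order == ["B", "A"]


def test_read_structure_bad_model_and_missing_file(tmp_path):
    structure, _ = fx.make_pair_structure("far")
    path = tmp_path / "pair.cif"
    fx.write_mmcif(structure, path)
    with pytest.raises(StructureParseError, match="model"):
        read_structure(path, model=3)
    with pytest.raises(StructureParseError):
        read_structure(tmp_path / "nope.cif")
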