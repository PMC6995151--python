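"""Core domain model for nucleic-acid annotation graphs.

The classification machinery in this package operates on an
:class:`AnnotationGraph`: an ordered list of nucleotide residues together
with the Leontis-Westhof-annotated base pairs and the base-stacking
contacts observed among them.  Graphs can be ingested from three sources:

* a 3D structure file (PDB/mmCIF) via :func:`read_structure` followed by
  the geometric annotator in :mod:`tetraquad.geometry`;
* a DSSR-style JSON annotation via :func:`read_dssr_json`;
* the package's own JSON dialect via :meth:`AnnotationGraph.from_dict`
  (written by :meth:`AnnotationGraph.to_dict`).

Residue identity follows PDB conventions (author chain id, author residue
number, insertion code); ``global_index`` is a 0-based rank in the
concatenated 5'->3' ordering of all chains and is the only quantity the
ONZ rules ever consult.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

import numpy as np

__all__ = [
    "Edge",
    "Orientation",
    "Residue",
    "BasePair",
    "StackingContact",
    "AnnotationGraph",
    "Structure3D",
    "TetraquadError",
    "StructureParseError",
    "EmptyStructureError",
    "AnnotationParseError",
    "read_structure",
    "read_dssr_json",
    "decode_lw",
    "encode_lw",
    "normalize_base",
]


class TetraquadError(Exception):
    """Base class for all errors raised by this package."""


class StructureParseError(TetraquadError):
    """Raised when a PDB/mmCIF/JSON input cannot be parsed."""


class EmptyStructureError(TetraquadError):
    """Raised when an input structure contains no nucleotide residues."""


class AnnotationParseError(TetraquadError):
    """Raised when an annotation JSON file is malformed or incomplete."""


class Edge(str, Enum):
    """Leontis-Westhof interacting edge of a nucleobase."""

    WATSON_CRICK = "W"
    HOOGSTEEN = "H"
    SUGAR = "S"
    UNKNOWN = "?"


class Orientation(str, Enum):
    """Relative glycosidic-bond orientation of a base pair."""

    CIS = "c"
    TRANS = "t"
    UNKNOWN = "?"


#: Parent-base table for common modified nucleotides (monomer id -> parent
#: one-letter code).  Unmapped residues keep base '?' and may still join
#: tetrads: non-strict mode admits non-canonical chemistry.
MODIFIED_PARENT = {
    "DA": "A", "DC": "C", "DG": "G", "DT": "T", "DU": "U",
    "ADE": "A", "CYT": "C", "GUA": "G", "THY": "T", "URA": "U",
    "BRU": "T",  # 5-bromo-dU pairs like thymine
    "5BU": "U",
    "PSU": "U", "H2U": "U", "5MU": "T", "4SU": "U", "OMU": "U",
    "5MC": "C", "OMC": "C", "CBR": "C",
    "1MA": "A", "2MA": "A", "MA6": "A", "OMA": "A",
    "2MG": "G", "7MG": "G", "M2G": "G", "OMG": "G", "1MG": "G",
    "GTP": "G", "GDP": "G", "ATP": "A",
}

_CANONICAL_BASES = frozenset({"A", "C", "G", "U", "T"})

#: Base combinations admissible as canonical pairs (cis WC/WC only):
#: Watson-Crick A-U/A-T and G-C plus the G-U/G-T wobble.
_CANONICAL_COMBOS = frozenset({
    frozenset("AU"), frozenset("AT"), frozenset("GC"),
    frozenset("GU"), frozenset("GT"),
})


def normalize_base(name: str, one_letter: Optional[str] = None) -> str:
    """Map a residue/monomer name to its parent one-letter base code.

    ``one_letter`` may carry an annotator-provided code (lowercase for
    modified residues, as DSSR and gemmi both emit).  Returns ``'?'``
    when no parent is known.
    """
    key = name.strip().upper()
    if key in _CANONICAL_BASES:
        return key
    if key in MODIFIED_PARENT:
        return MODIFIED_PARENT[key]
    if one_letter:
        letter = one_letter.strip().upper()
        if letter in _CANONICAL_BASES:
            return letter
    return "?"


@dataclass(eq=False)
class Residue:
    """One nucleotide.

    ``(chain_id, number, icode)`` is the author identity and must be
    unique within a model; ``global_index`` is the 0-based position in the
    committed 5'->3' chain ordering and is reassigned whenever a graph is
    re-ordered.
    """

    chain_id: str
    number: int
    icode: Optional[str] = None
    base: str = "?"
    global_index: int = -1

    @property
    def key(self) -> tuple:
        return (self.chain_id, self.number, self.icode or "")

    @property
    def label(self) -> str:
        """Human-readable id in DSSR style, e.g. ``A.G1`` or ``B.?12^A``."""
        ic = f"^{self.icode}" if self.icode else ""
        return f"{self.chain_id}.{self.base}{self.number}{ic}"

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Residue({self.label}@{self.global_index})"


@dataclass(eq=False)
class BasePair:
    """A base pair with per-residue Leontis-Westhof edges.

    The pair is stored once; ``edge_of(x)`` returns the edge *x itself*
    uses, so querying from either endpoint yields mutually swapped edge
    labels while the cis/trans orientation is shared.
    """

    donor: Residue
    acceptor: Residue
    donor_edge: Edge = Edge.UNKNOWN
    acceptor_edge: Edge = Edge.UNKNOWN
    orientation: Orientation = Orientation.UNKNOWN

    def involves(self, r: Residue) -> bool:
        return r is self.donor or r is self.acceptor

    def other(self, r: Residue) -> Residue:
        if r is self.donor:
            return self.acceptor
        if r is self.acceptor:
            return self.donor
        raise ValueError(f"{r!r} is not part of this pair")

    def edge_of(self, r: Residue) -> Edge:
        if r is self.donor:
            return self.donor_edge
        if r is self.acceptor:
            return self.acceptor_edge
        raise ValueError(f"{r!r} is not part of this pair")

    @property
    def canonical(self) -> bool:
        """True iff cis Watson-Crick/Watson-Crick A-U(T), G-C or G-U(T)."""
        return (
            self.orientation is Orientation.CIS
            and self.donor_edge is Edge.WATSON_CRICK
            and self.acceptor_edge is Edge.WATSON_CRICK
            and frozenset((self.donor.base, self.acceptor.base)) in _CANONICAL_COMBOS
        )

    @property
    def is_cwh(self) -> bool:
        """True iff this is a cis Watson-Crick/Hoogsteen pair (either way)."""
        return (
            self.orientation is Orientation.CIS
            and {self.donor_edge, self.acceptor_edge}
            == {Edge.WATSON_CRICK, Edge.HOOGSTEEN}
        )

    @property
    def lw(self) -> str:
        return encode_lw(self.orientation, self.donor_edge, self.acceptor_edge)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"BasePair({self.donor.label} {self.lw} {self.acceptor.label})"


@dataclass(frozen=True)
class StackingContact:
    """Symmetric base-stacking contact between two residues."""

    first: Residue
    second: Residue

    def __post_init__(self):
        if self.first is self.second:
            raise ValueError("a residue cannot stack on itself")

    def as_set(self) -> frozenset:
        return frozenset((self.first, self.second))


_LW_EDGE = {"W": Edge.WATSON_CRICK, "H": Edge.HOOGSTEEN, "S": Edge.SUGAR}
_LW_ORIENT = {"c": Orientation.CIS, "t": Orientation.TRANS}


def decode_lw(code: str) -> tuple[Orientation, Edge, Edge]:
    """Decode a Leontis-Westhof string such as ``"cWH"``.

    Unknown edge characters (``-``, ``.``) yield :attr:`Edge.UNKNOWN`;
    an unknown leading character yields :attr:`Orientation.UNKNOWN`.
    """
    code = code.strip()
    orient = _LW_ORIENT.get(code[:1].lower(), Orientation.UNKNOWN)
    e1 = _LW_EDGE.get(code[1:2].upper(), Edge.UNKNOWN)
    e2 = _LW_EDGE.get(code[2:3].upper(), Edge.UNKNOWN)
    return orient, e1, e2


def encode_lw(orientation: Orientation, e1: Edge, e2: Edge) -> str:
    o = orientation.value if orientation is not Orientation.UNKNOWN else "?"
    c1 = e1.value if e1 is not Edge.UNKNOWN else "-"
    c2 = e2.value if e2 is not Edge.UNKNOWN else "-"
    return f"{o}{c1}{c2}"


class AnnotationGraph:
    """Residues + base pairs + stacking contacts of one structure model.

    Residues are kept grouped by chain in ``chain_order``;
    ``global_index`` always reflects that ordering.  The graph owns its
    Residue objects: pairs and stacks reference them by identity, so
    re-ordering chains (``reorder``) renumbers in place without breaking
    any edge.
    """

    def __init__(
        self,
        residues: Sequence[Residue],
        pairs: Iterable[BasePair] = (),
        stacks: Iterable[StackingContact] = (),
        chain_order: Optional[Sequence[str]] = None,
    ):
        self.residues: list[Residue] = list(residues)
        if chain_order is None:
            chain_order = list(dict.fromkeys(r.chain_id for r in self.residues))
        self.chain_order: list[str] = list(chain_order)
        self.pairs: list[BasePair] = []
        self.stacks: set[frozenset] = set()
        self._pair_map: dict[frozenset, BasePair] = {}
        self._reindex()
        self._validate_residues()
        for p in pairs:
            self.add_pair(p)
        for s in stacks:
            self.add_stack(s.first, s.second)

    # -- construction -------------------------------------------------

    def _validate_residues(self) -> None:
        seen = set()
        for r in self.residues:
            if r.key in seen:
                raise TetraquadError(f"duplicate residue identity {r.key}")
            seen.add(r.key)
        chains = {r.chain_id for r in self.residues}
        if chains - set(self.chain_order):
            raise TetraquadError("chain_order does not cover all chains")
        if len(set(self.chain_order)) != len(self.chain_order):
            raise TetraquadError("chain_order contains a duplicate chain")

    def _reindex(self) -> None:
        """Sort residues by chain_order (stable within chains), renumber."""
        rank = {c: i for i, c in enumerate(self.chain_order)}
        self.residues.sort(key=lambda r: rank.get(r.chain_id, len(rank)))
        for i, r in enumerate(self.residues):
            r.global_index = i

    def add_pair(self, pair: BasePair) -> None:
        for r in (pair.donor, pair.acceptor):
            if r not in self._residue_set():
                raise TetraquadError(f"pair endpoint {r.label} not in graph")
        key = frozenset((pair.donor, pair.acceptor))
        if len(key) != 2:
            raise TetraquadError("a residue cannot pair with itself")
        if key in self._pair_map:
            return
        self._pair_map[key] = pair
        self.pairs.append(pair)

    def add_stack(self, a: Residue, b: Residue) -> None:
        if a is b:
            raise TetraquadError("a residue cannot stack on itself")
        self.stacks.add(frozenset((a, b)))

    def _residue_set(self) -> set:
        cached = getattr(self, "_rset", None)
        if cached is None or len(cached) != len(self.residues):
            cached = set(self.residues)
            self._rset = cached
        return cached

    # -- queries ------------------------------------------------------

    def pair_between(self, a: Residue, b: Residue) -> Optional[BasePair]:
        return self._pair_map.get(frozenset((a, b)))

    def pairs_of(self, r: Residue) -> list[BasePair]:
        return [p for p in self.pairs if p.involves(r)]

    def stacked(self, a: Residue, b: Residue) -> bool:
        return frozenset((a, b)) in self.stacks

    def chain_residues(self, chain_id: str) -> list[Residue]:
        return [r for r in self.residues if r.chain_id == chain_id]

    def within_chain_position(self) -> dict:
        """Map residue -> 0-based rank within its own chain (order-invariant)."""
        pos: dict[Residue, int] = {}
        counters: dict[str, int] = {}
        for r in self.residues:
            pos[r] = counters.get(r.chain_id, 0)
            counters[r.chain_id] = pos[r] + 1
        return pos

    # -- reordering ---------------------------------------------------

    def reorder(self, new_chain_order: Sequence[str]) -> None:
        """Commit a new chain order; global_index is recomputed in place."""
        if sorted(new_chain_order) != sorted(self.chain_order):
            raise TetraquadError("new chain order must be a permutation")
        self.chain_order = list(new_chain_order)
        self._reindex()

    # -- serialization (internal JSON dialect) -------------------------

    def to_dict(self) -> dict:
        index = {r: i for i, r in enumerate(self.residues)}
        return {
            "format": "tetraquad-annotation",
            "version": 1,
            "chain_order": list(self.chain_order),
            "residues": [
                {
                    "chain": r.chain_id,
                    "number": r.number,
                    "icode": r.icode,
                    "base": r.base,
                }
                for r in self.residues
            ],
            "pairs": sorted(
                (
                    {"nt1": index[p.donor], "nt2": index[p.acceptor], "lw": p.lw}
                    for p in self.pairs
                ),
                key=lambda d: (d["nt1"], d["nt2"]),
            ),
            "stacks": sorted(
                sorted(index[r] for r in s) for s in self.stacks
            ),
        }

    @classmethod
    def from_dict(cls, data: dict) -> "AnnotationGraph":
        try:
            residues = [
                Residue(
                    chain_id=d["chain"],
                    number=int(d["number"]),
                    icode=d.get("icode") or None,
                    base=d.get("base", "?"),
                )
                for d in data["residues"]
            ]
            graph = cls(residues, chain_order=data.get("chain_order"))
            for d in data.get("pairs", []):
                orient, e1, e2 = decode_lw(d["lw"])
                graph.add_pair(
                    BasePair(
                        donor=residues[d["nt1"]],
                        acceptor=residues[d["nt2"]],
                        donor_edge=e1,
                        acceptor_edge=e2,
                        orientation=orient,
                    )
                )
            for i, j in data.get("stacks", []):
                graph.add_stack(residues[i], residues[j])
        except (KeyError, IndexError, TypeError, ValueError) as exc:
            raise AnnotationParseError(f"invalid annotation dictionary: {exc}") from exc
        return graph

    def dump_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def load_json(cls, path) -> "AnnotationGraph":
        try:
            data = json.loads(Path(path).read_text())
        except json.JSONDecodeError as exc:
            raise AnnotationParseError(
                f"malformed JSON in {path}: line {exc.lineno}: {exc.msg}"
            ) from exc
        return cls.from_dict(data)


# ---------------------------------------------------------------------------
# 3D structure ingestion
# ---------------------------------------------------------------------------


@dataclass
class Structure3D:
    """Nucleotide residues of one model with their atomic coordinates.

    ``coords[i]`` maps atom name -> xyz (ndarray of shape (3,)) for
    ``residues[i]``.  Produced by :func:`read_structure`; consumed by the
    geometric annotator.
    """

    residues: list[Residue]
    coords: list[dict]
    chain_order: list[str]

    def to_graph_skeleton(self) -> AnnotationGraph:
        return AnnotationGraph(self.residues, chain_order=self.chain_order)


_FORMAT_BY_NAME = {"pdb": "Pdb", "mmcif": "Mmcif", "auto": "Detect"}


def read_structure(path, format: str = "auto", model: int = 1) -> Structure3D:
    """Read nucleotide residues + coordinates from a PDB or mmCIF file.

    Amino acids, waters and ions are excluded.  Modified nucleotides are
    mapped to a parent base where one is known; otherwise the residue is
    retained with base ``'?'``.  ``model`` selects the model of multi-model
    (NMR) files, 1-based; the default mirrors common annotator behaviour.
    """
    import gemmi

    if format not in _FORMAT_BY_NAME:
        raise ValueError(f"format must be one of {sorted(_FORMAT_BY_NAME)}")
    path = Path(path)
    if not path.exists():
        raise StructureParseError(f"no such file: {path}")
    fmt = getattr(gemmi.CoorFormat, _FORMAT_BY_NAME[format])
    try:
        st = gemmi.read_structure(str(path), format=fmt)
    except (RuntimeError, ValueError) as exc:
        raise StructureParseError(f"cannot parse {path}: {exc}") from exc
    if len(st) == 0:
        raise EmptyStructureError(f"{path} contains no models")
    if not 1 <= model <= len(st):
        raise StructureParseError(
            f"model {model} requested but {path} has {len(st)} model(s)"
        )
    mdl = st[model - 1]

    residues: list[Residue] = []
    coords: list[dict] = []
    chain_order: list[str] = []
    for chain in mdl:
        for res in chain:
            base = _nucleotide_base(res)
            if base is None:
                continue
            icode = res.seqid.icode.strip() or None
            residues.append(
                Residue(
                    chain_id=chain.name,
                    number=res.seqid.num,
                    icode=icode,
                    base=base,
                )
            )
            atom_xyz: dict = {}
            for atom in res:
                if atom.name in atom_xyz:
                    continue  # keep the first altloc
                atom_xyz[atom.name] = np.array(
                    [atom.pos.x, atom.pos.y, atom.pos.z], dtype=float
                )
            coords.append(atom_xyz)
        if any(r.chain_id == chain.name for r in residues):
            if chain.name not in chain_order:
                chain_order.append(chain.name)
    if not residues:
        raise EmptyStructureError(f"{path} contains no nucleotide residues")
    rank = {c: i for i, c in enumerate(chain_order)}
    order = sorted(range(len(residues)), key=lambda i: rank[residues[i].chain_id])
    residues = [residues[i] for i in order]
    coords = [coords[i] for i in order]
    for i, r in enumerate(residues):
        r.global_index = i
    return Structure3D(residues=residues, coords=coords, chain_order=chain_order)


def _nucleotide_base(res) -> Optional[str]:
    """Return the parent base letter for a gemmi residue, or None to skip."""
    import gemmi

    info = gemmi.find_tabulated_residue(res.name)
    if info is not None and info.is_nucleic_acid():
        return normalize_base(res.name, info.one_letter_code)
    if info is not None and (info.is_amino_acid() or info.is_water()):
        return None
    names = {a.name for a in res}
    # unknown ligand: accept it as a nucleotide when it has a ribose anchor
    if "C1'" in names and ("N9" in names or "N1" in names) and "O4'" in names:
        return normalize_base(res.name)
    return None


# ---------------------------------------------------------------------------
# DSSR-style JSON ingestion
# ---------------------------------------------------------------------------

_NT_ID_RE = re.compile(
    r"^(?:[^:]+:)?(?P<chain>[^.]+)\.(?P<name>.*?)(?P<num>-?\d+)(?:\^(?P<icode>\S))?$"
)


def _parse_nt_id(nt_id: str) -> tuple[str, str, int, Optional[str]]:
    m = _NT_ID_RE.match(nt_id.strip())
    if not m:
        raise AnnotationParseError(f"cannot parse nucleotide id {nt_id!r}")
    return m.group("chain"), m.group("name"), int(m.group("num")), m.group("icode")


def read_dssr_json(path) -> AnnotationGraph:
    """Build an :class:`AnnotationGraph` from DSSR-style JSON output.

    Expects the annotator's ``nts`` array (residue list, 5'->3'), ``pairs``
    (with ``LW`` strings such as ``"cWH"``) and, optionally, ``stacks``
    (consecutive members of each stack record become stacking contacts).
    """
    path = Path(path)
    try:
        data = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise AnnotationParseError(
            f"malformed JSON in {path}: line {exc.lineno}: {exc.msg}"
        ) from exc
    if not isinstance(data, dict):
        raise AnnotationParseError(f"{path}: top-level JSON object expected")
    if "pairs" not in data:
        raise AnnotationParseError(
            f"{path} has no 'pairs' array; re-run the annotator with JSON "
            "output enabled (e.g. x3dna-dssr --json) on the structure"
        )

    residues: list[Residue] = []
    by_id: dict[str, Residue] = {}

    def _register(nt_id, chain, name, num, icode, code=None):
        r = Residue(
            chain_id=chain,
            number=num,
            icode=icode,
            base=normalize_base(name, code),
        )
        residues.append(r)
        by_id[nt_id] = r
        return r

    for nt in data.get("nts", []):
        nt_id = nt.get("nt_id")
        if nt_id is None:
            raise AnnotationParseError(f"{path}: nts record without nt_id")
        chain = nt.get("chain_name")
        num = nt.get("nt_resnum")
        name = nt.get("nt_name", "")
        icode = None
        if chain is None or num is None:
            chain, name, num, icode = _parse_nt_id(nt_id)
        elif "^" in nt_id:
            icode = nt_id.rsplit("^", 1)[1] or None
        _register(nt_id, chain, name, int(num), icode, nt.get("nt_code"))

    def _resolve(nt_id: str) -> Residue:
        if nt_id not in by_id:
            chain, name, num, icode = _parse_nt_id(nt_id)
            _register(nt_id, chain, name, num, icode)
        return by_id[nt_id]

    pair_specs = []
    for rec in data["pairs"]:
        try:
            nt1, nt2, lw = rec["nt1"], rec["nt2"], rec.get("LW", rec.get("lw", ""))
        except (TypeError, KeyError) as exc:
            raise AnnotationParseError(f"{path}: invalid pair record {rec!r}") from exc
        pair_specs.append((_resolve(nt1), _resolve(nt2), lw))

    stack_specs = []
    for rec in data.get("stacks", []):
        ids = rec.get("nts_long") or rec.get("nts") or ""
        if isinstance(ids, str):
            ids = [s for s in ids.split(",") if s]
        members = [_resolve(i) for i in ids]
        for a, b in zip(members, members[1:]):
            stack_specs.append((a, b))

    graph = AnnotationGraph(residues)
    for r1, r2, lw in pair_specs:
        orient, e1, e2 = decode_lw(lw)
        graph.add_pair(
            BasePair(donor=r1, acceptor=r2, donor_edge=e1, acceptor_edge=e2,
                     orientation=orient)
        )
    for a, b in stack_specs:
        if a is not b:
            graph.add_stack(a, b)
    return graph
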