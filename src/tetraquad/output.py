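"""Two-line dot-bracket encoding, arc diagrams and reports.

A tetrad's four pairs form a 4-cycle, which no single line of properly
matched brackets can express, so the encoding uses two bracket lines
under one sequence line: each tetrad contributes its (A,B) and (C,D)
pairs to the first line and its (B,C) and (D,A) pairs to the second.
Crossing pairs within a line receive distinct bracket levels by greedy
interval-graph coloring in order of 5' endpoints, so each level is
properly nested and parsing both lines recovers exactly the emitted pair
set.  Chain breaks are rendered as ``-`` in all three lines.

The arc diagram places residues on a horizontal axis in the committed
chain order and draws tetrad pairs as arcs colored by ONZ class
(O blue, N green, Z orange; dark for '+', light for '-'); unclassified
tetrads are grey, and with ``complete_2d`` canonical pairs outside the
motifs appear black.  Rendering is deterministic: identical input yields
byte-identical SVG.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .model import AnnotationGraph, Residue
from .tetrads import Tetrad

__all__ = [
    "TwoLineDotBracket",
    "DEFAULT_PALETTE",
    "encode_dot_bracket",
    "parse_dot_bracket",
    "render_arc_diagram",
    "text_report",
    "json_report",
]

DEFAULT_PALETTE = {
    "O+": "#003366",
    "O-": "#99CCFF",
    "N+": "#006400",
    "N-": "#90EE90",
    "Z+": "#CC6600",
    "Z-": "#FFCC66",
    "unclassified": "#808080",
    "canonical": "#000000",
}

_BRACKETS = ["()", "[]", "{}", "<>"] + [
    chr(ord("A") + i) + chr(ord("a") + i) for i in range(26)
]


@dataclass(frozen=True)
class TwoLineDotBracket:
    """Sequence line plus the two bracket lines (equal lengths)."""

    sequence: str
    line1: str
    line2: str

    def __str__(self) -> str:
        return f"{self.sequence}\n{self.line1}\n{self.line2}"


def _columns(graph: AnnotationGraph) -> tuple[dict, int]:
    """Map residue -> text column, inserting one break column per chain gap."""
    col = {}
    c = 0
    prev_chain = None
    for r in graph.residues:
        if prev_chain is not None and r.chain_id != prev_chain:
            c += 1
        col[r] = c
        prev_chain = r.chain_id
        c += 1
    return col, c


def _crossing(a: tuple, b: tuple) -> bool:
    (i, j), (k, l) = a, b
    return (i < k < j < l) or (k < i < l < j)


def _assign_levels(pairs: Sequence[tuple]) -> dict:
    """Greedy interval coloring; pairs are (open_col, close_col) tuples."""
    levels: list[list[tuple]] = []
    assignment = {}
    for p in sorted(set(pairs)):
        for lvl, members in enumerate(levels):
            if not any(_crossing(p, q) for q in members):
                members.append(p)
                assignment[p] = lvl
                break
        else:
            if len(levels) >= len(_BRACKETS):
                raise ValueError("more bracket levels required than available")
            levels.append([p])
            assignment[p] = len(levels) - 1
    return assignment


def _render_line(pairs: Sequence[tuple], n_cols: int, break_cols: set) -> str:
    chars = ["."] * n_cols
    for c in break_cols:
        chars[c] = "-"
    for (i, j), lvl in _assign_levels(pairs).items():
        chars[i] = _BRACKETS[lvl][0]
        chars[j] = _BRACKETS[lvl][1]
    return "".join(chars)


def _gather_tetrads(result) -> list[Tetrad]:
    seen, out = set(), []
    for q in result.quadruplexes:
        for t in q.tetrads:
            if t not in seen:
                seen.add(t)
                out.append(t)
    for t in result.lone_tetrads:
        if t not in seen:
            seen.add(t)
            out.append(t)
    return out


def encode_dot_bracket(result) -> TwoLineDotBracket:
    """Encode all reported tetrads of an analysis result."""
    graph = result.graph
    col, n_cols = _columns(graph)
    break_cols = set(range(n_cols)) - set(col.values())
    seq = ["-"] * n_cols
    for r in graph.residues:
        seq[col[r]] = r.base
    line1_pairs, line2_pairs = [], []
    for t in _gather_tetrads(result):
        a, b, c, d = t.residues
        for line, (x, y) in (
            (line1_pairs, (a, b)),
            (line1_pairs, (c, d)),
            (line2_pairs, (b, c)),
            (line2_pairs, (d, a)),
        ):
            line.append(tuple(sorted((col[x], col[y]))))
    return TwoLineDotBracket(
        sequence="".join(seq),
        line1=_render_line(line1_pairs, n_cols, break_cols),
        line2=_render_line(line2_pairs, n_cols, break_cols),
    )


def parse_dot_bracket(db: TwoLineDotBracket) -> set:
    """Recover the encoded pair set as (column, column) tuples."""
    opens = {b[0]: i for i, b in enumerate(_BRACKETS)}
    closes = {b[1]: i for i, b in enumerate(_BRACKETS)}
    pairs = set()
    for line in (db.line1, db.line2):
        stacks: dict[int, list[int]] = {}
        for pos, ch in enumerate(line):
            if ch in opens:
                stacks.setdefault(opens[ch], []).append(pos)
            elif ch in closes:
                lvl = closes[ch]
                if not stacks.get(lvl):
                    raise ValueError(f"unbalanced bracket at column {pos}")
                pairs.add((stacks[lvl].pop(), pos))
        if any(s for s in stacks.values()):
            raise ValueError("unbalanced brackets at end of line")
    return pairs


# ---------------------------------------------------------------------------
# arc diagram
# ---------------------------------------------------------------------------

_X_STEP = 14
_MARGIN = 30
_BASELINE_FROM_TOP = 40


def render_arc_diagram(
    result,
    complete_2d: bool = False,
    palette: Optional[dict] = None,
) -> str:
    """Render the arc diagram as an SVG string (deterministic)."""
    pal = dict(DEFAULT_PALETTE)
    if palette:
        pal.update(palette)
    graph = result.graph
    col, n_cols = _columns(graph)

    arcs = []  # (x1_col, x2_col, color)
    tetrad_pairs = set()
    for t in _gather_tetrads(result):
        color = pal.get(t.onz, pal["unclassified"]) if t.onz else pal["unclassified"]
        for p in t.pairs:
            i, j = sorted((col[p.donor], col[p.acceptor]))
            arcs.append((i, j, color))
            tetrad_pairs.add(frozenset((p.donor, p.acceptor)))
    if complete_2d:
        for p in graph.pairs:
            if p.canonical and frozenset((p.donor, p.acceptor)) not in tetrad_pairs:
                i, j = sorted((col[p.donor], col[p.acceptor]))
                arcs.append((i, j, pal["canonical"]))
    arcs.sort()

    width = 2 * _MARGIN + max(n_cols - 1, 1) * _X_STEP
    max_span = max((j - i for i, j, _ in arcs), default=1)
    height = _BASELINE_FROM_TOP + (max_span * _X_STEP) // 2 + 40
    baseline = height - 30

    def x(c: int) -> float:
        return _MARGIN + c * _X_STEP

    parts = [
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{width}" '
        f'height="{height}" viewBox="0 0 {width} {height}">',
        f'<line x1="{_MARGIN}" y1="{baseline}" x2="{width - _MARGIN}" '
        f'y2="{baseline}" stroke="#B0B0B0" stroke-width="1"/>',
    ]
    for i, j, color in arcs:
        x1, x2 = x(i), x(j)
        r = (x2 - x1) / 2.0
        parts.append(
            f'<path d="M {x1:.1f} {baseline} A {r:.1f} {r:.1f} 0 0 1 '
            f'{x2:.1f} {baseline}" fill="none" stroke="{color}" '
            f'stroke-width="1.5"/>'
        )
    for res in graph.residues:
        cx = x(col[res])
        parts.append(
            f'<text x="{cx:.1f}" y="{baseline + 14}" font-size="9" '
            f'font-family="monospace" text-anchor="middle">{res.base}</text>'
        )
        if res.number % 5 == 0 or res.global_index == 0:
            parts.append(
                f'<text x="{cx:.1f}" y="{baseline + 26}" font-size="7" '
                f'font-family="monospace" text-anchor="middle">'
                f"{res.chain_id}{res.number}</text>"
            )
    parts.append("</svg>")
    return "\n".join(parts)


# ---------------------------------------------------------------------------
# reports
# ---------------------------------------------------------------------------


def text_report(result) -> str:
    lines = [f"Chain order: {', '.join(result.graph.chain_order)}"]
    if result.reordered:
        lines.append("(chain order optimized by strand reordering)")
    for qi, q in enumerate(result.quadruplexes, 1):
        lines.append(f"Quadruplex #{qi}: {q.onzm} ({len(q.tetrads)} tetrads)")
        for ti, t in enumerate(q.tetrads, 1):
            lines.append(f"  Tetrad {ti}: {t.label()}")
        for k, tract in enumerate(q.tracts):
            lines.append(
                f"  Tract {'ABCD'[k]}: " + " ".join(r.label for r in tract)
            )
    for t in result.lone_tetrads:
        lines.append(f"Lone tetrad: {t.label()}")
    for hi, h in enumerate(result.helices, 1):
        lines.append(
            f"N4-helix #{hi}: {len(h.tetrads)} tetrads in "
            f"{len(h.quadruplexes)} stacked quadruplex(es)"
        )
    db = encode_dot_bracket(result)
    lines.append("Dot-bracket:")
    lines.extend(f"  {ln}" for ln in str(db).splitlines())
    return "\n".join(lines) + "\n"


def json_report(result) -> dict:
    db = encode_dot_bracket(result)
    all_tetrads = _gather_tetrads(result)
    t_index = {t: i for i, t in enumerate(all_tetrads)}
    return {
        "chain_order": list(result.graph.chain_order),
        "reordered": result.reordered,
        "tetrads": [
            {
                "onz": t.onz,
                "residues": [r.label for r in t.residues],
                "pairs": [p.lw for p in t.pairs],
            }
            for t in all_tetrads
        ],
        "quadruplexes": [
            {
                "onzm": q.onzm,
                "tetrads": [t_index[t] for t in q.tetrads],
                "tracts": [[r.label for r in tract] for tract in q.tracts],
            }
            for q in result.quadruplexes
        ],
        "lone_tetrads": [t_index[t] for t in result.lone_tetrads],
        "n4_helices": [
            {"tetrads": [t_index[t] for t in h.tetrads]} for h in result.helices
        ],
        "dot_bracket": {
            "sequence": db.sequence,
            "line1": db.line1,
            "line2": db.line2,
        },
    }
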