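import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make `oracles` importable

from tetraquad.model import (
    AnnotationGraph,
    BasePair,
    Edge,
    Orientation,
    Residue,
)


def build_graph(n, cwh_cycles=(), extra_pairs=(), stacks=(), chains=None):
    """Small hand-built annotation graph.

    ``chains`` maps residue index -> chain id (default all 'A');
    ``cwh_cycles`` are index 4-tuples wired as donor-WC cis cycles;
    ``extra_pairs`` are (i, j, donor_edge, acceptor_edge, orientation).
    """
    chains = chains or {}
    per_chain: dict = {}
    residues = []
    for i in range(n):
        c = chains.get(i, "A")
        num = len(per_chain.setdefault(c, [])) + 1
        r = Residue(c, num, None, "G")
        per_chain[c].append(r)
        residues.append(r)
    order = list(dict.fromkeys(chains.get(i, "A") for i in range(n)))
    graph = AnnotationGraph(residues, chain_order=order)
    for cyc in cwh_cycles:
        members = [residues[i] for i in cyc]
        for a, b in zip(members, members[1:] + members[:1]):
            graph.add_pair(BasePair(
                donor=a, acceptor=b,
                donor_edge=Edge.WATSON_CRICK, acceptor_edge=Edge.HOOGSTEEN,
                orientation=Orientation.CIS,
            ))
    for i, j, e1, e2, orient in extra_pairs:
        graph.add_pair(BasePair(
            donor=residues[i], acceptor=residues[j],
            donor_edge=e1, acceptor_edge=e2, orientation=orient,
        ))
    for i, j in stacks:
        graph.add_stack(residues[i], residues[j])
    return graph


@pytest.fixture
def simple_tetrad_graph():
    return build_graph(4, cwh_cycles=[(0, 1, 2, 3)])
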