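"""ONZ classification of oriented tetrads.

With the tetrad oriented so that A is the 5'-most residue and the pair
cycle runs A-B-C-D-A (each residue binding the next along its
Watson-Crick edge), the class is read off the 5'->3' arrangement of
B, C, D in the sequence:

====================  =====
5' order after A      class
====================  =====
B  C  D               O+
D  C  B               O-
B  D  C               N+
C  D  B               N-
C  B  D               Z+
D  B  C               Z-
====================  =====

The six permutations of {B, C, D} are exhaustive and map bijectively
onto the six classes.  Classification depends only on the *relative*
order of global indices, so it is meaningful only under a committed
chain order; policy for uncommitted multi-strand tetrads lives in the
pipeline, not here.
"""

from __future__ import annotations

from typing import Callable, Optional

from .model import Residue
from .tetrads import Tetrad

__all__ = ["ONZ_CLASSES", "PATTERN_TO_CLASS", "classify_tetrad"]

PATTERN_TO_CLASS = {
    "BCD": "O+",
    "DCB": "O-",
    "BDC": "N+",
    "CDB": "N-",
    "CBD": "Z+",
    "DBC": "Z-",
}

ONZ_CLASSES = ("O+", "O-", "N+", "N-", "Z+", "Z-")


def classify_tetrad(
    tetrad: Tetrad, key: Optional[Callable[[Residue], object]] = None
) -> str:
    """Return the ONZ class of an oriented tetrad.

    ``key`` optionally overrides the sort key used for the 5'->3' order
    (default: ``global_index``); the reordering optimizer passes
    chain-permutation keys through it.
    """
    if key is None:
        key = lambda r: r.global_index
    a, b, c, d = tetrad.residues
    ka = key(a)
    labelled = sorted(
        (("B", b), ("C", c), ("D", d)), key=lambda item: key(item[1])
    )
    if any(key(r) <= ka for _, r in labelled):
        raise ValueError("tetrad is not oriented: A must be 5'-most")
    pattern = "".join(lab for lab, _ in labelled)
    return PATTERN_TO_CLASS[pattern]
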