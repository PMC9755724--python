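"""Distance trees from identity matrices.

Percent identity is turned into a simple complement distance
(``d = 100 − identity``, symmetrized) and a neighbor-joining tree is built
from it.  The trees are descriptive overviews of relatedness, not dated
phylogenies: no multiple-hit correction is applied, because at big-exon
identities near the random-alignment noise floor any such correction
diverges while the uncorrected complement stays well-behaved.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import skbio
from skbio import TreeNode
from skbio.tree import nj

from .homology import IdentityMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "DistanceMatrix",
    "identity_to_distance",
    "nj_tree",
    "write_newick",
    "read_newick",
]

#: Distance container: scikit-bio's validated symmetric zero-diagonal matrix.
DistanceMatrix = skbio.DistanceMatrix


def identity_to_distance(matrix: IdentityMatrix) -> DistanceMatrix:
    """Complement transform: d[i,j] = 100 − (v[i,j] + v[j,i]) / 2, zero diagonal."""
    v = np.asarray(matrix.values, dtype=float)
    d = 100.0 - (v + v.T) / 2.0
    np.fill_diagonal(d, 0.0)
    d = np.maximum(d, 0.0)
    return DistanceMatrix(d, ids=list(matrix.labels))


def nj_tree(d: DistanceMatrix) -> TreeNode:
    """Saitou–Nei neighbor joining; negative branch lengths clamped to 0.

    Requires at least 3 leaves.  On an additive distance matrix the
    generating topology and branch lengths are recovered exactly.
    """
    if d.shape[0] < 3:
        raise ValueError(f"neighbor joining needs >= 3 leaves, have {d.shape[0]}")
    tree = nj(d, neg_as_zero=True)
    n_clamped = sum(
        1 for node in tree.traverse() if node.length is not None and node.length == 0.0
    )
    if n_clamped:
        logger.debug("nj_tree: %d zero-length (possibly clamped) branches", n_clamped)
    return tree


def write_newick(tree: TreeNode, path: str | Path) -> None:
    """Serialize to standard Newick with 6-decimal branch lengths."""
    for node in tree.traverse():
        if node.length is not None:
            node.length = round(float(node.length), 6)
    tree.write(str(path), format="newick")


def read_newick(path: str | Path) -> TreeNode:
    """Parse a Newick file back into a tree."""
    return TreeNode.read(str(path), format="newick")
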