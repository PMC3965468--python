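"""Threshold clustering (BIN proxy) and neighbor-joining trees.

The Barcode Index Number (BIN) system groups specimens by single-linkage
clustering of COI distances followed by graph-analytical refinement.  The
proxy implemented here is the single-linkage stage alone: clusters are the
connected components of the graph joining every specimen pair whose K2P
distance is at or below a threshold (chaining allowed).  The refinement
stage is deliberately not reproduced, so cluster counts from real BOLD
BINs and from this proxy can differ.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from skbio import DistanceMatrix as _SkbioDM
from skbio.tree import nj as _skbio_nj

from .distances import DistanceMatrix
from .errors import ValidationError

#: Seed threshold of the BIN system, in percent.
DEFAULT_CLUSTER_THRESHOLD = 2.2


@dataclass
class ClusterPartition:
    """Specimen → cluster assignment from single-linkage threshold clustering.

    Cluster ids are dense integers from 0, numbered by first appearance in
    specimen input order (so the partition is order-invariant only up to
    relabeling).
    """

    assignment: dict[str, int]
    threshold: float
    n_clusters: int

    def members(self, cluster_id: int) -> list[str]:
        return [s for s, c in self.assignment.items() if c == cluster_id]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            list(self.assignment.items()), columns=["specimen_id", "cluster_id"]
        )

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def single_linkage_clusters(
    matrix: DistanceMatrix, threshold: float = DEFAULT_CLUSTER_THRESHOLD
) -> ClusterPartition:
    """Connected components of the graph with edges {pairs: d <= threshold}.

    Saturated (``inf``) and masked (``nan``) pairs contribute no edge, i.e.
    they are treated as exceeding any threshold.
    """
    n = len(matrix)
    if n == 0:
        raise ValidationError("cannot cluster an empty distance matrix")
    with np.errstate(invalid="ignore"):
        adj = matrix.values <= threshold
    adj &= ~np.isnan(matrix.values)
    _, raw = connected_components(csr_matrix(adj), directed=False)
    # relabel to dense ids ordered by first appearance
    relabel: dict[int, int] = {}
    assignment: dict[str, int] = {}
    for label, comp in zip(matrix.labels, raw.tolist()):
        if comp not in relabel:
            relabel[comp] = len(relabel)
        assignment[label] = relabel[comp]
    return ClusterPartition(
        assignment=assignment, threshold=threshold, n_clusters=len(relabel)
    )


@dataclass
class Tree:
    """Unrooted NJ tree over specimen (or representative) leaves.

    Wraps a scikit-bio ``TreeNode``; negative branch lengths produced by the
    NJ agglomeration are clamped to zero (``n_clamped`` records how many).
    """

    newick: str
    labels: list[str]
    n_clamped: int = 0

    def path_length_matrix(self) -> np.ndarray:
        """Leaf-to-leaf path lengths, rows/columns in ``labels`` order."""
        from skbio import TreeNode

        tree = TreeNode.read([self.newick])
        dm = tree.tip_tip_distances()
        order = [list(dm.ids).index(l) for l in self.labels]
        return dm.data[np.ix_(order, order)]

    def write_newick(self, path: str | Path) -> None:
        Path(path).write_text(self.newick + "\n")


def nj_tree(matrix: DistanceMatrix) -> Tree:
    """Neighbor-joining tree from a K2P distance matrix.

    Standard Saitou–Nei agglomeration; on an additive input matrix the
    leaf-to-leaf path lengths reproduce the input distances.  Requires
    finite entries (saturated/masked pairs must be resolved first).
    """
    if len(matrix) < 2:
        raise ValidationError("NJ requires at least 2 labels")
    bad = ~np.isfinite(matrix.values)
    np.fill_diagonal(bad, False)
    if bad.any():
        ii, jj = np.nonzero(np.triu(bad, k=1))
        pairs = [(matrix.labels[i], matrix.labels[j]) for i, j in zip(ii, jj)]
        raise ValidationError(f"non-finite distances for pair(s): {pairs[:10]}")
    if len(matrix) == 2:
        a, b = matrix.labels
        d = float(matrix.values[0, 1])
        return Tree(newick=f"({a}:{d / 2:.10g},{b}:{d / 2:.10g});", labels=[a, b])
    dm = _SkbioDM(matrix.values, ids=matrix.labels)
    raw = _skbio_nj(dm, neg_as_zero=False)
    n_clamped = 0
    for node in raw.traverse():
        if node.length is not None and node.length < 0:
            node.length = 0.0
            n_clamped += 1
    newick = str(raw).strip()
    return Tree(newick=newick, labels=list(matrix.labels), n_clamped=n_clamped)
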