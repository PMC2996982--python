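"""VH family assignment and UPGMA phylogram construction.

Families follow the WHO-IUIS convention: VH sequences sharing more than a
threshold nucleotide identity (default 75%, computed over complete exon 2)
belong to one family.  Identity is measured on a global alignment with
pairwise deletion — columns where either sequence has a gap are excluded
from both numerator and denominator.  Trees are built by UPGMA on
p-distances ``(100 - identity) / 100``.
"""

from __future__ import annotations

from dataclasses import dataclass
from io import StringIO

import numpy as np
from Bio import Align
from skbio import TreeNode

from .seqio import SequenceRecord

__all__ = [
    "IdentityMatrix",
    "FamilyAssignment",
    "make_aligner",
    "pairwise_identity",
    "build_identity_matrix",
    "cluster_families",
    "upgma_tree",
    "write_newick",
]


@dataclass(frozen=True)
class IdentityMatrix:
    """Symmetric percent-identity matrix over a fixed id order."""

    ids: tuple
    values: np.ndarray

    def __post_init__(self):
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match id count")

    def to_distances(self) -> np.ndarray:
        """p-distance matrix on the 0-1 scale."""
        return (100.0 - self.values) / 100.0


@dataclass(frozen=True)
class FamilyAssignment:
    labels: dict  # id -> family integer, 1-based, contiguous
    threshold: float
    n_families: int


def make_aligner(
    mode: str = "global",
    match: float = 1.0,
    mismatch: float = -1.0,
    gap_open: float = -5.0,
    gap_extend: float = -1.0,
) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global" if mode == "global" else "local"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    return aligner


def _alignment_identity(alignment) -> float:
    counts = alignment.counts()
    aligned = counts.identities + counts.mismatches
    if aligned == 0:
        return 0.0
    return 100.0 * counts.identities / aligned


def pairwise_identity(
    a: SequenceRecord,
    b: SequenceRecord,
    mode: str = "nucleotide",
    aligner: Align.PairwiseAligner | None = None,
) -> float:
    """Percent identity of a global alignment with pairwise deletion.

    Scoring defaults to match +1, mismatch -1, gap open -5, gap extend -1;
    pass a configured ``aligner`` to change them.  ``mode`` is a label for
    the caller ("nucleotide" or "protein"); both alphabets use the same
    scoring unless a custom aligner is supplied.
    """
    if mode not in ("nucleotide", "protein"):
        raise ValueError("mode must be 'nucleotide' or 'protein'")
    if not a.residues or not b.residues:
        raise ValueError("cannot align empty sequences")
    if aligner is None:
        aligner = make_aligner()
    alignment = aligner.align(a.residues, b.residues)[0]
    return _alignment_identity(alignment)


def build_identity_matrix(
    records: list[SequenceRecord],
    mode: str = "nucleotide",
    aligner: Align.PairwiseAligner | None = None,
) -> IdentityMatrix:
    if len(records) < 2:
        raise ValueError("need at least two sequences")
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sequence ids")
    if aligner is None:
        aligner = make_aligner()
    n = len(records)
    values = np.full((n, n), 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            ident = pairwise_identity(records[i], records[j], mode, aligner)
            values[i, j] = values[j, i] = ident
    return IdentityMatrix(ids=tuple(ids), values=values)


def cluster_families(
    matrix: IdentityMatrix, threshold: float = 75.0, linkage: str = "single"
) -> FamilyAssignment:
    """Assign family labels at an identity threshold.

    With single linkage (default) families are the connected components of
    the graph whose edges join pairs with identity strictly greater than
    the threshold; complete linkage requires every within-family pair to
    exceed it.  Families are numbered from 1 by descending size, ties by
    the lexicographically smallest member id, so the labelling does not
    depend on input order.
    """
    n = len(matrix.ids)
    order = np.argsort(np.array(matrix.ids, dtype=object))
    if linkage == "single":
        parent = list(range(n))

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for ii in range(n):
            for jj in range(ii + 1, n):
                i, j = int(order[ii]), int(order[jj])
                if matrix.values[i, j] > threshold:
                    parent[find(i)] = find(j)
        groups: dict[int, list[int]] = {}
        for i in range(n):
            groups.setdefault(find(i), []).append(i)
        components = list(groups.values())
    elif linkage == "complete":
        from scipy.cluster.hierarchy import fcluster, linkage as scipy_linkage
        from scipy.spatial.distance import squareform

        dist = matrix.to_distances()
        condensed = squareform(dist[np.ix_(order, order)], checks=False)
        z = scipy_linkage(condensed, method="complete")
        cut = fcluster(z, t=(100.0 - threshold) / 100.0, criterion="distance")
        groups = {}
        for pos, label in enumerate(cut):
            groups.setdefault(label, []).append(int(order[pos]))
        components = list(groups.values())
    else:
        raise ValueError("linkage must be 'single' or 'complete'")

    components.sort(key=lambda c: (-len(c), min(matrix.ids[i] for i in c)))
    labels = {}
    for fam, members in enumerate(components, start=1):
        for i in members:
            labels[matrix.ids[i]] = fam
    return FamilyAssignment(labels=labels, threshold=threshold, n_families=len(components))


def upgma_tree(matrix) -> TreeNode:
    """UPGMA agglomeration with arithmetic-mean updates.

    Accepts an :class:`IdentityMatrix` (converted to p-distances) or a
    ``(ids, distance_matrix)`` pair.  Ties are broken by the smallest
    lexicographic id pair, making the topology deterministic.  The result
    is a rooted ultrametric tree whose branch lengths place every pair of
    leaves at a root-to-leaf depth of half their cophenetic distance.
    """
    if isinstance(matrix, IdentityMatrix):
        ids = list(matrix.ids)
        dist = matrix.to_distances()
    else:
        ids, dist = matrix
        ids = list(ids)
        dist = np.asarray(dist, dtype=float)
    if np.isnan(dist).any():
        raise ValueError("distance matrix contains NaN")
    n = len(ids)
    if n < 2:
        raise ValueError("need at least two leaves")

    clusters = {
        i: {"node": TreeNode(name=ids[i]), "size": 1, "height": 0.0, "min_id": ids[i]}
        for i in range(n)
    }
    d = {frozenset((i, j)): float(dist[i, j]) for i in range(n) for j in range(i + 1, n)}
    next_idx = n
    while len(clusters) > 1:
        keys = sorted(clusters)
        best = None
        for ai in range(len(keys)):
            for bi in range(ai + 1, len(keys)):
                i, j = keys[ai], keys[bi]
                dij = d[frozenset((i, j))]
                pair_ids = tuple(sorted((clusters[i]["min_id"], clusters[j]["min_id"])))
                cand = (dij, pair_ids, i, j)
                if best is None or cand < best:
                    best = cand
        dij, _, i, j = best
        height = dij / 2.0
        ci, cj = clusters.pop(i), clusters.pop(j)
        node_i, node_j = ci["node"], cj["node"]
        node_i.length = height - ci["height"]
        node_j.length = height - cj["height"]
        new_node = TreeNode(children=[node_i, node_j])
        size = ci["size"] + cj["size"]
        for k in clusters:
            dk = (
                ci["size"] * d[frozenset((i, k))] + cj["size"] * d[frozenset((j, k))]
            ) / size
            d[frozenset((next_idx, k))] = dk
        clusters[next_idx] = {
            "node": new_node,
            "size": size,
            "height": height,
            "min_id": min(ci["min_id"], cj["min_id"]),
        }
        next_idx += 1
    root = next(iter(clusters.values()))["node"]
    root.length = None
    return root


def write_newick(tree: TreeNode, path) -> None:
    """Serialise a tree as Newick.

    Names with whitespace are written with the standard Newick underscore
    convention and are restored on parsing.
    """
    tree.write(str(path), format="newick")


def tree_to_newick(tree: TreeNode) -> str:
    buf = StringIO()
    tree.write(buf, format="newick")
    return buf.getvalue().strip()


def cophenetic_distance(tree: TreeNode, a: str, b: str) -> float:
    """Path distance between two leaves (used to verify ultrametricity)."""
    return float(tree.find(a).distance(tree.find(b)))
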