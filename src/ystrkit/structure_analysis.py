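"""Population-structure summaries of a genetic distance matrix.

Four views of a pairwise Rst (or any symmetric) distance matrix:

* classical (Torgerson) multidimensional scaling — double-center -d^2/2,
  eigendecompose, scale eigenvectors by sqrt(eigenvalue);
* UPGMA agglomerative clustering into an ultrametric rooted tree with
  Newick export;
* PCA treating each population's distance-matrix row as its feature vector;
* heatmap ordering: rows/columns permuted to UPGMA leaf order.

All outputs are deterministic: embedding axis signs are fixed by making the
largest-magnitude loading positive, and UPGMA ties break on the
lexicographically smallest cluster representative.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence
import warnings

import numpy as np

from .amova_rst import DistanceMatrix

__all__ = [
    "EmbeddingResult",
    "TreeNode",
    "classical_mds",
    "upgma_tree",
    "to_newick",
    "cophenetic_matrix",
    "pca_on_distance_matrix",
    "heatmap_order",
]


@dataclass(frozen=True)
class EmbeddingResult:
    """Low-dimensional coordinates with eigenvalue bookkeeping.

    Axes are ordered by nonincreasing eigenvalue; ``explained_fraction``
    is per-axis share of the retained (positive) spectrum for MDS, or of
    total variance for PCA.
    """

    labels: tuple[str, ...]
    coordinates: np.ndarray  # (n_labels, k)
    eigenvalues: np.ndarray
    explained_fraction: np.ndarray

    def to_dataframe(self):
        import pandas as pd

        cols = [f"axis{i + 1}" for i in range(self.coordinates.shape[1])]
        return pd.DataFrame(self.coordinates, index=self.labels, columns=cols)


@dataclass
class TreeNode:
    """Rooted tree node; leaves carry labels, internal nodes carry children.

    ``height`` is the node's ultrametric height (leaves at 0); a child's
    branch length is ``parent.height - child.height``.
    """

    label: str | None = None
    children: list["TreeNode"] = field(default_factory=list)
    height: float = 0.0

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        return [leaf for c in self.children for leaf in c.leaves()]

    def leaf_labels(self) -> list[str]:
        return [leaf.label for leaf in self.leaves()]


def _fix_signs(vectors: np.ndarray) -> np.ndarray:
    """Make the largest-magnitude loading of each column positive."""
    out = vectors.copy()
    for j in range(out.shape[1]):
        col = out[:, j]
        if col[np.argmax(np.abs(col))] < 0:
            out[:, j] = -col
    return out


def classical_mds(d: DistanceMatrix, k: int = 2) -> EmbeddingResult:
    """Torgerson metric scaling of a distance matrix into k dimensions.

    If the matrix has fewer than k positive eigenvalues (it is not
    Euclidean-embeddable in k dimensions), fewer axes are returned with a
    warning.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    D = d.values
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    eigval, eigvec = np.linalg.eigh((B + B.T) / 2)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    positive = eigval > max(1e-12, 1e-12 * abs(eigval[0]))
    n_pos = int(positive.sum())
    if n_pos < k:
        warnings.warn(
            f"only {n_pos} positive eigenvalue(s); returning {n_pos} axes",
            stacklevel=2,
        )
    k_eff = min(k, n_pos)
    vals = eigval[:k_eff]
    coords = _fix_signs(eigvec[:, :k_eff]) * np.sqrt(vals)
    total_pos = eigval[positive].sum()
    explained = vals / total_pos if total_pos > 0 else np.zeros(k_eff)
    return EmbeddingResult(
        labels=d.labels,
        coordinates=coords,
        eigenvalues=vals,
        explained_fraction=explained,
    )


def upgma_tree(d: DistanceMatrix) -> TreeNode:
    """Unweighted pair-group (arithmetic-mean) clustering of a distance matrix.

    At each step the closest pair of clusters merges at height = half their
    distance; the distance from the merged cluster to any other is the
    size-weighted mean of the members' distances (i.e. the arithmetic mean
    over all cross pairs — classical UPGMA). Ties break on the
    lexicographically smallest pair of cluster representatives, so output
    is invariant to input label order.
    """
    n = len(d.labels)
    if n < 2:
        raise ValueError("need at least 2 labels")
    nodes: dict[int, TreeNode] = {
        i: TreeNode(label=lab) for i, lab in enumerate(d.labels)
    }
    sizes = {i: 1 for i in range(n)}
    reps = {i: d.labels[i] for i in range(n)}  # min leaf label per cluster
    dist = {
        (i, j): float(d.values[i, j]) for i in range(n) for j in range(i + 1, n)
    }
    next_id = n
    while len(nodes) > 1:
        # closest pair; ties resolved by sorted representative labels
        best = min(
            dist.items(),
            key=lambda kv: (kv[1], tuple(sorted((reps[kv[0][0]], reps[kv[0][1]])))),
        )
        (a, b), dmin = best
        merged = TreeNode(
            children=sorted([nodes[a], nodes[b]], key=lambda t: min(t.leaf_labels())),
            height=dmin / 2,
        )
        new_sizes = sizes[a] + sizes[b]
        others = [k for k in nodes if k not in (a, b)]
        for o in others:
            da = dist[(min(a, o), max(a, o))]
            db = dist[(min(b, o), max(b, o))]
            dist[(min(next_id, o), max(next_id, o))] = (
                sizes[a] * da + sizes[b] * db
            ) / new_sizes
        for key in list(dist):
            if a in key or b in key:
                del dist[key]
        del nodes[a], nodes[b], sizes[a], sizes[b]
        nodes[next_id] = merged
        sizes[next_id] = new_sizes
        reps[next_id] = min(reps[a], reps[b])
        next_id += 1
    return next(iter(nodes.values()))


def _newick_label(label: str) -> str:
    if any(c in label for c in " ()[]:;,'"):
        return "'" + label.replace("'", "''") + "'"
    return label


def _newick_node(node: TreeNode, parent_height: float | None) -> str:
    if node.is_leaf:
        s = _newick_label(node.label)
    else:
        inner = ",".join(_newick_node(c, node.height) for c in node.children)
        s = f"({inner})"
    if parent_height is None:
        return s
    return f"{s}:{parent_height - node.height:.12g}"


def to_newick(tree: TreeNode) -> str:
    """Serialize with branch lengths; children already in label order, so
    output is byte-identical across runs."""
    return _newick_node(tree, None) + ";"


def cophenetic_matrix(tree: TreeNode, labels: Sequence[str]) -> np.ndarray:
    """Tree-implied distances: twice the height of each pair's ancestor."""
    idx = {lab: i for i, lab in enumerate(labels)}
    n = len(labels)
    out = np.zeros((n, n))

    def visit(node: TreeNode) -> list[str]:
        if node.is_leaf:
            return [node.label]
        groups = [visit(c) for c in node.children]
        for gi in range(len(groups)):
            for gj in range(gi + 1, len(groups)):
                for la in groups[gi]:
                    for lb in groups[gj]:
                        out[idx[la], idx[lb]] = out[idx[lb], idx[la]] = 2 * node.height
        return [lab for g in groups for lab in g]

    visit(tree)
    return out


def pca_on_distance_matrix(d: DistanceMatrix) -> EmbeddingResult:
    """PCA with each population's distance-matrix row as its feature vector.

    Columns are centered; scores come from the eigendecomposition of the
    covariance matrix. Explained fractions are over the full spectrum and
    sum to 1.
    """
    n = len(d.labels)
    if n < 3:
        raise ValueError("PCA needs at least 3 populations")
    X = d.values - d.values.mean(axis=0, keepdims=True)
    if np.allclose(X, 0):
        raise ValueError("constant distance matrix: no variance to decompose")
    cov = X.T @ X / (n - 1)
    eigval, eigvec = np.linalg.eigh(cov)
    order = np.argsort(eigval)[::-1]
    eigval = np.clip(eigval[order], 0, None)
    eigvec = _fix_signs(eigvec[:, order])
    scores = X @ eigvec
    explained = eigval / eigval.sum()
    return EmbeddingResult(
        labels=d.labels,
        coordinates=scores,
        eigenvalues=eigval,
        explained_fraction=explained,
    )


def heatmap_order(d: DistanceMatrix) -> tuple[tuple[str, ...], np.ndarray]:
    """Labels in UPGMA leaf order plus the correspondingly permuted matrix."""
    tree = upgma_tree(d)
    ordered = tuple(tree.leaf_labels())
    perm = [d.labels.index(lab) for lab in ordered]
    return ordered, d.values[np.ix_(perm, perm)]
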