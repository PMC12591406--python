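"""Community delineation on the association matrix.

Individuals are clustered by average-linkage (UPGMA) agglomeration on the
dissimilarity d = 1 − SRI.  Dendrogram fidelity is measured by the
cophenetic correlation coefficient (CCC): the Pearson correlation between
original dissimilarities and the merge heights at which pairs join.  The
partition is chosen by cutting the dendrogram at every distinct merge
height and keeping the cut maximizing the weighted Newman modularity

    Q = sum_c [ w_c / W − (s_c / 2W)^2 ]

with a_ij = SRI (off-diagonal), W the total edge weight, w_c the
within-cluster weight and s_c the summed strengths of cluster c.  Q > 0.3
conventionally indicates a meaningful division.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
from scipy.cluster import hierarchy as _hier
from scipy.spatial.distance import squareform

from .association import AssociationMatrix

__all__ = [
    "Dendrogram",
    "CommunityResult",
    "average_linkage",
    "cophenetic_correlation",
    "modularity",
    "best_partition",
    "export_network",
    "to_newick",
]


class UndefinedStatisticError(ValueError):
    """A statistic (CCC, Q) is undefined for this input (zero variance/weight)."""


@dataclass
class Dendrogram:
    """UPGMA merge tree over individuals.

    ``linkage`` is the (n−1, 4) scipy linkage matrix (cluster_a, cluster_b,
    height, size); ``ids`` are the leaf labels in matrix order.
    """

    ids: list[str]
    linkage: np.ndarray

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]


@dataclass
class CommunityResult:
    """Best dendrogram cut by modularity, with the full cut trace."""

    partition: dict[str, int]
    q_max: float
    ccc: float
    q_by_cut: list[tuple[float, int, float]]  # (height, k clusters, Q)

    @property
    def n_clusters(self) -> int:
        return len(set(self.partition.values()))

    def cluster_sizes(self) -> dict[int, int]:
        sizes: dict[int, int] = {}
        for label in self.partition.values():
            sizes[label] = sizes.get(label, 0) + 1
        return sizes

    def to_json(self, path: str | Path) -> None:
        payload = {
            "q_max": self.q_max,
            "ccc": self.ccc,
            "n_clusters": self.n_clusters,
            "partition": self.partition,
            "q_by_cut": [
                {"height": h, "k": k, "q": q} for h, k, q in self.q_by_cut
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def _dissimilarity(assoc: AssociationMatrix) -> np.ndarray:
    d = 1.0 - assoc.sri
    np.fill_diagonal(d, 0.0)
    if not np.isfinite(d).all():
        raise ValueError("non-finite dissimilarities")
    return d


def average_linkage(assoc: AssociationMatrix) -> Dendrogram:
    """UPGMA agglomeration on d = 1 − SRI.

    Deterministic given input order; equal-distance merges follow the
    linkage algorithm's stable nearest-neighbor order (lowest pair index
    first among exact ties).
    """
    if assoc.n_individuals < 2:
        raise ValueError("need at least 2 individuals to cluster")
    d = _dissimilarity(assoc)
    Z = _hier.linkage(squareform(d, checks=False), method="average")
    return Dendrogram(ids=list(assoc.ids), linkage=Z)


def cophenetic_correlation(dend: Dendrogram, assoc: AssociationMatrix) -> float:
    """Pearson correlation between cophenetic and observed dissimilarities.

    Computed over all unordered off-diagonal pairs; the sign is preserved
    (an anti-correlated tree yields a negative CCC).
    """
    d = squareform(_dissimilarity(assoc), checks=False)
    coph = _hier.cophenet(dend.linkage)
    if np.std(d) == 0 or np.std(coph) == 0:
        raise UndefinedStatisticError("zero variance: CCC undefined")
    return float(np.corrcoef(d, coph)[0, 1])


def modularity(partition: dict[str, int], assoc: AssociationMatrix) -> float:
    """Weighted Newman modularity of a partition of the association matrix.

    Uses a_ij = SRI with the diagonal excluded.  Raises if the matrix has
    no off-diagonal weight.
    """
    ids = assoc.ids
    if set(partition) != set(ids):
        raise ValueError("partition must cover exactly the matrix ids")
    a = assoc.sri.copy()
    np.fill_diagonal(a, 0.0)
    labels = np.array([partition[i] for i in ids])
    return _modularity_from_arrays(labels, a)


def _modularity_from_arrays(labels: np.ndarray, a: np.ndarray) -> float:
    two_w = a.sum()  # == 2W for a symmetric zero-diagonal matrix
    if two_w <= 0:
        raise UndefinedStatisticError("total association weight is zero: Q undefined")
    s = a.sum(axis=1)
    q = 0.0
    for c in np.unique(labels):
        mask = labels == c
        w_c2 = a[np.ix_(mask, mask)].sum()  # == 2 * within-weight
        s_c = s[mask].sum()
        q += w_c2 / two_w - (s_c / two_w) ** 2
    return float(q)


def best_partition(dend: Dendrogram, assoc: AssociationMatrix) -> CommunityResult:
    """Choose the dendrogram cut maximizing modularity.

    Q is evaluated at every distinct merge height (plus the trivial k = n
    cut below the first merge).  Ties are broken toward fewer clusters,
    then toward the lower cut height.  The full (height, k, Q) trace is
    retained in ``q_by_cut``.
    """
    ids = dend.ids
    a = assoc.sri.copy()
    np.fill_diagonal(a, 0.0)
    heights = sorted(set(dend.heights.tolist()))
    n = len(ids)

    cuts: list[tuple[float, np.ndarray]] = []
    # k = n cut: every leaf its own cluster (height below the first merge)
    first = heights[0] if heights else 0.0
    cuts.append((min(0.0, first) - 1e-12, np.arange(n)))
    for h in heights:
        labels = _hier.fcluster(dend.linkage, t=h, criterion="distance")
        cuts.append((h, labels))

    trace: list[tuple[float, int, float]] = []
    best: tuple[float, int, float] | None = None  # (q, k, height)
    best_labels: np.ndarray | None = None
    for h, labels in cuts:
        k = len(np.unique(labels))
        q = _modularity_from_arrays(np.asarray(labels), a)
        trace.append((float(h), int(k), q))
        key = (q, -k, -h)
        if best is None or key > (best[0], -best[1], -best[2]):
            best = (q, k, float(h))
            best_labels = np.asarray(labels)
    assert best is not None and best_labels is not None
    # relabel clusters 0..k-1 in order of first appearance
    remap: dict[int, int] = {}
    partition: dict[str, int] = {}
    for ind, lab in zip(ids, best_labels):
        partition[ind] = remap.setdefault(int(lab), len(remap))
    ccc = cophenetic_correlation(dend, assoc)
    return CommunityResult(partition=partition, q_max=best[0], ccc=ccc, q_by_cut=trace)


def export_network(
    assoc: AssociationMatrix,
    result: CommunityResult,
    min_edge: float = 0.0,
    path: str | Path | None = None,
) -> nx.Graph:
    """Build (and optionally write) the weighted sociogram.

    Nodes carry cluster labels; edges with SRI ≥ ``min_edge`` (and > 0)
    carry the index as weight.  Node and edge order is deterministic.
    If ``path`` ends in ``.graphml`` a GraphML file is written, otherwise a
    weighted edge-list CSV.
    """
    g = nx.Graph()
    for ind in assoc.ids:
        g.add_node(ind, cluster=int(result.partition[ind]))
    n = len(assoc.ids)
    for i in range(n):
        for j in range(i + 1, n):
            w = float(assoc.sri[i, j])
            if w > 0 and w >= min_edge:
                g.add_edge(assoc.ids[i], assoc.ids[j], weight=w)
    if path is not None:
        path = Path(path)
        if path.suffix == ".graphml":
            nx.write_graphml(g, path)
        else:
            with open(path, "w") as fh:
                fh.write("id_i,id_j,weight\n")
                for u, v, data in sorted(g.edges(data=True)):
                    fh.write(f"{u},{v},{data['weight']!r}\n")
    return g


def to_newick(dend: Dendrogram) -> str:
    """Serialize the dendrogram to Newick, branch lengths = height deltas."""
    tree = _hier.to_tree(dend.linkage)

    def walk(node, parent_height: float) -> str:
        length = parent_height - (0.0 if node.is_leaf() else node.dist)
        if node.is_leaf():
            return f"{dend.ids[node.id]}:{parent_height:.6g}"
        left = walk(node.left, node.dist)
        right = walk(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    body = walk(tree, tree.dist)
    # strip the root's zero-length branch
    return body.rsplit(":", 1)[0] + ";"
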