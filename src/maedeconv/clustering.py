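"""Centroid-linkage hierarchical clustering of the E_i matrix.

Epitopes whose abundance profiles across a related-donor cell-line panel
co-vary are likely presented by the same HLA allele, so the E_i matrix is
clustered agglomeratively in both dimensions.  Cluster-to-cluster distance
is the metric distance between cluster *centroids* (arithmetic mean
profiles), recomputed from the original rows at every step -- the scheme
used by Cluster 3.0, which can produce non-monotone merge heights and is
therefore implemented directly rather than through a Lance-Williams
recurrence.  The default metric is 1 - Pearson correlation (centered);
Euclidean distance is available as an option.

Internal vertices of the epitope dendrogram whose leaf counts fall inside
a size window become *nodes* -- candidate sets of co-presented epitopes
passed on to alignment and motif analysis.  The defaults (at least 9, at
most 100 epitopes) follow the observation that smaller or larger nodes
align poorly.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np

from .abundance_indices import EiMatrix


@dataclasses.dataclass
class Dendrogram:
    """Agglomerative merge history over named leaves.

    Clusters are numbered scipy-style: leaf i is cluster i, and the k-th
    merge (0-based) creates cluster ``len(leaves) + k``.  ``merges`` holds
    (cluster_a, cluster_b, height) in merge order.
    """

    leaves: list[str]
    merges: list[tuple[int, int, float]]

    def __post_init__(self) -> None:
        if len(self.merges) != len(self.leaves) - 1:
            raise ValueError(
                f"{len(self.leaves)} leaves require {len(self.leaves) - 1} "
                f"merges, got {len(self.merges)}"
            )
        for a, b, h in self.merges:
            if not np.isfinite(h) or h < 0:
                raise ValueError(f"merge height must be finite and >= 0, got {h}")

    def leaf_sets(self) -> dict[int, frozenset[int]]:
        """Leaf-index set under every cluster id (leaves and internal)."""
        n = len(self.leaves)
        sets: dict[int, frozenset[int]] = {i: frozenset([i]) for i in range(n)}
        for k, (a, b, _h) in enumerate(self.merges):
            sets[n + k] = sets[a] | sets[b]
        return sets

    def to_newick(self) -> str:
        n = len(self.leaves)
        reprs: dict[int, str] = {
            i: _quote_newick(name) for i, name in enumerate(self.leaves)
        }
        heights: dict[int, float] = {i: 0.0 for i in range(n)}
        for k, (a, b, h) in enumerate(self.merges):
            la = max(h - heights[a], 0.0)
            lb = max(h - heights[b], 0.0)
            reprs[n + k] = f"({reprs[a]}:{la:g},{reprs[b]}:{lb:g})"
            heights[n + k] = h
        return reprs[n + len(self.merges) - 1] + ";"


def _quote_newick(name: str) -> str:
    if any(c in name for c in "(),:;' \t"):
        return "'" + name.replace("'", "''") + "'"
    return name


@dataclasses.dataclass
class EpitopeNode:
    """Leaf set of one internal dendrogram vertex, with its mean profile."""

    node_id: str
    member_epitopes: frozenset[str]
    mean_profile: np.ndarray

    def __post_init__(self) -> None:
        if len(self.member_epitopes) < 2:
            raise ValueError("a node needs at least 2 member epitopes")


def correlation_distance(x: np.ndarray, y: np.ndarray) -> float:
    """1 - centered Pearson correlation; zero-variance vectors are distance
    0 from an identical vector and 1 from anything else."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xc = x - x.mean()
    yc = y - y.mean()
    nx = np.sqrt(xc @ xc)
    ny = np.sqrt(yc @ yc)
    if nx == 0.0 or ny == 0.0:
        return 0.0 if np.array_equal(x, y) else 1.0
    return float(1.0 - (xc @ yc) / (nx * ny))


def euclidean_distance(x: np.ndarray, y: np.ndarray) -> float:
    return float(np.linalg.norm(np.asarray(x, float) - np.asarray(y, float)))


_METRICS = {"correlation": correlation_distance, "euclidean": euclidean_distance}


def cluster_matrix(
    matrix: EiMatrix, axis: str = "epitopes", metric: str = "correlation"
) -> Dendrogram:
    """Centroid-linkage agglomerative clustering along one matrix axis.

    Centroids are re-derived as member means at each step.  Ties in the
    minimum inter-centroid distance are broken by the smallest (sorted)
    pair of each cluster's oldest member index, making the result
    deterministic and independent of any prior ordering.
    """
    if axis == "epitopes":
        data = matrix.values
        names = list(matrix.epitope_ids)
    elif axis == "cell_lines":
        data = matrix.values.T
        names = list(matrix.cell_lines)
    else:
        raise ValueError(f"axis must be 'epitopes' or 'cell_lines', got {axis!r}")
    if len(names) < 2:
        raise ValueError(f"need >= 2 items on the {axis} axis to cluster")
    dist = _METRICS[metric]

    n = len(names)
    active: dict[int, list[int]] = {i: [i] for i in range(n)}  # id -> leaf rows
    centroids: dict[int, np.ndarray] = {i: data[i].astype(float) for i in range(n)}
    dists: dict[tuple[int, int], float] = {}
    for i in range(n):
        for j in range(i + 1, n):
            dists[(i, j)] = dist(centroids[i], centroids[j])
    merges: list[tuple[int, int, float]] = []
    for step in range(n - 1):
        best: tuple[float, int, int, int, int] | None = None
        for (a, b), d in dists.items():
            ra, rb = min(active[a]), min(active[b])
            key = (d, min(ra, rb), max(ra, rb), a, b)
            if best is None or key < best:
                best = key
        d, _ra, _rb, a, b = best
        new_id = n + step
        active[new_id] = active.pop(a) + active.pop(b)
        centroids.pop(a)
        centroids.pop(b)
        centroids[new_id] = data[active[new_id]].mean(axis=0)
        dists = {
            pair: v for pair, v in dists.items() if a not in pair and b not in pair
        }
        for other in active:
            if other != new_id:
                dists[(other, new_id)] = dist(centroids[other], centroids[new_id])
        merges.append((a, b, max(d, 0.0)))
    return Dendrogram(leaves=names, merges=merges)


def extract_nodes(
    dendrogram: Dendrogram,
    matrix: EiMatrix,
    min_size: int = 9,
    max_size: int = 100,
) -> list[EpitopeNode]:
    """One node per internal vertex with leaf count in [min_size, max_size].

    Nested qualifying vertices all yield nodes.  ``mean_profile`` is the
    member-mean E_i per cell line, taken from ``matrix``.
    """
    if min_size > max_size:
        raise ValueError(f"min_size ({min_size}) > max_size ({max_size})")
    if min_size < 2:
        raise ValueError("min_size must be >= 2 (a node needs >= 2 members)")
    index = {eid: i for i, eid in enumerate(matrix.epitope_ids)}
    n = len(dendrogram.leaves)
    nodes: list[EpitopeNode] = []
    sets = dendrogram.leaf_sets()
    for k in range(len(dendrogram.merges)):
        leafset = sets[n + k]
        if min_size <= len(leafset) <= max_size:
            members = frozenset(dendrogram.leaves[i] for i in leafset)
            rows = [index[m] for m in sorted(members)]
            nodes.append(
                EpitopeNode(
                    node_id=f"N{k + 1:04d}",
                    member_epitopes=members,
                    mean_profile=matrix.values[rows].mean(axis=0),
                )
            )
    return nodes


def write_node_members(nodes: Sequence[EpitopeNode], path) -> None:
    import pandas as pd

    rows = [
        {"node_id": nd.node_id, "epitope_id": eid}
        for nd in nodes
        for eid in sorted(nd.member_epitopes)
    ]
    pd.DataFrame(rows, columns=["node_id", "epitope_id"]).to_csv(
        path, sep="\t", index=False
    )
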