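"""Agglomerative hierarchical clustering of rescue stations.

Average linkage (UPGMA) on Euclidean distances, implemented directly so the
tie-breaking rule is explicit and platform-independent: when two merge
candidates have equal average distance, the pair whose combined, sorted
member list is alphabetically first wins.  The resulting dendrogram is
therefore invariant under permutations of the input order.

The default station feature is the one-dimensional annual count of
non-time-critical operations (unscaled); a two-dimensional variant adds the
no-transport/with-transport percentage.  This feature convention is a
reconstruction that reproduces the documented five-cluster grouping of the
17 Hamburg stations; see ``docs/methods.md`` for its limits.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core_data import StationRegistry


@dataclass(frozen=True)
class Merge:
    members_a: tuple[str, ...]
    members_b: tuple[str, ...]
    height: float

    @property
    def size(self) -> int:
        return len(self.members_a) + len(self.members_b)


@dataclass
class LinkageTree:
    leaves: tuple[str, ...]
    merges: tuple[Merge, ...]

    def heights(self) -> list[float]:
        return [m.height for m in self.merges]


@dataclass
class ClusterAssignment:
    k: int
    labels: dict[str, int]  # station -> cluster id 1..k

    def clusters(self) -> list[list[str]]:
        out: dict[int, list[str]] = {}
        for station, cid in self.labels.items():
            out.setdefault(cid, []).append(station)
        return [sorted(out[c]) for c in sorted(out)]


def distance_matrix(features: np.ndarray) -> np.ndarray:
    """Symmetric Euclidean distance matrix of per-station feature vectors."""
    X = np.asarray(features, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if np.isnan(X).any():
        raise ValueError("features contain NaN")
    diff = X[:, None, :] - X[None, :, :]
    return np.sqrt((diff**2).sum(axis=-1))


def average_linkage(dist: np.ndarray, labels: Sequence[str]) -> LinkageTree:
    """UPGMA agglomeration: repeatedly merge the pair of clusters with the
    smallest average inter-cluster distance (mean over all leaf pairs)."""
    dist = np.asarray(dist, dtype=float)
    n = dist.shape[0]
    if n < 2:
        raise ValueError("need at least two items to cluster")
    if dist.shape != (n, n) or not np.allclose(dist, dist.T):
        raise ValueError("distance matrix must be square and symmetric")
    labels = [str(l) for l in labels]
    if len(labels) != n:
        raise ValueError("labels must match the distance matrix size")
    # active clusters as sorted member tuples; average distances maintained
    # by the Lance-Williams update for UPGMA
    clusters: list[tuple[str, ...]] = [(lab,) for lab in labels]
    d = {
        (i, j): dist[i, j]
        for i in range(n)
        for j in range(i + 1, n)
    }
    active = list(range(n))
    sizes = {i: 1 for i in range(n)}
    members = {i: clusters[i] for i in range(n)}
    merges: list[Merge] = []
    next_id = n
    while len(active) > 1:
        best = None
        for ai in range(len(active)):
            for aj in range(ai + 1, len(active)):
                i, j = active[ai], active[aj]
                key = (min(i, j), max(i, j))
                cand_dist = d[key]
                tie_key = tuple(sorted(members[i] + members[j]))
                cand = (cand_dist, tie_key, i, j)
                if best is None or cand[:2] < best[:2]:
                    best = cand
        height, _, i, j = best
        a, b = sorted((members[i], members[j]))
        merges.append(Merge(members_a=a, members_b=b, height=float(height)))
        new_members = tuple(sorted(members[i] + members[j]))
        new_size = sizes[i] + sizes[j]
        # UPGMA update against every remaining cluster
        for k_ in active:
            if k_ in (i, j):
                continue
            dik = d[(min(i, k_), max(i, k_))]
            djk = d[(min(j, k_), max(j, k_))]
            d[(min(next_id, k_), max(next_id, k_))] = (
                sizes[i] * dik + sizes[j] * djk
            ) / new_size
        active = [k_ for k_ in active if k_ not in (i, j)] + [next_id]
        members[next_id] = new_members
        sizes[next_id] = new_size
        next_id += 1
    return LinkageTree(leaves=tuple(sorted(labels)), merges=tuple(merges))


def cut(tree: LinkageTree, k: int) -> ClusterAssignment:
    """Partition into k clusters by undoing the last k-1 merges."""
    n = len(tree.leaves)
    if not 1 <= k <= n:
        raise ValueError(f"k must lie in 1..{n}, got {k}")
    clusters = {(leaf,) for leaf in tree.leaves}
    for merge in tree.merges[: n - k]:
        clusters.discard(merge.members_a)
        clusters.discard(merge.members_b)
        clusters.add(tuple(sorted(merge.members_a + merge.members_b)))
    ordered = sorted(clusters, key=lambda c: c[0])
    labels = {}
    for cid, cluster in enumerate(ordered, start=1):
        for station in cluster:
            labels[station] = cid
    return ClusterAssignment(k=k, labels=labels)


def station_features(
    registry: StationRegistry, features: str = "total"
) -> tuple[np.ndarray, list[str]]:
    """Feature matrix for clustering the registry's stations.

    ``"total"`` (default): 1-D annual non-time-critical count, unscaled.
    ``"total,ratio"``: adds the no-transport/with-transport percentage.
    """
    names = registry.names
    totals = np.array([r.ops_total for r in registry], dtype=float)
    if features == "total":
        X = totals[:, None]
    elif features in ("total,ratio", "ratio"):
        ratio = np.array(
            [
                100.0 * r.ops_without_transport / r.ops_with_transport
                for r in registry
            ]
        )
        X = np.column_stack([totals, ratio])
    else:
        raise ValueError(f"unknown feature set {features!r}")
    return X, names


def cluster_stations(
    registry: StationRegistry, k: int = 5, features: str = "total"
) -> ClusterAssignment:
    """Convenience: feature extraction + average linkage + cut."""
    X, names = station_features(registry, features)
    tree = average_linkage(distance_matrix(X), names)
    return cut(tree, k)


def to_newick(tree: LinkageTree) -> str:
    """Dendrogram as a newick string with merge heights as node comments."""
    node_of: dict[tuple[str, ...], str] = {
        (leaf,): leaf.replace(" ", "_") for leaf in tree.leaves
    }
    for merge in tree.merges:
        a = node_of.pop(merge.members_a)
        b = node_of.pop(merge.members_b)
        combined = tuple(sorted(merge.members_a + merge.members_b))
        node_of[combined] = f"({a},{b}):{merge.height:g}"
    (root,) = node_of.values()
    return root + ";"
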