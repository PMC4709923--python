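"""Ward hierarchical clustering of the component distance matrix.

At each step the pair of clusters whose merge least increases the within-
cluster error sum of squares (ESS) is joined.  With only a distance matrix
available (the MI distances have no coordinate embedding), the input
distances are treated as Euclidean and the Ward criterion is propagated with
the Lance-Williams recurrence -- the universal convention for "Ward on a
precomputed distance matrix".  Merge heights are reported as the Ward
pseudo-ESS increments d^2/2 (for two singletons at distance d the increase
is exactly d^2/2), which are non-decreasing along the merge sequence, so the
tree renders directly as a dendrogram.

Ties are broken deterministically in favour of the lexicographically
smallest cluster-index pair (leaves are 0..n-1, new clusters n, n+1, ...).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .midist import DistanceMatrix


@dataclass
class LinkageTree:
    """Sequence of Ward merges; heights are ESS increments."""

    merges: list[tuple[int, int, float, int]]  # (cluster a, cluster b, height, new size)
    leaf_ids: list[int]

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_ids)

    def to_scipy_linkage(self) -> np.ndarray:
        """Linkage array in scipy's (n-1, 4) format, heights = ESS increments."""
        z = np.array([[a, b, h, s] for a, b, h, s in self.merges], dtype=float)
        return z

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.merges, columns=["cluster_a", "cluster_b", "height", "new_size"]
        )

    def save(self, csv_path: str | Path) -> None:
        self.to_dataframe().to_csv(csv_path, index=False)


def ward_linkage(dist: DistanceMatrix | np.ndarray) -> LinkageTree:
    """Agglomerate with the Ward criterion via the Lance-Williams recurrence.

    ``dist`` is a :class:`DistanceMatrix` or a symmetric non-negative array.
    The recurrence runs on squared distances,

        d2(k, i+j) = ((n_i+n_k) d2(k,i) + (n_j+n_k) d2(k,j) - n_k d2(i,j))
                     / (n_i + n_j + n_k),

    and the merge chosen at each step minimises the ESS increment d2/2.
    """
    if isinstance(dist, DistanceMatrix):
        ids = dist.component_ids
        d = dist.values
    else:
        d = np.asarray(dist, dtype=float)
        ids = list(range(d.shape[0]))
    n = d.shape[0]
    if d.ndim != 2 or d.shape[1] != n or n < 2:
        raise ValueError("need a square distance matrix of size >= 2")
    if not np.allclose(d, d.T, atol=1e-8):
        raise ValueError("distance matrix must be symmetric")
    if (d < -1e-12).any():
        raise ValueError("distances must be non-negative")
    if np.abs(np.diag(d)).max() > 1e-8:
        raise ValueError("distance matrix must have a zero diagonal")

    d2 = {}
    for i in range(n):
        for j in range(i + 1, n):
            d2[(i, j)] = d[i, j] ** 2
    size = {i: 1 for i in range(n)}
    active = set(range(n))
    merges: list[tuple[int, int, float, int]] = []
    next_id = n
    for _ in range(n - 1):
        best = None
        for i in sorted(active):
            for j in sorted(active):
                if j <= i:
                    continue
                val = d2[(i, j)]
                if best is None or val < best[0] - 1e-15:
                    best = (val, i, j)
        val, i, j = best
        new_size = size[i] + size[j]
        merges.append((i, j, val / 2.0, new_size))
        for k in sorted(active - {i, j}):
            dik = d2[(min(i, k), max(i, k))]
            djk = d2[(min(j, k), max(j, k))]
            dij = d2[(i, j)]
            d2[(k, next_id)] = (
                (size[i] + size[k]) * dik + (size[j] + size[k]) * djk - size[k] * dij
            ) / (new_size + size[k])
        active -= {i, j}
        active.add(next_id)
        size[next_id] = new_size
        next_id += 1
    return LinkageTree(merges=merges, leaf_ids=ids)


def cophenetic_matrix(tree: LinkageTree) -> np.ndarray:
    """(n, n) matrix of heights at which leaves first share a cluster."""
    z = tree.to_scipy_linkage()
    return squareform(hierarchy.cophenet(z))


def render_dendrogram(
    tree: LinkageTree,
    labels: list[str] | None = None,
    path: str | Path | None = None,
    ax=None,
):
    """Draw the dendrogram (component labels on the abscissa, ESS-increment
    merge heights on the ordinate); optionally save to ``path``."""
    import matplotlib

    if path is not None and ax is None:
        matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if labels is None:
        labels = [f"IC{i}" for i in tree.leaf_ids]
    if ax is None:
        fig, ax = plt.subplots(figsize=(6, 4))
    else:
        fig = ax.figure
    hierarchy.dendrogram(tree.to_scipy_linkage(), labels=labels, ax=ax)
    ax.set_xlabel("component")
    ax.set_ylabel("Ward merge height (ESS increment)")
    if path is not None:
        fig.savefig(str(path), bbox_inches="tight")
        plt.close(fig)
    return ax
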