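"""Alpha/beta diversity and sample-level hierarchical clustering.

Distance matrices are :class:`skbio.DistanceMatrix` objects (square,
symmetric, zero diagonal, with sample ids attached); dendrograms are a
small merge-list structure with Newick export.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix

__all__ = [
    "shannon_index",
    "alpha_diversity",
    "bray_curtis",
    "manhattan",
    "Dendrogram",
    "hierarchical_cluster",
    "presence_absence",
]


def shannon_index(values, base: float | None = None) -> float:
    """Shannon diversity H = -sum p_i log p_i over non-zero proportions.

    ``values`` may be counts or proportions; they are normalised to sum to
    one. Natural log by default; pass ``base=2`` for bits.
    """
    p = np.asarray(values, dtype=float)
    if p.ndim != 1:
        raise ValueError("shannon_index expects a 1-D vector")
    if (p < 0).any():
        raise ValueError("negative values in abundance vector")
    total = p.sum()
    if total <= 0:
        raise ValueError("abundance vector sums to zero")
    p = p[p > 0] / total
    h = float(-(p * np.log(p)).sum())
    if base is not None:
        h /= np.log(base)
    return h


def alpha_diversity(table: pd.DataFrame, base: float | None = None) -> pd.Series:
    """Shannon index per sample column of an abundance table."""
    return pd.Series(
        {s: shannon_index(table[s].to_numpy(), base=base) for s in table.columns},
        name="shannon",
    )


def bray_curtis(rel: pd.DataFrame) -> DistanceMatrix:
    """Bray-Curtis dissimilarity between sample columns.

    BC(x, y) = sum|x_i - y_i| / sum(x_i + y_i), in [0, 1].
    """
    if rel.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    condensed = pdist(rel.to_numpy(dtype=float).T, metric="braycurtis")
    return DistanceMatrix(squareform(condensed, checks=False), ids=list(rel.columns))


def manhattan(values: pd.DataFrame) -> DistanceMatrix:
    """Manhattan (city-block) distance between sample columns."""
    if values.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    condensed = pdist(values.to_numpy(dtype=float).T, metric="cityblock")
    return DistanceMatrix(squareform(condensed, checks=False), ids=list(values.columns))


@dataclass
class Dendrogram:
    """Agglomerative merge history over sample leaves.

    ``merges`` holds ``(left_leaves, right_leaves, height)`` triples, one
    per merge, with leaves as sorted tuples and heights non-decreasing.
    """

    leaves: list[str]
    merges: list[tuple[tuple[str, ...], tuple[str, ...], float]]

    def cophenetic(self, a: str, b: str) -> float:
        """Height of the first merge joining leaves ``a`` and ``b``."""
        for left, right, height in self.merges:
            if (a in left and b in right) or (a in right and b in left):
                return height
        raise KeyError(f"{a!r} and {b!r} are never merged")

    def to_newick(self) -> str:
        """Ultrametric Newick string; branch lengths from merge heights."""
        height_of: dict[tuple[str, ...], float] = {(leaf,): 0.0 for leaf in self.leaves}
        text_of: dict[tuple[str, ...], str] = {(leaf,): leaf for leaf in self.leaves}
        for left, right, height in self.merges:
            node = tuple(sorted(left + right))
            bl_left = height - height_of[left]
            bl_right = height - height_of[right]
            text_of[node] = f"({text_of[left]}:{bl_left:g},{text_of[right]}:{bl_right:g})"
            height_of[node] = height
        root = tuple(sorted(self.leaves))
        return text_of[root] + ";"


def hierarchical_cluster(d: DistanceMatrix, linkage: str = "complete") -> Dendrogram:
    """Agglomerative clustering with complete (maximum) linkage.

    At each step the pair of clusters with the smallest maximum pairwise
    distance is merged; ties are broken toward the lexicographically
    smallest (left representative, right representative) leaf-label pair,
    making the result invariant to input sample order.
    """
    if linkage != "complete":
        raise ValueError(f"unsupported linkage {linkage!r}; only 'complete' is implemented")
    ids = list(d.ids)
    if len(ids) < 2:
        raise ValueError("need at least 2 samples to cluster")
    dist = pd.DataFrame(d.data, index=ids, columns=ids)
    # each active cluster keyed by its sorted leaf tuple
    active: list[tuple[str, ...]] = [(leaf,) for leaf in ids]
    merges: list[tuple[tuple[str, ...], tuple[str, ...], float]] = []

    def linkage_dist(a: tuple[str, ...], b: tuple[str, ...]) -> float:
        return float(dist.loc[list(a), list(b)].to_numpy().max())

    while len(active) > 1:
        best = None
        for i in range(len(active)):
            for j in range(i + 1, len(active)):
                a, b = active[i], active[j]
                if min(a) > min(b):
                    a, b = b, a
                cand = (linkage_dist(a, b), min(a), min(b), a, b)
                if best is None or cand[:3] < best[:3]:
                    best = cand
        height, _, _, left, right = best
        merges.append((left, right, height))
        active = [c for c in active if c is not left and c is not right]
        active.append(tuple(sorted(left + right)))
    return Dendrogram(leaves=sorted(ids), merges=merges)


def presence_absence(table: pd.DataFrame) -> pd.DataFrame:
    """Binary matrix: 1 where the value is positive, else 0."""
    return (table > 0).astype(np.int8)
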