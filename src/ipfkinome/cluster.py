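"""Hierarchical clustering of samples with the study's adjustment scheme.

The adjustment has two steps: (1) centre each sample column on its own
median, (2) divide each gene row of the centred matrix by that gene's
standard deviation across all samples (population SD by default; a pooled
whole-matrix SD is selectable). Zero-variance genes are dropped with a
warning rather than producing infinities.

The agglomeration itself is implemented here (uncentred Pearson correlation
distance with average linkage by default, the common defaults of the
classic clustering software for expression matrices) so that ties in merge
distance break deterministically towards the lexicographically smallest
leaf pair. Flat cuts reuse :func:`scipy.cluster.hierarchy.fcluster` on the
linkage matrix.
"""
from __future__ import annotations

import dataclasses
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy as _hier
from sklearn.metrics import adjusted_rand_score

from .normalize import ExpressionMatrix
from .panel import ValidationError

DISTANCES = ("uncentered_correlation", "correlation", "euclidean")
LINKAGES = ("average", "single", "complete")


@dataclasses.dataclass(frozen=True)
class AdjustedMatrix:
    """Median-centred, SD-scaled expression matrix with its adjustment records."""

    values: pd.DataFrame
    sample_medians: pd.Series
    gene_sds: pd.Series
    dropped_genes: tuple[str, ...]
    sd_mode: str
    ddof: int

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)


def adjust_matrix(expr: ExpressionMatrix | pd.DataFrame, sd_mode: str = "per_gene",
                  ddof: int = 0) -> AdjustedMatrix:
    """Centre each sample on its median, scale each gene by its SD."""
    X = expr.values if isinstance(expr, ExpressionMatrix) else pd.DataFrame(expr)
    if X.shape[1] < 2 or X.shape[0] < 1:
        raise ValidationError("adjustment needs at least 1 gene and 2 samples")
    if sd_mode not in ("per_gene", "pooled"):
        raise ValidationError(f"unknown sd_mode: {sd_mode!r}")
    medians = X.median(axis=0)
    centered = X - medians
    if sd_mode == "per_gene":
        sds = centered.std(axis=1, ddof=ddof)
    else:
        pooled = float(centered.to_numpy().std(ddof=ddof))
        sds = pd.Series(pooled, index=X.index)
    zero = ~(sds > 0)
    if zero.any():
        warnings.warn(
            f"dropping {int(zero.sum())} zero-variance gene(s) after centering: "
            f"{list(X.index[zero])[:10]}", stacklevel=2)
    keep = ~zero
    values = centered.loc[keep].div(sds[keep], axis=0)
    return AdjustedMatrix(values=values, sample_medians=medians,
                          gene_sds=sds[keep], dropped_genes=tuple(X.index[zero]),
                          sd_mode=sd_mode, ddof=ddof)


def _distance_matrix(X: np.ndarray, metric: str) -> np.ndarray:
    """Pairwise distances between the columns of X."""
    if metric == "euclidean":
        from scipy.spatial.distance import pdist, squareform
        return squareform(pdist(X.T, metric="euclidean"))
    if metric == "correlation":
        Xc = X - X.mean(axis=0, keepdims=True)
    elif metric == "uncentered_correlation":
        Xc = X
    else:
        raise ValidationError(f"unknown distance: {metric!r}")
    norms = np.sqrt((Xc ** 2).sum(axis=0))
    if np.any(norms == 0):
        raise ValidationError("cannot compute correlation distance for a "
                              "zero-variance sample column")
    sim = (Xc.T @ Xc) / np.outer(norms, norms)
    D = 1.0 - sim
    np.fill_diagonal(D, 0.0)
    return np.maximum(D, 0.0)


@dataclasses.dataclass(frozen=True)
class Dendrogram:
    """Agglomeration result in scipy linkage format plus sample labels."""

    linkage_matrix: np.ndarray  # (n-1, 4): child a, child b, height, size
    labels: tuple[str, ...]
    distance: str
    linkage: str

    @property
    def heights(self) -> np.ndarray:
        return self.linkage_matrix[:, 2]

    def cut(self, k: int) -> pd.Series:
        """Flat cluster labels (1..k) at a requested cluster count."""
        if not 1 <= k <= len(self.labels):
            raise ValidationError(f"cut count {k} outside 1..{len(self.labels)}")
        flat = _hier.fcluster(self.linkage_matrix, t=k, criterion="maxclust")
        return pd.Series(flat, index=list(self.labels), name="cluster")

    def to_newick(self, precision: int = 10) -> str:
        """Newick string with merge heights encoded as branch lengths."""
        n = len(self.labels)
        Z = self.linkage_matrix

        def node(idx: int) -> tuple[str, float]:
            if idx < n:
                return self.labels[idx], 0.0
            a, b, h, _ = Z[idx - n]
            sa, ha = node(int(a))
            sb, hb = node(int(b))
            return (f"({sa}:{max(h - ha, 0.0):.{precision}g},"
                    f"{sb}:{max(h - hb, 0.0):.{precision}g})"), h

        s, _ = node(2 * n - 2)
        return s + ";"

    def merge_table(self) -> pd.DataFrame:
        df = pd.DataFrame(self.linkage_matrix,
                          columns=["child_a", "child_b", "height", "size"])
        df["child_a"] = df["child_a"].astype(int)
        df["child_b"] = df["child_b"].astype(int)
        df["size"] = df["size"].astype(int)
        df.index.name = "merge"
        return df


def _agglomerate(D: np.ndarray, labels: Sequence[str], method: str,
                 atol: float = 1e-12) -> np.ndarray:
    """Naive O(n^3) agglomeration with lexicographic tie-breaking.

    On equal merge distances (within ``atol``) the pair whose smallest leaf
    labels sort lexicographically first is merged, making the dendrogram
    fully deterministic regardless of input order.
    """
    n = len(labels)
    dist: dict[tuple[int, int], float] = {
        (i, j): float(D[i, j]) for i in range(n) for j in range(i + 1, n)}
    size = {i: 1 for i in range(n)}
    key = {i: str(labels[i]) for i in range(n)}  # smallest leaf label in cluster
    active = set(range(n))
    Z = np.zeros((n - 1, 4))
    for step in range(n - 1):
        best_pair, best_d, best_key = None, np.inf, None
        for (i, j), d in dist.items():
            pair_key = tuple(sorted((key[i], key[j])))
            if d < best_d - atol or (abs(d - best_d) <= atol and
                                     (best_key is None or pair_key < best_key)):
                best_pair, best_d, best_key = (i, j), d, pair_key
        i, j = best_pair
        m = n + step
        Z[step] = [i, j, best_d, size[i] + size[j]]
        active.discard(i)
        active.discard(j)
        for k in list(active):
            dik = dist.pop((min(i, k), max(i, k)))
            djk = dist.pop((min(j, k), max(j, k)))
            if method == "average":
                d_new = (size[i] * dik + size[j] * djk) / (size[i] + size[j])
            elif method == "single":
                d_new = min(dik, djk)
            elif method == "complete":
                d_new = max(dik, djk)
            else:
                raise ValidationError(f"unknown linkage: {method!r}")
            dist[(min(m, k), max(m, k))] = d_new
        del dist[(i, j)]
        size[m] = size[i] + size[j]
        key[m] = min(key[i], key[j])
        active.add(m)
    return Z


def cluster_samples(adj: AdjustedMatrix | ExpressionMatrix | pd.DataFrame,
                    distance: str = "uncentered_correlation",
                    linkage: str = "average") -> Dendrogram:
    """Agglomerative clustering of sample columns."""
    if distance not in DISTANCES:
        raise ValidationError(f"unknown distance: {distance!r}")
    if linkage not in LINKAGES:
        raise ValidationError(f"unknown linkage: {linkage!r}")
    if isinstance(adj, (AdjustedMatrix, ExpressionMatrix)):
        X = adj.values
    else:
        X = pd.DataFrame(adj)
    if X.shape[1] < 2:
        raise ValidationError("clustering needs at least 2 samples")
    D = _distance_matrix(X.to_numpy(dtype=float), distance)
    Z = _agglomerate(D, list(X.columns), linkage)
    return Dendrogram(linkage_matrix=Z, labels=tuple(map(str, X.columns)),
                      distance=distance, linkage=linkage)


def compare_partitions(labels_a: Sequence, labels_b: Sequence) -> float:
    """Adjusted-for-chance pair-counting agreement (adjusted Rand index).

    1.0 iff the labelings are identical up to renaming; the expectation
    under random labelings is 0.
    """
    a = list(labels_a)
    b = list(labels_b)
    if len(a) != len(b):
        raise ValidationError(
            f"label vectors differ in length: {len(a)} vs {len(b)}")
    return float(adjusted_rand_score(a, b))
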