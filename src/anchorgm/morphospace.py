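"""Ordination, clustering and species-discrimination diagnostics.

PCA of aligned shape coordinates summarizes the morphospace; a cluster heat
map built from Ward clustering on Manhattan distances gives an assumption-
light check of how well specimens of a species group together; optimal
cluster-to-species matching turns the clustering into a misclassification
error; and a two-sample t ranking of shape variables between two clades
reproduces the inverted block structure used to read heat maps.

Note that Ward's minimum-variance criterion formally presumes squared
Euclidean input; applying the Lance-Williams Ward update to a Manhattan
dissimilarity matrix is unconventional but is retained here deliberately —
it is the combination used for anchor-shape heat maps.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, leaves_list, linkage
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import pdist

logger = logging.getLogger(__name__)


@dataclass
class PcaResult:
    """Principal component decomposition of a specimens x variables matrix."""

    scores: np.ndarray  # specimens x components
    loadings: np.ndarray  # variables x components, orthonormal columns
    variance_explained: np.ndarray  # proportion per component, sums to 1
    mean: np.ndarray  # column means removed before decomposition


def pca_shapes(matrix, center: bool = True) -> PcaResult:
    """PCA by singular value decomposition of the (centered) data matrix.

    Components are ordered by decreasing variance and carry a deterministic
    sign: the largest-magnitude loading of each component is positive.
    All components up to the matrix rank are returned, so the explained
    proportions sum to 1.
    """
    X = np.asarray(matrix, float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2D matrix with at least 2 rows")
    mean = X.mean(axis=0) if center else np.zeros(X.shape[1])
    Xc = X - mean
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    var = s**2
    total = var.sum()
    if total <= 0:
        raise ValueError("matrix has zero total variance")
    keep = var > total * 1e-12
    U, s, Vt, var = U[:, keep], s[keep], Vt[keep], var[keep]
    # sign convention: largest |loading| positive per component
    for j in range(Vt.shape[0]):
        i = np.argmax(np.abs(Vt[j]))
        if Vt[j, i] < 0:
            Vt[j] *= -1
            U[:, j] *= -1
    return PcaResult(
        scores=U * s,
        loadings=Vt.T,
        variance_explained=var / var.sum(),
        mean=mean,
    )


@dataclass
class SizePc1Result:
    """First principal component of the 55 pairwise-distance size variables."""

    scores: np.ndarray  # per-specimen size score (PC1)
    loadings: np.ndarray  # 55 loadings, oriented so their mean is positive
    same_sign: bool  # True when all loadings share one sign (size interpretation holds)
    variance_explained: float


def size_pc1(distances) -> SizePc1Result:
    """PC1 of a specimens x 55 inter-landmark distance matrix.

    When every PC1 loading shares one sign, PC1 is interpretable as overall
    size (all distances grow together along it); ``same_sign`` flags that
    condition. Loadings are oriented so larger specimens score higher.
    """
    D = np.asarray(distances, float)
    res = pca_shapes(D, center=True)
    loadings = res.loadings[:, 0].copy()
    scores = res.scores[:, 0].copy()
    if loadings.mean() < 0:
        loadings, scores = -loadings, -scores
    return SizePc1Result(
        scores=scores,
        loadings=loadings,
        same_sign=bool(np.all(loadings > 0) or np.all(loadings < 0)),
        variance_explained=float(res.variance_explained[0]),
    )


@dataclass
class ClusterResult:
    """Hierarchical clustering of specimens (Ward on Manhattan distances)."""

    labels: np.ndarray  # cluster label per specimen, 1..k
    merge_tree: np.ndarray  # scipy linkage matrix, for dendrograms/heat maps
    leaf_order: np.ndarray  # dendrogram leaf permutation for heat-map ordering


def cluster_specimens(matrix, k: int) -> ClusterResult:
    """Agglomerative Ward clustering on the Manhattan distance matrix, cut at k."""
    X = np.asarray(matrix, float)
    n = X.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"k must be between 1 and {n}; got {k}")
    dist = pdist(X, metric="cityblock")
    Z = linkage(dist, method="ward")  # Lance-Williams Ward update on the given dissimilarities
    labels = fcluster(Z, t=k, criterion="maxclust")
    return ClusterResult(labels=labels, merge_tree=Z, leaf_order=leaves_list(Z))


def misclassification_error(
    cluster_labels, species_labels
) -> tuple[float, pd.DataFrame]:
    """Fraction of specimens not matching the optimal cluster-to-species map.

    Clusters are matched one-to-one to species by maximizing the
    contingency-table trace (Hungarian assignment), so the error is
    well-defined even when clusters split species. Requires no more
    clusters than species.
    """
    cluster_labels = np.asarray(cluster_labels)
    species_labels = np.asarray(species_labels)
    if cluster_labels.shape != species_labels.shape:
        raise ValueError("label vectors must have equal length")
    table = pd.crosstab(
        pd.Series(cluster_labels, name="cluster"), pd.Series(species_labels, name="species")
    )
    if table.shape[0] > table.shape[1]:
        raise ValueError(
            f"{table.shape[0]} clusters but only {table.shape[1]} species; "
            "cannot match clusters one-to-one"
        )
    rows, cols = linear_sum_assignment(table.to_numpy(), maximize=True)
    matched = table.to_numpy()[rows, cols].sum()
    error = 1.0 - matched / cluster_labels.size
    return float(error), table


def clade_t_ranking(matrix, clade_labels) -> pd.DataFrame:
    """Rank shape variables by the pooled-variance two-sample t between two clades.

    Returns a table (variable, t, mean_a, mean_b) sorted by t descending,
    so variables relatively positive in the first clade form the top block
    and relatively negative ones the bottom block. A zero-pooled-variance
    column receives t = +/-inf (sign of the mean difference; 0 if the means
    also coincide) with a warning. Swapping the two group labels negates
    every t and reverses the ranking.
    """
    X = np.asarray(matrix, float)
    labels = np.asarray(clade_labels)
    groups = np.sort(pd.unique(labels))
    if groups.size != 2:
        raise ValueError(f"expected exactly 2 clades, got {groups.size}")
    a, b = X[labels == groups[0]], X[labels == groups[1]]
    na, nb = a.shape[0], b.shape[0]
    if na < 2 or nb < 2:
        raise ValueError("both clades need at least 2 specimens")
    diff = a.mean(axis=0) - b.mean(axis=0)
    pooled_var = ((na - 1) * a.var(axis=0, ddof=1) + (nb - 1) * b.var(axis=0, ddof=1)) / (
        na + nb - 2
    )
    se = np.sqrt(pooled_var * (1 / na + 1 / nb))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / se
    degenerate = se == 0
    if degenerate.any():
        logger.warning("%d column(s) have zero pooled variance; t set to +/-inf", degenerate.sum())
        t[degenerate] = np.sign(diff[degenerate]) * np.inf
        t[degenerate & (diff == 0)] = 0.0
    cols = (
        matrix.columns
        if isinstance(matrix, pd.DataFrame)
        else [f"var{i}" for i in range(X.shape[1])]
    )
    out = pd.DataFrame(
        {"variable": cols, "t": t, f"mean_{groups[0]}": a.mean(axis=0), f"mean_{groups[1]}": b.mean(axis=0)}
    )
    return out.sort_values("t", ascending=False, kind="mergesort").reset_index(drop=True)
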