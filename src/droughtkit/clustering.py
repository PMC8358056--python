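"""Expression quantification and expression-pattern clustering.

FPKM from raw fragment counts, log2(FPKM + 1) transformation, k-means
partitioning of gene profiles into expression-pattern clusters (k = 9 for
the two-tissue, five-timepoint drought design), per-cluster mean profiles,
and Pearson-correlation utilities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans


@dataclass
class ExpressionMatrix:
    """Gene x sample-group expression values (FPKM or log-transformed)."""

    values: pd.DataFrame
    transformed: bool = False

    def __post_init__(self) -> None:
        if self.values.isna().any().any():
            raise ValueError("expression matrix contains missing values")
        if not self.transformed and (self.values.to_numpy() < 0).any():
            raise ValueError("untransformed FPKM values must be nonnegative")

    @property
    def gene_ids(self) -> list:
        return list(self.values.index)

    @property
    def sample_groups(self) -> list:
        return list(self.values.columns)


def compute_fpkm(
    counts: pd.DataFrame,
    gene_lengths: pd.Series,
    library_sizes: pd.Series,
) -> ExpressionMatrix:
    """FPKM = count * 1e9 / (gene length in bp * library fragment total).

    Normalises each fragment count by transcript length (per kilobase) and
    sequencing depth (per million fragments).
    """
    lengths = gene_lengths.reindex(counts.index)
    libs = library_sizes.reindex(counts.columns)
    if lengths.isna().any():
        raise ValueError("missing gene lengths for some genes")
    if libs.isna().any():
        raise ValueError("missing library sizes for some samples")
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be > 0")
    if (libs <= 0).any():
        raise ValueError("library sizes must be > 0")
    fpkm = counts.astype(float).mul(1e9).div(lengths, axis=0).div(libs, axis=1)
    return ExpressionMatrix(values=fpkm, transformed=False)


def log_transform(matrix: ExpressionMatrix, pseudocount: float = 1.0) -> ExpressionMatrix:
    """Elementwise log2(value + pseudocount)."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    if matrix.transformed:
        raise ValueError("matrix is already log-transformed")
    return ExpressionMatrix(
        values=np.log2(matrix.values + pseudocount), transformed=True
    )


@dataclass
class ClusterAssignment:
    """Best-of-restarts k-means partition of gene expression profiles."""

    labels: pd.Series  # per-gene cluster id in 1..k
    k: int
    centroids: np.ndarray  # k x n_groups, in the clustered feature space
    objective: float  # within-cluster sum of squares
    seed: int
    n_restarts: int
    standardized: bool


def _standardize_rows(x: np.ndarray) -> np.ndarray:
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0  # flat profiles become all-zero rather than NaN
    return (x - mu) / sd


def kmeans_cluster(
    matrix: ExpressionMatrix,
    k: int = 9,
    seed: int = 0,
    n_restarts: int = 25,
    standardize: bool = True,
) -> ClusterAssignment:
    """Partition gene profiles into k expression-pattern clusters.

    k-means++ initialisation with ``n_restarts`` independent restarts,
    keeping the partition with the lowest within-cluster sum of squares.
    ``standardize`` z-scores each gene profile first so clusters group by
    temporal *shape* rather than expression magnitude.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if not matrix.transformed:
        raise ValueError("cluster log-transformed expression, not raw FPKM")
    x = matrix.values.to_numpy(dtype=float)
    if x.shape[0] < k:
        raise ValueError("fewer genes than clusters")
    feats = _standardize_rows(x) if standardize else x
    if np.unique(feats, axis=0).shape[0] < k:
        raise ValueError("fewer distinct profiles than clusters")
    km = KMeans(
        n_clusters=k,
        init="k-means++",
        n_init=n_restarts,
        max_iter=300,
        tol=1e-6,
        random_state=seed,
    ).fit(feats)
    labels = pd.Series(km.labels_ + 1, index=matrix.values.index, name="cluster")
    # recompute WCSS from the returned partition rather than trusting inertia
    objective = float(
        sum(
            ((feats[km.labels_ == j] - km.cluster_centers_[j]) ** 2).sum()
            for j in range(k)
        )
    )
    return ClusterAssignment(
        labels=labels,
        k=k,
        centroids=km.cluster_centers_,
        objective=objective,
        seed=seed,
        n_restarts=n_restarts,
        standardized=standardize,
    )


def cluster_profiles(
    assignment: ClusterAssignment, matrix: ExpressionMatrix
) -> pd.DataFrame:
    """Arithmetic mean expression profile of each cluster (cluster x group)."""
    if not assignment.labels.index.equals(matrix.values.index):
        raise ValueError("cluster labels do not match matrix rows")
    return matrix.values.groupby(assignment.labels).mean()


def pearson_correlation(matrix: ExpressionMatrix, axis: str = "groups") -> pd.DataFrame:
    """Pearson correlation between gene profiles or between sample groups."""
    if axis not in ("genes", "groups"):
        raise ValueError("axis must be 'genes' or 'groups'")
    df = matrix.values if axis == "genes" else matrix.values.T
    arr = df.to_numpy(dtype=float)
    if arr.shape[0] < 2:
        raise ValueError("need at least 2 vectors to correlate")
    sd = arr.std(axis=1)
    if (sd == 0).any():
        offender = df.index[int(np.argmax(sd == 0))]
        raise ValueError(f"zero-variance vector: {offender!r}")
    corr = np.corrcoef(arr)
    return pd.DataFrame(corr, index=df.index, columns=df.index)
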