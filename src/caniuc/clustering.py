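"""Sample embeddings and resampling-based consensus clustering.

Consensus clustering follows the subsampling scheme popularised for tumor
expression data: the samples are repeatedly subsampled (without
replacement), each subsample is cut into k groups by average-linkage
agglomerative clustering on Euclidean distances, and the consensus matrix
records, for every sample pair, the fraction of co-clustered resamples
among those in which both samples were drawn. Final assignments cut an
average-linkage tree of (1 - consensus); each sample's item consensus is
its mean consensus with the other members of its assigned cluster.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform


@dataclass
class EmbeddingResult:
    """Sample coordinates (samples x dims) plus, for PCA, the fraction of
    variance explained by each reported dimension."""

    coordinates: pd.DataFrame
    explained_variance_fraction: np.ndarray | None = None


@dataclass
class ConsensusResult:
    consensus_matrix: pd.DataFrame
    assignments: pd.Series
    item_consensus: pd.Series
    n_resamples: int
    k: int


def _fix_signs(coords: np.ndarray) -> np.ndarray:
    """Deterministic sign convention: the largest-magnitude entry of each
    coordinate column is made positive."""
    for j in range(coords.shape[1]):
        col = coords[:, j]
        if col.size and col[np.argmax(np.abs(col))] < 0:
            coords[:, j] = -col
    return coords


def pca_embed(expr: pd.DataFrame, n_dims: int = 2) -> EmbeddingResult:
    """PCA of samples from a genes x samples matrix (genes centered
    internally). Deterministic up to the fixed sign convention."""
    n_samples = expr.shape[1]
    if n_samples < 2:
        raise ValueError("need >=2 samples")
    if n_dims > n_samples - 1:
        raise ValueError(f"n_dims={n_dims} exceeds samples-1={n_samples - 1}")
    X = expr.to_numpy(dtype=float).T  # samples x genes
    X = X - X.mean(axis=0, keepdims=True)
    U, S, _ = np.linalg.svd(X, full_matrices=False)
    coords = _fix_signs(U[:, :n_dims] * S[:n_dims])
    total = np.sum(S**2)
    explained = (S[:n_dims] ** 2 / total) if total > 0 else np.zeros(n_dims)
    frame = pd.DataFrame(
        coords, index=expr.columns, columns=[f"PC{i + 1}" for i in range(n_dims)]
    )
    return EmbeddingResult(frame, explained)


def mds_embed(expr: pd.DataFrame, n_dims: int = 2) -> EmbeddingResult:
    """Classical (Torgerson) MDS on Euclidean sample distances via double
    centering; for Euclidean input this reproduces PCA up to rotation."""
    n_samples = expr.shape[1]
    if n_samples < 2:
        raise ValueError("need >=2 samples")
    if n_dims > n_samples - 1:
        raise ValueError(f"n_dims={n_dims} exceeds samples-1={n_samples - 1}")
    X = expr.to_numpy(dtype=float).T
    D2 = squareform(pdist(X, metric="sqeuclidean"))
    J = np.eye(n_samples) - np.ones((n_samples, n_samples)) / n_samples
    B = -0.5 * J @ D2 @ J
    eigval, eigvec = np.linalg.eigh(B)
    order = np.argsort(eigval)[::-1][:n_dims]
    lam = np.maximum(eigval[order], 0.0)
    coords = _fix_signs(eigvec[:, order] * np.sqrt(lam))
    frame = pd.DataFrame(
        coords, index=expr.columns, columns=[f"DIM{i + 1}" for i in range(n_dims)]
    )
    return EmbeddingResult(frame, None)


def select_features(expr: pd.DataFrame, n_features: int = 2000) -> pd.DataFrame:
    """Top genes by variance across samples (stable tie-break by row order)."""
    if expr.shape[0] <= n_features:
        return expr
    variances = expr.var(axis=1, ddof=1).to_numpy()
    order = np.argsort(-variances, kind="stable")[:n_features]
    return expr.iloc[np.sort(order)]


def _cut_tree(condensed: np.ndarray, k: int) -> np.ndarray:
    Z = linkage(condensed, method="average")
    return fcluster(Z, t=k, criterion="maxclust")


def consensus_cluster(
    expr: pd.DataFrame,
    k: int,
    n_resamples: int = 1000,
    subsample_frac: float = 0.8,
    seed: int = 0,
    n_features: int = 2000,
) -> ConsensusResult:
    """Consensus clustering of the samples of a genes x samples matrix.

    Distances use the ``n_features`` most variable genes. Each resample
    draws ceil(subsample_frac * n_samples) samples without replacement and
    cuts an average-linkage tree at k. Fully deterministic for a fixed seed.
    """
    n_samples = expr.shape[1]
    if n_samples < k + 1:
        raise ValueError(f"need >= k+1 = {k + 1} samples, got {n_samples}")
    n_sub = math.ceil(subsample_frac * n_samples)
    if n_sub < k + 1:
        raise ValueError(
            f"subsample of {n_sub} samples is too small to cut into {k} clusters"
        )
    selected = select_features(expr, n_features)
    X = selected.to_numpy(dtype=float).T
    # feature rows are fixed across resamples, so pairwise sample distances
    # can be computed once and subset per resample
    D = squareform(pdist(X, metric="euclidean"))

    rng = np.random.default_rng(seed)
    co_sampled = np.zeros((n_samples, n_samples))
    co_clustered = np.zeros((n_samples, n_samples))
    for _ in range(n_resamples):
        idx = np.sort(rng.choice(n_samples, size=n_sub, replace=False))
        sub = D[np.ix_(idx, idx)]
        labels = _cut_tree(squareform(sub, checks=False), k)
        same = labels[:, None] == labels[None, :]
        co_sampled[np.ix_(idx, idx)] += 1
        co_clustered[np.ix_(idx, idx)] += same

    with np.errstate(invalid="ignore", divide="ignore"):
        consensus = np.where(co_sampled > 0, co_clustered / co_sampled, 0.0)
    np.fill_diagonal(consensus, 1.0)

    final = _cut_tree(squareform(1.0 - consensus, checks=False), k)

    item = np.ones(n_samples)
    for i in range(n_samples):
        mates = np.flatnonzero((final == final[i]) & (np.arange(n_samples) != i))
        if mates.size:
            item[i] = consensus[i, mates].mean()

    samples = expr.columns
    return ConsensusResult(
        consensus_matrix=pd.DataFrame(consensus, index=samples, columns=samples),
        assignments=pd.Series(final, index=samples, name="cluster"),
        item_consensus=pd.Series(item, index=samples, name="item_consensus"),
        n_resamples=n_resamples,
        k=k,
    )
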