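"""Unsupervised views: k-means clustering of gene expression profiles and
PCA of samples over the signature panel."""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .normalization import ExpressionMatrix


def kmeans_clusters(
    em: ExpressionMatrix,
    k: int,
    seed: int,
    n_restarts: int = 50,
) -> tuple[pd.Series, pd.DataFrame]:
    """K-means over genes on row-z-scored log2 expression.

    Rows are z-scored so clusters reflect expression *profiles* across
    samples rather than absolute abundance; constant rows are mapped to the
    zero profile.  k-means++ initialization with ``n_restarts`` restarts,
    best inertia kept; deterministic for a fixed seed.

    Returns (per-gene cluster assignment, cluster x sample mean profiles in
    the original log2 units).
    """
    if em.state != "log2":
        raise ValueError("k-means clustering expects log2 expression")
    x = em.values.to_numpy(float)
    if k > x.shape[0]:
        raise ValueError(f"k={k} exceeds the number of genes ({x.shape[0]})")
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    z = np.where(sd > 0, (x - mu) / np.where(sd > 0, sd, 1.0), 0.0)
    km = KMeans(n_clusters=k, init="k-means++", n_init=n_restarts, random_state=seed)
    labels = km.fit_predict(z)
    assignment = pd.Series(labels, index=em.values.index, name="cluster")
    profiles = (
        em.values.groupby(assignment).mean().rename_axis(index="cluster")
    )
    return assignment, profiles


def pca_scores(
    em: ExpressionMatrix,
    n_components: int | None = None,
    scale: bool = False,
) -> tuple[pd.DataFrame, pd.Series]:
    """SVD-based PCA of samples over (signature) genes.

    Genes are centered across samples (and optionally unit-scaled);
    components are ordered by decreasing explained variance, with the sign
    convention that the largest-magnitude gene loading of each component is
    positive.  Returns (sample scores, percent variance explained).
    """
    x = em.values.to_numpy(float).T  # samples x genes
    n_samples, n_genes = x.shape
    if n_samples < 2:
        raise ValueError("PCA needs at least 2 samples")
    if np.allclose(x.std(axis=0), 0):
        raise ValueError("constant expression matrix; PCA undefined")
    if scale:
        sd = x.std(axis=0)
        x = x / np.where(sd > 0, sd, 1.0)
    if n_components is None:
        n_components = min(n_samples - 1, n_genes)
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(x)
    loadings = pca.components_
    # sign convention: largest-|loading| positive per component
    for i in range(loadings.shape[0]):
        j = int(np.argmax(np.abs(loadings[i])))
        if loadings[i, j] < 0:
            loadings[i] *= -1
            scores[:, i] *= -1
    cols = [f"PC{i + 1}" for i in range(scores.shape[1])]
    score_df = pd.DataFrame(scores, index=em.values.columns, columns=cols)
    var_pct = pd.Series(
        100.0 * pca.explained_variance_ratio_, index=cols, name="variance_explained_pct"
    )
    return score_df, var_pct
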