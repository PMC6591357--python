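"""Molecular subtype discovery: k-means clustering on a PCA embedding.

Tumors are embedded with PCA over the top variance-ranked genes and clustered
with k-means (k = 4 by default: BRAF^V600E-like, RAS-like, NBNR, and the
ATC-dominated fourth cluster).  Clusters are named by the majority reference
subtype they contain; a cluster with no reference majority that is enriched
in ATC histology is named "ATC-like".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

__all__ = ["ClusterParams", "pca_embed", "kmeans_classify", "name_clusters", "subtype_pipeline"]


@dataclass(frozen=True)
class ClusterParams:
    n_top_variable_genes: int = 2000
    n_components: int = 2
    k: int = 4
    n_init: int = 25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if self.n_components < 1:
            raise ValueError("n_components must be >= 1")


def pca_embed(matrix: pd.DataFrame, params: ClusterParams = ClusterParams()) -> pd.DataFrame:
    """Sample x component coordinates.

    Genes are ranked by variance and the top-N retained (all of them, with a
    warning, when fewer exist); each gene is centered; principal axes come
    from the SVD.  The embedding is deterministic up to component sign, which
    is fixed by making each component's largest-magnitude gene loading
    positive.
    """
    if matrix.shape[1] < params.k:
        raise ValueError("fewer samples than clusters")
    n_genes = matrix.shape[0]
    n_top = params.n_top_variable_genes
    if n_genes < n_top:
        warnings.warn(
            f"matrix has {n_genes} genes < requested {n_top}; using all genes"
        )
        n_top = n_genes
    variances = matrix.var(axis=1)
    top = variances.sort_values(ascending=False, kind="stable").index[:n_top]
    X = matrix.loc[top].to_numpy(dtype=float).T  # samples x genes
    X = X - X.mean(axis=0, keepdims=True)
    n_comp = min(params.n_components, min(X.shape))
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    scores = U[:, :n_comp] * S[:n_comp]
    for i in range(n_comp):
        j = int(np.argmax(np.abs(Vt[i])))
        if Vt[i, j] < 0:
            scores[:, i] = -scores[:, i]
    return pd.DataFrame(
        scores,
        index=matrix.columns,
        columns=[f"PC{i + 1}" for i in range(n_comp)],
    )


def kmeans_classify(
    embedding: pd.DataFrame, params: ClusterParams = ClusterParams()
) -> tuple[pd.Series, np.ndarray]:
    """k-means labels (k-means++ seeding, ``n_init`` restarts, fixed seed)."""
    X = embedding.to_numpy(dtype=float)
    if len(np.unique(X, axis=0)) < params.k:
        raise ValueError("fewer distinct points than clusters")
    km = KMeans(
        n_clusters=params.k,
        init="k-means++",
        n_init=params.n_init,
        random_state=params.seed,
    ).fit(X)
    labels = pd.Series(km.labels_, index=embedding.index, name="cluster")
    return labels, km.cluster_centers_


def name_clusters(
    labels: pd.Series,
    histology: Mapping[str, str],
    reference_assignments: Mapping[str, str],
    atc_fraction_threshold: float = 0.5,
) -> dict[int, str]:
    """Map cluster id -> subtype name.

    A cluster takes the name of the strict-majority reference subtype among
    its reference members.  A cluster with no reference majority whose ATC
    histology fraction reaches ``atc_fraction_threshold`` is named
    "ATC-like"; otherwise "unassigned".  When two clusters claim the same
    reference name the higher reference fraction keeps it and the loser is
    flagged with a ``*``.
    """
    provisional: dict[int, tuple[str, float]] = {}
    for cluster in sorted(labels.unique()):
        members = labels.index[labels == cluster]
        refs = [reference_assignments[s] for s in members if s in reference_assignments]
        name = None
        frac = 0.0
        if refs:
            counts = pd.Series(refs).value_counts()
            if counts.iloc[0] > len(refs) / 2:
                name = str(counts.index[0])
                frac = counts.iloc[0] / len(members)
        if name is None:
            atc_frac = float(
                np.mean([histology.get(s) == "ATC" for s in members])
            )
            name = "ATC-like" if atc_frac >= atc_fraction_threshold else "unassigned"
            frac = atc_frac
        provisional[int(cluster)] = (name, frac)

    out: dict[int, str] = {}
    by_name: dict[str, list[int]] = {}
    for cluster, (name, _) in provisional.items():
        by_name.setdefault(name, []).append(cluster)
    for name, clusters in by_name.items():
        if len(clusters) == 1 or name == "unassigned":
            for c in clusters:
                out[c] = name
        else:
            winner = max(clusters, key=lambda c: provisional[c][1])
            for c in clusters:
                out[c] = name if c == winner else f"{name}*"
    return out


def subtype_pipeline(
    matrix: pd.DataFrame,
    histology: Mapping[str, str],
    reference_assignments: Mapping[str, str],
    params: ClusterParams = ClusterParams(),
) -> pd.DataFrame:
    """Embed, cluster and name in one call.

    Returns a frame indexed by sample with PC coordinates, cluster id and
    subtype name.
    """
    emb = pca_embed(matrix, params)
    labels, _ = kmeans_classify(emb, params)
    names = name_clusters(labels, histology, reference_assignments)
    out = emb.copy()
    out["cluster"] = labels
    out["subtype"] = [names[int(c)] for c in labels]
    return out
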