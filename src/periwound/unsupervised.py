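"""Geometry-only unsupervised grouping of edge profiles, compared post hoc
with rater annotations.

Wounds are embedded from their depth-derived profile summaries, grouped by
k-means (k defaults to the merged category count so the post-hoc comparison
is one-to-one), and only then compared with the clinical labels via optimal
label matching + Cohen's kappa and the Adjusted Rand Index.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from . import agreement
from .io_config import AnnotationTable


class DegenerateVarianceError(ValueError):
    """Feature matrix has (near) zero variance; reduction is undefined."""


@dataclasses.dataclass(frozen=True)
class ClusterResult:
    """Unsupervised grouping plus its post-hoc agreement with each rater."""

    embedding: np.ndarray
    labels: np.ndarray  # cluster id per image
    k: int
    mappings: dict[str, dict]  # rater -> cluster-id -> category
    kappa_per_rater: dict[str, float]
    ari_per_rater: dict[str, float]
    kappa_mean: float
    kappa_sd: float
    ari: float  # headline ARI vs the reference rater
    reference_rater: str


def reduce(
    matrix: np.ndarray, method: str = "pca", dims: int = 2, seed: int = 0
) -> np.ndarray:
    """Deterministic dimensionality reduction of the profile matrix."""
    x = np.asarray(matrix, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("profile matrix contains non-finite values")
    if x.shape[0] < dims + 1:
        raise ValueError(f"need at least dims+1={dims + 1} rows")
    if np.allclose(x.std(axis=0), 0.0):
        raise DegenerateVarianceError("constant feature matrix")
    dims = min(dims, x.shape[1], x.shape[0])
    if method == "pca":
        return PCA(n_components=dims, svd_solver="full", random_state=seed).fit_transform(x)
    if method == "umap":
        import umap  # heavy import kept local

        return umap.UMAP(n_components=dims, random_state=seed).fit_transform(x)
    raise ValueError(f"unknown reduction method {method!r}")


def cluster(embedding: np.ndarray, k: int, seed: int = 0) -> np.ndarray:
    """k-means with k-means++ init, 10 restarts, best inertia kept."""
    emb = np.asarray(embedding, dtype=float)
    if emb.shape[0] < k:
        raise ValueError(f"cannot form k={k} clusters from {emb.shape[0]} points")
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    return km.fit_predict(emb)


def evaluate_unsupervised(
    labels: np.ndarray,
    table: AnnotationTable,
    embedding: np.ndarray | None = None,
    reference_rater: str | None = None,
) -> ClusterResult:
    """Post-hoc agreement of cluster labels with every rater's annotations.

    kappa uses optimal label matching per rater; ARI needs no matching (it is
    invariant to label permutations).  The headline ARI is reported against
    ``reference_rater`` (default: the table's first rater).
    """
    labels = np.asarray(labels)
    if len(labels) != len(table):
        raise ValueError(
            f"{len(labels)} cluster labels vs {len(table)} annotated images"
        )
    raters = table.raters
    reference = reference_rater or raters[0]
    if reference not in raters:
        raise KeyError(f"unknown reference rater {reference!r}")
    mappings, kappas, aris = {}, {}, {}
    for rater in raters:
        ref = table.labels(rater)
        mapping, relabeled = agreement.align_labels(labels, ref)
        mappings[rater] = mapping
        kappas[rater] = agreement.cohen_kappa(relabeled, ref)
        aris[rater] = agreement.adjusted_rand(labels, ref)
    vals = np.array([kappas[r] for r in raters])
    sd = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
    return ClusterResult(
        embedding=embedding if embedding is not None else np.empty((len(labels), 0)),
        labels=labels,
        k=int(len(np.unique(labels))),
        mappings=mappings,
        kappa_per_rater=kappas,
        ari_per_rater=aris,
        kappa_mean=float(vals.mean()),
        kappa_sd=sd,
        ari=float(aris[reference]),
        reference_rater=reference,
    )


def run_unsupervised(
    profile_matrix: np.ndarray,
    table: AnnotationTable,
    method: str = "pca",
    dims: int = 2,
    k: int = 5,
    seed: int = 0,
    reference_rater: str | None = None,
) -> ClusterResult:
    """reduce -> cluster -> evaluate, end to end."""
    emb = reduce(profile_matrix, method=method, dims=dims, seed=seed)
    labels = cluster(emb, k=k, seed=seed)
    return evaluate_unsupervised(
        labels, table, embedding=emb, reference_rater=reference_rater
    )
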